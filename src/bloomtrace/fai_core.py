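"""Per-pixel Floating Algae Index (FAI).

FAI measures the elevation of NIR reflectance above a linear baseline drawn
between the Red and SWIR bands and evaluated at the NIR wavelength:

    FAI = R_nir - [R_red + (R_swir - R_red) * (λ_nir - λ_red)/(λ_swir - λ_red)]

Floating or near-surface algae lift the NIR band ("red edge") while the
baseline subtraction cancels additive path-radiance offsets, which is why the
index tolerates varying aerosol much better than band-ratio vegetation
indices.  Inputs are assumed to be Rayleigh-corrected reflectance; no
atmospheric correction is performed here.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt

import numpy as np

from .errors import ConfigurationError, EmptySceneError
from .sensor_scene import REFLECTANCE_RANGE, Scene, SensorSpec


@dataclasses.dataclass
class FAIGrid:
    """FAI values with a validity mask (water, cloud-free, finite, in range)."""

    values: np.ndarray
    valid_mask: np.ndarray
    date: _dt.date
    level: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values/valid_mask shape mismatch")


def baseline_weight(sensor: SensorSpec) -> float:
    """Linear interpolation weight (λ_nir − λ_red)/(λ_swir − λ_red)."""
    denom = sensor.lambda_swir - sensor.lambda_red
    if denom == 0:
        raise ConfigurationError(
            f"sensor {sensor.name!r}: lambda_swir equals lambda_red"
        )
    return (sensor.lambda_nir - sensor.lambda_red) / denom


def compute_fai(scene: Scene) -> FAIGrid:
    """Compute FAI for every analyzable pixel of a scene.

    A pixel is valid when it is water, cloud-free, and all three reflectances
    are finite and inside the tolerated range.  Invalid pixels carry NaN and
    are excluded from all downstream statistics — they never count as zero.
    """
    w = baseline_weight(scene.sensor)
    red, nir, swir = scene.bands
    lo, hi = REFLECTANCE_RANGE
    with np.errstate(invalid="ignore"):
        finite = np.isfinite(red) & np.isfinite(nir) & np.isfinite(swir)
        in_range = finite.copy()
        for band in (red, nir, swir):
            in_range &= (band >= lo) & (band <= hi)
    valid = scene.water_mask & ~scene.cloud_mask & in_range

    baseline = red + (swir - red) * w
    values = np.where(valid, nir - baseline, np.nan)
    return FAIGrid(values=values, valid_mask=valid,
                   date=scene.date, level=scene.level)


def max_fai(fai: FAIGrid) -> float:
    """Maximum FAI over valid pixels; raises if the scene is entirely masked."""
    if not fai.valid_mask.any():
        raise EmptySceneError("no valid pixel in FAI grid")
    return float(np.nanmax(fai.values[fai.valid_mask]))
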