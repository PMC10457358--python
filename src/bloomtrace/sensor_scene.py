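"""Multispectral water scenes, masks, and sensor band metadata.

A :class:`Scene` is the unit of extraction: Rayleigh-corrected reflectance
grids for the Red / NIR / SWIR bands of one sensor on one date, together with
a water mask (analyzable sea pixels) and a cloud mask.  Scenes come in two
processing levels, ``low_sensitivity`` and ``high_sensitivity``, mirroring
the L1C (top-of-atmosphere) and L2A (bottom-of-atmosphere) product levels of
high-resolution optical satellites: the atmospherically corrected level shows
stronger floating-algae signal but also more coastal false positives.

Scenes are stored as multi-page TIFF files (pages ordered red, nir, swir as
float64, then optional water_mask, cloud_mask as uint8 0/1) with a JSON
sidecar ``<path>.json`` carrying date, level and sensor metadata.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage

from .errors import ConfigurationError, FormatError, ValidationError

LOW_SENSITIVITY = "low_sensitivity"
HIGH_SENSITIVITY = "high_sensitivity"
LEVELS = (LOW_SENSITIVITY, HIGH_SENSITIVITY)

#: Reflectance outside this range is treated as invalid (correction overshoot
#: tolerated down to -0.05; saturated / bad pixels above 1.2 are masked out,
#: not clipped).
REFLECTANCE_RANGE = (-0.05, 1.2)

_BAND_ORDER = ("red", "nir", "swir")


@dataclasses.dataclass(frozen=True)
class SensorSpec:
    """Band-center wavelengths (nm) and pixel footprint of one sensor.

    The wavelengths are the λ constants of the Floating Algae Index baseline;
    ``pixel_area`` (km²) converts pixel counts to bloom areas.
    """

    name: str
    lambda_red: float
    lambda_nir: float
    lambda_swir: float
    pixel_area: float

    def __post_init__(self):
        if not (self.lambda_red < self.lambda_nir < self.lambda_swir):
            raise ConfigurationError(
                f"sensor {self.name!r}: require lambda_red < lambda_nir < "
                f"lambda_swir, got ({self.lambda_red}, {self.lambda_nir}, "
                f"{self.lambda_swir})"
            )
        if not self.pixel_area > 0:
            raise ConfigurationError(
                f"sensor {self.name!r}: pixel_area must be positive"
            )


#: Shipped sensor registry.  "modis-like" uses the 500 m ocean-color bands
#: (645/859/1240 nm, 0.25 km² pixels); "s2-like" uses B4/B8/B11
#: (665/842/1610 nm, 10 m ≙ 1e-4 km² pixels).
DEFAULT_SENSORS: dict[str, SensorSpec] = {
    "modis-like": SensorSpec("modis-like", 645.0, 859.0, 1240.0, 0.25),
    "s2-like": SensorSpec("s2-like", 665.0, 842.0, 1610.0, 1e-4),
}


def get_sensor(name: str) -> SensorSpec:
    """Look up a sensor in the shipped registry."""
    try:
        return DEFAULT_SENSORS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown sensor {name!r}; known: {sorted(DEFAULT_SENSORS)}"
        ) from None


def load_sensor_registry(path) -> dict[str, SensorSpec]:
    """Load a sensor registry from a YAML/JSON mapping.

    Each entry maps a sensor name to ``{lambda_red, lambda_nir, lambda_swir,
    pixel_area}`` (nm and km²).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise FormatError(f"sensor registry {path}: expected a mapping")
    registry = {}
    for name, entry in raw.items():
        try:
            registry[name] = SensorSpec(
                name=name,
                lambda_red=float(entry["lambda_red"]),
                lambda_nir=float(entry["lambda_nir"]),
                lambda_swir=float(entry["lambda_swir"]),
                pixel_area=float(entry["pixel_area"]),
            )
        except (KeyError, TypeError) as exc:
            raise FormatError(
                f"sensor registry {path}: bad entry for {name!r}: {exc}"
            ) from exc
    return registry


@dataclasses.dataclass
class Scene:
    """One dated multiband water scene at one processing level."""

    date: _dt.date
    level: str
    sensor: SensorSpec
    red: np.ndarray
    nir: np.ndarray
    swir: np.ndarray
    water_mask: np.ndarray
    cloud_mask: np.ndarray

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValidationError(
                f"level must be one of {LEVELS}, got {self.level!r}"
            )
        grids = {
            "red": self.red,
            "nir": self.nir,
            "swir": self.swir,
            "water_mask": self.water_mask,
            "cloud_mask": self.cloud_mask,
        }
        shapes = {name: np.asarray(g).shape for name, g in grids.items()}
        if len(set(shapes.values())) != 1:
            raise ValidationError(f"grid shape mismatch: {shapes}")
        shape = self.red.shape
        if len(shape) != 2 or min(shape) == 0:
            raise ValidationError(f"grids must be non-empty 2-D, got {shape}")
        self.red = np.asarray(self.red, dtype=np.float64)
        self.nir = np.asarray(self.nir, dtype=np.float64)
        self.swir = np.asarray(self.swir, dtype=np.float64)
        self.water_mask = np.asarray(self.water_mask, dtype=bool)
        self.cloud_mask = np.asarray(self.cloud_mask, dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def bands(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.red, self.nir, self.swir


@dataclasses.dataclass
class ScenePair:
    """Same-date low/high-sensitivity scenes, optionally with planted truth."""

    low: Scene
    high: Scene
    truth_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.low.level != LOW_SENSITIVITY:
            raise ValidationError("pair.low must have level 'low_sensitivity'")
        if self.high.level != HIGH_SENSITIVITY:
            raise ValidationError("pair.high must have level 'high_sensitivity'")
        if self.low.date != self.high.date:
            raise ValidationError(
                f"pair dates differ: {self.low.date} vs {self.high.date}"
            )
        if self.low.grid_shape != self.high.grid_shape:
            raise ValidationError("pair grid shapes differ")
        if self.low.sensor != self.high.sensor:
            raise ValidationError("pair sensors differ")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask, dtype=bool)
            if self.truth_mask.shape != self.low.grid_shape:
                raise ValidationError("truth_mask shape mismatch")

    @property
    def date(self) -> _dt.date:
        return self.low.date


def write_scene(scene: Scene, path) -> None:
    """Write a scene as a multi-page TIFF plus a JSON metadata sidecar.

    Pages: red, nir, swir (float64), water_mask, cloud_mask (uint8 0/1).
    Round-trips bit-exactly through :func:`read_scene`.
    """
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for band in scene.bands:
            tif.write(band.astype(np.float64), contiguous=False)
        tif.write(scene.water_mask.astype(np.uint8), contiguous=False)
        tif.write(scene.cloud_mask.astype(np.uint8), contiguous=False)
    meta = {
        "date": scene.date.isoformat(),
        "level": scene.level,
        "sensor": dataclasses.asdict(scene.sensor),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_scene(path, meta: dict | None = None) -> Scene:
    """Read a scene written by :func:`write_scene`.

    ``meta`` (date/level/sensor) overrides the JSON sidecar; when a file has
    only the three reflectance pages the masks default to all-water, no-cloud.
    """
    path = Path(path)
    if meta is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FormatError(f"no metadata given and no sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
    date = meta["date"]
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    sensor = meta["sensor"]
    if isinstance(sensor, dict):
        sensor = SensorSpec(**sensor)

    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    for i, band in enumerate(_BAND_ORDER):
        if len(pages) <= i:
            raise FormatError(f"raster {path} is missing band {band!r}")
    shapes = {g.shape for g in pages[:3]}
    if len(shapes) != 1:
        raise FormatError(f"raster {path}: band shapes differ: {shapes}")
    red, nir, swir = pages[:3]
    water = pages[3].astype(bool) if len(pages) > 3 else np.ones(red.shape, bool)
    cloud = pages[4].astype(bool) if len(pages) > 4 else np.zeros(red.shape, bool)
    return Scene(
        date=date, level=meta["level"], sensor=sensor,
        red=red, nir=nir, swir=swir, water_mask=water, cloud_mask=cloud,
    )


def erode_water_mask(mask: np.ndarray, buffer_px: int) -> np.ndarray:
    """Erode a water mask by ``buffer_px`` in Chebyshev distance.

    Removes the coastal fringe where bottom reflectance and exposed sediment
    cause spurious index values: a cell survives only if every cell within
    Chebyshev distance ``buffer_px`` (including outside the grid, treated as
    land) is water.  ``buffer_px == 0`` returns the input unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if buffer_px < 0:
        raise ValidationError("buffer_px must be non-negative")
    if buffer_px == 0:
        return mask.copy()
    structure = np.ones((3, 3), dtype=bool)  # 8-connected => Chebyshev ball
    return ndimage.binary_erosion(
        mask, structure=structure, iterations=buffer_px, border_value=0
    )
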