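"""Single Threshold Multi-stage Weakening (STMW).

The atmospherically corrected (high-sensitivity) level measures bloom area
well but also extracts coastal sediment and shallow-beach false positives;
the uncorrected (low-sensitivity) level misses those false positives but
under-measures true blooms.  STMW applies one shared threshold to both
levels: a day is a bloom day only if the *low*-sensitivity extraction clears
the minimum-area filter, and on bloom days the area reported is the
*high*-sensitivity extraction.  Small extractions (≤ min_area, default
0.7 km²) are zeroed at both stages so a few noisy pixels can neither flag a
day nor contribute area.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from collections.abc import Iterable

from .bloom_extract import DEFAULT_MIN_AREA, segment
from .errors import ValidationError
from .fai_core import compute_fai
from .sensor_scene import ScenePair


@dataclasses.dataclass
class StmwResult:
    """Per-day STMW outcome.

    ``low_area`` / ``high_area`` are the raw (unfiltered) extraction areas of
    the two levels; ``area`` is the reported bloom area: the min-area-filtered
    high-sensitivity area on flagged days, otherwise 0.
    """

    date: _dt.date
    flagged: bool
    area: float
    low_area: float
    high_area: float


@dataclasses.dataclass
class StmwSeries:
    results: list[StmwResult]
    n_flagged: int
    #: days the high-sensitivity level alone would have reported as bloom
    #: but the low-sensitivity level vetoed
    n_suppressed: int


def stmw_day(
    pair: ScenePair, threshold: float, min_area: float = DEFAULT_MIN_AREA
) -> StmwResult:
    """Apply STMW to one scene pair at one shared threshold."""
    low_ext = segment(compute_fai(pair.low), threshold, pair.low.sensor)
    high_ext = segment(compute_fai(pair.high), threshold, pair.high.sensor)

    flagged = low_ext.area > min_area
    high_filtered = high_ext.area if high_ext.area > min_area else 0.0
    return StmwResult(
        date=pair.date,
        flagged=flagged,
        area=high_filtered if flagged else 0.0,
        low_area=low_ext.area,
        high_area=high_ext.area,
    )


def stmw_series(
    pairs: Iterable[ScenePair],
    threshold: float,
    min_area: float = DEFAULT_MIN_AREA,
) -> StmwSeries:
    """Apply STMW day by day, date-ascending; duplicate dates are an error."""
    pairs = sorted(pairs, key=lambda p: p.date)
    dates = [p.date for p in pairs]
    if len(set(dates)) != len(dates):
        dupes = sorted({d for d in dates if dates.count(d) > 1})
        raise ValidationError(f"duplicate dates in pair series: {dupes}")
    results = [stmw_day(p, threshold, min_area) for p in pairs]
    n_flagged = sum(r.flagged for r in results)
    n_suppressed = sum(
        (not r.flagged) and r.high_area > min_area for r in results
    )
    return StmwSeries(results=results, n_flagged=n_flagged,
                      n_suppressed=n_suppressed)
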