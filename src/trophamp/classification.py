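"""Six-type biomass-response classification and the amplification ratio R.

Per cell, the consumer-biomass change is compared with the NPP change:
same sign and larger in magnitude -> amplification; same sign and smaller
-> attenuation; opposite sign -> inversion.  The positive/negative prefix
is the direction of the biomass change.  R is the ratio of the two
relative changes: R > 1 amplification, 0 < R < 1 attenuation, R < 0
inversion.

Boundary rules (sets of measure zero, fixed for determinism): R exactly 1
-> attenuation; dB exactly 0 -> undefined; dNPP exactly 0 with dB != 0 ->
inversion with R = -inf sentinel (excluded from all means).  The R = 1 tie
is applied with a tiny relative tolerance so that a biomass change equal to
the NPP change up to float round-off still resolves to attenuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import numpy as np
import pandas as pd

from .grid_io import Grid

__all__ = [
    "ResponseType",
    "ResponseTypeMap",
    "RRatioField",
    "compute_r",
    "classify_cell",
    "classify_map",
    "compute_r_map",
    "type_area_fractions",
    "mean_r_by_type",
    "r_anova",
]


class ResponseType(IntEnum):
    UNDEFINED = 0
    POSITIVE_AMPLIFICATION = 1
    POSITIVE_ATTENUATION = 2
    POSITIVE_INVERSION = 3
    NEGATIVE_AMPLIFICATION = 4
    NEGATIVE_ATTENUATION = 5
    NEGATIVE_INVERSION = 6

    @property
    def short_name(self) -> str:
        return self.name.lower()


DEFINED_TYPES = tuple(t for t in ResponseType if t is not ResponseType.UNDEFINED)
AMPLIFICATIONS = (ResponseType.POSITIVE_AMPLIFICATION, ResponseType.NEGATIVE_AMPLIFICATION)
ATTENUATIONS = (ResponseType.POSITIVE_ATTENUATION, ResponseType.NEGATIVE_ATTENUATION)
INVERSIONS = (ResponseType.POSITIVE_INVERSION, ResponseType.NEGATIVE_INVERSION)

#: relative tolerance of the |dB| vs |dNPP| comparison (R = 1 tie band)
TIE_RTOL = 1e-9


@dataclass
class ResponseTypeMap:
    grid: Grid
    codes: np.ndarray  # int8, ResponseType values; UNDEFINED on land/masked

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != self.grid.shape:
            raise ValueError("type map shape does not match grid")


@dataclass
class RRatioField:
    grid: Grid
    r: np.ndarray  # signed ratio; NaN undefined, +-inf sentinel for dNPP == 0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        if self.r.shape != self.grid.shape:
            raise ValueError("R field shape does not match grid")


def compute_r(delta_b_pct: float, delta_npp_pct: float) -> float:
    """Ratio of relative biomass change to relative NPP change.

    A zero NPP change yields an undefined marker instead of raising:
    NaN when the biomass change is also zero, -inf otherwise (an
    inversion-side sentinel excluded from summary statistics).
    """
    if not (math.isfinite(delta_b_pct) and math.isfinite(delta_npp_pct)):
        return math.nan
    if delta_npp_pct == 0.0:
        return math.nan if delta_b_pct == 0.0 else -math.inf
    return delta_b_pct / delta_npp_pct


def classify_cell(delta_b_pct: float, delta_npp_pct: float) -> ResponseType:
    """Classify one cell from its biomass and NPP percentage changes."""
    db, dn = delta_b_pct, delta_npp_pct
    if not (math.isfinite(db) and math.isfinite(dn)):
        return ResponseType.UNDEFINED
    if db == 0.0:
        return ResponseType.UNDEFINED
    positive = db > 0.0
    if dn == 0.0 or (db > 0.0) != (dn > 0.0):
        return (ResponseType.POSITIVE_INVERSION if positive
                else ResponseType.NEGATIVE_INVERSION)
    if abs(db) > abs(dn) * (1.0 + TIE_RTOL):
        return (ResponseType.POSITIVE_AMPLIFICATION if positive
                else ResponseType.NEGATIVE_AMPLIFICATION)
    # ties (|dB| == |dNPP|, i.e. R == 1) fall to attenuation
    return (ResponseType.POSITIVE_ATTENUATION if positive
            else ResponseType.NEGATIVE_ATTENUATION)


def _classify_arrays(db: np.ndarray, dn: np.ndarray) -> np.ndarray:
    """Vectorised classify_cell on arrays of percentage changes."""
    codes = np.full(db.shape, int(ResponseType.UNDEFINED), dtype=np.int8)
    ok = np.isfinite(db) & np.isfinite(dn) & (db != 0.0)
    pos = db > 0.0
    inv = ok & ((dn == 0.0) | (pos != (dn > 0.0)))
    amp = ok & ~inv & (np.abs(db) > np.abs(dn) * (1.0 + TIE_RTOL))
    att = ok & ~inv & ~amp
    codes[inv & pos] = ResponseType.POSITIVE_INVERSION
    codes[inv & ~pos] = ResponseType.NEGATIVE_INVERSION
    codes[amp & pos] = ResponseType.POSITIVE_AMPLIFICATION
    codes[amp & ~pos] = ResponseType.NEGATIVE_AMPLIFICATION
    codes[att & pos] = ResponseType.POSITIVE_ATTENUATION
    codes[att & ~pos] = ResponseType.NEGATIVE_ATTENUATION
    return codes


def classify_map(changes) -> ResponseTypeMap:
    """Per-cell classification of a ChangeMaps object (undefined where masked)."""
    codes = _classify_arrays(changes.delta_b_pct, changes.delta_npp_pct)
    codes[~changes.grid.ocean_mask] = ResponseType.UNDEFINED
    return ResponseTypeMap(grid=changes.grid, codes=codes)


def compute_r_map(changes) -> RRatioField:
    """Per-cell R; NaN where undefined, +-inf sentinel where dNPP == 0."""
    db = changes.delta_b_pct
    dn = changes.delta_npp_pct
    with np.errstate(divide="ignore", invalid="ignore"):
        r = db / dn
    r = np.where(np.isfinite(db) & np.isfinite(dn), r, np.nan)
    zero_dn = np.isfinite(db) & (dn == 0.0)
    r = np.where(zero_dn & (db != 0.0), -np.inf, r)
    r = np.where(zero_dn & (db == 0.0), np.nan, r)
    r[~changes.grid.ocean_mask] = np.nan
    return RRatioField(grid=changes.grid, r=r)


def type_area_fractions(
    type_map: ResponseTypeMap,
    grid: Optional[Grid] = None,
    subset: Optional[np.ndarray] = None,
    weighted: bool = True,
) -> dict[ResponseType, float]:
    """Area-weighted fraction of each type (incl. undefined) within a subset.

    Fractions sum to 1 over the subset's ocean cells.
    """
    grid = grid or type_map.grid
    base = grid.ocean_mask if subset is None else (grid.ocean_mask & np.asarray(subset, bool))
    if not base.any():
        raise ValueError("empty subset: no ocean cell selected")
    w = grid.cell_area if weighted else np.ones(grid.shape)
    total = float(np.sum(w[base]))
    out: dict[ResponseType, float] = {}
    for t in ResponseType:
        out[t] = float(np.sum(w[base & (type_map.codes == int(t))]) / total)
    return out


def mean_r_by_type(
    r: RRatioField,
    type_map: ResponseTypeMap,
    delta_npp_pct: Optional[np.ndarray] = None,
    trim: tuple[float, float] = (2.5, 97.5),
    npp_exclusion_pct: float = 1.0,
    weighted: bool = True,
) -> dict[ResponseType, tuple[float, float, int]]:
    """Area-weighted (mean, sd, n) of R per response type.

    Cells with |dNPP| below ``npp_exclusion_pct`` are excluded (requires
    ``delta_npp_pct``), then R values beyond the ``trim`` percentiles
    (computed over the retained cells of this map) are dropped.  Types with
    no retained cells are absent from the result.
    """
    lo_p, hi_p = trim
    if not (0.0 <= lo_p <= hi_p <= 100.0):
        raise ValueError("trim percentiles must satisfy 0 <= lo <= hi <= 100")
    keep = r.grid.ocean_mask & np.isfinite(r.r)
    if delta_npp_pct is not None and npp_exclusion_pct > 0.0:
        keep &= np.abs(delta_npp_pct) >= npp_exclusion_pct
    if keep.any() and (lo_p > 0.0 or hi_p < 100.0):
        lo, hi = np.percentile(r.r[keep], [lo_p, hi_p])
        keep &= (r.r >= lo) & (r.r <= hi)
    w = r.grid.cell_area if weighted else np.ones(r.grid.shape)
    out: dict[ResponseType, tuple[float, float, int]] = {}
    for t in DEFINED_TYPES:
        sel = keep & (type_map.codes == int(t))
        n = int(np.count_nonzero(sel))
        if n == 0:
            continue
        ws, xs = w[sel], r.r[sel]
        mean = float(np.sum(ws * xs) / np.sum(ws))
        var = float(np.sum(ws * (xs - mean) ** 2) / np.sum(ws))
        out[t] = (mean, math.sqrt(var), n)
    return out


def r_anova(samples: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects ANOVA of R on categorical factors (type, member, ESM).

    ``samples`` needs columns ``r``, ``response_type``, ``mem`` and ``esm``.
    Reporting convenience, not a core diagnostic.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    needed = {"r", "response_type", "mem", "esm"}
    missing = needed - set(samples.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = samples.dropna(subset=["r"]).copy()
    df = df[np.isfinite(df["r"])]
    formula = "r ~ C(response_type) + C(mem) + C(esm)"
    # degenerate single-level factors break the design matrix; drop them
    for col in ("response_type", "mem", "esm"):
        if df[col].nunique() < 2:
            formula = formula.replace(f" + C({col})", "").replace(f"C({col}) + ", "")
    model = smf.ols(formula, data=df).fit()
    return sm.stats.anova_lm(model, typ=2)
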