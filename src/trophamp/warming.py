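"""R as a function of warming: SST-binned mean R curves by NPP direction.

Samples are (cell, year) pairs: annual changes versus the reference-window
climatology, pooled over all years.  Cells with |dNPP| below the exclusion
threshold are dropped, R is trimmed at the stated percentiles over the
retained samples, and means are taken within fixed-width dSST bins
(each retained cell-year counts once by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .changes import relative_change_pct, window_climatology
from .grid_io import GriddedField, MemberOutput

__all__ = ["WarmingCurve", "r_vs_warming", "warming_correlation"]


@dataclass
class WarmingCurve:
    """Binned curve; only populated bins (n >= min_count) are reported."""

    npp_direction: str            # "increase" | "decrease"
    bin_lo: np.ndarray            # degC lower edge per reported bin, ascending
    bin_hi: np.ndarray            # degC upper edge per reported bin
    mean_r: np.ndarray
    sd_r: np.ndarray
    n: np.ndarray                 # samples per reported bin
    mem_name: str = ""
    esm_name: str = ""
    note: str = ""                # set when the curve is empty

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_lo + self.bin_hi)

    @property
    def n_bins(self) -> int:
        return int(self.mean_r.size)

    @property
    def is_empty(self) -> bool:
        return self.n_bins == 0


def _empty_curve(direction: str, mem: str, esm: str, note: str) -> WarmingCurve:
    z = np.empty(0)
    return WarmingCurve(npp_direction=direction, bin_lo=z, bin_hi=z.copy(),
                        mean_r=z.copy(), sd_r=z.copy(), n=np.empty(0, dtype=int),
                        mem_name=mem, esm_name=esm, note=note)


def r_vs_warming(
    member: MemberOutput,
    npp: GriddedField,
    sst: GriddedField,
    reference_window: tuple[int, int] = (1995, 2014),
    direction: str = "decrease",
    bin_width: float = 0.1,
    npp_exclusion_pct: float = 1.0,
    trim: tuple[float, float] = (2.5, 97.5),
    min_count: int = 1,
    endpoint_only: bool = False,
    target_window: tuple[int, int] = (2090, 2099),
) -> WarmingCurve:
    """Binned mean R versus SST increase for one NPP-change direction.

    Default mode pools annual (cell, year) samples regardless of the year;
    ``endpoint_only=True`` instead bins the end-of-century change maps
    spatially (the alternative reading of the pooling rule).
    """
    if direction not in ("increase", "decrease"):
        raise ValueError(f"direction must be increase/decrease, got {direction!r}")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    tcb = member.tcb
    tcb.grid.require_compatible(npp.grid)
    tcb.grid.require_compatible(sst.grid)

    npp_ref = window_climatology(npp, reference_window)
    tcb_ref = window_climatology(tcb, reference_window)
    sst_ref = window_climatology(sst, reference_window)

    if endpoint_only:
        dn = relative_change_pct(npp_ref, window_climatology(npp, target_window))
        db = relative_change_pct(tcb_ref, window_climatology(tcb, target_window))
        ds = window_climatology(sst, target_window) - sst_ref
        dn, db, ds = (a.ravel() for a in (dn, db, ds))
    else:
        dn = relative_change_pct(npp_ref[None], npp.values).ravel()
        db = relative_change_pct(tcb_ref[None], tcb.values).ravel()
        ds = (sst.values - sst_ref[None]).ravel()

    ok = np.isfinite(dn) & np.isfinite(db) & np.isfinite(ds)
    ok &= (dn > npp_exclusion_pct) if direction == "increase" else (dn < -npp_exclusion_pct)
    if not ok.any():
        return _empty_curve(direction, member.mem_name, member.esm_name,
                            "no samples retained after direction/exclusion filters")
    r = db[ok] / dn[ok]
    ds = ds[ok]

    lo_p, hi_p = trim
    if not (0.0 <= lo_p <= hi_p <= 100.0):
        raise ValueError("trim percentiles must satisfy 0 <= lo <= hi <= 100")
    if lo_p > 0.0 or hi_p < 100.0:
        lo, hi = np.percentile(r, [lo_p, hi_p])
        keep = (r >= lo) & (r <= hi)
        r, ds = r[keep], ds[keep]
    if r.size == 0:
        return _empty_curve(direction, member.mem_name, member.esm_name,
                            "all samples trimmed")

    # zero-aligned contiguous bins covering the sampled dSST range
    i0 = math.floor(ds.min() / bin_width)
    i1 = max(math.ceil(ds.max() / bin_width), i0 + 1)
    edges = bin_width * np.arange(i0, i1 + 1)
    idx = np.clip(np.digitize(ds, edges) - 1, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1)
    sums = np.bincount(idx, weights=r, minlength=edges.size - 1)
    sq = np.bincount(idx, weights=r * r, minlength=edges.size - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
        var = np.maximum(sq / counts - means**2, 0.0)
    keep = counts >= max(min_count, 1)
    if not keep.any():
        return _empty_curve(direction, member.mem_name, member.esm_name,
                            "no bin reached min_count")
    return WarmingCurve(
        npp_direction=direction,
        bin_lo=edges[:-1][keep],
        bin_hi=edges[1:][keep],
        mean_r=means[keep],
        sd_r=np.sqrt(var[keep]),
        n=counts[keep].astype(int),
        mem_name=member.mem_name,
        esm_name=member.esm_name,
    )


def warming_correlation(curve: WarmingCurve) -> tuple[float, float, float]:
    """(pearson_r, p_value, shapiro_p) of bin-mean R against bin-center dSST.

    An exactly constant curve has an undefined correlation: the Pearson
    fields come back as NaN (flagged), the Shapiro diagnostic is still run.
    """
    if curve.n_bins < 3:
        raise ValueError("need at least 3 bins for correlation tests")
    y = curve.mean_r
    constant = np.ptp(y) <= 1e-10 * max(1.0, float(np.max(np.abs(y))))
    shapiro_p = math.nan if constant else float(stats.shapiro(y).pvalue)
    if constant:
        return (math.nan, math.nan, shapiro_p)
    pr = stats.pearsonr(curve.bin_centers, y)
    return (float(pr.statistic), float(pr.pvalue), shapiro_p)
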