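"""Size-class disaggregation of the amplification signal along the food web.

Per-class biomass changes are standardised as global area-weighted relative
changes versus the reference window.  Trophic-level-resolved schemes can be
converted to weight classes first (biomass-conserving), since changes are
not linear in general the conversion always operates on biomass fields and
changes are computed afterwards.

Length-based schemes are never force-converted to weight; cross-scheme
comparison is by rank (small to large) only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .changes import relative_change_pct, window_climatology
from .grid_io import ClassScheme, GriddedField, MemberOutput, area_weighted_mean

__all__ = [
    "ClassScheme",
    "TLWeightMap",
    "default_tl_weight_map",
    "per_class_relative_change",
    "convert_tl_to_weight",
    "amplification_profile",
]


@dataclass(frozen=True)
class TLWeightMap:
    """Fractional assignment of trophic-level bins to weight bins.

    ``mapping[i, j]`` is the fraction of TL bin i whose biomass lands in
    weight bin j; every row sums to 1 so total biomass is conserved.
    """

    tl_bins: tuple[tuple[float, float], ...]
    weight_bins: tuple[tuple[float, float], ...]
    mapping: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mapping, dtype=np.float64)
        object.__setattr__(self, "mapping", m)
        if m.shape != (len(self.tl_bins), len(self.weight_bins)):
            raise ValueError("mapping shape does not match bin counts")
        if (m < -1e-12).any():
            raise ValueError("mapping fractions must be >= 0")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each TL bin's fractions must sum to 1")


def default_tl_weight_map(
    tl_bins: Sequence[tuple[float, float]],
    weight_bins: Sequence[tuple[float, float]],
    ppmr: float = 100.0,
    tl0: float = 2.0,
    w0: float = 1.0,
) -> TLWeightMap:
    """Log-linear TL-to-weight correspondence, discretised to bin overlaps.

    TL(w) = tl0 + log(w / w0) / log(ppmr); the default predator-prey mass
    ratio of 100 makes one trophic step span two decadal weight bins.  This
    is an explicit stand-in: supply the real conversion table via config
    when one is available.
    """
    if ppmr <= 1.0:
        raise ValueError("ppmr must exceed 1")
    log_ppmr = np.log10(ppmr)

    def tl_of_weight(w: float) -> float:
        if np.isinf(w):
            return np.inf
        return tl0 + np.log10(w / w0) / log_ppmr

    w_edges_tl = [(tl_of_weight(lo), tl_of_weight(hi)) for lo, hi in weight_bins]
    # clip open ends to the overall covered range so overlaps are finite
    tl_max = max(hi for _, hi in tl_bins if np.isfinite(hi)) + 10.0
    mapping = np.zeros((len(tl_bins), len(weight_bins)))
    for i, (a, b) in enumerate(tl_bins):
        b_eff = min(b, tl_max) if np.isfinite(b) else tl_max
        a_eff = min(a, b_eff)
        width = b_eff - a_eff
        if width <= 0:
            raise ValueError(f"degenerate TL bin ({a}, {b})")
        for j, (wa, wb) in enumerate(w_edges_tl):
            wa_eff = wa if np.isfinite(wa) else -np.inf
            wb_eff = wb if np.isfinite(wb) else np.inf
            if j == 0:
                wa_eff = -np.inf  # smallest weight bin absorbs everything below
            if j == len(weight_bins) - 1:
                wb_eff = np.inf   # largest bin absorbs everything above
            overlap = max(0.0, min(b_eff, wb_eff) - max(a_eff, wa_eff))
            mapping[i, j] = overlap / width
    row = mapping.sum(axis=1)
    if not np.allclose(row, 1.0, atol=1e-9):
        raise ValueError("TL bins are not fully covered by the weight bins")
    return TLWeightMap(tl_bins=tuple(tl_bins), weight_bins=tuple(weight_bins),
                       mapping=mapping)


def convert_tl_to_weight(
    tl_fields: Sequence[GriddedField],
    tl_map: TLWeightMap,
    labels: Optional[Sequence[str]] = None,
) -> list[GriddedField]:
    """Redistribute TL-bin biomass fields onto weight bins (conserving)."""
    if len(tl_fields) != len(tl_map.tl_bins):
        raise ValueError("number of TL fields does not match the map's TL bins")
    grid = tl_fields[0].grid
    years = tl_fields[0].years
    for f in tl_fields[1:]:
        grid.require_compatible(f.grid)
        if not np.array_equal(years, f.years):
            raise ValueError("TL fields differ in year range")
    stack = np.stack([f.values for f in tl_fields])  # (n_tl, ny, nlat, nlon)
    out = np.einsum("tj,t...->j...", tl_map.mapping, stack)
    if labels is None:
        labels = [f"w{j}" for j in range(len(tl_map.weight_bins))]
    return [
        GriddedField(grid=grid, years=years, values=out[j],
                     var_name=f"b_{labels[j]}", units=tl_fields[0].units)
        for j in range(len(tl_map.weight_bins))
    ]


def per_class_relative_change(
    member: MemberOutput,
    reference_window: tuple[int, int] = (1995, 2014),
    target_window: tuple[int, int] = (2090, 2099),
    weighted: bool = True,
) -> dict[str, float]:
    """Global relative change (%) per class between the two windows.

    Area-weighted mean of the per-cell relative-change map (same recipe as
    the change-map statistics).  Classes with no valid cell are absent.
    """
    if not member.class_biomass:
        raise ValueError("member has no class-resolved biomass")
    out: dict[str, float] = {}
    for label, f in member.class_biomass:
        ref = window_climatology(f, reference_window)
        tgt = window_climatology(f, target_window)
        change = relative_change_pct(ref, tgt)
        if not np.isfinite(change).any():
            continue
        out[label] = area_weighted_mean(change, f.grid, weighted=weighted)
    return out


def _monotonicity(magnitudes: np.ndarray, tol: float) -> str:
    if magnitudes.size < 2 or np.ptp(magnitudes) < tol:
        return "flat"
    diffs = np.diff(magnitudes)
    if np.all(diffs > -tol):
        return "increasing"
    if np.all(diffs < tol):
        return "decreasing"
    return "non-monotone"


@dataclass
class AmplificationProfile:
    mem_name: str
    esm_name: str
    axis: str
    class_labels: tuple[str, ...]
    delta_b_pct: np.ndarray       # per class, ascending size order
    r: np.ndarray                 # per class, vs the shared dNPP%
    delta_npp_pct: float
    diagnostic: str               # monotonicity of |dB| across classes


def amplification_profile(
    member: MemberOutput,
    delta_npp_pct: float,
    reference_window: tuple[int, int] = (1995, 2014),
    target_window: tuple[int, int] = (2090, 2099),
    weighted: bool = True,
    flat_tol: float = 0.5,
) -> AmplificationProfile:
    """Ordered per-class (dB%, R) against one global NPP change.

    ``flat_tol`` (percentage points) bounds what still counts as a flat
    profile in the monotonicity diagnostic.
    """
    changes = per_class_relative_change(member, reference_window, target_window,
                                        weighted=weighted)
    labels = tuple(l for l, _ in member.class_biomass if l in changes)
    db = np.asarray([changes[l] for l in labels])
    if delta_npp_pct == 0.0:
        r = np.full(db.shape, np.nan)
    else:
        r = db / delta_npp_pct
    diag = _monotonicity(np.abs(db), flat_tol)
    return AmplificationProfile(
        mem_name=member.mem_name,
        esm_name=member.esm_name,
        axis=member.class_scheme.axis,
        class_labels=labels,
        delta_b_pct=db,
        r=r,
        delta_npp_pct=float(delta_npp_pct),
        diagnostic=diag,
    )
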