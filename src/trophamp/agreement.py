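"""Per-cell majority voting of response types across ensemble members.

A cell agrees when the most frequent defined type reaches the absolute vote
threshold (e.g. 6 of 7 members).  Undefined votes never count toward a
type; members missing a cell simply reduce its number of voters.  Ties at
or above the threshold are conservatively marked as no agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .classification import DEFINED_TYPES, ResponseType, ResponseTypeMap
from .grid_io import Grid

__all__ = ["AgreementMap", "NO_AGREEMENT", "vote_agreement", "agreement_area_fractions"]

#: integer code for cells where fewer than ``threshold`` members agree
NO_AGREEMENT = 7
#: code for cells with no defined vote at all (reuses the undefined code)
NO_DATA = int(ResponseType.UNDEFINED)


@dataclass
class AgreementMap:
    grid: Grid
    modal_type: np.ndarray  # int8: ResponseType code, NO_AGREEMENT or NO_DATA
    votes: np.ndarray       # count for the modal type (0 where no data)
    n_members: np.ndarray   # number of members voting a defined type per cell
    threshold: int

    def __post_init__(self) -> None:
        for name in ("modal_type", "votes", "n_members"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")


def vote_agreement(
    type_maps: Sequence[ResponseTypeMap],
    threshold: int,
    proportional: bool = False,
) -> AgreementMap:
    """Majority vote across members with an absolute agreement threshold.

    ``proportional=True`` applies ``threshold / n_maps`` to each cell's
    actual number of voters instead of the fixed count.
    """
    if len(type_maps) < 2:
        raise ValueError("need at least two type maps")
    grid = type_maps[0].grid
    for tm in type_maps[1:]:
        if not grid.same_layout(tm.grid):
            raise ValueError("type maps are on different grids")
    if not 1 <= threshold <= len(type_maps):
        raise ValueError("threshold must lie in [1, number of maps]")

    stack = np.stack([tm.codes for tm in type_maps])  # (n_members, nlat, nlon)
    counts = np.stack([
        np.sum(stack == int(t), axis=0) for t in DEFINED_TYPES
    ])  # (6, nlat, nlon)
    n_members = counts.sum(axis=0)
    best = counts.max(axis=0)
    # a tie exists when two types share the top count
    n_at_best = np.sum(counts == best[None], axis=0)
    argbest = counts.argmax(axis=0)
    modal_code = np.asarray([int(t) for t in DEFINED_TYPES])[argbest].astype(np.int8)

    if proportional:
        frac = threshold / len(type_maps)
        required = np.maximum(np.ceil(frac * n_members), 1).astype(int)
    else:
        required = np.full(grid.shape, threshold, dtype=int)

    agreeing = (best >= required) & (n_at_best == 1) & (best > 0)
    modal = np.where(agreeing, modal_code, NO_AGREEMENT).astype(np.int8)
    modal[n_members == 0] = NO_DATA
    modal[~grid.ocean_mask] = NO_DATA
    votes = np.where(agreeing, best, best).astype(np.int32)
    votes[~grid.ocean_mask] = 0
    return AgreementMap(grid=grid, modal_type=modal, votes=votes,
                        n_members=n_members.astype(np.int32), threshold=threshold)


def agreement_area_fractions(
    agreement: AgreementMap,
    grid: Optional[Grid] = None,
    weighted: bool = True,
) -> dict[Union[ResponseType, str], float]:
    """Area fractions over {each type, no_agreement, no_data}; sums to 1."""
    grid = grid or agreement.grid
    base = grid.ocean_mask
    if not base.any():
        raise ValueError("empty ocean")
    w = grid.cell_area if weighted else np.ones(grid.shape)
    total = float(np.sum(w[base]))
    out: dict[Union[ResponseType, str], float] = {}
    for t in DEFINED_TYPES:
        out[t] = float(np.sum(w[base & (agreement.modal_type == int(t))]) / total)
    out["no_agreement"] = float(
        np.sum(w[base & (agreement.modal_type == NO_AGREEMENT)]) / total)
    out["no_data"] = float(
        np.sum(w[base & (agreement.modal_type == NO_DATA)]) / total)
    return out
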