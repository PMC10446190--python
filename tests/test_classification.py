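import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophamp.changes import ChangeMaps
from trophamp.classification import (
    DEFINED_TYPES,
    ResponseType,
    ResponseTypeMap,
    RRatioField,
    classify_cell,
    classify_map,
    compute_r,
    compute_r_map,
    mean_r_by_type,
    r_anova,
    type_area_fractions,
)

from .conftest import make_grid

T = ResponseType


def change_maps(grid, dn, db, ds=None, ref=(1995, 2014), tgt=(2090, 2099)):
    ds = np.zeros(grid.shape) if ds is None else ds
    return ChangeMaps(grid=grid, delta_npp_pct=np.asarray(dn, float),
                      delta_b_pct=np.asarray(db, float),
                      delta_sst_degc=ds, reference_window=ref, target_window=tgt)


class TestComputeR:
    @pytest.mark.parametrize("db,dn,expected", [
        (-30.0, -10.0, 3.0),
        (-5.0, -10.0, 0.5),
        (-22.0, 10.0, -2.2),
    ])
    def test_worked_ratios(self, db, dn, expected):
        assert compute_r(db, dn) == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_marker(self):
        assert math.isnan(compute_r(0.0, 0.0))
        assert compute_r(5.0, 0.0) == -math.inf

    def test_nonfinite_inputs(self):
        assert math.isnan(compute_r(math.nan, 1.0))


class TestClassifyCell:
    @pytest.mark.parametrize("db,dn,expected", [
        (-30.0, -10.0, T.NEGATIVE_AMPLIFICATION),
        (-5.0, -10.0, T.NEGATIVE_ATTENUATION),
        (-22.0, 10.0, T.NEGATIVE_INVERSION),
        (4.0, 10.0, T.POSITIVE_ATTENUATION),
        (30.0, 10.0, T.POSITIVE_AMPLIFICATION),
        (5.0, -10.0, T.POSITIVE_INVERSION),
    ])
    def test_six_types(self, db, dn, expected):
        assert classify_cell(db, dn) is expected

    def test_tie_r_equals_one_is_attenuation(self):
        assert classify_cell(-10.0, -10.0) is T.NEGATIVE_ATTENUATION
        assert classify_cell(10.0, 10.0) is T.POSITIVE_ATTENUATION

    def test_zero_biomass_change_undefined(self):
        assert classify_cell(0.0, 5.0) is T.UNDEFINED

    def test_zero_npp_change_is_inversion(self):
        assert classify_cell(5.0, 0.0) is T.POSITIVE_INVERSION
        assert classify_cell(-5.0, 0.0) is T.NEGATIVE_INVERSION

    def test_nan_undefined(self):
        assert classify_cell(math.nan, 1.0) is T.UNDEFINED

    @settings(max_examples=200, deadline=None)
    @given(db=st.floats(-200, 200), dn=st.floats(-200, 200))
    def test_consistency_with_r(self, db, dn):
        if abs(dn) < 1.0 or db == 0.0:
            return
        r = compute_r(db, dn)
        t = classify_cell(db, dn)
        if abs(r - 1.0) < 1e-6:
            return  # tie band, resolved to attenuation by rule
        if r > 1.0:
            assert t in (T.POSITIVE_AMPLIFICATION, T.NEGATIVE_AMPLIFICATION)
        elif 0.0 < r < 1.0:
            assert t in (T.POSITIVE_ATTENUATION, T.NEGATIVE_ATTENUATION)
        elif r < 0.0:
            assert t in (T.POSITIVE_INVERSION, T.NEGATIVE_INVERSION)

    @settings(max_examples=200, deadline=None)
    @given(db=st.floats(-200, 200), dn=st.floats(-200, 200))
    def test_negation_symmetry(self, db, dn):
        if db == 0.0 or dn == 0.0:
            return
        t1 = classify_cell(db, dn)
        t2 = classify_cell(-db, -dn)
        swap = {
            T.POSITIVE_AMPLIFICATION: T.NEGATIVE_AMPLIFICATION,
            T.NEGATIVE_AMPLIFICATION: T.POSITIVE_AMPLIFICATION,
            T.POSITIVE_ATTENUATION: T.NEGATIVE_ATTENUATION,
            T.NEGATIVE_ATTENUATION: T.POSITIVE_ATTENUATION,
            T.POSITIVE_INVERSION: T.NEGATIVE_INVERSION,
            T.NEGATIVE_INVERSION: T.POSITIVE_INVERSION,
        }
        assert t2 is swap[t1]
        assert compute_r(-db, -dn) == pytest.approx(compute_r(db, dn), rel=1e-12)


class TestClassifyMap:
    def test_all_land_grid_all_undefined(self):
        grid = make_grid(3, 3, land_cells=[(i, j) for i in range(3) for j in range(3)])
        maps = change_maps(grid, np.full((3, 3), np.nan), np.full((3, 3), np.nan))
        out = classify_map(maps)
        assert (out.codes == int(T.UNDEFINED)).all()

    def test_vectorised_matches_scalar(self):
        grid = make_grid(5, 5)
        rng = np.random.default_rng(4)
        dn = rng.uniform(-50, 50, grid.shape)
        db = rng.uniform(-50, 50, grid.shape)
        out = classify_map(change_maps(grid, dn, db))
        for i in range(5):
            for j in range(5):
                assert out.codes[i, j] == int(classify_cell(db[i, j], dn[i, j]))

    def test_r_map_sentinels(self):
        grid = make_grid(2, 2)
        dn = np.array([[0.0, 0.0], [10.0, -10.0]])
        db = np.array([[5.0, 0.0], [20.0, -5.0]])
        r = compute_r_map(change_maps(grid, dn, db))
        assert r.r[0, 0] == -np.inf
        assert math.isnan(r.r[0, 1])
        assert r.r[1, 0] == pytest.approx(2.0)
        assert r.r[1, 1] == pytest.approx(0.5)


class TestTypeAreaFractions:
    def test_uniform_map(self):
        grid = make_grid(4, 4)
        codes = np.full(grid.shape, int(T.NEGATIVE_AMPLIFICATION), dtype=np.int8)
        fracs = type_area_fractions(ResponseTypeMap(grid=grid, codes=codes))
        assert fracs[T.NEGATIVE_AMPLIFICATION] == pytest.approx(1.0)
        assert fracs[T.POSITIVE_INVERSION] == 0.0

    def test_equator_symmetric_half_split(self):
        grid = make_grid(4, 4)  # symmetric about the equator
        codes = np.where(grid.lat[:, None] < 0, int(T.NEGATIVE_AMPLIFICATION),
                         int(T.POSITIVE_INVERSION)).astype(np.int8)
        codes = np.broadcast_to(codes, grid.shape).copy()
        fracs = type_area_fractions(ResponseTypeMap(grid=grid, codes=codes))
        assert fracs[T.NEGATIVE_AMPLIFICATION] == pytest.approx(0.5)
        assert fracs[T.POSITIVE_INVERSION] == pytest.approx(0.5)

    def test_toy_grid_hand_count(self):
        # 6x6 with 2 land cells; independent hand computation with cos weights
        grid = make_grid(6, 6, land_cells=[(0, 0), (3, 3)])
        rng = np.random.default_rng(9)
        codes = rng.integers(1, 7, size=grid.shape).astype(np.int8)
        codes[~grid.ocean_mask] = 0
        fracs = type_area_fractions(ResponseTypeMap(grid=grid, codes=codes))
        w = np.cos(np.deg2rad(grid.lat))
        for t in DEFINED_TYPES:
            num = den = 0.0
            for i in range(6):
                for j in range(6):
                    if not grid.ocean_mask[i, j]:
                        continue
                    den += w[i]
                    if codes[i, j] == int(t):
                        num += w[i]
            assert fracs[t] == pytest.approx(num / den, rel=1e-12)

    def test_partition_sums_to_one(self):
        grid = make_grid(5, 7, land_cells=[(2, 2)])
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 7, size=grid.shape).astype(np.int8)
        fracs = type_area_fractions(ResponseTypeMap(grid=grid, codes=codes))
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_subset_errors(self):
        grid = make_grid(3, 3)
        codes = np.ones(grid.shape, dtype=np.int8)
        with pytest.raises(ValueError, match="empty"):
            type_area_fractions(ResponseTypeMap(grid=grid, codes=codes),
                                subset=np.zeros(grid.shape, bool))


class TestMeanRByType:
    def test_identical_cells(self):
        grid = make_grid(4, 4)
        dn = np.full(grid.shape, -10.0)
        db = np.full(grid.shape, -30.0)
        maps = change_maps(grid, dn, db)
        stats = mean_r_by_type(compute_r_map(maps), classify_map(maps),
                               delta_npp_pct=dn)
        mean, sd, n = stats[T.NEGATIVE_AMPLIFICATION]
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert n == 16

    def test_no_trim_equals_untrimmed(self):
        grid = make_grid(6, 6)
        rng = np.random.default_rng(5)
        dn = rng.uniform(-40, 40, grid.shape)
        db = rng.uniform(-40, 40, grid.shape)
        maps = change_maps(grid, dn, db)
        r, tm = compute_r_map(maps), classify_map(maps)
        a = mean_r_by_type(r, tm, delta_npp_pct=dn, trim=(0.0, 100.0))
        b = mean_r_by_type(r, tm, delta_npp_pct=dn, trim=(0.0, 100.0),
                           npp_exclusion_pct=0.0)
        # with |dn| >= 1 nearly everywhere the two differ only via exclusion
        for t in a:
            assert a[t][2] <= b[t][2]

    def test_matches_bruteforce_oracle(self):
        grid = make_grid(8, 8, land_cells=[(0, 1)])
        rng = np.random.default_rng(6)
        dn = rng.uniform(-40, 40, grid.shape)
        db = rng.uniform(-40, 40, grid.shape)
        dn[~grid.ocean_mask] = np.nan
        db[~grid.ocean_mask] = np.nan
        maps = change_maps(grid, dn, db)
        r, tm = compute_r_map(maps), classify_map(maps)
        got = mean_r_by_type(r, tm, delta_npp_pct=dn, trim=(0.0, 100.0),
                             npp_exclusion_pct=1.0)
        # brute force: enumerate cells directly
        w = np.cos(np.deg2rad(grid.lat))
        buckets = {}
        for i in range(8):
            for j in range(8):
                if not grid.ocean_mask[i, j] or abs(dn[i, j]) < 1.0:
                    continue
                t = classify_cell(db[i, j], dn[i, j])
                buckets.setdefault(t, []).append((w[i], db[i, j] / dn[i, j]))
        for t, pairs in buckets.items():
            ws = np.array([p[0] for p in pairs])
            rs = np.array([p[1] for p in pairs])
            mean = (ws * rs).sum() / ws.sum()
            assert got[t][0] == pytest.approx(mean, rel=1e-12)
            assert got[t][2] == len(pairs)

    def test_empty_type_absent_not_nan(self):
        grid = make_grid(3, 3)
        dn = np.full(grid.shape, -10.0)
        db = np.full(grid.shape, -30.0)
        maps = change_maps(grid, dn, db)
        stats = mean_r_by_type(compute_r_map(maps), classify_map(maps),
                               delta_npp_pct=dn)
        assert T.POSITIVE_AMPLIFICATION not in stats
        assert all(np.isfinite(v[0]) for v in stats.values())

    def test_infinite_sentinels_excluded(self):
        grid = make_grid(2, 2)
        dn = np.array([[0.0, -10.0], [-10.0, -10.0]])
        db = np.array([[5.0, -30.0], [-30.0, -30.0]])
        maps = change_maps(grid, dn, db)
        stats = mean_r_by_type(compute_r_map(maps), classify_map(maps),
                               delta_npp_pct=dn, trim=(0.0, 100.0))
        assert stats[T.NEGATIVE_AMPLIFICATION][0] == pytest.approx(3.0)
        assert T.POSITIVE_INVERSION not in stats  # the inf cell


class TestAnova:
    def test_type_effect_detected(self):
        import pandas as pd
        rng = np.random.default_rng(8)
        rows = []
        for mem in ("a", "b"):
            for t, base in (("neg_amp", 3.0), ("neg_att", 0.5)):
                for _ in range(40):
                    rows.append({"r": base + rng.normal(0, 0.2),
                                 "response_type": t, "mem": mem, "esm": "e1"})
        table = r_anova(pd.DataFrame(rows))
        assert table.loc["C(response_type)", "PR(>F)"] < 0.05
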