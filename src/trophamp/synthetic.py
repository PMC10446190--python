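"""Seeded pseudo-ensemble generator with closed-form ground truth.

Forcings follow a smooth monotone ramp ``s(t)`` that is exactly 0 over the
reference window and exactly 1 over the target window (flat on both, linear
between), so window-based statistics coincide with the closed forms:

    SST_i(t) = SST0_i + trend_i * s(t) + eps
    NPP_i(t) = NPP0_i * (1 + g_i * s(t)) * noise

Each member's consumer response is multiplicative in NPP and exponential in
warming, with a per-class trophic distance d_c scaling the temperature
sensitivity lambda (a transfer-efficiency-style cumulative loss per trophic
step):

    B_c,i(t) = B0_c * NPP_i(t)/NPP0_i * exp(-lambda * d_c * (SST_i(t) - SST0_i)) * noise

so the noise-free relative change between windows is
``(1 + n_i) * exp(-lambda * d_c * dT_i) - 1``.  This is a generator with
controllable amplification behaviour, not a claim about any real ecosystem
model.  Noise is mean-one lognormal (keeps biomass positive and unbiased);
all streams are split deterministically from the master seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from .classification import ResponseType, ResponseTypeMap, _classify_arrays
from .grid_io import ClassScheme, Grid, GriddedField, MemberOutput

__all__ = [
    "MemberSpec",
    "SyntheticConfig",
    "EnsembleData",
    "default_class_scheme",
    "default_members",
    "base_fields",
    "forcing_ramp",
    "generate_forcings",
    "generate_member_response",
    "generate_ensemble",
    "analytic_expected_change",
    "analytic_tcb_change",
    "ground_truth_types",
]

#: the six standard weight classes (g) used by the default scheme
DEFAULT_WEIGHT_BINS = (
    (1.0, 10.0), (10.0, 100.0), (100.0, 1e3),
    (1e3, 1e4), (1e4, 1e5), (1e5, float("inf")),
)
DEFAULT_WEIGHT_LABELS = ("1-10g", "10-100g", "100g-1kg", "1-10kg", "10-100kg", ">100kg")


def default_class_scheme(n_classes: int = 6) -> ClassScheme:
    if not 1 <= n_classes <= 6:
        raise ValueError("default scheme supports 1..6 classes")
    return ClassScheme(
        axis="weight",
        bins=DEFAULT_WEIGHT_BINS[:n_classes],
        labels=DEFAULT_WEIGHT_LABELS[:n_classes],
        trophic_distance=tuple(float(d) for d in range(1, n_classes + 1)),
    )


@dataclass(frozen=True)
class MemberSpec:
    """One synthetic ensemble member.

    ``lambda_te`` is the per-degC sensitivity of transfer efficiency
    (0 = temperature-neutral member); ``baseline_te`` sets the biomass
    pyramid across classes when explicit baselines are not given.
    """

    mem_name: str
    lambda_te: float
    class_scheme: ClassScheme = dc_field(default_factory=default_class_scheme)
    baseline_te: float = 0.5
    class_baseline_biomass: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.lambda_te < 0:
            raise ValueError("lambda_te must be >= 0")
        if not 0.0 < self.baseline_te < 1.0:
            raise ValueError("baseline_te must lie in (0, 1)")
        if self.class_scheme.trophic_distance is None:
            raise ValueError("member class scheme needs trophic distances")
        if self.class_baseline_biomass is not None:
            if len(self.class_baseline_biomass) != self.class_scheme.n_classes:
                raise ValueError("class_baseline_biomass length mismatch")
            if any(b <= 0 for b in self.class_baseline_biomass):
                raise ValueError("class baselines must be positive")

    @property
    def trophic_distance(self) -> np.ndarray:
        return np.asarray(self.class_scheme.trophic_distance, dtype=np.float64)

    @property
    def class_weights(self) -> np.ndarray:
        """Baseline biomass per class (a TE0**(d-1) pyramid by default)."""
        if self.class_baseline_biomass is not None:
            return np.asarray(self.class_baseline_biomass, dtype=np.float64)
        d = self.trophic_distance
        return self.baseline_te ** (d - d[0])

    def validate_te_range(self, max_delta_t: float) -> None:
        te = self.baseline_te * np.exp(-self.lambda_te * max_delta_t)
        if not 0.0 < te < 1.0:
            raise ValueError("transfer efficiency leaves (0, 1) over the dT range")


def default_members(lambdas: Sequence[float] = (0.0, 0.05, 0.1, 0.15, 0.2)) -> tuple[MemberSpec, ...]:
    return tuple(
        MemberSpec(mem_name=f"mem{i}", lambda_te=float(lam))
        for i, lam in enumerate(lambdas)
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Fully determines a pseudo-ensemble and its analytic ground truth."""

    seed: int = 0
    grid_shape: tuple[int, int] = (45, 90)
    year_range: tuple[int, int] = (1950, 2099)
    reference_window: tuple[int, int] = (1995, 2014)
    target_window: tuple[int, int] = (2090, 2099)
    noise_sd: float = 0.05
    land_fraction: float = 0.3
    trend_noise_sd: float = 0.04
    esm_name: str = "synthetic-esm"
    members: tuple[MemberSpec, ...] = dc_field(default_factory=default_members)
    sst_trend_field: Optional[np.ndarray] = None
    npp_trend_field: Optional[np.ndarray] = None
    ocean_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        y0, y1 = self.year_range
        r0, r1 = self.reference_window
        t0, t1 = self.target_window
        if not (y0 <= r0 <= r1 < t0 <= t1 <= y1):
            raise ValueError("windows must be disjoint, ordered and inside year_range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for m in self.members:
            m.validate_te_range(MAX_WARMING * 1.5)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1, dtype=np.int64)


# ---------------------------------------------------------------------------
# Deterministic field construction

def _child_rng(seed: int, *tags: str) -> np.random.Generator:
    """Independent stream keyed by (seed, tags); member-order independent."""
    entropy = [seed] + [zlib.crc32(t.encode("utf8")) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], size: int = 5) -> np.ndarray:
    """Zero-mean smooth random field; periodic in lon, reflected in lat."""
    raw = rng.standard_normal(shape)
    sm = uniform_filter(raw, size=size, mode="wrap")
    sm = uniform_filter(sm, size=size, mode="reflect")
    return sm - sm.mean()


def build_grid(config: SyntheticConfig) -> Grid:
    nlat, nlon = config.grid_shape
    dlat = 180.0 / nlat
    dlon = 360.0 / nlon
    lat = -90.0 + dlat * (np.arange(nlat) + 0.5)
    lon = dlon * (np.arange(nlon) + 0.5)
    if config.ocean_mask is not None:
        mask = np.asarray(config.ocean_mask, dtype=bool)
        if mask.shape != (nlat, nlon):
            raise ValueError("ocean_mask shape mismatch")
    else:
        rng = _child_rng(config.seed, "mask")
        f = _smooth_noise(rng, (nlat, nlon), size=max(3, nlat // 9))
        thresh = np.quantile(f, 1.0 - config.land_fraction)
        mask = f <= thresh
    return Grid(lat=lat, lon=lon, ocean_mask=mask)


# Default zonal trend profiles.  Three latitude zones per hemisphere:
#   |lat| < ZONE_DECREASE_LAT : NPP declines; warming runs from WARMING_EQ at
#       the equator to WARMING_SUBPOLAR at the zone edge, and the decline
#       magnitude scales inversely with warming (|g| = NPP_DECLINE_PRODUCT/T)
#       so amplification strengthens toward stronger warming.
#   ZONE_DECREASE_LAT..ZONE_POLAR_LAT : NPP increases under strong warming
#       (warming overwhelms the NPP gain -> inversion regime).
#   |lat| >= ZONE_POLAR_LAT : NPP increases under weak warming (positive
#       regime).
# The zone edges are hard steps, which keeps every cell's noise-free change
# well away from the classification boundaries.
WARMING_EQ = 3.2           # degC per century at the equator
WARMING_SUBPOLAR = 1.0     # degC at the decrease-zone edge
WARMING_MIDBAND = 1.75     # degC in the warm increase band
WARMING_POLAR = 0.30       # degC in the polar increase band
NPP_DECLINE_PRODUCT = 0.35  # |g| * T in the decrease zone
NPP_INCREASE = 0.25        # fractional NPP gain per century where it increases
ZONE_DECREASE_LAT = 55.0
ZONE_POLAR_LAT = 72.0
MAX_WARMING = WARMING_EQ * 1.2


def base_fields(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Noise-free base state and per-century trend fields (NaN-free)."""
    grid = build_grid(config)
    nlat, nlon = grid.shape
    abslat = np.abs(grid.lat)[:, None]
    coslat2 = np.cos(np.deg2rad(grid.lat))[:, None] ** 2
    coslat2 = np.broadcast_to(coslat2, (nlat, nlon))

    sst0 = -2.0 + 30.0 * coslat2
    npp0 = 4.0 + 6.0 * coslat2

    decrease = abslat < ZONE_DECREASE_LAT
    midband = (abslat >= ZONE_DECREASE_LAT) & (abslat < ZONE_POLAR_LAT)

    if config.sst_trend_field is not None:
        sst_trend = np.asarray(config.sst_trend_field, dtype=np.float64)
    else:
        frac = np.clip(abslat / ZONE_DECREASE_LAT, 0.0, 1.0)
        t_profile = np.where(
            decrease, WARMING_EQ - (WARMING_EQ - WARMING_SUBPOLAR) * frac,
            np.where(midband, WARMING_MIDBAND, WARMING_POLAR))
        sst_trend = np.broadcast_to(t_profile, (nlat, nlon)) * (
            1.0 + config.trend_noise_sd
            * _smooth_noise(_child_rng(config.seed, "sst-trend"), (nlat, nlon)))
        sst_trend = np.clip(sst_trend, 0.05, MAX_WARMING)

    if config.npp_trend_field is not None:
        npp_trend = np.asarray(config.npp_trend_field, dtype=np.float64)
    else:
        g_profile = np.where(
            decrease, -NPP_DECLINE_PRODUCT / np.maximum(sst_trend, 0.2),
            NPP_INCREASE)
        npp_trend = g_profile * (
            1.0 + config.trend_noise_sd
            * _smooth_noise(_child_rng(config.seed, "npp-trend"), (nlat, nlon)))
        npp_trend = np.clip(npp_trend, -0.9, 2.0)

    for name, arr in (("sst_trend", sst_trend), ("npp_trend", npp_trend)):
        if arr.shape != (nlat, nlon):
            raise ValueError(f"{name} field shape mismatch")
    return {
        "grid": grid, "sst0": np.asarray(sst0, float), "npp0": npp0,
        "sst_trend": np.asarray(sst_trend, float), "npp_trend": npp_trend,
    }


def forcing_ramp(config: SyntheticConfig) -> np.ndarray:
    """Monotone ramp s(t): 0 over the reference window, 1 over the target.

    Flat on both windows (hence flat over the whole historical period) and
    linear between, so any window statistic sees the exact endpoint values.
    """
    r1 = config.reference_window[1]
    t0 = config.target_window[0]
    t = config.years.astype(np.float64)
    return np.clip((t - r1) / (t0 - r1), 0.0, 1.0)


def _mean_one_lognormal(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    if sd == 0.0:
        return np.ones(shape)
    return np.exp(rng.normal(0.0, sd, size=shape) - 0.5 * sd * sd)


def generate_forcings(config: SyntheticConfig) -> tuple[GriddedField, GriddedField]:
    """Generate the (sst, npp) forcing pair for the configured grid/years."""
    fields = base_fields(config)
    grid: Grid = fields["grid"]
    s = forcing_ramp(config)[:, None, None]
    land = ~grid.ocean_mask

    sst_vals = fields["sst0"][None] + fields["sst_trend"][None] * s
    if config.noise_sd > 0:
        rng = _child_rng(config.seed, "sst-noise")
        sst_vals = sst_vals + rng.normal(0.0, config.noise_sd, size=sst_vals.shape)
    sst_vals[:, land] = np.nan

    npp_vals = fields["npp0"][None] * (1.0 + fields["npp_trend"][None] * s)
    rng = _child_rng(config.seed, "npp-noise")
    npp_vals = npp_vals * _mean_one_lognormal(rng, config.noise_sd, npp_vals.shape)
    npp_vals = np.maximum(npp_vals, 1e-9)
    npp_vals[:, land] = np.nan

    sst = GriddedField(grid=grid, years=config.years, values=sst_vals,
                       var_name="sst", units="degC")
    npp = GriddedField(grid=grid, years=config.years, values=npp_vals,
                       var_name="npp", units="mol C m-2 yr-1")
    return sst, npp


def generate_member_response(
    config: SyntheticConfig,
    spec: MemberSpec,
    sst: GriddedField,
    npp: GriddedField,
) -> MemberOutput:
    """Per-class biomass fields plus their sum as total consumer biomass."""
    fields = base_fields(config)
    grid: Grid = fields["grid"]
    if not (grid.same_layout(sst.grid) and grid.same_layout(npp.grid)):
        raise ValueError("forcings are not on the config grid")
    sst.grid.require_compatible(npp.grid)

    land = ~grid.ocean_mask
    npp_ratio = npp.values / fields["npp0"][None]
    warming = sst.values - fields["sst0"][None]
    d = spec.trophic_distance
    weights = spec.class_weights

    class_fields: list[tuple[str, GriddedField]] = []
    total = np.zeros_like(npp.values)
    for c, label in enumerate(spec.class_scheme.labels):
        b = weights[c] * npp_ratio * np.exp(-spec.lambda_te * d[c] * warming)
        if config.noise_sd > 0:
            rng = _child_rng(config.seed, "member", spec.mem_name, f"class{c}")
            b = b * _mean_one_lognormal(rng, config.noise_sd, b.shape)
        b[:, land] = np.nan
        total += np.where(np.isnan(b), 0.0, b)
        class_fields.append((label, GriddedField(
            grid=grid, years=config.years, values=b,
            var_name=f"b_{label}", units="g m-2")))
    total[:, land] = np.nan
    tcb = GriddedField(grid=grid, years=config.years, values=total,
                       var_name="tcb", units="g m-2")
    return MemberOutput(mem_name=spec.mem_name, esm_name=config.esm_name,
                        tcb=tcb, class_biomass=class_fields,
                        class_scheme=spec.class_scheme)


@dataclass
class EnsembleData:
    grid: Grid
    sst: GriddedField
    npp: GriddedField
    members: list[MemberOutput]


def generate_ensemble(config: SyntheticConfig) -> EnsembleData:
    sst, npp = generate_forcings(config)
    members = [generate_member_response(config, m, sst, npp) for m in config.members]
    return EnsembleData(grid=sst.grid, sst=sst, npp=npp, members=members)


# ---------------------------------------------------------------------------
# Closed-form ground truth

def analytic_expected_change(n: float, delta_t: float, lambda_te: float, d: float):
    """Noise-free fractional biomass change: (1+n) * exp(-lambda*d*dT) - 1."""
    return (1.0 + np.asarray(n, float)) * np.exp(
        -lambda_te * d * np.asarray(delta_t, float)) - 1.0


def analytic_tcb_change(n, delta_t, spec: MemberSpec):
    """Noise-free fractional change of total consumer biomass.

    Class-weighted combination of the per-class closed forms, with the
    member's baseline biomass pyramid as weights.
    """
    n = np.asarray(n, dtype=np.float64)
    dt = np.asarray(delta_t, dtype=np.float64)
    d = spec.trophic_distance
    w = spec.class_weights
    num = np.zeros(np.broadcast_shapes(n.shape, dt.shape))
    for wc, dc in zip(w, d):
        num = num + wc * np.exp(-spec.lambda_te * dc * dt)
    return (1.0 + n) * num / w.sum() - 1.0


def ground_truth_types(config: SyntheticConfig, spec: MemberSpec) -> ResponseTypeMap:
    """True per-cell response type from the noise-free closed form."""
    fields = base_fields(config)
    grid: Grid = fields["grid"]
    n = fields["npp_trend"]
    dt = fields["sst_trend"]
    db_pct = 100.0 * analytic_tcb_change(n, dt, spec)
    dn_pct = 100.0 * n
    codes = _classify_arrays(db_pct, dn_pct)
    codes[~grid.ocean_mask] = ResponseType.UNDEFINED
    return ResponseTypeMap(grid=grid, codes=codes)
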