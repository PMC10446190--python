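"""Declarative run configuration (YAML) for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .grid_io import ClassScheme
from .synthetic import MemberSpec, SyntheticConfig, default_class_scheme, default_members

__all__ = ["ConfigError", "AnalysisOptions", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration (reported before any compute)."""


@dataclass(frozen=True)
class AnalysisOptions:
    agreement_threshold: int = 4
    npp_exclusion_pct: float = 1.0
    trim: tuple[float, float] = (2.5, 97.5)
    sst_bin_width: float = 0.1
    warming_min_count: int = 10
    weighted: bool = True

    def __post_init__(self) -> None:
        if self.agreement_threshold < 1:
            raise ConfigError("agreement_threshold must be >= 1")
        lo, hi = self.trim
        if not (0.0 <= lo <= hi <= 100.0):
            raise ConfigError("trim percentiles must satisfy 0 <= lo <= hi <= 100")
        if self.sst_bin_width <= 0:
            raise ConfigError("sst_bin_width must be > 0")
        if self.npp_exclusion_pct < 0:
            raise ConfigError("npp_exclusion_pct must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    synthetic: SyntheticConfig
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    output_dir: Path = Path("trophamp-run")

    def __post_init__(self) -> None:
        n = len(self.synthetic.members)
        if self.analysis.agreement_threshold > n:
            raise ConfigError(
                f"agreement_threshold {self.analysis.agreement_threshold} exceeds "
                f"the {n} ensemble members")

    @property
    def reference_window(self) -> tuple[int, int]:
        return self.synthetic.reference_window

    @property
    def target_window(self) -> tuple[int, int]:
        return self.synthetic.target_window

    def to_dict(self) -> dict[str, Any]:
        syn = self.synthetic
        return {
            "synthetic": {
                "seed": syn.seed,
                "grid_shape": list(syn.grid_shape),
                "year_range": list(syn.year_range),
                "reference_window": list(syn.reference_window),
                "target_window": list(syn.target_window),
                "noise_sd": syn.noise_sd,
                "land_fraction": syn.land_fraction,
                "trend_noise_sd": syn.trend_noise_sd,
                "esm_name": syn.esm_name,
                "members": [
                    {
                        "name": m.mem_name,
                        "lambda_te": m.lambda_te,
                        "baseline_te": m.baseline_te,
                        "n_classes": m.class_scheme.n_classes,
                        "trophic_distance": list(m.class_scheme.trophic_distance),
                    }
                    for m in syn.members
                ],
            },
            "analysis": {
                "agreement_threshold": self.analysis.agreement_threshold,
                "npp_exclusion_pct": self.analysis.npp_exclusion_pct,
                "trim": list(self.analysis.trim),
                "sst_bin_width": self.analysis.sst_bin_width,
                "warming_min_count": self.analysis.warming_min_count,
                "weighted": self.analysis.weighted,
            },
            "output_dir": str(self.output_dir),
        }


def _as_pair(value: Any, name: str) -> tuple:
    try:
        a, b = value
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name} must be a pair, got {value!r}") from exc
    return (a, b)


def _member_from_dict(d: dict[str, Any]) -> MemberSpec:
    if "name" not in d:
        raise ConfigError("each member needs a 'name'")
    dist = d.get("trophic_distance")
    if dist is not None:
        scheme = ClassScheme(
            axis=d.get("class_axis", "weight"),
            bins=default_class_scheme(len(dist)).bins,
            labels=default_class_scheme(len(dist)).labels,
            trophic_distance=tuple(float(x) for x in dist),
        )
    else:
        scheme = default_class_scheme(int(d.get("n_classes", 6)))
    return MemberSpec(
        mem_name=str(d["name"]),
        lambda_te=float(d.get("lambda_te", 0.0)),
        class_scheme=scheme,
        baseline_te=float(d.get("baseline_te", 0.5)),
        class_baseline_biomass=(
            tuple(float(x) for x in d["class_baseline_biomass"])
            if "class_baseline_biomass" in d else None),
    )


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    syn_raw = dict(raw.get("synthetic", {}))
    members_raw = syn_raw.pop("members", None)
    if members_raw is None:
        members = default_members()
    else:
        members = tuple(_member_from_dict(m) for m in members_raw)

    kwargs: dict[str, Any] = {"members": members}
    for key in ("seed", "noise_sd", "land_fraction", "trend_noise_sd", "esm_name"):
        if key in syn_raw:
            kwargs[key] = syn_raw[key]
    for key in ("grid_shape", "year_range", "reference_window", "target_window"):
        if key in syn_raw:
            kwargs[key] = tuple(_as_pair(syn_raw[key], key))
    unknown = set(syn_raw) - set(kwargs)
    if unknown:
        raise ConfigError(f"unknown synthetic config keys: {sorted(unknown)}")
    try:
        synthetic = SyntheticConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    ana_raw = dict(raw.get("analysis", {}))
    if "trim" in ana_raw:
        ana_raw["trim"] = tuple(float(x) for x in _as_pair(ana_raw["trim"], "trim"))
    known = {"agreement_threshold", "npp_exclusion_pct", "trim",
             "sst_bin_width", "warming_min_count", "weighted"}
    unknown = set(ana_raw) - known
    if unknown:
        raise ConfigError(f"unknown analysis config keys: {sorted(unknown)}")
    analysis = AnalysisOptions(**ana_raw)

    return RunConfig(
        synthetic=synthetic,
        analysis=analysis,
        output_dir=Path(raw.get("output_dir", "trophamp-run")),
    )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)
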