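"""Config-driven pipeline: generate -> changes -> classify -> agree ->
warming -> sizeclasses, each stage reading the previous stage's files.

Every stage consumes and produces the documented NetCDF/tabular interfaces
under the run's output directory, so stages compose and a single stage can
be re-run from cached inputs.  ``run_pipeline`` executes all stages and
writes a machine-readable manifest (config hash, versions, exclusion
counts, data checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import agreement_area_fractions, vote_agreement
from .changes import ChangeMaps, compute_change_maps
from .classification import (
    ResponseType,
    ResponseTypeMap,
    classify_map,
    compute_r_map,
    mean_r_by_type,
    type_area_fractions,
)
from .config import RunConfig
from .grid_io import GriddedField, read_gridded_netcdf, write_gridded_netcdf
from .sizeclass import amplification_profile
from .synthetic import generate_ensemble
from .warming import r_vs_warming, warming_correlation

logger = logging.getLogger(__name__)

STAGES = ("generate", "changes", "classify", "agree", "warming", "sizeclasses")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _safe(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", label)


def _member_names(cfg: RunConfig) -> list[str]:
    return [m.mem_name for m in cfg.synthetic.members]


def _write_map_nc(values2d: np.ndarray, grid, name: str, units: str,
                  year: int, path: Path) -> None:
    vals = values2d.astype(np.float64).copy()
    vals[~grid.ocean_mask] = np.nan
    f = GriddedField(grid=grid, years=np.array([year]),
                     values=vals[None], var_name=name, units=units)
    write_gridded_netcdf(f, path)


def _read_map_nc(path: Path, name: str) -> np.ndarray:
    return read_gridded_netcdf(path, name).values[0]


# ---------------------------------------------------------------------------
# Stages

def stage_generate(cfg: RunConfig, outdir: Path) -> None:
    ens = generate_ensemble(cfg.synthetic)
    fdir = outdir / "forcings"
    fdir.mkdir(parents=True, exist_ok=True)
    write_gridded_netcdf(ens.sst, fdir / "sst.nc")
    write_gridded_netcdf(ens.npp, fdir / "npp.nc")
    for mem in ens.members:
        mdir = outdir / "members" / _safe(mem.mem_name)
        mdir.mkdir(parents=True, exist_ok=True)
        write_gridded_netcdf(mem.tcb, mdir / "tcb.nc")
        for i, (label, f) in enumerate(mem.class_biomass):
            write_gridded_netcdf(f, mdir / f"class_{i}_{_safe(label)}.nc")
    logger.info("generate: wrote forcings and %d members to %s",
                len(ens.members), outdir)


def _load_forcings(cfg: RunConfig, outdir: Path) -> tuple[GriddedField, GriddedField]:
    fdir = outdir / "forcings"
    return (read_gridded_netcdf(fdir / "sst.nc", "sst"),
            read_gridded_netcdf(fdir / "npp.nc", "npp"))


def stage_changes(cfg: RunConfig, outdir: Path) -> None:
    sst, npp = _load_forcings(cfg, outdir)
    cdir = outdir / "changes"
    cdir.mkdir(parents=True, exist_ok=True)
    year = cfg.target_window[0]
    rows = []
    for name in _member_names(cfg):
        tcb = read_gridded_netcdf(outdir / "members" / _safe(name) / "tcb.nc", "tcb")
        maps = compute_change_maps(npp, tcb, sst, cfg.reference_window,
                                   cfg.target_window)
        _write_map_nc(maps.delta_b_pct, maps.grid, "delta_b_pct", "%",
                      year, cdir / f"{_safe(name)}_delta_b_pct.nc")
        if not rows:  # forcings are shared: write once
            _write_map_nc(maps.delta_npp_pct, maps.grid, "delta_npp_pct", "%",
                          year, cdir / "delta_npp_pct.nc")
            _write_map_nc(maps.delta_sst_degc, maps.grid, "delta_sst_degc", "degC",
                          year, cdir / "delta_sst_degc.nc")
        lat_idx, lon_idx = np.nonzero(maps.grid.ocean_mask)
        rows.append(pd.DataFrame({
            "mem": name,
            "lat": maps.grid.lat[lat_idx],
            "lon": maps.grid.lon[lon_idx],
            "delta_npp_pct": maps.delta_npp_pct[lat_idx, lon_idx],
            "delta_b_pct": maps.delta_b_pct[lat_idx, lon_idx],
            "delta_sst_degc": maps.delta_sst_degc[lat_idx, lon_idx],
        }))
    pd.concat(rows, ignore_index=True).to_csv(cdir / "change_maps.csv", index=False)


def _load_changes(cfg: RunConfig, outdir: Path, name: str) -> ChangeMaps:
    cdir = outdir / "changes"
    sst, _ = _load_forcings(cfg, outdir)
    dn = _read_map_nc(cdir / "delta_npp_pct.nc", "delta_npp_pct")
    ds = _read_map_nc(cdir / "delta_sst_degc.nc", "delta_sst_degc")
    db = _read_map_nc(cdir / f"{_safe(name)}_delta_b_pct.nc", "delta_b_pct")
    return ChangeMaps(grid=sst.grid, delta_npp_pct=dn, delta_b_pct=db,
                      delta_sst_degc=ds,
                      reference_window=cfg.reference_window,
                      target_window=cfg.target_window)


CODE_TABLE = {int(t): t.short_name for t in ResponseType}


def stage_classify(cfg: RunConfig, outdir: Path) -> None:
    kdir = outdir / "classify"
    kdir.mkdir(parents=True, exist_ok=True)
    year = cfg.target_window[0]
    frac_rows, r_rows = [], []
    for name in _member_names(cfg):
        maps = _load_changes(cfg, outdir, name)
        tmap = classify_map(maps)
        rfield = compute_r_map(maps)
        _write_map_nc(tmap.codes.astype(float), tmap.grid, "response_type", "",
                      year, kdir / f"{_safe(name)}_types.nc")
        _write_map_nc(rfield.r, rfield.grid, "r_ratio", "",
                      year, kdir / f"{_safe(name)}_r.nc")
        fracs = type_area_fractions(tmap, weighted=cfg.analysis.weighted)
        for t, frac in fracs.items():
            frac_rows.append({"mem": name, "esm": cfg.synthetic.esm_name,
                              "subset": "global", "response_type": t.short_name,
                              "area_fraction": frac})
        stats = mean_r_by_type(rfield, tmap, delta_npp_pct=maps.delta_npp_pct,
                               trim=cfg.analysis.trim,
                               npp_exclusion_pct=cfg.analysis.npp_exclusion_pct,
                               weighted=cfg.analysis.weighted)
        n_excluded = int(np.count_nonzero(
            tmap.grid.ocean_mask & np.isfinite(maps.delta_npp_pct)
            & (np.abs(maps.delta_npp_pct) < cfg.analysis.npp_exclusion_pct)))
        logger.info("classify[%s]: %d cells under the +-%.1f%% NPP exclusion",
                    name, n_excluded, cfg.analysis.npp_exclusion_pct)
        for t, (mean, sd, n) in stats.items():
            r_rows.append({"mem": name, "esm": cfg.synthetic.esm_name,
                           "subset": "global", "response_type": t.short_name,
                           "mean_r": mean, "sd_r": sd, "n_cells": n})
    pd.DataFrame(frac_rows).to_csv(kdir / "type_fractions.csv", index=False)
    pd.DataFrame(r_rows).to_csv(kdir / "mean_r_by_type.csv", index=False)
    with open(kdir / "code_table.json", "w") as fh:
        json.dump(CODE_TABLE, fh, indent=2, sort_keys=True)


def stage_agree(cfg: RunConfig, outdir: Path) -> None:
    kdir = outdir / "classify"
    sst, _ = _load_forcings(cfg, outdir)
    tmaps = []
    for name in _member_names(cfg):
        codes = _read_map_nc(kdir / f"{_safe(name)}_types.nc", "response_type")
        codes = np.where(np.isfinite(codes), codes, 0).astype(np.int8)
        tmaps.append(ResponseTypeMap(grid=sst.grid, codes=codes))
    agree = vote_agreement(tmaps, threshold=cfg.analysis.agreement_threshold)
    adir = outdir / "agreement"
    adir.mkdir(parents=True, exist_ok=True)
    year = cfg.target_window[0]
    _write_map_nc(agree.modal_type.astype(float), agree.grid, "modal_type", "",
                  year, adir / "agreement.nc")
    fracs = agreement_area_fractions(agree, weighted=cfg.analysis.weighted)
    rows = [{"category": (k.short_name if isinstance(k, ResponseType) else k),
             "area_fraction": v} for k, v in fracs.items()]
    pd.DataFrame(rows).to_csv(adir / "fractions.csv", index=False)


def stage_warming(cfg: RunConfig, outdir: Path) -> None:
    sst, npp = _load_forcings(cfg, outdir)
    wdir = outdir / "warming"
    wdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in _member_names(cfg):
        tcb = read_gridded_netcdf(outdir / "members" / _safe(name) / "tcb.nc", "tcb")
        member = _tcb_only_member(cfg, name, tcb)
        for direction in ("decrease", "increase"):
            curve = r_vs_warming(
                member, npp, sst,
                reference_window=cfg.reference_window,
                direction=direction,
                bin_width=cfg.analysis.sst_bin_width,
                npp_exclusion_pct=cfg.analysis.npp_exclusion_pct,
                trim=cfg.analysis.trim,
                min_count=cfg.analysis.warming_min_count,
            )
            if curve.is_empty:
                logger.info("warming[%s/%s]: %s", name, direction, curve.note)
                continue
            for i in range(curve.n_bins):
                rows.append({
                    "mem": name, "esm": cfg.synthetic.esm_name,
                    "direction": direction,
                    "bin_lo": curve.bin_lo[i], "bin_hi": curve.bin_hi[i],
                    "mean_r": curve.mean_r[i], "sd_r": curve.sd_r[i],
                    "n": int(curve.n[i]),
                })
            if curve.n_bins >= 3:
                pr, pp, sh = warming_correlation(curve)
                logger.info("warming[%s/%s]: pearson_r=%.3f p=%.2g shapiro_p=%.2g",
                            name, direction, pr, pp, sh)
    pd.DataFrame(rows).to_csv(wdir / "curves.csv", index=False)


def _tcb_only_member(cfg: RunConfig, name: str, tcb: GriddedField):
    from .grid_io import MemberOutput
    spec = next(m for m in cfg.synthetic.members if m.mem_name == name)
    return MemberOutput(mem_name=name, esm_name=cfg.synthetic.esm_name,
                        tcb=tcb, class_biomass=[], class_scheme=spec.class_scheme)


def stage_sizeclasses(cfg: RunConfig, outdir: Path) -> None:
    from .grid_io import MemberOutput, area_weighted_mean
    from .changes import relative_change_pct, window_climatology

    sst, npp = _load_forcings(cfg, outdir)
    npp_ref = window_climatology(npp, cfg.reference_window)
    npp_tgt = window_climatology(npp, cfg.target_window)
    dnpp = area_weighted_mean(relative_change_pct(npp_ref, npp_tgt), npp.grid,
                              weighted=cfg.analysis.weighted)
    rows = []
    for spec in cfg.synthetic.members:
        mdir = outdir / "members" / _safe(spec.mem_name)
        fields = []
        for i, label in enumerate(spec.class_scheme.labels):
            f = read_gridded_netcdf(mdir / f"class_{i}_{_safe(label)}.nc",
                                    f"b_{label}")
            fields.append((label, f))
        tcb = read_gridded_netcdf(mdir / "tcb.nc", "tcb")
        member = MemberOutput(mem_name=spec.mem_name,
                              esm_name=cfg.synthetic.esm_name, tcb=tcb,
                              class_biomass=fields,
                              class_scheme=spec.class_scheme)
        prof = amplification_profile(member, dnpp, cfg.reference_window,
                                     cfg.target_window,
                                     weighted=cfg.analysis.weighted)
        for label, db, r in zip(prof.class_labels, prof.delta_b_pct, prof.r):
            rows.append({"mem": spec.mem_name, "esm": cfg.synthetic.esm_name,
                         "class": label, "axis": prof.axis,
                         "delta_b_pct": db, "r": r,
                         "delta_npp_pct": dnpp, "diagnostic": prof.diagnostic})
    sdir = outdir / "sizeclass"
    sdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(sdir / "profiles.csv", index=False)


_STAGE_FUNCS = {
    "generate": stage_generate,
    "changes": stage_changes,
    "classify": stage_classify,
    "agree": stage_agree,
    "warming": stage_warming,
    "sizeclasses": stage_sizeclasses,
}


def run_stage(stage: str, cfg: RunConfig, outdir: Path) -> None:
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    try:
        _STAGE_FUNCS[stage](cfg, outdir)
    except (OSError, ValueError, KeyError) as exc:
        raise StageError(stage, str(exc)) from exc


# ---------------------------------------------------------------------------
# Manifest and full run

def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode("utf8")
    return hashlib.sha256(blob).hexdigest()


def _data_checksum(path: Path) -> str:
    """Checksum of a file's data payload (array bytes for NetCDF, raw
    bytes for text), so the manifest is independent of container-level
    NetCDF encoding details."""
    h = hashlib.sha256()
    if path.suffix == ".nc":
        import xarray as xr
        with xr.open_dataset(path, decode_times=False) as ds:
            for name in sorted(ds.variables):
                h.update(name.encode("utf8"))
                h.update(np.ascontiguousarray(ds[name].values).tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(cfg: RunConfig, outdir: Path) -> dict:
    checksums = {
        str(p.relative_to(outdir)): _data_checksum(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.suffix in (".nc", ".csv", ".json")
        and p.name != "manifest.json"
    }
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "versions": {
            "trophamp": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_ocean_cells": int(np.count_nonzero(
            generate_grid_mask(cfg))),
        "checksums": checksums,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def generate_grid_mask(cfg: RunConfig) -> np.ndarray:
    from .synthetic import build_grid
    return build_grid(cfg.synthetic).ocean_mask


def run_pipeline(cfg: RunConfig, outdir: Path | None = None) -> dict:
    """Execute every stage in order and write the run manifest."""
    outdir = Path(outdir) if outdir is not None else cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        logger.info("running stage %s", stage)
        run_stage(stage, cfg, outdir)
    return write_manifest(cfg, outdir)
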