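"""Pipeline drivers binding the analysis stages into reproducible runs.

Each run takes a configuration mapping (usually loaded from YAML),
validates every parameter block *before* any computation, executes the
stage graph and writes its artifacts plus a machine-readable provenance
record (canonical config, its hash, the seed and library versions) to the
output directory.  All randomness flows from the single config seed through
named substreams, so runs are bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import json
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import io as mio
from .emulate import EmulationParams, emulate_sted, flatten_to_plane
from .minflux import (DbscanParams, align_datasets, combine_events,
                      cross_dataset_min_distances, dbscan_filter,
                      export_sphere_model, filter_by_precision,
                      precision_summary)
from .probes import coverage_percent, designs_from_table, load_probe_table, \
    validate_design
from .sted import (build_mito_mask, cluster_ratio, count_density,
                   detect_spots, fit_spot_fwhm, min_cross_distances,
                   subtract_background)
from .synthetic import (MinfluxSceneParams, StedSceneParams,
                        generate_minflux_scene, generate_sted_scene)
from .types import SpotCallParams

PIPELINES = ("sted", "minflux", "emulate", "simulate-sted",
             "simulate-minflux", "probe")


def _canonical(config: dict) -> str:
    return json.dumps(config, sort_keys=True, default=str)


def provenance_record(config: dict) -> dict:
    import mitofish
    return {
        "config": json.loads(_canonical(config)),
        "config_sha256": hashlib.sha256(_canonical(config).encode()).hexdigest(),
        "seed": config.get("seed"),
        "versions": {
            "mitofish": mitofish.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }


def _write_provenance(config: dict, out: Path) -> None:
    mio.write_summary(provenance_record(config), out / "provenance.json")


def _summary_record(key_summaries: dict) -> dict:
    return {k: v.as_dict() for k, v in key_summaries.items()}


def run_sted(config: dict, out_dir: str | Path) -> Path:
    """Run the STED quantification pipeline on configured channel images."""
    params = SpotCallParams(**config.get("params", {}))
    images_cfg = config.get("images", [])
    if not images_cfg:
        raise ValueError("sted pipeline config needs an 'images' list")
    for entry in images_cfg:
        if not Path(entry["path"]).exists():
            raise FileNotFoundError(f"input image not found: {entry['path']}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spot_sets = {}
    bg_images = {}
    for entry in images_cfg:
        img = mio.read_image(entry["path"], pitch=config.get("pitch"),
                             channel=entry.get("channel"))
        bg = subtract_background(img, params)
        spots = detect_spots(bg, params, channel=img.channel)
        for s in spots.spots:
            s.fwhm_nm = fit_spot_fwhm(bg, s)
        spot_sets[img.channel] = spots
        bg_images[img.channel] = bg

    seeding = config.get("seeding_channels") or list(spot_sets)
    shape = next(iter(spot_sets.values())).shape
    mask = build_mito_mask([spot_sets[c] for c in seeding], shape, params)
    mio.write_mask(mask, out / "mask.tif")

    rows = []
    for ch, ss in spot_sets.items():
        for s in ss.spots:
            rows.append({"channel": ch, "x_nm": s.x_nm, "y_nm": s.y_nm,
                         "peak": s.peak_value, "fwhm_nm": s.fwhm_nm})
    pd.DataFrame(rows, columns=["channel", "x_nm", "y_nm", "peak", "fwhm_nm"]
                 ).to_csv(out / "spots.csv", index=False)

    summary: dict = {"channels": {}, "distances": {}}
    for ch, ss in spot_sets.items():
        entry = {"n_spots": len(ss)}
        if mask.area_px > 0:
            entry["density"] = count_density(ss, mask).as_dict()
        summary["channels"][ch] = entry
    ratio_cfg = config.get("ratio")  # {"mrna": ch, "mtdna": ch}
    if ratio_cfg:
        summary["ratio"] = cluster_ratio(spot_sets[ratio_cfg["mrna"]],
                                         spot_sets[ratio_cfg["mtdna"]], mask)
    pairs = config.get("distance_pairs") or list(combinations(spot_sets, 2))
    for a, b in pairs:
        if len(spot_sets[a]) and len(spot_sets[b]):
            ds = min_cross_distances(spot_sets[a], spot_sets[b])
            pd.DataFrame({"distance_nm": ds.distances}).to_csv(
                out / f"distances_{a}_{b}.csv", index=False)
            summary["distances"][f"{a}|{b}"] = ds.as_dict()
    summary["mask_area_um2"] = mask.area_um2
    mio.write_summary(summary, out / "summary.json")
    _write_provenance(config, out)
    return out


def run_minflux(config: dict, out_dir: str | Path) -> Path:
    """Run the MINFLUX localization-processing pipeline on one ROI."""
    db = DbscanParams(**config.get("dbscan", {}))
    s_r_convention = config.get("s_r_convention", "rms")
    if s_r_convention not in ("rms", "quadrature"):
        raise ValueError(f"invalid s_r_convention {s_r_convention!r}")
    raw = mio.read_localizations(config["raw"])
    beads = mio.read_beads(config["beads"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    aligned, aligned_beads, shifts = align_datasets(raw, beads)
    combined = combine_events(aligned, s_r_convention=s_r_convention)
    prec = precision_summary(combined)
    filtered = filter_by_precision(combined)
    clustered, noise = dbscan_filter(filtered, db)

    combined.to_csv(out / "combined.csv", index=False)
    filtered.to_csv(out / "filtered.csv", index=False)
    clustered.to_csv(out / "clustered.csv", index=False)
    noise.to_csv(out / "noise.csv", index=False)
    export_sphere_model(clustered, diameter=config.get("sphere_diameter", 10.0),
                        csv_path=out / "spheres.csv",
                        ply_path=out / "spheres.ply")

    summary: dict = {
        "alignment_shifts_nm": {k: list(v) for k, v in shifts.items()},
        "precision": prec.as_dict(),
        "n_combined": int(len(combined)),
        "n_filtered": int(len(filtered)),
        "n_clustered": int(len(clustered)),
        "n_noise": int(len(noise)),
        "distances": {},
    }
    if clustered["dataset_id"].nunique() >= 2:
        dists = cross_dataset_min_distances(clustered)
        for (a, b), ds in dists.items():
            pd.DataFrame({"distance_nm": ds.distances}).to_csv(
                out / f"distances_{a}_{b}.csv", index=False)
            summary["distances"][f"{a}|{b}"] = ds.as_dict()
    mio.write_summary(summary, out / "summary.json")
    _write_provenance(config, out)
    return out


def run_simulate_sted(config: dict, out_dir: str | Path) -> Path:
    params = StedSceneParams(**config.get("params", {}),
                             seed=config.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, truth = generate_sted_scene(params)
    for sp, img in images.items():
        mio.write_image(img, out / f"{sp}.tif")
    truth.save(out / "truth.json")
    _write_provenance(config, out)
    return out


def run_simulate_minflux(config: dict, out_dir: str | Path) -> Path:
    params = MinfluxSceneParams(**config.get("params", {}),
                                seed=config.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw, beads, truth = generate_minflux_scene(params)
    raw.to_csv(out / "raw.csv", index=False)
    beads.to_csv(out / "beads.csv", index=False)
    truth.save(out / "truth.json")
    _write_provenance(config, out)
    return out


def run_emulate(config: dict, out_dir: str | Path) -> Path:
    p = EmulationParams(target_fwhm=config.get("fwhm", 40.0),
                        pitch=config.get("pitch", 20.0),
                        projection_axis=config.get("projection_axis", "z"))
    points = pd.read_csv(config["points"])
    if not {"x_nm", "y_nm"}.issubset(points.columns):
        raise ValueError(f"points file {config['points']} needs x_nm and "
                         "y_nm columns")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = emulate_sted(flatten_to_plane(points, p), p)
    mio.write_image(img, out / "emulated.tif")
    _write_provenance(config, out)
    return out


def run_probe(config: dict, out_dir: str | Path) -> Path:
    table = load_probe_table(config.get("table"))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for d in designs_from_table(table):
        rep = validate_design(d)
        rows.append({"transcript": d.transcript,
                     "length_nt": d.length_nt,
                     "n_pairs": d.n_pairs,
                     "covered_nt": d.covered_nt,
                     "coverage_percent": coverage_percent(d),
                     "mean_footprint_nt": rep.mean_footprint_nt,
                     "valid": rep.valid,
                     "violations": "; ".join(rep.violations)})
    pd.DataFrame(rows).to_csv(out / "probe_coverage.csv", index=False)
    _write_provenance(config, out)
    return out


_RUNNERS = {
    "sted": run_sted,
    "minflux": run_minflux,
    "emulate": run_emulate,
    "simulate-sted": run_simulate_sted,
    "simulate-minflux": run_simulate_minflux,
    "probe": run_probe,
}


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Dispatch a configured pipeline run; validates before executing."""
    name = config.get("pipeline")
    if name not in _RUNNERS:
        raise ValueError(f"unknown pipeline {name!r}; expected one of {PIPELINES}")
    try:
        return _RUNNERS[name](config, out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline {name!r} failed: {exc}") from exc
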