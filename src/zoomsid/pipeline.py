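"""End-to-end pipeline: simulate -> preprocess -> classify -> summarize.

Configuration lives in a single YAML file; every output is regenerable
from config + seed alone, and a machine-readable manifest records both.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .classify import (DEFAULT_MIN_COMMON, DEFAULT_PAIR_MODE, classify_batch)
from .errors import ConfigError
from .example_assemblage import site_specs as example_site_specs
from .panel import MarkerPanel, load_panel
from .preprocess import (DEFAULT_BASELINE_WINDOW, DEFAULT_DEISOTOPE_TOL,
                         DEFAULT_MERGE_TOL, DEFAULT_MIN_PRESENCE,
                         DEFAULT_SMOOTH_POINTS, DEFAULT_SNR, process_specimen)
from .report import (records_from_frame, overall_summary, summaries_to_frame,
                     summarize_site)
from .simulate import DateRange, SimConfig, SiteSpec, simulate_assemblage
from .taxonomy import TaxonomyTree, load_taxonomy

log = logging.getLogger("zoomsid")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: Path = Path("zoomsid_out")
    panel_path: Path | None = None
    taxonomy_path: Path | None = None
    write_spectra: bool = False
    # preprocessing
    snr: float = DEFAULT_SNR
    baseline_window: float = DEFAULT_BASELINE_WINDOW
    smooth_points: int = DEFAULT_SMOOTH_POINTS
    deisotope_tol: float = DEFAULT_DEISOTOPE_TOL
    merge_tol: float = DEFAULT_MERGE_TOL
    min_presence: int = DEFAULT_MIN_PRESENCE
    # classification
    tol: float | None = None
    min_common: int = DEFAULT_MIN_COMMON
    pair_mode: str = DEFAULT_PAIR_MODE
    # simulation
    sim: SimConfig = field(default_factory=SimConfig)
    sites: list[SiteSpec] = field(default_factory=list)
    raw: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.snr <= 0:
            raise ConfigError("snr must be positive")
        if self.panel_path is not None and not Path(self.panel_path).exists():
            raise ConfigError(f"panel file not found: {self.panel_path}")
        if self.taxonomy_path is not None and not Path(self.taxonomy_path).exists():
            raise ConfigError(f"taxonomy file not found: {self.taxonomy_path}")


def load_config(path: str | Path) -> PipelineConfig:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text()) or {}
    cfg = PipelineConfig(raw=data)
    cfg.seed = int(data.get("seed", 0))
    cfg.out_dir = Path(data.get("out_dir", "zoomsid_out"))
    if data.get("panel"):
        cfg.panel_path = Path(data["panel"])
    if data.get("taxonomy"):
        cfg.taxonomy_path = Path(data["taxonomy"])
    cfg.write_spectra = bool(data.get("write_spectra", False))
    pp = data.get("preprocess", {}) or {}
    cfg.snr = float(pp.get("snr", cfg.snr))
    cfg.baseline_window = float(pp.get("baseline_window", cfg.baseline_window))
    cfg.smooth_points = int(pp.get("smooth_points", cfg.smooth_points))
    cfg.deisotope_tol = float(pp.get("deisotope_tol", cfg.deisotope_tol))
    cfg.merge_tol = float(pp.get("merge_tol", cfg.merge_tol))
    cfg.min_presence = int(pp.get("min_presence", cfg.min_presence))
    cl = data.get("classify", {}) or {}
    if "tol" in cl:
        cfg.tol = float(cl["tol"])
    cfg.min_common = int(cl.get("min_common", cfg.min_common))
    cfg.pair_mode = str(cl.get("pair_mode", cfg.pair_mode))
    sim = data.get("simulate", {}) or {}
    kw = {k: sim[k] for k in ("dropout_prob", "noise_sd", "peak_sigma",
                              "n_contaminants", "calib_shift",
                              "intensity_sigma") if k in sim}
    if "baseline" in sim:
        kw["baseline"] = tuple(sim["baseline"])
    cfg.sim = SimConfig(**kw)
    if sim.get("example_assemblage"):
        cfg.sites = example_site_specs(float(sim.get("scale", 1.0)))
    for s in sim.get("sites", []) or []:
        dates = tuple(
            DateRange(str(d.get("context", "C1")), int(d["start"]),
                      int(d["end"]), str(d.get("basis", "ceramic")))
            for d in s.get("dates", [{"context": "C1", "start": 601,
                                      "end": 1000}])
        )
        cfg.sites.append(SiteSpec(
            site_id=str(s["site_id"]), n_specimens=int(s["n_specimens"]),
            taxon_mix={str(k): float(v) for k, v in s["taxon_mix"].items()},
            preservation=float(s.get("preservation", 1.0)),
            date_ranges=dates,
            calib_shift=float(s.get("calib_shift", 0.0)),
        ))
    cfg.validate()
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_reference(cfg: PipelineConfig) -> tuple[MarkerPanel, TaxonomyTree]:
    return load_panel(cfg.panel_path), load_taxonomy(cfg.taxonomy_path)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute all stages in order; returns the output bundle in memory and
    writes CSV/JSON artefacts under ``cfg.out_dir``."""
    cfg.validate()
    if not cfg.sites:
        raise ConfigError("no simulation sites configured")
    panel, tree = load_reference(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulate: %d sites, seed %d", len(cfg.sites), cfg.seed)
    spectra, metadata, truth = simulate_assemblage(
        cfg.sites, panel, tree, seed=cfg.seed, base_cfg=cfg.sim,
        out_dir=out / "spectra" if cfg.write_spectra else None,
    )
    metadata.to_csv(out / "metadata.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)

    log.info("preprocess: %d specimens", len(spectra))
    peaklists = []
    for sid, reps in spectra.items():
        try:
            peaklists.append(process_specimen(
                reps, snr=cfg.snr, baseline_window=cfg.baseline_window,
                smooth_points=cfg.smooth_points,
                deisotope_tol=cfg.deisotope_tol, merge_tol=cfg.merge_tol,
                min_presence=cfg.min_presence,
            ))
        except Exception:
            log.error("preprocess failed at specimen %s", sid)
            raise
    pd.concat(
        [pl.to_frame().assign(specimen_id=pl.specimen_id) for pl in peaklists],
        ignore_index=True,
    ).to_csv(out / "peaks.csv", index=False)

    log.info("classify")
    results, clog = classify_batch(peaklists, panel, tree, tol=cfg.tol,
                                   min_common=cfg.min_common,
                                   pair_mode=cfg.pair_mode)
    (out / "classify.log").write_text("\n".join(clog) + "\n")
    pd.DataFrame([
        {
            "specimen_id": r.specimen_id, "call": r.display_call,
            "rank": r.rank, "tentative": r.tentative,
            "matched_markers": ";".join(sorted(r.matched_markers)),
            "missing_markers": ";".join(sorted(r.missing_markers)),
            "gate": "pass" if r.gate_passed else "fail",
            "gate_count": r.gate_count,
            "competing_taxa": ";".join(sorted(r.competing_taxa)),
        }
        for r in results
    ]).to_csv(out / "classifications.csv", index=False)

    log.info("summarize")
    records = records_from_frame(metadata)
    by_site: dict[str, tuple[list, list]] = {}
    for rec in records:
        by_site.setdefault(rec.site_id, ([], []))[0].append(rec)
    res_by_id = {r.specimen_id: r for r in results}
    for site_id, (recs, calls) in by_site.items():
        calls.extend(res_by_id[r.specimen_id] for r in recs)
    summaries = [
        summarize_site(recs, calls, tree)
        for recs, calls in by_site.values()
    ]
    totals = overall_summary(summaries)
    table = summaries_to_frame(summaries, totals)
    table.to_csv(out / "site_summary.csv", index=False)
    (out / "summary.json").write_text(json.dumps({
        "n_sampled": totals.n_sampled,
        "n_success": totals.n_success,
        "frac_success": totals.n_success / totals.n_sampled,
        "pct_success": totals.pct_success,
        "call_counts": dict(totals.call_counts),
        "cif_counts": dict(totals.cif_counts),
    }, indent=2))

    manifest = {
        "zoomsid_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n_sites": len(cfg.sites),
        "n_specimens": len(spectra),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "metadata": metadata, "truth": truth, "peaklists": peaklists,
        "results": results, "summaries": summaries, "totals": totals,
        "table": table, "manifest": manifest,
    }
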