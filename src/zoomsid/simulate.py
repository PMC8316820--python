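"""Seeded synthetic MALDI-ToF collagen spectra and assemblage metadata.

The generator produces what the downstream pipeline assumes real
acquisitions look like: taxon-specific marker peptides with Poisson isotope
envelopes, Gaussian peak shapes whose width grows with m/z, an exponential
chemical baseline, additive white noise, random contaminant peaks, optional
calibration drift, preservation-dependent collagen failure, and
degradation-driven marker dropout. Replicate spots of one specimen share
the specimen's marker dropout but have independent noise and contaminants,
so the triplicate consensus can separate chemistry from biology.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ZoomsError
from .panel import MarkerPanel, TaxonProfile
from .preprocess import ISOTOPE_SPACING, RawSpectrum
from .taxonomy import TaxonomyTree

MZ_MIN = 800.0
MZ_MAX = 3500.0
GRID_STEP = 0.05  # Da; resolves the ~1 Da isotope spacing
N_REPLICATES = 3

MORPH_CATEGORIES = ("exact", "group", "size_class", "mammal", "vertebrate",
                    "indeterminate")
#: probability of each morphological-identification specificity level
DEFAULT_MORPH_PROBS = (0.10, 0.55, 0.20, 0.10, 0.03, 0.02)

_SIZE_CLASS_OF = {
    "Capra hircus": "Bovid Size 2",
    "Ovis aries": "Mammal Size 2",
    "Cephalophus spp.": "Bovid Size 1-2",
    "Philantomba monticola": "Bovid Size 1-2",
    "Neotragus moschatus": "Bovid Size 1",
    "Bos spp.": "Bovid Size 2-3",
}


@dataclass(frozen=True)
class SimConfig:
    """Per-taxon simulation settings; every default is config-exposed."""

    taxon_id: str = "Capra hircus"
    n_specimens: int = 1
    dropout_prob: float = 0.05      # per marker region, models degradation
    preservation: float = 1.0       # P(specimen yields collagen at all)
    calib_shift: float = 0.0        # systematic m/z offset, Da
    peak_sigma: float = 0.15        # Gaussian sigma in Da at m/z 2000
    noise_sd: float = 0.02          # fraction of max marker peak height
    baseline: tuple[float, float, float] = (0.2, 600.0, 0.01)
    n_contaminants: int = 8         # per replicate
    isotope_model: str = "poisson"
    intensity_sigma: float = 0.3    # log-normal spread of marker amplitudes
    seed: int = 0

    def validate(self) -> None:
        for name in ("dropout_prob", "preservation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.peak_sigma <= 0:
            raise ConfigError("peak_sigma must be positive")
        if self.noise_sd < 0 or self.n_contaminants < 0:
            raise ConfigError("noise_sd and n_contaminants must be >= 0")
        if self.isotope_model != "poisson":
            raise ConfigError(f"unknown isotope_model {self.isotope_model!r}")


@dataclass(frozen=True)
class SpecimenTruth:
    specimen_id: str
    true_taxon: str
    dropped_markers: frozenset[str]
    collagen_present: bool


def mz_grid() -> np.ndarray:
    n = int(round((MZ_MAX - MZ_MIN) / GRID_STEP)) + 1
    return MZ_MIN + GRID_STEP * np.arange(n)


def _isotope_weights(mass: float, n_isotopes: int = 4) -> np.ndarray:
    """Poisson envelope, lambda = m/1800, truncated and renormalized.
    Adequate for tryptic collagen peptides of 1-3.5 kDa."""
    lam = mass / 1800.0
    k = np.arange(n_isotopes)
    w = np.exp(-lam) * lam ** k / np.array([1, 1, 2, 6], dtype=float)[:n_isotopes]
    return w / w.sum()


def _add_gaussian(grid: np.ndarray, out: np.ndarray, center: float,
                  height: float, sigma: float) -> None:
    lo = int(np.searchsorted(grid, center - 5 * sigma))
    hi = int(np.searchsorted(grid, center + 5 * sigma))
    if hi <= lo:
        return
    x = grid[lo:hi]
    out[lo:hi] += height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _specimen_dropout(profile: TaxonProfile, cfg: SimConfig,
                      rng: np.random.Generator,
                      forced: Iterable[str] | None = None) -> frozenset[str]:
    present = [mid for mid, d in profile.markers.items() if d is not None]
    dropped = {mid for mid in present if rng.random() < cfg.dropout_prob}
    if forced is not None:
        dropped |= set(forced) & set(present)
    return frozenset(dropped)


def _marker_amplitudes(profile: TaxonProfile, cfg: SimConfig,
                       rng: np.random.Generator) -> dict[float, float]:
    """Log-normal amplitude per mass; "(?)" masses somewhat weaker."""
    amps: dict[float, float] = {}
    for d in profile.markers.values():
        if d is None:
            continue
        for m, rel in zip(d.masses, d.reliable):
            base = 1.0 if rel else 0.7
            amps[m] = base * float(rng.lognormal(0.0, cfg.intensity_sigma))
    return amps


def simulate_spectrum(profile: TaxonProfile, cfg: SimConfig,
                      rng: np.random.Generator,
                      dropped_markers: frozenset[str] | None = None,
                      collagen_present: bool = True,
                      specimen_id: str = "S1",
                      replicate_id: int = 1) -> tuple[RawSpectrum, SpecimenTruth]:
    """One replicate acquisition plus its ground truth.

    ``dropped_markers`` may be supplied to share a dropout draw across the
    replicates of one specimen (or to force a specific loss, e.g. the
    COL1a2 757-789 region); if None a fresh draw is made.
    """
    cfg.validate()
    if not any(d is not None for d in profile.markers.values()):
        raise ZoomsError(f"profile {profile.taxon_id!r} has no markers")
    grid = mz_grid()
    out = np.zeros_like(grid)
    if dropped_markers is None:
        dropped_markers = _specimen_dropout(profile, cfg, rng)
    max_marker_height = 0.0
    if collagen_present:
        amps = _marker_amplitudes(profile, cfg, rng)
        for mid, d in profile.markers.items():
            if d is None or mid in dropped_markers:
                continue
            for mass in d.masses:
                amp = amps[mass]
                sigma = cfg.peak_sigma * mass / 2000.0
                for k, w in enumerate(_isotope_weights(mass)):
                    h = amp * w
                    max_marker_height = max(max_marker_height, h)
                    _add_gaussian(grid, out,
                                  mass + k * ISOTOPE_SPACING + cfg.calib_shift,
                                  h, sigma)
    scale = max_marker_height if max_marker_height > 0 else 1.0
    # contaminants: non-marker peptide-like peaks, independent per replicate
    for _ in range(cfg.n_contaminants):
        center = float(rng.uniform(MZ_MIN + 20, MZ_MAX - 20))
        h = 0.5 * scale * float(rng.lognormal(-0.7, 0.6))
        _add_gaussian(grid, out, center, h, cfg.peak_sigma * center / 2000.0)
    amp_b, decay, offset = cfg.baseline
    if amp_b or offset:
        out += scale * (amp_b * np.exp(-(grid - MZ_MIN) / decay) + offset)
    if cfg.noise_sd > 0:
        out += rng.normal(0.0, cfg.noise_sd * scale, grid.size)
    np.clip(out, 0.0, None, out=out)
    truth = SpecimenTruth(specimen_id=specimen_id,
                          true_taxon=profile.taxon_id,
                          dropped_markers=dropped_markers,
                          collagen_present=collagen_present)
    return RawSpectrum(grid, out, specimen_id=specimen_id,
                       replicate_id=replicate_id), truth


def simulate_specimen(profile: TaxonProfile, cfg: SimConfig,
                      rng: np.random.Generator,
                      specimen_id: str = "S1",
                      forced_dropout: Iterable[str] | None = None,
                      collagen_present: bool | None = None,
                      ) -> tuple[list[RawSpectrum], SpecimenTruth]:
    """Triplicate spots for one extract: shared dropout, independent
    noise/contaminants."""
    cfg.validate()
    if collagen_present is None:
        collagen_present = bool(rng.random() < cfg.preservation)
    dropped = _specimen_dropout(profile, cfg, rng, forced=forced_dropout)
    reps = []
    truth = None
    for r in range(1, N_REPLICATES + 1):
        s, truth = simulate_spectrum(
            profile, cfg, rng, dropped_markers=dropped,
            collagen_present=collagen_present,
            specimen_id=specimen_id, replicate_id=r,
        )
        reps.append(s)
    assert truth is not None
    return reps, truth


# ---------------------------------------------------------------------------
# assemblage-level simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DateRange:
    context_id: str
    start_ce: int
    end_ce: int
    basis: str = "ceramic"  # or "radiocarbon"

    def __post_init__(self) -> None:
        if self.start_ce > self.end_ce:
            raise ConfigError(
                f"{self.context_id}: date_start_CE must be <= date_end_CE"
            )
        if self.basis not in ("radiocarbon", "ceramic"):
            raise ConfigError(f"{self.context_id}: bad date basis {self.basis!r}")


@dataclass(frozen=True)
class SiteSpec:
    """Study conditions for one site."""

    site_id: str
    n_specimens: int
    taxon_mix: dict[str, float]
    preservation: float = 1.0
    date_ranges: tuple[DateRange, ...] = (DateRange("C1", 601, 1000),)
    calib_shift: float = 0.0
    morph_probs: tuple[float, ...] = DEFAULT_MORPH_PROBS

    def validate(self) -> None:
        tot = sum(self.taxon_mix.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigError(
                f"{self.site_id}: taxon_mix proportions sum to {tot}, not 1"
            )
        if not 0.0 <= self.preservation <= 1.0:
            raise ConfigError(f"{self.site_id}: preservation not in [0, 1]")
        if not self.date_ranges:
            raise ConfigError(f"{self.site_id}: at least one date range needed")


def _draw_morph(true_taxon: str, tree: TaxonomyTree, probs: Sequence[float],
                rng: np.random.Generator) -> str:
    """Morphological ID: the true taxon, or a coarser ancestor/size class."""
    level = MORPH_CATEGORIES[
        int(rng.choice(len(MORPH_CATEGORIES), p=np.asarray(probs) / sum(probs)))
    ]
    node = tree.resolve(true_taxon)
    if level == "exact":
        return node
    if level == "group":
        parent = tree.parent.get(node, "Vertebrata")
        return tree.display_name(parent)
    if level == "size_class":
        sc = _SIZE_CLASS_OF.get(node)
        return sc if sc is not None else "mammal"
    if level == "mammal":
        return "mammal" if "Mammalia" in tree.ancestors(node) else "vertebrate"
    if level == "vertebrate":
        return "vertebrate"
    return "indeterminate"


def simulate_assemblage(site_specs: Sequence[SiteSpec], panel: MarkerPanel,
                        tree: TaxonomyTree, seed: int,
                        base_cfg: SimConfig | None = None,
                        out_dir: str | Path | None = None,
                        ) -> tuple[dict[str, list[RawSpectrum]],
                                   pd.DataFrame, pd.DataFrame]:
    """Simulate every specimen of a multi-site assemblage.

    Returns (replicate spectra per specimen, specimen metadata table, truth
    table). If ``out_dir`` is given, also writes ``{specimen}_{1..3}.xy``
    spectrum files plus ``metadata.csv`` and ``truth.csv``.
    """
    if base_cfg is None:
        base_cfg = SimConfig()
    rng = np.random.default_rng(seed)
    spectra: dict[str, list[RawSpectrum]] = {}
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    protocols = ("acid_insoluble", "acid_soluble", "lyophilized")
    for spec in site_specs:
        spec.validate()
        taxa = sorted(spec.taxon_mix)
        probs = np.array([spec.taxon_mix[t] for t in taxa])
        counts = rng.multinomial(spec.n_specimens, probs)
        k = 0
        for taxon, n in zip(taxa, counts):
            profile = panel.profile(taxon)
            for _ in range(n):
                k += 1
                sid = f"{spec.site_id}-{k:04d}"
                cfg = replace(base_cfg, taxon_id=taxon,
                              preservation=spec.preservation,
                              calib_shift=spec.calib_shift)
                reps, truth = simulate_specimen(profile, cfg, rng,
                                                specimen_id=sid)
                spectra[sid] = reps
                dr = spec.date_ranges[int(rng.choice(len(spec.date_ranges)))]
                meta_rows.append({
                    "specimen_id": sid,
                    "site_id": spec.site_id,
                    "context_id": dr.context_id,
                    "morph_id": _draw_morph(taxon, tree, spec.morph_probs, rng),
                    "date_start_CE": dr.start_ce,
                    "date_end_CE": dr.end_ce,
                    "date_basis": dr.basis,
                    "protocol": protocols[int(rng.choice(3, p=[0.85, 0.1, 0.05]))],
                })
                truth_rows.append({
                    "specimen_id": sid,
                    "true_taxon": truth.true_taxon,
                    "dropped_markers": ";".join(sorted(truth.dropped_markers)),
                    "collagen_present": truth.collagen_present,
                })
    # specimen order within a site is multinomial-grouped by taxon; shuffle
    # rows so site files do not leak the truth through ordering
    metadata = pd.DataFrame(meta_rows)
    truth_df = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, reps in spectra.items():
            for s in reps:
                s.write_xy(out / f"{sid}_{s.replicate_id}.xy")
        metadata.to_csv(out / "metadata.csv", index=False)
        truth_df.to_csv(out / "truth.csv", index=False)
    return spectra, metadata, truth_df


def stable_seed(seed: int, *labels: str) -> int:
    """Derive a sub-seed (< 2**31) deterministically from labels."""
    h = hashlib.sha256(("|".join(map(str, (seed,) + labels))).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2 ** 31)
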