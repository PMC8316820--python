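"""Taxonomic assignment of specimen peak lists against the marker panel.

Decision rules, in order:

1. *Collagen gate* — too few of the panel-wide common collagen masses
   means the extraction failed: call ``"failed"``.
2. *Candidates* — taxa with at least one reliable marker mass matched and
   no matched peak that belongs exclusively to other taxa. Absence of a
   marker never contradicts a candidate (degraded collagen loses peaks);
   only observed peaks exclude. A peak matching any of a taxon's masses —
   including "(?)" masses — is compatible with that taxon, but "(?)"
   masses never count as supporting evidence.
3. *Species call* — a single surviving candidate whose reliable,
   applicable markers are all matched (for hydroxylation pairs, both
   masses when ``pair_mode="both"``).
4. *Group fallback* — several surviving candidates that differ only at
   markers missing from the peak list collapse to their lowest common
   group. With sheep and goat this reproduces the classic rule: peaks
   missing at COL1a2 757-789 demote the call to "caprine".
5. Anything else above the gate is ``"unknown"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import SpectrumError, ZoomsError
from .panel import MarkerPanel
from .preprocess import PeakList
from .taxonomy import TaxonomyTree, lowest_common_group

MATCHED = "matched"
MISSING = "missing"
NOT_APPLICABLE = "not_applicable"

DEFAULT_MIN_COMMON = 4
DEFAULT_PAIR_MODE = "both"


@dataclass(frozen=True)
class MassMatch:
    panel_mass: float
    peak_mz: float
    deviation: float  # observed - panel


@dataclass(frozen=True)
class MarkerMatch:
    """Per (taxon, marker-region) evidence."""

    status: str  # MATCHED / MISSING / NOT_APPLICABLE
    matches: tuple[MassMatch, ...] = ()
    missing_masses: tuple[float, ...] = ()


@dataclass(frozen=True)
class MatchTable:
    """Evidence grid: (taxon, marker) -> MarkerMatch."""

    entries: dict[tuple[str, str], MarkerMatch]
    tol: float

    def status(self, taxon: str, marker: str) -> str:
        return self.entries[(taxon, marker)].status

    def matched_markers(self, taxon: str) -> set[str]:
        return {m for (t, m), e in self.entries.items()
                if t == taxon and e.status == MATCHED}

    def missing_markers(self, taxon: str) -> set[str]:
        return {m for (t, m), e in self.entries.items()
                if t == taxon and e.status == MISSING}

    def is_complete(self, taxon: str) -> bool:
        return not self.missing_markers(taxon)

    def matched_mass_count(self, taxon: str) -> int:
        return sum(
            len(e.matches) for (t, _), e in self.entries.items() if t == taxon
        )


def _nearest_peak(peaks: np.ndarray, mass: float, tol: float) -> float | None:
    if peaks.size == 0:
        return None
    i = int(np.searchsorted(peaks, mass))
    best = None
    for j in (i - 1, i):
        if 0 <= j < peaks.size and abs(peaks[j] - mass) <= tol:
            if best is None or abs(peaks[j] - mass) < abs(best - mass):
                best = float(peaks[j])
    return best


def match_markers(p: PeakList, panel: MarkerPanel, tol: float | None = None,
                  pair_mode: str = DEFAULT_PAIR_MODE) -> MatchTable:
    """Match each reliable panel mass to the nearest peak within ``tol``.

    A marker region with no reliable masses (ABSENT, or all masses "(?)")
    is ``not_applicable`` and never creates matched/missing states. With
    ``pair_mode="both"`` every reliable mass of a region must be matched
    for the region to count as matched; ``"any"`` requires one.
    """
    if tol is None:
        tol = panel.mass_tolerance_default
    if tol <= 0:
        raise SpectrumError("matching tolerance must be positive")
    if pair_mode not in ("both", "any"):
        raise ZoomsError(f"pair_mode must be 'both' or 'any', got {pair_mode!r}")
    peaks = np.asarray(p.mz, dtype=float)
    entries: dict[tuple[str, str], MarkerMatch] = {}
    for prof in panel.profiles:
        for mid in panel.marker_vocabulary:
            mdef = prof.marker(mid)
            rel = mdef.reliable_masses if mdef is not None else ()
            if not rel:
                entries[(prof.taxon_id, mid)] = MarkerMatch(NOT_APPLICABLE)
                continue
            hits: list[MassMatch] = []
            missing: list[float] = []
            for mass in rel:
                mz = _nearest_peak(peaks, mass, tol)
                if mz is None:
                    missing.append(mass)
                else:
                    hits.append(MassMatch(mass, mz, mz - mass))
            ok = (not missing) if pair_mode == "both" else bool(hits)
            entries[(prof.taxon_id, mid)] = MarkerMatch(
                MATCHED if ok else MISSING,
                matches=tuple(hits),
                missing_masses=tuple(missing),
            )
    return MatchTable(entries=entries, tol=tol)


@dataclass(frozen=True)
class GateResult:
    passed: bool
    count: int
    matched_masses: tuple[float, ...]


def collagen_gate(p: PeakList, panel: MarkerPanel,
                  min_common: int = DEFAULT_MIN_COMMON,
                  tol: float | None = None) -> GateResult:
    """Collagen-success screen: enough of the masses shared across most of
    the panel (the common collagen peptides) must be present."""
    if tol is None:
        tol = panel.mass_tolerance_default
    peaks = np.asarray(p.mz, dtype=float)
    hit = tuple(
        m for m in panel.common_masses if _nearest_peak(peaks, m, tol) is not None
    )
    return GateResult(passed=len(hit) >= min_common, count=len(hit),
                      matched_masses=hit)


@dataclass(frozen=True)
class ClassificationResult:
    specimen_id: str
    call: str                      # taxon/group node, "unknown" or "failed"
    rank: str                      # species|genus|subfamily|...|none
    tentative: bool = False
    matched_markers: frozenset[str] = field(default_factory=frozenset)
    missing_markers: frozenset[str] = field(default_factory=frozenset)
    gate_passed: bool = False
    gate_count: int = 0
    competing_taxa: frozenset[str] = field(default_factory=frozenset)

    @property
    def display_call(self) -> str:
        return f"cf. {self.call}" if self.tentative else self.call

    @property
    def failed(self) -> bool:
        return self.call == "failed"


def _peak_compatible_taxa(p: PeakList, panel: MarkerPanel,
                          tol: float) -> list[tuple[float, frozenset[str]]]:
    """For each peak matching any panel mass: the set of taxa having *any*
    mass (reliable or not) within tol. Peaks matching nothing are
    contaminants/unknowns and constrain no taxon.

    Only peaks reproduced in every replicate spot of the specimen are
    eligible to *exclude* a taxon: spot-specific chemistry (contaminants,
    borderline noise) must not veto an otherwise consistent profile. A
    peak list built without replicate information carries
    n_replicates_present = 1 throughout and is unaffected.
    """
    nrep = p.n_replicates_present
    full = int(nrep.max()) if nrep.size else 1
    out = []
    for mz, n in zip(np.asarray(p.mz, dtype=float), nrep):
        if int(n) < full:
            continue
        owners = frozenset(
            prof.taxon_id
            for prof in panel.profiles
            if any(abs(m - mz) <= tol for m in prof.all_masses())
        )
        if owners:
            out.append((float(mz), owners))
    return out


def classify(p: PeakList, panel: MarkerPanel, tree: TaxonomyTree,
             tol: float | None = None,
             min_common: int = DEFAULT_MIN_COMMON,
             pair_mode: str = DEFAULT_PAIR_MODE) -> ClassificationResult:
    """Assign the most specific defensible taxon to one specimen."""
    if not panel.profiles:
        raise ZoomsError("empty panel")
    if tol is None:
        tol = panel.mass_tolerance_default
    gate = collagen_gate(p, panel, min_common=min_common, tol=tol)
    if not gate.passed:
        return ClassificationResult(
            specimen_id=p.specimen_id, call="failed", rank="none",
            gate_passed=False, gate_count=gate.count,
        )
    table = match_markers(p, panel, tol=tol, pair_mode=pair_mode)
    owned = _peak_compatible_taxa(p, panel, tol)

    def excluded(taxon: str) -> bool:
        return any(taxon not in owners for _, owners in owned)

    survivors = [
        prof for prof in panel.profiles
        if table.matched_mass_count(prof.taxon_id) > 0
        and not excluded(prof.taxon_id)
    ]
    complete = [prof for prof in survivors if table.is_complete(prof.taxon_id)]
    complete_any = {
        prof.taxon_id for prof in panel.profiles
        if table.is_complete(prof.taxon_id)
        and table.matched_mass_count(prof.taxon_id) > 0
    }

    def result(call: str, rank: str, tentative: bool,
               evidence_taxon: str | None,
               competing: Iterable[str]) -> ClassificationResult:
        matched = (
            table.matched_markers(evidence_taxon) if evidence_taxon else set()
        )
        missing = (
            table.missing_markers(evidence_taxon) if evidence_taxon else set()
        )
        return ClassificationResult(
            specimen_id=p.specimen_id, call=call, rank=rank,
            tentative=tentative, matched_markers=frozenset(matched),
            missing_markers=frozenset(missing), gate_passed=True,
            gate_count=gate.count, competing_taxa=frozenset(competing),
        )

    if not survivors:
        return result("unknown", "none", False, None, complete_any)

    if len(survivors) == 1:
        prof = survivors[0]
        if table.is_complete(prof.taxon_id):
            node = tree.resolve(prof.taxon_id)
            return result(tree.display_name(node), tree.rank[node],
                          prof.tentative, prof.taxon_id, ())
        # unique survivor but the species bar is not met: report the
        # containing group rather than an unsupported species call
        node = tree.parent[tree.resolve(prof.taxon_id)]
        return result(tree.display_name(node), tree.rank[node], False,
                      prof.taxon_id, {prof.taxon_id})

    if len(complete) >= 2:
        # two internally complete profiles that cannot exclude each other:
        # most plausibly a mixed-collagen spot; refuse a call
        return result("unknown", "none", False, None,
                      {prof.taxon_id for prof in complete})

    names = [prof.taxon_id for prof in survivors]
    node = lowest_common_group(names, tree)
    return result(tree.display_name(node), tree.rank[node], False, None, names)


def classify_batch(specimens: Sequence[PeakList], panel: MarkerPanel,
                   tree: TaxonomyTree, tol: float | None = None,
                   min_common: int = DEFAULT_MIN_COMMON,
                   pair_mode: str = DEFAULT_PAIR_MODE,
                   ) -> tuple[list[ClassificationResult], list[str]]:
    """Classify many specimens; order-independent, with a per-specimen log."""
    ids = [p.specimen_id for p in specimens]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ZoomsError(f"duplicate specimen_ids: {sorted(dupes)}")
    results: list[ClassificationResult] = []
    log: list[str] = []
    for p in specimens:
        r = classify(p, panel, tree, tol=tol, min_common=min_common,
                     pair_mode=pair_mode)
        results.append(r)
        log.append(
            f"{r.specimen_id}: peaks={len(p)} gate="
            f"{'pass' if r.gate_passed else 'fail'}({r.gate_count}) "
            f"matched={len(r.matched_markers)} call={r.display_call}"
        )
    return results, log
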