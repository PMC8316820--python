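"""Site- and assemblage-level summaries of specimen classifications.

Aggregates specimen calls with excavation metadata into the tabular form
zooarchaeological ZooMS surveys publish: sampled N and collagen success
percentage per site, counts per taxon call, a per-specimen comparison code
against the prior morphological identification (C confirmed / I improved /
F failed through unsuccessful extraction / X otherwise), and the earliest
associated date range per taxon of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import ClassificationResult
from .errors import ZoomsError
from .taxonomy import TaxonomyTree

C, I, F, X = "C", "I", "F", "X"

DEFAULT_DATE_TAXA = ("Capra hircus", "Ovis aries", "caprine")


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    site_id: str
    context_id: str
    morph_id: str
    date_start_ce: int
    date_end_ce: int
    date_basis: str = "ceramic"
    protocol: str = "acid_insoluble"

    def __post_init__(self) -> None:
        if self.date_start_ce > self.date_end_ce:
            raise ZoomsError(
                f"{self.specimen_id}: date_start_CE > date_end_CE"
            )


def records_from_frame(df: pd.DataFrame) -> list[SpecimenRecord]:
    """Build records from a metadata table (columns as written by
    :func:`zoomsid.simulate.simulate_assemblage`)."""
    return [
        SpecimenRecord(
            specimen_id=str(r.specimen_id), site_id=str(r.site_id),
            context_id=str(r.context_id), morph_id=str(r.morph_id),
            date_start_ce=int(r.date_start_CE), date_end_ce=int(r.date_end_CE),
            date_basis=str(r.date_basis), protocol=str(r.protocol),
        )
        for r in df.itertuples()
    ]


def compare_to_morphology(call: ClassificationResult, morph_id: str,
                          tree: TaxonomyTree) -> str:
    """Comparison code for one specimen.

    F: extraction failed. C: ZooMS matches the morphological ID (same node,
    or a coarser call consistent with it). I: ZooMS strictly refines the
    morphological ID (proper descent, or a taxon within a morphological
    size class's membership). X: anything else — contradictions, and
    "unknown" calls that cannot be compared.
    """
    morph = tree.resolve(morph_id)  # raises on unknown vocabulary
    if call.failed:
        return F
    if call.call == "unknown":
        return X
    node = tree.resolve(call.call)
    if node == morph:
        return C
    if tree.is_strict_descendant(node, morph):
        return I
    if morph in tree.membership:
        if tree.leaf_taxa(node) <= tree.membership[morph]:
            return I
    if tree.is_strict_descendant(morph, node):
        return C  # coarser than, but consistent with, the morphological ID
    if morph in tree.membership and tree.membership[morph] <= tree.leaf_taxa(node):
        return C
    return X


@dataclass(frozen=True)
class SiteSummary:
    site_id: str
    n_sampled: int
    n_success: int
    call_counts: Mapping[str, int]
    cif_counts: Mapping[str, int]
    earliest_dates: Mapping[str, tuple[int, int, str]] = field(
        default_factory=dict
    )

    @property
    def pct_success(self) -> int:
        return round(100 * self.n_success / self.n_sampled)

    @property
    def frac_success(self) -> float:
        return self.n_success / self.n_sampled


def _pair(records: Sequence[SpecimenRecord],
          calls: Sequence[ClassificationResult],
          ) -> list[tuple[SpecimenRecord, ClassificationResult]]:
    by_id = {r.specimen_id: r for r in records}
    out = []
    for c in calls:
        if c.specimen_id not in by_id:
            raise ZoomsError(f"call for {c.specimen_id!r} has no metadata record")
        out.append((by_id[c.specimen_id], c))
    return out


def earliest_association(records: Sequence[SpecimenRecord],
                         calls: Sequence[ClassificationResult],
                         taxon: str, tree: TaxonomyTree,
                         ) -> tuple[int, int, str] | None:
    """Earliest date range among specimens called as ``taxon`` or one of
    its descendants: smallest start year, ties broken by smaller end year,
    then radiocarbon preferred over ceramic."""
    target = tree.resolve(taxon)
    basis_pref = {"radiocarbon": 0, "ceramic": 1}
    best: tuple[int, int, int] | None = None
    best_out: tuple[int, int, str] | None = None
    for rec, call in _pair(records, calls):
        if call.failed or call.call == "unknown":
            continue
        node = tree.resolve(call.call)
        if node != target and not tree.is_strict_descendant(node, target):
            continue
        key = (rec.date_start_ce, rec.date_end_ce,
               basis_pref.get(rec.date_basis, 2))
        if best is None or key < best:
            best = key
            best_out = (rec.date_start_ce, rec.date_end_ce, rec.date_basis)
    return best_out


def summarize_site(records: Sequence[SpecimenRecord],
                   calls: Sequence[ClassificationResult],
                   tree: TaxonomyTree,
                   date_taxa: Iterable[str] = DEFAULT_DATE_TAXA,
                   ) -> SiteSummary:
    """Tallies for one site's specimens."""
    pairs = _pair(records, calls)
    if not pairs:
        raise ZoomsError("empty site: no specimens to summarize")
    sites = {r.site_id for r, _ in pairs}
    if len(sites) > 1:
        raise ZoomsError(f"records span several sites: {sorted(sites)}")
    n = len(pairs)
    n_success = sum(1 for _, c in pairs if not c.failed)
    call_counts: dict[str, int] = {}
    cif: dict[str, int] = {C: 0, I: 0, F: 0, X: 0}
    for rec, call in pairs:
        if not call.failed:
            key = call.display_call
            call_counts[key] = call_counts.get(key, 0) + 1
        cif[compare_to_morphology(call, rec.morph_id, tree)] += 1
    earliest: dict[str, tuple[int, int, str]] = {}
    for taxon in date_taxa:
        hit = earliest_association(records, calls, taxon, tree)
        if hit is not None:
            earliest[taxon] = hit
    return SiteSummary(site_id=sites.pop(), n_sampled=n, n_success=n_success,
                       call_counts=call_counts, cif_counts=cif,
                       earliest_dates=earliest)


def earliest_secure_occurrence(site_summaries: Sequence[SiteSummary],
                               taxon: str,
                               ) -> tuple[str, int, int, str] | None:
    """Cross-site earliest *securely dated* occurrence of a taxon.

    Per-site earliest dates (see :func:`earliest_association`) can be wide,
    low-resolution brackets; for the assemblage-wide chronology the useful
    quantity is the occurrence with the earliest terminus ante quem:
    radiocarbon-based associations are preferred over ceramic ones, ranked
    by interval end (the date by which the taxon is securely present),
    ties by interval start. Returns (site_id, start, end, basis) or None.
    """
    cands = [
        (s.site_id, *s.earliest_dates[taxon])
        for s in site_summaries
        if taxon in s.earliest_dates
    ]
    if not cands:
        return None
    radio = [c for c in cands if c[3] == "radiocarbon"]
    pool = radio if radio else cands
    return min(pool, key=lambda c: (c[2], c[1]))


@dataclass(frozen=True)
class OverallSummary:
    n_sampled: int
    n_success: int
    call_counts: Mapping[str, int]
    cif_counts: Mapping[str, int]

    @property
    def pct_success(self) -> int:
        return round(100 * self.n_success / self.n_sampled)

    def call_share_pct(self, call: str) -> int:
        """Share of successful specimens given to one call, as printed
        (rounded to the nearest integer percent)."""
        return round(100 * self.call_counts.get(call, 0) / self.n_success)

    def call_share(self, call: str) -> float:
        return self.call_counts.get(call, 0) / self.n_success


def overall_summary(site_summaries: Sequence[SiteSummary]) -> OverallSummary:
    """Totals row over sites; invariant to site order and partitioning."""
    if not site_summaries:
        raise ZoomsError("no site summaries")
    n = sum(s.n_sampled for s in site_summaries)
    ns = sum(s.n_success for s in site_summaries)
    calls: dict[str, int] = {}
    cif: dict[str, int] = {C: 0, I: 0, F: 0, X: 0}
    for s in site_summaries:
        for k, v in s.call_counts.items():
            calls[k] = calls.get(k, 0) + v
        for k, v in s.cif_counts.items():
            cif[k] = cif.get(k, 0) + v
    return OverallSummary(n_sampled=n, n_success=ns, call_counts=calls,
                          cif_counts=cif)


def summaries_to_frame(site_summaries: Sequence[SiteSummary],
                       totals: OverallSummary | None = None) -> pd.DataFrame:
    """Per-site CSV-ready table with an optional totals row."""
    all_calls = sorted({c for s in site_summaries for c in s.call_counts})
    rows = []
    for s in site_summaries:
        row: dict = {
            "site_id": s.site_id,
            "n_sampled": s.n_sampled,
            "n_success": s.n_success,
            "pct_success": s.pct_success,
            **{f"n_{c}": s.call_counts.get(c, 0) for c in all_calls},
            **{f"cif_{k}": s.cif_counts.get(k, 0) for k in (C, I, F, X)},
        }
        for taxon, (a, b, basis) in s.earliest_dates.items():
            row[f"earliest_{taxon}"] = f"{a}-{b} CE ({basis})"
        rows.append(row)
    if totals is not None:
        rows.append({
            "site_id": "TOTAL",
            "n_sampled": totals.n_sampled,
            "n_success": totals.n_success,
            "pct_success": totals.pct_success,
            **{f"n_{c}": totals.call_counts.get(c, 0) for c in all_calls},
            **{f"cif_{k}": totals.cif_counts.get(k, 0) for k in (C, I, F, X)},
        })
    return pd.DataFrame(rows)
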