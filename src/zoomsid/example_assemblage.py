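"""Packaged example assemblage: an eight-site Iron Age caprine survey of
the Zanzibar, Mafia and Comoros archipelagos.

Two things live here. ``REFERENCE_TALLIES`` are fixed per-site specimen
tallies (sampled N, per-call counts, morphological priors, associated date
ranges) with the structure and arithmetic of a published island eastern
Africa ZooMS survey: 394 sampled specimens of which 318 yielded collagen
(81%), goat dominating the identifications (259/318), a handful of sheep
(11/318), a best site at 242/244 (99%) and a worst at 4/65 (6%).
``site_specs()`` turns the same structure into generative study conditions
for :func:`zoomsid.simulate.simulate_assemblage`, using each site's success
rate as its preservation probability.

These tallies are *inputs* (they describe the survey the package models);
every percentage reported by the package is recomputed from them by the
reporting stage at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import ClassificationResult
from .report import SpecimenRecord
from .simulate import DateRange, SiteSpec
from .taxonomy import TaxonomyTree


@dataclass(frozen=True)
class SiteTally:
    site_id: str
    n_sampled: int
    # successful calls per taxon (display name); failures are the rest
    calls: tuple[tuple[str, int], ...]
    dates: tuple[DateRange, ...]


REFERENCE_TALLIES: tuple[SiteTally, ...] = (
    SiteTally("PK", 11,
              (("Capra hircus", 3), ("Neotragus moschatus", 7), ("Bos spp.", 1)),
              (DateRange("PK-1", 1020, 1150, "radiocarbon"),)),
    SiteTally("FK", 8,
              (("Capra hircus", 1), ("Neotragus moschatus", 3),
               ("cf. Philantomba monticola", 4)),
              (DateRange("FK-1", 601, 900, "ceramic"),)),
    SiteTally("UU", 244,
              (("Capra hircus", 215), ("Ovis aries", 9), ("caprine", 4),
               ("Neotragus moschatus", 5), ("Cephalophus spp.", 4),
               ("Cercopithecinae", 2), ("Suidae", 1), ("unknown", 2)),
              (DateRange("UU-T11", 655, 710, "radiocarbon"),
               DateRange("UU-T14", 670, 770, "radiocarbon"),
               DateRange("UU-S", 685, 855, "radiocarbon"))),
    SiteTally("KC", 8, (("Capra hircus", 1),),
              (DateRange("KC-1", 530, 1475, "radiocarbon"),)),
    SiteTally("JS", 65,
              (("Cephalophus spp.", 2), ("cf. Philantomba monticola", 1),
               ("Neotragus moschatus", 1)),
              (DateRange("JS-1", 301, 650, "ceramic"),)),
    SiteTally("PU", 2, (("Capra hircus", 2),),
              (DateRange("PU-1", 601, 700, "ceramic"),)),
    SiteTally("MMB", 45,
              (("Capra hircus", 33), ("Ovis aries", 1), ("caprine", 2),
               ("Bos spp.", 3), ("Felidae", 1), ("Neotragus moschatus", 4)),
              (DateRange("MMB-1", 701, 900, "ceramic"),)),
    SiteTally("SMA", 11,
              (("Capra hircus", 4), ("Ovis aries", 1), ("Cephalophus spp.", 1)),
              (DateRange("SMA-1", 701, 800, "ceramic"),)),
)


def reference_records_and_calls(tree: TaxonomyTree,
                                ) -> tuple[list[SpecimenRecord],
                                           list[ClassificationResult]]:
    """Expand the per-site tallies into specimen-level records and calls so
    the reporting stage can recompute every published percentage."""
    # morphological prior typical for each kind of call: most caprine-line
    # specimens entered the survey as morphological "caprine", wild bovids
    # as size classes, the rest as "mammal"
    morph_for = {
        "Capra hircus": "caprine", "Ovis aries": "caprine",
        "caprine": "caprine",
        "Neotragus moschatus": "Bovid Size 1",
        "Cephalophus spp.": "Bovid Size 1-2",
        "cf. Philantomba monticola": "Bovid Size 1-2",
    }
    records: list[SpecimenRecord] = []
    calls: list[ClassificationResult] = []
    for site in REFERENCE_TALLIES:
        k = 0
        n_success = sum(n for _, n in site.calls)
        for call_name, n in site.calls + (("failed", site.n_sampled - n_success),):
            for _ in range(n):
                k += 1
                sid = f"{site.site_id}-{k:04d}"
                # earliest-context dates attach to the caprine calls, as in
                # the survey's earliest-occurrence chronology
                if call_name == "Capra hircus":
                    dr = site.dates[0]
                elif call_name == "Ovis aries":
                    dr = site.dates[-1]
                else:
                    dr = site.dates[min(1, len(site.dates) - 1)]
                records.append(SpecimenRecord(
                    specimen_id=sid, site_id=site.site_id,
                    context_id=dr.context_id,
                    morph_id=morph_for.get(call_name, "mammal"),
                    date_start_ce=dr.start_ce, date_end_ce=dr.end_ce,
                    date_basis=dr.basis,
                ))
                failed = call_name == "failed"
                tentative = call_name.startswith("cf. ")
                clean = call_name[4:] if tentative else call_name
                if failed or clean == "unknown":
                    rank = "none"
                else:
                    rank = tree.rank[tree.resolve(clean)]
                calls.append(ClassificationResult(
                    specimen_id=sid, call=clean, rank=rank, tentative=tentative,
                    gate_passed=not failed, gate_count=0 if failed else 8,
                ))
    return records, calls


def site_specs(scale: float = 1.0) -> list[SiteSpec]:
    """Generative study conditions mirroring the reference tallies.

    Each site's taxon mix follows its successful-call composition (group
    calls folded into goat, unknowns into the most common wild taxon) and
    its preservation equals its success rate. ``scale`` shrinks specimen
    counts proportionally (minimum 2 per site) for quick runs.
    """
    fold = {"caprine": "Capra hircus", "unknown": "Neotragus moschatus"}
    specs = []
    for site in REFERENCE_TALLIES:
        n_success = sum(n for _, n in site.calls)
        mix: dict[str, float] = {}
        for name, n in site.calls:
            clean = name[4:] if name.startswith("cf. ") else name
            clean = fold.get(clean, clean)
            mix[clean] = mix.get(clean, 0.0) + n
        total = sum(mix.values())
        mix = {t: v / total for t, v in mix.items()}
        n = max(2, int(round(site.n_sampled * scale)))
        specs.append(SiteSpec(
            site_id=site.site_id, n_specimens=n, taxon_mix=mix,
            preservation=n_success / site.n_sampled,
            date_ranges=site.dates,
        ))
    return specs
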