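"""Collagen peptide-marker reference panel: data model, TSV I/O, validation.

A panel is a taxa x marker-region table of nominal singly-protonated peptide
masses ([M+H]+, Da). One marker region may carry several masses — typically
a hydroxylation pair ~16 Da apart. Masses flagged "(?)" in reference tables
are real peptides seen by LC-MS/MS but unsuitable for species
identification; they load with ``reliable=False`` and never create
matched/missing evidence, although they do count when deciding whether an
observed peak is *compatible* with a taxon (see :mod:`zoomsid.classify`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import PanelError

ABSENT = None  # sentinel used in profile mappings for "taxon lacks region"

_DASHES = {"", "-", "—", "–", "―"}


@dataclass(frozen=True)
class MarkerDef:
    """Masses observed for one marker region in one taxon."""

    marker_id: str
    masses: tuple[float, ...]
    reliable: tuple[bool, ...]
    note: str = ""
    inferred: bool = False

    def __post_init__(self) -> None:
        if not self.masses:
            raise PanelError(f"{self.marker_id}: marker present but no masses")
        if len(self.masses) != len(self.reliable):
            raise PanelError(f"{self.marker_id}: masses/reliable length mismatch")
        if any(m <= 0 for m in self.masses):
            raise PanelError(f"{self.marker_id}: non-positive mass")
        if any(b >= a for a, b in zip(self.masses[1:], self.masses)):
            raise PanelError(
                f"{self.marker_id}: masses must be strictly increasing"
            )

    @property
    def reliable_masses(self) -> tuple[float, ...]:
        return tuple(m for m, r in zip(self.masses, self.reliable) if r)


@dataclass(frozen=True)
class TaxonProfile:
    """One taxon's row of the panel.

    ``markers`` maps every marker_id of the panel vocabulary to a MarkerDef,
    or to ``ABSENT`` (None) where the reference table prints a dash.
    """

    taxon_id: str
    markers: Mapping[str, MarkerDef | None]
    tentative: bool = False

    def marker(self, marker_id: str) -> MarkerDef | None:
        return self.markers.get(marker_id, ABSENT)

    def reliable_set(self, marker_id: str) -> frozenset[float]:
        mdef = self.marker(marker_id)
        return frozenset(mdef.reliable_masses) if mdef is not None else frozenset()

    def all_masses(self) -> frozenset[float]:
        """Every mass of the profile, reliable or not."""
        return frozenset(
            m for d in self.markers.values() if d is not None for m in d.masses
        )

    def reliable_masses(self) -> frozenset[float]:
        return frozenset(
            m
            for d in self.markers.values()
            if d is not None
            for m in d.reliable_masses
        )

    @property
    def display_name(self) -> str:
        return f"cf. {self.taxon_id}" if self.tentative else self.taxon_id


@dataclass(frozen=True)
class MarkerPanel:
    """Validated taxa x marker reference library."""

    marker_vocabulary: tuple[str, ...]
    profiles: tuple[TaxonProfile, ...]
    mass_tolerance_default: float = 0.5
    common_masses: tuple[float, ...] = ()
    inferred_regions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookup ----------------------------------------------------------
    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(p.taxon_id for p in self.profiles)

    def profile(self, taxon_id: str) -> TaxonProfile:
        for p in self.profiles:
            if p.taxon_id == taxon_id:
                return p
        raise PanelError(f"unknown taxon {taxon_id!r}")

    def all_masses(self) -> frozenset[float]:
        return frozenset(m for p in self.profiles for m in p.all_masses())

    def subset(self, taxa: Iterable[str]) -> "MarkerPanel":
        """Panel restricted to the given taxa (order preserved)."""
        keep = list(taxa)
        for t in keep:
            self.profile(t)
        return replace(
            self,
            profiles=tuple(p for p in self.profiles if p.taxon_id in keep),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not self.profiles:
            raise PanelError("empty panel")
        seen: set[str] = set()
        for p in self.profiles:
            if p.taxon_id in seen:
                raise PanelError(f"duplicate taxon row: {p.taxon_id!r}")
            seen.add(p.taxon_id)
            for mid in p.markers:
                if mid not in self.marker_vocabulary:
                    raise PanelError(
                        f"{p.taxon_id}: marker {mid!r} not in panel vocabulary"
                    )
        if self.mass_tolerance_default <= 0:
            raise PanelError("mass_tolerance_default must be positive")

    def signature(self, taxon_id: str) -> tuple[frozenset[float], ...]:
        p = self.profile(taxon_id)
        return tuple(p.reliable_set(mid) for mid in self.marker_vocabulary)


def distinguishing_markers(a: str, b: str, panel: MarkerPanel) -> set[str]:
    """Marker regions whose *reliable* mass sets differ between two taxa.

    Symmetric; an ABSENT region compares as the empty mass set, so a region
    present in one taxon and absent in the other is distinguishing.
    """
    pa, pb = panel.profile(a), panel.profile(b)
    return {
        mid
        for mid in panel.marker_vocabulary
        if pa.reliable_set(mid) != pb.reliable_set(mid)
    }


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_cell(cell: str, marker_id: str, taxon: str) -> MarkerDef | None:
    cell = cell.strip()
    if cell in _DASHES:
        return ABSENT
    masses: list[float] = []
    reliable: list[bool] = []
    for tok in cell.split(";"):
        tok = tok.strip()
        ok = not tok.endswith("?")
        if not ok:
            tok = tok[:-1].strip()
        # also accept the typeset "(?)" form
        if tok.endswith("(?)"):
            tok, ok = tok[:-3].strip(), False
        try:
            mass = float(tok)
        except ValueError as exc:
            raise PanelError(
                f"non-numeric mass {tok!r} in row {taxon!r}, column {marker_id!r}"
            ) from exc
        masses.append(mass)
        reliable.append(ok)
    order = sorted(range(len(masses)), key=masses.__getitem__)
    return MarkerDef(
        marker_id=marker_id,
        masses=tuple(masses[i] for i in order),
        reliable=tuple(reliable[i] for i in order),
    )


def load_panel(path: str | Path | None = None) -> MarkerPanel:
    """Load a marker panel from a UTF-8 TSV file.

    With no argument, loads the panel bundled with the package. Lines
    starting with ``#`` are comments; ``#!`` lines are directives
    (tolerance, common-mass set, tentative taxa, inferred cells/regions).
    A leading ``cf.`` on a taxon name also marks the row tentative.
    """
    if path is None:
        src = resources.files("zoomsid.data").joinpath("markers.tsv")
        text = src.read_text(encoding="utf-8")
    else:
        p = Path(path)
        if not p.exists():
            raise PanelError(f"panel file not found: {p}")
        text = p.read_text(encoding="utf-8")

    tolerance = 0.5
    common: list[float] = []
    tentative: set[str] = set()
    inferred_regions: set[str] = set()
    inferred_cells: set[tuple[str, str]] = set()
    header: list[str] | None = None
    rows: list[tuple[str, list[str]]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#!"):
            parts = [t.strip() for t in line[2:].split("\t") if t.strip()]
            if not parts:
                continue
            key, args = parts[0], parts[1:]
            if key == "tolerance":
                tolerance = float(args[0])
            elif key == "common":
                common = [float(a) for a in args]
            elif key == "tentative":
                tentative.update(args)
            elif key == "inferred-region":
                inferred_regions.update(args)
            elif key == "inferred-cell" and len(args) == 2:
                inferred_cells.add((args[0], args[1]))
            continue
        if line.startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            if cells[0].strip().lower() != "taxon":
                raise PanelError(
                    f"line {lineno}: expected header starting with 'taxon'"
                )
            header = [c.strip() for c in cells[1:]]
            continue
        rows.append((cells[0].strip(), [c for c in cells[1:]]))

    if header is None or not rows:
        raise PanelError("empty panel file")

    profiles: list[TaxonProfile] = []
    for name, cells in rows:
        is_cf = name.startswith("cf.")
        taxon_id = name[3:].strip() if is_cf else name
        markers: dict[str, MarkerDef | None] = {}
        for i, mid in enumerate(header):
            cell = cells[i] if i < len(cells) else ""
            mdef = _parse_cell(cell, mid, taxon_id)
            if mdef is not None and (
                (name, mid) in inferred_cells
                or (taxon_id, mid) in inferred_cells
                or mid in inferred_regions
            ):
                mdef = replace(mdef, inferred=True)
            markers[mid] = mdef
        profiles.append(
            TaxonProfile(
                taxon_id=taxon_id,
                markers=markers,
                tentative=is_cf or taxon_id in tentative or name in tentative,
            )
        )

    return MarkerPanel(
        marker_vocabulary=tuple(header),
        profiles=tuple(profiles),
        mass_tolerance_default=tolerance,
        common_masses=tuple(common),
        inferred_regions=frozenset(inferred_regions),
    )


def _format_mass(m: float) -> str:
    return f"{m:g}"


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    """Write a panel back to TSV; ``load_panel`` round-trips the
    (taxon, marker, mass, reliable) content."""
    lines: list[str] = []
    lines.append(f"#! tolerance\t{panel.mass_tolerance_default:g}")
    if panel.common_masses:
        lines.append(
            "#! common\t" + "\t".join(_format_mass(m) for m in panel.common_masses)
        )
    tent = [p.taxon_id for p in panel.profiles if p.tentative]
    if tent:
        lines.append("#! tentative\t" + "\t".join(tent))
    if panel.inferred_regions:
        lines.append(
            "#! inferred-region\t" + "\t".join(sorted(panel.inferred_regions))
        )
    lines.append("taxon\t" + "\t".join(panel.marker_vocabulary))
    for p in panel.profiles:
        cells = []
        for mid in panel.marker_vocabulary:
            d = p.marker(mid)
            if d is None:
                cells.append("—")
            else:
                cells.append(
                    ";".join(
                        _format_mass(m) + ("" if r else "?")
                        for m, r in zip(d.masses, d.reliable)
                    )
                )
        lines.append(p.taxon_id + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
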