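"""Taxonomy tree for coarse-group calls and morphological comparison.

The tree mixes proper taxonomic nodes (species ... class) with the
morphological size-class categories zooarchaeologists assign to fragmented
bone ("Bovid Size 2" etc.). Size classes are not clades: they carry an
explicit membership set of panel taxa they can contain, and group-level
reasoning on them uses that set rather than tree descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import TaxonomyError

ROOT = "Vertebrata"


@dataclass(frozen=True)
class TaxonomyTree:
    parent: dict[str, str]            # child -> parent (root absent)
    rank: dict[str, str]              # node -> rank label
    membership: dict[str, frozenset[str]]  # size-class node -> panel taxa
    aliases: dict[str, str] = field(default_factory=dict)
    display: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, par in self.parent.items():
            if par != ROOT and par not in self.parent:
                raise TaxonomyError(f"parent {par!r} of {child!r} is not a node")
        for node, members in self.membership.items():
            if not members:
                raise TaxonomyError(f"size class {node!r} has empty membership")

    # -- name handling ---------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.parent) | {ROOT}

    def resolve(self, name: str) -> str:
        """Map a printed name (incl. 'cf. X' and morphological vocabulary
        like 'caprine'/'mammal'/'indeterminate') onto a tree node."""
        name = name.strip()
        if name.startswith("cf."):
            name = name[3:].strip()
        if name in self.nodes:
            return name
        if name in self.aliases:
            return self.aliases[name]
        low = name.lower()
        if low in self.aliases:
            return self.aliases[low]
        raise TaxonomyError(f"unknown taxon or category: {name!r}")

    def display_name(self, node: str) -> str:
        return self.display.get(node, node)

    # -- structure -------------------------------------------------------
    def ancestors(self, node: str) -> list[str]:
        """Path from node (inclusive) up to the root."""
        node = self.resolve(node)
        out = [node]
        while node != ROOT:
            node = self.parent[node]
            out.append(node)
        return out

    def is_strict_descendant(self, node: str, of: str) -> bool:
        node, of = self.resolve(node), self.resolve(of)
        return node != of and of in self.ancestors(node)[1:]

    def children(self, node: str) -> set[str]:
        return {c for c, p in self.parent.items() if p == node}

    def leaf_taxa(self, node: str) -> frozenset[str]:
        """Panel-taxon leaves under a node; for a size class, its
        membership set."""
        node = self.resolve(node)
        if node in self.membership:
            return self.membership[node]
        kids = {c for c in self.children(node) if c not in self.membership}
        if not kids:
            return frozenset({node})
        out: set[str] = set()
        for c in kids:
            out |= self.leaf_taxa(c)
        return frozenset(out)


def lowest_common_group(taxa: Iterable[str], tree: TaxonomyTree) -> str:
    """Nearest tree node dominating every input taxon.

    Idempotent and order-invariant; a singleton returns its own element.
    """
    names = list(taxa)
    if not names:
        raise TaxonomyError("lowest_common_group of an empty set")
    paths = [tree.ancestors(t)[::-1] for t in names]  # root -> node
    lca = ROOT
    for level in zip(*paths):
        if len(set(level)) == 1:
            lca = level[0]
        else:
            break
    return lca


def load_taxonomy(path: str | Path | None = None) -> TaxonomyTree:
    """Load the taxonomy edge list (child, parent, rank) plus ``#!``
    directive blocks for aliases, display labels and size-class membership.
    With no argument, loads the tree bundled with the package."""
    if path is None:
        src = resources.files("zoomsid.data").joinpath("taxonomy.tsv")
        text = src.read_text(encoding="utf-8")
    else:
        p = Path(path)
        if not p.exists():
            raise TaxonomyError(f"taxonomy file not found: {p}")
        text = p.read_text(encoding="utf-8")

    parent: dict[str, str] = {}
    rank: dict[str, str] = {ROOT: "subphylum"}
    membership: dict[str, frozenset[str]] = {}
    aliases: dict[str, str] = {}
    display: dict[str, str] = {}
    header_seen = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#!"):
            parts = [t.strip() for t in line[2:].split("\t") if t.strip()]
            if not parts:
                continue
            key, args = parts[0], parts[1:]
            if key == "alias" and len(args) == 2:
                aliases[args[0]] = args[1]
            elif key == "display" and len(args) == 2:
                display[args[0]] = args[1]
            elif key == "member" and len(args) >= 2:
                membership[args[0]] = frozenset(args[1:])
            else:
                raise TaxonomyError(f"line {lineno}: bad directive {line!r}")
            continue
        if line.startswith("#"):
            continue
        cells = [c.strip() for c in line.split("\t")]
        if not header_seen:
            if cells[0].lower() != "child":
                raise TaxonomyError(f"line {lineno}: expected edge-list header")
            header_seen = True
            continue
        if len(cells) < 2:
            raise TaxonomyError(f"line {lineno}: need child and parent")
        child, par = cells[0], cells[1]
        if child in parent:
            raise TaxonomyError(f"duplicate node {child!r}")
        parent[child] = par
        rank[child] = cells[2] if len(cells) > 2 else "unranked"

    tree = TaxonomyTree(
        parent=parent, rank=rank, membership=membership,
        aliases=aliases, display=display,
    )
    # every alias target and membership member must resolve
    for tgt in aliases.values():
        if tgt not in tree.nodes:
            raise TaxonomyError(f"alias target {tgt!r} is not a node")
    for node, members in membership.items():
        if node not in tree.nodes:
            raise TaxonomyError(f"size class {node!r} is not a node")
        for m in members:
            if m not in tree.nodes:
                raise TaxonomyError(f"member {m!r} of {node!r} is not a node")
    return tree
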