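"""Taxonomy handling: taxdump parsing, 7-rank lineages, LCA, Baltimore join.

Implements the taxonomic layer of the annotation engine:

* loading an NCBI-taxdump-dialect taxonomy (``nodes.dmp`` / ``names.dmp``,
  optional ``merged.dmp``) into an in-memory :class:`TaxonomyTree`;
* canonical 7-rank Linnaean lineages (kingdom .. species) with the
  ``superkingdom`` rank accepted into the kingdom slot, since NCBI dumps
  carry no ``kingdom`` node for most groups;
* plain lowest-common-ancestor queries and the *augmented* LCA used for
  read classification: when an LCA over a hit set degenerates to the
  global root (virus-vs-cellular evidence) or to the virus root
  (cross-realm viral evidence), the assignment reverts to the top hit and
  the row is flagged so downstream analysis can include or exclude it;
* the Baltimore classification join (viral family -> one of 7 groups),
  loaded from a packaged TSV resource.

Absent ranks are reported with the sentinel string ``"unclassified"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from virannot.errors import IntegrityError, ParseError

#: Sentinel used wherever a rank, lineage or taxid is absent/unassignable.
SENTINEL = "unclassified"

#: Taxid sentinel for unclassified assignments (0 is never a valid NCBI taxid).
SENTINEL_TAXID = 0

#: The 7 canonical Linnaean ranks, highest first.
RANKS7 = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

DEFAULT_ROOT_ID = 1
DEFAULT_VIRUS_ROOT_ID = 10239  # NCBI superkingdom Viruses


@dataclass
class TaxonomyTree:
    """Rank-annotated ancestry structure over integer taxids.

    ``nodes`` maps taxid -> (parent taxid, rank label); the root is its own
    parent. ``merged`` maps retired taxids onto their replacements and is
    consulted transparently by :meth:`resolve`.
    """

    nodes: dict[int, tuple[int, str]]
    names: dict[int, str]
    root_id: int = DEFAULT_ROOT_ID
    virus_root_id: int = DEFAULT_VIRUS_ROOT_ID
    merged: dict[int, int] = field(default_factory=dict)
    _depth: dict[int, int] = field(default_factory=dict, repr=False)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes or taxid in self.merged

    def resolve(self, taxid: int) -> int:
        """Map a possibly-merged taxid to its current id; KeyError if unknown."""
        if taxid in self.nodes:
            return taxid
        if taxid in self.merged:
            return self.merged[taxid]
        raise KeyError(taxid)

    def parent(self, taxid: int) -> int:
        return self.nodes[self.resolve(taxid)][0]

    def rank(self, taxid: int) -> str:
        return self.nodes[self.resolve(taxid)][1]

    def name(self, taxid: int) -> str:
        return self.names.get(self.resolve(taxid), SENTINEL)

    def root_path(self, taxid: int) -> list[int]:
        """Taxids from ``taxid`` up to and including the root."""
        taxid = self.resolve(taxid)
        path = [taxid]
        while taxid != self.root_id:
            taxid = self.nodes[taxid][0]
            path.append(taxid)
        return path

    def depth(self, taxid: int) -> int:
        """Number of edges between ``taxid`` and the root (root has depth 0)."""
        taxid = self.resolve(taxid)
        cached = self._depth.get(taxid)
        if cached is not None:
            return cached
        # walk up until a cached ancestor or the root, then fill in
        trail = []
        node = taxid
        while node != self.root_id and node not in self._depth:
            trail.append(node)
            node = self.nodes[node][0]
        base = 0 if node == self.root_id else self._depth[node]
        for offset, t in enumerate(reversed(trail), start=1):
            self._depth[t] = base + offset
        return self._depth.get(taxid, 0)

    def is_viral(self, taxid: int) -> bool:
        """True iff the virus root lies on the taxid's root path."""
        try:
            taxid = self.resolve(taxid)
        except KeyError:
            return False
        while True:
            if taxid == self.virus_root_id:
                return True
            if taxid == self.root_id:
                return False
            taxid = self.nodes[taxid][0]

    def validate(self) -> None:
        """Check the no-orphan and acyclicity invariants; IntegrityError on failure."""
        orphans = sorted(
            t for t, (p, _) in self.nodes.items() if t != self.root_id and p not in self.nodes
        )
        if orphans:
            raise IntegrityError(f"orphan taxids (parent absent): {orphans}")
        if self.root_id not in self.nodes:
            raise IntegrityError(f"root taxid {self.root_id} absent from nodes")
        for taxid in self.nodes:
            seen = set()
            node = taxid
            while node != self.root_id:
                if node in seen:
                    raise IntegrityError(f"cycle in parent links at taxid {node}")
                seen.add(node)
                node = self.nodes[node][0]


@dataclass(frozen=True)
class Lineage7:
    """Canonical 7-rank lineage; absent ranks hold the sentinel string."""

    kingdom: str = SENTINEL
    phylum: str = SENTINEL
    class_: str = SENTINEL
    order: str = SENTINEL
    family: str = SENTINEL
    genus: str = SENTINEL
    species: str = SENTINEL
    taxid: int = SENTINEL_TAXID

    def as_tuple(self) -> tuple[str, ...]:
        return (self.kingdom, self.phylum, self.class_, self.order,
                self.family, self.genus, self.species)


#: Lineage used for unclassified / unknown-taxid rows.
SENTINEL_LINEAGE = Lineage7()


@dataclass(frozen=True)
class LcaResult:
    """Outcome of an (augmented) LCA query.

    ``basis`` is ``"lca"`` for a plain assignment and ``"top_hit_reverted"``
    when the LCA degenerated to root/virus-root and the assignment reverted
    to the top hit; ``augmented`` is true exactly in the latter case.
    """

    taxid: int
    augmented: bool
    basis: str  # "lca" | "top_hit_reverted"

    def __post_init__(self):
        assert self.augmented == (self.basis == "top_hit_reverted")


@dataclass(frozen=True)
class BaltimoreEntry:
    family: str
    baltimore_group: str  # "I".."VII"
    nucleic_acid: str  # dsDNA, ssDNA, dsRNA, ssRNA(+), ssRNA(-), ssRNA-RT, dsDNA-RT


def _iter_dmp(path) -> Iterable[tuple[int, list[str]]]:
    """Yield (line number, fields) for a pipe-delimited .dmp file."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            yield lineno, line.split("\t|\t")


def load_taxdump(
    nodes_path,
    names_path,
    merged_path=None,
    root_id: int = DEFAULT_ROOT_ID,
    virus_root_id: int = DEFAULT_VIRUS_ROOT_ID,
) -> TaxonomyTree:
    """Load a taxdump-dialect taxonomy into a validated :class:`TaxonomyTree`.

    ``nodes.dmp`` needs the first three fields (taxid, parent, rank); extra
    fields are ignored and unknown rank labels are preserved verbatim.
    ``names.dmp`` contributes scientific names (fallback: first name seen).
    A ``merged.dmp`` file, when given, maps retired taxids to current ones.
    """
    nodes: dict[int, tuple[int, str]] = {}
    for lineno, fields in _iter_dmp(nodes_path):
        if len(fields) < 3:
            raise ParseError(
                f"nodes record needs >=3 fields, got {len(fields)}",
                path=nodes_path, line=lineno,
            )
        try:
            taxid = int(fields[0])
            parent = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"non-integer taxid field: {exc}",
                             path=nodes_path, line=lineno) from None
        nodes[taxid] = (parent, fields[2].strip())

    names: dict[int, str] = {}
    for lineno, fields in _iter_dmp(names_path):
        if len(fields) < 2:
            raise ParseError(
                f"names record needs >=2 fields, got {len(fields)}",
                path=names_path, line=lineno,
            )
        try:
            taxid = int(fields[0])
        except ValueError as exc:
            raise ParseError(f"non-integer taxid field: {exc}",
                             path=names_path, line=lineno) from None
        name_class = fields[3].strip() if len(fields) > 3 else "scientific name"
        if name_class == "scientific name" or taxid not in names:
            names[taxid] = fields[1].strip()

    merged: dict[int, int] = {}
    if merged_path is not None:
        for lineno, fields in _iter_dmp(merged_path):
            if len(fields) < 2:
                raise ParseError(
                    f"merged record needs 2 fields, got {len(fields)}",
                    path=merged_path, line=lineno,
                )
            merged[int(fields[0])] = int(fields[1])

    tree = TaxonomyTree(
        nodes=nodes, names=names, root_id=root_id,
        virus_root_id=virus_root_id, merged=merged,
    )
    tree.validate()
    return tree


def lineage7(tree: TaxonomyTree, taxid: int) -> Lineage7:
    """Canonical 7-rank lineage for ``taxid``.

    Each slot holds the name of the nearest ancestor-or-self carrying that
    rank label; the kingdom slot falls back to a ``superkingdom``-ranked
    node when no ``kingdom`` node exists on the path.
    """
    if taxid not in tree:
        raise KeyError(f"unknown taxid {taxid}")
    slots: dict[str, str] = {}
    superkingdom_name = None
    for node in tree.root_path(taxid):
        rank = tree.rank(node)
        if rank in RANKS7 and rank not in slots:
            slots[rank] = tree.name(node)
        elif rank == "superkingdom" and superkingdom_name is None:
            superkingdom_name = tree.name(node)
    if "kingdom" not in slots and superkingdom_name is not None:
        slots["kingdom"] = superkingdom_name
    return Lineage7(
        kingdom=slots.get("kingdom", SENTINEL),
        phylum=slots.get("phylum", SENTINEL),
        class_=slots.get("class", SENTINEL),
        order=slots.get("order", SENTINEL),
        family=slots.get("family", SENTINEL),
        genus=slots.get("genus", SENTINEL),
        species=slots.get("species", SENTINEL),
        taxid=tree.resolve(taxid),
    )


def lca(tree: TaxonomyTree, taxids: Iterable[int]) -> int:
    """Lowest common ancestor of a non-empty set of taxids.

    Pairwise depth-lifting fold: lift the deeper node to the shallower
    depth, then walk both up in lockstep.
    """
    ids = [tree.resolve(t) for t in set(taxids)]
    if not ids:
        raise ValueError("lca of an empty taxid set is undefined")
    current = ids[0]
    for other in ids[1:]:
        a, b = current, other
        da, db = tree.depth(a), tree.depth(b)
        while da > db:
            a = tree.parent(a)
            da -= 1
        while db > da:
            b = tree.parent(b)
            db -= 1
        while a != b:
            a = tree.parent(a)
            b = tree.parent(b)
        current = a
        if current == tree.root_id:
            break
    return current


def augmented_lca(tree: TaxonomyTree, hits_taxids: list[int]) -> LcaResult:
    """LCA over an ordered hit list with top-hit reversion.

    ``hits_taxids`` is ordered by hit priority (first element = top hit).
    If the plain LCA lands on the global root (cross-kingdom evidence,
    e.g. virus vs bacterium) or on the virus root (cross-realm viral
    evidence) and the list holds >=2 distinct taxids, the assignment
    reverts to the top hit and is flagged.
    """
    if not hits_taxids:
        raise ValueError("augmented_lca of an empty hit list is undefined")
    plain = lca(tree, hits_taxids)
    distinct = {tree.resolve(t) for t in hits_taxids}
    if plain in (tree.root_id, tree.virus_root_id) and len(distinct) >= 2:
        return LcaResult(taxid=tree.resolve(hits_taxids[0]),
                         augmented=True, basis="top_hit_reverted")
    return LcaResult(taxid=plain, augmented=False, basis="lca")


# -- Baltimore classification ------------------------------------------------

_BALTIMORE_GROUPS = frozenset({"I", "II", "III", "IV", "V", "VI", "VII"})


def load_baltimore(path=None) -> dict[str, BaltimoreEntry]:
    """Load the family -> Baltimore group table (packaged resource by default).

    The table is a 3-column TSV (family, baltimore_group, nucleic_acid) with
    a header row; groups are the closed vocabulary I..VII.
    """
    if path is None:
        source = resources.files("virannot").joinpath("data/baltimore.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, BaltimoreEntry] = {}
    lines = text.splitlines()
    if not lines or not lines[0].lower().startswith("family"):
        raise ParseError("Baltimore table must start with a header row", path=path)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"Baltimore row needs 3 columns, got {len(parts)}",
                             path=path, line=lineno)
        family, group, nucleic = (p.strip() for p in parts)
        if group not in _BALTIMORE_GROUPS:
            raise ParseError(f"unknown Baltimore group {group!r}", path=path, line=lineno)
        table[family] = BaltimoreEntry(family, group, nucleic)
    return table


def baltimore_lookup(
    table: Mapping[str, BaltimoreEntry], family: str
) -> BaltimoreEntry | None:
    """Exact, case-sensitive family lookup; a miss is a value (None), not an error."""
    return table.get(family)
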