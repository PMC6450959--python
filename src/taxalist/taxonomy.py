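"""Shared-taxa (ST) computation from NCBI-style taxonomies.

ST of a species is the number of taxonomy-tree edges its lineage shares with
the reference (human) lineage: the length, in edges below the root, of the
longest common prefix of the two root-to-leaf paths.  Goldfish, whose lineage
diverges from the human one after Euteleostomi, shares 13 edges; the rodent
clade (mouse, rat, and relatives splitting after Euarchontoglires) shares 22.

The packaged reference lineage has 32 edges, so a subject of the reference
species itself gets ST = MAX_ST = 32 while every other species gets at most
31 — matching a 31-element shared-taxa profile indexed 1..31.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

logger = logging.getLogger(__name__)

#: edges of the packaged reference (human) lineage; ST of same-species subjects
MAX_ST = 32
HUMAN_TAXID = 9606


class TaxonomyError(ValueError):
    """Unresolvable taxid, broken parent chain, or cycle."""


@dataclass(frozen=True)
class Lineage:
    """Root-to-taxon path of taxon ids."""

    taxid: int
    path: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.path:
            raise TaxonomyError(f"taxid {self.taxid}: empty lineage")
        if self.path[-1] != self.taxid:
            raise TaxonomyError(f"taxid {self.taxid}: path does not end at taxon")
        if len(set(self.path)) != len(self.path):
            raise TaxonomyError(f"taxid {self.taxid}: repeated node in lineage")

    @property
    def edges(self) -> int:
        return len(self.path) - 1


class TaxonomyStore:
    """Lineage lookup backed by a parent map (``nodes.dmp``) or explicit paths."""

    def __init__(
        self,
        parent: dict[int, int] | None = None,
        lineages: dict[int, Lineage] | None = None,
    ) -> None:
        self._parent = parent or {}
        self._lineages: dict[int, Lineage] = dict(lineages or {})

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._lineages or taxid in self._parent

    def lineage(self, taxid: int) -> Lineage:
        if taxid in self._lineages:
            return self._lineages[taxid]
        if taxid not in self._parent:
            raise TaxonomyError(f"taxid {taxid}: not in taxonomy")
        path: list[int] = []
        seen: set[int] = set()
        node = taxid
        while True:
            if node in seen:
                raise TaxonomyError(f"taxid {taxid}: cycle through node {node}")
            seen.add(node)
            path.append(node)
            parent = self._parent.get(node)
            if parent is None:
                raise TaxonomyError(
                    f"taxid {taxid}: broken parent chain at node {node}"
                )
            if parent == node:  # NCBI convention: root is its own parent
                break
            node = parent
        lin = Lineage(taxid, tuple(reversed(path)))
        self._lineages[taxid] = lin
        return lin


def load_taxdump(path) -> TaxonomyStore:
    """Load a taxonomy from NCBI ``nodes.dmp`` or a lineage TSV.

    ``nodes.dmp`` rows are pipe-delimited (``taxid | parent | rank | ...``);
    lineage TSV rows are ``taxid<TAB>root;...;leaf``.
    """
    with open(path) as fh:
        first = fh.readline()
    if "|" in first:
        return _load_nodes_dmp(path)
    return _load_lineage_tsv(path)


def _load_nodes_dmp(path) -> TaxonomyStore:
    parent: dict[int, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("|")]
            if len(fields) < 2:
                raise TaxonomyError(f"{path} line {line_no}: malformed nodes.dmp row")
            parent[int(fields[0])] = int(fields[1])
    return TaxonomyStore(parent=parent)


def _load_lineage_tsv(path) -> TaxonomyStore:
    lineages: dict[int, Lineage] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                taxid_s, path_s = line.split("\t")
                taxid = int(taxid_s)
                nodes = tuple(int(x) for x in path_s.split(";"))
            except ValueError as exc:
                raise TaxonomyError(f"{path} line {line_no}: {exc}") from exc
            lineages[taxid] = Lineage(taxid, nodes)
    return TaxonomyStore(lineages=lineages)


def write_lineage_tsv(path, lineages: list[Lineage]) -> None:
    with open(path, "w") as fh:
        for lin in lineages:
            fh.write(f"{lin.taxid}\t{';'.join(str(n) for n in lin.path)}\n")


def shared_taxa(reference: Lineage, other: Lineage) -> int:
    """Edges shared by two lineages (longest common path prefix, in edges)."""
    if reference.path[0] != other.path[0]:
        raise TaxonomyError(
            f"lineages of {reference.taxid} and {other.taxid} have different roots"
        )
    n = 0
    for a, b in zip(reference.path, other.path):
        if a != b:
            break
        n += 1
    return n - 1


@dataclass(frozen=True)
class SharedTaxaIndex:
    """Precomputed ST per taxid against a reference lineage."""

    reference_lineage: Lineage
    st_of: dict[int, int]

    def st(self, taxid: int) -> int:
        """ST for ``taxid``; unresolved taxids score 0 (no shared edges)."""
        return self.st_of.get(taxid, 0)


def build_shared_taxa_index(
    store: TaxonomyStore, reference_taxid: int, taxids
) -> SharedTaxaIndex:
    """ST for every taxid in ``taxids`` against ``reference_taxid``'s lineage.

    Unresolvable taxids are assigned ST 0 with a logged warning; an
    unresolvable reference is fatal.
    """
    try:
        ref = store.lineage(reference_taxid)
    except TaxonomyError as exc:
        raise TaxonomyError(f"reference taxid {reference_taxid}: {exc}") from exc
    st_of: dict[int, int] = {}
    for t in taxids:
        try:
            st_of[t] = shared_taxa(ref, store.lineage(t))
        except TaxonomyError:
            logger.warning("taxid %s unresolvable; assigned ST = 0", t)
            st_of[t] = 0
    return SharedTaxaIndex(reference_lineage=ref, st_of=st_of)


def load_reference_lineages() -> TaxonomyStore:
    """Packaged reference lineages (human, goldfish, mouse, rat).

    The human path has 32 edges; it mirrors the NCBI lineage with one
    synthetic tribe-level node (id 9999001) inserted below Homininae so the
    reference depth is exactly 32 while every clade split is preserved.
    """
    ref = resources.files("taxalist.data").joinpath("reference_lineages.tsv")
    with resources.as_file(ref) as p:
        return load_taxdump(p)


def human_lineage() -> Lineage:
    return load_reference_lineages().lineage(HUMAN_TAXID)
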