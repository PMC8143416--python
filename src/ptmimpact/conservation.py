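"""PTM-site conservation across orthologue alignments and taxonomy.

Type-specific conservation rules: an acetylated lysine counts as
conserved in an orthologue if a K appears at the site's alignment
column or one column up/downstream (acetylation tolerates a +/-1
positional shift); phospho-serine and phospho-threonine require S or T
at the exact column (the hydroxyls are interchangeable); phospho-
tyrosine requires Y at the exact column.  The conservation fraction is
the share of non-reference records satisfying the rule, and the set of
conserving taxa feeds a lowest-common-ancestor query against a
taxonomy tree.  Secondary-structure placement uses the 8-letter DSSP
alphabet simplified to helix / sheet / coil.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from scipy import stats as _sps

__all__ = [
    "Alignment",
    "ConservationResult",
    "TaxonomyTree",
    "column_of_position",
    "is_conserved",
    "conservation_fraction",
    "lowest_common_ancestor",
    "simplify_secondary_structure",
    "ss_preference",
    "conservation_ddg_correlation",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_taxonomy_newick",
    "read_taxonomy_table",
]

GAP = "-"
SS_SIMPLIFY = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "S": "C", "T": "C", "C": "C", "-": "C",
}


@dataclass(frozen=True)
class Alignment:
    """Gapped orthologue alignment; one record is the reference protein."""

    records: tuple[tuple[str, str, str], ...]  # (taxon id, name, aligned seq)
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        length = len(self.records[0][2])
        if any(len(r[2]) != length for r in self.records):
            raise ValueError("aligned sequences must share length")
        if not 0 <= self.reference_index < len(self.records):
            raise ValueError("reference record missing")

    @property
    def reference_seq(self) -> str:
        return self.records[self.reference_index][2]

    @property
    def n_orthologs(self) -> int:
        return len(self.records) - 1


@dataclass(frozen=True)
class ConservationResult:
    accession: str
    position: int
    fraction: float
    conserving_taxa: tuple[str, ...]
    n_orthologs: int


def column_of_position(aln: Alignment, ungapped_pos: int) -> int:
    """0-based alignment column of the 1-based ungapped reference position."""
    if ungapped_pos < 1:
        raise ValueError("ungapped position is 1-based")
    count = 0
    for col, ch in enumerate(aln.reference_seq):
        if ch != GAP:
            count += 1
            if count == ungapped_pos:
                return col
    raise ValueError("position beyond ungapped reference length")


def is_conserved(
    ortholog_seq: str, column: int, ptm_type: str, residue: str
) -> bool:
    """Type-specific conservation rule at one alignment column.

    Columns falling off the alignment edge (for the +/-1 acetylation
    window) count as non-matching.
    """
    def at(col: int) -> str:
        if 0 <= col < len(ortholog_seq):
            return ortholog_seq[col].upper()
        return GAP

    if ptm_type == "acetylation":
        return any(at(c) == "K" for c in (column - 1, column, column + 1))
    if ptm_type == "phosphorylation":
        if residue in ("S", "T"):
            return at(column) in ("S", "T")
        if residue == "Y":
            return at(column) == "Y"
    raise ValueError(f"unknown PTM {ptm_type!r} on {residue!r}")


def conservation_fraction(
    aln: Alignment, accession: str, position: int, ptm_type: str, residue: str
) -> ConservationResult:
    """Fraction of orthologues (reference excluded) conserving a site.

    Orthologues entirely gapped around the site count as non-conserving
    rather than being excluded from the denominator.
    """
    column = column_of_position(aln, position)
    ref_char = aln.reference_seq[column].upper()
    if ref_char != residue.upper():
        raise ValueError(
            f"reference_mismatch: expected {residue} at position {position}, "
            f"found {ref_char}"
        )
    conserving = [
        rec[0]
        for i, rec in enumerate(aln.records)
        if i != aln.reference_index and is_conserved(rec[2], column, ptm_type, residue)
    ]
    n = aln.n_orthologs
    return ConservationResult(
        accession=accession,
        position=position,
        fraction=len(conserving) / n if n else 0.0,
        conserving_taxa=tuple(conserving),
        n_orthologs=n,
    )


class TaxonomyTree:
    """Rooted taxonomy as parent pointers; supports LCA queries."""

    def __init__(self, nodes: Iterable[tuple[str, str, str | None]]):
        self.names: dict[str, str] = {}
        self.parent: dict[str, str | None] = {}
        for node_id, name, parent_id in nodes:
            if node_id in self.parent:
                raise ValueError(f"duplicate node {node_id}")
            self.names[node_id] = name
            self.parent[node_id] = parent_id
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("taxonomy must have exactly one root")
        for n, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"parent {p} of {n} missing from tree")
        self.root = roots[0]
        # cycle check via depth computation
        self._depth: dict[str, int] = {}
        for n in self.parent:
            self.depth(n)

    def depth(self, node_id: str) -> int:
        if node_id in self._depth:
            return self._depth[node_id]
        seen = []
        n: str | None = node_id
        while n is not None and n not in self._depth:
            if n in seen:
                raise ValueError("cycle in taxonomy")
            seen.append(n)
            n = self.parent[n]
        base = self._depth[n] if n is not None else -1
        for i, m in enumerate(reversed(seen)):
            self._depth[m] = base + 1 + i
        return self._depth[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.parent


def lowest_common_ancestor(tree: TaxonomyTree, taxa: Iterable[str]) -> str:
    """Deepest node that is an ancestor-or-self of every given taxon."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("empty taxon set")
    unknown = [t for t in taxa if t not in tree]
    if unknown:
        raise KeyError(f"unknown taxa: {unknown}")
    node = taxa[0]
    for other in taxa[1:]:
        a, b = node, other
        while tree.depth(a) > tree.depth(b):
            a = tree.parent[a]  # type: ignore[assignment]
        while tree.depth(b) > tree.depth(a):
            b = tree.parent[b]  # type: ignore[assignment]
        while a != b:
            a = tree.parent[a]  # type: ignore[assignment]
            b = tree.parent[b]  # type: ignore[assignment]
        node = a
    return node


def simplify_secondary_structure(code: str) -> str:
    """Collapse the 8-letter DSSP alphabet (plus '-') to H/E/C:
    H,G,I -> H; E,B -> E; S,T,C,- -> C."""
    try:
        return SS_SIMPLIFY[code.upper() if code != GAP else GAP]
    except KeyError:
        raise ValueError(f"unknown secondary-structure code {code!r}") from None


_ELEMENTS = ("H", "E", "C")


def ss_preference(
    site_codes: Sequence[str], background_codes: Sequence[str]
) -> dict[str, dict[str, float]]:
    """Secondary-structure placement of PTM sites vs matched
    non-modified residues of the same amino-acid type.

    Returns per-element fractions for both sets and their difference
    (site minus background); positive C difference means enrichment in
    unstructured regions.
    """
    if not site_codes or not background_codes:
        raise ValueError("need non-empty site and background sets")
    site_simple = [simplify_secondary_structure(c) for c in site_codes]
    bg_simple = [simplify_secondary_structure(c) for c in background_codes]
    site_frac = {e: site_simple.count(e) / len(site_simple) for e in _ELEMENTS}
    bg_frac = {e: bg_simple.count(e) / len(bg_simple) for e in _ELEMENTS}
    return {
        "sites": site_frac,
        "background": bg_frac,
        "difference": {e: site_frac[e] - bg_frac[e] for e in _ELEMENTS},
    }


def conservation_ddg_correlation(
    pairs: Sequence[tuple[float, float]], method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between site conservation fractions and local
    binding-contribution deltas; returns (coefficient, two-sided p)."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate_correlation")
    if method == "pearson":
        r = _sps.pearsonr(x, y)
    elif method == "spearman":
        r = _sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


# ---------------------------------------------------------------------------
# readers / writers

def read_alignment_fasta(path, reference_id: str) -> Alignment:
    """FASTA alignment; record ids are ``taxonid|name`` or a bare taxon id."""
    records = []
    ref_index = None
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        taxon_id, _, name = rec.description.partition("|")
        records.append((taxon_id, name or taxon_id, str(rec.seq).upper()))
        if taxon_id == reference_id:
            ref_index = i
    if ref_index is None:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    return Alignment(records=tuple(records), reference_index=ref_index)


def write_alignment_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for taxon_id, name, seq in aln.records:
            fh.write(f">{taxon_id}|{name}\n{seq}\n")


def read_taxonomy_newick(path) -> TaxonomyTree:
    """Newick tree with node labels used as taxon ids."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    nodes: list[tuple[str, str, str | None]] = []

    def label(node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        raise ValueError("every taxonomy node needs a label")

    for node in tree.preorder_node_iter():
        parent = None if node.parent_node is None else label(node.parent_node)
        nodes.append((label(node), label(node), parent))
    return TaxonomyTree(nodes)


def read_taxonomy_table(path) -> TaxonomyTree:
    """Tab-separated parent-pointer table: node_id, name, parent_id
    (empty parent marks the root)."""
    nodes: list[tuple[str, str, str | None]] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            node_id, name, parent = (line.rstrip("\n").split("\t") + [""])[:3]
            nodes.append((node_id, name, parent or None))
    return TaxonomyTree(nodes)
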