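"""PTM site catalogue: validation, structure mapping, multiplicity stats.

Sites come from tabular database exports (accession, 1-based position in
the full protein sequence, residue letter, modification type, growth
condition).  Acetylation is legal on lysine only; phosphorylation on
serine, threonine or tyrosine.  Mapping onto a structure chain goes
through an explicit residue map (structure residue number <-> protein
position, with a resolved flag), so sites falling into crystallographic
gaps or outside the crystallized construct are dropped and reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PTMSite",
    "ResidueMap",
    "MappedSite",
    "ChainPTMProfile",
    "validate_sites",
    "map_sites_to_chain",
    "per_chain_distribution",
    "multi_ptm_fraction",
    "read_ptm_table",
    "write_ptm_table",
]

LEGAL_RESIDUES = {"acetylation": {"K"}, "phosphorylation": {"S", "T", "Y"}}
CATEGORIES = ("acetyl_K", "phospho_S", "phospho_T", "phospho_Y")


@dataclass(frozen=True)
class PTMSite:
    protein_accession: str
    position: int  # 1-based in the full protein sequence
    residue: str
    ptm_type: str  # acetylation | phosphorylation
    condition: str  # normal | stress
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.ptm_type not in LEGAL_RESIDUES:
            raise ValueError(f"unknown ptm_type {self.ptm_type!r}")
        if self.condition not in ("normal", "stress"):
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def category(self) -> str:
        if self.ptm_type == "acetylation":
            return "acetyl_K"
        return f"phospho_{self.residue}"


@dataclass(frozen=True)
class ResidueMap:
    """Chain-level map between structure numbering and protein positions.

    ``entries`` are (structure residue number, protein position,
    resolved) triples ordered by protein position.
    """

    structure_id: str
    chain_id: str
    entries: tuple[tuple[int, int, bool], ...]

    def __post_init__(self) -> None:
        positions = [e[1] for e in self.entries]
        if any(b >= a for a, b in zip(positions[1:], positions[:-1])):
            raise ValueError("protein positions must be strictly increasing")
        resnums = [e[0] for e in self.entries]
        if len(set(resnums)) != len(resnums):
            raise ValueError("structure residue numbers must be unique in a chain")

    def lookup(self, protein_position: int) -> tuple[int, bool] | None:
        for resnum, pos, resolved in self.entries:
            if pos == protein_position:
                return resnum, resolved
        return None


@dataclass(frozen=True)
class MappedSite:
    structure_id: str
    chain_id: str
    structure_resnum: int
    site: PTMSite


@dataclass(frozen=True)
class ChainPTMProfile:
    structure_id: str
    chain_id: str
    condition: str
    counts: dict
    total: int


def validate_sites(
    sites: Iterable[PTMSite], sequences: Mapping[str, str]
) -> tuple[list[PTMSite], list[tuple[PTMSite, str]]]:
    """Keep sites whose residue letter matches the sequence and whose
    type/residue combination is legal; everything else is rejected with
    a reason.  An accession absent from ``sequences`` is an error, not a
    rejection.
    """
    kept: list[PTMSite] = []
    rejected: list[tuple[PTMSite, str]] = []
    for site in sites:
        seq = sequences.get(site.protein_accession)
        if seq is None:
            raise KeyError(f"unknown_accession: {site.protein_accession}")
        if site.residue not in LEGAL_RESIDUES[site.ptm_type]:
            rejected.append((site, "illegal_type_residue"))
            continue
        if site.position > len(seq) or seq[site.position - 1] != site.residue:
            rejected.append((site, "residue_mismatch"))
            continue
        kept.append(site)
    return kept, rejected


def map_sites_to_chain(
    sites: Iterable[PTMSite], rmap: ResidueMap
) -> tuple[list[MappedSite], list[tuple[PTMSite, str]]]:
    """Translate protein positions into structure residue numbers.

    A site maps only if its position is present in the residue map and
    resolved; sites in gaps are dropped with reason ``gap``, sites
    outside the crystallized construct with ``not_crystallized``.
    """
    mapped: list[MappedSite] = []
    dropped: list[tuple[PTMSite, str]] = []
    for site in sites:
        hit = rmap.lookup(site.position)
        if hit is None:
            dropped.append((site, "not_crystallized"))
        elif not hit[1]:
            dropped.append((site, "gap"))
        else:
            mapped.append(
                MappedSite(rmap.structure_id, rmap.chain_id, hit[0], site)
            )
    return mapped, dropped


def per_chain_distribution(
    mapped: Sequence[MappedSite],
    all_chains: Sequence[tuple[str, str, str]] | None = None,
) -> tuple[list[ChainPTMProfile], dict[int, float]]:
    """Per-chain modification multiplicity and its normalized histogram.

    One profile per (structure, chain, condition).  ``all_chains`` may
    list (structure_id, chain_id, condition) keys that should appear
    even with zero sites, so unmodified chains enter the 0 bin.
    Histogram values are fractions of chains and sum to 1.
    """
    per_chain: dict[tuple[str, str, str], Counter] = {}
    if all_chains:
        for key in all_chains:
            per_chain.setdefault(tuple(key), Counter())
    for ms in mapped:
        key = (ms.structure_id, ms.chain_id, ms.site.condition)
        per_chain.setdefault(key, Counter())[ms.site.category] += 1

    profiles = [
        ChainPTMProfile(
            structure_id=k[0],
            chain_id=k[1],
            condition=k[2],
            counts={cat: c.get(cat, 0) for cat in CATEGORIES},
            total=sum(c.values()),
        )
        for k, c in sorted(per_chain.items())
    ]
    totals = Counter(p.total for p in profiles)
    n = len(profiles)
    histogram = {k: v / n for k, v in sorted(totals.items())} if n else {}
    return profiles, histogram


def category_totals(sites: Iterable[PTMSite]) -> tuple[dict, int]:
    """Per-category site counts and their grand total."""
    counts = {cat: 0 for cat in CATEGORIES}
    for s in sites:
        counts[s.category] += 1
    return counts, sum(counts.values())


def multi_ptm_fraction(n_modified_entries: int, n_single_ptm_entries: int) -> float:
    """Percentage of modified entries carrying more than one PTM,
    reported to one decimal."""
    if n_modified_entries == 0:
        raise ValueError("empty_set")
    if not 0 <= n_single_ptm_entries <= n_modified_entries:
        raise ValueError("require 0 <= n_single <= n_modified")
    pct = 100.0 * (n_modified_entries - n_single_ptm_entries) / n_modified_entries
    return round(pct, 1)


PTM_COLUMNS = ["accession", "position", "residue", "ptm_type", "condition", "source"]


def read_ptm_table(path) -> list[PTMSite]:
    df = pd.read_csv(path, sep="\t", dtype={"source": str}, keep_default_na=False)
    return [
        PTMSite(
            protein_accession=str(r.accession),
            position=int(r.position),
            residue=str(r.residue),
            ptm_type=str(r.ptm_type),
            condition=str(r.condition),
            source_id=str(r.source),
        )
        for r in df.itertuples()
    ]


def write_ptm_table(sites: Iterable[PTMSite], path) -> None:
    pd.DataFrame(
        [
            {
                "accession": s.protein_accession,
                "position": s.position,
                "residue": s.residue,
                "ptm_type": s.ptm_type,
                "condition": s.condition,
                "source": s.source_id,
            }
            for s in sites
        ],
        columns=PTM_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
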