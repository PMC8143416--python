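"""Dataset-selection rules for multimeric protein structures.

Structures enter the pipeline only if they are complete enough, well
resolved, non-membrane, multimeric, and carry at least one mapped PTM
site.  Duplicate representations of the same complex are collapsed to
the best structure, and the surviving set is partitioned by the growth
conditions (normal / stress) of the PTM sites mapped onto it, from
which the molecular-dynamics job inventory follows: one non-modified
control per structure plus one modified run per condition present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ChainMeta",
    "StructureMeta",
    "CurationCriteria",
    "CurationDecision",
    "ConditionCoverage",
    "JobInventory",
    "Method",
    "evaluate_structure",
    "deduplicate_complexes",
    "classify_condition_coverage",
    "count_simulation_jobs",
    "read_structure_table",
    "write_decisions",
]


class Method(str, Enum):
    XRAY = "xray"
    NMR = "nmr"
    OTHER = "other"


@dataclass(frozen=True)
class ChainMeta:
    """Per-chain metadata of a deposited structure.

    ``full_length`` is the length of the full protein, ``n_crystallized``
    the number of residues in the crystallized construct and
    ``n_resolved`` the number of residues actually observed (not in
    gaps); 0 <= n_resolved <= n_crystallized <= full_length.
    """

    chain_id: str
    protein_accession: str
    organism_tag: str = "yeast"
    is_fusion: bool = False
    has_engineered_mutations: bool = False
    full_length: int = 0
    n_crystallized: int = 0
    n_resolved: int = 0

    def __post_init__(self) -> None:
        if self.full_length <= 0:
            raise ValueError("full_length must be positive")
        if not (0 <= self.n_resolved <= self.n_crystallized <= self.full_length):
            raise ValueError(
                "require 0 <= n_resolved <= n_crystallized <= full_length"
            )

    @property
    def pct_crystallized(self) -> float:
        return 100.0 * self.n_crystallized / self.full_length

    @property
    def pct_resolved(self) -> float:
        if self.n_crystallized == 0:
            return 0.0
        return 100.0 * self.n_resolved / self.n_crystallized


@dataclass(frozen=True)
class StructureMeta:
    structure_id: str
    method: Method
    chains: tuple[ChainMeta, ...]
    resolution: float | None = None  # Å; absent for NMR
    is_membrane: bool = False

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("structure needs at least one chain")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")

    @property
    def mean_pct_crystallized(self) -> float:
        return sum(c.pct_crystallized for c in self.chains) / len(self.chains)

    @property
    def mean_pct_resolved(self) -> float:
        return sum(c.pct_resolved for c in self.chains) / len(self.chains)

    @property
    def complex_identity(self) -> tuple[str, ...]:
        """Multiset of protein accessions, the identity of the complex.

        A homodimer of P1 and a P1/P2 heterodimer differ; so do a dimer
        and a trimer of the same protein.
        """
        return tuple(sorted(c.protein_accession for c in self.chains))


@dataclass(frozen=True)
class CurationCriteria:
    min_pct_crystallized: float = 70.0
    min_pct_resolved: float = 70.0
    max_resolution: float = 3.0  # Å, inclusive ("3.0 Å or better")
    require_multimer: bool = True
    require_mapped_ptm: bool = True

    def __post_init__(self) -> None:
        for pct in (self.min_pct_crystallized, self.min_pct_resolved):
            if not 0 < pct <= 100:
                raise ValueError("percent thresholds must be in (0, 100]")
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be positive")


#: reason codes emitted by :func:`evaluate_structure`
REASONS = (
    "fusion",
    "engineered_mutations",
    "pct_crystallized",
    "pct_resolved",
    "resolution",
    "membrane",
    "monomer",
    "no_mapped_ptm",
)


@dataclass(frozen=True)
class CurationDecision:
    structure_id: str
    kept: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kept and self.reasons:
            raise ValueError("a kept structure cannot carry reject reasons")


@dataclass(frozen=True)
class ConditionCoverage:
    n_normal_only: int
    n_stress_only: int
    n_both: int

    def __post_init__(self) -> None:
        if min(self.n_normal_only, self.n_stress_only, self.n_both) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class JobInventory:
    n_nonmodified: int
    n_normal: int
    n_stress: int
    n_total: int


def evaluate_structure(
    meta: StructureMeta,
    ptm_mapped: bool,
    criteria: CurationCriteria = CurationCriteria(),
) -> CurationDecision:
    """Apply every selection criterion and enumerate the failures.

    A structure is kept iff no chain is a fusion construct or carries
    engineered mutations, the chain-averaged crystallized and resolved
    percentages meet the thresholds, the resolution is within the limit
    (X-ray only; the criterion does not apply to NMR), the complex is
    not membrane-embedded, it is a multimer, and at least one PTM site
    maps onto it.
    """
    reasons: list[str] = []
    if any(c.is_fusion for c in meta.chains):
        reasons.append("fusion")
    if any(c.has_engineered_mutations for c in meta.chains):
        reasons.append("engineered_mutations")
    if meta.mean_pct_crystallized < criteria.min_pct_crystallized:
        reasons.append("pct_crystallized")
    if meta.mean_pct_resolved < criteria.min_pct_resolved:
        reasons.append("pct_resolved")
    if meta.method is Method.XRAY:
        if meta.resolution is None:
            raise ValueError("resolution_required")
        if meta.resolution > criteria.max_resolution:
            reasons.append("resolution")
    elif meta.method is Method.OTHER:
        warnings.warn(
            f"{meta.structure_id}: method 'other', resolution criterion skipped",
            stacklevel=2,
        )
    if meta.is_membrane:
        reasons.append("membrane")
    if criteria.require_multimer and len(meta.chains) < 2:
        reasons.append("monomer")
    if criteria.require_mapped_ptm and not ptm_mapped:
        reasons.append("no_mapped_ptm")
    return CurationDecision(meta.structure_id, kept=not reasons, reasons=tuple(reasons))


def _dedup_key(meta: StructureMeta) -> tuple:
    # lowest resolution wins; NMR (no resolution) sorts last
    res = meta.resolution if meta.resolution is not None else float("inf")
    return (res, -meta.mean_pct_resolved, meta.structure_id)


def deduplicate_complexes(kept: Iterable[StructureMeta]) -> list[StructureMeta]:
    """Keep one structure per complex identity (accession multiset).

    The better structure wins: lowest resolution value, then highest
    mean resolved percentage, then lexicographically smallest id.
    Output preserves the input order of the winners.
    """
    winners: dict[tuple[str, ...], StructureMeta] = {}
    order: list[tuple[str, ...]] = []
    for meta in kept:
        key = meta.complex_identity
        if key not in winners:
            winners[key] = meta
            order.append(key)
        elif _dedup_key(meta) < _dedup_key(winners[key]):
            winners[key] = meta
    return [winners[k] for k in order]


def classify_condition_coverage(
    kept: Sequence[StructureMeta],
    structure_conditions: Mapping[str, set[str]],
) -> ConditionCoverage:
    """Bin each kept structure by the conditions of its mapped sites.

    ``structure_conditions`` maps structure_id to the set of condition
    labels ("normal" / "stress") among the PTM sites mapped onto that
    structure.  Every kept structure must carry at least one site
    (otherwise it should have been filtered out).
    """
    n_normal = n_stress = n_both = 0
    for meta in kept:
        conds = structure_conditions.get(meta.structure_id, set())
        if not conds:
            raise ValueError(
                f"{meta.structure_id}: no mapped PTM sites; "
                "structure should have been filtered"
            )
        if conds == {"normal"}:
            n_normal += 1
        elif conds == {"stress"}:
            n_stress += 1
        elif conds == {"normal", "stress"}:
            n_both += 1
        else:
            raise ValueError(f"unknown condition labels: {conds}")
    return ConditionCoverage(n_normal, n_stress, n_both)


def count_simulation_jobs(cov: ConditionCoverage) -> JobInventory:
    """Derive the MD job inventory from the condition coverage.

    Each structure gets one non-modified control; structures with
    normal-condition sites get a normal-modified run, those with
    stress-condition sites a stress-modified run (both for structures
    covered in both conditions).
    """
    n_nonmod = cov.n_normal_only + cov.n_stress_only + cov.n_both
    n_normal = cov.n_normal_only + cov.n_both
    n_stress = cov.n_stress_only + cov.n_both
    return JobInventory(n_nonmod, n_normal, n_stress, n_nonmod + n_normal + n_stress)


_STRUCT_COLS = ["structure_id", "method", "resolution", "is_membrane"]
_CHAIN_COLS = [
    "chain_id",
    "protein_accession",
    "organism_tag",
    "is_fusion",
    "has_engineered_mutations",
    "full_length",
    "n_crystallized",
    "n_resolved",
]


def read_structure_table(path) -> list[StructureMeta]:
    """Read structure metadata from a tab-separated table, one row per chain."""
    df = pd.read_csv(path, sep="\t")
    out: list[StructureMeta] = []
    for sid, grp in df.groupby("structure_id", sort=False):
        first = grp.iloc[0]
        res = first["resolution"]
        chains = tuple(
            ChainMeta(
                chain_id=str(r["chain_id"]),
                protein_accession=str(r["protein_accession"]),
                organism_tag=str(r.get("organism_tag", "yeast")),
                is_fusion=bool(r["is_fusion"]),
                has_engineered_mutations=bool(r["has_engineered_mutations"]),
                full_length=int(r["full_length"]),
                n_crystallized=int(r["n_crystallized"]),
                n_resolved=int(r["n_resolved"]),
            )
            for _, r in grp.iterrows()
        )
        out.append(
            StructureMeta(
                structure_id=str(sid),
                method=Method(str(first["method"])),
                resolution=None if pd.isna(res) else float(res),
                is_membrane=bool(first["is_membrane"]),
                chains=chains,
            )
        )
    return out


def write_structure_table(structures: Iterable[StructureMeta], path) -> None:
    rows = []
    for s in structures:
        for c in s.chains:
            rows.append(
                {
                    "structure_id": s.structure_id,
                    "method": s.method.value,
                    "resolution": s.resolution,
                    "is_membrane": s.is_membrane,
                    "chain_id": c.chain_id,
                    "protein_accession": c.protein_accession,
                    "organism_tag": c.organism_tag,
                    "is_fusion": c.is_fusion,
                    "has_engineered_mutations": c.has_engineered_mutations,
                    "full_length": c.full_length,
                    "n_crystallized": c.n_crystallized,
                    "n_resolved": c.n_resolved,
                }
            )
    pd.DataFrame(rows, columns=_STRUCT_COLS + _CHAIN_COLS).to_csv(
        path, sep="\t", index=False
    )


def write_decisions(decisions: Iterable[CurationDecision], path) -> None:
    pd.DataFrame(
        [
            {
                "structure_id": d.structure_id,
                "kept": d.kept,
                "reasons": ",".join(d.reasons),
            }
            for d in decisions
        ]
    ).to_csv(path, sep="\t", index=False)
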