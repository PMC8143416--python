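"""End-point binding free-energy bookkeeping (MM/GBSA style).

The single-snapshot free energy of a molecular species is

    G = E_bonded + E_electrostatic + E_vdW + G_polar + G_nonpolar - TS,

with the entropy term omitted by default.  The binding free energy of a
ligand subunit to the receptor (remainder of the complex) is the
snapshot average

    dG_bind = < G_complex - G_receptor - G_ligand >,

and the effect of post-translational modifications is the difference

    ddG_bind = dG_bind(modified) - dG_bind(non-modified),

negative meaning the modifications stabilize binding.  Per-residue
decomposition deltas locate the effect: a residue whose decomposed
|ddG_bind| contribution exceeds 0.5 kcal/mol is considered
interface-located.  All energies are kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "EnergyComponents",
    "PartitionScheme",
    "BindingEnergy",
    "DDGResult",
    "ResidueContributionDelta",
    "StateContributions",
    "ROLES",
    "INTERFACE_THRESHOLD",
    "total_free_energy",
    "binding_energy",
    "ddg",
    "residue_contribution_delta",
    "outstanding_residues",
    "local_vs_global_gap",
    "state_contribution_split",
    "enumerate_partitions",
    "read_snapshot_table",
    "write_snapshot_table",
    "read_decomposition_table",
    "write_decomposition_table",
    "read_mmpbsa_decomposition",
]

ROLES = ("complex", "receptor", "ligand")
INTERFACE_THRESHOLD = 0.5  # kcal/mol, strict inequality
COMPONENT_FIELDS = ("e_bonded", "e_electrostatic", "e_vdw", "g_polar", "g_nonpolar")


@dataclass(frozen=True)
class EnergyComponents:
    """One species' energy terms for one snapshot, kcal/mol."""

    e_bonded: float
    e_electrostatic: float
    e_vdw: float
    g_polar: float
    g_nonpolar: float
    ts: float | None = None  # -TS enters with a minus sign; usually omitted

    def __post_init__(self) -> None:
        vals = [self.e_bonded, self.e_electrostatic, self.e_vdw, self.g_polar, self.g_nonpolar]
        if self.ts is not None:
            vals.append(self.ts)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("energy components must be finite")


@dataclass(frozen=True)
class PartitionScheme:
    """Which subunit of an n-mer is treated as the ligand."""

    n_subunits: int
    ligand_index: int  # 1-based

    def __post_init__(self) -> None:
        if self.n_subunits < 2:
            raise ValueError("a complex needs at least two subunits")
        if not 1 <= self.ligand_index <= self.n_subunits:
            raise ValueError("ligand_index out of range")


@dataclass(frozen=True)
class BindingEnergy:
    mean: float  # <dG_bind>, kcal/mol
    sem: float | None  # absent for a single snapshot
    n_snapshots: int
    role_means: dict  # mean G per role

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValueError("need at least one snapshot")
        if self.sem is not None and self.sem < 0:
            raise ValueError("sem must be non-negative")


@dataclass(frozen=True)
class DDGResult:
    ddg: float  # kcal/mol
    effect: str  # stabilizing | destabilizing | neutral


@dataclass(frozen=True)
class ResidueContributionDelta:
    chain_id: str
    resnum: int
    contribution_modified: float
    contribution_nonmodified: float
    delta: float
    interface: bool
    flag: str = ""  # absent_in_modified / absent_in_nonmodified


@dataclass(frozen=True)
class StateContributions:
    dg_complex: float
    dg_receptor: float
    dg_ligand: float
    pct_complex: float
    pct_receptor: float
    pct_ligand: float
    implied_ddg: float


def total_free_energy(c: EnergyComponents) -> float:
    """Single-snapshot free energy; the entropy term is subtracted only
    when supplied."""
    g = c.e_bonded + c.e_electrostatic + c.e_vdw + c.g_polar + c.g_nonpolar
    if c.ts is not None:
        g -= c.ts
    return g


def binding_energy(
    snapshots: pd.DataFrame, partition: PartitionScheme | None = None
) -> BindingEnergy:
    """Snapshot-averaged dG_bind from a per-snapshot, per-role table.

    ``snapshots`` holds one row per (snapshot, role) with the component
    columns; every snapshot index must carry all three roles.  The SEM
    uses the sample standard deviation (n-1) and is absent for n = 1.
    """
    df = snapshots.copy()
    df["g"] = df[list(COMPONENT_FIELDS)].sum(axis=1)
    if "ts" in df.columns:
        df["g"] -= df["ts"].fillna(0.0)
    pivot = df.pivot_table(index="snapshot", columns="role", values="g", aggfunc="first")
    missing = [r for r in ROLES if r not in pivot.columns]
    if missing or pivot[list(ROLES)].isna().any().any():
        raise ValueError("incomplete_snapshot")
    per_snap = pivot["complex"] - pivot["receptor"] - pivot["ligand"]
    n = len(per_snap)
    sem = float(per_snap.std(ddof=1) / math.sqrt(n)) if n > 1 else None
    return BindingEnergy(
        mean=float(per_snap.mean()),
        sem=sem,
        n_snapshots=n,
        role_means={r: float(pivot[r].mean()) for r in ROLES},
    )


def ddg(modified: BindingEnergy, nonmodified: BindingEnergy) -> DDGResult:
    """ddG_bind = dG(modified) - dG(non-modified); sign gives the effect."""
    value = modified.mean - nonmodified.mean
    if value < 0:
        effect = "stabilizing"
    elif value > 0:
        effect = "destabilizing"
    else:
        effect = "neutral"
    return DDGResult(ddg=value, effect=effect)


def residue_contribution_delta(
    mod: Mapping[tuple[str, int], float],
    nonmod: Mapping[tuple[str, int], float],
    threshold: float = INTERFACE_THRESHOLD,
) -> list[ResidueContributionDelta]:
    """Per-residue contribution differences between the variants.

    Residues present in only one variant (gap asymmetry between the
    subunits) contribute 0 in the other and are flagged.  Interface
    classification is |delta| strictly greater than the threshold.
    """
    out: list[ResidueContributionDelta] = []
    for key in sorted(set(mod) | set(nonmod)):
        m = mod.get(key)
        nm = nonmod.get(key)
        flag = ""
        if m is None:
            m, flag = 0.0, "absent_in_modified"
        if nm is None:
            nm, flag = 0.0, "absent_in_nonmodified"
        delta = m - nm
        out.append(
            ResidueContributionDelta(
                chain_id=key[0],
                resnum=key[1],
                contribution_modified=m,
                contribution_nonmodified=nm,
                delta=delta,
                interface=abs(delta) > threshold,
                flag=flag,
            )
        )
    return out


def outstanding_residues(
    deltas: Iterable[ResidueContributionDelta], cutoff: float = 5.0
) -> list[ResidueContributionDelta]:
    """Residues whose contribution difference between variants is
    outstanding (|delta| > cutoff, default 5 kcal/mol) — the case-study
    shortlist of modified and non-modified residues that change binding
    the most."""
    return [d for d in deltas if abs(d.delta) > cutoff]


def local_vs_global_gap(
    chain_ddg: float, site_deltas: Iterable[float], sem: float
) -> tuple[float, str]:
    """Gap between a chain's overall ddG_bind and the sum of its local
    per-site contributions; a gap outside +/- sem indicates long-range
    (allosteric) effects.
    """
    gap = chain_ddg - sum(site_deltas)
    if abs(gap) <= sem:
        return gap, "local_explains"
    return gap, "long_range_destabilizing" if gap > 0 else "long_range_stabilizing"


def state_contribution_split(
    role_means_modified: Mapping[str, float],
    role_means_nonmodified: Mapping[str, float],
) -> StateContributions:
    """Split ddG_bind into bound (complex) and unbound (receptor,
    ligand) state contributions.

    Each role's dG (modified minus non-modified mean G) is expressed as
    a signed percentage of the sum of the three absolute dG values, so
    the absolute percentages sum to 100.
    """
    dgs = {
        r: role_means_modified[r] - role_means_nonmodified[r] for r in ROLES
    }
    denom = sum(abs(v) for v in dgs.values())
    if denom == 0:
        raise ValueError("degenerate_split")
    pct = {r: 100.0 * dgs[r] / denom for r in ROLES}
    return StateContributions(
        dg_complex=dgs["complex"],
        dg_receptor=dgs["receptor"],
        dg_ligand=dgs["ligand"],
        pct_complex=pct["complex"],
        pct_receptor=pct["receptor"],
        pct_ligand=pct["ligand"],
        implied_ddg=dgs["complex"] - dgs["receptor"] - dgs["ligand"],
    )


def enumerate_partitions(n_subunits: int) -> list[PartitionScheme]:
    """All n ligand-vs-rest partitions of an n-meric complex."""
    return [PartitionScheme(n_subunits, i) for i in range(1, n_subunits + 1)]


# ---------------------------------------------------------------------------
# readers / writers

_SNAPSHOT_COLS = ["snapshot", "time", "role"] + list(COMPONENT_FIELDS)
_UNITS_HEADER = "# units: kcal/mol"


def _check_units(path) -> None:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        if first != _UNITS_HEADER:
            raise ValueError(
                f"unsupported units declaration {first!r}; "
                "tables must be kcal/mol (no conversion is attempted)"
            )


def read_snapshot_table(path) -> pd.DataFrame:
    """Tab-separated snapshot energy table; a leading ``# units:`` line
    must declare kcal/mol — other units are refused, never converted."""
    _check_units(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _SNAPSHOT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"snapshot table missing columns: {missing}")
    return df


def write_snapshot_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_UNITS_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_decomposition_table(path) -> dict[tuple[str, int], float]:
    """Per-residue contribution table: columns chain, resnum, contribution."""
    _check_units(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        (str(r.chain), int(r.resnum)): float(r.contribution) for r in df.itertuples()
    }


def write_decomposition_table(contrib: Mapping[tuple[str, int], float], path) -> None:
    with open(path, "w") as fh:
        fh.write(_UNITS_HEADER + "\n")
        pd.DataFrame(
            [
                {"chain": k[0], "resnum": k[1], "contribution": v}
                for k, v in sorted(contrib.items())
            ]
        ).to_csv(fh, sep="\t", index=False)


def read_mmpbsa_decomposition(path) -> dict[tuple[str, int], float]:
    """Read the comma-separated per-residue decomposition dialect
    (section headers, ``Residue`` rows like ``R A 42``, TOTAL column
    last).  Only the total-energy section is consumed.
    """
    rows: list[tuple[str, int, float]] = []
    in_section = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.lower().startswith("total energy decomposition"):
                in_section = True
                continue
            if in_section and line.endswith(":"):  # next section header
                break
            if in_section and "," in line:
                parts = [p.strip() for p in line.split(",")]
                if parts[0] == "Residue":  # column header row
                    continue
                toks = parts[0].split()
                if len(toks) != 3:
                    continue
                _, chain, resnum = toks
                rows.append((chain, int(resnum), float(parts[-1])))
    if not rows:
        raise ValueError("no residue rows found in decomposition file")
    return {(c, n): v for c, n, v in rows}
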