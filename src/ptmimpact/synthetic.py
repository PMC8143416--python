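"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data the analysis consumes — structure
metadata, PTM database exports, MM/GBSA-style snapshot energy and
per-residue decomposition tables, trajectory pairs, orthologue
alignments with a taxonomy — with controlled effect sizes and noise,
so every stage is testable without external downloads.

Effect structure of the energy generator: each PTM site carries a true
local binding contribution drawn around a type-specific mean
(acetylation stabilizing, mu = -1.0 kcal/mol; phosphorylation
destabilizing, mu = +1.5 / +1.0 / +1.0 kcal/mol for S/T/Y), and each
chain a long-range (allosteric) term spread over non-site residues.
Snapshot noise is centred within each run, so the realized mean
per-snapshot binding energy difference between the modified and
non-modified variant equals the sum of local terms plus the long-range
term exactly, and the per-residue decomposition sums to the mean
binding energy of its variant.

All generators are pure functions of the configuration: the root seed
is combined with a per-generator stream name, so adding a generator
never perturbs the output of another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import catalog, conformation, conservation, curation, energetics

__all__ = [
    "GeneratorConfig",
    "CurationFixture",
    "EnergyGroundTruth",
    "gen_curation_fixtures",
    "gen_ptm_table",
    "gen_energy_tables",
    "gen_trajectory_pair",
    "gen_alignment_and_tree",
    "generate_cohort",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: type-specific mean local contributions, kcal/mol
DEFAULT_MU = {
    "acetyl_K": -1.0,
    "phospho_S": +1.5,
    "phospho_T": +1.0,
    "phospho_Y": +1.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    # cohort shape
    n_complexes: int = 20
    n_subunits: int = 2
    chain_length: int = 120
    # PTM densities: probability that an eligible residue carries the PTM
    density_acetyl: float = 0.15
    density_phospho_S: float = 0.10
    density_phospho_T: float = 0.05
    density_phospho_Y: float = 0.02
    invalid_row_rate: float = 0.05
    # energy effect parameters, kcal/mol
    mu_acetyl: float = -1.0
    mu_phospho_S: float = +1.5
    mu_phospho_T: float = +1.0
    mu_phospho_Y: float = +1.0
    sigma_local: float = 0.5
    sigma_longrange: float = 2.0
    sigma_unbound: float = 1.0
    n_snapshots: int = 100
    snapshot_noise_sd: float = 2.0
    # alignment / taxonomy
    n_orthologs: int = 50
    conservation_p: float = 0.7
    # trajectories
    n_frames: int = 50
    n_residues: int = 30
    drift: float = 1.5
    jitter_sd: float = 0.3

    def __post_init__(self) -> None:
        for sd in (self.sigma_local, self.sigma_longrange, self.sigma_unbound,
                   self.snapshot_noise_sd, self.jitter_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        for p in (self.density_acetyl, self.density_phospho_S,
                  self.density_phospho_T, self.density_phospho_Y,
                  self.invalid_row_rate, self.conservation_p):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    def mu_for(self, category: str) -> float:
        return {
            "acetyl_K": self.mu_acetyl,
            "phospho_S": self.mu_phospho_S,
            "phospho_T": self.mu_phospho_T,
            "phospho_Y": self.mu_phospho_Y,
        }[category]


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    """Named substream: root seed + CRC of the stream name."""
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, zlib.crc32(stream.encode())]
    )


# ---------------------------------------------------------------------------
# curation fixtures

@dataclass(frozen=True)
class CurationFixture:
    meta: curation.StructureMeta
    ptm_mapped: bool
    tag: str  # "pass", "fail_<reason>", "dup_<k>"
    expected: curation.CurationDecision


def _chain(rng, chain_id="A", accession="P00001", **kw) -> curation.ChainMeta:
    defaults = dict(
        chain_id=chain_id,
        protein_accession=accession,
        full_length=100,
        n_crystallized=90,
        n_resolved=85,
    )
    defaults.update(kw)
    return curation.ChainMeta(**defaults)


def gen_curation_fixtures(config: GeneratorConfig) -> list[CurationFixture]:
    """Deterministic mixture of structures: one failing each single
    criterion, clean passes (X-ray and NMR), and duplicate complex
    identities for the deduplication rules."""
    rng = _rng(config, "curation")
    fixtures: list[CurationFixture] = []

    def add(meta, ptm_mapped, tag, reasons):
        fixtures.append(
            CurationFixture(
                meta=meta,
                ptm_mapped=ptm_mapped,
                tag=tag,
                expected=curation.CurationDecision(
                    meta.structure_id, kept=not reasons, reasons=tuple(reasons)
                ),
            )
        )

    def dimer(sid, acc1="P00001", acc2="P00002", res=2.0, **kw):
        return curation.StructureMeta(
            structure_id=sid,
            method=curation.Method.XRAY,
            resolution=res,
            chains=(
                _chain(rng, "A", acc1, **kw.pop("chain_kw", {})),
                _chain(rng, "B", acc2),
            ),
            **kw,
        )

    add(dimer("1PAS"), True, "pass", [])
    add(
        curation.StructureMeta(
            "1NMR",
            curation.Method.NMR,
            (
                _chain(rng, "A", "P00003", n_crystallized=80, n_resolved=68),
                _chain(rng, "B", "P00004", n_crystallized=80, n_resolved=68),
            ),
        ),
        True,
        "pass_nmr",
        [],
    )
    add(dimer("2RES", res=3.2), True, "fail_resolution", ["resolution"])
    add(
        dimer("2FUS", chain_kw={"is_fusion": True}),
        True,
        "fail_fusion",
        ["fusion"],
    )
    add(
        dimer("2MUT", chain_kw={"has_engineered_mutations": True}),
        True,
        "fail_engineered_mutations",
        ["engineered_mutations"],
    )
    add(
        dimer("2CRY", chain_kw={"n_crystallized": 45, "n_resolved": 40}),
        True,
        "fail_pct_crystallized",
        ["pct_crystallized"],
    )
    add(
        dimer("2GAP", chain_kw={"n_crystallized": 90, "n_resolved": 30}),
        True,
        "fail_pct_resolved",
        ["pct_resolved"],
    )
    add(dimer("2MEM", is_membrane=True), True, "fail_membrane", ["membrane"])
    add(
        curation.StructureMeta(
            "2MON", curation.Method.XRAY, (_chain(rng, "A", "P00005"),), resolution=1.8
        ),
        True,
        "fail_monomer",
        ["monomer"],
    )
    add(dimer("2PTM"), False, "fail_no_mapped_ptm", ["no_mapped_ptm"])

    # duplicate complex identities: same accession multiset, ranked by
    # resolution then completeness
    add(dimer("3DUP", "P00010", "P00011", res=2.0), True, "dup_best", [])
    add(dimer("3DUQ", "P00011", "P00010", res=2.5), True, "dup_worse", [])
    add(
        dimer("4DUP", "P00012", "P00012", res=2.2,
              chain_kw={"n_resolved": 88}),
        True,
        "dup_tie_best",
        [],
    )
    add(dimer("4DUQ", "P00012", "P00012", res=2.2), True, "dup_tie_worse", [])

    # filler passing structures with randomized completeness
    for i in range(config.n_complexes):
        n_cr = int(rng.integers(80, 101))
        n_res = int(rng.integers(int(0.8 * n_cr), n_cr + 1))
        add(
            curation.StructureMeta(
                f"5F{i:02d}",
                curation.Method.XRAY,
                (
                    _chain(rng, "A", f"P1{i:04d}", n_crystallized=n_cr, n_resolved=n_res),
                    _chain(rng, "B", f"P2{i:04d}", n_crystallized=n_cr, n_resolved=n_res),
                ),
                resolution=float(np.round(rng.uniform(1.5, 3.0), 2)),
            ),
            True,
            "pass_random",
            [],
        )
    return fixtures


# ---------------------------------------------------------------------------
# PTM tables

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_ptm_table(
    config: GeneratorConfig, n_proteins: int = 10
) -> tuple[list[catalog.PTMSite], dict[str, str], list[str]]:
    """PTM table with matching sequences and deliberate invalid rows.

    Returns (sites, sequences, invalid_source_ids); the invalid rows
    carry a wrong residue letter and are exactly the ones
    ``validate_sites`` must reject.
    """
    rng = _rng(config, "ptm_table")
    sequences = {
        f"P{k:05d}": _random_sequence(rng, config.chain_length)
        for k in range(n_proteins)
    }
    density = {
        "K": ("acetylation", config.density_acetyl),
        "S": ("phosphorylation", config.density_phospho_S),
        "T": ("phosphorylation", config.density_phospho_T),
        "Y": ("phosphorylation", config.density_phospho_Y),
    }
    sites: list[catalog.PTMSite] = []
    invalid: list[str] = []
    counter = 0
    for acc, seq in sequences.items():
        for pos, residue in enumerate(seq, start=1):
            if residue not in density:
                continue
            ptm_type, p = density[residue]
            if rng.random() >= p:
                continue
            counter += 1
            source = f"syn{counter:05d}"
            if ptm_type == "acetylation":
                condition = "normal"  # acetylation sites observed in normal growth
            else:
                condition = "normal" if rng.random() < 0.6 else "stress"
            if rng.random() < config.invalid_row_rate:
                # residue letter that contradicts the sequence
                wrong = "K" if residue != "K" else "S"
                sites.append(
                    catalog.PTMSite(acc, pos, wrong,
                                    "acetylation" if wrong == "K" else "phosphorylation",
                                    condition, source)
                )
                invalid.append(source)
            else:
                sites.append(
                    catalog.PTMSite(acc, pos, residue, ptm_type, condition, source)
                )
    return sites, sequences, invalid


# ---------------------------------------------------------------------------
# energy tables

@dataclass(frozen=True)
class EnergyGroundTruth:
    true_local: dict  # (chain, resnum) -> local contribution, kcal/mol
    longrange: float  # chain-level allosteric term, kcal/mol
    true_ddg: float  # sum of locals + longrange
    dg_receptor: float  # unbound-state shifts
    dg_ligand: float


def _components_for(rng: np.random.Generator, g: float) -> dict[str, float]:
    """Split a total G into the five component columns."""
    parts = rng.normal(0.0, 5.0, size=4)
    return {
        "e_bonded": float(parts[0]),
        "e_electrostatic": float(parts[1]),
        "e_vdw": float(parts[2]),
        "g_polar": float(parts[3]),
        "g_nonpolar": float(g - parts.sum()),
    }


def _role_rows(
    rng: np.random.Generator,
    role: str,
    g_per_snapshot: np.ndarray,
) -> list[dict]:
    rows = []
    for t, g in enumerate(g_per_snapshot):
        row = {"snapshot": t, "time": float(t * 100.0), "role": role}
        row.update(_components_for(rng, float(g)))
        rows.append(row)
    return rows


def gen_energy_tables(
    config: GeneratorConfig,
    site_keys: Sequence[tuple[str, int, str]],
    stream: str = "energy",
) -> tuple[pd.DataFrame, pd.DataFrame, dict, dict, EnergyGroundTruth]:
    """Snapshot energy tables and decompositions for one variant pair.

    ``site_keys`` are (chain, resnum, category) triples of the PTM
    sites present in the modified variant.  Returns
    (snapshots_nonmod, snapshots_mod, contrib_nonmod, contrib_mod,
    ground_truth).
    """
    rng = _rng(config, stream)
    chains = [chr(ord("A") + i) for i in range(config.n_subunits)]
    residues = [(c, r) for c in chains for r in range(1, config.chain_length + 1)]
    site_pos = {(c, r): cat for c, r, cat in site_keys}
    for key in site_pos:
        if key not in set(residues):
            raise ValueError(f"site {key} outside the complex")

    baseline = {key: float(v) for key, v in
                zip(residues, rng.normal(-10.0 / len(residues), 0.2, len(residues)))}

    true_local = {
        key: float(rng.normal(config.mu_for(cat), config.sigma_local))
        for key, cat in site_pos.items()
    }
    longrange = float(rng.normal(0.0, config.sigma_longrange))

    contrib_nonmod = dict(baseline)
    contrib_mod = dict(baseline)
    for key, local in true_local.items():
        contrib_mod[key] = contrib_mod[key] + local
    # long-range term spread over non-site residues
    nonsite = [k for k in residues if k not in site_pos]
    carriers = [nonsite[i] for i in rng.choice(len(nonsite), size=min(10, len(nonsite)), replace=False)]
    for key in carriers:
        contrib_mod[key] = contrib_mod[key] + longrange / len(carriers)

    dg_nonmod = sum(contrib_nonmod.values())
    true_ddg = sum(true_local.values()) + longrange
    dg_mod = dg_nonmod + true_ddg

    # unbound-state shifts in the modified variant
    u_rec = float(rng.normal(0.0, config.sigma_unbound))
    u_lig = float(rng.normal(0.0, config.sigma_unbound))

    n = config.n_snapshots

    def centred(sd: float) -> np.ndarray:
        x = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        return x - x.mean() if n > 1 else np.zeros(n)

    g_rec0, g_lig0 = -2000.0, -1000.0
    tables = {}
    for variant, (dg, rec_shift, lig_shift) in {
        "nonmod": (dg_nonmod, 0.0, 0.0),
        "mod": (dg_mod, u_rec, u_lig),
    }.items():
        g_rec = g_rec0 + rec_shift + centred(config.snapshot_noise_sd)
        g_lig = g_lig0 + lig_shift + centred(config.snapshot_noise_sd)
        g_cpx = g_rec + g_lig + dg + centred(config.snapshot_noise_sd)
        rows = (
            _role_rows(rng, "complex", g_cpx)
            + _role_rows(rng, "receptor", g_rec)
            + _role_rows(rng, "ligand", g_lig)
        )
        tables[variant] = pd.DataFrame(rows)

    truth = EnergyGroundTruth(
        true_local=true_local,
        longrange=longrange,
        true_ddg=true_ddg,
        dg_receptor=u_rec,
        dg_ligand=u_lig,
    )
    return tables["nonmod"], tables["mod"], contrib_nonmod, contrib_mod, truth


# ---------------------------------------------------------------------------
# trajectories

def _helix_backbone(n_residues: int) -> np.ndarray:
    """CA trace of an ideal alpha helix: 2.3 Å radius, 1.5 Å rise,
    100 degrees per residue."""
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    )


def _bending_mode(n_residues: int) -> np.ndarray:
    """Unit-RMS non-rigid displacement field along the chain."""
    i = np.arange(n_residues)
    mode = np.column_stack(
        [
            np.sin(2 * np.pi * i / n_residues),
            np.cos(3 * np.pi * i / n_residues),
            np.sin(4 * np.pi * i / n_residues + 0.5),
        ]
    )
    mode -= mode.mean(axis=0)
    return mode / np.sqrt(np.mean(np.sum(mode**2, axis=1)))


def gen_trajectory_pair(
    config: GeneratorConfig, delta: float = 0.0, stream: str = "trajectory"
) -> tuple[conformation.Trajectory, conformation.Trajectory, float]:
    """Toy helical trajectories sharing an initial frame.

    Both runs drift away from the start through a non-rigid bending
    mode with thermal jitter; the modified run additionally converges
    to an endpoint displaced by ``delta`` (Å, RMS of the displacement
    field) along an independent mode, so the recovered
    representative-vs-representative RMSD grows with delta.
    Returns (nonmodified, modified, delta).
    """
    rng = _rng(config, stream)
    n_res, n_frames = config.n_residues, config.n_frames
    x0 = _helix_backbone(n_res)
    labels = tuple(
        conformation.AtomLabel("A", i + 1, "CA", True) for i in range(n_res)
    )
    mode_common = _bending_mode(n_res)
    mode_delta = np.roll(_bending_mode(n_res), n_res // 3, axis=0)
    mode_delta -= mode_delta.mean(axis=0)
    mode_delta /= np.sqrt(np.mean(np.sum(mode_delta**2, axis=1)))

    times = np.arange(1.0, n_frames + 1)
    progress = times / n_frames

    def build(extra: float) -> conformation.Trajectory:
        frames = []
        for k, s in enumerate(progress):
            jitter = rng.normal(0.0, config.jitter_sd, size=(n_res, 3))
            coords = (
                x0
                + s * config.drift * mode_common
                + s * extra * mode_delta
                + jitter
            )
            frames.append(conformation.Frame(coords=coords, labels=labels))
        return conformation.Trajectory(frames=tuple(frames), times=times)

    return build(0.0), build(delta), delta


# ---------------------------------------------------------------------------
# alignments and taxonomy

def gen_alignment_and_tree(
    config: GeneratorConfig,
    sites: Sequence[tuple[int, str, str]] | None = None,
    stream: str = "alignment",
) -> tuple[conservation.Alignment, conservation.TaxonomyTree, dict[int, float]]:
    """Orthologue alignment plus taxonomy with known conservation.

    ``sites`` are (position, ptm_type, residue) triples on the
    reference; by default a spread of acetyl and phospho sites is
    placed along the sequence.  At each site every orthologue conserves
    with probability ``conservation_p``, acetylation realized at the
    column or one off with equal chance.  Returns the ground-truth
    probability per site position.
    """
    rng = _rng(config, stream)
    length = max(60, config.chain_length)
    if sites is None:
        sites = []
        pos = 5
        kinds = [("acetylation", "K"), ("phosphorylation", "S"),
                 ("phosphorylation", "T"), ("phosphorylation", "Y")]
        k = 0
        while pos < length - 5:
            sites.append((pos, *kinds[k % len(kinds)]))
            k += 1
            pos += 7
    # reference: random sequence with the site residues planted and the
    # acetylation +/-1 windows kept lysine-free
    ref = list(_random_sequence(rng, length))
    controlled: set[int] = set()
    for pos, ptm_type, residue in sites:
        col = pos - 1
        window = (col - 1, col, col + 1) if ptm_type == "acetylation" else (col,)
        for c in window:
            if 0 <= c < length:
                controlled.add(c)
        ref[col] = residue
        if ptm_type == "acetylation":
            for c in (col - 1, col + 1):
                if 0 <= c < length and ref[c] == "K":
                    ref[c] = "A"

    taxa = [f"t{i:03d}" for i in range(config.n_orthologs)]
    records = [("4932", "Saccharomyces cerevisiae", "".join(ref))]
    p = config.conservation_p
    for taxon in taxa:
        seq = [
            ch if rng.random() < 0.6 else str(rng.choice(list(AMINO_ACIDS)))
            for ch in ref
        ]
        # scrub accidental matches in controlled windows, then realize
        # conservation with the configured probability
        for pos, ptm_type, residue in sites:
            col = pos - 1
            if ptm_type == "acetylation":
                for c in (col - 1, col, col + 1):
                    if 0 <= c < length:
                        seq[c] = "A"
                if rng.random() < p:
                    offset = int(rng.integers(-1, 2))
                    c = min(max(col + offset, 0), length - 1)
                    seq[c] = "K"
            else:
                ok = {"S", "T"} if residue in ("S", "T") else {"Y"}
                if rng.random() < p:
                    seq[col] = str(rng.choice(sorted(ok)))
                elif seq[col] in ok:
                    seq[col] = "A"
        records.append((taxon, taxon, "".join(seq)))

    aln = conservation.Alignment(records=tuple(records), reference_index=0)
    tree = _random_tree(rng, ["4932"] + taxa)
    truth = {pos: p for pos, _, _ in sites}
    return aln, tree, truth


def _random_tree(rng: np.random.Generator, leaves: list[str]) -> conservation.TaxonomyTree:
    """Random binary taxonomy over the given leaf ids."""
    nodes: list[tuple[str, str, str | None]] = []
    counter = 0

    def split(members: list[str], parent: str | None) -> None:
        nonlocal counter
        if len(members) == 1:
            nodes.append((members[0], members[0], parent))
            return
        node_id = f"n{counter:03d}"
        counter += 1
        nodes.append((node_id, node_id, parent))
        k = int(rng.integers(1, len(members)))
        order = rng.permutation(len(members))
        left = [members[i] for i in order[:k]]
        right = [members[i] for i in order[k:]]
        split(left, node_id)
        split(right, node_id)

    split(list(leaves), None)
    return conservation.TaxonomyTree(nodes)


# ---------------------------------------------------------------------------
# cohort driver

def _cohort_sites(
    rng: np.random.Generator, config: GeneratorConfig
) -> list[tuple[str, int, str]]:
    """Site keys (chain, resnum, category) for one complex."""
    chains = [chr(ord("A") + i) for i in range(config.n_subunits)]
    cats = ["acetyl_K", "phospho_S", "phospho_T", "phospho_Y"]
    weights = np.array([
        config.density_acetyl, config.density_phospho_S,
        config.density_phospho_T, config.density_phospho_Y,
    ])
    weights = weights / weights.sum()
    keys: list[tuple[str, int, str]] = []
    used: set[tuple[str, int]] = set()
    n_sites = int(rng.integers(2, 7))
    while len(keys) < n_sites:
        chain = str(rng.choice(chains))
        resnum = int(rng.integers(1, config.chain_length + 1))
        if (chain, resnum) in used:
            continue
        used.add((chain, resnum))
        keys.append((chain, resnum, str(rng.choice(cats, p=weights))))
    return keys


def generate_cohort(config: GeneratorConfig) -> list[dict]:
    """One entry per complex: site keys, energy tables, decompositions
    and ground truth, ready for the energetics pipeline."""
    rng = _rng(config, "cohort")
    cohort = []
    for i in range(config.n_complexes):
        site_keys = _cohort_sites(rng, config)
        snap_nm, snap_m, dec_nm, dec_m, truth = gen_energy_tables(
            config, site_keys, stream=f"energy/{i}"
        )
        cohort.append(
            {
                "complex_id": f"C{i:03d}",
                "site_keys": site_keys,
                "snapshots_nonmod": snap_nm,
                "snapshots_mod": snap_m,
                "contrib_nonmod": dec_nm,
                "contrib_mod": dec_m,
                "truth": truth,
            }
        )
    return cohort


def write_cohort(config: GeneratorConfig, out_dir) -> None:
    """Emit a complete fixture cohort as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fixtures = gen_curation_fixtures(config)
    curation.write_structure_table((f.meta for f in fixtures), out / "structures.tsv")

    sites, sequences, invalid = gen_ptm_table(config)
    catalog.write_ptm_table(sites, out / "ptm_sites.tsv")
    with open(out / "sequences.fasta", "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n{seq}\n")

    cohort = generate_cohort(config)
    for entry in cohort:
        cid = entry["complex_id"]
        energetics.write_snapshot_table(
            entry["snapshots_nonmod"], out / f"{cid}_nonmod_snapshots.tsv"
        )
        energetics.write_snapshot_table(
            entry["snapshots_mod"], out / f"{cid}_mod_snapshots.tsv"
        )
        energetics.write_decomposition_table(
            entry["contrib_nonmod"], out / f"{cid}_nonmod_decomp.tsv"
        )
        energetics.write_decomposition_table(
            entry["contrib_mod"], out / f"{cid}_mod_decomp.tsv"
        )

    traj_nm, traj_m, delta = gen_trajectory_pair(config, delta=2.0)
    conformation.write_xyz_trajectory(traj_nm, out / "traj_nonmod.xyz")
    conformation.write_xyz_trajectory(traj_m, out / "traj_mod.xyz")

    aln, tree, truth_p = gen_alignment_and_tree(config)
    conservation.write_alignment_fasta(aln, out / "alignment.fasta")
    with open(out / "taxonomy.tsv", "w") as fh:
        fh.write("node_id\tname\tparent_id\n")
        for node_id, name in tree.names.items():
            parent = tree.parent[node_id] or ""
            fh.write(f"{node_id}\t{name}\t{parent}\n")

    truth = {
        "invalid_ptm_sources": invalid,
        "trajectory_delta": delta,
        "conservation_p": truth_p,
        "per_complex": {
            e["complex_id"]: {
                "true_ddg": e["truth"].true_ddg,
                "longrange": e["truth"].longrange,
                "true_local": {
                    f"{c}:{r}": v for (c, r), v in e["truth"].true_local.items()
                },
            }
            for e in cohort
        },
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
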