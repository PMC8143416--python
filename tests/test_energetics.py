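"""Free-energy bookkeeping, decomposition deltas and the state split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ptmimpact import synthetic
from ptmimpact.energetics import (
    BindingEnergy,
    EnergyComponents,
    PartitionScheme,
    binding_energy,
    ddg,
    enumerate_partitions,
    local_vs_global_gap,
    read_decomposition_table,
    read_mmpbsa_decomposition,
    read_snapshot_table,
    residue_contribution_delta,
    state_contribution_split,
    total_free_energy,
    write_decomposition_table,
    write_snapshot_table,
)


def snapshot_df(g_complex, g_receptor, g_ligand):
    """Build a snapshot table with the requested per-role totals."""
    rows = []
    for role, gs in (
        ("complex", g_complex), ("receptor", g_receptor), ("ligand", g_ligand)
    ):
        for t, g in enumerate(gs):
            rows.append(
                {
                    "snapshot": t, "time": float(t), "role": role,
                    "e_bonded": g, "e_electrostatic": 0.0, "e_vdw": 0.0,
                    "g_polar": 0.0, "g_nonpolar": 0.0,
                }
            )
    return pd.DataFrame(rows)


class TestTotalFreeEnergy:
    def test_sum_without_entropy(self):
        assert total_free_energy(EnergyComponents(1, 2, 3, 4, 5)) == 15

    def test_zero(self):
        assert total_free_energy(EnergyComponents(0, 0, 0, 0, 0)) == 0

    def test_entropy_subtracted_when_present(self):
        assert total_free_energy(EnergyComponents(1, 2, 3, 4, 5, ts=2)) == 13

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            EnergyComponents(float("nan"), 0, 0, 0, 0)


class TestBindingEnergy:
    def test_constant_per_snapshot_delta(self):
        be = binding_energy(snapshot_df([-100, -102], [-40, -40], [-50, -52]))
        assert be.mean == pytest.approx(-10.0)
        assert be.sem == pytest.approx(0.0)

    def test_single_snapshot_has_no_sem(self):
        be = binding_energy(snapshot_df([-100], [-40], [-50]))
        assert be.mean == pytest.approx(-10.0)
        assert be.sem is None and be.n_snapshots == 1

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(11)
        gc, gr, gl = (rng.normal(size=100) for _ in range(3))
        be = binding_energy(snapshot_df(gc, gr, gl))
        brute = sum(gc[i] - gr[i] - gl[i] for i in range(100)) / 100
        assert be.mean == pytest.approx(brute, abs=1e-12)

    def test_invariant_to_snapshot_order(self):
        rng = np.random.default_rng(5)
        df = snapshot_df(*(rng.normal(size=20) for _ in range(3)))
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a, b = binding_energy(df), binding_energy(shuffled)
        assert a.mean == pytest.approx(b.mean) and a.sem == pytest.approx(b.sem)

    def test_missing_role_is_error(self):
        df = snapshot_df([-100], [-40], [-50])
        with pytest.raises(ValueError, match="incomplete_snapshot"):
            binding_energy(df[df.role != "ligand"])


class TestDDG:
    def be(self, mean):
        return BindingEnergy(mean=mean, sem=0.1, n_snapshots=10, role_means={})

    @pytest.mark.parametrize(
        "mod, nonmod, value, effect",
        [
            (-10, -7, -3, "stabilizing"),
            (-7, -7, 0, "neutral"),
            (-5, -9, +4, "destabilizing"),
        ],
    )
    def test_sign_classification(self, mod, nonmod, value, effect):
        res = ddg(self.be(mod), self.be(nonmod))
        assert res.ddg == pytest.approx(value) and res.effect == effect


class TestResidueDeltas:
    def test_delta_and_interface_rule(self):
        (d,) = residue_contribution_delta({("A", 1): -2.0}, {("A", 1): -0.5})
        assert d.delta == pytest.approx(-1.5) and d.interface

    def test_boundary_is_not_interface(self):
        # the rule is strictly "larger than 0.5 kcal/mol"
        (d,) = residue_contribution_delta({("A", 1): 0.5}, {("A", 1): 0.0})
        assert d.delta == pytest.approx(0.5) and not d.interface

    def test_residue_missing_in_one_variant_flagged(self):
        (d,) = residue_contribution_delta({("A", 1): -1.0}, {})
        assert d.delta == pytest.approx(-1.0)
        assert d.flag == "absent_in_nonmodified"
        assert d.contribution_nonmodified == 0.0

    def test_outstanding_residue_shortlist(self):
        from ptmimpact.energetics import outstanding_residues

        deltas = residue_contribution_delta(
            {("A", 1): -6.0, ("A", 2): -5.0, ("B", 3): 7.5},
            {("A", 1): 0.0, ("A", 2): 0.0, ("B", 3): 0.0},
        )
        # strictly larger than the 5 kcal/mol cutoff
        picked = outstanding_residues(deltas)
        assert [(d.chain_id, d.resnum) for d in picked] == [("A", 1), ("B", 3)]


class TestLocalVsGlobal:
    def test_long_range_stabilizing(self):
        gap, label = local_vs_global_gap(-4.0, [-1.0], sem=0.5)
        assert gap == pytest.approx(-3.0) and label == "long_range_stabilizing"

    def test_local_explains_within_sem(self):
        gap, label = local_vs_global_gap(-1.0, [-1.0], sem=0.5)
        assert gap == pytest.approx(0.0) and label == "local_explains"

    def test_chain_without_sites_is_pure_long_range(self):
        gap, label = local_vs_global_gap(2.5, [], sem=0.5)
        assert gap == pytest.approx(2.5) and label == "long_range_destabilizing"


class TestStateSplit:
    def test_signed_percentages(self):
        s = state_contribution_split(
            {"complex": -6.0, "receptor": 2.0, "ligand": 2.0},
            {"complex": 0.0, "receptor": 0.0, "ligand": 0.0},
        )
        assert (s.pct_complex, s.pct_receptor, s.pct_ligand) == (-60.0, 20.0, 20.0)
        assert s.implied_ddg == pytest.approx(-10.0)

    def test_single_component(self):
        s = state_contribution_split(
            {"complex": -1.0, "receptor": 0.0, "ligand": 0.0},
            {"complex": 0.0, "receptor": 0.0, "ligand": 0.0},
        )
        assert (s.pct_complex, s.pct_receptor, s.pct_ligand) == (-100.0, 0.0, 0.0)

    def test_degenerate_split_is_error(self):
        means = {"complex": 1.0, "receptor": 1.0, "ligand": 1.0}
        with pytest.raises(ValueError, match="degenerate_split"):
            state_contribution_split(means, means)

    def test_absolute_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            m = {r: rng.normal() for r in ("complex", "receptor", "ligand")}
            s = state_contribution_split(m, {r: 0.0 for r in m})
            total = abs(s.pct_complex) + abs(s.pct_receptor) + abs(s.pct_ligand)
            assert total == pytest.approx(100.0, abs=1e-6)

    def test_split_matches_recompute_from_snapshots(self, small_cohort):
        """Role means fed to the split agree with an independent
        brute-force recomputation from the raw snapshot tables."""
        for entry in small_cohort:
            be_m = binding_energy(entry["snapshots_mod"])
            be_n = binding_energy(entry["snapshots_nonmod"])
            s = state_contribution_split(be_m.role_means, be_n.role_means)
            for role, got in (
                ("complex", s.dg_complex),
                ("receptor", s.dg_receptor),
                ("ligand", s.dg_ligand),
            ):
                def brute_mean(df):
                    sel = df[df.role == role]
                    cols = ["e_bonded", "e_electrostatic", "e_vdw",
                            "g_polar", "g_nonpolar"]
                    return sel[cols].to_numpy().sum(axis=1).mean()

                expected = brute_mean(entry["snapshots_mod"]) - brute_mean(
                    entry["snapshots_nonmod"]
                )
                assert got == pytest.approx(expected, abs=1e-9)


class TestIdentityAndPartitions:
    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6))
    def test_ddg_equals_state_split_identity(self, vals):
        mod = dict(zip(("complex", "receptor", "ligand"), vals[:3]))
        nonmod = dict(zip(("complex", "receptor", "ligand"), vals[3:]))
        dgs = [mod[r] - nonmod[r] for r in ("complex", "receptor", "ligand")]
        if sum(abs(v) for v in dgs) == 0:
            return
        be = lambda m: BindingEnergy(
            mean=m["complex"] - m["receptor"] - m["ligand"],
            sem=None, n_snapshots=1, role_means=m,
        )
        s = state_contribution_split(mod, nonmod)
        assert ddg(be(mod), be(nonmod)).ddg == pytest.approx(
            s.implied_ddg, abs=1e-9
        )

    def test_n_partitions_for_n_mer(self):
        parts = enumerate_partitions(5)
        assert len(parts) == 5
        assert [p.ligand_index for p in parts] == [1, 2, 3, 4, 5]
        with pytest.raises(ValueError):
            PartitionScheme(1, 1)


class TestReaders:
    def test_snapshot_roundtrip(self, tmp_path, small_cohort):
        df = small_cohort[0]["snapshots_mod"]
        path = tmp_path / "snap.tsv"
        write_snapshot_table(df, path)
        back = read_snapshot_table(path)
        pd.testing.assert_frame_equal(df.reset_index(drop=True), back)

    def test_units_refused(self, tmp_path):
        path = tmp_path / "snap.tsv"
        path.write_text("# units: kJ/mol\nsnapshot\ttime\trole\n")
        with pytest.raises(ValueError, match="kcal/mol"):
            read_snapshot_table(path)

    def test_decomposition_roundtrip(self, tmp_path):
        contrib = {("A", 1): -1.25, ("B", 42): 0.5}
        path = tmp_path / "dec.tsv"
        write_decomposition_table(contrib, path)
        assert read_decomposition_table(path) == contrib

    def test_mmpbsa_dialect(self, tmp_path):
        text = (
            "Energy Decomposition Analysis\n"
            "Total Energy Decomposition:\n"
            "Residue,Internal,van der Waals,Electrostatic,TOTAL\n"
            "R A 1,0.0,-0.5,-0.6,-1.1\n"
            "R B 42,0.1,0.2,0.2,0.5\n"
        )
        path = tmp_path / "mmpbsa.csv"
        path.write_text(text)
        assert read_mmpbsa_decomposition(path) == {("A", 1): -1.1, ("B", 42): 0.5}
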