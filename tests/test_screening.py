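"""Screening protocol: sampling, toy docking, K_D conversion, top-N, tables."""

import numpy as np
import pytest

from vcss import (ComplexRecord, ScreeningPlan, SubEnsembleLabel, ToyDockBackend,
                  binding_energy_from_kd, kd_from_binding_energy, read_energy_table,
                  run_screening, sample_structures, select_top_complexes,
                  write_energy_table, gen_toy_receptor)
from vcss.conformers import Conformer
from vcss.exceptions import EnergyTableError, InsufficientFramesError
from vcss.screening import BindingScore, Receptor, pair_potential_energy


class TestKdConversion:
    def test_zero_energy_gives_one_molar(self):
        assert kd_from_binding_energy(0.0, 298.15) == pytest.approx(1.0)

    def test_micromolar_closed_form(self):
        # DG = RT ln(1e-6) = -8.1854 kcal/mol at 298.15 K (RT = 0.59248)
        assert kd_from_binding_energy(-8.1854, 298.15) == pytest.approx(1e-6, abs=1e-9)

    def test_monotone_in_energy(self):
        assert kd_from_binding_energy(-2.0) < kd_from_binding_energy(-1.0)

    def test_round_trip_identity(self):
        for dg in np.linspace(-15.0, 0.0, 31):
            back = binding_energy_from_kd(kd_from_binding_energy(dg))
            assert back == pytest.approx(dg, abs=1e-9 * max(abs(dg), 1))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            kd_from_binding_energy(float("inf"))


class TestSampling:
    def test_draws_distinct_frames(self, mixed_labeled):
        picked = sample_structures(mixed_labeled, SubEnsembleLabel.E_CIS, 50, seed=3)
        ids = [c.id for c in picked]
        assert len(set(ids)) == 50

    def test_insufficient_frames_reports_count(self, mixed_labeled):
        n_avail = mixed_labeled.label_counts()[SubEnsembleLabel.E_TRANS]
        with pytest.raises(InsufficientFramesError, match=str(n_avail)):
            sample_structures(mixed_labeled, SubEnsembleLabel.E_TRANS,
                              n_avail + 1, seed=0)

    def test_seed_reproducible(self, mixed_labeled):
        a = sample_structures(mixed_labeled, SubEnsembleLabel.C_TRANS, 20, seed=9)
        b = sample_structures(mixed_labeled, SubEnsembleLabel.C_TRANS, 20, seed=9)
        assert [c.id for c in a] == [c.id for c in b]


def _single_bead(res_id, xyz, name="CA"):
    return Conformer(0, 0.0, np.array([name]), np.array([res_id]),
                     np.array(["ALA"]), np.array([xyz], float))


class TestToyDock:
    def test_pair_energy_at_minimum_is_minus_epsilon(self):
        # closed form: the 12-6 well reaches -eps exactly at r = sigma
        e = pair_potential_energy(np.array([[0.0, 0.0, 0.0]]),
                                  np.array([[0.55, 0.0, 0.0]]),
                                  epsilon=0.5, sigma=0.55)
        assert e == pytest.approx(-0.5, abs=1e-12)

    def test_overlap_worse_than_separation(self):
        lig = np.zeros((1, 3))
        overlap = pair_potential_energy(lig, np.full((5, 3), 1e-6), 0.5, 0.55)
        apart = pair_potential_energy(lig, np.full((5, 3), 0.55 / np.sqrt(3)), 0.5, 0.55)
        assert overlap > apart
        assert overlap == pytest.approx(5 * 10 * 0.5)   # cap at +10 eps per pair

    def test_seed_determinism(self, receptor, small_trans_traj):
        conf = small_trans_traj[0][0]
        backend = ToyDockBackend(n_poses=30)
        s1 = backend.dock(conf, receptor, seed=5)
        s2 = backend.dock(conf, receptor, seed=5)
        assert s1.energy == s2.energy
        np.testing.assert_array_equal(s1.rotation, s2.rotation)

    def test_invalid_pose_count(self, receptor, small_trans_traj):
        with pytest.raises(ValueError):
            ToyDockBackend().dock(small_trans_traj[0][0], receptor, n_poses=0)


class StubBackend:
    """Deterministic fake docking backend keyed on the derived seed."""

    def __call__(self, conformer, receptor, n_poses, seed):
        rng = np.random.default_rng(seed)
        return BindingScore(energy=-4.0 - rng.random())


class TestRunScreening:
    def test_record_count_conservation(self, mixed_labeled, receptor):
        plan = ScreeningPlan(n_structures=5, n_repeats=4, n_runs=2, seed=1)
        records = run_screening(plan, mixed_labeled, receptor, StubBackend())
        labels = {r.sub_ensemble for r in records}
        assert len(records) == 2 * len(labels) * 5 * 4
        for label in labels:
            for run in range(2):
                n = sum(1 for r in records
                        if r.sub_ensemble is label and r.run_id == run)
                assert n == 5 * 4

    def test_records_carry_requested_label_and_kd(self, mixed_labeled, receptor):
        plan = ScreeningPlan(n_structures=2, n_repeats=3, n_runs=1, seed=1)
        records = run_screening(plan, mixed_labeled, receptor, StubBackend())
        for r in records:
            assert r.kd == pytest.approx(kd_from_binding_energy(r.energy))

    def test_byte_identical_across_reruns(self, mixed_labeled, receptor):
        plan = ScreeningPlan(n_structures=3, n_repeats=2, n_runs=2, seed=4)
        a = run_screening(plan, mixed_labeled, receptor, StubBackend())
        b = run_screening(plan, mixed_labeled, receptor, StubBackend())
        assert a == b

    def test_insufficient_class_raises(self, mixed_labeled, receptor):
        plan = ScreeningPlan(n_structures=10 ** 6)
        with pytest.raises(InsufficientFramesError):
            run_screening(plan, mixed_labeled, receptor, StubBackend())


def _record(energy, conformer_id=0, repeat=0, label=SubEnsembleLabel.E_TRANS):
    return ComplexRecord(label, 0, conformer_id, repeat, energy,
                         kd_from_binding_energy(energy))


class TestTopSelection:
    def test_lowest_energies_win(self):
        records = [_record(e, i) for i, e in enumerate([-1, -5, -3, -2, -4, -0.5])]
        top = select_top_complexes(records, 3)
        assert [r.energy for r in top] == [-5, -4, -3]

    def test_tie_break_by_conformer_then_repeat(self):
        records = [_record(-2.0, 7, 1), _record(-2.0, 3, 2), _record(-2.0, 3, 0)]
        top = select_top_complexes(records, 2)
        assert [(r.conformer_id, r.repeat_index) for r in top] == [(3, 0), (3, 2)]

    def test_top_n_exceeding_returns_all_sorted_with_warning(self):
        records = [_record(-1.0, 0), _record(-2.0, 1)]
        with pytest.warns(UserWarning):
            top = select_top_complexes(records, 5)
        assert [r.energy for r in top] == [-2.0, -1.0]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_top_complexes([], 5)


TABLE_HEADER = "sub_ensemble\trun_id\tconformer_id\trepeat_index\tenergy_kcal_mol\tconvention\n"


class TestEnergyTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "energies.tsv"
        path.write_text(TABLE_HEADER + "".join(rows))
        return str(path)

    def test_well_formed_rows(self, tmp_path):
        path = self._write(tmp_path, [
            "E_TRANS\t0\t1\t0\t-7.5\tnegative_favorable\n",
            "C_TRANS\t0\t2\t0\t-6.0\tnegative_favorable\n",
            "E_CIS\t0\t3\t0\t-6.1\tnegative_favorable\n",
        ])
        records = read_energy_table(path)
        assert len(records) == 3
        assert records[0].energy == -7.5

    def test_positive_favorable_negated_on_ingest(self, tmp_path):
        path = self._write(tmp_path, ["E_TRANS\t0\t1\t0\t8.0\tpositive_favorable\n"])
        assert read_energy_table(path)[0].energy == -8.0

    def test_bad_numeric_names_line(self, tmp_path):
        path = self._write(tmp_path, [
            "E_TRANS\t0\t1\t0\t-7.5\tnegative_favorable\n",
            "E_TRANS\t0\t2\t0\tNA\tnegative_favorable\n",
        ])
        with pytest.raises(EnergyTableError, match="line 3"):
            read_energy_table(path)

    def test_unknown_label_and_duplicate_key(self, tmp_path):
        with pytest.raises(EnergyTableError, match="unknown"):
            read_energy_table(self._write(
                tmp_path, ["X_TRANS\t0\t1\t0\t-7.5\tnegative_favorable\n"]))
        with pytest.raises(EnergyTableError, match="duplicate"):
            read_energy_table(self._write(tmp_path, [
                "E_TRANS\t0\t1\t0\t-7.5\tnegative_favorable\n",
                "E_TRANS\t0\t1\t0\t-7.6\tnegative_favorable\n",
            ]))

    def test_round_trip_through_writer(self, tmp_path):
        records = [_record(-5.5, 1, 0), _record(-6.5, 2, 1, SubEnsembleLabel.E_CIS)]
        path = tmp_path / "rt.tsv"
        write_energy_table(records, str(path))
        assert read_energy_table(str(path)) == records
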