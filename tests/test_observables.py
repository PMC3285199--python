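"""Scalar couplings, RDC tensor fits and Q factors, ACFs and order parameters."""

import numpy as np
import pandas as pd
import pytest

from ffval import (
    AlignmentTensor,
    ConformationalEnsemble,
    CorrelationFunction,
    ExperimentalObservables,
    FfvalError,
    KarplusParameters,
    UnderdeterminedError,
    back_calculate_rdc,
    bond_dyadics,
    calc_coupling_table,
    coupling_agreement,
    fit_alignment_tensor,
    internal_acf,
    karplus_coupling,
    observable_agreement_panel,
    order_parameter,
    q_score,
)
from ffval.observables import _sem, read_coupling_table, read_rdc_table, read_s2_table
from ffval.synthetic import (
    generate_cone_ensemble,
    ConeMotionParams,
    random_alignment_tensor,
    random_unit_vectors,
)

from ffval import AtomRecord


def _kp(a, b, c, d):
    return KarplusParameters(a, b, c, d, "HNHA")


class TestKarplus:
    @pytest.mark.parametrize(
        "params, phis, expected",
        [
            (_kp(0, 0, 3.0, 0), [10.0, 120.0, -50.0], 3.0),
            (_kp(1, 0, 0, 0), [0.0], 1.0),
            (_kp(1, 1, 1, 0), [0.0, 180.0], 2.0),  # mean of 3 Hz and 1 Hz
        ],
    )
    def test_known_values(self, params, phis, expected):
        assert karplus_coupling(phis, params) == pytest.approx(expected, abs=1e-12)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            karplus_coupling([], _kp(1, 1, 1, 0))

    def test_phase_offset_shifts_curve(self):
        p60 = KarplusParameters(8.0, -1.0, 0.5, -60.0, "HNHA")
        assert karplus_coupling([60.0], p60) == pytest.approx(8.0 - 1.0 + 0.5)


class TestCouplingAgreement:
    def _table(self, values):
        return pd.DataFrame(
            {"residue": range(1, len(values) + 1), "type": "HNHA", "value_hz": values}
        )

    def test_identical_tables_give_zero(self):
        t = self._table([5.0, 6.0, 7.0])
        assert coupling_agreement(t, t).rmsd_hz == 0.0

    def test_uniform_offset(self):
        t = self._table([5.0, 6.0, 7.0])
        shifted = self._table([6.0, 7.0, 8.0])
        assert coupling_agreement(shifted, t).rmsd_hz == pytest.approx(1.0)

    def test_hand_computed_rms(self):
        calc = self._table([5.0, 9.0, 10.0])
        exp = self._table([5.0, 6.0, 6.0])  # diffs 0, 3, 4
        assert coupling_agreement(calc, exp).rmsd_hz == pytest.approx(5.0 / np.sqrt(3.0))

    def test_unmatched_rows_reported_not_dropped(self):
        calc = self._table([5.0, 6.0])
        exp = self._table([5.0, 6.0, 7.0])
        res = coupling_agreement(calc, exp)
        assert res.n_matched == 2
        assert res.unmatched_exp == [(3, "HNHA")]

    def test_empty_intersection_raises(self):
        calc = self._table([5.0])
        exp = self._table([5.0]).assign(type="HNCO")
        with pytest.raises(FfvalError):
            coupling_agreement(calc, exp)

    def test_row_order_permutation_invariant(self, rng):
        calc = self._table(rng.normal(6, 1, 8))
        exp = self._table(rng.normal(6, 1, 8))
        shuffled = exp.sample(frac=1.0, random_state=3)
        assert coupling_agreement(calc, exp).rmsd_hz == pytest.approx(
            coupling_agreement(calc, shuffled).rmsd_hz
        )


class TestAlignmentTensor:
    def test_recovers_generating_tensor(self, rng):
        truth = random_alignment_tensor(rng)
        b = random_unit_vectors(20, rng)
        d = np.einsum("ni,ij,nj->n", b, truth.saupe, b)
        dy = np.einsum("ni,nj->nij", b, b)
        fit = fit_alignment_tensor(dy, d)
        assert np.abs(fit.tensor.saupe - truth.saupe).max() < 1e-8
        assert np.trace(fit.tensor.saupe) == pytest.approx(0.0, abs=1e-12)

    def test_zero_rdcs_give_zero_tensor(self, rng):
        b = random_unit_vectors(10, rng)
        dy = np.einsum("ni,nj->nij", b, b)
        fit = fit_alignment_tensor(dy, np.zeros(10))
        assert np.abs(fit.tensor.saupe).max() < 1e-12

    def test_four_rdcs_underdetermined(self, rng):
        b = random_unit_vectors(4, rng)
        dy = np.einsum("ni,nj->nij", b, b)
        with pytest.raises(UnderdeterminedError):
            fit_alignment_tensor(dy, np.ones(4))

    def test_degenerate_directions_underdetermined(self):
        b = np.tile([0.0, 0.0, 1.0], (8, 1))
        dy = np.einsum("ni,nj->nij", b, b)
        with pytest.raises(UnderdeterminedError):
            fit_alignment_tensor(dy, np.ones(8))

    def test_roundtrip_through_back_calculation(self, rng):
        truth = random_alignment_tensor(rng)
        b = random_unit_vectors(25, rng)
        dy = np.einsum("ni,nj->nij", b, b)
        d = np.einsum("ni,ij,nj->n", b, truth.saupe, b)
        fit = fit_alignment_tensor(dy, d)
        calc = back_calculate_rdc(dy, fit.tensor)
        assert np.abs(calc["value_hz"].to_numpy() - d).max() < 1e-8


class TestBackCalculateRdc:
    def test_axial_geometry(self):
        s = 0.4
        tensor = AlignmentTensor(np.diag([-s / 2, -s / 2, s]), scale=2.0)
        dz = np.einsum("i,j->ij", [0, 0, 1.0], [0, 0, 1.0])[None]
        dx = np.einsum("i,j->ij", [1.0, 0, 0], [1.0, 0, 0])[None]
        assert back_calculate_rdc(dz, tensor)["value_hz"][0] == pytest.approx(2.0 * s)
        assert back_calculate_rdc(dx, tensor)["value_hz"][0] == pytest.approx(-s)

    def test_isotropic_average_vanishes(self, rng):
        tensor = random_alignment_tensor(rng)
        b = random_unit_vectors(200_000, rng)
        dy = (np.einsum("ni,nj->nij", b, b)).mean(axis=0)[None]
        d = back_calculate_rdc(dy, tensor)["value_hz"][0]
        assert abs(d) < 0.1  # Monte-Carlo average of a ~10 Hz tensor


class TestQScore:
    def test_exact_match_is_zero(self):
        assert q_score(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_zero_calc_is_one(self):
        assert q_score(np.zeros(3), np.array([1.0, -2.0, 3.0])) == pytest.approx(1.0)

    def test_doubled_values(self):
        assert q_score(np.array([2.0, -2.0, 4.0]), np.array([1.0, -1.0, 2.0])) == pytest.approx(1.0)

    def test_zero_experimental_rms_raises(self):
        with pytest.raises(FfvalError):
            q_score(np.ones(3), np.zeros(3))

    def test_table_matching_is_order_invariant(self, rng):
        n = 10
        calc = pd.DataFrame({"residue": range(n), "pair": "N-H", "value_hz": rng.normal(size=n)})
        exp = pd.DataFrame({"residue": range(n), "pair": "N-H", "value_hz": rng.normal(size=n)})
        assert q_score(calc, exp) == pytest.approx(q_score(calc, exp.iloc[::-1]))

    def test_small_perturbations_scale_linearly(self, rng):
        exp = rng.normal(0, 5, 30)
        delta = rng.normal(0, 1, 30)
        q1 = q_score(exp + 1e-3 * delta, exp)
        q2 = q_score(exp + 2e-3 * delta, exp)
        assert q2 / q1 == pytest.approx(2.0, rel=1e-6)

    def test_invariant_under_global_rotation_with_refit(self, rng):
        from ffval.ensemble import _rotation_from_axis_angle

        truth = random_alignment_tensor(rng)
        b = random_unit_vectors(30, rng)
        exp_d = np.einsum("ni,ij,nj->n", b, truth.saupe, b) + rng.normal(0, 0.5, 30)

        def q_for(vectors):
            dy = np.einsum("ni,nj->nij", vectors, vectors)
            fit = fit_alignment_tensor(dy, exp_d)
            calc = back_calculate_rdc(dy, fit.tensor)
            return q_score(calc["value_hz"].to_numpy(), exp_d)

        rot = _rotation_from_axis_angle(rng.standard_normal(3), 1.1)
        assert q_for(b @ rot.T) == pytest.approx(q_for(b), abs=1e-6)


# -- ACF and order parameters ----------------------------------------------

def _two_atom_ensemble(vectors, frame_interval_ns=0.1):
    """N at origin plus H along the given per-frame unit vectors, with a
    rigid triangle of backbone atoms so superposition is well defined."""
    atoms = [
        AtomRecord("N", 1), AtomRecord("CA", 1), AtomRecord("C", 1),
        AtomRecord("N", 2), AtomRecord("H", 2), AtomRecord("CA", 2), AtomRecord("C", 2),
    ]
    vectors = np.asarray(vectors, float)
    n = len(vectors)
    base = np.array(
        [[0, 0, 0], [1.5, 0, 0], [2.2, 1.2, 0], [3.5, 1.2, 0], [0, 0, 0], [4.6, 2.1, 0], [6.0, 2.0, 0.5]]
    )
    frames = np.repeat(base[None], n, axis=0)
    frames[:, 4] = frames[:, 3] + vectors  # H of residue 2
    return ConformationalEnsemble(atoms=atoms, frames=frames, frame_interval_ns=frame_interval_ns)


class TestInternalAcf:
    def test_rigid_ensemble_is_unity(self):
        vec = np.tile([0.0, 0.6, 0.8], (50, 1))
        acf = internal_acf(_two_atom_ensemble(vec), max_lag_frames=10)[2]
        assert np.allclose(acf.values, 1.0, atol=1e-9)

    def test_alternating_orthogonal_vectors(self):
        vec = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0]] * 30)
        acf = internal_acf(_two_atom_ensemble(vec), max_lag_frames=4)[2]
        assert acf.values[0] == pytest.approx(1.0)
        assert acf.values[1] == pytest.approx(-0.5)  # P2(cos 90) = -1/2
        assert acf.values[2] == pytest.approx(1.0)
        assert acf.values[3] == pytest.approx(-0.5)

    def test_isotropic_vectors_decorrelate(self, rng):
        vec = random_unit_vectors(10_000, rng)
        acf = internal_acf(_two_atom_ensemble(vec), max_lag_frames=5)[2]
        assert np.abs(acf.values[1:]).max() < 0.02

    def test_lag_longer_than_trajectory_raises(self):
        vec = np.tile([0.0, 0.0, 1.0], (10, 1))
        with pytest.raises(ValueError):
            internal_acf(_two_atom_ensemble(vec), max_lag_frames=10)


class TestOrderParameter:
    def test_unit_acf(self):
        acf = CorrelationFunction(np.arange(11.0), np.ones(11))
        assert order_parameter(acf, tau_c_ns=5.0, window=0.2) == 1.0

    def test_constant_plateau(self):
        acf = CorrelationFunction(np.arange(11.0), np.full(11, 0.8))
        assert order_parameter(acf, tau_c_ns=5.0, window=0.2) == pytest.approx(0.8)

    def test_window_outside_lags_raises(self):
        acf = CorrelationFunction(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError):
            order_parameter(acf, tau_c_ns=10.0, window=0.2)

    def test_cone_ensemble_recovers_analytic_s2(self):
        params = ConeMotionParams(half_angle_deg={3: 60.0}, n_frames=10_000, seed=7)
        ens = generate_cone_ensemble(params)
        acf = internal_acf(ens, max_lag_frames=20, residues=[3])[3]
        s2 = order_parameter(acf, tau_c_ns=0.1, window=0.2)
        assert s2 == pytest.approx(0.140625, abs=0.02)


class TestAgreementPanel:
    def test_sem_hand_value(self):
        # five block estimates with known sample standard deviation
        blocks = [1.0, 2.0, 3.0, 4.0, 5.0]
        expected = np.std(blocks, ddof=1) / np.sqrt(5)
        assert _sem(blocks) == pytest.approx(expected)
        assert _sem([2.0, 2.0, 2.0, 2.0]) == 0.0

    def test_repeated_reference_structure_gives_zero_sem(self, helix_peptide, rng):
        ens = ConformationalEnsemble(
            atoms=helix_peptide.atoms,
            frames=np.repeat(helix_peptide.frames, 50, axis=0),
            frame_interval_ns=0.1,
        )
        residues = [r for r in ens.residue_indices if ens.has_atom(r, "H")]
        keys, dy = bond_dyadics(ens, residues=residues)
        tensor = random_alignment_tensor(rng)
        exp_rdc = back_calculate_rdc(dy, tensor, keys)
        exp_coupling = calc_coupling_table(ens)
        exp = ExperimentalObservables(couplings=exp_coupling, rdcs=exp_rdc, tau_c_ns=0.5)
        panel = observable_agreement_panel(ens, exp, n_blocks=5)
        assert set(panel["observable"]) == {"couplings", "rdcs"}
        assert np.allclose(panel["value"], 0.0, atol=1e-8)
        assert np.allclose(panel["sem"], 0.0, atol=1e-8)


class TestTableReaders:
    def test_round_trip_all_three(self, tmp_path):
        couplings = pd.DataFrame({"residue": [2, 3], "type": ["HNHA", "HNCO"], "value_hz": [7.1, 1.2]})
        rdcs = pd.DataFrame({"residue": [2, 3], "pair": ["N-H", "N-H"], "value_hz": [5.0, -2.0]})
        s2 = pd.DataFrame({"residue": [2, 3], "s2": [0.85, 0.9]})
        couplings.to_csv(tmp_path / "c.tsv", sep="\t", index=False)
        rdcs.to_csv(tmp_path / "r.csv", index=False)
        s2.to_csv(tmp_path / "s.tsv", sep="\t", index=False)
        pd.testing.assert_frame_equal(read_coupling_table(tmp_path / "c.tsv"), couplings)
        pd.testing.assert_frame_equal(read_rdc_table(tmp_path / "r.csv"), rdcs)
        pd.testing.assert_frame_equal(read_s2_table(tmp_path / "s.tsv"), s2)

    def test_missing_column_raises(self, tmp_path):
        pd.DataFrame({"residue": [1], "value": [1.0]}).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(FfvalError, match="value_hz"):
            read_coupling_table(tmp_path / "bad.csv")
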