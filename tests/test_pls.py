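"""Task-PLS: matrix assembly, mean-centering, SVD against a brute-force
oracle, non-rotated contrasts, permutation and bootstrap behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aepstats as ap
from aepstats.containers import default_times
from aepstats.errors import ConfigError, DesignError
from aepstats.pls import (PlsDataMatrix, PlsDesign, TaskPLS, TaskPLSResults,
                          assemble_data_matrix, fit_mc_pls, fit_nr_pls,
                          mean_center_conditions)


def _matrix_from_rows(X, groups, sessions, subjects=None):
    n = len(X)
    rows = pd.DataFrame({
        "subject": subjects if subjects is not None
        else [f"s{i}" for i in range(n)],
        "group": groups, "session": sessions})
    X = np.asarray(X, float)
    return PlsDataMatrix(X=X, rows=rows,
                         electrodes=[f"e{j}" for j in range(X.shape[1])],
                         latencies=np.array([0.0]))


def _repeated_design(cond_means, n_subj=2, noise=0.0, seed=0):
    """Rows for a (group, session) design with every subject in every
    session of its group; condition means exactly as given."""
    rng = np.random.default_rng(seed)
    X, groups, sessions, subjects = [], [], [], []
    for (g, s), mean in cond_means.items():
        for i in range(n_subj):
            X.append(np.asarray(mean, float)
                     + noise * rng.standard_normal(len(mean)))
            groups.append(g)
            sessions.append(s)
            subjects.append(f"g{g}s{i}")
    return _matrix_from_rows(X, groups, sessions, subjects)


class TestAssembly:
    def test_full_design_shape(self, planted_evokeds, montage):
        _, evokeds, _ = planted_evokeds
        dm = assemble_data_matrix(evokeds, montage)
        assert dm.X.shape == (60, 59 * 301)
        assert dm.conditions == [(1, 1), (1, 2), (1, 3),
                                 (2, 1), (2, 2), (2, 3)]
        # rows grouped contiguously by condition
        cond_seq = list(zip(dm.rows["group"], dm.rows["session"]))
        assert cond_seq == sorted(cond_seq)

    def test_tiny_window_two_electrodes(self, make_ev):
        data = np.arange(6, dtype=float).reshape(2, 3)
        ev = make_ev(data, ["A", "B"], times=np.array([0.0, 1.0, 2.0]))
        montage = ap.default_montage()
        # use labels present in montage
        ev = make_ev(data, ["CZ", "FZ"], times=np.array([0.0, 1.0, 2.0]))
        dm = assemble_data_matrix({ev.key: ev}, montage, window=(0.0, 2.0))
        assert dm.X.shape == (1, 6)

    def test_column_round_trip(self, planted_evokeds, montage):
        _, evokeds, _ = planted_evokeds
        dm = assemble_data_matrix(evokeds, montage)
        key = sorted(evokeds.keys())[0]
        row = list(sorted(evokeds.keys(),
                          key=lambda k: (k[1], k[2], k[0]))).index(key)
        ev = evokeds[key]
        col = dm.col_index("TP9", 250.0)
        assert dm.X[row, col] == ev.get("TP9")[ev.times == 250.0][0]

    def test_mixed_stimuli_raise(self, planted_evokeds, montage):
        cfg, evokeds, _ = planted_evokeds
        other, _ = ap.simulate_study_evoked(cfg, stimulus="ba")
        both = {**evokeds, **other}
        with pytest.raises(DesignError):
            assemble_data_matrix(both, montage)


class TestMeanCentering:
    def test_hand_arithmetic(self):
        dm = _matrix_from_rows([[1.0, 2.0], [3.0, 4.0]], [1, 1], [1, 2])
        M = mean_center_conditions(dm)
        np.testing.assert_allclose(M, [[-1.0, -1.0], [1.0, 1.0]])

    def test_equal_condition_means_give_zero(self):
        dm = _matrix_from_rows([[2.0, 5.0]] * 4, [1, 1, 2, 2], [1, 1, 1, 1])
        np.testing.assert_allclose(mean_center_conditions(dm), 0.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 8))
        dm1 = _matrix_from_rows(X, [1, 1, 1, 2, 2, 2], [1, 2, 3, 1, 2, 3])
        dm2 = _matrix_from_rows(X + 7.3, [1, 1, 1, 2, 2, 2],
                                [1, 2, 3, 1, 2, 3])
        np.testing.assert_allclose(mean_center_conditions(dm1),
                                   mean_center_conditions(dm2), atol=1e-12)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        dm = _matrix_from_rows(rng.normal(size=(12, 5)),
                               [1] * 6 + [2] * 6, [1, 2, 3] * 4)
        M = mean_center_conditions(dm)
        np.testing.assert_allclose(M.sum(axis=0), 0.0, atol=1e-9)


class TestMeanCenteredPLS:
    def test_two_by_three_design_yields_six_lvs(self, planted_evokeds,
                                                montage):
        _, evokeds, _ = planted_evokeds
        dm = assemble_data_matrix(evokeds, montage)
        res = fit_mc_pls(dm)
        assert res.n_latent_variables == 6
        assert res.covariance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        # design saliencies orthonormal
        U = res.design_saliencies
        np.testing.assert_allclose(U.T @ U, np.eye(6), atol=1e-10)

    def test_known_two_condition_solution(self):
        dm = _repeated_design({(1, 1): [1.0, 2.0], (1, 2): [3.0, 4.0]})
        res = fit_mc_pls(dm)
        assert res.singular_values[0] == pytest.approx(2.0)
        assert res.singular_values[1] == pytest.approx(0.0, abs=1e-12)
        assert res.covariance_fractions[0] == pytest.approx(1.0)

    def test_zero_matrix_flagged_degenerate(self):
        dm = _repeated_design({(1, 1): [1.0, 1.0], (1, 2): [1.0, 1.0]})
        res = fit_mc_pls(dm)
        assert res.degenerate
        np.testing.assert_allclose(res.singular_values, 0.0)

    def test_reconstruction_and_oracle_small_random(self):
        # independent oracle: LAPACK full SVD of the centered matrix
        rng = np.random.default_rng(5)
        for trial in range(10):
            n_cond = rng.integers(2, 7)
            n_cols = rng.integers(n_cond, 21)
            means = {(1, s): rng.normal(size=n_cols)
                     for s in range(1, n_cond + 1)}
            dm = _repeated_design(means, n_subj=2)
            M = mean_center_conditions(dm)
            res = fit_mc_pls(dm)
            s_ref = np.linalg.svd(M, compute_uv=False)
            np.testing.assert_allclose(res.singular_values[:len(s_ref)],
                                       s_ref, atol=1e-8)
            recon = (res.design_saliencies
                     @ np.diag(res.singular_values)
                     @ res.electrode_saliencies.T)
            np.testing.assert_allclose(recon, M, atol=1e-8)

    def test_subject_scores_are_data_projections(self):
        dm = _repeated_design({(1, 1): [1.0, 2.0], (1, 2): [3.0, 4.0]},
                              noise=0.1, seed=2)
        res = fit_mc_pls(dm)
        np.testing.assert_allclose(res.subject_scores,
                                   dm.X @ res.electrode_saliencies)

    def test_fewer_rows_than_conditions_raises(self):
        X = np.zeros((2, 3))
        rows = pd.DataFrame({"subject": ["a", "a"], "group": [1, 1],
                             "session": [1, 2]})
        dm = PlsDataMatrix(X=X, rows=rows, electrodes=["e0", "e1", "e2"],
                           latencies=np.array([0.0]))
        rows3 = pd.DataFrame({"subject": ["a", "a", "a"],
                              "group": [1, 1, 1], "session": [1, 2, 3]})
        # 3 conditions but only 2 rows
        with pytest.raises(DesignError):
            TaskPLS(PlsDataMatrix(X=np.zeros((2, 3)), rows=rows,
                                  electrodes=["e0", "e1", "e2"],
                                  latencies=np.array([0.0])),
                    PlsDesign("non_rotated", np.array([-1, 0, 1.0])))

    @given(c=st.floats(0.1, 50.0))
    @settings(max_examples=10, deadline=None)
    def test_scale_equivariance(self, c):
        dm = _repeated_design({(1, 1): [1.0, 2.0, 0.5],
                               (1, 2): [3.0, 1.0, 0.0],
                               (1, 3): [0.0, 4.0, 1.0]}, noise=0.3, seed=3)
        scaled = PlsDataMatrix(X=c * dm.X, rows=dm.rows,
                               electrodes=dm.electrodes,
                               latencies=dm.latencies)
        a = fit_mc_pls(dm, n_boot=20, seed=1)
        b = fit_mc_pls(scaled, n_boot=20, seed=1)
        np.testing.assert_allclose(b.singular_values,
                                   c * a.singular_values, rtol=1e-8)
        np.testing.assert_allclose(b.electrode_saliencies,
                                   a.electrode_saliencies, atol=1e-8)
        np.testing.assert_allclose(b.bootstrap_ratios, a.bootstrap_ratios,
                                   rtol=1e-6, atol=1e-8)


class TestNonRotatedPLS:
    def test_single_lv_and_known_solution(self):
        dm = _repeated_design({(1, 1): [0.0, 0.0], (1, 2): [1.0, 0.0],
                               (1, 3): [2.0, 0.0]})
        res = fit_nr_pls(dm, contrast=(-1.0, 0.0, 1.0))
        assert res.n_latent_variables == 1
        assert res.singular_values[0] == pytest.approx(2.0 / np.sqrt(2.0))
        np.testing.assert_allclose(np.abs(res.electrode_saliencies[:, 0]),
                                   [1.0, 0.0], atol=1e-12)

    def test_contrast_orthogonal_to_differences_gives_zero(self):
        dm = _repeated_design({(1, 1): [1.0, 0.0], (1, 2): [0.0, 0.0],
                               (1, 3): [1.0, 0.0]})
        res = fit_nr_pls(dm, contrast=(-1.0, 0.0, 1.0))
        assert res.singular_values[0] == pytest.approx(0.0, abs=1e-12)

    def test_non_zero_sum_contrast_raises(self):
        dm = _repeated_design({(1, 1): [0.0], (1, 2): [1.0],
                               (1, 3): [2.0]})
        with pytest.raises(DesignError):
            fit_nr_pls(dm, contrast=(1.0, 0.0, 1.0))

    def test_contrast_length_mismatch_raises(self):
        dm = _repeated_design({(1, 1): [0.0], (1, 2): [1.0]})
        with pytest.raises(DesignError):
            fit_nr_pls(dm, contrast=(-1.0, 0.0, 1.0))


class TestPermutation:
    def test_counting_convention_floor(self):
        # overwhelming effect: observed beats every permutation
        dm = _repeated_design({(1, 1): [0.0, 0.0], (1, 2): [50.0, 0.0],
                               (1, 3): [100.0, 0.0]}, n_subj=6,
                              noise=0.01, seed=4)
        res = fit_nr_pls(dm, contrast=(-1, 0, 1), n_perm=500, seed=0)
        assert res.perm_p[0] == pytest.approx(1.0 / 501.0)

    def test_constant_matrix_p_one(self):
        dm = _repeated_design({(1, 1): [1.0, 1.0], (1, 2): [1.0, 1.0],
                               (1, 3): [1.0, 1.0]}, n_subj=3)
        res = fit_mc_pls(dm, n_perm=50, seed=0)
        np.testing.assert_allclose(res.perm_p, 1.0)

    def test_invalid_n_perm_raises(self):
        dm = _repeated_design({(1, 1): [0.0], (1, 2): [1.0]})
        with pytest.raises(ConfigError):
            TaskPLS(dm, PlsDesign("mean_centering"))._permutation(
                np.array([1.0]), 0, np.random.default_rng(0))


class TestBootstrap:
    def test_noiseless_effect_bsr_exceeds_any_finite_threshold(self):
        # zero resampling variance: BSR diverges at planted columns
        dm = _repeated_design({(1, 1): [0.0, 0.0], (1, 2): [1.0, 0.0],
                               (1, 3): [2.0, 0.0]}, n_subj=4)
        res = fit_nr_pls(dm, contrast=(-1, 0, 1), n_boot=50, seed=0)
        assert abs(res.bootstrap_ratios[0, 0]) > 1e6
        assert res.stable_mask[0, 0]
        assert not res.stable_mask[1, 0]

    def test_null_supra_threshold_fraction_small(self):
        # normal-tail heuristic at the study's sample size (10/group):
        # |BSR| > 3 in at most ~1% of columns on average
        def null_dm(seed):
            rng = np.random.default_rng(seed)
            means = {(g, s): np.zeros(40) for g in (1, 2) for s in (1, 2, 3)}
            return _repeated_design(means, n_subj=10, noise=1.0, seed=seed)

        fracs = []
        for rep in range(50):
            res = fit_mc_pls(null_dm(rep), n_boot=100, seed=5000 + rep)
            fracs.append(np.mean(np.abs(res.bootstrap_ratios[:, 0]) > 3))
        assert np.mean(fracs) <= 0.01

    def test_serialization_round_trip(self, tmp_path):
        dm = _repeated_design({(1, 1): [0.0, 1.0], (1, 2): [1.0, 0.5],
                               (1, 3): [2.0, 0.2]}, n_subj=3, noise=0.2,
                              seed=9)
        res = fit_mc_pls(dm, n_perm=20, n_boot=20, seed=1)
        path = tmp_path / "pls.json"
        res.save_json(path)
        back = TaskPLSResults.load_json(path)
        for attr in ("singular_values", "design_saliencies",
                     "electrode_saliencies", "covariance_fractions",
                     "subject_scores", "perm_p", "bootstrap_ratios"):
            np.testing.assert_array_equal(getattr(res, attr),
                                          getattr(back, attr))
        assert back.kind == res.kind
        assert back.conditions == res.conditions
        assert back.n_perm == res.n_perm
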