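"""Behavioral statistics, cluster permutation inference, partial correlation."""

import numpy as np
import pandas as pd
import pytest

from cuedmotion.stats import (
    InsufficientDataError,
    cluster_perm_between,
    cluster_perm_one_sample,
    cue_effect_timecourse,
    fisher_z,
    participant_qc,
    perceptual_bias,
    split_by_bias,
    trial_partial_correlation,
)


def _main_table(presented, cue, reported=None):
    n = len(presented)
    return pd.DataFrame({
        "trial_id": np.arange(n),
        "run": "main01",
        "task": "main",
        "cue": cue,
        "presented_dir": presented,
        "reported_dir": np.nan if reported is None else reported,
        "coherence": 0.2,
    })


class TestParticipantQC:
    def test_perfect_reports_pass(self):
        pres = np.tile([9.0, 27.0, 45.0, 63.0, 81.0], 4)
        t = _main_table(pres, "cue27", reported=pres)
        r, ok = participant_qc(t)
        assert r == pytest.approx(1.0) and ok

    def test_constant_reports_fail_with_undefined_r(self):
        pres = np.tile([9.0, 27.0, 45.0, 63.0, 81.0], 4)
        t = _main_table(pres, "cue27", reported=np.full_like(pres, 45.0))
        r, ok = participant_qc(t)
        assert np.isnan(r) and not ok

    def test_matches_hand_computed_pearson_on_toy_means(self):
        pres = np.array([9.0, 27.0, 45.0, 63.0, 81.0])
        rep = np.array([11.0, 25.0, 48.0, 60.0, 85.0])
        t = _main_table(pres, "cue27", reported=rep)
        r, _ = participant_qc(t)
        x0, y0 = pres - pres.mean(), rep - rep.mean()
        assert r == pytest.approx(float(x0 @ y0 / np.sqrt((x0 @ x0) * (y0 @ y0))))

    def test_too_few_directions_rejected(self):
        t = _main_table([9.0, 27.0] * 3, "cue27", reported=[9.0, 27.0] * 3)
        with pytest.raises(InsufficientDataError):
            participant_qc(t)


class TestPerceptualBias:
    def test_toy_table_bias_of_two_degrees(self):
        t = _main_table(
            [45.0, 45.0, 45.0, 45.0],
            ["cue63", "cue63", "cue27", "cue27"],
            reported=[48.0, 46.0, 46.0, 44.0],
        )
        assert perceptual_bias(t) == pytest.approx(2.0)

    def test_design_imbalance_cancels_under_cell_balancing(self):
        # reports track the stimulus exactly: no cue-induced shift, even
        # though cue63 trials see larger presented directions on average
        from cuedmotion.synth import make_main_design

        design = make_main_design(4, 60, seed=0)
        design["reported_dir"] = design["presented_dir"]
        assert perceptual_bias(design) == pytest.approx(0.0)
        assert perceptual_bias(design, balanced=False) == pytest.approx(18.0, abs=1e-9)

    def test_missing_cue_condition_rejected(self):
        t = _main_table([45.0] * 4, "cue27", reported=[45.0] * 4)
        with pytest.raises(InsufficientDataError):
            perceptual_bias(t)

    def test_monte_carlo_expectation_is_36_w(self):
        # weighted-average reports: bias converges to 36*w
        from cuedmotion.synth import Behavior, make_ground_truth, make_main_design, simulate_behavior

        w = 0.1
        gt = make_ground_truth(n_sensors=4, seed=2,
                               behavior=Behavior(cue_weight=w, report_noise_sd=8.0))
        design = make_main_design(n_runs=170, trials_per_run=60, seed=3)  # ~10^4 trials
        out = simulate_behavior(design, gt)
        assert perceptual_bias(out) == pytest.approx(36.0 * w, abs=0.5)


class TestSplit:
    def test_signs_partition_participants(self):
        groups = split_by_bias([2.0, -1.0, 0.0, 0.5])
        assert groups.tolist() == [True, False, False, True]


class TestCueEffect:
    def test_cue_independent_decoding_gives_null_effect(self):
        from cuedmotion.synth import make_main_design

        design = make_main_design(4, 60, seed=1)
        decoded = design["presented_dir"].to_numpy()[None, :] * 1.0
        eff = cue_effect_timecourse(decoded, design)
        assert eff[0] == pytest.approx(0.0, abs=1e-9)

    def test_equal_weight_cell_average_matches_hand_loop(self):
        from cuedmotion.synth import make_main_design

        design = make_main_design(2, 60, seed=2)
        rng = np.random.default_rng(0)
        decoded = rng.normal(45, 20, (3, len(design)))
        eff = cue_effect_timecourse(decoded, design)
        pres = design["presented_dir"].to_numpy()
        cue = design["cue"].to_numpy()
        for t in range(3):  # brute-force oracle
            per_cue = {}
            for c in ("cue27", "cue63"):
                cells = []
                for d in np.unique(pres):
                    sel = (cue == c) & (pres == d)
                    cells.append(decoded[t, sel].mean())
                per_cue[c] = np.mean(cells)
            assert eff[t] == pytest.approx(per_cue["cue63"] - per_cue["cue27"])

    def test_label_shuffle_centres_effect_at_zero(self):
        from cuedmotion.synth import make_main_design

        design = make_main_design(4, 60, seed=3)
        rng = np.random.default_rng(1)
        decoded = rng.normal(45, 20, (1, len(design)))
        effs = []
        for _ in range(200):
            shuffled = design.copy()
            shuffled["cue"] = rng.permutation(shuffled["cue"].to_numpy())
            effs.append(cue_effect_timecourse(decoded, shuffled)[0])
        assert np.mean(effs) == pytest.approx(0.0, abs=0.5)


class TestFisherZ:
    def test_reference_values_and_symmetry(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0))
        r = np.array([0.1, 0.7, 0.95])
        assert np.allclose(fisher_z(-r), -fisher_z(r))

    def test_inverse_of_tanh_on_open_interval(self):
        r = np.linspace(-0.99, 0.99, 21)
        assert np.allclose(np.tanh(fisher_z(r)), r)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestClusterOneSample:
    def test_no_clusters_on_exact_zeros(self):
        res = cluster_perm_one_sample(np.zeros((8, 30)), n_perm=200, seed=0)
        assert res.clusters == []

    def test_constant_shift_spans_axis_at_p_floor(self):
        rng = np.random.default_rng(1)
        X = 10.0 + 0.1 * rng.standard_normal((12, 40))
        res = cluster_perm_one_sample(X, n_perm=500, seed=2)
        assert len(res.clusters) == 1
        c = res.clusters[0]
        assert (c.start_ms, c.end_ms) == (0.0, 39.0)
        assert c.p == pytest.approx(1.0 / (1.0 + res.n_permutations))
        assert c.d > 5

    def test_exhaustive_enumeration_for_small_cohorts(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 20)) + 1.5
        res = cluster_perm_one_sample(X, n_perm=1000, seed=4)
        assert res.n_permutations == 64  # 2^6 sign patterns enumerated
        res2 = cluster_perm_one_sample(X, n_perm=1000, seed=99)
        assert [c.p for c in res.clusters] == [c.p for c in res2.clusters]

    def test_pvalue_validity_under_null(self):
        # P(any significant cluster) <= alpha + Monte-Carlo error
        rng = np.random.default_rng(5)
        alpha_hits = {0.01: 0, 0.05: 0}
        n_exp = 200
        for _ in range(n_exp):
            X = rng.standard_normal((12, 60))
            res = cluster_perm_one_sample(X, n_perm=500, seed=int(rng.integers(2**31)))
            pmin = min((c.p for c in res.clusters), default=1.0)
            for a in alpha_hits:
                alpha_hits[a] += pmin <= a
        assert alpha_hits[0.05] / n_exp < 0.05 + 0.04
        assert alpha_hits[0.01] / n_exp < 0.01 + 0.025

    def test_agrees_with_mne_cluster_permutation(self):
        # independent oracle: same cluster bounds and compatible p on a
        # signal with a genuine effect window
        mne_stats = pytest.importorskip("mne.stats")
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        X = rng.standard_normal((15, 50))
        X[:, 20:30] += 1.2
        res = cluster_perm_one_sample(X, n_perm=2000, seed=8)
        thr = sps.t.ppf(0.95, df=14)
        t_obs, clusters, pvals, _ = mne_stats.permutation_cluster_1samp_test(
            X, threshold=thr, tail=1, n_permutations=2000, seed=9, verbose=False,
        )
        ours = {(c.start_ms, c.end_ms): c.p for c in res.clusters}
        theirs = {}
        for cl, p in zip(clusters, pvals):
            idx = np.asarray(cl[0] if isinstance(cl, tuple) else cl)
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
            theirs[(float(idx.min()), float(idx.max()))] = p
        assert set(ours) == set(theirs)
        for k in ours:
            assert ours[k] == pytest.approx(theirs[k], abs=0.02)

    def test_insufficient_participants_rejected(self):
        with pytest.raises(InsufficientDataError):
            cluster_perm_one_sample(np.zeros((1, 10)))


class TestClusterBetween:
    def test_identical_groups_give_no_clusters(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((6, 25))
        res = cluster_perm_between(A, A.copy(), n_perm=300, seed=1)
        assert res.clusters == []

    def test_known_offset_window_is_detected(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((10, 40))
        B = rng.standard_normal((10, 40))
        A[:, 10:20] += 4.0
        res = cluster_perm_between(A, B, n_perm=500, seed=3)
        sig = res.significant()
        assert len(sig) == 1
        assert sig[0].start_ms <= 10.0 <= 19.0 <= sig[0].end_ms

    def test_group_swap_flips_sign_same_p(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((8, 30)) + 1.0
        B = rng.standard_normal((8, 30))
        r1 = cluster_perm_between(A, B, n_perm=400, seed=5)
        r2 = cluster_perm_between(B, A, n_perm=400, seed=5)
        m1 = sorted((c.start_ms, c.end_ms, round(c.mass, 6)) for c in r1.clusters)
        m2 = sorted((c.start_ms, c.end_ms, round(-c.mass, 6)) for c in r2.clusters)
        assert m1 == m2


class TestPartialCorrelation:
    def test_identical_signals_with_constant_covariate(self):
        rng = np.random.default_rng(0)
        y = rng.normal(45, 10, 30)
        r = trial_partial_correlation(y, y, np.full(30, 45.0))
        assert r == pytest.approx(1.0)

    def test_decoded_equal_to_presented_is_degenerate(self):
        pres = np.tile([9.0, 27.0, 45.0, 63.0, 81.0], 4)
        rep = pres + np.random.default_rng(1).normal(0, 3, 20)
        with pytest.warns(RuntimeWarning, match="undefined"):
            r = trial_partial_correlation(pres.copy(), rep, pres)
        assert np.isnan(r)

    def test_matches_textbook_partial_correlation_formula(self):
        rng = np.random.default_rng(2)
        n = 6
        z = rng.normal(45, 20, n)
        x = 0.5 * z + rng.normal(0, 5, n)
        y = 0.3 * z + rng.normal(0, 5, n)
        r = trial_partial_correlation(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r == pytest.approx(expected)

    def test_categorical_covariate_equals_within_level_demeaning(self):
        rng = np.random.default_rng(3)
        pres = np.repeat([9.0, 27.0, 45.0, 63.0, 81.0], 8)
        x = rng.normal(0, 1, 40) + pres * 0.2
        y = rng.normal(0, 1, 40) + pres * 0.1
        r = trial_partial_correlation(x, y, pres, covariate="categorical")
        xr, yr = x.copy(), y.copy()
        for d in np.unique(pres):
            xr[pres == d] -= xr[pres == d].mean()
            yr[pres == d] -= yr[pres == d].mean()
        assert r == pytest.approx(np.corrcoef(xr, yr)[0, 1])

    def test_per_time_rows_handled(self):
        rng = np.random.default_rng(4)
        pres = np.tile([9.0, 27.0, 45.0], 4)
        rep = rng.normal(45, 5, 12)
        decoded = rng.normal(45, 5, (3, 12))
        r = trial_partial_correlation(decoded, rep, pres)
        assert r.shape == (3,)
        assert r[0] == pytest.approx(trial_partial_correlation(decoded[0], rep, pres))

    def test_too_few_trials_rejected(self):
        with pytest.raises(InsufficientDataError):
            trial_partial_correlation(np.zeros(3), np.zeros(3), np.zeros(3))
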