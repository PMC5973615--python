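"""Molecular-distance-to-health scoring."""

import numpy as np
import pytest

from kdsig.mdth import (
    ControlReference,
    build_control_reference,
    mdth_delta,
    mdth_score,
    mdth_score_matrix,
)

from conftest import ids, matrix_from


def _ref(mu, sigma, tids=None):
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    tids = tids or [f"T{j}" for j in range(len(mu))]
    return ControlReference(tuple(tids), mu, sigma, n_controls=2)


def brute_force_mdth(sample, ref):
    """Independent per-transcript oracle."""
    score, hits = 0.0, 0
    for t, mu, sigma in zip(ref.transcript_ids, ref.mu, ref.sigma):
        dev = abs(sample[t] - mu)
        if dev > 2 * sigma:
            score += dev / sigma
            hits += 1
    return score, hits


class TestControlReference:
    def test_two_control_hand_computation(self):
        m = matrix_from([[8.0], [10.0]])
        ref = build_control_reference(m, m.sample_ids)
        assert ref.mu[0] == pytest.approx(9.0)
        assert ref.sigma[0] == pytest.approx(np.sqrt(2.0))  # n-1 denominator

    def test_zero_variance_transcript_dropped(self):
        m = matrix_from([[8.0, 5.0], [10.0, 5.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            ref = build_control_reference(m, m.sample_ids)
        assert ref.transcript_ids == ("T0",)

    def test_control_order_permutation_invariant(self):
        rng = np.random.default_rng(0)
        m = matrix_from(rng.normal(9, 1, size=(6, 10)))
        r1 = build_control_reference(m, m.sample_ids)
        r2 = build_control_reference(m, m.sample_ids[::-1])
        np.testing.assert_allclose(r1.mu, r2.mu)
        np.testing.assert_allclose(r1.sigma, r2.sigma)

    def test_fewer_than_two_controls_rejected(self):
        m = matrix_from([[8.0]])
        with pytest.raises(ValueError):
            build_control_reference(m, m.sample_ids)


class TestMdthScore:
    def test_control_mean_sample_scores_zero(self):
        ref = _ref([7.0, 8.0, 9.0], [0.5, 0.5, 0.5])
        entry = mdth_score({"T0": 7.0, "T1": 8.0, "T2": 9.0}, ref)
        assert entry.score == 0.0 and entry.n_perturbed == 0

    def test_hand_computed_contributions(self):
        # mu=0, sigma=1, sample (3, 1, -4): contributions (3, 0, 4)
        ref = _ref([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        entry = mdth_score({"T0": 3.0, "T1": 1.0, "T2": -4.0}, ref)
        assert entry.score == pytest.approx(7.0)
        assert entry.n_perturbed == 2

    def test_missing_transcript_rejected(self):
        ref = _ref([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="missing"):
            mdth_score({"T0": 1.0}, ref)

    @pytest.mark.parametrize("seed", range(4))
    def test_vectorized_matches_per_transcript_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        ref = _ref(rng.normal(9, 1, n), rng.uniform(0.2, 1.0, n))
        x = rng.normal(9, 3, size=(5, n))
        m = matrix_from(x, transcript_ids=list(ref.transcript_ids))
        result = mdth_score_matrix(m, ref)
        for i, sid in enumerate(m.sample_ids):
            sample = dict(zip(ref.transcript_ids, x[i]))
            score, hits = brute_force_mdth(sample, ref)
            assert result.per_sample[sid].score == pytest.approx(score, abs=1e-9)
            assert result.per_sample[sid].n_perturbed == hits

    def test_monotone_in_deviation(self):
        ref = _ref([0.0, 0.0], [1.0, 1.0])
        base = mdth_score({"T0": 3.0, "T1": 0.0}, ref).score
        inflated = mdth_score({"T0": 4.5, "T1": 0.0}, ref).score
        assert inflated > base

    def test_additive_over_disjoint_universes(self):
        rng = np.random.default_rng(1)
        mu, sigma = rng.normal(9, 1, 40), rng.uniform(0.3, 1.0, 40)
        sample_vals = rng.normal(9, 3, 40)
        full = _ref(mu, sigma)
        left = _ref(mu[:20], sigma[:20], [f"T{j}" for j in range(20)])
        right = _ref(mu[20:], sigma[20:], [f"T{j}" for j in range(20, 40)])
        sample = {f"T{j}": sample_vals[j] for j in range(40)}
        assert mdth_score(sample, full).score == pytest.approx(
            mdth_score(sample, left).score + mdth_score(sample, right).score
        )

    def test_transcript_permutation_invariance(self):
        rng = np.random.default_rng(2)
        mu, sigma = rng.normal(9, 1, 30), rng.uniform(0.3, 1.0, 30)
        vals = rng.normal(9, 3, 30)
        sample = {f"T{j}": vals[j] for j in range(30)}
        perm = rng.permutation(30)
        ref1 = _ref(mu, sigma)
        ref2 = _ref(mu[perm], sigma[perm], [f"T{j}" for j in perm])
        assert mdth_score(sample, ref1).score == pytest.approx(
            mdth_score(sample, ref2).score
        )

    def test_held_out_controls_score_far_below_patients(self, small_cohort):
        c = small_cohort
        hc = ids(c.annotations, "HC", "training")
        kd = ids(c.annotations, "cKD", "training")
        patient_scores, control_scores = [], []
        for held_out in hc:
            ref = build_control_reference(c.matrix, [s for s in hc if s != held_out])
            control_scores.append(
                mdth_score_matrix(c.matrix.subset(samples=[held_out]), ref)
                .scores()[held_out]
            )
        ref_all = build_control_reference(c.matrix, hc)
        patient_scores = list(
            mdth_score_matrix(c.matrix.subset(samples=kd), ref_all).scores().values()
        )
        # held-out controls sit near the reference noise floor; planted
        # patients score severalfold higher
        assert np.median(patient_scores) > 2 * np.median(control_scores)
        assert np.median(patient_scores) > max(control_scores)


class TestMdthDelta:
    def test_constant_series_gives_zero_deltas(self):
        series = {"P1": {"pre": 100.0, "post24h": 100.0, "convalescent": 100.0}}
        assert mdth_delta(series)["P1"] == (0.0, 0.0)

    def test_decaying_cohort_deltas_mostly_negative(self):
        from kdsig.synth import CohortConfig, generate_cohort, generate_longitudinal_series
        from kdsig.mdth import build_control_reference, mdth_score_matrix

        # module coverage comparable to the default design (most of the
        # universe carries a planted effect), 50 patients
        cfg = CohortConfig(
            n_transcripts=1600, n_modules=20, module_size_range=(40, 60),
            n_per_group={"cKD_training": 50, "HC_training": 14},
            longitudinal_decay=(1.0, 0.5, 0.1), seed=42,
        )
        c = generate_cohort(cfg)
        lm, _ = generate_longitudinal_series(cfg, c)
        hc = ids(c.annotations, "HC", "training")
        ref = build_control_reference(c.matrix, hc)
        kd = ids(c.annotations, "cKD")
        pre = mdth_score_matrix(c.matrix.subset(samples=kd), ref).scores()
        post = mdth_score_matrix(lm, ref).scores()
        series = {
            s: {"pre": pre[s], "post24h": post[s + "_24h"],
                "convalescent": post[s + "_conv"]}
            for s in kd
        }
        deltas = mdth_delta(series)
        frac_both_negative = np.mean(
            [d[0] < 0 and d[1] < 0 for d in deltas.values()]
        )
        assert frac_both_negative >= 0.9

    def test_missing_timepoint_skips_patient_with_warning(self):
        series = {
            "P1": {"pre": 50.0, "post24h": 40.0, "convalescent": 10.0},
            "P2": {"pre": 50.0},
        }
        with pytest.warns(UserWarning, match="skipped"):
            deltas = mdth_delta(series)
        assert set(deltas) == {"P1"}
        assert deltas["P1"] == (-10.0, -30.0)
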