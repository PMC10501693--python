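"""Stage-1 pooling: sampling covariances, FIML, heterogeneity."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from metamediate import SimConfig, generate_meta_dataset
from metamediate.effects import CorrelationSet, build_correlation_sets
from metamediate.stage1 import (
    correlation_acov,
    fixed_effects_pool,
    fit_random_effects,
    heterogeneity_stats,
    pool,
    sampling_covariance,
)

from conftest import make_record


def complete_set(study_id, r, n):
    return CorrelationSet(study_id=study_id, r=np.asarray(r, float),
                          mask=np.ones(3, bool), n=n)


class TestSamplingCovariance:
    def test_independence_case(self):
        V = correlation_acov(np.zeros(3), 100)
        np.testing.assert_allclose(V, 0.01 * np.eye(3), atol=1e-15)

    def test_single_element_variance(self):
        cset = CorrelationSet("S1", np.array([0.5, np.nan, np.nan]),
                              np.array([True, False, False]), n=25)
        sv = sampling_covariance(cset, np.array([0.5, 0.0, 0.0]))
        assert sv.V.shape == (1, 1)
        assert sv.V[0, 0] == pytest.approx((1 - 0.25) ** 2 / 25)

    def test_matches_monte_carlo(self, reference_triple):
        # moderate-size Monte Carlo; the acceptance suite runs the full-size one
        from metamediate._linalg import triple_to_matrix

        n, reps = 500, 20_000
        rng = np.random.default_rng(42)
        R = triple_to_matrix(reference_triple)
        L = np.linalg.cholesky(R)
        samples = np.empty((reps, 3))
        for i in range(reps):
            X = rng.standard_normal((n, 3)) @ L.T
            C = np.corrcoef(X, rowvar=False)
            samples[i] = (C[0, 1], C[0, 2], C[1, 2])
        emp = np.cov(samples, rowvar=False)
        V = correlation_acov(reference_triple, n)
        np.testing.assert_allclose(np.diag(V), np.diag(emp), rtol=0.10)

    def test_rejects_bad_inputs(self):
        cset = complete_set("S1", [0.2, 0.2, 0.2], 100)
        with pytest.raises(ValueError, match="not PD"):
            sampling_covariance(cset, np.array([0.99, 0.99, -0.99]))


class TestRandomEffectsPooling:
    def test_single_study_identity(self):
        cset = complete_set("S1", [0.2, 0.3, 0.4], 200)
        pooled = fit_random_effects([cset])
        np.testing.assert_allclose(pooled.rho, [0.2, 0.3, 0.4], atol=1e-6)
        np.testing.assert_allclose(pooled.tau2, 0.0, atol=1e-12)

    def test_identical_studies_no_heterogeneity(self):
        sets = [complete_set(f"S{i}", [0.2, 0.25, 0.3], 150) for i in range(50)]
        pooled = pool(sets)
        np.testing.assert_allclose(pooled.rho, [0.2, 0.25, 0.3], atol=1e-5)
        assert np.all(pooled.tau2 < 1e-6)
        assert pooled.Q == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(pooled.i2, 0.0, atol=1e-4)

    def test_matches_gls_closed_form_under_homogeneity(self):
        """With tau^2 = 0 and complete data, FIML equals the GLS estimator."""
        rng = np.random.default_rng(3)
        sets = [
            complete_set(f"S{i}", 0.25 + rng.normal(0, 0.03, 3),
                         int(rng.integers(80, 400)))
            for i in range(5)
        ]
        pooled = fit_random_effects(sets, fix_tau2_zero=True)
        from metamediate.stage1 import _study_covariances

        Vs, _, _ = _study_covariances(sets)
        rho_gls, _ = fixed_effects_pool(sets, Vs)
        np.testing.assert_allclose(pooled.rho, rho_gls, atol=1e-6)

    def test_parameter_recovery(self, reference_triple):
        recs = generate_meta_dataset(
            SimConfig(K=200, tau=0.10, seed=11, mode="fast",
                      missingness=(1, 1, 1), flags_rate={})
        )
        pooled = pool(build_correlation_sets(recs))
        np.testing.assert_allclose(pooled.rho, reference_triple, atol=0.02)
        np.testing.assert_allclose(pooled.tau2, 0.01, rtol=0.5)

    def test_order_invariance(self, small_meta):
        _, sets = small_meta
        p1 = fit_random_effects(sets)
        p2 = fit_random_effects(sets[::-1])
        np.testing.assert_allclose(p1.rho, p2.rho, atol=1e-6)
        np.testing.assert_allclose(p1.tau2, p2.tau2, atol=1e-6)

    def test_likelihood_optimum_beats_truth(self, small_meta, reference_triple):
        from metamediate.stage1 import _nll, _pattern_groups, _study_covariances

        _, sets = small_meta
        pooled = fit_random_effects(sets)
        Vs, _, _ = _study_covariances(sets)
        patterns = _pattern_groups(sets, Vs)
        tau_free = np.ones(3, bool)
        at_truth = _nll(
            np.concatenate([np.arctanh(reference_triple),
                            np.log(np.expm1(np.full(3, 0.01)))]),
            patterns, tau_free,
        )
        assert -pooled.loglik <= at_truth + 1e-6

    def test_sparse_element_tau_fixed_zero(self):
        sets = [
            complete_set("S0", [0.2, 0.25, 0.3], 100),
            CorrelationSet("S1", np.array([0.2, 0.3, np.nan]),
                           np.array([True, True, False]), 100),
            CorrelationSet("S2", np.array([0.25, np.nan, np.nan]),
                           np.array([True, False, False]), 100),
        ]
        with pytest.warns(UserWarning, match="tau"):
            pooled = fit_random_effects(sets)
        assert pooled.tau2[2] == 0.0
        assert pooled.tau2_fixed_zero[2]

    def test_unobserved_element_errors(self):
        sets = [
            CorrelationSet("S1", np.array([0.2, np.nan, np.nan]),
                           np.array([True, False, False]), 100)
            for _ in range(3)
        ]
        with pytest.raises(ValueError, match="no study"):
            fit_random_effects(sets)


class TestHeterogeneity:
    def test_df_bookkeeping(self):
        sets = [complete_set(f"S{i}", [0.2, 0.25, 0.3], 100) for i in range(10)]
        pooled = pool(sets)
        assert pooled.df == 30 - 3

    def test_q_permutation_invariant(self, small_meta):
        _, sets = small_meta
        p1, p2 = pool(sets), pool(sets[::-1])
        assert p1.Q == pytest.approx(p2.Q, rel=1e-9)

    def test_q_grows_with_displaced_duplicate(self):
        base = [complete_set(f"S{i}", [0.2, 0.25, 0.3], 100) for i in range(10)]
        q_values = []
        for displacement in (0.0, 0.1, 0.2):
            extra = complete_set("dup", np.array([0.2, 0.25, 0.3]) + displacement,
                                 100)
            q_values.append(pool(base + [extra]).Q)
        assert q_values[0] < q_values[1] < q_values[2]

    def test_high_heterogeneity_gives_high_i2(self):
        recs = generate_meta_dataset(
            SimConfig(K=80, tau=0.15, seed=5, mode="fast", flags_rate={})
        )
        pooled = pool(build_correlation_sets(recs))
        assert pooled.i2_mean > 0.9


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_cross_check_against_metafor():
    """FIML pooling agrees with an independent multivariate ML fit.

    metafor::rma.mv maximizes the same marginal likelihood (diagonal
    between-study structure, known within-study V); both routes should
    agree on the pooled triple to ~3 decimals on a small fixture.
    """
    recs = generate_meta_dataset(
        SimConfig(K=25, tau=0.08, seed=21, mode="fast", missingness=(1, 1, 1),
                  flags_rate={})
    )
    sets = build_correlation_sets(recs)
    pooled = fit_random_effects(sets)

    from metamediate.stage1 import _study_covariances

    Vs, _, _ = _study_covariances(sets)
    rows, vblocks = [], []
    for s, sv in zip(sets, Vs):
        for pos, k in enumerate(sv.indices):
            rows.append((s.study_id, ("XM", "XY", "MY")[k], float(s.r[k])))
        vblocks.append(sv.V)
    import scipy.linalg as sla

    Vfull = sla.block_diag(*vblocks)
    data_csv = "\n".join(f"{sid},{el},{val!r}" for sid, el, val in rows)
    v_csv = "\n".join(",".join(repr(float(x)) for x in row) for row in Vfull)
    script = textwrap.dedent("""
        suppressMessages(library(metafor))
        d <- read.csv("data.csv", header = FALSE,
                      col.names = c("study", "element", "r"))
        V <- as.matrix(read.csv("v.csv", header = FALSE))
        fit <- rma.mv(r ~ element - 1, V = V, random = ~ element | study,
                      struct = "DIAG", data = d, method = "ML")
        cat(coef(fit), sep = ",")
    """)
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        open(os.path.join(td, "data.csv"), "w").write(data_csv + "\n")
        open(os.path.join(td, "v.csv"), "w").write(v_csv + "\n")
        open(os.path.join(td, "fit.R"), "w").write(script)
        out = subprocess.run(["Rscript", "fit.R"], cwd=td, capture_output=True,
                             text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    r_est = np.array([float(x) for x in out.stdout.strip().split(",")])
    # metafor orders elements alphabetically: MY, XM, XY
    np.testing.assert_allclose(np.array([r_est[1], r_est[2], r_est[0]]),
                               pooled.rho, atol=2e-3)
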