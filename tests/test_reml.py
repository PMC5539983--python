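"""Restricted likelihood, AI-REML optimization, proportions and AIC."""

import numpy as np
import pytest
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

import seqherit as sh
from seqherit.reml import ModelSpec, ai_reml, aic, restricted_loglik


def _relmat(values, ids=None, kind="grm_vr1"):
    ids = ids or [f"i{k}" for k in range(values.shape[0])]
    return sh.RelationshipMatrix(values, ids, kind)


# ---------------------------------------------------------------------------
# restricted likelihood
# ---------------------------------------------------------------------------

def test_loglik_two_point_closed_form():
    # V = I2, y = 0: logL = -1/2 [log|I| + log(1'I1) + 0] = -log(2)/2
    y = np.zeros(2)
    ll = restricted_loglik(y, [], np.array([1.0]))
    assert ll == pytest.approx(-0.5 * np.log(2.0))


def test_loglik_invariant_to_intercept_shift(ld_genotypes):
    rng = np.random.default_rng(5)
    k = sh.grm_vanraden1(ld_genotypes)
    y = rng.normal(size=k.n)
    s = np.array([0.4, 0.6])
    a = restricted_loglik(y, [k.values], s)
    b = restricted_loglik(y + 17.3, [k.values], s)
    assert b == pytest.approx(a, abs=1e-8)


def test_loglik_matches_naive_dense_oracle():
    rng = np.random.default_rng(8)
    n = 50
    b = rng.normal(size=(n, n // 2))
    k = b @ b.T / (n // 2)
    y = rng.normal(size=n)
    sigma2 = np.array([0.7, 1.3])
    # independent evaluation with explicit inverses
    v = sigma2[0] * k + sigma2[1] * np.eye(n)
    vi = np.linalg.inv(v)
    ones = np.ones(n)
    s11 = ones @ vi @ ones
    p = vi - np.outer(vi @ ones, vi @ ones) / s11
    expected = -0.5 * (np.linalg.slogdet(v)[1] + np.log(s11) + y @ p @ y)
    assert restricted_loglik(y, [k], sigma2) == pytest.approx(expected, abs=1e-8)


def test_loglik_rejects_negative_variance():
    with pytest.raises(ValueError):
        restricted_loglik(np.zeros(3), [], np.array([-1.0]))


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------

def _profiled_oracle(y, kv):
    """Golden-section oracle: profile the total variance, search h in (0,1)."""
    n = y.size

    def pieces(h):
        w = h * kv + (1 - h) * np.eye(n)
        c = cho_factor(w, lower=True)
        ones = np.ones(n)
        wi1 = cho_solve(c, ones)
        wiy = cho_solve(c, y)
        s11 = float(ones @ wi1)
        py = wiy - wi1 * (float(ones @ wiy) / s11)
        ypy = float(y @ py)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        return s11, ypy, logdet

    def negll(h):
        s11, ypy, logdet = pieces(h)
        st = ypy / (n - 1)
        return 0.5 * (n * np.log(st) + logdet + np.log(s11) - np.log(st) + ypy / st)

    res = minimize_scalar(negll, bounds=(1e-6, 1 - 1e-6), method="bounded",
                          options={"xatol": 1e-10})
    h = res.x
    _, ypy, _ = pieces(h)
    st = ypy / (n - 1)
    return np.array([h * st, (1 - h) * st]), -res.fun


@pytest.fixture(scope="module")
def single_component_data():
    g = sh.simulate_genotypes(
        sh.SimulationConfig(
            n_individuals=400, n_variants=1500, n_chromosomes=3,
            founder_pool_size=60, seed=10,
        )
    )
    g, _ = sh.qc_filter(g)
    phe, truth = sh.simulate_phenotypes(
        g,
        sh.ArchitectureConfig(
            n_causal=200, target_h2=0.5, reliability_distribution=(0.85, 0.95), seed=11
        ),
    )
    return sh.grm_vanraden1(g), phe["drp"].to_numpy(), truth


def test_ai_reml_matches_grid_oracle_single_component(single_component_data):
    k, y, _ = single_component_data
    fit = ai_reml(y, ModelSpec([k], ["g"], "reml-grm"))
    oracle, oracle_ll = _profiled_oracle(y, k.values)
    assert fit.converged
    np.testing.assert_allclose(fit.estimates, oracle, rtol=1e-4)
    assert fit.loglik == pytest.approx(oracle_ll, abs=1e-4)


def test_ai_reml_estimate_within_two_se_of_truth(single_component_data):
    k, y, truth = single_component_data
    fit = ai_reml(y, ModelSpec([k], ["g"], "reml-grm"))
    assert abs(fit.estimates[0] - truth.true_total_genetic_variance) < 2 * fit.se[0]


def test_ai_reml_pure_noise_estimate_consistent_with_zero(ld_genotypes):
    """Under the null the genetic share piles up at the boundary: across
    replicate noise vectors the median estimate is ~0 and boundary fits are
    common."""
    k = sh.grm_vanraden1(ld_genotypes)
    props, boundary = [], 0
    for seed in range(10):
        y = np.random.default_rng(500 + seed).normal(size=k.n)
        fit = ai_reml(y, ModelSpec([k], ["g"], "reml-grm"), tol=1e-6)
        props.append(fit.proportions[0])
        boundary += bool(fit.at_boundary[0])
    assert np.median(props) < 0.1
    assert boundary >= 3


def test_accepted_iterations_never_decrease_loglik(single_component_data):
    k, y, _ = single_component_data
    fit = ai_reml(y, ModelSpec([k], ["g"], "reml-grm"))
    diffs = np.diff(fit.loglik_trace)
    assert np.all(diffs >= -1e-9)


def test_estimates_invariant_to_component_order(ld_genotypes):
    rng = np.random.default_rng(9)
    mafs = sh.compute_maf(ld_genotypes)
    lo = sh.grm_alpha(ld_genotypes.subset(variants=mafs < 0.1))
    hi = sh.grm_alpha(ld_genotypes.subset(variants=mafs >= 0.1))
    y = rng.normal(size=lo.n) + np.linalg.cholesky(
        hi.values + 1e-6 * np.eye(hi.n)
    ) @ rng.normal(size=hi.n)
    f1 = ai_reml(y, ModelSpec([lo, hi], ["lo", "hi"], "custom"))
    f2 = ai_reml(y, ModelSpec([hi, lo], ["hi", "lo"], "custom"))
    np.testing.assert_allclose(f1.estimates[[0, 1]], f2.estimates[[1, 0]], rtol=1e-5, atol=1e-8)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)


def test_proportions_sum_with_residual_to_one(single_component_data):
    k, y, _ = single_component_data
    fit = ai_reml(y, ModelSpec([k], ["g"], "reml-grm"))
    total = fit.total_explained + fit.sigma2_e / fit.total_variance
    assert total == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# proportions & SEs
# ---------------------------------------------------------------------------

def test_proportion_arithmetic():
    fit = sh.VarianceComponentFit(
        model="custom",
        component_labels=["a", "b", "c", "residual"],
        estimates=np.array([1.0, 1.0, 2.0, 4.0]),
        se=np.zeros(4),
        cov=np.zeros((4, 4)),
        loglik=0.0,
        loglik_trace=[0.0],
        n_iter=1,
        converged=True,
        at_boundary=np.zeros(4, dtype=bool),
        n=100,
    )
    props, _ = sh.proportion_explained(fit)
    np.testing.assert_allclose(props, [0.125, 0.125, 0.25])


def test_zero_component_zero_proportion(ld_genotypes):
    rng = np.random.default_rng(2)
    k = sh.grm_vanraden1(ld_genotypes)
    y = rng.normal(size=k.n)
    fit = ai_reml(y, ModelSpec([k], ["g"], "reml-grm"))
    if fit.at_boundary[0]:
        assert fit.proportions[0] == pytest.approx(0.0, abs=1e-6)


def test_delta_method_se_matches_parametric_bootstrap(ld_genotypes):
    """SE of the explained proportion vs the SD over parametric refits."""
    rng = np.random.default_rng(77)
    k = sh.grm_vanraden1(ld_genotypes)
    n = k.n
    sig_g, sig_e = 0.5, 0.5
    v = sig_g * k.values + sig_e * np.eye(n)
    chol = np.linalg.cholesky(v)
    y0 = chol @ rng.normal(size=n)
    fit0 = ai_reml(y0, ModelSpec([k], ["g"], "reml-grm"))
    v_hat = fit0.estimates[0] * k.values + fit0.estimates[1] * np.eye(n)
    chol_hat = np.linalg.cholesky(v_hat)
    props = []
    for _ in range(400):
        y = chol_hat @ rng.normal(size=n)
        fit = ai_reml(y, ModelSpec([k], ["g"], "reml-grm"), tol=1e-6)
        props.append(fit.proportions[0])
    boot_sd = float(np.std(props, ddof=1))
    assert fit0.proportion_se[0] == pytest.approx(boot_sd, rel=0.25)


# ---------------------------------------------------------------------------
# model assembly & AIC
# ---------------------------------------------------------------------------

def test_greml_ms_builds_seven_plus_residual(ld_genotypes):
    part = sh.assign_maf_classes(sh.compute_maf(ld_genotypes))
    phe, _ = sh.simulate_phenotypes(
        ld_genotypes, sh.ArchitectureConfig(n_causal=50, seed=3)
    )
    fit = sh.fit_model(phe, "greml-ms", genotypes=ld_genotypes, partition=part)
    n_nonempty = int(np.sum(part.class_sizes() > 0))
    assert len(fit.component_labels) == n_nonempty + 1
    assert fit.component_labels[-1] == "residual"


def test_greml_ldms_component_count(ld_genotypes):
    part = sh.assign_maf_classes(sh.compute_maf(ld_genotypes))
    table = sh.segment_mean_ld(sh.ld_scores(ld_genotypes))
    part4 = sh.stratify_ld_groups(part, table, 4)
    phe, _ = sh.simulate_phenotypes(
        ld_genotypes, sh.ArchitectureConfig(n_causal=50, seed=3)
    )
    fit = sh.fit_model(phe, "greml-ldms", genotypes=ld_genotypes, partition=part4)
    assert len(fit.component_labels) - 1 == len(part4.groups())


def test_aic_arithmetic_and_unconverged_guard():
    fit = sh.VarianceComponentFit(
        model="custom", component_labels=["g", "residual"],
        estimates=np.array([1.0, 1.0]), se=np.zeros(2), cov=np.zeros((2, 2)),
        loglik=-100.0, loglik_trace=[-100.0], n_iter=1, converged=True,
        at_boundary=np.zeros(2, dtype=bool), n=10,
    )
    assert aic(fit) == pytest.approx(204.0)
    fit.converged = False
    with pytest.raises(ValueError, match="unconverged"):
        aic(fit)


def test_nested_model_never_has_lower_loglik():
    ds = sh.simulate_pedigree_dataset(321, n_founders=40, n_generations=3, n_variants=600)
    g, _ = sh.qc_filter(ds.genotypes)
    ped_fit = sh.fit_model(ds.phenotypes, "reml-ped", pedigree=ds.pedigree)
    both_fit = sh.fit_model(ds.phenotypes, "reml-pedgrm", genotypes=g, pedigree=ds.pedigree)
    assert both_fit.loglik >= ped_fit.loglik - 1e-6


def test_pedgrm_total_consistent_with_ped_total():
    """Rescaled total genetic variance agrees between the pedigree-only and
    joint pedigree+genomic fits on data holding both structures."""
    ds = sh.simulate_pedigree_dataset(55, n_founders=60, n_generations=4, n_variants=800)
    g, _ = sh.qc_filter(ds.genotypes)
    ids = ds.phenotypes["id"].astype(str).tolist()
    a = sh.a_matrix(ds.pedigree).align(ids)
    base = float(np.mean(np.diag(a.values)) - np.mean(a.values))
    ped_fit = sh.fit_model(ds.phenotypes, "reml-ped", pedigree=ds.pedigree)
    both_fit = sh.fit_model(ds.phenotypes, "reml-pedgrm", genotypes=g, pedigree=ds.pedigree)
    ped_total = ped_fit.estimates[0] * base
    both_total = both_fit.estimates[0] + both_fit.estimates[1] * base
    pooled_se = np.hypot(ped_fit.se[0] * base, np.hypot(both_fit.se[0], both_fit.se[1] * base))
    assert abs(ped_total - both_total) < 2 * pooled_se


def test_reliabilities_are_validated_but_not_used_as_weights(ld_genotypes):
    phe, _ = sh.simulate_phenotypes(
        ld_genotypes, sh.ArchitectureConfig(n_causal=50, seed=3)
    )
    k = sh.grm_vanraden1(ld_genotypes)
    fit_a = sh.fit_model(phe, "reml-grm", grm=k)
    phe_b = phe.copy()
    phe_b["reliability"] = 0.5  # different reliabilities, same DRP
    fit_b = sh.fit_model(phe_b, "reml-grm", grm=k)
    np.testing.assert_array_equal(fit_a.estimates, fit_b.estimates)
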