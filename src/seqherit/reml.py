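"""Multi-component average-information REML for variance partitioning.

The model is ``y = 1 mu + sum_k g_k + e`` with ``g_k ~ N(0, K_k sigma2_k)``
and ``e ~ N(0, I sigma2_e)``; each K_k is a relationship matrix (a per-class
GRM, a single GRM, or the pedigree A matrix) and the incidence structure is
one record per individual.  The only fixed effect is the intercept, which
REML profiles out.

The restricted log-likelihood (up to an additive constant) is

    logL = -1/2 [ log|V| + log(1' V^-1 1) + y' P y ],

with ``V = sum_k sigma2_k K_k + sigma2_e I`` and
``P = V^-1 - V^-1 1 (1' V^-1 1)^-1 1' V^-1``.  Optimization uses
average-information (AI) updates with an EM fallback for the first
iterations and whenever an AI step leaves the feasible region, plus step
halving so accepted iterations never decrease the likelihood.  Components
that hit the lower bound are held at a small positive floor.  Standard
errors come from the inverse AI matrix at the optimum and proportions of
phenotypic (DRP) variance are computed as sigma2_k over the total with
delta-method standard errors using the full estimate covariance.

Reliabilities of deregressed proofs are carried in the phenotype table but
deliberately not used as residual weights, matching common practice when the
estimation software does not support weighting; a weighted mode is
intentionally absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .relmat import Pedigree, RelationshipMatrix, a_matrix, grm_alpha, grm_vanraden1
from .stratify import VariantPartition

logger = logging.getLogger("seqherit")

MODEL_LABELS = ("greml-ms", "greml-ldms", "reml-ped", "reml-grm", "reml-pedgrm")


def validate_phenotypes(phenotypes: pd.DataFrame, min_reliability: float = 0.2) -> pd.DataFrame:
    """Check the (id, trait, drp, reliability) table contract."""
    for col in ("id", "trait", "drp", "reliability"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    if phenotypes.duplicated(["id", "trait"]).any():
        raise ValueError("more than one record per individual per trait")
    r = phenotypes["reliability"].to_numpy(dtype=float)
    if np.any(r < min_reliability) or np.any(r > 1.0):
        raise ValueError(f"reliabilities outside [{min_reliability}, 1]")
    return phenotypes


@dataclass
class ModelSpec:
    """Ordered genetic variance components plus the implicit residual."""

    components: list[RelationshipMatrix]
    labels: list[str]
    model: str = "custom"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("need at least one genetic component")
        if len(self.labels) != len(self.components):
            raise ValueError("one label per component")
        ids = self.components[0].ids
        for k in self.components[1:]:
            if k.ids != ids:
                raise ValueError("components cover different (or differently ordered) individuals")


@dataclass
class VarianceComponentFit:
    """REML estimates with uncertainty, likelihood and convergence record."""

    model: str
    component_labels: list[str]  # genetic components then 'residual'
    estimates: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    at_boundary: np.ndarray
    n: int
    proportions: np.ndarray = field(default=None)  # genetic components only
    proportion_se: np.ndarray = field(default=None)

    @property
    def sigma2_e(self) -> float:
        return float(self.estimates[-1])

    @property
    def total_variance(self) -> float:
        return float(np.sum(self.estimates))

    @property
    def total_explained(self) -> float:
        return float(np.sum(self.proportions))

    @property
    def total_explained_se(self) -> float:
        """Delta-method SE of the summed genetic proportions (1 - sigma2_e/total)."""
        theta = self.estimates
        total = float(np.sum(theta))
        jac = np.full(theta.size, theta[-1] / total ** 2)
        jac[-1] -= 1.0 / total
        return float(np.sqrt(max(jac @ self.cov @ jac, 0.0)))

    def to_frame(self) -> pd.DataFrame:
        k = len(self.estimates) - 1
        return pd.DataFrame(
            {
                "component": self.component_labels,
                "sigma2": self.estimates,
                "se": self.se,
                "proportion": np.append(self.proportions, np.nan),
                "proportion_se": np.append(self.proportion_se, np.nan),
                "at_boundary": self.at_boundary,
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# model\t{self.model}\n")
            fh.write(f"# loglik\t{self.loglik:.10g}\n")
            fh.write(f"# iterations\t{self.n_iter}\n")
            fh.write(f"# converged\t{self.converged}\n")
            fh.write(f"# n\t{self.n}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _build_v(ks: list[np.ndarray], sigma2: np.ndarray, n: int) -> np.ndarray:
    v = sigma2[-1] * np.eye(n)
    for s, k in zip(sigma2[:-1], ks):
        v += s * k
    return v


def _chol(v: np.ndarray):
    try:
        return cho_factor(v, lower=True)
    except np.linalg.LinAlgError:
        logger.warning("V numerically singular; adding 1e-8 diagonal jitter")
        return cho_factor(v + 1e-8 * np.eye(v.shape[0]), lower=True)


def restricted_loglik(y: np.ndarray, ks: list[np.ndarray], sigma2: np.ndarray) -> float:
    """Restricted log-likelihood of an intercept-only variance model.

    Constant terms (``-n/2 log(2 pi)`` etc.) are dropped consistently.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 < 0):
        raise ValueError("variance components must be nonnegative")
    v = _build_v(ks, sigma2, n)
    c = _chol(v)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    ones = np.ones(n)
    vi1 = cho_solve(c, ones)
    viy = cho_solve(c, y)
    s11 = float(ones @ vi1)
    py = viy - vi1 * (float(ones @ viy) / s11)
    return -0.5 * (logdet + np.log(s11) + float(y @ py))


def _reml_pieces(y: np.ndarray, ks: list[np.ndarray], sigma2: np.ndarray):
    """One expensive pass: loglik, P, Py, and per-component quad/trace terms."""
    n = y.size
    v = _build_v(ks, sigma2, n)
    c = _chol(v)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    ones = np.ones(n)
    # same solve-based arithmetic as restricted_loglik, so candidate-step
    # likelihoods agree with iteration likelihoods to the bit even when V is
    # ill-conditioned
    vi1 = cho_solve(c, ones)
    viy = cho_solve(c, y)
    s11 = float(ones @ vi1)
    py = viy - vi1 * (float(ones @ viy) / s11)
    ll = -0.5 * (logdet + np.log(s11) + float(y @ py))
    vi = cho_solve(c, np.eye(n))
    p = vi - np.outer(vi1, vi1) / s11
    nk = len(ks)
    quad = np.empty(nk + 1)
    tr = np.empty(nk + 1)
    t = np.empty((n, nk + 1))
    for i, k in enumerate(ks):
        t[:, i] = k @ py
        quad[i] = float(py @ t[:, i])
        tr[i] = float(np.sum(p * k))  # tr(PK) for symmetric P, K
    t[:, nk] = py
    quad[nk] = float(py @ py)
    tr[nk] = float(np.trace(p))
    pt = p @ t
    ai = 0.5 * (t.T @ pt)
    return ll, quad, tr, ai


def ai_reml(
    y: np.ndarray,
    spec: ModelSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
    min_variance_fraction: float = 1e-8,
) -> VarianceComponentFit:
    """Maximize the restricted likelihood by stabilized AI-REML.

    Starting values split var(y) equally over all components (genetic plus
    residual).  The first two iterations use EM updates; afterwards AI steps
    are taken with step halving and an EM fallback whenever a step leaves
    the feasible region or would decrease the likelihood.  Convergence is
    declared when the likelihood changes by less than ``tol``; components at
    the lower bound (``min_variance_fraction * var(y)``) are flagged and not
    counted as free parameters.  A fit that does not converge is returned
    with ``converged=False``, never discarded.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    ks = [k.values for k in spec.components]
    nk = len(ks)
    if n <= nk + 1:
        raise ValueError(f"n={n} too small for {nk} genetic components")
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    bound = min_variance_fraction * vary
    theta = np.full(nk + 1, vary / (nk + 1))

    trace: list[float] = []
    ll = -np.inf
    converged = False
    it = 0
    ai = np.eye(nk + 1)
    for it in range(1, max_iter + 1):
        ll_new, quad, tr, ai = _reml_pieces(y, ks, theta)
        if trace and ll_new + 1e-10 < trace[-1]:
            # should not happen: candidate steps are only accepted if they
            # do not decrease the likelihood
            logger.warning("likelihood decreased by %.3g at accepted step", trace[-1] - ll_new)
        trace.append(ll_new)
        if it > 1 and abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

        grad = 0.5 * (quad - tr)
        em_step = theta + (theta ** 2) * (quad - tr) / n
        proposal = None
        if it > 2:
            # active set: components pinned at the floor whose gradient points
            # further down are excluded from the AI system
            pinned = (theta <= bound * (1 + 1e-9)) & (grad < 0)
            free_idx = np.flatnonzero(~pinned)
            delta = None
            if free_idx.size:
                sub = ai[np.ix_(free_idx, free_idx)]
                try:
                    d_free = np.linalg.solve(sub + 1e-12 * np.eye(free_idx.size), grad[free_idx])
                    delta = np.zeros(nk + 1)
                    delta[free_idx] = d_free
                except np.linalg.LinAlgError:
                    delta = None
            if delta is not None:
                step = 1.0
                for _ in range(12):
                    # components pushed below the floor are clamped there so the
                    # rest of the step is not shrunk with them
                    cand = np.maximum(theta + step * delta, bound)
                    cand_ll = restricted_loglik(y, ks, cand)
                    if cand_ll >= ll - 1e-12:
                        proposal = cand
                        break
                    step *= 0.5
        if proposal is None:
            cand = np.maximum(em_step, bound)
            cand_ll = restricted_loglik(y, ks, cand)
            if cand_ll >= ll - 1e-12:
                proposal = cand
            else:
                # damp the EM step toward the current point
                step = 0.5
                for _ in range(12):
                    cand = theta + step * (np.maximum(em_step, bound) - theta)
                    cand_ll = restricted_loglik(y, ks, cand)
                    if cand_ll >= ll - 1e-12:
                        proposal = cand
                        break
                    step *= 0.5
        if proposal is None or np.allclose(proposal, theta, rtol=0, atol=0):
            converged = True  # stationary: no direction improves
            break
        theta = proposal

    at_boundary = theta <= bound * (1 + 1e-6)
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    fit = VarianceComponentFit(
        model=spec.model,
        component_labels=list(spec.labels) + ["residual"],
        estimates=theta,
        se=se,
        cov=cov,
        loglik=ll,
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
        at_boundary=at_boundary,
        n=n,
    )
    props, prop_se = proportion_explained(fit)
    fit.proportions = props
    fit.proportion_se = prop_se
    if not converged:
        logger.warning("AI-REML did not converge in %d iterations (model %s)", max_iter, spec.model)
    return fit


def proportion_explained(fit: VarianceComponentFit) -> tuple[np.ndarray, np.ndarray]:
    """Per-genetic-component share of total (DRP) variance with delta-method SEs.

    The share of component i is ``sigma2_i / (sum_k sigma2_k + sigma2_e)``;
    the SE propagates the full covariance of all estimates through the ratio.
    """
    theta = fit.estimates
    total = float(np.sum(theta))
    if total <= 0:
        raise ValueError("total variance <= 0")
    nk = theta.size - 1
    props = theta[:nk] / total
    prop_se = np.empty(nk)
    for i in range(nk):
        jac = -theta[i] / total ** 2 * np.ones(theta.size)
        jac[i] += 1.0 / total
        prop_se[i] = np.sqrt(max(float(jac @ fit.cov @ jac), 0.0))
    return props, prop_se


def aic(fit: VarianceComponentFit) -> float:
    """Akaike information criterion 2k - 2 logL.

    k counts free variance components only (boundary-fixed components are
    excluded; the intercept is profiled out by REML and not counted).
    """
    if not fit.converged:
        raise ValueError("AIC undefined for an unconverged fit")
    k = int(np.sum(~fit.at_boundary))
    return 2.0 * k - 2.0 * fit.loglik


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _grms_from_partition(genotypes, partition: VariantPartition, alpha: float = -1.0):
    """One standardized GRM per (nonempty) MAF or MAF x LD group."""
    comps, labels = [], []
    for label, idx in partition.groups():
        sub = genotypes.subset(variants=idx)
        try:
            comps.append(grm_alpha(sub, alpha=alpha))
        except ValueError as err:
            logger.warning("dropping group %s: %s", label, err)
            continue
        labels.append(label)
    if not comps:
        raise ValueError("no nonempty variant groups")
    return comps, labels


def build_model_spec(
    model: str,
    *,
    genotypes=None,
    partition: VariantPartition | None = None,
    pedigree: Pedigree | None = None,
    grm: RelationshipMatrix | None = None,
) -> ModelSpec:
    """Assemble the variance components for one of the named models.

    greml-ms / greml-ldms use one standardized (alpha = -1) GRM per MAF or
    MAF x LD group; reml-grm and reml-pedgrm use a VanRaden method 1 GRM
    (or a caller-supplied matrix); reml-ped uses the pedigree A matrix.
    """
    model = model.lower()
    if model not in MODEL_LABELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_LABELS}")
    if model in ("greml-ms", "greml-ldms"):
        if genotypes is None or partition is None:
            raise ValueError(f"{model} requires genotypes and a variant partition")
        if model == "greml-ldms" and partition.ld_group is None:
            raise ValueError("greml-ldms requires a partition with LD groups")
        if model == "greml-ms" and partition.ld_group is not None:
            partition = VariantPartition(partition.maf_class, partition.spec)
        comps, labels = _grms_from_partition(genotypes, partition)
        return ModelSpec(comps, labels, model)
    if model == "reml-ped":
        if pedigree is None:
            raise ValueError("reml-ped requires a pedigree")
        return ModelSpec([a_matrix(pedigree)], ["pedigree"], model)
    g_comp = grm if grm is not None else (grm_vanraden1(genotypes) if genotypes is not None else None)
    if g_comp is None:
        raise ValueError(f"{model} requires genotypes or a GRM")
    if model == "reml-grm":
        return ModelSpec([g_comp], ["genomic"], model)
    if pedigree is None:
        raise ValueError("reml-pedgrm requires a pedigree")
    a = a_matrix(pedigree)
    return ModelSpec([g_comp, a], ["genomic", "pedigree"], model)


def fit_model(
    phenotypes: pd.DataFrame,
    model: str | ModelSpec,
    *,
    genotypes=None,
    partition: VariantPartition | None = None,
    pedigree: Pedigree | None = None,
    grm: RelationshipMatrix | None = None,
    trait: str | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    min_variance_fraction: float = 1e-8,
) -> VarianceComponentFit:
    """Fit one of the named variance models to a DRP table.

    The phenotype table has one record per individual per trait; matrices
    are aligned (subset and reordered) to the phenotyped individuals.
    """
    phenotypes = validate_phenotypes(phenotypes, min_reliability=0.0)
    if trait is None:
        traits = phenotypes["trait"].unique()
        if len(traits) != 1:
            raise ValueError(f"multiple traits present {list(traits)}; pass trait=")
        trait = traits[0]
    sub = phenotypes[phenotypes["trait"] == trait]
    ids = sub["id"].astype(str).tolist()
    y = sub["drp"].to_numpy(dtype=float)
    if isinstance(model, ModelSpec):
        spec = model
    else:
        spec = build_model_spec(
            model, genotypes=genotypes, partition=partition, pedigree=pedigree, grm=grm
        )
    spec = ModelSpec([k.align(ids) for k in spec.components], spec.labels, spec.model)
    return ai_reml(y, spec, max_iter=max_iter, tol=tol, min_variance_fraction=min_variance_fraction)
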