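"""Two-kernel mixed model: variance decomposition, BLUP, partial genetic values.

The model is

    y = X b + u_a + u_d + e,
    u_a ~ N(0, Ga sigma_a^2),  u_d ~ N(0, Gd sigma_d^2),  e ~ N(0, I sigma_e^2),

with Ga/Gd the additive and dominance genomic relationship matrices and one
record per genotyped individual (the incidence matrices linking records to
individuals are identities; a general id-mapping can be applied upstream by
row-expanding y and X).  Two estimation backends share the same output
container:

* ``fit_reml`` — average-information REML with EM fallback steps, standard
  errors from the inverse AI matrix, BLUPs from the mixed-model equations.
* ``fit_gibbs`` — a Gibbs sampler with scaled-inverse-chi-squared priors,
  run in the eigenbases of Ga and Gd so every conditional is diagonal.

The partial genetic values (PGVs) are ya = u_a and yd = u_d at the
individual level — the additive-only and dominance-only slices of each
animal's total genetic value — and are the response vectors the association
module can scan in place of the raw trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import linalg

from .kinship import GRM

_RIDGE = 1e-6  # solver-side diagonal ridge; never stored in a GRM


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class ModelSpec:
    """Inputs and settings for a variance-component fit.

    ``Gd=None`` drops the dominance kernel (single-GRM GBLUP).  ``X``
    defaults to an intercept-only design; the conventional default for this
    analysis is intercept + sex, built upstream from the phenotype table.
    """

    y: np.ndarray
    Ga: GRM
    Gd: GRM | None = None
    X: np.ndarray | None = None
    backend: Literal["reml", "gibbs"] = "reml"
    # reml settings
    max_iter: int = 100
    tol: float = 1e-6
    # gibbs settings
    iterations: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    prior_df: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        n = self.y.size
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.shape[0] != n or self.Ga.n != n or (self.Gd is not None and self.Gd.n != n):
            raise ValueError("y, X and GRMs must share sample ordering and length")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effects design X is rank deficient")


@dataclass
class VarianceComponents:
    """Estimated variance components and derived heritabilities.

    ``h2_a``/``h2_d`` are plug-in ratios of the point estimates; a Gibbs fit
    additionally carries the posterior mean of the per-iteration ratios in
    ``ratio_posterior_mean`` (the two conventions can differ noticeably when
    the posterior is wide).
    """

    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    se_a: float = np.nan
    se_d: float = np.nan
    se_e: float = np.nan
    ratio_posterior_mean: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_d + self.sigma2_e

    @property
    def h2_a(self) -> float:
        return self.sigma2_a / self.total

    @property
    def h2_d(self) -> float:
        return self.sigma2_d / self.total

    @property
    def dominance_share(self) -> float:
        """sigma_d^2 / (sigma_a^2 + sigma_d^2), the dominance fraction of genetic variance."""
        g = self.sigma2_a + self.sigma2_d
        if g == 0:
            return np.nan if self.sigma2_d == 0 and self.sigma2_a == 0 else 0.0
        return self.sigma2_d / g


@dataclass
class GeneticFit:
    """Variance components plus fixed effects, BLUPs and PGVs."""

    components: VarianceComponents
    b: np.ndarray
    ua: np.ndarray
    ud: np.ndarray
    samples: list[str]
    log_likelihood: float = np.nan
    n_iter: int = 0
    posterior: pd.DataFrame | None = None

    @property
    def ya(self) -> np.ndarray:
        """Additive partial genetic values (identity incidence: ya = ua)."""
        return self.ua

    @property
    def yd(self) -> np.ndarray:
        """Dominance partial genetic values."""
        return self.ud


def partial_genetic_values(fit: GeneticFit) -> tuple[np.ndarray, np.ndarray]:
    """The (ya, yd) response vectors for PGV-based association scans."""
    return fit.ya, fit.yd


def heritability_summary(vc: VarianceComponents) -> pd.Series:
    """One summary row: components, heritabilities, dominance share."""
    if vc.sigma2_a < 0 or vc.sigma2_d < 0 or vc.sigma2_e < 0:
        raise ValueError("variance components must be non-negative")
    return pd.Series(
        {
            "sigma2_a": vc.sigma2_a,
            "sigma2_d": vc.sigma2_d,
            "sigma2_e": vc.sigma2_e,
            "se_a": vc.se_a,
            "se_d": vc.se_d,
            "se_e": vc.se_e,
            "h2_a": vc.h2_a,
            "h2_d": vc.h2_d,
            "dominance_share": vc.dominance_share,
        }
    )


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------


def _reml_quantities(theta, kernels, y, X):
    """P-matrix quantities for the current components. Returns dict or None if V singular."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], kernels):
        V += t * K
    V[np.diag_indices(n)] += _RIDGE * theta[-1]
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdet_V = 2.0 * np.log(np.diag(c)).sum()
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    sign, logdet_X = np.linalg.slogdet(XtViX)
    C = np.linalg.inv(XtViX)
    P = Vi - ViX @ C @ ViX.T
    Py = P @ y
    ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    return {"Vi": Vi, "ViX": ViX, "C": C, "P": P, "Py": Py, "ll": ll}


def fit_reml(spec: ModelSpec) -> GeneticFit:
    """Average-information REML for the additive(+dominance) GRM model.

    Components are floored at ``1e-8 * var(y)``; an AI step that lowers the
    restricted likelihood is halved and ultimately replaced by an EM step.
    Standard errors come from the inverse AI matrix at convergence.
    """
    y, X = spec.y, spec.X
    n = y.size
    if n < 30:
        warnings.warn("fewer than 30 records; variance components will be unstable")
    kernels = [spec.Ga.values] + ([spec.Gd.values] if spec.Gd is not None else [])
    ncomp = len(kernels) + 1
    vary = float(np.var(y))
    floor = 1e-8 * vary
    theta = np.full(ncomp, vary / ncomp)

    trace = []
    q = _reml_quantities(theta, kernels, y, X)
    if q is None:
        raise ConvergenceError("initial variance matrix not positive definite")
    AI = None
    for it in range(spec.max_iter):
        P, Py = q["P"], q["Py"]
        Ks = kernels + [np.eye(n)]
        KPy = [K @ Py for K in Ks]
        score = np.array(
            [-0.5 * (float((P * K).sum()) - float(Py @ kpy)) for K, kpy in zip(Ks, KPy)]
        )
        AI = 0.5 * np.array([[float(ki @ P @ kj) for kj in KPy] for ki in KPy])
        trace.append({"iter": it, "theta": theta.copy(), "ll": q["ll"], "score": score.copy()})

        # active-set: components pinned at the floor that want to go lower
        # are frozen, otherwise the AI step oscillates against the boundary
        free = ~((theta <= floor * (1 + 1e-9)) & (score < 0))
        delta = np.zeros(ncomp)
        if free.any():
            try:
                delta[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
            except np.linalg.LinAlgError:
                delta[free] = (score * theta**2 * 2.0 / n)[free]  # EM-scale fallback

        accepted = None
        step = 1.0
        for _ in range(6):
            cand = np.maximum(theta + step * delta, floor)
            qc = _reml_quantities(cand, kernels, y, X)
            if qc is not None and qc["ll"] >= q["ll"] - 1e-10:
                accepted = (cand, qc)
                break
            step *= 0.5
        if accepted is None:
            # EM update: guaranteed uphill, slow but safe
            em = np.array(
                [
                    t + (t**2 / n) * (float(Py @ kpy) - float((P * K).sum()))
                    for t, K, kpy in zip(theta, Ks, KPy)
                ]
            )
            cand = np.maximum(em, floor)
            qc = _reml_quantities(cand, kernels, y, X)
            if qc is None:
                raise ConvergenceError("EM fallback produced a singular V", trace)
            accepted = (cand, qc)

        new_theta, new_q = accepted
        converged = abs(new_q["ll"] - q["ll"]) < spec.tol
        theta, q = new_theta, new_q
        if converged:
            break
    else:
        raise ConvergenceError(
            f"REML did not converge in {spec.max_iter} iterations", trace
        )

    if np.any(theta <= floor * (1 + 1e-9)):
        warnings.warn("one or more variance components hit the lower floor")

    # recompute the AI matrix at the converged estimates for the SEs
    P, Py = q["P"], q["Py"]
    Ks = kernels + [np.eye(n)]
    KPy = [K @ Py for K in Ks]
    AI = 0.5 * np.array([[float(ki @ P @ kj) for kj in KPy] for ki in KPy])
    try:
        se = np.sqrt(np.diag(np.linalg.inv(AI)))
    except np.linalg.LinAlgError:
        se = np.full(ncomp, np.nan)

    b = q["C"] @ (q["ViX"].T @ y)
    Py = q["Py"]
    ua = theta[0] * (spec.Ga.values @ Py)
    if spec.Gd is not None:
        ud = theta[1] * (spec.Gd.values @ Py)
        comp = VarianceComponents(theta[0], theta[1], theta[2], se[0], se[1], se[2])
    else:
        ud = np.zeros(n)
        comp = VarianceComponents(theta[0], 0.0, theta[1], se[0], np.nan, se[1])
    return GeneticFit(
        components=comp,
        b=b,
        ua=ua,
        ud=ud,
        samples=list(spec.Ga.samples),
        log_likelihood=q["ll"],
        n_iter=it + 1,
    )


def reml_score(fit_theta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Restricted-likelihood score vector at given components (diagnostics)."""
    kernels = [spec.Ga.values] + ([spec.Gd.values] if spec.Gd is not None else [])
    q = _reml_quantities(np.asarray(fit_theta, float), kernels, spec.y, spec.X)
    Ks = kernels + [np.eye(spec.y.size)]
    P, Py = q["P"], q["Py"]
    return np.array([-0.5 * (float((P * K).sum()) - float(Py @ (K @ Py))) for K in Ks])


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _scaled_inv_chi2(rng, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


def fit_gibbs(spec: ModelSpec) -> GeneticFit:
    """Gibbs sampler for the same model, mirroring a Bayesian kernel fit.

    Each genetic effect is sampled in the eigenbasis of its GRM, where the
    full conditional is diagonal; variance components get
    scaled-inverse-chi-squared updates with ``prior_df`` degrees of freedom
    and prior scales that split var(y) equally across the components.
    Reported point estimates are posterior means over the kept samples;
    ``ratio_posterior_mean`` carries the posterior means of the
    per-iteration heritability ratios.
    """
    y, X = spec.y, spec.X
    n = y.size
    rng = np.random.default_rng(spec.seed)
    kernels = [spec.Ga] + ([spec.Gd] if spec.Gd is not None else [])
    nk = len(kernels)
    eig = []
    for g in kernels:
        d, U = linalg.eigh(g.values, check_finite=False)
        if d.min() < -1e-6 * max(d.max(), 1.0):
            raise ValueError(f"{g.kind} GRM is not PSD within tolerance")
        pos = d > 1e-10 * max(d.max(), 1.0)
        eig.append((d[pos], U[:, pos]))

    vary = float(np.var(y))
    df0 = spec.prior_df
    # prior mean of each component ~ var(y)/(nk+1)
    s0 = vary / (nk + 1) * (df0 - 2.0) / df0

    XtX = X.T @ X
    XtX_chol = linalg.cho_factor(XtX)
    p = X.shape[1]

    b = np.zeros(p)
    alphas = [np.zeros(d.size) for d, _ in eig]
    us = [np.zeros(n) for _ in eig]
    sig = np.full(nk + 1, vary / (nk + 1))  # genetic comps then residual

    keep_draws = []
    sum_b = np.zeros(p)
    sum_u = [np.zeros(n) for _ in eig]
    n_kept = 0

    for it in range(spec.iterations):
        # fixed effects | rest
        resid_no_b = y - sum(us, start=np.zeros(n))
        bhat = linalg.cho_solve(XtX_chol, X.T @ resid_no_b)
        L = linalg.cholesky(np.linalg.inv(XtX) * sig[-1], lower=True)
        b = bhat + L @ rng.standard_normal(p)
        xb = X @ b

        # each genetic effect | rest
        for k, (d, U) in enumerate(eig):
            r = y - xb - sum(us[j] for j in range(nk) if j != k)
            Utr = U.T @ r
            prec = 1.0 / (sig[k] * d) + 1.0 / sig[-1]
            mean = (Utr / sig[-1]) / prec
            alphas[k] = mean + rng.standard_normal(d.size) / np.sqrt(prec)
            us[k] = U @ alphas[k]
            # variance component | alpha
            ss = float((alphas[k] ** 2 / d).sum())
            sig[k] = _scaled_inv_chi2(
                rng, df0 + d.size, (df0 * s0 + ss) / (df0 + d.size)
            )

        # residual variance
        e = y - xb - sum(us, start=np.zeros(n))
        sig[-1] = _scaled_inv_chi2(
            rng, df0 + n, (df0 * s0 + float(e @ e)) / (df0 + n)
        )

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            total = sig.sum()
            genetic = sig[:nk].sum()
            row = {"sigma2_a": sig[0], "sigma2_e": sig[-1], "h2_a": sig[0] / total}
            if nk == 2:
                row["sigma2_d"] = sig[1]
                row["h2_d"] = sig[1] / total
                row["dominance_share"] = sig[1] / genetic if genetic > 0 else np.nan
            keep_draws.append(row)
            sum_b += b
            for k in range(nk):
                sum_u[k] += us[k]
            n_kept += 1

    post = pd.DataFrame(keep_draws)
    means, sds = post.mean(), post.std(ddof=1)
    ratio_post = {
        k: float(means[k]) for k in ("h2_a", "h2_d", "dominance_share") if k in post
    }
    comp = VarianceComponents(
        sigma2_a=float(means["sigma2_a"]),
        sigma2_d=float(means.get("sigma2_d", 0.0)),
        sigma2_e=float(means["sigma2_e"]),
        se_a=float(sds["sigma2_a"]),
        se_d=float(sds.get("sigma2_d", np.nan)),
        se_e=float(sds["sigma2_e"]),
        ratio_posterior_mean=ratio_post,
    )
    ua = sum_u[0] / n_kept
    ud = sum_u[1] / n_kept if nk == 2 else np.zeros(n)
    return GeneticFit(
        components=comp,
        b=sum_b / n_kept,
        ua=ua,
        ud=ud,
        samples=list(spec.Ga.samples),
        posterior=post,
        n_iter=spec.iterations,
    )


def fit(spec: ModelSpec) -> GeneticFit:
    """Dispatch on ``spec.backend``."""
    return fit_reml(spec) if spec.backend == "reml" else fit_gibbs(spec)
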