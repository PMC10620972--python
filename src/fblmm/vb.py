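"""Coordinate-ascent mean-field variational Bayes for the family-based
Bayesian linear mixed model.

The model, for a centred quantitative outcome Y of length n:

    Y = X G b + sum_m r_m Z_m U_m + Z_gf U_gf + Z_ef U_ef + eps

with G = diag(gamma), gamma_j ~ Bernoulli(theta0), b_j ~ N(0, sigma_b^2)
(spike-and-slab fixed effects for isolated common variants);
U_m ~ N(0, I sigma_m^2), r_m ~ Bernoulli(p_r) (region random effects with
region selection); U_gf, U_ef Gaussian random effects on the kinship and
shared-environment eigen-designs; eps ~ N(0, I sigma_eps^2); inverse-gamma
priors on every variance component.

The posterior is approximated by the fully factorised family

    q = q(b) prod_j q(gamma_j) prod_m q(U_m) q(r_m) q(U_gf) q(U_ef)
        prod q(sigma^2 factors)

and each factor update below is the exact conditional-conjugate solution,
so the evidence lower bound (ELBO) is non-decreasing across sweeps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma, expit, gammaln

from .kernels import FamilialKernels, RegionKernel

__all__ = [
    "Hyperparameters",
    "VariationalState",
    "FitResult",
    "initialize_state",
    "cavi_sweep",
    "compute_elbo",
    "fit",
    "save_fit",
    "load_fit",
]

_CLIP = 1e-12
_RATE_FLOOR = 1e-12


@dataclass(frozen=True)
class Hyperparameters:
    """Prior settings.

    theta0      prior variant-inclusion probability for gamma_j
    sigma_beta2 fixed slab variance of the fixed effects
    p_region    prior region-inclusion probability for r_m
    (a1, b1)    inverse-gamma prior for each region variance sigma_m^2
    (a_gf0, b_gf0), (a_ef0, b_ef0), (a_eps0, b_eps0)
                inverse-gamma priors for the kinship, shared-environment
                and residual variances
    """

    theta0: float = 0.1
    sigma_beta2: float = 1.0
    p_region: float = 0.1
    a1: float = 0.1
    b1: float = 0.1
    a_gf0: float = 0.1
    b_gf0: float = 0.1
    a_ef0: float = 0.1
    b_ef0: float = 0.1
    a_eps0: float = 0.1
    b_eps0: float = 0.1
    beta_block_cap: int = 5000

    def __post_init__(self) -> None:
        for name in ("theta0", "p_region"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("sigma_beta2", "a1", "b1", "a_gf0", "b_gf0",
                     "a_ef0", "b_ef0", "a_eps0", "b_eps0"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GaussianFactor:
    """Diagonal-covariance Gaussian factor q(U) = N(mean, diag(var))."""

    mean: np.ndarray
    var: np.ndarray

    @property
    def second_moment_sum(self) -> float:
        return float(self.mean @ self.mean + self.var.sum())


@dataclass
class IGFactor:
    shape: float
    rate: float

    @property
    def mean_inv(self) -> float:
        return self.shape / self.rate

    @property
    def mean_log(self) -> float:
        return float(np.log(self.rate) - digamma(self.shape))


@dataclass
class VariationalState:
    """All q-distribution parameters plus the ELBO trace."""

    M_beta: np.ndarray
    S_beta: np.ndarray
    psi: np.ndarray
    regions: list[GaussianFactor]
    phi: np.ndarray
    region_ig: list[IGFactor]
    gf: Optional[GaussianFactor]
    gf_ig: Optional[IGFactor]
    ef: Optional[GaussianFactor]
    ef_ig: Optional[IGFactor]
    eps_ig: IGFactor = field(default_factory=lambda: IGFactor(0.1, 0.1))
    elbo_trace: list[float] = field(default_factory=list)

    def copy(self) -> "VariationalState":
        return VariationalState(
            M_beta=self.M_beta.copy(),
            S_beta=self.S_beta.copy(),
            psi=self.psi.copy(),
            regions=[GaussianFactor(g.mean.copy(), g.var.copy()) for g in self.regions],
            phi=self.phi.copy(),
            region_ig=[IGFactor(f.shape, f.rate) for f in self.region_ig],
            gf=GaussianFactor(self.gf.mean.copy(), self.gf.var.copy()) if self.gf else None,
            gf_ig=IGFactor(self.gf_ig.shape, self.gf_ig.rate) if self.gf_ig else None,
            ef=GaussianFactor(self.ef.mean.copy(), self.ef.var.copy()) if self.ef else None,
            ef_ig=IGFactor(self.ef_ig.shape, self.ef_ig.rate) if self.ef_ig else None,
            eps_ig=IGFactor(self.eps_ig.shape, self.eps_ig.rate),
            elbo_trace=list(self.elbo_trace),
        )


@dataclass
class ModelData:
    """Assembled training inputs: centred outcome, fixed-effect matrix and
    all eigen-designs with their diagonal Gram matrices."""

    Y: np.ndarray
    X: np.ndarray  # n x p, may have p = 0
    Z_regions: list[np.ndarray]
    lam_regions: list[np.ndarray]
    Z_gf: Optional[np.ndarray]
    lam_gf: Optional[np.ndarray]
    Z_ef: Optional[np.ndarray]
    lam_ef: Optional[np.ndarray]

    def __post_init__(self) -> None:
        self.XtX = self.X.T @ self.X if self.X.shape[1] else np.zeros((0, 0))

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def assemble_data(
    Y: np.ndarray,
    X: Optional[np.ndarray],
    region_kernels: Sequence[RegionKernel],
    familial: Optional[FamilialKernels],
) -> ModelData:
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    X = np.zeros((n, 0)) if X is None else np.asarray(X, dtype=float)
    Zs = [rk.Z for rk in region_kernels]
    lams = [rk.eigenvalues for rk in region_kernels]
    if familial is not None:
        return ModelData(Y, X, Zs, lams, familial.Z_gf, familial.lam_gf,
                         familial.Z_ef, familial.lam_ef)
    return ModelData(Y, X, Zs, lams, None, None, None, None)


def initialize_state(
    data: ModelData, hyper: Hyperparameters, seed: int = 0, gf_shrink: float = 1.0
) -> VariationalState:
    """Deterministic initial state: inclusion probabilities at their prior
    means, zero posterior means, prior-variance covariances, inverse-gamma
    factors at the prior with the residual rate seeded from the phenotype
    variance (method of moments).

    The seed is recorded for reproducibility bookkeeping; initialization
    itself is deterministic so identical seeds trivially give identical
    states.  ``gf_shrink`` > 1 starts the kinship variance factor at a
    higher precision (same prior mean of the shape/rate ratio scaled), the
    second start used by :func:`fit` to escape the local optimum where the
    kinship surrogate swallows shared-environment variance.
    """
    del seed  # initialization is deterministic
    p = data.p
    var_y = float(np.var(data.Y)) if data.n > 1 else 1.0
    var_y = max(var_y, 1e-8)
    regions = [
        GaussianFactor(np.zeros(lam.shape[0]), np.full(lam.shape[0], hyper.b1 / hyper.a1))
        for lam in data.lam_regions
    ]
    region_ig = [IGFactor(hyper.a1, hyper.b1) for _ in data.lam_regions]
    gf = ef = None
    gf_ig = ef_ig = None
    if data.Z_gf is not None:
        k = data.lam_gf.shape[0]
        gf = GaussianFactor(np.zeros(k), np.full(k, hyper.b_gf0 / hyper.a_gf0))
        gf_ig = IGFactor(hyper.a_gf0 * gf_shrink, hyper.b_gf0)
        k = data.lam_ef.shape[0]
        ef = GaussianFactor(np.zeros(k), np.full(k, hyper.b_ef0 / hyper.a_ef0))
        ef_ig = IGFactor(hyper.a_ef0, hyper.b_ef0)
    # moment-matched residual factor: E[sigma_eps^2] ~= var(Y)
    a_eps = hyper.a_eps0 + 1.0
    return VariationalState(
        M_beta=np.zeros(p),
        S_beta=np.eye(p) * hyper.sigma_beta2,
        psi=np.full(p, hyper.theta0),
        regions=regions,
        phi=np.full(len(data.lam_regions), hyper.p_region),
        region_ig=region_ig,
        gf=gf,
        gf_ig=gf_ig,
        ef=ef,
        ef_ig=ef_ig,
        eps_ig=IGFactor(a_eps, var_y * a_eps),
    )


def _component_means(state: VariationalState, data: ModelData) -> dict[str, np.ndarray]:
    n = data.n
    c = {}
    c["beta"] = data.X @ (state.psi * state.M_beta) if data.p else np.zeros(n)
    for m, Z in enumerate(data.Z_regions):
        c[f"region{m}"] = state.phi[m] * (Z @ state.regions[m].mean)
    c["gf"] = data.Z_gf @ state.gf.mean if state.gf is not None else np.zeros(n)
    c["ef"] = data.Z_ef @ state.ef.mean if state.ef is not None else np.zeros(n)
    return c


def fitted_mean(state: VariationalState, data: ModelData) -> np.ndarray:
    """Posterior-mean fitted values (sum of all expected components)."""
    comps = _component_means(state, data)
    return sum(comps.values())


def _check_finite(arr: np.ndarray, factor: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"non-finite values while updating {factor}")


def _expected_rss(state: VariationalState, data: ModelData) -> float:
    """E_q || Y - X G b - sum r_m Z_m U_m - Z_gf U_gf - Z_ef U_ef ||^2."""
    resid = data.Y - fitted_mean(state, data)
    total = float(resid @ resid)
    if data.p:
        psi, M = state.psi, state.M_beta
        B = state.S_beta + np.outer(M, M)
        DAD = data.XtX * np.outer(psi, psi)
        total += float(np.sum(DAD * state.S_beta))
        total += float(np.sum(psi * (1 - psi) * np.diag(data.XtX) * np.diag(B)))
    for m, lam in enumerate(data.lam_regions):
        g, ph = state.regions[m], float(state.phi[m])
        total += ph * float(lam @ g.var)
        total += ph * (1 - ph) * float(lam @ (g.mean**2))
    if state.gf is not None:
        total += float(data.lam_gf @ state.gf.var)
    if state.ef is not None:
        total += float(data.lam_ef @ state.ef.var)
    return total


def cavi_sweep(
    state: VariationalState, data: ModelData, hyper: Hyperparameters
) -> VariationalState:
    """One full coordinate-ascent pass over every variational factor.

    Order: q(b), each q(gamma_j), each (q(U_m), q(r_m)) pair in region
    order, q(U_gf), q(U_ef), then all inverse-gamma variance factors.
    Each update is the exact conditional-conjugate solution, so the ELBO
    cannot decrease.
    """
    state = state.copy()
    w_eps = state.eps_ig.mean_inv
    comps = _component_means(state, data)
    resid = data.Y - sum(comps.values())

    if data.p:
        _update_beta_gamma(state, data, hyper, w_eps, comps, resid)

    for m in range(len(data.Z_regions)):
        _update_region(state, data, hyper, w_eps, comps, resid, m)

    if state.gf is not None:
        _update_plain_gaussian(state, data, w_eps, comps, resid, which="gf")
    if state.ef is not None:
        _update_plain_gaussian(state, data, w_eps, comps, resid, which="ef")

    _update_variances(state, data, hyper)
    return state


def _update_beta_gamma(state, data, hyper, w_eps, comps, resid) -> None:
    p = data.p
    psi = state.psi
    A = data.XtX
    r_beta = resid + comps["beta"]  # residual excluding the fixed-effect block
    cap = hyper.beta_block_cap
    if p > cap:
        warnings.warn(
            f"p = {p} exceeds the joint-Gaussian cap ({cap}); updating the "
            "fixed-effect factor blockwise",
            RuntimeWarning,
        )
        blocks = [np.arange(i, min(i + cap, p)) for i in range(0, p, cap)]
    else:
        blocks = [np.arange(p)]

    for idx in blocks:
        sub_contrib = data.X[:, idx] @ (psi[idx] * state.M_beta[idx])
        r_blk = (resid + comps["beta"]) if len(blocks) == 1 else None
        if r_blk is None:
            # residual excluding only this block
            r_blk = data.Y - fitted_mean(state, data) + sub_contrib
        A_blk = A[np.ix_(idx, idx)]
        P = A_blk * np.outer(psi[idx], psi[idx])
        np.fill_diagonal(P, psi[idx] * np.diag(A_blk))
        prec = w_eps * P + np.eye(len(idx)) / hyper.sigma_beta2
        S = np.linalg.inv(prec)
        S = (S + S.T) / 2.0
        M = S @ (w_eps * psi[idx] * (data.X[:, idx].T @ r_blk))
        _check_finite(M, "q(beta)")
        if len(blocks) == 1:
            state.S_beta = S
            state.M_beta = M
        else:
            state.S_beta[np.ix_(idx, idx)] = S
            state.M_beta[idx] = M
    comps["beta"] = data.X @ (psi * state.M_beta)
    resid[:] = data.Y - sum(comps.values())
    r_beta = resid + comps["beta"]

    # gamma_j updates, sequential because inclusion of one variant shifts
    # the residual seen by the others
    M, S = state.M_beta, state.S_beta
    B = S + np.outer(M, M)
    logit_prior = np.log(hyper.theta0) - np.log1p(-hyper.theta0)
    XtR = data.X.T @ r_beta  # residual excluding the whole beta block
    for j in range(p):
        cross = float((A[j] * B[j]) @ psi) - psi[j] * A[j, j] * B[j, j]
        delta = w_eps * (M[j] * XtR[j] - 0.5 * A[j, j] * B[j, j] - cross)
        psi[j] = float(expit(logit_prior + delta))
    _check_finite(psi, "q(gamma)")
    comps["beta"] = data.X @ (psi * M)
    resid[:] = data.Y - sum(comps.values())


def _update_region(state, data, hyper, w_eps, comps, resid, m: int) -> None:
    Z, lam = data.Z_regions[m], data.lam_regions[m]
    g = state.regions[m]
    ph = float(state.phi[m])
    w_m = state.region_ig[m].mean_inv
    r_m = resid + comps[f"region{m}"]  # residual excluding region m
    ZtR = Z.T @ r_m
    var = 1.0 / (w_eps * ph * lam + w_m)
    mean = var * (w_eps * ph * ZtR)
    _check_finite(mean, f"q(U_{m})")
    g.mean, g.var = mean, var
    # region inclusion: prior log-odds plus the expected likelihood gain
    quad = float(lam @ (mean**2 + var))
    delta = w_eps * (float(mean @ ZtR) - 0.5 * quad)
    logit_prior = np.log(hyper.p_region) - np.log1p(-hyper.p_region)
    state.phi[m] = float(expit(logit_prior + delta))
    comps[f"region{m}"] = state.phi[m] * (Z @ mean)
    resid[:] = data.Y - sum(comps.values())


def _update_plain_gaussian(state, data, w_eps, comps, resid, which: str) -> None:
    if which == "gf":
        Z, lam, g, ig = data.Z_gf, data.lam_gf, state.gf, state.gf_ig
    else:
        Z, lam, g, ig = data.Z_ef, data.lam_ef, state.ef, state.ef_ig
    r_c = resid + comps[which]
    var = 1.0 / (w_eps * lam + ig.mean_inv)
    mean = var * (w_eps * (Z.T @ r_c))
    _check_finite(mean, f"q(U_{which})")
    g.mean, g.var = mean, var
    comps[which] = Z @ mean
    resid[:] = data.Y - sum(comps.values())


def _update_variances(state, data, hyper) -> None:
    for m, lam in enumerate(data.lam_regions):
        k = lam.shape[0]
        g = state.regions[m]
        state.region_ig[m] = IGFactor(
            hyper.a1 + 0.5 * k,
            max(hyper.b1 + 0.5 * g.second_moment_sum, _RATE_FLOOR),
        )
    if state.gf is not None:
        k = data.lam_gf.shape[0]
        state.gf_ig = IGFactor(
            hyper.a_gf0 + 0.5 * k,
            max(hyper.b_gf0 + 0.5 * state.gf.second_moment_sum, _RATE_FLOOR),
        )
    if state.ef is not None:
        k = data.lam_ef.shape[0]
        state.ef_ig = IGFactor(
            hyper.a_ef0 + 0.5 * k,
            max(hyper.b_ef0 + 0.5 * state.ef.second_moment_sum, _RATE_FLOOR),
        )
    rss = _expected_rss(state, data)
    state.eps_ig = IGFactor(
        hyper.a_eps0 + 0.5 * data.n,
        max(hyper.b_eps0 + 0.5 * rss, _RATE_FLOOR),
    )


def _bernoulli_terms(prob: np.ndarray, prior: float) -> tuple[float, float]:
    """(expected log prior, entropy) of independent Bernoulli factors."""
    p = np.clip(np.atleast_1d(prob), _CLIP, 1.0 - _CLIP)
    eplog = float(np.sum(p * np.log(prior) + (1 - p) * np.log1p(-prior)))
    ent = float(-np.sum(p * np.log(p) + (1 - p) * np.log1p(-p)))
    return eplog, ent


def _ig_cross_entropy(a0: float, b0: float, q: IGFactor) -> float:
    """E_q[log IG(x; a0, b0)] for q = IG(shape, rate)."""
    return float(
        a0 * np.log(b0) - gammaln(a0) - (a0 + 1.0) * q.mean_log - b0 * q.mean_inv
    )


def _ig_entropy(q: IGFactor) -> float:
    a, b = q.shape, q.rate
    return float(a + np.log(b) + gammaln(a) - (1.0 + a) * digamma(a))


def _gauss_prior_and_entropy(
    g: GaussianFactor, ig: IGFactor, log_s: Optional[float] = None
) -> float:
    """E[log N(U; 0, I sigma^2)] + H[q(U)] for a diagonal Gaussian factor
    whose prior variance has variational factor `ig` (or is fixed at
    exp(log_s))."""
    k = g.mean.shape[0]
    if k == 0:
        return 0.0
    if ig is not None:
        elog, winv = ig.mean_log, ig.mean_inv
    else:
        elog, winv = log_s, np.exp(-log_s)
    eplog = -0.5 * k * np.log(2 * np.pi) - 0.5 * k * elog - 0.5 * winv * g.second_moment_sum
    ent = 0.5 * (k * np.log(2 * np.pi * np.e) + float(np.sum(np.log(g.var))))
    return float(eplog + ent)


def compute_elbo(
    state: VariationalState, data: ModelData, hyper: Hyperparameters
) -> float:
    """Evidence lower bound E_q[log p(Y, xi)] - E_q[log q(xi)]."""
    n = data.n
    w_eps = state.eps_ig.mean_inv
    rss = _expected_rss(state, data)
    elbo = -0.5 * n * np.log(2 * np.pi) - 0.5 * n * state.eps_ig.mean_log - 0.5 * w_eps * rss

    if data.p:
        p = data.p
        B_tr = float(state.M_beta @ state.M_beta + np.trace(state.S_beta))
        elbo += -0.5 * p * np.log(2 * np.pi * hyper.sigma_beta2) - 0.5 * B_tr / hyper.sigma_beta2
        sign, logdet = np.linalg.slogdet(state.S_beta)
        if sign <= 0:
            raise FloatingPointError("S_beta not positive definite in ELBO")
        elbo += 0.5 * (p * np.log(2 * np.pi * np.e) + logdet)
        eplog, ent = _bernoulli_terms(state.psi, hyper.theta0)
        elbo += eplog + ent

    for m in range(len(data.Z_regions)):
        elbo += _gauss_prior_and_entropy(state.regions[m], state.region_ig[m])
        eplog, ent = _bernoulli_terms(state.phi[m : m + 1], hyper.p_region)
        elbo += eplog + ent
        elbo += _ig_cross_entropy(hyper.a1, hyper.b1, state.region_ig[m])
        elbo += _ig_entropy(state.region_ig[m])

    if state.gf is not None:
        elbo += _gauss_prior_and_entropy(state.gf, state.gf_ig)
        elbo += _ig_cross_entropy(hyper.a_gf0, hyper.b_gf0, state.gf_ig)
        elbo += _ig_entropy(state.gf_ig)
    if state.ef is not None:
        elbo += _gauss_prior_and_entropy(state.ef, state.ef_ig)
        elbo += _ig_cross_entropy(hyper.a_ef0, hyper.b_ef0, state.ef_ig)
        elbo += _ig_entropy(state.ef_ig)

    elbo += _ig_cross_entropy(hyper.a_eps0, hyper.b_eps0, state.eps_ig)
    elbo += _ig_entropy(state.eps_ig)

    if not np.isfinite(elbo):
        raise FloatingPointError("non-finite ELBO")
    return float(elbo)


@dataclass
class FitResult:
    """Converged variational state plus everything prediction needs."""

    state: VariationalState
    hyper: Hyperparameters
    y_mean: float
    y_var: float
    sample_ids: list[str]
    x_variant_ids: list[str]
    x_means: np.ndarray
    region_kernels: list[RegionKernel]
    familial: Optional[FamilialKernels]
    n_sweeps: int
    final_elbo: float
    stop_reason: str
    metadata: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.stop_reason == "elbo_converged"

    def variance_fractions(self) -> dict[str, float]:
        """Posterior-mean variance components as fractions of their total.

        E[sigma^2] of an IG(a, b) factor is b / (a - 1) for a > 1.
        """
        def ig_mean(f: IGFactor) -> float:
            return f.rate / (f.shape - 1.0) if f.shape > 1.0 else f.rate / f.shape

        parts: dict[str, float] = {}
        for m, f in enumerate(self.state.region_ig):
            parts[f"region:{self.region_kernels[m].name}"] = ig_mean(f)
        if self.state.gf_ig is not None:
            parts["kinship"] = ig_mean(self.state.gf_ig)
        if self.state.ef_ig is not None:
            parts["environment"] = ig_mean(self.state.ef_ig)
        parts["residual"] = ig_mean(self.state.eps_ig)
        total = sum(parts.values())
        return {k: v / total for k, v in parts.items()}

    def component_variance_fractions(self, X: Optional[np.ndarray] = None) -> dict[str, float]:
        """Sample variance of each fitted component divided by var(Y).

        Unlike :meth:`variance_fractions` this is on the phenotype scale
        regardless of kernel scaling.  The training X must be supplied when
        the model has fixed effects.
        """
        out: dict[str, float] = {}
        vy = max(self.y_var, 1e-12)
        if self.x_variant_ids:
            if X is None:
                raise ValueError("model has fixed effects: pass the training X")
            contrib = (np.asarray(X, float) - self.x_means) @ (
                self.state.psi * self.state.M_beta
            )
            out["fixed"] = float(np.var(contrib)) / vy
        for m, rk in enumerate(self.region_kernels):
            contrib = float(self.state.phi[m]) * (rk.Z @ self.state.regions[m].mean)
            out[f"region:{rk.name}"] = float(np.var(contrib)) / vy
        if self.familial is not None:
            out["kinship"] = float(np.var(self.familial.Z_gf @ self.state.gf.mean)) / vy
            out["environment"] = float(np.var(self.familial.Z_ef @ self.state.ef.mean)) / vy
        return out


def fit(
    Y: np.ndarray,
    X: Optional[np.ndarray],
    region_kernels: Sequence[RegionKernel],
    familial: Optional[FamilialKernels],
    hyper: Hyperparameters = Hyperparameters(),
    max_sweeps: int = 1000,
    rel_tol: float = 1e-5,
    seed: int = 0,
    sample_ids: Optional[Sequence[str]] = None,
    x_variant_ids: Optional[Sequence[str]] = None,
    track_elbo: bool = True,
    n_starts: int = 2,
) -> FitResult:
    """Fit the model by CAVI until the relative ELBO change drops below
    ``rel_tol`` or ``max_sweeps`` is reached.

    Y is centred internally (training mean restored at prediction); X
    columns are centred at their training means, which are stored in the
    result.  The whole procedure is deterministic given its inputs.

    When familial kernels are present and ``n_starts`` >= 2, coordinate
    ascent is run both from the default initialization and from one with
    the kinship variance factor started at high precision, and the run
    with the higher final ELBO is kept: the kinship and shared-environment
    surrogates overlap (both induce within-family covariance), and the
    default start can settle in a lower-ELBO optimum where the kinship
    term swallows shared-environment variance.
    """
    Y = np.asarray(Y, dtype=float)
    y_mean = float(Y.mean())
    Yc = Y - y_mean
    x_means = np.zeros(0)
    Xc = None
    if X is not None and X.shape[1] > 0:
        X = np.asarray(X, dtype=float)
        x_means = X.mean(axis=0)
        Xc = X - x_means
    data = assemble_data(Yc, Xc, region_kernels, familial)

    def run_start(gf_shrink: float):
        state = initialize_state(data, hyper, seed=seed, gf_shrink=gf_shrink)
        elbo_prev = -np.inf
        stop_reason = "max_sweeps"
        sweeps = 0
        for sweeps in range(1, max_sweeps + 1):
            state = cavi_sweep(state, data, hyper)
            elbo = compute_elbo(state, data, hyper)
            if track_elbo:
                state.elbo_trace.append(elbo)
            if np.isfinite(elbo_prev) and abs(elbo - elbo_prev) <= rel_tol * abs(elbo):
                stop_reason = "elbo_converged"
                elbo_prev = elbo
                break
            elbo_prev = elbo
        else:
            warnings.warn(
                f"ELBO not converged after {max_sweeps} sweeps", RuntimeWarning
            )
        return state, sweeps, float(elbo_prev), stop_reason

    shrinks = [1.0]
    if familial is not None and n_starts >= 2:
        shrinks.append(100.0)
    runs = [run_start(s) for s in shrinks]
    state, sweeps, elbo_prev, stop_reason = max(runs, key=lambda r: r[2])

    n = data.n
    return FitResult(
        state=state,
        hyper=hyper,
        y_mean=y_mean,
        y_var=float(Y.var()),
        sample_ids=list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)],
        x_variant_ids=list(x_variant_ids) if x_variant_ids is not None else [],
        x_means=x_means,
        region_kernels=list(region_kernels),
        familial=familial,
        n_sweeps=sweeps,
        final_elbo=float(elbo_prev),
        stop_reason=stop_reason,
        metadata={"seed": seed, "rel_tol": rel_tol, "max_sweeps": max_sweeps},
    )


# ---------------------------------------------------------------------------
# fit archive (npz with a JSON metadata entry)

_ARCHIVE_VERSION = 1


def save_fit(result: FitResult, path: str | Path) -> None:
    """Serialise a FitResult to a single .npz archive."""
    arrays: dict[str, np.ndarray] = {
        "M_beta": result.state.M_beta,
        "S_beta": result.state.S_beta,
        "psi": result.state.psi,
        "phi": result.state.phi,
        "x_means": result.x_means,
        "elbo_trace": np.asarray(result.state.elbo_trace),
    }
    for m, g in enumerate(result.state.regions):
        arrays[f"region{m}_mean"] = g.mean
        arrays[f"region{m}_var"] = g.var
    for m, rk in enumerate(result.region_kernels):
        arrays[f"kernel{m}_Q"] = rk.Q
        arrays[f"kernel{m}_lam"] = rk.eigenvalues
        arrays[f"kernel{m}_w"] = rk.weights
        arrays[f"kernel{m}_means"] = rk.column_means
        arrays[f"kernel{m}_A"] = rk.A
    if result.state.gf is not None:
        arrays["gf_mean"] = result.state.gf.mean
        arrays["gf_var"] = result.state.gf.var
        arrays["ef_mean"] = result.state.ef.mean
        arrays["ef_var"] = result.state.ef.var
        fam = result.familial
        arrays["K_gf"] = fam.K_gf
        arrays["Q_gf"] = fam.Q_gf
        arrays["lam_gf"] = fam.lam_gf
        arrays["Z_ef"] = fam.Z_ef
        arrays["lam_ef"] = fam.lam_ef
    ig_rows = [[f.shape, f.rate] for f in result.state.region_ig]
    arrays["region_ig"] = np.asarray(ig_rows).reshape(-1, 2)
    arrays["scalar_ig"] = np.asarray(
        [
            [result.state.gf_ig.shape, result.state.gf_ig.rate] if result.state.gf_ig else [np.nan, np.nan],
            [result.state.ef_ig.shape, result.state.ef_ig.rate] if result.state.ef_ig else [np.nan, np.nan],
            [result.state.eps_ig.shape, result.state.eps_ig.rate],
        ]
    )
    meta = {
        "version": _ARCHIVE_VERSION,
        "hyper": {k: getattr(result.hyper, k) for k in (
            "theta0", "sigma_beta2", "p_region", "a1", "b1", "a_gf0", "b_gf0",
            "a_ef0", "b_ef0", "a_eps0", "b_eps0", "beta_block_cap")},
        "y_mean": result.y_mean,
        "y_var": result.y_var,
        "sample_ids": result.sample_ids,
        "x_variant_ids": result.x_variant_ids,
        "region_names": [rk.name for rk in result.region_kernels],
        "region_variants": [rk.variant_ids for rk in result.region_kernels],
        "region_pm": [rk.p_m for rk in result.region_kernels],
        "region_centered": [rk.centered for rk in result.region_kernels],
        "has_familial": result.familial is not None,
        "familial_ids": result.familial.sample_ids if result.familial else [],
        "kinship_scale": result.familial.kinship_scale if result.familial else None,
        "n_sweeps": result.n_sweeps,
        "final_elbo": result.final_elbo,
        "stop_reason": result.stop_reason,
        "metadata": result.metadata,
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_fit(path: str | Path) -> FitResult:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != _ARCHIVE_VERSION:
            raise ValueError(f"unsupported fit archive version {meta['version']}")
        hyper = Hyperparameters(**meta["hyper"])
        regions = []
        kernels = []
        for m, name in enumerate(meta["region_names"]):
            regions.append(GaussianFactor(z[f"region{m}_mean"], z[f"region{m}_var"]))
            Q = z[f"kernel{m}_Q"]
            lam = z[f"kernel{m}_lam"]
            kernels.append(
                RegionKernel(
                    name=name,
                    K=(Q * lam) @ Q.T,
                    Q=Q,
                    eigenvalues=lam,
                    weights=z[f"kernel{m}_w"],
                    p_m=meta["region_pm"][m],
                    variant_ids=meta["region_variants"][m],
                    column_means=z[f"kernel{m}_means"],
                    centered=meta["region_centered"][m],
                    A=z[f"kernel{m}_A"],
                )
            )
        region_ig = [IGFactor(a, b) for a, b in z["region_ig"]]
        sc = z["scalar_ig"]
        gf = ef = None
        gf_ig = ef_ig = None
        familial = None
        if meta["has_familial"]:
            gf = GaussianFactor(z["gf_mean"], z["gf_var"])
            ef = GaussianFactor(z["ef_mean"], z["ef_var"])
            gf_ig = IGFactor(*sc[0])
            ef_ig = IGFactor(*sc[1])
            K_gf = z["K_gf"]
            Z_ef = z["Z_ef"]
            familial = FamilialKernels(
                sample_ids=meta["familial_ids"],
                K_gf=K_gf,
                Q_gf=z["Q_gf"],
                lam_gf=z["lam_gf"],
                K_ef=(Z_ef @ Z_ef.T),
                Z_ef=Z_ef,
                lam_ef=z["lam_ef"],
                kinship_scale=meta["kinship_scale"],
            )
        state = VariationalState(
            M_beta=z["M_beta"],
            S_beta=z["S_beta"],
            psi=z["psi"],
            regions=regions,
            phi=z["phi"],
            region_ig=region_ig,
            gf=gf,
            gf_ig=gf_ig,
            ef=ef,
            ef_ig=ef_ig,
            eps_ig=IGFactor(*sc[2]),
            elbo_trace=list(z["elbo_trace"]),
        )
        return FitResult(
            state=state,
            hyper=hyper,
            y_mean=meta["y_mean"],
            y_var=meta.get("y_var", 1.0),
            sample_ids=meta["sample_ids"],
            x_variant_ids=meta["x_variant_ids"],
            x_means=z["x_means"],
            region_kernels=kernels,
            familial=familial,
            n_sweeps=meta["n_sweeps"],
            final_elbo=meta["final_elbo"],
            stop_reason=meta["stop_reason"],
            metadata=meta["metadata"],
        )
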