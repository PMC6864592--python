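"""Constrained psychometric-function fitting.

Cumulative-Gaussian psychometric functions are fitted jointly to the five
experimental conditions (A, V, AV congruent, AV +conflict, AV -conflict)
by maximizing a binomial or betabinomial likelihood with a Nelder-Mead
simplex search.  The joint fit shares one lapse rate (and one
overdispersion scale, when the betabinomial likelihood is used) across
all conditions and, in the primary variant, one slope across the three
audiovisual conditions.

Slopes map to sensory noise through the 2IFC relation
``sigma**2 = 0.5 * (1 / beta)**2`` (both standard and probe are noisy,
so the discrimination JND equals ``sqrt(2) * sigma``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, expit, logit, ndtr, ndtri, xlogy

from cuecombine._optim import nelder_mead_batch

CONDITIONS = ("A", "V", "AV0", "AVp", "AVm")
AV_CONDITIONS = ("AV0", "AVp", "AVm")

# optimization box for the shared nuisance parameters (the exclusion rule
# already rejects lapse rates above .06, so a .1 cap loses nothing)
LAM_MAX = 0.1
ETA_LO = 1e-4
ETA_HI = 0.999

_RESTART_ALPHA_SHIFTS = (0.0, -1.0, 1.0)
_RESTART_BETA_SCALES = (1.0, 0.5, 2.0, 1.5)


class DegenerateDataError(ValueError):
    """A condition contains no information about the psychometric slope."""


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of one psychometric function.

    ``alpha`` is the point of subjective equality (deg), ``beta`` the
    slope (1/deg), ``lam`` the lapse rate and ``eta`` the overdispersion
    scale of the betabinomial response model.
    """

    alpha: float
    beta: float
    lam: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not 0.0 <= self.lam <= 0.5:
            raise ValueError(f"lam must lie in [0, 0.5], got {self.lam}")
        if not 0.0 <= self.eta < 1.0:
            raise ValueError(f"eta must lie in [0, 1), got {self.eta}")

    @property
    def jnd(self) -> float:
        return 1.0 / self.beta

    @property
    def sigma(self) -> float:
        return self.jnd / np.sqrt(2.0)


@dataclass
class ConditionCounts:
    """Per-location response tallies for one condition."""

    condition: str
    x: np.ndarray
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.k = np.asarray(self.k, dtype=int)
        if not (self.x.shape == self.n.shape == self.k.shape):
            raise ValueError("x, n, k must have identical shapes")
        if len(np.unique(self.x)) != len(self.x):
            raise ValueError("probe locations must be unique")
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("counts must satisfy 0 <= k <= n")

    @property
    def fraction(self) -> np.ndarray:
        return self.k / np.maximum(self.n, 1)


def psi(x, params: PsychometricParams) -> np.ndarray | float:
    """Lapse-compressed cumulative-Gaussian response probability."""
    return _psi(np.asarray(x, dtype=float), params.alpha, params.beta, params.lam)


def _psi(x, alpha, beta, lam):
    return lam + (1.0 - 2.0 * lam) * ndtr(beta * (x - alpha))


def loglik_binomial(counts: ConditionCounts, params: PsychometricParams) -> float:
    """Binomial log-likelihood (combinatorial constant omitted)."""
    p = psi(counts.x, params)
    return _binom_ll(counts.k, counts.n, p)


def _binom_ll(k, n, p):
    bad = ((p <= 0.0) & (k > 0)) | ((p >= 1.0) & (k < n))
    if np.any(bad):
        return -np.inf
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    return float(np.sum(xlogy(k, p) + xlogy(n - k, 1.0 - p)))


def loglik_betabinomial(counts: ConditionCounts, params: PsychometricParams) -> float:
    """Betabinomial log-likelihood with overdispersion scale ``eta``.

    Uses ``eta_prime = 1 / eta**2 - 1`` so that each cell's response
    probability is beta-distributed with mean ``psi`` and variance
    ``eta**2 * psi * (1 - psi)``.  ``eta = 0`` dispatches to the binomial
    likelihood (the exact limit).
    """
    if params.eta == 0.0:
        return loglik_binomial(counts, params)
    if params.eta >= 1.0:
        raise ValueError("eta must be < 1 (eta' = 1/eta^2 - 1 degenerates)")
    p = np.asarray(psi(counts.x, params), dtype=float)
    return float(np.sum(_betabinom_ll_terms(counts.k, counts.n, p, params.eta)))


def _betabinom_ll_terms(k, n, p, eta):
    eta_prime = 1.0 / eta**2 - 1.0
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    a = eta_prime * p
    b = eta_prime * (1.0 - p)
    return betaln(k + a, n - k + b) - betaln(a, b)


# ---------------------------------------------------------------------------
# joint constrained fit
# ---------------------------------------------------------------------------


@dataclass
class _JointData:
    """Stacked cell-level data plus the slope-sharing map."""

    x: np.ndarray
    n: np.ndarray
    k: np.ndarray
    cond_idx: np.ndarray
    slope_of_cond: np.ndarray  # condition index -> free-slope index
    n_slopes: int

    @property
    def slope_cell(self) -> np.ndarray:
        return self.slope_of_cond[self.cond_idx]


def _stack(all_counts: Sequence[ConditionCounts], shared_av_slope: bool) -> _JointData:
    by_label = {c.condition: c for c in all_counts}
    missing = [c for c in CONDITIONS if c not in by_label]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    xs, ns, ks, idx = [], [], [], []
    for i, label in enumerate(CONDITIONS):
        c = by_label[label]
        if np.all(c.k == 0) or np.all(c.k == c.n):
            raise DegenerateDataError(
                f"condition {label!r} has all-identical responses"
            )
        xs.append(c.x)
        ns.append(c.n)
        ks.append(c.k)
        idx.append(np.full(len(c.x), i))
    if shared_av_slope:
        slope_of_cond = np.array([0, 1, 2, 2, 2])
        n_slopes = 3
    else:
        slope_of_cond = np.arange(5)
        n_slopes = 5
    return _JointData(
        x=np.concatenate(xs),
        n=np.concatenate(ns),
        k=np.concatenate(ks),
        cond_idx=np.concatenate(idx),
        slope_of_cond=slope_of_cond,
        n_slopes=n_slopes,
    )


def _theta_size(data: _JointData, betabinomial: bool) -> int:
    return 5 + data.n_slopes + 1 + (1 if betabinomial else 0)


def _pack(alphas, betas_free, lam, eta, betabinomial):
    parts = [np.asarray(alphas, dtype=float), np.log(betas_free)]
    parts.append([logit(np.clip(lam / LAM_MAX, 1e-6, 1 - 1e-6))])
    if betabinomial:
        u = (eta - ETA_LO) / (ETA_HI - ETA_LO)
        parts.append([logit(np.clip(u, 1e-9, 1 - 1e-9))])
    return np.concatenate(parts)


def _unpack_batch(theta, data: _JointData, betabinomial: bool):
    """theta: (..., d) -> alphas (...,5), betas (...,n_slopes), lam, eta."""
    theta = np.atleast_2d(theta)
    alphas = theta[:, :5]
    betas = np.exp(theta[:, 5 : 5 + data.n_slopes])
    lam = LAM_MAX * expit(theta[:, 5 + data.n_slopes])
    if betabinomial:
        eta = ETA_LO + (ETA_HI - ETA_LO) * expit(theta[:, 6 + data.n_slopes])
    else:
        eta = np.zeros(theta.shape[0])
    return alphas, betas, lam, eta


def _joint_nll_batch(theta, data: _JointData, betabinomial: bool,
                     k=None) -> np.ndarray:
    """Negative joint log-likelihood for a (B, d) batch of parameters.

    ``k`` optionally overrides the observed counts with a (B, N) matrix of
    replicate counts (one row per batch member).
    """
    alphas, betas, lam, eta = _unpack_batch(theta, data, betabinomial)
    a_cell = alphas[:, data.cond_idx]
    b_cell = betas[:, data.slope_cell]
    p = lam[:, None] + (1.0 - 2.0 * lam[:, None]) * ndtr(
        b_cell * (data.x[None, :] - a_cell)
    )
    np.clip(p, 1e-12, 1.0 - 1e-12, out=p)
    kk = data.k[None, :] if k is None else k
    if betabinomial:
        n = data.n[None, :]
        eta_prime = 1.0 / eta**2 - 1.0
        a = eta_prime[:, None] * p
        b = eta_prime[:, None] * (1.0 - p)
        terms = betaln(kk + a, n - kk + b) - betaln(a, b)
        return -terms.sum(axis=1)
    lp = np.log(p)
    l1p = np.log1p(-p)
    if k is None:
        return -(lp @ data.k + l1p @ (data.n - data.k))
    return -(
        np.einsum("ij,ij->i", lp, kk)
        + np.einsum("ij,ij->i", l1p, data.n[None, :] - kk)
    )


@dataclass
class JointFitResult:
    """Result of the joint constrained psychometric fit."""

    alphas: dict[str, float]
    betas: dict[str, float]
    lam: float
    eta: float
    loglik: float
    converged: bool
    n_restarts_used: int
    shared_av_slope: bool
    likelihood: str
    condition_order: tuple[str, ...] = CONDITIONS
    restart_logliks: list[float] = field(default_factory=list)

    def params(self, condition: str) -> PsychometricParams:
        return PsychometricParams(
            alpha=self.alphas[condition],
            beta=self.betas[condition],
            lam=self.lam,
            eta=self.eta,
        )

    def sigma(self, condition: str) -> float:
        # JND = 1/beta and JND^2 = 2 sigma^2
        return (1.0 / self.betas[condition]) / np.sqrt(2.0)

    @property
    def sigma_A(self) -> float:
        return self.sigma("A")

    @property
    def sigma_V(self) -> float:
        return self.sigma("V")

    @property
    def sigma_AV(self) -> float:
        """Audiovisual sensory noise; the shared-slope estimate in the
        primary fit, the congruent-condition estimate otherwise."""
        return self.sigma("AV0")

    def to_dict(self) -> dict:
        return {
            "alphas": self.alphas,
            "betas": self.betas,
            "lam": self.lam,
            "eta": self.eta,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "shared_av_slope": self.shared_av_slope,
            "likelihood": self.likelihood,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointFitResult":
        return cls(
            alphas=dict(d["alphas"]),
            betas=dict(d["betas"]),
            lam=float(d["lam"]),
            eta=float(d["eta"]),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n_restarts_used=int(d["n_restarts_used"]),
            shared_av_slope=bool(d["shared_av_slope"]),
            likelihood=str(d["likelihood"]),
        )


def _probit_init(counts: ConditionCounts, lam_guess: float = 0.02):
    """Slope/PSE starting values from a probit-transformed line fit."""
    frac = (counts.k + 0.5) / (counts.n + 1.0)
    z = ndtri(np.clip((frac - lam_guess) / (1.0 - 2.0 * lam_guess), 1e-4, 1 - 1e-4))
    slope, intercept = np.polyfit(counts.x, z, 1)
    span = counts.x.max() - counts.x.min()
    if not np.isfinite(slope) or slope <= 1e-6:
        slope = 4.0 / max(span, 1e-6)
    alpha = np.clip(-intercept / slope, counts.x.min(), counts.x.max())
    return float(alpha), float(slope)


def fit_joint(
    all_counts: Sequence[ConditionCounts],
    *,
    shared_av_slope: bool = True,
    likelihood: str = "betabinomial",
    n_restarts: int = 12,
    xatol: float = 1e-8,
    fatol: float = 1e-8,
) -> JointFitResult:
    """Jointly fit five psychometric functions under shared constraints.

    The lapse rate (and overdispersion scale, for the betabinomial
    likelihood) is shared across all five conditions.  With
    ``shared_av_slope`` the three audiovisual conditions share one slope
    parameter; otherwise all five slopes are free.  A deterministic grid
    of Nelder-Mead restarts guards against local optima; the fit is
    flagged non-converged when the two best restarts disagree by more
    than 1e-3 log-likelihood units.
    """
    if likelihood not in ("binomial", "betabinomial"):
        raise ValueError(f"unknown likelihood {likelihood!r}")
    betabinomial = likelihood == "betabinomial"
    data = _stack(all_counts, shared_av_slope)
    by_label = {c.condition: c for c in all_counts}

    inits = {lab: _probit_init(by_label[lab]) for lab in CONDITIONS}
    alpha0 = np.array([inits[lab][0] for lab in CONDITIONS])
    beta_by_cond = np.array([inits[lab][1] for lab in CONDITIONS])
    if shared_av_slope:
        beta0 = np.array(
            [beta_by_cond[0], beta_by_cond[1], beta_by_cond[2:].mean()]
        )
    else:
        beta0 = beta_by_cond
    jnd0 = 1.0 / beta0.mean()

    def nll(theta):
        return float(_joint_nll_batch(theta[None, :], data, betabinomial)[0])

    results = []
    starts = [
        (shift, scale)
        for scale in _RESTART_BETA_SCALES
        for shift in _RESTART_ALPHA_SHIFTS
    ][:n_restarts]
    for shift, scale in starts:
        theta0 = _pack(alpha0 + shift * jnd0, beta0 * scale, 0.02, 0.1, betabinomial)
        res = minimize(
            nll,
            theta0,
            method="Nelder-Mead",
            options=dict(
                xatol=xatol, fatol=fatol, maxiter=400 * len(theta0), maxfev=400 * len(theta0)
            ),
        )
        results.append(res)

    results.sort(key=lambda r: r.fun)
    best = results[0]
    converged = bool(best.success)
    if len(results) > 1:
        converged = converged and bool((results[1].fun - best.fun) <= 1e-3)

    alphas, betas_free, lam, eta = _unpack_batch(best.x, data, betabinomial)
    beta_per_cond = betas_free[0][data.slope_of_cond]
    return JointFitResult(
        alphas={lab: float(a) for lab, a in zip(CONDITIONS, alphas[0])},
        betas={lab: float(b) for lab, b in zip(CONDITIONS, beta_per_cond)},
        lam=float(lam[0]),
        eta=float(eta[0]),
        loglik=float(-best.fun),
        converged=converged,
        n_restarts_used=len(starts),
        shared_av_slope=shared_av_slope,
        likelihood=likelihood,
        restart_logliks=[float(-r.fun) for r in results],
    )


def refit_batch(
    all_counts: Sequence[ConditionCounts],
    k_matrix: np.ndarray,
    init: JointFitResult,
    *,
    x0: np.ndarray | None = None,
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    maxiter: int | None = None,
):
    """Refit many replicate count matrices with a warm-started batched search.

    ``k_matrix`` has shape (B, N) where N is the total number of cells in
    the stacked five-condition layout; every replicate is fitted with the
    same constraints as ``init``.  Returns a dict of per-replicate
    parameter arrays.  Used by the parametric bootstrap and the power
    simulations; equivalence with per-replicate scipy fits is covered by
    the test suite.
    """
    betabinomial = init.likelihood == "betabinomial"
    data = _stack(all_counts, init.shared_av_slope)
    k_matrix = np.asarray(k_matrix)
    b = k_matrix.shape[0]

    alphas0 = np.array([init.alphas[lab] for lab in CONDITIONS])
    if init.shared_av_slope:
        betas0 = np.array(
            [init.betas["A"], init.betas["V"], init.betas["AV0"]]
        )
    else:
        betas0 = np.array([init.betas[lab] for lab in CONDITIONS])
    if x0 is None:
        theta0 = _pack(alphas0, betas0, max(init.lam, 1e-4), max(init.eta, 5e-3),
                       betabinomial)
        x0 = np.repeat(theta0[None, :], b, axis=0)

    def fun(theta, idx):
        return _joint_nll_batch(theta, data, betabinomial, k=k_matrix[idx])

    res = nelder_mead_batch(fun, x0, xatol=xatol, fatol=fatol, maxiter=maxiter)
    out = _named_params(res.x, data, betabinomial)
    out.update(loglik=-res.fun, converged=res.converged, theta=res.x)
    return out


def _named_params(theta, data, betabinomial):
    alphas, betas_free, lam, eta = _unpack_batch(theta, data, betabinomial)
    return {
        "alphas": alphas,
        "betas": betas_free[:, data.slope_of_cond],
        "lam": lam,
        "eta": eta,
    }


# ---------------------------------------------------------------------------
# single-condition fits (session-1 screening, lightweight GOF)
# ---------------------------------------------------------------------------


@dataclass
class SingleFitResult:
    """A single-condition psychometric fit."""

    params: PsychometricParams
    loglik: float
    converged: bool
    likelihood: str


def _single_nll_batch(theta, x, n, betabinomial, k):
    theta = np.atleast_2d(theta)
    alpha = theta[:, 0:1]
    beta = np.exp(theta[:, 1:2])
    lam = LAM_MAX * expit(theta[:, 2:3])
    p = lam + (1.0 - 2.0 * lam) * ndtr(beta * (x[None, :] - alpha))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    if betabinomial:
        eta = ETA_LO + (ETA_HI - ETA_LO) * expit(theta[:, 3:4])
        eta_prime = 1.0 / eta**2 - 1.0
        terms = betaln(k + eta_prime * p, n[None, :] - k + eta_prime * (1.0 - p))
        terms -= betaln(eta_prime * p, eta_prime * (1.0 - p))
    else:
        terms = xlogy(k, p) + xlogy(n[None, :] - k, 1.0 - p)
    return -terms.sum(axis=1)


def fit_single(
    counts: ConditionCounts,
    likelihood: str = "binomial",
    n_restarts: int = 6,
    xatol: float = 1e-8,
    fatol: float = 1e-8,
) -> SingleFitResult:
    """Fit one psychometric function to one condition's counts."""
    if likelihood not in ("binomial", "betabinomial"):
        raise ValueError(f"unknown likelihood {likelihood!r}")
    betabinomial = likelihood == "betabinomial"
    if np.all(counts.k == 0) or np.all(counts.k == counts.n):
        raise DegenerateDataError(
            f"condition {counts.condition!r} has all-identical responses"
        )
    alpha0, beta0 = _probit_init(counts)
    jnd0 = 1.0 / beta0

    def nll(theta):
        return float(
            _single_nll_batch(theta[None, :], counts.x, counts.n, betabinomial,
                              counts.k[None, :])[0]
        )

    starts = [
        (shift, scale)
        for scale in (1.0, 0.5, 2.0)
        for shift in _RESTART_ALPHA_SHIFTS
    ][:n_restarts]
    results = []
    for shift, scale in starts:
        theta0 = _pack_single(alpha0 + shift * jnd0, beta0 * scale, 0.02, 0.1,
                              betabinomial)
        res = minimize(
            nll, theta0, method="Nelder-Mead",
            options=dict(xatol=xatol, fatol=fatol, maxiter=2000, maxfev=2000),
        )
        results.append(res)
    results.sort(key=lambda r: r.fun)
    best = results[0]
    converged = bool(best.success)
    if len(results) > 1:
        converged = converged and bool((results[1].fun - best.fun) <= 1e-3)
    alpha = float(best.x[0])
    beta = float(np.exp(best.x[1]))
    lam = float(LAM_MAX * expit(best.x[2]))
    eta = float(ETA_LO + (ETA_HI - ETA_LO) * expit(best.x[3])) if betabinomial else 0.0
    return SingleFitResult(
        params=PsychometricParams(alpha=alpha, beta=beta, lam=lam, eta=eta),
        loglik=float(-best.fun),
        converged=converged,
        likelihood=likelihood,
    )


def _pack_single(alpha, beta, lam, eta, betabinomial):
    parts = [alpha, np.log(beta), logit(np.clip(lam / LAM_MAX, 1e-6, 1 - 1e-6))]
    if betabinomial:
        u = (eta - ETA_LO) / (ETA_HI - ETA_LO)
        parts.append(logit(np.clip(u, 1e-9, 1 - 1e-9)))
    return np.array(parts, dtype=float)


def refit_single_batch(
    counts: ConditionCounts,
    k_matrix: np.ndarray,
    init: PsychometricParams,
    likelihood: str = "binomial",
    *,
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    maxiter: int | None = None,
):
    """Warm-started batched refits of a single-condition fit."""
    betabinomial = likelihood == "betabinomial"
    k_matrix = np.asarray(k_matrix)
    theta0 = _pack_single(init.alpha, init.beta, max(init.lam, 1e-4),
                          max(init.eta, 5e-3), betabinomial)
    x0 = np.repeat(theta0[None, :], k_matrix.shape[0], axis=0)

    def fun(theta, idx):
        return _single_nll_batch(theta, counts.x, counts.n, betabinomial,
                                 k_matrix[idx])

    res = nelder_mead_batch(fun, x0, xatol=xatol, fatol=fatol, maxiter=maxiter)
    out = {
        "alpha": res.x[:, 0],
        "beta": np.exp(res.x[:, 1]),
        "lam": LAM_MAX * expit(res.x[:, 2]),
        "loglik": -res.fun,
        "converged": res.converged,
    }
    out["eta"] = (
        ETA_LO + (ETA_HI - ETA_LO) * expit(res.x[:, 3])
        if betabinomial
        else np.zeros(k_matrix.shape[0])
    )
    return out


# ---------------------------------------------------------------------------
# saturated model
# ---------------------------------------------------------------------------


def saturated_cell_loglik(k, n, eta) -> np.ndarray:
    """Maximized per-cell log-likelihood of the saturated model.

    One free response probability per cell, with the overdispersion scale
    fixed.  Vectorized over any array shape of ``k``/``n``.  For the
    binomial case (``eta = 0``) the optimum is ``k/n`` in closed form;
    otherwise a bracketed golden-section search is run on all cells at
    once (accuracy checked against a brute-force grid in the tests).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.all(eta == 0.0):
        p = k / n
        return xlogy(k, p) + xlogy(n - k, 1.0 - p)
    if np.any(eta == 0.0):
        raise ValueError("eta must be all-zero or all-positive")

    lo = np.full(k.shape, 1e-9)
    hi = np.full(k.shape, 1.0 - 1e-9)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(60):
        c = hi - invphi * (hi - lo)
        d = lo + invphi * (hi - lo)
        left = _betabinom_ll_terms(k, n, c, eta) > _betabinom_ll_terms(k, n, d, eta)
        hi = np.where(left, d, hi)
        lo = np.where(left, lo, c)
    p = 0.5 * (lo + hi)
    return _betabinom_ll_terms(k, n, p, eta)


def fit_saturated(all_counts: Sequence[ConditionCounts], eta_fixed: float = 0.0) -> float:
    """Summed saturated-model log-likelihood over all cells."""
    total = 0.0
    for c in all_counts:
        total += float(np.sum(saturated_cell_loglik(c.k, c.n, eta_fixed)))
    return total
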