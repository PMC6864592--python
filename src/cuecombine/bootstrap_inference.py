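"""Parametric-bootstrap machinery.

Replicate datasets are drawn from the fitted constrained model (with
beta-distributed cell probabilities when the betabinomial likelihood was
used) and refitted under identical constraints.  The replicate fits feed
three consumers: percentile confidence intervals, the goodness-of-fit
deviance test against the saturated model, and within-subject contrasts
between parameters or derived quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from cuecombine.psychometric_fit import (
    CONDITIONS,
    ConditionCounts,
    JointFitResult,
    SingleFitResult,
    fit_saturated,
    psi,
    refit_batch,
    refit_single_batch,
    saturated_cell_loglik,
)

_COND_INDEX = {lab: i for i, lab in enumerate(CONDITIONS)}


class BootstrapInstabilityError(RuntimeError):
    """Too many replicate refits failed to converge."""


@dataclass
class BootstrapResult:
    """Null distribution, CI and p-value for one bootstrap statistic."""

    n_boot: int
    statistic_obs: float
    null_distribution: np.ndarray
    ci_low: float
    ci_high: float
    p_value: float
    side: str

    def __post_init__(self) -> None:
        self.null_distribution = np.asarray(self.null_distribution, dtype=float)
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


@dataclass
class BootstrapReplicates:
    """Per-replicate refit parameters from a parametric bootstrap."""

    fit: JointFitResult
    disparity: float
    alphas: np.ndarray        # (B, 5) in CONDITIONS order
    betas: np.ndarray         # (B, 5)
    lam: np.ndarray
    eta: np.ndarray
    loglik: np.ndarray
    sat_loglik: np.ndarray
    converged: np.ndarray
    n_redrawn: int = 0
    seed: int | None = None

    @property
    def n_boot(self) -> int:
        return self.alphas.shape[0]


#: quantities computable from a fit or from replicate parameter arrays
DERIVED_QUANTITIES = (
    "sigma_A", "sigma_V", "sigma_AV", "sigma2_AV_emp", "min_sigma_uni",
    "sigma_AV_mle", "sigma2_AV_mle", "w_A_mle", "w_A_emp",
    "pse_A", "pse_V", "pse_AV0", "pse_AVp", "pse_AVm", "lam", "eta",
)


def _derive(alphas, betas, lam, eta, disparity, name):
    """Compute a named quantity from parameter arrays (vectorized)."""
    sigma = (1.0 / betas) / np.sqrt(2.0)
    if name.startswith("pse_"):
        return alphas[..., _COND_INDEX[name[4:]]]
    if name == "lam":
        return lam
    if name == "eta":
        return eta
    if name == "sigma_A":
        return sigma[..., 0]
    if name == "sigma_V":
        return sigma[..., 1]
    if name == "sigma_AV":
        return sigma[..., 2]
    if name == "sigma2_AV_emp":
        return sigma[..., 2] ** 2
    if name == "min_sigma_uni":
        return np.minimum(sigma[..., 0], sigma[..., 1])
    s2a, s2v = sigma[..., 0] ** 2, sigma[..., 1] ** 2
    if name == "sigma2_AV_mle":
        return s2a * s2v / (s2a + s2v)
    if name == "sigma_AV_mle":
        return np.sqrt(s2a * s2v / (s2a + s2v))
    if name == "w_A_mle":
        return (1.0 / s2a) / (1.0 / s2a + 1.0 / s2v)
    if name == "w_A_emp":
        pse_p = alphas[..., _COND_INDEX["AVp"]]
        pse_m = alphas[..., _COND_INDEX["AVm"]]
        return (pse_p - pse_m) / (2.0 * abs(disparity)) + 0.5
    raise ValueError(f"unknown derived quantity {name!r}")


def fit_quantity(fit: JointFitResult, name: str, disparity: float) -> float:
    alphas = np.array([fit.alphas[c] for c in CONDITIONS])
    betas = np.array([fit.betas[c] for c in CONDITIONS])
    return float(_derive(alphas, betas, fit.lam, fit.eta, disparity, name))


def replicate_quantity(rep: BootstrapReplicates, name: str) -> np.ndarray:
    return np.asarray(
        _derive(rep.alphas, rep.betas, rep.lam, rep.eta, rep.disparity, name)
    )


def _simulate_replicate_counts(psi_hat, n_cells, eta, n_boot, rng):
    if eta > 0.0:
        eta_prime = 1.0 / eta**2 - 1.0
        p = rng.beta(
            np.broadcast_to(eta_prime * psi_hat, (n_boot, len(psi_hat))),
            np.broadcast_to(eta_prime * (1.0 - psi_hat), (n_boot, len(psi_hat))),
        )
    else:
        p = np.broadcast_to(psi_hat, (n_boot, len(psi_hat)))
    return rng.binomial(np.broadcast_to(n_cells, p.shape), p)


def parametric_bootstrap(
    fit: JointFitResult,
    all_counts: Sequence[ConditionCounts],
    disparity: float,
    n_boot: int = 5000,
    seed: int = 0,
    *,
    saturated: str = "shared_eta",
    max_failure_fraction: float = 0.05,
    max_redraw_rounds: int = 5,
    refit_kwargs: dict | None = None,
) -> BootstrapReplicates:
    """Draw and refit ``n_boot`` parametric replicates of the fitted model.

    Each replicate draws cell probabilities from beta distributions with
    mean ``psi_hat`` and variance ``eta_hat**2 psi (1-psi)`` (degenerate at
    ``psi_hat`` when ``eta_hat = 0``), then binomial counts, then refits
    with the same constraints, warm-started from the original fit.
    Non-converged replicates are redrawn; more than
    ``max_failure_fraction`` persistent failures raises
    :class:`BootstrapInstabilityError`.

    ``saturated`` selects the dispersion scale of the per-replicate
    saturated model: ``"shared_eta"`` reuses each replicate's refitted
    eta, ``"binomial"`` forces the plain binomial saturated model.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    by_label = {c.condition: c for c in all_counts}
    ordered = [by_label[lab] for lab in CONDITIONS]
    psi_hat = np.concatenate(
        [np.asarray(psi(c.x, fit.params(c.condition))) for c in ordered]
    )
    n_cells = np.concatenate([c.n for c in ordered])

    rng = np.random.default_rng(seed)
    opts = refit_kwargs or {}
    k = _simulate_replicate_counts(psi_hat, n_cells, fit.eta, n_boot, rng)
    res = refit_batch(ordered, k, fit, **opts)

    def _polish(result, counts_matrix):
        """Restart the simplex for non-converged replicates in place."""
        bad = ~result["converged"]
        if bad.any():
            sub = refit_batch(
                ordered, counts_matrix[bad], fit, x0=result["theta"][bad], **opts
            )
            for key in result:
                result[key][bad] = sub[key]

    _polish(res, k)
    n_redrawn = 0
    for _ in range(max_redraw_rounds):
        bad = ~res["converged"]
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        k_new = _simulate_replicate_counts(
            psi_hat, n_cells, fit.eta, int(bad.sum()), rng
        )
        k[bad] = k_new
        sub = refit_batch(ordered, k_new, fit, **opts)
        for key in res:
            res[key][bad] = sub[key]
        _polish(res, k)
    n_failed = int((~res["converged"]).sum())
    if n_failed > max_failure_fraction * n_boot:
        raise BootstrapInstabilityError(
            f"{n_failed}/{n_boot} replicate refits failed to converge"
        )

    if saturated == "binomial" or fit.likelihood == "binomial":
        sat = saturated_cell_loglik(k, n_cells[None, :], 0.0).sum(axis=1)
    elif saturated == "shared_eta":
        sat = saturated_cell_loglik(
            k, np.broadcast_to(n_cells, k.shape), res["eta"][:, None]
        ).sum(axis=1)
    else:
        raise ValueError(f"unknown saturated option {saturated!r}")

    return BootstrapReplicates(
        fit=fit,
        disparity=disparity,
        alphas=res["alphas"],
        betas=res["betas"],
        lam=res["lam"],
        eta=res["eta"],
        loglik=res["loglik"],
        sat_loglik=sat,
        converged=res["converged"],
        n_redrawn=n_redrawn,
        seed=seed,
    )


def percentile_ci(values: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    """Plain percentile bootstrap CI (2.5/97.5 by default)."""
    lo, hi = np.percentile(values, [(100 - level) / 2, 100 - (100 - level) / 2])
    return float(lo), float(hi)


def gof_test(
    fit: JointFitResult,
    all_counts: Sequence[ConditionCounts],
    replicates: BootstrapReplicates,
    *,
    saturated: str = "shared_eta",
) -> BootstrapResult:
    """Goodness-of-fit deviance test against the saturated model.

    The statistic is ``D = 2 (loglik_saturated - loglik_constrained)``;
    the p-value is the fraction of replicate deviances at least as large
    as the observed one (the tail-equivalent of comparing likelihood
    ratios).  ``p < .05`` flags insufficient fit.
    """
    eta_sat = 0.0 if (saturated == "binomial" or fit.likelihood == "binomial") else fit.eta
    sat_obs = fit_saturated(all_counts, eta_fixed=eta_sat)
    d_obs = 2.0 * (sat_obs - fit.loglik)
    d_rep = 2.0 * (replicates.sat_loglik - replicates.loglik)
    p = float(np.mean(d_rep >= d_obs))
    lo, hi = percentile_ci(d_rep)
    return BootstrapResult(
        n_boot=replicates.n_boot,
        statistic_obs=float(d_obs),
        null_distribution=d_rep,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        side="one",
    )


def contrast_test(
    replicates: BootstrapReplicates,
    pair: tuple[str, str],
    side: str = "two",
) -> BootstrapResult:
    """Within-subject bootstrap test for a difference of two quantities.

    The observed difference ``d = q1 - q2`` is compared against the null
    distribution ``{d_b - d}`` (replicate differences recentred at zero).
    For a one-sided test order the pair so the predicted difference is
    positive; ``p = fraction(null >= d)``.  Two-sided tests use absolute
    values.  The CI fields describe the bootstrap distribution of the
    difference itself.
    """
    if side not in ("one", "two"):
        raise ValueError("side must be 'one' or 'two'")
    name1, name2 = pair
    d_obs = fit_quantity(replicates.fit, name1, replicates.disparity) - fit_quantity(
        replicates.fit, name2, replicates.disparity
    )
    d_rep = replicate_quantity(replicates, name1) - replicate_quantity(
        replicates, name2
    )
    if not np.all(np.isfinite(d_rep)):
        raise ValueError("undefined derived quantity in some replicates")
    null = d_rep - d_obs
    if side == "one":
        p = float(np.mean(null >= d_obs))
    else:
        p = float(np.mean(np.abs(null) >= abs(d_obs)))
    lo, hi = percentile_ci(d_rep)
    return BootstrapResult(
        n_boot=replicates.n_boot,
        statistic_obs=float(d_obs),
        null_distribution=null,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        side=side,
    )


def ci_for(replicates: BootstrapReplicates, name: str) -> tuple[float, float]:
    """95% percentile CI of one (possibly derived) parameter."""
    return percentile_ci(replicate_quantity(replicates, name))


def gof_single(
    single_fit: SingleFitResult,
    counts: ConditionCounts,
    n_boot: int = 500,
    seed: int = 0,
) -> BootstrapResult:
    """Goodness-of-fit bootstrap for one single-condition fit.

    Same deviance-tail logic as :func:`gof_test`, with warm-started
    batched refits of the single psychometric function.  Used for the
    session-1 screening fits, where only one condition is available.
    """
    params = single_fit.params
    psi_hat = np.asarray(psi(counts.x, params))
    rng = np.random.default_rng(seed)
    k = _simulate_replicate_counts(psi_hat, counts.n, params.eta, n_boot, rng)
    res = refit_single_batch(counts, k, params, single_fit.likelihood)
    eta_sat = 0.0 if single_fit.likelihood == "binomial" else params.eta
    if eta_sat > 0:
        sat_rep = saturated_cell_loglik(
            k, np.broadcast_to(counts.n, k.shape), res["eta"][:, None]
        ).sum(axis=1)
    else:
        sat_rep = saturated_cell_loglik(k, counts.n[None, :], 0.0).sum(axis=1)
    sat_obs = float(np.sum(saturated_cell_loglik(counts.k, counts.n, eta_sat)))
    d_obs = 2.0 * (sat_obs - single_fit.loglik)
    d_rep = 2.0 * (sat_rep - res["loglik"])
    lo, hi = percentile_ci(d_rep)
    return BootstrapResult(
        n_boot=n_boot,
        statistic_obs=float(d_obs),
        null_distribution=d_rep,
        ci_low=lo,
        ci_high=hi,
        p_value=float(np.mean(d_rep >= d_obs)),
        side="one",
    )
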