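"""Group-level inference battery.

One-sided paired tests with a normality screen, effect sizes, one-sided
JZS Bayes factors, repeated-measures ANOVA with Greenhouse-Geisser
correction, closed-form paired-t power, and the simulation-based power
analysis for deviations between empirical and predicted sensory weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats
from statsmodels.stats.diagnostic import lilliefors

from cuecombine import mle_model, observer_sim
from cuecombine.psychometric_fit import (
    CONDITIONS,
    JointFitResult,
    refit_batch,
)

JZS_SCALE = np.sqrt(2.0) / 2.0


class DegenerateSampleError(ValueError):
    """Paired differences carry no variance; tests undefined."""


@dataclass
class PairedSample:
    """Matched per-participant values for a paired comparison."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be matched 1-D arrays")
        if len(self.x) < 2:
            raise ValueError("need at least 2 participants")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def differences(self) -> np.ndarray:
        return self.x - self.y


@dataclass
class GroupTestReport:
    """Outcome of one group-level paired comparison."""

    test_used: str  # paired_t_one_sided | wilcoxon_one_sided
    statistic: float
    df: float | None
    p: float
    dz: float
    direction: str
    normality_p: float
    n: int
    bf01: float | None = None


def effect_size_dz(sample: PairedSample) -> float:
    """Within-pair effect size: |mean difference| / SD of differences.

    Algebraically equal to
    ``|mu_x - mu_y| / sqrt(sx^2 + sy^2 - 2 rho sx sy)``.
    """
    d = sample.differences
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("paired differences have zero variance")
    return float(abs(d.mean()) / sd)


def paired_one_sided(
    sample: PairedSample,
    direction: str = "greater",
    *,
    normality_alpha: float = 0.05,
    bonferroni: int = 1,
    with_bf: bool = False,
) -> GroupTestReport:
    """One-sided paired comparison with a normality screen.

    ``direction='greater'`` tests H1: mean(x - y) > 0.  A
    Lilliefors-corrected Kolmogorov-Smirnov test on the paired
    differences selects between the paired t-test and the Wilcoxon
    signed-rank test.  ``bonferroni`` multiplies the p-value (capped at
    1) for families of comparisons.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if sample.n < 3:
        raise ValueError("need at least 3 participants for a paired test")
    d = sample.differences
    if d.std(ddof=1) == 0:
        raise DegenerateSampleError("paired differences have zero variance")
    if sample.n >= 4:  # lilliefors table needs n >= 4
        _, norm_p = lilliefors(d, dist="norm", pvalmethod="table")
    else:
        norm_p = 1.0
    dz = effect_size_dz(sample)

    if norm_p < normality_alpha:
        stat, p = stats.wilcoxon(d, alternative=direction)
        test_used, df = "wilcoxon_one_sided", None
    else:
        n = sample.n
        t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        df = n - 1
        p = stats.t.sf(t, df) if direction == "greater" else stats.t.cdf(t, df)
        stat, test_used = t, "paired_t_one_sided"
    p = min(1.0, float(p) * bonferroni)
    report = GroupTestReport(
        test_used=test_used,
        statistic=float(stat),
        df=df,
        p=p,
        dz=dz,
        direction=direction,
        normality_p=float(norm_p),
        n=sample.n,
    )
    if with_bf:
        report.bf01 = bf01_one_sided(sample, direction)
    return report


def bf01_from_t(t: float, n: int, scale: float = JZS_SCALE) -> float:
    """One-sided JZS Bayes factor in favour of the null from a t value.

    The alternative places a Cauchy(0, scale) prior on the standardized
    effect size truncated to positive values (``t`` must already carry
    the predicted sign); the null is a point mass at zero.  Computed by
    adaptive quadrature of the noncentral-t marginal likelihood.
    """
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta):
        prior = 2.0 / (np.pi * scale * (1.0 + (delta / scale) ** 2))
        return stats.nct.pdf(t, df, delta * sqrt_n) * prior

    marginal_h1, err = integrate.quad(
        integrand, 0.0, np.inf, limit=200, epsabs=1e-12, epsrel=1e-10
    )
    if not np.isfinite(marginal_h1) or (marginal_h1 > 0 and err / marginal_h1 > 1e-3):
        raise RuntimeError(
            f"Bayes-factor quadrature did not converge (value={marginal_h1}, err={err})"
        )
    marginal_h0 = stats.t.pdf(t, df)
    return float(marginal_h0 / marginal_h1)


def bf01_one_sided(sample: PairedSample, direction: str = "greater") -> float:
    """One-sided JZS Bayes factor for a paired sample.

    BF01 > 3 is taken as evidence for the null (no difference); BF01 <
    1/3 as evidence for a directional difference.
    """
    d = sample.differences
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("paired differences have zero variance")
    t = d.mean() / (sd / np.sqrt(sample.n))
    if direction == "less":
        t = -t
    return bf01_from_t(float(t), sample.n)


def power_paired_t(dz: float, n: int, alpha: float = 0.05) -> float:
    """Exact one-sided paired-t power via the noncentral t distribution."""
    if dz <= 0:
        raise ValueError("dz must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    t_crit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(t_crit, df, dz * np.sqrt(n)))


@dataclass
class RMAnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    partial_eta2: float
    epsilon: float


def rm_anova_av_conditions(values: np.ndarray) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``values`` is (n_participants, 3): one audiovisual noise estimate per
    AV condition per participant.  The GG epsilon is applied
    unconditionally to the degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 3:
        raise ValueError("values must have shape (n_participants, 3)")
    if np.isnan(values).any():
        raise ValueError("missing cells are not allowed")
    n, k = values.shape
    if n < 3:
        raise ValueError("need at least 3 participants")

    grand = values.mean()
    subj_means = values.mean(axis=1)
    cond_means = values.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err

    # Greenhouse-Geisser epsilon from the sample covariance of conditions
    s = np.cov(values, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        np.sum(s**2) - 2.0 * k * np.sum(row_means**2) + k**2 * mean_all**2
    )
    eps = 1.0 if den == 0 else float(np.clip(num / den, 1.0 / (k - 1), 1.0))

    p = float(stats.f.sf(f, eps * df1, eps * df2)) if np.isfinite(f) else 0.0
    eta_p2 = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return RMAnovaResult(
        F=float(f), df1=eps * df1, df2=eps * df2, p=p,
        partial_eta2=float(eta_p2), epsilon=eps,
    )


@dataclass
class TwoSampleReport:
    statistic: float
    df: float
    p: float
    cohens_d: float
    side: str


def two_sample_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    side: str = "two",
    *,
    equal_var: bool = True,
) -> TwoSampleReport:
    """Independent two-sample t-test (pooled by default) with Cohen's d."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateSampleError("both groups have zero variance")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[side]
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else np.inf
    df = float(res.df) if hasattr(res, "df") else na + nb - 2
    return TwoSampleReport(
        statistic=float(res.statistic), df=df, p=float(res.pvalue),
        cohens_d=float(d), side=side,
    )


# ---------------------------------------------------------------------------
# simulation-based power analysis for weight deviations
# ---------------------------------------------------------------------------


def _truth_init_fit(
    observer: observer_sim.ObserverSpec,
    design: observer_sim.ExperimentDesign,
    likelihood: str,
) -> JointFitResult:
    """A fit-shaped container holding the generating truth, used purely as
    the warm-start for batched refits."""
    w_a, w_v = observer.weights()
    pse_p, pse_m = mle_model.mle_predicted_pses(w_a, design.disparity, 0.0)
    if observer.policy == "mle":
        var_av = mle_model.mle_fused_variance(observer.sigma_A**2, observer.sigma_V**2)
    elif observer.policy == "fixed_weight":
        var_av = w_a**2 * observer.sigma_A**2 + w_v**2 * observer.sigma_V**2
    else:
        var_av = min(observer.sigma_A, observer.sigma_V) ** 2
    beta_av = 1.0 / np.sqrt(2.0 * var_av)
    alphas = {
        "A": observer.bias_A, "V": observer.bias_V,
        "AV0": w_a * observer.bias_A + w_v * observer.bias_V,
        "AVp": pse_p, "AVm": pse_m,
    }
    betas = {
        "A": 1.0 / (observer.sigma_A * np.sqrt(2.0)),
        "V": 1.0 / (observer.sigma_V * np.sqrt(2.0)),
        "AV0": beta_av, "AVp": beta_av, "AVm": beta_av,
    }
    return JointFitResult(
        alphas=alphas, betas=betas,
        lam=observer.lapse, eta=observer.eta,
        loglik=np.nan, converged=True, n_restarts_used=0,
        shared_av_slope=True, likelihood=likelihood,
    )


def simulate_power_weights(
    deviation: float,
    *,
    observer_base: observer_sim.ObserverSpec | None = None,
    design: observer_sim.ExperimentDesign | None = None,
    n_participants: int = 36,
    n_experiments: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Estimated power to detect a weight deviation of ``deviation``.

    Each simulated experiment draws ``n_participants`` fixed-weight
    observers whose auditory weight is ``w_A_mle - deviation`` (with
    matched reliabilities, ``0.5 - deviation``), runs the full main
    design, refits the constrained psychometric model, computes empirical
    and MLE-predicted weights and applies the one-sided paired test.
    Returns the rejection fraction and per-experiment details.
    """
    if deviation < 0:
        raise ValueError("deviation must be non-negative")
    if observer_base is None:
        # clean a-priori-simulation observer: no betabinomial drift
        observer_base = observer_sim.ObserverSpec(
            sigma_A=2.0, sigma_V=2.0, lapse=0.02, eta=0.0, policy="mle"
        )
    if design is None:
        design = observer_sim.make_design(observer_base.jnd_A, 40)

    w_mle_true, _ = mle_model.mle_weights(
        observer_base.sigma_A**2, observer_base.sigma_V**2
    )
    import dataclasses as _dc

    observer = _dc.replace(
        observer_base,
        policy="fixed_weight",
        w_A_fixed=float(np.clip(w_mle_true - deviation, 0.0, 1.0)),
    )
    likelihood = "betabinomial" if observer.eta > 0 else "binomial"
    init = _truth_init_fit(observer, design, likelihood)
    conds = list(CONDITIONS)
    n_cells = len(design.probe_locations)

    rng = np.random.default_rng(seed)
    rejections = 0
    p_values = []
    for _ in range(n_experiments):
        k_rows = []
        template = None
        for _p in range(n_participants):
            counts = observer_sim.simulate_counts(
                observer, design, mode="cell_beta", rng=rng
            )
            if template is None:
                template = counts
            k_rows.append(np.concatenate([c.k for c in counts]))
        k_mat = np.array(k_rows)
        res = refit_batch(template, k_mat, init)
        bad = ~res["converged"]
        if bad.any():  # simplex restart for stragglers
            sub = refit_batch(template, k_mat[bad], init, x0=res["theta"][bad])
            for key in res:
                res[key][bad] = sub[key]
        sigma = (1.0 / res["betas"]) / np.sqrt(2.0)
        s2a, s2v = sigma[:, 0] ** 2, sigma[:, 1] ** 2
        w_mle = (1.0 / s2a) / (1.0 / s2a + 1.0 / s2v)
        i_p, i_m = conds.index("AVp"), conds.index("AVm")
        w_emp = (res["alphas"][:, i_p] - res["alphas"][:, i_m]) / (
            2.0 * design.disparity
        ) + 0.5
        report = paired_one_sided(
            PairedSample(w_mle, w_emp, labels=("w_A_mle", "w_A_emp")),
            direction="greater",
        )
        p_values.append(report.p)
        if report.p < alpha:
            rejections += 1

    return {
        "power": rejections / n_experiments,
        "n_experiments": n_experiments,
        "n_participants": n_participants,
        "deviation": deviation,
        "alpha": alpha,
        "p_values": p_values,
    }
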