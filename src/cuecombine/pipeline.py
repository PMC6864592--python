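"""Cohort-level orchestration.

Simulates participants one at a time through the three-session flow
(auditory screening, staircase-based reliability matching, confirmation,
main experiment), applies the exclusion rules, replaces excluded
participants until the target cohort size is reached, then runs fits,
MLE predictions, bootstrap inference and the group-level battery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cuecombine import bootstrap_inference as bi
from cuecombine import group_stats as gs
from cuecombine import mle_model, observer_sim
from cuecombine import psychometric_fit as pf
from cuecombine.observer_sim import TRIAL_COLUMNS, ExperimentDesign, ObserverSpec
from cuecombine.psychometric_fit import CONDITIONS, ConditionCounts

logger = logging.getLogger("cuecombine.pipeline")

#: fixed screening locations for the first auditory reliability measurement
SCREEN_LOCATIONS = (0.0, 1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 5.0, -5.0,
                    7.0, -7.0, 10.0, -10.0)

LAPSE_MAX = 0.06
GOF_ALPHA = 0.05
VARIANCE_MATCH_FACTOR = 2.0 / 3.0
ACCURACY_MIN = 0.90


class CohortInfeasibleError(RuntimeError):
    """Replacement budget exhausted before reaching the target cohort size."""


class TrialTableSchemaError(ValueError):
    """Trial table violates the expected schema."""


@dataclass
class CohortConfig:
    """Configuration of a full synthetic replication run."""

    n_target: int = 36
    seed: int = 0
    # observer population
    sigma_A_range: tuple[float, float] = (1.5, 3.0)
    bias_range: tuple[float, float] = (-0.3, 0.3)
    lapse_range: tuple[float, float] = (0.0, 0.04)
    eta_range: tuple[float, float] = (0.05, 0.15)
    policy_mix: dict = field(default_factory=lambda: {"mle": 1.0})
    weight_deviation: float = 0.0  # applied when policy == fixed_weight
    blob_to_sigma: float = observer_sim.BLOB_TO_SIGMA
    # design
    n_per_cell_main: int = 40
    n_per_cell_screen: int = 20
    include_no_interest: bool = True
    simulate_mode: str = "cell_beta"
    # fitting / inference
    likelihood: str = "betabinomial"
    n_restarts: int = 12
    n_boot: int = 5000
    n_boot_screen: int = 500
    run_bootstrap: bool = True
    replacement_factor: int = 3

    def __post_init__(self) -> None:
        if self.n_target < 2:
            raise ValueError("n_target must be >= 2")
        total = sum(self.policy_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("policy_mix fractions must sum to 1")

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        for key in ("sigma_A_range", "bias_range", "lapse_range", "eta_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class ParticipantRecord:
    """Everything known about one (simulated) participant."""

    id: str
    observer: ObserverSpec | None = None
    design: ExperimentDesign | None = None
    jnd_A_session1: float | None = None
    sigma_blob: float | None = None
    session1: dict = field(default_factory=dict)
    trials: pd.DataFrame | None = None
    fit_primary: pf.JointFitResult | None = None
    fit_control: pf.JointFitResult | None = None
    gof_p: float | None = None
    prediction: mle_model.MLEPrediction | None = None
    weights: dict = field(default_factory=dict)
    bootstrap_summary: dict = field(default_factory=dict)
    excluded: bool = False
    reasons: list[str] = field(default_factory=list)

    def exclude(self, reason: str) -> None:
        self.excluded = True
        if reason not in self.reasons:
            self.reasons.append(reason)


def tally_counts(
    trials: pd.DataFrame,
    of_interest_only: bool = True,
    honour_excluded_flag: bool = True,
) -> dict[str, ConditionCounts]:
    """Tally a trial table into per-condition counts.

    Rows flagged as not-of-interest or excluded are dropped according to
    the flags; AVp/AVm rows are checked for consistent disparity signs.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialTableSchemaError(f"missing columns: {missing}")
    bad_cond = ~trials["condition"].isin(CONDITIONS)
    if bad_cond.any():
        row = int(trials.index[bad_cond][0])
        raise TrialTableSchemaError(
            f"unknown condition {trials.loc[row, 'condition']!r} at row {row}"
        )
    bad_resp = ~trials["response"].isin([0, 1])
    if bad_resp.any():
        row = int(trials.index[bad_resp][0])
        raise TrialTableSchemaError(f"non-binary response at row {row}")
    for cond, sign in (("AVp", 1), ("AVm", -1)):
        sub = trials[trials["condition"] == cond]
        if len(sub) and np.any(np.sign(sub["disparity_deg"]) != sign):
            raise TrialTableSchemaError(
                f"condition {cond} contains disparities of the wrong sign"
            )

    df = trials
    if of_interest_only:
        df = df[df["of_interest"] == 1]
    if honour_excluded_flag:
        df = df[df["excluded"] == 0]
    out: dict[str, ConditionCounts] = {}
    for cond, grp in df.groupby("condition"):
        tab = grp.groupby("probe_x_deg")["response"].agg(["count", "sum"])
        out[cond] = ConditionCounts(
            condition=str(cond),
            x=tab.index.to_numpy(dtype=float),
            n=tab["count"].to_numpy(),
            k=tab["sum"].to_numpy(),
        )
    return out


# ---------------------------------------------------------------------------
# participant-level simulation
# ---------------------------------------------------------------------------


def _draw_observer(config: CohortConfig, rng: np.random.Generator, seed: int) -> ObserverSpec:
    sigma_a = rng.uniform(*config.sigma_A_range)
    policies = list(config.policy_mix)
    probs = np.array([config.policy_mix[p] for p in policies])
    policy = str(rng.choice(policies, p=probs / probs.sum()))
    w_fixed = None
    if policy == "fixed_weight":
        # matched-reliability baseline minus the configured deviation;
        # sigma_V is set by the staircase so w_mle is approximately .5
        w_fixed = float(np.clip(0.5 - config.weight_deviation, 0.0, 1.0))
    return ObserverSpec(
        sigma_A=float(sigma_a),
        sigma_V=float(sigma_a),  # provisional; staircase sets the true value
        bias_A=float(rng.uniform(*config.bias_range)),
        bias_V=float(rng.uniform(*config.bias_range)),
        lapse=float(rng.uniform(*config.lapse_range)),
        eta=float(rng.uniform(*config.eta_range)),
        policy=policy,
        w_A_fixed=w_fixed,
        seed=seed,
    )


def _simulate_condition_counts(observer, cond, x, n_per_cell, delta, rng, mode):
    """Counts for one condition at arbitrary locations."""
    x = np.asarray(x, dtype=float)
    n = np.full(len(x), n_per_cell)
    if mode == "trialwise":
        xs = np.repeat(x, n_per_cell)
        resp = observer_sim._trialwise_responses(observer, cond, xs, delta, rng)
        k = resp.reshape(len(x), n_per_cell).sum(axis=1)
    else:
        p = np.asarray(observer_sim.p_right(observer, cond, x, delta))
        if observer.eta > 0:
            eta_prime = 1.0 / observer.eta**2 - 1.0
            interior = (p > 0) & (p < 1)
            drawn = p.copy()
            drawn[interior] = rng.beta(
                eta_prime * p[interior], eta_prime * (1.0 - p[interior])
            )
            p = drawn
        k = rng.binomial(n, p)
    return ConditionCounts(condition=cond, x=x, n=n, k=k)


def _session1(record: ParticipantRecord, config: CohortConfig,
              rng: np.random.Generator) -> None:
    """Screening, JND refinement, staircases and visual confirmation."""
    obs = record.observer

    # auditory reliability, part 1: fixed locations
    counts_a1 = _simulate_condition_counts(
        obs, "A", np.array(SCREEN_LOCATIONS), config.n_per_cell_screen, 0.0,
        rng, config.simulate_mode)
    at_edge = np.isin(counts_a1.x, [10.0, -10.0])
    n_edge = counts_a1.n[at_edge].sum()
    correct = np.where(
        counts_a1.x[at_edge] > 0,
        counts_a1.k[at_edge],
        counts_a1.n[at_edge] - counts_a1.k[at_edge],
    ).sum()
    accuracy = correct / n_edge
    record.session1["accuracy_10deg"] = float(accuracy)
    if accuracy < ACCURACY_MIN:
        record.exclude("auditory_accuracy")
        return

    fit_a1 = pf.fit_single(counts_a1, likelihood="binomial")
    jnd1 = fit_a1.params.jnd

    # part 2: refined JND on individualized locations
    design1 = observer_sim.make_design(jnd1, config.n_per_cell_screen)
    counts_a2 = _simulate_condition_counts(
        obs, "A", np.array(design1.probe_locations), config.n_per_cell_screen,
        0.0, rng, config.simulate_mode)
    fit_a2 = pf.fit_single(counts_a2, likelihood="binomial")
    record.jnd_A_session1 = fit_a2.params.jnd
    record.session1["fit_A"] = fit_a2
    record.design = observer_sim.make_design(
        record.jnd_A_session1, config.n_per_cell_main)

    # visual reliability adjustment: 6 interleaved staircases
    staircases = []
    for loc_mult, u in ((0.5, 1), (0.85, 2), (1.2, 4)):
        loc = loc_mult * record.jnd_A_session1
        target = float(observer_sim.p_right(obs, "A", loc))
        target = float(np.clip(target, 0.55, 0.95))
        for start in (2.0, 40.0):
            st = observer_sim.make_staircase(start, target, u)
            st = observer_sim.run_staircase(
                st, loc, obs.lapse, rng, blob_to_sigma=config.blob_to_sigma)
            staircases.append(st)
    sigma_blob = observer_sim.pool_staircases(staircases)
    record.sigma_blob = sigma_blob
    sigma_v = config.blob_to_sigma * sigma_blob
    record.observer = dataclasses.replace(obs, sigma_V=float(sigma_v))
    obs = record.observer

    # visual reliability confirmation fit
    counts_v = _simulate_condition_counts(
        obs, "V", np.array(record.design.probe_locations),
        config.n_per_cell_screen, 0.0, rng, config.simulate_mode)
    fit_v = pf.fit_single(counts_v, likelihood="binomial")
    record.session1["fit_V"] = fit_v

    gof_seed = int(rng.integers(2**31))
    record.session1["gof_A_p"] = bi.gof_single(
        fit_a2, counts_a2, config.n_boot_screen, gof_seed).p_value
    record.session1["gof_V_p"] = bi.gof_single(
        fit_v, counts_v, config.n_boot_screen, gof_seed + 1).p_value

    screen_exclusions(record, stage="pre")


def screen_exclusions(record: ParticipantRecord, stage: str) -> ParticipantRecord:
    """Apply the exclusion rules; reasons are appended, never overwritten."""
    if stage == "pre":
        acc = record.session1.get("accuracy_10deg")
        if acc is not None and acc < ACCURACY_MIN:
            record.exclude("auditory_accuracy")
        fit_a = record.session1.get("fit_A")
        fit_v = record.session1.get("fit_V")
        if fit_a is not None and fit_v is not None:
            s2a = fit_a.params.sigma**2
            s2v = fit_v.params.sigma**2
            s2_av = mle_model.mle_fused_variance(s2a, s2v)
            if s2_av > VARIANCE_MATCH_FACTOR * min(s2a, s2v):
                record.exclude("variance_matching")
            for lab, f in (("A", fit_a), ("V", fit_v)):
                if f.params.lam > LAPSE_MAX:
                    record.exclude(f"lapse_{lab}")
        for lab in ("A", "V"):
            p = record.session1.get(f"gof_{lab}_p")
            if p is not None and p < GOF_ALPHA:
                record.exclude(f"gof_{lab}")
    elif stage == "post":
        if record.fit_primary is not None:
            if record.fit_primary.lam > LAPSE_MAX:
                record.exclude("lapse_main")
        if record.gof_p is not None and record.gof_p < GOF_ALPHA:
            record.exclude("gof_main")
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return record


def _no_interest_trials(record, config, rng):
    """Variable-blob-size filler trials; written but never analysed."""
    obs, design = record.observer, record.design
    rows = []
    specs = [("V", 1), ("AV0", 3)]
    for cond, mult in specs:
        n_trials = mult * config.n_per_cell_main * len(design.probe_locations)
        xs = rng.choice(design.probe_locations, size=n_trials)
        factors = rng.uniform(0.5, 2.0, size=n_trials)
        sigma_v = obs.sigma_V * factors
        root2 = np.sqrt(2.0)
        if cond == "V":
            diff = xs + sigma_v * root2 * rng.standard_normal(n_trials)
            resp = diff > obs.bias_V
        else:
            diff_a = xs + obs.sigma_A * root2 * rng.standard_normal(n_trials)
            diff_v = xs + sigma_v * root2 * rng.standard_normal(n_trials)
            s2a = np.full(n_trials, obs.sigma_A**2)
            s2v = sigma_v**2
            w_a = (1 / s2a) / (1 / s2a + 1 / s2v)
            diff = w_a * diff_a + (1 - w_a) * diff_v
            resp = diff > (w_a * obs.bias_A + (1 - w_a) * obs.bias_V)
        lapse_mask = rng.random(n_trials) < 2 * obs.lapse
        resp = np.where(lapse_mask, rng.random(n_trials) < 0.5, resp).astype(int)
        for x, s, r in zip(xs, sigma_v / config.blob_to_sigma, resp):
            rows.append((record.id, 2, cond, x, 0.0, s, 0, r, 0))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _main_experiment(record: ParticipantRecord, config: CohortConfig,
                     rng: np.random.Generator) -> None:
    obs, design = record.observer, record.design
    counts = observer_sim.simulate_counts(obs, design, config.simulate_mode, rng)
    frames = [observer_sim.counts_to_trials(
        counts, participant_id=record.id, session=2,
        blob_sigma=record.sigma_blob or np.nan, design=design)]
    if config.include_no_interest:
        frames.append(_no_interest_trials(record, config, rng))
    record.trials = pd.concat(frames, ignore_index=True)

    tallied = tally_counts(record.trials)
    ordered = [tallied[lab] for lab in CONDITIONS]
    record.fit_primary = pf.fit_joint(
        ordered, shared_av_slope=True, likelihood=config.likelihood,
        n_restarts=config.n_restarts)
    record.fit_control = pf.fit_joint(
        ordered, shared_av_slope=False, likelihood=config.likelihood,
        n_restarts=config.n_restarts)

    if config.run_bootstrap:
        reps = bi.parametric_bootstrap(
            record.fit_primary, ordered, design.disparity,
            n_boot=config.n_boot, seed=int(rng.integers(2**31)))
        gof = bi.gof_test(record.fit_primary, ordered, reps)
        record.gof_p = gof.p_value
        record.bootstrap_summary = _bootstrap_summary(reps, gof)

    fit = record.fit_primary
    pred = mle_model.predict(
        fit.sigma_A**2, fit.sigma_V**2, design.disparity, fit.alphas["AV0"])
    record.prediction = pred
    record.weights = {
        "w_A_emp": mle_model.empirical_weight_eq6(
            fit.alphas["AVp"], fit.alphas["AVm"], design.disparity).w_A_emp,
        "w_A_mle": pred.w_A_mle,
    }
    ctrl = record.fit_control
    try:
        record.weights["w_A_ALVR"] = mle_model.empirical_weight_eq8(
            ctrl.alphas["AVp"], ctrl.alphas["A"], ctrl.alphas["V"],
            design.disparity, "ALVR").w_A_emp
        record.weights["w_A_VLAR"] = mle_model.empirical_weight_eq8(
            ctrl.alphas["AVm"], ctrl.alphas["A"], ctrl.alphas["V"],
            design.disparity, "VLAR").w_A_emp
    except mle_model.DegenerateDenominatorError:  # pragma: no cover
        record.weights["w_A_ALVR"] = np.nan
        record.weights["w_A_VLAR"] = np.nan

    screen_exclusions(record, stage="post")


def _bootstrap_summary(reps: bi.BootstrapReplicates, gof) -> dict:
    summary = {
        "gof_p": gof.p_value,
        "n_boot": reps.n_boot,
        "n_redrawn": reps.n_redrawn,
        "ci": {name: bi.ci_for(reps, name)
               for name in ("sigma_A", "sigma_V", "sigma_AV", "w_A_emp",
                            "w_A_mle", "sigma_AV_mle")},
    }
    contrasts = {
        "sigmaV_vs_sigmaA": (("sigma_V", "sigma_A"), "two"),
        "min_uni_vs_sigmaAV": (("min_sigma_uni", "sigma_AV"), "one"),
        "sigmaAV_emp_vs_mle": (("sigma_AV", "sigma_AV_mle"), "one"),
        "wA_mle_vs_emp": (("w_A_mle", "w_A_emp"), "one"),
    }
    summary["contrasts"] = {
        name: {"p": bi.contrast_test(reps, pair, side).p_value,
               "difference": bi.contrast_test(reps, pair, side).statistic_obs,
               "side": side}
        for name, (pair, side) in contrasts.items()
    }
    return summary


# ---------------------------------------------------------------------------
# cohort-level orchestration
# ---------------------------------------------------------------------------


@dataclass
class CohortReport:
    config: CohortConfig
    included: list[ParticipantRecord]
    excluded: list[ParticipantRecord]
    tidy: pd.DataFrame
    group: dict


def simulate_participant(config: CohortConfig, index: int) -> ParticipantRecord:
    """Run one participant through all sessions (no replacement logic)."""
    seed_seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(index,))
    rng = np.random.default_rng(seed_seq)
    record = ParticipantRecord(id=f"p{index:03d}")
    record.observer = _draw_observer(config, rng, seed=index)
    _session1(record, config, rng)
    if record.excluded:
        return record
    _main_experiment(record, config, rng)
    return record


def tidy_row(record: ParticipantRecord) -> dict:
    fit = record.fit_primary
    pred = record.prediction
    return {
        "participant_id": record.id,
        "policy": record.observer.policy,
        "sigma_A": fit.sigma_A,
        "sigma_V": fit.sigma_V,
        "sigma_AV_emp": fit.sigma_AV,
        "sigma_AV_mle": float(np.sqrt(pred.sigma2_AV_mle)),
        "w_A_emp": record.weights["w_A_emp"],
        "w_A_mle": record.weights["w_A_mle"],
        "w_A_ALVR": record.weights.get("w_A_ALVR", np.nan),
        "w_A_VLAR": record.weights.get("w_A_VLAR", np.nan),
        "sigma_AV0_ctrl": record.fit_control.sigma("AV0"),
        "sigma_AVp_ctrl": record.fit_control.sigma("AVp"),
        "sigma_AVm_ctrl": record.fit_control.sigma("AVm"),
        "lam": fit.lam,
        "eta": fit.eta,
        "gof_p": record.gof_p,
    }


def group_battery(tidy: pd.DataFrame) -> dict:
    """The group-level test battery on the tidy per-participant table.

    With fewer than 3 participants the inferential tests are undefined;
    the affected sections then carry a ``skipped`` marker so that tiny
    smoke cohorts still produce a complete report.
    """
    out: dict = {}
    n = len(tidy)
    weights = gs.PairedSample(
        tidy["w_A_mle"].to_numpy(), tidy["w_A_emp"].to_numpy(),
        labels=("w_A_mle", "w_A_emp"))
    variances = gs.PairedSample(
        tidy["sigma_AV_emp"].to_numpy() ** 2, tidy["sigma_AV_mle"].to_numpy() ** 2,
        labels=("sigma2_AV_emp", "sigma2_AV_mle"))
    if n >= 3:
        out["weights_test"] = dataclasses.asdict(
            gs.paired_one_sided(weights, "greater", with_bf=True))
        out["variance_test"] = dataclasses.asdict(
            gs.paired_one_sided(variances, "greater", with_bf=True))
        out["rm_anova_av"] = dataclasses.asdict(gs.rm_anova_av_conditions(
            tidy[["sigma_AV0_ctrl", "sigma_AVp_ctrl",
                  "sigma_AVm_ctrl"]].to_numpy()))
    else:
        skip = {"skipped": f"n={n} < 3 participants"}
        out["weights_test"] = dict(skip)
        out["variance_test"] = dict(skip)
        out["rm_anova_av"] = dict(skip)
    out["descriptives"] = {
        "n": n,
        "mean_w_A_emp": float(tidy["w_A_emp"].mean()),
        "mean_w_A_mle": float(tidy["w_A_mle"].mean()),
        "mean_sigma_AV_emp": float(tidy["sigma_AV_emp"].mean()),
        "mean_sigma_AV_mle": float(tidy["sigma_AV_mle"].mean()),
    }
    return out


def run_replication(config: CohortConfig, outdir=None) -> CohortReport:
    """Simulate, screen, replace, fit and analyse a full cohort.

    Deterministic for a given configuration: participant ``i`` always
    receives the same RNG stream regardless of how many exclusions
    happened before.  Raises :class:`CohortInfeasibleError` when the
    replacement budget (``replacement_factor * n_target`` attempts) runs
    out.
    """
    included: list[ParticipantRecord] = []
    excluded: list[ParticipantRecord] = []
    budget = config.replacement_factor * config.n_target
    index = 0
    while len(included) < config.n_target:
        if index >= budget:
            raise CohortInfeasibleError(
                f"only {len(included)}/{config.n_target} participants "
                f"after {budget} attempts")
        record = simulate_participant(config, index)
        index += 1
        if record.excluded:
            logger.info("participant %s excluded: %s", record.id, record.reasons)
            excluded.append(record)
        else:
            logger.info(
                "participant %s included (loglik=%.2f, gof_p=%s)",
                record.id, record.fit_primary.loglik, record.gof_p)
            included.append(record)

    tidy = pd.DataFrame([tidy_row(r) for r in included])
    group = group_battery(tidy)
    report = CohortReport(
        config=config, included=included, excluded=excluded,
        tidy=tidy, group=group)
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: CohortReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.tidy.to_csv(outdir / "tidy.csv", index=False)
    with open(outdir / "group_report.json", "w") as fh:
        json.dump(_jsonable(report.group), fh, indent=2)
    exclusions = [
        {"participant_id": r.id, "reasons": r.reasons} for r in report.excluded
    ]
    with open(outdir / "exclusions.json", "w") as fh:
        json.dump(exclusions, fh, indent=2)
    trials_dir = outdir / "trials"
    trials_dir.mkdir(exist_ok=True)
    fits = {}
    for r in report.included:
        if r.trials is not None:
            observer_sim.write_trials(r.trials, trials_dir / f"{r.id}.csv")
        fits[r.id] = {
            "primary": r.fit_primary.to_dict(),
            "control": r.fit_control.to_dict(),
            "weights": _jsonable(r.weights),
            "bootstrap": _jsonable(r.bootstrap_summary),
        }
    with open(outdir / "fits.json", "w") as fh:
        json.dump(_jsonable(fits), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
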