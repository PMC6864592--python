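"""Synthetic 2IFC localization experiments for model observers.

Generates experiment designs (JND-scaled probe locations, one-JND
audiovisual disparity), trial-level or cell-level responses for MLE,
cue-switching and fixed-weight observers, and the adaptive-staircase
machinery used to match visual to auditory reliability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from cuecombine import mle_model
from cuecombine.psychometric_fit import CONDITIONS, ConditionCounts

#: default conversion from visual blob size to visual sensory noise SD.
#: The true mapping is an empirical, per-participant quantity; any
#: monotone link suffices to exercise the staircase logic.
BLOB_TO_SIGMA = 0.25

SIGMA_BLOB_MIN = 0.1
SIGMA_BLOB_MAX = 60.0

TRIAL_COLUMNS = [
    "participant_id",
    "session",
    "condition",
    "probe_x_deg",
    "disparity_deg",
    "blob_sigma_deg",
    "of_interest",
    "response",
    "excluded",
]


class InsufficientDataError(ValueError):
    """Not enough staircase reversals to pool an estimate."""


@dataclass(frozen=True)
class ObserverSpec:
    """Generative ground truth for one simulated observer."""

    sigma_A: float
    sigma_V: float
    bias_A: float = 0.0
    bias_V: float = 0.0
    lapse: float = 0.0
    eta: float = 0.0
    policy: Literal["mle", "switching", "fixed_weight"] = "mle"
    w_A_fixed: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_A <= 0 or self.sigma_V <= 0:
            raise ValueError("sensory noise SDs must be positive")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError(f"lapse must lie in [0, 0.5), got {self.lapse}")
        if not 0.0 <= self.eta < 1.0:
            raise ValueError(f"eta must lie in [0, 1), got {self.eta}")
        if self.policy not in ("mle", "switching", "fixed_weight"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.policy == "fixed_weight":
            if self.w_A_fixed is None or not 0.0 <= self.w_A_fixed <= 1.0:
                raise ValueError("policy='fixed_weight' requires w_A_fixed in [0, 1]")

    @property
    def jnd_A(self) -> float:
        return self.sigma_A * np.sqrt(2.0)

    def weights(self) -> tuple[float, float]:
        """Auditory/visual weights the observer applies to AV stimuli."""
        if self.policy == "fixed_weight":
            return float(self.w_A_fixed), 1.0 - float(self.w_A_fixed)
        return mle_model.mle_weights(self.sigma_A**2, self.sigma_V**2)


@dataclass(frozen=True)
class ExperimentDesign:
    """Probe locations, disparity and trial counts of one experiment."""

    probe_locations: tuple[float, ...]
    disparity: float
    n_per_cell: int
    jnd_A: float
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if len(self.probe_locations) != 13:
            raise ValueError("a design must have 13 probe locations")
        if len(set(self.probe_locations)) != 13:
            raise ValueError("probe locations must be unique")
        locs = np.array(sorted(self.probe_locations))
        if not np.allclose(locs, -locs[::-1]):
            raise ValueError("probe locations must be symmetric about 0")
        if self.disparity <= 0:
            raise ValueError("disparity must be positive")
        if self.n_per_cell <= 0:
            raise ValueError("n_per_cell must be positive")

    def signed_disparity(self, condition: str) -> float:
        if condition in ("A", "V", "AV0"):
            return 0.0
        if condition == "AVp":
            return self.disparity
        if condition == "AVm":
            return -self.disparity
        raise ValueError(f"unknown condition {condition!r}")


def make_design(jnd_A: float, n_per_cell: int = 40) -> ExperimentDesign:
    """Build the 13-location main design from an auditory JND.

    Locations are ``(0, +/-0.5, +/-1, ..., +/-3) * jnd_A`` rounded to the
    nearest 0.5 deg; rounding collisions are resolved by pushing the outer
    duplicate outward in 0.5 deg steps so the 13 locations stay unique.
    The audiovisual disparity equals one auditory JND.
    """
    if jnd_A <= 0:
        raise ValueError(f"jnd_A must be positive, got {jnd_A}")
    positive = []
    prev = 0.0
    for mult in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0):
        loc = float(np.round(mult * jnd_A * 2.0) / 2.0)
        loc = max(loc, prev + 0.5)
        positive.append(loc)
        prev = loc
    locs = tuple(sorted([-v for v in positive] + [0.0] + positive))
    return ExperimentDesign(
        probe_locations=locs,
        disparity=float(jnd_A),
        n_per_cell=int(n_per_cell),
        jnd_A=float(jnd_A),
    )


# ---------------------------------------------------------------------------
# response-probability model
# ---------------------------------------------------------------------------


def p_right(observer: ObserverSpec, condition: str, x, disparity: float = 0.0):
    """Probability of a 'probe right' response.

    ``disparity`` is the signed audiovisual conflict of the probe: the
    visual component sits at ``x + disparity/2`` and the auditory one at
    ``x - disparity/2``.  The sqrt(2) in the effective noise reflects the
    2IFC task (standard and probe are both noisy).
    """
    x = np.asarray(x, dtype=float)
    lam = observer.lapse
    root2 = np.sqrt(2.0)

    if condition == "A":
        core = ndtr((x - observer.bias_A) / (observer.sigma_A * root2))
    elif condition == "V":
        core = ndtr((x - observer.bias_V) / (observer.sigma_V * root2))
    elif condition in ("AV0", "AVp", "AVm"):
        x_v = x + disparity / 2.0
        x_a = x - disparity / 2.0
        w_a, w_v = observer.weights()
        if observer.policy == "switching":
            core = w_a * ndtr(
                (x_a - observer.bias_A) / (observer.sigma_A * root2)
            ) + w_v * ndtr((x_v - observer.bias_V) / (observer.sigma_V * root2))
        else:
            mu = w_a * x_a + w_v * x_v
            bias = w_a * observer.bias_A + w_v * observer.bias_V
            if observer.policy == "mle":
                var = mle_model.mle_fused_variance(
                    observer.sigma_A**2, observer.sigma_V**2
                )
            else:
                var = w_a**2 * observer.sigma_A**2 + w_v**2 * observer.sigma_V**2
            core = ndtr((mu - bias) / (np.sqrt(var) * root2))
    else:
        raise ValueError(f"unknown condition {condition!r}")
    out = lam + (1.0 - 2.0 * lam) * core
    return out if out.ndim else float(out)


def _simulate_cell_beta(observer, design, rng):
    counts = []
    for cond in design.conditions:
        delta = design.signed_disparity(cond)
        x = np.array(design.probe_locations)
        p = np.asarray(p_right(observer, cond, x, delta), dtype=float)
        n = np.full(len(x), design.n_per_cell)
        if observer.eta > 0.0:
            var = observer.eta**2 * p * (1.0 - p)
            feasible = p * (1.0 - p)
            bad = var > feasible + 1e-12
            if np.any(bad):
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"infeasible beta variance in cell ({cond}, x={x[i]:g})"
                )
            eta_prime = 1.0 / observer.eta**2 - 1.0
            interior = (p > 0.0) & (p < 1.0)
            p_draw = p.copy()
            p_draw[interior] = rng.beta(
                eta_prime * p[interior], eta_prime * (1.0 - p[interior])
            )
            p = p_draw
        k = rng.binomial(n, p)
        counts.append(ConditionCounts(condition=cond, x=x, n=n, k=k))
    return counts


def _trialwise_responses(observer, cond, x, delta, rng):
    """Vector of 0/1 responses for probe locations ``x`` (one trial each)."""
    m = len(x)
    root2 = np.sqrt(2.0)
    if cond == "A":
        diff = x + observer.sigma_A * root2 * rng.standard_normal(m)
        resp = diff > observer.bias_A
    elif cond == "V":
        diff = x + observer.sigma_V * root2 * rng.standard_normal(m)
        resp = diff > observer.bias_V
    else:
        x_v = x + delta / 2.0
        x_a = x - delta / 2.0
        w_a, w_v = observer.weights()
        # probe minus standard internal estimates; the standard is congruent
        # at 0 so each modality contributes noise in both intervals
        diff_a = x_a + observer.sigma_A * root2 * rng.standard_normal(m)
        diff_v = x_v + observer.sigma_V * root2 * rng.standard_normal(m)
        if observer.policy == "switching":
            pick_a = rng.random(m) < w_a
            diff = np.where(pick_a, diff_a, diff_v)
            bias = np.where(pick_a, observer.bias_A, observer.bias_V)
            resp = diff > bias
        else:
            diff = w_a * diff_a + w_v * diff_v
            resp = diff > (w_a * observer.bias_A + w_v * observer.bias_V)
    lapse_mask = rng.random(m) < 2.0 * observer.lapse
    guesses = rng.random(m) < 0.5
    return np.where(lapse_mask, guesses, resp).astype(int)


def _simulate_trialwise(observer, design, rng):
    counts = []
    for cond in design.conditions:
        delta = design.signed_disparity(cond)
        x = np.array(design.probe_locations)
        xs = np.repeat(x, design.n_per_cell)
        resp = _trialwise_responses(observer, cond, xs, delta, rng)
        k = resp.reshape(len(x), design.n_per_cell).sum(axis=1)
        n = np.full(len(x), design.n_per_cell)
        counts.append(ConditionCounts(condition=cond, x=x, n=n, k=k))
    return counts


def simulate_counts(
    observer: ObserverSpec,
    design: ExperimentDesign,
    mode: Literal["cell_beta", "trialwise"] = "cell_beta",
    rng: np.random.Generator | None = None,
) -> list[ConditionCounts]:
    """Simulate per-cell response counts for the full design.

    ``cell_beta`` draws each cell's response probability from a beta
    distribution with mean psi and variance ``eta**2 * psi * (1 - psi)``
    and then binomial counts (the data-generating process assumed by the
    betabinomial likelihood).  ``trialwise`` draws noisy internal
    estimates per trial and responds by sign comparison; ``eta`` is
    ignored in this mode.
    """
    if rng is None:
        rng = np.random.default_rng(observer.seed)
    if mode == "cell_beta":
        return _simulate_cell_beta(observer, design, rng)
    if mode == "trialwise":
        return _simulate_trialwise(observer, design, rng)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# adaptive staircases
# ---------------------------------------------------------------------------


@dataclass
class StaircaseState:
    """State of one transformed, weighted up/down staircase.

    Steps are applied on the log of the blob size, so the up/down step
    sizes ``step_up``/``step_down`` are multiplicative.  The convergence
    target follows ``fraction_correct = (step_down /
    (step_down + step_up)) ** (1/U)``.
    """

    sigma_blob: float
    U: int
    step_up: float
    step_down: float
    target_fraction: float
    reversals: list[float] = field(default_factory=list)
    direction_history: list[int] = field(default_factory=list)
    consecutive_correct: int = 0
    last_move: int = 0
    sigma_min: float = SIGMA_BLOB_MIN
    sigma_max: float = SIGMA_BLOB_MAX


def make_staircase(
    start_sigma: float,
    target_fraction: float,
    U: int,
    step_down: float = 0.1,
) -> StaircaseState:
    """Build a staircase whose step ratio converges on ``target_fraction``.

    Inverting the fraction-correct rule gives
    ``step_up = step_down * (1 - f**U) / f**U``.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    if U not in (1, 2, 4):
        raise ValueError(f"U must be one of 1, 2, 4; got {U}")
    f_u = target_fraction**U
    step_up = step_down * (1.0 - f_u) / f_u
    return StaircaseState(
        sigma_blob=float(start_sigma),
        U=int(U),
        step_up=float(step_up),
        step_down=float(step_down),
        target_fraction=float(target_fraction),
    )


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance a staircase by one trial.

    Blob size decreases (making the stimulus more reliable) after each
    incorrect response and increases after ``U`` consecutive correct
    responses.  A change of movement direction records the pre-move blob
    size as a reversal.
    """
    state = dataclasses.replace(
        state,
        reversals=list(state.reversals),
        direction_history=list(state.direction_history),
    )
    move = 0
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= state.U:
            move = 1
            state.consecutive_correct = 0
    else:
        move = -1
        state.consecutive_correct = 0
    if move != 0:
        if state.last_move != 0 and move != state.last_move:
            state.reversals.append(state.sigma_blob)
        log_sigma = np.log(state.sigma_blob) + move * (
            state.step_up if move > 0 else state.step_down
        )
        state.sigma_blob = float(
            np.clip(np.exp(log_sigma), state.sigma_min, state.sigma_max)
        )
        state.direction_history.append(move)
        state.last_move = move
    return state


def run_staircase(
    state: StaircaseState,
    location: float,
    lapse: float,
    rng: np.random.Generator,
    blob_to_sigma: float = BLOB_TO_SIGMA,
    n_reversals: int = 30,
    max_trials: int = 10_000,
) -> StaircaseState:
    """Run a visual 2IFC staircase at ``+/-location`` until it reverses
    ``n_reversals`` times.

    The probability of a correct left/right judgement at the current blob
    size is ``lam + (1 - 2 lam) * Phi(location / (sigma_V * sqrt(2)))``
    with ``sigma_V = blob_to_sigma * sigma_blob``.
    """
    for _ in range(max_trials):
        if len(state.reversals) >= n_reversals:
            break
        sigma_v = blob_to_sigma * state.sigma_blob
        p_correct = lapse + (1.0 - 2.0 * lapse) * ndtr(
            location / (sigma_v * np.sqrt(2.0))
        )
        state = staircase_step(state, bool(rng.random() < p_correct))
    return state


def pool_staircases(staircases: Sequence[StaircaseState]) -> float:
    """Pool six staircases into one final blob-size estimate.

    Each staircase contributes the RMS of its last 20 reversal values;
    the staircase whose estimate lies farthest from the six-staircase
    pooled RMS is discarded and the RMS over the remaining 5 x 20
    reversal values is returned.
    """
    if len(staircases) != 6:
        raise ValueError(f"expected 6 staircases, got {len(staircases)}")
    for i, s in enumerate(staircases):
        if len(s.reversals) < 30:
            raise InsufficientDataError(
                f"staircase {i} has only {len(s.reversals)} reversals (need >= 30)"
            )
    tails = [np.asarray(s.reversals[-20:], dtype=float) for s in staircases]
    per_stair = np.array([np.sqrt(np.mean(t**2)) for t in tails])
    pooled_all = np.sqrt(np.mean(np.concatenate(tails) ** 2))
    drop = int(np.argmax(np.abs(per_stair - pooled_all)))
    kept = np.concatenate([t for i, t in enumerate(tails) if i != drop])
    return float(np.sqrt(np.mean(kept**2)))


# ---------------------------------------------------------------------------
# trial-table plumbing
# ---------------------------------------------------------------------------


def counts_to_trials(
    counts: Sequence[ConditionCounts],
    participant_id: str = "sim",
    session: int = 2,
    blob_sigma: float = np.nan,
    design: ExperimentDesign | None = None,
    of_interest: int = 1,
) -> pd.DataFrame:
    """Expand per-cell counts into one row per trial."""
    rows = []
    for c in counts:
        delta = design.signed_disparity(c.condition) if design is not None else 0.0
        for x, n, k in zip(c.x, c.n, c.k):
            responses = [1] * int(k) + [0] * int(n - k)
            for r in responses:
                rows.append(
                    (participant_id, session, c.condition, x, delta,
                     blob_sigma, of_interest, r, 0)
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(trials, path) -> None:
    """Write a trial table CSV (schema in ``TRIAL_COLUMNS``).

    ``trials`` is either a DataFrame already in the schema or a sequence
    of ``ConditionCounts`` (expanded via :func:`counts_to_trials`).
    """
    if not isinstance(trials, pd.DataFrame):
        trials = counts_to_trials(trials)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df
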