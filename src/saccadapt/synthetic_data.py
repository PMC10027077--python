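"""Synthetic experiments with known ground truth.

This module emulates a two-experiment, four-condition saccade-adaptation
design so that every downstream stage (saccade detection, exclusion rules,
kinematic decomposition, model fitting, summaries) can be exercised against
a known generative truth, without any recorded data.

Design emulated per experiment x condition:

* 350 automatically paced trials: 50 baseline, 200 adaptation, 100
  retention, in that order, with a set break after every 50th trial.
* An upward saccade target at 10 deg vertical eccentricity.  On adaptation
  trials a first candidate stimulus appears at +/-2 deg horizontal
  eccentricity for 150 ms upon saccade detection, followed after a 200 ms
  gap by a second candidate at the opposite location for 150 ms.  In the
  single-candidate conditions only one of the two is shown.
* The perceptual task (report which side of the task-relevant candidate
  has a gap; four alternatives) yields a correctness flag per adaptation
  trial whose accuracy declines with retinal error.

Sign convention: positive horizontal values point toward the first
candidate stimulus.  Internally everything is simulated in a canonical
frame with the first candidate at +2 deg and reflected afterwards when
``first_candidate_side`` is ``"minus"``; flipping the side therefore flips
every signed output exactly, leaving magnitudes unchanged.

Trial-level amplitudes are generated by running the two-process model
forward (same recursion as :mod:`saccadapt.model`) and adding i.i.d.
Gaussian motor noise.  Gaze traces place a single saccade with a smooth
unimodal speed profile inside a fixation epoch; a skew parameter controls
which fraction of the horizontal displacement falls before the speed peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .errors import DesignError
from .model import ModelParams, forward_simulate

__all__ = [
    "EXPERIMENTS",
    "CONDITIONS",
    "SIDES",
    "ExperimentDesign",
    "GazeTrace",
    "GroundTruth",
    "build_design",
    "simulate_amplitudes",
    "simulate_trial_trace",
    "simulate_responses",
    "inject_artifacts",
    "simulate_participant",
]

EXPERIMENTS = ("small_target", "large_target")
CONDITIONS = (
    "discriminate_1st",
    "discriminate_2nd",
    "discriminate_1st_no_2nd",
    "discriminate_2nd_no_1st",
)
SIDES = ("plus", "minus")

N_BASELINE = 50
N_ADAPTATION = 200
N_RETENTION = 100
N_TRIALS = N_BASELINE + N_ADAPTATION + N_RETENTION

CANDIDATE_ECCENTRICITY_DEG = 2.0
TARGET_VERTICAL_ECCENTRICITY_DEG = 10.0
SAMPLING_RATE_HZ = 1000

#: Stimulus timing in milliseconds.  ``first_candidate_net_viewing_deficit``
#: records that online presentation while the saccade is still in flight
#: shortens the first candidate's net viewing time by roughly 30 ms; it is
#: design metadata only and enters no computation.
TIMING_MS = {
    "first_candidate_duration": 150.0,
    "inter_candidate_delay": 200.0,
    "second_candidate_duration": 150.0,
    "first_candidate_net_viewing_deficit": 30.0,
    "saccade_timeout": 1500.0,
    "response_timeout": 1500.0,
}


@dataclass(frozen=True)
class ExperimentDesign:
    """The full 350-trial schedule for one experiment x condition."""

    experiment_id: str
    condition: str
    first_candidate_side: str
    n_trials: int
    phase: np.ndarray               # per-trial {"baseline","adaptation","retention"}
    loc_first: np.ndarray           # signed deg; NaN where not shown
    loc_second: np.ndarray          # signed deg; NaN where not shown
    loc_task_relevant: np.ndarray   # signed deg; 0 in baseline and retention
    set_break_after: tuple[int, ...]  # 1-based trial numbers followed by a break
    timing_ms: dict = field(default_factory=lambda: dict(TIMING_MS))
    target_vertical_eccentricity: float = TARGET_VERTICAL_ECCENTRICITY_DEG
    sampling_rate_hz: int = SAMPLING_RATE_HZ

    @property
    def side_sign(self) -> int:
        return 1 if self.first_candidate_side == "plus" else -1


@dataclass(frozen=True)
class GazeTrace:
    """Sampled gaze position over one trial at 1 ms resolution.

    Positions are degrees of visual angle with fixation at the origin,
    positive y toward the saccade target and positive x toward the first
    candidate stimulus.  Blinks are represented as NaN samples.
    """

    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    sample_interval_ms: float = 1.0

    def __post_init__(self) -> None:
        if not (len(self.t_ms) == len(self.x_deg) == len(self.y_deg)):
            raise ValueError("t, x and y must share a length")
        dt = np.diff(self.t_ms)
        if len(dt) and not np.allclose(dt, self.sample_interval_ms):
            raise ValueError("t must increase in fixed sample steps")

    def __len__(self) -> int:
        return len(self.t_ms)

    def segment(self, start_ms: float, stop_ms: float) -> "GazeTrace":
        """Sub-trace with ``start_ms <= t <= stop_ms``."""
        keep = (self.t_ms >= start_ms) & (self.t_ms <= stop_ms)
        return GazeTrace(
            self.t_ms[keep], self.x_deg[keep], self.y_deg[keep],
            self.sample_interval_ms,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters for one synthetic participant."""

    params_true: ModelParams
    noise_sd: float = 0.5            # trial-to-trial amplitude noise, deg
    acc_frac_true: float = 0.5       # horizontal displacement before peak speed
    psychometric: dict = field(
        default_factory=lambda: {"asymptote": 0.9, "chance": 0.25, "scale": 1.0}
    )
    artifact_rates: dict = field(
        default_factory=lambda: {"blink": 0.0, "timeout": 0.0, "hypometric": 0.0}
    )

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.acc_frac_true <= 1.0:
            raise ValueError("acc_frac_true must lie in [0, 1]")
        if not 0.25 <= self.psychometric["asymptote"] <= 1.0:
            raise ValueError("psychometric asymptote must lie in [0.25, 1]")

    def to_json(self, seed=None) -> str:
        p = self.params_true
        payload = {
            "params_true": {"w": p.w, "r": p.r, "d": p.d, "init": p.init},
            "noise_sd": self.noise_sd,
            "acc_frac_true": self.acc_frac_true,
            "psychometric": self.psychometric,
            "artifact_rates": self.artifact_rates,
            "seed": seed,
        }
        return json.dumps(payload, indent=2)


def build_design(
    experiment_id: str, condition: str, first_candidate_side: str
) -> ExperimentDesign:
    """Build the deterministic 350-trial schedule for one condition.

    The first candidate sits at ``+/-2`` deg (sign per
    ``first_candidate_side``) and the second at the opposite location.  In
    the ``*_no_*`` conditions only the discriminated candidate is shown.
    ``loc_task_relevant`` is the location of the candidate that carries the
    perceptual task on adaptation trials and 0 elsewhere.
    """
    if experiment_id not in EXPERIMENTS:
        raise DesignError(f"unknown experiment_id {experiment_id!r}")
    if condition not in CONDITIONS:
        raise DesignError(f"unknown condition {condition!r}")
    if first_candidate_side not in SIDES:
        raise DesignError(f"unknown first_candidate_side {first_candidate_side!r}")

    sign = 1 if first_candidate_side == "plus" else -1
    loc1 = sign * CANDIDATE_ECCENTRICITY_DEG
    loc2 = -loc1

    phase = np.array(
        ["baseline"] * N_BASELINE
        + ["adaptation"] * N_ADAPTATION
        + ["retention"] * N_RETENTION
    )
    adapt = phase == "adaptation"

    loc_first = np.full(N_TRIALS, np.nan)
    loc_second = np.full(N_TRIALS, np.nan)
    if condition != "discriminate_2nd_no_1st":
        loc_first[adapt] = loc1
    if condition != "discriminate_1st_no_2nd":
        loc_second[adapt] = loc2

    task_loc = loc1 if condition in ("discriminate_1st", "discriminate_1st_no_2nd") else loc2
    loc_task_relevant = np.zeros(N_TRIALS)
    loc_task_relevant[adapt] = task_loc

    breaks = tuple(range(50, N_TRIALS + 1, 50))

    return ExperimentDesign(
        experiment_id=experiment_id,
        condition=condition,
        first_candidate_side=first_candidate_side,
        n_trials=N_TRIALS,
        phase=phase,
        loc_first=loc_first,
        loc_second=loc_second,
        loc_task_relevant=loc_task_relevant,
        set_break_after=breaks,
    )


def _canonical_design(design: ExperimentDesign) -> ExperimentDesign:
    """The same design with the first candidate on the plus side."""
    if design.first_candidate_side == "plus":
        return design
    return build_design(design.experiment_id, design.condition, "plus")


def simulate_amplitudes(
    design: ExperimentDesign, ground_truth: GroundTruth, seed=None,
    set_break_offset: float = 0.0,
) -> np.ndarray:
    """Per-trial observed horizontal amplitudes, baseline-referenced degrees.

    Runs the two-process recursion forward over the full 350-trial
    task-relevant location sequence (0 in baseline and retention, so
    retention decays toward zero at the model's own carry-over rate) and
    adds i.i.d. Gaussian motor noise.  The noise is drawn in the canonical
    frame, so flipping ``first_candidate_side`` under the same seed flips
    the output exactly.

    ``set_break_offset`` optionally adds a transient amplitude offset
    (canonical-frame degrees) to the first trial after every set break,
    emulating the rapid amplitude changes seen at set-break onsets; it is
    0 by default and not part of the model dynamics.
    """
    canonical = _canonical_design(design)
    state = forward_simulate(ground_truth.params_true, canonical.loc_task_relevant)
    amps = state.hor_amp.copy()
    if set_break_offset != 0.0:
        first_after = [b for b in design.set_break_after if b < design.n_trials]
        amps[first_after] += set_break_offset
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, ground_truth.noise_sd, size=design.n_trials)
    return design.side_sign * (amps + noise)


def _beta_shape_for_acc_frac(acc_frac: float, concentration: float = 6.0):
    """Beta(a, b) velocity-profile shape whose pre-peak area is acc_frac.

    With ``a + b = concentration`` fixed, the profile peaks at
    ``m = (a-1)/(a+b-2)`` and the displacement fraction accumulated before
    the peak is the regularised incomplete beta ``I_m(a, b)``; solve for
    ``a``.  acc_frac is clipped away from 0 and 1 where the profile
    degenerates.
    """
    c = concentration
    frac = float(np.clip(acc_frac, 0.02, 0.98))

    def pre_peak_area(a: float) -> float:
        mode = (a - 1.0) / (c - 2.0)
        return special.betainc(a, c - a, mode)

    a = optimize.brentq(lambda a: pre_peak_area(a) - frac, 1.0 + 1e-9, c - 1.0 - 1e-9)
    return a, c - a


def simulate_trial_trace(
    total_horizontal_amp: float,
    vertical_amp: float,
    acc_frac: float,
    duration_ms: float = 50.0,
    seed=None,
    *,
    latency_ms: float = 200.0,
    trial_length_ms: float | None = None,
    start_xy: tuple[float, float] = (0.0, 0.0),
    position_noise_sd: float = 0.0,
    concentration: float = 6.0,
) -> GazeTrace:
    """Generate a trial trace containing a single saccade.

    The eye fixates ``start_xy``, launches after ``latency_ms`` into a
    saccade of ``duration_ms`` with a smooth unimodal beta-family speed
    profile, and fixates the landing point for the rest of the trial.
    Horizontal and vertical components share the time course, so the speed
    profile is unimodal in 2-D and the fraction of horizontal displacement
    accumulated before the speed peak equals ``acc_frac`` (the saccade
    onset is phase-shifted so the continuous-time peak falls exactly on a
    1 ms sample).

    ``position_noise_sd`` adds white positional noise (degrees) for
    robustness checks; the default trace is noiseless.
    """
    if not 0.0 <= acc_frac <= 1.0:
        raise ValueError(f"acc_frac must lie in [0, 1], got {acc_frac}")
    if duration_ms < 20.0:
        raise ValueError(f"duration_ms must be >= 20, got {duration_ms}")

    a, b = _beta_shape_for_acc_frac(acc_frac, concentration)
    mode = (a - 1.0) / (a + b - 2.0)

    if trial_length_ms is None:
        trial_length_ms = latency_ms + duration_ms + 250.0
    t = np.arange(0.0, trial_length_ms, 1.0)

    # Shift onset so that the continuous-time speed peak lands on a sample.
    t_peak = latency_ms + mode * duration_ms
    onset = latency_ms + (np.round(t_peak) - t_peak)

    tau = np.clip((t - onset) / duration_ms, 0.0, 1.0)
    s = special.betainc(a, b, tau)   # normalised displacement profile

    x = start_xy[0] + total_horizontal_amp * s
    y = start_xy[1] + vertical_amp * s
    if position_noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, position_noise_sd, size=t.shape)
        y = y + rng.normal(0.0, position_noise_sd, size=t.shape)

    return GazeTrace(t_ms=t, x_deg=x, y_deg=y)


def simulate_responses(retinal_errors, psychometric: dict, seed=None) -> np.ndarray:
    """Simulate 4-alternative perceptual correctness per trial.

    ``P(correct | e) = chance + (asymptote - chance) * g(|e|)`` with the
    logistic-family decline ``g(e) = 2 / (1 + exp(e / scale))``, which is 1
    at zero retinal error and falls monotonically to 0, so accuracy decays
    from the asymptote to the 4-alternative chance level of 0.25.
    """
    e = np.abs(np.asarray(retinal_errors, dtype=float))
    chance = psychometric.get("chance", 0.25)
    asymptote = psychometric["asymptote"]
    scale = psychometric.get("scale", 1.0)
    g = 2.0 / (1.0 + np.exp(e / scale))
    p = chance + (asymptote - chance) * g
    rng = np.random.default_rng(seed)
    return rng.random(size=e.shape) < p


def response_probability(retinal_errors, psychometric: dict) -> np.ndarray:
    """The correctness probability used by :func:`simulate_responses`."""
    e = np.abs(np.asarray(retinal_errors, dtype=float))
    chance = psychometric.get("chance", 0.25)
    asymptote = psychometric["asymptote"]
    scale = psychometric.get("scale", 1.0)
    return chance + (asymptote - chance) * 2.0 / (1.0 + np.exp(e / scale))


HYPOMETRIC_VERTICAL_AMP_DEG = 4.0  # < 50% of the 10 deg target distance


def inject_artifacts(trials: pd.DataFrame, artifact_rates: dict, seed=None) -> pd.DataFrame:
    """Independently doctor trials with blink / timeout / hypometric artifacts.

    Each artifact type is applied per trial with its own rate.  The
    injected markers are exactly the fields the exclusion rules read:

    * ``blink``: sets ``blink_in_window`` True;
    * ``timeout``: no primary saccade within 1,500 ms — latency and all
      saccade measurements become NaN;
    * ``hypometric``: the vertical amplitude drops below half the target
      distance.

    Ground-truth indicator columns ``artifact_*`` record which trials were
    doctored.  Rates of zero leave the table unchanged.
    """
    for name, rate in artifact_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"artifact rate {name}={rate} outside [0, 1]")
    out = trials.copy()
    n = len(out)
    rng = np.random.default_rng(seed)
    hit = {
        name: rng.random(n) < artifact_rates.get(name, 0.0)
        for name in ("blink", "timeout", "hypometric")
    }
    for name, mask in hit.items():
        out[f"artifact_{name}"] = mask

    if hit["blink"].any():
        out.loc[hit["blink"], "blink_in_window"] = True
    if hit["timeout"].any():
        cols = [c for c in ("primary_latency_ms", "hor_amp", "vert_amp",
                            "acc_disp", "dec_disp") if c in out.columns]
        out.loc[hit["timeout"], cols] = np.nan
    if hit["hypometric"].any():
        out.loc[hit["hypometric"], "vert_amp"] = HYPOMETRIC_VERTICAL_AMP_DEG
    return out


def simulate_participant(
    design: ExperimentDesign,
    ground_truth: GroundTruth,
    seed=None,
    participant_id: str = "sim01",
    *,
    with_traces: bool = False,
    saccade_duration_ms: float = 50.0,
    latency_mean_ms: float = 200.0,
    latency_sd_ms: float = 50.0,
):
    """Simulate one participant's full trial table (and optionally traces).

    Returns ``(trials, traces)`` where ``trials`` is a tidy one-row-per-
    trial DataFrame and ``traces`` maps 1-based trial index to
    :class:`GazeTrace` (empty dict unless ``with_traces``).

    All signed quantities are produced in the canonical plus-side frame
    and reflected afterwards, so flipping ``first_candidate_side`` under a
    fixed seed mirrors every signed column exactly.  Vertical amplitudes
    scatter around the 10 deg target.  The horizontal acceleration/
    deceleration displacement split follows ``acc_frac_true``.  Perceptual
    responses exist on adaptation trials only; retinal error is taken
    relative to the task-relevant candidate location.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4)

    canonical = _canonical_design(design)
    hor_canonical = simulate_amplitudes(canonical, ground_truth, seed=sub_seeds[0])
    sign = design.side_sign
    hor = sign * hor_canonical

    vert = TARGET_VERTICAL_ECCENTRICITY_DEG + rng.normal(
        0.0, 0.3, size=design.n_trials
    )
    latency = np.clip(
        rng.normal(latency_mean_ms, latency_sd_ms, size=design.n_trials), 80.0, 1400.0
    )

    acc = ground_truth.acc_frac_true * hor
    dec = hor - acc

    adapt = design.phase == "adaptation"
    retinal_error = np.abs(hor - design.loc_task_relevant)
    correct = simulate_responses(
        retinal_error, ground_truth.psychometric, seed=sub_seeds[1]
    )
    response_correct = np.where(adapt, correct, np.nan)

    trials = pd.DataFrame(
        {
            "participant_id": participant_id,
            "experiment": design.experiment_id,
            "condition": design.condition,
            "trial_index": np.arange(1, design.n_trials + 1),
            "phase": design.phase,
            "loc_first": design.loc_first,
            "loc_second": design.loc_second,
            "loc_task_relevant": design.loc_task_relevant,
            "hor_amp": hor,
            "vert_amp": vert,
            "acc_disp": acc,
            "dec_disp": dec,
            "primary_latency_ms": latency,
            "blink_in_window": False,
            "fixation_max_dev_deg": np.abs(rng.normal(0.0, 0.3, size=design.n_trials)),
            "response_given": adapt,
            "response_correct": response_correct,
        }
    )
    trials = inject_artifacts(trials, ground_truth.artifact_rates, seed=sub_seeds[2])

    traces: dict[int, GazeTrace] = {}
    if with_traces:
        for i in range(design.n_trials):
            if not np.isfinite(trials.loc[i, "hor_amp"]):
                continue
            # acc_frac is defined for the canonical-frame amplitude; the
            # reflection below flips x, keeping the pre/post-peak split.
            tr = simulate_trial_trace(
                total_horizontal_amp=float(hor_canonical[i]),
                vertical_amp=float(trials.loc[i, "vert_amp"]),
                acc_frac=ground_truth.acc_frac_true,
                duration_ms=saccade_duration_ms,
                latency_ms=float(trials.loc[i, "primary_latency_ms"]),
            )
            traces[i + 1] = GazeTrace(tr.t_ms, sign * tr.x_deg, tr.y_deg)
    return trials, traces
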