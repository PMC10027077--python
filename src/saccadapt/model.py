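"""Two-process state-space model of saccade adaptation.

The model describes the horizontal amplitude component of primary saccades
in a double-step-like adaptation paradigm as a weighted mixture of two
learning processes.  On every trial ``n`` the predicted horizontal
amplitude is

    horAmp_n = w * strategic_n + (1 - w) * gradual_n

where the *strategic* process re-aims voluntarily and compensates the full
error relative to the adaptation target,

    strategic_n = loc_{n-1} * d

and the *gradual* process corrects a fraction ``r`` of the previous error,

    gradual_n = horAmp_{n-1} - r * (horAmp_{n-1} - loc_{n-1} * d)

``loc_n`` is the signed horizontal location of the task-relevant candidate
stimulus on trial ``n`` (zero on trials without candidates) and the binary
parameter ``d`` selects whether adaptation is directed toward the
task-relevant (+1) or the task-irrelevant (-1) candidate.

Substituting the two process equations into the mixture shows that the
predicted series obeys a single linear recursion

    horAmp_n = a * horAmp_{n-1} + (1 - a) * loc_{n-1} * d,
    a = (1 - w) * (1 - r)

so the trajectory (and hence any least-squares objective) depends on
``(w, r)`` only through the retention factor ``a``.  Individual values of
``w`` and ``r`` are identified only up to the ridge
``(1 - w)(1 - r) = a``; :func:`fit` therefore also reports the identifiable
effective learning rate ``1 - a``.  See the package methods documentation
for a discussion.

Fitting follows a multi-start scheme: ``d`` is enumerated exhaustively over
{-1, +1}, and for each sign the bounded least-squares problem over
``(w, r)`` is restarted from 101 starting values of ``r``.  The winner is
selected by BIC.  The model is fitted to baseline and adaptation trials
only, never to retention trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .errors import (
    DegenerateFitWarning,
    EmptySequenceError,
    FitError,
    InsufficientTrialsError,
    NoBaselineTrialsError,
)

__all__ = [
    "ModelParams",
    "ModelState",
    "StartRecord",
    "ModelFit",
    "forward_simulate",
    "objective",
    "bic",
    "fit",
]

#: Number of free parameters reported to the BIC: w, r and d.  d is found
#: by exhaustive enumeration rather than continuous optimisation, but it is
#: free in the statistical sense.  Because every restart shares the same k
#: and n, the choice cannot change which restart wins.
K_PARAMS = 3


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-process model.

    Parameters
    ----------
    w : float
        Mixture weight of the strategic process, in [0, 1].
    r : float
        Learning rate of the gradual process, in [0, 1].
    d : int
        Adaptation-target choice: +1 adapts toward the task-relevant
        candidate location, -1 toward its mirror image.
    init : float
        Predicted horizontal amplitude on trial 1, in degrees.  When
        fitting, this is fixed to the participant's mean baseline
        amplitude and is not a free parameter.
    """

    w: float
    r: float
    d: int
    init: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must lie in [0, 1], got {self.r}")
        if self.d not in (-1, 1):
            raise ValueError(f"d must be -1 or +1, got {self.d}")

    @property
    def retention_factor(self) -> float:
        """The identifiable trial-to-trial carry-over ``(1-w)(1-r)``."""
        return (1.0 - self.w) * (1.0 - self.r)

    @property
    def effective_rate(self) -> float:
        """Effective per-trial learning rate ``1 - (1-w)(1-r)``."""
        return 1.0 - self.retention_factor


@dataclass(frozen=True)
class ModelState:
    """Per-trial process states and model output, all in degrees."""

    strategic: np.ndarray
    gradual: np.ndarray
    hor_amp: np.ndarray

    def __len__(self) -> int:
        return len(self.hor_amp)


@dataclass(frozen=True)
class StartRecord:
    """Outcome of one optimisation restart."""

    d: int
    r_start: float
    w_start: float
    w_hat: float
    r_hat: float
    rss: float
    bic: float
    success: bool
    message: str = ""


@dataclass(frozen=True)
class ModelFit:
    """Result of the multi-start fit."""

    params: ModelParams
    rss: float
    n_fitted: int
    k_params: int
    bic: float
    predicted: ModelState
    n_starts: int
    starts: tuple[StartRecord, ...]
    converged: bool
    degenerate: bool

    @property
    def effective_rate(self) -> float:
        return self.params.effective_rate


def _forward_horamp(a: float, target: np.ndarray, init: float) -> np.ndarray:
    """Fast forward pass of hor_amp[n] = a*hor_amp[n-1] + (1-a)*target[n-1]."""
    n = target.shape[0]
    if n == 1:
        return np.array([init])
    drive = (1.0 - a) * target[:-1]
    rest, _ = signal.lfilter([1.0], [1.0, -a], drive, zi=np.array([a * init]))
    out = np.empty(n)
    out[0] = init
    out[1:] = rest
    return out


def forward_simulate(params: ModelParams, loc_sequence) -> ModelState:
    """Deterministically simulate the model over a candidate-location series.

    ``loc_sequence`` is the per-trial signed horizontal location of the
    task-relevant candidate stimulus in degrees (0 on trials without
    candidates), covering baseline and adaptation trials in design order.

    The recursion is run in pure simulation mode: the previous *model
    output* feeds the next update, never an observed amplitude.  On trial 1
    both process states are set to ``init`` so that the mixture identity
    ``hor_amp = w*strategic + (1-w)*gradual`` holds on every trial.
    """
    loc = np.asarray(loc_sequence, dtype=float)
    if loc.ndim != 1:
        raise ValueError("loc_sequence must be one-dimensional")
    if loc.size == 0:
        raise EmptySequenceError("loc_sequence is empty")

    target = loc * params.d
    hor_amp = _forward_horamp(params.retention_factor, target, params.init)

    strategic = np.empty_like(hor_amp)
    strategic[0] = params.init
    strategic[1:] = target[:-1]

    gradual = np.empty_like(hor_amp)
    gradual[0] = params.init
    gradual[1:] = hor_amp[:-1] - params.r * (hor_amp[:-1] - target[:-1])

    return ModelState(strategic=strategic, gradual=gradual, hor_amp=hor_amp)


def one_step_ahead(params: ModelParams, loc_sequence, observed) -> np.ndarray:
    """Teacher-forced predictions: each update reads the observed history.

    Sensitivity-analysis variant of :func:`forward_simulate` in which the
    previous *observed* amplitude, not the previous model output, feeds
    the update.  Trial 1 predicts ``init``.  Note that the prediction
    still depends on ``(w, r)`` only through ``(1-w)(1-r)``, so the
    identifiability situation is unchanged.
    """
    loc = np.asarray(loc_sequence, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if loc.size == 0:
        raise EmptySequenceError("loc_sequence is empty")
    if loc.shape != obs.shape:
        raise ValueError("loc_sequence and observed must share a shape")
    a = params.retention_factor
    pred = np.empty_like(obs)
    pred[0] = params.init
    pred[1:] = a * obs[:-1] + (1.0 - a) * loc[:-1] * params.d
    return pred


def objective(predicted, observed, include_mask) -> float:
    """Sum of squared residuals over the masked-in trials.

    ``include_mask`` selects the trials that enter the objective; it must
    exclude trials removed by preprocessing and all retention trials.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    mask = np.asarray(include_mask, dtype=bool)
    if not predicted.shape == observed.shape == mask.shape:
        raise ValueError("predicted, observed and include_mask must share a shape")
    if not mask.any():
        raise InsufficientTrialsError("include_mask selects zero trials")
    resid = observed[mask] - predicted[mask]
    return float(resid @ resid)


def bic(rss: float, n: int, k: int) -> float:
    """Bayesian information criterion under a Gaussian profile likelihood.

    ``n * ln(rss / n) + k * ln(n)``; lower is better.  A perfect fit
    (``rss == 0``) returns ``-inf`` so that it wins every comparison.
    """
    if n <= k:
        raise ValueError(f"bic requires n > k, got n={n}, k={k}")
    if rss < 0:
        raise ValueError("rss must be nonnegative")
    if rss == 0.0:
        return -np.inf
    return float(n * np.log(rss / n) + k * np.log(n))


def _start_values_r(n_starts: int, rng: np.random.Generator) -> np.ndarray:
    """Evenly spaced starting values of r on [0, 1] with a small jitter."""
    base = np.linspace(0.0, 1.0, n_starts)
    if n_starts > 1:
        jitter = rng.normal(0.0, 0.25 / (n_starts - 1), size=n_starts)
        base = np.clip(base + jitter, 0.0, 1.0)
    return base


def fit(
    observed,
    design,
    exclusion_mask=None,
    n_starts: int = 101,
    seed: int | None = None,
    *,
    w_start: float = 0.5,
    min_adaptation_trials: int = 10,
    tol: float = 1e-8,
) -> ModelFit:
    """Fit the model to one participant's observed horizontal amplitudes.

    Parameters
    ----------
    observed : array-like
        Per-trial observed horizontal amplitudes (degrees), design order,
        covering at least the baseline and adaptation phases.
    design : object
        Anything exposing per-trial ``phase`` labels (``"baseline"``,
        ``"adaptation"``, ``"retention"``) and ``loc_task_relevant``
        (signed degrees, 0 where no candidate was shown).
    exclusion_mask : array-like of bool, optional
        True marks trials excluded by preprocessing.  Excluded trials are
        removed from the objective only; the recursion still runs over the
        full design-ordered location sequence, because the participant
        experienced those trials.
    n_starts : int
        Number of restarts per sign of ``d`` (starting values of ``r``).
    seed : int, optional
        Seed for the start-value jitter.

    Notes
    -----
    ``init`` is fixed to the mean observed amplitude over usable baseline
    trials, not fitted.  ``d`` is handled by exhaustive enumeration.
    Retention trials never enter the objective and are not simulated.
    """
    observed = np.asarray(observed, dtype=float)
    phase = np.asarray(design.phase)
    loc = np.asarray(design.loc_task_relevant, dtype=float)
    if observed.shape != phase.shape:
        raise ValueError("observed and design phases must share a length")
    if exclusion_mask is None:
        exclusion_mask = np.zeros(observed.shape, dtype=bool)
    excluded = np.asarray(exclusion_mask, dtype=bool)

    usable = ~excluded & np.isfinite(observed)
    base_usable = usable & (phase == "baseline")
    if not base_usable.any():
        raise NoBaselineTrialsError("no usable baseline trial to set init")
    init = float(observed[base_usable].mean())

    adapt_usable = usable & (phase == "adaptation")
    if adapt_usable.sum() < min_adaptation_trials:
        raise InsufficientTrialsError(
            f"need >= {min_adaptation_trials} usable adaptation trials, "
            f"got {int(adapt_usable.sum())}"
        )

    fitted_phase = phase != "retention"
    loc_fit = np.ascontiguousarray(loc[fitted_phase])
    obs_fit = np.ascontiguousarray(observed[fitted_phase])
    mask_fit = usable[fitted_phase]
    n_fitted = int(mask_fit.sum())
    obs_masked = obs_fit[mask_fit]

    rng = np.random.default_rng(seed)
    r_starts = _start_values_r(n_starts, rng)

    def rss_for(w: float, r: float, target: np.ndarray) -> float:
        a = (1.0 - w) * (1.0 - r)
        pred = _forward_horamp(a, target, init)
        resid = obs_masked - pred[mask_fit]
        return float(resid @ resid)

    records: list[StartRecord] = []
    for d in (1, -1):
        target = loc_fit * d
        fun = lambda p: rss_for(p[0], p[1], target)  # noqa: E731
        for r0 in r_starts:
            res = optimize.minimize(
                fun,
                x0=np.array([w_start, r0]),
                method="L-BFGS-B",
                bounds=[(0.0, 1.0), (0.0, 1.0)],
                options={"ftol": tol, "gtol": tol},
            )
            rec_rss = float(res.fun)
            records.append(
                StartRecord(
                    d=d,
                    r_start=float(r0),
                    w_start=w_start,
                    w_hat=float(res.x[0]),
                    r_hat=float(res.x[1]),
                    rss=rec_rss,
                    bic=bic(rec_rss, n_fitted, K_PARAMS),
                    success=bool(res.success),
                    message=str(res.message),
                )
            )

    winners = [rec for rec in records if rec.success]
    if not winners:
        raise FitError("optimizer failed to converge on every restart")
    best = min(winners, key=lambda rec: rec.bic)

    params = ModelParams(w=best.w_hat, r=best.r_hat, d=best.d, init=init)
    predicted = forward_simulate(params, loc_fit)

    # The fit is degenerate when it is no better than the constant model
    # (a = 1): flat data carry no learning signal, so w and r are entirely
    # unidentified, not merely ridge-coupled.
    resid_const = obs_masked - init
    rss_const = float(resid_const @ resid_const)
    degenerate = best.rss >= rss_const - 1e-9 * max(rss_const, 1.0)
    if degenerate:
        warnings.warn(
            "fit no better than a constant model: w and r are unidentifiable",
            DegenerateFitWarning,
            stacklevel=2,
        )

    return ModelFit(
        params=params,
        rss=best.rss,
        n_fitted=n_fitted,
        k_params=K_PARAMS,
        bic=best.bic,
        predicted=predicted,
        n_starts=n_starts,
        starts=tuple(records),
        converged=True,
        degenerate=degenerate,
    )
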