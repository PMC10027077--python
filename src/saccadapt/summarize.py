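"""Descriptive surfaces: moving averages, block statistics, cohort tables.

Blocks are runs of 50 trials separated by set breaks.  The moving average
is asymmetric and restarts in every block: the first bin of a block
averages the 2 trials at and after the current sample, the second bin 4
trials, and every later bin 6 trials, with windows truncated at the block
end.  This right-sided scheme accentuates the rapid amplitude changes at
set-break onsets.  Excluded trials (NaN) are skipped, not interpolated.

Per-participant significance uses the two-sided 95% t-interval of the
trials in a block: an adaptation effect counts as significant when the
interval excludes zero, and its direction is the sign of the block mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InsufficientTrialsError
from .synthetic_data import ExperimentDesign, N_BASELINE, N_ADAPTATION

__all__ = [
    "BlockSummary",
    "moving_average",
    "block_stats",
    "adaptation_summary",
    "psychometric_summary",
]

BLOCK_SIZE = 50


@dataclass(frozen=True)
class BlockSummary:
    """Mean, 95% CI, significance and direction of one 50-trial block."""

    block_id: int
    mean: float
    ci95_low: float
    ci95_high: float
    n_used: int

    @property
    def significant(self) -> bool:
        return not (self.ci95_low <= 0.0 <= self.ci95_high)

    @property
    def direction_sign(self) -> int:
        if not self.significant:
            return 0
        return 1 if self.mean > 0 else -1


def moving_average(series, block_size: int = BLOCK_SIZE) -> np.ndarray:
    """Asymmetric right-sided moving average, restarted at block bounds.

    Window widths are 2 trials for the first bin of a block, 4 for the
    second, 6 afterwards; windows truncate at the block end.  NaN entries
    (excluded trials) are skipped; a window with no usable trial yields
    NaN.  Output has the same length as the input, one bin per trial.
    """
    x = np.asarray(series, dtype=float)
    out = np.full_like(x, np.nan)
    for b0 in range(0, len(x), block_size):
        b1 = min(b0 + block_size, len(x))
        for i in range(b0, b1):
            width = 2 if i == b0 else 4 if i == b0 + 1 else 6
            window = x[i:min(i + width, b1)]
            good = np.isfinite(window)
            if good.any():
                out[i] = window[good].mean()
    return out


def block_stats(values, block_id: int = 0) -> BlockSummary:
    """Mean and two-sided 95% t-interval over a block's usable trials."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise InsufficientTrialsError(f"block needs >= 2 usable trials, got {n}")
    mean = float(x.mean())
    sem = float(x.std(ddof=1)) / np.sqrt(n)
    if sem == 0.0:
        lo = hi = mean
    else:
        tcrit = stats.t.ppf(0.975, df=n - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    return BlockSummary(block_id=block_id, mean=mean, ci95_low=float(lo),
                        ci95_high=float(hi), n_used=n)


LAST_ADAPTATION_BLOCK = slice(N_BASELINE + N_ADAPTATION - BLOCK_SIZE,
                              N_BASELINE + N_ADAPTATION)
FIRST_RETENTION_BLOCK = slice(N_BASELINE + N_ADAPTATION,
                              N_BASELINE + N_ADAPTATION + BLOCK_SIZE)


def adaptation_summary(per_participant_series: dict, design: ExperimentDesign):
    """Cohort summary of the last adaptation and first retention block.

    ``per_participant_series`` maps participant id to a design-ordered,
    baseline-corrected amplitude series (NaN = excluded).  Returns
    ``(participants, condition)``:

    * ``participants`` — one row per participant x block with the block
      mean, its 95% CI, the significance flag and the direction sign;
    * ``condition`` — one row per block with the group mean, its 95%
      t-interval across participants, and tallies of participants by
      significance x direction (the "18 out of 21 significant changes were
      positive"-style counts).

    Invariant to participant ordering.
    """
    if not per_participant_series:
        raise InsufficientTrialsError("need at least one participant")

    rows = []
    for pid in sorted(per_participant_series):
        series = np.asarray(per_participant_series[pid], dtype=float)
        for label, sl in (("last_adaptation", LAST_ADAPTATION_BLOCK),
                          ("first_retention", FIRST_RETENTION_BLOCK)):
            bs = block_stats(series[sl], block_id=sl.start // BLOCK_SIZE)
            rows.append(
                {
                    "participant_id": pid,
                    "experiment": design.experiment_id,
                    "condition": design.condition,
                    "block": label,
                    "mean": bs.mean,
                    "ci95_low": bs.ci95_low,
                    "ci95_high": bs.ci95_high,
                    "n_used": bs.n_used,
                    "significant": bs.significant,
                    "direction_sign": bs.direction_sign,
                }
            )
    participants = pd.DataFrame(rows)

    cond_rows = []
    for label, sub in participants.groupby("block", sort=False):
        bs = block_stats(sub["mean"].to_numpy())
        n_sig = int(sub["significant"].sum())
        cond_rows.append(
            {
                "experiment": design.experiment_id,
                "condition": design.condition,
                "block": label,
                "n_participants": len(sub),
                "group_mean": bs.mean,
                "ci95_low": bs.ci95_low,
                "ci95_high": bs.ci95_high,
                "n_significant": n_sig,
                "n_significant_positive": int(
                    ((sub["direction_sign"] == 1) & sub["significant"]).sum()
                ),
                "n_significant_negative": int(
                    ((sub["direction_sign"] == -1) & sub["significant"]).sum()
                ),
            }
        )
    condition = pd.DataFrame(cond_rows)
    return participants, condition


def psychometric_summary(responses, retinal_errors, bin_edges):
    """Proportion correct by retinal-error bin, with binomial CIs.

    Returns ``(table, decline)`` where ``table`` has one row per bin
    (center, n, proportion correct, 95% Wilson CI; empty bins are reported
    with NaN, not zero) and ``decline`` carries the Spearman rank
    correlation of bin accuracy against bin center over the populated
    bins — its sign is the monotone-decline check statistic.
    """
    correct = np.asarray(responses, dtype=float)
    err = np.abs(np.asarray(retinal_errors, dtype=float))
    good = np.isfinite(correct) & np.isfinite(err)
    correct, err = correct[good], err[good]

    edges = np.asarray(bin_edges, dtype=float)
    if err.size and (err.min() < edges[0] or err.max() > edges[-1]):
        raise ValueError("bin_edges must cover the observed error range")

    idx = np.clip(np.digitize(err, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        center = 0.5 * (edges[b] + edges[b + 1])
        if n == 0:
            rows.append({"bin_center": center, "n": 0, "prop_correct": np.nan,
                         "ci95_low": np.nan, "ci95_high": np.nan})
            continue
        k = int(correct[sel].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append({"bin_center": center, "n": n, "prop_correct": k / n,
                     "ci95_low": float(lo), "ci95_high": float(hi)})
    table = pd.DataFrame(rows)

    filled = table[table["n"] > 0]
    if len(filled) >= 3 and filled["prop_correct"].nunique() > 1:
        rho, pval = stats.spearmanr(filled["bin_center"], filled["prop_correct"])
        decline = {"spearman_rho": float(rho), "p_value": float(pval),
                   "declining": bool(rho < 0)}
    else:
        decline = {"spearman_rho": np.nan, "p_value": np.nan, "declining": None}
    return table, decline
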