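"""Button-press scoring and behavioral summary measures.

A press within (onset + 100, onset + 1100] ms after a target counts as a hit
(reaction time = press − onset); a press in the same window after a random
standard counts as a false alarm on that standard. Presses after predictive
standards are tallied separately ("FAs inside the predictive sequence") and
excluded from the reported FA percentage, whose denominator is the number of
random standards presented. Sensitivity is

    d' = Phi^-1(hit rate to randTs) − Phi^-1(FA rate outside the sequence)

with rates of exactly 0 or 1 clamped to 1/(2N) and 1 − 1/(2N), N being the
corresponding trial count (standard signal-detection edge correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import paradigm

logger = logging.getLogger(__name__)

#: Response window relative to stimulus onset, ms.
RESPONSE_WINDOW_MS = (100.0, 1100.0)


@dataclass
class BehaviorSummary:
    """Per-subject behavioral summary (percentages in [0, 100], RT in ms)."""

    pct_hits_randT: float
    pct_hits_predT: float
    pct_fa: float                    # FAs outside the predictive sequence
    pct_fa_inside: float             # FAs on predS1–predS3 (reported separately)
    mean_rt_randT: float
    mean_rt_predT: float
    dprime: float
    rt_benefit: float                # mean_rt_randT − mean_rt_predT
    n_randT: int
    n_predT: int
    n_random_standards: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def score_responses(events: pd.DataFrame, presses: pd.DataFrame,
                    window_ms: tuple[float, float] = RESPONSE_WINDOW_MS
                    ) -> pd.DataFrame:
    """Score each press against the stimulus stream.

    Returns a per-trial outcome table aligned with ``events``: columns
    ``outcome`` in {hit, miss, fa, none} and ``rt_ms`` (hits only, NaN
    otherwise). Each press scores at most one trial; when several trials are
    eligible the earliest eligible target wins, then the earliest standard.
    Presses before the first stimulus or in no stimulus' window are ignored
    with a logged warning.
    """
    lo, hi = window_ms
    outcome = np.full(len(events), "none", dtype=object)
    rt = np.full(len(events), np.nan)
    cats = events["category"].astype(str).to_numpy()
    is_target = np.isin(cats, paradigm.TARGET_CATEGORIES)
    outcome[is_target] = "miss"

    for block, blk_presses in presses.groupby("block"):
        blk_idx = events.index[events["block"] == block].to_numpy()
        onsets = events.loc[blk_idx, "onset_ms"].to_numpy()
        for t in np.sort(blk_presses["press_time_ms"].to_numpy()):
            if len(onsets) == 0 or t <= onsets[0]:
                logger.warning("press at %.1f ms (block %s) before first "
                               "stimulus; ignored", t, block)
                continue
            in_window = (t > onsets + lo) & (t <= onsets + hi)
            eligible = np.flatnonzero(in_window)
            # prefer the earliest unclaimed target, then earliest unclaimed standard
            chosen = None
            for j in eligible:
                gi = blk_idx[j]
                if is_target[events.index.get_loc(gi)] and outcome[events.index.get_loc(gi)] == "miss":
                    chosen = gi
                    break
            if chosen is None:
                for j in eligible:
                    gi = blk_idx[j]
                    k = events.index.get_loc(gi)
                    if not is_target[k] and outcome[k] == "none":
                        chosen = gi
                        break
            if chosen is None:
                logger.warning("press at %.1f ms (block %s) matched no "
                               "scorable stimulus; ignored", t, block)
                continue
            k = events.index.get_loc(chosen)
            if is_target[k]:
                outcome[k] = "hit"
                rt[k] = t - events.loc[chosen, "onset_ms"]
            else:
                outcome[k] = "fa"

    out = events.copy()
    out["outcome"] = outcome
    out["rt_ms"] = rt
    return out


def _clamp_rate(rate: float, n: int | None) -> float:
    if rate in (0.0, 1.0):
        if n is None:
            raise ValueError(
                "rate of exactly 0 or 1 needs the trial count N for the "
                "1/(2N) edge correction")
        return 1.0 - 1.0 / (2 * n) if rate == 1.0 else 1.0 / (2 * n)
    return rate


def compute_dprime(hit_rate: float, fa_rate: float,
                   n_targets: int | None = None,
                   n_standards: int | None = None) -> float:
    """Signal-detection sensitivity d' with 1/(2N) edge correction."""
    for r in (hit_rate, fa_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {r} outside [0, 1]")
    h = _clamp_rate(hit_rate, n_targets)
    f = _clamp_rate(fa_rate, n_standards)
    return float(norm.ppf(h) - norm.ppf(f))


def summarize_subject(outcomes: pd.DataFrame) -> BehaviorSummary:
    """Behavioral summary over a scored session.

    RT means are over hits only, separately for random and predicted targets.
    A target class with zero presented trials yields NaN fields, never zero.
    """
    cats = outcomes["category"].astype(str)

    def _target_stats(cond):
        sub = outcomes[cats == cond]
        n = len(sub)
        if n == 0:
            return n, np.nan, np.nan
        hits = (sub["outcome"] == "hit").sum()
        mean_rt = sub.loc[sub["outcome"] == "hit", "rt_ms"].mean()
        return n, 100.0 * hits / n, mean_rt

    n_randT, pct_hits_randT, rt_randT = _target_stats("randT")
    n_predT, pct_hits_predT, rt_predT = _target_stats("predT")

    rand_std = cats.isin(paradigm.RANDOM_STANDARDS)
    pred_std = cats.isin(("predS1", "predS2", "predS3"))
    n_rs = int(rand_std.sum())
    fa_out = int(((outcomes["outcome"] == "fa") & rand_std).sum())
    fa_in = int(((outcomes["outcome"] == "fa") & pred_std).sum())
    pct_fa = 100.0 * fa_out / n_rs if n_rs else np.nan
    pct_fa_inside = (100.0 * fa_in / int(pred_std.sum())
                     if pred_std.any() else np.nan)

    if n_randT and n_rs:
        dprime = compute_dprime(pct_hits_randT / 100.0, fa_out / n_rs,
                                n_targets=n_randT, n_standards=n_rs)
    else:
        dprime = np.nan

    return BehaviorSummary(
        pct_hits_randT=pct_hits_randT, pct_hits_predT=pct_hits_predT,
        pct_fa=pct_fa, pct_fa_inside=pct_fa_inside,
        mean_rt_randT=rt_randT, mean_rt_predT=rt_predT,
        dprime=dprime, rt_benefit=rt_randT - rt_predT,
        n_randT=n_randT, n_predT=n_predT, n_random_standards=n_rs,
    )
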