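"""Synthetic behavioral logs and component-structured EEG epochs.

The generator emulates the predictive-sequence detection study so that every
downstream stage (scoring, trial selection, ERP measurement, statistics) has a
parameter-recovery test surface with known ground truth:

* **CNV** (contingent negative variation): a linear negative ramp that starts
  at a configurable pre-stimulus time (default -500 ms), reaches its extremum
  at stimulus onset and is zero afterwards. Slope (µV/s) and per-electrode
  topography weights depend on age group and on the (current) stimulus'
  predictive status — after predS3, a target is certain, so the preparatory
  ramp is steeper.
* **P3**: a Gaussian bump (peak amplitude µV, peak latency ms, width as FWHM)
  added post-stimulus, again weighted by a group x condition topography.
* **Noise**: independent Gaussian samples per channel (no 1/f spectrum, no
  spatial covariance) — sufficient for recovery testing.
* **Behavior**: for each target, a button press with probability ``hit_p`` at
  onset + Normal(rt_mean, rt_sd) truncated to the 100–1100 ms response window
  (truncation keeps the hit probability exactly ``hit_p``); for each standard,
  a false-alarm press with probability ``fa_p`` uniform in (100, 1100) ms.

Between-subject variability enters as a multiplicative amplitude scale and an
additive RT offset drawn once per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import paradigm
from .epochs import EpochSet, sample_indices
from .montage import Montage, standard_64_montage

AGE_GROUPS = ("12-14", "14-17", "18-24")

#: Age ranges (years) from which subject ages are drawn uniformly.
AGE_RANGES = {"12-14": (12.2, 14.0), "14-17": (14.5, 17.0), "18-24": (18.0, 24.0)}

#: Per-group sample sizes of the original cohort.
COHORT_GROUP_SIZES = {"12-14": 11, "14-17": 13, "18-24": 12}


@dataclass(frozen=True)
class CnvParams:
    """Pre-stimulus ramp for one group x condition."""

    slope_uv_per_s: float            # negative for a negative-going CNV
    weights: dict[str, float]        # electrode -> topography weight
    default_weight: float = 0.25     # weight for electrodes not listed


@dataclass(frozen=True)
class P3Params:
    """Post-stimulus Gaussian bump for one group x condition."""

    amp_uv: float
    latency_ms: float
    width_fwhm_ms: float
    weights: dict[str, float]
    default_weight: float = 0.25


@dataclass(frozen=True)
class TargetBehavior:
    hit_p: float
    rt_mean_ms: float
    rt_sd_ms: float


@dataclass(frozen=True)
class GroupBehavior:
    """Behavioral parameters for one age group."""

    randT: TargetBehavior
    predT: TargetBehavior
    fa_p: float                      # false-alarm probability per standard


@dataclass
class SimulationConfig:
    """Full study configuration; defaults reproduce the paradigm's conditions."""

    n_subjects_per_group: dict[str, int]
    cnv_params: dict[str, dict[str, CnvParams]]      # group -> condition -> params
    p3_params: dict[str, dict[str, P3Params]]
    behavior_params: dict[str, GroupBehavior]
    montage: Montage = field(default_factory=standard_64_montage)
    age_groups: tuple[str, ...] = AGE_GROUPS
    age_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(AGE_RANGES))
    n_blocks: int = 15
    sfreq: float = 512.0
    epoch_window_ms: tuple[float, float] = (-700.0, 800.0)
    cnv_start_ms: float = -500.0
    response_window_ms: tuple[float, float] = (100.0, 1100.0)
    noise_sd: float = 20.0           # µV per sample per channel
    subject_amp_sd: float = 0.15     # sd of the multiplicative amplitude scale
    subject_rt_sd_ms: float = 30.0   # sd of the additive per-subject RT offset
    dtype: str = "float32"
    rng_seed: int = 0

    def validate(self) -> None:
        if self.sfreq <= 2 * 30.0:
            raise ValueError("sfreq must exceed twice the 30 Hz filter edge")
        for group in self.age_groups:
            gb = self.behavior_params[group]
            for tb in (gb.randT, gb.predT):
                if not 0.0 <= tb.hit_p <= 1.0:
                    raise ValueError("hit probability outside [0, 1]")
                lo, hi = self.response_window_ms
                if not lo <= tb.rt_mean_ms <= hi:
                    raise ValueError("RT mean outside the response window")
            if not 0.0 <= gb.fa_p <= 1.0:
                raise ValueError("FA probability outside [0, 1]")


@dataclass
class SubjectSim:
    """One simulated subject."""

    subject_id: str
    group: str
    age_years: float
    events: pd.DataFrame
    epochs: EpochSet
    presses: pd.DataFrame


# ---------------------------------------------------------------------------
# default study conditions

def _weight_table(fz: float, cz: float, pz: float, cpz: float) -> dict[str, float]:
    return {"Fz": fz, "Cz": cz, "Pz": pz, "CPz": cpz}


#: CNV topography weights per age group. The frontal (Fz) contribution grows
#: with age while the parietal one shrinks — the maturational "frontal shift".
_CNV_WEIGHTS = {
    "12-14": _weight_table(0.40, 1.00, 0.80, 0.90),
    "14-17": _weight_table(0.50, 1.00, 0.75, 0.88),
    "18-24": _weight_table(0.90, 1.00, 0.60, 0.85),
}

#: P3 topography weights per age group: frontal share grows with age, the
#: parietal share of the target P3 decreases.
_P3_WEIGHTS = {
    "12-14": _weight_table(0.30, 0.80, 1.00, 1.00),
    "14-17": _weight_table(0.45, 0.85, 0.95, 1.00),
    "18-24": _weight_table(0.70, 0.90, 0.80, 1.00),
}

#: CNV amplitude at stimulus onset (µV, at weight 1) per condition. The ramp
#: spans 500 ms, so slope = amplitude / 0.5 s. Predictive S3 and targets show
#: the preparatory enhancement; S1/S2 do not (the predictive status of the
#: sequence is unknown at S1 and weakly established at S2).
_CNV_ONSET_AMP = {
    "randS1": -3.0, "randS2": -3.0, "randS3": -3.0, "randT": -3.0,
    "predS1": -3.0, "predS2": -3.0, "predS3": -5.0, "predT": -6.0,
}

#: P3 peak amplitude (µV at weight 1), latency (ms) and FWHM (ms) per
#: condition. Predictive S2/S3 carry the predictive-value enhancement; the
#: target P3 peaks earlier for predicted targets with unchanged amplitude.
_P3_SHAPE = {
    "randS1": (4.0, 450.0, 150.0), "predS1": (4.0, 450.0, 150.0),
    "randS2": (4.0, 450.0, 150.0), "predS2": (6.0, 450.0, 150.0),
    "randS3": (4.0, 450.0, 150.0), "predS3": (7.0, 450.0, 150.0),
    "randT": (10.0, 500.0, 150.0), "predT": (10.0, 440.0, 150.0),
}

#: Behavioral parameters per group: hits rise and false alarms fall with age;
#: predicted targets are answered ~60 ms faster at every age, while mean RT
#: itself does not change with age (the study's RT age effect was null).
_BEHAVIOR = {
    "12-14": GroupBehavior(TargetBehavior(0.84, 405.0, 90.0),
                           TargetBehavior(0.86, 345.0, 90.0), fa_p=0.010),
    "14-17": GroupBehavior(TargetBehavior(0.90, 405.0, 90.0),
                           TargetBehavior(0.91, 345.0, 90.0), fa_p=0.006),
    "18-24": GroupBehavior(TargetBehavior(0.95, 405.0, 90.0),
                           TargetBehavior(0.96, 345.0, 90.0), fa_p=0.003),
}


def default_effect_config(n_subjects_per_group: int | dict[str, int] = 12,
                          n_blocks: int = 15,
                          montage: Montage | None = None,
                          noise_sd: float = 20.0,
                          rng_seed: int = 0) -> SimulationConfig:
    """Study conditions with the reported effect structure built in.

    Frontal CNV/P3 weights increase monotonically over the three age groups
    (parietal target-P3 weight decreases); CNV before predS3/predT and P3 to
    predS2/predS3 exceed their random counterparts; the predicted-target P3
    peaks 60 ms earlier; hit rate rises and FA rate falls with age; predicted
    targets are answered faster.
    """
    if isinstance(n_subjects_per_group, int):
        n_subjects_per_group = {g: n_subjects_per_group for g in AGE_GROUPS}
    cnv = {
        g: {cond: CnvParams(_CNV_ONSET_AMP[cond] / 0.5, _CNV_WEIGHTS[g])
            for cond in paradigm.CATEGORIES}
        for g in AGE_GROUPS
    }
    p3 = {
        g: {cond: P3Params(*_P3_SHAPE[cond], weights=_P3_WEIGHTS[g])
            for cond in paradigm.CATEGORIES}
        for g in AGE_GROUPS
    }
    cfg = SimulationConfig(
        n_subjects_per_group=dict(n_subjects_per_group),
        cnv_params=cnv, p3_params=p3,
        behavior_params=dict(_BEHAVIOR),
        montage=montage if montage is not None else standard_64_montage(),
        n_blocks=n_blocks, noise_sd=noise_sd, rng_seed=rng_seed,
    )
    cfg.validate()
    return cfg


def null_effect_config(**kwargs) -> SimulationConfig:
    """Conditions with *no* group or predictability differences.

    Every group gets the middle group's topography/behavior and every pred*
    condition its rand* counterpart's component parameters — the data-generating
    null for false-positive-rate checks.
    """
    cfg = default_effect_config(**kwargs)
    mid = "14-17"
    flat_cnv = {cond: CnvParams(_CNV_ONSET_AMP["rand" + cond[4:]] / 0.5,
                                _CNV_WEIGHTS[mid])
                for cond in paradigm.CATEGORIES}
    flat_p3 = {cond: P3Params(*_P3_SHAPE["rand" + cond[4:]],
                              weights=_P3_WEIGHTS[mid])
               for cond in paradigm.CATEGORIES}
    tb = _BEHAVIOR[mid].randT
    flat_behavior = GroupBehavior(tb, tb, fa_p=_BEHAVIOR[mid].fa_p)
    return replace(
        cfg,
        cnv_params={g: dict(flat_cnv) for g in AGE_GROUPS},
        p3_params={g: dict(flat_p3) for g in AGE_GROUPS},
        behavior_params={g: flat_behavior for g in AGE_GROUPS},
    )


# ---------------------------------------------------------------------------
# waveform construction

def _weight_vector(montage: Montage, weights: dict[str, float],
                   default: float) -> np.ndarray:
    return np.array([weights.get(lb, default) for lb in montage.labels])


def cnv_time_course(times_s: np.ndarray, slope_uv_per_s: float,
                    start_s: float) -> np.ndarray:
    """Linear ramp from ``start_s`` up to and including onset, zero elsewhere
    (µV at weight 1); the value at t = 0 is slope x ramp duration."""
    tc = np.where((times_s >= start_s) & (times_s <= 0.0),
                  slope_uv_per_s * (times_s - start_s), 0.0)
    return tc


def p3_time_course(times_s: np.ndarray, amp_uv: float, latency_ms: float,
                   width_fwhm_ms: float) -> np.ndarray:
    """Gaussian bump peaking at ``latency_ms`` (µV at weight 1)."""
    sigma_s = width_fwhm_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amp_uv * np.exp(-0.5 * ((times_s - latency_ms / 1000.0) / sigma_s) ** 2)


def condition_waveform(config: SimulationConfig, group: str,
                       condition: str) -> np.ndarray:
    """Noise-free channels x samples waveform for one group x condition."""
    times_s = sample_indices(config.epoch_window_ms, config.sfreq) / config.sfreq
    cnv = config.cnv_params[group][condition]
    p3 = config.p3_params[group][condition]
    wf = np.outer(
        _weight_vector(config.montage, cnv.weights, cnv.default_weight),
        cnv_time_course(times_s, cnv.slope_uv_per_s, config.cnv_start_ms / 1000.0),
    )
    wf += np.outer(
        _weight_vector(config.montage, p3.weights, p3.default_weight),
        p3_time_course(times_s, p3.amp_uv, p3.latency_ms, p3.width_fwhm_ms),
    )
    return wf


# ---------------------------------------------------------------------------
# analytic ground truth (independent of the sampled waveforms)

def expected_cnv_amp(config: SimulationConfig, group: str, condition: str,
                     electrode: str, window_ms=(-150.0, 0.0)) -> float:
    """Analytic mean of the configured ramp over a pre-stimulus window (µV)."""
    cnv = config.cnv_params[group][condition]
    w = cnv.weights.get(electrode, cnv.default_weight)
    a, b = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    start = config.cnv_start_ms / 1000.0
    a = max(a, start)
    mid = 0.5 * (a + b)
    return w * cnv.slope_uv_per_s * (mid - start)


def _gaussian_window_mean(amp, lat_s, sigma_s, a, b):
    z = sps.norm(loc=lat_s, scale=sigma_s)
    return amp * sigma_s * np.sqrt(2 * np.pi) * (z.cdf(b) - z.cdf(a)) / (b - a)


def expected_p3_amp(config: SimulationConfig, group: str, condition: str,
                    electrode: str, window_ms=(350.0, 600.0),
                    baseline_ms=(-100.0, 0.0)) -> float:
    """Analytic baseline-corrected mean of the configured bump (µV).

    Baseline correction subtracts the per-channel mean of the pre-stimulus
    baseline window, which contains the tail of the CNV ramp; the expectation
    accounts for that leak.
    """
    p3 = config.p3_params[group][condition]
    w = p3.weights.get(electrode, p3.default_weight)
    sigma_s = p3.width_fwhm_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    a, b = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    val = w * _gaussian_window_mean(p3.amp_uv, p3.latency_ms / 1000.0,
                                    sigma_s, a, b)
    if baseline_ms is not None:
        val -= expected_cnv_amp(config, group, condition, electrode,
                                window_ms=baseline_ms)
        val -= w * _gaussian_window_mean(
            p3.amp_uv, p3.latency_ms / 1000.0, sigma_s,
            baseline_ms[0] / 1000.0, baseline_ms[1] / 1000.0)
    return val


def expected_p3_peak_latency(config: SimulationConfig, group: str,
                             condition: str) -> float:
    """Configured P3 peak latency in ms (the Gaussian bump's center)."""
    return config.p3_params[group][condition].latency_ms


# ---------------------------------------------------------------------------
# simulation

def _simulate_presses(config: SimulationConfig, group: str,
                      events: pd.DataFrame, rng: np.random.Generator,
                      rt_offset_ms: float) -> pd.DataFrame:
    gb = config.behavior_params[group]
    lo, hi = config.response_window_ms
    rows = []
    for onset, cat, block in zip(events["onset_ms"], events["category"].astype(str),
                                 events["block"]):
        if cat in paradigm.TARGET_CATEGORIES:
            tb = gb.randT if cat == "randT" else gb.predT
            if rng.random() < tb.hit_p:
                mean = tb.rt_mean_ms + rt_offset_ms
                a = (lo - mean) / tb.rt_sd_ms
                b = (hi - mean) / tb.rt_sd_ms
                rt = sps.truncnorm.rvs(a, b, loc=mean, scale=tb.rt_sd_ms,
                                       random_state=rng)
                rows.append((onset + rt, block))
        else:
            if rng.random() < gb.fa_p:
                rt = rng.uniform(lo, hi)
                rows.append((onset + rt, block))
    presses = pd.DataFrame(rows, columns=["press_time_ms", "block"])
    return presses.sort_values(["block", "press_time_ms"]).reset_index(drop=True)


def _press_adjacency(events: pd.DataFrame,
                     presses: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Flags: stimulus immediately before / after any button press."""
    followed = np.zeros(len(events), dtype=bool)   # press occurs right after it
    preceded = np.zeros(len(events), dtype=bool)   # press occurred right before
    for block, blk_presses in presses.groupby("block"):
        blk = events.index[events["block"] == block]
        onsets = events.loc[blk, "onset_ms"].to_numpy()
        for t in blk_presses["press_time_ms"]:
            i = np.searchsorted(onsets, t, side="right") - 1
            if i >= 0:
                followed[blk[i]] = True
            if i + 1 < len(blk):
                preceded[blk[i + 1]] = True
    return followed, preceded


def annotate_press_adjacency(epochs: EpochSet, events: pd.DataFrame,
                             presses: pd.DataFrame) -> EpochSet:
    """Return epochs whose press-adjacency flags reflect ``presses``.

    Useful when scoring a press table other than the one the epochs were
    simulated with (e.g. hand-constructed presses in tests).
    """
    followed, preceded = _press_adjacency(events, presses)
    meta = epochs.trial_meta.copy()
    meta["followed_by_press"] = followed
    meta["preceded_by_press"] = preceded
    from dataclasses import replace as _replace
    return _replace(epochs, trial_meta=meta)


def simulate_subject(config: SimulationConfig, group: str,
                     events: pd.DataFrame, seed: int,
                     subject_id: str = "sub-00") -> tuple[EpochSet, pd.DataFrame]:
    """Simulate one subject's epochs and button presses for a given stream."""
    if group not in config.age_groups:
        raise ValueError(f"unknown group label {group!r}")
    config.validate()
    rng = np.random.default_rng(seed)
    amp_scale = max(0.1, 1.0 + rng.normal(0.0, config.subject_amp_sd))
    rt_offset = rng.normal(0.0, config.subject_rt_sd_ms)

    presses = _simulate_presses(config, group, events, rng, rt_offset)

    n_samples = len(sample_indices(config.epoch_window_ms, config.sfreq))
    n_ch = len(config.montage)
    cats = events["category"].astype(str).to_numpy()
    data = np.empty((len(events), n_ch, n_samples), dtype=config.dtype)
    for cond in paradigm.CATEGORIES:
        mask = cats == cond
        if mask.any():
            data[mask] = (amp_scale *
                          condition_waveform(config, group, cond)).astype(config.dtype)
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd,
                           size=data.shape).astype(config.dtype)

    followed, preceded = _press_adjacency(events, presses)
    grp = events.groupby("block")["category"]
    meta = pd.DataFrame({
        "category": cats,
        "block": events["block"].to_numpy(),
        "position": events["position"].to_numpy(),
        "onset_ms": events["onset_ms"].to_numpy(),
        "preceding_category": grp.shift(1).astype(object).where(
            lambda s: s.notna(), None).to_numpy(),
        "following_category": grp.shift(-1).astype(object).where(
            lambda s: s.notna(), None).to_numpy(),
        "followed_by_press": followed,
        "preceded_by_press": preceded,
    })
    epochs = EpochSet(
        data=data, trial_meta=meta,
        channel_labels=tuple(config.montage.labels),
        sfreq=config.sfreq, window_ms=config.epoch_window_ms,
    )
    return epochs, presses


def simulate_study(config: SimulationConfig) -> Iterator[SubjectSim]:
    """Yield one :class:`SubjectSim` per subject (groups in config order).

    Subjects get independent stimulus streams (``config.n_blocks`` blocks) and
    independent seeds derived from ``config.rng_seed``; ages are uniform within
    each group's range.
    """
    config.validate()
    i = 0
    for group in config.age_groups:
        n = config.n_subjects_per_group.get(group, 0)
        for _ in range(n):
            ss = np.random.SeedSequence([config.rng_seed, i])
            ev_seed, sub_seed, age_seed = (int(s) for s in ss.generate_state(3) >> 1)
            events = paradigm.generate_session(config.n_blocks, ev_seed)
            epochs, presses = simulate_subject(
                config, group, events, sub_seed, subject_id=f"sub-{i:02d}")
            lo, hi = config.age_ranges[group]
            age = float(np.random.default_rng(age_seed).uniform(lo, hi))
            yield SubjectSim(f"sub-{i:02d}", group, age, events, epochs, presses)
            i += 1
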