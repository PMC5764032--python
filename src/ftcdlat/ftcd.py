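"""Laterality-index pipeline for bilateral functional transcranial Doppler recordings.

The chain turns a two-channel middle-cerebral-artery (MCA) velocity recording
with talk-onset markers into a per-child laterality result:

    heart-cycle integration -> epoching -> dropout imputation -> mean-100
    normalisation -> range-based artefact rejection -> baseline correction ->
    grand averaging -> peak-window laterality index (LI) with SE / 95% CI,
    categorisation, usability screening, split-half LIs and per-artery
    percent-change summaries.

Velocities are in cm/s until normalisation, after which every channel is on a
dimensionless scale with mean 100, so differences read directly as percent
units. The period of interest (POI) starts 4 s after talk onset and lasts
10 s; the 12 s of silent animation viewing immediately before talk onset are
the baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .errors import ProcessingError, ValidationError

logger = logging.getLogger("ftcdlat")

_EPS = 1e-9

# Default pipeline parameters. Timing parameters follow the animation
# description paradigm (12 s viewing, 10 s talk); thresholds without a
# published value (artefact bounds, dropout rule, heart-rate band) are package
# defaults and are configurable everywhere they are used.
EPOCH_WINDOW = (-12.0, 15.0)          # s relative to talk onset, half-open
POI = (4.0, 14.0)                     # s, closed at sample resolution
PEAK_WINDOW_WIDTH = 2.0               # s, centred on the peak |difference|
BASELINE_WINDOW = (-12.0, 0.0)        # s, half-open
ARTEFACT_BOUNDS = (60.0, 140.0)       # normalised units
CI_MULTIPLIER = 1.96
MIN_VALID_TRIALS = 12
LI_CAP = 10.0
HEART_RATE_BAND = (40.0, 150.0)       # plausible paediatric beats/min
DROPOUT_MAD_K = 4.0
DROPOUT_MAX_RUN = 1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """A two-channel MCA velocity recording with trial markers.

    ``markers`` holds talk-onset times in seconds; ``trial_validity`` and
    ``word_counts`` are per-marker behavioural annotations.
    """

    child_id: str
    sampling_rate: float
    time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    markers: np.ndarray
    trial_validity: np.ndarray
    word_counts: np.ndarray

    def validate(self) -> None:
        n = len(self.time)
        if len(self.left) != n or len(self.right) != n:
            raise ValidationError(f"{self.child_id}: channel length != time length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or np.ptp(dt) > 1e-6:
                raise ValidationError(f"{self.child_id}: time axis not uniform/increasing")
        if not (np.all(np.isfinite(self.left)) and np.all(np.isfinite(self.right))):
            raise ValidationError(f"{self.child_id}: non-finite velocities")
        if len(self.markers) and (
            self.markers.min() < self.time[0] - _EPS or self.markers.max() > self.time[-1] + _EPS
        ):
            raise ValidationError(f"{self.child_id}: marker outside recording span")
        if len(self.trial_validity) != len(self.markers) or len(self.word_counts) != len(self.markers):
            raise ValidationError(f"{self.child_id}: per-trial annotations do not match markers")


REJECT_BEHAVIOUR = "behaviour"
REJECT_RANGE = "range"
REJECT_FLAT = "flat/dropout"


@dataclass
class TrialEpoch:
    """One trial's two-channel segment on a time axis relative to talk onset."""

    index: int
    rel_time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    status: str = "accepted"           # "accepted" or "rejected"
    reason: str | None = None
    imputed_points: int = 0
    word_count: int = 0

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    def reject(self, reason: str) -> None:
        # earlier rejection reasons take precedence
        if self.accepted:
            self.status = "rejected"
            self.reason = reason


@dataclass
class LateralityResult:
    """Per-child laterality summary."""

    child_id: str
    li: float
    peak_time: float
    window: tuple[float, float]
    trial_lis: np.ndarray
    se: float
    ci95: tuple[float, float]
    category: str
    n_valid: int
    usable: bool
    unusable_reason: str | None
    pct_change_left: float
    pct_change_right: float
    li_odd: float | None
    li_even: float | None
    mean_words_per_valid_trial: float
    n_markers: int = 0
    n_rejected: dict = field(default_factory=dict)
    imputed_points: int = 0
    curves: tuple | None = None   # (rel_time, left mean, right mean, difference)


# ---------------------------------------------------------------------------
# Heart-cycle integration
# ---------------------------------------------------------------------------

def integrate_heart_cycles(
    rec: RawRecording,
    min_rate: float = HEART_RATE_BAND[0],
    max_rate: float = HEART_RATE_BAND[1],
    peaks: np.ndarray | None = None,
) -> RawRecording:
    """Remove cardiac pulsatility by replacing samples with per-cycle means.

    Systolic peaks are detected on the summed channels (so the operation is
    exactly symmetric under a left/right swap) with a minimum inter-peak
    interval of ``60 / max_rate`` s. Every sample inside a cycle
    ``[p_i, p_{i+1})`` is replaced by that cycle's per-channel mean; samples
    before the first and after the last peak take the nearest cycle's mean.
    Inter-peak stretches longer than ``60 / min_rate`` s cannot be cardiac
    cycles (e.g. in a recording without pulsatile content) and are passed
    through unchanged.

    ``peaks`` overrides detection (sample indices), mainly for testing.
    """
    fs = rec.sampling_rate
    if len(rec.time) < 2 * fs * 60.0 / min_rate:
        raise ProcessingError(f"{rec.child_id}: recording shorter than 2 cardiac cycles")
    summed = rec.left + rec.right
    if peaks is None:
        distance = max(1, int(round(fs * 60.0 / max_rate)))
        peaks, _ = _signal.find_peaks(summed, distance=distance)
    peaks = np.asarray(peaks, dtype=int)
    if len(peaks) < 2:
        raise ProcessingError(f"{rec.child_id}: no cardiac signal")

    max_cycle = 60.0 / min_rate * fs  # samples
    left = rec.left.copy()
    right = rec.right.copy()

    def cycle_mean(lo: int, hi: int) -> tuple[float, float]:
        return float(rec.left[lo:hi].mean()), float(rec.right[lo:hi].mean())

    first_plausible = None
    last_plausible = None
    for lo, hi in zip(peaks[:-1], peaks[1:]):
        if hi - lo > max_cycle:
            continue  # not a cardiac cycle; leave untouched
        ml, mr = cycle_mean(lo, hi)
        left[lo:hi] = ml
        right[lo:hi] = mr
        if first_plausible is None:
            first_plausible = (lo, hi)
        last_plausible = (lo, hi)

    # edges inherit the nearest plausible cycle's mean, provided they are
    # within one cycle length of it
    if first_plausible is not None:
        lo, hi = first_plausible
        if lo == peaks[0] and lo <= max_cycle:
            ml, mr = cycle_mean(lo, hi)
            left[:lo] = ml
            right[:lo] = mr
        lo, hi = last_plausible
        if hi == peaks[-1] and len(rec.time) - hi <= max_cycle:
            ml, mr = cycle_mean(lo, hi)
            left[hi:] = ml
            right[hi:] = mr

    return replace(rec, left=left, right=right)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch(rec: RawRecording, window: tuple[float, float] = EPOCH_WINDOW) -> list[TrialEpoch]:
    """Cut one half-open epoch per marker; drop epochs leaving the recording.

    Behaviourally invalid trials are kept but carry status rejected
    ("behaviour") so that downstream bookkeeping sees every marker.
    """
    if len(rec.markers) == 0:
        raise ProcessingError(f"{rec.child_id}: no trials")
    fs = rec.sampling_rate
    w0, w1 = window
    n_pre = int(round(-w0 * fs))
    n_total = int(round((w1 - w0) * fs))
    rel_time = (np.arange(n_total) - n_pre) / fs
    t0 = rec.time[0]
    epochs: list[TrialEpoch] = []
    for k, m in enumerate(rec.markers):
        onset_idx = int(round((m - t0) * fs))
        i0 = onset_idx - n_pre
        if i0 < 0 or i0 + n_total > len(rec.time):
            logger.warning("%s: trial %d extends outside the recording; dropped", rec.child_id, k)
            continue
        ep = TrialEpoch(
            index=k,
            rel_time=rel_time,
            left=rec.left[i0:i0 + n_total].copy(),
            right=rec.right[i0:i0 + n_total].copy(),
            word_count=int(rec.word_counts[k]),
        )
        if not rec.trial_validity[k]:
            ep.reject(REJECT_BEHAVIOUR)
        epochs.append(ep)
    return epochs


# ---------------------------------------------------------------------------
# Dropout detection and imputation
# ---------------------------------------------------------------------------

def _impute_channel(x: np.ndarray, mad_k: float, max_run: int) -> tuple[np.ndarray, int, bool]:
    """Return (corrected, n_imputed, all_candidates) for one channel of one trial."""
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    candidates = (x <= 0) | (np.abs(x - med) > mad_k * mad)
    if candidates.all():
        return x, 0, True
    out = x.copy()
    fill = x[~candidates].mean()
    n_imputed = 0
    i = 0
    n = len(x)
    while i < n:
        if candidates[i]:
            j = i
            while j < n and candidates[j]:
                j += 1
            if j - i <= max_run:
                out[i:j] = fill
                n_imputed += j - i
            i = j
        else:
            i += 1
    return out, n_imputed, False


def detect_and_impute_dropouts(
    ep: TrialEpoch, mad_k: float = DROPOUT_MAD_K, max_run: int = DROPOUT_MAX_RUN
) -> TrialEpoch:
    """Replace brief signal dropouts by the trial mean, in place.

    A sample is a dropout candidate if it is <= 0 or deviates from the trial
    median by more than ``mad_k`` scaled median absolute deviations. Candidate
    runs no longer than ``max_run`` samples are replaced by the mean of the
    trial's non-candidate samples; longer runs are left for the range-based
    artefact rejection to catch. A trial consisting entirely of candidates is
    rejected as flat/dropout.
    """
    if len(ep.rel_time) < 10:
        raise ValidationError(f"trial {ep.index}: fewer than 10 samples")
    total = 0
    for ch in ("left", "right"):
        x = getattr(ep, ch)
        out, n_imp, all_bad = _impute_channel(x, mad_k, max_run)
        if all_bad:
            ep.reject(REJECT_FLAT)
            return ep
        setattr(ep, ch, out)
        total += n_imp
    ep.imputed_points += total
    return ep


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalise(rec: RawRecording) -> RawRecording:
    """Scale each channel linearly so its mean is exactly 100."""
    ml = rec.left.mean()
    mr = rec.right.mean()
    if ml <= 0 or mr <= 0:
        raise ProcessingError(f"{rec.child_id}: non-positive channel mean")
    return replace(rec, left=rec.left * (100.0 / ml), right=rec.right * (100.0 / mr))


def normalise_epochs(epochs: Sequence[TrialEpoch]) -> None:
    """Scale channels to mean 100 over all samples of currently retained epochs.

    The scaling constant is per channel and shared across epochs, mirroring a
    whole-recording normalisation restricted to analysable data.
    """
    retained = [ep for ep in epochs if ep.accepted]
    if not retained:
        raise ProcessingError("no retained epochs to normalise")
    for ch in ("left", "right"):
        m = np.concatenate([getattr(ep, ch) for ep in retained]).mean()
        if m <= 0:
            raise ProcessingError("non-positive channel mean")
        scale = 100.0 / m
        for ep in epochs:
            setattr(ep, ch, getattr(ep, ch) * scale)


# ---------------------------------------------------------------------------
# Artefact rejection and baseline correction
# ---------------------------------------------------------------------------

def reject_artefact_trials(
    epochs: Sequence[TrialEpoch], bounds: tuple[float, float] = ARTEFACT_BOUNDS
) -> Sequence[TrialEpoch]:
    """Reject accepted epochs with any sample outside ``bounds`` on either channel."""
    lo, hi = bounds
    for ep in epochs:
        if not ep.accepted:
            continue
        for ch in (ep.left, ep.right):
            if ch.min() < lo or ch.max() > hi:
                ep.reject(REJECT_RANGE)
                break
    return epochs


def baseline_correct(ep: TrialEpoch, baseline: tuple[float, float] = BASELINE_WINDOW) -> TrialEpoch:
    """Subtract each channel's mean over the pre-talk baseline window."""
    mask = (ep.rel_time >= baseline[0] - _EPS) & (ep.rel_time < baseline[1] - _EPS)
    if not mask.any():
        raise ProcessingError(f"trial {ep.index}: empty baseline window")
    ep.left = ep.left - ep.left[mask].mean()
    ep.right = ep.right - ep.right[mask].mean()
    return ep


# ---------------------------------------------------------------------------
# Averaging and the laterality index
# ---------------------------------------------------------------------------

def grand_average(epochs: Sequence[TrialEpoch]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise means over accepted epochs: (rel_time, left, right, left-right)."""
    acc = [ep for ep in epochs if ep.accepted]
    if not acc:
        raise ProcessingError("no accepted epochs")
    left = np.mean([ep.left for ep in acc], axis=0)
    right = np.mean([ep.right for ep in acc], axis=0)
    return acc[0].rel_time, left, right, left - right


def compute_li(
    rel_time: np.ndarray,
    diff: np.ndarray,
    poi: tuple[float, float] = POI,
    window_width: float = PEAK_WINDOW_WIDTH,
) -> tuple[float, float, tuple[float, float]]:
    """Peak-window LI from a grand-average difference curve.

    The peak is the sample of greatest absolute left-minus-right difference
    inside the POI (earliest sample on ties); the LI is the signed mean of the
    difference over a ``window_width`` window centred on that sample, clipped
    to the epoch's extent.
    """
    mask = (rel_time >= poi[0] - _EPS) & (rel_time <= poi[1] + _EPS)
    if not mask.any():
        raise ProcessingError("period of interest outside the epoch window")
    poi_t = rel_time[mask]
    poi_d = diff[mask]
    peak_time = float(poi_t[np.argmax(np.abs(poi_d))])  # argmax -> earliest tie
    half = window_width / 2.0
    lo = max(peak_time - half, float(rel_time[0]))
    hi = min(peak_time + half, float(rel_time[-1]))
    wmask = (rel_time >= lo - _EPS) & (rel_time <= hi + _EPS)
    li = float(diff[wmask].mean())
    return li, peak_time, (lo, hi)


def li_se_ci(
    epochs: Sequence[TrialEpoch],
    window: tuple[float, float],
    li: float,
    multiplier: float = CI_MULTIPLIER,
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Trial-by-trial LIs within the peak window, their SE, and the 95% CI.

    SE = SD(trial LIs; n-1 denominator) / sqrt(n); CI = LI +/- multiplier*SE
    around the grand-average LI.
    """
    acc = [ep for ep in epochs if ep.accepted]
    if len(acc) < 2:
        raise ProcessingError("fewer than 2 accepted epochs")
    rel = acc[0].rel_time
    wmask = (rel >= window[0] - _EPS) & (rel <= window[1] + _EPS)
    trial_lis = np.array([(ep.left[wmask] - ep.right[wmask]).mean() for ep in acc])
    se = float(trial_lis.std(ddof=1) / math.sqrt(len(trial_lis)))
    ci = (li - multiplier * se, li + multiplier * se)
    return trial_lis, se, ci


def categorise_laterality(li: float, ci95: tuple[float, float]) -> str:
    """left if the CI is entirely above zero, right if entirely below, else bilateral.

    An endpoint exactly at zero counts as crossing zero (bilateral).
    """
    lo, hi = ci95
    if lo > 0:
        return "left"
    if hi < 0:
        return "right"
    return "bilateral"


def usability(n_valid: int, li: float, min_trials: int = MIN_VALID_TRIALS, cap: float = LI_CAP) -> tuple[bool, str | None]:
    """Usable iff at least ``min_trials`` accepted trials and |LI| <= cap."""
    if n_valid < min_trials:
        return False, "too few trials"
    if not (-cap <= li <= cap):
        return False, "extreme LI"
    return True, None


def split_half(
    epochs: Sequence[TrialEpoch],
    poi: tuple[float, float] = POI,
    window_width: float = PEAK_WINDOW_WIDTH,
) -> tuple[float | None, float | None]:
    """LIs from odd- and even-numbered accepted trials (1-based order).

    Each half reruns grand averaging and peak finding independently, so each
    half gets its own peak window. A half with no epochs yields None.
    """
    acc = [ep for ep in epochs if ep.accepted]
    halves = []
    for sel in (acc[0::2], acc[1::2]):
        if not sel:
            logger.warning("split-half: empty half; child omitted from reliability")
            halves.append(None)
            continue
        rel, _, _, diff = grand_average(sel)
        li, _, _ = compute_li(rel, diff, poi, window_width)
        halves.append(li)
    return halves[0], halves[1]


def cohort_reliability(li_odd: Sequence[float], li_even: Sequence[float]) -> float:
    """Pearson correlation of odd- vs even-trial LIs across usable children."""
    pairs = [(o, e) for o, e in zip(li_odd, li_even) if o is not None and e is not None]
    if len(pairs) < 3:
        raise ProcessingError("fewer than 3 children with both split-half LIs")
    o, e = zip(*pairs)
    return float(_stats.pearsonr(o, e)[0])


def percent_change(epochs: Sequence[TrialEpoch], poi: tuple[float, float] = POI) -> tuple[float, float]:
    """Mean POI value of the baseline-corrected signal per channel, over accepted epochs.

    After mean-100 normalisation and baseline correction these are percent
    changes relative to the immediately preceding baseline.
    """
    acc = [ep for ep in epochs if ep.accepted]
    if not acc:
        raise ProcessingError("no accepted epochs")
    rel = acc[0].rel_time
    mask = (rel >= poi[0] - _EPS) & (rel <= poi[1] + _EPS)
    pl = float(np.mean([ep.left[mask].mean() for ep in acc]))
    pr = float(np.mean([ep.right[mask].mean() for ep in acc]))
    return pl, pr


# ---------------------------------------------------------------------------
# Whole-recording pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineParams:
    """Tunable parameters of the per-child processing chain."""

    epoch_window: tuple[float, float] = EPOCH_WINDOW
    poi: tuple[float, float] = POI
    window_width: float = PEAK_WINDOW_WIDTH
    baseline: tuple[float, float] = BASELINE_WINDOW
    artefact_bounds: tuple[float, float] = ARTEFACT_BOUNDS
    mad_k: float = DROPOUT_MAD_K
    max_run: int = DROPOUT_MAX_RUN
    min_trials: int = MIN_VALID_TRIALS
    li_cap: float = LI_CAP
    ci_multiplier: float = CI_MULTIPLIER
    heart_rate_band: tuple[float, float] = HEART_RATE_BAND


def impute_recording_dropouts(
    rec: RawRecording,
    epoch_window: tuple[float, float] = EPOCH_WINDOW,
    mad_k: float = DROPOUT_MAD_K,
    max_run: int = DROPOUT_MAX_RUN,
) -> tuple[RawRecording, dict[int, int], set[int]]:
    """Impute brief dropouts within each provisional trial span of a raw recording.

    Single aberrant samples must be caught before heart-cycle integration
    (cycle averaging dilutes them beyond recognition) and before normalisation
    (an extreme value would distort the scaling constant). Returns the
    corrected recording, per-trial imputation counts, and the indices of
    trials that were entirely dropout (rejected as flat).
    """
    provisional = epoch(rec, epoch_window)
    left = rec.left.copy()
    right = rec.right.copy()
    fs = rec.sampling_rate
    n_pre = int(round(-epoch_window[0] * fs))
    n_total = int(round((epoch_window[1] - epoch_window[0]) * fs))
    t0 = rec.time[0]
    counts: dict[int, int] = {}
    flat: set[int] = set()
    for ep in provisional:
        detect_and_impute_dropouts(ep, mad_k, max_run)
        if ep.reason == REJECT_FLAT:
            flat.add(ep.index)
            continue
        if ep.imputed_points:
            i0 = int(round((rec.markers[ep.index] - t0) * fs)) - n_pre
            left[i0:i0 + n_total] = ep.left
            right[i0:i0 + n_total] = ep.right
            counts[ep.index] = ep.imputed_points
    return replace(rec, left=left, right=right), counts, flat


def process_recording(rec: RawRecording, params: PipelineParams | None = None) -> LateralityResult:
    """Run the full chain on one recording and return the laterality result.

    Order: provisional epoching with dropout imputation on the raw trial
    spans, heart-cycle integration, epoching, normalisation (constant from
    retained samples), range-based artefact rejection, baseline correction,
    then LI derivation. Imputation precedes both integration (cycle averaging
    would dilute a single aberrant point past recognition) and normalisation
    (an extreme value would distort the scaling constant).
    """
    p = params or PipelineParams()
    rec.validate()
    imputed, imput_counts, flat_trials = impute_recording_dropouts(
        rec, p.epoch_window, p.mad_k, p.max_run)
    integrated = integrate_heart_cycles(imputed, *p.heart_rate_band)
    epochs = epoch(integrated, p.epoch_window)
    if not epochs:
        raise ProcessingError(f"{rec.child_id}: no complete epochs")
    for ep in epochs:
        ep.imputed_points = imput_counts.get(ep.index, 0)
        if ep.index in flat_trials:
            ep.reject(REJECT_FLAT)
    normalise_epochs(epochs)
    reject_artefact_trials(epochs, p.artefact_bounds)
    accepted = [ep for ep in epochs if ep.accepted]
    for ep in accepted:
        baseline_correct(ep, p.baseline)

    n_rejected: dict[str, int] = {}
    for ep in epochs:
        if not ep.accepted:
            n_rejected[ep.reason] = n_rejected.get(ep.reason, 0) + 1

    n_valid = len(accepted)
    if n_valid < 2:
        # too little data for any LI: report an unusable shell result
        return LateralityResult(
            child_id=rec.child_id, li=float("nan"), peak_time=float("nan"),
            window=(float("nan"), float("nan")), trial_lis=np.array([]), se=float("nan"),
            ci95=(float("nan"), float("nan")), category="none", n_valid=n_valid,
            usable=False, unusable_reason="too few trials",
            pct_change_left=float("nan"), pct_change_right=float("nan"),
            li_odd=None, li_even=None, mean_words_per_valid_trial=float("nan"),
            n_markers=len(rec.markers), n_rejected=n_rejected,
            imputed_points=sum(ep.imputed_points for ep in epochs),
        )

    rel, left_mean, right_mean, diff = grand_average(epochs)
    li, peak_time, window = compute_li(rel, diff, p.poi, p.window_width)
    trial_lis, se, ci = li_se_ci(epochs, window, li, p.ci_multiplier)
    category = categorise_laterality(li, ci)
    usable, reason = usability(n_valid, li, p.min_trials, p.li_cap)
    li_odd, li_even = split_half(epochs, p.poi, p.window_width)
    pct_l, pct_r = percent_change(epochs, p.poi)
    words = float(np.mean([ep.word_count for ep in accepted]))

    return LateralityResult(
        child_id=rec.child_id, li=li, peak_time=peak_time, window=window,
        trial_lis=trial_lis, se=se, ci95=ci, category=category, n_valid=n_valid,
        usable=usable, unusable_reason=reason,
        pct_change_left=pct_l, pct_change_right=pct_r,
        li_odd=li_odd, li_even=li_even, mean_words_per_valid_trial=words,
        n_markers=len(rec.markers), n_rejected=n_rejected,
        imputed_points=sum(ep.imputed_points for ep in epochs),
        curves=(rel, left_mean, right_mean, diff),
    )
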