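"""Synthetic twin-cohort generator with known ground truth.

Emulates the structures the pipeline and statistics consume: bilateral MCA
velocity recordings during an animation-description task (cardiac
pulsatility, an early bilateral activation peak after talk onset, a sustained
left-minus-right plateau over the period of interest, probe artefacts and
brief dropouts, behaviourally invalid trials), twin-pair correlated true
laterality, a majority-left-lateralised population with controllable
right/bilateral minorities, handedness item responses and reach logs driven
by a latent hand-preference trait, and correlated normed language/literacy
scores with a controllable disorder prevalence.

Every quantity that downstream stages estimate (true lateral effect, true
dominance class, destined group, handedness latent) is recorded in the ground
truth, and identical (config, seed) yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from . import behav
from .errors import ConfigurationError
from .ftcd import RawRecording

# trial timing (s): 12 s silent viewing, 10 s talk, 5 s inter-trial gap
VIEW_S = 12.0
TALK_S = 10.0
GAP_S = 5.0
TRIAL_SPACING_S = VIEW_S + TALK_S + GAP_S   # 27 s between talk onsets
FIRST_MARKER_S = 14.0                       # > 12 s lead-in for the baseline
TAIL_S = 16.0                               # > 15 s after the last onset


@dataclass
class HandednessParams:
    """Latent-trait model for the EHI items and QHP reaches.

    Each child has a latent ``h``; an EHI action is performed right-handed if
    ``h`` plus logistic noise exceeds ``item_cut``, left-handed below
    ``-item_cut``, otherwise with both hands. A QHP reach at position ``j``
    (1..7, 4 = midline) is right-handed with probability
    ``expit(h + position_slope * (j - 4))``, so reaches into left hemispace
    are hardest for the right hand.
    """

    latent_mean: float = 3.0
    latent_sd: float = 3.0
    item_cut: float = 0.8
    position_slope: float = 0.9


@dataclass
class LanguageScoreParams:
    """Correlated normed scores with a latent deficit for destined-DLD children.

    Standardised scores share an exchangeable correlation ``inter_measure_corr``;
    children destined for the DLD class have ``dld_shift`` SD subtracted from
    every language/literacy measure and ``dld_iq_shift`` SD from performance
    IQ. Norm scales default to the conventional scale per instrument family.
    """

    inter_measure_corr: float = 0.6
    dld_shift: float = 1.3
    dld_iq_shift: float = 0.6
    norms: dict = field(default_factory=lambda: dict(behav.DEFAULT_NORMS))


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults follow the emulated study where it states a value (30-trial
    maximum, trial timing, a mean LI near 2 with SD near 3, roughly 15% right
    and 18% bilateral laterality, ~40% DLD prevalence, ~20 words per trial)
    and conventional values elsewhere.
    """

    n_pairs: int = 50
    prop_dld_target: float = 0.4
    zygosity_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # MZ, DZ same-sex, DZ opposite-sex
    sampling_rate: float = 25.0
    n_trials: int = 30
    heart_rate_mean: float = 90.0
    heart_rate_sd: float = 8.0
    base_velocity_left: float = 60.0
    base_velocity_right: float = 55.0
    pulsatility_amplitude: float = 12.0
    activation_peak_pct: float = 4.0
    lateral_effect_mean: float = 2.0
    lateral_effect_sd: float = 2.5
    prop_right_dominant: float = 0.15
    prop_bilateral: float = 0.18
    group_li_shift: float = 0.0
    pair_icc_li: float = 0.3
    artefact_rate: float = 0.03
    dropout_rate: float = 0.05
    invalid_trial_rate: float = 0.08
    signal_noise_pct: float = 1.5     # white noise SD, % of base velocity
    trial_effect_sd: float = 2.0      # per-trial jitter of the lateral effect, % units
    words_per_trial_mean: float = 20.0
    handedness_latent_params: HandednessParams = field(default_factory=HandednessParams)
    language_score_params: LanguageScoreParams = field(default_factory=LanguageScoreParams)
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "prop_dld_target": self.prop_dld_target,
            "prop_right_dominant": self.prop_right_dominant,
            "prop_bilateral": self.prop_bilateral,
            "pair_icc_li": self.pair_icc_li,
            "artefact_rate": self.artefact_rate,
            "dropout_rate": self.dropout_rate,
            "invalid_trial_rate": self.invalid_trial_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_pairs < 1:
            raise ConfigurationError(f"n_pairs must be >= 1, got {self.n_pairs}")
        if self.n_trials < 1:
            raise ConfigurationError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.sampling_rate < 10:
            raise ConfigurationError(f"sampling_rate must be >= 10 Hz, got {self.sampling_rate}")
        if abs(sum(self.zygosity_mix) - 1.0) > 1e-9:
            raise ConfigurationError(f"zygosity_mix must sum to 1, got {self.zygosity_mix}")
        if any(z < 0 for z in self.zygosity_mix):
            raise ConfigurationError(f"zygosity_mix fractions must be >= 0, got {self.zygosity_mix}")
        if self.prop_right_dominant + self.prop_bilateral > 1.0:
            raise ConfigurationError("prop_right_dominant + prop_bilateral must be <= 1")
        if not 0 <= self.language_score_params.inter_measure_corr < 1:
            raise ConfigurationError("inter_measure_corr must be in [0, 1)")


@dataclass
class SyntheticCohort:
    """Everything generate_cohort produces."""

    recordings: list
    cohort: pd.DataFrame        # per-child metadata + behavioural scores + classifier group
    truth: pd.DataFrame         # per-child ground truth
    trials: pd.DataFrame        # per-trial validity flags and word counts
    ehi_items: pd.DataFrame     # 10 item responses per child
    qhp_reaches: pd.DataFrame   # 21 reach records per child
    artefact_log: pd.DataFrame  # injected artefact positions
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Recording synthesis
# ---------------------------------------------------------------------------

def _activation_bump(tau: np.ndarray, t_peak: float = 1.5, k: float = 3.0) -> np.ndarray:
    """Smooth gamma-shaped bilateral peak after talk onset, max 1 at t_peak."""
    out = np.zeros_like(tau)
    pos = tau > 0
    r = tau[pos] / t_peak
    out[pos] = r**k * np.exp(k * (1.0 - r))
    return out


def _plateau(tau: np.ndarray) -> np.ndarray:
    """Lateralised response: cosine ramps 3-4 s and 14-15 s around a sustained plateau.

    The plateau carries a gentle (1%) maximum at 9 s, mid-period-of-interest:
    evoked responses are sustained but not perfectly flat, and the interior
    maximum keeps the peak-window search off the onset ramp.
    """
    out = np.zeros_like(tau)
    up = (tau >= 3.0) & (tau < 4.0)
    out[up] = 0.5 * (1 - np.cos(np.pi * (tau[up] - 3.0)))
    mid = (tau >= 4.0) & (tau <= 14.0)
    out[mid] = 1.0
    down = (tau > 14.0) & (tau <= 15.0)
    out[down] = 0.5 * (1 + np.cos(np.pi * (tau[down] - 14.0)))
    out[mid] *= 1.0 + 0.01 * np.exp(-((tau[mid] - 9.0) ** 2) / 8.0)
    return out


def synthesize_recording(
    child_id: str,
    *,
    sampling_rate: float,
    n_trials: int,
    base_left: float,
    base_right: float,
    pulsatility_amplitude: float,
    heart_rate: float,
    heart_phase: float,
    activation_peak_pct: float,
    poi_offsets_left: np.ndarray,
    poi_offsets_right: np.ndarray,
    signal_noise_pct: float,
    trial_validity: np.ndarray,
    word_counts: np.ndarray,
    rng: np.random.Generator,
) -> RawRecording:
    """Build one two-channel recording with markers at each talk onset.

    ``poi_offsets_left/right`` give, per trial, the percent offset applied to
    each channel over the plateau; the pipeline's LI recovers approximately
    ``left - right`` of these.
    """
    fs = sampling_rate
    markers = FIRST_MARKER_S + TRIAL_SPACING_S * np.arange(n_trials)
    duration = markers[-1] + TAIL_S
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    act_left = np.zeros(n)
    act_right = np.zeros(n)
    for k, m in enumerate(markers):
        tau = t - m
        bump = activation_peak_pct * _activation_bump(tau)
        plat = _plateau(tau)
        act_left += bump + poi_offsets_left[k] * plat
        act_right += bump + poi_offsets_right[k] * plat

    pulse = pulsatility_amplitude * np.sin(2 * np.pi * heart_rate / 60.0 * t + heart_phase)
    left = base_left * (1.0 + act_left / 100.0) + pulse
    right = base_right * (1.0 + act_right / 100.0) + pulse
    if signal_noise_pct > 0:
        left = left + base_left * signal_noise_pct / 100.0 * rng.standard_normal(n)
        right = right + base_right * signal_noise_pct / 100.0 * rng.standard_normal(n)

    return RawRecording(
        child_id=child_id, sampling_rate=fs, time=t, left=left, right=right,
        markers=markers, trial_validity=trial_validity.astype(bool),
        word_counts=word_counts.astype(int),
    )


# ---------------------------------------------------------------------------
# Artefact injection
# ---------------------------------------------------------------------------

def inject_artefacts(
    rec: RawRecording,
    artefact_rate: float,
    dropout_rate: float,
    seed: int,
) -> tuple[RawRecording, pd.DataFrame]:
    """Insert probe artefacts into a recording; return (recording, log).

    Spikes are ~0.5 s excursions to 1.9x the running level (probe-movement
    transients lasting about a cardiac cycle, so they survive heart-cycle
    averaging and are caught by the range rule after normalisation); dropouts
    are single zero samples (80%, imputable downstream) or ~0.5 s runs of
    zeros (20%, forcing range rejection of the trial).
    """
    for name, r in (("artefact_rate", artefact_rate), ("dropout_rate", dropout_rate)):
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    fs = rec.sampling_rate
    left = rec.left.copy()
    right = rec.right.copy()
    log: list[dict] = []
    chans = {"left": left, "right": right}
    long_run = max(2, int(round(0.5 * fs)))
    for k, m in enumerate(rec.markers):
        lo = int(round((m - VIEW_S) * fs))
        hi = int(round((m + 15.0) * fs))
        lo = max(lo, 0)
        hi = min(hi, len(rec.time))
        if rng.random() < artefact_rate:
            ch = rng.choice(["left", "right"])
            i = int(rng.integers(lo, hi - long_run))
            chans[ch][i:i + long_run] *= 1.9
            log.append({"trial": k, "channel": ch, "sample": i, "kind": "spike", "length": long_run})
        if rng.random() < dropout_rate:
            ch = rng.choice(["left", "right"])
            run = 1 if rng.random() < 0.8 else long_run
            i = int(rng.integers(lo, hi - run))
            chans[ch][i:i + run] = 0.0
            log.append({"trial": k, "channel": ch, "sample": i, "kind": "dropout", "length": run})
    out = RawRecording(
        child_id=rec.child_id, sampling_rate=fs, time=rec.time, left=left, right=right,
        markers=rec.markers, trial_validity=rec.trial_validity, word_counts=rec.word_counts,
    )
    cols = ["trial", "channel", "sample", "kind", "length"]
    return out, pd.DataFrame(log, columns=cols)


# ---------------------------------------------------------------------------
# Behaviour and psychometrics
# ---------------------------------------------------------------------------

def generate_handedness(
    truth: pd.DataFrame, params: HandednessParams, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EHI item responses and QHP reach logs from each child's handedness latent."""
    rng = np.random.default_rng(seed)
    ehi_rows: list[dict] = []
    qhp_rows: list[dict] = []
    for _, row in truth.iterrows():
        h = row["handedness_latent"]
        u = h + rng.logistic(size=10)
        items = np.where(u > params.item_cut, "right", np.where(u < -params.item_cut, "left", "both"))
        for i, it in enumerate(items):
            ehi_rows.append({"child_id": row["child_id"], "item": behav.EHI_ITEMS[i], "response": it})
        for pos in range(1, 8):
            p_right = expit(h + params.position_slope * (pos - 4))
            for rep in range(3):
                hand = "right" if rng.random() < p_right else "left"
                qhp_rows.append({"child_id": row["child_id"], "position": pos, "rep": rep + 1, "hand": hand})
    return pd.DataFrame(ehi_rows), pd.DataFrame(qhp_rows)


def _dld_probability(params: LanguageScoreParams, shift: float, n_mc: int = 20000, seed: int = 12345) -> float:
    """Monte-Carlo P(>=2 of 13 measures more than 1 SD below norm) under the model."""
    rng = np.random.default_rng(seed)
    rho = params.inter_measure_corr
    n_meas = len(behav.LANGUAGE_MEASURES)
    f = rng.standard_normal((n_mc, 1))
    e = rng.standard_normal((n_mc, n_meas))
    z = np.sqrt(rho) * f + np.sqrt(1 - rho) * e - shift
    flags = (z < -1.0).sum(axis=1)
    return float((flags >= 2).mean())


def calibrate_dld_destination_prob(config: SimulationConfig) -> float:
    """Probability of destining a child for DLD so expected prevalence hits target."""
    p = config.language_score_params
    q0 = _dld_probability(p, 0.0)
    q1 = _dld_probability(p, p.dld_shift)
    if q1 <= q0:
        raise ConfigurationError("language_score_params: dld_shift does not raise DLD probability")
    return float(np.clip((config.prop_dld_target - q0) / (q1 - q0), 0.0, 1.0))


def generate_language_scores(
    truth: pd.DataFrame, params: LanguageScoreParams, seed: int
) -> pd.DataFrame:
    """Correlated normed scores (13 language/literacy measures + performance IQ).

    Raises on a correlation target that is not positive definite.
    """
    rng = np.random.default_rng(seed)
    rho = params.inter_measure_corr
    measures = list(behav.LANGUAGE_MEASURES) + ["performance_iq"]
    n_meas = len(measures)
    corr = np.full((n_meas, n_meas), rho)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("inter-measure correlation target is not positive definite") from exc
    n = len(truth)
    z = rng.standard_normal((n, n_meas)) @ chol.T
    dld = truth["destined_dld"].to_numpy().astype(float)
    z[:, :-1] -= params.dld_shift * dld[:, None]
    z[:, -1] -= params.dld_iq_shift * dld
    out = {"child_id": truth["child_id"].to_numpy()}
    for j, m in enumerate(measures):
        mean, sd = params.norms[m]
        out[m] = mean + sd * z[:, j]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _true_dominance_class(effect: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Label children by thresholding the true effect at marginal-distribution quantiles.

    Right-dominant below the prop_right_dominant quantile, bilateral in the
    next prop_bilateral band, left above; keeps the effect distribution (and
    hence its pair ICC) untouched while realized prevalences are binomial
    around the targets.
    """
    mean = config.lateral_effect_mean
    sd = config.lateral_effect_sd
    if sd <= 0:
        return np.where(effect > 0, "left", np.where(effect < 0, "right", "bilateral"))
    t_right = mean + sd * ndtri(config.prop_right_dominant) if config.prop_right_dominant > 0 else -np.inf
    t_bil = (
        mean + sd * ndtri(config.prop_right_dominant + config.prop_bilateral)
        if config.prop_right_dominant + config.prop_bilateral > 0
        else -np.inf
    )
    return np.where(effect < t_right, "right", np.where(effect < t_bil, "bilateral", "left"))


def generate_truth(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the per-child ground truth table (no recordings or instruments).

    Twin structure (shared pair id, zygosity and age; MZ pairs share sex),
    destined group membership, the pair-correlated true lateral effect, the
    derived dominance class, and the handedness latent.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[0])
    n_pairs = config.n_pairs
    n_children = 2 * n_pairs
    zyg_labels = np.array(["MZ", "DZss", "DZos"])
    zyg = rng.choice(zyg_labels, size=n_pairs, p=np.asarray(config.zygosity_mix))
    pair_ids = np.repeat([f"P{i:04d}" for i in range(n_pairs)], 2)
    child_ids = np.array([f"P{i:04d}-{t}" for i in range(n_pairs) for t in (1, 2)])
    twin_label = np.tile([1, 2], n_pairs)

    sex = np.empty(n_children, dtype=object)
    for i in range(n_pairs):
        if zyg[i] == "DZos":
            s = rng.permutation(["M", "F"])
        else:
            s = [rng.choice(["M", "F"])] * 2
        sex[2 * i], sex[2 * i + 1] = s[0], s[1]
    age = np.repeat(rng.uniform(6.0, 11.99, size=n_pairs), 2).round(2)

    # destined group, with calibrated destination probability
    p_dest = calibrate_dld_destination_prob(config)
    destined = rng.random(n_children) < p_dest

    # true lateral effect: pair-shared + individual components giving pair_icc_li
    icc = config.pair_icc_li
    sd = config.lateral_effect_sd
    u_pair = np.repeat(rng.standard_normal(n_pairs), 2)
    e_child = rng.standard_normal(n_children)
    effect = config.lateral_effect_mean + sd * (np.sqrt(icc) * u_pair + np.sqrt(1 - icc) * e_child)
    effect = effect + config.group_li_shift * destined
    dominance = _true_dominance_class(effect, config)

    hp = config.handedness_latent_params
    latent = hp.latent_mean + hp.latent_sd * rng.standard_normal(n_children)

    return pd.DataFrame({
        "child_id": child_ids, "pair_id": pair_ids, "twin_label": twin_label,
        "zygosity": np.repeat(zyg, 2), "sex": sex, "age": age,
        "destined_dld": destined, "true_li": effect,
        "true_dominance": dominance, "handedness_latent": latent,
    })


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic twin cohort: recordings, behaviour, psychometrics.

    Deterministic under (config, seed): identical inputs give bit-identical
    outputs.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    keys = ss.spawn(6)
    truth = generate_truth(config, np.random.default_rng(keys[0]))
    child_ids = truth["child_id"].to_numpy()
    effect = truth["true_li"].to_numpy()

    scores = generate_language_scores(truth, config.language_score_params, int(keys[1].generate_state(1)[0] % 2**31))
    hp = config.handedness_latent_params
    n_children = 2 * config.n_pairs
    ehi_items, qhp_reaches = generate_handedness(truth, hp, int(keys[2].generate_state(1)[0] % 2**31))

    # per-trial annotations and recordings
    rec_rng = np.random.default_rng(keys[3])
    art_seeds = keys[4].spawn(n_children)
    recordings = []
    trial_rows: list[dict] = []
    art_logs = []
    for i in range(n_children):
        hr = float(np.clip(rec_rng.normal(config.heart_rate_mean, config.heart_rate_sd), 55.0, 140.0))
        phase = float(rec_rng.uniform(0, 2 * np.pi))
        d_trials = effect[i] + config.trial_effect_sd * rec_rng.standard_normal(config.n_trials)
        valid = rec_rng.random(config.n_trials) >= config.invalid_trial_rate
        words = rec_rng.poisson(config.words_per_trial_mean, size=config.n_trials)
        rec = synthesize_recording(
            child_ids[i],
            sampling_rate=config.sampling_rate,
            n_trials=config.n_trials,
            base_left=config.base_velocity_left,
            base_right=config.base_velocity_right,
            pulsatility_amplitude=config.pulsatility_amplitude,
            heart_rate=hr,
            heart_phase=phase,
            activation_peak_pct=config.activation_peak_pct,
            poi_offsets_left=d_trials / 2.0,
            poi_offsets_right=-d_trials / 2.0,
            signal_noise_pct=config.signal_noise_pct,
            trial_validity=valid,
            word_counts=words,
            rng=rec_rng,
        )
        if config.artefact_rate > 0 or config.dropout_rate > 0:
            rec, alog = inject_artefacts(
                rec, config.artefact_rate, config.dropout_rate,
                seed=int(art_seeds[i].generate_state(1)[0] % 2**31),
            )
            alog.insert(0, "child_id", child_ids[i])
            art_logs.append(alog)
        recordings.append(rec)
        for k in range(config.n_trials):
            trial_rows.append({
                "child_id": child_ids[i], "trial_index": k,
                "talk_onset_s": rec.markers[k], "valid_flag": bool(valid[k]),
                "word_count": int(words[k]),
            })

    trials = pd.DataFrame(trial_rows)
    artefact_log = (
        pd.concat(art_logs, ignore_index=True)
        if art_logs
        else pd.DataFrame(columns=["child_id", "trial", "channel", "sample", "kind", "length"])
    )

    # cohort table: metadata + scored behaviour + classifier group
    cohort = truth[["child_id", "pair_id", "twin_label", "zygosity", "sex", "age"]].copy()
    cohort = cohort.merge(scores, on="child_id")
    groups, n_flags = [], []
    norms = config.language_score_params.norms
    for _, row in cohort.iterrows():
        nf, grp = behav.classify_dld({m: row[m] for m in behav.LANGUAGE_MEASURES}, norms)
        groups.append(grp)
        n_flags.append(nf)
    cohort["n_flags"] = n_flags
    cohort["group"] = groups
    ehi_scored = behav.score_ehi_table(ehi_items)
    qhp_scored = behav.score_qhp_table(qhp_reaches)
    cohort = cohort.merge(ehi_scored, on="child_id").merge(qhp_scored, on="child_id")

    return SyntheticCohort(
        recordings=recordings, cohort=cohort, truth=truth, trials=trials,
        ehi_items=ehi_items, qhp_reaches=qhp_reaches, artefact_log=artefact_log,
        config=config,
    )
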