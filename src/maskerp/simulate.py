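"""Synthetic behavioral (PAS) and EEG cohorts for the backward-masking
face paradigm.

The behavioral generator is an equal-variance SDT model on a single latent
"visibility" axis: each trial draws a latent strength from
``Normal(mu(stim_type, isi), 1)`` and the 4-point PAS rating is the number
of the participant's ordered criteria ``c1 < c2 < c3`` the sample exceeds,
plus one.  Condition means and criterion placement are chosen so that the
dichotomized SDT measures (yes/no at c1 for ISI0, at c2 for ISI200)
reproduce the magnitude and direction of the group-level sensitivity and
bias reported for this paradigm: a small positive d' with a strongly
conservative criterion under immediate masking, and high d' with a slightly
liberal criterion at ISI 200 ms.

The EEG generator plants P1 and N170 component templates (temporal
Gaussians times a zero-sum spatial pattern) into 1/f-plus-white noise,
adds a mask-evoked response delayed by target duration + ISI, and injects
artifacts (blinks on EOG with frontal propagation, gross-amplitude trials,
flat trials).  Component amplitudes per (stimulus type x ISI) cell are
calibrated so that the preprocessing pipeline's windowed means recover the
group condition means reported for the paradigm (e.g. conscious-face P1
near 2.4 uV, conscious-face N170 near -2.6 uV relative to scrambles and
blanks); the mask response's own contribution to each analysis window is
compensated analytically so the calibration is exact in the noiseless
limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .containers import EpochSet
from . import design as _design

__all__ = [
    "BehaviorGenParams",
    "EEGGenParams",
    "SyntheticCohort",
    "simulate_pas",
    "simulate_epochs",
    "simulate_cohort",
    "default_behavior_params",
    "default_eeg_params",
]

ANALYSIS_CHANNELS = ("P9", "P7", "PO7", "P10", "P8", "PO8")
EXTRA_SCALP = ("Oz", "POz", "Pz", "CPz", "Cz", "Fz", "Fp1", "Fp2")
EOG_CHANNELS = ("HEOG", "VEOG")

P1_WINDOW_S = (0.080, 0.100)
N170_WINDOW_S = (0.130, 0.170)


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorGenParams:
    """Latent-strength SDT generative model for PAS ratings.

    ``mu`` maps (stim_type, isi_ms) to the latent mean in latent-SD units.
    Criteria are drawn per participant as ``criteria_mean`` plus a shared
    normal shift (between-participant criterion SD) plus small per-criterion
    jitter, kept strictly increasing.  ``outlier_rate`` participants receive
    an additional ``outlier_offset`` shift on all criteria, emulating the
    extreme-response-bias participants the exclusion rule must catch.
    """

    mu: dict = field(
        default_factory=lambda: {
            ("face", 0): 0.45,
            ("scramble", 0): 0.30,
            ("blank", 0): 0.00,
            ("face", 200): 4.70,
            ("scramble", 200): 2.10,
            ("blank", 200): 2.00,
        }
    )
    criteria_mean: tuple[float, float, float] = (1.40, 2.85, 3.60)
    criteria_shift_sd: float = 0.35
    criteria_jitter_sd: float = 0.08
    sensitivity_sd: float = 0.45
    outlier_rate: float = 0.0
    outlier_offset: float = 4.0

    def validate(self) -> None:
        c = self.criteria_mean
        if not (c[0] < c[1] < c[2]):
            raise ValueError("criteria_mean must be strictly increasing")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must lie in [0, 1]")


def draw_participant_behavior(
    params: BehaviorGenParams, rng: np.random.Generator, force_outlier: bool | None = None
) -> dict:
    """Per-participant ground truth: criteria, sensitivity gain, outlier flag."""
    shift = rng.normal(0.0, params.criteria_shift_sd)
    jitter = rng.normal(0.0, params.criteria_jitter_sd, 3)
    is_outlier = (
        bool(rng.random() < params.outlier_rate) if force_outlier is None else force_outlier
    )
    if is_outlier:
        shift += params.outlier_offset * (1 if rng.random() < 0.5 else -1)
    criteria = np.sort(np.asarray(params.criteria_mean) + shift + jitter)
    # sort guards against jitter-induced swaps; enforce strict increase
    eps = 1e-6
    for i in (1, 2):
        if criteria[i] <= criteria[i - 1]:
            criteria[i] = criteria[i - 1] + eps
    gain = rng.normal(0.0, params.sensitivity_sd)
    return {"criteria": criteria, "sensitivity_offset": gain, "is_outlier": is_outlier}


def simulate_pas(
    plan: pd.DataFrame,
    params: BehaviorGenParams,
    seed: int | np.random.Generator = 0,
    participant: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a 4-point PAS rating for every trial of ``plan``.

    Returns ``(plan_with_pas, participant_ground_truth)``.  The rating is
    ``1 + #(criteria below the latent sample)``; the latent mean is the
    condition mean plus the participant's sensitivity offset for non-blank
    targets (blanks carry no signal to be more or less sensitive to).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    if participant is None:
        participant = draw_participant_behavior(params, rng)
    criteria = np.asarray(participant["criteria"], dtype=float)
    if not (criteria[0] < criteria[1] < criteria[2]):
        raise ValueError("participant criteria must be strictly increasing")
    mu = np.array(
        [
            params.mu[(st, isi)]
            + (participant["sensitivity_offset"] if st != "blank" else 0.0)
            for st, isi in zip(plan["stim_type"], plan["isi_ms"])
        ]
    )
    latent = rng.normal(mu, 1.0)
    pas = 1 + (latent[:, None] > criteria[None, :]).sum(axis=1)
    out = plan.copy()
    out["pas"] = pas.astype(int)
    return out, participant


# --------------------------------------------------------------------------
# EEG
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EEGGenParams:
    """Signal model for synthetic epochs.

    Component templates are temporal Gaussians (peak latency / width in
    seconds) times a spatial pattern that is 1 on the six occipito-temporal
    analysis channels and balances to zero mean across scalp channels, so
    average-referencing leaves planted amplitudes untouched.  Each template
    is normalized so a unit amplitude yields a windowed mean of exactly
    1 uV in its own analysis window.

    ``p1_uv`` / ``n170_uv`` give the target pipeline-recovered windowed
    mean (uV) per (stim_type, isi_ms) cell; the mask-evoked response's
    window contribution is subtracted from these internally.
    """

    sfreq: float = 512.0
    tmin: float = -0.2
    tmax: float = 0.8
    target_duration_s: float = 0.017

    p1_latency_s: float = 0.090
    p1_width_s: float = 0.010
    n170_latency_s: float = 0.150
    n170_width_s: float = 0.015

    p1_uv: dict = field(
        default_factory=lambda: {
            ("face", 0): 2.45,
            ("scramble", 0): 2.40,
            ("blank", 0): 2.15,
            ("face", 200): 2.35,
            ("scramble", 200): 2.30,
            ("blank", 200): 1.35,
        }
    )
    n170_uv: dict = field(
        default_factory=lambda: {
            ("face", 0): -0.65,
            ("scramble", 0): 0.50,
            ("blank", 0): 0.45,
            ("face", 200): -4.50,
            ("scramble", 200): -1.00,
            ("blank", 200): -0.95,
        }
    )

    mask_p1_uv: float = 3.0
    mask_n1_uv: float = -2.0

    participant_gain_sd: float = 0.25
    participant_offset_sd: float = 2.0
    trial_amplitude_sd: float = 1.0

    pink_noise_uv: float = 6.0
    white_noise_uv: float = 3.0
    pink_exponent: float = 1.0

    blink_rate: float = 0.05
    gross_artifact_rate: float = 0.02
    flat_rate: float = 0.005

    ch_names: tuple = ANALYSIS_CHANNELS + EXTRA_SCALP + EOG_CHANNELS

    def validate(self) -> None:
        if self.sfreq <= 0 or self.tmax <= self.tmin:
            raise ValueError("invalid epoch geometry")
        for lat in (self.p1_latency_s, self.n170_latency_s):
            if not (self.tmin < lat < self.tmax):
                raise ValueError("component latency outside the epoch window")
        for rate in (self.blink_rate, self.gross_artifact_rate, self.flat_rate):
            if not 0 <= rate <= 1:
                raise ValueError("artifact rates must lie in [0, 1]")
        if self.pink_noise_uv < 0 or self.white_noise_uv < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round((self.tmax - self.tmin) * self.sfreq)) + 1

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sfreq

    @property
    def ch_types(self) -> list[str]:
        return ["eog" if n in EOG_CHANNELS else "eeg" for n in self.ch_names]


def _window_mask(times: np.ndarray, window_s: tuple[float, float]) -> np.ndarray:
    return (times >= window_s[0] - 1e-9) & (times <= window_s[1] + 1e-9)


def _spatial_pattern(params: EEGGenParams) -> np.ndarray:
    """Occipital pattern: 1 on analysis channels, zero-sum over scalp."""
    names = list(params.ch_names)
    pattern = np.zeros(len(names))
    ana = [names.index(c) for c in ANALYSIS_CHANNELS]
    extras = [i for i, n in enumerate(names) if n in EXTRA_SCALP]
    pattern[ana] = 1.0
    pattern[extras] = -len(ana) / len(extras)
    return pattern


def _temporal_gaussian(times: np.ndarray, latency: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - latency) / width) ** 2)


def component_template(
    params: EEGGenParams, latency: float, width: float, window_s: tuple[float, float]
) -> np.ndarray:
    """channels x samples template whose windowed mean (analysis channels,
    inclusive window) equals exactly 1 for unit amplitude."""
    g = _temporal_gaussian(params.times, latency, width)
    pattern = _spatial_pattern(params)
    tpl = pattern[:, None] * g[None, :]
    names = list(params.ch_names)
    ana = [names.index(c) for c in ANALYSIS_CHANNELS]
    win = _window_mask(params.times, window_s)
    norm = tpl[np.ix_(ana, np.where(win)[0])].mean()
    return tpl / norm


def mask_response(params: EEGGenParams, isi_ms: int) -> np.ndarray:
    """Mask-evoked waveform: its own P1/N1-like bumps, onset at target
    duration + ISI."""
    onset = params.target_duration_s + isi_ms / 1000.0
    g1 = _temporal_gaussian(params.times, onset + params.p1_latency_s, params.p1_width_s)
    g2 = _temporal_gaussian(params.times, onset + params.n170_latency_s, params.n170_width_s)
    pattern = _spatial_pattern(params)
    return pattern[:, None] * (params.mask_p1_uv * g1 + params.mask_n1_uv * g2)[None, :]


def _mask_window_contribution(params: EEGGenParams, isi_ms: int) -> tuple[float, float]:
    """Mean of the mask-evoked waveform over the P1 / N170 analysis windows
    (analysis channels), used to compensate target amplitudes."""
    tpl = mask_response(params, isi_ms)
    names = list(params.ch_names)
    ana = [names.index(c) for c in ANALYSIS_CHANNELS]
    p1 = tpl[np.ix_(ana, np.where(_window_mask(params.times, P1_WINDOW_S))[0])].mean()
    n170 = tpl[np.ix_(ana, np.where(_window_mask(params.times, N170_WINDOW_S))[0])].mean()
    return p1, n170


def _pink_noise(rng: np.random.Generator, shape: tuple, sfreq: float, exponent: float) -> np.ndarray:
    """1/f^exponent amplitude-shaped Gaussian noise, unit variance, on the
    last axis."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1) * scale
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def draw_participant_eeg(params: EEGGenParams, rng: np.random.Generator) -> dict:
    """Participant-level ERP ground truth: multiplicative gain on condition
    effects and additive per-component offsets (shared across conditions)."""
    return {
        "gain": 1.0 + rng.normal(0.0, params.participant_gain_sd),
        "p1_offset": rng.normal(0.0, params.participant_offset_sd),
        "n170_offset": rng.normal(0.0, params.participant_offset_sd),
    }


def simulate_epochs(
    plan: pd.DataFrame,
    params: EEGGenParams,
    seed: int | np.random.Generator = 0,
    participant: dict | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """Synthesize one participant's epochs for every trial of ``plan``.

    ``plan`` must carry ``stim_type``, ``isi_ms`` and (if available) ``pas``
    columns.  Returns ``(EpochSet, ground_truth)`` where ground truth lists,
    per trial, the planted P1/N170 windowed-mean amplitudes and any injected
    artifact.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    if participant is None:
        participant = draw_participant_eeg(params, rng)

    n_trials = len(plan)
    n_ch = len(params.ch_names)
    n_t = params.n_samples
    times = params.times
    names = list(params.ch_names)

    p1_tpl = component_template(params, params.p1_latency_s, params.p1_width_s, P1_WINDOW_S)
    n170_tpl = component_template(params, params.n170_latency_s, params.n170_width_s, N170_WINDOW_S)
    mask_tpls = {isi: mask_response(params, isi) for isi in (0, 200)}
    mask_contrib = {isi: _mask_window_contribution(params, isi) for isi in (0, 200)}

    data = np.empty((n_trials, n_ch, n_t))
    noise = params.pink_noise_uv * _pink_noise(
        rng, (n_trials, n_ch, n_t), params.sfreq, params.pink_exponent
    ) + params.white_noise_uv * rng.standard_normal((n_trials, n_ch, n_t))

    gt_rows = []
    gain = participant["gain"]
    stim = plan["stim_type"].to_numpy()
    isi = plan["isi_ms"].to_numpy()
    eog_ix = [names.index(c) for c in EOG_CHANNELS]
    frontal = {"Fp1": 0.30, "Fp2": 0.30, "Fz": 0.15, "Cz": 0.07}

    for i in range(n_trials):
        key = (stim[i], int(isi[i]))
        p1_target = gain * (params.p1_uv[key] - mask_contrib[key[1]][0]) + participant["p1_offset"]
        n170_target = gain * (params.n170_uv[key] - mask_contrib[key[1]][1]) + participant["n170_offset"]
        a_p1 = p1_target + rng.normal(0.0, params.trial_amplitude_sd)
        a_n170 = n170_target + rng.normal(0.0, params.trial_amplitude_sd)
        epoch = a_p1 * p1_tpl + a_n170 * n170_tpl + gain * mask_tpls[key[1]] + noise[i]

        artifact = "none"
        u = rng.random()
        if u < params.flat_rate:
            artifact = "flat"
            epoch[:] = 0.0
        elif u < params.flat_rate + params.gross_artifact_rate:
            artifact = "gross"
            ch = rng.integers(0, n_ch - len(eog_ix))
            t0 = rng.integers(0, n_t - 20)
            epoch[ch, t0 : t0 + 20] += rng.choice([-1, 1]) * rng.uniform(200, 400)
        elif u < params.flat_rate + params.gross_artifact_rate + params.blink_rate:
            artifact = "blink"
            bl = rng.uniform(150, 350) * _temporal_gaussian(
                times, rng.uniform(times[0] + 0.1, times[-1] - 0.1), 0.05
            )
            epoch[names.index("VEOG")] += bl
            for chname, coef in frontal.items():
                epoch[names.index(chname)] += coef * bl

        data[i] = epoch
        gt_rows.append(
            {
                "trial": i,
                "p1_planted_uv": a_p1 + gain * mask_contrib[key[1]][0],
                "n170_planted_uv": a_n170 + gain * mask_contrib[key[1]][1],
                "artifact": artifact,
            }
        )

    metadata = plan.reset_index(drop=True).copy()
    epochs = EpochSet(
        data=data,
        sfreq=params.sfreq,
        ch_names=names,
        ch_types=params.ch_types,
        tmin=params.tmin,
        metadata=metadata,
    )
    return epochs, pd.DataFrame(gt_rows)


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Lazy cohort: per-participant data are regenerated deterministically
    from the master seed on each iteration, so a 40-participant cohort never
    needs to be held in memory at once."""

    n_participants: int
    behavior: BehaviorGenParams
    eeg: EEGGenParams
    seed: int
    n_exemplars: int = 80
    reps: int = 1
    outlier_participants: tuple[int, ...] = ()  # 1-based indices forced to extreme bias

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        ss = np.random.SeedSequence(self.seed)
        self._design_seed, self._participant_root = ss.spawn(2)
        self.versions = _design.make_versions(
            4, n_exemplars=self.n_exemplars, reps=self.reps, seed=int(self._design_seed.generate_state(1)[0] % 2**31)
        )

    def participant_plan(self, pid: int) -> pd.DataFrame:
        version = _design.assign_version(pid)
        plan = self.versions[version - 1].copy()
        plan.insert(0, "participant_id", pid)
        return plan

    def simulate_participant(self, pid: int, with_eeg: bool = True) -> dict:
        """Deterministically generate one participant (1-based id)."""
        child = np.random.SeedSequence(entropy=self._participant_root.entropy, spawn_key=(1, pid))
        rng = np.random.default_rng(child)
        plan = self.participant_plan(pid)
        force = True if pid in self.outlier_participants else None
        pb = draw_participant_behavior(self.behavior, rng, force_outlier=force)
        plan, pb = simulate_pas(plan, self.behavior, seed=rng, participant=pb)
        out = {"participant_id": pid, "plan": plan, "behavior_truth": pb}
        if with_eeg:
            pe = draw_participant_eeg(self.eeg, rng)
            epochs, gt = simulate_epochs(plan, self.eeg, seed=rng, participant=pe)
            out.update(epochs=epochs, eeg_truth=pe, trial_truth=gt)
        return out

    def iter_participants(self, with_eeg: bool = True) -> Iterator[dict]:
        for pid in range(1, self.n_participants + 1):
            yield self.simulate_participant(pid, with_eeg=with_eeg)

    def behavioral_table(self) -> pd.DataFrame:
        """All participants' trial tables with PAS ratings (no EEG)."""
        return pd.concat(
            [p["plan"] for p in self.iter_participants(with_eeg=False)], ignore_index=True
        )


def default_behavior_params(**overrides) -> BehaviorGenParams:
    return replace(BehaviorGenParams(), **overrides) if overrides else BehaviorGenParams()


def default_eeg_params(**overrides) -> EEGGenParams:
    return replace(EEGGenParams(), **overrides) if overrides else EEGGenParams()


def simulate_cohort(
    n_participants: int,
    behavior: BehaviorGenParams | None = None,
    eeg: EEGGenParams | None = None,
    seed: int = 0,
    scale: str = "reduced",
    **kwargs,
) -> SyntheticCohort:
    """Build a deterministic synthetic cohort.

    ``scale='reduced'`` runs the full 80-exemplar design at one repetition
    (480 trials/participant); ``scale='full'`` uses the complete two-
    repetition, 960-trial design.
    """
    if scale not in ("reduced", "full"):
        raise ValueError("scale must be 'reduced' or 'full'")
    reps = 1 if scale == "reduced" else 2
    return SyntheticCohort(
        n_participants=n_participants,
        behavior=behavior or BehaviorGenParams(),
        eeg=eeg or EEGGenParams(),
        seed=seed,
        reps=reps,
        **kwargs,
    )
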