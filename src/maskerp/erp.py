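"""EEG preprocessing and ERP component quantification.

Pipeline stages mirror a conventional backward-masking ERP analysis:
average reference over scalp channels, 0.01-40 Hz band-pass (first-order
high-pass, fourth-order low-pass Butterworth, applied zero-phase), EOG
regression, artifact rejection on absolute amplitude / gradient / low
signal, spherical-spline interpolation of bad channels, 200-ms pre-stimulus
baseline, awareness labeling (nonconscious = ISI0 & PAS 1, conscious =
ISI200 & PAS > 1), per-condition averaging with a minimum-trial participant
criterion, and windowed mean amplitudes for the P1 (80-100 ms) and N170
(130-170 ms) over the occipito-temporal channel clusters P9/P7/PO7 and
P10/P8/PO8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .containers import EpochSet

__all__ = [
    "RejectionSpec",
    "ComponentSpec",
    "P1_SPEC",
    "N170_SPEC",
    "bandpass",
    "average_reference",
    "eog_correct",
    "baseline_correct",
    "reject_artifacts",
    "interpolate_bad_channels",
    "label_awareness",
    "condition_average",
    "window_mean",
    "preprocess",
    "amplitude_table",
]

ANALYSIS_CHANNELS = ("P9", "P7", "PO7", "P10", "P8", "PO8")


@dataclass(frozen=True)
class RejectionSpec:
    """Artifact thresholds: absolute amplitude, sample-to-sample gradient,
    and a minimum within-epoch peak-to-peak ("low signal")."""

    abs_max_uv: float = 120.0
    gradient_max_uv: float = 75.0
    low_signal_min_uv: float = 0.01

    def __post_init__(self) -> None:
        if min(self.abs_max_uv, self.gradient_max_uv, self.low_signal_min_uv) <= 0:
            raise ValueError("rejection thresholds must be positive")


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    window_s: tuple[float, float]
    channels: tuple[str, ...] = ANALYSIS_CHANNELS


P1_SPEC = ComponentSpec("P1", (0.080, 0.100))
N170_SPEC = ComponentSpec("N170", (0.130, 0.170))


# --------------------------------------------------------------------------
# signal-level operations
# --------------------------------------------------------------------------

def bandpass(
    data: np.ndarray,
    sfreq: float,
    low_hz: float = 0.01,
    high_hz: float = 40.0,
) -> np.ndarray:
    """Zero-phase band-pass on the last axis.

    A first-order Butterworth high-pass (6 dB/octave) cascaded with a
    fourth-order low-pass (24 dB/octave), each applied forward-backward, so
    the effective magnitude response is the squared single-pass response.
    """
    if high_hz >= sfreq / 2:
        raise ValueError("high cutoff must be below Nyquist")
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    sos = np.vstack(
        [
            spsig.butter(1, low_hz, btype="highpass", fs=sfreq, output="sos"),
            spsig.butter(4, high_hz, btype="lowpass", fs=sfreq, output="sos"),
        ]
    )
    flat = data.reshape(-1, data.shape[-1])
    return spsig.sosfiltfilt(sos, flat, axis=-1).reshape(data.shape)


def average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the mean of scalp (EEG-type) channels; EOG channels
    do not enter the reference but are re-expressed against it."""
    scalp = epochs.scalp_indices()
    if scalp.size < 2:
        raise ValueError("average reference needs at least 2 scalp channels")
    out = epochs.copy()
    ref = out.data[:, scalp, :].mean(axis=1, keepdims=True)
    out.data[:, scalp, :] -= ref
    return out


def eog_correct(epochs: EpochSet) -> tuple[EpochSet, np.ndarray]:
    """Remove ocular activity from scalp channels by least-squares
    regression on the EOG channels (documented stand-in for proprietary
    automatic eye-artifact correction).

    Propagation coefficients are estimated on the concatenated epochs and
    subtracted: ``y <- y - B @ eog``.  Returns the corrected epochs and the
    (n_scalp, n_eog) coefficient matrix.  Zero-variance EOG channels yield
    zero coefficients with a warning.
    """
    eog = epochs.eog_indices()
    scalp = epochs.scalp_indices()
    if eog.size < 1:
        raise ValueError("no EOG channels present")
    out = epochs.copy()
    X = out.data[:, eog, :].transpose(1, 0, 2).reshape(eog.size, -1)
    Y = out.data[:, scalp, :].transpose(1, 0, 2).reshape(scalp.size, -1)
    X = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    gram = X @ X.T
    if np.linalg.matrix_rank(gram) < eog.size or np.any(np.diag(gram) == 0):
        warnings.warn("degenerate EOG covariance; coefficients set to 0")
        B = np.zeros((scalp.size, eog.size))
    else:
        B = np.linalg.solve(gram, X @ Yc.T).T
    corrected = Y - B @ X
    out.data[:, scalp, :] = corrected.reshape(scalp.size, epochs.n_trials, -1).transpose(1, 0, 2)
    return out, B


def baseline_correct(epochs: EpochSet, window_s: tuple[float, float] = (-0.2, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    times = epochs.times
    mask = (times >= window_s[0] - 1e-9) & (times <= window_s[1] + 1e-9)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def reject_artifacts(
    epochs: EpochSet, spec: RejectionSpec = RejectionSpec()
) -> tuple[np.ndarray, list[str]]:
    """Per-trial keep mask plus rejection reasons.

    A trial is rejected if any scalp channel exceeds the absolute-amplitude
    or gradient threshold, or its within-epoch peak-to-peak falls below the
    low-signal threshold.
    """
    scalp = epochs.scalp_indices()
    x = epochs.data[:, scalp, :]
    absmax = np.abs(x).max(axis=2)
    grad = np.abs(np.diff(x, axis=2)).max(axis=2) if x.shape[2] > 1 else np.zeros_like(absmax)
    ptp = x.max(axis=2) - x.min(axis=2)
    bad_abs = (absmax > spec.abs_max_uv).any(axis=1)
    bad_grad = (grad > spec.gradient_max_uv).any(axis=1)
    bad_low = (ptp < spec.low_signal_min_uv).any(axis=1)
    keep = ~(bad_abs | bad_grad | bad_low)
    reasons = []
    for a, g, l in zip(bad_abs, bad_grad, bad_low):
        tags = [t for t, b in (("absolute", a), ("gradient", g), ("low_signal", l)) if b]
        reasons.append("+".join(tags) if tags else "ok")
    return keep, reasons


def interpolate_bad_channels(
    epochs: EpochSet, bad_channels: list[str], montage: str = "standard_1005"
) -> EpochSet:
    """Replace bad scalp channels with spherical-spline estimates (Perrin
    interpolation, via mne) from the remaining scalp channels."""
    if not bad_channels:
        return epochs.copy()
    scalp_names = [n for n, t in zip(epochs.ch_names, epochs.ch_types) if t == "eeg"]
    unknown = set(bad_channels) - set(scalp_names)
    if unknown:
        raise KeyError(f"bad channels not in scalp set: {sorted(unknown)}")
    if len(bad_channels) > len(scalp_names) / 2:
        raise ValueError("more than half of the scalp channels marked bad")
    import mne

    info = mne.create_info(epochs.ch_names, sfreq=epochs.sfreq, ch_types=epochs.ch_types)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        info.set_montage(mne.channels.make_standard_montage(montage), on_missing="raise")
    mne_epochs = mne.EpochsArray(
        epochs.data * 1e-6, info, tmin=epochs.tmin, verbose="error"
    )
    mne_epochs.info["bads"] = list(bad_channels)
    mne_epochs.interpolate_bads(reset_bads=True, mode="accurate", verbose="error")
    out = epochs.copy()
    out.data = mne_epochs.get_data(copy=True) * 1e6
    return out


# --------------------------------------------------------------------------
# trial labeling and quantification
# --------------------------------------------------------------------------

def label_awareness(isi_ms, pas) -> np.ndarray:
    """Nonconscious: ISI 0 & PAS 1.  Conscious: ISI 200 & PAS > 1.
    Everything else is excluded from the ERP averages."""
    isi = np.asarray(isi_ms)
    pas = np.asarray(pas)
    out = np.full(isi.shape, "excluded", dtype=object)
    out[(isi == 0) & (pas == 1)] = "nonconscious"
    out[(isi == 200) & (pas > 1)] = "conscious"
    return out


def condition_average(
    epochs: EpochSet,
    keep: np.ndarray | None = None,
    min_trials: int = 40,
) -> tuple[pd.DataFrame, bool]:
    """Average retained epochs per (awareness x stim_type) cell.

    Returns ``(table, participant_ok)``; the table has one row per cell
    with the mean waveform (channels x samples), the trial count, and a
    ``sufficient`` flag.  ``participant_ok`` is False when any of the six
    cells holds fewer than ``min_trials`` trials.
    """
    md = epochs.metadata
    if md is None or not {"stim_type", "isi_ms", "pas"} <= set(md.columns):
        raise ValueError("epochs need stim_type/isi_ms/pas metadata")
    keep = np.ones(epochs.n_trials, bool) if keep is None else np.asarray(keep, bool)
    awareness = label_awareness(md["isi_ms"].to_numpy(), md["pas"].to_numpy())
    rows = []
    ok = True
    for aw in ("conscious", "nonconscious"):
        for st in ("face", "scramble", "blank"):
            mask = keep & (awareness == aw) & (md["stim_type"].to_numpy() == st)
            n = int(mask.sum())
            waveform = epochs.data[mask].mean(axis=0) if n else None
            sufficient = n >= min_trials
            ok &= sufficient
            rows.append(
                {
                    "awareness": aw,
                    "stim_type": st,
                    "n_trials": n,
                    "sufficient": sufficient,
                    "waveform": waveform,
                }
            )
    return pd.DataFrame(rows), ok


def window_mean(
    waveform: np.ndarray,
    ch_names: list[str],
    times: np.ndarray,
    comp: ComponentSpec,
) -> float:
    """Mean amplitude over the component's channels and all samples whose
    time lies inside the window (inclusive bounds)."""
    missing = [c for c in comp.channels if c not in ch_names]
    if missing:
        raise KeyError(f"missing channels: {missing}")
    chan_ix = [ch_names.index(c) for c in comp.channels]
    tmask = (times >= comp.window_s[0] - 1e-9) & (times <= comp.window_s[1] + 1e-9)
    if not tmask.any():
        raise ValueError("window contains no samples")
    return float(waveform[np.ix_(chan_ix, np.where(tmask)[0])].mean())


# --------------------------------------------------------------------------
# participant-level driver
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessConfig:
    filter_low_hz: float = 0.01
    filter_high_hz: float = 40.0
    apply_filter: bool = True
    rejection: RejectionSpec = field(default_factory=RejectionSpec)
    bad_channels: tuple[str, ...] = ()
    baseline_s: tuple[float, float] = (-0.2, 0.0)
    min_trials: int = 40
    components: tuple[ComponentSpec, ...] = (P1_SPEC, N170_SPEC)


def preprocess(epochs: EpochSet, cfg: PreprocessConfig = PreprocessConfig()) -> dict:
    """Run the full participant-level pipeline.

    Order: average reference -> band-pass -> EOG regression -> artifact
    rejection -> bad-channel interpolation -> baseline -> awareness
    labeling -> condition averages -> windowed component means.

    Returns a dict with the condition-average table, component amplitudes
    (long format), rejection bookkeeping, and the min-trials flag.
    """
    x = average_reference(epochs)
    if cfg.apply_filter:
        x = x.copy()
        x.data = bandpass(x.data, x.sfreq, cfg.filter_low_hz, cfg.filter_high_hz)
    x, eog_coefs = eog_correct(x)
    keep, reasons = reject_artifacts(x, cfg.rejection)
    if cfg.bad_channels:
        x = interpolate_bad_channels(x, list(cfg.bad_channels))
    x = baseline_correct(x, cfg.baseline_s)
    averages, participant_ok = condition_average(x, keep=keep, min_trials=cfg.min_trials)

    amp_rows = []
    for _, row in averages.iterrows():
        for comp in cfg.components:
            amp = (
                window_mean(row["waveform"], x.ch_names, x.times, comp)
                if row["waveform"] is not None
                else np.nan
            )
            amp_rows.append(
                {
                    "awareness": row["awareness"],
                    "stim_type": row["stim_type"],
                    "component": comp.name,
                    "amplitude_uv": amp,
                    "n_trials": row["n_trials"],
                }
            )
    return {
        "averages": averages,
        "amplitudes": pd.DataFrame(amp_rows),
        "keep": keep,
        "rejection_reasons": reasons,
        "n_rejected": int((~keep).sum()),
        "participant_ok": participant_ok,
        "eog_coefficients": eog_coefs,
    }


def amplitude_table(per_participant: dict[int, dict]) -> pd.DataFrame:
    """Stack participant preprocess outputs into one long table
    (participant_id x awareness x stim_type x component)."""
    frames = []
    for pid, res in per_participant.items():
        df = res["amplitudes"].copy()
        df.insert(0, "participant_id", pid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
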