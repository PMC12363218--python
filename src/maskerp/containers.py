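"""In-memory container for epoched multichannel EEG."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class EpochSet:
    """Trials x channels x samples array of EEG epochs, in microvolts.

    ``tmin`` is the time of the first sample relative to target onset in
    seconds (default -0.2, i.e. a 200-ms pre-stimulus baseline).  Per-trial
    metadata (condition, ISI, PAS rating, ...) rides along as a DataFrame
    with one row per epoch.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    ch_types: list[str]
    tmin: float = -0.2
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        if len(self.ch_types) != len(self.ch_names):
            raise ValueError("ch_types must align with ch_names")
        if self.metadata is not None and len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to target onset."""
        return self.tmin + np.arange(self.n_samples) / self.sfreq

    def channel_indices(self, names) -> np.ndarray:
        try:
            return np.array([self.ch_names.index(n) for n in names])
        except ValueError as err:
            raise KeyError(f"channel not present: {err}") from None

    def scalp_indices(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.ch_types) if t == "eeg"])

    def eog_indices(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.ch_types) if t == "eog"])

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            ch_types=list(self.ch_types),
            tmin=self.tmin,
            metadata=None if self.metadata is None else self.metadata.copy(),
        )

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset trials by boolean mask or index array."""
        md = None
        if self.metadata is not None:
            mask_arr = np.asarray(mask)
            md = self.metadata[mask_arr] if mask_arr.dtype == bool else self.metadata.iloc[mask_arr]
            md = md.reset_index(drop=True)
        return EpochSet(
            data=self.data[mask],
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            ch_types=list(self.ch_types),
            tmin=self.tmin,
            metadata=md,
        )

    # --- disk round trip (array + JSON sidecar + metadata TSV) ---

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "epochs.npy", self.data)
        sidecar = {
            "sfreq": self.sfreq,
            "tmin": self.tmin,
            "units": "uV",
            "ch_names": self.ch_names,
            "ch_types": self.ch_types,
        }
        (d / "epochs.json").write_text(json.dumps(sidecar, indent=1))
        if self.metadata is not None:
            self.metadata.to_csv(d / "metadata.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "EpochSet":
        d = Path(directory)
        sidecar = json.loads((d / "epochs.json").read_text())
        md_path = d / "metadata.tsv"
        metadata = pd.read_csv(md_path, sep="\t") if md_path.exists() else None
        return cls(
            data=np.load(d / "epochs.npy"),
            sfreq=sidecar["sfreq"],
            tmin=sidecar["tmin"],
            ch_names=sidecar["ch_names"],
            ch_types=sidecar["ch_types"],
            metadata=metadata,
        )


def read_raw_epochs(path: str | Path, **kwargs) -> "mne.io.BaseRaw":
    """Read a real continuous EEG recording (EDF/BDF) via mne."""
    import mne

    path = Path(path)
    if path.suffix.lower() == ".bdf":
        return mne.io.read_raw_bdf(path, preload=True, **kwargs)
    return mne.io.read_raw_edf(path, preload=True, **kwargs)
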