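"""Multichannel epoch container shared by all pipeline stages.

An :class:`EpochSet` holds a trials x channels x samples array together
with the sampling rate, channel names/types (64 scalp electrodes in the
BioSemi layout plus 4 EOG channels by default), and per-trial metadata
(condition cell, factor levels, provenance).  Round-trips to HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

BIOSEMI64 = "biosemi64"
EOG_CHANNELS = ("EXG1", "EXG2", "EXG3", "EXG4")


def default_channel_names() -> tuple[list[str], list[str]]:
    """64 BioSemi scalp labels plus 4 bipolar EOG channels."""
    import mne

    scalp = list(mne.channels.make_standard_montage(BIOSEMI64).ch_names)
    names = scalp + list(EOG_CHANNELS)
    types = ["eeg"] * len(scalp) + ["eog"] * len(EOG_CHANNELS)
    return names, types


@dataclass
class EpochSet:
    """Trials x channels x samples array with montage and trial metadata."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    sfreq: float
    ch_names: list[str]
    ch_types: list[str]
    metadata: pd.DataFrame  # one row per trial; must carry a "condition" column
    montage: str = BIOSEMI64

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must match trial count")
        if "condition" not in self.metadata.columns:
            raise ValueError("metadata must include a 'condition' column")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def conditions(self) -> pd.Series:
        return self.metadata["condition"]

    def scalp_picks(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.ch_types) == np.array("eeg"))

    def eog_picks(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.ch_types) == np.array("eog"))

    def pick_channel(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            ch_types=list(self.ch_types),
            metadata=self.metadata.copy(),
            montage=self.montage,
        )

    def select_trials(self, index) -> "EpochSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return EpochSet(
            data=self.data[index],
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            ch_types=list(self.ch_types),
            metadata=self.metadata.iloc[index].reset_index(drop=True),
            montage=self.montage,
        )

    def select_condition(self, label: str) -> "EpochSet":
        return self.select_trials((self.conditions == label).to_numpy())

    # -- HDF5 round trip ---------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data, compression="gzip")
            fh.attrs["sfreq"] = self.sfreq
            fh.attrs["montage"] = self.montage
            fh.create_dataset("ch_names", data=np.array(self.ch_names, dtype="S"))
            fh.create_dataset("ch_types", data=np.array(self.ch_types, dtype="S"))
            meta = fh.create_group("metadata")
            for col in self.metadata.columns:
                vals = self.metadata[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                meta.create_dataset(col, data=vals)
            meta.attrs["columns"] = np.array(self.metadata.columns, dtype="S")

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as fh:
            cols = [c.decode() for c in fh["metadata"].attrs["columns"]]
            meta = {}
            for col in cols:
                vals = fh["metadata"][col][()]
                if vals.dtype.kind == "S":
                    vals = np.array([v.decode() for v in vals])
                meta[col] = vals
            return cls(
                data=fh["data"][()],
                sfreq=float(fh.attrs["sfreq"]),
                ch_names=[c.decode() for c in fh["ch_names"][()]],
                ch_types=[c.decode() for c in fh["ch_types"][()]],
                metadata=pd.DataFrame(meta),
                montage=str(fh.attrs["montage"]),
            )

    def to_mne(self):
        """View as an mne.EpochsArray (volts, montage attached)."""
        import mne

        info = mne.create_info(self.ch_names, self.sfreq, self.ch_types)
        epo = mne.EpochsArray(self.data * 1e-6, info, verbose="error")
        epo.set_montage(self.montage, on_missing="ignore", verbose="error")
        return epo


def montage_positions(ch_names: list[str], montage: str = BIOSEMI64) -> np.ndarray:
    """3-D electrode positions (meters); EOG channels get NaN rows."""
    import mne

    mont = mne.channels.make_standard_montage(montage)
    pos = mont.get_positions()["ch_pos"]
    out = np.full((len(ch_names), 3), np.nan)
    for i, name in enumerate(ch_names):
        if name in pos:
            out[i] = pos[name]
    return out
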