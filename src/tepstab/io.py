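"""Readers and writers: internal HDF5 packed epochs, EEGLAB ``.set`` epochs,
optional FIF epochs (requires ``mne``), and stamped CSV/JSON outputs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .core import BlockMetadata, EpochedEEG

__all__ = [
    "save_block_h5",
    "load_block_h5",
    "read_eeglab_set",
    "read_fif_epochs",
    "read_epochs",
    "write_table",
    "read_table",
    "config_hash",
]

_META_FIELDS = (
    "subject_id", "age_years", "hemisphere", "day", "block_order",
    "rmt_pct_mso", "asm_use", "n_pulses", "block_id",
)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_block_h5(path, ep: EpochedEEG) -> None:
    """Write one block to the internal packed format (HDF5)."""
    with h5py.File(path, "w") as f:
        # track_times=False keeps reruns byte-identical
        f.create_dataset("data", data=ep.data, compression="gzip",
                         compression_opts=1, track_times=False)
        f.attrs["fs"] = ep.fs
        f.attrs["t0"] = ep.t0
        f.create_dataset("channels", data=np.array(ep.channels, dtype="S16"), track_times=False)
        f.create_dataset("bad_channels", data=np.array(sorted(ep.bad_channels), dtype="S16"), track_times=False)
        f.create_dataset("bad_trials", data=np.array(sorted(ep.bad_trials), dtype=int), track_times=False)
        if ep.meta is not None:
            g = f.create_group("meta")
            for k in _META_FIELDS:
                g.attrs[k] = getattr(ep.meta, k)
        f.attrs["tepstab_version"] = __version__


def load_block_h5(path) -> EpochedEEG:
    with h5py.File(path, "r") as f:
        meta = None
        if "meta" in f:
            a = dict(f["meta"].attrs)
            meta = BlockMetadata(
                subject_id=str(a["subject_id"]),
                age_years=float(a["age_years"]),
                hemisphere=str(a["hemisphere"]),
                day=int(a["day"]),
                block_order=int(a["block_order"]),
                rmt_pct_mso=float(a["rmt_pct_mso"]),
                asm_use=bool(a["asm_use"]),
                n_pulses=int(a["n_pulses"]),
                block_id=str(a["block_id"]),
            )
        return EpochedEEG(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            t0=float(f.attrs["t0"]),
            channels=tuple(c.decode() for c in f["channels"][()]),
            bad_channels=frozenset(c.decode() for c in f["bad_channels"][()]),
            bad_trials=frozenset(int(i) for i in f["bad_trials"][()]),
            meta=meta,
        )


def read_eeglab_set(path, meta: BlockMetadata | None = None) -> EpochedEEG:
    """Read epoched EEGLAB ``.set`` data (MAT container) via scipy.

    Expects the EEG struct with ``data`` (channels x samples x trials),
    ``srate``, ``xmin`` (s) and ``chanlocs.labels``.
    """
    from scipy.io import loadmat

    mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    eeg = mat.get("EEG", mat)
    if not hasattr(eeg, "data"):
        raise ValueError(f"{path}: no EEG struct with data found")
    data = np.asarray(eeg.data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    data = np.transpose(data, (2, 0, 1))  # -> trials x channels x samples
    chanlocs = np.atleast_1d(eeg.chanlocs)
    channels = tuple(str(c.labels) for c in chanlocs)
    return EpochedEEG(
        data=data,
        fs=float(eeg.srate),
        t0=float(eeg.xmin) * 1000.0,
        channels=channels,
        meta=meta,
    )


def read_fif_epochs(path, meta: BlockMetadata | None = None) -> EpochedEEG:
    """Read FIF epochs via ``mne`` (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is optional
        raise ImportError(
            "reading FIF epochs requires the optional 'mne' dependency "
            "(pip install tepstab[fif])"
        ) from exc
    epochs = mne.read_epochs(path, preload=True, verbose="error")
    data = epochs.get_data(copy=True) * 1e6  # V -> µV
    return EpochedEEG(
        data=data,
        fs=float(epochs.info["sfreq"]),
        t0=float(epochs.times[0]) * 1000.0,
        channels=tuple(epochs.ch_names),
        meta=meta,
    )


def read_epochs(path, meta: BlockMetadata | None = None) -> EpochedEEG:
    """Dispatch on file extension: .h5/.hdf5, .set, or .fif."""
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return load_block_h5(path)
    if suffix == ".set":
        return read_eeglab_set(path, meta)
    if suffix == ".fif":
        return read_fif_epochs(path, meta)
    raise ValueError(f"unsupported epoch file format: {suffix}")


# ---------------------------------------------------------------------------
# stamped tabular outputs


def write_table(df: pd.DataFrame, path, cfg_hash: str = "") -> None:
    """Write a CSV with a provenance comment header (version + config hash).

    Floats are fixed at 6 significant digits so reruns are byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write(f"# tepstab {__version__} config_hash={cfg_hash}\n")
        df.to_csv(f, index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
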