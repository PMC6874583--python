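"""Epoch container import/export.

Two interchangeable on-disk layouts for simulated (or real, pre-cleaned)
single-trial epochs:

* MNE FIF epoch files (``-epo.fif``), with the 64-channel BioSemi montage
  and one event code per condition — readable by any EEG toolchain;
* a compressed-array layout (``.npz`` per-condition arrays in µV plus a
  JSON sidecar with sampling metadata), convenient for bulk pipelines.
"""

from __future__ import annotations

import json

import numpy as np

from . import _arrayzip

from .montage import channel_names
from .simulate import (
    CONDITIONS,
    N_SAMPLES,
    ONSET_INDEX,
    SFREQ,
    SubjectData,
    SubjectSpec,
)

_EVENT_ID = {c: i + 1 for i, c in enumerate(CONDITIONS)}


def export_epochs_fif(subject: SubjectData, path) -> None:
    """Write one subject's epochs as an MNE FIF file (data in volts)."""
    import mne

    data, events = [], []
    for cond in CONDITIONS:
        arr = subject.epochs[cond]
        data.append(arr)
        events.extend([_EVENT_ID[cond]] * arr.shape[0])
    data = np.concatenate(data).astype(np.float64) * 1e-6  # µV -> V
    info = mne.create_info(list(channel_names()), SFREQ, ch_types="eeg")
    info.set_montage("biosemi64")
    n = data.shape[0]
    ev = np.column_stack(
        [np.arange(n) * N_SAMPLES, np.zeros(n, int), np.asarray(events)]
    )
    epochs = mne.EpochsArray(
        data,
        info,
        events=ev,
        tmin=-ONSET_INDEX / SFREQ,
        event_id=_EVENT_ID,
        baseline=None,
        verbose="error",
    )
    epochs.save(path, overwrite=True, verbose="error")


def import_epochs_fif(path, subject_id: str, group: str) -> SubjectData:
    """Read a FIF epoch file back into the per-condition layout (µV)."""
    import mne

    epochs = mne.read_epochs(path, preload=True, verbose="error")
    out = {}
    for cond in CONDITIONS:
        arr = epochs[cond].get_data(copy=True) * 1e6
        if arr.shape[1:] != (64, N_SAMPLES):
            raise ValueError(f"unexpected epoch shape {arr.shape[1:]} in {path}")
        out[cond] = arr.astype(np.float32)
    return SubjectData(spec=SubjectSpec(subject_id=subject_id, group=group), epochs=out)


def export_epochs_npz(subject: SubjectData, path) -> None:
    path = str(path).removesuffix(".npz")
    _arrayzip.savez(path, **{c: subject.epochs[c] for c in CONDITIONS})
    meta = {
        "subject_id": subject.subject_id,
        "group": subject.group,
        "sfreq": SFREQ,
        "onset_index": ONSET_INDEX,
        "units": "uV",
        "channels": list(channel_names()),
        "conditions": list(CONDITIONS),
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def import_epochs_npz(path) -> SubjectData:
    path = str(path).removesuffix(".npz")
    with open(path + ".json") as fh:
        meta = json.load(fh)
    with np.load(path + ".npz") as npz:
        epochs = {c: npz[c] for c in CONDITIONS}
    return SubjectData(
        spec=SubjectSpec(subject_id=meta["subject_id"], group=meta["group"]),
        epochs=epochs,
    )
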