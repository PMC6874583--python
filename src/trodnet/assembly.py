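"""Observation-tensor assembly.

Turns per-condition single-trial epochs into the fixed-size inputs the
classifier consumes: per subject, exactly 36 trials per condition
(sampling standards without replacement, bootstrapping under-represented
deviants), a 50-700 ms analysis window of S = 332 samples, and stacking of
one trial from each of the three conditions into an observation matrix of
N = 192 rows (64 channels x 3 conditions, condition-major). A cohort's
observations form a dataset tensor of shape T x N x S with aligned label
and subject-id vectors; a complete 54-subject first-test set has
T = 36 x 54 = 1944 observations.

Standardization (per flattened feature, mean 0 / variance 1) is fitted on
training observations only and applied as a frozen affine map elsewhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _arrayzip

from .montage import N_CHANNELS
from .simulate import CONDITIONS, Cohort, Epoch, SubjectData

#: trials retained per condition per subject
TRIALS_PER_CONDITION = 36
#: analysis-window length in samples: floor(0.650 s x 512 Hz)
WINDOW_SAMPLES = 332
#: window start, in samples after stimulus onset: ceil(0.050 x 512)
WINDOW_START_AFTER_ONSET = 26
#: observation row count: 64 channels x 3 conditions
N_ROWS = N_CHANNELS * len(CONDITIONS)

LABEL_OF_GROUP = {"control": 0, "concussed": 1}


# ---------------------------------------------------------------------------
# trial selection and windowing


def select_trials(
    epochs: np.ndarray, condition: str, target: int = TRIALS_PER_CONDITION, seed=0
) -> np.ndarray:
    """Bring one subject-condition epoch set to exactly ``target`` trials.

    Standards must have at least ``target`` trials and are sampled without
    replacement. Deviants with a surplus are subsampled without
    replacement; deviants short of ``target`` keep every original trial and
    are topped up by resampling with replacement (bootstrap).
    """
    epochs = np.asarray(epochs)
    n = epochs.shape[0]
    if n < 1:
        raise ValueError("need at least one epoch")
    rng = np.random.default_rng(seed)
    if condition == "standard":
        if n < target:
            raise ValueError(
                f"standard condition has {n} < {target} trials; the paradigm "
                "guarantees enough standards, so this indicates an upstream problem"
            )
        idx = rng.choice(n, size=target, replace=False)
    elif n >= target:
        idx = rng.choice(n, size=target, replace=False)
    else:
        extra = rng.choice(n, size=target - n, replace=True)
        idx = np.concatenate([np.arange(n), extra])
    return epochs[idx]


def slice_window(epoch) -> np.ndarray:
    """Extract the 64 x 332 analysis window (50-700 ms) from an epoch.

    Accepts an :class:`~trodnet.simulate.Epoch` or a bare (64, n_samples)
    array laid out on the same grid. The window starts at the first sample
    at or after +50 ms — 26 samples after stimulus onset — and spans
    exactly 332 samples. Idempotent on 332-sample inputs.
    """
    if isinstance(epoch, Epoch):
        data = epoch.data
        start = epoch.onset_index + WINDOW_START_AFTER_ONSET
    else:
        data = np.asarray(epoch)
        if data.shape[-1] == WINDOW_SAMPLES:
            return data
        from .simulate import ONSET_INDEX

        start = ONSET_INDEX + WINDOW_START_AFTER_ONSET
    if data.shape[-1] < start + WINDOW_SAMPLES:
        raise ValueError(
            f"epoch with {data.shape[-1]} samples does not cover the "
            f"{WINDOW_SAMPLES}-sample window starting at sample {start}"
        )
    return data[..., start : start + WINDOW_SAMPLES]


def build_observations(
    trials_by_condition: dict, subject_id: str, label: int
) -> "DatasetTensor":
    """Stack per-condition windowed trials into observations.

    ``trials_by_condition`` maps each condition to an array of exactly 36
    windowed trials (36, 64, 332). Observation k vertically stacks trial k
    of each condition in the fixed block order (standard, FDev, DDev); no
    trial is reused across observations within a condition.
    """
    blocks = []
    for cond in CONDITIONS:
        arr = np.asarray(trials_by_condition[cond])
        if arr.shape != (TRIALS_PER_CONDITION, N_CHANNELS, WINDOW_SAMPLES):
            raise ValueError(
                f"{cond}: expected {(TRIALS_PER_CONDITION, N_CHANNELS, WINDOW_SAMPLES)}, "
                f"got {arr.shape}"
            )
        blocks.append(arr)
    X = np.concatenate(blocks, axis=1).astype(np.float32)  # (36, 192, 332)
    return DatasetTensor(
        X=X,
        labels=np.full(TRIALS_PER_CONDITION, label, dtype=np.int64),
        subjects=np.array([subject_id] * TRIALS_PER_CONDITION),
    )


# ---------------------------------------------------------------------------
# dataset tensor


@dataclass
class DatasetTensor:
    """Stacked observations with aligned labels and subject ids."""

    X: np.ndarray  # (T, 192, 332) float32
    labels: np.ndarray  # (T,) int
    subjects: np.ndarray  # (T,) str
    session: str = "first"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        T = self.X.shape[0]
        if self.X.ndim != 3 or self.X.shape[1:] != (N_ROWS, WINDOW_SAMPLES):
            raise ValueError(f"X must be (T, {N_ROWS}, {WINDOW_SAMPLES})")
        if self.labels.shape != (T,) or self.subjects.shape != (T,):
            raise ValueError("labels and subjects must align with X")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def subject_ids(self) -> np.ndarray:
        """Unique subject ids in order of first appearance."""
        _, idx = np.unique(self.subjects, return_index=True)
        return self.subjects[np.sort(idx)]

    def subject_label(self, subject_id: str) -> int:
        lab = np.unique(self.labels[self.subjects == subject_id])
        if lab.size != 1:
            raise ValueError(f"inconsistent labels for subject {subject_id}")
        return int(lab[0])

    def subset(self, subject_ids) -> "DatasetTensor":
        mask = np.isin(self.subjects, np.asarray(list(subject_ids)))
        return DatasetTensor(
            self.X[mask], self.labels[mask], self.subjects[mask], self.session
        )

    @staticmethod
    def concatenate(tensors: list) -> "DatasetTensor":
        return DatasetTensor(
            np.concatenate([t.X for t in tensors]),
            np.concatenate([t.labels for t in tensors]),
            np.concatenate([t.subjects for t in tensors]),
            tensors[0].session,
        )

    def save(self, path) -> None:
        """Compressed-array export with a JSON metadata sidecar."""
        path = str(path)
        _arrayzip.savez(path, X=self.X)
        meta = {
            "labels": self.labels.tolist(),
            "subjects": self.subjects.tolist(),
            "session": self.session,
            "condition_order": list(CONDITIONS),
            "window": {
                "start_after_onset_samples": WINDOW_START_AFTER_ONSET,
                "n_samples": WINDOW_SAMPLES,
            },
        }
        with open(path.removesuffix(".npz") + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "DatasetTensor":
        path = str(path).removesuffix(".npz")
        with np.load(path + ".npz") as npz:
            X = npz["X"]
        with open(path + ".json") as fh:
            meta = json.load(fh)
        return cls(
            X=X,
            labels=np.asarray(meta["labels"]),
            subjects=np.asarray(meta["subjects"]),
            session=meta.get("session", "first"),
        )


def assemble_subject(subject: SubjectData, seed=0) -> DatasetTensor:
    """Select, window and pair one subject's trials into 36 observations.

    Trials are brought to 36 per condition, windowed, then independently
    shuffled within each condition (seeded) before pairing by index — the
    cross-condition pairing is arbitrary, so it is randomised rather than
    tied to acquisition order.
    """
    rng = np.random.default_rng(seed)
    trials = {}
    for cond in CONDITIONS:
        sel = select_trials(
            subject.epochs[cond], cond, seed=rng.integers(2**31)
        )
        windowed = slice_window(sel)
        trials[cond] = windowed[rng.permutation(TRIALS_PER_CONDITION)]
    return build_observations(
        trials, subject.subject_id, LABEL_OF_GROUP[subject.group]
    )


def assemble_cohort(cohort: Cohort, seed=0, session: str = "first") -> DatasetTensor:
    """Assemble every subject of a cohort into one dataset tensor."""
    rng = np.random.default_rng(seed)
    parts = [
        assemble_subject(s, seed=rng.integers(2**31)) for s in cohort.subjects
    ]
    out = DatasetTensor.concatenate(parts)
    out.session = session
    return out


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardizer:
    """Per-feature affine standardizer fitted on training data only.

    A feature is one (row, time-sample) cell of the N x S observation
    grid. Standard deviations below ``eps`` are floored (with a warning),
    keeping the transform finite and invertible where std > eps.
    """

    mean: np.ndarray = field(default=None)
    std: np.ndarray = field(default=None)
    eps: float = 1e-8

    def fit(self, train: DatasetTensor) -> "Standardizer":
        if len(train) == 0:
            raise ValueError("cannot fit a standardizer on an empty tensor")
        # float64 accumulators without materialising a float64 copy
        self.mean = train.X.mean(axis=0, dtype=np.float64)
        self.std = np.sqrt(train.X.var(axis=0, dtype=np.float64))
        n_floored = int((self.std < self.eps).sum())
        if n_floored:
            warnings.warn(
                f"{n_floored} features have (near-)zero variance; "
                f"flooring their scale at eps={self.eps}",
                stacklevel=2,
            )
            self.std = np.maximum(self.std, self.eps)
        return self

    def transform(self, data: DatasetTensor) -> DatasetTensor:
        if self.mean is None:
            raise ValueError("standardizer has not been fitted")
        Z = (data.X - self.mean.astype(np.float32)) / self.std.astype(np.float32)
        return DatasetTensor(Z, data.labels, data.subjects, data.session)

    def transform_array(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise ValueError("standardizer has not been fitted")
        return ((X - self.mean) / self.std).astype(np.float32)


def fit_standardizer(train: DatasetTensor, eps: float = 1e-8) -> Standardizer:
    return Standardizer(eps=eps).fit(train)


def apply_standardizer(std: Standardizer, data: DatasetTensor) -> DatasetTensor:
    return std.transform(data)
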