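"""Attribution of trained-model decisions and topographic summaries.

Decisions are explained with a DeepLIFT-style backward pass: every input
cell receives a signed contribution to the concussed-class pre-softmax
score relative to a reference input (the all-zero observation in
standardized space, i.e. the training mean). Linear layers propagate
exact multipliers; ReLUs use the rescale rule (delta-output over
delta-input); max-pooling routes each pooled delta to the window position
that attains the maximum on the actual input. Each local rule satisfies
summation-to-delta, so the chain-ruled attributions satisfy the
completeness property: they sum to f(x) - f(reference) up to floating
point error.

Following the subject-averaged protocol, attributions are computed on each
subject's mean standardized observation, and the cohort summary is the
mean of |attribution| over subjects, reshaped to (condition, channel,
time) for topographic display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _arrayzip
import pandas as pd

from .assembly import DatasetTensor, WINDOW_SAMPLES, WINDOW_START_AFTER_ONSET
from .montage import channel_names, layout_positions
from .simulate import CONDITIONS, SFREQ
from .model import TRODNet

#: guard for near-zero denominators in rescale multipliers
_EPS = 1e-7

CONCUSSED_CLASS = 1


def window_times_ms() -> np.ndarray:
    """Post-stimulus time (ms) of each analysis-window sample."""
    idx = WINDOW_START_AFTER_ONSET + np.arange(WINDOW_SAMPLES)
    return idx / SFREQ * 1000.0


def subject_average_inputs(tensor: DatasetTensor) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean observation per subject (standardized space).

    Returns ``(averages, subject_ids)`` with averages of shape
    (n_subjects, 192, 332), subject order = order of first appearance.
    """
    sids = tensor.subject_ids
    if len(tensor) == 0:
        raise ValueError("empty tensor")
    out = np.stack(
        [tensor.X[tensor.subjects == s].mean(axis=0) for s in sids]
    )
    return out.astype(np.float64), sids


def _forward_trace(model: TRODNet, X: np.ndarray) -> dict:
    """Float64 forward pass retaining pre-activations (attribution path)."""
    c = model.config
    p = {k: np.asarray(v, np.float64) for k, v in model.params.items()}
    B = X.shape[0]
    Xc = X.reshape(B, c.n_conditions, c.n_channels, c.n_samples)
    Z1 = np.einsum("bcht,chm->bcmt", Xc, p["W_conv"]) + p["b_conv"][None, :, :, None]
    A1 = np.maximum(Z1, 0.0)
    Fm = A1.reshape(B, c.n_conditions * c.n_maps, c.n_samples)
    starts = c.pool_stride * np.arange(c.pooled_length)
    win = starts[:, None] + np.arange(c.pool_size)[None, :]
    Fw = Fm[:, :, win]
    Pm = Fw.max(axis=3)
    flat = Pm.transpose(0, 2, 1).reshape(B, c.n_features)
    Zd = flat @ p["W_dense"] + p["b_dense"]
    H = np.maximum(Zd, 0.0)
    logits = H @ p["W_out"] + p["b_out"]
    return dict(Xc=Xc, Z1=Z1, Fm=Fm, Fw=Fw, Pm=Pm, Zd=Zd, H=H, logits=logits, win=win)


def _rescale(delta_out: np.ndarray, delta_in: np.ndarray, active: np.ndarray) -> np.ndarray:
    """ReLU multipliers: delta-ratio where defined, gradient at the input
    elsewhere (the two coincide in the limit)."""
    small = np.abs(delta_in) < _EPS
    safe = np.where(small, 1.0, delta_in)
    mult = delta_out / safe
    return np.where(small, active.astype(float), mult)


def attribute(
    model: TRODNet, inputs: np.ndarray, reference: np.ndarray, class_index: int = CONCUSSED_CLASS
) -> np.ndarray:
    """Signed per-cell attributions of the class score f(x) - f(reference).

    ``inputs`` is (n, 192, 332) (standardized space); ``reference`` a single
    (192, 332) observation. Returns attributions of the inputs' shape whose
    cell-sum equals the pre-softmax score difference for ``class_index``
    up to numerical tolerance.
    """
    c = model.config
    inputs = np.asarray(inputs, np.float64)
    single = inputs.ndim == 2
    if single:
        inputs = inputs[None]
    reference = np.asarray(reference, np.float64)
    if reference.shape != (c.n_rows, c.n_samples):
        raise ValueError(
            f"reference must have shape {(c.n_rows, c.n_samples)}, got {reference.shape}"
        )
    if inputs.shape[1:] != (c.n_rows, c.n_samples):
        raise ValueError("inputs and reference shapes disagree")

    tx = _forward_trace(model, inputs)
    tr = _forward_trace(model, np.broadcast_to(reference, inputs.shape).copy())
    p = {k: np.asarray(v, np.float64) for k, v in model.params.items()}
    B = inputs.shape[0]
    nm = c.n_conditions * c.n_maps

    # output layer -> dense activations (linear, exact)
    m_H = np.broadcast_to(p["W_out"][:, class_index], (B, c.dense_units)).copy()
    # dense ReLU (rescale)
    m_Zd = m_H * _rescale(
        np.maximum(tx["Zd"], 0) - np.maximum(tr["Zd"], 0),
        tx["Zd"] - tr["Zd"],
        tx["Zd"] > 0,
    )
    # dense linear -> pooled features
    m_flat = m_Zd @ p["W_dense"].T  # (B, features)
    m_P = m_flat.reshape(B, c.pooled_length, nm).transpose(0, 2, 1)  # (B, nm, pooled)

    # max-pool: route each pooled delta to the maximum position on x
    dPm = tx["Pm"] - tr["Pm"]  # (B, nm, pooled)
    dFm_full = tx["Fm"] - tr["Fm"]  # (B, nm, S)
    dFw = dFm_full[:, :, tx["win"]]  # (B, nm, pooled, pool)
    arg = tx["Fw"].argmax(axis=3)
    # if the x-argmax cell has (near-)zero delta, fall back to the window
    # cell with the largest |delta| so the local rule stays exact
    d_at_arg = np.take_along_axis(dFw, arg[..., None], axis=3)[..., 0]
    fallback = np.abs(dFw).argmax(axis=3)
    use_fallback = np.abs(d_at_arg) < _EPS
    route = np.where(use_fallback, fallback, arg)
    d_route = np.take_along_axis(dFw, route[..., None], axis=3)[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        m_route = np.where(np.abs(d_route) < _EPS, 0.0, m_P * dPm / np.where(d_route == 0, 1.0, d_route))
    m_Fm = np.zeros_like(tx["Fm"])
    cols = tx["win"][:, 0][None, None, :] + route
    bidx = np.arange(B)[:, None, None]
    jidx = np.arange(nm)[None, :, None]
    np.add.at(m_Fm, (bidx, jidx, cols), m_route)

    # conv ReLU (rescale)
    m_A1 = m_Fm.reshape(B, c.n_conditions, c.n_maps, c.n_samples)
    m_Z1 = m_A1 * _rescale(
        np.maximum(tx["Z1"], 0) - np.maximum(tr["Z1"], 0),
        tx["Z1"] - tr["Z1"],
        tx["Z1"] > 0,
    )
    # conv linear -> input channels
    m_X = np.einsum("bcmt,chm->bcht", m_Z1, p["W_conv"])
    attr = m_X.reshape(B, c.n_rows, c.n_samples) * (inputs - reference)
    return attr[0] if single else attr


def completeness_residual(
    model: TRODNet, inputs: np.ndarray, reference: np.ndarray, class_index: int = CONCUSSED_CLASS
) -> np.ndarray:
    """|sum(attributions) - (f(x) - f(ref))| per input — the additivity audit."""
    inputs = np.asarray(inputs, np.float64)
    if inputs.ndim == 2:
        inputs = inputs[None]
    attr = attribute(model, inputs, reference, class_index)
    fx = _forward_trace(model, inputs)["logits"][:, class_index]
    fr = _forward_trace(model, np.broadcast_to(reference, inputs.shape).copy())[
        "logits"
    ][:, class_index]
    return np.abs(attr.sum(axis=(1, 2)) - (fx - fr))


@dataclass
class AttributionSummary:
    """Mean absolute attribution per (condition, channel, time sample)."""

    values: np.ndarray  # (3, 64, 332), nonnegative
    n_subjects: int

    def __post_init__(self):
        self.values = np.asarray(self.values, np.float64)
        if self.values.shape != (len(CONDITIONS), 64, WINDOW_SAMPLES):
            raise ValueError(f"summary must be (3, 64, {WINDOW_SAMPLES})")
        if (self.values < 0).any():
            raise ValueError("mean absolute attributions must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        """Long table: condition, channel, time_ms, value."""
        names = channel_names()
        times = window_times_ms()
        rows = []
        for ci, cond in enumerate(CONDITIONS):
            for ch in range(64):
                rows.append(
                    pd.DataFrame(
                        {
                            "condition": cond,
                            "channel": names[ch],
                            "time_ms": times,
                            "value": self.values[ci, ch],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def save(self, path) -> None:
        path = str(path).removesuffix(".npz")
        _arrayzip.savez(
            path,
            values=self.values,
            n_subjects=np.asarray(self.n_subjects),
            layout=layout_positions(),
        )
        self.to_frame().to_csv(path + ".csv", index=False)


def summarize_attributions(attributions: np.ndarray) -> AttributionSummary:
    """Mean of |attribution| over subjects, on the (condition, channel,
    time) grid. Invariant to subject order; sign information is discarded
    before averaging, so opposite-signed contributions do not cancel."""
    attributions = np.asarray(attributions, np.float64)
    if attributions.ndim == 2:
        attributions = attributions[None]
    if attributions.ndim != 3 or attributions.shape[1:] != (
        len(CONDITIONS) * 64,
        WINDOW_SAMPLES,
    ):
        raise ValueError("attributions must be (n_subjects, 192, 332)")
    mean_abs = np.abs(attributions).mean(axis=0)
    values = mean_abs.reshape(len(CONDITIONS), 64, WINDOW_SAMPLES)
    return AttributionSummary(values=values, n_subjects=attributions.shape[0])


def explain_cohort(
    model: TRODNet, standardized: DatasetTensor
) -> tuple[AttributionSummary, np.ndarray, np.ndarray]:
    """Subject-averaged attribution summary for a standardized tensor.

    The model should be trained on all of ``standardized`` (the protocol
    interprets a single all-data model, not the CV fold models). Returns
    the summary plus the per-subject signed attributions and subject ids.
    """
    averages, sids = subject_average_inputs(standardized)
    reference = np.zeros((model.config.n_rows, model.config.n_samples))
    attrs = attribute(model, averages, reference)
    return summarize_attributions(attrs), attrs, sids


def plot_topographic_summary(summary: AttributionSummary, condition: str, path=None):
    """64-panel head plot of one condition's attribution time courses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ci = CONDITIONS.index(condition)
    xy = layout_positions()
    names = channel_names()
    # normalise electrode coordinates into [0, 1] panel positions
    span = xy.max(axis=0) - xy.min(axis=0)
    pos = (xy - xy.min(axis=0)) / span
    fig = plt.figure(figsize=(14, 12))
    vmax = summary.values[ci].max() or 1.0
    times = window_times_ms()
    for ch in range(64):
        ax = fig.add_axes(
            [0.04 + 0.9 * pos[ch, 0], 0.04 + 0.9 * pos[ch, 1], 0.07, 0.05]
        )
        ax.plot(times, summary.values[ci, ch], lw=0.7, color="tab:red")
        ax.set_ylim(0, vmax * 1.05)
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(names[ch], fontsize=5, pad=1)
    fig.suptitle(f"mean |attribution| — {condition}")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
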