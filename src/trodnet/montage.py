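"""64-channel sensor layout used throughout the package.

The simulator, the attribution summaries and the plotting helpers all share
one fixed channel order: the BioSemi 64-electrode cap (extended 10/20
positions, Fp1..O2), as provided by MNE's ``biosemi64`` standard montage.
Scalp topographies are defined on the 2-D projection of these positions.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

N_CHANNELS = 64


@lru_cache(maxsize=1)
def channel_names() -> tuple[str, ...]:
    """The fixed 64-channel order (BioSemi cap, 10/20 names)."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    return tuple(montage.ch_names)


@lru_cache(maxsize=1)
def layout_positions() -> np.ndarray:
    """(64, 2) array of 2-D head-plane coordinates, one row per channel.

    The 3-D montage positions are projected onto the x-y plane, which is
    adequate for the Gaussian-falloff topographies and topographic figure
    panels used here (no exact azimuthal projection is required).
    """
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    xy = np.array([pos[name][:2] for name in channel_names()], dtype=float)
    return xy


def channel_index(name: str) -> int:
    try:
        return channel_names().index(name)
    except ValueError as err:
        raise KeyError(f"unknown channel {name!r}") from err


def gaussian_topography(center: str, spread_m: float = 0.045) -> np.ndarray:
    """Unit-max Gaussian scalp weighting centred on an electrode.

    Parameters
    ----------
    center
        Electrode name (10/20 label, e.g. ``"Pz"``).
    spread_m
        Spatial standard deviation of the falloff in metres on the 2-D
        layout; 0.045 m gives the broad, smoothly decaying fields typical
        of auditory ERP components.
    """
    xy = layout_positions()
    c = xy[channel_index(center)]
    d2 = ((xy - c) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * spread_m**2))
    return w / w.max()
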