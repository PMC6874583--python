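"""Deterministic compressed array container.

``numpy.savez_compressed`` stamps zip entries with the current time, so two
identical runs produce different bytes. This writer emits the same
npz-compatible format (readable by ``numpy.load``) with a fixed timestamp,
making output checksums reproducible.
"""

from __future__ import annotations

import io
import zipfile

import numpy as np

_EPOCH = (1980, 1, 1, 0, 0, 0)


def savez(path, **arrays) -> None:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, value in arrays.items():
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asanyarray(value), allow_pickle=False)
            info = zipfile.ZipInfo(name + ".npy", date_time=_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())
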