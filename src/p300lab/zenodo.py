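"""Optional adapter for a locally downloaded Brain Invaders recording
(Zenodo record 2649069).

Nothing in the package or its tests depends on this module; it exists so
the pipeline can be pointed at the real dataset when the .mat files have
been fetched manually. Each session file is expected to hold a samples x
(1 + channels + 1) matrix (time, EEG channels, event column) under one of
the conventional variable names; event codes >= 1 mark flash onsets, with
the TARGET/NON-TARGET distinction in the code value (2 = target flash,
1 = non-target flash).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .exceptions import FormatError
from .synth import NONTARGET, TARGET

_VAR_NAMES = ("samples", "data", "y")


def load_zenodo_bi(path: str | Path, sfreq: float = 512.0):
    """Read one session .mat file into (record, onsets, labels, sfreq).

    Returns the continuous record as (channels, samples) plus flash onset
    sample indices and TARGET/NON-TARGET labels, ready for the standard
    ``bandpass`` / ``extract_epochs`` pipeline.
    """
    from scipy.io import loadmat

    path = Path(path)
    try:
        mat = loadmat(path)
    except Exception as exc:  # noqa: BLE001 - scipy raises various types
        raise FormatError(f"cannot read {path} as a .mat file: {exc}") from exc
    array = None
    for name in _VAR_NAMES:
        if name in mat:
            array = np.asarray(mat[name], dtype=float)
            break
    if array is None:
        raise FormatError(
            f"{path} contains none of the expected variables {_VAR_NAMES}; "
            f"found {sorted(k for k in mat if not k.startswith('__'))}"
        )
    if array.ndim != 2 or array.shape[1] < 3:
        raise FormatError(
            f"expected a samples x (time + channels + event) matrix, got "
            f"shape {array.shape}"
        )
    record = array[:, 1:-1].T  # drop time column and event column
    events = array[:, -1].astype(int)
    onsets = np.flatnonzero(events > 0)
    labels = np.where(events[onsets] >= 2, TARGET, NONTARGET)
    return record, onsets, labels, sfreq
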