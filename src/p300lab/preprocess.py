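"""Band-pass filtering and epoch extraction.

The band-pass is a Hamming-window FIR applied forward and backward
(zero net group delay); the epoch sample convention is half-open,
``[floor(tmin * sfreq), floor(tmax * sfreq))`` relative to each onset,
which yields 77 samples for the default 0.1-0.7 s window at 128 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import BoundsError, ParameterError
from .synth import EpochSet


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: pass band edges and FIR taper."""

    low: float = 1.0
    high: float = 24.0
    window: str = "hamming"
    numtaps: int | None = None  # derived from the transition width if None

    def validate(self, sfreq: float) -> None:
        if not 0 < self.low < self.high < sfreq / 2:
            raise ParameterError(
                f"need 0 < low < high < sfreq/2, got low={self.low}, "
                f"high={self.high}, sfreq={sfreq}"
            )

    def resolve_numtaps(self, sfreq: float) -> int:
        if self.numtaps is not None:
            n = int(self.numtaps)
        else:
            # Hamming window: ~3.3 / transition-width(normalized) taps; the
            # narrow transition is at the low edge.
            transition = min(self.low, sfreq / 2 - self.high)
            n = int(np.ceil(3.3 * sfreq / transition))
        return n + 1 if n % 2 == 0 else n  # odd => symmetric type-I FIR


def design_bandpass(spec: FilterSpec, sfreq: float) -> np.ndarray:
    """Return the FIR taps for one forward pass."""
    spec.validate(sfreq)
    numtaps = spec.resolve_numtaps(sfreq)
    return signal.firwin(
        numtaps,
        [spec.low, spec.high],
        pass_zero=False,
        window=spec.window,
        fs=sfreq,
    )


def bandpass(
    record: np.ndarray, sfreq: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Zero-phase band-pass of a (channels, samples) record.

    Forward-backward application with reflect padding; the record must be
    longer than 3x the filter order.
    """
    record = np.atleast_2d(np.asarray(record, dtype=float))
    taps = design_bandpass(spec, sfreq)
    padlen = 3 * (len(taps) - 1)
    if record.shape[-1] <= padlen:
        raise ParameterError(
            f"record length {record.shape[-1]} must exceed 3x filter order "
            f"({padlen} samples)"
        )
    return signal.filtfilt(taps, [1.0], record, axis=-1, padtype="even",
                           padlen=padlen)


def epoch_sample_span(sfreq: float, tmin: float, tmax: float) -> tuple[int, int]:
    """Half-open sample offsets [start, stop) of the epoch window."""
    start = int(np.floor(tmin * sfreq))
    stop = int(np.floor(tmax * sfreq))
    if stop <= start:
        raise ParameterError(f"empty epoch window: tmin={tmin}, tmax={tmax}")
    return start, stop


def extract_epochs(
    record: np.ndarray,
    onsets: np.ndarray,
    labels: np.ndarray,
    sfreq: float,
    tmin: float = 0.1,
    tmax: float = 0.7,
) -> EpochSet:
    """Cut one fixed-length epoch per onset from a continuous record."""
    record = np.atleast_2d(np.asarray(record, dtype=float))
    onsets = np.asarray(onsets, dtype=int)
    labels = np.asarray(labels)
    if len(onsets) != len(labels):
        raise ParameterError(
            f"onsets ({len(onsets)}) and labels ({len(labels)}) differ in length"
        )
    start, stop = epoch_sample_span(sfreq, tmin, tmax)
    n_samples = record.shape[-1]
    data = np.empty((len(onsets), record.shape[0], stop - start))
    for i, onset in enumerate(onsets):
        lo, hi = onset + start, onset + stop
        if lo < 0 or hi > n_samples:
            raise BoundsError(
                f"epoch window [{lo}, {hi}) for onset index {i} "
                f"(sample {onset}) exceeds record bounds [0, {n_samples})"
            )
        data[i] = record[:, lo:hi]
    return EpochSet(data=data, labels=labels, sfreq=sfreq, window=(tmin, tmax))
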