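"""Hilbert-transform envelope of a filtered heart-sound signal.

The instantaneous envelope is the modulus of the analytic signal,

    e(t) = sqrt(x(t)^2 + xh(t)^2),

where ``xh`` is the Hilbert transform of ``x`` (the principal-value
convolution of x with 1/(pi t)).  The discrete transform is realized
through the standard frequency-domain analytic-signal construction
(``scipy.signal.hilbert``): zero the negative-frequency half of the
DFT, double the positive half, inverse-transform, and take real and
imaginary parts.

The envelope is computed once over the full filtered recording and
then windowed per cardiac phase downstream.  Computing it per beat
would re-introduce Hilbert edge artifacts at every beat boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .filtering import FilteredSignal

__all__ = ["EnvelopeTrace", "hilbert_envelope"]


@dataclass(frozen=True)
class EnvelopeTrace:
    """Envelope e(t) plus the Hilbert component it was built from."""

    envelope: np.ndarray
    hilbert_component: np.ndarray
    sampling_rate: float
    source: Optional[FilteredSignal] = None

    def __len__(self) -> int:
        return len(self.envelope)


def hilbert_envelope(signal: FilteredSignal | np.ndarray, sampling_rate: float | None = None) -> EnvelopeTrace:
    """Compute the analytic-signal envelope of a filtered channel.

    Accepts either a :class:`FilteredSignal` or a bare array plus
    ``sampling_rate``.  Raises on non-finite input or signals shorter
    than 16 samples (too short for a meaningful analytic signal).
    """
    if isinstance(signal, FilteredSignal):
        x = signal.samples
        fs = signal.sampling_rate
        src = signal
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required when passing a bare array")
        x = np.asarray(signal, dtype=float)
        fs = float(sampling_rate)
        src = None
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if len(x) < 16:
        raise ValueError(f"signal too short for envelope extraction ({len(x)} < 16 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in input signal")
    analytic = sps.hilbert(x)
    env = np.abs(analytic)
    return EnvelopeTrace(env, analytic.imag, fs, src)
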