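"""Anti-aliased down-sampling of tri-axial streams (e.g. 100 -> 50/25/10 Hz).

Polyphase resampling with a linear-phase Kaiser-window FIR low-pass:
cutoff 0.45x the target rate, stopband attenuation >= 60 dB, transition
band from the cutoff to the target Nyquist. The signal is reflect-padded by
one filter length on each side before filtering, so the symmetric filter's
group delay is fully compensated (zero-phase behaviour) and edge transients
from zero-padding are avoided. DC gain is exactly one, so constant
(gravity-only) signals survive to well below 1e-6 g.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import ConfigurationError, TriaxialRecord, UnsupportedOperationError

__all__ = ["downsample", "resample_all", "design_antialias_fir"]

log = logging.getLogger(__name__)

STOPBAND_DB = 60.0
CUTOFF_FRACTION = 0.45  # of the target sample rate


def design_antialias_fir(source_hz: float, target_hz: float, up: int = 1) -> np.ndarray:
    """Kaiser-window FIR for decimation from ``source_hz*up`` to ``target_hz``.

    The filter operates at the upsampled rate ``source_hz * up``; its cutoff
    sits at ``CUTOFF_FRACTION * target_hz`` and the stopband starts at the
    target Nyquist ``target_hz / 2``.
    """
    work_nyq = source_hz * up / 2.0
    cutoff = CUTOFF_FRACTION * target_hz
    stop = target_hz / 2.0
    width = (stop - cutoff) / work_nyq
    numtaps, beta = signal.kaiserord(STOPBAND_DB, width)
    numtaps |= 1  # odd length -> integer group delay, exactly linear phase
    taps = signal.firwin(numtaps, cutoff / work_nyq, window=("kaiser", beta))
    return taps


def _resample_axis(a: np.ndarray, up: int, down: int, taps: np.ndarray) -> np.ndarray:
    """Polyphase resample one axis with reflect padding and delay compensation."""
    # pad enough input samples to cover the filter's half length at the
    # upsampled rate on both sides
    pad = int(np.ceil(len(taps) / (2 * up))) + down
    pad = min(pad, len(a) - 1)
    padded = np.concatenate([a[pad:0:-1], a, a[-2 : -2 - pad : -1]])
    # resample_poly centers the symmetric filter itself (zero-phase)
    out = signal.resample_poly(padded, up, down, window=taps * up)
    # strip the resampled padding: pad input samples correspond to
    # pad * up / down output samples
    lead = int(round(pad * up / down))
    n_out = int(np.floor(len(a) * up / down))
    return out[lead : lead + n_out]


def downsample(record: TriaxialRecord, target_rate_hz: float) -> TriaxialRecord:
    """Down-sample a record to ``target_rate_hz`` with anti-aliasing.

    The source/target ratio must be rational (denominator <= 1000). Output
    timestamps are regenerated on the target grid starting at the source's
    first timestamp.
    """
    source = record.sample_rate_hz
    if target_rate_hz > source:
        raise UnsupportedOperationError(
            f"up-sampling {source} -> {target_rate_hz} Hz is not supported; "
            "information above the source Nyquist cannot be recovered"
        )
    if target_rate_hz <= 0:
        raise ConfigurationError("target rate must be positive")
    if target_rate_hz == source:
        return TriaxialRecord(
            timestamps=record.timestamps.copy(),
            x=record.x.copy(),
            y=record.y.copy(),
            z=record.z.copy(),
            sample_rate_hz=source,
            dynamic_range_g=record.dynamic_range_g,
        )
    frac = Fraction(target_rate_hz / source).limit_denominator(1000)
    if abs(float(frac) - target_rate_hz / source) > 1e-9:
        raise ConfigurationError(
            f"rate ratio {target_rate_hz}/{source} is not a small rational number"
        )
    up, down = frac.numerator, frac.denominator
    taps = design_antialias_fir(source, target_rate_hz, up)
    log.info(
        "downsampling %g -> %g Hz (up=%d, down=%d, %d-tap Kaiser FIR, "
        "cutoff %.3g Hz, stopband %g dB)",
        source, target_rate_hz, up, down, len(taps),
        CUTOFF_FRACTION * target_rate_hz, STOPBAND_DB,
    )
    axes = [_resample_axis(a, up, down, taps) for a in (record.x, record.y, record.z)]
    n_out = len(axes[0])
    t0 = record.timestamps[0]
    timestamps = t0 + np.arange(n_out) / target_rate_hz
    # anti-alias filtering can overshoot slightly near clipped samples
    clipped = [np.clip(a, -record.dynamic_range_g, record.dynamic_range_g) for a in axes]
    return TriaxialRecord(
        timestamps=timestamps,
        x=clipped[0],
        y=clipped[1],
        z=clipped[2],
        sample_rate_hz=target_rate_hz,
        dynamic_range_g=record.dynamic_range_g,
    )


def resample_all(record: TriaxialRecord, rates) -> dict[float, TriaxialRecord]:
    """Down-sample the *original* record to each rate independently.

    Rates are processed from the source record, never cascaded, so each
    output sees exactly one anti-aliasing filter.
    """
    return {float(r): downsample(record, r) for r in rates}
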