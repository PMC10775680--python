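"""Measurement noise model.

Additive zero-mean Gaussian i.i.d. noise at a prescribed SNR.  The signal
power is measured over each emitter's full receiver block (all receivers,
all time samples), so every acquisition is corrupted at the same
block-level SNR,

    SNR_dB = 10 log10( P_signal / P_noise ).
"""

from __future__ import annotations

import numpy as np

__all__ = ["add_measurement_noise"]


def add_measurement_noise(channel_data, snr_db: float, seed: int):
    """Return a noisy copy of emitter x receiver x time channel data.

    Parameters
    ----------
    channel_data : ChannelData
        Traces of shape (n_emitters, n_receivers, nt).
    snr_db : float
        Target block SNR in dB; ``np.inf`` returns the input unchanged.
    seed : int
        Seed for the random generator; identical seeds give identical noise.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible noise")
    if not (np.isfinite(snr_db) or snr_db == np.inf):
        raise ValueError("snr_db must be finite or +inf")
    out = channel_data.copy()
    if snr_db == np.inf:
        return out
    rng = np.random.default_rng(seed)
    traces = out.traces
    for i in range(traces.shape[0]):
        block = traces[i]
        p_signal = float(np.mean(block.astype(np.float64) ** 2))
        sigma = np.sqrt(p_signal * 10.0 ** (-snr_db / 10.0))
        block += rng.normal(0.0, sigma, size=block.shape).astype(block.dtype)
    return out
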