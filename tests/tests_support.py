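"""Shared helpers for the test suite."""

import numpy as np

from epidmvct.preprocess import EPIDImage


def native_pair(rows=1280, cols=1280, pitch=0.336, i0=1000.0,
                field_half_mm=154.0):
    """Analytic full-resolution EPID pair: collimated flat open field and a
    smoothly attenuated transmission image (no ray tracing)."""
    v = (np.arange(rows) - (rows - 1) / 2) * pitch
    u = (np.arange(cols) - (cols - 1) / 2) * pitch
    uu, vv = np.meshgrid(u, v)
    mask = (np.abs(uu) <= field_half_mm) & (np.abs(vv) <= field_half_mm)
    open_vals = np.where(mask, i0, 0.0)
    atten = 0.6 * np.exp(-(uu ** 2 + vv ** 2) / (2 * 80.0 ** 2))
    trans_vals = open_vals * np.exp(-atten)
    return EPIDImage(open_vals, pitch), EPIDImage(trans_vals, pitch)
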