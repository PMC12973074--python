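"""Canonical double-gamma hemodynamic response function.

The canonical HRF links neural events to the delayed BOLD response.  It is
the difference of two gamma densities: a positive peak (shape 6, unit
dispersion, mode at 5 s) and a later undershoot (shape 16) scaled down by a
peak:undershoot ratio of 6.  The kernel is normalised to unit peak so
convolved regressors keep an interpretable amplitude scale.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["canonical_hrf"]

PEAK_DELAY = 6.0
UNDERSHOOT_DELAY = 16.0
PEAK_DISPERSION = 1.0
UNDERSHOOT_DISPERSION = 1.0
PEAK_UNDERSHOOT_RATIO = 6.0
DEFAULT_DURATION_S = 32.0


def canonical_hrf(fs_hz: float, duration_s: float = DEFAULT_DURATION_S) -> np.ndarray:
    """Sample the canonical double-gamma HRF.

    Parameters
    ----------
    fs_hz : float
        Sampling rate of the returned kernel, Hz.
    duration_s : float
        Kernel support in seconds; must cover the undershoot (>= 20 s).

    Returns
    -------
    ndarray
        ``round(duration_s * fs_hz)`` samples, scaled to unit peak.
        The value at t = 0 is 0 and the single positive peak sits near 5 s
        (the mode of a gamma with shape 6, unit scale), followed by one
        negative undershoot.
    """
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if duration_s < 20:
        raise ValueError("duration_s must be >= 20 s to cover the undershoot")
    t = np.arange(round(duration_s * fs_hz)) / fs_hz
    peak = stats.gamma.pdf(t, PEAK_DELAY / PEAK_DISPERSION, scale=PEAK_DISPERSION)
    under = stats.gamma.pdf(
        t, UNDERSHOOT_DELAY / UNDERSHOOT_DISPERSION, scale=UNDERSHOOT_DISPERSION
    )
    kernel = peak - under / PEAK_UNDERSHOOT_RATIO
    return kernel / kernel.max()
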