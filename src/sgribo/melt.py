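"""Melting-temperature estimation from thermal-denaturation curves.

Differential scanning fluorimetry reports dye fluorescence while the
temperature ramps (here 25→95 °C in 0.2 °C steps); protein unfolding
exposes hydrophobic surface and fluorescence rises sigmoidally. The
melting temperature Tm is the inflection of that transition, located as
the maximum of the first derivative of the (smoothed) curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simdata import MeltCurve

__all__ = ["TmEstimate", "melt_curve_tm"]


class NoTransitionError(ValueError):
    """Raised when the curve has no rising phase to locate a Tm in."""


@dataclass
class TmEstimate:
    tm: float                  # °C
    derivative: np.ndarray     # dF/dT per grid point
    smooth_window: int         # points


def melt_curve_tm(curve: MeltCurve, smooth_window: int = 1) -> TmEstimate:
    """Tm as the derivative maximum of the smoothed melt curve.

    Fluorescence is smoothed by a centered moving average of
    ``smooth_window`` points (odd; 1 = no smoothing), the first derivative
    is taken by central differences, and Tm is the temperature of the
    derivative maximum. A curve whose derivative never exceeds zero has no
    unfolding transition and raises :class:`NoTransitionError`.
    """
    t = np.asarray(curve.temperature, dtype=float)
    f = np.asarray(curve.fluorescence, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 grid points")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("temperature grid must be uniform")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd count")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        fpad = np.pad(f, pad, mode="edge")
        f = np.convolve(fpad, kernel, mode="valid")
    deriv = np.gradient(f, t)
    if deriv.max() <= 0:
        raise NoTransitionError("monotone-decreasing curve: no melting transition")
    tm = float(t[int(np.argmax(deriv))])
    return TmEstimate(tm=tm, derivative=deriv, smooth_window=smooth_window)
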