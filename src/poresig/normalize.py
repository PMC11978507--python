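"""Per-read linear normalization of current into pore-model units.

Iteration 1 is a method-of-moments fit restricted to the reference span
covered by the basecalled alignment:

    scale = sigma(K) / sigma(E);  shift = mu(K) - scale * mu(E)

where E are the read's event mean currents and K the model means of the
covered reference k-mers (population standard deviations throughout).
Iteration 2 refines by ordinary least squares of the model means on the
per-reference-position observed means (all raw samples aligned to each
position averaged first, so every k-mer contributes equally regardless of
dwell time); slope and intercept compose with the iteration-1 transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError


@dataclass
class NormParams:
    scale: float
    shift: float
    iteration: int = 1

    def __post_init__(self):
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise DegenerateSignalError(f"invalid scale {self.scale}")

    def apply(self, x):
        return self.scale * np.asarray(x, dtype=float) + self.shift

    def compose(self, outer_scale: float, outer_shift: float) -> "NormParams":
        """Return the transform outer o self."""
        return NormParams(outer_scale * self.scale,
                          outer_scale * self.shift + outer_shift,
                          iteration=self.iteration + 1)


def mom_normalize(event_means, ref_kmer_means) -> NormParams:
    """Method-of-moments normalization (iteration 1)."""
    e = np.asarray(event_means, dtype=float)
    k = np.asarray(ref_kmer_means, dtype=float)
    if len(e) < 2 or len(k) < 2:
        raise DegenerateSignalError("need at least 2 events and 2 reference k-mers")
    sd_e = float(np.std(e))
    if sd_e == 0:
        raise DegenerateSignalError("zero-variance event means")
    scale = float(np.std(k)) / sd_e
    shift = float(np.mean(k)) - scale * float(np.mean(e))
    return NormParams(scale, shift, iteration=1)


def regression_normalize(observed, model_means, prev: NormParams,
                         trim_mad: float = 2.5, trim_rounds: int = 2) -> NormParams:
    """OLS refinement (iteration 2), composed with the iteration-1 transform.

    ``observed`` are per-reference-position current means in the iteration-1
    normalized space; ``model_means`` the corresponding model k-mer means.
    A small fraction of positions can be grossly misassigned by the first
    alignment pass, which attenuates a plain least-squares slope, so
    residuals beyond ``trim_mad`` robust standard deviations of an initial
    fit are dropped before the final fit (``trim_mad=None`` disables).
    Falls back to ``prev`` with a warning when the fit is degenerate.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(model_means, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0:
        warnings.warn("degenerate regression input; keeping iteration-1 normalization")
        return prev
    slope, intercept = np.polyfit(x, y, 1)
    if trim_mad is not None:
        for _ in range(trim_rounds):
            resid = y - (slope * x + intercept)
            med = np.median(resid)
            mad = np.median(np.abs(resid - med))
            keep = np.abs(resid - med) <= max(trim_mad * 1.4826 * mad, 1e-12)
            if keep.sum() < max(3, 0.5 * len(x)) or np.std(x[keep]) == 0:
                break
            slope, intercept = np.polyfit(x[keep], y[keep], 1)
    if not (np.isfinite(slope) and slope > 0):
        warnings.warn("non-positive regression slope; keeping iteration-1 normalization")
        return prev
    return prev.compose(float(slope), float(intercept))
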