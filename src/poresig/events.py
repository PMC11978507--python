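"""Event segmentation: rolling Welch t-tests split raw signal into events.

An event is a contiguous run of samples at an approximately constant current
level, nominally one k-mer dwell.  Boundaries are placed at local maxima of
the rolling two-window Welch t-statistic, computed at two window lengths;
a peak must exceed its window's threshold and suppresses further boundaries
within one window span.

Window lengths / thresholds default to the predecessor convention:
DNA (3, 6) samples with thresholds (1.4, 9.0); RNA (7, 14) with (2.5, 9.0)
to accommodate the slower traversal speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EventParams:
    windows: tuple = (3, 6)
    thresholds: tuple = (1.4, 9.0)

    @staticmethod
    def for_chemistry(rna: bool) -> "EventParams":
        return EventParams((7, 14), (2.5, 9.0)) if rna else EventParams()


@dataclass
class Event:
    start: int
    length: int
    mean: float
    sd: float

    @property
    def end(self) -> int:
        return self.start + self.length


def _tstats(x: np.ndarray, w: int) -> np.ndarray:
    """|Welch t| between windows [i-w,i) and [i,i+w) for i in [w, n-w]."""
    n = len(x)
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    i = np.arange(w, n - w + 1)
    s1 = c1[i] - c1[i - w]
    s2 = c1[i + w] - c1[i]
    q1 = c2[i] - c2[i - w]
    q2 = c2[i + w] - c2[i]
    m1, m2 = s1 / w, s2 / w
    v1 = np.maximum(q1 / w - m1 * m1, 0.0)
    v2 = np.maximum(q2 / w - m2 * m2, 0.0)
    # clamp cumsum cancellation dust so constant stretches stay constant
    dust = 1e-12 * (1.0 + m1 * m1 + m2 * m2)
    v1[v1 < dust] = 0.0
    v2[v2 < dust] = 0.0
    num = np.abs(m1 - m2)
    num[num * num < dust] = 0.0
    den = np.sqrt((v1 + v2) / w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
    t[(den == 0) & (num > 0)] = np.inf
    t[(den == 0) & (num == 0)] = 0.0
    full = np.zeros(n + 1)
    full[i] = t
    return full


def _peaks(t: np.ndarray, threshold: float, w: int) -> list[int]:
    """Boundary candidates: above-threshold local maxima, masked within w."""
    out = []
    last = -w
    n = len(t)
    for i in range(1, n - 1):
        if t[i] < threshold or i - last < w:
            continue
        lo = max(0, i - 1)
        hi = min(n, i + 2)
        if t[i] >= t[lo:hi].max():
            out.append(i)
            last = i
    return out


def detect_events(raw: np.ndarray, params: EventParams = EventParams()) -> list[Event]:
    """Segment a raw signal into events tiling all samples.

    Boundaries from both window lengths are pooled; events are the intervals
    between consecutive boundaries, with per-event mean/sd (population)
    computed from the raw samples.
    """
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    long_w = max(params.windows)
    if n < 2 * long_w:
        warnings.warn("signal shorter than event-detection windows; single event")
        return [Event(0, n, float(raw.mean()), float(raw.std()))]
    cuts: set[int] = set()
    for w, thr in zip(params.windows, params.thresholds):
        if n < 2 * w:
            continue
        cuts.update(_peaks(_tstats(raw, w), thr, w))
    bounds = [0] + sorted(c for c in cuts if 0 < c < n) + [n]
    events = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = raw[lo:hi]
        events.append(Event(lo, hi - lo, float(seg.mean()), float(seg.std())))
    return events


def split_events_at(events: list[Event], raw: np.ndarray, cuts) -> list[Event]:
    """Force additional boundaries (e.g. at masked-range edges), recomputing
    the statistics of the split pieces from the raw samples."""
    cutset = sorted(set(int(c) for c in cuts))
    if not cutset:
        return events
    raw = np.asarray(raw, dtype=float)
    out = []
    for ev in events:
        inner = [c for c in cutset if ev.start < c < ev.end]
        if not inner:
            out.append(ev)
            continue
        bounds = [ev.start] + inner + [ev.end]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = raw[lo:hi]
            out.append(Event(lo, hi - lo, float(seg.mean()), float(seg.std())))
    return out
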