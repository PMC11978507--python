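"""Alignment-comparison metrics and reference-/read-level statistics.

Comparison metrics between two signal alignments of the same read:

* signal Jaccard distance — per reference position, 1 - |A∩B|/|A∪B| over
  the sets of raw samples each method assigns to the position (0 = perfect
  overlap, 1 = disjoint).
* signal-to-reference distance — the average number of reference bases
  between where each raw sample lands under the two methods; computed
  reciprocally (averaged A->B and B->A) unless comparing against the
  low-resolution ref-moves (mvcmp.dist), which is one-sided.

Reference-level statistics pool per-read per-position current means across
reads: two-sample Kolmogorov-Smirnov statistics and z-scores for
modification detection, plus plain summaries.  Positions under the minimum
basecalled coverage (20 by default) are emitted as null.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import scipy.stats

from .aln_store import Alignment, derived_layer

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 20
SUMMARY_STATS = ("mean", "median", "stdv", "var", "skew", "kurt")


# ---------------------------------------------------------------------------
# per-read comparison metrics

def interval_jaccard(a_start, a_end, b_start, b_end):
    """Vectorized Jaccard distance between two interval families."""
    a0, a1 = np.asarray(a_start, float), np.asarray(a_end, float)
    b0, b1 = np.asarray(b_start, float), np.asarray(b_end, float)
    inter = np.maximum(0.0, np.minimum(a1, b1) - np.maximum(a0, b0))
    union = (a1 - a0) + (b1 - b0) - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    # a position with an empty sample set under either method is skipped
    d[(union <= 0) | (a1 <= a0) | (b1 <= b0)] = np.nan
    return d


def _common_positions(a: Alignment, b: Alignment):
    pa, pb = a.positions, b.positions
    common, ia, ib = np.intersect1d(pa, pb, return_indices=True)
    return common, ia, ib


def jaccard_distance(a: Alignment, b: Alignment):
    """Per-position signal Jaccard distance over positions both cover.

    Positions where either method assigns no samples are skipped (NaN).
    Returns (positions, distances).
    """
    common, ia, ib = _common_positions(a, b)
    d = interval_jaccard(a.sample_start[ia], a.sample_end[ia],
                        b.sample_start[ib], b.sample_end[ib])
    return common, d


def _sample_to_ref(aln: Alignment):
    """Forward map sample index -> reference coordinate (NaN where masked)."""
    lo, hi = aln.signal_lo, aln.signal_hi
    ref = np.full(hi - lo, np.nan)
    pos = aln.positions
    for p in range(aln.n_positions):
        s, e = int(aln.sample_start[p]), int(aln.sample_end[p])
        if e > s:
            ref[s - lo:e - lo] = pos[p]
    return ref, lo


def sig2ref_distance(a: Alignment, b: Alignment, reciprocal: bool = True):
    """Average reference-base distance between the two methods' placements.

    For coordinate r under A, averages |r - r'(s)| over A's samples s at r,
    where r' is the position B assigns sample s; samples unaligned under B
    are excluded and counted.  Reciprocal mode averages the A->B and B->A
    values at each position.  Returns (positions, distances, n_unaligned).
    """
    ref_b, lo_b = _sample_to_ref(b)
    common, ia, ib = _common_positions(a, b)
    d_ab = np.full(len(common), np.nan)
    unaligned = 0
    for x, p in enumerate(ia):
        s, e = int(a.sample_start[p]), int(a.sample_end[p])
        if e <= s:
            continue
        idx = np.arange(s, e) - lo_b
        idx = idx[(idx >= 0) & (idx < len(ref_b))]
        tgt = ref_b[idx] if len(idx) else np.empty(0)
        ok = np.isfinite(tgt)
        unaligned += int(e - s - ok.sum())
        if ok.any():
            d_ab[x] = float(np.mean(np.abs(common[x] - tgt[ok])))
    if not reciprocal:
        return common, d_ab, unaligned
    common2, d_ba, un2 = sig2ref_distance(b, a, reciprocal=False)
    # common and common2 are identical sets (intersection is symmetric)
    both = np.isfinite(d_ab) & np.isfinite(d_ba)
    out = np.where(both, 0.5 * (d_ab + d_ba), np.where(np.isfinite(d_ab), d_ab, d_ba))
    return common, out, unaligned + un2


def mvcmp_dist(aln: Alignment, refmoves):
    """One-sided signal-to-reference distance from an alignment to the
    move projection of the same read (averaging only over the alignment's
    raw samples, not the low-resolution ref-moves)."""
    order = np.argsort(refmoves.positions, kind="stable")
    pos = refmoves.positions[order]
    lo = refmoves.lo[order]
    hi = refmoves.hi[order]
    span_lo = int(refmoves.lo.min())
    span_hi = int(refmoves.hi.max())
    ref = np.full(span_hi - span_lo, np.nan)
    for j in range(len(pos)):
        if hi[j] > lo[j]:
            ref[lo[j] - span_lo:hi[j] - span_lo] = pos[j]
    # fill unassigned samples with the nearest assigned position
    idx = np.arange(len(ref))
    ok = np.isfinite(ref)
    if not ok.any():
        return aln.positions, np.full(aln.n_positions, np.nan)
    ref = np.interp(idx, idx[ok], ref[ok])
    out = np.full(aln.n_positions, np.nan)
    apos = aln.positions
    for p in range(aln.n_positions):
        s, e = int(aln.sample_start[p]), int(aln.sample_end[p])
        if e <= s:
            continue
        sl = np.clip(np.arange(s, e) - span_lo, 0, len(ref) - 1)
        out[p] = float(np.mean(np.abs(apos[p] - ref[sl])))
    return apos, out


def attach_mvcmp(aln: Alignment, refmoves) -> None:
    _, d = mvcmp_dist(aln, refmoves)
    aln.extra["mvcmp.dist"] = d


# ---------------------------------------------------------------------------
# reference-level statistics

def pileup_layer(alns, layer: str = "dtw.current", model=None) -> dict:
    """position -> array of per-read layer values (finite, unmasked only)."""
    acc: dict[int, list] = {}
    for aln in alns:
        vals = derived_layer(aln, layer, model=model)
        vals = np.where(aln.masked, np.nan, vals)
        for p, v in zip(aln.positions, vals):
            if np.isfinite(v):
                acc.setdefault(int(p), []).append(float(v))
    return {p: np.array(v) for p, v in acc.items()}


def ks_refstats(track1: dict, track2: dict,
                min_coverage: int = DEFAULT_MIN_COVERAGE) -> dict:
    """Per-position two-sample KS statistic between two pileup tracks.

    sup_x |F1(x) - F2(x)| over the empirical distributions of per-read
    per-position current means; under-covered positions are null (absent).
    """
    out = {}
    for p in sorted(set(track1) & set(track2)):
        x, y = track1[p], track2[p]
        if len(x) < min_coverage or len(y) < min_coverage:
            continue
        out[p] = float(scipy.stats.ks_2samp(x, y, method="asymp").statistic)
    return out


def zscore_refstats(track1: dict, track2: dict,
                    min_coverage: int = DEFAULT_MIN_COVERAGE) -> dict:
    """Per-position Welch z-score (mu1-mu2)/sqrt(s1^2/n1 + s2^2/n2) with
    unbiased sample variances; zero pooled variance yields null."""
    out = {}
    for p in sorted(set(track1) & set(track2)):
        x, y = track1[p], track2[p]
        if len(x) < min_coverage or len(y) < min_coverage:
            continue
        v = np.var(x, ddof=1) / len(x) + np.var(y, ddof=1) / len(y)
        if v == 0:
            warnings.warn(f"position {p}: zero pooled variance; z-score is null")
            continue
        out[p] = float((np.mean(x) - np.mean(y)) / np.sqrt(v))
    return out


def summary_refstats(track: dict, stat: str,
                     min_coverage: int = DEFAULT_MIN_COVERAGE) -> dict:
    funcs = {
        "mean": np.mean,
        "median": np.median,
        "stdv": lambda x: np.std(x, ddof=0),
        "var": lambda x: np.var(x, ddof=0),
        "skew": scipy.stats.skew,
        "kurt": scipy.stats.kurtosis,
    }
    if stat not in funcs:
        raise ValueError(f"unknown statistic {stat!r}; valid: {SUMMARY_STATS}")
    return {p: float(funcs[stat](v)) for p, v in track.items()
            if len(v) >= min_coverage}


def model_mad(aln: Alignment, model) -> float:
    """Median absolute difference between a read's per-position current
    means and the pore model — a proxy for alignment quality."""
    diff = derived_layer(aln, "dtw.model_diff", model=model)
    diff = diff[np.isfinite(diff) & ~aln.masked]
    return float(np.median(diff)) if len(diff) else np.nan


def dwell_offset_variability(alns, ref_seq: str, m: int = 5,
                             offsets=range(-15, 6), min_kmers: int = 2) -> dict:
    """Sequence influence on dwell time by positional offset.

    For each offset d, positions are grouped by the m-mer starting at
    r+d, the median dwell is taken per group (pooled over reads), and the
    population sd of the group medians is returned.  Offsets with fewer
    than ``min_kmers`` observed m-mers are null.
    """
    dwells = pileup_layer(alns, "dtw.dwell")
    dwells = {p: v[v > 0] for p, v in dwells.items()}
    positions = np.array(sorted(p for p, v in dwells.items() if len(v)))
    out = {}
    L = len(ref_seq)
    for d in offsets:
        groups: dict[str, list] = {}
        for p in positions:
            a = p + d
            if a < 0 or a + m > L:
                continue
            groups.setdefault(ref_seq[a:a + m], []).extend(dwells[p])
        med = [np.median(v) for v in groups.values() if len(v)]
        out[int(d)] = float(np.std(med)) if len(med) >= min_kmers else np.nan
    return out


# ---------------------------------------------------------------------------
# generic helpers

def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted q-values (helper; detection thresholds raw statistics
    by default)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    q[order] = p[order] * n / (np.arange(n) + 1)
    q[order] = np.minimum.accumulate(q[order][::-1])[::-1]
    return np.clip(q, 0, 1)


def auroc(pos_scores, neg_scores) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) statistic."""
    x = np.asarray(pos_scores, float)
    y = np.asarray(neg_scores, float)
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    rx = ranks[:len(x)].sum()
    return float((rx - len(x) * (len(x) + 1) / 2) / (len(x) * len(y)))
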