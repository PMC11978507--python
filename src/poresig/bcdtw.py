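"""Basecaller-guided banded dynamic time warping (bcDTW).

The basecaller's "moves" table gives a low-resolution mapping from signal
blocks (one stride of raw samples, 5 for DNA / 10 for RNA) to read bases.
Projecting the moves through the read's CIGAR yields *ref-moves*: for every
reference position, an approximate raw-sample interval.  The DTW band is
centered on these ref-moves before alignment begins, allowing a narrow
bandwidth (25 events by default).

The recurrence is standard DTW with a multiplicative skip penalty:

    D[i,j] = cost(i,j) + min(D[i-1,j-1], D[i-1,j], skip * D[i,j-1])

with cost(i,j) = |normalized event mean i - model mean at reference index j|
and skip = 2 by default (4 during pore-model training).  Insertions and
deletions longer than ``del_max`` (10 by default) are spliced out of the
read or the reference respectively before alignment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np

from . import aln_store
from .errors import AlignmentError
from .events import EventParams, detect_events, split_events_at
from .normalize import NormParams, mom_normalize, regression_normalize
from .pore_model import PoreModel, kmer_index, revcomp
from .signal_io import RawRead

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_READ_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


def parse_cigar(cigar) -> list[tuple[str, int]]:
    if isinstance(cigar, str):
        ops = [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]
        if "".join(f"{n}{op}" for op, n in ops) != cigar:
            raise AlignmentError(f"unparsable cigar {cigar!r}")
        return ops
    return [(op, int(n)) for op, n in cigar]


@dataclass
class ReadAlignmentMeta:
    """Basecalled-alignment metadata needed to guide signal alignment."""

    read_id: str
    ref_name: str
    ref_start: int
    strand: str
    cigar: str
    moves: np.ndarray
    stride: int
    signal_offset: int = 0


@dataclass
class RefMoves:
    """Move projection: per reference position, a candidate sample interval.

    Arrays run in *signal order* (ascending sample coordinate); ``positions``
    holds forward-reference coordinates, which descend when the signal
    traverses the reference 3'->5' (reverse strand, or direct RNA).
    """

    positions: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    stride: int
    strand: str
    insertions: list = field(default_factory=list)   # (idx, s0, s1, n_bases)
    deletions: list = field(default_factory=list)    # (idx, length, is_intron)

    def __len__(self):
        return len(self.positions)

    @property
    def signal_span(self) -> tuple[int, int]:
        return int(self.lo.min()), int(self.hi.max())

    def ref_blocks(self) -> list[tuple[int, int]]:
        """Maximal runs of consecutive reference coordinates, ascending."""
        pos = np.sort(self.positions)
        breaks = np.flatnonzero(np.diff(pos) != 1)
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks, [len(pos) - 1]))
        return [(int(pos[a]), int(pos[b]) + 1) for a, b in zip(starts, stops)]


def project_moves(moves, stride: int, signal_offset: int, cigar, ref_start: int,
                  strand: str = "+", reverse_signal: bool = False) -> RefMoves:
    """Project basecaller moves into reference coordinates via the CIGAR.

    Read base b occupies samples [signal_offset + stride*step_b,
    signal_offset + stride*step_{b+1}).  Match columns map base intervals to
    reference positions; insertion/soft-clip samples merge into the
    preceding position's interval; deletions get empty intervals
    interpolated between their flanks; N introns are recorded for splicing.
    """
    moves = np.asarray(moves).astype(np.int64)
    steps = np.flatnonzero(moves)
    n_bases = len(steps)
    starts = signal_offset + stride * steps
    ends = signal_offset + stride * np.append(steps[1:], len(moves))
    ops = parse_cigar(cigar)
    read_len = sum(n for op, n in ops if op in _READ_OPS)
    if read_len != n_bases:
        raise AlignmentError(
            f"cigar consumes {read_len} read bases but move table has {n_bases}")
    ref_len = sum(n for op, n in ops if op in _REF_OPS)
    desc = (strand == "-") != bool(reverse_signal)
    if desc:
        ops = ops[::-1]
        ref, ref_step = ref_start + ref_len - 1, -1
    else:
        ref, ref_step = ref_start, 1
    pos: list[int] = []
    lo: list[int] = []
    hi: list[int] = []
    insertions = []
    deletions = []
    s = 0  # next read base in signal order
    for op, ln in ops:
        if op in "M=X":
            for _ in range(ln):
                pos.append(ref)
                lo.append(int(starts[s]))
                hi.append(int(ends[s]))
                ref += ref_step
                s += 1
        elif op in "IS":
            s0, s1 = int(starts[s]), int(ends[s + ln - 1])
            if pos:
                hi[-1] = max(hi[-1], s1)
                insertions.append((len(pos) - 1, s0, s1, ln))
            s += ln
        elif op in "DN":
            deletions.append((len(pos), ln, op == "N"))
            for _ in range(ln):
                pos.append(ref)
                lo.append(-1)
                hi.append(-1)
                ref += ref_step
        # H and P consume nothing relevant
    lo = np.array(lo, dtype=np.int64)
    hi = np.array(hi, dtype=np.int64)
    # interpolate deletion placeholders between flanking intervals
    n = len(pos)
    for a, g, _ in deletions:
        left = hi[a - 1] if a > 0 else (lo[a + g] if a + g < n else 0)
        right = lo[a + g] if a + g < n else left
        for i in range(g):
            b = int(round(left + (right - left) * (i + 1) / (g + 1)))
            lo[a + i] = b
            hi[a + i] = b
    return RefMoves(np.array(pos, dtype=np.int64), lo, hi, stride, strand,
                    insertions, deletions)


def splice_indels(rm: RefMoves, del_max: int = 10):
    """Splice out indels larger than del_max.

    Insertions > del_max have their samples removed from the alignable
    signal (returned as masked sample ranges); deletions/introns > del_max
    have their reference positions excised (returned as excised reference
    ranges).  Smaller indels are left for the DTW to resolve.
    """
    if del_max < 1:
        raise AlignmentError("del_max must be >= 1")
    keep = np.ones(len(rm), dtype=bool)
    excised = []
    for a, g, intron in rm.deletions:
        if intron or g > del_max:
            keep[a:a + g] = False
            run = rm.positions[a:a + g]
            excised.append((int(run.min()), int(run.max()) + 1))
    masked = []
    hi = rm.hi.copy()
    for idx, s0, s1, n_bases in rm.insertions:
        if n_bases > del_max:
            if hi[idx] >= s1:
                hi[idx] = s0
            masked.append((s0, s1))
    out = RefMoves(rm.positions[keep], rm.lo[keep], hi[keep], rm.stride,
                   rm.strand, [], [])
    return out, masked, excised


@dataclass
class Band:
    """Per-reference-index allowed event interval [top_j, bottom_j)."""

    top: np.ndarray
    bottom: np.ndarray
    width: int

    def __len__(self):
        return len(self.top)


def place_band(rm: RefMoves, events, width: int = 25) -> Band:
    """Center the band on the event containing each ref-moves midpoint.

    Intervals are clipped to the valid event range and forced monotone
    non-decreasing in the reference index.
    """
    if not events:
        raise AlignmentError("cannot place a band without events")
    n_ev = len(events)
    ev_starts = np.array([e.start for e in events])
    mid = (rm.lo + rm.hi) // 2
    centers = np.clip(np.searchsorted(ev_starts, mid, side="right") - 1, 0, n_ev - 1)
    top = centers - width // 2
    bottom = top + width
    top = np.maximum.accumulate(np.clip(top, 0, n_ev - 1))
    bottom = np.maximum.accumulate(np.clip(bottom, 1, n_ev))
    bottom = np.maximum(bottom, top + 1)
    # connectivity: adjacent columns must overlap even when the ref-moves
    # jump by more than the bandwidth (long dwells, merged events)
    top[1:] = np.minimum(top[1:], bottom[:-1])
    return Band(top.astype(np.int64), bottom.astype(np.int64), width)


def full_band(n_events: int, n_refs: int) -> Band:
    return Band(np.zeros(n_refs, dtype=np.int64),
                np.full(n_refs, n_events, dtype=np.int64), n_events)


def clamp_band_endpoints(band: Band, n_events: int) -> Band:
    """Ensure the band admits the full path (0,0) .. (n_events-1, M-1)."""
    top = band.top.copy()
    bottom = band.bottom.copy()
    top[0] = 0
    bottom[-1] = n_events
    return Band(top, np.maximum(bottom, top + 1), band.width)


@dataclass
class DtwPath:
    """Monotone warping path: (event index, reference index) pairs.

    ``moves[p]`` records how pair p was entered: 'start', 'match' (diagonal),
    'stay' (new event, same reference position) or 'skip' (same event, next
    reference position).
    """

    pairs: np.ndarray
    moves: list
    cost: float
    n_events: int
    n_refs: int


def banded_dtw(event_means, expected_means, band: Band,
               skip_cost: float = 2.0, expected_sds=None) -> DtwPath:
    """Fill the banded DP matrix and trace back the optimal path.

    cost(i,j) = |event_mean_i - expected_mean_j| (optionally z-scaled by the
    model sd); cells outside the band are +inf; ties in the traceback break
    diagonal > stay > skip.
    """
    e = np.asarray(event_means, dtype=float)
    m = np.asarray(expected_means, dtype=float)
    N, M = len(e), len(m)
    if N == 0 or M == 0:
        raise AlignmentError("empty events or reference")
    top, bottom = band.top, band.bottom
    if len(top) != M:
        raise AlignmentError("band length does not match reference length")
    if not (top[0] <= 0 < bottom[0] and top[-1] <= N - 1 < bottom[-1]):
        raise AlignmentError("band does not connect signal start to signal end")
    if skip_cost < 1:
        raise AlignmentError("skip_cost must be >= 1")
    INF = np.inf
    D: list[np.ndarray] = []
    for j in range(M):
        t, b = int(top[j]), int(bottom[j])
        c = np.abs(e[t:b] - m[j])
        if expected_sds is not None:
            c = c / expected_sds[j]
        n = b - t
        a = np.full(n, INF)
        if j == 0:
            if t == 0:
                a[0] = 0.0
        else:
            tp, bp = int(top[j - 1]), int(bottom[j - 1])
            Dp = D[j - 1]
            i = np.arange(t, b)
            pi = i - 1 - tp
            ok = (pi >= 0) & (pi < bp - tp)
            a[ok] = Dp[pi[ok]]
            pi2 = i - tp
            ok2 = (pi2 >= 0) & (pi2 < bp - tp)
            a[ok2] = np.minimum(a[ok2], skip_cost * Dp[pi2[ok2]])
        S = np.cumsum(c)
        T = a - np.concatenate(([0.0], S[:-1]))
        D.append(S + np.minimum.accumulate(T))
    total = float(D[M - 1][N - 1 - top[M - 1]])
    if not np.isfinite(total):
        raise AlignmentError("no finite alignment path within the band")
    # traceback; ties break diagonal > stay > skip
    i, j = N - 1, M - 1
    rev_pairs = [(i, j)]
    rev_moves = []
    while i > 0 or j > 0:
        cand = []
        if i > 0 and j > 0 and top[j - 1] <= i - 1 < bottom[j - 1]:
            cand.append((D[j - 1][i - 1 - top[j - 1]], 0, i - 1, j - 1, "match"))
        if i > 0 and top[j] <= i - 1 < bottom[j]:
            cand.append((D[j][i - 1 - top[j]], 1, i - 1, j, "stay"))
        if j > 0 and top[j - 1] <= i < bottom[j - 1]:
            cand.append((skip_cost * D[j - 1][i - top[j - 1]], 2, i, j - 1, "skip"))
        if not cand:
            raise AlignmentError("traceback left the band")
        _, _, ni, nj, mv = min(cand, key=lambda x: (x[0], x[1]))
        rev_moves.append(mv)
        rev_pairs.append((ni, nj))
        i, j = ni, nj
    rev_moves.append("start")
    pairs = np.array(rev_pairs[::-1], dtype=np.int64)
    moves = rev_moves[::-1]
    return DtwPath(pairs, moves, total, N, M)


@dataclass
class SkipGroup:
    """A run of >= 2 consecutive reference positions sharing one event."""

    members: list
    carrier: int
    event: int
    kept: int | None  # None => every member masked


def find_skip_groups(path: DtwPath) -> list[SkipGroup]:
    groups = []
    pairs, moves = path.pairs, path.moves
    p = 0
    L = len(pairs)
    while p < L:
        if moves[p] == "skip":
            i = int(pairs[p][0])
            start = p
            while p + 1 < L and moves[p + 1] == "skip":
                p += 1
            carrier = int(pairs[start][1]) - 1
            members = list(range(carrier, int(pairs[p][1]) + 1))
            groups.append(SkipGroup(members, carrier, i, carrier))
        p += 1
    return groups


def mask_skips(path: DtwPath, mode: str, expected_means, event_means) -> list[SkipGroup]:
    """Resolve skip runs per the masking mode.

    'none' keeps the carrier as owner of the shared samples with values
    copied to every member; 'all' masks every member; 'keep_best' keeps the
    member whose expected mean is closest to the shared observed mean.
    """
    groups = find_skip_groups(path)
    if mode == "none":
        return groups
    expected_means = np.asarray(expected_means, dtype=float)
    for g in groups:
        if mode == "all":
            g.kept = None
        elif mode == "keep_best":
            obs = float(event_means[g.event])
            best = min(g.members, key=lambda j: (abs(expected_means[j] - obs), j))
            g.kept = best
        else:
            raise ValueError(f"unknown mask-skips mode {mode!r}")
    return groups


@dataclass(frozen=True)
class AlignParams:
    """Tunables of the align pipeline (production defaults)."""

    bandwidth: int = 25
    skip_cost: float = 2.0
    del_max: int = 10
    mask_skips: str = "none"
    unmask_splice: bool = False
    norm_iterations: int = 2
    count_events: bool = False
    zscore_cost: bool = False
    event_params: EventParams | None = None

    @staticmethod
    def training() -> "AlignParams":
        return AlignParams(skip_cost=4.0, mask_skips="keep_best", norm_iterations=1)


def _expected_for_positions(rm: RefMoves, ref_seq: str, model: PoreModel):
    """Expected (kmer id, mean, sd) per kept position, spliced across gaps.

    Returns (keep mask over rm indices, kmer_ids, means, sds, splice_mask):
    positions whose k-mer window runs off the covered context are dropped;
    windows straddling an excision junction are built from the spliced
    sequence and flagged.
    """
    k, c = model.k, model.central_pos
    blocks = rm.ref_blocks()
    left = max(0, blocks[0][0] - k)
    right = min(len(ref_seq), blocks[-1][1] + k)
    pieces = [ref_seq[left:blocks[0][0]]]
    offsets = {}  # block start -> spliced index of that coordinate
    cursor = blocks[0][0] - left
    junctions = []
    for bi, (b0, b1) in enumerate(blocks):
        offsets[b0] = cursor
        pieces.append(ref_seq[b0:b1])
        cursor += b1 - b0
        if bi + 1 < len(blocks):
            junctions.append(cursor)
    pieces.append(ref_seq[blocks[-1][1]:right])
    S = "".join(pieces)
    block_starts = np.array([b0 for b0, _ in blocks])
    block_stops = np.array([b1 for _, b1 in blocks])
    block_off = np.array([offsets[b0] for b0, _ in blocks])

    def spliced_index(r):
        bi = np.searchsorted(block_stops, r, side="right")
        return int(block_off[bi] + (r - block_starts[bi]))

    fwd = rm.strand == "+"
    keep = np.zeros(len(rm), dtype=bool)
    ids = np.full(len(rm), -1, dtype=np.int64)
    splice_mask = np.zeros(len(rm), dtype=bool)
    for x, r in enumerate(rm.positions):
        si = spliced_index(int(r))
        w0 = si - c if fwd else si - (k - 1 - c)
        w1 = w0 + k
        if w0 < 0 or w1 > len(S):
            continue
        kmer = S[w0:w1]
        if not fwd:
            kmer = revcomp(kmer)
        keep[x] = True
        ids[x] = kmer_index(kmer, k)
        if any(w0 < jx < w1 for jx in junctions):
            splice_mask[x] = True
    ids = ids[keep]
    return keep, ids, model.means[ids], model.sds[ids], splice_mask[keep]


def align_read(raw: RawRead, meta: ReadAlignmentMeta, ref_seq: str,
               model: PoreModel, params: AlignParams = AlignParams()):
    """Full signal-to-reference alignment of one read.

    events -> project_moves -> splice_indels -> place_band -> mom_normalize
    -> banded DTW -> regression_normalize -> (second DTW pass) -> layers.
    Returns an :class:`poresig.aln_store.Alignment`.
    """
    if meta.moves is None or len(np.atleast_1d(meta.moves)) == 0:
        raise AlignmentError(f"read {meta.read_id}: no move table")
    rm0 = project_moves(meta.moves, meta.stride, meta.signal_offset, meta.cigar,
                        meta.ref_start, meta.strand, model.reverse_signal)
    # the last move block may overhang the raw signal by up to stride-1
    np.clip(rm0.hi, None, len(raw.samples), out=rm0.hi)
    np.clip(rm0.lo, None, len(raw.samples), out=rm0.lo)
    rm, masked_ranges, excised = splice_indels(rm0, params.del_max)
    if len(rm) < 2:
        raise AlignmentError(f"read {meta.read_id}: fewer than 2 aligned positions")
    keep, kmer_ids, exp_means, exp_sds, splice_mask = \
        _expected_for_positions(rm, ref_seq, model)
    rm = RefMoves(rm.positions[keep], rm.lo[keep], rm.hi[keep], rm.stride, rm.strand)
    if params.unmask_splice:
        splice_mask[:] = False
    span_lo, span_hi = rm.signal_span
    for s0, s1 in masked_ranges:
        span_lo, span_hi = min(span_lo, s0), max(span_hi, s1)
    cal = raw.calibrated()
    if span_hi > len(cal):
        raise AlignmentError(f"read {meta.read_id}: moves extend past the raw signal")
    ev_params = params.event_params or EventParams.for_chemistry(model.reverse_signal)
    events = detect_events(cal[span_lo:span_hi], ev_params)
    for ev in events:
        ev.start += span_lo
    cuts = [c for s0, s1 in masked_ranges for c in (s0, s1)]
    events = split_events_at(events, cal, cuts)
    events = [ev for ev in events
              if not any(s0 <= ev.start and ev.end <= s1 for s0, s1 in masked_ranges)]
    if len(events) < 2:
        raise AlignmentError(f"read {meta.read_id}: too few events")
    ev_means_pa = np.array([e.mean for e in events])
    norm = mom_normalize(ev_means_pa, exp_means)
    ev_means = norm.apply(ev_means_pa)
    band = clamp_band_endpoints(place_band(rm, events, params.bandwidth), len(events))
    sds = exp_sds if params.zscore_cost else None
    path = banded_dtw(ev_means, exp_means, band, params.skip_cost, sds)
    if params.norm_iterations >= 2:
        norm_samples = norm.apply(cal)
        obs = _per_position_observed(path, events, norm_samples, len(rm))
        norm2 = regression_normalize(obs, exp_means, norm)
        if norm2 is not norm:
            norm = norm2
            ev_means = norm.apply(ev_means_pa)
            path = banded_dtw(ev_means, exp_means, band, params.skip_cost, sds)
            # refit on the realigned (cleaner) per-position observations
            obs = _per_position_observed(path, events, norm.apply(cal), len(rm))
            norm3 = regression_normalize(obs, exp_means, norm)
            if norm3 is not norm:
                norm = norm3
    groups = mask_skips(path, params.mask_skips, exp_means, ev_means)
    norm_samples = norm.apply(cal)
    aln = aln_store.compute_layers(
        path, groups, norm_samples, events, rm.positions,
        masked_ranges=masked_ranges, splice_mask=splice_mask,
        kmer_ids=kmer_ids, expected_means=exp_means,
        read_id=meta.read_id, ref_name=meta.ref_name, strand=meta.strand,
        norm=norm, model_name=model.name,
        with_event_counts=params.count_events,
        signal_span=(span_lo, span_hi),
    )
    return aln


def _per_position_observed(path: DtwPath, events, norm_samples, n_pos):
    """Mean over all raw samples aligned to each reference position
    (iteration-1 normalized space), for the regression refinement."""
    out = np.full(n_pos, np.nan)
    owned = aln_store.owned_events(path)
    for j, evs in enumerate(owned):
        if not evs:
            continue
        lo = events[evs[0]].start
        hi = events[evs[-1]].end
        if hi > lo:
            out[j] = float(np.mean(norm_samples[lo:hi]))
    return out
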