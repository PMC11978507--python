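"""Per-reference-position alignment layers and their BAM tag encoding.

A signal alignment is stored per reference position as three base layers —
aligned sample count ("length", 0 marking a skip), current mean and current
standard deviation — plus reference blocks and the normalization transform.
The BAM encoding uses five auxiliary tags:

us  signal-order sample counts: positive = samples per consecutive
    reference position, negative = masked signal run, zero = skip; any
    magnitude >= 65535 is emitted as the sentinel 65535 grouped with the
    subsequent entry (the decoder sums sentinel chains).
ur  flattened [start, stop) reference coordinate blocks.
uc  current means as 16-bit fixed precision over [-5, 5]:
    q = round((x+5)/10 * 65534), with 65535 reserved as the null quantum.
ud  current standard deviations, same quantization.
un  normalization (scale, shift) mapping calibrated pA to model units.
ub  [signal_lo, signal_hi): the consumed raw-signal span, so conservation
    (sum |us| == signal length) is checkable from the record alone.

Conservation invariants asserted on every encode and decode: sum(|us|)
equals the consumed signal length, and the total ur span equals the number
of non-negative us entries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, IntegrityError, PoresigError
from .normalize import NormParams

logger = logging.getLogger(__name__)

FIXED_MIN, FIXED_MAX = -5.0, 5.0
QUANTA = 65534          # highest regular quantum
NULL_QUANTUM = 65535
SENTINEL = 65535        # overflow sentinel for us magnitudes
JSON_HEADER_KEY = "poresig.json"

BASE_LAYERS = ("dtw.length", "dtw.dwell", "dtw.current", "dtw.current_sd",
               "seq.kmer", "dtw.model_diff", "mvcmp.dist", "event_count")


@dataclass
class Alignment:
    """One read's signal alignment, positions ascending on the forward
    reference across ``ref_blocks``."""

    read_id: str
    ref_name: str
    strand: str
    ref_blocks: list                 # [(start, stop), ...] ascending
    sample_start: np.ndarray         # per position; start == end => no signal
    sample_end: np.ndarray
    current: np.ndarray              # NaN = null
    current_sd: np.ndarray
    masked: np.ndarray               # bool; null in the encoded output
    norm: NormParams
    signal_lo: int
    signal_hi: int
    masked_ranges: list = field(default_factory=list)  # [(lo, hi)] sample coords
    event_count: np.ndarray | None = None
    kmer_ids: np.ndarray | None = None
    signal_descending: bool = False
    model_name: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return len(self.sample_start)

    @property
    def lengths(self) -> np.ndarray:
        return (self.sample_end - self.sample_start).astype(np.int64)

    @property
    def positions(self) -> np.ndarray:
        return np.concatenate([np.arange(a, b) for a, b in self.ref_blocks])

    def validate(self):
        span = sum(b - a for a, b in self.ref_blocks)
        if span != self.n_positions:
            raise IntegrityError(
                f"{self.read_id}: ref blocks span {span} but {self.n_positions} entries")
        consumed = int(self.lengths.sum()) + sum(h - l for l, h in self.masked_ranges)
        if consumed != self.signal_hi - self.signal_lo:
            raise IntegrityError(
                f"{self.read_id}: samples {consumed} != signal span "
                f"{self.signal_hi - self.signal_lo}")


def owned_events(path) -> list:
    """Events entered at each reference index via start/match/stay (skips
    own nothing; the shared event stays with the position it entered at)."""
    out = [[] for _ in range(path.n_refs)]
    for (i, j), mv in zip(path.pairs, path.moves):
        if mv != "skip":
            out[int(j)].append(int(i))
    return out


def _pop_stats(x: np.ndarray):
    if len(x) == 0:
        return np.nan, np.nan
    return float(np.mean(x)), float(np.std(x))


def compute_layers(path, groups, norm_samples, events, positions,
                   masked_ranges=(), splice_mask=None, kmer_ids=None,
                   expected_means=None, read_id="", ref_name="", strand="+",
                   norm=None, model_name="", with_event_counts=False,
                   signal_span=None) -> Alignment:
    """Collapse a DTW path into per-reference-position layers.

    Per position: length = assigned sample count, current = mean and
    current_sd = population sd of the raw (normalized) samples between the
    assigned event boundaries.  Skip-group members copy the shared values
    unless masked; event counts are fractional (1/g) across a skip group
    of g positions.
    """
    n = path.n_refs
    owned = [list(e) for e in owned_events(path)]
    masked = np.zeros(n, dtype=bool) if splice_mask is None else splice_mask.copy()
    group_of = {}
    extra_masked = list(masked_ranges)
    for g in groups:
        for m in g.members:
            group_of[m] = g
        shared = owned[g.carrier][-1] if owned[g.carrier] else None
        if shared is None:
            continue
        if g.kept is None:
            owned[g.carrier].pop()
            ev = events[shared]
            if ev.length > 0:
                extra_masked.append((ev.start, ev.end))
            for m in g.members:
                masked[m] = True
        elif g.kept != g.carrier:
            owned[g.carrier].pop()
            owned[g.kept].append(shared)
            for m in g.members:
                if m != g.kept:
                    masked[m] = True
        else:
            pass  # carrier keeps the samples; members copy values below
    start = np.zeros(n, dtype=np.int64)
    end = np.zeros(n, dtype=np.int64)
    cur = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    counts = np.zeros(n, dtype=float)
    cursor = None
    for j in range(n):
        evs = owned[j]
        if evs:
            # events may straddle a masked (spliced) gap; a position's
            # samples must be one contiguous run, so keep the longest run
            # and mask the rest
            runs = [[evs[0]]]
            for a, b in zip(evs[:-1], evs[1:]):
                if events[a].end == events[b].start:
                    runs[-1].append(b)
                else:
                    runs.append([b])
            if len(runs) > 1:
                best = max(runs, key=lambda r: sum(events[x].length for x in r))
                for r in runs:
                    if r is not best:
                        extra_masked.append((events[r[0]].start, events[r[-1]].end))
                evs = best
            lo = events[evs[0]].start
            hi = events[evs[-1]].end
            start[j], end[j] = lo, hi
            cur[j], sd[j] = _pop_stats(norm_samples[lo:hi])
            cursor = hi
        else:
            c = cursor if cursor is not None else (events[0].start if events else 0)
            start[j] = end[j] = c
    # skip members copy the shared event's values; masked members stay null
    for g in groups:
        owner = g.kept if g.kept is not None else None
        if owner is None:
            continue
        ev = events[g.event]
        ev_mean, ev_sd = _pop_stats(norm_samples[ev.start:ev.end])
        for m in g.members:
            if m == owner or masked[m]:
                continue
            cur[m], sd[m] = ev_mean, ev_sd
            start[m] = end[m] = end[owner]
    if with_event_counts:
        for j in range(n):
            counts[j] = len(owned[j])
        for g in groups:
            gsize = len(g.members)
            share = 1.0 / gsize
            owner = g.kept
            if owner is not None:
                counts[owner] -= 1.0
            for m in g.members:
                counts[m] += share
    cur[masked] = np.nan
    sd[masked] = np.nan

    descending = len(positions) > 1 and positions[0] > positions[-1]
    order = slice(None, None, -1) if descending else slice(None)
    pos_sorted = np.asarray(positions)[order]
    breaks = np.flatnonzero(np.diff(pos_sorted) != 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [len(pos_sorted) - 1]))
    blocks = [(int(pos_sorted[a]), int(pos_sorted[b]) + 1) for a, b in zip(starts, stops)]
    if signal_span is None:
        lo = int(min(start.min(), min((l for l, _ in extra_masked), default=start.min())))
        hi = int(max(end.max(), max((h for _, h in extra_masked), default=end.max())))
        signal_span = (lo, hi)
    aln = Alignment(
        read_id=read_id, ref_name=ref_name, strand=strand, ref_blocks=blocks,
        sample_start=start[order].copy(), sample_end=end[order].copy(),
        current=cur[order].copy(), current_sd=sd[order].copy(),
        masked=masked[order].copy(),
        norm=norm if norm is not None else NormParams(1.0, 0.0),
        signal_lo=int(signal_span[0]), signal_hi=int(signal_span[1]),
        masked_ranges=sorted(extra_masked),
        event_count=counts[order].copy() if with_event_counts else None,
        kmer_ids=np.asarray(kmer_ids)[order].copy() if kmer_ids is not None else None,
        signal_descending=bool(descending),
        model_name=model_name,
    )
    aln.validate()
    return aln


def derived_layer(aln: Alignment, name: str, offset: int = 0, model=None) -> np.ndarray:
    """A per-position layer, optionally shifted: value at r is the base
    layer at r+offset (null off the ends)."""
    if name in ("dtw.length", "dtw.dwell", "length", "dwell"):
        base = aln.lengths.astype(float)
    elif name in ("dtw.current", "current"):
        base = aln.current
    elif name in ("dtw.current_sd", "current_sd"):
        base = aln.current_sd
    elif name in ("seq.kmer", "kmer"):
        if aln.kmer_ids is None:
            raise PoresigError("alignment carries no k-mer layer")
        base = aln.kmer_ids.astype(float)
    elif name in ("dtw.model_diff", "model_diff"):
        if model is None or aln.kmer_ids is None:
            raise PoresigError("model_diff requires a pore model and k-mer ids")
        base = np.abs(aln.current - model.means[aln.kmer_ids])
    elif name in ("mvcmp.dist", "event_count"):
        key = "event_count" if name == "event_count" else name
        if key == "event_count" and aln.event_count is not None:
            base = aln.event_count.astype(float)
        elif key in aln.extra:
            base = np.asarray(aln.extra[key], dtype=float)
        else:
            raise PoresigError(f"layer {name!r} not attached to this alignment")
    else:
        raise PoresigError(f"unknown layer {name!r}; valid: {BASE_LAYERS}")
    if offset == 0:
        return np.asarray(base, dtype=float).copy()
    out = np.full(len(base), np.nan)
    if offset > 0:
        out[:len(base) - offset] = base[offset:]
    else:
        out[-offset:] = base[:len(base) + offset]
    return out


# ---------------------------------------------------------------------------
# tag codec

def _emit_chain(out: list, value: int, sign: int):
    v = int(value)
    while v >= SENTINEL:
        out.append(sign * SENTINEL)
        v -= SENTINEL
    out.append(sign * v)


def _quantize(x: np.ndarray) -> tuple[np.ndarray, int]:
    q = np.full(len(x), NULL_QUANTUM, dtype=np.int64)
    ok = np.isfinite(x)
    raw = np.round((x[ok] - FIXED_MIN) / (FIXED_MAX - FIXED_MIN) * QUANTA)
    clipped = int(np.sum((raw < 0) | (raw > QUANTA)))
    q[ok] = np.clip(raw, 0, QUANTA).astype(np.int64)
    return q, clipped


def _dequantize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.int64)
    x = q / QUANTA * (FIXED_MAX - FIXED_MIN) + FIXED_MIN
    x[q == NULL_QUANTUM] = np.nan
    return x


def encode_tags(aln: Alignment) -> dict:
    """Encode an alignment as the us/ur/uc/ud/un (+ub) tag arrays."""
    aln.validate()
    n = aln.n_positions
    order = np.arange(n)[::-1] if aln.signal_descending else np.arange(n)
    pending = sorted(aln.masked_ranges)
    us: list[int] = []
    cursor = aln.signal_lo
    pi = 0
    for j in order:
        s, e = int(aln.sample_start[j]), int(aln.sample_end[j])
        while pi < len(pending) and pending[pi][0] <= max(cursor, s) and pending[pi][0] == cursor:
            lo, hi = pending[pi]
            _emit_chain(us, hi - lo, -1)
            cursor = hi
            pi += 1
        if e > s:
            if s != cursor:
                raise IntegrityError(
                    f"{aln.read_id}: signal gap at sample {cursor} (next position at {s})")
            _emit_chain(us, e - s, +1)
            cursor = e
        else:
            us.append(0)
    while pi < len(pending):
        lo, hi = pending[pi]
        if lo != cursor:
            raise IntegrityError(f"{aln.read_id}: trailing signal gap at {cursor}")
        _emit_chain(us, hi - lo, -1)
        cursor = hi
        pi += 1
    if cursor != aln.signal_hi:
        raise IntegrityError(f"{aln.read_id}: encoded {cursor - aln.signal_lo} samples, "
                             f"span is {aln.signal_hi - aln.signal_lo}")
    uc, c1 = _quantize(aln.current[order])
    ud, c2 = _quantize(aln.current_sd[order])
    if c1 or c2:
        logger.warning("%s: %d current values clipped to [%s, %s]",
                       aln.read_id, c1 + c2, FIXED_MIN, FIXED_MAX)
    ur = [c for blk in aln.ref_blocks for c in blk]
    tags = {
        "us": np.array(us, dtype=np.int64),
        "ur": np.array(ur, dtype=np.int64),
        "uc": uc,
        "ud": ud,
        "un": np.array([aln.norm.scale, aln.norm.shift], dtype=float),
        "ub": np.array([aln.signal_lo, aln.signal_hi], dtype=np.int64),
    }
    if aln.event_count is not None:
        tags["ue"] = aln.event_count[order].astype(float)
    return tags


def header_json(model_name="", ref_path="", signal_path="", reverse_signal=False) -> str:
    return json.dumps({
        "tags": {"us": "sample counts", "ur": "ref blocks", "uc": "current",
                 "ud": "current sd", "un": "norm scale/shift",
                 "ub": "signal span", "ue": "event counts"},
        "fixed_range": [FIXED_MIN, FIXED_MAX],
        "model": model_name,
        "reverse_signal": bool(reverse_signal),
        "ref": str(ref_path),
        "signal": str(signal_path),
    })


def _decode_us(us) -> list[tuple[str, int]]:
    """Expand sentinel chains: list of ('sig', n) / ('mask', n) / ('skip', 0)."""
    items = []
    acc = 0
    sign = 0
    for v in np.asarray(us, dtype=np.int64):
        v = int(v)
        if sign != 0:  # inside a chain
            if (v >= 0) != (sign > 0) and v != 0:
                raise IntegrityError("sentinel chain changes sign")
            acc += abs(v)
            if abs(v) != SENTINEL:
                items.append(("sig" if sign > 0 else "mask", acc))
                acc, sign = 0, 0
            continue
        if v == 0:
            items.append(("skip", 0))
        elif abs(v) == SENTINEL:
            sign = 1 if v > 0 else -1
            acc = SENTINEL
        elif v > 0:
            items.append(("sig", v))
        else:
            items.append(("mask", -v))
    if sign != 0:
        raise IntegrityError("unterminated sentinel chain in us tag")
    return items


def decode_tags(tags: dict, strand: str = "+", reverse_signal: bool = False,
                read_id: str = "", ref_name: str = "", model_name: str = "") -> Alignment:
    """Rebuild an Alignment from its tag arrays, verifying conservation."""
    us = tags["us"]
    ur = np.asarray(tags["ur"], dtype=np.int64)
    uc = _dequantize(tags["uc"])
    ud = _dequantize(tags["ud"])
    un = np.asarray(tags["un"], dtype=float)
    lo, hi = (int(v) for v in tags["ub"])
    items = _decode_us(us)
    total = sum(n for _, n in items)
    if total != hi - lo:
        raise IntegrityError(
            f"{read_id}: sum |us| = {total} but signal span is {hi - lo}")
    blocks = [(int(ur[i]), int(ur[i + 1])) for i in range(0, len(ur), 2)]
    span = sum(b - a for a, b in blocks)
    n_pos_entries = sum(1 for kind, _ in items if kind != "mask")
    if span != n_pos_entries:
        raise IntegrityError(
            f"{read_id}: ur span {span} != {n_pos_entries} non-negative us entries")
    start = np.zeros(n_pos_entries, dtype=np.int64)
    end = np.zeros(n_pos_entries, dtype=np.int64)
    masked_ranges = []
    cursor = lo
    j = 0
    for kind, nsamp in items:
        if kind == "mask":
            masked_ranges.append((cursor, cursor + nsamp))
            cursor += nsamp
        elif kind == "sig":
            start[j], end[j] = cursor, cursor + nsamp
            cursor += nsamp
            j += 1
        else:
            start[j] = end[j] = cursor
            j += 1
    descending = (strand == "-") != bool(reverse_signal)
    order = slice(None, None, -1) if descending else slice(None)
    ec = tags.get("ue")
    aln = Alignment(
        read_id=read_id, ref_name=ref_name, strand=strand, ref_blocks=blocks,
        sample_start=start[order].copy(), sample_end=end[order].copy(),
        current=uc[order].copy(), current_sd=ud[order].copy(),
        masked=~np.isfinite(uc[order]),
        norm=NormParams(float(un[0]), float(un[1])),
        signal_lo=lo, signal_hi=hi, masked_ranges=masked_ranges,
        event_count=np.asarray(ec, dtype=float)[order].copy() if ec is not None else None,
        signal_descending=descending, model_name=model_name,
    )
    aln.validate()
    return aln


# ---------------------------------------------------------------------------
# BAM I/O (pysam)

def attach_tags(record, aln: Alignment) -> None:
    """Write the signal-alignment tags onto a pysam AlignedSegment."""
    import array

    tags = encode_tags(aln)
    record.set_tag("us", array.array("i", [int(v) for v in tags["us"]]))
    record.set_tag("ur", array.array("i", [int(v) for v in tags["ur"]]))
    record.set_tag("uc", array.array("I", [int(v) for v in tags["uc"]]))
    record.set_tag("ud", array.array("I", [int(v) for v in tags["ud"]]))
    record.set_tag("un", array.array("f", [float(v) for v in tags["un"]]))
    record.set_tag("ub", array.array("i", [int(v) for v in tags["ub"]]))
    if "ue" in tags:
        record.set_tag("ue", array.array("f", [float(v) for v in tags["ue"]]))


def tags_from_record(record) -> dict:
    out = {}
    for tag in ("us", "ur", "uc", "ud", "un", "ub", "ue"):
        if record.has_tag(tag):
            out[tag] = np.array(record.get_tag(tag))
    missing = [t for t in ("us", "ur", "uc", "ud", "un", "ub") if t not in out]
    if missing:
        raise FormatError(f"record {record.query_name}: missing tag(s) {missing}")
    return out


def alignment_from_record(record, reverse_signal: bool = False) -> Alignment:
    strand = "-" if record.is_reverse else "+"
    return decode_tags(tags_from_record(record), strand=strand,
                       reverse_signal=reverse_signal,
                       read_id=record.query_name,
                       ref_name=record.reference_name or "")


def read_header_json(bam) -> dict:
    for co in bam.header.to_dict().get("CO", []):
        if co.startswith(JSON_HEADER_KEY + "="):
            return json.loads(co[len(JSON_HEADER_KEY) + 1:])
    return {}


def add_header_json(header_dict: dict, js: str) -> dict:
    header_dict = dict(header_dict)
    co = [c for c in header_dict.get("CO", []) if not c.startswith(JSON_HEADER_KEY + "=")]
    co.append(f"{JSON_HEADER_KEY}={js}")
    header_dict["CO"] = co
    return header_dict


def iter_alignments(bam_path):
    """Yield (pysam record, decoded Alignment) for every tagged record."""
    import pysam

    with pysam.AlignmentFile(str(bam_path), "rb", check_sq=False) as bam:
        meta = read_header_json(bam)
        rev = bool(meta.get("reverse_signal", False))
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or not rec.has_tag("us"):
                continue
            yield rec, alignment_from_record(rec, reverse_signal=rev)


# ---------------------------------------------------------------------------
# text formats

EVENTALIGN_COLUMNS = [
    "contig", "position", "reference_kmer", "read_name", "strand",
    "event_index", "event_level_mean", "event_stdv", "event_length",
    "model_kmer", "model_mean", "model_stdv", "standardized_level",
    "start_idx", "end_idx",
]


def write_eventalign(alns, model, path, ref_seqs=None) -> None:
    """Nanopolish-style tab-delimited export, one row per unmasked
    reference position (per-position averaging; event_index is a running
    counter; event_length is in raw samples)."""
    from .pore_model import index_to_kmer, revcomp as _rc

    with open(path, "w") as fh:
        fh.write("\t".join(EVENTALIGN_COLUMNS) + "\n")
        for aln in alns:
            if aln.kmer_ids is None:
                raise PoresigError(f"{aln.read_id}: no k-mer layer; supply the reference")
            positions = aln.positions
            idx = 0
            for p in range(aln.n_positions):
                if aln.masked[p] or not np.isfinite(aln.current[p]):
                    continue
                kid = int(aln.kmer_ids[p])
                model_kmer = index_to_kmer(kid, model.k)
                ref_kmer = model_kmer if aln.strand == "+" else _rc(model_kmer)
                mm = float(model.means[kid])
                ms = float(model.sds[kid])
                std_lvl = (float(aln.current[p]) - mm) / ms
                fh.write("\t".join(str(v) for v in (
                    aln.ref_name, int(positions[p]), ref_kmer, aln.read_id,
                    "t" if aln.strand == "+" else "c", idx,
                    round(float(aln.current[p]), 5),
                    round(float(aln.current_sd[p]), 5),
                    int(aln.sample_end[p] - aln.sample_start[p]),
                    model_kmer, round(mm, 5), round(ms, 5),
                    round(std_lvl, 5),
                    int(aln.sample_start[p]), int(aln.sample_end[p]),
                )) + "\n")
                idx += 1


def write_tsv(alns, layers, path, model=None) -> None:
    """Customizable tab-delimited export of any layer set."""
    with open(path, "w") as fh:
        fh.write("#read_id\tcontig\tposition\t" + "\t".join(layers) + "\n")
        for aln in alns:
            cols = [derived_layer(aln, ly, model=model) for ly in layers]
            positions = aln.positions
            for p in range(aln.n_positions):
                vals = "\t".join("" if not np.isfinite(c[p]) else f"{c[p]:g}"
                                 for c in cols)
                fh.write(f"{aln.read_id}\t{aln.ref_name}\t{int(positions[p])}\t{vals}\n")


def read_eventalign(path):
    """Parse an eventalign file into per-read Alignments.

    Multiple rows per position (per-event exports) are collapsed to
    per-position means weighted by event_length.  Rows for a read must be
    in ascending coordinate order.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"contig", "position", "read_name", "event_level_mean",
                "event_stdv", "event_length", "start_idx", "end_idx"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing eventalign column(s) {sorted(missing)}")
    out = []
    for (read, contig), grp in df.groupby(["read_name", "contig"], sort=False):
        pos = grp["position"].to_numpy()
        if np.any(np.diff(np.unique(pos)) < 0) or not np.all(np.diff(pos) >= 0):
            raise FormatError(f"{path}: rows for read {read} out of coordinate order")
        w = grp["event_length"].to_numpy(dtype=float).clip(min=1e-9)
        agg = {}
        for p, mean, sdv, wt, s0, s1, strand in zip(
                pos, grp["event_level_mean"], grp["event_stdv"], w,
                grp["start_idx"], grp["end_idx"],
                grp.get("strand", pd.Series(["t"] * len(grp)))):
            rec = agg.setdefault(int(p), [0.0, 0.0, 0.0, np.inf, -np.inf, strand])
            rec[0] += wt * mean
            rec[1] += wt * sdv
            rec[2] += wt
            rec[3] = min(rec[3], int(s0))
            rec[4] = max(rec[4], int(s1))
        ps = sorted(agg)
        start = np.array([agg[p][3] for p in ps], dtype=np.int64)
        end = np.array([agg[p][4] for p in ps], dtype=np.int64)
        cur = np.array([agg[p][0] / agg[p][2] for p in ps])
        sdv = np.array([agg[p][1] / agg[p][2] for p in ps])
        strand = "+" if agg[ps[0]][5] == "t" else "-"
        pos_arr = np.array(ps, dtype=np.int64)
        breaks = np.flatnonzero(np.diff(pos_arr) != 1)
        bs = np.concatenate(([0], breaks + 1))
        be = np.concatenate((breaks, [len(pos_arr) - 1]))
        blocks = [(int(pos_arr[a]), int(pos_arr[b]) + 1) for a, b in zip(bs, be)]
        # signal-order gaps between consecutive intervals become masked runs
        osort = np.argsort(start, kind="stable")
        masked_ranges = []
        cursor = int(start[osort[0]])
        lo_sig = cursor
        for oi in osort:
            s, e = int(start[oi]), int(end[oi])
            if e > s:
                if s > cursor:
                    masked_ranges.append((cursor, s))
                cursor = max(cursor, e)
        out.append(Alignment(
            read_id=read, ref_name=contig, strand=strand, ref_blocks=blocks,
            sample_start=start, sample_end=end, current=cur, current_sd=sdv,
            masked=np.zeros(len(ps), dtype=bool),
            norm=NormParams(1.0, 0.0), signal_lo=lo_sig, signal_hi=cursor,
            masked_ranges=masked_ranges,
            signal_descending=bool(len(start) > 1 and start[0] > start[-1]),
        ))
    return out
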