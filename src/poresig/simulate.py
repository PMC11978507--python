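"""Squiggle simulation with full ground truth.

The generator embodies the nanopore signal model the aligner assumes:
per-k-mer Gaussian current levels, stochastic dwell times (shifted
geometric, memoryless per-sample advance), skips, read-level affine
scale/shift distortion, a low-resolution move table with positional jitter,
and optional current shifts at "modified" positions.  Default regimes:
mean dwell 8 samples, skip probability 2%, move stride 5 (DNA), noise sd
0.3 of the per-k-mer model sd.

Every read carries its truth: the exact sample interval of each reference
position, the move table, the cigar and the applied distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .bcdtw import ReadAlignmentMeta
from .errors import PoresigError
from .pore_model import (BASES, PoreModel, expected_signal, index_to_kmer,
                         kmer_index, seq_to_codes)
from .signal_io import RawRead

logger = logging.getLogger(__name__)

_BASE_CODE_LOCAL = {"A": 0, "C": 1, "G": 2, "T": 3}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the generator (see module docstring)."""

    noise_sd: float = 0.3
    dwell_mean: float = 8.0
    dwell_min: int = 1
    skip_prob: float = 0.02
    move_jitter: int = 1
    scale_sd: float = 0.02
    shift_sd: float = 0.05
    stride: int = 5
    indel_spec: tuple = ()           # ((ref_pos, 'I'|'D', length), ...)
    dwell_boost: tuple | None = None  # (offset, base, factor)
    digitisation: float = 8192.0
    dac_offset: float = 0.0
    range: float = 1500.0
    sampling_rate: float = 4000.0
    quantize: bool = True


@dataclass
class SimulatedRead:
    """A raw read plus its ground truth."""

    raw: RawRead
    read_seq: str
    cigar: str
    moves: np.ndarray
    stride: int
    ref_start: int
    strand: str
    truth_start: np.ndarray   # per reference position; -1 = deleted
    truth_end: np.ndarray
    scale_true: float
    shift_true: float

    def meta(self, ref_name: str = "ref") -> ReadAlignmentMeta:
        return ReadAlignmentMeta(
            read_id=self.raw.read_id, ref_name=ref_name, ref_start=self.ref_start,
            strand=self.strand, cigar=self.cigar, moves=self.moves,
            stride=self.stride, signal_offset=0)


def random_reference(length: int, seed: int, ensure_kmers: int | None = None,
                     max_homopolymer: int | None = None) -> str:
    """Random ACGT sequence; with ensure_kmers=k a De Bruijn(4,k) core is
    embedded so every k-mer occurs at least once (training precondition).

    With ensure_kmers, homopolymer runs longer than k are broken: adjacent
    reference positions carrying an identical k-mer produce no current step
    and are unidentifiable from signal alone.
    """
    rng = np.random.default_rng(seed)
    if ensure_kmers:
        # permute the alphabet and rotate the cycle so different seeds give
        # different local sequence contexts for every k-mer
        k = ensure_kmers
        cyc = debruijn_sequence(k)[:4 ** k]
        perm = rng.permutation(4)
        cyc = "".join(BASES[perm[_BASE_CODE_LOCAL[c]]] for c in cyc)
        rot = int(rng.integers(len(cyc)))
        cyc = cyc[rot:] + cyc[:rot]
        core = cyc + cyc[:k - 1]
    else:
        core = ""
    if len(core) > length:
        raise PoresigError(f"length {length} cannot contain all {ensure_kmers}-mers")
    fill = "".join(BASES[i] for i in rng.integers(0, 4, size=length - len(core)))
    seq = list(core + fill)
    cap = max_homopolymer if max_homopolymer is not None else ensure_kmers
    if cap:
        run = 1
        for i in range(1, len(seq)):
            run = run + 1 if seq[i] == seq[i - 1] else 1
            if run > cap:
                choices = [b for b in BASES if b != seq[i]]
                seq[i] = choices[int(rng.integers(3))]
                run = 1
    seq = "".join(seq)
    if ensure_kmers:
        # run-breaking only ever edits filler (the De Bruijn core has no
        # over-long runs), but verify completeness and repair if needed
        k = ensure_kmers
        present = {seq[i:i + k] for i in range(len(seq) - k + 1)}
        for i in range(4 ** k):
            km = index_to_kmer(i, k)
            if km not in present:
                sep = "C" if km[0] != "C" else "G"
                seq = seq + sep + km
    return seq


def debruijn_sequence(k: int) -> str:
    """Linearized de Bruijn sequence over ACGT containing every k-mer once."""
    seq = []
    a = [0] * 4 * k

    def db(t, p):
        if t > k:
            if k % p == 0:
                seq.extend(a[1:p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, 4):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    cyc = seq + seq[:k - 1]
    return "".join(BASES[c] for c in cyc)


def plant_motif_reference(length: int, motif: str, positions, seed: int) -> str:
    """Background sequence free of ``motif`` with the motif planted at the
    given positions (used to place isolated 'modified' sites)."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < length:
        out.append(BASES[rng.integers(0, 4)])
        if len(out) >= len(motif) and "".join(out[-len(motif):]) == motif:
            out[-1] = BASES[(kmer_index(out[-1], 1) + 1) % 4]
    for p in positions:
        if p + len(motif) > length:
            raise PoresigError(f"motif at {p} exceeds reference length")
        out[p:p + len(motif)] = motif
    s = "".join(out[:length])
    return s


def _apply_indels(reference: str, indel_spec) -> tuple[str, str, np.ndarray]:
    """Build the read sequence and cigar; returns (read_seq, cigar,
    per-read-base reference coordinate, -1 for inserted bases)."""
    spec_key = sum((p * 131 + ln * 17 + ord(op)) for p, op, ln in indel_spec)
    rng = np.random.default_rng(spec_key & 0x7FFFFFFF)
    ins = {p: ln for p, op, ln in indel_spec if op == "I"}
    dels = {p: ln for p, op, ln in indel_spec if op == "D"}
    read = []
    ref_of = []
    ops = []

    def push(op, n=1):
        if ops and ops[-1][0] == op:
            ops[-1][1] += n
        else:
            ops.append([op, n])

    r = 0
    L = len(reference)
    while r < L:
        if r in dels:
            g = min(dels[r], L - r)
            push("D", g)
            r += g
            continue
        read.append(reference[r])
        ref_of.append(r)
        push("M")
        if r in ins:
            for _ in range(ins[r]):
                read.append(BASES[rng.integers(0, 4)])
                ref_of.append(-1)
            push("I", ins[r])
        r += 1
    cigar = "".join(f"{n}{op}" for op, n in ops)
    return "".join(read), cigar, np.array(ref_of, dtype=np.int64)


def simulate_read(reference: str, model: PoreModel, params: SimParams = SimParams(),
                  seed: int = 0, read_id: str = "sim") -> SimulatedRead:
    """Generate one read's raw signal plus ground truth.

    Per reference position: dwell ~ shifted-geometric(mean dwell_mean,
    minimum 1), zeroed with probability skip_prob; samples ~
    Normal(model mean, noise_sd * model sd); the whole read is distorted by
    scale ~ N(1, scale_sd), shift ~ N(0, shift_sd) before pA calibration.
    """
    if params.dwell_mean < 1:
        raise PoresigError("dwell_mean must be >= 1")
    if len(reference) < model.k:
        raise PoresigError("reference shorter than the model k-mer")
    rng = np.random.default_rng(seed)
    read_seq, cigar, ref_of = _apply_indels(reference, params.indel_spec)
    n = len(read_seq)
    pos, kids, means, sds = expected_signal(read_seq, model)
    if model.reverse_signal:
        pos, kids, means, sds = pos[::-1], kids[::-1], means[::-1], sds[::-1]
    # extend k-mer context to the untrimmed flanking bases
    base_mean = np.empty(n)
    base_sd = np.empty(n)
    base_mean[pos] = means
    base_sd[pos] = sds
    c = model.central_pos
    base_mean[:c] = base_mean[c]
    base_sd[:c] = base_sd[c]
    tail = n - (model.k - 1 - c)
    base_mean[tail:] = base_mean[tail - 1]
    base_sd[tail:] = base_sd[tail - 1]

    if params.dwell_mean < params.dwell_min:
        raise PoresigError("dwell_mean must be >= dwell_min")
    shift_d = params.dwell_min - 1
    p_geom = 1.0 / (params.dwell_mean - shift_d)
    scale_true = float(rng.normal(1.0, params.scale_sd))
    shift_true = float(rng.normal(0.0, params.shift_sd))

    # per-position randomness is keyed by (seed, reference coordinate) so a
    # pair of reads differing only by an indel is identical elsewhere
    pos_rng = {r: np.random.default_rng((seed, r))
               for r in np.unique(ref_of[ref_of >= 0])}
    dwell = np.zeros(n, dtype=np.int64)
    jitter = np.zeros(n, dtype=np.int64)
    for b in range(n):
        r = ref_of[b]
        g = pos_rng[r] if r >= 0 else rng
        mean_dwell = params.dwell_mean
        if params.dwell_boost is not None and r >= 0:
            off, base, factor = params.dwell_boost
            if 0 <= r + off < len(reference) and reference[r + off] == base:
                mean_dwell = max(params.dwell_min + 1e-9, mean_dwell * factor)
        dwell[b] = shift_d + g.geometric(1.0 / (mean_dwell - shift_d))
        if g.random() < params.skip_prob:
            dwell[b] = 0
        if params.move_jitter > 0:
            jitter[b] = g.integers(-params.move_jitter, params.move_jitter + 1)
    if dwell.sum() < 2:
        dwell[0] = max(dwell[0], 2)

    order = np.arange(n)[::-1] if model.reverse_signal else np.arange(n)
    starts_read = np.zeros(n, dtype=np.int64)  # per read base, signal order
    chunks = []
    t = 0
    for b in order:
        starts_read[b] = t
        d = int(dwell[b])
        if d > 0:
            r = ref_of[b]
            g = pos_rng[r] if r >= 0 else rng
            chunks.append(g.normal(base_mean[b], params.noise_sd * base_sd[b], size=d))
        t += d
    total = t
    x = np.concatenate(chunks) if chunks else np.zeros(0)
    x = scale_true * x + shift_true
    pa = model.pa_mean + model.pa_sd * x
    dac = pa * params.digitisation / params.range - params.dac_offset
    if params.quantize:
        dac = np.round(dac).astype(np.int32)
    raw = RawRead(read_id=read_id, samples=dac,
                  digitisation=params.digitisation, offset=params.dac_offset,
                  range=params.range, sampling_rate=params.sampling_rate)

    # move table: one 1-entry per read base in signal order, with jitter
    n_blocks = int(np.ceil(total / params.stride))
    sig_starts = starts_read[::-1] if model.reverse_signal else starts_read
    sig_jitter = jitter[::-1] if model.reverse_signal else jitter
    steps = np.round(sig_starts / params.stride).astype(np.int64) + sig_jitter
    for b in range(n):
        lo = steps[b - 1] + 1 if b > 0 else 0
        cap = n_blocks - (n - 1 - b)
        steps[b] = min(max(steps[b], lo), cap - 1)
    if np.any(np.diff(steps) < 1):
        raise PoresigError("cannot fit one move per base at this stride")
    moves = np.zeros(n_blocks, dtype=np.int8)
    moves[steps] = 1

    # ground truth per reference position
    truth_start = np.full(len(reference), -1, dtype=np.int64)
    truth_end = np.full(len(reference), -1, dtype=np.int64)
    for b in range(n):
        r = ref_of[b]
        if r >= 0:
            truth_start[r] = starts_read[b]
            truth_end[r] = starts_read[b] + dwell[b]
    return SimulatedRead(
        raw=raw, read_seq=read_seq, cigar=cigar, moves=moves,
        stride=params.stride, ref_start=0, strand="+",
        truth_start=truth_start, truth_end=truth_end,
        scale_true=scale_true, shift_true=shift_true)


def simulate_batch(reference: str, model: PoreModel, n_reads: int,
                   params: SimParams, seed: int, ref_name: str = "ref"):
    """n_reads simulated reads plus their guide metadata."""
    rng = np.random.default_rng(seed)
    sims = [simulate_read(reference, model, params, seed=int(rng.integers(2 ** 31)),
                          read_id=f"read{i:05d}")
            for i in range(n_reads)]
    metas = [s.meta(ref_name) for s in sims]
    return sims, metas


def truth_position_of_samples(sim: SimulatedRead, n_ref: int) -> np.ndarray:
    """Per raw sample, the true reference position (-1 where unassigned)."""
    out = np.full(len(sim.raw.samples), -1, dtype=np.int64)
    for r in range(n_ref):
        if sim.truth_start[r] >= 0:
            out[sim.truth_start[r]:sim.truth_end[r]] = r
    return out


def aligned_position_of_samples(aln, n_samples: int) -> np.ndarray:
    """Per raw sample, the reference position an alignment assigns (-1 =
    unassigned/masked signal)."""
    out = np.full(n_samples, -1, dtype=np.int64)
    pos = aln.positions
    for x in range(aln.n_positions):
        out[aln.sample_start[x]:aln.sample_end[x]] = pos[x]
    return out


def sample_position_errors(sim: SimulatedRead, aln, n_ref: int) -> np.ndarray:
    """|true - aligned| reference coordinate per raw sample aligned by both."""
    truth = truth_position_of_samples(sim, n_ref)
    got = aligned_position_of_samples(aln, len(sim.raw.samples))
    ok = (truth >= 0) & (got >= 0)
    return np.abs(truth[ok] - got[ok])


def make_truth_model(k: int, seed: int = 0, central_pos: int | None = None,
                     name: str = "synthetic") -> PoreModel:
    """A synthetic normalized truth model with unit per-k-mer sds, built
    from additive per-position effects plus k-mer-specific deviations so the
    central base dominates the substitution profile."""
    rng = np.random.default_rng(seed)
    if central_pos is None:
        central_pos = (k - 1) // 2
    n = 4 ** k
    means = np.zeros(n)
    idx = np.arange(n)
    for p in range(k):
        if p == central_pos:
            # real pores have a dominant, well-separated central-base
            # effect (the premise of the central-base anchor); a random
            # draw can be degenerate, so use a fixed spaced pattern with
            # a seeded base assignment
            effects = 4.0 * rng.permutation([-1.161, -0.387, 0.387, 1.161])
        else:
            effects = rng.normal(0, 1.0, size=4)
        digit = (idx // 4 ** (k - 1 - p)) % 4
        means += effects[digit]
    means += rng.normal(0, 0.25, size=n)
    model = PoreModel(k=k, means=means, sds=np.ones(n), central_pos=central_pos,
                      pa_mean=90.0, pa_sd=12.0, name=name).normalized()
    # unit per-k-mer sds in final normalized units, so a generator noise_sd
    # is directly a normalized-current standard deviation
    return replace(model, sds=np.ones(n))


def inject_modification(model: PoreModel, motif: str, offset: int,
                        delta: float) -> PoreModel:
    """Shift the means of k-mers matching an IUPAC motif at the given
    offset within the k-mer by delta normalized units (the 'modified'
    track's model)."""
    if offset < 0 or offset + len(motif) > model.k:
        raise PoresigError(f"motif {motif!r} at offset {offset} exceeds the k-mer")
    allowed = [IUPAC[c.upper()] for c in motif]
    means = model.means.copy()
    hits = 0
    for i in range(model.n_kmers):
        kmer = index_to_kmer(i, model.k)
        if all(kmer[offset + j] in allowed[j] for j in range(len(motif))):
            means[i] += delta
            hits += 1
    if hits == 0:
        logger.warning("motif %r matches no %d-mer", motif, model.k)
    return replace(model, means=means, name=f"{model.name}+{motif}")


def simulate_dataset(reference: str, model: PoreModel, n_reads: int,
                     params: SimParams, seed: int, out_dir,
                     ref_name: str = "ref") -> dict:
    """Write a complete synthetic dataset: FASTA reference, SLOW5 signal,
    BAM with move metadata (mv/ts tags) and a truth TSV."""
    import os

    import pysam

    from . import signal_io
    from .pore_model import save_model

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "ref": os.path.join(out_dir, "ref.fa"),
        "slow5": os.path.join(out_dir, "reads.slow5"),
        "bam": os.path.join(out_dir, "reads.bam"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "model": os.path.join(out_dir, "model.tsv"),
    }
    rng = np.random.default_rng(seed)
    sims = [simulate_read(reference, model, params, seed=int(rng.integers(2 ** 31)),
                          read_id=f"read{i:05d}")
            for i in range(n_reads)]
    with open(paths["ref"], "w") as fh:
        fh.write(f">{ref_name}\n")
        for i in range(0, len(reference), 60):
            fh.write(reference[i:i + 60] + "\n")
    signal_io.write_slow5([s.raw for s in sims], paths["slow5"])
    save_model(model, paths["model"])
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": ref_name, "LN": len(reference)}]}
    with pysam.AlignmentFile(paths["bam"], "wb", header=header) as bam:
        for s in sims:
            rec = pysam.AlignedSegment(bam.header)
            rec.query_name = s.raw.read_id
            rec.query_sequence = s.read_seq
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = s.ref_start
            rec.mapping_quality = 60
            rec.cigarstring = s.cigar
            import array as _array
            rec.set_tag("mv", _array.array(
                "b", [int(s.stride)] + [int(v) for v in s.moves]))
            rec.set_tag("ts", 0)
            bam.write(rec)
    with open(paths["truth"], "w") as fh:
        fh.write("#read_id\tposition\tsample_start\tsample_end\n")
        for s in sims:
            for r in range(len(reference)):
                if s.truth_start[r] >= 0:
                    fh.write(f"{s.raw.read_id}\t{r}\t{s.truth_start[r]}\t{s.truth_end[r]}\n")
    return paths
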