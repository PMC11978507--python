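"""k-mer pore models: the lookup table from nucleotide k-mers to expected current.

A pore model maps each length-k word to the mean and standard deviation of
the normalized ionic current observed while that word occupies the pore.
Models are stored as Nanopolish-style TSV (columns ``kmer``, ``level_mean``,
``level_stdv``) with ``#key<TAB>value`` header lines carrying the k-mer
geometry (``central_pos``) and the pA calibration (``pa_mean``, ``pa_sd``).

Normalized-unit models are kept at mean 0 / sd 1 over all k-mers (population
denominator), so a per-read linear normalization maps raw current into model
space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, InvalidSequenceError

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3,
              "a": 0, "c": 1, "g": 2, "t": 3, "u": 3}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a nucleotide string as base-4 digits (A=0, C=1, G=2, T=3).

    U is silently mapped to T.  Raises InvalidSequenceError on anything else.
    """
    try:
        return np.array([_BASE_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as e:
        raise InvalidSequenceError(f"invalid base {e.args[0]!r} in sequence") from None


def codes_to_seq(codes) -> str:
    return "".join(BASES[int(c)] for c in codes)


def kmer_index(kmer: str, k: int) -> int:
    """Canonical base-4 index of a k-mer (leftmost base most significant)."""
    if len(kmer) != k:
        raise InvalidSequenceError(f"expected a {k}-mer, got {kmer!r}")
    codes = seq_to_codes(kmer)
    idx = 0
    for c in codes:
        idx = idx * 4 + int(c)
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def _kmer_digits(k: int) -> np.ndarray:
    """(4**k, k) array of base codes for every k-mer, row i = digits of i."""
    idx = np.arange(4 ** k)
    return np.stack([(idx >> (2 * (k - 1 - p))) & 3 for p in range(k)], axis=1)


@dataclass
class PoreModel:
    """Expected normalized current per k-mer plus pA calibration.

    central_pos is the 0-based offset of the base with the strongest
    influence on current; per-reference-position statistics are anchored on
    it.  reverse_signal marks chemistries (direct RNA) whose signal
    traverses the sequence 3'->5'.
    """

    k: int
    means: np.ndarray
    sds: np.ndarray
    central_pos: int = 0
    pa_mean: float = 90.0
    pa_sd: float = 12.0
    name: str = "unnamed"
    reverse_signal: bool = False

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        n = 4 ** self.k
        if self.means.shape != (n,) or self.sds.shape != (n,):
            raise FormatError(
                f"model arrays must have 4^{self.k}={n} entries, "
                f"got {self.means.shape[0]}")
        if not (0 <= self.central_pos < self.k):
            raise FormatError(f"central_pos {self.central_pos} outside k-mer of length {self.k}")
        if np.any(self.sds <= 0):
            raise FormatError("model sds must be strictly positive")

    @property
    def n_kmers(self) -> int:
        return 4 ** self.k

    def normalized(self) -> "PoreModel":
        """Rescale so k-mer means have mean 0 / sd 1 (population denominator)."""
        mu = float(np.mean(self.means))
        sigma = float(np.std(self.means))
        if sigma == 0:
            raise FormatError("cannot normalize a constant model")
        return replace(
            self,
            means=(self.means - mu) / sigma,
            sds=self.sds / sigma,
            pa_mean=self.pa_mean + self.pa_sd * mu,
            pa_sd=self.pa_sd * sigma,
        )

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return (abs(float(np.mean(self.means))) < tol
                and abs(float(np.std(self.means)) - 1.0) < tol)

    def to_pa(self, x):
        return self.pa_mean + self.pa_sd * np.asarray(x, dtype=float)


def save_model(model: PoreModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k\t{model.k}\n")
        fh.write(f"#central_pos\t{model.central_pos}\n")
        fh.write(f"#pa_mean\t{float(model.pa_mean)!r}\n")
        fh.write(f"#pa_sd\t{float(model.pa_sd)!r}\n")
        fh.write(f"#name\t{model.name}\n")
        fh.write(f"#reverse_signal\t{int(model.reverse_signal)}\n")
        fh.write("kmer\tlevel_mean\tlevel_stdv\n")
        for i in range(model.n_kmers):
            fh.write(f"{index_to_kmer(i, model.k)}\t{float(model.means[i])!r}\t"
                     f"{float(model.sds[i])!r}\n")


def load_model(path) -> PoreModel:
    """Load a TSV pore model; all 4^k k-mers must be present exactly once."""
    meta = {}
    rows = {}
    k = None
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                meta[key] = val
                continue
            fields = line.split("\t")
            if fields[0] == "kmer":
                header_seen = True
                continue
            if not header_seen:
                raise FormatError(f"{path}: missing 'kmer<TAB>level_mean<TAB>level_stdv' header")
            if len(fields) < 3:
                raise FormatError(f"{path}: malformed row {line!r}")
            kmer, mean, sd = fields[0], float(fields[1]), float(fields[2])
            if k is None:
                k = len(kmer)
            elif len(kmer) != k:
                raise FormatError(f"{path}: inconsistent k-mer lengths ({k} vs {len(kmer)})")
            if kmer in rows:
                raise FormatError(f"{path}: duplicate k-mer {kmer}")
            rows[kmer] = (mean, sd)
    if k is None:
        raise FormatError(f"{path}: no k-mer rows")
    if "k" in meta and int(meta["k"]) != k:
        raise FormatError(f"{path}: header k={meta['k']} but rows are {k}-mers")
    if len(rows) != 4 ** k:
        raise FormatError(f"{path}: expected {4 ** k} k-mers, found {len(rows)}")
    means = np.empty(4 ** k)
    sds = np.empty(4 ** k)
    for kmer, (m, s) in rows.items():
        means[kmer_index(kmer, k)] = m
        sds[kmer_index(kmer, k)] = s
    return PoreModel(
        k=k,
        means=means,
        sds=sds,
        central_pos=int(meta.get("central_pos", 0)),
        pa_mean=float(meta.get("pa_mean", 90.0)),
        pa_sd=float(meta.get("pa_sd", 12.0)),
        name=meta.get("name", "unnamed"),
        reverse_signal=bool(int(meta.get("reverse_signal", 0))),
    )


def revcomp(seq: str) -> str:
    return codes_to_seq([_COMP[int(c)] for c in seq_to_codes(seq)[::-1]])


def sequence_kmer_ids(seq: str, k: int) -> np.ndarray:
    """Base-4 indices of all len(seq)-k+1 k-mer windows of seq."""
    codes = seq_to_codes(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    ids = np.zeros(n, dtype=np.int64)
    for j in range(k):
        ids = ids * 4 + codes[j:j + n]
    return ids


def expected_signal(sequence: str, model: PoreModel, strand: str = "+"):
    """Per-reference-position expected current for a sequence.

    Position r (0-based, on the forward reference) is assigned the k-mer
    sequence[r-central_pos : r-central_pos+k]; the central_pos leading and
    k-1-central_pos trailing positions have no full k-mer context and are
    unassigned.  Returns (positions, kmer_ids, means, sds).

    For strand '-', k-mers come from the reverse complement but positions
    remain ascending forward-reference coordinates.  When
    model.reverse_signal is true the emitted order is reversed so that
    index 0 is the first k-mer to traverse the pore.
    """
    k, c = model.k, model.central_pos
    L = len(sequence)
    if L < k:
        warnings.warn("sequence shorter than k; no positions assigned")
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0), np.empty(0)
    if strand == "-":
        ids_rc = sequence_kmer_ids(revcomp(sequence), k)
        # window w on revcomp covers forward positions [L-w-k, L-w); its
        # central base sits at forward coordinate L-1-(w+c).
        pos = (L - 1 - c) - np.arange(len(ids_rc))
        order = np.argsort(pos)
        positions, ids = pos[order], ids_rc[order]
    else:
        ids = sequence_kmer_ids(sequence, k)
        positions = np.arange(len(ids)) + c
        ids = ids
    means = model.means[ids]
    sds = model.sds[ids]
    if model.reverse_signal:
        positions, ids, means, sds = (positions[::-1], ids[::-1],
                                      means[::-1], sds[::-1])
    return positions, ids, means, sds


def substitution_profile(model: PoreModel) -> np.ndarray:
    """(4, k) matrix: mean |current change| from substituting base b at position p.

    Entry (b, p) averages |mean(kmer) - mean(kmer with position p set to b)|
    over all 4^k k-mers; self-substitutions contribute zero and are included.
    """
    k = model.k
    prof = np.zeros((4, k))
    idx = np.arange(4 ** k)
    for p in range(k):
        weight = 4 ** (k - 1 - p)
        digit = (idx // weight) % 4
        for b in range(4):
            sub = idx + (b - digit) * weight
            prof[b, p] = np.mean(np.abs(model.means - model.means[sub]))
    return prof


def central_base(model: PoreModel) -> int:
    """Position with the highest average per-position change in the
    substitution profile; ties break toward the smaller index."""
    prof = substitution_profile(model)
    col = prof.mean(axis=0)
    if np.allclose(col, 0):
        warnings.warn("degenerate model: no base influences current")
    return int(np.argmax(col))


def reduce_model(model: PoreModel, m: int, anchor: int | None = None) -> PoreModel:
    """Collapse a k-mer model to an m-mer model over a kept window.

    The kept window is the m contiguous positions starting at ``anchor``
    (default: a window containing central_pos).  The reduced mean of each
    m-mer is the arithmetic mean of all k-mers spelling it on the kept
    positions; sds combine as root-mean-square.
    """
    k = model.k
    if not 1 <= m <= k:
        raise FormatError(f"cannot reduce {k}-mer model to m={m}")
    if anchor is None:
        anchor = min(max(model.central_pos - (m - 1) // 2, 0), k - m)
    if not (0 <= anchor and anchor + m <= k):
        raise FormatError(f"window [{anchor},{anchor + m}) outside k-mer of length {k}")
    idx = np.arange(4 ** k)
    key = np.zeros(4 ** k, dtype=np.int64)
    for j in range(m):
        key = key * 4 + (idx // 4 ** (k - 1 - (anchor + j))) % 4
    counts = np.bincount(key, minlength=4 ** m)
    means = np.bincount(key, weights=model.means, minlength=4 ** m) / counts
    sds = np.sqrt(np.bincount(key, weights=model.sds ** 2, minlength=4 ** m) / counts)
    new_central = min(max(model.central_pos - anchor, 0), m - 1)
    return PoreModel(k=m, means=means, sds=sds, central_pos=new_central,
                     pa_mean=model.pa_mean, pa_sd=model.pa_sd,
                     name=f"{model.name}.reduce{m}", reverse_signal=model.reverse_signal)
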