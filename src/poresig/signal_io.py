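"""Raw nanopore signal I/O: the SLOW5 ASCII dialect plus pA calibration.

SLOW5 ASCII is the canonical plain-text raw-signal container here; POD5,
FAST5 and BLOW5 adapters are declared interface stubs behind a capability
flag.  Calibration follows the standard nanopore convention

    pA(s) = (s + offset) * range / digitisation
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import FormatError, NotFoundError

logger = logging.getLogger(__name__)

SLOW5_COLUMNS = ["read_id", "read_group", "digitisation", "offset", "range",
                 "sampling_rate", "len_raw_signal", "raw_signal"]

#: raw formats understood by :func:`open_signal`; only slow5 is implemented.
CAPABILITIES = {"slow5": True, "blow5": False, "pod5": False, "fast5": False}


@dataclass
class RawRead:
    """One raw read: integer DAC samples plus calibration constants."""

    read_id: str
    samples: np.ndarray
    digitisation: float = 8192.0
    offset: float = 0.0
    range: float = 1500.0
    sampling_rate: float = 4000.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.size == 0:
            raise FormatError(f"read {self.read_id}: empty signal")

    def calibrated(self) -> np.ndarray:
        """Signal in picoamps."""
        return (self.samples.astype(float) + self.offset) * self.range / self.digitisation


def calibrate(samples, digitisation: float, offset: float, rng: float) -> np.ndarray:
    return (np.asarray(samples, dtype=float) + offset) * rng / digitisation


def write_slow5(reads, path) -> None:
    with open(path, "w") as fh:
        fh.write("#slow5_version\t2.0\n")
        fh.write("#num_read_groups\t1\n")
        fh.write("@asic_id\tsynthetic\n")
        fh.write("#char*\tuint32_t\tdouble\tdouble\tdouble\tdouble\tuint64_t\tint16_t*\n")
        fh.write("#" + "\t".join(SLOW5_COLUMNS) + "\n")
        for r in reads:
            sig = ",".join(str(int(s)) for s in np.asarray(r.samples))
            fh.write(f"{r.read_id}\t0\t{r.digitisation!r}\t{r.offset!r}\t"
                     f"{r.range!r}\t{r.sampling_rate!r}\t{len(r.samples)}\t{sig}\n")


def read_slow5(path) -> Iterator[RawRead]:
    """Yield reads from a SLOW5 ASCII file in file order.

    A read whose declared len_raw_signal disagrees with the number of
    signal values is skipped with a log entry; header problems raise
    FormatError.
    """
    with open(path) as fh:
        cols = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            if line.startswith("#"):
                fields = line[1:].split("\t")
                if fields[0] == "read_id":
                    cols = fields
                continue
            if cols is None:
                raise FormatError(f"{path}: missing '#read_id ...' column header")
            missing = [c for c in SLOW5_COLUMNS if c not in cols]
            if missing:
                raise FormatError(f"{path}: missing mandatory column(s) {missing}")
            rec = dict(zip(cols, line.split("\t")))
            try:
                declared = int(rec["len_raw_signal"])
                samples = np.array([int(v) for v in rec["raw_signal"].split(",") if v != ""],
                                   dtype=np.int32)
            except (KeyError, ValueError) as e:
                logger.error("%s: unparsable record (%s); read skipped", path, e)
                continue
            if len(samples) != declared:
                logger.error("%s: read %s declares %d samples but has %d; skipped",
                             path, rec.get("read_id"), declared, len(samples))
                continue
            yield RawRead(
                read_id=rec["read_id"],
                samples=samples,
                digitisation=float(rec["digitisation"]),
                offset=float(rec["offset"]),
                range=float(rec["range"]),
                sampling_rate=float(rec["sampling_rate"]),
            )


def get_read(path, read_id: str) -> RawRead:
    """Random access by read name; first occurrence wins on duplicates."""
    found = None
    for r in read_slow5(path):
        if r.read_id == read_id:
            if found is None:
                found = r
            else:
                logger.warning("%s: duplicate read id %s; first occurrence returned",
                               path, read_id)
                break
    if found is None:
        raise NotFoundError(f"read id {read_id!r} not found in {path}")
    return found


class SignalIndex:
    """In-memory id -> RawRead map over one or more signal files."""

    def __init__(self, *paths):
        self._reads = {}
        for p in paths:
            for r in read_slow5(p):
                self._reads.setdefault(r.read_id, r)

    def __getitem__(self, read_id: str) -> RawRead:
        try:
            return self._reads[read_id]
        except KeyError:
            raise NotFoundError(f"read id {read_id!r} not found") from None

    def __contains__(self, read_id):
        return read_id in self._reads

    def __len__(self):
        return len(self._reads)


def open_signal(path) -> Iterator[RawRead]:
    """Dispatch on file extension; non-SLOW5 formats are declared adapters."""
    p = str(path)
    for ext, ok in CAPABILITIES.items():
        if p.endswith("." + ext):
            if not ok:
                raise NotImplementedError(
                    f"{ext} input is a declared adapter interface; only SLOW5 ASCII "
                    "is implemented")
            return read_slow5(path)
    return read_slow5(path)
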