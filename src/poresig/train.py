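"""Iterative k-mer pore-model training.

Each iteration aligns reads (skip cost 4, keep_best skip masking, a single
normalization iteration) until every k-mer has been observed a minimum
number of times (500 by default), keeps only positions whose distance to
the move projection is small (mvcmp.dist <= 1 by default), then records the
median and standard deviation of the pooled per-position current means as
the next model.  De novo initialization treats the ref-moves themselves as
a (noisy) signal alignment, starting at a short k-mer length to average out
their one-to-two-base errors and expanding the k-mer length every few
iterations until the target length is reached.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .bcdtw import AlignParams, ReadAlignmentMeta, align_read, project_moves, splice_indels
from .errors import PoresigError
from .normalize import mom_normalize
from .pore_model import PoreModel, save_model, sequence_kmer_ids
from .stats import attach_mvcmp

logger = logging.getLogger(__name__)


def proportional_central(k: int, target_k: int, target_central: int) -> int:
    """Central position for an intermediate k, keeping the relative anchor."""
    if target_k <= 1 or k <= 1:
        return 0
    return int(round(target_central * (k - 1) / (target_k - 1)))


@dataclass(frozen=True)
class TrainSchedule:
    """Training cadence and filters (production defaults from the method)."""

    target_k: int = 5
    init_k: int = 1
    target_central: int | None = None
    iters_per_k: int = 2
    min_kmer_count: int = 500
    dist_max: float = 1.0
    skip_cost: float = 4.0
    mask_skips: str = "keep_best"
    norm_iterations: int = 1
    max_iterations: int = 6
    bandwidth: int = 25
    del_max: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.init_k > self.target_k:
            raise PoresigError("init_k must be <= target_k")
        if self.min_kmer_count < 1:
            raise PoresigError("min_kmer_count must be >= 1")

    @property
    def central(self) -> int:
        if self.target_central is not None:
            return self.target_central
        return (self.target_k - 1) // 2

    def align_params(self) -> AlignParams:
        return AlignParams(bandwidth=self.bandwidth, skip_cost=self.skip_cost,
                           del_max=self.del_max, mask_skips=self.mask_skips,
                           norm_iterations=self.norm_iterations)

    def k_sequence(self) -> list:
        ks = []
        k = self.init_k
        for it in range(self.max_iterations):
            if it > 0 and it % self.iters_per_k == 0 and k < self.target_k:
                k = min(k + 2, self.target_k)
            ks.append(k)
        return ks


def _pooled_model(values_by_kmer, model_in: PoreModel, min_count: int,
                  name: str) -> tuple[PoreModel, dict]:
    """Median/sd pooling into a new normalized model; under-covered k-mers
    inherit the previous model."""
    n = model_in.n_kmers
    means = model_in.means.copy()
    sds = model_in.sds.copy()
    counts = np.zeros(n, dtype=np.int64)
    for kid, vals in values_by_kmer.items():
        counts[kid] = len(vals)
        if len(vals) >= min_count:
            v = np.asarray(vals)
            means[kid] = float(np.median(v))
            s = float(np.std(v))
            sds[kid] = s if s > 0 else sds[kid]
    under = int(np.sum(counts < min_count))
    if under:
        level = logging.WARNING if under > 0.1 * n else logging.INFO
        logger.log(level, "%d/%d k-mers under the minimum count %d; inheriting "
                   "previous values", under, n, min_count)
    if counts.sum() == 0:
        raise PoresigError("no k-mer coverage at all; cannot train")
    out = PoreModel(k=model_in.k, means=means, sds=sds,
                    central_pos=model_in.central_pos, pa_mean=model_in.pa_mean,
                    pa_sd=model_in.pa_sd, name=name,
                    reverse_signal=model_in.reverse_signal).normalized()
    report = {"k": model_in.k, "counts": counts, "under_covered": under}
    return out, report


def _read_order(n: int, seed: int, iteration: int) -> np.ndarray:
    rng = np.random.default_rng((seed, iteration))
    return rng.permutation(n)


def train_iteration(reads, metas, ref_seqs, model_in: PoreModel,
                    schedule: TrainSchedule, iteration: int = 0):
    """One training pass: align, filter by mvcmp.dist, pool, re-estimate.

    Reads are streamed in a seeded random order until every k-mer reaches
    min_kmer_count or the reads are exhausted.
    """
    params = schedule.align_params()
    values: dict[int, list] = {}
    counts = np.zeros(model_in.n_kmers, dtype=np.int64)
    n_fail = 0
    for ri in _read_order(len(reads), schedule.seed, iteration):
        raw, meta = reads[ri], metas[ri]
        ref_seq = ref_seqs[meta.ref_name]
        try:
            aln = align_read(raw, meta, ref_seq, model_in, params)
        except PoresigError as e:
            n_fail += 1
            logger.debug("training alignment failed for %s: %s", meta.read_id, e)
            continue
        rm, _, _ = splice_indels(
            project_moves(meta.moves, meta.stride, meta.signal_offset, meta.cigar,
                          meta.ref_start, meta.strand, model_in.reverse_signal),
            schedule.del_max)
        attach_mvcmp(aln, rm)
        dist = aln.extra["mvcmp.dist"]
        ok = (np.isfinite(aln.current) & ~aln.masked & np.isfinite(dist)
              & (dist <= schedule.dist_max))
        if aln.kmer_ids is None:
            continue
        for kid, cur in zip(aln.kmer_ids[ok], aln.current[ok]):
            values.setdefault(int(kid), []).append(float(cur))
            counts[int(kid)] += 1
        if counts.min() >= schedule.min_kmer_count:
            break
    if n_fail:
        logger.info("iteration %d: %d reads failed to align", iteration, n_fail)
    model, report = _pooled_model(values, model_in, schedule.min_kmer_count,
                                  name=f"{model_in.name}.it{iteration}")
    report["n_failed"] = n_fail
    return model, report


def init_from_moves(reads, metas, ref_seqs, init_k: int, central_pos: int = 0,
                    schedule: TrainSchedule | None = None,
                    reverse_signal: bool = False) -> PoreModel:
    """De novo draft model from the move projections alone.

    Per-position currents are taken from the ref-moves sample intervals
    (normalized per read to zero mean / unit sd over position means) and
    pooled by init_k-mer; median and sd define the draft.
    """
    schedule = schedule or TrainSchedule(target_k=init_k, init_k=init_k,
                                         min_kmer_count=1)
    if init_k == schedule.target_k and init_k > 1:
        logger.warning("init_k equals the target k; move errors will not be "
                       "averaged out")
    values: dict[int, list] = {}
    pa_means = []
    pa_sds = []
    for raw, meta in zip(reads, metas):
        ref_seq = ref_seqs[meta.ref_name]
        rm, _, _ = splice_indels(
            project_moves(meta.moves, meta.stride, meta.signal_offset, meta.cigar,
                          meta.ref_start, meta.strand, reverse_signal),
            schedule.del_max)
        cal = raw.calibrated()
        obs = np.full(len(rm), np.nan)
        for j in range(len(rm)):
            lo, hi = int(rm.lo[j]), int(rm.hi[j])
            if hi > lo and hi <= len(cal):
                obs[j] = float(np.mean(cal[lo:hi]))
        ok = np.isfinite(obs)
        if ok.sum() < 2:
            continue
        mu = float(np.mean(obs[ok]))
        sd = float(np.std(obs[ok]))
        if sd == 0:
            continue
        pa_means.append(mu)
        pa_sds.append(sd)
        norm_obs = (obs - mu) / sd
        if rm.strand != "+":
            # reverse-strand reads are skipped during de novo init; forward
            # coverage suffices and keeps the window arithmetic simple
            logger.debug("init_from_moves: skipping reverse read %s", meta.read_id)
            continue
        ids = sequence_kmer_ids(ref_seq, init_k)
        for j in range(len(rm)):
            if not ok[j]:
                continue
            w = int(rm.positions[j]) - central_pos
            if 0 <= w < len(ids):
                values.setdefault(int(ids[w]), []).append(float(norm_obs[j]))
    if not values:
        raise PoresigError("no usable move projections; cannot initialize")
    n = 4 ** init_k
    means = np.zeros(n)
    sds = np.ones(n)
    counts = np.zeros(n, dtype=np.int64)
    for kid, vals in values.items():
        v = np.asarray(vals)
        counts[kid] = len(v)
        means[kid] = float(np.median(v))
        s = float(np.std(v))
        sds[kid] = s if s > 0 else 1.0
    missing = int(np.sum(counts == 0))
    if missing:
        logger.warning("%d/%d init k-mers unobserved; left at zero", missing, n)
    model = PoreModel(k=init_k, means=means, sds=sds, central_pos=central_pos,
                      pa_mean=float(np.mean(pa_means)),
                      pa_sd=float(np.mean(pa_sds)),
                      name="denovo", reverse_signal=reverse_signal)
    return model.normalized()


def expand_kmer(model: PoreModel, k_new: int, central_new: int | None = None) -> PoreModel:
    """Lift an m-mer model to k_new-mers: every k_new-mer inherits the
    mean/sd of its contained m-mer, windows placed so the central
    positions coincide (expand then reduce is the identity)."""
    m = model.k
    if k_new <= m:
        raise PoresigError(f"k_new={k_new} must exceed the current k={m}")
    if central_new is None:
        central_new = proportional_central(k_new, k_new, (k_new - 1) // 2)
    offset = central_new - model.central_pos
    if offset < 0 or offset + m > k_new:
        raise PoresigError(
            f"cannot place a {m}-mer window with central {model.central_pos} "
            f"inside a {k_new}-mer with central {central_new}")
    idx = np.arange(4 ** k_new)
    key = np.zeros(4 ** k_new, dtype=np.int64)
    for j in range(m):
        key = key * 4 + (idx // 4 ** (k_new - 1 - (offset + j))) % 4
    return PoreModel(k=k_new, means=model.means[key].copy(), sds=model.sds[key].copy(),
                     central_pos=central_new, pa_mean=model.pa_mean,
                     pa_sd=model.pa_sd, name=f"{model.name}.x{k_new}",
                     reverse_signal=model.reverse_signal)


def train(reads, metas, ref_seqs, schedule: TrainSchedule,
          init_model: PoreModel | None = None, out_dir=None,
          reverse_signal: bool = False):
    """Full training loop: init (moves or draft), iterate, expand on cadence.

    Returns (models, reports): one trained model and report per iteration;
    deterministic given the schedule seed.
    """
    ks = schedule.k_sequence()
    if init_model is not None:
        model = init_model
        if model.k != ks[0]:
            raise PoresigError(f"draft model is a {model.k}-mer model but the "
                               f"schedule starts at k={ks[0]}")
    else:
        model = init_from_moves(
            reads, metas, ref_seqs, schedule.init_k,
            central_pos=proportional_central(ks[0], schedule.target_k, schedule.central),
            schedule=schedule, reverse_signal=reverse_signal)
    models = []
    reports = []
    prev = None
    for it, k in enumerate(ks):
        if k > model.k:
            model = expand_kmer(
                model, k,
                central_new=proportional_central(k, schedule.target_k, schedule.central))
        model, report = train_iteration(reads, metas, ref_seqs, model, schedule,
                                        iteration=it)
        if prev is not None and prev.k == model.k:
            report["corr_prev"] = float(np.corrcoef(prev.means, model.means)[0, 1])
        else:
            report["corr_prev"] = np.nan
        prev = model
        models.append(model)
        reports.append(report)
        logger.info("iteration %d: k=%d, %d under-covered, corr_prev=%.4f",
                    it, model.k, report["under_covered"], report["corr_prev"])
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            save_model(model, os.path.join(out_dir, f"model.it{it}.k{model.k}.tsv"))
    if out_dir is not None:
        with open(os.path.join(out_dir, "report.tsv"), "w") as fh:
            fh.write("#iteration\tk\tunder_covered\tn_failed\tcorr_prev\n")
            for it, rep in enumerate(reports):
                fh.write(f"{it}\t{rep['k']}\t{rep['under_covered']}\t"
                         f"{rep.get('n_failed', 0)}\t{rep['corr_prev']:.6f}\n")
    return models, reports
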