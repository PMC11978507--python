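"""Move projection, splicing, band placement and banded DTW."""

import numpy as np
import pytest

import poresig as ps
from poresig.bcdtw import (Band, clamp_band_endpoints, find_skip_groups,
                           full_band, parse_cigar)
from poresig.errors import AlignmentError
from poresig.events import Event
from poresig.simulate import SimParams
from conftest import noiseless_params


def dtw_oracle(cost: np.ndarray, skip: float) -> float:
    """Independent unbanded brute-force implementation of the recurrence
    D[i,j] = cost(i,j) + min(D[i-1,j-1], D[i-1,j], skip*D[i,j-1])."""
    N, M = cost.shape
    D = np.full((N, M), np.inf)
    for i in range(N):
        for j in range(M):
            if i == 0 and j == 0:
                best = 0.0
            else:
                cands = []
                if i > 0 and j > 0:
                    cands.append(D[i - 1, j - 1])
                if i > 0:
                    cands.append(D[i - 1, j])
                if j > 0:
                    cands.append(skip * D[i, j - 1])
                best = min(cands)
            D[i, j] = cost[i, j] + best
    return float(D[N - 1, M - 1])


# ---------------------------------------------------------------------------
# project_moves

def test_project_moves_direct_mapping():
    rm = ps.project_moves(np.ones(4), stride=5, signal_offset=0, cigar="4M",
                          ref_start=7, strand="+")
    assert list(rm.positions) == [7, 8, 9, 10]
    assert list(rm.lo) == [0, 5, 10, 15]
    assert list(rm.hi) == [5, 10, 15, 20]


def test_project_moves_deletion_interpolated():
    rm = ps.project_moves(np.ones(4), 5, 0, "2M1D2M", 0, "+")
    assert list(rm.positions) == [0, 1, 2, 3, 4]
    # middle (deleted) position interpolated between flanks, monotone
    assert rm.lo[2] == rm.hi[2]
    assert rm.hi[1] <= rm.lo[2] <= rm.lo[3]
    assert all(rm.lo[i] <= rm.lo[i + 1] for i in range(4))


def test_project_moves_insertion_merged():
    rm = ps.project_moves(np.ones(4), 5, 0, "2M1I1M", 0, "+")
    assert list(rm.positions) == [0, 1, 2]
    # inserted base's 5 samples appended to the preceding match position
    assert list(rm.hi) == [5, 15, 20]
    assert rm.insertions == [(1, 10, 15, 1)]


def test_project_moves_mismatched_cigar():
    with pytest.raises(AlignmentError):
        ps.project_moves(np.ones(4), 5, 0, "5M", 0, "+")


def test_project_moves_reverse_strand_descending():
    rm = ps.project_moves(np.ones(4), 5, 0, "4M", 10, "-")
    assert list(rm.positions) == [13, 12, 11, 10]  # signal order, forward coords
    assert list(rm.lo) == [0, 5, 10, 15]


def test_project_moves_signal_offset():
    rm = ps.project_moves(np.ones(3), 5, 100, "3M", 0, "+")
    assert list(rm.lo) == [100, 105, 110]


# ---------------------------------------------------------------------------
# splice_indels

def test_splice_noop_without_indels():
    rm = ps.project_moves(np.ones(5), 5, 0, "5M", 0, "+")
    out, masked, excised = ps.splice_indels(rm, del_max=10)
    assert masked == [] and excised == []
    np.testing.assert_array_equal(out.positions, rm.positions)
    np.testing.assert_array_equal(out.hi, rm.hi)


def test_splice_large_deletion_excised():
    rm = ps.project_moves(np.ones(6), 5, 0, "3M15D3M", 0, "+")
    out, masked, excised = ps.splice_indels(rm, del_max=10)
    assert excised == [(3, 18)]
    assert masked == []
    assert out.ref_blocks() == [(0, 3), (18, 21)]


def test_splice_large_insertion_masked():
    rm = ps.project_moves(np.ones(21), 5, 0, "3M15I3M", 0, "+")
    out, masked, excised = ps.splice_indels(rm, del_max=10)
    assert masked == [(15, 90)]  # 15 bases * 5 samples
    assert excised == []
    assert out.ref_blocks() == [(0, 6)]
    assert out.hi[2] == 15  # absorbing interval restored


def test_splice_small_indels_left_for_dtw():
    rm = ps.project_moves(np.ones(10), 5, 0, "4M2D2M4I", 0, "+")
    out, masked, excised = ps.splice_indels(rm, del_max=10)
    assert masked == [] and excised == []
    assert len(out) == 8


# ---------------------------------------------------------------------------
# place_band

def _unit_events(n):
    return [Event(i, 1, float(i), 0.0) for i in range(n)]


def test_place_band_diagonal():
    n = 40
    rm = ps.RefMoves(np.arange(n), np.arange(n), np.arange(n) + 1, 1, "+")
    band = ps.place_band(rm, _unit_events(n), width=10)
    mid = n // 2
    assert band.bottom[mid] - band.top[mid] == 10
    assert band.top[mid] <= mid < band.bottom[mid]


def test_place_band_translation_equivariance():
    n = 40
    ev = _unit_events(n + 5)
    rm1 = ps.RefMoves(np.arange(n), np.arange(n), np.arange(n) + 1, 1, "+")
    rm2 = ps.RefMoves(np.arange(n), np.arange(n) + 2, np.arange(n) + 3, 1, "+")
    b1 = ps.place_band(rm1, ev, width=10)
    b2 = ps.place_band(rm2, ev, width=10)
    mid = slice(10, 30)
    np.testing.assert_array_equal(b2.top[mid], b1.top[mid] + 2)


def test_place_band_monotonicity_repair():
    # centers go backwards (5 then 3); intervals must not move backwards
    rm = ps.RefMoves(np.array([0, 1]), np.array([5, 3]), np.array([6, 4]), 1, "+")
    band = ps.place_band(rm, _unit_events(10), width=4)
    assert band.top[1] >= band.top[0]
    assert band.bottom[1] >= band.bottom[0]


def test_place_band_requires_events():
    rm = ps.RefMoves(np.array([0]), np.array([0]), np.array([1]), 1, "+")
    with pytest.raises(AlignmentError):
        ps.place_band(rm, [], width=4)


# ---------------------------------------------------------------------------
# banded_dtw

def test_dtw_perfect_diagonal():
    path = ps.banded_dtw([0.0, 1.0], [(0.0), (1.0)], full_band(2, 2), 2.0)
    assert path.cost == 0.0
    assert [tuple(p) for p in path.pairs] == [(0, 0), (1, 1)]
    assert path.moves == ["start", "match"]


def test_dtw_single_event_skip():
    path = ps.banded_dtw([0.0], [0.0, 0.0], full_band(1, 2), 2.0)
    assert [tuple(p) for p in path.pairs] == [(0, 0), (0, 1)]
    assert path.moves == ["start", "skip"]
    assert path.cost == 0.0  # skip multiplies a zero accumulate


def test_dtw_band_disconnect_raises():
    band = Band(np.array([0, 3]), np.array([1, 4]), 1)
    with pytest.raises(AlignmentError):
        ps.banded_dtw([0.0, 0.0, 0.0, 0.0], [0.0, 0.0], band, 2.0)


@pytest.mark.parametrize("trial", range(20))
def test_dtw_full_band_matches_oracle(trial):
    rng = np.random.default_rng(trial)
    N, M = rng.integers(2, 16, size=2)
    e = rng.normal(size=N)
    m = rng.normal(size=M)
    skip = rng.choice([1.0, 2.0, 4.0])
    cost = np.abs(e[:, None] - m[None, :])
    path = ps.banded_dtw(e, m, full_band(N, M), skip)
    assert path.cost == pytest.approx(dtw_oracle(cost, skip), abs=1e-9)
    # path validity: monotone steps of one, complete
    pairs = path.pairs
    assert tuple(pairs[0]) == (0, 0)
    assert tuple(pairs[-1]) == (N - 1, M - 1)
    d = np.diff(pairs, axis=0)
    assert np.all((d >= 0) & (d <= 1)) and np.all(d.sum(axis=1) >= 1)


def test_dtw_band_shrunk_around_truth_is_stable():
    rng = np.random.default_rng(99)
    N = M = 18
    e = rng.normal(size=N)
    m = rng.normal(size=M)
    path = ps.banded_dtw(e, m, full_band(N, M), 2.0)
    # build a tight band containing the optimal path
    top = np.full(M, N, dtype=np.int64)
    bottom = np.zeros(M, dtype=np.int64)
    for i, j in path.pairs:
        top[j] = min(top[j], i)
        bottom[j] = max(bottom[j], i + 1)
    top = np.minimum.accumulate(top[::-1])[::-1]
    bottom = np.maximum.accumulate(bottom)
    banded = ps.banded_dtw(e, m, Band(top, bottom, N), 2.0)
    assert banded.cost == pytest.approx(path.cost, abs=1e-9)


# ---------------------------------------------------------------------------
# mask_skips

def _skip_path():
    # one event aligned to refs 0..2 (skip run), then a match
    pairs = np.array([(0, 0), (0, 1), (0, 2), (1, 3)])
    moves = ["start", "skip", "skip", "match"]
    return ps.DtwPath(pairs, moves, 0.0, 2, 4)


def test_mask_skips_none_keeps_groups():
    groups = ps.mask_skips(_skip_path(), "none", np.zeros(4), np.zeros(2))
    assert len(groups) == 1
    g = groups[0]
    assert g.members == [0, 1, 2] and g.kept == g.carrier == 0


def test_mask_skips_keep_best_nearest_expected():
    expected = np.array([0.1, 1.0, 2.0, 5.0])
    event_means = np.array([0.9, 5.0])
    groups = ps.mask_skips(_skip_path(), "keep_best", expected, event_means)
    assert groups[0].kept == 1  # expected 1.0 closest to observed 0.9


def test_mask_skips_all():
    groups = ps.mask_skips(_skip_path(), "all", np.zeros(4), np.zeros(2))
    assert groups[0].kept is None


def test_no_skips_unchanged():
    pairs = np.array([(0, 0), (1, 1)])
    path = ps.DtwPath(pairs, ["start", "match"], 0.0, 2, 2)
    for mode in ("none", "all", "keep_best"):
        assert ps.mask_skips(path, mode, np.zeros(2), np.zeros(2)) == []


# ---------------------------------------------------------------------------
# align_read end-to-end

def test_align_noiseless_recovers_truth(model5, ref500, noiseless_aligned):
    sim, aln = noiseless_aligned
    pos = aln.positions
    exact = 0
    for x, r in enumerate(pos):
        if aln.sample_start[x] == sim.truth_start[r] and \
                aln.sample_end[x] == sim.truth_end[r]:
            exact += 1
    # all interior positions exact (the outer edges lack k-mer context)
    assert exact >= aln.n_positions - 2
    errs = ps.simulate.sample_position_errors(sim, aln, len(ref500))
    assert np.median(errs) == 0


def test_align_noisy_median_error_small(model5, ref2k):
    params = SimParams(noise_sd=0.3, skip_prob=0.02, move_jitter=1)
    sim = ps.simulate_read(ref2k, model5, params, seed=33, read_id="n1")
    aln = ps.align_read(sim.raw, sim.meta(), ref2k, model5, ps.AlignParams())
    errs = ps.simulate.sample_position_errors(sim, aln, len(ref2k))
    assert np.median(errs) <= 1


def test_align_splice_invariance(model5, ref500):
    """Alignments of paired reads differing only by one >del_max insertion
    are identical outside the spliced region."""
    base = noiseless_params()
    sim_plain = ps.simulate_read(ref500, model5, base, seed=77, read_id="p")
    ins_at = 250
    sim_ins = ps.simulate_read(ref500, model5,
                               SimParams(**{**base.__dict__,
                                            "indel_spec": ((ins_at, "I", 15),)}),
                               seed=77, read_id="i")
    a = ps.align_read(sim_plain.raw, sim_plain.meta(), ref500, model5,
                      ps.AlignParams())
    b = ps.align_read(sim_ins.raw, sim_ins.meta(), ref500, model5,
                      ps.AlignParams())
    pos_a, pos_b = a.positions, b.positions
    la = {int(p): int(l) for p, l in zip(pos_a, a.lengths)}
    lb = {int(p): int(l) for p, l in zip(pos_b, b.lengths)}
    window = set(range(ins_at - model5.k, ins_at + model5.k + 1))
    edges = {int(pos_a[0]), int(pos_a[-1]), int(pos_b[0]), int(pos_b[-1])}
    common = (set(la) & set(lb)) - window - edges  # edges absorb trimmed flanks
    mismatch = [p for p in common if la[p] != lb[p]]
    assert len(mismatch) == 0


def test_align_missing_moves_fails(model5, ref500):
    sim = ps.simulate_read(ref500, model5, noiseless_params(), seed=5)
    meta = sim.meta()
    meta.moves = np.array([])
    with pytest.raises(AlignmentError):
        ps.align_read(sim.raw, meta, ref500, model5, ps.AlignParams())


def test_align_conservation_fuzz(model5, ref500):
    """Every raw sample within the consumed span is assigned to exactly one
    reference position or masked range, across noise settings."""
    for seed in range(4):
        params = SimParams(noise_sd=0.4, skip_prob=0.05, move_jitter=2)
        sim = ps.simulate_read(ref500, model5, params, seed=seed)
        aln = ps.align_read(sim.raw, sim.meta(), ref500, model5, ps.AlignParams())
        aln.validate()  # raises on any conservation violation
        tags = ps.encode_tags(aln)
        assert np.abs(tags["us"]).sum() == aln.signal_hi - aln.signal_lo


def test_parse_cigar_roundtrip():
    ops = parse_cigar("3M1I2D10M2S")
    assert ops == [("M", 3), ("I", 1), ("D", 2), ("M", 10), ("S", 2)]
    with pytest.raises(AlignmentError):
        parse_cigar("3M1Q")
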