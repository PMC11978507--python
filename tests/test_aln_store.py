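"""Layer computation, BAM tag codec and text export."""

import numpy as np
import pytest

import poresig as ps
from poresig.aln_store import (SENTINEL, Alignment, _decode_us, _emit_chain,
                               _dequantize, _quantize, compute_layers,
                               read_eventalign, write_eventalign)
from poresig.bcdtw import DtwPath, SkipGroup
from poresig.errors import IntegrityError, PoresigError
from poresig.events import Event
from poresig.normalize import NormParams
from poresig.simulate import SimParams
from conftest import noiseless_params


def _mini_alignment(currents, lengths, masked_ranges=(), blocks=None,
                    masked=None, lo=0):
    """Positions tiling the signal in order; currents NaN => null."""
    currents = np.asarray(currents, dtype=float)
    lengths = np.asarray(lengths, dtype=np.int64)
    start = np.zeros(len(lengths), dtype=np.int64)
    cursor = lo
    pending = sorted(masked_ranges)
    pi = 0
    for j in range(len(lengths)):
        while pi < len(pending) and pending[pi][0] == cursor:
            cursor = pending[pi][1]
            pi += 1
        start[j] = cursor
        cursor += lengths[j]
    hi = cursor
    while pi < len(pending):
        hi = pending[pi][1]
        pi += 1
    n = len(lengths)
    return Alignment(
        read_id="t", ref_name="ref", strand="+",
        ref_blocks=blocks or [(0, n)],
        sample_start=start, sample_end=start + lengths,
        current=currents, current_sd=np.abs(currents) * 0.1,
        masked=np.zeros(n, dtype=bool) if masked is None else np.asarray(masked),
        norm=NormParams(0.1, -2.0), signal_lo=lo, signal_hi=hi,
        masked_ranges=list(masked_ranges))


# ---------------------------------------------------------------------------
# compute_layers

def test_compute_layers_two_point_stats():
    events = [Event(0, 2, 2.0, 1.0)]
    path = DtwPath(np.array([(0, 0)]), ["start"], 0.0, 1, 1)
    aln = compute_layers(path, [], np.array([1.0, 3.0]), events, np.array([0]),
                         signal_span=(0, 2))
    assert aln.lengths[0] == 2
    assert aln.current[0] == pytest.approx(2.0)
    assert aln.current_sd[0] == pytest.approx(1.0)  # population sd


def test_compute_layers_skip_group_shares_values():
    events = [Event(0, 4, 0.5, 0.0), Event(4, 2, 1.0, 0.0)]
    pairs = np.array([(0, 0), (0, 1), (1, 2)])
    path = DtwPath(pairs, ["start", "skip", "match"], 0.0, 2, 3)
    groups = [SkipGroup([0, 1], 0, 0, 0)]
    samples = np.array([0.5, 0.5, 0.5, 0.5, 1.0, 1.0])
    aln = compute_layers(path, groups, samples, events, np.arange(3),
                         with_event_counts=True, signal_span=(0, 6))
    assert aln.current[0] == aln.current[1] == pytest.approx(0.5)
    assert aln.lengths[0] == 4 and aln.lengths[1] == 0
    np.testing.assert_allclose(aln.event_count[:2], [0.5, 0.5])
    assert aln.event_count[2] == 1.0


def test_compute_layers_stay_counts():
    events = [Event(0, 2, 1.0, 0.0), Event(2, 3, 1.1, 0.0), Event(5, 1, 0.9, 0.0)]
    pairs = np.array([(0, 0), (1, 0), (2, 0)])
    path = DtwPath(pairs, ["start", "stay", "stay"], 0.0, 3, 1)
    samples = np.array([1.0, 1.0, 1.1, 1.1, 1.1, 0.9])
    aln = compute_layers(path, [], samples, events, np.array([0]),
                         with_event_counts=True, signal_span=(0, 6))
    assert aln.event_count[0] == 3
    assert aln.lengths[0] == 6


# ---------------------------------------------------------------------------
# derived layers

def test_derived_layer_model_diff_and_offsets(model5):
    aln = _mini_alignment([0.1, 0.2, 0.3], [2, 2, 2])
    aln.kmer_ids = np.array([0, 1, 2])
    diff = ps.derived_layer(aln, "dtw.model_diff", model=model5)
    np.testing.assert_allclose(
        diff, np.abs(aln.current - model5.means[[0, 1, 2]]))
    # read equal to model exactly -> all zeros
    aln.current = model5.means[[0, 1, 2]].copy()
    np.testing.assert_allclose(
        ps.derived_layer(aln, "dtw.model_diff", model=model5), 0.0)
    # offset 0 is the identity
    np.testing.assert_allclose(ps.derived_layer(aln, "dtw.dwell", 0),
                               aln.lengths.astype(float))
    # negative offset shifts with leading nulls
    shifted = ps.derived_layer(aln, "dtw.dwell", offset=-2)
    assert np.isnan(shifted[0]) and np.isnan(shifted[1])
    assert shifted[2] == aln.lengths[0]


def test_derived_layer_unknown_name():
    aln = _mini_alignment([0.1], [1])
    with pytest.raises(PoresigError, match="dtw.current"):
        ps.derived_layer(aln, "nope")


# ---------------------------------------------------------------------------
# tag codec

def test_us_encoding_masked_then_positions():
    aln = _mini_alignment([np.nan, 0.5, 0.5, 0.2], [0, 5, 0, 3],
                          masked_ranges=[(0, 7)],
                          masked=[True, False, False, False])
    # force the skip layout: position 2 shares position 1's samples
    aln.sample_start[0] = aln.sample_end[0] = 7
    aln.sample_start[2] = aln.sample_end[2] = 12
    tags = ps.encode_tags(aln)
    assert list(tags["us"]) == [-7, 0, 5, 0, 3]
    assert np.abs(tags["us"]).sum() == 15


def test_quantization_endpoints():
    q, _ = _quantize(np.array([0.0, -5.0, 5.0, np.nan]))
    assert list(q) == [32767, 0, 65534, 65535]
    x = _dequantize(np.array([32767, 0, 65534, 65535]))
    assert x[0] == pytest.approx(0.0, abs=1e-4)
    assert x[1] == -5.0 and x[2] == 5.0 and np.isnan(x[3])


def test_sentinel_chain_roundtrip():
    out = []
    _emit_chain(out, 70000, +1)
    assert out == [SENTINEL, 4465]
    items = _decode_us(np.array(out))
    assert items == [("sig", 70000)]
    # negative (masked) runs chain by symmetry
    out = []
    _emit_chain(out, 70000, -1)
    assert _decode_us(np.array(out)) == [("mask", 70000)]
    # exact sentinel magnitude terminates with an explicit zero
    out = []
    _emit_chain(out, SENTINEL, +1)
    assert out == [SENTINEL, 0]
    assert _decode_us(np.array(out)) == [("sig", SENTINEL)]


def test_decode_corrupted_us_raises():
    aln = _mini_alignment([0.1, 0.2], [3, 4])
    tags = ps.encode_tags(aln)
    bad = dict(tags)
    bad["us"] = tags["us"][:-1]
    with pytest.raises(IntegrityError):
        ps.decode_tags(bad, read_id="t")


def test_roundtrip_simulated_alignments(model5, ref500):
    """decode(encode(a)): lengths/coordinates exact, currents within half a
    quantum (10/65534/2 ~ 7.7e-5 normalized units)."""
    half_q = 10 / 65534 / 2
    for seed in range(25):
        sim = ps.simulate_read(ref500, model5,
                               SimParams(noise_sd=0.3, skip_prob=0.03), seed=seed)
        aln = ps.align_read(sim.raw, sim.meta(), ref500, model5,
                            ps.AlignParams(count_events=True))
        back = ps.decode_tags(ps.encode_tags(aln), strand=aln.strand,
                              read_id=aln.read_id)
        np.testing.assert_array_equal(back.lengths, aln.lengths)
        assert back.ref_blocks == aln.ref_blocks
        assert (back.signal_lo, back.signal_hi) == (aln.signal_lo, aln.signal_hi)
        ok = np.isfinite(aln.current) & ~aln.masked
        assert np.all(np.abs(back.current[ok] - aln.current[ok]) <= half_q)
        assert np.all(np.abs(back.current_sd[ok] - aln.current_sd[ok]) <= half_q)
        np.testing.assert_allclose(back.event_count, aln.event_count, atol=1e-6)


def test_null_quantum_null_current():
    aln = _mini_alignment([np.nan, 0.2], [3, 4], masked=[True, False])
    back = ps.decode_tags(ps.encode_tags(aln))
    assert np.isnan(back.current[0]) and back.masked[0]
    assert back.lengths[0] == 3  # masked position keeps its signal length


# ---------------------------------------------------------------------------
# eventalign / TSV / convert

@pytest.fixture()
def aligned_read(model5, ref500):
    sim = ps.simulate_read(ref500, model5, noiseless_params(), seed=8)
    aln = ps.align_read(sim.raw, sim.meta(), ref500, model5, ps.AlignParams())
    return aln


def test_eventalign_columns_and_masking(tmp_path, model5, aligned_read):
    import pandas as pd

    p = tmp_path / "ev.tsv"
    write_eventalign([aligned_read], model5, p)
    df = pd.read_csv(p, sep="\t")
    n_unmasked = int((~aligned_read.masked
                      & np.isfinite(aligned_read.current)).sum())
    assert len(df) == n_unmasked
    np.testing.assert_allclose(
        df["standardized_level"],
        (df["event_level_mean"] - df["model_mean"]) / df["model_stdv"],
        atol=2e-4)
    assert list(df.columns) == list(ps.aln_store.EVENTALIGN_COLUMNS)


def test_eventalign_roundtrip(tmp_path, model5, aligned_read):
    p = tmp_path / "ev.tsv"
    write_eventalign([aligned_read], model5, p)
    [back] = read_eventalign(p)
    a_pos = {int(p): (int(l), c) for p, l, c in
             zip(aligned_read.positions, aligned_read.lengths, aligned_read.current)
             if np.isfinite(c)}
    b_pos = {int(p): (int(l), c) for p, l, c in
             zip(back.positions, back.lengths, back.current)}
    assert set(b_pos) == set(a_pos)
    for p in a_pos:
        assert b_pos[p][0] == a_pos[p][0]
        assert b_pos[p][1] == pytest.approx(a_pos[p][1], abs=1e-4)


def test_eventalign_multirow_collapse(tmp_path):
    """Per-event rows collapse to per-position means weighted by length."""
    header = "\t".join(ps.aln_store.EVENTALIGN_COLUMNS)
    rows = [
        # two events on position 5: means 1.0 (len 6) and 4.0 (len 2)
        "ref\t5\tAAAAA\tr1\tt\t0\t1.0\t0.1\t6\tAAAAA\t0.0\t1.0\t1.0\t0\t6",
        "ref\t5\tAAAAA\tr1\tt\t1\t4.0\t0.3\t2\tAAAAA\t0.0\t1.0\t4.0\t6\t8",
        "ref\t6\tAAAAC\tr1\tt\t2\t2.0\t0.2\t4\tAAAAC\t0.0\t1.0\t2.0\t8\t12",
    ]
    p = tmp_path / "ev.tsv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    [aln] = read_eventalign(p)
    # weighted mean: (6*1 + 2*4)/8 = 1.75
    assert aln.current[0] == pytest.approx(1.75)
    assert aln.lengths[0] == 8
    assert aln.ref_blocks == [(5, 7)]


def test_eventalign_out_of_order_rejected(tmp_path):
    header = "\t".join(ps.aln_store.EVENTALIGN_COLUMNS)
    rows = [
        "ref\t6\tAAAAC\tr1\tt\t0\t2.0\t0.2\t4\tAAAAC\t0.0\t1.0\t2.0\t8\t12",
        "ref\t5\tAAAAA\tr1\tt\t1\t1.0\t0.1\t6\tAAAAA\t0.0\t1.0\t1.0\t0\t6",
    ]
    p = tmp_path / "ev.tsv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    with pytest.raises(ps.FormatError):
        read_eventalign(p)


def test_write_tsv_layers(tmp_path, model5, aligned_read):
    import pandas as pd

    p = tmp_path / "layers.tsv"
    ps.write_tsv([aligned_read], ["dtw.dwell", "dtw.current"], p, model=model5)
    df = pd.read_csv(p, sep="\t")
    assert len(df) == aligned_read.n_positions
    with pytest.raises(PoresigError):
        ps.write_tsv([aligned_read], ["bogus.layer"], p)


def test_bam_roundtrip(tmp_path, model5, ref500):
    """Tags survive a BAM write/read byte-exactly."""
    import pysam

    sims, metas = ps.simulate.simulate_batch(ref500, model5, 3,
                                             SimParams(noise_sd=0.3), seed=3)
    alns = [ps.align_read(s.raw, m, ref500, model5, ps.AlignParams())
            for s, m in zip(sims, metas)]
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref", "LN": len(ref500)}]}
    header = ps.aln_store.add_header_json(
        header, ps.aln_store.header_json(model5.name, "ref.fa", "reads.slow5"))
    path = tmp_path / "out.bam"
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for sim, aln in zip(sims, alns):
            rec = pysam.AlignedSegment(bam.header)
            rec.query_name = aln.read_id
            rec.query_sequence = sim.read_seq
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = 0
            rec.cigarstring = sim.cigar
            ps.aln_store.attach_tags(rec, aln)
            bam.write(rec)
    back = {a.read_id: a for _, a in ps.aln_store.iter_alignments(path)}
    assert len(back) == 3
    for aln in alns:
        b = back[aln.read_id]
        np.testing.assert_array_equal(b.lengths, aln.lengths)
        assert b.ref_blocks == aln.ref_blocks
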