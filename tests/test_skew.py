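import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strandbias import (AnnotatedGenome, content_series, delta_s, dpr2,
                        gene_orientation_skew, genomic_skew_decomposition,
                        pair_skew, s_profile, windowed_skew,
                        SyntheticGenomeSpec, generate)
from strandbias.skew import AT, GC, PAIRS
from strandbias._util import revcomp

seqs = st.text(alphabet="ACGT", min_size=1, max_size=300)


@pytest.mark.parametrize("seq,pair,expected", [
    ("CCCC", "gc", 1.0),    # all-C maximum
    ("CCGG", "gc", 0.0),
    ("GGGC", "gc", -0.5),   # (1 - 3) / 4
    ("TTTA", "at", 0.5),
    ("GGAA", "purine", 1.0),
    ("GGTT", "keto", 1.0),
])
def test_pair_skew_values(seq, pair, expected):
    assert pair_skew(seq, pair) == pytest.approx(expected)


def test_pair_skew_zero_denominator_flag():
    value, flagged = pair_skew("AAAA", "gc", with_flag=True)
    assert value == 0.0 and flagged


@settings(derandomize=True, max_examples=100)
@given(seqs)
def test_pair_skew_revcomp_antisymmetry(seq):
    for pair in ("gc", "at"):
        assert pair_skew(revcomp(seq), pair) == pytest.approx(
            -pair_skew(seq, pair))


@settings(derandomize=True, max_examples=100)
@given(seqs)
def test_dpr2_bounds(seq):
    at, gc = pair_skew(seq, AT), pair_skew(seq, GC)
    d = dpr2(seq)
    assert d == pytest.approx(math.hypot(at, gc))
    assert max(abs(at), abs(gc)) - 1e-12 <= d <= abs(at) + abs(gc) + 1e-12


def test_dpr2_parity_and_pythagorean():
    assert dpr2("ACGT") == 0.0
    # ATskew=0.3 (13T vs 7A), GCskew=0.4 (14C vs 6G): 3-4-5 triangle
    seq = "T" * 13 + "A" * 7 + "C" * 14 + "G" * 6
    assert dpr2(seq) == pytest.approx(0.5)


def test_dpr2_small_on_unbiased(rng):
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    assert dpr2(seq) <= 0.05


def test_windowed_skew_homopolymer_halves():
    genome = AnnotatedGenome("C" * 100 + "G" * 100)
    series = windowed_skew(genome, GC, W=2)
    assert series.values.tolist() == [1.0, -1.0]
    cum = windowed_skew(genome, GC, W=2, cumulative=True)
    assert cum.values.tolist() == [1.0, 0.0]
    assert int(np.argmax(cum.values)) == 0  # skew shift point


def test_windowed_skew_unbiased_bounded(unbiased_fixture):
    genome, _ = unbiased_fixture
    series = windowed_skew(genome, GC, W=512)  # ~390 bp windows
    assert np.all(np.abs(series.values) <= 0.25)


def test_windowed_skew_values_in_unit_interval(biased_fixture):
    genome, _ = biased_fixture
    series = windowed_skew(genome, GC, W=1024)
    assert np.all(series.values >= -1) and np.all(series.values <= 1)
    cum = series.accumulate()
    assert cum.values[-1] == pytest.approx(series.values.sum())


def test_window_partition_conservation(biased_fixture):
    """Sum over windows of (X - Y) counts equals the whole-genome difference."""
    genome, _ = biased_fixture
    series = windowed_skew(genome, GC, W=256)
    total_c = genome.sequence.count("C")
    total_g = genome.sequence.count("G")
    assert int((series.x_counts - series.y_counts).sum()) == total_c - total_g


def test_rotation_leaves_window_multiset(unbiased_fixture):
    genome, _ = unbiased_fixture
    W = 100
    wl = len(genome) // W
    base = windowed_skew(genome, GC, W=W).values
    k = 7 * wl  # rotate by a whole number of windows
    rotated = AnnotatedGenome(genome.sequence[k:] + genome.sequence[:k])
    rot = windowed_skew(rotated, GC, W=W).values
    assert np.allclose(np.roll(rot, 7), base)


def test_w_larger_than_genome_rejected():
    with pytest.raises(ValueError):
        windowed_skew(AnnotatedGenome("ACGT" * 10), W=100)


def test_content_series():
    assert content_series(AnnotatedGenome("GGCCAATT"), "GC", W=2).values.tolist() \
        == [1.0, 0.0]
    genome, _ = generate(SyntheticGenomeSpec(L=100_000, delta=0.0,
                                             mode="unbiased", gene_count=0,
                                             seed=11))
    mean = content_series(genome, "GC", W=100).values.mean()
    assert mean == pytest.approx(0.5, abs=0.01)


def test_gene_orientation_skew_counts():
    genes = []
    from strandbias import GeneAnnotation
    # 3 forward + 1 reverse in the first half, only forward in the second
    for i, strand in enumerate([1, 1, 1, -1]):
        genes.append(GeneAnnotation(f"a{i}", i * 100, i * 100 + 60, strand))
    genes.append(GeneAnnotation("b", 600, 660, 1))
    genome = AnnotatedGenome("ACGT" * 250, genes=genes)
    series = gene_orientation_skew(genome, W=2)
    assert series.values.tolist() == [0.5, 1.0]


def test_gene_skew_extrema_at_ori_ter(biased_fixture):
    genome, truth = biased_fixture
    series = gene_orientation_skew(genome, W=100, cumulative=True)
    L = len(genome)
    extrema = {int(series.window_starts[int(np.argmax(series.values))]),
               int(series.window_starts[int(np.argmin(series.values))])}
    for pos in (truth["ori"], truth["ter"]):
        err = min(min(abs(pos - e), L - abs(pos - e)) for e in extrema)
        assert err <= 0.02 * L


def test_genomic_skew_decomposition_conservation(biased_fixture):
    genome, _ = biased_fixture
    parts = genomic_skew_decomposition(genome, GC, W=128)
    whole, cod, non = parts["whole"], parts["coding"], parts["noncoding"]
    assert np.array_equal(whole.x_counts, cod.x_counts + non.x_counts)
    assert np.array_equal(whole.y_counts, cod.y_counts + non.y_counts)


def test_genomic_skew_no_genes():
    genome, _ = generate(SyntheticGenomeSpec(L=50_000, delta=0.0,
                                             mode="unbiased", gene_count=0,
                                             seed=2))
    parts = genomic_skew_decomposition(genome, GC, W=64)
    assert parts["coding"].flags.all()
    assert np.allclose(parts["noncoding"].values, parts["whole"].values)


def test_s_profile_identity_and_delta_s(unbiased_fixture):
    genome, _ = unbiased_fixture
    prof = s_profile(genome)
    assert np.allclose(prof.s, prof.s_gc + prof.s_at)
    assert abs(delta_s(prof, 100_000, 50_000)) <= 0.05


def test_delta_s_nshape_origin():
    genome, truth = generate(SyntheticGenomeSpec(
        L=400_000, delta=0.1, mode="nshape", gene_count=0, seed=2))
    prof = s_profile(genome)
    flank = 80_000
    ds = delta_s(prof, truth["ori"], flank)
    up = prof.s[((prof.positions - (truth["ori"] - flank)) % len(genome))
                < flank].mean()
    assert ds > 0.5
    assert ds == pytest.approx(2 * up, rel=0.15)


def test_delta_s_flank_validation(unbiased_fixture):
    genome, _ = unbiased_fixture
    prof = s_profile(genome)
    with pytest.raises(ValueError):
        delta_s(prof, 0, len(genome))
    with pytest.raises(ValueError):
        delta_s(prof, 0, 500)  # smaller than the window


def test_all_pairs_partition():
    for name in ("purine", "keto", "amino"):
        pair = PAIRS[name]
        assert pair.x | pair.y == frozenset("ACGT")
        assert not pair.x & pair.y
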