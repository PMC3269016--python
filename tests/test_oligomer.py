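import math

import numpy as np
import pytest

from strandbias import (AnnotatedGenome, inject_oligomer, oligomer_d, s_curve,
                        sn_ratio, d_table, SyntheticGenomeSpec, generate)
from strandbias.oligomer import _kmer_ids, _pair_indices, id_to_oligomer
from strandbias._util import revcomp


@pytest.mark.parametrize("lead,lag,expected", [
    (7, 7, 0.0),
    (10, 0, 10 * math.log2(3)),
    (0, 10, 10 * math.log2(3)),  # sign symmetry of the product
    (0, 0, 0.0),
])
def test_oligomer_d_values(lead, lag, expected):
    assert oligomer_d(lead, lag) == pytest.approx(expected)


def test_oligomer_d_symmetry_and_monotonicity():
    for a, b in [(3, 9), (0, 4), (12, 2)]:
        assert oligomer_d(a, b) == pytest.approx(oligomer_d(b, a))
    fixed_min = 5
    values = [oligomer_d(fixed_min + gap, fixed_min) for gap in range(10)]
    assert all(x < y for x, y in zip(values, values[1:]))


def brute_force_counts(seq: str, k: int) -> dict:
    """Oracle: circular overlapping k-mer scan."""
    ext = seq + seq[: k - 1]
    counts = {}
    for i in range(len(seq)):
        word = ext[i : i + k]
        if "N" in word:
            continue
        counts[word] = counts.get(word, 0) + 1
    return counts


def test_kmer_ids_match_brute_force(rng):
    seq = "".join(rng.choice(list("ACGTN"), size=5000, p=[0.24] * 4 + [0.04]))
    genome = AnnotatedGenome(seq)
    for k in (1, 2, 3, 4):
        ids = _kmer_ids(genome.codes, k)
        counts = np.bincount(ids, minlength=4 ** k + 1)
        oracle = brute_force_counts(genome.sequence, k)
        for i in range(4 ** k):
            word = id_to_oligomer(i, k)
            assert counts[i] == oracle.get(word, 0), word


def test_pair_indices_exclude_palindromes():
    rep, partner = _pair_indices(4)
    words = {id_to_oligomer(int(i), 4) for i in rep}
    assert "GATC" not in words and "GATC" not in {
        id_to_oligomer(int(j), 4) for j in partner}
    # every pair counted once: representative strictly smaller than partner
    assert len(rep) == (256 - 16) / 2
    for i, j in zip(rep[:20], partner[:20]):
        assert id_to_oligomer(int(j), 4) == revcomp(id_to_oligomer(int(i), 4))


def test_d_table_matches_brute_force(rng):
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    genome = AnnotatedGenome(seq)
    table = d_table(genome, position=100, fraction=0.6, k_max=2)
    w = int(round(0.6 * 3000))
    arc = (seq + seq)[100 : 100 + w]
    oracle = {}
    for k in (1, 2):  # linear scan of the arc: complete words only
        for i in range(len(arc) - k + 1):
            oracle[arc[i : i + k]] = oracle.get(arc[i : i + k], 0) + 1
    for word, d in table.items():
        n1 = oracle.get(word, 0)
        n2 = oracle.get(revcomp(word), 0)
        assert d == pytest.approx(oligomer_d(n1, n2)), word


def test_s_curve_wraparound_and_bounds(unbiased_fixture):
    genome, _ = unbiased_fixture
    profile = s_curve(genome, k_max=3, n_positions=16)
    assert profile.sn >= 1.0
    assert np.all(profile.s_curve >= 0)


def test_s_curve_recovers_origin(biased_fixture):
    genome, truth = biased_fixture
    L = len(genome)
    profile = s_curve(genome, k_max=4, n_positions=200)
    err = min((profile.argmax_position - truth["ori"]) % L,
              (truth["ori"] - profile.argmax_position) % L)
    assert err <= 0.02 * L
    assert profile.sn > 5


def test_sn_ratio_flags_and_arithmetic():
    prof = s_curve(AnnotatedGenome("ACGT" * 300), k_max=2, n_positions=8)
    assert sn_ratio(prof) == prof.sn >= 1.0
    with pytest.raises(ValueError):
        s_curve(AnnotatedGenome("ACGT" * 300), k_max=13)


def test_revcomp_genome_preserves_sn(biased_fixture):
    """S_curve reflects under reverse complement, leaving S/N unchanged
    (up to grid quantization of the reflected positions)."""
    genome, _ = biased_fixture
    p1 = s_curve(genome, k_max=3, n_positions=200)
    p2 = s_curve(AnnotatedGenome(revcomp(genome.sequence)), k_max=3,
                 n_positions=200)
    assert p2.sn == pytest.approx(p1.sn, rel=0.1)


def test_injection_increases_sn():
    spec = SyntheticGenomeSpec(L=100_000, delta=0.02, gene_count=0, seed=14)
    genome, truth = generate(spec)
    before = s_curve(genome, k_max=8, n_positions=50).sn
    injected = inject_oligomer(genome, truth, "GCTGGTGG", fold=300, seed=1)
    after = s_curve(injected, k_max=8, n_positions=50).sn
    assert after > before
    assert truth["injected"][0]["copies"] > 0


def test_injection_fold_zero_noop():
    genome, truth = generate(SyntheticGenomeSpec(L=20_000, delta=0.0,
                                                 mode="unbiased",
                                                 gene_count=0, seed=1))
    same = inject_oligomer(genome, truth, "GCTGGTGG", fold=0)
    assert same.sequence == genome.sequence


def test_injection_rejects_palindrome():
    genome, truth = generate(SyntheticGenomeSpec(L=20_000, delta=0.0,
                                                 mode="unbiased",
                                                 gene_count=0, seed=1))
    with pytest.raises(ValueError, match="palindromic"):
        inject_oligomer(genome, truth, "GATC", fold=1)


def test_injected_octamer_is_leading_biased():
    spec = SyntheticGenomeSpec(L=100_000, delta=0.0, mode="unbiased",
                               gene_count=0, seed=15)
    genome, truth = generate(spec)
    injected = inject_oligomer(genome, truth, "GCTGGTGG", fold=30, seed=2)
    L = len(injected)
    ori, ter = truth["ori"], truth["ter"]
    arc_a = injected.slice(ori, ter)          # forward strand leading
    arc_b = injected.slice(ter, ori)          # forward strand lagging
    lead_count = arc_a.count("GCTGGTGG") + revcomp(arc_b).count("GCTGGTGG")
    lag_count = revcomp(arc_a).count("GCTGGTGG") + arc_b.count("GCTGGTGG")
    assert lead_count >= 10 * max(lag_count, 1)
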