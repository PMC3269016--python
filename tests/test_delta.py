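import math

import numpy as np
import pytest

from strandbias import (AnnotatedGenome, GeneAnnotation, ReplichoreMap,
                        b_index, delta_skew, SyntheticGenomeSpec, generate)


def test_delta_skew_maximum_two_arc_homopolymer():
    """All-C leading arc vs all-G lagging arc attains the maximum of 2."""
    genome = AnnotatedGenome("C" * 500 + "G" * 500)
    rmap = ReplichoreMap(0, 500, 1000)
    result = delta_skew(genome, rmap, method="all")
    assert result.value == pytest.approx(2.0)
    # forward-arc contrast gives the same extremum here
    fwd = delta_skew(genome, rmap, method="all", arc_mode="forward")
    assert fwd.value == pytest.approx(2.0)


def test_delta_skew_null_is_zero():
    genome = AnnotatedGenome("ACGT" * 250)
    rmap = ReplichoreMap(0, 500, 1000)
    assert delta_skew(genome, rmap, method="all").value == pytest.approx(0.0)


def test_delta_skew_antisymmetric_under_label_swap(biased_fixture):
    genome, truth = biased_fixture
    rmap = ReplichoreMap(truth["ori"], truth["ter"], len(genome))
    swapped = ReplichoreMap(truth["ter"], truth["ori"], len(genome))
    for method in ("all", "gene", "gc3"):
        a = delta_skew(genome, rmap, method=method).value
        b = delta_skew(genome, swapped, method=method).value
        assert a == pytest.approx(-b, abs=1e-9)


def test_delta_skew_matches_emission_probabilities():
    """Leading C=0.3, G=0.2 mirrored on the lagging arc -> delta = 0.4."""
    spec = SyntheticGenomeSpec(L=1_000_000, delta=-0.05, gene_count=0, seed=12)
    genome, truth = generate(spec)
    rmap = ReplichoreMap(truth["ori"], truth["ter"], len(genome))
    result = delta_skew(genome, rmap, method="all")
    assert truth["expected"]["delta_gcskew_all"] == pytest.approx(0.4)
    assert result.value == pytest.approx(0.4, abs=0.02)


def test_delta_skew_converges_to_closed_form(biased_fixture):
    """The measured index approaches the generator's analytic expectation."""
    genome, truth = biased_fixture
    rmap = ReplichoreMap(truth["ori"], truth["ter"], len(genome))
    expected = truth["expected"]["delta_gcskew_all"]
    got = delta_skew(genome, rmap, method="all").value
    # 3 binomial standard errors on a ~250 kb arc is well under 0.01
    assert got == pytest.approx(expected, abs=0.01)
    gc3 = delta_skew(genome, rmap, method="gc3").value
    assert gc3 == pytest.approx(truth["expected"]["delta_gcskew_gc3"], abs=0.05)


def test_delta_skew_gene_method_and_errors(biased_fixture):
    genome, truth = biased_fixture
    rmap = ReplichoreMap(truth["ori"], truth["ter"], len(genome))
    gene_val = delta_skew(genome, rmap, method="gene")
    assert gene_val.n_leading + gene_val.n_lagging == len(genome.genes)
    assert gene_val.value < 0  # leading genes are G/T-rich at position 3
    with pytest.raises(ValueError):
        delta_skew(genome, rmap, pair="gc", method="nope")


def test_delta_skew_empty_class_error():
    genome, truth = generate(SyntheticGenomeSpec(
        L=60_000, delta=0.05, gene_count=10, orientation_bias=1.0, seed=5))
    rmap = ReplichoreMap(truth["ori"], truth["ter"], len(genome))
    with pytest.raises(ValueError, match="lagging"):
        delta_skew(genome, rmap, method="gene")


def _two_gene_genome(lead_cds: str, lag_cds: str):
    seq = lead_cds + lag_cds
    genes = [GeneAnnotation("lead", 0, len(lead_cds), 1),
             GeneAnnotation("lag", len(lead_cds), len(seq), 1)]
    genome = AnnotatedGenome(seq, genes=genes)
    # forward strand is leading on [0, len(lead_cds)), lagging beyond
    rmap = ReplichoreMap(0, len(lead_cds), len(seq))
    return genome, rmap


def test_b1_attains_sqrt2_on_maximal_construct():
    """Leading thirds all G/T (x=y=1) vs lagging all C/A (x=y=0)."""
    genome, rmap = _two_gene_genome("GGGGGT" * 20, "GGCGGA" * 20)
    result = b_index(genome, rmap, "gc3")
    assert (result.x_leading, result.y_leading) == (1.0, 1.0)
    assert (result.x_lagging, result.y_lagging) == (0.0, 0.0)
    assert result.b1 == pytest.approx(math.sqrt(2))
    # class averages sit at parity, so B_II vanishes
    assert result.b2 == pytest.approx(0.0)


def test_b1_zero_when_classes_match():
    genome, rmap = _two_gene_genome("GGTGGC" * 20, "GGTGGC" * 20)
    result = b_index(genome, rmap, "gc3")
    assert result.b1 == pytest.approx(0.0)
    assert result.x_leading == result.x_lagging


def test_b1_invariant_under_label_swap(biased_fixture):
    genome, truth = biased_fixture
    rmap = ReplichoreMap(truth["ori"], truth["ter"], len(genome))
    swapped = ReplichoreMap(truth["ter"], truth["ori"], len(genome))
    a = b_index(genome, rmap)
    b = b_index(genome, swapped)
    assert a.b1 == pytest.approx(b.b1)
    assert a.b1 <= math.sqrt(2) + 1e-12


def test_b1_matches_generator_expectation(biased_fixture):
    genome, truth = biased_fixture
    rmap = ReplichoreMap(truth["ori"], truth["ter"], len(genome))
    result = b_index(genome, rmap, "gc3")
    assert result.b1 == pytest.approx(truth["expected"]["b1"], abs=0.05)
    assert result.x_leading == pytest.approx(truth["expected"]["x_leading"],
                                             abs=0.03)
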