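"""Leading-minus-lagging skew differences (ΔGC skew family) and B indices.

ΔGC skew cancels replication-independent biases by subtracting the skew
of the lagging-strand class from that of the leading-strand class.  Three
variants are provided: over all bases of the replichore arcs, as the
unweighted mean of per-gene skews, and over third codon positions
(optionally restricted to four-fold degenerate codons).  B_I and B_II are
the Euclidean analogues built from x = G/(G+C) and y = T/(T+A) at third
codon positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._util import encode
from .genome import AnnotatedGenome, coding_sequence, third_codon_bases, FlaggedGeneError
from .replichore import ReplichoreMap, classify_gene
from .skew import GC, BasePair, get_pair, pair_skew

logger = logging.getLogger(__name__)

METHODS = ("all", "gene", "gc3", "degenerate")


@dataclass
class DeltaSkewResult:
    value: float
    pair: str
    method: str
    n_leading: int
    n_lagging: int


@dataclass
class BIndexResult:
    b1: float
    b2: float
    x_leading: float
    x_lagging: float
    y_leading: float
    y_lagging: float
    x_c: float
    y_c: float
    codon_filter: str
    n_leading: int
    n_lagging: int


def _arc_base_counts(genome: AnnotatedGenome, start: int, end: int) -> np.ndarray:
    codes = encode(genome.slice(start, end))
    return np.bincount(codes, minlength=5)[:4]


def _set_count(counts: np.ndarray, bases) -> int:
    return int(sum(counts["ACGT".index(b)] for b in bases))


def _split_genes(genome: AnnotatedGenome, rmap: ReplichoreMap):
    leading, lagging, skipped = [], [], 0
    for gene in genome.cds_genes():
        try:
            cds = coding_sequence(genome, gene)
        except FlaggedGeneError:
            skipped += 1
            continue
        (leading if classify_gene(rmap, gene) == "leading" else lagging).append(cds)
    if skipped:
        logger.warning("skipped %d flagged CDS genes", skipped)
    return leading, lagging


def _require_both(leading, lagging) -> None:
    if not leading:
        raise ValueError("no genes in the leading class")
    if not lagging:
        raise ValueError("no genes in the lagging class")


def delta_skew(genome: AnnotatedGenome, rmap: ReplichoreMap,
               pair: str | BasePair = GC, method: str = "degenerate",
               arc_mode: str = "replication") -> DeltaSkewResult:
    """Leading-class skew minus lagging-class skew.

    method="all" uses every base of the two replichore arcs; by default
    each replichore contributes its leading-strand sequence read in the
    replication direction (``arc_mode="forward"`` instead contrasts the
    two forward-strand arcs, matching skew-graph plots).  method="gene"
    averages per-gene coding-strand skews, unweighted by gene length.
    method="gc3"/"degenerate" pools third-codon-position bases per class,
    the latter restricted to four-fold degenerate codons.
    """
    pair = get_pair(pair)
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    L = len(genome)

    if method == "all":
        counts_a = _arc_base_counts(genome, rmap.ori, rmap.ter)  # forward leading
        counts_b = _arc_base_counts(genome, rmap.ter, rmap.ori)  # forward lagging
        if arc_mode == "forward":
            skew_a = _counts_skew(counts_a, pair)
            skew_b = _counts_skew(counts_b, pair)
            value = skew_a - skew_b
        elif arc_mode == "replication":
            # leading strand of replichore B is the reverse complement of its
            # forward arc; complementation maps the X set onto the Y set for
            # every supported pair, so pooled leading counts are X_A + Y_B.
            x = _set_count(counts_a, pair.x) + _set_count(counts_b, pair.y)
            y = _set_count(counts_a, pair.y) + _set_count(counts_b, pair.x)
            skew_leading = 0.0 if x + y == 0 else (x - y) / (x + y)
            value = 2.0 * skew_leading  # lagging pool is the exact revcomp
        else:
            raise ValueError("arc_mode must be 'replication' or 'forward'")
        n_lead = (rmap.ter - rmap.ori) % L
        n_lag = L - n_lead
        return DeltaSkewResult(float(value), pair.name, method, n_lead, n_lag)

    leading, lagging = _split_genes(genome, rmap)
    _require_both(leading, lagging)

    if method == "gene":
        mean_lead = float(np.mean([pair_skew(c, pair) for c in leading]))
        mean_lag = float(np.mean([pair_skew(c, pair) for c in lagging]))
        return DeltaSkewResult(mean_lead - mean_lag, pair.name, method,
                               len(leading), len(lagging))

    fourfold = method == "degenerate"
    pooled_lead = "".join(third_codon_bases(c, fourfold) for c in leading)
    pooled_lag = "".join(third_codon_bases(c, fourfold) for c in lagging)
    if not pooled_lead or not pooled_lag:
        raise ValueError("no third-position bases in one strand class")
    value = pair_skew(pooled_lead, pair) - pair_skew(pooled_lag, pair)
    return DeltaSkewResult(float(value), pair.name, method,
                           len(leading), len(lagging))


def _counts_skew(counts: np.ndarray, pair: BasePair) -> float:
    x = _set_count(counts, pair.x)
    y = _set_count(counts, pair.y)
    return 0.0 if x + y == 0 else (x - y) / (x + y)


def _xy(counts: np.ndarray) -> tuple[float, float, bool]:
    """x = G/(G+C), y = T/(T+A) from pooled base counts; flags empty ratios."""
    a, c, g, t = (int(counts[i]) for i in range(4))
    flagged = False
    if g + c == 0:
        x, flagged = 0.5, True
    else:
        x = g / (g + c)
    if t + a == 0:
        y, flagged = 0.5, True
    else:
        y = t / (t + a)
    return x, y, flagged


def b_index(genome: AnnotatedGenome, rmap: ReplichoreMap,
            codon_filter: str = "gc3") -> BIndexResult:
    """B_I and B_II from third-codon-position compositions per strand class.

    B_I = sqrt((x_lead - x_lag)^2 + (y_lead - y_lag)^2) measures the
    leading/lagging contrast; B_II measures the joint deviation of the
    class-averaged x_c, y_c from parity (0.5, 0.5).  ``codon_filter`` is
    "gc3" (all third positions) or "degenerate" (four-fold families only).
    """
    if codon_filter not in ("gc3", "degenerate"):
        raise ValueError("codon_filter must be 'gc3' or 'degenerate'")
    fourfold = codon_filter == "degenerate"
    leading, lagging = _split_genes(genome, rmap)
    _require_both(leading, lagging)
    pooled = []
    for group in (leading, lagging):
        bases = "".join(third_codon_bases(c, fourfold) for c in group)
        pooled.append(np.bincount(encode(bases), minlength=5)[:4])
    x_lead, y_lead, flag1 = _xy(pooled[0])
    x_lag, y_lag, flag2 = _xy(pooled[1])
    if flag1 or flag2:
        logger.warning("zero G+C or T+A in a strand class; component set to 0.5")
    x_c = (x_lead + x_lag) / 2
    y_c = (y_lead + y_lag) / 2
    b1 = math.hypot(x_lead - x_lag, y_lead - y_lag)
    b2 = math.hypot(x_c - 0.5, y_c - 0.5)
    return BIndexResult(b1, b2, x_lead, x_lag, y_lead, y_lag, x_c, y_c,
                        codon_filter, len(leading), len(lagging))
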