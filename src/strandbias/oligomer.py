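"""Oligonucleotide strand-bias scoring: D_i, S_p curve, and the S/N ratio.

For a hypothetical origin p the forward-strand arc downstream of p is the
candidate leading region.  For every non-palindromic oligomer pair
{i, revcomp(i)} the weighted double Kullback-Leibler distance

    D_i = (N_lead - N_lag) * log2((N_lead + r) / (N_lag + r))

contrasts the occurrences of i with those of its reverse complement in
that single-stranded arc (r = 5 cushions low counts).  S_p sums D_i over
all oligomer pairs up to ``k_max``; it peaks at the true origin, and the
genome-level signal-to-noise ratio S/N = S_max / S_min (>= 1, with no
theoretical upper bound) quantifies the overall oligomer strand bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .genome import AnnotatedGenome

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.50, 0.55, 0.60, 0.65, 0.70)
REFERENCE_FRACTION = 0.60


def oligomer_d(n_leading: int, n_lagging: int, r: int = 5) -> float:
    """Weighted double Kullback-Leibler distance of one oligomer pair."""
    if n_leading < 0 or n_lagging < 0:
        raise ValueError("counts must be non-negative")
    return (n_leading - n_lagging) * math.log2((n_leading + r) / (n_lagging + r))


def _kmer_ids(codes: np.ndarray, k: int) -> np.ndarray:
    """Circular k-mer ids at every start position; N-containing k-mers -> 4^k."""
    L = len(codes)
    ext = np.concatenate([codes, codes[: k - 1]]).astype(np.int64)
    ids = np.zeros(L, dtype=np.int64)
    bad = np.zeros(L, dtype=bool)
    for j in range(k):
        ids = ids * 4 + np.where(ext[j : j + L] == 4, 0, ext[j : j + L])
        bad |= ext[j : j + L] == 4
    ids[bad] = 4 ** k
    return ids


def _revcomp_ids(k: int) -> np.ndarray:
    """Permutation mapping each k-mer id to the id of its reverse complement."""
    ids = np.arange(4 ** k)
    rc = np.zeros_like(ids)
    tmp = ids.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc


def id_to_oligomer(i: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[i % 4])
        i //= 4
    return "".join(reversed(out))


@dataclass
class OligomerSkewProfile:
    positions: np.ndarray
    s_curve: np.ndarray
    k_min: int
    k_max: int
    r: int
    fractions: tuple
    genome_length: int
    s_min_zero: bool = False

    @property
    def s_max(self) -> float:
        return float(np.max(self.s_curve))

    @property
    def s_min(self) -> float:
        return float(np.min(self.s_curve))

    @property
    def sn(self) -> float:
        return self.s_max / self.s_min if self.s_min > 0 else math.inf

    @property
    def argmax_position(self) -> int:
        return int(self.positions[int(np.argmax(self.s_curve))])


def _pair_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Representative / partner ids for each non-palindromic complementary pair."""
    rc = _revcomp_ids(k)
    rep = np.nonzero(np.arange(4 ** k) < rc)[0]  # strict: palindromes dropped
    return rep, rc[rep]


def s_curve(genome: AnnotatedGenome, k_max: int = 8, k_min: int = 1,
            fractions: tuple = DEFAULT_FRACTIONS, n_positions: int = 200,
            r: int = 5) -> OligomerSkewProfile:
    """S_p over a grid of hypothetical origin positions.

    Per position and window fraction f, the candidate leading region is the
    forward-strand arc of round(f*L) bp starting at p; S_p(f) sums D_i over
    all non-palindromic oligomer pairs of lengths k_min..k_max (each
    unordered pair once), and S_p is the median of the S_p(f) after
    rescaling each by 0.60/f to the common 60%-window scale.
    """
    if not genome.is_circular:
        raise ValueError("s_curve requires a circular genome")
    if k_max > 12:
        raise ValueError("k_max > 12 refused (4^k oligomer table blowup)")
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    L = len(genome)
    if L < 4 ** k_max:
        logger.warning("genome length %d < 4^%d; high-order counts are sparse",
                       L, k_max)
    fractions = tuple(sorted(fractions))
    positions = (np.arange(n_positions) * L) // n_positions
    arc_lens = [int(round(f * L)) for f in fractions]
    if max(arc_lens) > L:
        raise ValueError("window fraction exceeds the genome")

    s_pf = np.zeros((n_positions, len(fractions)))
    for k in range(k_min, k_max + 1):
        ids = _kmer_ids(genome.codes, k)
        ext = np.concatenate([ids, ids[: max(arc_lens)]])
        rep, partner = _pair_indices(k)
        nbins = 4 ** k + 1
        rf = float(r)
        for ip, p in enumerate(positions):
            counts = None
            prev = 0
            for jf, w in enumerate(arc_lens):
                # occurrences fully inside the arc: starts p .. p + w - k;
                # nested arcs extend the previous count vector incrementally
                inc = np.bincount(ext[p + prev : p + w - k + 1],
                                  minlength=nbins)
                counts = inc if counts is None else counts + inc
                prev = w - k + 1
                n1 = counts[rep].astype(float)
                n2 = counts[partner].astype(float)
                d = (n1 - n2) * np.log2((n1 + rf) / (n2 + rf))
                s_pf[ip, jf] += float(d.sum())

    scaled = s_pf * (REFERENCE_FRACTION / np.asarray(fractions))
    s_p = np.median(scaled, axis=1)
    profile = OligomerSkewProfile(positions, s_p, k_min, k_max, r, fractions, L)
    if profile.s_min <= 0:
        profile.s_min_zero = True
        logger.warning("S_min <= 0; S/N flagged as infinite")
    return profile


def sn_ratio(profile: OligomerSkewProfile) -> float:
    """S/N = S_max / S_min of a computed S_p curve (>= 1; inf when S_min = 0)."""
    return profile.sn


def d_table(genome: AnnotatedGenome, position: int,
            fraction: float = REFERENCE_FRACTION, k_max: int = 8,
            k_min: int = 1, r: int = 5) -> dict[str, float]:
    """Per-oligomer D_i map for one hypothetical origin position."""
    L = len(genome)
    w = int(round(fraction * L))
    table: dict[str, float] = {}
    for k in range(k_min, k_max + 1):
        ids = _kmer_ids(genome.codes, k)
        ext = np.concatenate([ids, ids[:w]])
        counts = np.bincount(ext[position : position + w - k + 1],
                             minlength=4 ** k + 1)
        rep, partner = _pair_indices(k)
        for i, j in zip(rep, partner):
            table[id_to_oligomer(int(i), k)] = oligomer_d(
                int(counts[i]), int(counts[j]), r)
    return table
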