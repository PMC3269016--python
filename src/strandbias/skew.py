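"""Base-pair skews, windowed and cumulative skew series, and the S profile.

The default orientation for all skews is the graph convention
``(C - G) / (C + G)`` and ``(T - A) / (T + A)``: an excess of G over C —
the signature of the leading strand — gives a *negative* GC skew.  The
eukaryotic S profile (:func:`s_profile`) is the one deliberate exception:
there ``S_GC = (G - C)/(G + C)`` and ``S_AT = (T - A)/(T + A)``, matching
the convention its literature prints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import encode
from .genome import AnnotatedGenome


@dataclass(frozen=True)
class BasePair:
    """A complementary base contrast: skew = (#X - #Y) / (#X + #Y)."""

    name: str
    x: frozenset  # numerator bases
    y: frozenset  # denominator-partner bases


GC = BasePair("gc", frozenset("C"), frozenset("G"))
AT = BasePair("at", frozenset("T"), frozenset("A"))
PURINE = BasePair("purine", frozenset("GA"), frozenset("CT"))
KETO = BasePair("keto", frozenset("GT"), frozenset("AC"))
AMINO = BasePair("amino", frozenset("AC"), frozenset("GT"))

PAIRS: Mapping[str, BasePair] = {p.name: p for p in (GC, AT, PURINE, KETO, AMINO)}


def get_pair(pair: str | BasePair) -> BasePair:
    if isinstance(pair, BasePair):
        return pair
    try:
        return PAIRS[pair.lower()]
    except KeyError:
        raise ValueError(f"unknown base pair {pair!r}; choose from {sorted(PAIRS)}")


def _idx(bases: frozenset) -> list[int]:
    return ["ACGT".index(b) for b in sorted(bases)]


def pair_skew(seq: str | AnnotatedGenome, pair: str | BasePair = GC,
              with_flag: bool = False):
    """Scalar skew (#X - #Y)/(#X + #Y) of a sequence.

    Returns 0.0 when the denominator is zero; pass ``with_flag=True`` to
    also receive the zero-denominator flag.
    """
    pair = get_pair(pair)
    if isinstance(seq, AnnotatedGenome):
        codes = seq.codes
    else:
        codes = encode(seq)
    if codes.size == 0:
        raise ValueError("empty sequence")
    counts = np.bincount(codes, minlength=5)[:4]
    x = int(counts[_idx(pair.x)].sum())
    y = int(counts[_idx(pair.y)].sum())
    value = 0.0 if x + y == 0 else (x - y) / (x + y)
    if with_flag:
        return value, x + y == 0
    return value


def dpr2(seq: str | AnnotatedGenome) -> float:
    """Euclidean distance from compositional parity: sqrt(ATskew^2 + GCskew^2)."""
    return math.hypot(pair_skew(seq, AT), pair_skew(seq, GC))


@dataclass
class SkewSeries:
    """Per-window skew signal f(n), optionally in cumulative (prefix-sum) form."""

    pair: str
    values: np.ndarray
    window_starts: np.ndarray
    window_ends: np.ndarray
    genome_length: int
    cumulative: bool = False
    flags: np.ndarray = field(default=None)  # zero-denominator windows
    x_counts: np.ndarray = field(default=None)
    y_counts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = np.zeros(len(self.values), dtype=bool)

    def __len__(self) -> int:
        return len(self.values)

    def accumulate(self) -> "SkewSeries":
        if self.cumulative:
            return self
        return SkewSeries(self.pair, np.cumsum(self.values), self.window_starts,
                          self.window_ends, self.genome_length, True,
                          self.flags, self.x_counts, self.y_counts)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form with 1-based inclusive coordinates."""
        return pd.DataFrame({
            "window_start": self.window_starts + 1,
            "window_end": np.where(self.window_ends > self.genome_length,
                                   self.window_ends - self.genome_length,
                                   self.window_ends),
            "value": self.values,
            "flag": self.flags.astype(int),
        })


def _prefix_counts(codes: np.ndarray) -> np.ndarray:
    """(L+1, 4) prefix base counts; row i counts bases in codes[:i]."""
    onehot = np.zeros((len(codes) + 1, 4), dtype=np.int64)
    for b in range(4):
        onehot[1:, b] = codes == b
    return np.cumsum(onehot, axis=0)


def _range_counts(prefix: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                  L: int) -> np.ndarray:
    """Base counts over [start, end) ranges; ends beyond L wrap circularly."""
    ends = np.asarray(ends)
    starts = np.asarray(starts)
    wrap = ends > L
    plain_end = np.where(wrap, L, ends)
    counts = prefix[plain_end] - prefix[starts]
    if wrap.any():
        counts[wrap] += prefix[ends[wrap] - L]
    return counts


def _tiling(L: int, W: int) -> tuple[np.ndarray, np.ndarray]:
    """W non-overlapping windows of floor(L/W) bp; the last absorbs the remainder."""
    wl = L // W
    starts = np.arange(W, dtype=np.int64) * wl
    ends = starts + wl
    ends[-1] = L
    return starts, ends


def _windows(genome: AnnotatedGenome, W: int | None, window_size: int | None,
             step: int | None) -> tuple[np.ndarray, np.ndarray]:
    L = len(genome)
    if W is not None:
        if W > L:
            raise ValueError(f"W={W} exceeds genome length {L}")
        if W < 2:
            raise ValueError("need at least 2 windows")
        return _tiling(L, W)
    if window_size is None or window_size < 1:
        raise ValueError("provide W or window_size >= 1")
    step = step or window_size
    starts = np.arange(0, L, step, dtype=np.int64)
    ends = starts + window_size
    if not genome.is_circular:
        ends = np.minimum(ends, L)
    return starts, ends


def windowed_skew(genome: AnnotatedGenome, pair: str | BasePair = GC,
                  W: int | None = None, window_size: int | None = None,
                  cumulative: bool = False, step: int | None = None) -> SkewSeries:
    """Windowed skew series of a genome.

    With ``W`` the genome is tiled into W non-overlapping windows (the
    canonical input for cumulative analysis and the GC Skew Index); with
    ``window_size``/``step`` a sliding series for plotting is produced.
    """
    pair = get_pair(pair)
    starts, ends = _windows(genome, W, window_size, step)
    prefix = _prefix_counts(genome.codes)
    counts = _range_counts(prefix, starts, ends, len(genome))
    x = counts[:, _idx(pair.x)].sum(axis=1)
    y = counts[:, _idx(pair.y)].sum(axis=1)
    denom = x + y
    flags = denom == 0
    values = np.divide(x - y, denom, out=np.zeros(len(x)), where=~flags)
    series = SkewSeries(pair.name, values, starts, ends, len(genome),
                        False, flags, x, y)
    return series.accumulate() if cumulative else series


def content_series(genome: AnnotatedGenome, base_set: str = "GC",
                   W: int | None = None, window_size: int | None = None,
                   step: int | None = None) -> SkewSeries:
    """Fraction of window bases in ``base_set`` (N excluded from the denominator)."""
    bases = frozenset(base_set.upper())
    if not bases <= frozenset("ACGT"):
        raise ValueError(f"base_set must be over ACGT, got {base_set!r}")
    starts, ends = _windows(genome, W, window_size, step)
    prefix = _prefix_counts(genome.codes)
    counts = _range_counts(prefix, starts, ends, len(genome))
    x = counts[:, _idx(bases)].sum(axis=1)
    total = counts.sum(axis=1)
    flags = total == 0
    values = np.divide(x, total, out=np.zeros(len(x), dtype=float), where=~flags)
    return SkewSeries("+".join(sorted(bases)), values, starts, ends,
                      len(genome), False, flags, x, total - x)


def gene_orientation_skew(genome: AnnotatedGenome, W: int | None = None,
                          window_size: int | None = None,
                          cumulative: bool = False) -> SkewSeries:
    """Per-window (forward - reverse)/(forward + reverse) gene counts.

    Genes are assigned to windows by midpoint.
    """
    if not genome.genes:
        raise ValueError("genome has no gene annotations")
    starts, ends = _windows(genome, W, window_size, None)
    L = len(genome)
    mids = np.array([g.midpoint(L) for g in genome.genes])
    strands = np.array([g.strand for g in genome.genes])
    # midpoint -> tiling window index (last window absorbs the remainder)
    wl = starts[1] - starts[0] if len(starts) > 1 else L
    idx = np.minimum(mids // wl, len(starts) - 1)
    fwd = np.bincount(idx[strands == 1], minlength=len(starts))
    rev = np.bincount(idx[strands == -1], minlength=len(starts))
    denom = fwd + rev
    flags = denom == 0
    values = np.divide(fwd - rev, denom, out=np.zeros(len(fwd)), where=~flags)
    series = SkewSeries("gene", values, starts, ends, L, False, flags, fwd, rev)
    return series.accumulate() if cumulative else series


def _coding_mask(genome: AnnotatedGenome) -> np.ndarray:
    L = len(genome)
    mask = np.zeros(L, dtype=bool)
    for g in genome.genes:
        if g.wraps():
            mask[g.start:] = True
            mask[: g.end] = True
        else:
            mask[g.start : g.end] = True
    return mask


def _gc3_positions(genome: AnnotatedGenome) -> np.ndarray:
    """Forward-strand coordinates of every third-codon-position base."""
    L = len(genome)
    pos = []
    for g in genome.cds_genes():
        n = g.length(L)
        if n % 3 != 0:
            continue
        if g.strand == 1:
            p = (g.start + np.arange(2, n, 3)) % L
        else:
            p = (g.start + np.arange(0, n, 3)) % L
        pos.append(p)
    if not pos:
        return np.array([], dtype=np.int64)
    return np.concatenate(pos)


def genomic_skew_decomposition(genome: AnnotatedGenome,
                               pair: str | BasePair = GC,
                               W: int = 2048) -> dict[str, SkewSeries]:
    """Windowed skew split into whole / coding / non-coding / GC3 components.

    All components are forward-strand properties of the same tiling; per
    window the coding and non-coding base counts sum to the whole-window
    counts.
    """
    pair = get_pair(pair)
    starts, ends = _tiling(len(genome), W)
    L = len(genome)
    wl = starts[1] - starts[0]
    codes = genome.codes
    win_of = np.minimum(np.arange(L) // wl, W - 1)
    coding = _coding_mask(genome)

    def counted(mask_codes: np.ndarray, mask_win: np.ndarray, name: str) -> SkewSeries:
        xs = np.zeros(W, dtype=np.int64)
        ys = np.zeros(W, dtype=np.int64)
        for b in _idx(pair.x):
            xs += np.bincount(mask_win[mask_codes == b], minlength=W)
        for b in _idx(pair.y):
            ys += np.bincount(mask_win[mask_codes == b], minlength=W)
        denom = xs + ys
        flags = denom == 0
        values = np.divide(xs - ys, denom, out=np.zeros(W, dtype=float), where=~flags)
        return SkewSeries(name, values, starts, ends, L, False, flags, xs, ys)

    whole = counted(codes, win_of, pair.name)
    coding_s = counted(codes[coding], win_of[coding], f"{pair.name}:coding")
    noncoding_s = counted(codes[~coding], win_of[~coding], f"{pair.name}:noncoding")
    p3 = _gc3_positions(genome)
    gc3_s = counted(codes[p3], win_of[p3], f"{pair.name}:gc3")
    return {"whole": whole, "coding": coding_s, "noncoding": noncoding_s, "gc3": gc3_s}


# ---------------------------------------------------------------------------
# Eukaryotic S profile
# ---------------------------------------------------------------------------


@dataclass
class SProfile:
    """Windowed S = S_AT + S_GC profile with S_GC=(G-C)/(G+C), S_AT=(T-A)/(T+A)."""

    positions: np.ndarray
    s_gc: np.ndarray
    s_at: np.ndarray
    s: np.ndarray
    window_size: int
    genome_length: int
    circular: bool


def s_profile(genome: AnnotatedGenome, window_size: int = 1000) -> SProfile:
    L = len(genome)
    n = max(L // window_size, 1)
    starts, ends = _tiling(L, n) if n >= 2 else (np.array([0]), np.array([L]))
    prefix = _prefix_counts(genome.codes)
    counts = _range_counts(prefix, starts, ends, L)
    a, c, g, t = (counts[:, i].astype(float) for i in range(4))
    with np.errstate(invalid="ignore", divide="ignore"):
        s_gc = np.where(g + c > 0, (g - c) / (g + c), 0.0)
        s_at = np.where(t + a > 0, (t - a) / (t + a), 0.0)
    return SProfile(starts, s_gc, s_at, s_gc + s_at, window_size, L,
                    genome.is_circular)


def delta_s(profile: SProfile, origin: int, flank: int) -> float:
    """Mean S over [origin - flank, origin) minus mean S over [origin, origin + flank)."""
    L = profile.genome_length
    w = profile.window_size
    if flank <= w:
        raise ValueError("flank must exceed the window size")
    if 2 * flank > L:
        raise ValueError("flank exceeds half the sequence length")
    starts = profile.positions
    if profile.circular:
        rel_up = (starts - (origin - flank)) % L
        rel_dn = (starts - origin) % L
    else:
        rel_up = starts - (origin - flank)
        rel_dn = starts - origin
    up = (rel_up >= 0) & (rel_up + w <= flank)
    dn = (rel_dn >= 0) & (rel_dn + w <= flank)
    if not up.any() or not dn.any():
        raise ValueError("no complete windows in one of the flanks")
    return float(profile.s[up].mean() - profile.s[dn].mean())
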