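"""Origin/terminus prediction from cumulative skew and leading/lagging mapping.

Under the ``(C - G)/(C + G)`` convention the leading strand shows a
G-excess, so walking forward from the origin along the replichore where
the forward strand is leading, the cumulative GC skew *decreases*.  The
origin is therefore the global maximum of the cumulative series and the
terminus its global minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import AnnotatedGenome, GeneAnnotation
from .skew import GC, BasePair, SkewSeries, get_pair, windowed_skew


@dataclass(frozen=True)
class ReplichoreMap:
    """Origin/terminus positions inducing a leading/lagging strand map.

    The arc walked forward from ``ori`` to ``ter`` is the replichore on
    which the *forward* strand is the leading strand.
    """

    ori: int
    ter: int
    genome_length: int

    def __post_init__(self) -> None:
        L = self.genome_length
        if not (0 <= self.ori < L and 0 <= self.ter < L):
            raise ValueError("ori/ter outside [0, L)")
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")

    def forward_is_leading(self, position: int) -> bool:
        """True on the arc [ori, ter) walking forward (ties go to the arc
        starting at the boundary position)."""
        L = self.genome_length
        return (position - self.ori) % L < (self.ter - self.ori) % L

    def classify(self, position: int, strand: int) -> str:
        if strand not in (+1, -1):
            raise ValueError("strand must be +1 or -1")
        leading_fwd = self.forward_is_leading(position % self.genome_length)
        return "leading" if (strand == 1) == leading_fwd else "lagging"


@dataclass
class OriTerResult:
    ori: int
    ter: int
    confidence: float      # raw_confidence * arc_balance
    raw_confidence: float  # (max - min) of the cumulative series / W
    arc_balance: float     # 4 a (1 - a), a = shorter-arc fraction
    map: ReplichoreMap
    cumulative: SkewSeries
    pair: str
    lowpass: float | None = None


def lowpass_filter(values: np.ndarray, percent: float) -> np.ndarray:
    """FFT low-pass: keep components 0..floor((100-p)/100 * N/2) and their
    conjugate partners, zero the rest, inverse-transform."""
    if not (0 < percent < 100):
        raise ValueError("lowpass percent must be in (0, 100)")
    N = len(values)
    keep = int((100 - percent) / 100 * (N / 2))
    spectrum = np.fft.fft(values)
    mask = np.zeros(N, dtype=bool)
    mask[: keep + 1] = True
    if keep >= 1:
        mask[-keep:] = True
    return np.real(np.fft.ifft(np.where(mask, spectrum, 0)))


def find_ori_ter(genome: AnnotatedGenome, pair: str | BasePair = GC,
                 W: int = 2048, lowpass: float | None = None) -> OriTerResult:
    """Predict origin and terminus from the cumulative windowed skew.

    ori is the window-start position of the global maximum of the
    cumulative (C-G)/(C+G) series and ter that of the global minimum
    (first index on ties).  ``lowpass=p`` FFT-filters the windowed series,
    retaining the lowest (100-p)% of frequency components, before
    accumulation.  Confidence is the cumulative max-min range per window,
    scaled by the arc-balance penalty 4a(1-a).
    """
    if not genome.is_circular:
        raise ValueError(
            "find_ori_ter requires a circular genome; for linear sequences "
            "use s_profile/delta_s around a known origin"
        )
    pair = get_pair(pair)
    W = min(W, len(genome))
    series = windowed_skew(genome, pair, W=W)
    values = series.values
    if lowpass is not None:
        values = lowpass_filter(values, lowpass)
    cum = np.cumsum(values)
    imax = int(np.argmax(cum))
    imin = int(np.argmin(cum))
    ori = int(series.window_starts[imax])
    ter = int(series.window_starts[imin])
    raw = float((cum[imax] - cum[imin]) / W)
    L = len(genome)
    if ori == ter:
        # degenerate (e.g. constant series): no shift points
        ter = (ori + L // 2) % L
        raw = 0.0
    a = min((ter - ori) % L, (ori - ter) % L) / L
    balance = 4 * a * (1 - a)
    cum_series = SkewSeries(pair.name, cum, series.window_starts,
                            series.window_ends, L, True, series.flags,
                            series.x_counts, series.y_counts)
    return OriTerResult(ori, ter, raw * balance, raw, balance,
                        ReplichoreMap(ori, ter, L), cum_series, pair.name,
                        lowpass)


def classify_gene(rmap: ReplichoreMap, gene: GeneAnnotation) -> str:
    """Leading/lagging class of a gene from its midpoint and strand."""
    return rmap.classify(gene.midpoint(rmap.genome_length), gene.strand)
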