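# Methods

This note records the models and conventions the package implements, the
choices made where the underlying methods are underspecified, and what
the synthetic-genome validation does and does not demonstrate.

## Skew conventions

All scalar and windowed skews use (#X − #Y)/(#X + #Y) with the pair
definitions GC → X=C, Y=G and AT → X=T, Y=A; purine (G,A vs C,T), keto
(G,T vs A,C) and amino (A,C vs G,T) contrasts are set-based analogues.
Under this convention a leading-strand G-excess makes the GC skew
*negative*, so the cumulative GC skew attains its **maximum at the
replication origin** and its **minimum at the terminus**. The eukaryotic
S profile is the one deliberate exception: there S_GC = (G−C)/(G+C) and
S_AT = (T−A)/(T+A), following the sign convention that literature prints;
the two conventions are opposite in sign and we keep each local to its
context rather than reconciling them.

Bases outside {A,C,G,T} are normalized to N and excluded from every
numerator and denominator. Zero-denominator windows report a value of 0
plus a flag (never NaN), keeping cumulative sums and FFT inputs finite.

Windowing: the canonical form tiles the genome into W non-overlapping
windows of ⌊L/W⌋ bp (remainder absorbed by the last window); sliding
windows exist for plotting only. Genes are assigned to windows by
midpoint. Coordinates are 0-based half-open internally and 1-based
inclusive in CLI output.

## Replichore mapping and ΔGC skew

`find_ori_ter` takes ori as the window-start of the cumulative-series
global maximum and ter as that of the minimum (first index on ties), with
optional FFT low-pass filtering of the windowed series (retaining the
lowest (100−p)% of components) before accumulation. Confidence is the
cumulative max−min range per window; because replichores need not be
symmetric, it is additionally scaled by the arc-balance penalty 4a(1−a)
(a = shorter-arc fraction) and both values are reported — pseudo-shift
points from inversions or horizontally transferred material typically
produce unbalanced arcs.

A gene is *leading* when its coding strand is the continuously
synthesized strand of its replichore: forward-strand genes on the arc
walked forward from ori to ter, reverse-strand genes on the other arc.
Midpoints exactly on a boundary belong to the arc starting there.

ΔGC skew (`method="all"`) contrasts the two replichores using each arc's
leading-strand sequence read in the replication direction; since
complementation swaps the X and Y base sets for every supported pair, the
lagging pool is the exact reverse complement of the leading pool and
Δ = 2·skew(leading pool). An `arc_mode="forward"` option contrasts the
two forward-strand arcs instead, matching what skew plots show; the two
agree in magnitude in expectation. `method="gene"` averages per-gene
coding-strand skews unweighted by length, exactly as the defining
summation is written; `gc3`/`degenerate` pool third-codon-position bases
per class (the latter restricted to the eight standard-code four-fold
families GCN, CGN, GGN, CTN, CCN, TCN, ACN, GTN; stop codons always
excluded). For B_II, x_c and y_c are the *unweighted* means of the two
class values — matching the symmetric role of the classes — not the
pooled-gene means.

## LDA predictability

The discriminant is a two-class Fisher LDA with equal priors on the
pooled within-class covariance, ridge-shrunk toward its diagonal scale
(λ = 10⁻⁶, raised to 10⁻³ on numerical failure); compositional features
(fractions summing to 1) make the covariance rank-deficient, which the
shrinkage absorbs. The headline predictability is the in-sample
(resubstitution) accuracy, since that is how the score is used in the
literature this implements; a 5-fold cross-validated accuracy is reported
alongside as an honesty check. Fitting requires at least max(10, d+2)
genes. Origin localization scans a grid of candidate boundaries (default
64, each paired with its antipode), refits the discriminant under the
induced labeling, and takes the argmax of accuracy; which end of the
winning pair is the origin is resolved by requiring forward-strand
G-excess on the ori→ter arc.

## Oligomer skew

Occurrence counting is overlapping, wraps the circular junction, counts
only words fully inside the evaluated arc, and skips N-containing words.
Each complementary pair {i, revcomp(i)} contributes once (representative
chosen as the smaller 2-bit encoding); palindromes are excluded since a
self-complementary word cannot carry strand information; odd lengths are
all eligible. The S_p evaluation uses window fractions {50, 55, 60, 65,
70}% of the genome anchored at the candidate origin; "normalized to the
60% scale" is implemented as linear count rescaling by 0.60/f before
taking the median across fractions, on the grounds that counts scale
linearly with region length under stationarity — this normalization and
the default 200-position evaluation grid are interpretations, both
exposed as parameters. k_max defaults to 8 ("up to octamers"); k_max > 12
is refused.

Under no bias the S/N ratio sits at its floor: with the full octamer
range, unbiased 100 kb genomes give S/N ≈ 1.04–1.07. At strongly reduced
oligomer ranges (k_max = 4) the null S/N is noticeably noisier (~1.4–1.9
at 100 kb) because far fewer pairs are summed; the bound S/N ≥ 1 is exact
in all cases. Tests that assert the near-1 null therefore use k_max = 8,
while speed-constrained recovery tests use k_max = 4.

## GCSI

GCSI = √(k₁·SA · k₂·dist_norm) with k₁ = 1/6000, k₂ = 1/600;
SA = k₄·(k₃·PS(1))^α with k₃ = 6·10⁵, k₄ = 40, α = 0.4; and
dist_norm = |ΔGCskew_all|·4096/W, with the arcs bounded by the extrema of
the cumulative windowed skew. PS(1) is taken from the **unnormalized**
forward DFT (no 1/N factor); the published empirical constants are
consistent with this reading. The absolute value in dist_norm makes the
index orientation-independent, and PS is magnitude-based, so GCSI is
invariant under reverse complement and (up to window quantization) under
rotation.

Window-number dependence: with the unnormalized DFT, SA scales as W^0.8
and dist_norm as W^−1, so GCSI drifts as W^−0.1 — about 7% per doubling
of W. This is the closest-to-invariant reading of the definition; W =
2048 is the recommended default for chromosome-scale genomes (windows ≳ 1
kb, averaging out gene-level effects) and W ≥ 32 for plasmids, and
reported GCSI values should quote W.

Significance: the null permutes the W window-level skew values (carrying
their base counts), preserving the marginal skew distribution while
destroying the spatial sine arrangement that SA detects; a
nucleotide-shuffling null is available as an option. The p-value is the
one-sided upper tail of the z-score of the observed GCSI against the
permutation null (bias can only raise GCSI above a null built from the
same values). Default 1000 permutations, seeded. On unbiased genomes the
fraction of p < 0.05 over repeated runs is close to nominal. A
rolling-circle genome (uniform polarity) shows the documented signature:
monotone cumulative skew, hence high dist_norm, low SA, and a
non-significant p-value.

## Synthetic genomes

The generator emits forward-strand bases i.i.d. per position: on the arc
where the forward strand is leading, P(G) = p_G + δ and P(C) = p_C − δ,
mirrored on the other arc (modes: unbiased δ = 0 everywhere;
rolling-circle one polarity genome-wide; N-shaped with δ decaying
linearly to 0 at ± one flank from the origin, for the eukaryotic S/ΔS
profile). Genes are packed without overlap inside the two arcs — never
spanning ori or ter, so leading/lagging labels are exact — with strand
drawn leading with probability `orientation_bias`, and bodies emitted
codon-wise (ATG … TAA) from class-specific tables over the 61 sense
codons. Two knobs shape the class tables: δ shifts the third-position
base probabilities (G,T up / A,C down on the leading strand, mirrored on
the lagging), so that B_I and GC3-based indices respond to the same bias
parameter as the intergenic composition; `codon_delta` additionally
re-weights codons by third-base class, giving codon-level separability
for the LDA without changing first/second-position composition much.

Defaults model a small bacterial chromosome: L = 1 Mb, antipodal ori/ter,
δ = 0.05 (windowed skews of a few percent, in the range of typical
eubacteria), 200 genes of mean length 900 bp, orientation bias 0.7
(genes preferentially leading, below the ~0.9 extreme observed in highly
biased Firmicutes). Every expected index value implied by the emission
probabilities (leading-arc skew, ΔGC variants, B_I components) is
computed by an independent closed-form routine and stored in the truth
record; tests check convergence of the measured indices to these values.

Because emission is i.i.d., the generator reproduces *compositional*
structure only: no Markov correlation, no motif content beyond explicit
`inject_oligomer` calls, no length/essentiality/expression covariates, no
replication-age gradients. Passing tests therefore demonstrate
correctness of the measures on composition-driven bias, not performance
on the full complexity of real genomes — in particular, real genomes can
present pseudo-shift points (inversions, HGT) that the i.i.d. model never
produces; the arc-balance penalty exists for that case but is exercised
only lightly.

## Problem sizes and test design

Recovery tests use 500 kb genomes with δ = 0.1 and 300 genes (origin
recovery within 2% of L by cumulative skew, S_p argmax, and LDA
localization; 100% leading/lagging classification away from a boundary
margin of 2% + one window). Null calibrations use 100 kb (S/N), 1.2 Mb ×
1000 genes (LDA at random labels), and 2 Mb × 10 seeds (GCSI ≤ 0.05);
p-value uniformity uses 200 runs of 50 kb genomes at W = 128 with 200
permutations. Monotonicity of GCSI, |ΔGC|, B_I and S/N across
δ ∈ {0, 0.05, 0.10} is asserted on 20-seed medians at 200 kb. These sizes
keep the full suite under a minute while leaving every stochastic
assertion several standard errors of headroom.

The single real-data anchor — GCSI of E. coli K-12 MG1655 (RefSeq
NC_000913) equal to 0.096 ± 0.01 at default settings — runs only when a
local copy of the sequence is provided under `data/`, since the genome is
too large to ship and the test environment has no network access; the
test reports its absence as a failure rather than silently passing. This
check is the designated detector for the DFT-normalization reading
described above.

## Known limitations

- Single-record genomes only; no multi-contig assemblies, no EMBL format.
- Standard genetic code only (four-fold degeneracy families fixed).
- The LDA covariance treatment and the exact S_p normalization/grid are
  documented interpretations of underspecified procedures.
- GCSI's empirical constants are taken as given, not re-derived; archaeal
  multi-origin variants are out of scope.
- The permutation scheme behind published GCSI p-values is not public;
  ours is a documented choice and p-values should be compared only within
  this implementation.
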