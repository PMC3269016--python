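"""Synthetic biased-genome generator with analytic ground truth.

Emulates the compositional consequences of bacterial replication: two
replichores of opposite polarity with a per-base G-over-C excess ``delta``
on the leading strand, gene orientation bias toward the leading strand,
and class-specific codon usage.  Degenerate modes produce unbiased
genomes, rolling-circle genomes (uniform polarity), and "N-shaped"
eukaryote-like origins where the bias decays with distance from the
origin.  Bases are emitted i.i.d. per position, so every downstream index
has a closed-form expected value, computed independently by
:func:`expected_values` and stored in the truth record.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._util import revcomp
from .genome import AnnotatedGenome, GeneAnnotation, STOP_CODONS
from .lda import SENSE_CODONS

MODES = ("replichore", "unbiased", "rolling_circle", "nshape")

_BASE_ORDER = "ACGT"


@dataclass
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome; ``delta`` is the per-base
    leading-strand G-excess probability shift."""

    L: int = 1_000_000
    ori: int | None = None          # default L // 4
    ter: int | None = None          # default 3L // 4
    delta: float = 0.05
    base_probs: tuple = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    gene_count: int = 200
    gene_len_mean: int = 900        # bp, multiple of 3 after rounding
    orientation_bias: float = 0.7   # P(gene is on its local leading strand)
    codon_delta: float = 0.0        # codon-usage shift between strand classes
    mode: str = "replichore"
    nshape_flank: int | None = None  # default L // 4
    topology: str = "circular"
    seed: int = 0

    def resolved(self) -> "SyntheticGenomeSpec":
        spec = SyntheticGenomeSpec(**asdict(self))
        if spec.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if spec.ori is None:
            spec.ori = spec.L // 4
        if spec.ter is None:
            spec.ter = 3 * spec.L // 4
        if spec.nshape_flank is None:
            spec.nshape_flank = spec.L // 4
        if spec.mode == "unbiased":
            spec.delta = 0.0
        if abs(sum(spec.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        pA, pC, pG, pT = spec.base_probs
        if min(pC - abs(spec.delta), pG - abs(spec.delta)) < 0:
            raise ValueError("delta exceeds background G/C probability")
        if not 0 <= spec.orientation_bias <= 1:
            raise ValueError("orientation_bias must be in [0, 1]")
        return spec


def _class_codon_table(spec: SyntheticGenomeSpec, leading: bool) -> np.ndarray:
    """Codon emission probabilities over the 61 sense codons for one class.

    Third-position base probabilities carry the replication shift (+delta
    to G and T, -delta to A and C on the leading strand, mirrored on the
    lagging strand); ``codon_delta`` additionally re-weights codons whose
    third base is G/T up (leading) or down (lagging).
    """
    pA, pC, pG, pT = spec.base_probs
    sign = 1.0 if leading else -1.0
    d = sign * spec.delta
    p12 = {"A": pA, "C": pC, "G": pG, "T": pT}
    p3 = {"A": pA - d, "C": pC - d, "G": pG + d, "T": pT + d}
    if min(p3.values()) < 0:
        raise ValueError("delta too large for third-position probabilities")
    w = np.empty(len(SENSE_CODONS))
    for i, codon in enumerate(SENSE_CODONS):
        s = 1.0 if codon[2] in "GT" else -1.0
        w[i] = (p12[codon[0]] * p12[codon[1]] * p3[codon[2]]
                * (1.0 + sign * spec.codon_delta * s))
    if w.min() < 0:
        raise ValueError("codon_delta too large")
    return w / w.sum()


def _background_codes(spec: SyntheticGenomeSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw the intergenic forward strand, position by position."""
    L = spec.L
    pA, pC, pG, pT = spec.base_probs
    d_gc = np.zeros(L)
    d_at = np.zeros(L)
    if spec.mode == "replichore":
        lead = (np.arange(L) - spec.ori) % L < (spec.ter - spec.ori) % L
        d_gc = np.where(lead, spec.delta, -spec.delta)
    elif spec.mode == "rolling_circle":
        d_gc += spec.delta
    elif spec.mode == "nshape":
        pos = np.arange(L)
        flank = spec.nshape_flank
        if spec.topology == "circular":
            up = (spec.ori - pos) % L
            dn = (pos - spec.ori) % L
        else:
            up = spec.ori - pos
            dn = pos - spec.ori
        wu = np.where((up > 0) & (up <= flank), 1 - up / flank, 0.0)
        wd = np.where((dn >= 0) & (dn < flank), 1 - dn / flank, 0.0)
        w = wu - wd
        d_gc = spec.delta * w
        d_at = spec.delta * w
    # per-position thresholds over the order A, C, G, T
    t1 = pA - d_at
    t2 = t1 + pC - d_gc
    t3 = t2 + pG + d_gc
    u = rng.random(L)
    return ((u >= t1).astype(np.int8) + (u >= t2) + (u >= t3)).astype(np.int8)


def _place_genes(spec: SyntheticGenomeSpec, rng: np.random.Generator):
    """Non-overlapping gene intervals that never span ori or ter."""
    L = spec.L
    if spec.mode == "rolling_circle":
        arcs = [(0, L)]  # single replichore: everything is leading-forward
    else:
        arcs = [(spec.ori, (spec.ter - spec.ori) % L),
                (spec.ter, (spec.ori - spec.ter) % L)]
    n_codons = np.maximum(
        12, np.rint(rng.normal(spec.gene_len_mean / 3,
                               spec.gene_len_mean / 12,
                               spec.gene_count)).astype(int))
    lengths = 3 * n_codons
    arc_lens = np.array([a[1] for a in arcs], dtype=float)
    arc_of = rng.choice(len(arcs), size=spec.gene_count,
                        p=arc_lens / arc_lens.sum())
    genes = []
    gid = 0
    for ai, (arc_start, arc_len) in enumerate(arcs):
        lens = lengths[arc_of == ai]
        free = arc_len - int(lens.sum())
        if free < len(lens) + 1:
            raise ValueError("infeasible gene packing: arcs too crowded")
        gaps = rng.multinomial(free, np.full(len(lens) + 1,
                                             1.0 / (len(lens) + 1)))
        cursor = arc_start
        for glen, gap in zip(lens, gaps[:-1]):
            start = (cursor + int(gap)) % L
            end = (start + int(glen)) % L
            on_leading = rng.random() < spec.orientation_bias
            fwd_is_leading = ai == 0  # arc 0: forward strand is leading
            strand = 1 if on_leading == fwd_is_leading else -1
            genes.append((GeneAnnotation(f"gene_{gid:04d}", start,
                                         end if end != 0 else L, strand),
                          "leading" if on_leading else "lagging"))
            gid += 1
            cursor += int(gap) + int(glen)
    genes.sort(key=lambda t: t[0].start)
    return genes


def _emit_gene(codons: int, table: np.ndarray,
               rng: np.random.Generator) -> str:
    body = rng.choice(len(SENSE_CODONS), size=codons - 2, p=table)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


def generate(spec: SyntheticGenomeSpec) -> tuple[AnnotatedGenome, dict]:
    """Generate a genome and its ground-truth record (deterministic per seed)."""
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    codes = _background_codes(spec, rng)
    genes: list[GeneAnnotation] = []
    gene_truth = []
    if spec.gene_count > 0 and spec.mode != "nshape":
        tables = {"leading": _class_codon_table(spec, True),
                  "lagging": _class_codon_table(spec, False)}
        placed = _place_genes(spec, rng)
        L = spec.L
        for gene, cls in placed:
            glen = gene.length(L)
            cds = _emit_gene(glen // 3, tables[cls], rng)
            if gene.strand == -1:
                cds = revcomp(cds)
            pos = (gene.start + np.arange(glen)) % L
            codes[pos] = [_BASE_ORDER.index(b) for b in cds]
            genes.append(gene)
            gene_truth.append({"id": gene.id, "start": gene.start,
                               "end": gene.end, "strand": gene.strand,
                               "class": cls})
    sequence = codes_to_str(codes)
    genome = AnnotatedGenome(sequence, spec.topology, genes,
                             id=f"synth_{spec.mode}_seed{spec.seed}")
    truth = {
        "mode": spec.mode, "L": spec.L, "ori": spec.ori, "ter": spec.ter,
        "delta": spec.delta, "codon_delta": spec.codon_delta,
        "orientation_bias": spec.orientation_bias, "seed": spec.seed,
        "base_probs": list(spec.base_probs), "genes": gene_truth,
        "expected": expected_values(spec), "injected": [],
    }
    return genome, truth


def codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes.astype(np.int8)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Closed-form expectations (independent of the sampling path)
# ---------------------------------------------------------------------------


def _table_marginal(table: np.ndarray, position: int) -> dict[str, float]:
    out = {b: 0.0 for b in _BASE_ORDER}
    for p, codon in zip(table, SENSE_CODONS):
        out[codon[position]] += float(p)
    return out


def expected_values(spec: SyntheticGenomeSpec) -> dict:
    """Analytic expected indices implied by the emission probabilities."""
    spec = spec.resolved()
    pA, pC, pG, pT = spec.base_probs
    d = spec.delta if spec.mode in ("replichore", "rolling_circle") else 0.0
    bg_lead = {"A": pA, "C": pC - d, "G": pG + d, "T": pT}

    out: dict = {}
    skew_bg = ((bg_lead["C"] - bg_lead["G"])
               / max(bg_lead["C"] + bg_lead["G"], 1e-12))
    out["leading_gc_skew_intergenic"] = skew_bg
    out["delta_gcskew_all_intergenic"] = 2 * skew_bg

    if spec.gene_count > 0 and spec.mode != "nshape":
        t_lead = _class_codon_table(spec, True)
        t_lag = _class_codon_table(spec, False)
        mean_codons = spec.gene_len_mean / 3
        # third-position composition incl. the fixed ATG/TAA per gene
        def third(table: np.ndarray) -> dict[str, float]:
            m = _table_marginal(table, 2)
            body = mean_codons - 2
            return {b: (body * m[b] + (b == "G") + (b == "A"))
                    / (body + 2) for b in _BASE_ORDER}

        e3_lead, e3_lag = third(t_lead), third(t_lag)
        skew3 = lambda e: (e["C"] - e["G"]) / (e["C"] + e["G"])
        out["delta_gcskew_gc3"] = skew3(e3_lead) - skew3(e3_lag)
        x = lambda e: e["G"] / (e["G"] + e["C"])
        y = lambda e: e["T"] / (e["T"] + e["A"])
        out["x_leading"], out["x_lagging"] = x(e3_lead), x(e3_lag)
        out["y_leading"], out["y_lagging"] = y(e3_lead), y(e3_lag)
        out["b1"] = float(np.hypot(x(e3_lead) - x(e3_lag),
                                   y(e3_lead) - y(e3_lag)))

        # forward-strand composition of the arc where forward is leading
        ob = spec.orientation_bias
        coding_frac = min(spec.gene_count * spec.gene_len_mean / spec.L, 1.0)

        def coding_fwd(base: str) -> float:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
            p_lead = np.mean([_table_marginal(t_lead, j)[base]
                              for j in range(3)])
            p_lag_rc = np.mean([_table_marginal(t_lag, j)[comp]
                                for j in range(3)])
            return ob * p_lead + (1 - ob) * p_lag_rc

        fwd = {b: (1 - coding_frac) * bg_lead[b] + coding_frac * coding_fwd(b)
               for b in _BASE_ORDER}
        skew_arc = float((fwd["C"] - fwd["G"]) / (fwd["C"] + fwd["G"]))
        out["leading_gc_skew"] = skew_arc
        out["delta_gcskew_all"] = 2 * skew_arc
    else:
        out["delta_gcskew_all"] = out["delta_gcskew_all_intergenic"]
        out["leading_gc_skew"] = skew_bg
    return out


# ---------------------------------------------------------------------------
# Oligomer injection and truth IO
# ---------------------------------------------------------------------------


def inject_oligomer(genome: AnnotatedGenome, truth: dict, oligomer: str,
                    fold: float, seed: int = 0) -> AnnotatedGenome:
    """Plant extra leading-strand copies of a non-palindromic oligomer.

    round(fold * expected) copies are written at random non-gene positions
    (expected = L / 4^k occurrences genome-wide under uniform composition);
    on the replichore where the forward strand is lagging, the reverse
    complement is written so the oligomer itself sits on the leading
    strand.  The injection is recorded in the truth record.
    """
    oligomer = oligomer.upper()
    if oligomer == revcomp(oligomer):
        raise ValueError("palindromic oligomer cannot create strand asymmetry")
    L = len(genome)
    k = len(oligomer)
    n = int(round(fold * L / 4 ** k))
    if n == 0:
        return genome
    rng = np.random.default_rng(seed)
    ori, ter = truth["ori"], truth["ter"]
    arc_a = (ter - ori) % L
    occupied = np.zeros(L, dtype=bool)
    for g in genome.genes:
        span = (g.start + np.arange(g.length(L))) % L
        occupied[span] = True
    seq = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8).copy()
    fwd = np.frombuffer(oligomer.encode("ascii"), dtype=np.uint8)
    rev = np.frombuffer(revcomp(oligomer).encode("ascii"), dtype=np.uint8)
    placed = 0
    attempts = 0
    while placed < n and attempts < 100 * n:
        attempts += 1
        start = int(rng.integers(0, L))
        span = (start + np.arange(k)) % L
        if occupied[span].any():
            continue
        rel = (start - ori) % L
        # keep the site inside one replichore
        if rel < arc_a:
            if rel + k > arc_a:
                continue
            seq[span] = fwd
        else:
            if rel + k > L:
                continue
            seq[span] = rev
        occupied[span] = True
        placed += 1
    if placed < n:
        raise ValueError("could not place all oligomer copies")
    truth["injected"].append({"oligomer": oligomer, "fold": fold,
                              "copies": placed, "seed": seed})
    return AnnotatedGenome(seq.tobytes().decode("ascii"), genome.topology,
                           list(genome.genes), id=genome.id)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=float)


def load_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
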