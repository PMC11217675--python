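"""Synthetic benchmarks with the compositional structure the method exploits.

Real UCNEs differ from bulk genome in three ways this package's features
pick up: lower GC content (about 37% vs 42%), enrichment of the GpC
dinucleotide alongside depletion of CC and GG, and a characteristic
excess of dinucleotide pairs spaced at L=4 (two spacer bases).  The
generator reproduces each knob independently:

* a first-order Markov chain whose stationary distribution is solved to
  hit a target GC content and target GpC / (CC+GG) fold-changes relative
  to the independence baseline at that GC;
* lengths from a discretized log-normal clipped to [200, 1000] nt with
  mode near 300 nt, mimicking the real UCNE length distribution;
* optional motif planting: L=4 pair patterns written over the sequence at
  a chosen rate per kb (wildcard positions filled uniformly), keeping
  length exact.

A toy ClinVar-style VCF generator rounds out the fixtures so the
Monte-Carlo variant analysis is testable without downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize

from .patterns import F3_PAIRS, Motif
from .seqio import MaskedSequence

_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class LengthModel:
    """Discretized log-normal fragment-length model, clipped to [min, max]."""

    min: int = 200
    mode: int = 300
    max: int = 1000
    sigma: float = 0.45  # log-scale sd; controls the right tail

    def __post_init__(self) -> None:
        if not (self.min <= self.mode <= self.max):
            raise ValueError("require min <= mode <= max")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # mode of lognormal(mu, sigma) is exp(mu - sigma^2)
        mu = np.log(self.mode) + self.sigma**2
        lengths = rng.lognormal(mu, self.sigma, size=n)
        return np.clip(np.round(lengths), self.min, self.max).astype(int)


@dataclass(frozen=True)
class CompositionSpec:
    """First-order Markov composition: conditional next-base matrix plus
    initial distribution, a length model, and optional planted motifs
    given as (motif, insertions per kb)."""

    dinucleotide_probs: tuple[tuple[float, ...], ...]
    initial_probs: tuple[float, ...]
    length_model: LengthModel = LengthModel()
    planted_motifs: tuple[tuple[Motif, float], ...] = ()

    def __post_init__(self) -> None:
        P = np.asarray(self.dinucleotide_probs, dtype=float)
        if P.shape != (4, 4) or np.any(P < 0):
            raise ValueError("dinucleotide_probs must be a non-negative 4x4 matrix")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of dinucleotide_probs must sum to 1")
        p0 = np.asarray(self.initial_probs, dtype=float)
        if p0.shape != (4,) or not np.isclose(p0.sum(), 1.0, atol=1e-9):
            raise ValueError("initial_probs must be a 4-vector summing to 1")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.dinucleotide_probs, dtype=float)

    def stationary(self) -> np.ndarray:
        """Stationary base distribution pi of the transition matrix."""
        return stationary_distribution(self.matrix)

    def stationary_dinucleotides(self) -> np.ndarray:
        """Stationary dinucleotide frequencies pi_i * P[i, j] (4x4)."""
        pi = self.stationary()
        return pi[:, None] * self.matrix

    def to_dict(self) -> dict:
        return {
            "dinucleotide_probs": [list(r) for r in self.dinucleotide_probs],
            "initial_probs": list(self.initial_probs),
            "length_model": {"min": self.length_model.min,
                             "mode": self.length_model.mode,
                             "max": self.length_model.max,
                             "sigma": self.length_model.sigma},
            "planted_motifs": [[m.pattern, rate] for m, rate in self.planted_motifs],
        }


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 4-state stochastic matrix (left
    eigenvector of eigenvalue 1, normalized)."""
    # solve pi (P - I) = 0 with sum(pi) = 1 as a least-squares system; this
    # is smooth in P, which matters for the root solver in spec_from_targets
    A = np.vstack([P.T - np.eye(4), np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def spec_from_targets(gc_percent: float, gpc_enrichment: float = 1.0,
                      ccgg_depletion: float = 1.0,
                      length_model: LengthModel = LengthModel(),
                      planted_motifs: Sequence[tuple[Motif, float]] = (),
                      ) -> CompositionSpec:
    """Solve for a Markov matrix with prescribed stationary composition.

    Targets: stationary GC content equal to ``gc_percent``; stationary GpC
    frequency equal to ``gpc_enrichment`` times the independence baseline
    at that GC; stationary CC+GG frequency equal to ``ccgg_depletion``
    times its baseline.  The matrix is parametrized as a tilted product
    form and the three tilts are solved numerically against the stationary
    distribution.
    """
    if not (0 < gc_percent < 100):
        raise ValueError("gc_percent must be in (0, 100)")
    if gpc_enrichment <= 0 or ccgg_depletion <= 0:
        raise ValueError("fold changes must be > 0")
    gc = gc_percent / 100.0
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    q_gc = base[_IDX["G"]] * base[_IDX["C"]]
    q_ccgg = base[_IDX["C"]] ** 2 + base[_IDX["G"]] ** 2
    target_gc_dinuc = gpc_enrichment * q_gc
    target_ccgg = ccgg_depletion * q_ccgg

    def build(params: np.ndarray) -> np.ndarray:
        a, b, c = np.exp(params)  # positivity via log-parametrization
        w = base.copy()
        w[[_IDX["C"], _IDX["G"]]] *= c
        M = np.tile(w, (4, 1))
        M[_IDX["G"], _IDX["C"]] *= a
        M[_IDX["C"], _IDX["C"]] *= b
        M[_IDX["G"], _IDX["G"]] *= b
        return M / M.sum(axis=1, keepdims=True)

    def residual(params: np.ndarray) -> np.ndarray:
        M = build(params)
        pi = stationary_distribution(M)
        dinuc = pi[:, None] * M
        return np.array([
            pi[_IDX["C"]] + pi[_IDX["G"]] - gc,
            dinuc[_IDX["G"], _IDX["C"]] - target_gc_dinuc,
            dinuc[_IDX["C"], _IDX["C"]] + dinuc[_IDX["G"], _IDX["G"]] - target_ccgg,
        ])

    x0 = np.log([gpc_enrichment, ccgg_depletion, 1.0])
    sol = optimize.root(residual, x0, method="hybr", tol=1e-12)
    if np.max(np.abs(residual(sol.x))) > 1e-8:
        raise ValueError(
            f"infeasible composition targets gc={gc_percent}, "
            f"gpc={gpc_enrichment}, ccgg={ccgg_depletion}: {sol.message}")
    M = build(sol.x)
    pi = stationary_distribution(M)
    return CompositionSpec(
        dinucleotide_probs=tuple(tuple(row) for row in M),
        initial_probs=tuple(pi),
        length_model=length_model,
        planted_motifs=tuple((m, float(r)) for m, r in planted_motifs),
    )


def _generate_one(spec: CompositionSpec, length: int,
                  rng: np.random.Generator) -> str:
    cum = np.cumsum(spec.matrix, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    state = int(np.searchsorted(np.cumsum(spec.initial_probs), u[0]))
    out[0] = state
    for i in range(1, length):
        state = int(np.searchsorted(cum[state], u[i]))
        out[i] = state
    return "".join(_BASES[b] for b in out)


def _plant(residues: str, spec: CompositionSpec,
           rng: np.random.Generator) -> str:
    """Write planted motifs over the sequence at their per-kb rates.

    Insertion counts are Poisson(rate * length / 1000) per motif; each
    insertion overwrites the underlying bases at a uniform position
    (length unchanged) with wildcards filled uniformly.
    """
    if not spec.planted_motifs:
        return residues
    s = list(residues)
    n = len(s)
    for motif, rate in spec.planted_motifs:
        w = len(motif)
        if w > n:
            continue
        for _ in range(rng.poisson(rate * n / 1000.0)):
            pos = int(rng.integers(n - w + 1))
            for k, char in enumerate(motif.pattern):
                s[pos + k] = char if char != "n" else _BASES[int(rng.integers(4))]
    return "".join(s)


def plant_motifs(seqs: Sequence[MaskedSequence],
                 planted_motifs: Sequence[tuple[Motif, float]],
                 seed: int) -> list[MaskedSequence]:
    """Plant motifs into existing sequences at the given per-kb rates.

    Returns planted copies (same ids/lengths); useful for paired
    signal-vs-background comparisons on identical base sequences.
    """
    rng = np.random.default_rng(seed)
    carrier = CompositionSpec(
        ((0.25,) * 4,) * 4, (0.25,) * 4,
        planted_motifs=tuple((m, float(r)) for m, r in planted_motifs))
    return [MaskedSequence(s.id, _plant(s.residues, carrier, rng))
            for s in seqs]


def markov_generate(spec: CompositionSpec, n: int, seed: int,
                    prefix: str = "synth") -> list[MaskedSequence]:
    """Generate ``n`` sequences from ``spec``; deterministic given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = spec.length_model.sample(n, rng)
    out = []
    for i, length in enumerate(lengths):
        residues = _generate_one(spec, int(length), rng)
        residues = _plant(residues, spec, rng)
        out.append(MaskedSequence(id=f"{prefix}-{i + 1}", residues=residues))
    return out


def default_positive_spec(gpc_enrichment: float = 1.5,
                          ccgg_depletion: float = 0.7,
                          plant_rate_per_kb: float = 2.0) -> CompositionSpec:
    """UCNE-like composition: GC 37%, GpC enriched, CC+GG depleted, and the
    17 L=4 pair patterns planted at a combined ``plant_rate_per_kb``."""
    per_motif = plant_rate_per_kb / len(F3_PAIRS)
    planted = [(Motif(d1 + "nn" + d2), per_motif) for d1, d2 in F3_PAIRS]
    return spec_from_targets(37.0, gpc_enrichment, ccgg_depletion,
                             planted_motifs=planted)


def default_negative_spec() -> CompositionSpec:
    """Bulk-genome-like composition: GC 42%, neutral dinucleotide folds."""
    return spec_from_targets(42.0, 1.0, 1.0)


@dataclass
class BenchmarkSet:
    """A labeled synthetic benchmark: positives vs negatives plus the specs
    and master seed that produced them."""

    positives: list[MaskedSequence]
    negatives: list[MaskedSequence]
    pos_spec: CompositionSpec
    neg_spec: CompositionSpec
    seed: int

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_positives": len(self.positives),
            "n_negatives": len(self.negatives),
            "pos_spec": self.pos_spec.to_dict(),
            "neg_spec": self.neg_spec.to_dict(),
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2) + "\n")


def make_benchmark(pos_spec: CompositionSpec | None = None,
                   neg_spec: CompositionSpec | None = None,
                   n_per_class: int = 500, seed: int = 0) -> BenchmarkSet:
    """Build a labeled benchmark (default: UCNE-like vs bulk-genome-like)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if pos_spec is None:
        pos_spec = default_positive_spec()
    if neg_spec is None:
        neg_spec = default_negative_spec()
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    return BenchmarkSet(
        positives=markov_generate(pos_spec, n_per_class, int(ss[0]), "pos"),
        negatives=markov_generate(neg_spec, n_per_class, int(ss[1]), "neg"),
        pos_spec=pos_spec, neg_spec=neg_spec, seed=seed,
    )


# ---------------------------------------------------------------------------
# Toy ClinVar-style VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.1
##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">
##contig=<ID={chrom},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def synthetic_snp_vcf(path: str | Path, genome_length: int, n_snps: int,
                      clnsig_proportions: dict[str, float], seed: int,
                      chrom: str = "chrS") -> list[tuple[str, int]]:
    """Write a toy ClinVar-style VCF and return the (chrom, 1-based pos) list.

    SNP positions are drawn uniformly (without replacement) over the
    genome; each record carries CLNSIG with probability given by
    ``clnsig_proportions`` (category -> fraction; the remainder gets no
    CLNSIG key, standing in for variants absent from ClinVar annotation).
    """
    total = sum(clnsig_proportions.values())
    if total > 1 + 1e-9:
        raise ValueError("clnsig_proportions must sum to <= 1")
    if n_snps > genome_length:
        raise ValueError("more SNPs than positions")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(genome_length, size=n_snps, replace=False)) + 1
    cats = list(clnsig_proportions)
    probs = [clnsig_proportions[c] for c in cats] + [1.0 - total]
    assignments = rng.choice(len(cats) + 1, size=n_snps, p=np.clip(probs, 0, None))
    bases = "ACGT"
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom, length=genome_length))
        for i, pos in enumerate(positions):
            ref = bases[int(rng.integers(4))]
            alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
            k = int(assignments[i])
            info = f"CLNSIG={cats[k]}" if k < len(cats) else "."
            fh.write(f"{chrom}\t{pos}\trs{i + 1}\t{ref}\t{alt}\t.\t.\t{info}\n")
    return [(chrom, int(p)) for p in positions]
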