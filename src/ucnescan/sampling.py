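"""Length-matched control sampling and dinucleotide-preserving shuffles.

Two genomic background sets mirror the study design:

* **WGE** (whole-genome elements): random fragments drawn from the genome,
  repeats and all, length-matched fragment-for-fragment to a reference
  set (typically the UCNE set), so both sets share the exact same length
  multiset.
* **uWGE** (unique WGE): the same, but accepted fragments must be free of
  soft-masked (lowercase) residues and of N — repeat-free unique sequence.

Fragments containing N (assembly gaps) are rejected in every mode.

A ``walk`` mode reproduces the same-chromosome sampling variant: starting
from a random origin, successive fragments are taken by advancing a fixed
step (default 5000 nt) down a single contig.

The quasi-random null is an exact dinucleotide-preserving shuffle
(Altschul-Erickson): the output is a uniform draw from all sequences with
identical first and last base and an identical dinucleotide count vector,
via a uniformly random Eulerian path in the dinucleotide multigraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .seqio import MaskedSequence


@dataclass(frozen=True)
class LengthSpec:
    """The multiset of fragment lengths to reproduce (all >= 1)."""

    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.lengths or min(self.lengths) < 1:
            raise ValueError("LengthSpec requires a non-empty list of lengths >= 1")

    @classmethod
    def from_sequences(cls, seqs: Sequence[MaskedSequence]) -> "LengthSpec":
        return cls(tuple(len(s) for s in seqs))

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass(frozen=True)
class Fragment:
    """A sampled fragment plus its provenance coordinates (manifest row)."""

    seq: MaskedSequence
    chrom: str
    start: int
    end: int


class PlacementError(RuntimeError):
    """Raised when a required fragment length cannot be placed."""


def _draw_fragment(genome: Sequence[MaskedSequence], cum: np.ndarray,
                   length: int, rng: np.random.Generator,
                   accept: Callable[[str], bool], max_tries: int = 10_000,
                   ) -> tuple[int, int, str]:
    """Rejection-sample (contig index, start, residues) uniformly over
    eligible start positions genome-wide."""
    total = int(cum[-1])
    for _ in range(max_tries):
        flat = int(rng.integers(total))
        ci = int(np.searchsorted(cum, flat, side="right"))
        start = flat - int(cum[ci - 1]) if ci > 0 else flat
        contig = genome[ci]
        if start + length > len(contig):
            continue
        piece = contig.residues[start:start + length]
        if accept(piece):
            return ci, start, piece
    raise PlacementError(
        f"could not place a fragment of length {length} after {max_tries} tries")


def _sample(genome: Sequence[MaskedSequence], spec: LengthSpec,
            rng: np.random.Generator, accept: Callable[[str], bool],
            prefix: str) -> list[Fragment]:
    genome = list(genome)
    if not genome:
        raise ValueError("empty genome")
    cum = np.cumsum([len(c) for c in genome])
    out = []
    for i, length in enumerate(spec.lengths):
        ci, start, piece = _draw_fragment(genome, cum, length, rng, accept)
        out.append(Fragment(
            seq=MaskedSequence(id=f"{prefix}-{i + 1}", residues=piece),
            chrom=genome[ci].id, start=start, end=start + length))
    return out


def _no_n(piece: str) -> bool:
    return "N" not in piece and "n" not in piece


def _repeat_free(piece: str) -> bool:
    return piece.isupper() and "N" not in piece


def sample_wge(genome: Sequence[MaskedSequence], spec: LengthSpec, seed: int,
               mode: str = "uniform", step: int = 5000,
               with_coords: bool = False):
    """Random genomic fragments whose length multiset equals ``spec`` exactly.

    ``mode="uniform"`` draws start positions uniformly over eligible loci
    genome-wide (overlaps permitted; N-containing placements resampled).
    ``mode="walk"`` picks a random origin on one contig and advances the
    cursor by ``step`` nt between consecutive fragments, erroring if the
    contig is exhausted.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        frags = _sample(genome, spec, rng, _no_n, "WGE")
    elif mode == "walk":
        frags = _walk(genome, spec, rng, step)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return frags if with_coords else [f.seq for f in frags]


def _walk(genome: Sequence[MaskedSequence], spec: LengthSpec,
          rng: np.random.Generator, step: int) -> list[Fragment]:
    genome = list(genome)
    lengths = spec.lengths
    contig = genome[int(rng.integers(len(genome)))]
    span_needed = step * (len(lengths) - 1) + max(lengths)
    if span_needed > len(contig):
        raise PlacementError(
            f"walk of {len(lengths)} fragments at step {step} needs "
            f"{span_needed} nt but contig {contig.id!r} has {len(contig)}")
    cursor = int(rng.integers(len(contig) - span_needed + 1))
    out = []
    for i, length in enumerate(lengths):
        # N placements (assembly gaps) are skipped by stepping onward
        while True:
            if cursor + length > len(contig):
                raise PlacementError(
                    f"walk exhausted contig {contig.id!r} after "
                    f"{len(out)} of {len(lengths)} fragments")
            piece = contig.residues[cursor:cursor + length]
            if _no_n(piece):
                break
            cursor += step
        out.append(Fragment(
            seq=MaskedSequence(id=f"WGE-walk-{i + 1}", residues=piece),
            chrom=contig.id, start=cursor, end=cursor + length))
        cursor += step
    return out


def sample_uwge(genome: Sequence[MaskedSequence], spec: LengthSpec, seed: int,
                with_coords: bool = False):
    """Repeat-free controls: like uniform WGE but accepted fragments contain
    no lowercase (soft-masked) and no N residues."""
    rng = np.random.default_rng(seed)
    frags = _sample(genome, spec, rng, _repeat_free, "uWGE")
    return frags if with_coords else [f.seq for f in frags]


def subset_replicates(pool_sampler: Callable[[int], list],
                      n_subsets: int, seed: int) -> list[list]:
    """``n_subsets`` independent control sets from distinct sub-seeds.

    ``pool_sampler(sub_seed)`` builds one control set; sub-seeds are spawned
    from the master seed so every subset is individually reproducible.
    """
    if n_subsets < 2:
        raise ValueError("n_subsets must be >= 2")
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_subsets) % (2**31)
    return [pool_sampler(int(s)) for s in sub_seeds]


# ---------------------------------------------------------------------------
# Exact dinucleotide-preserving shuffle (Altschul-Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: MaskedSequence | str, seed: int) -> MaskedSequence:
    """Uniform exact dinucleotide-preserving shuffle of ``seq``.

    The sequence is viewed as an Eulerian path in the multigraph whose
    vertices are bases and whose edges are the observed dinucleotides; a
    uniformly random Eulerian path with the same endpoints is drawn by the
    Altschul-Erickson construction (random last-edge arborescence toward
    the final vertex, then random permutation of the remaining edge lists).
    The output therefore has *exactly* the input's dinucleotide count
    vector (hence identical mononucleotide counts and GC content).

    Output is uppercase; input must be N-free and at least 3 nt.
    """
    residues = seq.residues if isinstance(seq, MaskedSequence) else seq
    name = seq.id if isinstance(seq, MaskedSequence) else "shuffled"
    s = residues.upper()
    if "N" in s:
        raise ValueError("dinucleotide_shuffle requires an N-free sequence")
    if len(s) < 3:
        raise ValueError("dinucleotide_shuffle requires length >= 3")
    rng = np.random.default_rng(seed)
    order = dict((b, i) for i, b in enumerate("ACGT"))
    first, last = order[s[0]], order[s[-1]]
    # adjacency lists: edges[u] = list of target vertices, one per dinucleotide
    edges: list[list[int]] = [[] for _ in range(4)]
    for a, b in zip(s[:-1], s[1:]):
        edges[order[a]].append(order[b])
    present = [u for u in range(4) if edges[u] or u == last]

    # Altschul-Erickson: pick one random outgoing "last edge" per vertex
    # (except the end vertex) until those edges form an arborescence into
    # the end vertex; acceptance is fast on a 4-vertex graph.
    while True:
        last_edge = {}
        for u in present:
            if u != last and edges[u]:
                last_edge[u] = edges[u][int(rng.integers(len(edges[u])))]
        ok = True
        for u in last_edge:
            seen, v = {u}, u
            while v != last:
                v = last_edge.get(v, None)
                if v is None or v in seen:
                    ok = False
                    break
                seen.add(v)
            if not ok:
                break
        if ok:
            break

    # shuffle every edge list, then move each reserved last edge to the end
    shuffled: list[list[int]] = []
    for u in range(4):
        lst = list(edges[u])
        if u in last_edge:
            lst.remove(last_edge[u])
        lst = [lst[i] for i in rng.permutation(len(lst))]
        if u in last_edge:
            lst.append(last_edge[u])
        shuffled.append(lst)

    # walk the Eulerian path
    bases = "ACGT"
    out = [bases[first]]
    ptr = [0, 0, 0, 0]
    v = first
    for _ in range(len(s) - 1):
        w = shuffled[v][ptr[v]]
        ptr[v] += 1
        out.append(bases[w])
        v = w
    result = "".join(out)
    assert v == last and all(ptr[u] == len(shuffled[u]) for u in range(4))
    return MaskedSequence(id=name, residues=result)
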