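"""Counting engine for dinucleotide arrangements.

Overlapping motif occurrences (with the single-base wildcard ``n``),
16-way dinucleotide tallies, and spacing-distance profiles between
dinucleotide pairs.

The spacing distance L between two dinucleotides is the difference of
their start positions: L=1 means the dinucleotides intersect (share one
base, e.g. AT and TG in ATG), L=2 means they are adjacent, L=3 leaves
one spacer base, L=4 leaves two.

Counting conventions, used consistently everywhere:

* case-insensitive (soft-masking marks repeats; it does not change the
  sequence content being counted);
* overlapping matches count ("AAA" contains AA twice);
* any window containing N is excluded from both the match count and the
  valid-window denominator, so N-padded fragments do not dilute
  frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .seqio import MaskedSequence

SequenceLike = Union[str, MaskedSequence]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_N_CODE = 4
_CODE[ord("N")] = _N_CODE
_CODE[ord("n")] = _N_CODE

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")


def encode(seq: SequenceLike) -> np.ndarray:
    """Encode residues as uint8 codes A=0 C=1 G=2 T=3 N=4, case-folded."""
    s = seq.residues if isinstance(seq, MaskedSequence) else seq
    arr = _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = int(np.argmax(arr == 255))
        raise ValueError(f"illegal residue {s[bad]!r} at position {bad}")
    return arr


@dataclass(frozen=True)
class Motif:
    """A fixed-width DNA pattern over {A,C,G,T,n}; ``n`` matches any single base
    (never N)."""

    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError(f"motif {self.pattern!r}: length must be >= 2")
        if any(c not in "ACGTn" for c in self.pattern):
            raise ValueError(f"motif {self.pattern!r}: characters must be in ACGTn")
        if sum(c != "n" for c in self.pattern) < 2:
            raise ValueError(f"motif {self.pattern!r}: need >= 2 non-wildcard bases")

    def __len__(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern


@dataclass(frozen=True)
class MotifSet:
    """A named list of unique motifs (e.g. the published F6 4-mer table)."""

    name: str
    motifs: tuple[Motif, ...]

    def __post_init__(self) -> None:
        patterns = [m.pattern for m in self.motifs]
        if len(set(patterns)) != len(patterns):
            raise ValueError(f"motif set {self.name!r}: duplicate motifs")

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)


def _motif_set(name: str, patterns: Sequence[str]) -> MotifSet:
    return MotifSet(name, tuple(Motif(p) for p in patterns))


#: The 17 dinucleotide pairs whose L=4 spacing peak distinguishes UCNEs.
#: Each pair (d1, d2) is examined at L=3 (one spacer, d1nd2) and L=4
#: (two spacers, d1nnd2).
F3_PAIRS: tuple[tuple[str, str], ...] = (
    ("TA", "GA"), ("TA", "GC"), ("TA", "GG"), ("TA", "GT"),
    ("AC", "TA"), ("CC", "TA"), ("GC", "TA"), ("TC", "TA"),
    ("AA", "GC"), ("AT", "GC"), ("GC", "TT"), ("AG", "AT"),
    ("GG", "AT"), ("AG", "GT"), ("AC", "CT"), ("AT", "CT"),
    ("GC", "TC"),
)

F3_L3_MOTIFS = _motif_set("F3_L3", [d1 + "n" + d2 for d1, d2 in F3_PAIRS])
F3_L4_MOTIFS = _motif_set("F3_L4", [d1 + "nn" + d2 for d1, d2 in F3_PAIRS])

#: GC-rich triplets (feature F4).
F4_MOTIFS = _motif_set("F4", ["GGG", "CCC", "GAG", "CCT", "CCA", "CTC", "TGG", "AGG"])

#: AT-rich triplets (feature F5).
F5_MOTIFS = _motif_set("F5", ["TTA", "TAA", "ATT", "AAT"])

#: Adjacent dinucleotide pairs (4-mers) enriched in UCNEs (feature F6).
F6_MOTIFS = _motif_set("F6", [
    "AATT", "TACA", "TTAC", "GTAA", "TTAT", "ATAA", "AATG", "CATT", "ATTA",
    "TAAT", "TCAT", "ATGA", "TTAA", "TCAA", "TTGA", "CAAT", "ATTG",
])

#: One-spacer dinucleotide pairs (wildcard 5-mers) enriched in UCNEs (feature F7).
F7_MOTIFS = _motif_set("F7", [
    "ACnGC", "GCnGT", "ACnGT", "AAnAG", "CTnTT", "TGnCA", "CTnAT", "ATnAG",
    "CAnTA", "TAnTG", "TTnAT", "ATnAA", "TTnTC", "GAnAA", "TAnTA", "GTnAT",
    "ATnAC", "ATnAT",
])


def spacing_distance(start1: int, start2: int) -> int:
    """Spacing distance L between dinucleotides starting at ``start1 < start2``.

    L = start2 - start1, so L=1 means intersected (one shared base),
    L=2 adjacent, L=3 one spacer base, L=4 two spacer bases.
    """
    if start2 <= start1:
        raise ValueError(f"require start2 > start1, got {start1} >= {start2}")
    return start2 - start1


def _window_matches(codes: np.ndarray, motif: Motif) -> np.ndarray:
    """Boolean array over window start positions: True where the motif matches.

    Windows containing N never match; wildcards match A/C/G/T only.
    """
    w = len(motif)
    n = codes.size - w + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    ok = np.ones(n, dtype=bool)
    for offset, char in enumerate(motif.pattern):
        col = codes[offset:offset + n]
        if char == "n":
            ok &= col != _N_CODE
        else:
            ok &= col == _CODE[ord(char)]
    return ok


def count_motif(seq: SequenceLike, motif: Motif | str) -> int:
    """Number of (possibly overlapping) matches of ``motif`` in ``seq``."""
    if isinstance(motif, str):
        motif = Motif(motif)
    return int(_window_matches(encode(seq), motif).sum())


def valid_windows(seq: SequenceLike, width: int) -> int:
    """Number of width-``width`` windows free of N (the frequency denominator)."""
    codes = encode(seq)
    n = codes.size - width + 1
    if n <= 0:
        return 0
    ok = np.ones(n, dtype=bool)
    for offset in range(width):
        ok &= codes[offset:offset + n] != _N_CODE
    return int(ok.sum())


def count_dinucleotides(seq: SequenceLike) -> dict[str, int]:
    """Counts of the 16 ordered dinucleotides over all N-free windows.

    The counts sum to the number of valid dinucleotide windows.
    """
    codes = encode(seq)
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    if codes.size < 2:
        return counts
    a, b = codes[:-1], codes[1:]
    keep = (a != _N_CODE) & (b != _N_CODE)
    idx, n = np.unique(a[keep] * 4 + b[keep], return_counts=True)
    for i, c in zip(idx, n):
        counts[DINUCLEOTIDES[int(i)]] = int(c)
    return counts


@dataclass
class SpacingProfile:
    """Spacing-distance distribution for one dinucleotide pair over a sequence set.

    ``counts[L]`` totals co-occurrences of d1 at position p and d2 at p+L
    across sequences; ``frequencies[L]`` is the mean per-sequence frequency
    (count / valid windows of width L+2); ``sigma[L]`` the across-sequence
    standard deviation of that frequency.  ``band(k)`` returns the
    mean ± k·SEM envelope used when plotting averaged curves.
    """

    pair: tuple[str, str]
    counts: dict[int, int]
    frequencies: dict[int, float]
    sigma: dict[int, float]
    n_sequences: int

    @property
    def lmax(self) -> int:
        return max(self.counts)

    def sem(self, L: int) -> float:
        """Standard error of the mean frequency at distance L."""
        return self.sigma[L] / np.sqrt(self.n_sequences)

    def band(self, L: int, k: float = 3.0) -> tuple[float, float]:
        """(lo, hi) envelope mean ± k·SEM at distance L (default the 99.7% band)."""
        half = k * self.sem(L)
        return self.frequencies[L] - half, self.frequencies[L] + half

    def to_rows(self) -> list[tuple[str, int, int, float, float]]:
        """Rows (pair, L, count, frequency, sigma) for TSV export."""
        tag = "".join(self.pair)
        return [(tag, L, self.counts[L], self.frequencies[L], self.sigma[L])
                for L in sorted(self.counts)]


def pair_cooccurrence(seq: SequenceLike, d1: str, d2: str, lmax: int) -> np.ndarray:
    """Counts of (d1 at p, d2 at p+L) for L = 1..lmax in a single sequence."""
    codes = encode(seq)
    m1 = _window_matches(codes, Motif(d1))
    m2 = _window_matches(codes, Motif(d2))
    out = np.zeros(lmax, dtype=np.int64)
    for L in range(1, lmax + 1):
        if m1.size > L:
            out[L - 1] = int(np.sum(m1[:-L] & m2[L:]))
    return out


def spacing_profile(seqs: Sequence[SequenceLike], d1: str, d2: str,
                    lmax: int = 50) -> SpacingProfile:
    """Spacing-distance profile of the (d1, d2) pair over a sequence set.

    Frequencies are normalized per valid (N-free) window of width L+2, the
    positions at which a co-occurrence at distance L could start.
    """
    if lmax < 1:
        raise ValueError("lmax must be >= 1")
    seqs = list(seqs)
    if not seqs:
        raise ValueError("spacing_profile requires at least one sequence")
    per_seq_counts = np.zeros((len(seqs), lmax), dtype=np.int64)
    per_seq_freq = np.zeros((len(seqs), lmax), dtype=float)
    for i, seq in enumerate(seqs):
        per_seq_counts[i] = pair_cooccurrence(seq, d1, d2, lmax)
        for L in range(1, lmax + 1):
            denom = valid_windows(seq, L + 2)
            per_seq_freq[i, L - 1] = per_seq_counts[i, L - 1] / denom if denom else 0.0
    totals = per_seq_counts.sum(axis=0)
    mean = per_seq_freq.mean(axis=0)
    sd = per_seq_freq.std(axis=0, ddof=1) if len(seqs) > 1 else np.zeros(lmax)
    return SpacingProfile(
        pair=(d1.upper(), d2.upper()),
        counts={L: int(totals[L - 1]) for L in range(1, lmax + 1)},
        frequencies={L: float(mean[L - 1]) for L in range(1, lmax + 1)},
        sigma={L: float(sd[L - 1]) for L in range(1, lmax + 1)},
        n_sequences=len(seqs),
    )


def write_profiles_tsv(profiles: Iterable[SpacingProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair\tL\tcount\tfrequency\tsigma\n")
        for prof in profiles:
            for row in prof.to_rows():
                fh.write("\t".join(str(x) for x in row) + "\n")


def load_motif_set(path: str | Path, name: str | None = None) -> MotifSet:
    """Load a motif set from a plain-text file, one motif per line (# comments)."""
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                patterns.append(line)
    return _motif_set(name or Path(path).stem, patterns)
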