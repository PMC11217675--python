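"""The nine dinucleotide-arrangement features and the labeled ML table.

Feature summary (all counts are overlapping, case-insensitive, N-excluded):

=====  ==============================================================
F1     GpC frequency, per 100 valid dinucleotide windows
F2     CC + GG combined frequency, per 100 valid dinucleotide windows
F3     100 x (sum of the 17 pair counts at L=4) / (same at L=3);
       values above 100 are UCNE-like
F4     combined frequency of 8 GC-rich triplets, per 100 triplet windows
F5     combined frequency of 4 AT-rich triplets, per 100 triplet windows
F6     combined frequency of 17 adjacent-pair 4-mers, per 100 4-mer windows
F7     combined frequency of 18 one-spacer 5-mers, per 100 5-mer windows
F8     (TG+CA+GT+AC) / (AG+CT+GA+TC) dinucleotide ratio
F9     GC content, percent
=====  ==============================================================

The absolute scale of the frequency features is immaterial for the ML
stage: any per-column positive rescaling cancels under z-normalization
(a property the test suite asserts end to end).

F3 and F8 have degenerate denominators on short or skewed sequences;
per-sequence they surface as NaN, and at table-build time NaN cells are
replaced by a sentinel (by default the column's maximum observed finite
value — a zero-L3 sequence is an extreme, not a missing, observation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import patterns
from .patterns import (F3_L3_MOTIFS, F3_L4_MOTIFS, F4_MOTIFS, F5_MOTIFS,
                       F6_MOTIFS, F7_MOTIFS)
from .seqio import MaskedSequence

FEATURE_NAMES = ("F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8", "F9")

#: Alternating (purine/pyrimidine) dinucleotides — F8 numerator.
ALTERNATING = ("TG", "CA", "GT", "AC")
#: Homotype (purine/purine, pyrimidine/pyrimidine) dinucleotides — F8 denominator.
HOMOTYPE = ("AG", "CT", "GA", "TC")

#: Default minimum sequence length (nt) for feature computation; UCNEs are
#: at least 200 bp by definition.
MIN_LENGTH = 200


@dataclass(frozen=True)
class FeatureVector:
    """One labeled ML input row: the nine features plus the class label
    (1 = UCNE-like, 0 = background)."""

    id: str
    F1: float
    F2: float
    F3: float
    F4: float
    F5: float
    F6: float
    F7: float
    F8: float
    F9: float
    class_label: int = 0

    def values(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


def _combined_frequency(seq, motifs, width: int) -> float:
    denom = patterns.valid_windows(seq, width)
    if denom == 0:
        raise ValueError("sequence has no valid windows of width %d" % width)
    total = sum(patterns.count_motif(seq, m) for m in motifs)
    return 100.0 * total / denom


def f1_gpc(seq) -> float:
    """F1: GpC dinucleotide frequency per 100 valid dinucleotide windows."""
    counts = patterns.count_dinucleotides(seq)
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no valid dinucleotide windows")
    return 100.0 * counts["GC"] / denom


def f2_ccgg(seq) -> float:
    """F2: combined CC + GG frequency per 100 valid dinucleotide windows."""
    counts = patterns.count_dinucleotides(seq)
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no valid dinucleotide windows")
    return 100.0 * (counts["CC"] + counts["GG"]) / denom


def ratio_R(f1: float, f2: float) -> float:
    """R = (2*F1/F2) x 100%, the single-number GpC vs CC+GG contrast.

    Returns NaN when F2 = 0 (no CC or GG dinucleotides at all).
    """
    if f2 == 0:
        return 0.0 if f1 == 0 else math.nan
    return 200.0 * f1 / f2


def f3_l4_l3_ratio(seq) -> float:
    """F3: 100 x (total 17-pair pattern count at L=4) / (total at L=3).

    Values above 100 indicate a UCNE-like excess of the two-spacer
    arrangement.  NaN when the sequence has no L=3 occurrence at all
    (sentinel-filled at table-build time).
    """
    l4 = sum(patterns.count_motif(seq, m) for m in F3_L4_MOTIFS)
    l3 = sum(patterns.count_motif(seq, m) for m in F3_L3_MOTIFS)
    if l3 == 0:
        return math.nan
    return 100.0 * l4 / l3


def f4_gc_triplets(seq) -> float:
    """F4: combined GC-rich triplet frequency per 100 valid triplet windows."""
    return _combined_frequency(seq, F4_MOTIFS, 3)


def f5_at_triplets(seq) -> float:
    """F5: combined AT-rich triplet frequency per 100 valid triplet windows."""
    return _combined_frequency(seq, F5_MOTIFS, 3)


def f6_adjacent_pairs(seq) -> float:
    """F6: combined adjacent-pair 4-mer frequency per 100 valid 4-mer windows."""
    return _combined_frequency(seq, F6_MOTIFS, 4)


def f7_one_spacer_pairs(seq) -> float:
    """F7: combined one-spacer 5-mer frequency per 100 valid 5-mer windows."""
    return _combined_frequency(seq, F7_MOTIFS, 5)


def f8_alt_ratio(seq) -> float:
    """F8: alternating / homotype dinucleotide ratio.

    Numerator TG+CA+GT+AC (purine/pyrimidine alternations), denominator
    AG+CT+GA+TC (same-type neighbors).  NaN when the denominator is zero.
    """
    counts = patterns.count_dinucleotides(seq)
    num = sum(counts[d] for d in ALTERNATING)
    den = sum(counts[d] for d in HOMOTYPE)
    if den == 0:
        return math.nan
    return num / den


def f9_gc(seq) -> float:
    """F9: GC content as a percentage of non-N bases."""
    codes = patterns.encode(seq)
    acgt = codes[codes != 4]
    if acgt.size == 0:
        raise ValueError("sequence has no non-N bases")
    gc = int(np.sum((acgt == 1) | (acgt == 2)))
    return 100.0 * gc / acgt.size


def compute_features(seq: MaskedSequence, min_length: int = MIN_LENGTH,
                     class_label: int = 0) -> FeatureVector:
    """All nine features for one sequence.  Deterministic; F3/F8 may be NaN."""
    if len(seq) < min_length:
        raise ValueError(
            f"sequence {seq.id!r} is {len(seq)} nt, below the minimum {min_length}"
        )
    return FeatureVector(
        id=seq.id,
        F1=f1_gpc(seq), F2=f2_ccgg(seq), F3=f3_l4_l3_ratio(seq),
        F4=f4_gc_triplets(seq), F5=f5_at_triplets(seq),
        F6=f6_adjacent_pairs(seq), F7=f7_one_spacer_pairs(seq),
        F8=f8_alt_ratio(seq), F9=f9_gc(seq),
        class_label=class_label,
    )


@dataclass
class FeatureTable:
    """The labeled feature matrix that feeds the classifiers."""

    frame: pd.DataFrame  # columns: ID, F1..F9, Class
    provenance: str = ""

    def __post_init__(self) -> None:
        expected = ["ID", *FEATURE_NAMES, "Class"]
        if list(self.frame.columns) != expected:
            raise ValueError(f"feature table columns must be {expected}")
        if self.frame["ID"].duplicated().any():
            dup = self.frame["ID"][self.frame["ID"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sequence id {dup!r}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(FEATURE_NAMES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["Class"].to_numpy(dtype=int)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "FeatureTable":
        return cls(pd.read_csv(path, sep="\t"), provenance=provenance)


def build_feature_table(positives: Sequence[MaskedSequence],
                        negatives: Sequence[MaskedSequence],
                        min_length: int = MIN_LENGTH,
                        sentinel: float | None = None,
                        provenance: str = "") -> FeatureTable:
    """Assemble the labeled table: one row per sequence, positives first.

    NaN cells from degenerate F3/F8 denominators are replaced by
    ``sentinel``, or by that column's maximum observed finite value when
    ``sentinel`` is None (with a warning naming the column).
    """
    if not positives or not negatives:
        raise ValueError("both positive and negative sequence lists must be non-empty")
    rows = []
    for label, group in ((1, positives), (0, negatives)):
        for seq in group:
            fv = compute_features(seq, min_length=min_length, class_label=label)
            rows.append((fv.id, *fv.values(), label))
    frame = pd.DataFrame(rows, columns=["ID", *FEATURE_NAMES, "Class"])
    for col in FEATURE_NAMES:
        mask = frame[col].isna()
        if mask.any():
            fill = sentinel if sentinel is not None else frame.loc[~mask, col].max()
            warnings.warn(
                f"{int(mask.sum())} degenerate {col} value(s) replaced by "
                f"sentinel {fill:g}", stacklevel=2)
            frame.loc[mask, col] = fill
    return FeatureTable(frame, provenance=provenance)


def single_feature_power(values: Sequence[float], labels: Sequence[int]) -> float:
    """Best achievable 0/1 accuracy with a single threshold on one feature.

    Sweeps every threshold between distinct values, in both orientations
    (high-is-positive and low-is-positive), and returns the maximum
    accuracy.  This is the per-feature "prediction power" screen: only
    features clearing ~0.67 on the real data were kept for the ML stage.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D sequences")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")
    order = np.argsort(v, kind="stable")
    y_sorted = y[order]
    n = y.size
    n_pos = int(y.sum())
    # cum_pos[i] = positives among the i smallest values; a cut after the
    # i smallest predicts those i as class 0 (high-is-positive orientation).
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
    # valid cut indices: only between distinct values (plus the two ends)
    distinct = np.concatenate([[True], v[order][1:] != v[order][:-1], [True]])
    cuts = np.flatnonzero(distinct)
    i = cuts.astype(float)
    correct_high = (i - cum_pos[cuts]) + (n_pos - cum_pos[cuts])
    correct_low = cum_pos[cuts] + ((n - i) - (n_pos - cum_pos[cuts]))
    return float(np.maximum(correct_high, correct_low).max() / n)
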