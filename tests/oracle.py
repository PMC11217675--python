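"""Independent brute-force oracles used only by the test suite.

Everything here deliberately avoids the package's counting engine:
motif counts use regex lookahead on the uppercased string, spacing
profiles use an explicit double loop over positions, and the feature
formulas are restated from scratch.
"""

import re


def regex_count(seq: str, pattern: str) -> int:
    """Overlapping matches of an ACGTn pattern; N never matches anything."""
    body = "".join("[ACGT]" if c == "n" else c for c in pattern)
    return len(re.findall(f"(?={body})", seq.upper()))


def valid_windows(seq: str, width: int) -> int:
    return len(re.findall(f"(?=[ACGT]{{{width}}})", seq.upper()))


def dinucleotide_counts(seq: str) -> dict:
    s = seq.upper()
    counts = {a + b: 0 for a in "ACGT" for b in "ACGT"}
    for i in range(len(s) - 1):
        d = s[i:i + 2]
        if d in counts:
            counts[d] += 1
    return counts


def spacing_counts(seq: str, d1: str, d2: str, lmax: int) -> dict:
    """Count (d1 at p, d2 at p+L) pairs by exhaustive position enumeration."""
    s = seq.upper()
    p1 = [i for i in range(len(s) - 1) if s[i:i + 2] == d1.upper()]
    p2 = [i for i in range(len(s) - 1) if s[i:i + 2] == d2.upper()]
    counts = {L: 0 for L in range(1, lmax + 1)}
    for a in p1:
        for b in p2:
            L = b - a
            if 1 <= L <= lmax:
                counts[L] += 1
    return counts


# --- feature formulas, restated ---

F3_PAIRS = [("TA", "GA"), ("TA", "GC"), ("TA", "GG"), ("TA", "GT"),
            ("AC", "TA"), ("CC", "TA"), ("GC", "TA"), ("TC", "TA"),
            ("AA", "GC"), ("AT", "GC"), ("GC", "TT"), ("AG", "AT"),
            ("GG", "AT"), ("AG", "GT"), ("AC", "CT"), ("AT", "CT"),
            ("GC", "TC")]
F4 = ["GGG", "CCC", "GAG", "CCT", "CCA", "CTC", "TGG", "AGG"]
F5 = ["TTA", "TAA", "ATT", "AAT"]
F6 = ["AATT", "TACA", "TTAC", "GTAA", "TTAT", "ATAA", "AATG", "CATT", "ATTA",
      "TAAT", "TCAT", "ATGA", "TTAA", "TCAA", "TTGA", "CAAT", "ATTG"]
F7 = ["ACnGC", "GCnGT", "ACnGT", "AAnAG", "CTnTT", "TGnCA", "CTnAT", "ATnAG",
      "CAnTA", "TAnTG", "TTnAT", "ATnAA", "TTnTC", "GAnAA", "TAnTA", "GTnAT",
      "ATnAC", "ATnAT"]


def oracle_features(seq: str) -> dict:
    dc = dinucleotide_counts(seq)
    v2 = valid_windows(seq, 2)
    out = {}
    out["F1"] = 100.0 * dc["GC"] / v2
    out["F2"] = 100.0 * (dc["CC"] + dc["GG"]) / v2
    l3 = sum(regex_count(seq, d1 + "n" + d2) for d1, d2 in F3_PAIRS)
    l4 = sum(regex_count(seq, d1 + "nn" + d2) for d1, d2 in F3_PAIRS)
    out["F3"] = 100.0 * l4 / l3 if l3 else None
    out["F4"] = 100.0 * sum(regex_count(seq, m) for m in F4) / valid_windows(seq, 3)
    out["F5"] = 100.0 * sum(regex_count(seq, m) for m in F5) / valid_windows(seq, 3)
    out["F6"] = 100.0 * sum(regex_count(seq, m) for m in F6) / valid_windows(seq, 4)
    out["F7"] = 100.0 * sum(regex_count(seq, m) for m in F7) / valid_windows(seq, 5)
    num = dc["TG"] + dc["CA"] + dc["GT"] + dc["AC"]
    den = dc["AG"] + dc["CT"] + dc["GA"] + dc["TC"]
    out["F8"] = num / den if den else None
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    out["F9"] = 100.0 * (s.count("G") + s.count("C")) / acgt
    return out


def brute_force_power(values, labels) -> float:
    """Best single-threshold accuracy by trying every cut in both directions."""
    n = len(values)
    best = 0
    thresholds = sorted(set(values))
    cuts = [min(values) - 1] + [t for t in thresholds] + [max(values) + 1]
    for t in cuts:
        high = sum((v > t) == bool(y) for v, y in zip(values, labels))
        best = max(best, high, n - high)
    return best / n


def pair_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney pair statistic with half-credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
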