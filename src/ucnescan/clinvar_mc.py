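"""Monte-Carlo analysis of ClinVar clinical-significance categories.

Given a SNP set of interest (e.g. the SNPs falling inside UCNE
intervals), a ClinVar-style VCF, and a large pool of background SNPs,
this module answers: is the observed count of a CLNSIG category (say
"Pathogenic") among the SNPs of interest higher or lower than expected
for equally many random SNPs?

The null is built by drawing size-matched random SNP sets without
replacement from the pool and tabulating each one.  The empirical
p-value uses the add-one convention p = (1 + #{null at least as
extreme}) / (n_sets + 1), so with 100 null sets the smallest attainable
p is 1/101 (printed as 0.01) — a Monte-Carlo p-value can never be zero.
Depletion (observed <= null) is the default direction of the test.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .seqio import GenomicInterval

#: Bucket for input SNPs with no match in the ClinVar table.
ABSENT = "absent_from_clinvar"


@dataclass(frozen=True)
class SnpRecord:
    """One SNV: 1-based position on ingest, stored 0-based internally."""

    chrom: str
    pos0: int  # 0-based
    id: str = ""
    ref: str = ""
    alt: str = ""
    clnsig: str | None = None

    @classmethod
    def from_1based(cls, chrom: str, pos: int, **kw) -> "SnpRecord":
        if pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {pos}")
        return cls(chrom=chrom, pos0=pos - 1, **kw)

    @property
    def pos1(self) -> int:
        return self.pos0 + 1


def parse_clinvar_vcf(path: str | Path) -> list[SnpRecord]:
    """Read SNV records from a ClinVar-style VCF (v4.1, CLNSIG INFO key).

    Multi-allelic lines are split into one record per ALT; non-SNV
    alleles (indels, symbolic) are skipped.  CLNSIG is taken verbatim
    when present.
    """
    records = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            clnsig = rec.info.get("CLNSIG")
            if isinstance(clnsig, tuple):
                clnsig = ",".join(str(c) for c in clnsig)
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or alt is None or len(alt) != 1 \
                        or alt not in "ACGT":
                    skipped += 1
                    continue
                records.append(SnpRecord.from_1based(
                    chrom=rec.chrom, pos=rec.pos, id=rec.id or "",
                    ref=rec.ref, alt=alt,
                    clnsig=str(clnsig) if clnsig is not None else None))
    if skipped:
        import logging
        logging.getLogger(__name__).info("skipped %d non-SNV alleles", skipped)
    return records


def overlap_snps(snps: Sequence[SnpRecord],
                 intervals: Sequence[GenomicInterval]) -> list[SnpRecord]:
    """SNPs whose 0-based position falls in [start, end) of any interval.

    Each SNP is returned at most once.  Implemented with per-chromosome
    sorted boundary arrays (binary search); equivalent to the naive double
    loop, which the test suite checks.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    bounds = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        starts = np.array([iv.start for iv in ivs])
        # running maximum of ends handles nested/overlapping intervals
        max_ends = np.maximum.accumulate([iv.end for iv in ivs])
        bounds[chrom] = (starts, max_ends, ivs)
    out = []
    for snp in snps:
        b = bounds.get(snp.chrom)
        if b is None:
            continue
        starts, max_ends, ivs = b
        k = int(np.searchsorted(starts, snp.pos0, side="right"))
        for j in range(k - 1, -1, -1):
            if max_ends[j] <= snp.pos0:
                break  # nothing further left can reach this position
            if ivs[j].contains(snp.pos0):
                out.append(snp)
                break
    return out


def _clinvar_index(clinvar: Sequence[SnpRecord]) -> dict:
    """Lookup keyed by (chrom, pos0, ref, alt) and (chrom, pos0)."""
    exact, loose = {}, {}
    for rec in clinvar:
        if rec.ref and rec.alt:
            exact[(rec.chrom, rec.pos0, rec.ref, rec.alt)] = rec
        loose.setdefault((rec.chrom, rec.pos0), rec)
    return {"exact": exact, "loose": loose}


def tabulate_clnsig(snps: Sequence[SnpRecord],
                    clinvar: Sequence[SnpRecord]) -> dict[str, int]:
    """Count CLNSIG categories among ``snps`` as annotated by ``clinvar``.

    Matching is by chrom+pos+ref/alt when both sides carry alleles, else
    by chrom+pos.  SNPs with no ClinVar match land in the
    ``absent_from_clinvar`` bucket; matched records whose CLNSIG is
    missing count under "no_clnsig".  Counts (including absent) sum to
    the number of input SNPs.
    """
    idx = _clinvar_index(clinvar)
    counts: Counter[str] = Counter()
    for snp in snps:
        rec = None
        if snp.ref and snp.alt:
            rec = idx["exact"].get((snp.chrom, snp.pos0, snp.ref, snp.alt))
        if rec is None:
            rec = idx["loose"].get((snp.chrom, snp.pos0))
        if rec is None:
            counts[ABSENT] += 1
        elif rec.clnsig is None:
            counts["no_clnsig"] += 1
        else:
            counts[rec.clnsig] += 1
    return dict(counts)


@dataclass
class EnrichmentReport:
    """Monte-Carlo comparison of an observed category count to random sets."""

    category: str
    observed: int
    null_counts: list[int]
    set_size: int
    direction: str  # "depleted" or "enriched"
    p_value: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def null_sets(self) -> int:
        return len(self.null_counts)

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sets": self.null_sets,
            "set_size": self.set_size,
            "direction": self.direction,
            "p_value": self.p_value,
        }


def empirical_p(observed: int, null_counts: Sequence[int],
                direction: str = "depleted") -> float:
    """Add-one empirical p-value: (1 + #{null at least as extreme}) / (N + 1).

    "Depleted" counts null values <= observed as extreme; "enriched"
    counts null values >= observed.
    """
    null_counts = np.asarray(null_counts)
    if direction == "depleted":
        extreme = int(np.sum(null_counts <= observed))
    elif direction == "enriched":
        extreme = int(np.sum(null_counts >= observed))
    else:
        raise ValueError("direction must be 'depleted' or 'enriched'")
    return (1 + extreme) / (len(null_counts) + 1)


def monte_carlo_enrichment(observed_count: int,
                           null_pool: Sequence[SnpRecord],
                           set_size: int,
                           category: str,
                           clinvar: Sequence[SnpRecord],
                           n_sets: int = 100,
                           direction: str = "depleted",
                           seed: int = 0) -> EnrichmentReport:
    """Compare an observed category count to ``n_sets`` size-matched random
    SNP sets drawn without replacement from ``null_pool``."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if set_size > len(null_pool):
        raise ValueError(
            f"set_size {set_size} exceeds pool size {len(null_pool)}")
    rng = np.random.default_rng(seed)
    pool = list(null_pool)
    null_counts = []
    for _ in range(n_sets):
        pick = rng.choice(len(pool), size=set_size, replace=False)
        subset = [pool[i] for i in pick]
        tab = tabulate_clnsig(subset, clinvar)
        null_counts.append(tab.get(category, 0))
    return EnrichmentReport(
        category=category, observed=observed_count, null_counts=null_counts,
        set_size=set_size, direction=direction,
        p_value=empirical_p(observed_count, null_counts, direction))


def write_report(observed_tab: dict[str, int],
                 null_tabs: Sequence[dict[str, int]],
                 reports: Sequence[EnrichmentReport],
                 tsv_path: str | Path, json_path: str | Path) -> None:
    """Write the category table (TSV: category, observed, null mean) and the
    Monte-Carlo settings/p-values (JSON)."""
    cats = sorted(set(observed_tab) | {c for t in null_tabs for c in t})
    with open(tsv_path, "w") as fh:
        fh.write("category\tobserved\tnull_mean\n")
        for cat in cats:
            if null_tabs:
                null_mean = f"{np.mean([t.get(cat, 0) for t in null_tabs]):g}"
            else:
                null_mean = "NA"
            fh.write(f"{cat}\t{observed_tab.get(cat, 0)}\t{null_mean}\n")
    Path(json_path).write_text(
        json.dumps([r.to_dict() for r in reports], indent=2) + "\n")
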