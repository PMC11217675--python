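# Methods

This note documents the models, conventions and design choices behind
`ucnescan`: what each stage computes, which knobs matter, what the
synthetic generator does and does not emulate, and where genuinely open
design questions were settled.

## Counting conventions

All pattern counting shares three rules, applied uniformly so that
every feature and profile is comparable:

1. **Case-insensitive.** Lowercase residues mark soft-masked repeats in
   genome FASTA; masking governs *eligibility* of control fragments
   (uWGE), never the counts themselves.
2. **Overlapping matches count.** `AAA` contains `AA` twice. This is the
   standard k-mer convention and the only one under which the per-window
   denominators below are exact.
3. **N-containing windows are excluded from numerator and denominator.**
   An N (assembly gap or hard-masked base) is not sequence; dropping the
   window from both sides keeps frequencies unbiased in N-padded
   fragments. The single-base wildcard `n` in motifs matches A/C/G/T
   only, never N.

The spacing distance between two dinucleotides is the difference of
their start positions: L=1 means they intersect (share a base, as AT and
TG do in ATG), L=2 adjacent, L=3 one spacer base, L=4 two spacer bases.

## The nine features

F1 (GpC) and F2 (CC+GG) are frequencies per 100 valid dinucleotide
windows; F4–F7 are combined frequencies of fixed motif lists per 100
windows of the motif width (triplets, 4-mers, wildcard 5-mers); F3 is
100 × the ratio of total 17-pair counts at L=4 to L=3; F8 is the ratio
of alternating (TG, CA, GT, AC) to homotype (AG, CT, GA, TC)
dinucleotides; F9 is GC percent of non-N bases.

**Units are deliberately not load-bearing.** The absolute scale of a
frequency column cancels under z-normalization (any positive per-column
rescaling yields identical z-scores, a property asserted end-to-end in
the test suite: rescaling a column by 7.3 leaves all three models'
test-set predictions unchanged). The per-100-windows convention was
chosen for readability; nothing downstream depends on it.

**Degenerate denominators.** A sequence can lack any L=3 occurrence of
the 17 pairs (F3) or any homotype dinucleotide (F8). Per sequence these
surface as NaN; at table-build time NaN cells are replaced by a sentinel
— by default the column's maximum observed finite value, on the
reasoning that a zero denominator is an extreme observation in the
direction of the numerator, not missing data. The sentinel is
configurable and every substitution is warned about. Realistic
sequences (≥200 nt of non-degenerate composition) essentially never
trigger it.

**Minimum length** defaults to 200 nt — the defining lower bound of the
element class — and is overridable.

Only the given strand is analyzed; no reverse-complement
symmetrization is applied, because no orientation convention exists for
these elements and the published feature lists are strand-specific.

`single_feature_power` is the screen used to admit features: the best
0/1 accuracy achievable with one threshold on one feature, maximized
over every cut point and both orientations. It is computed exactly by a
sorted sweep (verified against an O(n²) brute force).

## Control sampling

WGE fragments are drawn uniformly over eligible genome positions with
the *exact* length multiset of the reference set (multiset equality, not
distribution approximation); fragments containing N are resampled;
repeats (lowercase) are allowed. uWGE adds the constraint that a
fragment be entirely uppercase and N-free. Overlap between fragments is
permitted in uniform mode — on genome-scale inputs collisions are
negligible, and forbidding them would bias long fragments. Walk mode
picks a random origin and advances a fixed step (default 5000 nt) along
one contig, skipping gap placements, for same-chromosome controls.
Replicated control subsets derive from named sub-seeds of one master
seed, so any single subset is independently reproducible.

The quasi-random null is an exact dinucleotide-preserving shuffle
(Altschul–Erickson): a uniformly random Eulerian path in the
dinucleotide multigraph with endpoints fixed, giving an output with
*exactly* the input's dinucleotide count vector (hence identical
mononucleotide counts and GC). Uniformity over arrangements is verified
against exhaustive enumeration on small words.

## Spacing profiles

`spacing_profile` counts co-occurrences of d1 at p and d2 at p+L for
L = 1..Lmax (default 50). Per-sequence frequencies divide by the number
of valid windows of width L+2 — the positions where such a
co-occurrence could start. The published figures this mirrors do not fix
the denominator; per-valid-window was chosen because it is length- and
gap-unbiased, so curve heights here are not directly comparable to other
normalizations. The stored `sigma` is the across-sequence standard
deviation; the plotted ±3σ band on an averaged curve uses the standard
error of the mean (`band()`), since the mean of n sequences is √n less
variable.

## Synthetic benchmark

The generator emulates the compositional structure the method exploits,
as study conditions, not tunable dials:

- **Composition:** first-order Markov chains. `spec_from_targets` solves
  a 3-parameter tilted matrix (GpC tilt, CC/GG tilt, C+G column weight)
  against its stationary distribution so that stationary GC hits the
  target and stationary GpC and CC+GG frequencies are the requested
  fold-changes of the independence baseline at that GC. The defaults are
  GC 37% / GpC ×1.5 / CC+GG ×0.7 for the UCNE-like class and GC 42% /
  neutral for the genome-like class — the published compositional
  contrast.
- **Lengths:** discretized log-normal (σ_log = 0.45) clipped to
  [200, 1000] nt with mode ≈ 300 nt, mimicking the real element-length
  distribution's shape without digitizing it.
- **L=4 planting:** the 17 pair patterns as 6-mers `d1 n n d2`, at a
  combined rate of 2 insertions/kb spread uniformly over the 17 patterns
  (Poisson counts, uniform positions, wildcards filled uniformly).
  Insertions overwrite the underlying bases so lengths stay exact.
- **Toy VCF:** uniform SNP positions, `CLNSIG` categories by fixed
  proportions, VCF v4.1 text parsed back through the same reader used
  for real files.

What the generator does **not** emulate: evolutionary conservation
itself, higher-order (beyond first-order) dependencies, isochore
structure, repeat families, CpG islands, or linkage between variants.
Passing benchmarks therefore demonstrate that the pipeline detects the
modeled compositional signals at realistic sizes — not that real-genome
accuracy is reproduced. The published real-data accuracies (82–84%,
AUC 0.90–0.91 on curated elements vs hg38 controls) require those
datasets and are out of scope here; the synthetic benchmark is the
testable substitute, and its AUC ≥ 0.8 / accuracy ≥ 0.75 guarantees are
asserted in the acceptance tests at 500 sequences per class.

## Classification protocol

Stratified 70/30 split (stratification keeps the balanced design exact
in both halves), z-scoring with sample (n−1) standard deviation fitted
on the training rows only — fitting on all rows would leak test
statistics; with balanced classes the numerical difference is
negligible, but the train-only convention is the defensible one.
Hyperparameters are constants, not searched: SVM radial C = 1.0,
γ = 0.155; random forest 500 trees; ANN one hidden layer of 5 units,
decay (L2) 0.1, weight cap 1000 (the 9-input network uses 56 weights).
The "network size 5" is read as one hidden layer of five units — the
single-hidden-layer framework the setting originates from cannot express
five layers.

AUC is the trapezoidal area over the full ROC sweep of the
positive-class score (SVM decision values; class-1 probabilities
otherwise), with half-credit for ties; it equals the normalized
Mann–Whitney U statistic, an identity the tests assert. The accuracy CI
is exact binomial (Clopper–Pearson). `repeated_eval` reruns the whole
protocol over independently re-sampled control subsets and reports the
mean and one-sigma spread of accuracy — the stability measure for
background-draw sensitivity.

## Monte-Carlo variant analysis

SNP positions are converted to 0-based half-open coordinates on ingest
(all interval logic in the package uses the BED convention; VCF's
1-based positions are converted exactly once, at parse time).
Overlap uses per-chromosome sorted intervals with a running-max end
(correct for nested intervals), verified against a naive double loop.
ClinVar matching is by chrom+pos+ref/alt when both sides carry alleles,
chrom+pos otherwise; multi-allelic lines are split on ingest; indels and
symbolic alleles are skipped.

Null sets are drawn without replacement, size-matched to the observed
set. The empirical p-value is the add-one (Davison–Hinkley) form
p = (1 + #{null at least as extreme}) / (n_sets + 1): it can never be
zero, and its floor at 100 sets is 1/101 ≈ 0.01 — exactly the smallest
p reportable from a 100-set simulation. Depletion (observed ≤ null) is
the default direction. Under a true null the p-value is uniform on
{1/(N+1), …, 1} up to ties; the test suite checks this with a KS test
after rank-randomized tie-breaking.

## Problem sizes and numerical choices

Test and acceptance runs use 150–500 sequences per class and 100–199
Monte-Carlo sets — sizes at which every asserted effect is resolved by
a comfortable margin while the whole suite stays interactive. The
composition solver accepts a solution when the stationary residuals are
below 1e-8; stationary vectors come from a least-squares solve of
π(P−I) = 0 with Σπ = 1 (smooth in P, which the root-finder needs).
Shuffle acceptance (the last-edge arborescence draw) is rejection-based
and fast on the 4-vertex dinucleotide graph. Ties in ROC scores get
half-credit; ties in `single_feature_power` thresholds are handled by
cutting only between distinct values.

## Known limitations

- First-order Markov structure cannot represent longer-range
  correlations of real conserved elements; F3-style spacing signals
  exist in the synthetic data only where planted.
- The sentinel policy for degenerate F3/F8 makes the (rare) affected
  rows depend weakly on the rest of the table.
- `sample_wge` holds contigs in memory; it is intended for
  chromosome-scale FASTA, not multi-terabase collections.
- The ANN's hidden-layer optimization is seed-deterministic but
  implementation-specific; exact weight values are not portable across
  library versions, though evaluation metrics are stable.
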