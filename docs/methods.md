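# Methods

## Models and procedures

### Sequence evolution and insertion dating

An LTR retrotransposon integrates with two identical long terminal
repeats; afterwards each LTR accumulates substitutions independently.
The simulator realizes exactly this: a copy of age T has each LTR (and
the internal region) evolved along an independent branch of expected
length rT substitutions/site under the Kimura two-parameter (K2P)
continuous-time Markov process, so the expected inter-LTR divergence is
2rT. The process is simulated from the closed-form transition
probabilities of the chain (transition probability
¼ + ¼e^(−4βt) − ½e^(−2(α+β)t), each transversion ¼ − ¼e^(−4βt), with
αt + 2βt equal to the branch length and κ = α/β), so multiple hits and
back-mutations are handled exactly — the simulator inverts precisely the
model the estimator assumes, which is what makes the dating recovery
tests meaningful.

The estimator computes transition (P) and transversion (Q) proportions
over gap-free, unambiguous alignment columns (pairwise deletion) and

    K = −½ ln[(1 − 2P − Q) √(1 − 2Q)],    T = K / 2r.

Saturated inputs (1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0) raise an explicit
`SaturationError` and are skipped, never clamped, by downstream
summaries. At K = 0 the age is exactly 0. The dating variance is driven
by LTR length L: sd(K) ≈ √(K/L), i.e. roughly ±0.4 Mya per copy for a
400 bp LTR at 2 Mya, which is why family-level age distributions, not
single copies, are the meaningful output.

Parameters: substitution rate r (default 1.5 × 10⁻⁸
substitutions·site⁻¹·year⁻¹, the standard plant LTR clock);
transition/transversion ratio κ (default 2, a typical plant nuclear
value); both configurable in `SimulationConfig`.

### Alignment

All pairwise comparisons share one affine scoring scheme — match +1,
mismatch −1, gap open −3, gap extend −1 per base — delegated to
Biopython's `PairwiseAligner` (Gotoh, C implementation), globally for
LTR pairs and semi-globally (free genome-window overhangs) for copy
discovery. Identity is matches over alignment columns with terminal
gaps excluded and internal gaps counted; coverage is aligned reference
positions over reference length. The aligner's first optimal traceback
is deterministic for fixed inputs; test oracles verify optimal scores
by exhaustive dynamic programming on small strings, so correctness does
not rest on the library's tie-break order.

Semi-global alignments are trimmed to their maximum-scoring contiguous
column run (a Kadane pass over per-column scores) before identity and
coverage are computed. Without this, an optimal alignment drags
unmatched reference tails through random flanking sequence as mismatch
columns (a 600 bp tail costs ~−300 as mismatches versus ~−600 as a
gap), inflating coverage and misattributing truncation to low identity.

### Copy mining

Discovery is seed-and-extend: exact 12-mer seeds are clustered by
diagonal (band = max(60, reference/10)); clusters with fewer than three
seeds are dropped as chance collisions (a random 500 kb genome yields
~70 isolated 12-mer hits per reference, while even a 20 %-diverged copy
retains hundreds of clustered seeds). Overlapping candidate windows are
merged, aligned, and competing candidates (including hits to multiple
references) are resolved greedily by identity, ties to the longer
reference. LTR boundaries are projected from the reference annotation
through the alignment and each outer boundary refined within ±3 bp
toward the TG/CA terminal motifs. A copy is full length iff identity
> 0.80, coverage ≥ 0.80 and termini are canonical; TSD presence (the
longest exact 4–6 bp flank duplication, searched longest-first) is
additionally required for dating ("intact"), not for counting.
Candidates below identity 0.5 or coverage 0.3 are not reported at all;
between the floors and the thresholds they are reported with an
explanatory rejection status.

Minus-strand copies are mined on the reverse-complemented genome and
mapped back, so all structural checks run in element orientation;
`date_element` likewise expects element-oriented sequence.

### Family classification, naming, lineage, diversity

Families are single-linkage connected components over LTR pairs with
≥ 80 % identity covering ≥ 80 % of the shorter LTR (the denominator the
rule leaves open; shorter-LTR is the conservative choice), numbered by
descending size with lexicographic tie-break, and named
`RLC|RLG_<host><lineage>_<index>`. Lineage assignment is
nearest-reference by K2P distance on a reverse-transcriptase fragment
with a configurable ceiling (default 0.6) beyond which the call is
"unclassified"; exact ties keep panel order and set an ambiguity flag.
Per-family LTR diversity Pi is the mean pairwise p-distance (pairwise
deletion) with the sample standard deviation over pairs.

### qPCR quantification

Standard curves: ordinary least squares of mean Ct per dilution point on
log₁₀ concentration; efficiency E = (10^(−1/y) − 1) × 100 from the slope
y, per-cycle fold 1 + E/100. The anchor is exact: a tenfold series
stepping 1/log₁₀2 = 3.3219 cycles gives E = 100 % and fold 2. Relative
copy number is 2^(−ΔΔCt) with ΔCt = Ct(target) − Ct(single-copy gene),
technical replicates averaged at the Ct level. Relative expression is
(1+E)^(−ΔΔCt) — the negative exponent so that lower Ct (more template)
gives higher RQ — with the calibrator defaulting to the sample with the
highest normalized Ct, whose RQ is exactly 1; efficiencies below a
configurable threshold (default 0.90) are refused. geNorm M for gene j
is the mean over other genes k of the SD across samples of
log₂(xⱼ/xₖ) (sample SD, ddof = 1). Group comparison is one-way ANOVA
(sums of squares computed locally, cross-checked against
`scipy.stats.f_oneway`) gating Fisher's LSD pairwise t-tests on the
pooled MSE at N − k df, summarized as a greedy compact letter display;
zero within-group variance with distinct means is flagged degenerate and
reported as exact separation.

### Dominant markers

Jaccard similarity GSj = a/(a+b+c) via integer matrix products; pairs
with no band in either individual are undefined (NaN, warned), and
band-free individuals can be dropped explicitly before clustering.
UPGMA uses size-weighted average linkage, merges at half the pair
distance (so the tree is ultrametric by construction) and breaks ties by
the lexicographically smallest member id; output is Newick.
Polymorphism tables count, per species × primer, scorable loci (≥ 1
presence in the species) and polymorphic loci (neither fixed present nor
fixed absent), with per-species means across primers; single-individual
species are flagged undefined. `read_band_calls` merges fragment sizes
into loci greedily within a fractional tolerance (default ±2 %), seeded
from the smallest size.

## What the simulator does and does not emulate

It emulates: planted full-length copies with exact TSDs, canonical
termini (exempt from mutation by default so structural checks decouple
from dating), known ages and family labels; dilution-series and sample
Ct tables with exact log-linear chemistry plus homoscedastic Gaussian
noise; marker matrices with shared/private loci at stated rates. It
does not emulate: indels (substitutions only — real LTR alignments gap),
solo LTRs from unequal recombination, nested or tandem insertions
(placements are ≥ 8 kb apart so candidate windows never merge),
GC heterogeneity or repeat-rich backgrounds, PCR artefacts
(heteroscedastic noise, inhibition, off-target bands) or gel-scoring
error. Passing tests therefore demonstrate correctness of the
algorithms under their stated models, not robustness to those real-data
complications; on real genomes the mining recall will degrade with
divergence, fragmentation and nesting in ways the synthetic suite does
not measure.

## Numerical and design choices

- Coordinates are 0-based half-open in memory, 1-based inclusive in all
  file output (GFF3 convention).
- Gap cost convention: a gap of length L costs 3 + L (Biopython
  open −4, extend −1).
- TSD length is drawn uniformly from {4, 5, 6} unless fixed — the
  canonical LTR-RTE range; observed per-element lengths are not
  constrained by the source data.
- Saturated K2P distances propagate as explicit errors; lineage calls
  treat saturation as "no information" for that panel member.
- The `K2P` event probabilities at κ → ∞ make transversions vanish;
  κ = 0 is permitted (transitions at the transversion rate).
- Family numbering: descending member count, ties by smallest member id
  (the exact ordering convention is otherwise arbitrary).
- Jaccard undefinedness is confined to pairs of band-free individuals;
  a band-free versus banded pair is a defined similarity of 0.
- Greedy compact-letter display can in principle miss exotic overlap
  patterns; for the small designs this package targets it reproduces
  the textbook letters.

## Problem sizes in the test and acceptance runs

Dating recovery uses 100 replicates per age at 1 kb LTRs (Monte-Carlo SE
≈ 0.026 Mya at 2 Mya); mining uses one 500 kb genome with 30 planted
copies from 3 families (400 bp LTRs, 2.2 kb elements, ages 0.5–3 Mya);
oracle sweeps use 1 000 random substitution patterns and 200 random
marker matrices. These sizes keep the full suite under a minute while
leaving the Monte-Carlo bands narrow enough to detect percent-level
bias.

## Known limitations

Reference-guided only: de novo LTR discovery, solo-LTR cataloguing and
nested-element resolution are out of scope. The aligner is O(nm) per
candidate window, so very long references on large genomes will be slow;
the seed filter keeps the window count near the true copy count. The
80-80-80 implementation classifies on LTRs only — elements with
conserved coding regions but diverged LTRs are deliberately split, which
matches the field convention for that situation.
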