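# Methods

## Sequence validity

The window scanner requires sequences over the 20 canonical amino acids
(`ACDEFGHIKLMNPQRSTVWY`) no longer than 10,000 residues. Records failing
either rule — or with an empty sequence — are excluded from *all* downstream
statistics, including denominators of fractions and coverages. Letters
B, J, O, U, X, Z count as non-canonical. Coordinates are 0-based half-open
everywhere inside the package; converters to 1-based inclusive exist only
at the I/O boundary.

## AR scanning

A scoring matrix assigns window `w` (length `W`, default 6 — the
hexapeptide convention of PSSM amyloid predictors) the score
`S(w) = Σ_{j<W} M[j, w_j]`; windows with `S ≥ T` are positive. Overlapping
*or directly adjacent* positive windows are unioned into maximal regions
(a contiguous amyloid-prone stretch should be one region); the region score
is the maximum member-window score. Regions shorter than `min_len = 10`
residues are discarded, because 6–9-residue hits are too short to bear on
full-length protein behaviour; a protein is flagged iff ≥ 1 region
survives. Merged regions are exactly the union of positive windows — the
test suite holds the scan to a per-residue bitmap reference on random
sequences. Raising `T` can only shrink the called set (monotonicity,
property-tested). Trained weights (e.g. the Waltz matrix at pH 7) are
pluggable input data; reproducing any particular published scanner's output
byte-for-byte is out of scope.

## CBR detection

For residue class `C` with background frequency `p`, a stretch of length
`L` with `k` members is scored by the one-sided binomial upper tail
`P(X ≥ k)` for `X ~ Bin(L, p)`. Candidates are anchored — first and last
residue are class members — which is lossless (trimming a non-member end
strictly lowers the tail) and caps candidates at `m(m+1)/2` for `m` member
occurrences. All candidates with tail `< threshold` (default 10⁻⁸, applied
per region, strict inequality) enter a greedy selection: lowest probability
first, ties broken longest-then-leftmost for determinism, discarding
anything overlapping a chosen region. Reported regions are therefore
disjoint, each individually below threshold. A protein is flagged on
compositional grounds iff it has ≥ 1 CBR in class QN or E.

The background `p` is estimated per proteome (class-member residues /
total residues over the valid proteome), matching the cross-species
variability such screens observe; a fixed override (`fixed:<p>`) is
available. A class absent from the proteome raises rather than silently
using `p = 0`.

For a pure member-run of length `L`, the tail reduces to `p^L`; at
`p = 0.05` the minimal pure run crossing 10⁻⁸ is `L = 7`
(`0.05⁷ ≈ 7.8e-10`, while `0.05⁶ ≈ 1.56e-8` fails). This closed form, the
exhaustive brute-force equivalence on random sequences, and threshold
monotonicity are all asserted in the tests.

### Numerical route for the tail

`scipy.stats.binom.logsf` computes `log(sf)` after the survival function
itself, so it underflows to `-inf` once the tail drops below ~1e-308 —
easily reached at the lengths scanned here. The tail is instead computed as
a log-sum-exp over `gammaln`-based log-pmf terms, identically for scalars
and arrays (so greedy ranking is reproducible). Against an exact
rational-arithmetic oracle (`fractions.Fraction` summation, 50-digit
`Decimal` logarithm), the relative error on the probability is ~1e-12 for
`L ≤ 1000`, comfortably beyond 10 significant digits.

## Proteome statistics

Flagged fraction is `100 · flagged / valid proteins`; coverage is
`100 · Σ region residues / Σ protein residues` with per-protein interval
union so overlapping calls are not double counted. Region-length summaries
report the median (mean of central pair for even n) and mode (smallest
length on ties, since a single modal value is reported). Organellar subsets
filter records by their genome-of-encoding annotation; all statistics apply
unchanged to subsets. Cross-species comparison builds the 2×2 table
(flagged, unflagged) × (species A, B), tests it with the two-sided Fisher's
exact test (point-probability summation convention — the most common
two-sided definition; sidedness is a package choice), and adjusts across
all pairs jointly with Benjamini–Hochberg. Tables with a zero margin are
degenerate and rejected. Fisher goes through `scipy.stats.fisher_exact`;
the test suite checks it against exact rational enumeration over every
table with total count ≤ 30. The BH step-up is implemented directly (five
lines of numpy) and cross-checked against `statsmodels.multipletests`.

## Enrichment

Per term, the one-sided hypergeometric tail
`P(overlap ≥ observed | N, K, n)` on (universe size, term size, interest
size). A term is *reported* iff `p < alpha` (default 0.01) **and** the
overlap (interest proteins carrying the term) is ≥ `min_interest`
(default 5). No multiple-testing correction is applied inside this step:
the raw alpha cut is the selection rule, by design. The heat-map export
takes, per species, the top-k reported terms ranked by p (k = 30), unions
the term sets across species, and writes interest fractions
(`overlap / term size`) with unreported cells zeroed. Annotations are taken
as given — no ontology-graph propagation or term decorrelation (graph-aware
methods such as topGO's weighting would shrink some p-values relative to
this classic per-term test).

Calibration, asserted in the acceptance tests: under a null with term
assignment independent of the interest set, ≤ 2% of 1000 terms reach
p < 0.01 (the discrete hypergeometric test is conservative, so the
realised rate is below 1%); a planted 4-fold enriched term (universe 2000,
term size 100, interest 200) is reported in ≥ 95 of 100 seeded replicates.

## Feature overlap and PFAM summary

For each feature type, same-type intervals are unioned per protein;
residues covered by no feature form the synthetic `unannotated` type, so
types partition each protein. The overlap fraction is
`Σ |regions ∩ type| / Σ |type|`; types of zero total length are omitted
(undefined fraction). The distribution of ARs over CBR classes uses the
same arithmetic with one CBR class as the feature. Overlap mass is
conserved across a partition (tested), and sums match a per-residue bitmap
reference on random fixtures.

The PFAM summary restricts to storage proteins (GO:0045735): per accession,
protein and species counts plus the counts among Q/N-rich proteins (those
bearing ≥ 1 QN CBR — the same flag the screen uses). A species counts as
Q/N-rich for a family iff ≥ 1 such protein exists in its proteome. The
Total row counts *distinct* proteins and species across accessions, so
multi-domain proteins are not double counted. Percentages are rounded
half-up to 2 decimals, matching published table formatting; the acceptance
suite reproduces every percentage cell of the published seed-storage table
from its printed count columns.

## Synthetic proteomes

Background residues are drawn i.i.d. from a frequency profile (uniform
0.05 per residue by default; `qn_background(p)` builds a profile with a
chosen class frequency). Protein lengths are uniform on a range, default
100–600 — bracketing typical proteome median lengths (~350). Planted CBR
segments place class members with probability `purity` (non-members drawn
from the background restricted to non-members) at uniform, non-overlapping
positions in exactly `round(fraction · n)` proteins. Planted AR stretches
of length `W + n_windows − 1` set each position to the residue maximizing
its summed matrix score over the windows covering it, then verify every
window clears the threshold (raising if the matrix admits none).
Annotations draw term sizes uniformly; planted-enriched terms sample
members with weight `fold` on proteins carrying planted regions. One
integer seed drives all draws; identical spec + seed gives byte-identical
output.

What the generator does *not* emulate: real gene families, domain
architecture, composition–length correlations, or realistic annotation
density. Passing recovery tests therefore demonstrates correctness of the
detectors under the stated statistical model, not performance on real
proteomes.

Recovery is scored with a boundary tolerance (default ±5 residues): a
planted region counts as recovered iff a called region of the same
kind/class overlaps it with both boundaries within tolerance; precision is
the fraction of calls matching some planted region (undefined without
calls). At purity 0.9, length 40, background 0.08, sensitivity and
precision pooled over 20 seeded proteomes are ≥ 0.95 (asserted); the
residual misses are boundary extensions past tolerance when background
members happen to chain just outside the planted segment.

## Problem sizes and numerical conventions

The test and acceptance workloads use: 500 random sequences ≤ 200 aa (20
seeds) for the CBR brute-force equivalence, 500 sequences ≤ 100 aa for the
AR bitmap equivalence, every 2×2 table with total ≤ 30 (~44,500 tables)
for Fisher, 20 × 50-protein proteomes (lengths 200–500) for planted
recovery, one 1000-protein proteome for flagged-fraction recovery, and
1000 null terms / 100 planted replicates on a 2000-protein universe for
enrichment calibration — sizes at which every check is exhaustive or
statistically decisive while a full run stays in the minutes range.

Ties: greedy CBR selection breaks on (probability, longest, leftmost);
length modes on the smallest value; enrichment ranking on (p, term id).
Degenerate inputs (empty proteome, absent class, zero-margin table,
interest ⊄ universe, infeasible plants) raise with explicit messages
rather than returning conventions.

## Known limitations

- Proteome-scale published figures (median flagged fractions, CBR length
  medians) depend on the original input snapshots and the exact internals
  of the original scanners (trained PSSM weights, the reference CBR
  finder's extension rules), none of which are distributed here; this
  package fixes a declared, oracle-tested model instead of reverse
  engineering those tools.
- The greedy disjoint selection is a deterministic approximation to "the
  set of maximal significant stretches"; other conventions (e.g. merging
  nearby calls) would shift CBR length distributions.
- Enrichment treats annotations as flat sets; GO graph structure is
  ignored.
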