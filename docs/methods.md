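# Methods

## Substitution counting (the statistical core)

Pairwise divergence is measured with Nei–Gojobori (1986) unweighted codon
counting followed by Jukes–Cantor correction.

**Sites.** Each codon position contributes a fractional synonymous-site
count: the number of single-nucleotide changes at that position that
preserve the amino acid, divided by the number of changes that do not
create a stop codon. Changes to stop codons are removed from both numerator
and denominator (renormalization), so every codon contributes exactly
s + n = 3 sites and the invariant S + N = 3 × (compared codons) holds to
machine precision for any column subset. For a pair, S is the mean of the
two sequences' site totals.

**Differences.** For codons differing at k positions, all k! substitution
orderings are enumerated. Orderings whose intermediate codons are stops are
excluded and the synonymous/nonsynonymous step counts averaged over the
remainder; in the (standard-code-impossible for k ≤ 2, rare for k = 3) case
that every ordering is blocked, all orderings are used with stop-traversing
steps counted as nonsynonymous. For stop-free pathways Sd + Nd equals the
nucleotide Hamming distance of the codon pair.

**Correction.** Proportions pS = Sd/S and pN = Nd/N are corrected with
d = −(3/4)·ln(1 − (4/3)·p). The formula diverges at p ≥ 3/4; such pairs are
flagged `saturated_S`/`saturated_N` and excluded from summaries. When
S = 0 over the compared columns (possible in tiny windows of Met/Trp-rich
sequence), pS is taken as 0 — there are no synonymous opportunities and no
synonymous differences can have been counted there.

**Gap handling.** Columns where either sequence of a pair has a gap, an
ambiguous base, or a stop codon are excluded for that pair only (pairwise
deletion). This maximizes the data available per pair; the cost is that
different pairs may be compared over slightly different column sets, which
the per-pair `compared_codons` column makes explicit.

**ω when dS = 0.** A pair with nonsynonymous change but no synonymous
change has undefined (infinite) ω. The default policy reports it as
undefined with flag `dS_zero` and excludes it from averages, which keeps
summary statistics finite; `zero_ds_policy="inf"` reports +∞ instead for
users who want the other convention. Identical sequences are `both_zero`
and likewise excluded from ω means (their dN and dS of 0 still enter the dN
and dS means).

## Windows and region summaries

Windows are defined on alignment codon columns, not on any single
sequence's ungapped coordinates, so all pairs share the same window grid;
gap handling inside a window is inherited from pairwise deletion. Window w
starting at column i covers [i, i+w−1] and is plotted at center
i + (w−1)/2. The default step is 1 codon; defaults of 10 and 30 codons are
offered because short windows resolve individual conserved subdomains while
long ones show lobe-scale trends.

Per-window and per-region statistics are the mean and sample (n−1) standard
deviation across pairs of each quantity's defined values, with ω averaged as
the mean of per-pair ratios. A ratio-of-means variant (pool counts across
pairs, then correct once) is available; mean-of-ratios was chosen as the
primary because per-pair ω values are the published unit of comparison.
Note that mean-of-ratios is upward-biased for short windows at neutrality
(Jensen's inequality applied to the noisy dS denominator): neutral flanks
in 10-codon windows average ω ≈ 1.3–1.5 rather than 1.0. The bias
disappears as windows lengthen and does not affect the ordering of
purifying vs neutral regions, which is what the window scan is for.

Regions are specified in 1-based codon coordinates on one designated
reference row and mapped to alignment columns by walking the reference's
non-gap codons; columns where the reference is gapped between a region's
first and last codon belong to the region, keeping regions contiguous in
alignment space. Because NG86 counts are additive over disjoint column
sets, a domain map that tiles the alignment reproduces whole-gene counts
exactly by summation (tested).

## Clustering

Rows of the percent-identity matrix are clustered by UPGMA on plain
Euclidean distance between raw identity rows; columns by distances between
columns of the row-reordered data. Inter-cluster distance is the unweighted
arithmetic mean over all cross pairs; merge height is half the merge
distance, making cophenetic distances an ultrametric; ties are broken by
the lexicographically smallest pair of cluster labels (a cluster's label is
its smallest leaf id), which makes the tree a pure function of the input.
Z-scoring (row mean 0, sample SD 1) is applied only to the exported
visualization matrix — clustering on z-scored rows is available by flag but
raw identities are the default, since standardization erases the overall
identity level that distinguishes tight from loose clusters. Identity
matrices are not symmetrized: query/subject asymmetry is genuine in
search-derived identities, and rows and columns are clustered separately
anyway.

## Codon-alignment projection

Protein-alignment gaps become `---`; each residue is replaced by its source
codon. Terminal stop codons are trimmed from the CDS before projection
(coding records routinely include them; the protein alignment never does).
Translation of every projected codon is checked against the aligned
residue: by default any mismatch is an error naming the residue, because a
single frameshift corrupts every downstream count; `max_mismatches > 0`
tolerates isolated annotation noise, keeping the codon and warning.
Ambiguity codons translate to X and are skipped by the counting core's
pairwise deletion. The standard genetic code (NCBI table 1) is the default;
any unambiguous-DNA table id is accepted.

## Synthetic data

`simulate_family` evolves each taxon independently from a common ancestor
(star phylogeny — sufficient for validating a pairwise estimator, since
every pair's divergence is just the two branches). The ancestor is uniform
over the 61 sense codons. Per branch, each nucleotide site receives a
Poisson(μ) number of proposed point mutations (target base uniform over the
three alternatives); proposals creating stops are rejected, synonymous
proposals accepted, nonsynonymous ones accepted with probability
min(ω, 1). For ω > 1 the model instead suppresses synonymous acceptance to
1/ω so acceptance remains a probability — consequently realized dS scales
down by 1/ω in diversifying regimes, and all recovery checks compare
against *realized* ω computed from the truth table (accepted counts divided
by ancestor NG86 site totals), never against nominal ω.

Default study conditions used by the tests and the acceptance script:

* ω-recovery: 2 taxa × 3,000 codons, μ = 0.1 per branch (realized pairwise
  dS ≈ 0.2, comfortably below saturation), ω ∈ {0.1, 1.0, 2.0};
* window localization: 6 taxa × 300 codons, μ = 0.15, a planted ω = 0.05
  block at codons 101–200 in ω = 1 flanks — emulating the kinase-domain vs
  termini contrast in real families;
* identity fixtures: two blocks of five, 90% within, 50% between, jitter
  SD 2 percentage points;
* hit fixtures: passing rows sampled above the thresholds with one row
  exactly on every inclusive boundary, failing rows violating ≥ 1 criterion.

What the generator does **not** emulate: indels (projection tests inject
gaps into protein rows deterministically instead), codon-usage bias,
among-site rate heterogeneity beyond the region-ω structure, transition/
transversion bias, and non-star phylogenies. Passing tests therefore
demonstrate correctness of the counting, windowing and clustering
machinery under the NG86 model's own assumptions — not robustness to the
biases of real sequence data, where NG86 without a ts/tv weighting is known
to be conservative.

## Numerical and design choices

* All screening comparisons are inclusive (≥ / ≤), matching how such
  thresholds are conventionally stated; boundary rows are kept.
* Deduplication keeps the highest-bitscore hit per (query, species), ties
  broken by smallest subject id; merging across queries keeps the
  highest-bitscore record per subject. Both are order-independent.
* The completeness screen (default 95% of the reference coding length)
  measures length in codons.
* Windows: number of windows is L − w + 1 at step 1; a window of size L
  equals the whole-gene estimate exactly (tested).
* Sample (n−1) standard deviations throughout, matching the z-score
  convention of clustergram-style tools and the small-sample examples used
  in tests.
* No canonical kinase subdomain coordinates ship with the package: real
  coordinate sets are alignment- and reference-specific, so the domain map
  is always a user input. Maps with subdomain/interdomain counts other
  than 12/11 trigger a warning (not an error) in strict mode.
* Determinism: every stochastic component takes an explicit integer seed
  and uses `numpy.random.default_rng`; the pipeline manifest records
  SHA-256 checksums so reruns can be verified byte for byte.

## Known limitations

* NG86 is a counting method: no maximum-likelihood codon model, no ts/tv
  or codon-frequency parameters, no site-specific selection tests. ω here
  is a pairwise average, appropriate for the family-/region-level scans the
  package produces.
* Jukes–Cantor saturation (p ≥ 3/4) is reported, not extrapolated; deeply
  diverged pairs should be analyzed with ML methods instead.
* The per-window mean-of-ratios bias discussed above.
* Hit tables are consumed in the 12-column tabular convention (plus a
  coverage column); XML or archive formats of search tools are out of
  scope, as is running the search or the protein aligner themselves.
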