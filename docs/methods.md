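# Methods

## Statistical model for seasonal differential abundance

Reporter intensities are modeled as log-normal: all inference happens on
log2-transformed values. Zero intensities denote non-detection and are
treated as missing; missing values are dropped per protein (pairwise
deletion) and never imputed — omission is conservative and avoids inventing
variance structure. A protein is testable only with ≥ 2 non-missing values
in each season (`min_per_season`, default 2, also the both-seasons filter
threshold).

Normalization is the total-peptide-amount method: one multiplicative factor
per sample so every column sum (over non-missing entries) equals the mean
input column sum. It preserves within-sample ratios exactly and fails
loudly on a zero-total sample.

The unadjusted test is a one-way ANOVA on season followed by the Tukey HSD
season contrast. With exactly two seasons Tukey HSD reduces to the pairwise
comparison: the studentized-range statistic is q = √2·|t| and its k = 2
tail probability equals the two-sided pooled-*t* p-value, which is what the
implementation evaluates (the identity is asserted in the tests against an
explicit studentized-range computation, and F = t² links the omnibus and
contrast routes). Both p-value sources are exposed
(`p_source="contrast"|"omnibus"`, default contrast) because which of the
two enters the FDR correction is a genuinely open choice; at two groups
they coincide anyway.

Batch/year adjustment, when requested, is an additive fixed-effects linear
model (season + factors, no interactions) fitted by least squares; the
reported log2FC is the season coefficient and its p-value a *t*-test on the
residual degrees of freedom. The additive model is the simplest structure
consistent with "accounting for" batch and year; a confounded design
(season in the span of one factor's dummies) is rejected with the factor
named rather than silently producing an unidentifiable contrast. The
adjusted route is verified against a statsmodels OLS fit of the same
formula.

Benjamini–Hochberg correction is applied within species over tested
proteins only (each species is analyzed separately; untested proteins carry
no evidence). DAP calls use |log2FC| ≥ 1 (inclusive) and adjusted p < 0.05
(strict), with fold change winter − summer on the log2 scale.

## Orthogroup aggregation and convergence

Orthogroup-level fold change is the arithmetic mean of member-protein
log2FCs within a species group; untested proteins and proteins without an
orthogroup assignment are excluded. A species group is a species label
optionally split by year, so within-species year contrasts are first-class
comparisons; with six groups and nine categories the downstream chi-square
has 40 degrees of freedom.

Orthogroup DAP status is "any member protein is a DAP", not a test of the
mean — a mean-based rule would undercount multi-member orthogroups where
one paralog responds strongly. Spearman correlations (average-rank ties)
are computed over all orthogroups quantified in both groups regardless of
DAP status, which matches the observation that pairwise n far exceeds DAP
counts; fewer than 3 shared orthogroups is an error rather than a
meaningless coefficient. Co-occurrence counts are exclusive: each DAP
orthogroup contributes to exactly one class (the exact subset of groups
calling it), so class counts sum to the total by construction, and sharing
fractions (≥ 1 other, ≥ 2 others) are ratios over that total. Top-N
selection orders winter-up DAPs by log2FC descending, then smaller adjusted
p, then protein id — a total order, so output is reproducible.

## Cold-category map and homogeneity test

The nine cold-tolerance categories ship as an editable TSV keyword map
(`rhizoprot/data/categories_default.tsv`): first matching category in
priority order wins; no match falls to "other/uncategorized". The shipped
keywords are a documented, auditable approximation of manual curation —
the goal is reproducibility of the binning procedure, not recovery of any
particular curator's judgment. The homogeneity test is the plain Pearson
chi-square on the species-group × category table (no continuity
correction, df = (r−1)(c−1)); a warning fires when > 20% of expected
counts fall below 5.

## Tiered peptide reassignment

Candidate targets per source protein are ranked by (1) distinct peptide
count, (2) summed bitscore, (3) median percent identity, each descending.
"Distinct peptides" counts unique peptide ids, not alignment positions. The
ladder as stated does not define a total order, so a fourth lexicographic
tier is added for determinism; `decided_at_tier` records the first level
that uniquely ranked the winner, which the engineered test scenarios pin to
their planted tier. Sources colliding on one target have their intensity
rows summed (additive evidence for the same protein), missing + value =
value, and all-missing stays missing; unassigned rows are emitted
separately so total intensity is conserved and auditable. An exact
substring mapper (pident 100, bitscore = 2 × peptide length, Leu/Ile
distinct) stands in for an external aligner in tests and small runs;
optional `min_pident` / `max_evalue` pre-filters are off by default since
no pre-filtering rule is canonical.

## Motif grammar and hydropathy

The 11-mer grammar constrains positions 1, 2, 5, 9 to an apolar set and
positions 6–8 to (+, −, +) or (+, Q, +). Default sets: apolar
{A, T, V, L, I, M, F} (threonine admitted alongside alanine), + = {K, R},
− = {D, E}; histidine is excluded from the charge sets (ambiguous
protonation). The sets are an interpretation — "apolar" is not an
enumerated alphabet anywhere — and are fully configurable on `MotifRule`.
Detection is a greedy left-to-right non-overlapping scan (after a match the
scan resumes 11 residues later); a brute-force all-windows oracle plus the
same greedy selection is the test-side ground truth. `mismatch_allowance`
is 0 by default; the `lenient_pos1` preset tolerates exactly one deviation at
motif position 1, supporting chains whose first repeat deviates there. All
coordinates are 1-based inclusive.

Hydropathy profiles are windowed means of per-residue scale values
(Kyte–Doolittle default, Eisenberg available), window 11 to match the
motif length, undefined (NaN) where the window does not fit; unknown
residues (X) raise by default or skip on request. Position-class statistics
average the profile over residues congruent to each motif position mod 11
within a region. Profile comparison takes an aligned-position pairing
(internal Needleman–Wunsch global alignment, BLOSUM62, gap of length L
costing 10 + (L − 1); or any externally produced alignment), drops gapped
columns, and reports ΔHydro = mean(score_a − score_b) and the Pearson
pattern correlation over the region; < 3 paired positions or zero variance
is an error. Published per-position hydropathy values for real LEA3
orthologs depend on an unstated scale normalization, so recovering them
exactly is treated as an external-validation exercise with configurable
scale options, not a unit-testable claim.

## Synthetic data: what it emulates and what it does not

The abundance generator draws log2 baselines N(20, 2), adds the planted
seasonal effect (±`effect_size_log2` for member proteins of regulated
orthogroups), an additive per-batch offset shared by all proteins of a
batch (the structure the batch-adjusted model must remove), and i.i.d.
Gaussian log2 noise; batches are balanced across seasons so the default
design is never confounded. A `shared_frac` subset of regulated orthogroups
is regulated with one common sign in every species; the rest in exactly one
species. Defaults — effect 3, noise SD 0.3, 4 replicates/season, 5% up +
5% down, 400 orthogroups — are the package's study conditions for recovery
measurements. Not emulated: intensity-dependent variance, correlated
missingness (missingness is uniform), peptide-level rollup, ratio
compression, or isotopic interference; passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to every artifact of real TMT data.

Motif-bearing sequences embed grammar-valid motifs in filler drawn from
{G, S, N, P} — residues outside every grammar alphabet — so any window
starting on filler fails the apolar constraint at position 1 and negatives
are negatives by construction, without rejection sampling; within-motif
offsets cannot start a match either because positions 3, 4, 6, 7, 8, 10, 11
are non-apolar by construction. Insertions are filler of the requested
length placed between two consecutive motifs. Peptide scenarios engineer
decoy targets resolved at each ladder tier in rotation; tier-4 full ties
draw the decoy id to sort before or after the true target, making about
half of them unrecoverable on purpose, which is what drives the monotone
recovery degradation as decoy prevalence rises.

## Determinism and problem sizes

Every generator is a pure function of its config and seed
(`numpy.random.default_rng`). The pipeline uses one master seed with
per-stage seeds derived arithmetically (kept below 2³¹), so partial reruns
are reproducible; re-running from a persisted config reproduces all
deterministic outputs byte-identically. Recovery measurements use 2,000
proteins × 20 simulation replicates for sensitivity/FDR, 50 replicates for
batch-bias, 1,000 random sequences (length ≤ 200) for the motif oracle
comparison, and 500 source proteins for reassignment checks — sizes at
which the binomial error of the measured rates is far below the acceptance
margins while the whole suite stays fast.

## Known limitations

- The adjusted model is fixed-effects only; no mixed models, variance
  moderation (empirical-Bayes shrinkage), or imputation.
- The internal peptide mapper is exact-match; it does not model mutations
  or alignment scores beyond a length surrogate.
- The keyword map is keyword/GO substring matching; it cannot resolve
  descriptions whose category depends on context.
- Spearman inclusion uses all orthogroups quantified in both groups; other
  inclusion rules (e.g. DAP-restricted) would change n and rho.
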