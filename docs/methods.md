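# Methods

## Study design and data model

The package analyses a 2×2×2 mouse design: treatment (Ctrl vs
aggressor-exposed AggE), stress regimen (5-day vs 10-day repeated defeat),
and time point (acute = 24 h after the last defeat; chronic = 1.5–4 weeks
of withdrawal). Eight canonical two-group comparisons are fixed in
deterministic order: AggE vs Ctrl within each regimen × time point (A is
always AggE), then acute vs chronic within each treatment × regimen (A is
always acute). Intensities are non-negative, vendor-style scaled values;
"NA" or empty cells are missing.

Preprocessing (`median_scale_min_impute`) divides each metabolite by its
observed median and fills missing entries with the observed scaled
minimum. Medians and minima use observed values only (scale, then impute),
the convention for vendor metabolomics tables where missingness mostly
reflects values below detection. All-missing and zero-median metabolites
are dropped with a warning. All hypothesis tests run on natural-log
intensities; fold change is the ratio of arithmetic group means on the
original scale, matching how vendor reports pair "FC" with p-values. A
`none` mode skips preprocessing for data that arrive already scaled.

Metabolites observed in fewer than half the samples of a compared group
(or with fewer than two observed values in a group) are reported as
untestable with a reason code rather than dropped silently.

## Univariate screen

Welch's unequal-variance *t* with Satterthwaite df (two-sided). Degenerate
conventions: both groups constant and equal means → p = 1; both constant,
different means → p = 0. The 2×2 ANOVA (treatment × time, regimens pooled)
uses Type-II sums of squares, appropriate for the near-balanced 5–6
mice/cell layout; it reports treatment, time and interaction p-values.
Benjamini–Hochberg step-up q-values are computed within each comparison
over testable metabolites. BH is not idempotent in general (re-adjusting
q-values can raise them further), so only boundedness, dominance over the
raw p-values and order preservation are treated as invariants.

## Direction-of-change machinery

Each metabolite's 8-bit direction profile records whether its group-A mean
exceeds its group-B mean in each canonical comparison. Exact ties are
coded 0 and flagged; on continuous data they have probability ~0.

The pathway direction test is the exact binomial tail
P(X ≥ max(k, n−k)) under Binomial(n, ½) for k of n members up. The
default is this one-sided tail, with a two-sided variant (doubled, capped
at 1) available: the stated convention for this analysis family is
two-tailed, but every reproducible printed value (0.031 for 5/5, 0.004 for
8/8, 0.013 for 16/21) is the one-sided tail, so the default reproduces the
reported semantics and the discrepancy is documented here. Groupings with
fewer than 3 profiled members are skipped — they cannot reach p ≤ 0.1.

The time-point contrast of proportions uses the pooled two-proportion
z-test with Yates continuity correction (|p̂₁−p̂₂| reduced by
(1/n₁+1/n₂)/2, floored at 0), the form R's `prop.test` implements; the
correction is on by default because the reproduced values (0.182, 0.005,
0.002) require it. Degenerate pooled proportions (all up or all down in
both groups) return p = 1.

## Coordination statistic

For a subpathway with k ≥ 2 profiled members, the statistic is the mean of
all C(k,2) pairwise Manhattan (Hamming) distances between 8-bit profiles,
ranging 0 (all members identical in direction) to 8. Because the bits are
0/1, the pair-distance sum equals Σ_c n₁c(k−n₁c) over comparisons c, where
n₁c is the column count of ones — the permutation null is computed from
column counts only, which keeps m = 10,000 draws per subpathway fast.

The null draws m random k-subsets without replacement from all profiled
metabolites; p = (b+1)/(m+1) with b the count of null statistics at least
as extreme as observed, ties counting toward b (the add-one form is
slightly conservative and bounds p in [1/(m+1), 1]). The default tail is
`low` — b counts null mean distances ≤ observed — because coordination
means *small* distances; a `high` tail covers anti-coordination. (A
literal "greater than observed" counting rule would make coordinated
subpathways non-significant, contradicting the reported p = 1E-04 for
strongly coherent branches; the low tail reproduces the reported
semantics.) The resampling universe is the named, profiled metabolites;
unidentified compounds can be included by generating them and leaving them
in the profile table.

Subpathway direction behaviour is summarised as the mean-bit profile
(fraction of members up per comparison). Coordinated subpathways are
clustered agglomeratively (average linkage by default; complete available)
on pairwise L1 distances between mean-bit profiles, with lexicographic
input ordering for deterministic merges, and serialised as Newick text.

## Biomarker workflow

Random-forest importance is the mean decrease in out-of-bag accuracy
(MDA): CART trees are bagged over bootstrap samples (√p features per
split), and for each tree every feature the tree uses is permuted among
that tree's out-of-bag samples; the score is the mean OOB accuracy drop
over all trees. This OOB-permutation loop is implemented in-package over
scikit-learn decision trees, since the classic OOB form of MDA is not
exposed by scikit-learn's forest API. Ranks break ties by metabolite id.

Top-decile lists are the best ⌊0.10·n + 0.5⌋ metabolites (33 of 330); list
overlap is tested with the hypergeometric upper tail P(X ≥ overlap).

The five univariate scores: best single-threshold split by Gini impurity
decrease and by information gain (bits), with exact separators flagged;
Yates-corrected chi-square of the 2×2 table from a median split; the
two-sample Kolmogorov–Smirnov statistic; and a leave-one-out
nearest-centroid accuracy in which equidistant assignments count as errors
(conservative). Samples within 5% of a metabolite's range extremes are
reported alongside the centroid score as "near-extremum" — the qualifier
has no algorithmic role beyond this flag, as no more specific definition
is recoverable.

Candidate consolidation: the union of each method's five top scorers is
grouped by single linkage at Pearson r > 0.7 (log intensities); each
group's representative is the metabolite with the largest maximum raw
intensity; the representative set is expanded with every metabolite
correlating above the threshold with a representative; all Gini exact
separators are added.

Panel search is exhaustive over candidate subsets up to the panel-size cap
(guarded at 10⁶ subsets). DD-KNN ("distance-dependent" KNN) is read as
inverse-distance-weighted voting — k = 3 neighbours by Euclidean distance
on z-scored log intensities (training-fold statistics only), votes
weighted 1/(d+ε) with ε = 10⁻⁹; uniform and 1/d² weightings are options.
The rule-based classifier fits one threshold rule per panel member
(direction and midpoint cutpoint maximising training balanced accuracy,
lowest qualifying cutpoint on ties) and combines rules by majority vote.
Both are evaluated by leave-one-out confusion counts with AggE as the
positive class; panels are ranked by balanced accuracy with deterministic
tie-breaks (smaller panel, then lexicographic members).

## Synthetic data generator

The generator emulates the study's shape: 330 named metabolites in 65
subpathways under 7 superpathways with the fuel superpathways at their
reported sizes (Carbohydrate 21, Amino acid 98, Lipid 134), a full
2×2×2 design with 6 mice per cell, per-metabolite log-normal intensities
(log-mean ~ N(0,1), log-sd ~ U(0.2, 0.6) — typical untargeted plasma CVs),
and 5% missing-at-random dropout applied after effects. Effects are
multiplicative and target metabolite lists, subpathways or superpathways
in one of three scopes: AggE samples at acute time points, AggE samples at
chronic time points, or all acute samples (a pure time effect). A
coherence parameter sets the fraction of target metabolites receiving the
stated sign. Every non-zero net injected log-FC per canonical comparison
is recorded in a truth table. One integer seed drives a single root
generator with fixed draw order, so runs are byte-identical.

The paper-like preset injects: the five gut-derived metabolites
(phenylpropionylglycine, hippurate, 3-phenylpropionate, phenol sulfate,
p-cresol sulfate) elevated 6.7-fold acutely and 2.8-fold chronically;
carbohydrates up acutely (+1.5-fold, coherence 0.8) and down chronically
(−1.4-fold, coherence 0.75); amino acids down chronically; lipids up
chronically (+1.5-fold, coherence 0.8); and conjugated bile acids down
1.32-fold acutely then up 3.12-fold after withdrawal.

What the generator does **not** emulate: inter-metabolite correlation
within pathways (metabolites are independent given the injected effects),
shared per-mouse scaling, left-censored missingness, batch effects, or the
166 unidentified compounds' annotation behaviour (they can be generated
but default to 0). Passing tests therefore demonstrate correct statistical
machinery and calibration under independence, not performance under the
correlated noise of real plasma data — on real data the permutation null
(which resamples real profiles) remains valid, but power statements from
the simulations do not transfer directly.

## Calibration notes and problem sizes

Null calibration uses eight effect-free generator runs (520 subpathways,
≥ 500). The coordination test's rejection rate at α = 0.05 is ~0.04 —
slightly conservative because tied null statistics count toward b. The
exact binomial scan is markedly conservative at the study's subpathway
sizes (3–10 members): its attainable size per n is 0 (n = 3, 4), 0.0625
(n = 5), 0.031 (n = 6), 0.016 (n = 7), 0.070 (n = 8), 0.039 (n = 9),
0.021 (n = 10), giving a size-weighted null rejection rate of ~0.02. This
is a property of discrete exact tests at small n, not a miscalibration;
the rate rises toward nominal only for larger groupings.

Calibration and recovery simulations in the test suite and acceptance
script use m = 999–2,000 permutation draws per test (p resolution well
below the α = 0.05 and 0.01 decision points) and 8–20 generator seeds;
the package default for a single reported analysis remains m = 10,000.
Numerical conventions: permutation tie tolerance 1e-12; clustering merges
tie-break lexicographically; rank ties break by metabolite id; KNN weight
ties predict the negative (Ctrl) class.

## Known limitations

- The two-proportion z-test treats the up/down counts of a pathway at two
  time points as independent binomials; members are shared between time
  points, so the test is approximate (as in the original analysis).
- The binomial direction test treats member metabolites as independent
  coins; correlated members inflate its false-positive rate on real data —
  the coordination statistic, whose null resamples observed profiles, is
  the robust companion.
- ANOVA pools regimens into a 2×2 layout; regimen-specific time effects
  surface only in the per-comparison Welch screen.
- The exhaustive panel search guard (10⁶ subsets) limits candidates to
  ~100 at panel size 3.
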