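# Methods

`cublink` implements a codon-usage-bias (CUB) analysis linking a query
organism (the plant side of a plant-PGPR pair, e.g. *Arabidopsis thaliana*)
to a partner organism (the bacterium side, e.g. *Bacillus
amyloliquefaciens*): per-gene CUB indices, host-adaptation indices against a
reference organism, a gene-by-gene RSCU correlation screen, and an
expression-response stage (DEG merging, short-series model-profile
clustering with an exact permutation null, and 2^-ddCt relative
quantification). A synthetic-data generator produces every input with known
ground truth.

## Codon-usage indices

All indices operate on per-gene codon counts in frame 0 under the standard
genetic code (NCBI table 1). For CDS-internal codons the bacterial table
(11) makes identical assignments, so one table serves both organisms. A
terminal stop codon, when present, is excluded from every count; CDS dumps
are inconsistent about including it.

**RSCU.** RSCU_c = x_c / ((1/k) Σ_{c'∈fam} x_{c'}) for a family of size k.
Families with zero usage in a gene yield *undefined* entries, carried as
NaN plus explicit masks and pairwise-deleted downstream — never zero-filled,
because fabricated zeros both distort correlations and silently shift
family sums. Family sums equal k whenever the family is observed;
single-codon families (Met, Trp) are excluded from all bias statistics.

**ENC** (Wright's effective number of codons). Per family with n ≥ 2
occurrences, homozygosity F = (n Σ p_i² − 1)/(n − 1); F values ≤ 0
(possible at small n) are dropped. Class means F̄_k average F over families
of equal degeneracy; Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61.
The sixfold families (Leu, Ser, Arg) are treated as single 6-fold classes,
per the original formulation — tools that split them 2+4 will differ
slightly. A missing F̄₃ (Ile absent) is imputed as (F̄₂ + F̄₄)/2; if any
other class has no usable F the gene's ENC is undefined and reported as an
exclusion, not silently dropped.

**Expected ENC curve.** ENC_exp(s) = 2 + s + 29/(s² + (1−s)²) with s = GC3.
Genes far below the curve are biased beyond what mutation pressure alone
explains.

**SCUO.** For each amino acid with k ≥ 2 and n > 0, orderliness
O = (log₂k − H)/log₂k with H the Shannon entropy of the within-family
frequencies; SCUO is the usage-weighted mean of O, 0 (uniform) to 1 (one
codon per family).

**PR2.** A gene is placed at (G3/(G3+C3), A3/(A3+T3)). By default third
positions are restricted to the five strictly fourfold-degenerate families
(Ala, Gly, Pro, Thr, Val), where the third base is fully synonymous; the
fourfold boxes of sixfold families are excluded because their usage also
reflects the choice between boxes. An all-third-positions mode is available
(`fourfold_only=False`) since published analyses do not always state their
convention. Quadrants use strict inequalities; exact 0.5 on either axis is
labelled `boundary` and excluded from the four quadrant counts, so counts
are deterministic.

## Host-adaptation indices

**CAI.** Relative adaptiveness w_c = x_c / max(x over family) from the
host's pooled CDS counts; zero reference counts get a 0.5 pseudocount first,
so all weights are positive and each family maximum is exactly 1. A gene's
CAI is the count-weighted geometric mean of w over its informative codons.
The reference set is the entire host CDS collection, not a curated
highly-expressed subset; any FASTA can be substituted as the reference.

**RCDI.** RCDI = (1/N) Σ_c (CiF_gene(c)/CiF_host(c)) · x_c over informative
codons, with CiF the within-family relative frequency (host frequencies
pseudocounted the same way) and N the gene's informative codon total. RCDI
is exactly 1 iff the gene's within-family frequencies match the host's on
every observed family.

**SiD.** SiD = (1 − R)/2 with R the cosine similarity of two
organism-level usage vectors: 0 means identical direction, 0.5 orthogonal.
The default basis is organism-level RSCU over the 59 informative codons,
matching the screen's standardization; raw codon frequencies are available
via `basis="frequency"` since the published organism-level value does not
state its basis.

## The similarity screen

Each query gene's 59-entry RSCU vector is correlated (Pearson) with the
partner's organism-level RSCU vector; codons undefined in either vector are
pairwise-deleted and genes with fewer than 10 usable codons are flagged
untestable. p-values come from t = r√((n−2)/(1−r²)) with n−2 df,
two-sided; selection is r ≥ 0.5 and p < 0.05 with **no multiple-testing
correction by default** (the convention of the published screens this
follows; Benjamini–Hochberg is available via `fdr="bh"`). A best-gene mode
correlates against every partner gene instead and reports the best match;
the profile mode is the default because it yields exactly one test per
query gene. Output ordering (descending r, ties by gene id) is
deterministic.

**Known property: the nominal p-values are anticonservative.** RSCU entries
within a family sum to the family size, so both the gene vector and the
profile deviate from their (exactly 1) means inside a 41-dimensional
subspace of the 59 codon coordinates (59 codons minus 18 family
constraints), while the t reference assumes 57 free dimensions. Under a
true null the p < 0.05 fraction therefore lands near 0.09–0.13 rather than
0.05 (the acceptance script recomputes this as
`screen_null_fraction_p_below_005`). The screen is still a faithful
implementation of the conventional procedure, and its *selection* behaviour
is dominated by the r ≥ 0.5 threshold at realistic gene lengths; but the
p-values should be read as a ranking device, not calibrated error rates.
`fdr="bh"` tightens but does not repair this.

## Expression response

**DEG merging.** Differential-expression fitting is out of scope: two
methods' tabular calls (gene, log2FC, p, adjusted p) are consumed, each
thresholded at adjusted p < 0.05 and |log2FC| ≥ 1 (a raw fold-change
threshold of 1 would be vacuous, so the fold threshold is interpreted on
the log2 scale; both knobs are configurable). Common up = up ∩ up, common
down symmetric; genes called in opposite directions are excluded and
reported. The merge is symmetric in its arguments.

**Model profiles.** Candidates are all integer templates of length T
starting at 0 with per-step change in [−c, c] — (2c+1)^(T−1) of them
(27 at T=4, c=1; 125 at c=2). m representatives are selected greedily by
max-min correlation distance d = 1 − r, starting from the candidate
farthest from the flat profile; the flat profile is never a selection
candidate and correlation with it is defined as 0 (distance 1), so the
first pick — and every tie — is resolved lexicographically, making the
selection fully deterministic. Defaults T=4 (Control, Bacterium, Calcium,
Calcium+Bacterium), c=2, m=50, the conventional short-series defaults.

**Assignment and significance.** Per gene, v_t = s_t − s_baseline with s_t
the group mean of log2(CPM+1); genes with zero variance stay unassigned,
ties go to the lower profile id. CPM uses per-sample totals of the supplied
matrix unless `library_sizes` is given — pass the full matrix's totals when
clustering a subset, otherwise a signal shared by most subset genes is
absorbed into the scaling (a compositional artifact the analysis scripts
avoid this way). The null assignment distribution is computed by exact
enumeration of all T! = 24 permutations of each gene's v — cheap at T=4 and
free of Monte-Carlo noise; per profile, significance is the upper-tail
binomial probability of the observed assigned count at the
permutation-expected proportion, Bonferroni-corrected by m. The *rescue*
profile (0, 0, +k, 0) — elevated under calcium stress, restored by the
bacterium — is identified by exact shape match among the selected profiles
(falling back to the best-correlated one) and reported by id.

**Assignment noise floor.** With NB dispersion φ the group-mean log2 noise
per entry of v is ≈ √φ/ln2/√(replicates), independent of expression level.
At φ = 0.1 and 3 replicates this is ≈ 0.26, while the m = 50 profile set
contains several neighbours of the rescue pattern at r ≥ 0.85; even with
idealized Gaussian noise at that floor at most ~85% of genes planted on the
rescue pattern are assigned to it, and realistic count-level noise yields
~60–70% (the acceptance script recomputes this as
`rescue_profile_recovery`). Recovery above 90% requires φ ≲ 0.05. Profile
*significance* is far more robust than per-gene assignment and is the
statistic to interpret.

**2^-ddCt.** Per sample, dCt = Ct_target − Ct_reference (reference gene
GAPDH by default); ddCt subtracts the control-group mean dCt of the same
target; fold = 2^−ddCt. Samples missing the reference are dropped with a
warning. The control group's geometric mean fold is 1 by construction, and
folds are invariant to any global Ct shift.

## Synthetic data

The generator defines the study conditions used throughout the tests and
analyses:

* **CDS sets.** Amino-acid sequences are drawn from a fixed proteome-like
  background composition; codons are drawn per family from an organism
  model with per-gene Dirichlet jitter (concentration 60, so genes scatter
  realistically around the organism's usage). Lengths are log-normal with
  median 300 codons (sd 0.35 on the log scale, floor 60). Every gene starts
  with ATG, ends with a stop and contains no internal stop or ambiguous
  base, so generated FASTA passes strict QC untouched. The default organism
  models are fixed and seeded: a plant-like model with a moderate A/T-ending
  tilt (β = −0.5) and a bacterium-like model with a mild G/C lean
  (β = +0.3), each with family-specific Dirichlet structure — emulating the
  shared A/T-ending preference plus organism-specific codon choices seen in
  such pairs. Planted "similar" genes draw codons from
  (1−λ)·own + λ·partner, so similarity is continuous in λ and recovery
  curves are meaningful.
* **Counts.** Negative binomial with var = μ + φμ², default φ = 0.1 (a
  realistic bulk-RNA-seq biological dispersion), per-gene log-normal
  baselines around 100 (sd 0.6 on the natural-log scale), four groups ×
  three replicates. Planted genes multiply their group mean by
  2^(effect·pattern_t). Two DEG tables per contrast are fabricated by
  deliberately simple recipes — a Welch t-type test on log2(CPM+1) and an
  exact Mann–Whitney test — because the artifact tests *merging*, not the
  estimators. The exact rank test cannot reject at 3v3 replicates (minimum
  two-sided p = 0.1), which is faithful to its discreteness; the z-type
  recipe is approximately calibrated. For exact merge arithmetic,
  `simulate_deg_tables` fabricates call tables with planted common/only/
  conflict blocks directly.
* **Ct tables** are built backwards from true fold changes, exactly
  recoverable at zero noise.

What the generator does **not** emulate: real gene structure (introns,
UTRs, start-context), expression-correlated codon bias, GC-content
covariates between expression and usage, batch effects, or library-size
artifacts beyond per-sample scaling. Passing tests therefore demonstrate
the correctness and operating characteristics of the computations, not that
biological conclusions transfer to any real organism pair.

## Numerical choices

Undefined values are NaN plus explicit flags, never silent zeros; summary
tables count exclusions. Correlations with fewer than 3 complete pairs are
undefined. Assignment correlations are rounded to 12 decimals before
argmax so exact ties break by profile id rather than floating-point noise.
All randomness flows through one `numpy` generator per call, seeded
explicitly; identical seeds give byte-identical files, and the pipeline
manifest records sha256 checksums of every output so reproducibility is
checkable. Problem sizes in the analysis scripts and acceptance script
(2,000 genes per organism, 2,000-gene count matrices) keep every stage
within seconds while leaving planted-structure recovery well-powered.

## Known limitations

* The screen's nominal p-values are anticonservative (see above); the
  selection threshold r ≥ 0.5 carries the specificity.
* Per-gene profile assignment saturates below 100% recovery at realistic
  dispersions; interpret profile-level significance, not single-gene
  membership.
* CAI uses the whole host CDS set as reference; expression-weighted
  references are deliberately out of scope.
* The published organism-level numbers for a real genome pair depend on the
  exact (unversioned) assemblies; this package reproduces the *procedure*
  and validates it on synthetic ground truth.
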