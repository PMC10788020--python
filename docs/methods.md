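# Methods

## Scope and model

`cubtk` treats a set of validated coding sequences as draws from per-gene
codon-usage distributions and summarises departure from uniform synonymous
usage. All statistics are functions of sense-codon counts under the
standard genetic code (translation table 1): the 61 sense codons, of which
59 carry synonymous choice (Met and Trp are singletons). The terminal stop
codon is stripped before counting, so every reported codon count is a
sense-codon count.

## CDS validation

A candidate is kept when it starts with ATG; ends with TAA, TAG or TGA;
is at least 300 bp long (inclusive bound, configurable — inclusive so that
short genes of exactly 100 sense codons are not silently dropped); has
length an exact multiple of 3; contains only A/C/G/T; has no internal stop
codon (an untranslatable CDS would corrupt every downstream statistic);
and is not an exact string duplicate of an earlier candidate (first
occurrence kept). All reasons for rejection are recorded per candidate,
not just the first. GenBank CDS features are extracted with join()
segments concatenated in feature order and complement() features
reverse-complemented, using 1-based inclusive coordinates.

## Statistics

**RSCU.** RSCU_ij = k_i x_ij / Σ_j x_ij. A family with zero usage yields
NaN (not 0) for its codons, so "unused" and "avoided" are distinguishable.
Family sums equal the degeneracy whenever defined.

**Silent-site composition.** GC3s is the fraction of synonymous codons
ending G or C. Each X3s is availability-normalised: its denominator counts
only codons whose family contains an X-ending synonym. The four X3s values
therefore need not sum to 100 — this matches the convention of the classic
codon-usage programs, where the four silent-site base fractions typically
sum to well over 100%.

**ENC.** Wright's estimator. Per family with usage n ≥ 2, homozygosity
F̂ = (nΣp² − 1)/(n − 1). Families with n < 2 or F̂ ≤ 0 are skipped when
averaging within a degeneracy class (the estimator is undefined at n ≤ 1
and a zero homozygosity would send the class term to infinity). ENC =
2 + 9/F̄₂ + 1/F₃ + 5/F̄₄ + 3/F̄₆, capped at 61 because the estimator can
exceed the theoretical maximum on small samples. A missing 3-fold class
(Ile) is imputed as F₃ = (F̄₂ + F̄₄)/2; any other empty class makes ENC NaN
with a warning — transparent failure rather than silent rescaling. Real
organellar genes of ≥ 100 codons essentially never trigger this, but very
small toy counts with exactly uniform 4-/6-fold usage do (every such
family has F̂ = 0 exactly), which is why the estimator is undefined there.

**CAI weights.** The classic programs do not fix a reference set for
organellar genomes; here the default reference is the pooled counts of the
lowest-ENC 10% of the input genes (the same high-bias group used for
optimal codons), overridable with any user-supplied gene set. Zero counts
are replaced by 0.5 before normalising by the family maximum so log-weights
stay finite. Because the reference is data-derived, CAI/CBI/Fop values are
comparable within a run but not across differently composed inputs.

**CBI and Fop.** Computed over families containing at least one optimal
codon: Fop = N_opt/N_syn and CBI = (N_opt − N_rand)/(N_syn − N_rand) with
N_rand = Σ n_fam · (#optimal in family)/degeneracy. The default optimal
set is the one derived from the input by the group-contrast rule.

**ENC-plot.** Expected ENC uses Wright's denominator s² + (1−s)²; a
first-order variant of the denominator that circulates in print is
available as `variant="as-printed"` for audit but is not the default (it
gives ≈ 41.2 at s = 0.5, inconsistent with every published ENC-plot
curve). The ENC-ratio histogram uses width-0.05 bins over [−0.15, 0.25],
left-closed.

**Neutrality plot.** OLS of GC12 on GC3 as fractions; Pearson r with the
two-sided t-test on n−2 df. Raised errors, not NaN, for < 3 genes or zero
GC3 variance.

**PR2.** Restricted to exactly Val/Pro/Thr/Ala/Gly: the fourfold
subfamilies of Leu/Arg/Ser are excluded, because their 2-fold halves mix
amino-acid identity into the third-position signal. Counts are pooled per
gene (not averaged per amino acid). A zero denominator yields NaN for that
axis only.

**Correlations.** Pairwise Pearson r over CC, GC1, GC2, GC3, GCall, GC3s,
ENC, CAI, CBI, Fop with unadjusted two-sided p-values and 0.05/0.01 stars;
no multiple-testing correction, matching how such matrices are reported.

## Optimal codons

Genes with defined ENC are ranked ascending; the first and last
k = max(1, round-half-up(0.10·N)) form the high- and low-bias groups (ties
at the boundary broken lexicographically by gene id, for determinism).
Round-half-up is used because it is the only reading that makes 10% of a
28-gene set integral (k = 3). RSCU is computed on each group's pooled
counts; a codon is optimal iff RSCU_high > 1 strictly and ΔRSCU =
RSCU_high − RSCU_low > 0.08 strictly. Both inequalities are strict: on the
published reference contrast shipped with the package, a codon with
RSCU_high exactly 1.00 and a codon with ΔRSCU above threshold but
RSCU_high 0.95 are both excluded, and only the strict rule reproduces the
published 22-codon optimal set exactly. High-frequency codons use the
whole-set pooled RSCU with the same strict > 1.

## Species clustering

Each species contributes the RSCU vector of its pooled counts over the 59
synonymous codons (stop, Met, Trp codons excluded). Distances are squared
Euclidean; linkage defaults to between-groups average (the default of the
common statistics packages used for such dendrograms), with complete and
single available. Variables are not standardised — RSCU is already
family-normalised to a common scale. Rows are sorted by species label
before linkage so the topology is independent of input order. Newick
export writes merge heights as branch lengths; topology, not heights, is
the meaningful output.

## Synthetic data generator

`synthetic_cds` emulates the statistical structure of an organellar CDS
set: gene lengths uniform over 101–673 codons by default (the span
observed in plant mitochondrial gene sets), ATG start, single terminal
stop, no internal stops. Amino acids are drawn uniformly over the 20
(simplicity over realism; configurable via custom weights), then codons
i.i.d. from a per-family regime distribution:

- `uniform`, `single_codon` — the two ENC extremes (61 and 20);
- `dirichlet(concentration)` — graded skew, drawn once per regime;
- `gc3_target(level)` — mass `level` on G/C-ending synonyms, varying GC3
  while leaving GC1/GC2 governed by amino-acid composition (the
  selection-like regime: neutrality slope ≈ 0);
- `mutation_equilibrium(level)` — codons drawn over all 61 sense codons
  with probability proportional to the product of per-position base
  probabilities at GC level `level` (the neutral regime: GC12 tracks GC3,
  neutrality slope ≈ 1);
- a `high_bias_fraction` of genes can instead favour a recorded preferred
  codon set (default: one A/T-ending codon per family) with weight 0.8 —
  used for optimal-codon recovery tests.

`gc3_level` may be a range, sampled per gene, which is what gives the
neutrality regressions their spread. All randomness flows through one
`numpy` Generator seeded from the spec; the seed, regime assignments,
probability tables and realized GC3 are recorded in a `TruthRecord`.

What the generator does *not* emulate: real amino-acid composition,
length–function correlation, strand asymmetry, RNA editing, and
phylogenetic correlation between genes. Passing recovery tests therefore
demonstrates correctness of the estimators under i.i.d. codon sampling,
not that real mitochondrial data satisfy those assumptions.

## Numerical choices

Internal computation is full-precision float (exact integer counts where
possible); rounding is half-up and applied only in report writers — 2
decimals for percentages and ENC, 4 for slope and r. Codons are DNA
internally and transcribed to RNA only in user-facing tables. Degenerate
inputs raise (`ValueError`) rather than returning silent NaN wherever the
result would be scientifically meaningless: empty gene sets, zero-variance
regressors, empty synonymous families in a clustering matrix.

## Problem sizes in the test suite

Property tests use 100 genes of ~500 codons for regression recovery, one
10⁵-codon gene for PR2 centring, and 6-species sets over 5 seeds for
cluster-separation checks — sizes at which binomial sampling error is
comfortably inside the asserted bounds (verified by simulation) while the
whole suite stays fast.

## Known limitations

- ENC is Wright's original estimator; the rare-amino-acid corrections of
  later authors are not implemented.
- CAI depends on the data-derived reference set (see above); absolute CAI
  values are not comparable to publications using a different reference.
- The optimal-codon rule is the ENC-extreme group contrast only; no
  expression-weighted definition.
- No phylogenetic tree inference from sequence alignments: the RSCU
  dendrogram is a usage-similarity summary, not a phylogeny.
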