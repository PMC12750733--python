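# Methods

This note documents the statistical machinery implemented in `duinet`,
the assumptions of the synthetic-data generators, and the numerical and
design choices made where the design was genuinely open.  All empirical
statements here are computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external runs.

## Relative-rate convergence scan

For each gene (orthogroup) tree the per-species **relative evolutionary
rate** is

    r_s = log( d_s(gene) / d_s(species) ) − median_s' r_s'

where `d_s` is the root-to-tip path length on the topology shared by the
gene tree and the reference species tree.  Median centring removes the
gene-wide rate factor, so `r_s` is invariant to global rescaling of the
gene tree.  The convergence statistic aggregates every foreground
(DUI) × background (SMI) species pair:

    T = Σ_p w_p (r_fg − r_bg) / Σ_p w_p

Negative `T` means foreground lineages evolve relatively slower
("constrained"), positive means "accelerated".

**Pair weighting.** Two weightings are implemented.  `uniform` reduces
`T` to the difference of foreground and background means.  The default,
`mrca_depth`, gives each pair weight `1/m` where `m` is the number of
pairs whose comparison passes through the same MRCA node.  The default
matters: foreground species come in clades, and a clade of k tips
contributes k nearly-redundant pairs against every background species.
Redundancy weighting both raises power for genuine clade-level shifts and
suppresses the both-direction inflation that phylogenetically clustered
*random* taggings otherwise show, which is essential for the control
harness below.

**Significance.** `p = (1 + #{|T*| ≥ |T|}) / (n_perm + 1)` with
permutations redrawing the foreground set, of the same size, uniformly
among the tips present in the gene tree (default `n_perm = 999`; the
pipeline uses 499).  This permutation p-value is exact under label
exchangeability — the calibration experiments draw the tagging uniformly
and recover the nominal 5% rejection rate.  Under the *clustered* DUI
tagging tips are not exchangeable with uniform redraws, and the test is
only approximately calibrated (mildly conservative with uniform weights,
mildly anti-conservative with MRCA weights).  That residual geometry
sensitivity is exactly why the analysis design carries its own controls:

**Control harness.** `control_scan` re-runs the scan under (a) the true
tagging, (b) `n_random = 50` uniform taggings of 10 background species,
and (c) a phylogenetic control tagging the nearest background relative(s)
of each foreground clade (clade-sized, by patristic distance).  Each run
is summarized by its fraction of genes with `p < α`, split by direction,
and the true run is ranked among the random runs (rank 1 = most
enriched).  Rank ties are broken uniformly at random from the scan's
seeded generator, so under a fully exchangeable null the rank is uniform
on 1..51 even when many runs tie at zero.

## Branch-model selection test

The GY94 codon model over the 61 sense codons of the standard code:
`q_ij = π_j · κ^[transition] · ω_c^[nonsynonymous]` for single-nucleotide
codon changes, zero otherwise; rows normalized so one unit of branch
length is one expected substitution under the *background* class, which
keeps foreground and background branches on a common scale.  Foreground
branches are the terminal branches of foreground tips plus internal
branches whose descendant tips are all foreground ("DUI clades").

The likelihood is Felsenstein pruning over compressed site patterns;
`P(t) = exp(Qt)` is computed from the symmetric eigendecomposition of the
π-reversible generator (the matrix `Π^{1/2} Q Π^{-1/2}` is symmetric), so
a full likelihood evaluation needs two 61×61 eigendecompositions plus one
batched matrix product per branch.  Gaps and ambiguous codons are
marginalized; in-frame stops are an error naming sequence and site.

`branch_model_lrt` fits the one-ratio model (κ, ω, one branch-length
scalar) and the two-ratio model (κ, ω_bg, ω_fg, scalar) by bounded
L-BFGS-B in log-parameter space (ω ∈ [10⁻⁴, 10], κ ∈ [0.1, 20]).  Branch
lengths are taken from the input tree and rescaled by a single free
scalar per model rather than fully re-optimized — a deliberate
tractability choice for desk-scale fitting.  The two-ratio fit is
warm-started at the one-ratio optimum, which both guarantees
`lnL1 ≥ lnL0` up to optimizer tolerance and roughly halves the cost; one
additional randomized start is used by default.  `Λ = 2(lnL1 − lnL0)` is
referred to χ²(1), and `Δω = ω_fg − ω_bg < 0` is the convergent-
purifying-selection criterion.  Codon frequencies default to empirical
F1×4 (uniform and user-supplied vectors are available); nucleotide
frequencies are floored at 10⁻⁶ so the reversible symmetrization stays
well-posed.

## Evolutionary rate covariation (ERC)

Root-to-tip distances of the gene tree and of the mitochondrial tree are
computed on their shared species (minimum 10), adjusted for phylogenetic
non-independence with **phylogenetic independent contrasts** on the
reference species tree pruned to those species, and the gene contrasts
are regressed on the mito contrasts **through the origin** — the standard
treatment for contrasts, whose expectation is zero.  The t statistic for
the slope uses n−1 residual degrees of freedom; contrasts are signed (an
absolute-value mode is deliberately not the default).  Under independent
Brownian evolution of the two distance vectors the p-value is uniform,
which the calibration suite verifies.

PIC follows Felsenstein's recursion with deterministic post-order (child
subtrees ordered by smallest tip label) so outputs are reproducible;
zero-length terminal branches are nudged by ε = 10⁻⁸ before the
recursion, and a zero-length internal cherry is an error rather than a
silent fix.

Over-representation of significant ERC among convergently evolving genes
uses a 2×2 chi-square (no continuity correction) or Fisher's exact test;
degenerate margins refuse the chi-square.

## Expression stage

Egg pools are labelled from operator-scored fractions of
aggregated-pattern embryos: the median across operators is the sex-ratio
proxy; `median ≥ 0.70` is male-biased, `1 − median ≥ 0.70` female-biased,
otherwise unassigned.  Features need cpm ≥ 2 in at least one sample
(library sizes from the unfiltered matrix).  TMM normalization follows
the trimmed-mean-of-M definition: reference sample = upper-quartile cpm
closest to the mean upper quartile; per-sample log-ratios doubly trimmed
(30% on M, 5% on A, rank-based) and averaged with inverse-variance
weights; factors rescaled to geometric mean one; normalized values are
cpm on effective library sizes.

**Differential deposition.** Per feature, `M = log2((x̄_A + ½)/(x̄_B + ½))`
and `D = |x̄_A − x̄_B|` on normalized values.  The null re-splits the
feature's *own* eight samples into balanced pseudo-groups — all 70
balanced splits are enumerated (random splits are drawn when the design
has more than `n_null` splits) — and `prob` is the fraction of null
pairs strictly dominated (`|M*| < |M|` and `D* < D`); a feature is
called at `prob > 0.95`.  Two points are deliberate: (i) the null is
**per-feature**, because a pooled cross-feature null makes joint (|M|, D)
dominance abundance-biased — a low-abundance feature can never dominate
the large-D tail contributed by abundant features, regardless of effect
size; (ii) dominance is **strict**, so the complementary exceedance count
includes the observed split itself and the call rate stays conservative
under the null (measured ≈ 2–3% at q = 0.95).  The decision geometry —
joint |M|/D exceedance against an empirical null with a `prob > q` call —
is retained from the nonparametric DE method it stands in for.

Called features are tested for Spearman correlation with the per-sample
offspring sex ratio; for n ≤ 9 without ties the p-value is exact (the
null distribution of ρ is enumerated over all n! rankings and cached),
otherwise asymptotic.

## lncRNA hits and the interactome

Similarity hits are kept when strictly longer than 100 bp, covering more
than 50% of the lncRNA and above 90% identity; coordinates are 0-based
half-open internally (the 12-column tabular dialect is converted on
read).  A hit belongs to a gene when contained in the gene body ± 100 bp
on the same sequence; orientation is antisense when strands differ; hits
spanning several genes yield one assignment each.  Enrichment inside a
focal gene set resamples same-size gene sets uniformly from the universe
(`p = (1 + #{null ≥ obs})/(n_resample + 1)`); a length-stratified null is
a documented alternative, since longer genes catch more hits.

Interactome edges below score 0.400 are dropped at load.  Edge
enrichment of a node set resamples uniform node sets of equal size —
the expected-edge count is a resampling mean, not an analytic formula,
so printed "expected edges" from other tools are not numerically
reproduced.  Stress centrality is Shimbel stress: the number of shortest
paths between unordered pairs (s, t), s ≠ v ≠ t, through v, counting all
co-optimal paths (ordered-pair counting would exactly double it);
computed by all-pairs BFS with path counting.  Degree/Stress/neighborhood
connectivity contrasts between CE and DE products use two-sided
Wilcoxon rank-sum and two-sample Kolmogorov–Smirnov tests.

## Synthetic data: what it emulates, and what it does not

* **Species tree** — random ultrametric merges with lineage-proportional
  waiting-time increments, rescaled to mean branch length 0.1
  substitutions/site; 36 taxa, six foreground clades (sizes 2,2,2,2,1,1)
  separated by background tips, three monophyletic subclasses.
  Ultrametricity makes root-to-tip depths constant, so reference-tree
  depth structure cannot masquerade as rate covariation; the
  lineage-proportional increments give the long terminal branches typical
  of sparse taxon sampling across a deep clade (which also carries most
  of the convergence signal, since rate shifts act on terminal and
  within-clade branches).
* **Gene trees** — branch lengths `b · g_gene · ε_e · m` with lognormal
  gene rate (sd 0.3), lognormal edge noise (sd 0.2 by default), and
  `m = 0.3` on foreground branches of constrained genes (1/0.3 for
  accelerated); tips dropped at 10% with resampling until the ≥15
  species / ≥4 DUI retention rule holds ("filter-safe").
* **Mito-nuclear covariation** — one lognormal branch-rate field `η_e`
  (sd 0.35) shared between the mitochondrial tree and ERC-linked genes;
  unlinked genes receive independent fields of matched variance.  The sd
  is a free parameter of this package (no empirical estimate exists):
  large enough that linked genes are detectable, small enough not to
  drown the planted convergence shifts.
* **Counts** — negative-binomial with
  `μ_fs = L_s · q_f · 2^(lfc_f · x_s)`, `x_s` the centred sex ratio;
  default 8 samples at ratios 0.95…0.05 (4 vs 4), dispersion 0.1,
  lognormal relative abundances (sd 1.5), planted |lfc| = 3 with most
  planted features higher in female-biased eggs, matching the direction
  asymmetry of the system.
* **Hits / interactome** — length-weighted hit placement with a focal-gene
  multiplier; Erdős–Rényi background with a planted dense cross-module;
  all scores ≥ 0.400 so the graph survives the load filter.

What the generators do **not** model: read-level noise, assembly and
orthology errors, alignment uncertainty, correlated expression between
features, degree-heterogeneous (scale-free) interactomes, and real
genome structure.  Passing tests therefore demonstrate that the
*inference machinery* is correct and calibrated under its assumed
statistical structure — not that the biological conclusions of any real
dataset are reproduced.

## Problem sizes and numerical choices

Calibration and recovery experiments run at sizes chosen to make their
binomial/KS tolerances meaningful on a single CPU: 1 000 genes × 199
permutations for the convergence null; 200 null replicates of 10-taxon,
200-codon alignments for the LRT χ²(1) check; 100 replicates at 300
codons for Δω sign recovery; 500 Brownian replicates for ERC; 200
replicates each for the resampling-enrichment nulls; 24 meta-replicates
for null-rank uniformity.  The default pipeline configuration (120
orthogroups, 3 000 features, 50 random control taggings, 499
permutations) is sized to finish in a few minutes while keeping every
planted signal at detectable strength.

Determinism: every public generator and test is a pure function of
(parameters, seed); the pipeline fans one master seed out on a fixed
per-stage schedule, writes TSVs with a fixed float format, and sorts JSON
keys, so repeated runs are byte-identical.

Known limitations: the convergence statistic summarizes whole root-to-tip
paths, so shifts confined to short internal branches are diluted; the
branch-model fit rescales rather than re-optimizes branch lengths; the
ERC regression inherits the usual caveat that root-to-tip distances share
path segments across species even after contrasts; and the empirical-null
DE call has the resolution of the 70 balanced splits available in a
4-vs-4 design (finest attainable q step ≈ 0.014).
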