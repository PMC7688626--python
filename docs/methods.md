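# Methods

This note documents the statistical models behind `mirscreen`, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical conventions used throughout.

## Differential expression

**miRNA layer.** Each miRNA is tested with a two-sample Student t-test
(pooled variance) on log2(CPM + 1), two-sided, and called DE at p < 0.05
with no fold-change requirement.  The log scale stabilises the variance of
count-derived abundances at typical small-RNA depths; the pooled variant is
the default because it matches common small-n practice and the pooled-error
convention of the LSD post hoc used downstream (Welch is available via
`equal_var=False`).  Whether raw, normalised or log counts should feed the
t-test is genuinely open in this kind of screen; CPM+log is the package's
choice and is exposed in one place (`call_de`).

**mRNA layer.** Counts are first equalized: every sample is scaled to the
geometric-mean library size and rounded half-to-even to integer
pseudocounts.  Each gene is then tested with a negative-binomial exact test:
under a shared per-sample mean and a common dispersion φ (Var = μ + φμ²),
the test conditions on the combined total *t* of the two groups and sums the
probabilities of every split of *t* that is no more likely than the observed
one (group sums are NB with sizes adding across samples).  At φ = 0 the
conditional distribution is Binomial(t, n_A/(n_A+n_B)) and the test reduces
to the conditional Poisson (binomial) test — this limit and small-total
cases are verified against enumeration oracles in the test suite.  φ is
estimated by moments: per feature, ((s² − m)/m²) within each replicated
group, averaged, then the median over features, clamped at 0.  This is a
deliberately simple common-dispersion estimator; tagwise empirical-Bayes
shrinkage is out of scope, and exact numerical agreement with any particular
DE package is a non-goal — the test surface is type-I control (≈5% at
α = 0.05 under the null generator) and planted-effect recovery.

mRNAs are called DE at p < 0.05 **and** |log2FC| > 1 (strict inequalities,
as is conventional when thresholds are quoted as "p < 0.05").  log2FC is
computed from mean CPM with a pseudocount of 0.5 so zero-count groups stay
finite.  Raw p-values are thresholded directly; Benjamini–Hochberg is
available (`adjust="bh"`) but off by default, matching screens that filter
on unadjusted p.

## Target intersection

Predicted miRNA→gene records carry a binding score in [0, 1]; the filter
keeps scores strictly above 0.95.  Duplicate (miRNA, gene) rows collapse to
the **maximum** score — the most permissive choice with respect to a strict
`> 0.95` cut.  The overlap set of a comparison is (∪ targets of DE miRNAs)
∩ (DE mRNAs); no direction-concordance filter is applied at this stage (the
screen's sign logic lives in the pathway z-score and the hub reversal
requirement), though `require_opposite_sign=True` is available.

## Pathway activity

Enrichment uses the hypergeometric upper tail (one-sided Fisher test): with
a gene universe of size N, a pathway of size K (intersected with the
universe), and an overlap set of size n, the p-value is P(X ≥ k) for the
observed k overlap genes in the pathway.  The pipeline takes the universe to
be all genes of the mRNA expression matrix: overlap genes not annotated to
any pathway still count in n but can never inflate a pathway's k.  (The
stricter alternative — universe = genes present in both matrix and catalog —
would reject DE genes missing from the catalog outright; the chosen
convention degrades gracefully on sparse catalogs.)

The activation z-score is z = Σᵢ sᵢ/√N with unit weights, where
sᵢ = (observed DE direction of gene i) × (annotated effect sign of gene i)
over the N genes carrying both annotations.  Activity classes: increased
(z > 0), decreased (z < 0), zero (z computed and exactly 0), unknown (no
annotated gene overlaps; z undefined).  Proprietary curated edge weights
used by commercial pathway engines are not reproducible and are out of
scope; with unit weights |z| ≤ √N and z flips sign when all observed
directions flip (both property-tested).

Selection keeps, among pathways with p < 0.05: the top 20 by z among z > 0,
the 20 most negative among z < 0, and the top 20 by p among unknown —
zero-activity pathways are never selected, under-full strata are kept whole.
Ties break by p ascending then pathway id, so selection is deterministic.
Pathways selected in both comparisons are classified by their activity pair:
`up_then_down`, `down_then_up`, `unknown_pattern` (either side unknown), and
`same_sign` — the latter reported explicitly rather than dropped.

## Network screen and hub selection

The tripartite network links DE miRNAs to their filtered overlap targets and
overlap genes to the selected pathways containing them; gene nodes lacking
either a miRNA edge or a pathway edge are pruned (pruning is idempotent),
while all selected pathways remain as nodes.  The count-score of a
(miRNA, pathway) pair counts the genes the two share through the network;
pairs with count-score ≥ 2 (inclusive) become edges of the bipartite
miRNA–pathway network, with the count-score retained as an edge weight.
Degree is the unweighted edge count; Σ miRNA degrees = Σ pathway degrees =
|edges| always (handshake identity, enforced by tests).

Hub screening intersects the two comparisons' surviving pairs by exact
(miRNA, pathway) identity, ignoring count-score values.  Hub-network degrees
are recomputed from the intersected edge set itself rather than inherited
from the per-comparison networks — recomputation is the only convention
under which the handshake identity is guaranteed to hold on the hub network.
Validation hubs are miRNAs with degree ≥ 3 whose two-comparison pattern
reverses (`down_up` or `up_down`); both the cut and the reversal requirement
are parameters, since a degree threshold of this kind is inherently a
screening convenience rather than an inferential quantity.

## qPCR validation

Relative quantities follow the Livak 2^−ΔΔCt convention: replicates averaged
per (sample, assay); ΔCt = Ct_assay − Ct_reference within each sample;
ΔΔCt referenced to the **arithmetic mean ΔCt of the control group** (the
common convention when no single calibrator sample is designated); RQ =
2^−ΔΔCt with amplification efficiency fixed at 2.  The reference assay's own
RQ is exactly 1 for every sample and RQ is invariant to adding a constant to
all Ct values of a sample (both tested).  Group comparisons use one-way
ANOVA followed by Fisher's LSD — pairwise t statistics sharing the ANOVA
pooled MSE and its within-group degrees of freedom, so for two groups the
LSD p equals the pooled t-test p.  Statistics run on the RQ scale by default
because that is the quantity conventionally plotted; a ΔCt-scale option
(`on="delta_ct"`) exists since RQ is log-normal in principle.  An assay is
concordant with sequencing when the sign of its log2 mean-RQ ratio matches
the DE call and its LSD p < 0.05.

## Synthetic cohort

The generator emulates a three-arm design: control (ND), disease (WD) and
treated (YBT) groups of n = 8, two count layers (200 miRNAs, 2,000 mRNAs by
default), NB counts with a common dispersion φ = 0.1 and log-normal library
sizes (CV 20%) so normalisation is non-trivial.  Per-feature base means are
log-normal (log2 mean 6, sd 1.5, clipped to [2, 12]).

Planted structure: 4 hub miRNAs (75% shifted down in disease, the rest up)
with |log2FC| = 1.5 in the disease group and full restoration to the control
mean under treatment (`restore_fraction` exposes partial restoration).  Each
hub owns a disjoint block of 40 true target genes shifted oppositely with
|log2FC| = 1.4, chosen so that the mRNA rule's strict |log2FC| > 1 cut
retains ≥80% of planted targets at n = 8 (1.2 was measurably underpowered at
~74%).  True miRNA–target pairs receive binding scores > 0.95 with
probability 0.9; decoy pairs with probability 0.1.  Each hub seeds 5
pathways with 8 of its true targets plus unplanted filler genes (sizes
15–40); seeded genes carry effect signs equal to their disease-direction, so
seeded pathways score z > 0 (or < 0) in disease-vs-control and reverse under
treatment.  Five pathways per hub with 8 seeded genes each make a hub's
degree ≥ 3 robust to per-gene losses from DE power, the binding filter and
selection, keeping recovery achievable by construction.  Remaining pathways
are unsigned decoys.

The Ct table covers the planted hubs plus a flat U6 reference: Ct = base −
log2(relative expression) + noise, with per-sample biological variation
(sd 0.25 log2 units), a per-sample loading offset common to all assays (which
ΔCt removes), and technical replicate noise (sd 0.15), 3 replicates per
sample.

Everything derives from one `numpy` generator seeded by `rng_seed`:
identical config + seed gives a byte-identical bundle on disk.

**What the generator does not emulate:** read-level sequencing artifacts
(GC/length bias, multimapping), tagwise dispersion heterogeneity,
correlated genes outside the planted blocks, miRNAs sharing targets,
partially overlapping pathway memberships between seeded and decoy sets, or
real miRNA seed-match biology.  Passing the recovery suite therefore shows
the chain of thresholds is implemented coherently and has power under an
idealised signal, not that the screen is calibrated for any particular real
dataset.

## Numerical conventions

- Strict inequalities at every published-style threshold (p < 0.05,
  |log2FC| > 1, binding > 0.95); inclusive count-score ≥ 2 and degree ≥ 3.
- Exact-test ties: splits whose probability is within a 1e-10 relative
  tolerance of the observed one count as ties (guarding float noise in the
  two-sided sum).
- Degenerate inputs: zero-variance t-test features give p = 1 (equal means)
  or 0; an all-zero feature total gives p = 1 in the exact test; empty DE
  sets propagate as valid empty downstream stages (an α = 0 run completes
  with an empty report).
- All derived outputs are sorted (lexicographic tie-breaks everywhere), so
  identical inputs produce byte-identical files.
- Sums of per-class counts always equal reported totals (DE up/down, node
  types, activity classes, cross-comparison patterns); these identities are
  asserted in the test suite rather than assumed.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` averages pipeline recovery over 20 simulated cohorts
at the default sizes above, measures null type-I rates on 2,000 features per
layer at n = 8 per group, and runs 3 zero-effect cohorts for the
chance-level baseline.  These sizes give stable averages (recovery metrics
move by well under the acceptance margins across seeds) while keeping a full
reproduction in the minutes range on one CPU.

## Known limitations

- The common-dispersion moment estimator is biased downward when means are
  small; the NB exact test is then slightly anti-conservative (measured
  type-I ≈ 0.055–0.065 at α = 0.05 under the default generator).
- The activation z-score treats annotated genes as independent unit-weight
  votes; curated interaction strength, redundancy between genes, and
  pathway-pathway overlap are ignored.
- Count-score and degree treat all selected pathways equally; no correction
  is made for pathway size when ranking hubs.
- The enrichment universe convention (all expressed genes) makes p-values
  conservative for catalogs covering only part of the transcriptome.
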