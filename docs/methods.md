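# Methods

This note documents the statistical models, the synthetic-data design,
the numerical choices, and the known limitations of `mirkey`. It is the
package's own account of what it computes; every empirical statement
here is exercised by the test suite or the examples.

## Marker meta-analysis

The effect size is Hedges *g*: Cohen's *d* on log2 expression with the
small-sample correction *J* = 1 − 3/(4(n₁+n₀−2)−1) and the conventional
large-sample variance var(*g*) = (n₁+n₀)/(n₁n₀) + *g*²/2(n₁+n₀). The
literature this workflow comes from says only "SMD"; Hedges *g* is the
standard default for continuous outcomes and the choice is recorded in
the output metadata.

Fixed-effect pooling is inverse-variance. Workflows of this kind
sometimes label their fixed model "Mantel–Haenszel", but MH weighting is
defined for binary outcomes, not SMDs; inverse-variance is what meta
packages actually compute for continuous effects, so that is what is
implemented. Random effects use DerSimonian–Laird:
τ² = max(0, (Q−df)/C) with C = Σw − Σw²/Σw on fixed weights, then
re-weighting by 1/(vᵢ+τ²). Confidence intervals use the normal 1.96
multiplier (not Student t, no Hartung–Knapp), matching conventional SMD
meta output; the DL path is cross-checked in the tests against
`statsmodels.stats.meta_analysis.combine_effects`.

Heterogeneity: Q with a χ²(k−1) reference and *I*² = max(0,(Q−df)/Q)·100
reported on the percent scale. Model selection is the declared rule —
random iff *P*_Q < 0.05 or *I*² > 50, both strict, so *I*² = 50 exactly
selects fixed.

Egger's test regresses gᵢ/SEᵢ on 1/SEᵢ and tests the intercept against
zero with a t reference on k−2 df; asymmetry is called at *P* < 0.1.
With the very small k typical of these workflows (3–5 studies) the test
has poor calibration — it is reported, not used to alter the analysis.

Influence analysis re-pools after omitting each study. An omission is
*flagged* when the full-analysis pooled estimate falls outside the
leave-one-out CI, or significance at 0.05 flips — an operationalization
of "the point estimate is not outside the combined CI and there is no
significant statistical change".

## Candidate screen

The per-gene test is Welch's t on log2 values with BH adjustment; a DEG
requires |log₂FC| > 1 *and* FDR < 0.05. Empirical-Bayes variance
moderation (limma-style) is deliberately not used: the cascade's logic
is the thresholding, and the test is a plain, pluggable function.
Constant rows get p = 1 with a warning rather than NaN, so degenerate
synthetic inputs cannot poison the BH step.

The target-vote filter keeps genes predicted by at least 5 of the 12
databases (≥, so 5 votes pass and 4 do not). The clinical battery maps
item type to test — multi-class → Kruskal–Wallis (statistic H), binary →
Wilcoxon rank-sum reported as a rank-biserial correlation so the
statistic column stays on a correlation-like scale, continuous →
Spearman ρ, survival → univariate Cox (lifelines; Wald p). Ranks use
average-tie handling via scipy. One BH column spans the whole battery.

## Enrichment

One-sided hypergeometric over-representation with two modes: `exact`
(P(X ≥ k)) and `ease` (P(X ≥ k−1) for k ≥ 1), the deliberately
conservative DAVID default; `ease` is the package default for the same
reason, and `ease` ≥ `exact` always. The universe is the expression
matrix intersected with the annotation — the desk-scale analog of an
annotation-backed background. Terms with zero overlap are dropped. Both
the GO call threshold (default 0.01, with 0.001 as a stricter
alternative) and the pathway threshold (0.05) are config
knobs.

## Interaction-network hubs

Edges with confidence below 0.7 are removed (STRING integer scores are
divided by 1000 on read); the largest connected component is kept (ties
broken by edge count, then lexicographically smallest node set); the
core is the induced subgraph on nodes strictly above both the mean
degree and the mean *unnormalized* betweenness of the component — strict
inequalities, so a regular graph has an empty core and the function
raises rather than silently returning nothing.

The twelve centralities follow the cytoHubba definitions; where the
original tool leaves tie-breaking unspecified, it is fixed here for
reproducibility:

* **Stress** counts shortest paths through v (σ_sv·σ_vt summed over
  unordered pairs with d(s,v)+d(v,t)=d(s,t)); **Betweenness** is the
  fractional version (networkx Brandes, unnormalized).
* **MNC** is the order of the largest connected component induced by
  N(v); **DMNC** divides that component's edge count by |V|^1.7.
* **MCC** sums (|C|−1)! over maximal cliques containing v.
* **EPC** keeps each edge with probability ½ in 1000 seeded realizations
  and averages the size of v's component; it is deterministic under a
  fixed seed and stable to ~1% across seeds at that sample size.
* **BottleNeck** builds one BFS shortest-path tree per source with the
  first-discovered parent rule (neighbours visited in sorted order) and
  awards a point whenever more than n/4 tree nodes descend from v.
* Closeness, EcCentricity (1/eccentricity), Radiality
  (Σ(Δ+1−d)/(n−1)) and the local clustering coefficient are standard.

Plain centralities are delegated to networkx; the cytoHubba-specific
ones are implemented here and all are verified against independent
brute-force oracles (Floyd–Warshall distances, minimal-length walk
counts, subset clique enumeration, exact edge-subset expectation) on the
exhaustive connected-graph atlas up to 7 nodes plus seeded 8–10-node
samples.

Consensus: per algorithm the top 20 scores are taken with all ties at
the 20th score included (dense cutoffs prevent arbitrary truncation);
a gene in ≥ 2 lists is a hub.

## Pathway crosstalk and MCODE

Crosstalk edges require ≥ 2 shared genes between pathways with ≥ 3
genes; edge attributes carry JC, OC and their mean. MCODE runs on the
unweighted topology with Cytoscape defaults (vertex-weight percentage
0.2, haircut on, fluff off): vertex weight = core level × density of the
highest k-core of the closed neighbourhood; seed-and-grow admits unseen
neighbours within the weight threshold; haircut takes the cluster
2-core. Cluster score = density × size, retained when > 4 strictly. The
fluff option is accepted for interface parity but not applied.

The bipartite gene/pathway core pools genes and pathways into one degree
average ("nodes with degree > average", not per-side), strict inequality.

## Key genes (median-rank meta-analysis)

The external-compendium meta-analysis is emulated as a declared,
seeded procedure: within every study all genes are ranked by Welch p
(1 = smallest); the statistic is the median rank across studies; the
combined p is the permutation tail probability of a median rank at least
that small under independent uniform ranks, with the add-one correction
(b+1)/(n_perm+1), so the smallest attainable p is 1/(n_perm+1) and
repeated values across leave-one-out columns are expected — the null is
discrete. Ranking happens within each study's *full* gene panel: ranking
only a shortlist of jointly significant genes would destroy the signal
by construction. The permutation null is matched per gene to the number
of studies the gene appears in. Tests verify the permutation p against
full enumeration of the m^k rank configurations at small size, and
uniformity under the null by KS.

Stability: a gene is key iff the combined p and every
leave-one-study-out combined p are < 0.05 (so raising alpha can only
enlarge the key set). Crucial pathways are the intersection of the key
genes' pathway memberships among the enrichment-significant pathways.

## Seed sites and AU-rich elements

The binding criterion is perfect pairing of miRNA positions 2–8 (1-based
from the 5′ end): the scanner reports every (possibly overlapping)
occurrence of the reverse complement of that 7-mer on the UTR, 0-based
half-open coordinates, with the site's A+U fraction. T is accepted and
read as U. Supplemental pairing, wobbles and hybridization energies are
out of scope by design — the stated criterion is the exact 7-mer.

ARE classes use declared defaults where the literature gives none:
U-rich windows are 10-nt stretches with U fraction ≥ 0.8 (merged),
"near" means within 20 nt, and two AUUUA starts < 5 nt apart count as
overlapping. Class II requires an overlapping pair near a U-rich window;
class I a pentamer near one; class III a U-rich window with *no*
pentamer anywhere; a pentamer far from any U-rich window yields "none".

## Synthetic data: what it emulates and what it does not

Every generator is deterministic under `(seed, stream-tag)` and returns
its planted truth. Defaults are the package's study conditions:

* **Marker studies**: 4 studies, 20+20 samples, planted SMD 2.85 in
  pooled-SD units on the log2 scale, Gaussian noise (σ = 1), emitted on
  the raw scale (2^x) so the pipeline's log2 step is exercised. Subgroup
  labels alternate squamous/adeno.
* **Screening matrix**: 800 genes, 25% DE at |log₂FC| = 3, 30+30
  samples; gene baselines U(5,10) log2 units. The planted hub-module
  genes are always upregulated DE targets.
* **Votes**: 12 independent databases, sensitivity 0.7 / specificity
  0.9 around a 50% true-target set — so a true target passes the ≥5
  filter with probability P(Bin(12,0.7) ≥ 5) ≈ 0.991 and a non-target
  with P(Bin(12,0.1) ≥ 5) ≈ 2.8·10⁻³.
* **Interaction graph**: 120 nodes; a Barabási–Albert backbone (m = 2)
  over candidate-like genes with edge confidences U(0.5, 1), plus a
  planted 15-node module with edge probability 0.9 and confidences
  U(0.75, 1), each module node attached to 4 backbone nodes — the
  module survives the 0.7 filter intact and carries enough through
  traffic to clear the degree/betweenness core.
* **Pathways**: 30 sets of 12–28 genes. The first 8 draw from a shared
  60-gene candidate pool (dense crosstalk, strong enrichment); the
  first 3 are designated and contain all three anchor genes; every
  other cluster pathway contains exactly two of the three, and no
  background pathway ever contains all three — making the designated
  pathways the unique crucial-pathway answer. Background pairs share
  `overlap_rate` of their genes.
* **Sequences**: 300-nt UTRs; positive UTRs carry exactly 2 planted
  sites inside 15-nt windows with A/U flanks (window AU ≥ 0.6);
  negative UTRs are scrubbed of the site 7-mer.
* **Clinical**: 300 samples; lymph-node class follows a latent
  0.8·z(expression) + N(0,1) quartile binning; all other covariates and
  the censored survival times are independent of expression.
* **Validation compendium**: 9 studies, 20+20 samples, in which *only*
  the anchors carry a 2σ planted shift — this is what makes "exactly
  the anchors become key genes" a recoverable truth.

What the generators do **not** emulate: batch effects, platform/probe
models, correlated database votes, HPV biology, weighted shortest
paths, or realistic pathway topology. Passing recovery tests therefore
demonstrates the *machinery* — thresholds, rankings, intersections,
permutation nulls — not robustness to real-data artefacts.

## Numerical and engineering choices

* Strict inequalities everywhere a threshold is
  stated (score < 0.7 removed; ≥ 5 votes; *I*² > 50; MCODE score > 4;
  degree > average).
* BH adjustment via `statsmodels.stats.multitest`; t-tests, rank tests
  and hypergeometric tails via scipy; Cox via lifelines (an established
  survival implementation in place of a hand-rolled Newton–Raphson);
  graphs via networkx.
* Enrichment tie-break: ascending p, then larger overlap k, then
  lexical term id.
* The pipeline halts with the failing stage's name; an empty candidate
  set halts after the screen stage.
* Problem sizes in the tests (desk scale: 800-gene universes, 120-node
  graphs, 300–1000 replicate calibrations, 50-seed end-to-end recovery)
  were chosen so every stage's recovery property is measurable with
  comfortable Monte-Carlo margins.

## Known limitations

* The DL random-effects CI undercovers slightly at k = 4 (measured
  ≈ 0.95 under homogeneity here, but below 0.95 under strong
  heterogeneity); Hartung–Knapp is out of scope.
* Egger's test at k = 4 is noisy; its output is descriptive.
* The median-rank permutation null assumes independent ranks across
  studies and exchangeable genes within a study; correlated genes make
  the combined p anticonservative in a way the synthetic data does not
  probe.
* MCODE's fluff step and directed KEGG topology inside pathways are not
  implemented.
* EPC is Monte-Carlo; ranks of near-tied nodes can swap between seeds
  (consensus voting over twelve algorithms absorbs this in practice).
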