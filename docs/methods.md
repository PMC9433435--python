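# Methods

`collemsel` implements a phylomitogenomic selection analysis: given a
rooted, dated (ultrametric, Ma) phylogeny, a discrete ecological trait
(the springtail life forms — aquatic, myrmecophilous, euedaphic,
hemiedaphic, epiedaphic — by default, any discrete character in general),
and in-frame codon alignments of mitochondrial protein-coding genes under
the invertebrate mitochondrial code (NCBI table 5), it asks whether
branches on which the trait shifted away from its reconstructed ancestral
state carry an excess of nonsynonymous change. This note documents the
models, the defaults and why, what the simulators do and do not emulate,
and the numerical choices.

## Ancestral states

**Parsimony.** Hartigan's generalisation of Fitch counting, exact on
multifurcating trees. The down-pass resolves one most-parsimonious
labelling; when an optimal set has several members not containing the
parent's state, a user-supplied preferred state wins if present, otherwise
the lowest state index, and the node is recorded as a tie. Shift events
are the maximal subtrees whose root is reconstructed in a non-ancestral
state while the parent keeps the ancestral state; each event records its
origin node, divergence (parent) node, member terminals in the derived
state, and the sister branches still in the ancestral state.

**Retention index.** Each life form is recoded as binary presence/absence;
RI = (g − s)/(g − r) with g = min(#tips in, #tips out), s = Fitch steps,
r = 1 when both states occur. For an autapomorphic or constant character
g = r makes the ratio 0/0; the package reports 0 with `defined=False`,
matching the convention under which single-taxon states print as 0.

**Maximum likelihood.** Continuous-time Mk models with uniform root prior
(configurable): Mk1 with one rate (closed-form 2-parameter kernel used
implicitly through the eigendecomposition), and an asymmetric
generalisation with all k(k−1) ordered-pair rates, which reduces to the
classical 2-parameter asymmetric model at k = 2. Rates are optimised on a
log10 scale in [1e−9, 1e3] per Ma (Mk1 by bounded scalar search, the
asymmetric model by multistart L-BFGS-B seeded at the Mk1 estimate);
constant characters drive the rate to the lower bound and are flagged.
The LRT uses df = k(k−1) − 1. Marginal ancestral probabilities come from
the up-down algorithm with per-node rescaling.

**Bayesian MCMC.** Metropolis-Hastings over the asymmetric rates with a
hierarchical prior: rates iid Exponential(mean m), m ~ Uniform(0, 30);
this is a deliberate simplification of reversible-jump model averaging
over rate-class partitions, which is out of scope. Proposals are lognormal
random walks (rates jointly, scale 0.35; m separately, scale 1.0) with
Jacobian corrections. One tree is drawn uniformly per iteration when
several are supplied, so topological uncertainty is integrated over.
Chains are initialised at the Mk1 ML rate with per-chain jitter so that
desk-scale runs start near the posterior mode. Per-iteration marginal
state probabilities at the focal MRCA are recorded after burn-in;
near-flat samples (maximum probability within 0.05 of 1/k) are discarded
as equivocal, the rest averaged within and then across chains, and a state
is called supported only above 0.7. Defaults: 3 chains, 30,000 iterations,
25% burn-in, chain seeds = seed + chain index (full-scale analyses of this
kind run orders of magnitude longer; the desk default is sized for the
packaged fixture). Effective sample size per chain uses Geyer's initial
positive-sequence estimator on the focal-probability trace; chains under
200 are flagged. Note one honest property of this prior: it is nearly
scale-invariant and retains mass in strongly asymmetric rate regimes
whose focal marginal is uninformative, so even a constant character
plateaus near 0.94 rather than 1.0 — the support call, not the raw
posterior, is the decision quantity.

## Codon-level selection

**Model.** GY94: single-nucleotide codon moves with transition bias κ,
selection parameter ω on nonsynonymous moves, and target frequencies π
(F3×4 from the alignment by default; empirical codon frequencies
optional). Matrices are reversible; transition probabilities come from a
symmetrised eigendecomposition, batched over branches. Site models M0 (one
ω), M1a (ω0 < 1, ω1 = 1) and M2a (adds ω2 ≥ 1) are ω-mixtures with the
likelihood summed per site over classes. **Normalisation is joint across
the mixture**: classes share one scale so that high-ω classes genuinely
accumulate more substitutions — per-class normalisation would silently
discard the rate signal that gives the M1a/M2a LRT its power.

Because input trees are dated in Ma, a global tree-scale parameter
(expected substitutions per codon per Ma) is estimated jointly with the
other parameters, playing the role branch-length estimation plays in
conventional codon-model software. Optimisation is bounded multistart
L-BFGS-B (κ ∈ [0.1, 50], ω ∈ [1e−4, 20], proportions via logistic
transforms; 5 starts by default, warm-startable from a nested fit;
absolute log-likelihood tolerance 1e−8 by default). The M1a→M2a LRT uses
df = 2. Per-site positive-class posteriors are Naive Empirical Bayes at
the MLEs — parameter uncertainty is not integrated over, so posteriors
near the 0.95 call threshold should be read cautiously.

**Counting.** Branch-wise synonymous/nonsynonymous changes are obtained by
(1) marginal ML ancestral codon reconstruction under the fitted (or
supplied) M0 model, then (2) Nei–Gojobori-style comparison of each node
with its parent: site fractions per codon exclude stop-codon neighbours
from the denominator, and multi-step codon differences are averaged over
all minimal stop-free mutational pathways (fractional counts). Columns
containing a gap or ambiguity in any taxon are masked out of both counts
and site totals. No multiple-hit correction is applied: post-
reconstruction branch divergences are small, the regime where uncorrected
counts track the true event counts (verified against simulation event
logs, median absolute deviation ≤ 10% at ≤ 0.3 expected
substitutions/codon per branch). Counting-based ω̂ therefore biases
slightly toward 1 at high divergence (at true ω = 2 the recovered value is
~1.7); a known, documented limitation.

Per-branch ω = (dN/N)/(dS/S) with gene-level site totals N, S averaged
across the gene's sequences; branches without synonymous changes report ω
as undefined rather than infinite. Branch classification: purifying below
1 − tol, diversifying above 1 + tol, neutral within, with tol = 0.05 —
the neutrality band is a package choice, configurable. Gene- and
complex-level burdens use the standardisation
`nonsynonymous changes / (gene size × branches) × 100` with gene size in
codons (configurable reading; nucleotides were also defensible), counts
and sizes summed within an OXPHOS complex before the formula.

## Shift-vs-sister comparison

Per-branch nonsynonymous proportions P = dN/(dN + dS) are computed per
gene first and then averaged per branch (genes contributing no changes on
a branch are excluded from that branch's average). Important caveat the
package makes explicit: with roughly three nonsynonymous sites for every
synonymous site per codon, neutral evolution already gives P ≈ N/(N+S) ≈
0.75, so only contrasts between branch groups are meaningful, never the
absolute level. For each shift event the shift side is every terminal and
internal branch of the derived clade including its stem (equal weight per
branch — the per-path weighting is available as an option), the sister
side every branch of the divergence node's other lineages still
reconstructed in the ancestral state; nested second shifts are excluded.
Side means are compared as shares (always summing to 100%) and by a
classical paired t-test across events. Regressions of P on branch age
(the parent-node age; for terminal branches on an ultrametric tree this
equals the branch length) are ordinary least squares per group, with group
equality tested by a joint F-test on the group main effect and group×age
interaction in a single linear model. No phylogenetic correction (PGLS) is
applied — branch-level observations are not independent, a known
limitation of the procedure the package reimplements.

## Physicochemical (TreeSAAP-style) scan

Twenty amino-acid property scales ship with the package (sources named in
the data file), including the three that matter for the mitochondrial
analysis: equilibrium constant (ionisation of COOH), solvent accessible
reduction ratio, and buriedness. For each property, all single-nucleotide
nonsynonymous sense-codon changes under the genetic code are enumerated;
the range of |Δproperty| is cut into 8 equal-width categories (1 most
conservative, 8 most radical). The neutral expectation is the category
distribution over that enumeration — unweighted by default, optionally
weighted by source-codon frequency over its non-stop neighbour count; the
output records the choice. Observed replacements are collected from every
branch of the reconstructed gene history, with multi-step codon
differences contributing pathway-averaged fractional replacements.
Per-category z-scores are binomial:
z_c = (O_c − N p_c) / sqrt(N p_c (1 − p_c)), with |z| > 3.09 (one-sided
p < 0.001) the significance threshold. A sliding window (15 codons,
step 1) localises signal; a gene is flagged for radical positive selection
when category 7 or 8 of its whole-gene profile exceeds the threshold,
reporting category 8's z when both do. Multiplicity across 20 properties ×
8 categories × windows is reported, not corrected (the convention of the
tool being emulated); calibration under neutral simulation keeps the
per-test call rate ≤ 1%.

## Synthetic data

Generators are event-based (Gillespie) rather than endpoint samplers so
the *true* per-branch substitution counts exist as oracles — the
pipeline's central statistic is a count, so the simulator must know the
truth at that granularity.

* **Trees**: forward birth–death simulation conditioned on the tip count
  (accepted the moment the extant count is reached, extinct lineages
  pruned, both root children required to survive), rescaled to a chosen
  root age. Defaults emulate the study system scale: 16–64 tips, root
  ages ~400 Ma.
* **Traits**: Gillespie Mk jumps along branches; true node states and
  per-branch jump logs recorded.
* **Codon alignments**: GY94 jump chains per site and branch; root drawn
  from π over sense codons; per-branch ω overrides and M1a/M2a site-class
  mixtures supported, with the same joint normalisation as the fitted
  models; event logs record site, codons and synonymy.
* **Shift scenarios**: disjoint derived-state clades are designated (their
  divergence nodes keep at least one untouched ancestral sister lineage),
  and ω is multiplied on every branch of those clades; multiplier 1 is the
  null bundle. Default conditions: 16 tips, 4 shifts of 1–2 taxa,
  5 genes × 300 codons, κ = 2, base ω = 0.2, root-to-tip divergence
  0.4 substitutions/codon — life-form-shift counts, gene sizes and
  mito-like divergences at the scale of the study system.

What the generators do **not** emulate: indels and alignment error,
among-site rate variation beyond ω classes, codon usage trends along the
tree, saturation-level divergence, base-composition heterogeneity across
lineages, and topological uncertainty in the input tree. Passing
calibration and power tests therefore demonstrates internal correctness
of the statistics under the assumed generating process, not robustness to
real mitogenome alignment pathologies.

## Study-scale problem sizes used by the validation suite

The packaged validation studies run at desk scale: oracle equivalence on
≤ 6-tip trees (500 exhaustive cases; codon pruning on 3-taxon trees, 50
cases); M1a/M2a type-I error from 200 null replicates (6 taxa, 100
codons); LRT power from 100 replicates of the stated alternative
(p2 = 0.15, ω2 = 4, 8 taxa, 300 codons); shift-pipeline null calibration
from 60 bundles and power from 100 bundles at the default scenario size;
physicochemical calibration from 200 neutral gene replicates. Replicate
fits use 1–2 optimiser starts with warm-starting from the nested model and
a 1e−4/1e−5 log-likelihood tolerance (verified on pilots to reproduce the
default-tolerance LRT statistics to 4 decimals).

## Degenerate inputs and tie-breaking

Zero-length branches are legal everywhere (transition matrices reduce to
identity). Constant characters: parsimony gives 0 steps; Mk fits hit the
rate lower bound and are flagged; the Bayesian sampler is dominated by the
root prior times the equivocal filter. Branches with no counted changes
are excluded from proportion analyses with a warning; shift events whose
sister side has no counted branches are an error in the library and
skipped with a warning in the CLI. All pathway enumeration falls back to
independent per-position classification when every minimal path crosses a
stop codon (flagged, vanishingly rare under table 5). Parsimony ties
prefer the designated ancestral state, then the lowest state index, and
are reported.
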