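# Methods

This note documents the models implemented in `scfaphase`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
cohort does and does not emulate.

## Profile typing

Profiles (taxon compositions, or SCFA panels converted to per-sample
proportions of total measured acid, pH excluded) are compared with the square
root of the Jensen–Shannon divergence using base-2 entropies, which is a
metric bounded by [0, 1]. A pseudocount (default 1e−9) is added before
renormalising so structural zeros do not produce infinite log-ratios; results
are insensitive to this value over several orders of magnitude because it
only regularises coordinates that are exactly zero in both profiles being
compared. SCFA tables can also be typed on raw concentrations
(`JSDTyper(proportion=False)` requires rows already on the simplex);
proportion typing is the default because JSD is a divergence between
distributions.

PAM is the deterministic textbook algorithm: BUILD seeds medoids greedily
(first medoid minimises total distance; each later medoid maximises the cost
reduction; ties break to the lowest sample index), then SWAP repeatedly
applies the single medoid/non-medoid exchange with the steepest cost decrease
until no exchange improves the cost. The result is locally optimal under
single swaps — the algorithm's contract — and matches exhaustive k-medoid
search on clustered data; on unstructured instances it can stop in the same
non-global local optima as the reference R `cluster::pam` implementation
(verified on a frozen instance in the test suite). No random restarts are
used by default, so runs are reproducible bit-for-bit.

The number of clusters is selected by the Calinski–Harabasz index over
k = 2..8. Because CH is defined for points in a Euclidean space, samples are
embedded by classical scaling (PCoA: double-centre −½D², eigendecompose,
keep axes with positive eigenvalues; negative eigenvalues are dropped with a
logged warning) and CH is computed there with centroids. A medoid-based CH
variant that stays in distance space is available via `ch_index(...,
method="medoid")`. Ties in k go to the smaller k.

Cluster characterisation reports per-cluster feature means with two rankings:
raw means (compositions — the dominant order names the cluster) and
enrichment, cluster mean divided by global mean (concentration panels —
acetate is the largest acid in every phase, so phases are described by what
is elevated relative to the cohort: succinate, lactate/formate, or
propionate/butyrate).

α-diversity uses rarefaction to 5000 sequences (multivariate hypergeometric,
i.e. subsampling without replacement); samples below depth are flagged and
excluded from diversity summaries but retained everywhere else. Shannon
entropy uses the natural log. Faith's PD is the branch-length sum of the
subtree spanning the observed taxa and the root, computed directly on the
tree so star/multifurcating phylogenies are accepted; it equals scikit-bio's
`faith_pd` on strictly rooted trees (asserted in the tests).

## Regime trajectories and events

Per-sample cluster labels are noisy near regime boundaries, so a regime
change is declared only when ≥ L consecutive samples (default L = 3) carry a
new label; shorter excursions are relabelled to the surrounding regime. The
transition day is the day of the first sample of the stable run — with dense
early sampling this differs negligibly from midpoint conventions, and it is
well defined when sampling is sparse. The rule is idempotent and raising L
can only remove transitions. Subjects may revisit regimes; summaries use the
first occurrence of each ordered (from, to) pair. Months are days / 30.44
(mean Gregorian month). Event offsets are signed (transition day − event
day); subjects missing either datum are skipped with a log entry.

## Per-subject association

Within each subject's time series, Spearman's rank correlation (average-rank
ties; two-sided p from the t approximation with n−2 df, permutation-exact
optionally for small n) is computed for each retained taxon × metabolite
pair. Taxa are order-level abundances with cohort-wide mean > 2%, at most 6
(both configurable). Benjamini–Hochberg correction is applied within subject
across all pairs tested — the natural family for per-subject inference — with
a global-grid option. Constant series give an undefined r, reported as
missing and excluded from cross-subject means; the cross-subject SD uses the
n−1 denominator and is absent for a single subject.

Consecutive stool samples are autocorrelated and no adjustment is made, so
nominal p-values are anti-conservative for trend-like series; the package
treats the per-subject r values and their cross-subject consistency as the
primary evidence, not individual p-values. Mixed-effects or
changepoint-aware inference is out of scope.

## Genotype calling

Hit tables (outfmt-6-like: query, subject, pident, evalue, bitscore, plus
gene/pathway annotations) are filtered at e-value strictly < 1e−5 and
identity ≥ 70% — "cut-off" leaves boundary semantics open, so the strict/
inclusive pair is fixed here and documented. Phylotypes map to the genome
with the top bit score (ties to the lexicographically smallest id, logged).

A butyrate pathway is called present when all its core genes are hit
(`required_core_fraction` = 1.0 by default; the completeness fraction is
configurable because gene catalogues differ in granularity) and, for
pathways with terminal alternatives, at least one terminal gene — *but*
(butyryl-CoA:acetate CoA-transferase, which consumes luminal acetate) or
*buk* (butyrate kinase) — is present; the terminal that fired is recorded.
The shipped YAML covers the four standard routes (acetyl-CoA, glutarate,
4-aminobutyrate, lysine) with editable gene tokens, keeping the package
independent of any specific catalogue's identifiers.

The five-way subgrouping is an ordered decision list: (1) weaned;
(2) breastfed with Bifidobacteriales below a colonisation threshold (default
0.1); then breastfed + colonised samples split by fucosylated-HMO gene
complement: (3) no route gene, (4) partial (some but not a complete set),
(5) complete — FL-SBP (intact 2′-FL import) or extracellular fucosidase
together with FucP (cross-feeding). The threshold and the complete/partial
rule are config-exposed; they are a documented convention, not a measured
fact. Subgroup SCFA comparisons use Mann–Whitney tests of the complete-route
group against each other subgroup, BH-corrected across all tests.

## Fermentation stoichiometry

The model is a steady-state yield model: reactions are lumped to the level at
which the carbon skeleton and the cofactor budget are decided, every
non-exchange metabolite — including the NAD+/NADH and CoA pools — must net to
zero, the fed substrate is consumed exactly, other feedable substrates are
held at zero, products may only accumulate, and the minimum-total-flux
solution (HiGHS LP) is reported. Endpoint yields, not kinetics: complete
substrate conversion is assumed because the quantities of interest are molar
product ratios. ATP/ADP are tracked in the reactions but not constrained, as
biomass and maintenance are not modelled; inorganic phosphate is not tracked.
Carbon audits count acetyl-CoA as its C2 acetyl moiety and cofactors as
carbon-free, so every reaction conserves the transformed skeleton
(validated at construction).

Both terminal redox sinks (lactate dehydrogenase and the pyruvate
formate-lyase route) are present in every network; which one carries flux is
decided by the NADH balance. On hexose, lower glycolysis produces NADH that
only lactate formation can discharge, so formate is zero; on fucose, the
NAD+ spent on fucose oxidation is regenerated by lactaldehyde → 1,2-PD, so
lactate is forced to zero and pyruvate goes to formate + acetyl-CoA. The
balance is infeasible when a network lacks a redox sink, and the error names
the least-balanceable metabolite (largest least-squares residual).

The co-culture model makes 2′-FL (C18) accessible through two routes: intact
import (FL-SBP plus an intracellular fucose pathway) and extracellular
hydrolysis (fucosidase), releasing 1 fucose + 1 lactose per mole. Released
fucose is consumed by FucP-plus-pathway carriers, lactose by any organism
with the shunt; pools are split equally among eligible consumers by default
(configurable weights; totals are allocation-invariant when consumers share
a network, asserted in tests), and unconsumed pool metabolites are reported
as accumulating in the medium. An organism with fucosidase but no fucose
pathway (B. bifidum-like) is idealised to zero formate production — the
observed trace production in culture is attributed to the absent pathway, so
the model rounds it to the structural zero.

## Synthetic cohort

The generator emulates the study design the analysis assumes: 12 subjects
sampled on the fixed cadence — daily for week 1, alternate days to day 29,
weekly from day 35 to day 364, fortnightly from day 378 — giving exactly 92
points over 730 days. Per subject, the latent truth is: T1 (En→Bi change)
log-normal with median 18 d (≈ 0.6 months), clipped to [3, 180]; T2 (Bi→Cl)
normal with median 396 d (≈ 13 months), SD 90 d, clipped to [240, 730];
weaning = T2 + N(0, 7 d); solid food uniform on [120, 210] d; a dominant
bifidobacterial scenario drawn from {B. infantis 0.30, B. bifidum + B. breve
0.30, B. breve 0.25, none 0.15} which fixes the within-Bifidobacteriales
species split and hence the HMO-genotype flags.

Compositions blend three order-level archetypes (Enterobacterales-,
Bifidobacteriales-, Clostridiales-dominant) with two logistic ramps centred
at T1 and T2. The configured ramp width (default 21 d) is the 10–90%
transition span; the first ramp's span is additionally capped at T1/2,
because a succession completed by day T1 cannot have taken longer than the
infant's age — without the cap, subjects transitioning in week 2–3 would
spend most of their densely sampled early days in mid-blend states that no
real infant occupies. Samples are Dirichlet draws around the blend
(concentration 200), and Clostridiales mass is split 60/40 into
butyrate-producer/non-producer bins.

SCFA concentrations are sums of producer terms with log-normal multiplicative
noise (σ = 0.3): Enterobacterales → succinate + a little acetate;
Bifidobacteriales ferment milk hexose through the bifid shunt using the
stoichiometric model's own yields (acetate:lactate 3:2), plus HMO fucose →
formate when the genotype grants fucose access (FL-SBP with the pathway, or
FucP carrier with a co-resident fucosidase donor) and the infant is
breastfed; butyrate-producer Clostridiales → butyrate, amplified 5× after
weaning and debited against acetate (the *but* route); Bacteroidales/
Clostridiales → propionate and acetate. pH is a decreasing affine function
of total acid with extra lactate weight, clipped to [4.0, 8.5]. All
magnitudes are order-of-magnitude placeholders chosen once to give
physiologically plausible medians and the three described phases
(succinate-high and acetate-poor early; lactate/formate-high while breastfed
and bifidobacteria-dominant; propionate/butyrate-high after weaning); they
are parameters in one YAML-serialisable config, not claims about real
faeces. The optional antibiotic perturbation (off by default) transiently
multiplies Bifidobacteriales by 0.2 with a 7-day exponential recovery.

What the generator does **not** emulate: read-level noise and compositional
count effects (no sequencing simulation, no 16S copy-number variation),
absolute abundances, within-regime ecological dynamics (blooms, strain
turnover), covariation between noise terms, diet beyond the
breastfed/weaned switch, and realistic phylogenies. Passing recovery tests
therefore demonstrates that the analysis chain recovers the planted
structure under idealised noise — a necessary condition, not evidence about
real cohorts.

## Problem sizes and numerics

Tests and the acceptance script run at the study scale (12 × 92 = 1104
samples) for single-cohort checks; multi-seed recovery checks use 10 seeds
(cluster-number recovery), 50 seeds (transition-day recovery, with
nearest-archetype labels standing in for full typing, which does not change
the detection rule being tested), 100 seeds (planted-k recovery on small
mixture fixtures; type-I and permutation-null calibrations). Balance
residual tolerance is 1e−9; distance matrices are symmetrised and clipped at
0 before use; PCoA drops eigenvalues below 1e−12 of the largest; PAM ties
break to the lowest index everywhere, making every pipeline stage
deterministic for a fixed seed.

## Known limitations

- Spearman p-values ignore serial autocorrelation (see above).
- PAM is locally optimal under single swaps; rare non-global optima are
  shared with the reference implementation.
- The CH index is computed in the PCoA embedding; with strongly
  non-Euclidean distances the dropped negative axes could distort dispersion
  (sqrt-JSD matrices here are near-Euclidean, and the medoid variant is
  available).
- The stoichiometric model has no kinetics, growth, or substrate
  competition; co-culture allocation is a convention, not a prediction.
- The five-way subgrouping thresholds are conventions to be tuned per
  dataset.
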