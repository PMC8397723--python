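# scfaphase

Tools for analysing **dense longitudinal infant gut cohorts**: how the
microbial community succeeds from Enterobacterales- to Bifidobacteriales- to
Clostridiales-dominant states over the first two years of life, and how that
succession shapes the faecal **short-chain fatty acid (SCFA)** profile — the
early succinate phase, the breastfed lactate/formate phase driven by
HMO-utilising bifidobacteria, and the post-weaning propionate/butyrate phase
driven by Clostridiales.

The package is aimed at microbiome researchers who have per-sample taxon
relative-abundance tables and SCFA concentration panels (plus optional life
events and marker-gene qPCR calls) and want a tested, reusable version of the
standard analysis chain for this design.

## What it does

- **Profile typing** (`scfaphase.cluster`): samples are compared with the
  square-root Jensen–Shannon divergence, `d(p, q) = sqrt(H((p+q)/2) −
  (H(p)+H(q))/2)` with base-2 entropies; partitioning-around-medoids (PAM,
  deterministic BUILD + steepest-descent SWAP) clusters the distance matrix;
  the number of clusters k is chosen by the Calinski–Harabasz index
  `CH = [B/(k−1)] / [W/(n−k)]` evaluated in the PCoA embedding. Exposed as
  scikit-learn-style estimators (`PAMClusterer`, `JSDTyper`).
- **Regime trajectories** (`scfaphase.trajectories`): per-subject cluster
  sequences are smoothed with a run-length rule (a regime change needs ≥ L
  consecutive samples of the new label, default L = 3), transitions are dated,
  summarised in months (30.44 d/month), aligned to weaning/solid food, and the
  microbiota-cluster × SCFA-type contingency table is computed.
- **Per-subject association** (`scfaphase.associations`): Spearman's rank
  correlation between each taxon and each metabolite within every subject's
  time series, Benjamini–Hochberg q-values, and cross-subject summaries
  (mean ± SD of r, number of subjects with q below threshold).
- **Genotype calling** (`scfaphase.genotypes`): butyrate-production pathway
  calls per phylotype from sequence-similarity hit tables (e-value < 1e−5,
  identity ≥ 70%, editable pathway YAML with *but*/*buk* terminal
  alternatives), producer-abundance summaries, B. longum subspecies
  partitioning by qPCR ratio, and the five-way sample subgrouping by feeding,
  bifidobacterial colonisation and fucosylated-HMO gene complement
  (FL-SBP / FucP / extracellular fucosidase).
- **Fermentation stoichiometry** (`scfaphase.stoichiometry`): a flux-balance
  yield model of the bifid shunt (2 glucose → 3 acetate + 2 lactate) and of
  fucose catabolism (fucose → formate + acetate + 1,2-propanediol at 1:1:1),
  with explicit NAD+/NADH and CoA balancing — lactate on hexose and formate
  on fucose are forced by the redox budget, not hard-coded — and a co-culture
  model of 2′-FL cross-feeding between a fucosidase donor (B. bifidum-like)
  and a fucose consumer (B. breve-like).
- **Synthetic cohorts** (`scfaphase.synthetic`): a seeded generator emulating
  the study design (12 subjects, 92-point sampling schedule over 730 days,
  logistic regime succession with subject-specific transition days, genotype-
  dependent formate, weaning-coupled butyrate) with ground truth attached,
  used for parameter-recovery testing throughout.

## Worked example

Generate a cohort, type both tables, and correlate:

```sh
$ scfaphase generate --seed 3 --out cohort
wrote 1104 samples for 12 subjects to cohort

$ scfaphase type --table cohort/composition.tsv --out typed_comp
selected k = 3; CH scores: k=2: 1036.6, k=3: 7625.6, k=4: 6687.3, ...

$ scfaphase type --table cohort/scfa.tsv --out typed_scfa
selected k = 3; CH scores: k=2: 1432.2, k=3: 3508.3, k=4: 2785.9, ...

$ scfaphase correlate --cohort cohort --out corr
            taxon metabolite   mean_r     sd_r  n_subjects  n_significant
    Clostridiales   butyrate 0.851379 0.029078          12             12
    Bacteroidales propionate 0.847439 0.037192          12             12
Bifidobacteriales    acetate 0.782822 0.053014          12             12
```

The CH index peaks at k = 3 for both the order-level composition table and
the SCFA table: the generator's three community regimes and three metabolite
phases are recovered without being told k. The correlation summary ranks
Clostridiales × butyrate first (mean per-subject Spearman r = 0.85 here,
significant at q < 0.01 in all 12 subjects), reflecting the planted coupling
between butyrate and butyrate-producer Clostridiales abundance.

Fermentation yields from the library:

```sh
$ scfaphase ferment --network fucose --substrate fucose --amount 1
1,2-PD  1
acetate 1
formate 1
fucose  -1
lactate 0
```

One mole of fucose yields one mole each of formate, acetate and
1,2-propanediol and **no lactate**: the NAD+ spent oxidising fucose is
regenerated by lactaldehyde reduction, leaving none for lactate
dehydrogenase.

```python
import scfaphase as sp
shunt, fucose, combined = sp.build_default_networks()
sp.ferment(shunt, "glucose", 2.0).production
# {'acetate': 3.0, 'lactate': 2.0, 'formate': 0.0, '1,2-PD': 0.0, 'glucose': -2.0}
```

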