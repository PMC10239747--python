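# Methods

`sarcomir` implements a computational treatment-discovery workflow for
sarcoma: from a conserved miRNA deregulation signature to hub biomarker
genes to ranked drug proposals. This note documents the models, the
parameters that matter, the synthetic study the test suite relies on, and
the numerical choices made where the design was genuinely open.

## The discovery workflow

1. **Conserved miRNA signature.** Differential expression is computed
   separately in two cohorts — sarcoma cell lines vs a nontumor line, and
   tumor vs nontumor tissue — and the per-cohort calls are intersected
   direction-aware. Only miRNAs called in the *same* direction in both
   cohorts enter the signature; discordant calls are reported separately.
   The published analysis this mirrors found 16 conserved down-regulated
   miRNAs and one conserved up-regulated miRNA (hsa-miR-138-5p, excluded
   downstream for its dual oncogene/suppressor role — treated here as a
   post-hoc curation flag, not an algorithmic rule).
2. **Survival stratification.** Patients are scored by the mean of
   feature-wise z-scores over the signature miRNAs and split at the median
   score; the two halves are compared with a log-rank test.
3. **Target mapping.** Signature miRNAs are mapped to candidate target
   genes through a user-supplied (or synthetic) miRNA→target table; a gene
   is retained only if it is up-regulated in tumors AND Spearman
   anti-correlated with at least one of its regulating down-miRNAs.
   Hypergeometric over-representation against a GMT collection summarizes
   the retained set.
4. **Rule mining.** Each patient becomes a transaction of binary items —
   `<gene>:high` (expression strictly above the per-gene upper quartile),
   `MET` (metastasis recorded), `SURV_LT5` (death observed before 60
   months). A from-scratch level-wise Apriori enumerates frequent itemsets;
   rules are kept when their consequent contains both outcome items and the
   antecedent consists only of gene items. **Hub genes** are the genes
   appearing in the antecedents of at least a fraction `hub_fraction` of
   the top rules.
5. **Therapy translation.** Hubs map to primary drugs via a gene–drug
   table; all unordered pairs of distinct primary drugs are proposed as
   combinations. Secondary drugs are ranked by counting distinct
   (hub, rule) pairs for rules of the form
   {hub-high, MET, …} → {drug-annotated gene high, …}, pooled across hubs
   (per-hub counts remain available in the provenance records).

## Statistical components

- **Differential expression**: Welch unequal-variance t on log2 values,
  two-sided, BH step-up FDR across all features. Defaults
  `fc_threshold = 1.0` (log2), `q_threshold = 0.05`; a call requires both
  thresholds, which guards against significant-but-tiny effects. In the
  noise-free limit (both group variances zero) p is defined as 0 when the
  means differ and 1 when they agree.
- **Signature score**: mean of per-feature z-scores (population SD across
  samples). A zero-variance feature contributes 0 rather than dropping
  samples; missing features are skipped with a warning, and an empty
  effective signature is an error.
- **Log-rank**: the standard two-group statistic, written out directly: at
  each distinct event time the observed group-A events are compared with
  their hypergeometric expectation given the risk sets; ties use the
  hypergeometric variance; the squared standardized sum is referred to
  chi-square(1). Zero total variance returns (0, 1). Median splits send
  ties to the low-score group, making the dichotomization deterministic.
- **Enrichment**: upper-tail hypergeometric survival function with BH
  across sets; an empty overlap has p = 1 by the upper-tail convention.
- **Apriori**: candidate generation by (k−1)-prefix join over
  lexicographically sorted itemsets with subset pruning; support counted by
  a full transaction scan; all rule bipartitions enumerated from the
  frequent map with a transaction-scan fallback for subsets below the
  support floor. Sorting is total — (support, confidence, lift)
  descending, then lexicographic antecedent and consequent — so rule lists
  and hub extraction are reproducible to the byte.

## Mining defaults

`min_support = 0.10`, `min_confidence = 0.50`, `min_lift = 1.2`,
`max_itemset_size = 4`, upper-quartile discretization,
`survival_cutoff_months = 60`, `top_n_rules = 50`, `hub_fraction = 0.30`.
Two of these deserve justification:

- *Confidence floor 0.50.* The confidence of any gene→{MET, SURV_LT5} rule
  is bounded above by P(metastasis | biomarker-high) × (1 − censor rate) ×
  P(observed death before 60 months | biomarker-high), because a censored
  patient never carries the short-survival item. With realistic censoring
  (15–30 % of follow-ups) this bound sits near 0.6–0.7 even for a perfect
  biomarker, so a floor much above 0.5 would discard true rules on
  censoring alone.
- *Hub fraction 0.30.* Because the outcome filter accepts any consequent
  that is a superset of {MET, SURV_LT5}, each frequent itemset
  {hub_i, hub_j, MET, SURV_LT5} also emits rules that carry the other hub
  in the consequent. Counting antecedent appearances over k mutually
  co-occurring hubs then yields a per-hub share of 3/5 (k = 2), 5/12
  (k = 3) or 7/22 (k = 4) of the filtered rules — never above 1/2 for
  k ≥ 2. A threshold of 0.30 detects up to ~4 co-occurring hubs while
  genes without real outcome association, which essentially never reach the
  confidence floor, stay far below it.

Censoring is deliberately asymmetric: a patient censored before 60 months
receives neither a short-survival item nor a long-survival item, since
censoring is evidence of neither.

## The synthetic study

The generator (`sarcomir.synth`) emulates the study design end to end with
implanted, recoverable ground truth. Defaults (the study conditions used
throughout the tests and the acceptance script):

| parameter | default | meaning |
|---|---|---|
| `n_mirnas` / `n_genes` | 200 / 300 | feature-space sizes |
| `n_cell_samples`, `n_tumor_samples` | 20 per group | miRNA cohort sizes |
| `n_clinical_samples` | 500 | rule-mining cohort |
| `n_conserved_down`, `n_cellline_only_down`, `n_up` | 16 / 7 / 1 | implanted signature |
| `n_hub_genes`, `targets_per_mirna` | 3 / 5 | implanted targets (hubs shared round-robin) |
| `n_bystanders`, `n_decoy_drug_genes` | 10 / 20 | secondary-drug signal and decoys |
| `effect_log2fc`, `noise_sd` | 2.0 / 0.5 | log2 effect and noise scales |
| `hub_high_frac` | 0.25 | latent hub-high fraction (aligned with the upper-quartile cut) |
| `met_prob_hub_high` / `met_prob_base` | 0.90 / 0.15 | metastasis probabilities |
| `hazard_ratio_hub`, `baseline_median_months` | 6.0 / 120 | exponential survival model |
| `censor_rate` | 0.20 | uniform-backdated censoring fraction |
| `mirna_hub_coupling`, `target_coupling` | 0.25 / 0.8 | latent→miRNA and miRNA→gene couplings |

Expression is generated and consumed on log2 scale, with per-feature
baselines drawn from a normal distribution (microarray convention).
Survival is exponential in months ("5 years" = 60 months); censored times
are uniform fractions of the latent event time. Target genes respond
linearly and negatively to the mean deviation of their regulating miRNAs,
which makes them up-regulated in tumors (where the signature miRNAs are
down) and anti-correlated with them; hub and bystander genes additionally
gain `effect_log2fc` in the latent hub-high subgroup, and the signature
miRNAs dip further there (`mirna_hub_coupling`), tying the miRNA signature
to survival. The mRNA matrix includes the tumor-cohort samples (values
coupled to the same miRNA realizations) so the anti-correlation filter has
shared samples and a nontumor contrast; clinical outcome rows exist only
for the clinical samples.

A single integer seed drives named, independently derived RNG sub-streams
(one per artifact), so identical configurations are byte-identical after
serialization and any table can be regenerated alone.

What the generator does **not** emulate: probe-level artifacts, batch
effects, non-Gaussian expression noise, competing risks, non-proportional
hazards, partial or noisy target annotations, and drug-name synonymy.
Passing recovery tests therefore demonstrate correctness of the pipeline's
logic under a clean, favorable signal model — not performance on real
microarray cohorts, where annotation noise and confounding will dominate.

## Problem sizes used by the test suite and acceptance script

Recovery checks run the full pipeline over 20 independent seeds at the
default study conditions above and require success in ≥ 18 of 20. The
Apriori engine is compared with an exhaustive bitmask powerset enumerator
on 200 random transaction databases (≤ 12 items, ≤ 40 transactions,
randomized thresholds), exact to 1e-12. Log-rank and hypergeometric
components are checked against independent oracles (lifelines;
closed-form combinatorial sums) on instances of ≤ 20 samples/genes.

## Known limitations

- Hub extraction assumes hubs co-occur in the same high-risk patients; a
  set of hubs marking *disjoint* patient subgroups would dilute each
  other's rule share (support halves per additional disjoint hub).
- The anti-correlation filter tests each (gene, regulator) pair
  marginally; coordinated but individually weak regulation is missed.
- Secondary-drug ranking counts rules, not patients, so densely annotated
  gene families can inflate a drug's count; the provenance table makes
  this auditable.
- The supplementary-list reproduction uses synthetic stand-in identifiers
  (only hsa-miR-138-5p is a real miRNA name), since the published
  supplementary tables are not redistributable.
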