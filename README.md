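# esccmut

Integrated somatic-mutation cohort analysis for esophageal squamous cell
carcinoma (ESCC).

Multi-source ESCC sequencing studies are individually too small to resolve
clinically relevant mutational features — prognostic genes mutated in <5%
of patients, signature/clinical associations, stage-specific survival
effects.  Pooling dozens of WGS/WES cohorts solves the power problem but
introduces its own hazards: unverifiable mutation records, duplicated
samples shared between studies, capture platforms that miss parts of some
genes, and sources that deposited only nonsilent calls.  `esccmut`
implements the full analysis stack for such an integrated cohort, for
researchers building or reanalyzing multi-study somatic mutation datasets:

- **ingest** — MAF-like record reading with reject reporting,
  reference-base verification against the genome build, duplicate-sample
  detection by pairwise Jaccard of site-allele profiles, nonsilent
  classification, and gene × patient indicator/multiplicity matrices.
- **cohort_stats** — per-dataset and DerSimonian–Laird random-effects
  pooled mutation frequencies (logit scale, inverse-variance weights),
  mutational load with Kruskal–Wallis/Wilcoxon group comparisons, pathway
  burden, Fisher co-occurrence/exclusivity with BH correction, clinical
  group comparisons, and Cochran–Armitage age trends.
- **capture** — signed distance of each variant to the nearest exome
  capture boundary; the platform bias estimate is the percentage of
  WGS-derived SNVs more than 200 bp outside capture minus the same
  percentage in platform-sequenced reference genomes; genes with
  incompletely covered CDS are listed for downstream exclusion.
- **drivers** — per-gene mutational density
  `(mutations / patients) / (CDS length in Mb)`, the raw dN/dS count
  ratio, and the five-criterion combined selection
  (frequency ≥ 2%, Q ≤ 0.01, cluster score ≥ 0.2, density ≥ 50, dN/dS ≥ 5)
  consuming external background-model and hotspot-clustering scores.
- **signatures** — SBS96 matrices (pyrimidine-strand convention), de novo
  NMF signature extraction (multiplicative updates, Frobenius) with a
  cophenetic/RSS rank survey, non-negative-least-squares exposure
  refitting, cosine matching to a COSMIC-style catalog, and
  dominant-signature patient clustering.
- **survival** — multivariable Cox per gene (age, sex, stage adjusted;
  Efron ties), KM/log-rank, the four-step prognostic panel construction,
  and the count-based **mutational score**
  `score = Σ_{x ∈ panel} I(x mutated)`, banded 0 / 1 / ≥2, with
  per-dataset stage-adjusted validation.
- **simulate** — a synthetic cohort generator (toy genome, capture masks,
  mutation records, signature mixtures, proportional-hazards survival with
  planted effects) so the whole pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from esccmut import simulate as sim, ingest, cohort_stats as cs, survival as sv

models = [sim.GeneModel("TP53", 1182, 0.70, 0.03),
          sim.GeneModel("NFE2L2", 1818, 0.08, 0.02),
          sim.GeneModel("EP300", 7245, 0.10, 0.03),
          sim.GeneModel("NOTCH1", 7668, 0.15, 0.03)]
cfg = sim.SimulationConfig(dataset_sizes=[300, 200, 150], gene_models=models,
                           platform_masks=[0.0, 0.05, 0.1],
                           panel_truth={"NFE2L2": float(np.log(1.9))}, seed=11)
coh = sim.simulate_cohort(cfg)

records, rejects = ingest.read_records("mutations.maf.tsv")  # from sim.write_cohort
verified, mismatches = ingest.verify_reference(records, coh.genome)
gm = ingest.build_gene_matrix(verified, coh.clinical)

freq = cs.gene_frequencies(gm.indicator, coh.clinical, by="dataset")
tp53 = freq[freq["gene"] == "TP53"]
meta = cs.pooled_frequency(tp53[["n_mut", "n_total"]], gene="TP53")

row = sv.adjusted_cox(gm.indicator, ingest.prepare_clinical(coh.clinical), "NFE2L2")
```

This prints (via the obvious f-strings):

```
records read: 775  rejected: 0  reference mismatches: 0
TP53 pooled frequency: 0.669 (95% CI 0.632-0.704, tau2=0.0000)
NFE2L2 adjusted HR: 1.71 (95% CI 1.27-2.31, p=0.0005)
```

Every simulated record passed reference verification (the generator's
contract); the three datasets' TP53 frequencies pool with no detectable
between-study heterogeneity (τ² = 0); and the gene planted with a hazard
ratio of 1.9 is recovered at 1.71 with a confidence interval covering the
truth.

A thin CLI mirrors the main stages:
`esccmut simulate | ingest | capture-bias | drivers | score`.

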