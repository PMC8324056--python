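# sedadiv

Replicate-aware quality control, harmonization and diversity analysis for
lake sedimentary ancient DNA (sedaDNA) metabarcoding records.

## The problem

Plant communities of the past can be reconstructed from DNA preserved in
dated lake-sediment cores, amplified at a short barcode locus (the trnL
p6-loop) in multiple PCR replicates per sample. Before any ecology can be
done, two hard problems must be solved: deciding which samples are
trustworthy at all (extract inhibition and ultralow template produce
sporadic, irreproducible amplification), and turning noisy per-replicate
sequence counts into a harmonized taxon table. `sedadiv` implements a
complete pipeline for multi-lake studies of this kind, from dereplicated
per-replicate read counts through to richness-driver models, together with
a synthetic multi-lake data generator so every stage is testable without
any sequencing data.

## What it computes

* **Replication quality scores.** For each sample, the MTQ score is the
  proportion of positive PCR detections among the 10 most read-abundant
  sequences (out of 10 × 8 = 80 possible detections), computed before
  taxonomic identification; the MAQ score is the same statistic over
  identified, blacklist-cleaned sequences. Samples pass QC iff
  MTQ ≥ 0.75 and MAQ ≥ 0.2; the gate excludes negative controls.
* **Filtering and harmonization.** Per-replicate removal of ≤2-read
  sequences, exact-match taxonomic assignment, blacklist removal,
  dataset-wide removal of sequences with <10 reads or <3 positive
  replicates, merging of co-occurring same-taxon barcodes (reads summed,
  replicate detections unioned), a 3′ poly-A rule separating two
  *Vaccinium* species, and exclusion of aquatics, algae and above-family
  identifications.
* **Detectability-weighted diversity.** Per-taxon detectability
  wtRep = (Σ retained reads of the replicates where the taxon was
  detected) / (Σ retained reads of all replicates); Hill numbers
  N0 (richness) and N1 = exp(−Σ pᵢ log pᵢ) on the normalized
  detectability profile; analytic rarefied richness.
* **Regional species pool.** Time-ordered taxon accumulation across all
  lakes with piecewise growth rates; 500-year bins completed by Beals
  co-occurrence smoothing with per-taxon minimum-probability thresholds;
  standardized pool size from 1000 subsamples of 5 samples per bin.
* **Richness drivers.** Catchment nutrient index
  NI = (P + K + ln Ca) / H_min; penalized-spline Poisson trends (GAM)
  with optional continuous-time AR1 residuals; a regional GAMM with lake
  random intercepts; and a linear mixed model of log richness on a
  δ¹⁸O temperature proxy and NI interacted with Holocene period
  (Early 11.7–8.3 ka, Middle 8.3–4.25 ka, Late 4.25–0 ka), with random
  intercept and age slope per lake.

## Worked example

Generate a synthetic ten-lake study and run the whole pipeline:

```sh
sedadiv simulate --seed 1 --out-dir fixture
cd fixture && sedadiv all --seed 1 --out-dir results
```

or from Python:

```python
from sedadiv.synthetic import SimulationConfig, generate_dataset, write_fixture
from sedadiv.io import PipelineConfig
from sedadiv.pipeline import run_pipeline

write_fixture(generate_dataset(SimulationConfig(seed=1)), "fixture")
res = run_pipeline(PipelineConfig(
    counts_path="fixture/counts.tsv", reference_fasta="fixture/reference.fasta",
    taxonomy_path="fixture/taxonomy.tsv",
    blacklist_synthetic="fixture/blacklist_synthetic.txt",
    blacklist_false_positives="fixture/blacklist_false_positives.txt",
    lakes_path="fixture/lakes.tsv", proxy_path="fixture/proxy.tsv",
    out_dir="results", seed=1))
print(res["summary"])
```

prints

```
{'config_hash': '...', 'n_samples_retained': 274, 'n_taxa_final': 287,
 'negative_controls_failed': 27, 'negative_controls_total': 27}
```

meaning 274 of 333 simulated samples passed the MTQ/MAQ gate, every one of
the 27 negative controls failed it, and 287 terrestrial taxa survived
harmonization. `results/` then holds per-sample QC scores, the harmonized
taxon table, per-sample Hill diversity, lake and regional accumulation
curves, the 500-year binned pool estimates and the driver-model
coefficients. On this fixture the regional pool accumulates at about 42,
11 and 22 taxa per millennium in the Early, mid- and late-Holocene windows,
and the mixed model attributes a positive temperature effect on richness
to the Early Holocene only.

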