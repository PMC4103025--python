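# chromstate

Chromatin-state analysis of transcription start sites (TSSs) from ChIP-seq
tag data, built for studies that compare histone-methylation landscapes
across cellular conditions — e.g. quiescent vs activated muscle stem cells,
or the same cells in young vs aged animals.

Given aligned tags (BED) for H3K4me3, H3K27me3 and H3K36me3 plus an input
control, gene models (BED) and optionally a gene × condition expression
table, the package:

* calls enriched **domains** per mark with a windowed Poisson test against a
  local background λ = max(scaled input in the window, scaled input in the
  surrounding 10 kb, genome-wide ChIP expectation), Benjamini–Hochberg FDR
  across windows, and gap-merging of significant windows;
* classifies every gene's TSS (±2 kb window) into one of **four states** —
  K4-only, K27-only, **bivalent** (both marks, the poised configuration), or
  none — and cross-tabulates states between conditions (transition tables,
  retention fractions, gained/lost-mark gene lists);
* computes **normalized tag intensities** (tags per 10 million), ±3 kb
  strand-oriented metagene profiles, per-gene TSS-window intensities, and
  young-vs-old intensity fold changes (input-scaled, so genome-wide changes
  of a mark remain measurable);
* characterizes domains by **genomic context** (TSS-proximal / genic /
  intergenic) and width, the signature of the age-linked accumulation of
  intergenic H3K27me3 peaks;
* integrates with **expression**: poised-state rank-sum test, condition
  signatures, >40 % down-regulation screens with family rollups (histone
  subfamilies), and hypergeometric gene-set enrichment over GMT sets;
* ships a seeded **synthetic-data generator** with full per-gene ground
  truth — including an aging transform (global H3K27me3 amplification,
  novel 0.5–1 kb intergenic domains, histone-gene repression) — so every
  stage is validated end-to-end against known truth.

## Worked example

```python
import chromstate as cs

cfg = cs.aging_study_config(seed=1)        # 10 Mb genome, 500 genes
layout, genes, truth = cs.make_genome(cfg)
old = cs.apply_aging(truth, cfg)           # K27 ×4, intergenic peaks, histone genes
tss = truth.tss_table()

k27_y = cs.simulate_chip(truth, "H3K27me3"); inp_y = cs.simulate_chip(truth, "INPUT")
k27_o = cs.simulate_chip(old,  "H3K27me3"); inp_o = cs.simulate_chip(old,  "INPUT")

fc = cs.tss_intensity_fold_change(k27_y, k27_o, tss,
                                  input_young=inp_y, input_old=inp_o)
print(f"global H3K27me3 TSS fold change: {fc.global_fold:.2f}")

part = cs.partition_genome(genes, layout)
for age, chip, ctrl in [("young", k27_y, inp_y), ("old", k27_o, inp_o)]:
    dom = cs.classify_domain_context(cs.call_domains(chip, ctrl, "H3K27me3"), part)
    frac = cs.context_fractions(dom)["intergenic"]
    print(f"{age}: {len(dom)} H3K27me3 domains, {100*frac:.1f}% intergenic")
```

Output:

```
global H3K27me3 TSS fold change: 4.03
young: 228 H3K27me3 domains, 0.0% intergenic
old: 298 H3K27me3 domains, 16.8% intergenic
```

The fold change recovers the generator's 4× H3K27me3 amplification, and the
intergenic share of called H3K27me3 peaks rises with age because the aged
truth plants novel peaks away from genes — the two hallmarks of the
repressive-mark drift this pipeline is designed to quantify.

A full file-based run (domain BEDs, state TSVs, transition tables, aging
report, JSON summary) is one command:

```sh
chromstate generate --aging-study --seed 1 --out data/
chromstate run --config pipeline.yaml --out results/
```

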