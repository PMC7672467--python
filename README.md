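# offscan

Genome-wide off-target site search, scoring and integrated prediction for
the CRISPR SpCas9 knockout system.

When Cas9 is programmed with a guide RNA (a 20-nt protospacer followed by a
3-nt PAM, canonically NGG), it can cleave genomic loci that differ from the
intended target by several mismatches. `offscan` is for researchers who need
the full genome-wide candidate population of such off-target sites (OTS) and
a calibrated ranking of which candidates are likely to be cleaved:

* **search** — enumerate every 23-nt window, on either strand, whose PAM
  matches an IUPAC pattern (NGG default, NRG supported) and whose first
  20 nt lie within a mismatch budget (≤6 by default) of the protospacer;
* **curation** — reduce validated OTS tables from heterogeneous detection
  assays to a uniform population (23-nt span, canonical NGG, ≤6 mismatches,
  guide GC ≤ 75%), merge duplicates per cell type, and label candidates;
* **scoring** — four native position-weighted specificity scores (CFD-style,
  MIT/Hsu, CCTop, CROP-IT-style) plus ingestion of external tool scores
  (energy- or learning-based tools are not re-implemented);
* **evaluation** — tie-aware ROC and precision–recall curves built for
  extreme class imbalance (positives are a fraction of a percent);
* **ensemble** — a SAMME.R real-boosting AdaBoost of decision stumps
  (280 estimators, learning rate 0.1) whose class-1 probability is the
  integrated cleavage score used for ranking.

The core statistic: for a candidate with mismatch positions *M* (position 1
PAM-distal, 20 PAM-proximal),

* CFD = ∏<sub>p∈M</sub> f(p, g<sub>p</sub>, d<sub>p</sub>) · f<sub>PAM</sub>
* MIT = ∏<sub>p∈M</sub>(1−W[p]) · 1/(((19−d̄)/19)·4+1) · 1/n²
* CCTop feature = −Σ<sub>p∈M</sub> 1.2<sup>p</sup>
* CROP-IT = matched segment-weight mass / total mass

and the integrated score is P(cleaved = 1 | tool scores) under the boosted
stump ensemble. See `docs/methods.md` for conventions, constants and
limitations (the shipped CFD/CROP-IT constants are representative synthetic
defaults, swappable via `ScoreTables.from_files`).

## Worked example

Plant three off-targets (0, 2 and 4 mismatches) in a random 50-kb genome,
search, label against the planted truth, and score:

```python
import offscan as o

g = o.random_guide(7, "demo", cell_type="HEK293")
genome, truth = o.plant_sites(
    o.make_genome(50_000, seed=8),
    o.PlantSpec(guide=g, sites=[(0, "+", "GG"), (2, "-", "GG"), (4, "+", "GG")], seed=9),
)
cands = o.enumerate_candidates(genome, g, max_mm=6)
validated = o.CuratedDataset(
    guides=[g],
    records=[o.OtsRecord(t.guide_name, t.chrom, t.start, t.end, t.strand,
                         t.site_seq, "planted", "HEK293") for t in truth],
)
labeled = o.label_candidates(cands, validated).candidates
df = o.build_feature_matrix(labeled, [g], o.ScoreTables.load_default())
print(df[["chrom", "start", "strand", "n_mismatch",
          "CFD", "MIT", "CCTop", "CROP-IT", "label"]].round(4).to_string(index=False))
```

prints

```
  chrom  start strand  n_mismatch    CFD    MIT    CCTop  CROP-IT  label
contig1  24236      +           4 0.0012 0.0001 -91.4568   0.6977      1
contig1  32117      -           2 0.0868 0.0211 -34.9340   0.8915      1
contig1  43493      +           0 1.0000 1.0000   0.0000   1.0000      1
```

All three planted sites are recovered at their exact loci and mismatch
counts; every score column ranks the perfect match highest (CCTop's 0 is its
maximum — columns are oriented "larger = more cleavage-prone"), and the
labels reproduce the planted truth. On labeled tables,
`fit_adaboost_samme_r` / `predict_integrated` then produce the integrated
probability, and `benchmark_tools` reports per-column ROC/PR-AUC pooled and
per cell type.

The same workflow is available from the shell:

```sh
offscan search --genome genome.fa --guides guides.tsv --out candidates.tsv
offscan score --candidates candidates.tsv --guides guides.tsv --unlabeled --out features.tsv
offscan train --features labeled_features.tsv --seed 1 --out model.json
offscan predict --candidates candidates.tsv --guides guides.tsv --model model.json --out ranked.tsv
```

`predict` writes the full ranked report plus a separate top-200 slice of the
riskiest sites; `benchmark` and `simulate` round out the workflow.

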