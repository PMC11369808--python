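# borderquant

Quantification pipeline for studies of SoxB1 transcription factors at the
*Xenopus* neural plate border (NPB). Developmental biologists working with
explant imaging and ChIP-seq readouts typically stitch these analyses
together from Fiji macros, spreadsheet formulas and one-off R snippets;
`borderquant` packages the same procedures as tested, seeded library code:

* **Image colocalization** — per-nucleus double-positive quantification of
  multi-channel explant images: DAPI is segmented with Bernsen's local
  contrast threshold, signal channels (nascent *pax3* transcript, Sox3
  protein) with the Rényi-entropy histogram threshold, connected clusters of
  ≥ 20 DAPI pixels are called as nuclei, and the statistic
  Sox3&pax3⁺⁺ / total pax3⁺ is computed over randomly sampled regions of
  50 nuclei (3 regions per explant, 18 regions per stage).
* **Peak annotation and enrichment** — nearest-TSS assignment of ChIP peaks
  to genes, peak-set overlap, and 2×2 contingency enrichment of k-means
  expression clusters with Fisher's exact test and odds ratios
  OR = (a·d)/(b·c) with Woolf 95% CIs (forest-plot ready).
* **Motif scanning** — log-odds PWM scanning of peak sequences on both
  strands with *exact* p-values from the dynamic-programming score
  distribution; ships the canonical 15-bp Oct4-Sox2 composite element
  (Sox HMG half-site + POU octamer, `CTTTGTTATGCAAAT`) for composite-motif
  incidence.
* **Bench statistics** — ΔΔCT qPCR fold changes (fold = 2^(−ΔΔCT),
  reference gene *odc*), western-blot densitometry normalization, and
  two-tailed t-tests.
* **Synthetic data with ground truth** — every input above can be generated
  with a seed and a known truth (latent per-nucleus labels, intended
  peak→cluster associations, motif implant flags), so the entire pipeline is
  testable end to end without any external data.

## Worked example

Recover the stagewise colocalization profile from synthetic explants
(6 explants × 3 regions × 50 nuclei per stage):

```python
from borderquant.pipeline import colocalization_profile

per_region, summary = colocalization_profile(seed=7)
print(summary.round(4).to_string(index=False))
```

```
stage  n   mean     q1  median     q3  n_outliers
 10.5 18 1.0000 1.0000  1.0000 1.0000           0
 11.5 18 0.7784 0.7548  0.7710 0.8031           2
 12.5 18 0.7260 0.6839  0.7236 0.7644           0
   13 18 0.3655 0.3161  0.3406 0.4303           0
   15 18 0.1430 0.0777  0.1113 0.1868           1
```

Each row is one developmental stage: `mean` is the mean fraction of
pax3-positive nuclei that are also Sox3-positive over the 18 regions
(generator ground truth 1.00 / 0.79 / 0.69 / 0.34 / 0.14), the quartiles
describe the region-to-region spread, and `n_outliers` counts Tukey-fence
outliers (the unfilled circles of a violin plot).

Cluster enrichment on the packaged 5300-peak genome fixture:

```python
from borderquant.pipeline import cluster_enrichment_run

print(cluster_enrichment_run("fig4", seed=11)
      [["cluster", "n_peaks", "percent_of_peaks_int",
        "odds_ratio", "ci_low", "ci_high", "p"]].round(3).to_string(index=False))
```

```
 cluster  n_peaks  percent_of_peaks_int  odds_ratio  ci_low  ci_high     p
     NPB      596                    11       3.078   2.773    3.416 0.000
blastula      125                     2       0.780   0.646    0.943 0.010
      NC      105                     2       1.036   0.842    1.274 0.748
     C10      122                     2       0.372   0.309    0.446 0.000
```

11% of the 5300 peaks (n = 596) have their nearest TSS in the neural plate
border cluster, and the gene-centric odds ratio shows the border cluster as
the only enriched one — the forest-plot pattern expected for a factor bound
preferentially at border genes.

The same stages are available from a shell:

```sh
borderquant figures fig1c --seed 7 --out out/      # writes CSVs + manifest
borderquant simulate image --stage 11.5 --out explant.tiff
borderquant coloc --image explant.tiff --out regions.csv
borderquant annotate --peaks peaks.bed --genes genes.gtf --out assoc.tsv
```

## Layout

```
src/borderquant/
  synthetic_data.py   seeded generators + fixture profiles (fig1c, fig4, …)
  imagequant.py       thresholding, nucleus calling, colocalization
  peak_annotation.py  BED/GTF model, nearest TSS, peak overlap
  enrichment.py       Fisher / odds ratios / BH / forest data
  motifscan.py        PWM construction, scanning, exact p-values
  quant_stats.py      ΔΔCT, densitometry, t-tests
  pipeline.py, cli.py orchestration, presets, manifests, CLI
docs/methods.md       model and design notes
```
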