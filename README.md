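# dimetab

Downstream analysis of **direct-injection FT-ICR MS metabolomics** data.
Ultra-high-resolution mass spectrometry of complex mixtures (dissolved and
soil organic matter, exometabolomes, leachates) yields thousands of peaks
per sample, each with an assigned molecular formula (CHONSP) and an
intensity per sample — but no compound identifications. `dimetab` takes
that report table and runs the analyses this field actually uses, in one
command:

1. **Pre-processing** — filter peaks (m/z window, ¹³C isotopologues,
   assignment error ≤ 0.5 ppm, minimum presence), compute thermodynamic and
   molecular indices per formula, assign van Krevelen compound classes, and
   normalize intensities (max / minmax / mean / median / sum / zscore).
2. **Diagnostics** — per-sample peak and formula counts, error
   distributions.
3. **Exploration** — composition summaries, van Krevelen data, pairwise
   shared/unique peak sets, ANOVA + Tukey HSD on index distributions.
4. **Chemodiversity** — richness, Shannon, Gini–Simpson, Chao1, and Rao's
   quadratic entropy on elemental / unsaturation / reactivity traits.
5. **Statistics** — Bray–Curtis / Euclidean / Jaccard distances, PERMANOVA
   (one- and two-way), NMDS ordination, PCA summaries.
6. **Transformation networks** (optional) — mass-difference matching
   against a biochemical-transformation key at 1 ppm, per-sample graphs
   (GraphML + edge CSVs) and network statistics.

The core quantities, for a neutral formula C_c H_h N_n O_o P_p S_s:

```
NOSC  = 4 − (4c + h − 3n − 2o + 5p − 2s)/c         (nominal oxidation state of C)
GFE   = 60.3 − 28.5·NOSC                            [kJ (mol C)⁻¹]
DBE   = 1 + (2c − h + n + p)/2
AImod = (1 + c − o/2 − s − (n+p+h)/2)/(c − o/2 − n − s − p), truncated at 0
```

and, for networks, an edge between peaks i < j for key entry δ whenever
|Δm_ij − δ| ≤ δ·1e-6 (1 ppm of the key mass). A bundled `testnorm` step
scores every normalization × peak-subset combination for group bias (mean
log10 Kruskal–Wallis p of the per-sample normalization factors vs. the
grouping) and recommends the least-biased method.

A synthetic-study generator (`dimetab simulate`, or `dimetab.simulate` in
Python) produces Formularity-style reports with known ground truth, so the
whole pipeline runs and is testable without any external data.

## Worked example

```bash
# generate a 12-sample, 800-peak synthetic study (two groups, A/B)
dimetab simulate -o study --n-samples 12 --n-peaks 800 --seed 1

# which normalization is least biased for the A/B grouping?
dimetab testnorm -i study/report.csv -m study/metadata.csv -o norm -g Group
# -> recommended normalization method: mean

# full pipeline, transformation networks included
dimetab run -i study/report.csv -m study/metadata.csv -o results \
    -g Group -n median -t --seed 1
# -> preprocess: ok (0.102 s)
#    diagnostics: ok (0.028 s)
#    explore: ok (0.568 s)
#    diversity: ok (0.508 s)
#    stats: ok (0.77 s)
#    networks: ok (0.472 s)
```

`results/` then contains one subdirectory per step. A few of the numbers
this run prints into them:

- `1_preprocessing/filter_audit.csv` — 41 of 800 peaks removed (40 ¹³C
  isotopologues, 1 assignment error > 0.5 ppm): the filter audit, one
  count per rule.
- `5_statistics/permanova.csv` — `Group: pseudo_F = 1.08, R² = 0.097,
  p = 0.276` (999 permutations): this default simulated study carries no
  group effect, and the test correctly finds none.
- `5_statistics/nmds_scores.csv` — 2-D NMDS scores with `stress = 0.112`,
  a typical "usable but fuzzy" ordination for weak structure.
- `6_networks/network_stats.csv` — ~188 putative transformation edges per
  sample; `transformations_per_sample.csv` shows CH2 (methylation) at
  ~10.4 % of edges per sample — homologous CH2 series dominate, the usual
  finding for formula-rich mixtures.

All CSVs are deterministic: rerunning with the same `--seed` reproduces
them byte for byte.

## Layout

```
src/dimetab/
  io.py             # report / metadata / transformation-key reading, RunConfig
  preprocessing.py  # filters, indices, compound classes, normalization
  spans.py          # normalization bias scoring and recommendation
  exploration.py    # diagnostics, composition, pairwise sets, Tukey tests
  diversity.py      # Shannon / Gini-Simpson / Chao1 / Rao Q
  multivariate.py   # distances, PERMANOVA, NMDS, PCA
  networks.py       # mass-difference matching, graphs, statistics
  simulate.py       # synthetic-study generator with ground truth
  pipeline.py       # step orchestration, manifest
  cli.py            # dimetab run | testnorm | simulate
```

See `docs/methods.md` for the full methodological account (index
definitions, class-region table, zero handling, permutation conventions,
generator realism and limitations).
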