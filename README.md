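# ldamark

Biomarker discovery for two-class compositional feature tables (e.g.
microbial relative abundances): a Kruskal–Wallis class screen, an optional
strict sign-consistent Wilcoxon rank-sum subclass screen, and direct
full-data two-class linear discriminant analysis producing signed
`log10` effect-size scores. The package also ships the three standard
visualizations (score barplot, per-feature abundance histogram, annotated
radial cladogram), a synthetic-data generator with known ground truth, and
a bootstrap stability/convergence experiment harness.

Key properties:

- **Deterministic main path.** The discovery pipeline draws no random
  numbers: identical inputs give byte-identical outputs, with no seed.
- **No noise injection.** Rank-deficient inputs are handled by filtering
  degenerate features (all-zero, constant, duplicate rows); a genuinely
  singular within-class scatter is reported with candidate collinear
  features rather than masked.
- **Direct estimation.** LDA coefficients are computed once on the full
  data. A subsample-averaged estimator (`bootstrap_lda_reference`) is
  provided only for comparison experiments and demonstrably converges to
  the direct coefficients while adding run-to-run selection instability.

## Library use

```python
from ldamark import (
    PipelineConfig, SyntheticSpec, find_markers, generate_synthetic,
    read_feature_table, write_results,
)

table, groups = read_feature_table(
    "table.tsv", "metadata.tsv", class_column="condition",
    subclass_column="age_group",
)
result = find_markers(table, groups, PipelineConfig())  # 0.05 / 0.05 / 2.0
write_results(result, "markers.tsv")   # columns: features, scores
```

Defaults: alpha 0.05 for both screens, minimum absolute score 2.0, no
p-value adjustment (`none`; `holm`, `hochberg`, `hommel`, `bonferroni`,
`BH`, `BY`, `fdr` available), per-sample scaling to one million — so a
score of 2.0 corresponds to an absolute raw effect of 100 scaled
relative-abundance units. The first class level in order of appearance is
the reference (negative-score) class; override with `reference_level`.

## CLI

```sh
ldamark run --input table.tsv --metadata metadata.tsv \
    --class-col condition --subclass-col age_group --output markers.tsv

# classic single-TSV dialect (leading class/subclass/id rows):
ldamark run --input classic.tsv --class-row 0 --subclass-row 1 --id-row 2 \
    --output markers.tsv

ldamark plot bar   --results markers.tsv --output bar.png
ldamark plot hist  --input table.tsv --metadata metadata.tsv \
    --class-col condition --feature "k__Bacteria|..." --output hist.png
ldamark plot clado --results markers.tsv --input table.tsv --output clado.svg

ldamark simulate  --seed 1 --n-features 100 --n-per-class 30 \
    --n-spiked 5 --fold-change 4 --out-dir sim/
ldamark stability --input sim/table.tsv --metadata sim/metadata.tsv \
    --class-col class --seed 1 --output stability.tsv
```

`run` is seed-free by design; `simulate` and `stability` require an
explicit `--seed`.

## Layout

- `src/ldamark/data_model.py` — domain types, validation, configuration
- `src/ldamark/io_formats.py` — TSV readers/writers, lineage parsing
- `src/ldamark/stat_screen.py` — rank-test screens, p-value adjustment
- `src/ldamark/lda_effect.py` — scaling, filtering, LDA, effect sizes, pipeline
- `src/ldamark/viz.py` — barplot, histogram, cladogram (layout + rendering)
- `src/ldamark/synth_bench.py` — synthetic generator, stability experiment,
  TP−FP ranking evaluation
- `src/ldamark/cli.py` — `ldamark` entry point
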