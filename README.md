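# mirlink

Integrated miRNA–mRNA expression analysis for bulk time-course injury
studies, modelled on radiation-induced lung injury (RILI) in the rat:
stage-wise differential expression on probe-level microarray intensities,
per-miRNA Fisher-exact target-enrichment screening, reciprocal
(anti-correlated) miRNA→target pair extraction, gene-set enrichment,
regulatory-network export, and 2^−ΔΔCt qPCR quantification — plus a
synthetic-data generator that plants known regulatory structure so every
stage of the pipeline can be verified against ground truth.

It is written for bioinformaticians analysing paired miRNA/mRNA array (or
array-like) experiments with few replicates per condition, and for anyone
who wants the anti-correlation screening step as an auditable library
instead of a black box.

## The method

For each post-irradiation stage *s* (e.g. 3, 12, 26 weeks, each with its
own sham control) and each feature *g*:

* **Differential expression.** Welch's t-test on log2-normalized values,
  log2FC = mean(irradiated) − mean(control); Benjamini–Hochberg FDR within
  each (platform, stage) family; *g* is called up when
  log2FC ≥ 1 and p < 0.05 (2-fold rule; the significance gate is
  switchable to FDR), down symmetrically.
* **Target screening.** For every DE miRNA *m* with predicted target set
  T(m) (TargetScan-style input), a 2×2 table over the universe U of tested
  mRNAs against each directional DE list D:

  |            | target | not target |
  |------------|--------|------------|
  | DE (D)     | a      | b          |
  | not DE     | c      | d          |

  with a two-tailed Fisher exact test (minimum-likelihood convention) and
  odds ratio ad/bc.
* **Reciprocal pairs.** Every predicted edge (m, g) with *m* and *g* DE in
  opposite directions at the same stage; summarized per stage as "N
  up-regulated miRNAs had M down-regulated targets" (and vice versa).
* **Enrichment.** Upper-tail hypergeometric test of DE gene lists against
  GMT gene-set collections, BH-corrected within category.
* **qPCR.** rq = 2^−ΔΔCt with replicate averaging on the Ct scale,
  explicit reference assay, calibrator-group normalization per stage.

The synthetic generator plants a bipartite miRNA→gene repression graph
(each predicted edge functional with probability 0.8, effects of ~2 log2
units, ~6% of miRNAs DE, realistic noise) and emits matching truth tables,
so DE sensitivity/FDP, pair precision/recall and screen ranking can be
scored exactly. See `docs/methods.md` for the full model and its
assumptions.

## Worked example

Generate a fixture at the default study conditions (3 stages, 4 replicate
hybridizations per condition, 1000 genes, 100 miRNAs, triplicate probes)
and run the whole pipeline:

```python
import pandas as pd
from mirlink import DesignSpec, EffectModel, PipelineConfig, run_all
from mirlink.synthetic import write_fixture

paths = write_fixture("fixture", DesignSpec(seed=1), EffectModel())
cfg = PipelineConfig(
    mrna_expression=str(paths["mrna_expression"]),
    mrna_flags=str(paths["mrna_flags"]),
    mirna_expression=str(paths["mirna_expression"]),
    mirna_flags=str(paths["mirna_flags"]),
    sample_sheet=str(paths["sample_sheet"]),
    target_map=str(paths["target_map"]),
    truth_de_labels=str(paths["truth_de_labels"]),
    truth_reciprocal_pairs=str(paths["truth_reciprocal_pairs"]),
    out_dir="run", seed=1,
)
out = run_all(cfg)
print(pd.read_csv(out / "pair_summary.tsv", sep="\t").to_string(index=False))
print(pd.read_csv(out / "recovery_report.tsv", sep="\t")
      [["stage", "de_sensitivity", "de_fdp", "pair_precision", "pair_recall"]]
      .to_string(index=False))
```

prints

```
stage  n_up_mirnas  n_down_target_genes  n_down_mirnas  n_up_target_genes
  12w            2                   49              2                 44
  26w            2                   46              4                 88
   3w            2                   44              4                 89
stage  de_sensitivity   de_fdp  pair_precision  pair_recall
  12w        1.000000 0.000000        1.000000     1.000000
  26w        1.000000 0.006757        1.000000     1.000000
   3w        0.993197 0.013514        0.985714     0.992806
```

The pair summary is the per-stage count of distinct up-regulated miRNAs
with at least one down-regulated predicted target (and their distinct
target genes), and the reverse class; the recovery report scores the
calls against the planted truth — here the pipeline recovers ≥ 99% of
planted DE features per stage with ≲ 1% false discoveries, and the
extracted reciprocal pairs match the planted regulation almost exactly.

The same run is available from the shell:

```bash
mirlink simulate --out-dir fixture --seed 1
mirlink run-all --config pipeline.yaml     # paths + options, YAML
mirlink qpcr --ct-table ct.tsv --reference-assay U6 --out rq.tsv
```

Every output is a headed TSV (plus SIF/GraphML network exports) and each
run writes a `manifest.tsv` of SHA-256 hashes: re-running the same config
reproduces it byte for byte.

## File formats

* expression TSV: `probe_id`, `feature_id`, `feature_type` (mrna|mirna),
  then one log2-intensity column per sample; companion flag TSV of the
  same shape (0 = fine signal);
* sample sheet: `sample_id`, `group` (control|irradiated), `stage`,
  `replicate`;
* target map: `mirna_id`, `gene_id` (extra columns ignored); GMT for gene
  sets; long-format Ct tables for qPCR
  (`sample_id, group, stage, assay_id, assay_role, ct`);
* truth tables (written by the generator): `truth_de_labels.tsv`
  (feature, stage, signed log2 effect, label), `truth_regulation_edges.tsv`
  (functional miRNA→gene edges) and `truth_reciprocal_pairs.tsv`.

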