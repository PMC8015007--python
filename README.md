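# tmtdiff

Statistical detection of differentially abundant proteins in isobaric-label
(TMT) experiments with multiple mixtures, technical replicates, and
unbalanced designs.

The workflow has four stages, each usable on its own:

1. **Convert** — read a PSM-level quantification report (long, wide,
   Proteome-Discoverer-like or MaxQuant-like TSV/CSV), remove shared
   peptides and sparse spectra, keep one best spectrum per peptide ion and
   run, deduplicate fractions, and join the run/channel annotation into a
   long-format feature table of log2 reporter intensities.
2. **Normalize** — global median normalization equalizes the median log2
   intensity of every (run, channel); after summarization, local
   reference-channel normalization aligns each protein's "Norm"-channel
   summaries across runs.
3. **Summarize** — per protein and run, missing feature intensities are
   imputed under a left-censored Gaussian accelerated-failure-time model and
   the feature-by-channel table is decomposed with Tukey's median polish;
   the per-channel protein abundance is the overall term plus the channel
   effect.
4. **Compare** — per protein, a linear mixed-effects model
   (`abundance = condition + mixture + techrep(mixture) + subject + error`,
   reduced automatically to what the design and the protein's data support)
   is fit by REML; residual variances are moderated across proteins with the
   standard empirical-Bayes log-variance moment matching; condition
   contrasts are tested with moderated t-statistics on Satterthwaite degrees
   of freedom and adjusted per comparison by Benjamini-Hochberg.

A spike-in simulator (dilution-series ground truth, pooled reference
channel, MCAR/left-censored missingness, and subject-level biological
variation shared across technical replicates) and an evaluation harness
(eFDR, sensitivity, specificity, AUC) make the whole pipeline testable
without any external data.

## Command line

```sh
# simulate a controlled mixture: psm.tsv, annotation.tsv, truth.tsv
tmtdiff simulate --config sim.yaml --seed 7 --out-dir sim/

# full pipeline: feature table -> normalization -> summaries -> results
tmtdiff run --psm sim/psm.tsv --annotation sim/annotation.tsv \
    --out-dir out/ --seed 7

# score against ground truth
tmtdiff evaluate --results out/results.tsv --truth sim/truth.tsv \
    --fdr 0.05 --out out/metrics.tsv
```

Individual stages are available as `convert`, `normalize`, `summarize`, and
`compare`. Useful flags: `--no-reference-norm`, `--no-imputation`,
`--moderation/--no-moderation`, `--fdr` (default 0.05),
`--max-missing-fraction` (default 0.5). `run` also accepts a YAML config
whose keys mirror the flags.

Input conventions: the annotation TSV has columns
`Run, Channel, Condition, BioReplicate, Mixture, TechRepMixture`; reference
channels carry the reserved condition label `Norm`; biological replicate ids
must be unique across mixtures and conditions. Contrast files are TSVs with
comparison labels as rows, conditions as columns, and zero-sum weights as
entries (all pairwise comparisons are tested when omitted).

## Layout

```
src/tmtdiff/
  io_psm.py         PSM readers, filters, feature-table construction
  normalization.py  global median + reference-channel normalization
  summarization.py  AFT imputation, median polish, protein summaries
  mixed.py          dense REML engine with Satterthwaite df
  modeling.py       model selection, EB moderation, contrasts, BH
  simulator.py      spike-in and biological-variation generators
  evaluation.py     confusion counts, eFDR/sensitivity/specificity, AUC
  cli.py            click-based command line
tests/              pytest suite (tests/test_acceptance.py holds the
                    acceptance criteria)
scripts/acceptance.py
```
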