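# prepvote

Prognostic classification with **ensembles of preprocessing pipelines**.

Microarray gene-abundance data can be normalized in many defensible ways, and
risk calls from prognostic gene signatures shift with the choice.  `prepvote`
implements a complete, testable version of the ensemble workflow built around
that observation:

1. **Pipeline enumeration** — the 6 algorithms x 2 annotations x 2 handling
   modes = 24 preprocessing configurations (`prepvote.pipelines`).
2. **Synthetic cohorts** — latent abundance matrices with a hypoxia-activity
   factor driving an exponential survival hazard, plus per-pipeline monotone
   distortions, noise, batch offsets and gene dropout, so every downstream
   stage is testable without external data (`prepvote.cohort`).
3. **Signature scoring** — median-dichotomized gene votes summed into a
   per-patient score, dichotomized again into high/low risk, honoring
   separate-versus-merged dataset stratification (`prepvote.scoring`).
4. **Vote ensembles** — the patients x pipelines vote matrix, 12 engineered
   vote-summary count features, and the unanimous-vote classifier
   (`prepvote.votes`).
5. **Learned classifiers** — 5-year binary outcome, stratified 1:1 splits,
   class-balanced bagged-tree ensembles with (mtry, ntree) grid tuning, and
   shadow-feature (Boruta-style) all-relevant selection (`prepvote.classify`).
6. **Survival statistics** — Kaplan-Meier with Greenwood variance, log-rank,
   unadjusted two-group proportional-hazards HR (Breslow ties, bracketed 1-D
   maximizer), BH-FDR, ROC/AUC, confusion metrics, paired t on log2 HRs
   (`prepvote.survstats`).
7. **Novel signature discovery** — per-gene univariate hazard scans with FDR
   control, top-100 signatures per merged pipeline, 10-fold cross-validated
   per-signature classifiers, and a stacked meta-ensemble
   (`prepvote.discovery`).

## Command-line workflow

All stages exchange plain TSV files.  A full run on a simulated cohort:

```bash
# simulate: clinical.tsv + one abundance TSV per pipeline + true_signature.txt
prepvote --seed 1 simulate --out-dir data --n-patients 500 --n-genes 200

# score the signature across all 24 pipeline variants
prepvote --seed 1 votes --signature data/true_signature.txt \
    --pipeline-dir data --clinical data/clinical.tsv \
    --out votes.tsv --engineered-out engineered.tsv

# unanimous-vote classifier and its survival evaluation
prepvote unanimous --votes votes.tsv --out unanimous.tsv
prepvote --seed 1 evaluate --predictions unanimous.tsv \
    --clinical data/clinical.tsv --name unanimous --out report.json

# tuned tree ensemble on vote features (votes | votes+eng | eng | boruta)
prepvote --seed 1 train-ensemble --votes votes.tsv --clinical data/clinical.tsv \
    --feature-set eng --grid-mtry 2,4,8 --grid-ntree 500 --out-prefix rf

# per-pipeline signature discovery (merged pipelines) and the meta-ensemble
prepvote --seed 1 discover-signatures --pipeline-dir data \
    --clinical data/clinical.tsv --out-dir signatures
prepvote --seed 1 meta-ensemble --pipeline-dir data --signature-dir signatures \
    --clinical data/clinical.tsv --out-prefix meta

# paired t-test on log2 hazard ratios from two classifier families
prepvote compare --hr-a hrs_a.txt --hr-b hrs_b.txt
```

`--config config.yaml` can supply a full run configuration (seed, horizon,
split ratio, tuning grids, FDR alpha, top-k, CV folds); `--seed` overrides
the configured seed.  All randomness flows from the master seed through
token-keyed per-stage substreams, so any stage can be re-run in isolation.

## Layout

```
src/prepvote/
  pipelines.py   configuration-space enumeration
  config.py      run configuration + seed substreams
  io.py          TSV/signature/vote-matrix readers and writers
  cohort.py      synthetic cohort + pipeline distortions
  scoring.py     signature scoring and vote matrices
  votes.py       engineered features + unanimous classifier
  classify.py    outcomes, splits, tree ensembles, tuning, feature selection
  survstats.py   KM / log-rank / Cox / FDR / ROC / confusion / paired t
  discovery.py   gene scans, signature selection, CV classifiers, meta-ensemble
  report.py      evaluation reports (JSON + KM TSV companions)
  cli.py         click-based CLI (`prepvote`)
```
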