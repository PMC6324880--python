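# File formats

All tabular artifacts are UTF-8 tab-separated values with a header row and
`.` decimals; models, statistics and manifests are JSON. Subject identifiers
must be unique within a table.

## Cohort table (`*_cohort.tsv`)

One row per subject.

| column | type | meaning |
|---|---|---|
| `subject_id` | str | unique identifier |
| `diagnosis` | str | `HC`, `SCZ`, `MDD`, `OCD` or `ASD` |
| `site` | str | acquisition site label |
| `age` | float | years |
| `sex` | str | `M` / `F` |
| `wma_true` | float | generator's true working-memory ability (synthetic cohorts only) |
| `score_3back` | float | measured letter 3-back learning plateau (d' units) |
| `score_nback` | float | visual n-back accuracy percentage |
| `score_digit` | float | digit-sequencing score |
| `fluid_iq` | float | fluid-intelligence score |
| `composite_cog` | float | composite cognition score (z-scaled) |
| `mean_fd` | float | mean framewise displacement, mm |

## FC matrix (`*_fc.tsv`)

Subjects x features; first column `subject_id`, then one column per
connectivity feature in canonical order: `within:<network>` for networks
1..18, then `between:<network_i>|<network_j>` for all pairs i < j in
lexicographic order (171 columns for the default 18-network atlas). Values
are raw Pearson correlations in [-1, 1].

## Time series / motion (per subject)

- `<id>_ts.tsv` — voxels x frames signal matrix (plain numbers).
- `<id>_motion.tsv` — frames x 6 realignment parameters: 3 translations
  (mm), 3 rotations (radians).
- voxel map: one 0-based network id per voxel, one per line.

## Behaviour

- d' table: `subject_id` + one column per session of per-session d' values.
- trial counts (long): `subject_id`, `session`, `hits`, `misses`,
  `false_alarms`, `correct_rejections`.
- plateau table (output): `subject_id`, `a` (plateau), `b` (learning
  speed), `sse`.

## QC report (`qc.tsv`)

`subject_id`, `scrub_ratio` (fraction of frames removed at FD > 0.5 mm),
`excluded` (True when scrub_ratio > 0.40), `n_frames_kept`.

## Model (`model.json`)

Keys: `schema` (`wmconn-model-1`), `weights` (length-171, zeros off
support), `intercept`, `support` (selected feature indices),
`support_labels`, `feature_means`/`feature_sds`/`target_mean`/`target_sd`
(standardization used during fitting), `ard_precision` (null = pruned),
`diagnostics` (`n_iter`, `converged`, `final_elbo`), `params` (estimator
hyperparameters).

## Ground truth (`ground_truth.json`)

`w_true`, `support`, `intercept_true`, `noise_sd`, `fc_mean`,
`fc_subject_sd`, `delta` (diagnosis -> per-feature FC mean shift),
`confound_coupling`, `seed`.

## Decomposition outputs

- `d_scores.tsv` / `z_scores.tsv` — patients x selected connections.
- `stats.json` — permutation two-way ANOVA (`F_diagnosis`, `p_main`,
  `F_interaction`, `p_interaction`, post-hoc pairs, permutation counts,
  seed), per-connection Kruskal-Wallis FDR summary, and the
  selected-vs-other-connections KS test.
- `cluster_dscores.tsv` — `cluster`, `diagnosis`, `summed_d` (summed
  diagnosis-mean D-scores over between-cluster connections touching the
  cluster).

## Manifest (`manifest.json`)

`schema`, `config` (subcommand parameters), `config_sha256`, `seeds`,
`versions` (wmconn / python / numpy / pandas). Re-running a subcommand with
the same config and seeds reproduces its numeric outputs byte-identically.
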