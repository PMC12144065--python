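# vacmorph

Quantification of vacuole morphodynamics in stigma papilla cells, built as a
tested, fully synthetic-data-driven pipeline:

* **`vacmorph.synthetic`** — generators for every input the pipeline needs:
  tonoplast time-lapse movies of a capsule-shaped papilla cell with
  ground-truth constriction/fusion event logs, NCC series drawn directly from
  the Bayesian state-space observation model, and pollen-hydration width
  trajectories / rendered ellipse frames. Scenario presets encode the
  qualitative orderings of the experimental conditions (unpollinated,
  pollinated, mock, E-64d, PDMP, wortmannin dose series, rop2 mutant).
* **`vacmorph.morphodynamics`** — the preprocessing chain (medial z-slice,
  3×3 median filter, 97th-percentile normalization) and the normalized
  correlation coefficient (NCC) time series of each frame against frame 0.
* **`vacmorph.constriction`** — automated counting of vacuole borders that
  appear completely across the cell (span, persistence, and merge-distance
  parameters), plus ingestion of manual counts and mean ± SEM summaries.
* **`vacmorph.hydration`** — pollen width by moments-equivalent ellipse fit
  (minor axis) and hydration rate `(L_t − L_0)/L_0 × 100` at 5/10/15 min.
* **`vacmorph.ssm`** — Bayesian state-space model for NCC series: Normal
  random-walk control mean, Cauchy random-walk group difference,
  Beta-proportion observations (`Beta(mu*kappa, (1-mu)*kappa)`), uniform
  priors over the constrained supports. Sampled with a built-in NUTS
  implementation (analytic gradients, dual-averaging step size, windowed
  diagonal mass adaptation, non-centered difference path); summaries are
  per-time medians and 95% credible bands with an excludes-zero flag;
  diagnostics (split R-hat, bulk ESS) via `arviz`.
* **`vacmorph.pipeline`** / **`vacmorph.cli`** — end-to-end orchestration
  (simulate → NCC/constriction/hydration → state-space comparison → Dunnett /
  Tukey-HSD / Welch tests → plots) with a reproducibility manifest.

## CLI

```bash
vacmorph simulate unpollinated --out movie.tif --seed 1 --events-csv events.csv
vacmorph ncc movie.tif --out ncc.csv --condition unpollinated
vacmorph constrict --tiff movie.tif --mask-tiff mask.tif --out counts.csv
vacmorph hydrate widths.csv --out rates.csv
vacmorph ssm ncc_all.csv --control mock --experimental wortmannin_500 --out-prefix fit
vacmorph compare values.csv --out tests.csv --method dunnett --control mock
vacmorph run-all --scenarios mock,wortmannin_500 --control mock --out run1 --seed 1
```

`run-all` writes NCC CSVs, constriction counts and tests, hydration tables,
state-space summaries/draws, band and bar plots, and a `manifest.json`
recording versions, seeds, and parameters; reruns with the same seed are
bit-identical.

## Layout

```
src/vacmorph/          package (one module per pipeline stage)
tests/                 pytest suite; test_acceptance.py holds the
                       acceptance criteria at their stated tolerances
scripts/acceptance.py  acceptance report generator
```
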