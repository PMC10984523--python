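# crcburden

Modelling pipeline for estimating the downstream colorectal-cancer (CRC)
burden of temporary disruptions to screening, diagnosis, and treatment
services, and the effect of post-disruption capacity mitigation.

The pipeline has five stages, each usable on its own:

1. **`crcburden.natural_history`** — a synthetic natural-history
   generator (precursor → preclinical cancer → clinical presentation,
   exponential dwell times, biennial screening with no catch-up).
   It produces monthly case streams split by detection mode, stage and
   age, and reacts to screening-participation changes the way a full
   microsimulation would: fewer screen-detected cancers during a dip, a
   later compensating excess with a worse stage mix, and a small
   long-term incidence rise from missed precursor removals. All scenario
   pairs share one latent population per seed (paired-seed design), so a
   participation series identical to 1.0 reproduces the comparator stream
   byte for byte.
2. **`crcburden.timeline`** — converts observed relative changes in
   procedure volumes into per-timestep capacity multiplier series,
   including the procedures→diagnoses magnitude scaling (0.504) and
   mitigation uplifts from 2022 onward.
3. **`crcburden.backlog`** — two queue engines turn capacity shocks into
   per-patient additional waits: a stochastic agent queue on a 2-week
   timestep (each waiting patient served with probability
   `min(1, capacity/waiting)`) and a deterministic weekly aggregate
   backlog calculator. Patients still queued at the horizon are served in
   a flagged drain phase.
4. **`crcburden.impact`** — converts waits into excess mortality via a
   hazard ratio per 4-week delay (default 1.06) applied under
   proportional hazards to stage-specific survival curves, plus optional
   one-stage upstaging for diagnostic delays. Diagnostic delays of
   screen-detected cancers are excluded from the hazard ratio to avoid
   double counting with the natural-history stage.
5. **`crcburden.scenarios` / `crcburden.reporting`** — compose the
   scenario sets (comparator, screening-only, pandemic without
   mitigation, pandemic with 5%/15% mitigation), difference outcomes
   against the paired comparator, decompose excess deaths into
   screening-related and diagnosis/treatment-related components, and
   compute annual age-standardised rates against the Segi world standard.

All defaults (cohort parameters, survival anchors, treatment mix,
country shock inputs) live in `src/crcburden/data/default_config.yaml`
and can be overridden by a user YAML file.

## CLI

```bash
crcburden config show                          # print merged configuration
crcburden simulate --out cases.csv             # synthetic case stream
crcburden timeline build --records records.csv --baseline baseline.csv \
    --mitigation 0.05 --mitigation-start 2022-01 --out capacity.csv
crcburden queue run --engine agent --arrivals arrivals.csv \
    --capacity capacity.csv --seed 1 --out delays.csv
crcburden scenario run --country canada --out results/canada
```

`scenario run` writes per-scenario outcome tables, the windowed excess
table (CSV + JSON), and a manifest recording every seed and the full
config snapshot. A global `--seed` flag fully determines all stochastic
output.

## Conventions

- Month index 0 = January 2018; all windows are half-open `[start, end)`.
- A month is 4 weeks for sub-monthly resampling (2 steps per month at
  the 2-week timestep).
- Additional waits are measured beyond status-quo waiting times; an
  undisrupted balanced queue yields exactly zero additional wait.
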