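# phasemet

Phase-I metabolite identification and temporal metabolic profiling for
the synthetic cannabinoids **5F-ADB-PINACA** (indazole core) and
**5F-ADBICA** (indole core), built as a reusable, tested pipeline:

- **`phasemet.formula`** — elemental-formula algebra: parsing, exact
  monoisotopic masses (pinned atomic-mass table), `[M+H]+` and
  intrinsic-cation m/z, signed ppm errors, bounded formula
  decomposition from accurate mass.
- **`phasemet.rules`** — phase-I biotransformations (hydroxylation,
  dehydrogenation, amide hydrolysis, deamination, hydrolytic/oxidative
  defluorination, carboxylation, N-dealkylation) as composition deltas
  with site constraints; bounded enumeration of candidate metabolites
  (depth ≤ 3 by default) and deduplication of formula-degenerate
  candidates. Rulesets serialize to YAML so new scaffolds need no code
  changes.
- **`phasemet.annotate`** — MS1 peak matching at ±5 ppm and MS2
  site localization: scaffold-specific acylium diagnostic fragments
  (plus hydrate/dehydrate congeners and precursor neutral losses) score
  every legal site-assignment hypothesis; ties are flagged, never
  silently broken. ADB-residue modifications are localized by
  elimination.
- **`phasemet.profiling`** — replicate mean-aggregation, normalization
  to the most abundant signal, rule-based trend classification,
  Pearson correlation clustering (connected components at |ρ| > 0.8),
  four-way categorization and composite biomarker ranking
  (0.5·AUC + 0.3·persistence + 0.2·cluster centrality).
- **`phasemet.kinetics` / `phasemet.synth`** — first-order kinetic
  networks (closed-form cascade + RK4) and seeded synthetic studies
  with log-normal replicate noise and ppm-scale mass jitter, emitting
  the same CSV schemas the annotator and profiler consume, plus ground
  truth for recovery testing.
- **`phasemet.cli`** — `simulate`, `annotate`, `profile`, `fullrun`
  subcommands with a YAML config; every report embeds the resolved
  config, its hash and the tool version.

The package ships the published metabolite inventories of both parents
(`src/phasemet/data/*.csv`: retention times, neutral formulas, reported
`[M+H]+` values, reaction/site assignments, diagnostic product ions) as
reference fixtures.

## CLI

```sh
# seeded synthetic study (peaks.csv, ms2.csv, intensities.csv, ground_truth.json)
phasemet simulate --seed 1 --out-dir out/sim

# annotate a peak list against enumerated candidates
phasemet annotate --parent 5F-ADB-PINACA --peaks out/sim/peaks.csv \
    --ms2 out/sim/ms2.csv --out-dir out/ann

# temporal profiling of a long-format intensity table
phasemet profile --intensities out/sim/intensities.csv --out-dir out/prof

# simulate -> annotate -> profile with a consolidated recovery report
phasemet fullrun --seed 1 --out-dir out/full
```

Input schemas: peak list CSV `id,mz,intensity[,rt_min]`; MS2 CSV
`precursor_id,mz,intensity`; intensity CSV
`metabolite_id,time_h,replicate,intensity` (time grid 1/2/4/8/12/24 h,
3 replicates by default).

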