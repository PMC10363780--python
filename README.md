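# boarrest

Resting-site analysis for GPS + activity biologging of nocturnal ungulates.

Wild boars (*Sus scrofa*) living near people become nocturnal, which moves
their entire resting phase into the daytime — exactly when human activity
peaks.  Understanding how they choose, re-use, and abandon daytime resting
sites (RSs) is therefore a question about one consolidated diurnal rest bout
per day, anchored to sunset, interrupted only rarely by within-rest
relocations.  `boarrest` implements that analysis chain for movement
ecologists working with dual-sensor collars (a 0–255 activity summary, ACT,
every 5 min plus a GPS fix every 30 min):

1. **Segmentation** — classify epochs resting (ACT ≤ 40) / active (ACT > 40),
   smooth short activity bouts, and extract one inactive phase per day,
   anchored against NOAA sunrise/sunset.
2. **Relocation detection** — a sustained supra-threshold ACT bout whose
   pre/post mean GPS positions are > 100 m apart is a relocation of the
   resting animal.
3. **Resting sites** — daily resting locations (mean of pre-relocation
   fixes) clustered per animal by average linkage with a 50 m cut; visits
   counted per hunting season.
4. **Landscape covariates** — villages derived from building footprints by
   ±50 m morphological closing (components > 1.5 ha), high-traffic road
   filtering, dense-vegetation classification, signed distances, and a
   drive-hunt calendar (open season 15 Aug – end Feb/Mar; hunting days =
   Wed/Sat/Sun + bank holidays).
5. **Resource selection** — a use–availability RSF: each used RS against
   1000 uniform points from the animal's 90% kernel home range, fitted as a
   binomial GLMM with `veg × d(road)` and `veg × d(village)` interactions
   and animal-within-study-site random intercepts; selection ratios
   SR = (n_avail/n_used)·exp(η) with SR > 1 meaning selection; model skill
   by area-adjusted-frequency cross-validation (5 folds, 10 bins, 20 reps,
   Spearman rank correlation).
6. **Behavioral models** — site revisitation counts as a zero-truncated
   Poisson GLMM (P(Y=k|k≥1) = λᵏe^{−λ}/(k!(1−e^{−λ}))) with log survey
   length as control; relocation probability as a binomial GLMM with a
   3-level season factor; relocation distance (km) as a gamma log-link GLMM.

A first-class synthetic generator (`boarrest.simulate`) produces landscapes
and ground-truthed collar series with the statistical structure the analysis
assumes, so every stage is testable without field data.  All mixed models
run on a built-in Laplace-approximation engine for nested random intercepts
(see `docs/methods.md`).

## Worked example

```python
from boarrest import SimulationConfig, simulate_study
from boarrest.pipeline import PipelineOptions, analyze_study, validate_against_truth

study = simulate_study(SimulationConfig(seed=3, n_animals=5, survey_length_days=120))
results = analyze_study(study, PipelineOptions(run_selection=False,
                                               run_behavior_models=False))
print(validate_against_truth(study, results))
```

prints

```
{'phase_recovery_rate': 0.9916666666666667, 'n_days': 600,
 'reloc_recall': 1.0, 'reloc_fpr': 0.0, 'n_true_relocations': 41,
 'n_phases': 600, 'site_ari': 1.0}
```

Of 600 simulated animal-days, 99.2% of inactive phases are recovered with
both bounds within one 5-min epoch of the generator's truth; all 41 true
relocations (each > 100 m by construction) are detected with zero false
positives on the 559 undisturbed phases; and the recovered site partition
matches the true site labels exactly (adjusted Rand index 1.0) even at the
default 15 m GPS noise.  The full pipeline (`analyze_study` with all stages
on) additionally returns the seasonal RSF fits with selection-ratio curves
and cross-validation scores, the revisitation and relocation model
coefficient tables (β, SE, z, p) with marginal Nakagawa R², and a summary
with the time budget, sunset/sunrise anchoring fractions, revisit fraction
and per-season relocation probabilities.

The same pipeline is scriptable from a shell:

```sh
boarrest simulate --seed 1 --out sim_out     # sensor CSVs + GeoJSON + truth
boarrest validate --seed 1                   # truth-recovery metrics
boarrest run config.yaml --out out           # full run on a config
```

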