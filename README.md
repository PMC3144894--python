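# socnetlong

Social-network structure and adult longevity in wild group-living
mammals: association networks from daily field observations,
permutation-gated network inference, weighted clique-percolation group
assignment, centrality-dispersion measures, randomization regressions
of age at death, and Barker joint mark-recapture survival models —
with a synthetic study generator so the whole chain is testable
without field data.

## Who this is for

Behavioral ecologists analyzing long-term observation and
capture-mark-recapture records of marked, group-living animals (the
motivating system is a plural-breeding rock-dwelling mammal observed
daily over many field seasons), and methodologists who want a tested,
scriptable reimplementation of the SocProg / CFinder / Ucinet / MARK
workflow for this class of analysis.

## The analysis in brief

1. **Networks.** For each site and season, dyadic tie weights are the
   simple ratio index `SRI(a,b) = |days together| / |days a or b seen|`
   at one-day resolution, from affiliative interaction events only
   (agonistic and tree-foraging records, and events involving unmarked
   animals, are excluded).
2. **Gate.** Each network is tested against a within-day swap null
   ("gambit of the group"): individuals are permuted among the
   interaction clusters of the same day, preserving cluster sizes and
   individual sighting records. The observed SD of dyadic indices is
   compared to the null; only networks with p < 0.05 (long-term
   preferred companions) are analyzed further.
3. **Groups.** Individuals are assigned to social groups by weighted
   clique percolation (CPMw, default k = 3): k-cliques above an
   intensity threshold (geometric mean of edge weights) are merged
   when they share k−1 members; uncovered animals are solitary.
4. **Measures.** Per individual: strength (weighted degree), Bonacich
   power `c = (I − βW)⁻¹W·1`, and Stephenson–Zelen information
   centrality. Per group: the SD of each across members — the group
   *centrality SD*, an inequality measure — plus distance-based
   cohesion and Freeman-style centralization.
5. **Longevity.** For animals of known age that died as adults,
   metrics are averaged over ages 2..death and regressed on age at
   death; p-values come from response-permutation randomization tests,
   with residual regression to control group size and a fixed-effects
   group term to probe within-group dependence.
6. **Survival.** Encounter histories (live recaptures, live resights,
   dead recoveries) are fit with the Barker model — parameters S, p,
   r, R, R′, F, F′ on the logit scale — via a hidden-state forward
   likelihood; candidate structures are ranked by QAICc, averaged by
   Akaike weight, and compared by likelihood-ratio tests (e.g.
   solitary vs. group survival).

See `docs/methods.md` for models, defaults, numerical decisions, and
what the synthetic generator does and does not emulate.

## Worked example

Generate a synthetic study and run the full pipeline:

```sh
socnetlong synth -o fixture --seed 0
socnetlong run -c config.yaml     # or use the library directly:
```

```python
from socnetlong.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(
    observations="fixture/observations.csv",
    individuals="fixture/individuals.csv",
    encounters="fixture/encounters.csv",
    output_dir="output", panel_n=34, seed=0,
))
sd = next(r for r in report["regressions"]
          if r["predictor"] == "mean_sd_strength" and not r["controls"])
print(f"retained networks: "
      f"{sum(v['retained'] for v in report['periods'].values())}"
      f"/{len(report['periods'])}")
print(f"centrality SD vs longevity: slope={sd['slope']:.3f} "
      f"r2={sd['r_squared']:.3f} p={sd['p_randomization']:.4f} (n={sd['n']})")
for g, est in report["survival"]["averaged_S"].items():
    print(f"S[{g}] = {est['estimate']:.3f} +/- {est['se']:.3f}")
```

Output for seed 0:

```
retained networks: 6/6
centrality SD vs longevity: slope=-26.194 r2=0.154 p=0.0205 (n=34)
S[group_hi] = 0.756 +/- 0.029
S[group_lo] = 0.759 +/- 0.031
S[solitary] = 0.654 +/- 0.041
```

All six site-year networks show nonrandom association and pass the
gate. The negative slope says animals in groups with more unequal
strength centrality died younger (the generator injects this effect on
the hazard scale); r² is the variance in age at death explained across
the 34 dead adults, and p is the randomization-test probability of a
slope this extreme under permuted ages. The model-averaged survival
estimates recover the key simulated contrast: solitary males survive
clearly worse than members of either social group (the two group
strata, simulated at S = 0.77 and 0.71, are within one standard error
of each other at this sample size).

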