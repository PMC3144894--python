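# Methods

This package reimplements, as a tested library, the analysis chain that
links the social-network structure of wild group-living mammals to
adult longevity and survival: daily co-observation networks, a
permutation gate for nonrandom association, weighted clique-percolation
group assignment, individual and group centrality measures,
randomization regressions of age at death, and a Barker joint
mark-recapture model.  This note records the models, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
study generator does and does not emulate.

## Association networks

Observations are long-format records: one row per individual per
interaction event per day.  Only affiliative records (physical contact,
coordinated activity) enter the networks; agonistic and tree-foraging
records are excluded because they do not express positive association,
and any event involving an unmarked animal is dropped whole because it
cannot be attributed to identified dyads.

Associations use a one-day resolution: a dyad is "together" on a day if
it co-occurs in at least one retained event that day (co-membership in
an event, not mere same-day presence — the record stream counts
interactions, not co-sightings; the alternative rule would need
explicit group-scan data that the record schema does not carry).  The
tie weight is the simple ratio index

    SRI(a, b) = |days together| / |days a seen ∪ days b seen|,

in [0, 1], undefined (an error, not zero) when neither animal was ever
seen.  The union denominator is the classical simple-ratio form; the
equivalent x/(x + y_a + y_b + y_ab) decomposition coincides with it
under this reading.  Individuals seen on zero days are dropped from
that period's network with a warning.

## Permutation gate

Whether a network reflects long-term preferred companionship is tested
against a "gambit of the group" null: individuals are shuffled among
the interaction clusters observed on the same day (events sharing
members are merged first), preserving every cluster's size and every
individual's daily sighting record.  A Markov chain of checkerboard
swaps (two individuals exchanged between two clusters of one day)
generates null matrices; because daily presence is invariant, only the
days-together counts are updated incrementally, which keeps the chain
cheap.

The test statistic is the standard deviation of the dyadic association
indices over **all** dyads (CV and mean are options, as is restricting
to nonzero dyads).  The all-dyad default matters: in a maximally
structured network (fixed cliques, always together) the nonzero indices
are all 1 and their SD is zero, so a nonzero-only statistic has no
power exactly where the signal is strongest.  High observed SD relative
to the null indicates preferred companions (upper tail); the lower tail
tests avoidance.  P-values use the add-one rule (count + 1)/(n + 1)
and the chain stops early once p changes by less than a tolerance
(default 0.01) between consecutive blocks, mirroring the
"progressively increasing permutations until stabilization" protocol;
tolerance 0 forces the full run.  Chain defaults — 1,000 burn-in swaps,
100 swaps between retained permutations, at most 10,000 permutations —
follow common practice for swap-based null models and are configurable.
Only networks with p below alpha (default 0.05) proceed downstream.

The chain starts at the observed data, so the sequential p-value is of
the Besag–Clifford serial type; the calibration test in the acceptance
suite confirms the realized type-I error is nominal.

## Group assignment (weighted clique percolation)

Groups are communities under CPMw: k-cliques whose intensity — the
geometric mean of their edge weights, (∏w)^(2/(k(k−1))) — reaches a
threshold are linked when they share k−1 nodes, and communities are
the node unions of the resulting components.  Animals covered by no
retained clique are solitary.  Default k = 3, the smallest meaningful
clique and the common software default.

No intensity threshold is prescribed by the method itself, so the
default strategy scans candidate thresholds (the distinct clique
intensities, thinned to at most 40 quantiles on large graphs) and keeps
the largest threshold at which the biggest community still holds at
least half the clique-covered nodes — the usual "just below the
critical point" heuristic.  A fixed threshold can be supplied instead,
and results that depend on (k, threshold) are config-sensitive by
design.

Communities can overlap.  Group-level statistics need disjoint groups,
so a shared individual is assigned to the community where the sum of
its weights to co-members is largest (ties: larger community, then
lexicographic order).

## The seven network measures

Per individual (on the period's weighted graph):

1. **Strength centrality** — the row sum of association indices.
2. **Bonacich power** — c = (I − βW)⁻¹W·1, which weights neighbours by
   their own connectedness; requires |β| < 1/ρ(W).  β is unreported in
   typical applications, so the default is 0.5/ρ(W), recorded in the
   output; the vector is scaled so Σc² = n.
3. **Information centrality** (Stephenson–Zelen) — with B = D − W + J
   and C = B⁻¹, I_i = n/(n·C_ii + tr C − 2·rowsum_i C).  Weights are
   used directly as conductances.  Defined per connected component.

Per group: the standard deviation of each of the three measures across
members (population SD by default, matching network-software
convention; sample SD available), computed on the group's induced
subgraph, plus:

6. **Distance-based cohesion** (compactness) — mean over ordered pairs
   of 1/d_ij with 1/d = 0 for unreachable pairs; shortest paths use
   edge length 1/w by default (binary lengths available for
   cross-checks).
7. **Network centralization** — Σ(s_max − s_i) / ((n−1)(n−2)·w_max).
   Centralization has no standard weighted normalization; this
   w_max-scaled Freeman form is chosen because it anchors the scale at
   1 for a uniform star and 0 for any weight-regular graph.  Absolute
   values depend on this choice.

## Longevity panel and regressions

Only animals of known age that died as adults (age ≥ 2) enter the
panel.  Each metric is averaged over the animal's adult years (age 2 to
death); a year with a missing metric is skipped with a warning.  Age at
death is counted in whole years between March-1 reference dates (the
population breeds synchronously, so pups are aged from March 1 of the
capture year and yearling juveniles from March 1 of the previous year);
animals not captured young are aged from the sex-specific log-log
body-weight regressions.  The printed regression coefficients do not
state their log base or age unit; base 10 with age in days is the only
combination giving plausible adult ages for a 3–4 kg animal and is the
default, with both configurable.

Because age at death is skewed, regression p-values come from a
randomization test: the response is permuted (default 10,000 times,
2,000 in the pipeline), the slope refit, and p computed by the add-one
rule, two-tailed on the slope by default.  Group size and observation
effort are removed by residual regression (residuals of both response
and predictor on the controls, the Frisch–Waugh device).  Dependence
within social groups is probed by an indicator-variable ANCOVA —
y ~ predictor + group — with partial F tests for each term; this
fixed-effects form reproduces the F_{g−1, n−g−1}-style test without a
mixed-model dependency and approximates a random group effect
evaluated by its F statistic.  Aggression rates are residuals of
agonistic-day counts on group size and observation days.  No
multiple-testing correction is applied across the metric regressions;
the report records how many tests were run.

## Barker survival model

Encounter histories combine live recaptures at trapping occasions with
between-occasion live resights and dead recoveries.  Seven parameter
families: S (survival), p (capture given at risk), r (dead recovery),
R (resight given survival), R′ (resight before death), F (fidelity),
F′ (re-immigration).  The likelihood is a per-animal forward recursion
over hidden states {alive at risk, alive off risk, dead}: per interval,
survival, then the resight/recovery emission (R for survivors; R′ and r
independently for deaths — the standard structure; permanent emigration
is the fixed value F′ = 0), the fidelity transition, and the capture
emission at the next occasion (off-risk animals cannot be captured).
This recursion is algebraically equivalent to the published multinomial
form and is verified against exhaustive hidden-path enumeration for
T ≤ 4 and against completeness (all histories sum to 1) for T ≤ 3 in
the test suite; with r = R = R′ = 0 and F = 1 it reduces to
Cormack-Jolly-Seber, checked against an independent CJS fit.

Model structures per parameter — constant, time, group, two age
classes (first year after release as a pup vs. older), and additive
combinations — act on the logit scale.  Fitting maximizes the joint
log-likelihood with L-BFGS-B (gradient tolerance 1e-8, optional
jittered multi-start); non-convergence and boundary estimates
(|logit| > 10) are flagged, never silent.  Standard errors come from
the numerical information matrix by the delta method, inflated by
√ĉ.  Model selection uses QAICc = −2lnL/ĉ + 2K + 2K(K+1)/(n_eff−K−1)
with normalized Akaike weights, model averaging with unconditional
standard errors (within-model variance plus between-model spread), and
likelihood-ratio tests for nested pairs.  Two conventions are explicit
decisions: the effective sample size is the number of released animals
(capture-recapture software varies here; a caveat, not a claim), and
the overdispersion coefficient ĉ is a user-supplied constant
(default 1) — the median-ĉ bootstrap is out of scope.  Terminal-
occasion parameters confounded in the likelihood are reported but not
separately identifiable.

## Synthetic study generator

The generator emulates the statistical structure of a long-term field
study of a plural breeder living in mainly-female groups: two sites,
two social groups per site with sizes drawn near 14 ± 5 (clipped to
7–21), a 60-day season per year, several consecutive years over the
same populations, daily detection probability 0.5, and a 10%
contamination of agonistic / tree-foraging / unmarked events to
exercise the record filters.  Within a group, each animal has a
lognormal gregariousness (mean 1, SD = the heterogeneity knob) and a
dyad's daily interaction probability is base × greg_i × greg_j clamped
to [0, 1]; base 0.25 within groups puts realized nonzero indices in the
0.17–0.37 band reported for such systems.  Gregariousness is
multiplicative because it is the simplest mechanism that spreads
strength centrality without much changing its mean — a modelling
choice, not a biological claim.  Group heterogeneity is drawn uniform
on (0.05, 0.55) so realized group centrality SDs span a wide range.

Longevity is discrete yearly survival (matching the yearly resolution
of the analysis): after reaching adulthood at age 2 an animal dies each
year with probability q, logit(q) = logit(0.25) + 1.2·z(group SD) +
0.3·z(group size), capped at age 14 (animals reaching the cap are
censored, not panel members).  The coefficients are per-SD log-odds
effects on the *realized* group strength-centrality SD and group size;
1.2 makes the induced longevity correlation comparable to a panel-of-34
field study with r² around 0.2, i.e. an effect a study of this size is
powered to detect.  Encounter histories are forward simulations of the
exact generative process the likelihood describes, with staggered entry,
under three strata (two social groups at S = 0.77 and 0.71 and solitary
males at S = 0.65, recapture 0.85) — the survival regime such studies
report.

What the generator does **not** emulate, hence what passing tests do
not show about field data: observation effort is homogeneous (no
weather, observer, or visibility effects); group membership is closed
(no dispersal, no between-group edges in the study generator); every
animal is simulated as observable in all study years, with the analysis
side discarding years after its death (a stylization that leaves each
year's network full-sized); ages are aligned so all animals turn adult
in the first study year; and detection is independent across
individuals, ignoring the correlated visibility of huddled animals.

## Pipeline and problem sizes

The pipeline runs: read → period split (site × calendar year) →
permutation gate → CPMw groups → measure tables → dead-adult panel →
regressions (unadjusted and residual-controlled for each measure, plus
the group-effect and aggression models) → Barker model set (constant;
S by group; S and p by group) with QAICc table, model-averaged survival
per stratum, and the group-vs-constant likelihood-ratio test.  Reports
embed the seeds, a config hash, and per-period gate decisions; reruns
with the same seeds are byte-identical.

Default analysis sizes are chosen to make a full study run take on the
order of a second so that replicated end-to-end studies (100 seeded
runs in the acceptance suite) are routine: pipeline permutation gates
use up to 1,000 permutations with 20-swap thinning, panel regressions
2,000 permutations, and the recovery studies 300-permutation gates with
999-permutation regressions.  These are analysis-quality/runtime
trade-offs, configurable upward for production use.

## Known limitations

- The permutation gate's swaps act within days only; permuting group
  membership across days (a flip variant some software offers) is
  exposed as future work, not implemented.
- Weighted centralization values are normalization-dependent (above);
  compare only within one convention.
- The Barker implementation handles categorical structures only — no
  individual continuous covariates, multistate extensions, or robust
  design.
- MARK file-format compatibility is a non-goal; the LD-string exporter
  is best effort.
- Half-weight/twice-weight association indices and lagged association
  rates are not implemented.
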