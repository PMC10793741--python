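# Methods

This note documents the models, defaults, and numerical choices behind
`ecsurv`, and what the synthetic world does and does not establish.

## Synthetic cohort generator

The generator is a *stated world*: its defaults are the published facts
about the cohort the pipeline was designed for, plus a small number of
choices made once and documented here.

**Recurrence timing.** First-recurrence times follow a two-parameter
log-normal density re-parameterised by its modal month *m*\* (default 7)
and the month *h* at which the density has fallen to half its modal value
(default 24). In closed form

    sigma = ln(h / m*) / sqrt(2 ln 2),    mu = ln(m*) + sigma^2,

which reproduces exactly the two shape facts available (peak near month 7,
half-peak near month 24) without inventing further structure. Group IV adds
a second log-normal mode at month 42 as a mixture component with weight
0.12 and its own log-scale spread `second_peak_sigma = 0.15`; the narrow
width is a generator parameter because only the bump's *location* is
stated, and a component as wide as the primary one produces no visible
local maximum at all. The whole density is scaled so the discretised
60-month cumulative incidence equals the group's five-year recurrence
probability (defaults 0.239 / 0.409 / 0.619 / 0.763).

Monthly probabilities are centre-of-bin masses, `p_m` = mass of
(m − ½, m + ½], so the grid argmax coincides with the continuous mode. An
important consequence of the log-normal choice: only ≈ 49 % of in-horizon
events fall within the first two years, flatter than the real cohort this
emulates (≈ 75 %). Schedule-efficiency conclusions on this world are
therefore *conservative* — equal-risk schedules need 13 visits to match the
14-visit NCCN calendar here, where a more front-loaded world allows 10–12.

**Covariates.** Node counts, LVI, and PNI are drawn per group so that the
published four-group rule reproduces the ground-truth label exactly
(pN derived from positive-node counts with the usual bins: 0 / 1–2 / 3–6 /
≥ 7). Age, sex (78.9 % male), neoadjuvant status (18.3 %), and pT are
cosmetic and independent of the recurrence process — which is what makes
the neoadjuvant-overlap check assertable. Default group mix
(0.40, 0.25, 0.22, 0.13) is a realistic surgical case mix; it is not a
published quantity.

**Censoring.** Administrative censoring uniform on [36, 96] months plus
exponential dropout (default 0.002/month), independent of recurrence — the
standard noninformative assumption behind the KM/logrank machinery.

**Recurrence type and sites.** Event type (LRR only / DM only / both) uses
the published 285 : 630 : 360 proportions. Distant sites are independent
per-site Bernoulli draws at the published frequencies (lung 0.308, liver
0.178, neck 0.253, remainder "other"). Those frequencies sum to 1, so
independence plus faithful marginals force the expected number of sites per
metastatic patient to one: a minority of DM patients carry *no* recorded
site (read: unlocalised first metastasis), and multi-site patients are
correspondingly rare. Configured co-occurrence pairs multiply the second
site's odds given the first; this perturbs that site's marginal slightly
and is off by default. Co-occurrence analyses must be run on
metastasis-bearing patients only — pooling LRR-only rows (all-false)
creates spurious positive association between every site pair.

## Survival tree and merging

Splits maximise the two-sample logrank statistic over all covariate /
threshold candidates (midpoints of consecutive observed values, capped at
32 quantile-spaced thresholds per covariate per node). The stopping rule
compares a **Šidák-corrected** best-split p-value, `1 − (1 − p)^M` with M
the candidates examined at the node, against `stop_p = 0.01`. Without the
correction, best-split selection bias makes a null cohort split far more
often than the nominal rate; with it, a 500-patient cohort whose DFS is
independent of every covariate stays a single leaf in ≥ 90 % of seeds.
Defaults `min_leaf = 50`, `max_depth = 4` keep leaves large enough for the
merge step's logrank tests to be meaningful at n ≈ 4000.

Merging recombines, at each round, the pair of groups with the largest raw
logrank p until every remaining pair satisfies both p < 0.001 and
BH-adjusted p < 0.01 (the published thresholds). Final groups are labelled
I..k by increasing KM 60-month cumulative incidence, making labels stable
across runs. Note that statistical power, not the implementation, decides
how many groups survive: under heavy administrative censoring
(U[36, 96]) the planted III-vs-IV contrast yields logrank chi² ≈ 9
(p ≈ 0.003 > 0.001) and is *correctly* merged; recovery of all four groups
is established on cohorts followed to month 60.

Bootstrap validation subsamples 70 % of records **without** replacement
("downsampling"), re-assigns groups by rule, and reports the fraction of
trials in which all pairwise logrank tests are significant.

## Hazard estimators

**Forest.** scikit-survival's random survival forest (with-replacement
bootstrap per tree, logrank split criterion, Nelson–Aalen terminal
estimates). Defaults follow the canonical construction: 500 trees,
`mtry = ceil(sqrt(p))`, minimum terminal size 15. The group curve averages
the ensemble cumulative hazard over trees and group members,
`S(m) = exp(−H̄(m))`, `p_m = S(m−1) − S(m)`. Tests run desk-scale forests
(100–200 trees, terminal size 80–100, prediction averaged over a 1000-member
subsample) purely for runtime; recovery tolerances are unchanged.

**Spline.** Monthly event counts with person-month exposures fitted by a
penalised B-spline Poisson GLM (statsmodels GLMGam, default 6 df, penalty
weight 1.0) on the **log-time** axis — early-follow-up hazard features (the
month-7 peak) need more resolution than the flat tail, and a linear-time
basis at the same df oversmooths the peak to ~month 10. Hazards convert to
monthly probabilities by `p_m = S(m−1)(1 − exp(−h_m))`.

The monthly probability is deliberately the *unconditional* first-event
mass, not the conditional hazard: scheduling inverts the cumulative
incidence, and the Markov model reconstructs conditional hazards from it.

## Schedule design and DDT

Equal-cumulative-risk design places visit j at the first month where
`F(m) ≥ (j/k) F(60)`; collisions advance to the next free month and month
60 is always the final visit, so every in-horizon event has a coming visit
and DDT is total. Recommended group schedules keep the published per-year
visit counts (12/12/12/11 visits; mean 11.75) and place months within each
year by the same equal-risk rule restricted to that year, since the
published recommendation fixes only the yearly counts, not the months. DDT is purely schedule-geometric — no
interval symptomatic detection; that mechanism lives in the Markov model.

## Markov cohort model

Four states (DiseaseFree, RecurrenceUndetected, RecurrenceDetected, Death),
monthly cycles, 40-year horizon, 3 % annual discount. Disease-free patients
recur at the conditional hazard implied by the group curve (flat
configurable tail of 0.002/cycle after month 60); undetected recurrences
are found with certainty at scheduled visits (sensitivity configurable) and
with probability 0.08/cycle symptomatically in between; post-detection
mortality (0.020/cycle) is scaled by a linear delay penalty
`1 + 0.02 × delay_months` — the mechanism by which earlier detection buys
QALYs — and undetected mortality (0.030/cycle) exceeds it. Costs: $150 per
visit, $8000 salvage at detection, $5000 terminal; utilities 0.85 / 0.60 /
0.55 per year for the three alive states. The cohort trace tracks
undetected mass by recurrence cycle and detected mass by detection delay,
so the delay penalty is exact rather than averaged.

**Every one of these rates, costs, and utilities is a placeholder**: the
source model's parameter table is unpublished, so absolute costs and QALYs
are not reproducible and are not claimed — the model demonstrates the
mechanism (mass conservation, cost monotone in visits, earlier detection
weakly increasing QALYs) and the ICER arithmetic layer is exact.

## Statistical conventions

Two-sided Fisher p uses the point-probability (minimum-likelihood) rule.
Rank tests use exact null distributions for small tie-free samples
(signed-rank n ≤ 25, rank-sum n ≤ 25) and mid-rank normal approximations
otherwise. All multiple-testing adjustment is Benjamini–Hochberg;
degenerate inputs (no events, all-zero differences, zero margins) return
the conventional p = 1 with a warning rather than raising. BH adjustment is
*not* idempotent in general (reapplying it can inflate already-adjusted
values), so only its true properties — output ≥ input, order preservation —
are asserted.

## Known limitations

- The log-normal tail makes the synthetic world less front-loaded than the
  real cohort (see above); DDT advantages of risk-based schedules are
  understated, never overstated.
- The generator emulates only the covariates the published rule needs plus
  basic demographics, not the 51-variable case-report form.
- The Markov model is deterministic (no probabilistic sensitivity
  analysis) and uncalibrated to real cost data.
- Detection modality (CT vs PET-CT vs endoscopy) is outside the DDT
  definition; sites feed only the co-occurrence analysis.
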