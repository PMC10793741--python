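# ecsurv — recurrence-risk-adaptive surveillance for resected esophageal cancer

After radical esophagectomy roughly half of patients relapse, yet most
guidelines prescribe one follow-up calendar for everyone. `ecsurv`
implements, as a reusable and tested pipeline, a risk-adaptive alternative
for biostatisticians and health-services researchers:

1. **Risk stratification** — recursive partitioning of disease-free survival
   (DFS) with logrank splits, followed by iterative logrank merging of
   prognostically similar leaves (stop when every pair differs at
   *p* < 0.001 and BH-adjusted *p* < 0.01); plus the published four-group
   rule: group I = pN0 without LVI/PNI, II = pN0 with LVI or PNI or pN1 with
   LNR ≤ 0.05, III = pN1 with LNR > 0.05 or pN2, IV = pN3.
2. **Hazard estimation** — a random survival forest (logrank splits,
   Nelson–Aalen terminal estimates) turned into per-group monthly
   recurrence probabilities `p_m = S(m−1) − S(m)` on a 60-month grid, with a
   penalized-spline Poisson log-hazard fit as the sensitivity method.
3. **Schedule design** — the *j*-th of *k* visits is placed at the first
   month where cumulative incidence reaches `(j/k)·F(60)`, so every
   inter-visit interval carries equal recurrence mass; guideline protocols
   (CROSS 9 visits, NEOCRT5010 12, NCCN 14, NCT03001596 14) are encoded for
   comparison.
4. **Evaluation** — the delayed detection time (DDT): the gap from a
   recurrence to the nearest coming visit (recurrence in month 12, next
   visit month 14 → DDT 2 months), compared across strategies overall, per
   follow-up year, and under bootstrap resampling; metastasis-site
   co-occurrence by Fisher's exact test with BH correction.
5. **Cost-effectiveness** — a four-state Markov cohort model
   (DiseaseFree → RecurrenceUndetected → RecurrenceDetected → Death) with
   discounted costs and QALYs and incremental cost-effectiveness ratios
   (ICER = ΔCost/ΔQALY) versus a reference strategy.

Because the source cohort is not public, a first-class synthetic-cohort
generator reproduces the stated recurrence structure (group five-year
cumulative incidences 23.9/40.9/61.9/76.3 %, a hazard peak near month 7
decaying to half by month 24, a late distant-metastasis bump near month 42
in group IV, site frequencies lung 30.8 % / liver 17.8 % / neck 25.3 %) with
ground truth attached for recovery testing. See `docs/methods.md` for the
model details and what the generator does *not* emulate.

## Worked example

```python
import numpy as np
from ecsurv import GeneratorConfig, true_hazard
from ecsurv.schedule import design_schedule, protocol_schedule, recommended_schedule
from ecsurv.evaluate import compute_ddt
from ecsurv.simulate import sample_event_months

config = GeneratorConfig()
curve = true_hazard(config, "IV")            # group-IV monthly curve
print(round(curve.cum_at(60), 3), curve.peak_month)

rec = recommended_schedule(curve, "IV")      # published per-year counts 4,4,1,1,1
print(rec.visit_months)

events = sample_event_months(config, "IV", 2000, seed=7)
for sched in (protocol_schedule("NCCN"), design_schedule(curve, 14)):
    print(sched.label, sched.n_visits, round(compute_ddt(events, sched).median, 2))
```

prints

```
0.763 7
(5, 7, 10, 12, 15, 18, 21, 24, 36, 48, 60)
NCCN 14 1.91
risk_14 14 1.83
```

— the group-IV curve integrates to the 76.3 % five-year incidence and peaks
in month 7; the recommended 11-visit schedule concentrates eight visits in
the first two years; and with the *same* 14 visits, the risk-placed
schedule detects recurrences sooner (median 1.83 vs 1.91 months) than the
NCCN calendar.

The same chain is available from the shell:

```bash
ecsurv pipeline --seed 7 --out-dir out/   # simulate → stratify → curves →
                                          # schedules → DDT table → CEA table
ecsurv schedule --protocol CROSS --out cross.json
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's reference quantity from scratch — the worked DDT
example (a recurrence in month 12 against a schedule whose next visit is in
month 14), evaluated by the same DDT engine the pipeline uses — and writes
it as JSON.

## Layout

- `src/ecsurv/simulate.py` — synthetic cohorts and ground-truth curves
- `src/ecsurv/stats.py` — KM / Nelson–Aalen / logrank / Wilcoxon / Fisher / BH
- `src/ecsurv/stratify.py` — survival tree, logrank merging, published rules
- `src/ecsurv/hazard.py` — survival forest and spline hazard estimators
- `src/ecsurv/schedule.py` — protocols and equal-risk schedule design
- `src/ecsurv/evaluate.py` — DDT, strategy comparison, co-occurrence
- `src/ecsurv/cea.py` — Markov cohort model and ICER table
- `src/ecsurv/cli.py`, `src/ecsurv/io.py` — command line and cohort CSV I/O
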