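# planrbe — radiobiological evaluation of radiotherapy treatment plans

`planrbe` answers a planning-study question: **does sparing the urethra in
focally dose-escalated, moderately hypofractionated prostate radiotherapy
cost tumour control, and does it buy a lower complication risk?**  It
implements the full evaluation chain a medical physicist would run on
exported dose matrices and structure sets:

- **TCP** — voxelized Poisson linear-quadratic tumour control,
  `TCP = exp(−ρ_cl Σ_i v_i e^{−α·EQD0_i})`, on EQD0-converted doses;
- **NTCP (urethra)** — Lyman-Kutcher-Burman probit in gEUD,
  `Φ((gEUD − D50)/(m·D50))` with D50 = 116.7 Gy, m = 0.23, n = 0.3, on
  EQD2 doses (α/β = 5 Gy);
- **NTCP (bladder, rectum)** — relative seriality
  `[1 − Π_i (1 − P(D_i)^s)^{Δv_i}]^{1/s}` with the Källman voxel response,
  D50 = 80 Gy EQD2 and (γ, s) = (2.59, 1.3) / (1.79, 0.75);
- **P+** — complication-free tumour control, `P+ = TCP·(1 − P_I)` with
  `P_I = 1 − Π_j w_j(1 − NTCP_j)`;
- **DVH metrics and constraints** (exact-order-statistics DX%, cumulative
  DVH, pass/fail verdicts), **geometry metrics** (Dice, coverage, minimum
  distances), **intrafractional motion** (anisotropic Gaussian dose
  blurring), **exact Wilcoxon signed-rank** plan comparisons, and
  parameter-robustness scans.

Because the corresponding patient datasets are not public, the package
ships a seeded **synthetic prostate-phantom generator** that emulates the
study design: per patient, three 60/70 Gy simultaneous-integrated-boost
plans in 20 fractions — plan 1 without urethral constraints, plan 2
respecting a 62.4 Gy D2% limit for the urethra, plan 3 for the urethra +
2 mm margin (PRV).  See `docs/methods.md` for the models, generator design
and its limits.

## Worked example

```python
import planrbe as p

cohort = p.make_cohort(10, seed=1)                      # 10 cases x 3 plans
records = p.evaluate_cohort(cohort, kernel=p.MotionKernel())
df = p.records_frame(records)
print(df[~df.motion].groupby("plan")[
    ["tcp", "ntcp_urethra", "p_plus"]].median().round(4))
print(p.compare_plans(records).query(
    "endpoint == 'ntcp_urethra' and not motion")[["pair", "p_value"]])
```

prints (seed 1, no motion):

```
          tcp  ntcp_urethra  p_plus
plan
plan1  0.9971        0.0647  0.8919
plan2  0.9966        0.0341  0.9209
plan3  0.9975        0.0321  0.9203

             pair  p_value
   plan1_vs_plan2 0.001953
   plan1_vs_plan3 0.001953
   plan2_vs_plan3 0.001953
```

Read: boosting the imaging-defined tumour to 70 Gy while capping the
urethra (plans 2/3) roughly halves the urethral stricture probability
(6.5 % → 3.2 %, exact Wilcoxon p = 0.002 at n = 10) while tumour control
stays at ≈ 99.7 %; the complication-free tumour control P+ rises from
0.89 to 0.92, and it does so in every simulated case.

## Analysis scripts

The numbered drivers under `analysis/` reproduce the study's analysis
sequence on the synthetic cohort and write their tables under `results/`:

| script | writes | content |
|---|---|---|
| `01_simulate_cohort.py` | `cohort_geometry.csv` | volumes, coverage, tumour–urethra distances |
| `02_dose_metrics.py` | `dose_metrics.csv`, `constraints.csv` | D98/D50/D2 per structure/plan ± motion, constraint verdicts |
| `03_outcomes.py` | `outcome_records.csv`, `outcomes_summary.csv`, `plan_comparisons.csv` | TCP/NTCP/P+ medians and exact Wilcoxon comparisons |
| `04_robustness.py` | `tcp_robustness.csv`, `lkb_scan.csv` | α/β robustness sets; 364-point LKB (D50, m) scan |

Each accepts `--seed` and `--n-cases`.

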