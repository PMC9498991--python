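# radiosens

Multi-endpoint modelling of individual radiosensitivity for radiobiologists
and biostatisticians working on the prediction of radiotherapy toxicity.

About 5–20 % of radiotherapy patients develop tissue overreactions, graded
0 (no event) to 5 (death) on the CTCAE scale.  Several cellular and
molecular assays on patient-derived skin fibroblasts have been proposed to
predict these reactions after a standard 2 Gy X-ray exposure:

* **SF2** — clonogenic surviving fraction at 2 Gy (percent), from the
  linear-quadratic model *S(D) = exp(−(αD + βD²))*;
* **MN_24h** — residual micronuclei per 100 cells at 24 h (mitotic death);
* **γH2AX_24h** — residual γH2AX foci per cell at 24 h (unrepaired
  double-strand breaks recognized by NHEJ);
* **pATMmax** — the maximal number of pATM foci per cell reached at 10 min
  or 1 h (peak nuclear ATM kinase activity).

`radiosens` implements the quantitative model that links all of these
endpoints to one another and to the CTCAE grade:

```
SF2(%)   = 61.55 − 11.72 · grade                (linear)
SF2(%)   = 62.2  · exp(−0.107 · MN_24h)          (exponential)
SF2(%)   = 62.56 · exp(−0.216 · γH2AX_24h)       (exponential)
pATMmax  = 41.72 − 6.78 · grade                  (linear)
SF2(%)   = 1.422 · pATMmax                       (proportional)
```

With the bounded endpoint values (max/min SF2, max MN_24h, max γH2AX_24h,
max/min pATMmax) these laws collapse onto five coefficients

```
k0 = ΔSF2/5     k1 = ln(maxSF2/minSF2)/max MN_24h
k2 = ln(maxSF2/minSF2)/max γH2AX_24h
k3 = ΔpATMmax/5  k4 = maxSF2/max pATMmax
```

that solve the coupled system dSF2/dgrade = −k0, dSF2/dMN = −k1·SF2,
dSF2/dH2AX = −k2·SF2, dpATMmax/dgrade = −k3, dSF2/dpATMmax = +k4.

The package provides:

* `cohort` — validated cell-line records and CSV interchange;
* `simulate` — a synthetic cohort generator reproducing the study
  structure (population grade frequencies 65/17/10/5/2.5/0.5 %, SF2
  anchors 62.1 %/3.3 %, ATM-null and LIG4 phenotypes, clonogenic-subset
  SF2 coverage, calibrated noise);
* `survival` — linear-quadratic fitting (`LinearQuadraticSurvival`,
  scikit-learn style) and plating-efficiency/SF2 computation;
* `laws` — candidate-law fitting (linear, proportional, quadratic,
  exponential, power) with CIs, model selection and the "complex"-link
  flag (`EndpointLawModel`);
* `coefficients` — the k0..k4 system, closed-form inter-endpoint
  predictions, consistency audits, numerical ODE verification;
* `discrimination` — one-way ANOVA of each endpoint across grades and for
  the binary radioresistant (grades 0–2) / radiosensitive (3–5) split;
* `predict` — CTCAE grade prediction by law inversion (`GradePredictor`)
  and classification into radioresistant / intermediate /
  hyper-radiosensitive / LIG4-like phenotypes;
* a `radiosens` command line (`simulate`, `fit`, `coefficients`,
  `discriminate`, `predict`, `report`, `pipeline`).

## Worked example

```python
from radiosens import (simulate_cohort, fit_endpoint_laws,
                       binary_discrimination, grade_from_patmmax)
from radiosens.cohort import patmmax

cohort = simulate_cohort(200, seed=7)        # study-shaped synthetic cohort
fits = fit_endpoint_laws(cohort)             # the five inter-endpoint laws
for name, fit in fits.items():
    pars = " ".join(f"{k}={v:.4g}" for k, v in fit.params.items())
    print(f"{name}: {fit.law} {pars} r2_adj={fit.r2_adjusted:.3f} n={fit.n}")

f, p = binary_discrimination(cohort, "patmmax")
print(f"binary pATMmax: F={f:.1f} p={p:.3g}")

rec = cohort.records[30]
pred = grade_from_patmmax(patmmax(rec), fits["patmmax_vs_grade"])
print(f"record {rec.id}: true grade {rec.ctcae_grade}, "
      f"pATMmax {patmmax(rec):.1f} -> predicted {pred.continuous_grade:.2f} "
      f"(rounded {pred.rounded_grade})")
```

prints

```
sf2_vs_grade: linear a1=-11.36 a2=60.21 r2_adj=0.981 n=33
sf2_vs_mn24h: exponential a=62.12 b=-0.1075 r2_adj=0.990 n=33
sf2_vs_h2ax24h: exponential a=62.29 b=-0.1991 r2_adj=0.940 n=27
patmmax_vs_grade: linear a1=-6.842 a2=41.75 r2_adj=0.766 n=200
sf2_vs_patmmax: proportional a1=1.316 r2_adj=0.872 n=32
binary pATMmax: F=206.8 p=1.42e-32
record CL0009: true grade 0, pATMmax 35.3 -> predicted 0.94 (rounded 1)
```

Re-fitting the synthetic cohort recovers the ground-truth slope
(−11.36 vs −11.72), the micronucleus decay (−0.1075 vs −0.107), the foci
decay (−0.199 vs −0.216) and the pATMmax law (−6.84/41.75 vs −6.78/41.72)
from 200 lines, of which only ~33 carry SF2 — the same coverage as a real
clonogenic campaign.  The F statistic confirms that pATMmax separates
radioresistant from radiosensitive lines, and the last line shows a grade
prediction for one cell line by inverting the pATMmax law.

The same analysis end-to-end, writing all artifacts to `out/`:

```
radiosens pipeline --seed 7 --cohort-size 200 --output-dir out
```

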