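# oxydeficit

Breath-by-breath expired-gas analysis and oxygen-deficit (OD) diagnostics.

The package implements the full measurement chain of a noninvasive
gas-exchange monitor and the statistics used to compare OD against pulse
oximetry as a predictor of needing supplemental oxygen:

1. **`trace_synth`** — synthetic 100 Hz expired PO2/PCO2 traces with planted
   end-tidal plateaus, per-breath noise, drift, cough artifacts, and an
   unsteady-then-steady end-tidal CO2 wander (ground truth carried in
   metadata).
2. **`breath_engine`** — CO2-threshold breath segmentation with artifact
   flagging, detection of the 45 s end-tidal CO2 steady state, and averaging
   of five consecutive steady-state breaths into PAO2/PACO2.
3. **`physiology`** — Hill-curve inversion (n = 2.88) of SpO2 into a
   calculated arterial O2 tension (gPaO2) with a CO2/Bohr-corrected P50
   (Henderson–Hasselbalch pH estimate, configurable constants), plus
   OD = PAO2 − gPaO2 and the ODFlip = 100 − OD orientation dummy.
4. **`cohort_synth`** — simulated cohorts: direct draws from a correlated
   (ODFlip, SpO2) Gaussian with a planted logistic outcome, or end-to-end
   rows computed by pushing trace plans through the whole pipeline (with
   censoring of participants who never reach steady state).
5. **`diagnostics`** — IRLS logistic regression with Wald inference
   (B / S.E. / Wald / df / Sig. / Exp(B) / 95% CI), Box–Tidwell
   linearity-of-the-logit checks with a Bonferroni threshold, ROC curves with
   Mann–Whitney AUROC and DeLong CIs, Youden operating points, paired DeLong
   AUROC comparison, and a full per-cohort evaluation report.
6. **`io_cli`** — trace/cohort CSV dialects, JSON run configuration, and the
   command-line interface.

## CLI

```bash
# synthetic trace (optionally with coughs / an unsteady lead-in)
oxydeficit simulate-trace --seed 3 --duration 120 --out trace.csv --truth-out truth.json

# analyze a trace into a one-row gas-exchange summary
oxydeficit analyze-trace trace.csv --out summary.csv     # exit 3 = no steady state

# simulated cohort table and the full diagnostic comparison
oxydeficit simulate-cohort --n 72 --seed 0 --out cohort.csv
oxydeficit evaluate cohort.csv --out report.json --roc-csv roc.csv
```

Exit codes: 0 success, 2 usage error, 3 steady state not achieved,
4 statistical failure.

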