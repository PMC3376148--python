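# fragmatch

DNA fragment-size control and quality tooling for array comparative genomic
hybridization (aCGH), aimed at labs running copy-number arrays on
formalin-fixed paraffin-embedded (FFPE) or frozen tumor DNA.

Array CGH competitively hybridizes differentially labeled test and reference
DNA; probe log₂ intensity ratios report copy number. Because hybridization
efficiency depends on fragment length, arrays fail — even self-hybridizations
of a single pristine DNA sample — when the two aliquots have *mismatched*
fragment-size distributions, and quality is best when both are matched at a
mode fragment size ≥ 400 bp. fragmatch implements the workflow that exploits
this:

1. **Thermodegradation modeling (the fragmentation-simulation workflow).**
   A small decay series — the mode fragment size f(t) of a sample after
   t ∈ {0, 0.5, 1, 2} min (FFPE) or {0, 2, 4, 6} min (frozen) of 95 °C heat
   fragmentation plus a simulated labeling exposure — is fit per sample with
   the shifted inverse power law

   f(t) = θ₁ + θ₂ (t + θ₃)^(−θ₄)

   by bounded multi-start nonlinear least squares, then inverted in closed
   form, t\* = (θ₂ / (f\* − θ₁))^(1/θ₄) − θ₃, to prescribe the heat time
   reaching a target mode size f\* (default 400 bp).
2. **Gel densitometry.** Lane intensity profiles are background-subtracted
   (rolling minimum), ladder bands detected and refined parabolically, and a
   monotone migration → log₁₀(bp) calibration sizes each smear at its
   maximum-intensity point.
3. **Array QC and calling.** The derivative log ratio spread
   dLRsd = IQR(Δ)/(1.349·√2) over within-chromosome consecutive-probe log₂
   ratio differences Δ (pass: dLRsd < 0.3); GC-wave correction; an
   interval-score surrogate for the ADM-2 caller
   (score = |mean log₂|·√n/σ̂ ≥ 6, calls spanning more than five probes with
   |mean log₂| > 0.3); probe-level ROC/FPR/FNR; call-set concordance.
4. **Seeded simulators** for decay series, gel lanes and probe tables whose
   noise scale grows with fragment-size mismatch and with sizes below the
   400 bp optimum.

## Worked example

```python
import fragmatch as fm

# decay series for one FFPE sample (sizes in bp after labeling exposure)
obs = [fm.DecayObservation("GBM1", t, bp)
       for t, bp in [(0.0, 612), (0.5, 541), (1.0, 488), (2.0, 422), (4.0, 345)]]
model = fm.fit_decay_model(obs)
rec = fm.predict_time(model, target_bp=400)
print(f"theta = ({model.theta1:.1f}, {model.theta2:.1f}, "
      f"{model.theta3:.3f}, {model.theta4:.3f}), rss = {model.rss:.2f}")
print(f"recommended heat time for 400 bp: {rec.time_min:.2f} min (feasible={rec.feasible})")

matched = fm.simulate_hybridization(fm.HybridizationConfig(400, 400, n_probes=50_000, seed=1))
mismatched = fm.simulate_hybridization(fm.HybridizationConfig(525, 140, n_probes=50_000, seed=1))
print(f"dLRsd matched 400/400:   {fm.dlrsd(matched).dlrsd:.3f}  pass<0.3: {fm.dlrsd(matched).pass_03}")
print(f"dLRsd mismatched 525/140: {fm.dlrsd(mismatched).dlrsd:.3f}  pass<0.3: {fm.dlrsd(mismatched).pass_03}")
```

prints

```
theta = (62.5, 749.0, 1.742, 0.558), rss = 3.13
recommended heat time for 400 bp: 2.44 min (feasible=True)
dLRsd matched 400/400:   0.162  pass<0.3: True
dLRsd mismatched 525/140: 0.515  pass<0.3: False
```

The fitted θ describe this sample's decay curve (asymptotic floor 62.5 bp,
well-conditioned fit with residual sum of squares 3.1 bp²); heating it 2.44
minutes brings its mode fragment size to the 400 bp target. The two
simulated self-hybridizations show the size effect the workflow exists to
fix: matched aliquots pass the 0.3 dLRsd quality gate, badly mismatched
ones fail it by a wide margin.

The same steps are available from the shell:

```sh
fragmatch fsm fit --decay-csv decay.csv --target-bp 400 --out model.json --report report.tsv
fragmatch gel analyze --profile lane.tsv --ladder-profile ladder.tsv
fragmatch qc dlrsd --probes probes.tsv
fragmatch qc call --probes probes.tsv --threshold 6.0 --min-probes 6 --min-abs-log2 0.3 --out calls.bed
fragmatch sim hyb --mode-test 525 --mode-ref 140 --n-probes 50000 --seed 7 --out probes.tsv
```

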