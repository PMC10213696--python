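# capgrow

Cell-proliferation analysis for capacitance biosensor arrays.

Lab-on-CMOS microsystems culture cells directly on a chip whose
electrodes report the interfacial capacitance change ΔC (attofarads)
caused by cells adhering and spreading near each sensor. `capgrow`
turns the two records such an experiment produces — a per-electrode ΔC
time series (16 electrodes, one sample every 29 s) and a stack of
timestamped micrographs (one every 5 min) — into proliferation
statistics for the region of interest (ROI) spanned by the electrode
array:

* **in-ROI cell counts** N_m per frame, by zero-normalized
  cross-correlation (ZNCC) template matching with greedy non-maximum
  suppression;
* the **average capacitance growth factor** S_avg and its spread σ,
  from the slopes of 1-h overlapping segments of Savitzky-Golay (SG)
  smoothed electrode traces, pooled across the array;
* a **log-linear calibration** ln N_m = α·ΔC_m + K between counts and
  the electrode-averaged capacitance, with Pearson r and p-value;
* the **boundary-condition exponential growth model**

      N(t) = Γ·e^{α·S_avg·t} + β,
      Γ = (N_f − N_0) / (e^{α·S_avg·t_n} − e^{α·S_avg·t_0}),
      β = N_0 − Γ·e^{α·S_avg·t_0},

  pinned to the measured counts N_0, N_f at the window boundaries, with
  R², adjusted R² (k = 3) and the in-ROI **doubling time**
  t_d = ln((2N_0 − β)/Γ)/(α·S_avg) − t_0, reported as undefined when
  the population does not double inside the 30-h analysis window.

Raw sensor/imaging data of this kind are rarely public, so the package
ships a first-class synthetic generator (`capgrow.synthetic`) that
produces ground-truth trajectories, noisy electrode traces tied to them
through the log-linear law, and renderable micrograph stacks — every
stage of the analysis is testable closed-loop against known truth.

## Worked example

```python
import capgrow as cg

params = cg.paper_like(seed=0)            # 16 electrodes, 29-s cadence, 30 h
exp = cg.simulate_experiment(params, img_stride=6)   # micrographs every 30 min
counts = cg.measured_counts(exp)          # template-matched in-ROI counts
report = cg.analyze_series(exp.capacitance, counts)

print(f"S_avg  = {report.S_avg:6.2f} aF/h   (generator truth: {params.S_avg_true})")
print(f"sigma  = {report.sigma:6.2f} aF/h   ({report.n_slopes} pooled slopes)")
print(f"r      = {report.pearson_r:6.3f}        (p = {report.p_value:.2e})")
print(f"alpha  = {report.alpha:.5f} 1/aF  (truth: {params.alpha:.5f})")
print(f"adj R2 = {report.adjR2:6.3f}")
print(f"t_d    = {report.t_d:6.1f} h      (within window: {report.within_window})")
```

prints

```
S_avg  =   3.80 aF/h   (generator truth: 3.38)
sigma  =  19.18 aF/h   (928 pooled slopes)
r      =  0.996        (p = 1.69e-62)
alpha  = 0.00674 1/aF  (truth: 0.00789)
adj R2 =  1.000
t_d    =   26.0 h      (within window: True)
```

Reading this: the pooled slope distribution recovers the true growth
factor (3.80 vs 3.38 aF/h) within its sampling scatter; ln N and ΔC_m
correlate almost perfectly (r = 0.996), as the generative law demands;
and although α and S_avg individually carry calibration noise, their
product — the exponential rate — is accurate, so the fitted model
reproduces the 26-h doubling time. Note σ ≈ 19 aF/h ≫ S_avg: most of
the spread is genuine electrode-to-electrode heterogeneity, which
averages out of the array-level estimate.

The same pipeline runs from the shell on on-disk data:

```sh
capgrow simulate --preset paper-like --seed 0 --out-dir exp0
capgrow trend --capacitance-csv exp0/capacitance.csv --out-dir exp0/out
capgrow pipeline --config config.yaml --out-dir exp0/out
```

File formats are plain: a wide CSV (`time_s,e00,…,e15`) for
capacitance, `frame_t{seconds}.png` image stacks, YAML config, and a
canonical JSON run report.

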