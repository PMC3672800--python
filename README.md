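# rigidnet

Quantifying Parkinsonian rigidity from two directions at once: motor
performance during pursuit tracking, and directed brain connectivity that
predicts clinical rigidity scores.

Rigidity — increased resistance to passive limb movement — is rated
clinically on the ordinal 0–4 UPDRS items, summed over four limbs and the
trunk into a global score in [0, 20]. This package implements a fully
testable pipeline for two complementary analyses of that score:

1. **Tracking performance.** A subject squeezes a bulb to follow a 0.5 Hz
   sinusoidal force target between 5 and 15 %MVC, sampled at ~50 Hz over
   90 s runs. Beyond the RMS tracking error
   `E_RMS = sqrt((1/N) * sum_i (y[i] - u[i])^2)`, performance is modelled
   as a discrete second-order linear dynamical system
   `x_t = A x_{t-1} + B u_{t-1}`, `y_t = C x_t + D u_t`. The eigenvalues of
   `A`, mapped to continuous poles `s = log(lambda)/dt`, satisfy
   `s_{1,2} = -ζω_n ± ω_n sqrt(ζ² - 1)`, giving the damping ratio ζ (low ζ
   = overshoot, high ζ = sluggish tracking) and natural frequency ω_n,
   plus rise, peak and settling times.
2. **Connectivity.** Per-subject ROI time series (TR = 1.985 s) are
   detrended (discrete-cosine high-pass, 128 s cutoff) and standardized; a
   group-level directed lag-1 network over the `R(R-1)` edge universe
   (2,652 for 52 ROIs) is learned by a PC-style conditional-independence
   search with Benjamini–Hochberg FDR control at 5%; per-subject connection
   strengths come from linear-Gaussian dynamic-Bayesian-network regressions;
   and rigidity scores are predicted from strengths via
   `Y = X·β + ε` with a 10-fold cross-validated LASSO followed by robust
   (bisquare IRLS) refitting of the selected edges.

A seeded synthetic-data module generates every input with known ground
truth — tracking trials from second-order systems, stationary sparse
vector-autoregressive ROI series, cohorts with sparse strength→score
effects — so each stage has a recovery test and the whole pipeline runs
end to end without any external data.

## Worked example

```python
from rigidnet import simulate, tracking

spec = simulate.TrackingSimSpec(zeta=0.7, omega_n=3.0, noise_sd=0.1, seed=4)
trial = simulate.simulate_tracking_trial(spec)
m = tracking.trial_metrics(trial)
print(f"rms={tracking.rms_error(trial):.3f}  zeta={m.zeta:.3f}  "
      f"omega_n={m.omega_n:.3f}  peak_time={m.peak_time:.3f}s")
```

prints

```
rms=4.527  zeta=0.699  omega_n=3.000  peak_time=1.465s
```

The RMS error of ~4.5 %MVC reflects the phase lag of a ζ=0.7, ω_n=3 rad/s
tracker behind a 0.5 Hz target; the fitted damping ratio and natural
frequency recover the generating values to three decimals despite the
response noise, and the peak time is the underdamped step-response peak
`π/(ω_n sqrt(1-ζ²))`.

A complete synthetic study (20 subjects, 52 ROIs, 227 true connections)
runs from a config file:

```bash
rigidnet run --config config.yaml   # or: python -m rigidnet.cli ...
```

writing trial CSVs, ROI TSVs, per-run/per-subject metric tables, the
FDR-controlled network JSON, per-subject strengths, the LASSO selection and
robust-regression results, plus a manifest with a config hash and output
checksums; rerunning the same config is byte-identical.

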