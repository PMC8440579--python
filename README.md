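# smlife

Quantitative analysis of nonstandard-amino-acid (nsAA) titration experiments
on bacterial cell division: single-molecule FtsZ subunit lifetimes from TIRF
time lapses, Z-ring morphometry from snapshot images, and Hill dose-response
characterization of inducible promoters — plus a synthetic-data generator
that produces all of these inputs with exact ground truth.

## Who this is for

Translational titration with an nsAA incorporated at an amber (TAG) codon
lets an experimenter tune the expression of a division inhibitor such as
MciZ almost continuously, and read the consequences out at three levels:

1. **FtsZ filament dynamics.** FtsZ subunits treadmill through filaments;
   a subunit's residence time ("lifetime") is about filament length over
   treadmilling speed, so shorter lifetimes mean shorter and/or faster
   filaments. The lifetime is measured by sparse single-molecule TIRF
   imaging: spots are detected and tracked, intensity traces are extracted,
   a hidden Markov model separates bound (fluorescent) from unbound
   intervals, and the accepted dwell times are fit with a truncated
   exponential.
2. **Z-ring morphology.** From epifluorescence snapshots plus cell masks,
   intensity is averaged along each cell midline; rings are called by peak
   detection, and ring frequency per µm of cell length and ring full width
   at half maximum (FWHM) quantify division-site assembly.
3. **Promoter characteristics.** Titration tables are fit with the Hill
   equation `r(d) = leak + (max − leak)·dⁿ/(Kⁿ + dⁿ)`, yielding dynamic
   range (max/leak), leakiness (% of a reference promoter's maximum) and
   the Hill coefficient n with a bootstrap 95% CI.

The core statistical object is the left-truncated exponential lifetime
model: dwells below the 2-s cutoff are discarded by the event filter, and
by memorylessness the maximum-likelihood mean lifetime is the closed form
**τ̂ = mean(dwells) − truncation**, with bootstrap confidence intervals.

## Worked example

```python
from smlife import (AcquisitionParams, DwellModel, PhotophysicsParams,
                    render_movie, run_lifetime)

acq = AcquisitionParams(frame_interval_s=0.5, exposure_s=0.5, n_frames=480)
movie, mask, manifest = render_movie(
    n_cells=84, molecules_per_cell=3,
    model=DwellModel(mode="exponential", tau_s=5.0),
    acq=acq, phot=PhotophysicsParams(),
    image_shape=(512, 384), seed=2,
)
results, report, tables = run_lifetime(movie, mask, seed=2)
print(results.summary())
```

prints (true lifetime 5 s, 252 simulated molecules):

```
Truncated-exponential lifetime fit
==========================================
  mean lifetime tau           4.619 s
  95% CI (bootstrap)     [3.914, 5.362] s
  events                        181
  left truncation              2.00 s
  method                 truncated-exponential MLE, percentile bootstrap CI
```

The estimate is the mean accepted dwell minus the 2-s truncation; the CI
resamples events. The estimate sits a few percent below the programmed
lifetime by design of the measurement itself — dwell durations are whole
frames and long dwells are preferentially censored at the movie end — a
selection effect quantified in `docs/methods.md`. `report.stages` records how many spots, traces and
events each filter kept and why the rest were dropped.

Hill fitting follows the same model/results pattern:

```python
from smlife import HillModel, simulate_titration
table, truth = simulate_titration(1.0, 100.0, 1.0, 1.0,
                                  doses=[0, .03, .1, .3, 1, 3, 10, 30],
                                  replicates=3, noise_cv=0.1, seed=2)
fit = HillModel.from_dataframe(table).fit(seed=2)
print(fit.summary())   # leak/max/K/n, 95% CI on n, dynamic range, saturation flag
```

A thin CLI wraps the same pipelines:
`smlife simulate movie|rings|titration`, `smlife lifetime`, `smlife rings`,
`smlife titrate` (see `smlife --help`).

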