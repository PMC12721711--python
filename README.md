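# retinaln

Analysis and simulation tools for a classic question in retinal neural
coding: how do *transient* and *sustained* retinal ganglion cell (RGC)
responses arise from a shared cone-photoreceptor input?  The package is
aimed at visual neuroscientists who fit linear–nonlinear (LN) encoding
models to noise-stimulus recordings and quantify response kinetics of RGCs,
bipolar cells and their ribbon synapses.

It provides two tightly coupled halves:

* **Analysis** — spike-triggered averages (STA), LN-model estimation by
  reverse correlation, formula-defined kinetics statistics (zero-cross time,
  biphasic index, time-to-peak, steady-state % of peak, paired-flash ratio),
  excitatory/inhibitory conductance decomposition from two holding
  potentials, and ribbon-morphometry regression.
* **Synthesis** — generators with known ground truth for every analysis
  stage: band-limited Gaussian-noise/step/paired-flash stimuli, LN cells,
  inhomogeneous-Poisson spiking, a single-pool depressing ribbon synapse,
  EPSC and glutamate-sensor (iGluSnFR-style) forward models, and ribbon
  volume/vesicle-count tables.  Frozen presets `ont` (ON-transient-like) and
  `ons` (ON-sustained-like) encode the two kinetic phenotypes.

## The models

**LN cascade.** A response $r(t)$ to a full-field stimulus with Weber
contrast $c(t) = (I(t) - \bar I)/\bar I$ is modelled as

$$r(t) = N\!\Big(\int_0^{T} f(\tau)\, c(t-\tau)\, d\tau\Big) + \varepsilon(t),$$

with a causal linear filter $f$ and a static monotone nonlinearity $N$.
The filter is estimated either as the STA of spiking responses or, for
continuous responses, by cross-correlating stimulus and response and
dividing by the stimulus power spectrum; $N$ is read off by binning the
measured response along the predicted filter output.  Filter kinetics are
summarized by the zero-cross time between the first and second lobes and
the biphasic index $|A|/|B|$ (secondary- over initial-lobe peak magnitude).

**Depressing ribbon synapse.** Release is drawn from a single
readily-releasable pool of size $P_0$ with occupancy $p(t)$:

$$\frac{dp}{dt} = \frac{P_0 - p}{\tau_r} - k\,[d(t)-\theta]_+\, p, \qquad
R(t) = k\,[d(t)-\theta]_+\, p(t),$$

where $d(t)$ is the presynaptic drive, $\theta$ a release threshold, $k$ the
release-rate constant and $\tau_r$ the replenishment time constant.  This
minimal model produces transient versus sustained release, paired-flash
depression and its recovery with inter-flash interval.

## Worked example

Simulate one transient and one sustained model cell, fit LN models to their
noise responses, and quantify step, paired-flash and conductance behaviour:

```python
from retinaln import RunConfig, run_experiment

cfg = RunConfig(seeds=[1])
table = run_experiment(cfg)
cols = ["cell_id", "biphasic_index", "zero_cross_s", "ln_r",
        "steady_state_pct", "pfr_50ms", "pfr_400ms", "peak_g_ratio"]
print(table[cols].round(3).to_string(index=False))
```

```
cell_id  biphasic_index  zero_cross_s  ln_r  steady_state_pct  pfr_50ms  pfr_400ms  peak_g_ratio
 ont_s1           0.723         0.079 0.539             4.376     0.041      0.252         1.336
 ons_s1           0.514         0.073 0.644            25.910     0.290      0.838         3.876
```

Reading the rows: the transient cell's estimated filter is more biphasic
(0.72 vs 0.51) and slightly slower (zero-cross 79 ms vs 73 ms); its LN model
predicts held-out responses a little worse (r = 0.54 vs 0.64); its
step-evoked EPSC decays almost completely (steady state 4% of peak vs 26%);
and a second flash 50 ms after the first is nearly abolished (paired-flash
ratio 0.04 vs 0.29), recovering with interval as the vesicle pool refills.
The last column is the peak excitatory-to-inhibitory conductance ratio
recovered by decomposing currents simulated at the two reversal potentials
(0 and −68.5 mV).

Every stage is also available piecemeal (`make_gaussian_noise`,
`compute_sta`, `fit_ln_model`, `step_kinetics`, `paired_flash_ratio`,
`decompose_conductances`, `fit_ribbon_regression`, ...) and from the shell
via the `retinaln` command (`retinaln simulate|ribbons|sta|lnfit|lnpredict|
kinetics|gdecomp|morpho|run`).

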