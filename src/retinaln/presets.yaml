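# Frozen cell presets, calibrated once against the published kinetics regimes
# (see docs/methods.md for the calibration story and what each number means).
# Units: times in s, filter amplitudes in response-units per unit contrast per
# second, currents in pA, conductances in nS, rates in Hz.

bipolar:
  # Shared presynaptic voltage kernel: sustained, mildly biphasic; scaled so
  # a 50%-contrast step drives a unit plateau at the synapse (drive units).
  filter:
    peak_amp: 68.8385
    trough_amp: 10.3258
    tau_rise_s: 0.04
    tau_damp_s: 0.08
    order: 6

presets:
  ont:
    label: "ON-transient"
    # zero-cross 0.080 s, biphasic index 0.630 (fine-grid ground truth)
    filter_params:
      peak_amp: 10000.0
      trough_amp: 6838.9
      tau_rise_s: 0.056250
      tau_damp_s: 0.090000
      order: 6
    # slower, less biphasic inhibitory kernel (index 0.34)
    inh_filter_params:
      peak_amp: 10000.0
      trough_amp: 4776.8
      tau_rise_s: 0.063223
      tau_damp_s: 0.101157
      order: 6
    nonlinearity:
      threshold: 0.0
      gain: 1.0
    # trial noise giving held-out LN performance r ~ 0.5 on 5-trial means
    response_noise_sd: 122.8
    # small pool, high release threshold, slow refill: transient phenotype,
    # paired-flash ratio 0.04 at 50 ms
    synapse:
      pool_size: 40.0
      release_rate_k: 76.03
      threshold: 0.90
      tau_replenish_s: 1.5
    epsc:
      quantal_amp_pA: 1.5
      kernel_tau_s: 0.002
    # peak G_exc / peak G_inh ~ 1.46
    conductance:
      g_exc_gain_nS: 0.053028
      g_inh_gain_nS: 0.034111
    spiking:
      rate_gain_hz: 0.451984
      refractory_s: 0.002
  ons:
    label: "ON-sustained"
    # zero-cross 0.072 s, biphasic index 0.430 (fine-grid ground truth)
    filter_params:
      peak_amp: 10000.0
      trough_amp: 5484.0
      tau_rise_s: 0.047358
      tau_damp_s: 0.075772
      order: 6
    # weak inhibitory kernel (index 0.16)
    inh_filter_params:
      peak_amp: 10000.0
      trough_amp: 3047.9
      tau_rise_s: 0.053329
      tau_damp_s: 0.085326
      order: 6
    nonlinearity:
      threshold: 0.0
      gain: 1.0
    # trial noise giving held-out LN performance r ~ 0.6 on 5-trial means
    response_noise_sd: 85.9
    # large pool, lower threshold, fast refill: sustained phenotype,
    # paired-flash ratio 0.29 at 50 ms
    synapse:
      pool_size: 120.0
      release_rate_k: 27.16
      threshold: 0.70
      tau_replenish_s: 0.25
    epsc:
      quantal_amp_pA: 1.5
      kernel_tau_s: 0.002
    # peak G_exc / peak G_inh ~ 4.04
    conductance:
      g_exc_gain_nS: 0.059827
      g_inh_gain_nS: 0.011715
    spiking:
      rate_gain_hz: 0.505478
      refractory_s: 0.002
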