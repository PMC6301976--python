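# Packaged scenario and site presets.
#
# Sites carry the published posterior summaries for each reef / taxon:
# carrying capacity K (% cover), posterior-mean intrinsic rate r (yr^-1) and
# the Beta(alpha, beta) summary of the posterior r draws used for yearly
# stochastic draws in forward runs.  p0 is the simulation's initial cover,
# set to half the carrying capacity (a recovering, mid-succession reef).
sites:
  japan:
    description: "Sesoko Island, southern Japan (total cover)"
    K: 52.63
    r_mean: 0.39
    beta: {alpha: 3.16, beta: 5.14}
    p0: 26.0
  western_australia:
    description: "Scott Reef, Western Australia (total cover)"
    K: 63.85
    r_mean: 0.17
    beta: {alpha: 27.01, beta: 127.78}
    p0: 32.0
  acropora:
    description: "Scott Reef, Western Australia (Acropora spp.)"
    K: 39.52
    r_mean: 0.19
    beta: {alpha: 35.29, beta: 147.51}
    p0: 20.0
  porites:
    description: "Scott Reef, Western Australia (Porites spp.)"
    K: 25.95
    r_mean: 0.09
    beta: {alpha: 8.33, beta: 84.67}
    p0: 13.0

# Scenarios combine an SST coefficient set (temperature key) with the
# stress parameters of the forward runs.  eps is the extreme-event
# coefficient.  Because event mortality here runs on elapsed time in years
# (exp(-eps^3 * (t - t_k))), the intensity axis is calibrated to the regime
# each pathway is expected to produce: low-magnitude anomalies (eps 1.5)
# keep populations near carrying capacity under the conservative pathway;
# the mid pathway sits in the recovery-or-collapse transition band
# (eps 2.5); business-as-usual stress runs use the high knob (8), under
# which any event razes cover to the floor.  gamma is the background
# temperature-impact coefficient (0.001 base, 0.005 high).
scenarios:
  modern:
    temperature: modern
    gamma: 0.001
    eps: 1.5
    interval: [3, 9]
    mean_interval: 6.0
  rcp45:
    temperature: rcp45
    gamma: 0.001
    eps: 1.5
    interval: [3, 9]
    mean_interval: 6.0
  rcp60:
    temperature: rcp60
    gamma: 0.001
    eps: 2.5
    interval: [3, 9]
    mean_interval: 6.0
  rcp85_low_intensity:
    temperature: rcp85
    gamma: 0.005
    eps: 3.0
    interval: [3, 9]
    mean_interval: 6.0
  rcp85_high_intensity:
    temperature: rcp85
    gamma: 0.005
    eps: 8.0
    interval: [3, 9]
    mean_interval: 6.0
  rcp85_high_frequency:
    temperature: rcp85
    gamma: 0.005
    eps: 8.0
    interval: [3, 6]
    mean_interval: 4.5
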