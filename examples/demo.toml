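# Annotated pipeline configuration for the synthetic two-condition demo.
# Section names are organizational only; keys are matched by name.

[simulation]
n_participants = 20   # cohort size (>= 2)
fs = 250.0            # sampling rate, Hz (>= 200 so the 90-Hz band resolves)
duration = 60.0       # seconds per recording (>= 2)
seed = 11             # mandatory whenever any stage is stochastic

[preprocessing]
highpass_hz = 1.0     # pass-band edge; -6 dB point falls at half of this
highpass_order = 827  # FIR taps (odd); 827 at 250 Hz spans 3.3 s
epoch_length = 1.0    # seconds per epoch (1 s -> 1-Hz spectral resolution)
notch_hz = 50.0       # AC line bin replaced by its neighbors' mean

[analysis]
band_preset = "stats" # "stats": theta 4-7, alpha 8-12 | "alt": theta 4-8, alpha 9-12
split_hz = 25.0       # low/high segment boundary for the 1/f fits (try 30.0)
pac_channel = "Oz"
pac_phase_freq = 9.0
pac_amp_band = [31.0, 90.0]

[stats]
p_thresh = 0.01       # cluster-forming per-electrode threshold
min_cluster = 4       # minimum adjacent electrodes per cluster
n_perm = 500          # label-reversal permutations (production default: 2000)

[output]
out_dir = "results/demo"
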