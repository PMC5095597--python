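# Annotated run configuration for `cestkit run-all --config <file>`.
# Every field is optional; omitted fields take the defaults shown here.

seed: 0                 # drives all randomness (noise, optimizer starts)
noise_sd: 0.005         # Gaussian noise sd on normalized Z, per voxel
n_voxels: 21            # voxels per phantom ROI (disc of radius ~2.5 px)
compressed_scheme: false  # false: 26 ms pulse + 26 ms gap (15.6 s train)
                          # true: back-to-back pulses (7.8 s train)
omega: 2.8              # target offset for all metrics, ppm
delta_omega: 1.4        # flanking spacing for the three-offset metrics, ppm
family_size: 24         # Holm-Sidak family for slope comparisons
prior_mode: both        # default | measured | both (which CESTR* variants)
fit_backend: map        # map (penalized least squares) | mcmc (emcee audit)
delta_ph_metric: cestr_measured   # metric inverted for pairwise delta-pH
out_dir: null           # set by --out on the command line
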