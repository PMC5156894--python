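# Example run configuration. Every key is optional; unset keys take the
# documented defaults (the values shown here). Unknown keys are an error.

dialect: default          # trace CSV dialect name
lenient: false            # downgrade time-monotonicity violations to row drops

# respirometry reduction
lead_trim_s: 60.0         # seconds discarded after sealing each phase
tail_trim_s: 60.0         # seconds discarded before reopening
bg_frac_threshold: 0.25   # reject records with background > this fraction of RMR
r2_threshold: 0.90        # below this, slopes carry a low_r2 QC flag (no auto-reject)
background_mode: auto     # auto | constant | linear_in_time
fish_density_kg_per_l: 1.0

# statistics
alpha: 0.05               # significance level for the reduction protocol
sum_of_squares: 2         # type of SS for term tests
tukey_on_log_scale: true

# run plumbing
seed: 0
out_dir: results
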