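# Demo end-to-end pipeline config (orifire run --config configs/demo.yaml).
# All analysis parameters are named so deviations from the defaults are
# visible; values not listed fall back to orifire.cli.DEFAULTS.
genome: minimal          # fixture: one chromosome, one origin
seed: 0
n_cells: 300
sample_time: 30.0        # minutes in HU before harvesting ssDNA
hu_mode: true
fork_speed: 0.3          # kb/min under 200 mM HU
dntp_budget: 50.0        # kb of synthesis per cell
ssdna_footprint_sd: 1000 # bp
log_sd: 0.15             # multiplicative array noise
outlier_rate: 0.001      # extreme-spike probability per probe
window: 6000             # LOESS window, bp (9000 for noisy samples)
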