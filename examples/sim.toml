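# Example simulation config: one association/dissociation cycle with a
# common-mode bulk shift, written as active/reference channel files.
seed = 42

[kinetics]
k_on_per_m_s = 1.0e4
k_off_per_s = 1.0e-3
r_max_deg = 0.6

[schedule]
start_s = 60.0
association_s = 720.0
dissociation_s = 180.0
concentration_um = 100.0

[noise]
sd_deg = 0.002
bulk_shift_deg = 0.05
drift_deg_per_s = 0.0

[output]
active_file = "active.tsv"
reference_file = "reference.tsv"
sample_interval_s = 1.0
analyte = "test-analyte"
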