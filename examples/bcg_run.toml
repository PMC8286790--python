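# Example run configuration: three peptide measurements on BCG-coated
# channels of a 1-mm-spot SPR instrument.  Immobilization responses are the
# monolayer coverages times the modeled 2.28-degree full-monolayer maximum;
# binding responses are the plateau mass densities divided by 600 ng/cm^2/deg.
seed = 1
output_dir = "results"

[stack]
file = "bcg_sensor.toml"

[particle]
volume_um3 = 0.3887
refractive_index = 1.35
packing_fraction = 0.74
fill_factor = 0.524

[spot]
diameter_mm = 1.0

[conversion]
k_ng_per_cm2_deg = 600.0

[[measurements]]
name = "6K-AH1"
molecular_weight = 1868.21
anchor = "polyK"
immobilization_deg = 0.51528
binding_deg = 0.05883333333333333
concentration_um = 100.0

[[measurements]]
name = "6K-TRP2"
molecular_weight = 1944.4
anchor = "polyK"
immobilization_deg = 0.31008
binding_deg = 0.5026666666666667
concentration_um = 100.0

[[measurements]]
name = "CPP-SIINFEKL"
molecular_weight = 3279.9
anchor = "CPP"
immobilization_deg = 0.2508
binding_deg = 0.2716666666666667
concentration_um = 100.0
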