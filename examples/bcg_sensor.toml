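# Calibrated stand-in for the Au-SiO2 SPR sensor slide at 670 nm.
# The prism index was calibrated so that a 351.1 nm adlayer of n = 1.35 in
# PBS shifts the resonance dip by 2.28 degrees.  Replace layer values with
# measured slide parameters when available.
wavelength_nm = 670.0

[[layers]]
name = "prism"
n_real = 1.4977

[[layers]]
name = "Cr"
n_real = 3.0
n_imag = 3.5
thickness_nm = 2.0

[[layers]]
name = "Au"
n_real = 0.14
n_imag = 3.80
thickness_nm = 50.0

[[layers]]
name = "SiO2"
n_real = 1.456
thickness_nm = 15.0

[[layers]]
name = "PBS"
n_real = 1.335
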