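# sprquant

Quantify how many ligand molecules are attached per particle from
multi-parametric SPR measurements of particle-coated sensor surfaces.

The package implements the full estimation chain for a rod-shaped
bacterial particle (BCG by default) immobilized on an Au–SiO₂ SPR slide
and coated with anchored peptides:

1. **geometry** — convert rod dimensions (or a direct cell volume) to an
   equivalent sphere, apply the hexagonal-packing monolayer model
   (area fraction 0.74, sphere-to-slab fill factor 0.524) to get the
   effective homogeneous monolayer thickness, and compute the per-particle
   sensor footprint.
2. **optics** — p-polarized transfer-matrix reflectance of the sensor
   stack at 670 nm, SPR dip localization with sub-grid parabolic
   refinement, and the dip shift produced by an adsorbed layer. The
   full-monolayer shift (2.28° for the default BCG model) is the
   denominator that converts measured immobilization responses into
   surface coverage.
3. **sensorgram** — read/write delimited sensorgram files, subtract the
   uncoated reference channel, extract steady-state plateaus, and simulate
   noisy two-channel Langmuir 1:1 sensorgrams (plus parameter-recovery
   fitting) so the whole pipeline is testable without instrument data.
4. **quantify** — coverage → particle count → adsorbed mass
   (600 ng/cm² per degree) → molecule count (Avogadro) → molecules per
   particle.

Every constant is overridable through the run configuration; the values
above are the defaults.

## Command line

```bash
# check a run configuration and report all problems at once
sprquant validate --config examples/bcg_run.toml

# run the full estimation chain; writes report.tsv + report.json + run.log
sprquant quantify --config examples/bcg_run.toml --out results/

# export the reflectance-versus-angle curve of a sensor stack
sprquant scan --stack examples/bcg_sensor.toml --from 60 --to 85 --step 0.005 --out curve.tsv

# generate synthetic two-channel sensorgrams (active + reference)
sprquant simulate --config examples/sim.toml --seed 42
```

`examples/bcg_run.toml` is a complete run configuration for three peptide
measurements; `examples/bcg_sensor.toml` describes the calibrated default
sensor stack (prism / Cr 2 nm / Au 50 nm / SiO₂ 15 nm / PBS). Measurements
can be given either as steady-state responses in degrees or as sensorgram
file pairs with a plateau window; in the latter case the reference channel
is subtracted before plateau extraction.

Reports are deterministic: the same configuration and seed reproduce
byte-identical output files.

## Notes on the default sensor stack

The shipped stack (`src/sprquant/data/bcg_sensor.toml`) is a documented
stand-in for a typical Au–SiO₂ slide: the prism index was calibrated so
that the canonical full-monolayer adlayer (n = 1.35, 351.1 nm, PBS
ambient) shifts the dip by 2.28°. Replace the layer values with measured
slide parameters when they are available; all downstream results scale
through the modeled full-monolayer response.
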