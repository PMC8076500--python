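# Transwell diffusion, oscillatory-force (OF) release rate.
# Measured rate: 986.3 exosomes per hour per 1e5 cells; 3.6e6 seeded cells.
# Geometry dimensions are artifact defaults modeled on a 6-well insert.
scenario = "transwell"
seed = 0
output_dir = "out/transwell_of"

[transwell]
condition = "OF"
cell_count = 3.6e6
diffusion_m2_s = 2.0e-3
duration_h = 72.0
well_diameter_mm = 34.8
insert_diameter_mm = 24.0
bottom_chamber_height_mm = 2.0
top_chamber_height_mm = 2.0
counting = "cumulative_flux"
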