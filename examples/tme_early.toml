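# Early-stage tumor microenvironment: synthetic layout, 2.5 exosomes/s
# released from the tumor surface, interstitial inflow 0.75 um/s from the
# left.  Domain size, cell counts and the diffusion coefficient are
# artifact defaults (declared here, not literature values).
scenario = "tme"
seed = 1
output_dir = "out/tme_early"

[tme]
stage = "early"
release_rate_per_s = 2.5
inlet_velocity_um_s = 0.75
diffusion_m2_s = 4.5e-12
duration_min = 45.0
resolution = 256
domain_size_um = 1000.0
tumor_radius_early_um = 100.0
n_macrophages = 10
n_tcells = 15
n_mdscs = 5
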