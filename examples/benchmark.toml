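# Sheared-Gaussian verification benchmark.
# Exact-solution parameters: U = 5.0e-6 m/s, shear rate 5.0e-4 1/s,
# source strength M = 1.0, diffusion coefficient 1.0e-8 m^2/s, on a
# 100 x 100 mm square with the origin at the geometric center.
scenario = "benchmark"
seed = 0
output_dir = "out/benchmark"

[benchmark]
U_m_s = 5.0e-6
shear_rate_1_s = 5.0e-4
M = 1.0
D_m2_s = 1.0e-8
t_init_s = 60.0
duration_min = 45.0
nx = 200
scheme = "quick"
cfl = 0.5
variant = "standard"
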