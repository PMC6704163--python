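# Dense dentin slab: 122 water-filled tubules (n = 1.33, a = 1 um) in dentin
# (n = 1.52) over 40.4 x 69.3 um^2; mean free path ~ 7 um, so most detected
# light is multiply scattered.  Analytic (single-scattering) path shown here;
# switch solver.type to "grid" for the full multiple-scattering solve.

[instrument]
n_med = 1.52

[spectrum]
epsilon = 1e-8
N = 40

[scene]
type = "dentin_slab"
count = 122
region = ["rectangle", 0.0, 40.4e-6, -34.65e-6, 34.65e-6]
radius = 1e-6
seed = 7

[solver]
type = "analytic"

[scan]
polarisation = "perpendicular"
y_min = -20e-6
y_max = 20e-6
n_positions = 11

[output]
scale = "linear"
formats = ["npy", "csv"]
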