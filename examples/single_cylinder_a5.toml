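# Single cylinder, a = 5 um, n_cyl = 1.42 in n_med = 1.35: the standard
# small-cylinder run.  The on-axis A-scan shows the front- and back-surface
# echoes separated by 2 a n_cyl/n_med ~ 10.52 um.

[instrument]
n_med = 1.35

[spectrum]
lambda0 = 1.3e-6
delta_lambda = 170e-9
epsilon = 1e-3
N = 160

[scene]
type = "single_cylinder"
radius = 5e-6
n_cyl = 1.42

[solver]
type = "analytic"

[scan]
polarisation = "perpendicular"
y_min = -10e-6
y_max = 10e-6
n_positions = 5

[output]
scale = "log"
formats = ["npy", "csv"]
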