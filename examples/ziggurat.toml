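# Stepped scatterer with three plateaus; surfaces normal to the optical axis
# are the one geometry whose tomogram traces the physical boundaries.
# Uses the grid solver on a deliberately small domain.

[instrument]
n_med = 1.35

[spectrum]
epsilon = 1e-3
N = 24

[scene]
type = "ziggurat"
plateau_widths = [12e-6, 8e-6, 4e-6]
step_height = 2e-6
index = 1.42
x_top = -3e-6

[solver]
type = "grid"
dx_over_lambda0 = 0.0769   # lambda0/13
boundary_width = 6e-6

[scan]
polarisation = "perpendicular"
y_min = 0.0
y_max = 0.0
n_positions = 1

[output]
scale = "log"
formats = ["npy", "csv"]
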