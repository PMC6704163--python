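# Fig-7-like phantom: 83 cylinders of radius 0.5 um, index 1.42, arranged on
# a mirror-symmetric hexagonal lattice inside a 10 um disc (the published
# symmetric coordinates are not tabulated; this is the package's stand-in).
# A short spectrum keeps the bundled example quick; raise N for real use.

[instrument]
n_med = 1.35

[spectrum]
epsilon = 1e-8
N = 40

[scene]
type = "cluster"
count = 83
region = ["disc", 0.0, 0.0, 10e-6]
radius = 0.5e-6
index = 1.42
seed = 1

[solver]
type = "analytic"

[scan]
polarisation = "perpendicular"
y_min = -12e-6
y_max = 12e-6
n_positions = 13

[output]
scale = "linear"
formats = ["npy", "csv"]
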