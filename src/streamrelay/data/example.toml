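# Repository default parameter set, in chamber units (lengths / chamber
# length, times / (chamber length / cell speed), concentrations / reservoir
# concentration).  These defaults are package choices sized to the gradient-
# chamber geometry; they are configuration, not constants of the model.

degradation = { kind = "parabolic", kmax = 40.0 }

[dimensionless]
D = 2.0        # chemoattractant diffusivity
beta = 0.07    # secretion rate per cell (signal relay strength)
sigma = 0.1    # angular noise amplitude (stationary angle s.d. ~ 0.5 rad)
T = 0.02       # orientation response time
f0 = 3.0       # soft-disk repulsion strength (keeps jammed aggregates fluid)
J = 60.0       # injection flux (cells per unit time per unit width)
W = 0.5        # chamber aspect ratio (width / length)
R = 0.0125     # cell radius

[numerics]
h = 0.025      # grid spacing (1/h must be an integer; W/h too)
dt = 7.5e-5    # shared time step, inside the explicit stability bound
t_end = 3.0    # total simulated time (~3 chamber transits)
n_snapshots = 5
record_stride = 100
seed = 0
init_angle_halfwidth = 0.0
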