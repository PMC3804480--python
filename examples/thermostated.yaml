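# Thermostated scenario: constant field F=1 with isokinetic control,
# conservative interactions (pi=0) at unit rate, zero-mean Gaussian
# transitions, even initial profile supported on [-1, 1].
grid:
  u_min: -3.0
  u_max: 3.0
  M: 200
velocities: [1.0]
kernels:
  iota: 1.0
  A:
    kind: gaussian
    sigma: 0.5
    center: 0.0
  pi: 0.0
force: 1.0
thermostat: true
initial:
  kind: parabolic
  mass: 1.0
  support_min: -1.0
  support_max: 1.0
run:
  t_end: 5.0
  record_every: 10
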