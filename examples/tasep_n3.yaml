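# Worked TASEP simulation: 3 sites, 8 configurations, forcing period 2*pi.
model:
  type: tasep
  n: 3
  period: 6.283185307179586
  rates:
    alpha: "1+1*cos(1*t+0)"
    beta: "1+1*cos(1*t+3.141592653589793)"
    h: ["0.5", "0.25"]
initial: uniform
horizon_periods: 20
solver:
  rtol: 1.0e-9
  atol: 1.0e-12
sampling:
  n_time: 25
  n_state: 200
seed: 1
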