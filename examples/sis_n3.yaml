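# Worked stochastic SIS simulation: population 3, seasonal recovery and import.
model:
  type: sis
  N: 3
  period: 6.283185307179586
  rates:
    a: "1"
    b: "3+3*cos(1*t+0.5)"
    c: "2-2*sin(1*t+0.75)"
initial: [0.25, 0.25, 0.25, 0.25]
horizon_periods: 20
solver:
  rtol: 1.0e-9
  atol: 1.0e-12
sampling:
  n_time: 25
  n_state: 200
seed: 1
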