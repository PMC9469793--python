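"""Order selection: prediction error versus model order.

For a true ARX(6) realization the one-step prediction error falls steeply
and levels off exactly at order six.  For a moving-average process of the
same spectral character (which is NOT an ARX process) the metrics stop
improving around order three -- the sweep identifies model mismatch.
"""

import gammaloop as gl

stim = gl.step_stimulus(2000, amplitude=2.0)
arx = gl.simulate_arx(gl.reference_arx_model(), 1.0, stim, seed=1)
ma = gl.make_ma_process(seed=7, n_samples=2000)

t_arx = gl.order_sweep(arx, range(1, 13), 1.0, stim)
t_ma = gl.order_sweep(ma, range(1, 13), 1.0, stim)

print(f"{'p':>3} {'eps_pred (ARX)':>15} {'eps_pred (MA)':>15}")
for (_, ra), (_, rm) in zip(t_arx.iterrows(), t_ma.iterrows()):
    print(f"{int(ra.p):>3} {ra.eps_pred:>15.4e} {rm.eps_pred:>15.4e}")

eps = t_arx.set_index("p")["eps_pred"]
print(f"\nARX: improvement from p=5 to p=6 is {eps[5]/eps[6]:.1f}x,"
      f" from p=6 to p=12 only {100*(eps[6]-eps[12])/eps[6]:.2f}%"
      " -- the knee sits at the true order.")
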