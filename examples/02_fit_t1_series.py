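"""Fit the response models to a noisy T1 time series.

Simulates one liver session at the published 1.0 L operating point with
5 ms measurement noise and recovers the dynamic parameters by bounded
multi-start least squares.
"""

import numpy as np

from hydromark import LtiParams, Marker, RectShape, fit_liver, generate_t1_series

truth = LtiParams(gain=150.0, tau=3007.0, delay=821.0, baseline=740.0)
shape = RectShape(delta=1534.0)

schedule = np.concatenate([[-600.0, -300.0], np.arange(300.0, 4201.0, 300.0)])
series = generate_t1_series(truth, shape, schedule, noise_sd=5.0,
                            rng=np.random.default_rng(1), marker=Marker.T1_LIVER)

fit = fit_liver(series)
print("parameter        truth    estimate")
print(f"gain (ms)      {truth.gain:7.1f}   {fit.params.gain:8.1f}")
print(f"tau (s)        {truth.tau:7.0f}   {fit.params.tau:8.0f}")
print(f"delay (s)      {truth.delay:7.0f}   {fit.params.delay:8.0f}")
print(f"pulse (s)      {shape.delta:7.0f}   {fit.shape.delta:8.0f}")
print(f"\nconverged={fit.converged}  SSE={fit.sse:.1f} ms^2  start#{fit.init_used}")
print("\nThe time constant tau is the organ's water-uptake rate parameter; "
      "with 16 samples and 5 ms noise it is typically recovered within a "
      "few percent, while delay and pulse length trade off more.")
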