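"""Sensitivity of the directional Bayes factor to the Cauchy prior width.

The evidence depends on what H+ predicts, i.e. on the prior; sweeping the
width r maps out that dependence.  At r = 0 the alternative collapses onto
the null and the Bayes factor is 1 by construction; the curve then rises
steeply and peaks near Jeffreys's historical "wide prior" r = 1.
"""

import numpy as np

import repbayes as rb

summary = rb.TTestSummary(t=4.178, n1=18, n2=69)
curve = rb.robustness_curve(
    summary, side="positive", r_grid=np.linspace(0.0, 1.5, 201)
)

for r in (0.0, 0.1, 2**-0.5, 1.0, 1.5):
    bf = curve.bf_values[np.argmin(np.abs(curve.r_values - r))]
    print(f"r = {r:5.3f}  ->  BF+0 = {bf:8.2f}")
print(f"peak: BF+0 = {curve.max_bf:.0f} at r = {curve.argmax_r:.3f}")
print("evidence for H+ is in the hundreds for every non-tiny width:")
print("the conclusion is robust to the prior-width choice.")
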