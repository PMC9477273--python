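"""Find the minimum detectable concentration on a simulated dilution series.

A sensor with an 8-fold saturating response (EC50 = 1 uM) is measured down
a two-fold dilution series; the summary reports the lowest measured
concentration whose fold change clears 2 with a confident interval.
"""

import numpy as np

import cleavekit as ck
from cleavekit.cleaveseq import fold_change_frame
from cleavekit.profiling import DosePoint
from cleavekit.synthetic import TargetResponse

rng = np.random.default_rng(31)
target = TargetResponse(fc_max=8.0, ec50_um=1.0)
c0, depth = 0.6, 5000
points = []
for conc in [10.0 / 2**i for i in range(10)]:
    odds = (c0 / (1 - c0)) / target.fold_change(conc)
    c = odds / (1 + odds)
    a_ref, a_test = rng.binomial(depth, c0), rng.binomial(depth, c)
    f = fold_change_frame(a_ref, depth - a_ref, a_test, depth - a_test).iloc[0]
    points.append(DosePoint(conc, float(f.fc), (float(f.ci95_lo), float(f.ci95_hi))))
    print(f"  {conc:8.4f} uM  fc={f.fc:5.2f}  CI ({f.ci95_lo:.2f}, {f.ci95_hi:.2f})")

series = ck.DoseSeries("sensor", "compound", points)
res = ck.min_detectable_concentration(series, fc_threshold=2.0)
analytic = target.ec50_um / (target.fc_max - 2.0)
print(f"\nminimum detectable concentration: {res.min_concentration_um} uM")
print(f"analytic FC(x)=2 crossing: {analytic:.3f} uM (result is within one dilution)")
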