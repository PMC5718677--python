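"""Evaluate the published threshold models at clinical operating points.

The pooled models predict the percent-of-maximum threshold from target
cross-sectional area (small-area form only), target-to-background ratio
and reconstruction smoothing.  Small or low-contrast cross-sections need
thresholds near the maximum; large high-contrast ones sit near 40-50%.
"""

import petthresh as pt

models = pt.published_models().pooled

cases = [
    ("medium target, good contrast", dict(area=100.0, tb=4.0, fwhm=8.0)),
    ("small faint node slice", dict(area=46.0, tb=2.9, fwhm=8.0)),
    ("large target, moderate contrast", dict(area=400.0, tb=2.0, fwhm=6.0)),
    ("large target, high contrast", dict(area=800.0, tb=16.0, fwhm=8.0)),
]
for label, kw in cases:
    model = models.select(kw["area"])
    area = kw["area"] if model.form == "small_area" else None
    ts, flags = pt.predict_ts(model, tb=kw["tb"], area=area, fwhm=kw["fwhm"])
    note = " (extrapolated)" if flags.extrapolated else ""
    print(f"{label:34s} A={kw['area']:6.0f} mm2  TB={kw['tb']:5.1f}  "
          f"FWHM={kw['fwhm']:.0f} mm  ->  TS = {ts:5.2f}%{note} [{model.form}]")
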