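"""Percent improvement from adding secondary traits to the GS model.

Reproduces the reporting arithmetic on a published accuracy table:
grain-yield cross-validation accuracy per environment for the
markers-only model versus the multi-trait model with grain-filling
spectra, the per-environment improvements, and their average.
"""

import phenogs as pg

unigs = {"2014": 0.43, "2015": 0.40, "2016": 0.45}
multi = {"2014": 0.58, "2015": 0.41, "2016": 0.55}

out = pg.summarize_improvement(unigs, multi)
print(out.to_string(index=False))
print(
    "\nReading: adding spectral indices lifted grain-yield prediction "
    "accuracy by\n35% (2014), 2.5% (2015) and 22% (2016) — a 20% average "
    "gain for the\nsame field season, markers and trial design."
)
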