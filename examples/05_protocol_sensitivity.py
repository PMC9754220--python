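"""Quantify the acquisition-protocol bias on a paired cohort.

Images both eyes of 6 subjects under the standard (25 x 512) and the
high-resolution (97 x 1024) raster from the same true surfaces, then fits
per-parameter mixed models with a protocol indicator.  The 25-B-scan raster
undersamples the fovea vertically: interpolation across the pit minimum
inflates the central foveal thickness and flattens the radial profile.

Runs the full raster pipeline on 24 scans; takes about half a minute.
"""

import octmorph as om
from octmorph.sensitivity import run_sensitivity

table, bias = run_sensitivity(om.GeneratorConfig(), n_subjects=6, seed=3)
cols = ["parameter", "absolute_bias", "relative_bias_pct", "p"]
print(bias[cols].round(3).to_string(index=False))
# Expected pattern: whole-macula layer means are protocol-robust (|bias|
# well under 1%), while CFT is biased upward by a few percent and the mean
# slope downward — the undersampling signature of the standard protocol.
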