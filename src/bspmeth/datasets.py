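"""Small published summary tables bundled for reference and defaults.

These are group-level statistics (no raw measurements) from a Lushi-chicken
blue-eggshell laying study; they seed the synthetic-data generator's
default study conditions and support arithmetic cross-checks.
"""

from __future__ import annotations

import pandas as pd

#: Weekly eggshell-color statistics measured with a colorimeter over the
#: laying cycle (weeks 20-60).  Columns: sample size, mean color value
#: (larger = lighter shell), sample SD, observed max/min, and the printed
#: variable coefficient (CV = SD/mean, rounded to 4 decimals as published;
#: for weeks 20, 35 and 55 the printed CV differs from SD/mean recomputed
#: from the rounded mean and SD in the 4th decimal).
EGGSHELL_COLOR_WEEKLY = pd.DataFrame(
    {
        "week": [20, 25, 30, 35, 40, 45, 50, 55, 60],
        "n": [264, 337, 313, 290, 285, 319, 348, 313, 184],
        "mean": [53.53, 53.86, 56.14, 56.59, 56.95, 56.88, 58.57, 57.79, 58.40],
        "sd": [2.80, 2.58, 3.14, 2.93, 3.33, 4.07, 2.97, 3.48, 3.19],
        "max": [57.31, 60.30, 62.32, 64.02, 64.84, 64.38, 65.30, 65.55, 64.34],
        "min": [48.24, 49.63, 48.43, 49.75, 48.37, 48.77, 51.80, 50.43, 51.66],
        "cv_printed": [0.0524, 0.0479, 0.0559, 0.0517, 0.0585, 0.0716, 0.0507, 0.0603, 0.0546],
    }
).set_index("week")

#: Published overall (integral) promoter methylation rates, as fractions,
#: for the eight weeks with shell-gland samples.  Used as the generator's
#: default planted per-week rates.
OVERALL_METHYLATION_BY_WEEK = {
    25: 0.8393,
    30: 0.8437,
    35: 0.8527,
    40: 0.8776,
    45: 0.9082,
    50: 0.9167,
    55: 0.9107,
    60: 0.9133,
}

#: Published pooled methylation rate of each of the 14 promoter CpG sites
#: (fractions).  Used as the generator's default relative site profile.
SITE_METHYLATION_PROFILE = [
    0.7193, 0.9123, 0.8596, 0.8860, 0.9211, 0.9474, 0.5614,
    0.9211, 0.9211, 0.9649, 0.8684, 0.9123, 0.8947, 0.9649,
]

#: CpG ordinals reported as covered by predicted TF binding sites
#: (C/EBPalpha, Sp1 and Oct-1 class motifs) in the promoter.
TFBS_COVERED_SITES = [2, 3, 5, 6, 8, 9]
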