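"""Assay arithmetic: specific lysis, promoter lengths, dual-chain rates.

The exactly specified numerics behind the wet-lab readouts: the
chromium-release specific-lysis formula, promoter construct lengths in
transcription-start-site coordinates (no position 0), and the rounding
convention for dual-chain percentages.
"""

import pandas as pd

from tcrforge.assaymath import (
    LysisMeasurement,
    PromoterInterval,
    event_summary,
    promoter_interval_length,
    rate_percent,
    specific_lysis,
    summarize_lysis_plate,
)

m = LysisMeasurement(experimental_cpm=50, spontaneous_cpm=20, maximum_cpm=120)
print(f"specific lysis (50, 20, 120 cpm): {specific_lysis(m):.1f} %")

short = PromoterInterval(-319, 46)
long = PromoterInterval(-1800, 119)
print(f"NR4A1 short promoter (-319..+46): {promoter_interval_length(short)} bp")
print(f"NR4A1 long promoter (-1800..+119): {promoter_interval_length(long)} bp")

print(f"dual TCRα rate, 2 of 86 cells: {rate_percent(2, 86)} %")
print(f"dual TCRβ rate, 1 of 86 cells: {rate_percent(1, 86)} % "
      "(half-away-from-zero rounding)")

frac, mean = event_summary([420, 980, 1530, 260, 2210], threshold=1000)
print(f"GFP events above threshold: {frac:.0%}, mean intensity {mean:.0f}")

plate = pd.DataFrame({
    "condition": ["E:T 10:1"] * 3 + ["E:T 1:1"] * 3,
    "experimental_cpm": [88, 95, 90, 41, 38, 45],
    "spontaneous_cpm": [22] * 6,
    "maximum_cpm": [130] * 6,
})
print(summarize_lysis_plate(plate).to_string(index=False))
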