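"""Assay arithmetic: specific lysis, promoter coordinates, rates, events.

Small, exactly specified utilities backing the wet-lab readouts the rest
of the toolkit is designed to feed: chromium-release specific lysis,
promoter construct lengths under the transcription-start-site coordinate
convention (positions are signed and there is no position 0), dual-chain
rate percentages, and threshold-based fluorescence event summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LysisMeasurement:
    """Chromium-release counts per minute for one well/condition."""

    experimental_cpm: float
    spontaneous_cpm: float
    maximum_cpm: float

    def __post_init__(self):
        if min(self.experimental_cpm, self.spontaneous_cpm, self.maximum_cpm) < 0:
            raise ValueError("cpm values must be non-negative")
        if self.maximum_cpm <= self.spontaneous_cpm:
            raise ValueError("maximum release must exceed spontaneous release")


def specific_lysis(m: LysisMeasurement) -> float:
    """Percent specific lysis:
    100 x (experimental - spontaneous) / (maximum - spontaneous).

    May legitimately fall below 0 or above 100; reported as-is.
    """
    return (
        100.0
        * (m.experimental_cpm - m.spontaneous_cpm)
        / (m.maximum_cpm - m.spontaneous_cpm)
    )


@dataclass(frozen=True)
class PromoterInterval:
    """Signed positions relative to the transcription start site; by the
    biology convention there is no position 0, so an interval spanning
    the TSS counts |start| + end bases."""

    start: int
    end: int

    def __post_init__(self):
        if self.start == 0 or self.end == 0:
            raise ValueError("position 0 does not exist in TSS coordinates")
        if self.start >= self.end:
            raise ValueError("start must lie upstream of end")


def promoter_interval_length(p: PromoterInterval) -> int:
    """Length in bp of a promoter interval in TSS coordinates."""
    if p.start < 0 < p.end:
        return -p.start + p.end
    return p.end - p.start + 1


def rate_percent(count: int, total: int, decimals: int = 1) -> float:
    """100 x count / total, rounded half-away-from-zero to ``decimals``."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


def event_summary(values, threshold: float) -> tuple[float, float]:
    """(fraction of events above threshold, mean of all events)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("event list must be non-empty")
    return float(np.mean(arr > threshold)), float(arr.mean())


LYSIS_PLATE_COLUMNS = ["condition", "experimental_cpm", "spontaneous_cpm", "maximum_cpm"]


def summarize_lysis_plate(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate wells per condition and report mean +/- sd of
    percent specific lysis.

    ``table`` needs columns condition / experimental_cpm / spontaneous_cpm
    / maximum_cpm, one row per replicate well (typically triplicate).
    """
    missing = set(LYSIS_PLATE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"lysis table missing columns {sorted(missing)}")
    rows = []
    for condition, group in table.groupby("condition", sort=True):
        lysis = [
            specific_lysis(
                LysisMeasurement(
                    r["experimental_cpm"], r["spontaneous_cpm"], r["maximum_cpm"]
                )
            )
            for r in group.to_dict("records")
        ]
        rows.append(
            {
                "condition": condition,
                "n_wells": len(lysis),
                "specific_lysis_mean": float(np.mean(lysis)),
                "specific_lysis_sd": float(np.std(lysis, ddof=1)) if len(lysis) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
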