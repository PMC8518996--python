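"""Per-recording wheeze indexes.

Five scalar indexes summarize a recording's wheeze power bands:

1. number of bands per 30 s (normalized for non-30-s files, hence
   continuous — a non-integer count such as a cutoff of 11.1 on the
   count scale is meaningful);
2. mean band duration (ms);
3. mean of per-band lowest frequencies (Hz);
4. mean of per-band highest frequencies (Hz);
5. mean of per-band maximum-intensity (dominant) frequencies (Hz).

Frequency and duration summaries are undefined (NaN) for recordings
with no bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import WheezePowerBand


@dataclass(frozen=True)
class WheezeIndexSet:
    count_per_30s: float
    duration_ms: float
    lowest_hz: float
    highest_hz: float
    maxint_hz: float
    n_bands_raw: int

    @property
    def has_bands(self) -> bool:
        return self.n_bands_raw > 0

    def as_dict(self) -> dict[str, float]:
        return {
            "count_per_30s": self.count_per_30s,
            "duration_ms": self.duration_ms,
            "lowest_hz": self.lowest_hz,
            "highest_hz": self.highest_hz,
            "maxint_hz": self.maxint_hz,
            "n_bands_raw": self.n_bands_raw,
        }


def compute_indexes(
    bands: Sequence[WheezePowerBand], recording_duration_s: float = 30.0
) -> WheezeIndexSet:
    """Reduce a band list to the five per-recording indexes.

    The band count is normalized to a 30-s equivalent:
    ``count_per_30s = n_bands * 30 / recording_duration_s``.
    """
    if recording_duration_s <= 0:
        raise ValueError("recording_duration_s must be positive")
    n = len(bands)
    count = n * 30.0 / recording_duration_s
    if n == 0:
        nan = math.nan
        return WheezeIndexSet(count, nan, nan, nan, nan, 0)
    return WheezeIndexSet(
        count_per_30s=count,
        duration_ms=float(np.mean([b.duration_ms for b in bands])),
        lowest_hz=float(np.mean([b.lowest_hz for b in bands])),
        highest_hz=float(np.mean([b.highest_hz for b in bands])),
        maxint_hz=float(np.mean([b.maxint_hz for b in bands])),
        n_bands_raw=n,
    )


def bands_frame(bands: Sequence[WheezePowerBand]) -> pd.DataFrame:
    """Tabulate bands (one row each) for CSV export."""
    return pd.DataFrame(
        [
            {
                "start_s": b.start_s,
                "end_s": b.end_s,
                "duration_ms": b.duration_ms,
                "lowest_hz": b.lowest_hz,
                "highest_hz": b.highest_hz,
                "maxint_hz": b.maxint_hz,
                "mean_power_db": b.mean_power_db,
            }
            for b in bands
        ],
        columns=[
            "start_s",
            "end_s",
            "duration_ms",
            "lowest_hz",
            "highest_hz",
            "maxint_hz",
            "mean_power_db",
        ],
    )
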