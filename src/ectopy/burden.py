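"""Daily ventricular-ectopy burden aggregation.

Burden is the count of PVC-labelled beats (singles plus couplet/triplet
member beats) divided by the total number of detected beats in a window,
expressed as a percentage. A window with no detected beats has *undefined*
burden, which is deliberately distinct from 0%: a dead signal must not
read as healthy. Windows anchor at recording start for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError
from .morphology import BeatLabel

__all__ = ["BurdenReport", "daily_burden", "burden_series"]


@dataclass
class BurdenReport:
    window_start: float
    window_len: float
    n_pvc: int
    n_beats: int
    burden_pct: float          # NaN when undefined (no beats)
    sequence_ppt: float        # percentage points contributed by couplet/triplet beats
    threshold_pct: float
    alert: bool
    partial: bool = False      # trailing window shorter than window_len

    @property
    def defined(self) -> bool:
        return not math.isnan(self.burden_pct)


def daily_burden(labels: list[BeatLabel], window_start: float = 0.0,
                 window_len: float = 86400.0,
                 threshold_pct: float = 5.0,
                 partial: bool = False) -> BurdenReport:
    """Burden over [window_start, window_start + window_len)."""
    if window_len <= 0:
        raise InvalidInputError("window length must be positive")
    lo, hi = window_start, window_start + window_len
    in_win = [l for l in labels if lo <= l.beat.time < hi]
    n_beats = len(in_win)
    pvc = [l for l in in_win if l.is_pvc]
    n_pvc = len(pvc)
    n_seq = sum(1 for l in pvc if l.seq_type in ("couplet", "triplet"))
    if n_beats == 0:
        return BurdenReport(window_start, window_len, 0, 0,
                            float("nan"), float("nan"),
                            threshold_pct, alert=False, partial=partial)
    burden = 100.0 * n_pvc / n_beats
    seq_ppt = 100.0 * n_seq / n_beats
    return BurdenReport(window_start, window_len, n_pvc, n_beats,
                        burden, seq_ppt, threshold_pct,
                        alert=burden >= threshold_pct, partial=partial)


def burden_series(labels: list[BeatLabel], record_span: float,
                  window_len: float = 86400.0,
                  threshold_pct: float = 5.0,
                  anchor: float = 0.0) -> list[BurdenReport]:
    """Consecutive non-overlapping windows from ``anchor``.

    A trailing partial window (if the record span is not a whole multiple
    of the window length) is reported with ``partial=True``.
    """
    if window_len <= 0:
        raise InvalidInputError("window length must be positive")
    if record_span < window_len:
        raise InvalidInputError("record shorter than one full window")
    out = []
    start = anchor
    while start + window_len <= record_span + 1e-9:
        out.append(daily_burden(labels, start, window_len, threshold_pct))
        start += window_len
    if record_span - start > 1e-9:
        rep = daily_burden(labels, start, record_span - start,
                           threshold_pct, partial=True)
        out.append(rep)
    return out
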