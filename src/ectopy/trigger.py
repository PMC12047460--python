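"""Stage 1: interval/amplitude screening of every beat.

Every detected beat is cheaply screened; a beat becomes a PVC candidate
when it is premature relative to the local rhythm or when its peak
amplitude is far outside the range of its neighbours (so non-premature
ectopy and escape beats still reach the morphology stage). Consecutive
candidates are grouped into couplet/triplet sequences; longer runs leave
PVC candidacy (they belong to tachyarrhythmia detection, not ectopy
counting). Candidates whose defining RR intervals touch a noise interval
are dropped, which suppresses false triggers from artifact.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .beat_detection import BeatEvent, NoiseInterval, in_noise
from .config import TriggerConfig

__all__ = ["CandidateEvent", "interval_features", "trigger_scan"]

SEQ_SINGLE, SEQ_COUPLET, SEQ_TRIPLET = "single", "couplet", "triplet"


@dataclass
class CandidateEvent:
    beat: BeatEvent
    index: int                  # position in the beat list
    seq_type: str | None        # single/couplet/triplet; None for long runs
    member_index: int           # 0-based position within its sequence
    rr_prev: float
    rr_next: float
    rr_local_mean: float
    prematurity: float          # rr_prev / rr_local_mean
    amp_ratio: float            # |peak| / mean |neighbour peak|


def interval_features(beats: list[BeatEvent], i: int,
                      rr_local_mean: float) -> tuple[float, float, float, float, float]:
    """RR and amplitude context for interior beat ``i``.

    Boundary beats (first/last) are not evaluable; callers exclude them
    from candidacy.
    """
    if not (1 <= i <= len(beats) - 2):
        raise IndexError("interval features are defined for interior beats only")
    rr_prev = beats[i].time - beats[i - 1].time
    rr_next = beats[i + 1].time - beats[i].time
    prematurity = rr_prev / rr_local_mean
    neigh = 0.5 * (abs(beats[i - 1].peak_amp) + abs(beats[i + 1].peak_amp))
    amp_ratio = abs(beats[i].peak_amp) / neigh if neigh > 0 else 1.0
    return rr_prev, rr_next, rr_local_mean, prematurity, amp_ratio


def trigger_scan(beats: list[BeatEvent], noise: list[NoiseInterval],
                 cfg: TriggerConfig | None = None) -> list[CandidateEvent]:
    """Nominate PVC candidates and tag their sequence type.

    The local RR mean is the mean of the trailing ``rr_history``
    non-candidate RR intervals, so runs of ectopy do not drag the rhythm
    estimate down. Runs of more than ``max_run`` consecutive candidates are
    emitted untagged (``seq_type=None``) and are not counted as PVCs
    downstream.
    """
    cfg = cfg or TriggerConfig()
    n = len(beats)
    if n < 3:
        return []
    rr_all = [beats[k + 1].time - beats[k].time for k in range(n - 1)]
    seed = float(np.median(rr_all[: max(10, cfg.rr_history)]))
    history: deque[float] = deque([seed] * cfg.rr_history, maxlen=cfg.rr_history)

    raw: list[CandidateEvent] = []
    prev_was_candidate = False
    for i in range(1, n - 1):
        rr_local = float(np.mean(history))
        rr_prev, rr_next, _, prematurity, amp_ratio = interval_features(
            beats, i, rr_local)
        is_cand = (prematurity <= cfg.premature_factor
                   or not (cfg.amp_lo <= amp_ratio <= cfg.amp_hi))
        if is_cand and in_noise(beats[i - 1].time, beats[i + 1].time, noise):
            is_cand = False
            prev_was_candidate = False  # noisy context: distrust the pattern
            continue
        if is_cand:
            raw.append(CandidateEvent(
                beat=beats[i], index=i, seq_type=None, member_index=0,
                rr_prev=rr_prev, rr_next=rr_next, rr_local_mean=rr_local,
                prematurity=prematurity, amp_ratio=amp_ratio))
        elif not prev_was_candidate and 0.7 * rr_local <= rr_prev <= 1.3 * rr_local:
            # only plausible intervals with non-candidate endpoints enter the
            # history; the band keeps seed gaps and pauses from inflating it
            history.append(rr_prev)
        prev_was_candidate = is_cand

    # group candidates into sequences: consecutive beat indices joined by a
    # short mutual RR form one block (a couplet/triplet has tightly coupled
    # members; adjacent candidates a full cycle apart — e.g. bigeminy with a
    # spuriously triggered interposed beat — do not merge)
    out: list[CandidateEvent] = []
    k = 0
    while k < len(raw):
        j = k
        while (j + 1 < len(raw)
               and raw[j + 1].index == raw[j].index + 1
               and raw[j + 1].rr_prev <= cfg.seq_rr_factor * raw[j + 1].rr_local_mean):
            j += 1
        block = raw[k : j + 1]
        if len(block) == 1:
            block[0].seq_type, block[0].member_index = SEQ_SINGLE, 0
        elif len(block) == 2:
            for m, c in enumerate(block):
                c.seq_type, c.member_index = SEQ_COUPLET, m
        elif len(block) == 3:
            for m, c in enumerate(block):
                c.seq_type, c.member_index = SEQ_TRIPLET, m
        else:
            for m, c in enumerate(block):
                c.seq_type, c.member_index = None, m  # long run: not PVC candidates
        out.extend(block)
        k = j + 1
    return out
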