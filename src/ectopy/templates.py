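"""Average-NSR QRS template and correlation waveform analysis.

The morphology stage compares each candidate beat against a template formed
from recent normal sinus beats. Similarity is CWA — the mean-removed,
amplitude-normalised correlation at zero lag — and DCWA, its maximum over a
small range of integer alignment shifts, which absorbs fiducial jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beat_detection import BeatEvent
from .config import TemplateConfig
from .errors import InvalidInputError
from .io_signals import EcgSignal

__all__ = ["NsrTemplate", "extract_window", "form_template", "cwa", "dcwa"]


@dataclass
class NsrTemplate:
    """Averaged NSR QRS window, fiducial-centered, in μV."""

    window: np.ndarray
    formed_at: float = 0.0
    n_beats_used: int = 0
    valid: bool = False

    def __len__(self) -> int:
        return len(self.window)


def window_length(fs: float, window_s: float = 0.200) -> int:
    """Odd sample count spanning ``window_s`` at rate ``fs``."""
    L = int(round(window_s * fs))
    return L + 1 - (L % 2)


def extract_window(signal: EcgSignal, t: float, length: int) -> np.ndarray | None:
    """Length-``length`` window centered on time ``t``; None at record edges."""
    c = signal.time_to_index(t)
    half = length // 2
    lo, hi = c - half, c + half + 1
    if lo < 0 or hi > signal.samples.size:
        return None
    return signal.samples[lo:hi]


def form_template(signal: EcgSignal, beats: list[BeatEvent], at_time: float,
                  cfg: TemplateConfig | None = None) -> NsrTemplate:
    """Attempt template formation from beats preceding ``at_time``.

    The most recent ``k_beats`` beats qualify if (a) both adjacent RR
    intervals are within ``rr_tol`` of the local median RR — which rejects
    premature beats and post-ectopic pauses — and (b) their correlation with
    the running mean stays above ``min_corr`` — which rejects morphology
    outliers. Fewer than ``n_min`` qualifiers leaves the template invalid;
    an invalid template is a legal state ("attempted", not guaranteed).
    """
    cfg = cfg or TemplateConfig()
    L = window_length(signal.fs, cfg.window_s)
    prior = [b for b in beats if b.time <= at_time]
    if len(prior) < 3:
        return NsrTemplate(window=np.zeros(L), formed_at=at_time)
    times = np.array([b.time for b in prior])
    rr = np.diff(times)
    # local median over the trailing stretch the template draws from
    tail = rr[-(4 * cfg.k_beats):]
    med = float(np.median(tail))
    acc: np.ndarray | None = None
    used = 0
    # walk backwards from the most recent interior beat
    for i in range(len(prior) - 2, 0, -1):
        if used >= cfg.k_beats:
            break
        rr_prev, rr_next = rr[i - 1], rr[i]
        if abs(rr_prev - med) > cfg.rr_tol * med:
            continue
        if abs(rr_next - med) > cfg.rr_tol * med:
            continue
        w = extract_window(signal, prior[i].time, L)
        if w is None:
            continue
        if acc is not None and used >= 2:
            if _pearson(w, acc / used) < cfg.min_corr:
                continue
        acc = w.astype(float).copy() if acc is None else acc + w
        used += 1
    if used < cfg.n_min or acc is None:
        return NsrTemplate(window=np.zeros(L), formed_at=at_time,
                           n_beats_used=used, valid=False)
    return NsrTemplate(window=acc / used, formed_at=at_time,
                       n_beats_used=used, valid=True)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def cwa(beat_window: np.ndarray, template: NsrTemplate | np.ndarray) -> float:
    """Correlation waveform analysis score at zero lag, in [-1, 1].

    Zero variance in either vector scores 0 (no morphology information).
    """
    tmpl = template.window if isinstance(template, NsrTemplate) else np.asarray(template)
    beat_window = np.asarray(beat_window, dtype=float)
    if beat_window.shape != tmpl.shape:
        raise InvalidInputError(
            f"window length {len(beat_window)} != template length {len(tmpl)}")
    return _pearson(beat_window, np.asarray(tmpl, dtype=float))


def dcwa(beat_window: np.ndarray, template: NsrTemplate | np.ndarray,
         max_shift: int = 10) -> tuple[float, int]:
    """Dynamic CWA: best overlap correlation over integer shifts.

    A positive shift means the beat window's content is later than the
    template's, i.e. the template is compared against ``window[s:]``. Ties
    resolve to the smallest |shift|, then to the negative shift. Always
    >= the zero-lag CWA since shift 0 is in the search set.
    """
    if max_shift < 0:
        raise InvalidInputError("max_shift must be >= 0")
    tmpl = template.window if isinstance(template, NsrTemplate) else np.asarray(template)
    beat_window = np.asarray(beat_window, dtype=float)
    if beat_window.shape != np.asarray(tmpl).shape:
        raise InvalidInputError(
            f"window length {len(beat_window)} != template length {len(tmpl)}")
    L = len(tmpl)
    best = (-np.inf, 0)
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), -(s < 0))):
        if s >= 0:
            score = _pearson(beat_window[s:L], np.asarray(tmpl[: L - s], dtype=float))
        else:
            score = _pearson(beat_window[: L + s], np.asarray(tmpl[-s:], dtype=float))
        if score > best[0]:
            best = (score, s)
    return best
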