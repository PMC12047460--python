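"""Record I/O, signal preconditioning and amplitude quality control.

All amplitudes are carried internally in microvolts and all times in
seconds from record start; WFDB sample indices and physical units are
converted at the boundary.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from . import _wfdb
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "EcgSignal", "ReferenceAnnotation", "BEAT_SYMBOLS", "aami_class",
    "read_record", "write_record", "preprocess", "amplitude_qc",
    "annotations_to_csv", "annotations_from_csv",
]

# WFDB mnemonics that denote beats, and their five-class grouping used in
# beat-by-beat scoring (normal / supraventricular / ventricular / fusion /
# unclassifiable).
_AAMI_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}
BEAT_SYMBOLS = frozenset(_AAMI_MAP)


def aami_class(symbol: str) -> str:
    """Map a WFDB beat mnemonic onto {N, S, V, F, Q}; 'other' for non-beats."""
    return _AAMI_MAP.get(symbol, "other")


@dataclass
class EcgSignal:
    """Uniformly sampled single-lead voltage trace.

    samples are μV; time of sample i is ``t0 + i / fs``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    lead_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise InvalidInputError("sampling rate must be positive")
        if self.samples.size < 1:
            raise InvalidInputError("signal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def time_to_index(self, t: float) -> int:
        return int(round((t - self.t0) * self.fs))

    def index_to_time(self, i: int) -> float:
        return self.t0 + i / self.fs


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Adjudicated beat (or event) marker: time in seconds + WFDB symbol."""

    time: float
    symbol: str

    @property
    def aami(self) -> str:
        return aami_class(self.symbol)

    @property
    def is_beat(self) -> bool:
        return self.symbol in BEAT_SYMBOLS


def read_record(path: str, lead_selector: str = "") -> tuple[EcgSignal, list[ReferenceAnnotation]]:
    """Read a WFDB record and its beat annotations.

    Parameters
    ----------
    path
        Record path with or without the ``.hea`` extension.
    lead_selector
        Channel description to select (e.g. ``"MLII"``). Empty selects the
        first channel of a single-channel record, otherwise it is required.

    Returns
    -------
    The selected channel converted to μV, and all annotations (beat and
    non-beat) with times in seconds, in record order.
    """
    stem = path[:-4] if path.endswith(".hea") else path
    hea = stem + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"no WFDB header at {hea}")
    hdr, phys = _wfdb.read_signals(hea)
    labels = [s.description or f"ch{i}" for i, s in enumerate(hdr.signals)]
    if lead_selector:
        if lead_selector not in labels:
            raise ConfigurationError(
                f"lead {lead_selector!r} not in record; available: {labels}")
        ch = labels.index(lead_selector)
    elif hdr.n_sig == 1:
        ch = 0
    else:
        raise ConfigurationError(
            f"record has {hdr.n_sig} channels; choose one of {labels}")
    spec = hdr.signals[ch]
    scale = {"mV": 1000.0, "uV": 1.0, "V": 1e6}.get(spec.units, 1000.0)
    sig = EcgSignal(samples=phys[:, ch] * scale, fs=hdr.fs, t0=0.0,
                    lead_label=labels[ch])
    annotations: list[ReferenceAnnotation] = []
    atr = stem + ".atr"
    if os.path.exists(atr):
        annotations = [ReferenceAnnotation(time=s / hdr.fs, symbol=sym)
                       for s, sym in _wfdb.read_annotations(atr)]
    return sig, annotations


def write_record(path_stem: str, signal: EcgSignal,
                 annotations: list[ReferenceAnnotation] | None = None) -> None:
    """Write a single-channel WFDB record (format 16) plus ``.atr`` file."""
    ann = None
    if annotations is not None:
        ann = [(int(round((a.time - signal.t0) * signal.fs)), a.symbol)
               for a in annotations]
    _wfdb.write_record(path_stem, signal.samples, signal.fs,
                       lead_label=signal.lead_label or "ECG",
                       annotations=ann)


def preprocess(signal: EcgSignal, band_lo: float = 0.5, band_hi: float = 40.0,
               target_fs: float = 256.0) -> EcgSignal:
    """Band-pass and resample onto the working rate.

    Filtering is zero-phase (forward-backward second-order sections), so
    fiducials do not shift. ``band_lo = 0`` degenerates to a pure low-pass.
    """
    if not (0 <= band_lo < band_hi < target_fs / 2):
        raise ConfigurationError(
            f"need 0 <= band_lo < band_hi < target_fs/2; got "
            f"({band_lo}, {band_hi}) at {target_fs} Hz")
    x = signal.samples
    fs = signal.fs
    if abs(fs - target_fs) > 1e-9:
        frac = Fraction(target_fs / fs).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
        fs = fs * frac.numerator / frac.denominator
    nyq = fs / 2
    if band_lo > 0:
        sos = sps.butter(2, [band_lo / nyq, band_hi / nyq], btype="bandpass",
                         output="sos")
    else:
        sos = sps.butter(2, band_hi / nyq, btype="lowpass", output="sos")
    x = sps.sosfiltfilt(sos, x)
    return EcgSignal(samples=x, fs=fs, t0=signal.t0,
                     lead_label=signal.lead_label)


def amplitude_qc(signal: EcgSignal, beats, min_mean_r_uv: float = 100.0,
                 half_window_s: float = 0.050) -> tuple[bool, float]:
    """Mean absolute R amplitude over beats; pass iff >= ``min_mean_r_uv``.

    Mirrors the episode-level screening rule that rejects records whose mean
    R-wave amplitude falls below 100 μV. ``beats`` may be BeatEvents or bare
    times in seconds.
    """
    if len(beats) == 0:
        raise InvalidInputError("amplitude QC requires at least one beat")
    half = max(1, int(round(half_window_s * signal.fs)))
    n = signal.samples.size
    amps = []
    for b in beats:
        t = getattr(b, "time", b)
        i = signal.time_to_index(t)
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if lo < hi:
            amps.append(float(np.max(np.abs(signal.samples[lo:hi]))))
    mean_amp = float(np.mean(amps))
    return mean_amp >= min_mean_r_uv, mean_amp


def annotations_to_csv(path: str, annotations: list[ReferenceAnnotation]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "symbol"])
        for a in annotations:
            w.writerow([f"{a.time:.6f}", a.symbol])


def annotations_from_csv(path: str) -> list[ReferenceAnnotation]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(ReferenceAnnotation(time=float(row["time_s"]),
                                           symbol=row["symbol"]))
    return out
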