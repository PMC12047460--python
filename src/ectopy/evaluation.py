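"""Beat-by-beat and patient-level scoring of ectopy detections.

Detections are matched to adjudicated PVC locations one-to-one within a
±150 ms tolerance. References carrying ambiguous symbols (fusion beats by
default) are excluded from both the sensitivity and PPV pools. Specificity
is the *modified* form normalised by detected beats rather than adjudicated
normal beats, because beat sensing is treated as validated separately;
the classical form is available behind a flag. Cluster-adjusted marginal
metrics use generalized estimating equations with a binomial link and
exchangeable working correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "MatchResult", "MetricSet", "GeeResult",
    "match", "beat_metrics", "patient_average", "gee_adjusted",
    "burden_agreement", "threshold_metrics", "f1_score",
]

NAN = float("nan")


@dataclass
class MatchResult:
    tolerance: float
    tp: list[tuple[float, float]] = field(default_factory=list)  # (det, ref)
    fp: list[float] = field(default_factory=list)                # unmatched detections
    fn: list[float] = field(default_factory=list)                # unmatched references
    excluded: list[float] = field(default_factory=list)          # dets absorbed by ambiguous refs

    @property
    def n_tp(self) -> int:
        return len(self.tp)

    @property
    def n_fp(self) -> int:
        return len(self.fp)

    @property
    def n_fn(self) -> int:
        return len(self.fn)


@dataclass
class MetricSet:
    sensitivity: float = NAN
    specificity: float = NAN
    ppv: float = NAN
    f1: float = NAN
    level: str = "gross"
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * getattr(self, k)
                for k in ("sensitivity", "specificity", "ppv", "f1")}


@dataclass
class GeeResult:
    estimate: float
    ci95: tuple[float, float]
    degenerate: bool = False


def f1_score(sensitivity: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and positive predictive value."""
    if math.isnan(sensitivity) or math.isnan(ppv) or sensitivity + ppv == 0:
        return NAN
    return 2.0 * sensitivity * ppv / (sensitivity + ppv)


def match(detections, references, tolerance: float = 0.150,
          excluded_references=()) -> MatchResult:
    """Optimal one-to-one nearest-in-time matching within ``tolerance``.

    Solves the small assignment problem exactly: among pairings with
    |Δt| <= tolerance, the matched-pair count is maximised first and the
    total |Δt| minimised second. (A purely greedy closest-first scan can
    lose a match when one detection's best reference is another
    detection's only reference; the exact solution never does.)
    Detections left over that fall within tolerance of an excluded
    (ambiguous) reference are removed from the FP pool, and excluded
    references never count as FN.
    """
    from scipy.optimize import linear_sum_assignment

    det = sorted(float(getattr(d, "time", d)) for d in detections)
    ref = sorted(float(getattr(r, "time", r)) for r in references)
    excl = sorted(float(getattr(r, "time", r)) for r in excluded_references)

    res = MatchResult(tolerance=tolerance)
    matched_d: set[int] = set()
    matched_r: set[int] = set()
    if det and ref:
        d_arr = np.asarray(det)[:, None]
        r_arr = np.asarray(ref)[None, :]
        dt = np.abs(d_arr - r_arr)
        big = 1e9  # dwarfs any feasible total |Δt|, so valid pairs win first
        cost = np.where(dt <= tolerance, dt, big)
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < big:
                matched_d.add(i)
                matched_r.add(j)
                res.tp.append((det[i], ref[j]))
    res.tp.sort()
    res.fn = [r for j, r in enumerate(ref) if j not in matched_r]
    for i, d in enumerate(det):
        if i in matched_d:
            continue
        if any(abs(d - e) <= tolerance for e in excl):
            res.excluded.append(d)
        else:
            res.fp.append(d)
    return res


def beat_metrics(m: MatchResult, n_detected_beats: int,
                 classical_specificity_n_normal: int | None = None) -> MetricSet:
    """Gross beat-level metrics from one match result.

    Modified specificity treats every detected beat that is neither a true
    PVC nor labelled PVC as a true negative:
    ``TN* = n_detected_beats - TP - FP - FN``. (In bypass mode every
    reference PVC corresponds to a detected beat, so undetected-FN
    corrections vanish.) Passing ``classical_specificity_n_normal``
    switches the denominator to adjudicated normal beats instead.
    """
    tp, fp, fn = m.n_tp, m.n_fp, m.n_fn
    if n_detected_beats < tp + fp:
        raise InvalidInputError("detected-beat count below TP+FP")
    sens = tp / (tp + fn) if tp + fn > 0 else NAN
    ppv = tp / (tp + fp) if tp + fp > 0 else NAN
    f1 = f1_score(sens, ppv)
    if tp == 0 and fn + fp > 0:
        f1 = 0.0  # no hits against a non-empty problem is a zero score
    if classical_specificity_n_normal is not None:
        tn = classical_specificity_n_normal - fp
    else:
        tn = n_detected_beats - tp - fp - fn
    spec = tn / (tn + fp) if tn + fp > 0 else NAN
    return MetricSet(sensitivity=sens, specificity=spec, ppv=ppv,
                     f1=f1, level="gross")


def patient_average(per_patient: list[MetricSet]) -> MetricSet:
    """Unweighted mean of each metric over patients with defined values."""
    if not per_patient:
        raise InvalidInputError("need at least one patient")
    out = MetricSet(level="patient_average")
    for name in ("sensitivity", "specificity", "ppv", "f1"):
        vals = [getattr(p, name) for p in per_patient
                if not math.isnan(getattr(p, name))]
        setattr(out, name, float(np.mean(vals)) if vals else NAN)
    return out


def gee_adjusted(per_patient: list[tuple[int, int]]) -> GeeResult:
    """Marginal proportion under an intercept-only exchangeable GEE.

    ``per_patient`` holds (successes, trials) per cluster. The estimate is
    back-transformed from the logit scale; the 95% CI uses robust
    (sandwich) standard errors. All-zero or all-one outcomes give a
    degenerate result with the observed proportion and NaN CI.
    """
    import statsmodels.api as sm

    if len(per_patient) < 2:
        raise InvalidInputError("GEE adjustment needs at least 2 clusters")
    if any(t < 1 or s < 0 or s > t for s, t in per_patient):
        raise InvalidInputError("need 0 <= successes <= trials, trials >= 1")
    total_s = sum(s for s, _ in per_patient)
    total_t = sum(t for _, t in per_patient)
    if total_s == 0 or total_s == total_t:
        return GeeResult(estimate=total_s / total_t, ci95=(NAN, NAN),
                         degenerate=True)
    y, groups = [], []
    for g, (s, t) in enumerate(per_patient):
        y.extend([1] * s + [0] * (t - s))
        groups.extend([g] * t)
    y = np.asarray(y, dtype=float)
    X = np.ones((len(y), 1))
    model = sm.GEE(y, X, groups=np.asarray(groups),
                   family=sm.families.Binomial(),
                   cov_struct=sm.cov_struct.Exchangeable())
    fit = model.fit()
    b = float(fit.params[0])
    se = float(fit.bse[0])
    expit = lambda z: 1.0 / (1.0 + np.exp(-z))
    return GeeResult(estimate=float(expit(b)),
                     ci95=(float(expit(b - 1.96 * se)),
                           float(expit(b + 1.96 * se))))


def burden_agreement(est, ref) -> tuple[float, float, tuple[float, float]]:
    """Pearson r, mean bias (est − ref, percentage points) and 95% limits
    of agreement (bias ± 1.96·SD of the paired differences)."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.size < 3:
        raise InvalidInputError("need equal-length burden lists, n >= 3")
    diff = est - ref
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    if np.std(est) == 0 or np.std(ref) == 0:
        return NAN, bias, loa
    r = float(stats.pearsonr(est, ref)[0])
    return r, bias, loa


def threshold_metrics(est, ref, threshold_pct: float
                      ) -> tuple[float, float, float]:
    """Patient-level sensitivity/specificity/PPV for elevated-burden
    screening: a patient is called positive when the estimated burden
    meets ``threshold_pct``, and truly positive when the reference does."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise InvalidInputError("burden lists must have equal length")
    pred = est >= threshold_pct
    true = ref >= threshold_pct
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    sens = tp / (tp + fn) if tp + fn > 0 else NAN
    spec = tn / (tn + fp) if tn + fp > 0 else NAN
    ppv = tp / (tp + fp) if tp + fp > 0 else NAN
    return sens, spec, ppv
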