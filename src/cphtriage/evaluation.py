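"""ROC/AUC machinery for comparing triage scores as mortality discriminators.

AUC is computed by pair counting (Mann-Whitney; ties count one half) and
its standard error by DeLong's structural-components method, which also
supplies the paired test for two correlated AUCs measured on the same
encounters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ROCResult", "auc", "compare_auc_paired", "roc_curve"]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    n_pos: int
    n_neg: int


def _check_inputs(scores, outcomes):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be equal-length 1-d vectors")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("both outcome classes must be present")
    return s, y


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")

def _structural_components(s: np.ndarray, y: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = pos.size, neg.size
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    v10 = (tz[:m] - tx) / n                    # P(X > Y) + 0.5 P(X = Y) per death
    v01 = 1.0 - (tz[m:] - ty) / m              # same, per survivor
    return v10, v01


def auc(scores, outcomes) -> ROCResult:
    """Mann-Whitney AUC with DeLong standard error.

    AUC is the probability that a randomly chosen death scores strictly
    higher than a randomly chosen survivor, with ties counted one half.
    """
    s, y = _check_inputs(scores, outcomes)
    v10, v01 = _structural_components(s, y)
    m, n = v10.size, v01.size
    a = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    return ROCResult(auc=a, se=se, n_pos=m, n_neg=n)


def compare_auc_paired(scores_a, scores_b, outcomes) -> dict[str, float]:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be measured on the same encounters.  Returns
    the AUC difference (a minus b), its standard error, the z statistic
    and the two-sided normal p-value.  Identical scores give delta 0 and
    p = 1.
    """
    sa, y = _check_inputs(scores_a, outcomes)
    sb, yb = _check_inputs(scores_b, outcomes)
    if sa.size != sb.size:
        raise ValueError("scores_a and scores_b length mismatch")
    if not np.array_equal(y, yb):
        raise ValueError("outcomes differ between the two score vectors")
    va10, va01 = _structural_components(sa, y)
    vb10, vb01 = _structural_components(sb, y)
    m, n = va10.size, va01.size
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    delta = auc_a - auc_b
    if m > 1 and n > 1:
        s10 = np.cov(np.vstack([va10, vb10]))
        s01 = np.cov(np.vstack([va01, vb01]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        var = 0.0
    var = max(var, 0.0)
    if var == 0.0:
        z = 0.0 if delta == 0.0 else np.inf * np.sign(delta)
    else:
        z = delta / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return {"auc_a": auc_a, "auc_b": auc_b, "delta_auc": delta,
            "se": float(np.sqrt(var)), "z": float(z), "p": p}


def roc_curve(scores, outcomes) -> list[tuple[float, float]]:
    """ROC points (fpr, tpr), one per distinct threshold, incl. (0,0), (1,1).

    The trapezoidal area under the returned polyline equals the
    pair-counting AUC (ties contribute the diagonal segments exactly).
    """
    from sklearn.metrics import roc_curve as _sk_roc

    s, y = _check_inputs(scores, outcomes)
    fpr, tpr, _ = _sk_roc(y, s, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))
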