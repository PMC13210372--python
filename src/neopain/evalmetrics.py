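"""Evaluation metrics: ordinal agreement, calibration, and
abstention-aware (selective) reporting.

Quadratic weighted kappa (QWK) is the chance-corrected agreement for the
4-level ordinal pain scale: ``QWK = 1 - sum(W*O) / sum(W*E)`` with weights
``W_ij = (i-j)^2 / (K-1)^2``, observed counts O and expected counts E from
the product of marginals scaled to n. Calibration uses 15 equal-width bins
on the predicted class's probability (ECE/MCE) and the multiclass
sum-of-squares Brier score. Selective metrics report coverage (fraction of
non-abstained cases) and the metric panel on the covered subset.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import ValidationError

K_CLASSES = 4
_QWK_W = (np.subtract.outer(np.arange(4), np.arange(4)) ** 2) / 9.0


def qwk(y_true, y_pred) -> float:
    """Quadratic weighted kappa in [-1, 1]; 1.0 for perfect (or degenerate
    equal-constant) agreement."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred) or len(y_true) < 1:
        raise ValidationError("labels", "equal non-zero lengths required")
    if np.any((y_true < 0) | (y_true > 3) | (y_pred < 0) | (y_pred > 3)):
        raise ValidationError("labels", "labels must lie in {0..3}")
    n = len(y_true)
    O = np.zeros((4, 4))
    np.add.at(O, (y_true, y_pred), 1.0)
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / n
    denom = (_QWK_W * E).sum()
    if denom == 0.0:
        return 1.0
    return float(1.0 - (_QWK_W * O).sum() / denom)


def _check_simplex(probabilities: np.ndarray) -> np.ndarray:
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != K_CLASSES:
        raise ValidationError("probabilities", f"expected (n, {K_CLASSES})")
    if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValidationError("probabilities", "rows must lie on the simplex")
    return p


def _binned_calibration(probabilities, labels, n_bins: int):
    p = _check_simplex(probabilities)
    y = np.asarray(labels, dtype=int)
    conf = p.max(axis=1)
    pred = p.argmax(axis=1)
    correct = (pred == y).astype(np.float64)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(conf, edges[1:-1]), 0, n_bins - 1)
    gaps, weights = [], []
    for b in range(n_bins):
        m = which == b
        if not m.any():
            continue
        gaps.append(abs(correct[m].mean() - conf[m].mean()))
        weights.append(m.mean())
    return np.array(gaps), np.array(weights)


def ece(probabilities, labels, n_bins: int = 15) -> float:
    """Expected calibration error: bin-weighted |accuracy - confidence|
    over equal-width confidence bins (empty bins contribute 0)."""
    gaps, weights = _binned_calibration(probabilities, labels, n_bins)
    return float((gaps * weights).sum()) if len(gaps) else 0.0


def mce(probabilities, labels, n_bins: int = 15) -> float:
    """Maximum calibration error across non-empty bins."""
    gaps, _ = _binned_calibration(probabilities, labels, n_bins)
    return float(gaps.max()) if len(gaps) else 0.0


def brier(probabilities, labels) -> float:
    """Multiclass sum-of-squares Brier score (mean over samples)."""
    p = _check_simplex(probabilities)
    onehot = np.eye(K_CLASSES)[np.asarray(labels, dtype=int)]
    return float(((p - onehot) ** 2).sum(axis=1).mean())


def accuracy(y_true, y_pred) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


def f1_macro(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    f1s = []
    for c in range(K_CLASSES):
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        if tp + fp + fn == 0:
            continue
        f1s.append(2 * tp / (2 * tp + fp + fn))
    return float(np.mean(f1s)) if f1s else float("nan")


def per_class_panel(y_true, y_pred) -> dict:
    """One-vs-rest sensitivity / specificity / PPV / NPV per pain level."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    panel = {}
    for c in range(K_CLASSES):
        tp = float(np.sum((y_pred == c) & (y_true == c)))
        fp = float(np.sum((y_pred == c) & (y_true != c)))
        fn = float(np.sum((y_pred != c) & (y_true == c)))
        tn = float(np.sum((y_pred != c) & (y_true != c)))
        panel[f"level_{c}"] = {
            "sensitivity": tp / (tp + fn) if tp + fn else None,
            "specificity": tn / (tn + fp) if tn + fp else None,
            "ppv": tp / (tp + fp) if tp + fp else None,
            "npv": tn / (tn + fn) if tn + fn else None,
        }
    return panel


@dataclass
class EvalReport:
    """Full metric panel with abstention-aware coverage."""

    accuracy: float | None
    f1_macro: float | None
    qwk: float | None
    ece: float | None
    mce: float | None
    brier: float | None
    coverage: float
    selective_accuracy: float | None
    per_class: dict | None

    def to_dict(self) -> dict:
        return asdict(self)


def selective_report(pred_levels, abstained, labels,
                     probabilities=None) -> EvalReport:
    """Metric panel on non-abstained cases plus coverage.

    ``pred_levels`` may hold None (or any placeholder) where ``abstained``
    is True. With zero covered cases all selective metrics are None and
    coverage is 0.
    """
    abstained = np.asarray(abstained, dtype=bool)
    labels = np.asarray(labels, dtype=int)
    covered = ~abstained
    coverage = float(covered.mean()) if len(abstained) else 0.0
    if not covered.any():
        return EvalReport(accuracy=None, f1_macro=None, qwk=None, ece=None,
                          mce=None, brier=None, coverage=0.0,
                          selective_accuracy=None, per_class=None)
    yp = np.array([int(v) for v, a in zip(pred_levels, abstained) if not a])
    yt = labels[covered]
    cal = {}
    if probabilities is not None:
        p = np.asarray(probabilities, dtype=np.float64)[covered]
        cal = {"ece": ece(p, yt), "mce": mce(p, yt), "brier": brier(p, yt)}
    acc = accuracy(yt, yp)
    return EvalReport(accuracy=acc, f1_macro=f1_macro(yt, yp),
                      qwk=qwk(yt, yp), ece=cal.get("ece"), mce=cal.get("mce"),
                      brier=cal.get("brier"), coverage=coverage,
                      selective_accuracy=acc,
                      per_class=per_class_panel(yt, yp))


def risk_coverage_curve(u_values, pred_levels, labels,
                        taus=None) -> list[dict]:
    """Selective accuracy and coverage as the abstention threshold varies."""
    u = np.asarray(u_values, dtype=np.float64)
    yp = np.asarray(pred_levels, dtype=int)
    yt = np.asarray(labels, dtype=int)
    taus = np.linspace(0.05, 1.0, 20) if taus is None else np.asarray(taus)
    curve = []
    for tau in taus:
        covered = u <= tau
        curve.append({
            "tau": float(tau),
            "coverage": float(covered.mean()),
            "selective_accuracy": (float(np.mean(yp[covered] == yt[covered]))
                                   if covered.any() else None),
        })
    return curve
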