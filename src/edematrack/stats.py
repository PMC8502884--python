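"""ROC/AUC/Youden diagnostics, paired Wilcoxon signed-rank test, and the
barycentric (ternary) projection of the NODDI volume fractions.

Also ships the packaged clinical fixture: per-patient edema volume, LTD and
motor-decline label for the 24-patient cohort.

Conventions
-----------
ROC orientation is always explicit: ``direction='greater'`` means the
positive class is expected to have *larger* values.  The AUC is the
Mann-Whitney probability P(X_pos > X_neg) + 0.5 P(=), which equals the
trapezoidal integral of the empirical ROC curve.  At a threshold t,
sensitivity is the fraction of the positive class strictly above t and
specificity the fraction of the negative class at or below t (mirrored for
``direction='less'``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ParameterError, ValidationError

__all__ = [
    "load_table1",
    "RocResult",
    "roc",
    "sens_spec_at",
    "youden",
    "wilcoxon_signed_rank",
    "ternary_coordinates",
    "plot_ternary",
]


def load_table1() -> pd.DataFrame:
    """The packaged 24-patient clinical fixture (edema volume, LTD, label)."""
    with resources.files("edematrack.data").joinpath("table1_patients.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def _validate(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ParameterError("values and labels must be equal-length 1D")
    if labels.all() or not labels.any():
        raise ParameterError("both classes must be non-empty")
    return values, labels


@dataclass
class RocResult:
    """Empirical ROC curve with Mann-Whitney AUC and the Youden optimum."""

    thresholds: np.ndarray  # candidate cutoffs: value midpoints plus +/-inf
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_j: float
    direction: str

    def summary(self) -> str:
        return (
            "ROC analysis\n"
            "============\n"
            f"direction        : positive class has {self.direction} values\n"
            f"AUC              : {self.auc:.4f}\n"
            f"Youden threshold : {self.youden_threshold:.6g}\n"
            f"Youden J         : {self.youden_j:.4f}"
        )


def sens_spec_at(values, labels, threshold: float, direction: str = "greater"):
    """(sensitivity, specificity) at a given cutoff.

    For ``direction='greater'``: sensitivity = P(positive value > t),
    specificity = P(negative value <= t); mirrored for ``'less'``.
    """
    values, labels = _validate(values, labels)
    pos, neg = values[labels], values[~labels]
    if direction == "greater":
        return float((pos > threshold).mean()), float((neg <= threshold).mean())
    if direction == "less":
        return float((pos < threshold).mean()), float((neg >= threshold).mean())
    raise ParameterError("direction must be 'greater' or 'less'")


def roc(values, labels, direction: str = "greater") -> RocResult:
    """Empirical ROC curve; AUC as the Mann-Whitney statistic (ties 0.5)."""
    values, labels = _validate(values, labels)
    if direction not in ("greater", "less"):
        raise ParameterError("direction must be 'greater' or 'less'")
    v = values if direction == "greater" else -values
    pos, neg = v[labels], v[~labels]
    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0) / (
        len(pos) * len(neg)
    )
    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thr = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(pos > t).mean() for t in thr])
    spec = np.array([(neg <= t).mean() for t in thr])
    j = sens + spec - 1.0
    # tie-break: max J, then higher specificity, then smaller threshold
    order = np.lexsort((thr, -spec, -j))
    best = order[0]
    out_thr = thr if direction == "greater" else -thr
    return RocResult(
        thresholds=out_thr,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        youden_threshold=float(out_thr[best]),
        youden_j=float(j[best]),
        direction=direction,
    )


def youden(r: RocResult) -> tuple[float, float]:
    """The Youden-optimal cutoff and J = max_t {sens(t) + spec(t) - 1}."""
    return r.youden_threshold, r.youden_j


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test.

    Returns (W, two-sided p) with W the smaller of the positive/negative
    rank sums over the non-zero differences (average ranks for tied |d|).
    The p-value is exact (enumeration of all 2^n sign patterns) for
    n <= 12, otherwise a normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1D")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ParameterError("all paired differences are zero")
    if n < 5:
        raise ParameterError("need >= 5 non-zero differences")
    ranks = rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    w = min(w_pos, w_neg)
    if n <= 12:
        # exact: enumerate every sign assignment of the ranked |d|
        count = 0
        total = 2**n
        for signs in product((0, 1), repeat=n):
            s = sum(r for r, take in zip(ranks, signs) if take)
            s = min(s, ranks.sum() - s)
            if s <= w + 1e-12:
                count += 1
        p = count / total
    else:
        mean = n * (n + 1) / 4.0
        tie_term = 0.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        from scipy.stats import norm

        z = (w - mean + 0.5) / np.sqrt(var)  # continuity-corrected
        p = 2.0 * norm.cdf(z)
    return float(w), float(min(p, 1.0))


_V_IC = np.array([0.0, 0.0])
_V_EC = np.array([1.0, 0.0])
_V_ISO = np.array([0.5, np.sqrt(3.0) / 2.0])


def ternary_coordinates(vf_ic, vf_ec, vf_iso) -> np.ndarray:
    """Barycentric embedding of (VF_ic, VF_ec, VF_iso) onto the unit
    triangle with vertices VF_ic=(0,0), VF_ec=(1,0), VF_iso=(1/2, sqrt3/2)."""
    f = np.stack(
        np.broadcast_arrays(
            np.asarray(vf_ic, float), np.asarray(vf_ec, float), np.asarray(vf_iso, float)
        ),
        axis=-1,
    )
    if np.any(f < -1e-9):
        raise ValidationError("volume fractions must be non-negative")
    if np.any(np.abs(f.sum(axis=-1) - 1.0) > 1e-6):
        raise ValidationError("volume fractions must sum to 1")
    verts = np.stack([_V_IC, _V_EC, _V_ISO])  # (3, 2)
    return f @ verts


def plot_ternary(points_by_group: dict[str, np.ndarray], ax=None):
    """Scatter fraction triplets (rows of (vf_ic, vf_ec, vf_iso)) on the
    barycentric triangle, one color per group.  Returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    tri = np.stack([_V_IC, _V_EC, _V_ISO, _V_IC])
    ax.plot(tri[:, 0], tri[:, 1], color="0.3", lw=1)
    for name, xy in (("VF_ic", _V_IC), ("VF_ec", _V_EC), ("VF_iso", _V_ISO)):
        ax.annotate(name, xy, textcoords="offset points", xytext=(0, 5), ha="center")
    for label, fracs in points_by_group.items():
        fracs = np.atleast_2d(np.asarray(fracs, float))
        xy = ternary_coordinates(fracs[:, 0], fracs[:, 1], fracs[:, 2])
        ax.scatter(xy[:, 0], xy[:, 1], s=18, label=label, alpha=0.8)
    ax.legend(loc="upper right", frameon=False)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
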