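"""Inter-rater agreement statistics for ordinal scores.

Cohen's kappa with its large-sample standard error and Wald 95% CI,
quadratic weighted kappa (agreement weights 1 - (i-j)^2/(k-1)^2, i.e. weight
0 at the maximal disagreement), Spearman rank correlation with a
t-approximation p-value and Fisher-z CI, and the Landis-Koch verbal
interpretation of kappa magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DegenerateAgreementError",
    "AgreementReport",
    "contingency_table",
    "cohens_kappa",
    "quadratic_weighted_kappa",
    "spearman",
    "landis_koch",
    "agreement_report",
    "format_report",
]


class DegenerateAgreementError(ValueError):
    """Raised when agreement is undefined (e.g. constant raters that disagree)."""


@dataclass
class AgreementReport:
    """Agreement summary between two raters on a common ordinal scale."""

    n: int
    kappa: float
    se: float
    ci95: tuple
    weighted_kappa: float
    weighted_se: float
    spearman_rho: float
    spearman_p: float
    rho_ci95: tuple
    landis_koch: str

    def __post_init__(self):
        assert -1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12
        assert self.ci95[0] <= self.ci95[1]


def _as_pairs(a, b=None):
    if b is None:
        arr = np.asarray(list(a))
        a, b = arr[:, 0], arr[:, 1]
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be two equal-length 1-D sequences")
    return a, b


def contingency_table(a, b, categories=None):
    """k x k table of joint rating counts over an explicit category set."""
    a, b = _as_pairs(a, b)
    if categories is None:
        categories = np.unique(np.concatenate([a, b]))
    categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    bad = [x for x in np.concatenate([a, b]) if x not in index]
    if bad:
        raise ValueError(f"ratings outside the category set: {sorted(set(bad))}")
    k = len(categories)
    table = np.zeros((k, k), dtype=float)
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    return table, categories


def cohens_kappa(a, b=None, categories=None):
    """Cohen's kappa with large-sample SE and Wald 95% CI.

    Returns (kappa, se, (lo, hi)).  If both raters are constant, kappa is 1
    when they agree everywhere and undefined (raises) otherwise.
    """
    a, b = _as_pairs(a, b)
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 rating pairs")
    table, _ = contingency_table(a, b, categories)
    p = table / n
    po = float(np.trace(p))
    row, col = p.sum(axis=1), p.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0 - 1e-12:
        if po >= 1.0 - 1e-12:
            return 1.0, 0.0, (1.0, 1.0)
        raise DegenerateAgreementError(
            "both raters constant but not identical; kappa undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    se = float(np.sqrt(max(po * (1.0 - po), 0.0) / (n * (1.0 - pe) ** 2)))
    ci = (kappa - 1.96 * se, kappa + 1.96 * se)
    return float(kappa), se, ci


def _quadratic_weights(k: int) -> np.ndarray:
    i = np.arange(k)
    return 1.0 - (i[:, None] - i[None, :]) ** 2 / (k - 1) ** 2


def quadratic_weighted_kappa(a, b=None, categories=None):
    """Quadratic weighted kappa with the Fleiss-Cohen-Everitt large-sample SE.

    Agreement weights are w_ij = 1 - (i-j)^2/(k-1)^2 over the ordered
    category set, so the maximal disagreement carries weight 0.  Returns
    (kappa_w, se).
    """
    a, b = _as_pairs(a, b)
    n = a.size
    if categories is None:
        categories = np.unique(np.concatenate([a, b]))
    categories = list(categories)
    k = len(categories)
    if k < 2:
        raise DegenerateAgreementError("need at least 2 categories for weighted kappa")
    table, _ = contingency_table(a, b, categories)
    w = _quadratic_weights(k)
    p = table / n
    row, col = p.sum(axis=1), p.sum(axis=0)
    po = float((w * p).sum())
    pe = float(row @ w @ col)
    if pe >= 1.0 - 1e-12:
        if po >= 1.0 - 1e-12:
            return 1.0, 0.0
        raise DegenerateAgreementError("weighted chance agreement is 1; kappa undefined")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt large-sample variance for weighted kappa
    wbar_i = w @ col  # expected weight of row category i
    wbar_j = row @ w  # expected weight of column category j
    term = w - (wbar_i[:, None] + wbar_j[None, :]) * (1.0 - kappa)
    var = (p * term**2).sum() - (kappa - pe * (1.0 - kappa)) ** 2
    var /= n * (1.0 - pe) ** 2
    return float(kappa), float(np.sqrt(max(var, 0.0)))


def spearman(a, b=None):
    """Spearman rank correlation with t-approximation p and Fisher-z 95% CI.

    Ties receive average ranks.  Returns (rho, p, (lo, hi)).
    """
    a, b = _as_pairs(a, b)
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs for Spearman correlation")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise DegenerateAgreementError("a rater has zero variance; rho undefined")
    rho = float(np.corrcoef(ra, rb)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if n > 3 and abs(rho) < 1.0:
        z = np.arctanh(rho)
        hw = 1.96 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
    else:
        ci = (rho, rho)
    return rho, p, ci


_LANDIS_KOCH_BANDS = [
    (0.0, "poor"),
    (0.205, "slight"),
    (0.405, "fair"),
    (0.605, "moderate"),
    (0.805, "substantial"),
    (np.inf, "almost perfect"),
]


def landis_koch(kappa: float) -> str:
    """Verbal agreement band of a kappa value (Landis-Koch convention).

    Published band edges leave gaps (0.20 vs 0.21); midpoint cutoffs
    (0.205, 0.405, 0.605, 0.805) are used so every kappa maps to one label.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    for edge, label in _LANDIS_KOCH_BANDS:
        if kappa < edge:
            return label
    return "almost perfect"


def agreement_report(a, b=None, categories=None) -> AgreementReport:
    """Compute the full agreement summary for one pair of raters."""
    a, b = _as_pairs(a, b)
    kappa, se, ci = cohens_kappa(a, b, categories)
    kw, kw_se = quadratic_weighted_kappa(a, b, categories)
    try:
        rho, p, rho_ci = spearman(a, b)
    except DegenerateAgreementError:
        rho, p, rho_ci = float("nan"), float("nan"), (float("nan"), float("nan"))
    return AgreementReport(
        n=int(a.size),
        kappa=kappa,
        se=se,
        ci95=ci,
        weighted_kappa=kw,
        weighted_se=kw_se,
        spearman_rho=rho,
        spearman_p=p,
        rho_ci95=rho_ci,
        landis_koch=landis_koch(max(-1.0, min(1.0, kappa))),
    )


def _fmt_p(p: float) -> str:
    return "< 0.0001" if p < 1e-4 else f"= {p:.4f}"


def format_report(report: AgreementReport) -> str:
    """Human-readable text block in the conventional reporting style."""
    lines = [
        f"n = {report.n}",
        (
            f"Cohen's kappa = {report.kappa:.3f}, SE = {report.se:.4f}, "
            f"95%CI = {report.ci95[0]:.3f}-{report.ci95[1]:.3f} "
            f"({report.landis_koch} agreement)"
        ),
        (
            f"quadratic weighted kappa = {report.weighted_kappa:.3f}, "
            f"SE = {report.weighted_se:.4f}"
        ),
        (
            f"Spearman's rho = {report.spearman_rho:.3f}, p {_fmt_p(report.spearman_p)}, "
            f"95% CI for rho {report.rho_ci95[0]:.3f}-{report.rho_ci95[1]:.3f}"
        ),
    ]
    return "\n".join(lines)
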