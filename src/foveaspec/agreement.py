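"""Agreement statistics: weighted Cohen's kappa, Bland–Altman, group tests.

Interobserver agreement on the ordinal hypoplasia scale uses Cohen's kappa
with Cicchetti–Allison (linear) weights, ``w_ij = 1 − |i−j|/(k−1)``, so
near-miss disagreements count partially.  Agreement between predicted and
observed acuity uses Bland–Altman limits of agreement with a linear trend
test of the bias against the pair mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class KappaResult:
    confusion: np.ndarray
    weights: np.ndarray
    observed_agreement: float          # unweighted proportion on the diagonal
    weighted_observed: float
    weighted_expected: float
    kappa: float
    flags: list[str] = field(default_factory=list)


def linear_weights(k: int) -> np.ndarray:
    """Cicchetti–Allison weight matrix: 1 on the diagonal, linear falloff."""
    i = np.arange(k)
    return 1.0 - np.abs(i[:, None] - i[None, :]) / (k - 1)


def confusion_matrix(labels_a, labels_b, k: int) -> np.ndarray:
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.min() < 1 or a.max() > k or b.min() < 1 or b.max() > k:
        raise ValueError(f"labels must lie on the ordinal scale 1..{k}")
    m = np.zeros((k, k))
    np.add.at(m, (a - 1, b - 1), 1.0)
    return m


def weighted_kappa_from_confusion(confusion: np.ndarray,
                                  weights: np.ndarray | None = None) -> KappaResult:
    """Weighted kappa from a k×k confusion matrix of counts."""
    m = np.asarray(confusion, dtype=float)
    k = m.shape[0]
    if m.shape != (k, k) or k < 2:
        raise ValueError("confusion matrix must be square, k >= 2")
    w = linear_weights(k) if weights is None else np.asarray(weights, dtype=float)
    n = m.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p = m / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.sum(w * p))
    pe = float(np.sum(w * np.outer(row, col)))
    flags: list[str] = []
    if abs(1.0 - pe) < 1e-12:
        kappa = float("nan")
        flags.append("kappa_undefined_degenerate_marginals")
    else:
        kappa = (po - pe) / (1.0 - pe)
    return KappaResult(
        confusion=m, weights=w,
        observed_agreement=float(np.trace(p)),
        weighted_observed=po, weighted_expected=pe,
        kappa=kappa, flags=flags,
    )


def weighted_kappa(labels_a, labels_b, k_categories: int) -> KappaResult:
    """Weighted Cohen's kappa for two raters on an ordinal 1..k scale."""
    m = confusion_matrix(labels_a, labels_b, k_categories)
    return weighted_kappa_from_confusion(m)


@dataclass
class TrendRegression:
    slope: float
    intercept: float
    f_statistic: float
    dfn: int
    dfd: int
    p_value: float


@dataclass
class BlandAltmanResult:
    differences: np.ndarray            # pred − obs
    means: np.ndarray                  # (pred + obs) / 2
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    trend: TrendRegression | None
    flags: list[str] = field(default_factory=list)


def bland_altman(pred, obs, ci_level: float = 0.95) -> BlandAltmanResult:
    """Bland–Altman agreement between predicted and observed values.

    Limits of agreement are bias ± 1.96·SD of the differences.  CIs use the
    large-sample formulas: bias ± t·SD/√n and LOA ± t·SD·√(3/n).  The trend
    regression is OLS of differences on pair means with an F-test
    (DFn = 1, DFd = n − 2).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("need at least 3 equal-length pairs")
    d = pred - obs
    m = (pred + obs) / 2.0
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo, loa_hi = bias - 1.96 * sd, bias + 1.96 * sd
    t = stats.t.ppf(0.5 + ci_level / 2.0, n - 1)
    half_bias = t * sd / np.sqrt(n)
    half_loa = t * sd * np.sqrt(3.0 / n)
    flags: list[str] = []
    trend = None
    if np.var(m) > 0:
        lr = stats.linregress(m, d)
        f = float(lr.rvalue**2 * (n - 2) / max(1.0 - lr.rvalue**2, 1e-300))
        pval = float(stats.f.sf(f, 1, n - 2))
        trend = TrendRegression(float(lr.slope), float(lr.intercept),
                                f, 1, n - 2, pval)
    else:
        flags.append("trend_undefined_zero_variance")
    return BlandAltmanResult(
        differences=d, means=m, bias=bias, sd=sd,
        loa_lower=loa_lo, loa_upper=loa_hi,
        bias_ci=(bias - half_bias, bias + half_bias),
        loa_lower_ci=(loa_lo - half_loa, loa_lo + half_loa),
        loa_upper_ci=(loa_hi - half_loa, loa_hi + half_loa),
        trend=trend, flags=flags,
    )


def plot_bland_altman(result: BlandAltmanResult, path: str) -> None:
    """Bias / limits-of-agreement plot with CI bands, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, s=18, color="k", zorder=3)
    for lo, hi in (result.bias_ci, result.loa_lower_ci, result.loa_upper_ci):
        ax.axhspan(lo, hi, color="0.85", zorder=1)
    ax.axhline(result.bias, color="k", lw=1.5, zorder=2)
    ax.axhline(result.loa_lower, color="k", ls="--", lw=1.0, zorder=2)
    ax.axhline(result.loa_upper, color="k", ls="--", lw=1.0, zorder=2)
    ax.set_xlabel("mean of predicted and observed")
    ax.set_ylabel("predicted − observed")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _holm_sidak(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        val = 1.0 - (1.0 - pvals[i]) ** (m - rank)
        running = max(running, val)
        adj[i] = min(running, 1.0)
    return adj


def _dunn_posthoc(values: np.ndarray, codes: np.ndarray, names: list) -> list[dict]:
    """Dunn's rank-based pairwise test with tie correction, Holm–Šídák adjusted."""
    ranks = stats.rankdata(values)
    n = values.size
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    pairs, pvals = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = ranks[codes == i], ranks[codes == j]
            se = np.sqrt(var_base * (1.0 / gi.size + 1.0 / gj.size))
            z = (gi.mean() - gj.mean()) / se
            pairs.append((names[i], names[j], float(z)))
            pvals.append(2.0 * stats.norm.sf(abs(z)))
    adj = _holm_sidak(np.asarray(pvals))
    return [{"groups": (a, b), "statistic": z, "p_adjusted": float(p)}
            for (a, b, z), p in zip(pairs, adj)]


def _pairwise_t_posthoc(values: np.ndarray, codes: np.ndarray, names: list) -> list[dict]:
    pairs, pvals = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = stats.ttest_ind(values[codes == i], values[codes == j])
            pairs.append((names[i], names[j], float(res.statistic)))
            pvals.append(float(res.pvalue))
    adj = _holm_sidak(np.asarray(pvals))
    return [{"groups": (a, b), "statistic": t, "p_adjusted": float(p)}
            for (a, b, t), p in zip(pairs, adj)]


def distribution_tests(values, groups, alpha: float = 0.05) -> dict:
    """Normality-gated omnibus test across groups with post-hoc comparisons.

    Shapiro–Wilk per group (normal when P > ``alpha``); all groups normal →
    one-way ANOVA with Holm–Šídák-adjusted pairwise t tests, otherwise
    Kruskal–Wallis with Dunn's post-hoc.  Degenerate groups are flagged.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(set(groups.tolist()))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    codes = np.array([names.index(g) for g in groups])
    report: dict = {"groups": names, "flags": [], "shapiro": {}}
    normal = True
    for i, name in enumerate(names):
        gv = values[codes == i]
        if gv.size < 3:
            report["flags"].append(f"shapiro_undefined_small_group:{name}")
            continue
        if np.ptp(gv) == 0:
            report["flags"].append(f"shapiro_undefined_constant_group:{name}")
            normal = False
            continue
        w, p = stats.shapiro(gv)
        report["shapiro"][name] = {"W": float(w), "p": float(p)}
        normal = normal and (p > alpha)
    samples = [values[codes == i] for i in range(len(names))]
    if normal:
        stat, p = stats.f_oneway(*samples)
        report["omnibus"] = {"test": "anova", "statistic": float(stat), "p": float(p)}
        report["posthoc"] = _pairwise_t_posthoc(values, codes, names)
    else:
        stat, p = stats.kruskal(*samples)
        report["omnibus"] = {"test": "kruskal", "statistic": float(stat), "p": float(p)}
        report["posthoc"] = _dunn_posthoc(values, codes, names)
    return report
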