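"""Cohort-level statistics over evaluated plans.

Non-parametric machinery for characterizing how plan-quality metrics depend
on target volume across a cohort: Spearman rank correlations (optionally
split at a threshold volume), Wilcoxon signed-rank comparisons of paired
metrics, the Jonckheere-Terpstra ordered-trend test (with a seeded
permutation p-value), and extremum-volume location.

Results use the three-level significance scale p < 0.05 (*), < 0.01 (**),
< 0.001 (***). Degenerate inputs (constant vectors, all-zero differences)
yield NaN markers rather than exceptions.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .metrics import evaluate_plan

__all__ = [
    "spearman",
    "wilcoxon_signed_rank",
    "jt_statistic",
    "jonckheere_terpstra",
    "split_correlation",
    "find_extremum",
    "significance_tier",
    "evaluate_cohort",
    "analyze_cohort",
]


def significance_tier(p: float) -> str:
    """The three-level significance scale: ``***``, ``**``, ``*`` or ``""``."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _clean_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("inputs must be equal-length 1-D vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    Requires at least 4 finite pairs; a constant input yields ``(nan, nan)``
    (the correlation is undefined).
    """
    x, y = _clean_pairs(x, y)
    if x.size < 4:
        raise DomainError(f"need at least 4 finite pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are discarded; at least 5 non-zero pairs are required.
    The null distribution is exact for n <= 25 when there are no tied
    absolute differences, otherwise a normal approximation with tie-corrected
    variance is used. All differences zero yields ``(nan, nan)``.
    """
    a, b = _clean_pairs(a, b)
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return (math.nan, math.nan)
    if d.size < 5:
        raise DomainError(f"need at least 5 non-zero paired differences, got {d.size}")
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, method=method)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------- #
# Jonckheere-Terpstra                                                         #
# --------------------------------------------------------------------------- #


def jt_statistic(groups) -> float:
    """Jonckheere-Terpstra statistic: the Mann-Whitney count summed over
    ordered group pairs, ``J = sum_{i<j} #(x_i < x_j) + 0.5 #(x_i = x_j)``."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    j = 0.0
    for i in range(len(gs)):
        for k in range(i + 1, len(gs)):
            xi = gs[i][:, None]
            xj = gs[k][None, :]
            j += float(np.sum(xi < xj) + 0.5 * np.sum(xi == xj))
    return j


def _jt_null_moments(sizes) -> tuple[float, float]:
    n = np.asarray(sizes)
    N = int(n.sum())
    mean = (N**2 - np.sum(n**2)) / 4.0
    var = (N**2 * (2 * N + 3) - np.sum(n**2 * (2 * n + 3))) / 72.0
    return float(mean), float(var)


def _jt_permutation_distribution(values, sizes, n_permutations, rng, chunk=2000):
    """JT statistics under random reassignment of values to groups."""
    N = values.size
    g = len(sizes)
    labels = np.repeat(np.arange(g), sizes)
    order = np.argsort(values, kind="stable")
    no_ties = np.unique(values).size == N
    upper = np.triu(np.ones((g, g)), k=1)  # [i, j] = 1 for i < j
    out = np.empty(n_permutations)
    done = 0
    sorted_vals = values[order]
    while done < n_permutations:
        c = min(chunk, n_permutations - done)
        perm_labels = rng.permuted(np.tile(labels, (c, 1)), axis=1)
        if no_ties:
            # values are fixed; only labels permute. Walk the sorted order and
            # count, for each position with label j, earlier positions with
            # label i < j.
            sl = perm_labels[:, order]
            onehot = sl[:, :, None] == np.arange(g)[None, None, :]
            cum_excl = np.cumsum(onehot, axis=1) - onehot
            out[done : done + c] = np.einsum(
                "pti,ij,ptj->p", cum_excl.astype(float), upper, onehot.astype(float)
            )
        else:
            for m in range(c):
                parts = np.split(
                    np.concatenate([values[perm_labels[m] == i] for i in range(g)]),
                    np.cumsum(sizes)[:-1],
                )
                out[done + m] = jt_statistic(parts)
        done += c
    return out


def jonckheere_terpstra(
    groups,
    alternative: str = "increasing",
    method: str = "permutation",
    n_permutations: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Jonckheere-Terpstra test for an ordered trend across >= 3 groups.

    Parameters
    ----------
    groups
        Sequence of 1-D samples in their hypothesized order.
    alternative
        ``"increasing"``, ``"decreasing"``, or ``"two-sided"``.
    method
        ``"permutation"`` (default; assumption-free, seeded) or
        ``"asymptotic"`` (normal approximation from the exact null moments,
        also the fallback inside the permutation p for reproducibility
        checks).
    n_permutations, seed
        Permutation settings; the p-value uses the add-one estimator
        ``(1 + #{as extreme}) / (n_permutations + 1)``.

    Returns
    -------
    (statistic, p_value)
    """
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    gs = [g[np.isfinite(g)] for g in gs]
    if len(gs) < 3:
        raise DomainError(f"need at least 3 ordered groups, got {len(gs)}")
    if any(g.size == 0 for g in gs):
        raise DomainError("every group must be non-empty")
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise DomainError(f"unknown alternative {alternative!r}")
    sizes = np.array([g.size for g in gs])
    j_obs = jt_statistic(gs)
    mean, var = _jt_null_moments(sizes)

    if method == "asymptotic":
        if var <= 0:
            return j_obs, math.nan
        z = (j_obs - mean) / math.sqrt(var)
        if alternative == "increasing":
            p = stats.norm.sf(z)
        elif alternative == "decreasing":
            p = stats.norm.cdf(z)
        else:
            p = 2 * stats.norm.sf(abs(z))
        return j_obs, float(min(p, 1.0))
    if method != "permutation":
        raise DomainError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    values = np.concatenate(gs)
    perm = _jt_permutation_distribution(values, sizes, n_permutations, rng)
    eps = 1e-9
    if alternative == "increasing":
        extreme = np.sum(perm >= j_obs - eps)
    elif alternative == "decreasing":
        extreme = np.sum(perm <= j_obs + eps)
    else:
        extreme = np.sum(np.abs(perm - mean) >= abs(j_obs - mean) - eps)
    return j_obs, float((1 + extreme) / (n_permutations + 1))


# --------------------------------------------------------------------------- #
# split correlations and extremum location                                    #
# --------------------------------------------------------------------------- #


def split_correlation(x, y, threshold: float) -> tuple[float, float, float, float]:
    """Spearman correlation on both sides of a threshold in ``x``.

    The threshold row belongs to *both* sides (the splits are ``x <=`` and
    ``x >=`` threshold). Returns ``(rho_below, rho_above, p_below, p_above)``;
    a side with fewer than 4 pairs is marked NaN.
    """
    x, y = _clean_pairs(x, y)
    out = []
    for sel in (x <= threshold, x >= threshold):
        if sel.sum() < 4:
            out.append((math.nan, math.nan))
        else:
            out.append(spearman(x[sel], y[sel]))
    (rho_b, p_b), (rho_a, p_a) = out
    return rho_b, rho_a, p_b, p_a


def find_extremum(
    table: pd.DataFrame,
    metric: str,
    mode: str = "min",
    volume_column: str = "gtv_cc",
) -> tuple[float, bool]:
    """GTV volume at which a metric attains its extremum across the cohort.

    Returns ``(volume_cc, tied)``; ties report the smallest such volume with
    the tie flag set. Rows with missing metric values are ignored.
    """
    if mode not in ("min", "max"):
        raise DomainError(f"mode must be 'min' or 'max', got {mode!r}")
    sub = table[[volume_column, metric]].dropna()
    if sub.empty:
        raise DomainError(f"metric {metric!r} has no finite values")
    vals = sub[metric].to_numpy(dtype=float)
    target = vals.min() if mode == "min" else vals.max()
    hits = sub[volume_column].to_numpy(dtype=float)[vals == target]
    return float(hits.min()), bool(hits.size > 1)


# --------------------------------------------------------------------------- #
# cohort table and the full analysis battery                                  #
# --------------------------------------------------------------------------- #


def evaluate_cohort(plans) -> pd.DataFrame:
    """One row of metric values per plan (columns as in MetricReport)."""
    rows = []
    for plan in plans:
        d = evaluate_plan(plan).to_dict()
        d["truncated"] = ";".join(d["truncated"])
        rows.append(d)
    df = pd.DataFrame(rows).sort_values("gtv_cc", ignore_index=True)
    return df


#: metric columns correlated against target volume in :func:`analyze_cohort`
VOLUME_CORRELATES = [
    "d98_pct_pd",
    "pd_to_nearmax_pct",
    "coverage_deiiv_pct",
    "spill_deiiv_cc",
    "spill_piv_cc",
    "spill_50piv_cc",
    "mpitv",
    "mgi_dv001",
    "agd_pd_mm",
    "agd_deiiv_mm",
    "ratio_plus2_pct",
    "ratio_minus2_pct",
]

#: gradient-index variants in decreasing order of expected value (i.e.
#: increasing target coverage by the reference isodose surface)
GI_ORDER = ["mgi_deiiv", "mgi_d98", "mgi_dv001", "mgi_plus2_deiiv"]


def analyze_cohort(
    table: pd.DataFrame,
    seed: int = 0,
    n_permutations: int = 9999,
    steepest_volume_cc: float = 0.72,
    most_heterogeneous_volume_cc: float = 1.71,
) -> dict:
    """The cohort-level statistical battery over an evaluated cohort table.

    Volume correlations (Spearman), the paired comparison of the two AGD
    definitions (Wilcoxon), the ordered trend across the four gradient-index
    variants (Jonckheere-Terpstra, permutation p), split correlations at the
    threshold volumes, and extremum-volume locations. Returns a JSON-able
    dict; all stochastic steps are governed by ``seed``.
    """
    out: dict = {"n_plans": int(len(table))}

    corr = {}
    for metric in VOLUME_CORRELATES:
        sub = table[["gtv_cc", metric]].dropna()
        if len(sub) < 4:
            corr[metric] = None
            continue
        rho, p = spearman(sub["gtv_cc"], sub[metric])
        corr[metric] = {"rho": rho, "p": p, "tier": significance_tier(p)}
    out["spearman_vs_volume"] = corr

    paired = table[["agd_deiiv_mm", "agd_pd_mm"]].dropna()
    try:
        stat, p = wilcoxon_signed_rank(paired["agd_deiiv_mm"], paired["agd_pd_mm"])
        diff = paired["agd_deiiv_mm"] - paired["agd_pd_mm"]
        out["wilcoxon_agd_deiiv_vs_pd"] = {
            "statistic": stat,
            "p": p,
            "tier": significance_tier(p),
            "median_difference_mm": float(diff.median()),
            "deiiv_longer": bool(diff.median() > 0),
        }
    except DomainError:
        out["wilcoxon_agd_deiiv_vs_pd"] = None  # cohort too small

    groups = [table[c].dropna().to_numpy() for c in GI_ORDER]
    try:
        stat, p = jonckheere_terpstra(
            groups, alternative="decreasing", n_permutations=n_permutations, seed=seed
        )
        out["jt_gradient_index_trend"] = {
            "order": GI_ORDER,
            "statistic": stat,
            "p": p,
            "tier": significance_tier(p),
        }
    except DomainError:
        out["jt_gradient_index_trend"] = None

    splits = {}
    for metric, thr in [
        ("agd_pd_mm", steepest_volume_cc),
        ("agd_deiiv_mm", steepest_volume_cc),
        ("ratio_plus2_pct", steepest_volume_cc),
        ("pd_to_nearmax_pct", most_heterogeneous_volume_cc),
        ("ratio_minus2_pct", most_heterogeneous_volume_cc),
    ]:
        sub = table[["gtv_cc", metric]].dropna()
        rho_b, rho_a, p_b, p_a = split_correlation(sub["gtv_cc"], sub[metric], thr)
        splits[metric] = {
            "threshold_cc": thr,
            "rho_below": rho_b,
            "p_below": p_b,
            "tier_below": significance_tier(p_b),
            "rho_above": rho_a,
            "p_above": p_a,
            "tier_above": significance_tier(p_a),
        }
    out["split_correlations"] = splits

    extrema = {}
    for metric, mode in [
        ("agd_pd_mm", "min"),
        ("agd_deiiv_mm", "min"),
        ("ratio_plus2_pct", "min"),
        ("pd_to_nearmax_pct", "min"),
        ("ratio_minus2_pct", "max"),
    ]:
        try:
            vol, tied = find_extremum(table, metric, mode)
        except DomainError:
            extrema[metric] = None
            continue
        extrema[metric] = {"mode": mode, "volume_cc": vol, "tied": tied}
    out["extrema"] = extrema
    return _jsonable(out)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
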