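"""Evaluation statistics.

Precision (CV%), signed relative trueness (%), the exact two-sided rank-sum
(Mann–Whitney) test used for zgpr-vs-NOESYpr comparisons, a Kruskal–Wallis
test for the operator effect, and PCA with projection of a held-out
"theoretical" sample.

The rank-sum test is implemented by full enumeration of the C(n+m, n) group
assignments of the pooled mid-ranks whenever that is feasible (n+m <= 14),
which handles ties exactly; with two samples of five values each the
attainable two-sided p-values are exactly the multiples 2k/252.  Larger
samples fall back to the tie-corrected normal approximation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

__all__ = [
    "precision_cv",
    "relative_trueness",
    "rank_sum_exact",
    "kruskal_wallis",
    "pca_with_projection",
    "summarize_study",
]

EXACT_ENUMERATION_LIMIT = 14  # n + m up to this -> exact enumeration


def precision_cv(values) -> float:
    """Coefficient of variation in %, sample (n−1) standard deviation.

    Undefined (ValueError) for fewer than two values or zero mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("precision needs at least 2 replicate values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("precision undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def relative_trueness(values, theoretical: float) -> float:
    """Signed % deviation of the replicate mean from the theoretical value."""
    if theoretical <= 0:
        raise ValueError("theoretical value must be > 0")
    v = np.asarray(values, dtype=float)
    return float(100.0 * (v.mean() - theoretical) / theoretical)


def _u_statistic_from_ranks(ranks_x: np.ndarray, n: int, m: int) -> float:
    return float(ranks_x.sum() - n * (n + 1) / 2.0)


def rank_sum_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney rank-sum test.

    Returns (U statistic of the first sample, two-sided p).  The p-value is
    the fraction of all C(n+m, n) assignments of the pooled mid-ranks whose
    U is at least as far from the null mean nm/2 as the observed one — a
    symmetric-tail definition that yields p = 1 for identical samples and
    the 2k/252 lattice for n = m = 5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values are not allowed")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    u_obs = _u_statistic_from_ranks(ranks[:n], n, m)
    center = n * m / 2.0
    if n + m <= EXACT_ENUMERATION_LIMIT:
        total = comb(n + m, n)
        dev_obs = abs(u_obs - center)
        count = 0
        idx_all = range(n + m)
        for subset in combinations(idx_all, n):
            u = float(ranks[list(subset)].sum() - n * (n + 1) / 2.0)
            if abs(u - center) >= dev_obs - 1e-12:
                count += 1
        return u_obs, count / total
    # tie-corrected normal approximation for larger samples
    nties = np.unique(ranks, return_counts=True)[1]
    tie_term = ((nties ** 3 - nties).sum()) / ((n + m) * (n + m - 1))
    sigma2 = n * m / 12.0 * ((n + m + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - center) - 0.5) / sqrt(sigma2)
    return u_obs, float(2.0 * sps.norm.sf(max(z, 0.0)))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from chi-square (k−1 df).

    Degenerate all-equal data yields H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    counts = np.unique(pooled, return_counts=True)[1]
    correction = 1.0 - ((counts ** 3 - counts).sum()) / (n_total ** 3 - n_total)
    if correction <= 0:  # all values identical
        return 0.0, 1.0
    h /= correction
    h = max(h, 0.0)
    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def pca_with_projection(
    matrix: pd.DataFrame, held_out: pd.Series, n_components: int = 2
) -> dict:
    """PCA of the autoscaled matrix, with the held-out row projected.

    The matrix is mean-centred and unit-variance scaled per column
    (training statistics only); the held-out row is scaled with the training
    means/sds and projected with the training loadings.  Constant columns
    are dropped with a warning entry in the report.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    dropped = [c for c in matrix.columns if matrix[c].std(ddof=0) == 0]
    use = [c for c in matrix.columns if c not in dropped]
    if not use:
        raise ValueError("all columns constant")
    X = matrix[use].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Z = (X - mu) / sd
    n_components = min(n_components, Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z)
    z_held = (held_out[use].to_numpy(dtype=float) - mu) / sd
    projected = pca.transform(z_held[None, :])[0]
    return {
        "scores": pd.DataFrame(
            scores, index=matrix.index,
            columns=[f"PC{i+1}" for i in range(n_components)],
        ),
        "loadings": pd.DataFrame(
            pca.components_.T, index=use,
            columns=[f"PC{i+1}" for i in range(n_components)],
        ),
        "variance_fractions": pca.explained_variance_ratio_.tolist(),
        "projected": pd.Series(
            projected, index=[f"PC{i+1}" for i in range(n_components)]
        ),
        "dropped_columns": dropped,
    }


# ---------------------------------------------------------------------------
# study-level report
# ---------------------------------------------------------------------------

def summarize_study(
    quant_table: pd.DataFrame,
    truth: dict[str, float],
    operator_strategy: str = "int_extcal",
) -> dict[str, pd.DataFrame]:
    """Aggregate a long quantification table into the benchmark report.

    ``quant_table`` columns: quantity, strategy, pulse_sequence, operator,
    replicate, concentration_uM (NaN rows are ND and stay ND).  Produces:

    * ``per_operator`` — CV% and trueness% per quantity × strategy ×
      sequence × operator;
    * ``aggregated`` — mean ± SD of CV and trueness across operators;
    * ``sequence_comparison`` — per quantity (for ``operator_strategy``):
      NOESYpr/zgpr ratios of CV and trueness plus exact rank-sum p-values
      across the per-operator values;
    * ``operator_effect`` — Kruskal–Wallis p per quantity for
      ``operator_strategy`` on zgpr replicate concentrations.
    """
    rows = []
    group_cols = ["quantity", "strategy", "pulse_sequence", "operator"]
    for keys, grp in quant_table.groupby(group_cols, sort=False):
        conc = grp["concentration_uM"].to_numpy(dtype=float)
        quantity = keys[0]
        if np.any(np.isnan(conc)) or conc.size < 2:
            cv = np.nan
            tru = np.nan
        else:
            cv = precision_cv(conc) if conc.mean() != 0 else np.nan
            theo = truth.get(quantity)
            tru = relative_trueness(conc, theo) if theo and theo > 0 else np.nan
        rows.append(dict(zip(group_cols, keys), cv_percent=cv, trueness_percent=tru))
    per_operator = pd.DataFrame(rows)

    aggregated = (
        per_operator.groupby(["quantity", "strategy", "pulse_sequence"], sort=False)
        .agg(
            cv_mean=("cv_percent", "mean"),
            cv_sd=("cv_percent", "std"),
            trueness_mean=("trueness_percent", "mean"),
            trueness_sd=("trueness_percent", "std"),
            n_operators=("operator", "nunique"),
        )
        .reset_index()
    )

    seq_rows = []
    sub = per_operator[per_operator["strategy"] == operator_strategy]
    for quantity, grp in sub.groupby("quantity", sort=False):
        z = grp[grp["pulse_sequence"] == "zgpr"].sort_values("operator")
        n = grp[grp["pulse_sequence"] == "noesypr"].sort_values("operator")
        if z.empty or n.empty:
            continue
        zc, nc = z["cv_percent"].to_numpy(), n["cv_percent"].to_numpy()
        zt, nt = z["trueness_percent"].to_numpy(), n["trueness_percent"].to_numpy()
        if np.any(np.isnan(zc)) or np.any(np.isnan(nc)):
            continue
        _, p_cv = rank_sum_exact(nc, zc)
        _, p_tru = rank_sum_exact(nt, zt)
        seq_rows.append(
            {
                "quantity": quantity,
                "cv_ratio_noesypr_over_zgpr": nc.mean() / zc.mean() if zc.mean() else np.nan,
                "cv_p_value": p_cv,
                "trueness_ratio_noesypr_over_zgpr": (
                    nt.mean() / zt.mean() if zt.mean() else np.nan
                ),
                "trueness_p_value": p_tru,
            }
        )
    sequence_comparison = pd.DataFrame(seq_rows)

    op_rows = []
    zsub = quant_table[
        (quant_table["strategy"] == operator_strategy)
        & (quant_table["pulse_sequence"] == "zgpr")
    ]
    for quantity, grp in zsub.groupby("quantity", sort=False):
        groups = [
            g["concentration_uM"].to_numpy(dtype=float)
            for _, g in grp.groupby("operator", sort=False)
        ]
        groups = [g for g in groups if not np.any(np.isnan(g))]
        if len(groups) < 2:
            continue
        h, p = kruskal_wallis(groups)
        op_rows.append({"quantity": quantity, "H": h, "p_value": p})
    operator_effect = pd.DataFrame(op_rows)

    return {
        "per_operator": per_operator,
        "aggregated": aggregated,
        "sequence_comparison": sequence_comparison,
        "operator_effect": operator_effect,
    }
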