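"""Per-layer preprocessing and two-group differential abundance.

The pipeline per layer: average technical replicates to one column per
(group, processing replicate), filter features to a minimum of two valid
values in at least one condition, then a two-sided Student t test
(pooled variance) on log2 intensities at unadjusted p <= 0.05. Fold change
is oriented comparison-minus-reference (metastatic minus primary), so
"up" means higher in the metastatic-derived EVs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from evcargo.datatypes import OmicsMatrix, SampleMeta

DIFF_COLUMNS = [
    "mean_g1", "mean_g2", "log2fc", "t_stat", "p_value", "direction",
    "n_valid_g1", "n_valid_g2", "passed_filter",
]


def average_technical_replicates(m: OmicsMatrix) -> OmicsMatrix:
    """Collapse technical replicates to their mean per processing replicate.

    The mean is over non-missing technical values; a triple with every
    technical measurement missing stays missing. With a single technical
    replicate this is the identity.
    """
    key_to_cols: dict[tuple[str, int], list[str]] = {}
    order: list[tuple[str, int]] = []
    for s in m.samples:
        key = (s.group, s.processing_replicate)
        if key not in key_to_cols:
            key_to_cols[key] = []
            order.append(key)
        key_to_cols[key].append(s.sample_id)
    if all(len(cols) == 1 for cols in key_to_cols.values()):
        return m
    new_cols = {}
    new_samples = []
    for group, pr in order:
        cols = key_to_cols[(group, pr)]
        new_id = f"{group}_p{pr}"
        new_cols[new_id] = m.data[cols].mean(axis=1, skipna=True)
        new_samples.append(SampleMeta(new_id, group, pr, 1))
    data = pd.DataFrame(new_cols, index=m.data.index)
    return OmicsMatrix(layer=m.layer, data=data, samples=new_samples)


def filter_valid_values(
    m: OmicsMatrix, min_valid: int = 2
) -> tuple[OmicsMatrix, list[str]]:
    """Keep features quantified in >= min_valid replicates of either group.

    Returns the filtered matrix and the rejected feature ids, so no row is
    ever silently dropped.
    """
    g1, g2 = m.groups
    n1 = m.data[m.group_columns(g1)].notna().sum(axis=1)
    n2 = m.data[m.group_columns(g2)].notna().sum(axis=1)
    keep = (n1 >= min_valid) | (n2 >= min_valid)
    rejected = m.data.index[~keep].tolist()
    kept = OmicsMatrix(layer=m.layer, data=m.data.loc[keep].copy(), samples=m.samples)
    return kept, rejected


def two_group_ttest(
    m: OmicsMatrix,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sided Student t test per feature on log2 intensities.

    Pooled-variance ("Student") by default; ``equal_var=False`` switches to
    Welch. Missing values reduce the per-group n; features with fewer than
    two valid values in either group get a missing p and direction "ns".
    No multiple-testing adjustment is applied (a ``p_bh`` column with
    Benjamini-Hochberg values is appended for reference only).

    Degenerate convention: zero pooled variance with equal means gives
    t=0, p=1; with unequal means gives t=+/-inf, p=0.
    """
    g1, g2 = m.groups
    a = m.data[m.group_columns(g1)].to_numpy(dtype=float)
    b = m.data[m.group_columns(g2)].to_numpy(dtype=float)
    n1 = (~np.isnan(a)).sum(axis=1)
    n2 = (~np.isnan(b)).sum(axis=1)
    # all-missing rows yield a NaN mean without the empty-slice warning
    sum1, sum2 = np.nansum(a, axis=1), np.nansum(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean1 = np.where(n1 > 0, sum1 / n1, np.nan)
        mean2 = np.where(n2 > 0, sum2 / n2, np.nan)
    log2fc = mean2 - mean1

    testable = (n1 >= 2) & (n2 >= 2)
    t_stat = np.full(m.data.shape[0], np.nan)
    p_value = np.full(m.data.shape[0], np.nan)
    if testable.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(
                a[testable], b[testable], axis=1,
                equal_var=equal_var, nan_policy="omit",
            )
        # fold change / t sign: comparison (g2) minus reference (g1)
        t_sub = -np.asarray(res.statistic, dtype=float)
        p_sub = np.asarray(res.pvalue, dtype=float)
        # zero-variance conventions (scipy yields nan there)
        var1 = np.nanvar(a[testable], axis=1, ddof=1)
        var2 = np.nanvar(b[testable], axis=1, ddof=1)
        zero_var = (var1 == 0) & (var2 == 0)
        d = mean2[testable] - mean1[testable]
        eq = zero_var & (d == 0)
        ne = zero_var & (d != 0)
        t_sub[eq], p_sub[eq] = 0.0, 1.0
        t_sub[ne] = np.sign(d[ne]) * np.inf
        p_sub[ne] = 0.0
        t_stat[testable] = t_sub
        p_value[testable] = p_sub

    direction = np.where(
        (p_value <= alpha) & (log2fc > 0), "up",
        np.where((p_value <= alpha) & (log2fc < 0), "down", "ns"),
    )
    direction = np.where(np.isnan(p_value), "ns", direction)

    table = pd.DataFrame(
        {
            "mean_g1": mean1,
            "mean_g2": mean2,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p_value": p_value,
            "direction": direction,
            "n_valid_g1": n1,
            "n_valid_g2": n2,
            "passed_filter": True,
        },
        index=m.data.index,
    )
    tested = table["p_value"].dropna()
    if len(tested):
        table["p_bh"] = np.nan
        table.loc[tested.index, "p_bh"] = _benjamini_hochberg(tested.to_numpy())
    else:
        table["p_bh"] = np.nan
    table.attrs["group1"] = g1
    table.attrs["group2"] = g2
    table.attrs["alpha"] = alpha
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def normalize_tic(m: OmicsMatrix) -> OmicsMatrix:
    """Total-ion-count normalization of a raw-scale matrix, then log2.

    Each column is divided by its column sum over non-missing values; the
    proportions are then log2-transformed. Zero intensities become missing.
    """
    raw = m.data.to_numpy(dtype=float)
    if (raw[~np.isnan(raw)] < 0).any():
        raise ValueError("normalize_tic expects raw (non-negative) intensities")
    colsum = np.nansum(raw, axis=0)
    if np.isnan(raw).all(axis=0).any() or (colsum == 0).any():
        bad = [m.sample_ids[j] for j in range(raw.shape[1])
               if np.isnan(raw[:, j]).all() or colsum[j] == 0]
        raise ValueError(f"column(s) with no signal: {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = raw / colsum
        prop[~(prop > 0)] = np.nan
        logged = np.log2(prop)
    data = pd.DataFrame(logged, index=m.data.index, columns=m.data.columns)
    return OmicsMatrix(layer=m.layer, data=data, samples=list(m.samples))


def differential_pipeline(
    m: OmicsMatrix,
    min_valid: int = 2,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Full per-layer chain: average tech reps -> valid-value filter -> t test.

    Returns the differential table (filtered features only, with
    ``passed_filter`` True) and the list of filtered-out feature ids.
    """
    averaged = average_technical_replicates(m)
    filtered, rejected = filter_valid_values(averaged, min_valid=min_valid)
    table = two_group_ttest(filtered, alpha=alpha, equal_var=equal_var)
    return table, rejected


def differential_counts(table: pd.DataFrame) -> dict[str, int]:
    """Totals the study reports: tested, differential, up, down."""
    sig = table["p_value"].notna() & (table["p_value"] <= table.attrs.get("alpha", 0.05))
    return {
        "n_features": int(len(table)),
        "n_tested": int(table["p_value"].notna().sum()),
        "n_differential": int(sig.sum()),
        "n_up": int((table["direction"] == "up").sum()),
        "n_down": int((table["direction"] == "down").sum()),
    }
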