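"""Comparative delta-delta-CT qPCR quantification and focused-array
differential flagging.

Relative expression by the classical comparative method with amplification
efficiency fixed at 2: per replicate, dCt = Ct(target) - Ct(housekeeping);
per condition, ddCt = mean dCt(condition) - mean dCt(reference); fold change
= 2^(-ddCt), so the reference condition's fold is exactly 1.

For the focused oxidative-stress array, genes are flagged up/down when the
fold change exceeds 2 (or falls below 1/2) AND a two-sided Welch t-test on
the replicate dCt values gives p < 0.05; everything else is 'unchanged'.
A Benjamini-Hochberg column is emitted for transparency even though the
per-gene rule applies no multiplicity correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REQUIRED_COLUMNS = ("sample", "condition", "gene", "ct", "housekeeping_ct")


def _validate(ct_table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = ct_table["housekeeping_ct"].isna()
    if bad.any():
        rows = ct_table.index[bad].tolist()
        raise ValueError(f"missing housekeeping Ct in rows {rows[:10]}")
    for col in ("ct", "housekeeping_ct"):
        vals = ct_table[col].astype(float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError(f"{col} values must be finite and > 0")
    return ct_table


def delta_delta_ct(ct_table: pd.DataFrame, reference_condition: str) -> pd.DataFrame:
    """Relative expression per (gene, condition) against a reference condition.

    ``ct_table`` columns: sample, condition, gene, ct, housekeeping_ct
    (optionally replicate).  Returns one row per gene x condition with
    n, delta_ct_mean, delta_delta_ct, fold_change and fold_sd (SD of the
    per-replicate folds 2^-(dCt - mean dCt(reference))).
    """
    ct_table = _validate(ct_table)
    if reference_condition not in set(ct_table["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} not in table")
    df = ct_table.copy()
    df["delta_ct"] = df["ct"].astype(float) - df["housekeeping_ct"].astype(float)

    rows = []
    for gene, gdf in df.groupby("gene", sort=False):
        ref = gdf.loc[gdf["condition"] == reference_condition, "delta_ct"]
        if ref.empty:
            raise ValueError(f"gene {gene!r} has no measurements in the reference condition")
        ref_mean = ref.mean()
        for cond, cdf in gdf.groupby("condition", sort=False):
            dct = cdf["delta_ct"].to_numpy(dtype=float)
            ddct = float(dct.mean() - ref_mean)
            rep_folds = 2.0 ** (-(dct - ref_mean))
            rows.append(dict(
                gene=gene, condition=cond, n=len(dct),
                delta_ct_mean=float(dct.mean()),
                delta_delta_ct=ddct,
                fold_change=float(2.0 ** (-ddct)),
                fold_sd=float(rep_folds.std(ddof=1)) if len(dct) > 1 else np.nan,
            ))
    return pd.DataFrame(rows)


def flag_array_genes(ct_table: pd.DataFrame, reference_condition: str,
                     test_condition: str, fold_threshold: float = 2.0,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Differential flags for a two-condition focused expression array.

    Per gene: fold change of ``test_condition`` vs ``reference_condition``
    by delta-delta-CT, and a two-sided Welch t-test on the replicate dCt
    values (equivalent to testing log2 relative expression).  Status is
    'up' iff fold > ``fold_threshold`` and p < ``alpha``; 'down' iff fold <
    1/``fold_threshold`` and p < ``alpha``; otherwise 'unchanged'.  Genes
    with fewer than 2 replicates in either condition are 'untestable'.
    Sorted by gene; a BH-adjusted q-value column is included.
    """
    ct_table = _validate(ct_table)
    present = set(ct_table["condition"])
    for cond in (reference_condition, test_condition):
        if cond not in present:
            raise ValueError(f"condition {cond!r} not in table")
    df = ct_table.copy()
    df["delta_ct"] = df["ct"].astype(float) - df["housekeeping_ct"].astype(float)

    rows = []
    for gene, gdf in df.groupby("gene", sort=True):
        ref = gdf.loc[gdf["condition"] == reference_condition, "delta_ct"].to_numpy(dtype=float)
        tst = gdf.loc[gdf["condition"] == test_condition, "delta_ct"].to_numpy(dtype=float)
        if len(ref) < 2 or len(tst) < 2:
            rows.append(dict(gene=gene, log2_fold=np.nan, fold_change=np.nan,
                             p_value=np.nan, status="untestable"))
            continue
        ddct = tst.mean() - ref.mean()
        log2_fold = -ddct  # fold = 2^-ddCt
        if np.ptp(ref) == 0 and np.ptp(tst) == 0:
            p = 1.0 if ddct == 0 else 0.0  # noiseless replicates: degenerate t
        else:
            p = float(stats.ttest_ind(tst, ref, equal_var=False).pvalue)
        fold = 2.0 ** log2_fold
        if fold > fold_threshold and p < alpha:
            status = "up"
        elif fold < 1.0 / fold_threshold and p < alpha:
            status = "down"
        else:
            status = "unchanged"
        rows.append(dict(gene=gene, log2_fold=float(log2_fold),
                         fold_change=float(fold), p_value=p, status=status))
    out = pd.DataFrame(rows)
    testable = out["p_value"].notna()
    out["q_value_bh"] = np.nan
    if testable.any():
        out.loc[testable, "q_value_bh"] = multipletests(
            out.loc[testable, "p_value"], method="fdr_bh")[1]
    return out
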