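"""Gene-signature NRF2 activity scoring.

NRF2 (NFE2L2) activity cannot be read off *NFE2L2* mRNA itself, because the
pathway is regulated post-translationally through KEAP1-mediated degradation.
Activity is therefore quantified through surrogate target genes: each
signature gene is z-scored across the cohort and the per-sample signature
score is the mean z-score over the gene set, giving a combined score with a
zero mean across the cohort.  Tumour/normal differences in the score are
tested with Welch's t-test.

The default panel uses the single prototypical target gene *NQO1* and the
five-gene set *NQO1, GPX2, TXNRD1, GCLC, GCLM*; externally published NRF2
signatures can be supplied as plain gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

NRF2_5_GENE_SIGNATURE = ("NQO1", "GPX2", "TXNRD1", "GCLC", "GCLM")

TUMOUR = "tumour"
NORMAL = "normal"


@dataclass
class ExpressionCohort:
    """Genes x samples expression matrix (FPKM-like, non-negative) with a
    per-sample tumour/normal label.

    ``values`` is a DataFrame indexed by gene symbol with sample IDs as
    columns; duplicate gene symbols are allowed on input and resolved by
    :func:`collapse_duplicate_genes` before scoring.
    """

    values: pd.DataFrame
    labels: pd.Series
    name: str = "cohort"

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise ValueError(f"samples without labels: {missing}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class SignatureScore:
    """Per-sample combined signature score (zero mean across the cohort)."""

    gene_set: tuple[str, ...]
    per_sample_score: pd.Series
    gene_set_name: str = ""


@dataclass
class GroupComparison:
    """Welch's t-test of a score between two sample groups."""

    t_statistic: float
    df: float
    p_value: float
    group_means: tuple[float, float]  # (tumour, normal)


def collapse_duplicate_genes(cohort: ExpressionCohort) -> ExpressionCohort:
    """Collapse duplicate gene symbols to their per-sample median expression.

    Mirrors the convention of collapsing multiple transcript/Ensembl IDs
    mapping to one symbol.  Gene order follows first appearance.
    """
    if not cohort.values.index.duplicated().any():
        return cohort
    order = cohort.values.index.drop_duplicates()
    collapsed = cohort.values.groupby(level=0, sort=False).median().loc[order]
    return ExpressionCohort(values=collapsed, labels=cohort.labels, name=cohort.name)


def standardize_genes(cohort: ExpressionCohort) -> pd.DataFrame:
    """Row-wise z-scores over all samples (tumour + normal pooled).

    Uses the sample standard deviation (ddof=1).  Raises on zero-variance
    genes, naming them, because a z-score is undefined there.
    """
    values = cohort.values
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    zero_var = sd.index[(sd == 0) | sd.isna()]
    if len(zero_var):
        raise ValueError(
            "zero-variance genes cannot be standardized: "
            + ", ".join(map(str, zero_var[:10]))
        )
    return values.sub(mean, axis=0).div(sd, axis=0)


def combined_score(
    zmatrix: pd.DataFrame, gene_set, gene_set_name: str = ""
) -> SignatureScore:
    """Mean z-score over ``gene_set`` per sample.

    The mean (rather than sum) keeps scores comparable across gene sets of
    different sizes; both share the zero-mean property.  Since every gene row
    has mean zero across samples, the per-sample score averages to zero over
    the cohort by construction.
    """
    gene_set = tuple(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    missing = [g for g in gene_set if g not in zmatrix.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    score = zmatrix.loc[list(gene_set)].mean(axis=0)
    return SignatureScore(gene_set=gene_set, per_sample_score=score, gene_set_name=gene_set_name)


def compare_groups(score: SignatureScore, labels: pd.Series) -> GroupComparison:
    """Welch's t-test (unequal variances, Satterthwaite df) of the score in
    tumour vs normal samples; two-sided p."""
    s = score.per_sample_score
    labels = labels.reindex(s.index)
    tum = s[labels == TUMOUR].to_numpy(dtype=float)
    nor = s[labels == NORMAL].to_numpy(dtype=float)
    if len(tum) < 2 or len(nor) < 2:
        raise ValueError(
            f"need >= 2 samples per group (tumour={len(tum)}, normal={len(nor)})"
        )
    res = stats.ttest_ind(tum, nor, equal_var=False)
    if np.ptp(np.concatenate([tum, nor])) == 0:
        # identical constant groups: define t = 0, p = 1
        return GroupComparison(0.0, float(res.df) if np.isfinite(res.df) else len(s) - 2.0,
                               1.0, (float(tum.mean()), float(nor.mean())))
    return GroupComparison(
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        group_means=(float(tum.mean()), float(nor.mean())),
    )


def default_gene_sets() -> dict[str, tuple[str, ...]]:
    return {"NQO1": ("NQO1",), "NRF2_5gene": NRF2_5_GENE_SIGNATURE}


def run_signature_panel(
    cohort: ExpressionCohort,
    gene_sets: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Score a panel of gene sets and compare tumour vs normal per set.

    One row per gene set: gene_set, n_genes, t, df, p, mean_tumour,
    mean_normal, status.  A gene set with members absent from the cohort is
    flagged ``failed`` and the run continues.
    """
    gene_sets = gene_sets if gene_sets is not None else default_gene_sets()
    cohort = collapse_duplicate_genes(cohort)
    zmatrix = standardize_genes(cohort)
    rows = []
    for name, genes in gene_sets.items():
        try:
            score = combined_score(zmatrix, genes, gene_set_name=name)
            cmp = compare_groups(score, cohort.labels)
            rows.append(
                dict(gene_set=name, cohort=cohort.name, n_genes=len(genes),
                     t=cmp.t_statistic, df=cmp.df, p=cmp.p_value,
                     mean_tumour=cmp.group_means[0], mean_normal=cmp.group_means[1],
                     status="ok")
            )
        except (KeyError, ValueError) as exc:
            rows.append(
                dict(gene_set=name, cohort=cohort.name, n_genes=len(tuple(genes)),
                     t=np.nan, df=np.nan, p=np.nan,
                     mean_tumour=np.nan, mean_normal=np.nan,
                     status=f"failed: {exc}")
            )
    return pd.DataFrame(rows)
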