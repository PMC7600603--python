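"""Tissue-microarray weighted histoscore, dual-observer concordance and
Kaplan-Meier survival analysis.

Each patient core is scored as the percentage of tumour cells that are
unstained / weakly / moderately / strongly stained; the weighted histoscore
is 0*u + 1*w + 2*m + 3*s, ranging 0-300.  A second observer re-scores a
subset for quality control: agreement is summarised by a two-way
absolute-agreement single-rater ICC (acceptable when > 0.8) and a
Bland-Altman bias with 1.96*SD limits; pairs differing by more than 50
histoscore units are discordant.  Scores are dichotomized (median by
default) into high/low groups and compared with the Kaplan-Meier
product-limit estimator, the log-rank test and the restricted-mean
survival difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

HISTOSCORE_WEIGHTS = (0.0, 1.0, 2.0, 3.0)
STAIN_COLUMNS = ("pct_unstained", "pct_weak", "pct_moderate", "pct_strong")
DISCORDANCE_LIMIT = 50.0  # strictly more than 50 units apart = discordant
ICC_ACCEPTABLE = 0.8


@dataclass
class ConcordanceReport:
    icc: float
    icc_type: str
    bland_altman_bias: float
    bland_altman_limits: tuple[float, float]
    discordant_patients: list
    acceptable: bool
    n_pairs: int


@dataclass
class SurvivalFit:
    """Per-group Kaplan-Meier fits plus the log-rank comparison."""

    fitters: dict  # group -> lifelines.KaplanMeierFitter
    logrank_statistic: float
    p_value: float
    rmst: dict  # group -> restricted mean survival time (months)
    rmst_horizon: float  # common follow-up horizon used for the RMST (months)

    def rmst_difference(self, group_a: str, group_b: str) -> float:
        """Restricted-mean survival difference (months), group_a - group_b."""
        return self.rmst[group_a] - self.rmst[group_b]

    def survival_function(self, group: str) -> pd.DataFrame:
        return self.fitters[group].survival_function_


def weighted_histoscore(pct_unstained: float, pct_weak: float,
                        pct_moderate: float, pct_strong: float,
                        sum_tolerance: float = 0.5) -> float:
    """Weighted histoscore 0*u + 1*w + 2*m + 3*s, range 0 (all unstained) to
    300 (all strongly stained).

    Percentages must each lie in [0, 100] and sum to 100 within
    ``sum_tolerance``.
    """
    fractions = np.array([pct_unstained, pct_weak, pct_moderate, pct_strong], dtype=float)
    if not np.isfinite(fractions).all():
        raise ValueError("staining percentages must be finite")
    if ((fractions < 0) | (fractions > 100)).any():
        raise ValueError(f"staining percentages outside [0, 100]: {fractions.tolist()}")
    total = fractions.sum()
    if abs(total - 100.0) > sum_tolerance:
        raise ValueError(f"staining percentages sum to {total}, expected 100 "
                         f"(tolerance {sum_tolerance})")
    return float(fractions @ HISTOSCORE_WEIGHTS)


def score_table(tma: pd.DataFrame, sum_tolerance: float = 0.5) -> pd.DataFrame:
    """Histoscore for every row of a TMA table with the four ``pct_*``
    staining columns; appends a ``histoscore`` column."""
    missing = set(STAIN_COLUMNS) - set(tma.columns)
    if missing:
        raise ValueError(f"TMA table missing columns: {sorted(missing)}")
    out = tma.copy()
    out["histoscore"] = [
        weighted_histoscore(*row, sum_tolerance=sum_tolerance)
        for row in tma[list(STAIN_COLUMNS)].to_numpy(dtype=float)
    ]
    return out


def concordance(scores_obs1: pd.Series, scores_obs2: pd.Series) -> ConcordanceReport:
    """Dual-observer agreement: ICC(2,1), Bland-Altman bias/limits and the
    list of discordant patients (|difference| strictly greater than 50).

    Both series must be indexed by patient; unpaired patients raise.
    """
    unpaired = scores_obs1.index.symmetric_difference(scores_obs2.index)
    if len(unpaired):
        raise ValueError(f"unpaired patients: {list(unpaired[:10])}")
    if len(scores_obs1) < 3:
        raise ValueError("need >= 3 paired scores for concordance")
    s1 = scores_obs1.sort_index().astype(float)
    s2 = scores_obs2.reindex(s1.index).astype(float)

    icc = _icc2_single_rater(s1.to_numpy(), s2.to_numpy())
    diff = s2 - s1
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    limits = (bias - 1.96 * sd, bias + 1.96 * sd)
    discordant = diff.index[diff.abs() > DISCORDANCE_LIMIT].tolist()
    return ConcordanceReport(
        icc=icc, icc_type="ICC2 (two-way random, absolute agreement, single rater)",
        bland_altman_bias=bias, bland_altman_limits=limits,
        discordant_patients=discordant, acceptable=bool(icc > ICC_ACCEPTABLE),
        n_pairs=len(s1),
    )


def _icc2_single_rater(s1: np.ndarray, s2: np.ndarray) -> float:
    """ICC(2,1) via pingouin; identical raters (zero residual variance) are
    a valid perfect-agreement edge case and return 1.0."""
    if np.array_equal(s1, s2):
        return 1.0
    import pingouin as pg  # deferred: pingouin import is heavy

    n = len(s1)
    long = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["obs1", "obs2"], n),
        "score": np.concatenate([s1, s2]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(data=long, targets="target", raters="rater",
                                   ratings="score").set_index("Type")
    # pingouin labels ICC2 as "ICC2" or "ICC(A,1)" depending on version
    label = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    return float(table.loc[label, "ICC"])


def dichotomize(scores: pd.Series, method: str | float = "median"
                ) -> tuple[pd.Series, float]:
    """Split scores into 'high'/'low' at a cutoff.

    ``method`` is either the string ``"median"`` (cohort median) or an
    explicit numeric cutoff.  Scores strictly above the cutoff are 'high';
    ties at the cutoff go to 'low'.  All-equal scores cannot be split.
    """
    scores = scores.astype(float)
    if scores.nunique() < 2:
        raise ValueError("cannot dichotomize: fewer than 2 distinct score values")
    if isinstance(method, str):
        if method != "median":
            raise ValueError(f"unknown dichotomization method {method!r}")
        cutoff = float(scores.median())
    else:
        cutoff = float(method)
    labels = pd.Series(np.where(scores > cutoff, "high", "low"),
                       index=scores.index, name="nrf2_group")
    return labels, cutoff


def kaplan_meier(times, events, groups) -> SurvivalFit:
    """Kaplan-Meier product-limit estimates per group with a log-rank test
    and restricted-mean survival times.

    ``times`` (months, >= 0), ``events`` (1 = event, 0 = censored) and
    ``groups`` are parallel sequences.  With no events anywhere the log-rank
    test is undefined and is reported as p = 1 with a warning.  The RMST
    horizon is the smallest per-group maximum observed time (the common
    follow-up window).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test
    from lifelines.utils import restricted_mean_survival_time

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = pd.Series(groups).reset_index(drop=True)
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be binary (0/1)")

    fitters, rmst = {}, {}
    for g in groups.unique():
        mask = (groups == g).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} has no subjects")
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(times[mask], events[mask])
        fitters[g] = kmf
    horizon = min(float(times[(groups == g).to_numpy()].max()) for g in fitters)
    for g, kmf in fitters.items():
        rmst[g] = float(restricted_mean_survival_time(kmf, t=horizon))

    if events.sum() == 0:
        warnings.warn("no events observed in any group; log-rank undefined, "
                      "reporting p = 1", stacklevel=2)
        stat, p = float("nan"), 1.0
    else:
        res = multivariate_logrank_test(times, groups, events)
        stat, p = float(res.test_statistic), float(res.p_value)
    return SurvivalFit(fitters=fitters, logrank_statistic=stat, p_value=p,
                       rmst=rmst, rmst_horizon=horizon)


def plot_km(fit: SurvivalFit, ax=None):
    """Kaplan-Meier plot of all groups (matplotlib, optional use)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g, kmf in fit.fitters.items():
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("cancer-specific survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"log-rank p = {fit.p_value:.3g}")
    return ax
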