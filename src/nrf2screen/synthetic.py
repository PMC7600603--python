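"""Synthetic-data generators with known ground truth.

Every downstream stage (signature scoring, qPCR, TMA survival, drug screen)
is exercised against data these generators produce, so parameter recovery
can be checked in closed loop.  Defaults mirror the study design they
emulate: a colon-scale expression cohort (478 tumour / 41 normal), a
528-compound screen library (158 approved / 285 investigational / 85
probes) plated at 5 concentrations over a 10,000-fold range with DMSO
negative and benzethonium-chloride positive controls, and a 356-patient
TMA with dual-observer scoring.

All generators are pure functions of (spec, seed): the same spec yields
bitwise-identical output, and ground truth is always returned alongside the
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import stream_rng
from .screen import DSS_THRESHOLD, NEG_CTRL, POS_CTRL, LogisticFit, dss
from .signature import NRF2_5_GENE_SIGNATURE, NORMAL, TUMOUR, ExpressionCohort

CELL_LINES = ("WT", "GOF")
READOUTS = ("CTG", "CTX")

# raw-signal orientation per readout: CTG is a viability (ATP) readout where
# high signal = live cells; CTX is a cytotoxicity readout where high signal
# = dead cells.  (negative-control mean, positive-control mean) raw units:
_CONTROL_MEANS = {"CTG": (100_000.0, 2_000.0), "CTX": (2_000.0, 50_000.0)}


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Log-normal FPKM cohort with elevated signature genes in tumours.

    log2 expression = per-gene baseline + log2_effect * [signature gene and
    tumour sample] + Normal(0, noise_sd); FPKM = 2^(log2 expression).
    """

    n_tumour: int = 478
    n_normal: int = 41
    n_genes: int = 1000
    signature_genes: tuple[str, ...] = NRF2_5_GENE_SIGNATURE
    log2_effect: float = 1.0
    noise_sd: float = 0.5
    genes: tuple[str, ...] | None = None  # explicit universe (optional)
    seed: int = 0
    name: str = "synthetic-cohort"

    def __post_init__(self) -> None:
        if self.n_tumour < 2 or self.n_normal < 2:
            raise ValueError("need n_tumour >= 2 and n_normal >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.genes is not None:
            missing = set(self.signature_genes) - set(self.genes)
            if missing:
                raise ValueError(f"signature genes absent from gene universe: {sorted(missing)}")
        elif self.n_genes < len(self.signature_genes):
            raise ValueError("n_genes smaller than the signature gene set")

    @property
    def gene_universe(self) -> tuple[str, ...]:
        if self.genes is not None:
            return tuple(self.genes)
        n_fill = self.n_genes - len(self.signature_genes)
        fillers = tuple(f"GENE{i:05d}" for i in range(n_fill))
        return tuple(self.signature_genes) + fillers


def generate_expression_cohort(spec: CohortSpec) -> ExpressionCohort:
    """Genes x samples FPKM-like matrix with tumour/normal labels.

    Tumour samples have signature-gene expression multiplied by
    2^log2_effect in expectation; all values strictly positive.
    """
    rng = stream_rng(spec.seed, "cohort")
    genes = list(spec.gene_universe)
    n_genes = len(genes)
    n_samples = spec.n_tumour + spec.n_normal

    baseline = rng.normal(loc=3.0, scale=1.5, size=n_genes)  # log2 FPKM
    noise = rng.normal(scale=spec.noise_sd, size=(n_genes, n_samples))
    log2 = baseline[:, None] + noise

    is_sig = np.isin(genes, list(spec.signature_genes))
    log2[np.ix_(is_sig, np.arange(spec.n_tumour))] += spec.log2_effect

    samples = [f"T{i:04d}" for i in range(spec.n_tumour)] + \
              [f"N{i:04d}" for i in range(spec.n_normal)]
    labels = pd.Series([TUMOUR] * spec.n_tumour + [NORMAL] * spec.n_normal,
                       index=samples, name="class")
    values = pd.DataFrame(2.0 ** log2, index=pd.Index(genes, name="gene"),
                          columns=samples)
    return ExpressionCohort(values=values, labels=labels, name=spec.name)


# ---------------------------------------------------------------------------
# drug-screen plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSpec:
    """384-well dual-readout screen of an isogenic WT/GOF pair.

    Compounds fall into three ground-truth activity classes: ``inactive``
    (maximal effect below the DSS activity threshold), ``shared`` (equally
    active in both lines) and ``differential`` (GOF-selective with true
    delta-DSS >= min_true_delta_dss).  Both readouts share a compound's
    true effect profile per line; only the raw-signal orientation differs.
    """

    n_compounds: int = 528
    composition: tuple[tuple[str, int], ...] = (
        ("approved", 158), ("investigational", 285), ("probe", 85))
    n_doses: int = 5
    dose_range_fold: float = 10_000.0
    cmax_nM: float = 10_000.0
    control_wells: tuple[int, int] = (16, 8)  # (negative, positive) per plate
    noise_cv: float = 0.05
    fraction_differential: float = 0.06
    fraction_shared_active: float = 0.24
    min_true_delta_dss: float = 8.0
    true_profiles: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(n for _, n in self.composition)
        if total != self.n_compounds:
            raise ValueError(
                f"composition sums to {total}, expected n_compounds={self.n_compounds}")
        if self.n_doses < 2:
            raise ValueError("n_doses must be >= 2")
        if self.dose_range_fold <= 1:
            raise ValueError("dose_range_fold must be > 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def doses_nM(self) -> np.ndarray:
        """Log-spaced dose series: consecutive ratio dose_range_fold^(1/(n-1))."""
        cmin = self.cmax_nM / self.dose_range_fold
        return np.geomspace(cmin, self.cmax_nM, self.n_doses)


def _true_dss(bottom, top, ec50, slope, cmin, cmax) -> float:
    fit = LogisticFit(bottom=bottom, top=top, ec50=ec50, hill_slope=slope,
                      converged=True, residual_sd=0.0)
    return dss(fit, cmin, cmax, DSS_THRESHOLD).dss


def _draw_profiles(spec: ScreenSpec, rng: np.random.Generator) -> pd.DataFrame:
    names, categories = [], []
    for cat, n in spec.composition:
        prefix = cat[:3].upper()
        for i in range(n):
            names.append(f"{prefix}-{i + 1:04d}")
            categories.append(cat)

    n = spec.n_compounds
    n_diff = int(round(n * spec.fraction_differential))
    n_shared = int(round(n * spec.fraction_shared_active))
    classes = np.array(["differential"] * n_diff + ["shared"] * n_shared
                       + ["inactive"] * (n - n_diff - n_shared))
    rng.shuffle(classes)

    cmin, cmax = float(spec.doses_nM[0]), float(spec.doses_nM[-1])
    rows = []
    for comp, cat, cls in zip(names, categories, classes):
        if cls == "inactive":
            top = rng.uniform(0.0, 8.0)
            ec50 = np.exp(rng.uniform(np.log(cmin), np.log(cmax)))
            slope = rng.uniform(0.5, 2.0)
            params = {line: (0.0, top, ec50, slope) for line in CELL_LINES}
        elif cls == "shared":
            top = rng.uniform(40.0, 100.0)
            ec50 = np.exp(rng.uniform(np.log(cmin * 10), np.log(cmax / 10)))
            slope = rng.uniform(0.7, 2.0)
            params = {line: (0.0, top, ec50, slope) for line in CELL_LINES}
        else:  # differential: GOF-selective; redraw until delta-DSS clears the floor
            for _ in range(200):
                top = rng.uniform(75.0, 100.0)
                ec50_gof = np.exp(rng.uniform(np.log(cmin * 10), np.log(cmax / 30)))
                slope = rng.uniform(0.8, 2.0)
                shift = 10.0 ** rng.uniform(1.5, 3.0)
                ec50_wt = ec50_gof * shift
                delta = (_true_dss(0.0, top, ec50_gof, slope, cmin, cmax)
                         - _true_dss(0.0, top, ec50_wt, slope, cmin, cmax))
                if delta >= spec.min_true_delta_dss:
                    break
            params = {"WT": (0.0, top, ec50_wt, slope),
                      "GOF": (0.0, top, ec50_gof, slope)}
        for line in CELL_LINES:
            b, t, e, s = params[line]
            rows.append(dict(compound=comp, category=cat, activity_class=cls,
                             cell_line=line, bottom=b, top=t, ec50_nM=e, slope=s))
    return pd.DataFrame(rows)


def generate_screen_plates(spec: ScreenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw 384-well plate tables for two cell lines x two readouts, plus the
    ground-truth profile table.

    Returns ``(plates, truth)``.  ``plates`` columns: plate, well, compound,
    dose_nM, cell_line, readout, signal (raw units); control wells carry
    NEG_CTRL/POS_CTRL in the compound column with dose_nM = 0.  ``truth``
    holds per compound x line the 4PL parameters, the true DSS over the
    tested range and the per-compound true delta-DSS.
    """
    rng = stream_rng(spec.seed, "screen")
    if spec.true_profiles is not None:
        truth = spec.true_profiles.copy()
        required = {"compound", "cell_line", "bottom", "top", "ec50_nM", "slope"}
        if not required <= set(truth.columns):
            raise ValueError(f"true_profiles needs columns {sorted(required)}")
    else:
        truth = _draw_profiles(spec, rng)

    doses = spec.doses_nM
    cmin, cmax = float(doses[0]), float(doses[-1])
    truth["true_dss"] = [
        _true_dss(r.bottom, r.top, r.ec50_nM, r.slope, cmin, cmax)
        for r in truth.itertuples()
    ]
    wide = truth.pivot_table(index="compound", columns="cell_line",
                             values="true_dss", aggfunc="first")
    delta = (wide["GOF"] - wide["WT"]).rename("true_delta_dss")
    truth = truth.merge(delta, on="compound", how="left")

    compounds = truth["compound"].drop_duplicates().tolist()
    n_neg, n_pos = spec.control_wells
    per_plate = (384 - n_neg - n_pos) // spec.n_doses
    if per_plate < 1:
        raise ValueError("control wells leave no room for compounds on a 384-well plate")

    well_labels = [f"{r}{c:02d}" for r in "ABCDEFGHIJKLMNOP" for c in range(1, 25)]
    params = {(r.compound, r.cell_line): (r.bottom, r.top, r.ec50_nM, r.slope)
              for r in truth.itertuples()}

    plate_ids, wells, comp_col, dose_col = [], [], [], []
    for p_start in range(0, len(compounds), per_plate):
        plate = f"P{p_start // per_plate + 1:02d}"
        chunk = compounds[p_start:p_start + per_plate]
        idx = 0
        for _ in range(n_neg):
            plate_ids.append(plate); wells.append(well_labels[idx])
            comp_col.append(NEG_CTRL); dose_col.append(0.0); idx += 1
        for _ in range(n_pos):
            plate_ids.append(plate); wells.append(well_labels[idx])
            comp_col.append(POS_CTRL); dose_col.append(0.0); idx += 1
        for comp in chunk:
            for d in doses:
                plate_ids.append(plate); wells.append(well_labels[idx])
                comp_col.append(comp); dose_col.append(float(d)); idx += 1

    layout = pd.DataFrame(dict(plate=plate_ids, well=wells,
                               compound=comp_col, dose_nM=dose_col))

    frames = []
    for line in CELL_LINES:
        for readout in READOUTS:
            neg_mean, pos_mean = _CONTROL_MEANS[readout]
            df = layout.copy()
            df["cell_line"] = line
            df["readout"] = readout
            effect = np.zeros(len(df))
            is_cmp = ~df["compound"].isin([NEG_CTRL, POS_CTRL])
            idx = np.flatnonzero(is_cmp.to_numpy())
            par = np.array([params[(c, line)]
                            for c in df.loc[idx, "compound"]])  # (n, 4)
            x = np.log10(df.loc[idx, "dose_nM"].to_numpy(dtype=float))
            b, t, e, s = par[:, 0], par[:, 1], par[:, 2], par[:, 3]
            effect[idx] = b + (t - b) / (1.0 + 10.0 ** (s * (np.log10(e) - x)))
            effect[(df["compound"] == POS_CTRL).to_numpy()] = 100.0
            clean = neg_mean + effect / 100.0 * (pos_mean - neg_mean)
            if spec.noise_cv > 0:
                clean = clean * (1.0 + spec.noise_cv * rng.standard_normal(len(df)))
            df["signal"] = np.clip(clean, 0.0, None)
            frames.append(df)
    plates = pd.concat(frames, ignore_index=True)
    return plates, truth


# ---------------------------------------------------------------------------
# TMA cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TmaSpec:
    """TMA cohort: staining fractions per patient for two observers plus
    exponential survival with a proportional hazard for the high-NRF2 group.

    Censoring: each subject is independently censored with probability
    ``censor_rate`` at a time uniform on (0, event time).
    """

    n_patients: int = 356
    high_fraction: float = 0.5
    hazard_ratio: float = 2.0
    censor_rate: float = 0.3
    observer2_noise: float = 5.0  # SD (percentage points) of obs2 perturbation
    median_survival_low_months: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.high_fraction < 1:
            raise ValueError("high_fraction must be in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


# Dirichlet concentrations over (unstained, weak, moderate, strong): the
# high-NRF2 group is skewed toward strong staining.
_ALPHA_LOW = np.array([10.0, 6.0, 3.0, 1.0])
_ALPHA_HIGH = np.array([1.0, 3.0, 6.0, 10.0])


def generate_tma_cohort(spec: TmaSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient staining percentages for two observers plus survival.

    Returns ``(tma, truth)``.  ``tma`` is long by observer with columns
    patient, observer, pct_unstained, pct_weak, pct_moderate, pct_strong,
    time_months, event; percentages sum to 100 per row.  ``truth`` holds the
    generating group and uncensored event time per patient.
    """
    rng = stream_rng(spec.seed, "tma")
    n = spec.n_patients
    n_high = int(round(n * spec.high_fraction))
    group = np.array(["high"] * n_high + ["low"] * (n - n_high))
    rng.shuffle(group)
    patients = [f"PT{i:04d}" for i in range(n)]

    frac1 = np.empty((n, 4))
    for i, g in enumerate(group):
        alpha = _ALPHA_HIGH if g == "high" else _ALPHA_LOW
        frac1[i] = rng.dirichlet(alpha) * 100.0

    if spec.observer2_noise > 0:
        pert = frac1 + rng.normal(scale=spec.observer2_noise, size=frac1.shape)
        pert = np.clip(pert, 0.0, None)
        sums = pert.sum(axis=1, keepdims=True)
        degenerate = (sums == 0).ravel()
        pert[degenerate] = frac1[degenerate]
        sums[degenerate] = 100.0
        frac2 = pert / pert.sum(axis=1, keepdims=True) * 100.0
    else:
        frac2 = frac1.copy()

    lam_low = np.log(2.0) / spec.median_survival_low_months
    lam = np.where(group == "high", lam_low * spec.hazard_ratio, lam_low)
    t_event = rng.exponential(1.0 / lam)
    censored = rng.random(n) < spec.censor_rate
    time = np.where(censored, rng.uniform(0.0, t_event), t_event)
    event = (~censored).astype(int)

    def frame(obs: int, frac: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(dict(
            patient=patients, observer=obs,
            pct_unstained=frac[:, 0], pct_weak=frac[:, 1],
            pct_moderate=frac[:, 2], pct_strong=frac[:, 3],
            time_months=time, event=event,
        ))

    tma = pd.concat([frame(1, frac1), frame(2, frac2)], ignore_index=True)
    truth = pd.DataFrame(dict(patient=patients, group=group,
                              event_time_months=t_event, censored=censored))
    return tma, truth


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def generate_qpcr_table(conditions, true_fold_changes, ct_noise: float = 0.2,
                        seed: int = 0, n_replicates: int = 3,
                        reference: str | None = None,
                        housekeeping_gene: str = "HPRT1") -> pd.DataFrame:
    """Ct table whose delta-delta-CT analysis recovers ``true_fold_changes``.

    ``true_fold_changes`` maps gene -> {condition -> fold vs reference};
    the reference condition (default: first of ``conditions``) is pinned to
    fold 1.  Ct model: housekeeping Ct ~ 20 + noise per sample, target Ct =
    housekeeping Ct + per-gene baseline dCt - log2(fold) + noise, so
    2^-ddCt equals the true fold in expectation (exactly at zero noise).
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("need at least one condition")
    reference = conditions[0] if reference is None else reference
    if reference not in conditions:
        raise ValueError(f"reference {reference!r} not among conditions")
    if ct_noise < 0:
        raise ValueError("ct_noise must be >= 0")
    rng = stream_rng(seed, "qpcr")

    genes = list(true_fold_changes)
    base_dct = {g: rng.uniform(3.0, 8.0) for g in genes}

    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_r{rep}"
            hk_ct = 20.0 + (rng.normal(scale=ct_noise) if ct_noise else 0.0)
            for gene in genes:
                fold = 1.0 if cond == reference else float(
                    true_fold_changes[gene].get(cond, 1.0))
                if fold <= 0:
                    raise ValueError(f"fold change must be > 0 ({gene}/{cond})")
                ct = (hk_ct + base_dct[gene] - np.log2(fold)
                      + (rng.normal(scale=ct_noise) if ct_noise else 0.0))
                rows.append(dict(sample=sample, condition=cond, gene=gene,
                                 housekeeping_gene=housekeeping_gene,
                                 ct=ct, housekeeping_ct=hk_ct, replicate=rep))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inducer-sensitization viability tables
# ---------------------------------------------------------------------------

def generate_sensitization_table(
    inducers=("DMSO", "SFN", "TBE31", "HB229"),
    at9283_doses_nM=(0.0, 80.0, 200.0),
    at_alone_drop_pct=None,
    combo_drop_pct=None,
    inducer_toxicity_pct: float = 0.0,
    noise_sd_pct: float = 3.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw viability signals for an inducer x AT9283-dose factorial.

    In the DMSO arm AT9283 alone drops viability by ``at_alone_drop_pct``
    (default: a few percent, i.e. essentially inactive at these doses); in
    inducer arms the combination drops it by ``combo_drop_pct``.  The
    inducer alone reduces viability by ``inducer_toxicity_pct`` (default 0).
    All wells share one raw-signal scale, as on a real plate.
    """
    if at_alone_drop_pct is None:
        at_alone_drop_pct = {80.0: 2.0, 200.0: 5.0}
    if combo_drop_pct is None:
        combo_drop_pct = {80.0: 25.0, 200.0: 45.0}
    rng = stream_rng(seed, "sensitization")

    rows = []
    scale = 50_000.0
    for ind in inducers:
        base = 100.0 - (inducer_toxicity_pct if ind != "DMSO" else 0.0)
        for dose in at9283_doses_nM:
            if dose == 0:
                drop = 0.0
            elif ind == "DMSO":
                drop = float(at_alone_drop_pct.get(dose, 0.0))
            else:
                drop = float(combo_drop_pct.get(dose, 0.0))
            for rep in range(1, n_replicates + 1):
                viability = max(base - drop + rng.normal(scale=noise_sd_pct), 0.0)
                rows.append(dict(inducer=ind, at9283_nM=float(dose), replicate=rep,
                                 signal=scale * viability / 100.0))
    return pd.DataFrame(rows)
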