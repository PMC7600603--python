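"""Umbrella pipeline tying the stages into the end-to-end narrative:
simulate -> signature -> qpcr -> tma -> screen, with per-stage isolation
and a run manifest.

The default configuration is a demonstration-scale run (small cohort and
library) so the whole chain executes in seconds; study-scale sizes are a
config change away (e.g. ``screen: {n_compounds: 528}``).
"""

from __future__ import annotations

import time
import traceback
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

from . import io as nio
from ._util import write_dataframe
from .qpcr import delta_delta_ct, flag_array_genes
from .screen import analyze_screen
from .signature import run_signature_panel
from .synthetic import (CohortSpec, ScreenSpec, TmaSpec,
                        generate_expression_cohort, generate_qpcr_table,
                        generate_screen_plates, generate_tma_cohort)
from .tma import concordance, dichotomize, kaplan_meier, score_table

try:
    __version__ = version("nrf2screen")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"

#: demonstration-scale defaults; override any key via the config mapping
DEMO_CONFIG = {
    "cohort": {"n_tumour": 60, "n_normal": 25, "n_genes": 300,
               "log2_effect": 1.0, "noise_sd": 0.5},
    "screen": {"n_compounds": 60,
               "composition": (("approved", 18), ("investigational", 32), ("probe", 10)),
               "noise_cv": 0.05},
    "tma": {"n_patients": 120, "hazard_ratio": 2.0, "censor_rate": 0.3},
    "qpcr": {"conditions": ["WT_DMSO", "GOF_DMSO"],
             "true_fold_changes": {"NQO1": {"GOF_DMSO": 8.0},
                                   "AKR1B10": {"GOF_DMSO": 4.0},
                                   "NFE2L2": {"GOF_DMSO": 1.0}},
             "ct_noise": 0.1},
    "cutoff": "median",
}


def _merged(config: dict | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEMO_CONFIG.items()}
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _normalize_composition(screen_cfg: dict) -> dict:
    comp = screen_cfg.get("composition")
    if comp is not None:
        screen_cfg["composition"] = tuple((str(c), int(n)) for c, n in comp)
    return screen_cfg


def run_pipeline(out_dir, seed: int = 0, config: dict | None = None) -> dict:
    """Run every stage on freshly simulated data; write outputs under
    ``out_dir`` and return the run manifest.

    Stage failures are isolated: a failing stage is recorded in the
    manifest and the remaining stages still run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _merged(config)
    manifest: dict = {"seed": seed, "config": cfg, "software_version": __version__,
                      "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "stages": {}, "parameter_provenance": {
                          "histoscore_weights_0_1_2_3": "published rule",
                          "hit_threshold_delta_dss_gt_5_both_readouts": "published rule",
                          "array_flag_fold_gt_2_p_lt_0.05": "published rule",
                          "dss_activity_threshold_10pct": "package decision",
                          "dichotomization_median": "package decision",
                          "icc_form_ICC2_single_rater": "package decision",
                      }}
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
            manifest["stages"][name] = {"status": "ok",
                                        "seconds": round(time.perf_counter() - t0, 3)}
        except Exception as exc:  # isolate stage failures
            manifest["stages"][name] = {"status": "failed", "error": str(exc),
                                        "traceback": traceback.format_exc(limit=3)}

    def do_simulate():
        cohort = generate_expression_cohort(CohortSpec(seed=seed, **cfg["cohort"]))
        nio.write_expression_tsv(cohort, out / "expression.tsv", out / "labels.csv")
        state["cohort"] = cohort

        plates, truth = generate_screen_plates(
            ScreenSpec(seed=seed, **_normalize_composition(dict(cfg["screen"]))))
        write_dataframe(plates, out / "plates.csv")
        write_dataframe(truth, out / "screen_truth.csv")
        state["plates"] = plates

        tma, tma_truth = generate_tma_cohort(TmaSpec(seed=seed, **cfg["tma"]))
        write_dataframe(tma, out / "tma.csv")
        write_dataframe(tma_truth, out / "tma_truth.csv")
        state["tma"] = tma

        qcfg = cfg["qpcr"]
        ct = generate_qpcr_table(qcfg["conditions"], qcfg["true_fold_changes"],
                                 ct_noise=qcfg.get("ct_noise", 0.2), seed=seed)
        write_dataframe(ct, out / "qpcr_ct.csv")
        state["qpcr"] = ct

    def do_signature():
        panel = run_signature_panel(state["cohort"])
        write_dataframe(panel, out / "signature_results.csv")

    def do_qpcr():
        ct = state["qpcr"]
        reference = cfg["qpcr"]["conditions"][0]
        folds = delta_delta_ct(ct, reference)
        write_dataframe(folds, out / "qpcr_folds.csv")
        others = [c for c in cfg["qpcr"]["conditions"] if c != reference]
        if others:
            flags = flag_array_genes(ct, reference, others[0])
            write_dataframe(flags, out / "qpcr_flags.csv")

    def do_tma():
        tma = state["tma"]
        scored = score_table(tma)
        write_dataframe(scored, out / "tma_scores.csv")
        obs1 = scored[scored["observer"] == 1].set_index("patient")
        obs2 = scored[scored["observer"] == 2].set_index("patient")
        rep = concordance(obs1["histoscore"], obs2["histoscore"])
        nio.write_json({
            "icc": rep.icc, "icc_type": rep.icc_type, "acceptable": rep.acceptable,
            "bland_altman_bias": rep.bland_altman_bias,
            "bland_altman_limits": list(rep.bland_altman_limits),
            "n_discordant": len(rep.discordant_patients),
            "discordant_patients": rep.discordant_patients,
        }, out / "concordance.json")
        labels, cutoff = dichotomize(obs1["histoscore"], cfg.get("cutoff", "median"))
        fit = kaplan_meier(obs1["time_months"], obs1["event"], labels)
        nio.write_json({
            "cutoff_histoscore": cutoff,
            "logrank_statistic": fit.logrank_statistic,
            "logrank_p": fit.p_value,
            "rmst_months": fit.rmst,
            "rmst_difference_months_low_minus_high": fit.rmst_difference("low", "high"),
            "rmst_horizon_months": fit.rmst_horizon,
        }, out / "survival_summary.json")

    def do_screen():
        hits, metrics, qc = analyze_screen(state["plates"])
        write_dataframe(hits, out / "screen_hits.csv")
        write_dataframe(metrics, out / "screen_metrics.csv")
        write_dataframe(qc, out / "screen_qc.csv")

    stage("simulate", do_simulate)
    stage("signature", do_signature)
    stage("qpcr", do_qpcr)
    stage("tma", do_tma)
    stage("screen", do_screen)

    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["output_checksums"] = nio.file_checksums(sorted(out.glob("*.csv")))
    nio.write_json(manifest, out / "manifest.json")
    return manifest
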