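"""Benchmark harness for the combination methods on simulated multi-study data.

For each simulation setting and trial the driver simulates counts, runs the
per-study NB-GLM stage, assembles the union gene pool, applies each
combination method (IN with post-hoc conflict removal, MIN, FIN) and scores:

* **AUC** — probability that a true-DE gene outranks a non-DE gene when
  genes are ordered by combined p-value (Mann–Whitney with midranks);
* **empirical FDR** — false fraction of the DEG calls at BH < alpha;
* **unique-DEG TP proportion** — among genes a method calls that the IN
  baseline does not, the fraction that are truly DE;
* **direction recovery** — among truly-DE method-unique calls, the fraction
  whose effective direction matches the simulated truth.

In simulation mode DEGs are called on FDR alone (no fold-change filter);
the absolute-log2FC criterion belongs to real-data applications.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .de import DEConfig, run_study_de
from .meta import EvidenceTable, run_meta
from .simulate import (
    TABLE1_SETTINGS,
    SimParams,
    default_sim_params,
    design_for_setting,
    simulate_counts,
)

__all__ = [
    "roc_auc",
    "empirical_fdr",
    "unique_tp_proportion",
    "direction_recovery",
    "run_trial",
    "run_simulation_study",
]

logger = logging.getLogger(__name__)


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve; larger scores must mean "more likely DE"."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("AUC undefined: need both true-DE and non-DE genes")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def empirical_fdr(called: set, true_de: set) -> float:
    """Fraction of called genes that are not truly DE; 0 for an empty call set."""
    if not called:
        logger.info("empty call set; empirical FDR reported as 0")
        return 0.0
    return len(called - true_de) / len(called)


def unique_tp_proportion(calls_method: set, calls_reference: set, true_de: set) -> float:
    """Truly-DE fraction of the method-unique calls; NaN when none are unique."""
    unique = calls_method - calls_reference
    if not unique:
        return float("nan")
    return len(unique & true_de) / len(unique)


def direction_recovery(
    effective: pd.Series, true_direction: pd.Series, subset: set
) -> float:
    """Fraction of ``subset`` whose effective direction matches the truth.

    ``effective`` holds "+"/"-" strings, ``true_direction`` +1/-1.  NaN when
    the subset is empty.
    """
    if not subset:
        return float("nan")
    genes = sorted(subset)
    eff_sign = effective.loc[genes].map({"+": 1, "-": -1, "−": -1}).to_numpy()
    return float(np.mean(eff_sign == true_direction.loc[genes].to_numpy()))


def run_trial(
    params: SimParams,
    seed: int,
    *,
    methods: tuple[str, ...] = ("IN", "MIN", "FIN"),
    alpha: float = 0.05,
    de_config: DEConfig | None = None,
    fc_filter: bool = False,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """One simulation trial: simulate, per-study DE, combine, score.

    Returns one row per method with the trial's AUC, empirical FDR,
    unique-vs-IN TP proportion and direction recovery.
    """
    data = simulate_counts(params, seed=seed)
    results = {sid: run_study_de(cm, de_config) for sid, cm in data.studies.items()}

    design = params.design
    union = sorted(set().union(*(r.index for r in results.values())))
    pvals = pd.DataFrame(np.nan, index=union, columns=list(design.studies))
    lfc = pd.DataFrame(np.nan, index=union, columns=list(design.studies))
    for sid, res in results.items():
        pvals.loc[res.index, sid] = res["pvalue"].to_numpy()
        lfc.loc[res.index, sid] = res["log2FC"].to_numpy()
    evidence = EvidenceTable(design=design, pvalues=pvals, log2fc=lfc)

    truth = data.truth.loc[evidence.genes]
    true_de = set(truth.index[truth["is_de"]])
    if not true_de or len(true_de) == len(truth):
        raise ValueError("simulated universe lost one of the truth classes")

    meta = {
        m: run_meta(
            evidence, m, alpha=alpha, fc_filter=fc_filter, lfc_threshold=lfc_threshold
        ).set_index("gene")
        for m in methods
    }
    calls = {m: set(t.index[t["is_DEG"]]) for m, t in meta.items()}
    ref_calls = calls.get("IN", set())

    rows = []
    for m in methods:
        t = meta[m]
        auc = roc_auc(-t["pvalue_combined"].to_numpy(), truth["is_de"].to_numpy())
        fdr = empirical_fdr(calls[m], true_de)
        if m == "IN":
            utp, drec, n_unique = float("nan"), float("nan"), 0
        else:
            unique = calls[m] - ref_calls
            utp = unique_tp_proportion(calls[m], ref_calls, true_de)
            truly_unique = unique & true_de
            drec = direction_recovery(
                t["effective_direction"], truth["true_direction"], truly_unique
            )
            n_unique = len(unique)
        rows.append(
            {
                "method": m,
                "auc": auc,
                "empirical_fdr": fdr,
                "n_deg": len(calls[m]),
                "n_unique_vs_in": n_unique,
                "unique_tp_prop": utp,
                "direction_recovery": drec,
            }
        )
    return pd.DataFrame(rows)


def run_simulation_study(
    settings: tuple[int, ...] = (1, 2, 3, 4),
    n_trials: int = 20,
    *,
    n_genes: int = 5000,
    pi_de: float = 0.1,
    seed: int = 0,
    methods: tuple[str, ...] = ("IN", "MIN", "FIN"),
    alpha: float = 0.05,
    de_config: DEConfig | None = None,
    sim_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the multi-setting simulation benchmark.

    Each setting pairs an inter-study variability sigma (0.15 or 0.5) with a
    3- or 5-study replicate layout; every trial draws fresh generative
    parameters and counts from a seed derived as ``seed + 1000*setting +
    trial``, so runs are reproducible and trials independent.

    Returns ``(summary, per_trial)``: the summary has one row per setting and
    method with trial means (and the AUC standard deviation), the per-trial
    frame keeps every individual measurement.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    sim_kwargs = dict(sim_kwargs or {})
    per_trial = []
    for setting in settings:
        if setting not in TABLE1_SETTINGS:
            raise ValueError(f"unknown setting {setting}; expected 1-4")
        sigma = TABLE1_SETTINGS[setting]["sigma"]
        design = design_for_setting(setting)
        for trial in range(n_trials):
            trial_seed = int(seed) + 1000 * setting + trial
            params = default_sim_params(
                n_genes=n_genes,
                pi_de=pi_de,
                sigma=sigma,
                design=design,
                seed=trial_seed,
                **sim_kwargs,
            )
            res = run_trial(
                params, seed=trial_seed, methods=methods, alpha=alpha, de_config=de_config
            )
            res.insert(0, "setting", setting)
            res.insert(1, "sigma", sigma)
            res.insert(2, "n_studies", design.n_studies)
            res.insert(3, "trial", trial)
            per_trial.append(res)
    per_trial = pd.concat(per_trial, ignore_index=True)

    summary = (
        per_trial.groupby(["setting", "sigma", "n_studies", "method"], sort=True)
        .agg(
            mean_auc=("auc", "mean"),
            sd_auc=("auc", "std"),
            mean_fdr=("empirical_fdr", "mean"),
            mean_n_deg=("n_deg", "mean"),
            mean_n_unique=("n_unique_vs_in", "mean"),
            unique_tp_prop=("unique_tp_prop", "mean"),
            direction_recovery=("direction_recovery", "mean"),
            n_trials=("trial", "count"),
        )
        .reset_index()
    )
    return summary, per_trial
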