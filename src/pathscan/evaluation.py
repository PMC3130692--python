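"""Type I error, power, joint power, sensitivity, specificity of the scan test.

All measures are estimated over replicated simulated datasets.  Each dataset
gets its own permutation critical value (the ceil(α(B+1))-th highest null scan
maximum); the null is rejected when the observed scan statistic exceeds it.
At cluster risk ratio 1 the rejection proportion is the empirical type I
error.  Joint power additionally demands exact recovery of the true cluster's
member set; sensitivity and specificity grade partial recovery of the most
likely cluster against the planted cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv_data import Cohort
from .pathway_graph import PathwayGraph, Window, dedupe_windows, enumerate_windows, truncated_distances
from .scan_statistic import WindowMatrix, permutation_test
from .simulator import DiseaseModel, simulate_dataset

__all__ = [
    "EvaluationReport",
    "DatasetOutcome",
    "critical_value",
    "run_datasets",
    "standard_power",
    "joint_power",
    "sensitivity_specificity",
    "evaluate_crr_grid",
]


def critical_value(null_maxima: Sequence[float], alpha: float = 0.05) -> float:
    """The ceil(α(B+1))-th highest of B null scan maxima.

    For α = 0.05 and B = 999 this is the 50th highest value; for B = 19 it is
    the maximum.  Raises when α(B+1) exceeds B (no attainable critical value —
    choose B with α(B+1) <= B, e.g. B = 999 for α = 0.05).
    """
    vals = np.asarray(null_maxima, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("null_maxima must be non-empty")
    k = math.ceil(alpha * (vals.size + 1))
    if k < 1 or k > vals.size:
        raise ValueError(
            f"alpha*(B+1) = {alpha * (vals.size + 1):.3g} gives no attainable "
            f"critical value for B={vals.size}; use B >= ceil(1/alpha) - 1")
    return float(np.sort(vals)[::-1][k - 1])


@dataclass
class DatasetOutcome:
    """Per-dataset scan summary used by all evaluation measures."""

    scan_T: float | None
    critical: float
    rejected: bool
    detected: frozenset  # most likely cluster's member set (empty if no window)
    p_value: float


@dataclass
class EvaluationReport:
    crr: float
    n_datasets: int
    rejection_rate: float  # standard power; type I error at CRR = 1
    joint_power: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict:
        return {
            "crr": self.crr,
            "n_datasets": self.n_datasets,
            "rejection_rate": self.rejection_rate,
            "joint_power": self.joint_power,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def run_datasets(datasets: Sequence[Cohort], windows: list[Window],
                 alpha: float = 0.05, B: int = 999,
                 seed: int | None = None,
                 wm: WindowMatrix | None = None) -> list[DatasetOutcome]:
    """Permutation-test every dataset against its own critical value."""
    if wm is None:
        wm = WindowMatrix(windows)
    ss = np.random.SeedSequence(seed)
    outcomes = []
    for cohort, child in zip(datasets, ss.spawn(len(datasets))):
        rng = np.random.default_rng(child)
        res = permutation_test(cohort, windows, B=B, rng=rng, wm=wm)
        crit = critical_value(res.null_T, alpha)
        obs = res.scan_T if res.scan_T is not None else -np.inf
        detected = (res.most_likely.window.members
                    if res.most_likely is not None else frozenset())
        outcomes.append(DatasetOutcome(
            scan_T=res.scan_T, critical=crit, rejected=bool(obs > crit),
            detected=detected, p_value=res.p_value))
    return outcomes


def standard_power(datasets: Sequence[Cohort], windows: list[Window],
                   alpha: float = 0.05, B: int = 999,
                   seed: int | None = None) -> float:
    """Rejection proportion (empirical type I error when data are null)."""
    outcomes = run_datasets(datasets, windows, alpha=alpha, B=B, seed=seed)
    return _standard_power(outcomes)


def _standard_power(outcomes: Sequence[DatasetOutcome]) -> float:
    return float(np.mean([o.rejected for o in outcomes]))


def joint_power(datasets: Sequence[Cohort], windows: list[Window],
                true_cluster: frozenset, alpha: float = 0.05, B: int = 999,
                seed: int | None = None) -> float:
    """Proportion rejecting AND recovering the true member set exactly.

    Any discrepancy — even one extra or missing gene — counts as failure to
    detect.
    """
    outcomes = run_datasets(datasets, windows, alpha=alpha, B=B, seed=seed)
    return _joint_power(outcomes, true_cluster)


def _joint_power(outcomes: Sequence[DatasetOutcome],
                 true_cluster: frozenset) -> float:
    return float(np.mean([o.rejected and o.detected == true_cluster
                          for o in outcomes]))


def sensitivity_specificity(datasets: Sequence[Cohort], windows: list[Window],
                            true_cluster: frozenset,
                            pathway_genes: Sequence[str],
                            alpha: float = 0.05, B: int = 999,
                            seed: int | None = None,
                            condition_on_rejection: bool = False
                            ) -> tuple[float, float]:
    """Mean per-dataset recovery of the true cluster by the most likely cluster.

    sensitivity = |detected ∩ true| / |true|;
    specificity = |non-detected ∩ non-true| / |non-true|, complements within
    the pathway gene universe.  By default every dataset's most likely cluster
    contributes; with ``condition_on_rejection`` only rejected datasets are
    averaged (nan when none reject).
    """
    outcomes = run_datasets(datasets, windows, alpha=alpha, B=B, seed=seed)
    return _sens_spec(outcomes, true_cluster, pathway_genes,
                      condition_on_rejection)


def _sens_spec(outcomes: Sequence[DatasetOutcome], true_cluster: frozenset,
               pathway_genes: Sequence[str],
               condition_on_rejection: bool = False) -> tuple[float, float]:
    universe = frozenset(pathway_genes)
    if not true_cluster or not true_cluster <= universe:
        raise ValueError("true_cluster must be a non-empty subset of the pathway")
    non_true = universe - true_cluster
    sens, spec = [], []
    for o in outcomes:
        if condition_on_rejection and not o.rejected:
            continue
        detected = o.detected & universe
        sens.append(len(detected & true_cluster) / len(true_cluster))
        spec.append(len(non_true - detected) / len(non_true) if non_true else 1.0)
    if not sens:
        return float("nan"), float("nan")
    return float(np.mean(sens)), float(np.mean(spec))


def evaluate_crr_grid(graph: PathwayGraph, cluster: frozenset,
                      crr_grid: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0),
                      n_datasets: int = 100, n_cases: int = 200,
                      n_controls: int = 200, p: float = 1e-4,
                      prevalence: float = 0.01, R: int = 4, B: int = 199,
                      alpha: float = 0.05, seed: int | None = None,
                      condition_on_rejection: bool = False,
                      ) -> list[EvaluationReport]:
    """Full evaluation over a grid of cluster risk ratios.

    Shared seeds: dataset i uses the same simulation and permutation random
    streams at every CRR level (common random numbers), so power differences
    across the grid are not masked by simulation noise.
    """
    d = truncated_distances(graph, R)
    windows = dedupe_windows(enumerate_windows(graph, d, R))
    wm = WindowMatrix(windows)
    ss = np.random.SeedSequence(seed)
    sim_seeds, perm_seeds = ss.spawn(2)
    sim_children = sim_seeds.spawn(n_datasets)
    perm_children = perm_seeds.spawn(n_datasets)

    reports = []
    for crr in crr_grid:
        model = DiseaseModel.from_cluster(cluster, p=p, K=prevalence, gamma=crr)
        outcomes = []
        for i in range(n_datasets):
            cohort = simulate_dataset(model, graph.genes, n_cases, n_controls,
                                      rng=np.random.default_rng(sim_children[i]))
            res = permutation_test(cohort, windows, B=B, wm=wm,
                                   rng=np.random.default_rng(perm_children[i]))
            crit = critical_value(res.null_T, alpha)
            obs = res.scan_T if res.scan_T is not None else -np.inf
            detected = (res.most_likely.window.members
                        if res.most_likely is not None else frozenset())
            outcomes.append(DatasetOutcome(
                scan_T=res.scan_T, critical=crit, rejected=bool(obs > crit),
                detected=detected, p_value=res.p_value))
        sens, spec = _sens_spec(outcomes, cluster, graph.genes,
                                condition_on_rejection)
        reports.append(EvaluationReport(
            crr=crr, n_datasets=n_datasets,
            rejection_rate=_standard_power(outcomes),
            joint_power=_joint_power(outcomes, cluster),
            sensitivity=sens, specificity=spec))
    return reports


def reports_to_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])
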