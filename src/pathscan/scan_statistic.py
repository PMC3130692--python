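"""Locality statistic, graph scan statistic, permutation test, secondary clusters.

For a window Z let sum_x = Σ_i x_i(Z) and sum_y = Σ_i y_i(Z) be the numbers of
affected-gene incidences falling in Z over cases and controls, and n1, n0 the
pathway-wide totals.  The locality statistic is the pooled-variance
two-proportion z statistic

    T(Z) = (φ1 − φ0) / sqrt( φ̄ (1 − φ̄) (1/n1 + 1/n0) ),

with φ1 = sum_x/n1, φ0 = sum_y/n0 and pooled φ̄ = (sum_x+sum_y)/(n1+n0) — the
signed form of the cumulative minor-allele test (CMAT) statistic.  Large
positive T means case excess; the test is one-tailed.  The scan statistic is
the maximum T over all windows with sum_x > 0, and its null distribution comes
from permuting the case/control labels (subjects keep their gene sets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .cnv_data import Cohort
from .pathway_graph import Window

__all__ = [
    "LocalityResult",
    "ScanResult",
    "WindowMatrix",
    "locality_statistic",
    "scan",
    "permutation_test",
    "secondary_clusters",
]


def locality_statistic(sum_x: int, sum_y: int, n1: int, n0: int) -> float:
    """Pooled two-proportion z for one window (scalar form).

    Defined only for n1, n0 > 0 and sum_x >= 1, and only when the pooled
    proportion is strictly inside (0, 1); otherwise raises ValueError (the
    scan simply skips such windows).
    """
    if n1 <= 0 or n0 <= 0:
        raise ValueError("locality statistic requires n1 > 0 and n0 > 0")
    if sum_x < 1:
        raise ValueError("locality statistic requires sum_x >= 1")
    if sum_x > n1 or sum_y > n0:
        raise ValueError("window counts cannot exceed group totals")
    pooled = (sum_x + sum_y) / (n1 + n0)
    if pooled <= 0 or pooled >= 1:
        raise ValueError("pooled proportion degenerate; window undefined")
    phi1 = sum_x / n1
    phi0 = sum_y / n0
    return (phi1 - phi0) / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n0))


@dataclass(frozen=True)
class LocalityResult:
    window: Window
    sum_x: int
    sum_y: int
    T: float


@dataclass
class ScanResult:
    """Ranked windows, the scan maximum, and (after permutation) the p-value."""

    ranked: list[LocalityResult]
    scan_T: float | None
    most_likely: LocalityResult | None
    null_T: np.ndarray | None = None
    p_value: float | None = None
    secondary: list[tuple[LocalityResult, float]] = field(default_factory=list)
    n_permutations: int | None = None
    seed: int | None = None


class WindowMatrix:
    """Sparse window-by-gene membership matrix for vectorised scanning."""

    def __init__(self, windows: list[Window]):
        self.windows = windows
        genes = sorted(set().union(*(w.members for w in windows))) if windows else []
        self.genes = genes
        self.gene_index = {g: i for i, g in enumerate(genes)}
        rows, cols = [], []
        for wi, w in enumerate(windows):
            for g in w.members:
                rows.append(wi)
                cols.append(self.gene_index[g])
        self.M = sparse.csr_matrix(
            (np.ones(len(rows), dtype=np.float64), (rows, cols)),
            shape=(len(windows), len(genes)),
        )
        self.sizes = np.array([w.size for w in windows], dtype=np.int64)

    def subject_gene_matrix(self, cohort: Cohort) -> np.ndarray:
        """Dense (n_subjects x n_window_genes) 0/1 matrix of affected genes."""
        A = np.zeros((cohort.n_subjects, len(self.genes)), dtype=np.float64)
        for i, genes in enumerate(cohort.affected):
            for g in genes:
                j = self.gene_index.get(g)
                if j is not None:
                    A[i, j] = 1.0
        return A


def _vector_T(sx: np.ndarray, sy: np.ndarray,
              n1: np.ndarray | float, n0: np.ndarray | float) -> np.ndarray:
    """Vectorised T; undefined windows get -inf.

    ``sx``/``sy`` may be 1-D (one dataset) or 2-D (replicates x windows) with
    ``n1``/``n0`` broadcastable column vectors.
    """
    n1 = np.asarray(n1, dtype=np.float64)
    n0 = np.asarray(n0, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (sx + sy) / (n1 + n0)
        phi1 = sx / n1
        phi0 = sy / n0
        var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n0)
        T = (phi1 - phi0) / np.sqrt(var)
    bad = (sx < 1) | (pooled <= 0) | (pooled >= 1) | (n1 <= 0) | (n0 <= 0)
    T = np.where(bad, -np.inf, T)
    return T


def _rank_key(lr: LocalityResult):
    # descending T; ties prefer the smaller window, then the smaller center
    # id, then the smaller radius (parsimony: circular scans tend to absorb
    # surrounding null genes).
    return (-lr.T, lr.window.size, lr.window.center, lr.window.radius)


def scan(cohort: Cohort, windows: list[Window],
         wm: WindowMatrix | None = None,
         A: np.ndarray | None = None) -> ScanResult:
    """Evaluate T over all windows with sum_x > 0 and take the maximum.

    ``wm``/``A`` allow reusing the precomputed membership and subject-gene
    matrices across repeated scans of the same windows/cohort.
    """
    if not windows:
        raise ValueError("windows must be non-empty")
    if wm is None:
        wm = WindowMatrix(windows)
    if A is None:
        A = wm.subject_gene_matrix(cohort)

    case = cohort.case_mask
    n1, n0 = cohort.n1, cohort.n0
    case_counts = A[case].sum(axis=0)          # per-gene counts over cases
    ctrl_counts = A[~case].sum(axis=0)
    sx = wm.M @ case_counts
    sy = wm.M @ ctrl_counts
    if n1 > 0 and n0 > 0:
        T = _vector_T(sx, sy, n1, n0)
    else:
        T = np.full(len(windows), -np.inf)

    defined = np.isfinite(T)
    ranked = sorted(
        (LocalityResult(wm.windows[i], int(sx[i]), int(sy[i]), float(T[i]))
         for i in np.flatnonzero(defined)),
        key=_rank_key,
    )
    if not ranked:
        return ScanResult(ranked=[], scan_T=None, most_likely=None, p_value=1.0)
    top = ranked[0]
    return ScanResult(ranked=ranked, scan_T=top.T, most_likely=top)


def _null_scan_maxima(cohort: Cohort, wm: WindowMatrix, A: np.ndarray,
                      B: int, rng: np.random.Generator,
                      batch: int = 256) -> np.ndarray:
    """Scan maxima under B random case/control label permutations.

    Subjects keep their gene sets; only the labels move, preserving m1/m0.
    Replicates where no window has sum_x > 0 contribute -inf.
    """
    n_sub = cohort.n_subjects
    m1 = cohort.m1
    sizes = np.array([len(s) for s in cohort.affected], dtype=np.float64)
    total_n = sizes.sum()
    gene_totals = A.sum(axis=0)
    win_totals = wm.M @ gene_totals          # sum_x + sum_y per window (fixed)
    Md = wm.M.T.tocsc()                      # genes x windows for right-multiplication

    out = np.empty(B, dtype=np.float64)
    done = 0
    while done < B:
        b = min(batch, B - done)
        # boolean case masks: m1 smallest ranks of iid uniforms
        u = rng.random((b, n_sub))
        masks = (np.argsort(np.argsort(u, axis=1), axis=1) < m1).astype(np.float64)
        case_gene = masks @ A                # (b x genes)
        sx = case_gene @ Md                  # (b x windows)
        sy = win_totals[None, :] - sx
        n1 = masks @ sizes
        n0 = total_n - n1
        T = _vector_T(sx, sy, n1[:, None], n0[:, None])
        out[done:done + b] = T.max(axis=1, initial=-np.inf)
        done += b
    return out


def permutation_test(cohort: Cohort, windows: list[Window], B: int = 999,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     wm: WindowMatrix | None = None) -> ScanResult:
    """Scan + permutation null: p = (1 + #{null >= observed}) / (1 + B)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if wm is None:
        wm = WindowMatrix(windows)
    A = wm.subject_gene_matrix(cohort)

    result = scan(cohort, windows, wm=wm, A=A)
    null_T = _null_scan_maxima(cohort, wm, A, B, rng)
    result.null_T = null_T
    result.n_permutations = B
    result.seed = seed
    if result.scan_T is None:
        result.p_value = 1.0
    else:
        result.p_value = float((1 + np.sum(null_T >= result.scan_T)) / (1 + B))
    return result


def secondary_clusters(result: ScanResult, alpha: float = 0.05
                       ) -> list[tuple[LocalityResult, float]]:
    """Non-overlapping significant clusters beyond the most likely one.

    Walk the ranked windows in descending T.  A window is a candidate only if
    its member set is disjoint from the most likely cluster and from every
    secondary cluster already kept; its p-value is computed against the same
    permutation null distribution as the scan maximum (hence conservative).
    The walk stops at the first disjoint candidate with p >= alpha.
    """
    if result.null_T is None or result.n_permutations is None:
        raise ValueError("run permutation_test before extracting secondary clusters")
    if result.most_likely is None or result.p_value is None or result.p_value >= alpha:
        result.secondary = []
        return []
    kept_members = [result.most_likely.window.members]
    secondary: list[tuple[LocalityResult, float]] = []
    B = result.n_permutations
    for lr in result.ranked[1:]:
        if any(not lr.window.members.isdisjoint(m) for m in kept_members):
            continue
        p = float((1 + np.sum(result.null_T >= lr.T)) / (1 + B))
        if p >= alpha:
            break
        kept_members.append(lr.window.members)
        secondary.append((lr, p))
    result.secondary = secondary
    return secondary
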