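"""Binomial constant-risk-ratio disease model and synthetic data generation.

The disease model: a causal cluster of M pathway genes; every gene mutates
(carries a rare CNV) independently with probability p; a subject carrying at
least one mutated cluster gene has disease risk multiplied by the cluster risk
ratio γ relative to a carrier of none; disease prevalence is K = P(D=1).
With P0 = (1−p)^M the baseline risk solves

    K = P(D=1|g0) · [P0 + γ(1−P0)]   ⇒   P(D=1|g0) = K / (P0 + γ(1−P0)),

and Bayes' rule gives the case/control-conditional distributions of the number
of mutated cluster genes.  Genes outside the cluster are independent of
disease status and mutate with the same p.

Defaults mirror a rare-CNV study of a common disease: p = 1e-4 per gene,
prevalence K = 1%, γ on a grid of 1–5.

This module also generates the other desk-scale synthetic inputs the pipeline
consumes: a scale-free gene network, a planted causal cluster that is exactly
a circular window, BED-style gene annotations, CNV interval calls consistent
with a cohort, and GMT gene-set collections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .cnv_data import CASE, CONTROL, CNVCall, Cohort, GeneAnnotation
from .pathway_graph import PathwayGraph, Window, truncated_distances

__all__ = [
    "DiseaseModel",
    "CountDistribution",
    "baseline_case_prob",
    "conditional_count_pmf",
    "expected_count",
    "simulate_subject",
    "simulate_dataset",
    "generate_random_pathway",
    "choose_cluster_window",
    "synthetic_gene_annotation",
    "synthetic_cnv_calls",
    "synthetic_gene_sets",
]

DEFAULT_P = 1e-4
DEFAULT_PREVALENCE = 0.01
DEFAULT_CRR_GRID = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class DiseaseModel:
    """(M, p, K, γ) with an optional designated causal cluster.

    ``cluster_genes`` may be omitted for closed-form work (expected counts);
    it is required for simulation.
    """

    M: int
    p: float
    K: float
    gamma: float
    cluster_genes: frozenset | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if not 0 < self.K < 1:
            raise ValueError("prevalence K must be in (0, 1)")
        if self.gamma < 1:
            raise ValueError("cluster risk ratio gamma must be >= 1")
        if self.M < 1:
            raise ValueError("cluster size M must be >= 1")
        if self.cluster_genes is not None and len(self.cluster_genes) != self.M:
            raise ValueError("|cluster_genes| must equal M")
        # carrier risk gamma * P(D=1|g0) must be a probability
        if self.gamma * baseline_case_prob(self) > 1:
            raise ValueError("invalid model: gamma * P(D=1|g0) > 1")

    @classmethod
    def from_cluster(cls, cluster_genes, p: float = DEFAULT_P,
                     K: float = DEFAULT_PREVALENCE, gamma: float = 1.0
                     ) -> "DiseaseModel":
        cluster = frozenset(cluster_genes)
        return cls(M=len(cluster), p=p, K=K, gamma=gamma, cluster_genes=cluster)


@dataclass(frozen=True)
class CountDistribution:
    """Pmf of the number of mutated cluster genes, given phenotype."""

    phenotype: str
    support: np.ndarray  # 0..M
    pmf: np.ndarray

    def mean(self) -> float:
        return float(self.support @ self.pmf)


def _p0(model: DiseaseModel) -> float:
    return (1.0 - model.p) ** model.M


def baseline_case_prob(model: DiseaseModel) -> float:
    """P(D=1 | no mutated cluster gene) = K / (P0 + γ(1−P0))."""
    pd = model.K / (_p0(model) + model.gamma * (1.0 - _p0(model)))
    if pd > 1:
        raise ValueError("invalid model: P(D=1|g0) > 1")
    return pd


def conditional_count_pmf(model: DiseaseModel, phenotype: str) -> CountDistribution:
    """Distribution of the mutated-cluster-gene count given case/control status.

    With B(i) = C(M,i) p^i (1−p)^{M−i} and Pd = P(D=1|g0):
        P(i|D=1) = B(i) γ^{[i>0]} Pd / K
        P(i|D=0) = B(i) (1 − γ^{[i>0]} Pd) / (1 − K)
    """
    if phenotype not in (CASE, CONTROL):
        raise ValueError(f"phenotype must be {CASE!r} or {CONTROL!r}")
    i = np.arange(model.M + 1)
    b = stats.binom.pmf(i, model.M, model.p)
    pd = baseline_case_prob(model)
    risk = np.where(i > 0, model.gamma * pd, pd)  # P(D=1 | i mutated genes)
    if phenotype == CASE:
        pmf = b * risk / model.K
    else:
        pmf = b * (1.0 - risk) / (1.0 - model.K)
    total = pmf.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"conditional pmf normalises to {total}, not 1")
    return CountDistribution(phenotype=phenotype, support=i, pmf=pmf / total)


def expected_count(model: DiseaseModel, phenotype: str) -> float:
    """Closed-form expected number of affected cluster genes per subject.

    E[case] = γ M p / (P0 + γ(1−P0));
    E[control] = M p (1 − γ K / (P0 + γ(1−P0))) / (1 − K).
    """
    if phenotype not in (CASE, CONTROL):
        raise ValueError(f"phenotype must be {CASE!r} or {CONTROL!r}")
    denom = _p0(model) + model.gamma * (1.0 - _p0(model))
    if phenotype == CASE:
        return model.gamma * model.M * model.p / denom
    return model.M * model.p * (1.0 - model.gamma * model.K / denom) / (1.0 - model.K)


def simulate_subject(model: DiseaseModel, phenotype: str,
                     pathway_genes: Sequence[str],
                     rng: np.random.Generator) -> frozenset:
    """Draw one subject's affected-gene set.

    The mutated-cluster-gene count i is drawn from the phenotype-conditional
    pmf and i distinct cluster genes are chosen uniformly; every non-cluster
    pathway gene mutates independently with probability p (outside the cluster
    genotype and disease status are independent).
    """
    if model.cluster_genes is None:
        raise ValueError("model has no designated cluster_genes")
    cluster = sorted(model.cluster_genes)
    dist = conditional_count_pmf(model, phenotype)
    i = int(rng.choice(dist.support, p=dist.pmf))
    affected = set(rng.choice(cluster, size=i, replace=False)) if i else set()
    outside = [g for g in pathway_genes if g not in model.cluster_genes]
    hits = rng.random(len(outside)) < model.p
    affected.update(g for g, h in zip(outside, hits) if h)
    return frozenset(affected)


def simulate_dataset(model: DiseaseModel, pathway_genes: Sequence[str],
                     n_cases: int, n_controls: int,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> Cohort:
    """Simulate a case-control cohort of affected-gene sets (reproducible)."""
    if model.cluster_genes is None:
        raise ValueError("model has no designated cluster_genes")
    if not model.cluster_genes <= set(pathway_genes):
        raise ValueError("cluster_genes must be a subset of the pathway genes")
    if rng is None:
        rng = np.random.default_rng(seed)

    cluster = np.array(sorted(model.cluster_genes))
    outside = np.array([g for g in pathway_genes if g not in model.cluster_genes])

    ids: list[str] = []
    phenos: list[str] = []
    affected: list[frozenset] = []
    for phenotype, n, tag in ((CASE, n_cases, "case"), (CONTROL, n_controls, "ctrl")):
        if n == 0:
            continue
        dist = conditional_count_pmf(model, phenotype)
        counts = rng.choice(dist.support, size=n, p=dist.pmf)
        out_hits = rng.random((n, len(outside))) < model.p
        for j in range(n):
            i = int(counts[j])
            genes = set(rng.choice(cluster, size=i, replace=False)) if i else set()
            if len(outside):
                genes.update(outside[out_hits[j]])
            ids.append(f"{tag}{j:05d}")
            phenos.append(phenotype)
            affected.append(frozenset(genes))
    return Cohort(ids, phenos, affected)


def generate_random_pathway(n_genes: int, attachment_parameter: int = 2,
                            seed: int | None = None) -> PathwayGraph:
    """Connected scale-free-like random gene network (preferential attachment).

    Node labels are G0000, G0001, ... in attachment order; deterministic for a
    given seed.  Barabási–Albert attachment yields the heavy-tailed degree
    distribution typical of protein-interaction networks.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    m = max(1, min(attachment_parameter, n_genes - 1))
    g = nx.barabasi_albert_graph(n_genes, m, seed=seed)
    mapping = {i: f"G{i:04d}" for i in g.nodes()}
    return PathwayGraph.from_networkx(nx.relabel_nodes(g, mapping))


def choose_cluster_window(graph: PathwayGraph, target_size: int,
                          R: int = 4) -> Window:
    """Pick the circular window whose size is closest to ``target_size``.

    The planted causal cluster is chosen to be exactly a window so that exact
    recovery (joint power) is attainable.  Deterministic: ties resolve by
    smaller radius, then gene order.
    """
    d = truncated_distances(graph, R)
    best: Window | None = None
    best_key = None
    for gi, gene in enumerate(graph.genes):
        reach = d.dist[gene]
        for r in range(R + 1):
            members = frozenset(l for l, dd in reach.items() if dd <= r)
            key = (abs(len(members) - target_size), r, gi)
            if best_key is None or key < best_key:
                best_key = key
                best = Window(center=gene, radius=r, members=members)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Desk-scale synthetic raw inputs (annotation, CNV calls, gene sets)
# ---------------------------------------------------------------------------

def synthetic_gene_annotation(genes: Sequence[str], gene_length: int = 10_000,
                              gap: int = 5_000, genes_per_chrom: int = 25
                              ) -> list[GeneAnnotation]:
    """Tile genes along synthetic chromosomes (BED-style coordinates)."""
    annot = []
    for idx, gene in enumerate(genes):
        chrom = f"chr{idx // genes_per_chrom + 1}"
        pos = (idx % genes_per_chrom) * (gene_length + gap)
        annot.append(GeneAnnotation(gene=gene, chrom=chrom,
                                    start=pos, end=pos + gene_length))
    return annot


def synthetic_cnv_calls(cohort: Cohort, annot: Sequence[GeneAnnotation],
                        rng: np.random.Generator,
                        copy_numbers: Sequence[int] = (0, 1)
                        ) -> list[CNVCall]:
    """Interval calls consistent with a cohort: one deletion per affected gene.

    Each call lands strictly inside its gene's interval, so mapping the calls
    back through the annotation reproduces the cohort's affected-gene sets.
    """
    loci = {a.gene: a for a in annot}
    calls = []
    for sid, genes in zip(cohort.subject_ids, cohort.affected):
        for gene in sorted(genes):
            a = loci[gene]
            span = a.end - a.start
            s = a.start + int(rng.integers(0, max(1, span // 4)))
            e = min(a.end, s + max(1, span // 2))
            cn = int(rng.choice(copy_numbers))
            calls.append(CNVCall(subject_id=sid, chrom=a.chrom,
                                 start=s, end=e, copy_number=cn))
    return calls


def synthetic_gene_sets(genes: Sequence[str], n_sets: int,
                        rng: np.random.Generator,
                        size_range: tuple[int, int] = (5, 40),
                        cluster: frozenset | None = None,
                        n_cluster_sets: int = 0) -> dict[str, frozenset]:
    """Random named gene sets, optionally including sets drawn from a cluster.

    Mimics a curated gene-set collection at desk scale; ``n_cluster_sets``
    of the sets are sampled mostly from ``cluster`` to give the overlap
    machinery something to find.
    """
    genes = list(genes)
    lo, hi = size_range
    sets: dict[str, frozenset] = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if cluster and k < n_cluster_sets:
            pool = sorted(cluster)
            size = min(size, len(pool))
            members = list(rng.choice(pool, size=size, replace=False))
        else:
            members = list(rng.choice(genes, size=min(size, len(genes)),
                                      replace=False))
        sets[f"SET_{k:03d}"] = frozenset(members)
    return sets
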