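"""Interpretation of detected clusters against curated gene-set collections.

Two complementary tools: (i) the overlap proportion |cluster ∩ set| / |set|
used to read biological meaning into a detected cluster, and (ii) the
comparison gene-set association test — a one-tailed Fisher's exact test on the
affected-gene 2x2 table (inside/outside the set by case/control) with Holm and
Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cnv_data import Cohort

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "overlap_proportions",
    "fisher_gene_set_test",
    "adjust_pvalues",
    "gene_set_table",
]


class GMTParseError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. an MSigDB-style curated collection)."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <TAB> description <TAB> gene [<TAB> gene ...].

    Duplicate genes within a line collapse.  A line with fewer than three
    fields is a parse error.  An empty file yields an empty collection.
    """
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise GMTParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: Mapping[str, frozenset] | GeneSetCollection, path,
              description: str = "na") -> None:
    items = collection.items() if hasattr(collection, "items") else collection
    with open(path, "w") as fh:
        for name, genes in items:
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def overlap_proportions(cluster: frozenset,
                        sets: GeneSetCollection | Mapping[str, frozenset],
                        min_prop: float = 0.5) -> pd.DataFrame:
    """Gene sets overlapping the cluster at proportion >= ``min_prop``.

    The proportion is |cluster ∩ set| / |set| — the fraction of the gene set
    captured by the detected cluster — sorted descending.
    """
    items = sets.items() if hasattr(sets, "items") else sets
    rows = []
    cluster = frozenset(cluster)
    for name, genes in items:
        prop = len(cluster & genes) / len(genes)
        if prop >= min_prop:
            rows.append((name, prop, len(genes)))
    df = pd.DataFrame(rows, columns=["gene_set", "overlap_proportion", "set_size"])
    return df.sort_values(["overlap_proportion", "gene_set"],
                          ascending=[False, True]).reset_index(drop=True)


def fisher_gene_set_test(cohort: Cohort, gene_set: frozenset) -> float:
    """One-tailed Fisher's exact test for case enrichment of affected genes.

    2x2 table rows: affected-gene incidences inside/outside the set; columns:
    cases/controls (totals n1, n0 over all pathway genes).  One-tailed toward
    case excess inside the set.
    """
    gene_set = frozenset(gene_set)
    case = cohort.case_mask
    sum_x = sum(len(s & gene_set) for s, c in zip(cohort.affected, case) if c)
    sum_y = sum(len(s & gene_set) for s, c in zip(cohort.affected, case) if not c)
    n1, n0 = cohort.n1, cohort.n0
    if n1 == 0 or n0 == 0:
        warnings.warn("no affected genes in one phenotype group; p = 1",
                      stacklevel=2)
        return 1.0
    table = [[sum_x, sum_y], [n1 - sum_x, n0 - sum_y]]
    return float(stats.fisher_exact(table, alternative="greater").pvalue)


def adjust_pvalues(pvalues: Sequence[float], method: str) -> np.ndarray:
    """Holm step-down or Benjamini-Hochberg step-up adjusted p-values."""
    methods = {"holm": "holm", "bh": "fdr_bh"}
    if method not in methods:
        raise ValueError(f"method must be one of {sorted(methods)}")
    pvalues = np.asarray(pvalues, dtype=np.float64)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method=methods[method])[1]


def gene_set_table(cohort: Cohort,
                   sets: GeneSetCollection | Mapping[str, frozenset],
                   cluster: frozenset | None = None) -> pd.DataFrame:
    """Per-set association table: nominal p, BH q, Holm p, optional overlap."""
    items = list(sets.items() if hasattr(sets, "items") else sets)
    names = [name for name, _ in items]
    pvals = np.array([fisher_gene_set_test(cohort, genes) for _, genes in items])
    df = pd.DataFrame({
        "gene_set": names,
        "nominal_p": pvals,
        "fdr_q": adjust_pvalues(pvals, "bh") if len(pvals) else pvals,
        "holm_p": adjust_pvalues(pvals, "holm") if len(pvals) else pvals,
        "set_size": [len(genes) for _, genes in items],
    })
    if cluster is not None:
        cluster = frozenset(cluster)
        df["overlap_proportion"] = [len(cluster & genes) / len(genes)
                                    for _, genes in items]
    return df.sort_values("nominal_p").reset_index(drop=True)
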