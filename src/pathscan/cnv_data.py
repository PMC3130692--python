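"""Case-control CNV data: interval-to-gene mapping, filters, and the cohort container.

A cohort holds, for every subject, the set of distinct pathway genes affected
by that subject's rare CNVs.  The group totals n1 (cases) and n0 (controls)
are the pathway-wide affected-gene counts that normalise the locality
statistic.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .pathway_graph import PathwayGraph

__all__ = [
    "CNVCall",
    "GeneAnnotation",
    "Cohort",
    "map_cnvs_to_genes",
    "filter_deletions",
    "filter_rare",
    "restrict_to_pathway",
]

CASE = "case"
CONTROL = "control"

#: Sentinel gene value for a subject row with no affected genes (keeps the
#: subject in the cohort TSV, where one row normally means one affected gene).
NO_GENE = "."


@dataclass(frozen=True)
class CNVCall:
    """A copy-number call on BED-style 0-based half-open coordinates."""

    subject_id: str
    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"CNV {self.subject_id} {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.copy_number == 2:
            raise ValueError("copy_number 2 is not a CNV")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene locus on BED-style 0-based half-open coordinates."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene}: start must be < end")


@dataclass
class Cohort:
    """Subjects with phenotype labels and per-subject affected-gene sets.

    ``n1``/``n0`` are the totals of per-subject set sizes over cases/controls;
    ``m1``/``m0`` are the group sizes.  Subjects with empty sets are retained.
    """

    subject_ids: list[str]
    phenotypes: list[str]  # CASE or CONTROL per subject
    affected: list[frozenset]

    def __post_init__(self) -> None:
        if not (len(self.subject_ids) == len(self.phenotypes) == len(self.affected)):
            raise ValueError("subject_ids, phenotypes, affected must align")
        bad = set(self.phenotypes) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        self.affected = [frozenset(s) for s in self.affected]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([ph == CASE for ph in self.phenotypes], dtype=bool)

    @property
    def m1(self) -> int:
        return int(self.case_mask.sum())

    @property
    def m0(self) -> int:
        return self.n_subjects - self.m1

    @property
    def n1(self) -> int:
        mask = self.case_mask
        return int(sum(len(s) for s, c in zip(self.affected, mask) if c))

    @property
    def n0(self) -> int:
        mask = self.case_mask
        return int(sum(len(s) for s, c in zip(self.affected, mask) if not c))

    def genes(self) -> frozenset:
        out: set = set()
        for s in self.affected:
            out |= s
        return frozenset(out)

    # ---- TSV round trip (direct input mode) --------------------------------

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "Cohort":
        """Build from a long table with columns subject_id, phenotype, gene.

        One row per (subject, affected gene); a row whose gene field is empty
        or ``.`` registers the subject with no affected genes.
        """
        required = {"subject_id", "phenotype", "gene"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        sets: dict[str, set] = {}
        pheno: dict[str, str] = {}
        order: list[str] = []
        for sid, ph, gene in zip(df["subject_id"].astype(str),
                                 df["phenotype"].astype(str),
                                 df["gene"]):
            if sid not in sets:
                sets[sid] = set()
                pheno[sid] = ph
                order.append(sid)
            elif pheno[sid] != ph:
                raise ValueError(f"subject {sid} has conflicting phenotype labels")
            if not (pd.isna(gene) or str(gene) in ("", NO_GENE)):
                sets[sid].add(str(gene))
        return cls(order, [pheno[s] for s in order],
                   [frozenset(sets[s]) for s in order])

    @classmethod
    def read_tsv(cls, path) -> "Cohort":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=[])
        return cls.from_table(df)

    def to_tsv(self, path) -> None:
        rows = []
        for sid, ph, genes in zip(self.subject_ids, self.phenotypes, self.affected):
            if genes:
                for g in sorted(genes):
                    rows.append((sid, ph, g))
            else:
                rows.append((sid, ph, NO_GENE))
        pd.DataFrame(rows, columns=["subject_id", "phenotype", "gene"]).to_csv(
            path, sep="\t", index=False)


def filter_deletions(calls: Iterable[CNVCall]) -> list[CNVCall]:
    """Keep deletions only: copy number 0 (homozygous) or 1 (heterozygous)."""
    return [c for c in calls if c.copy_number in (0, 1)]


def map_cnvs_to_genes(calls: Sequence[CNVCall],
                      annot: Sequence[GeneAnnotation],
                      subjects: Iterable[str] | None = None,
                      ) -> dict[str, frozenset]:
    """Per-subject sets of genes overlapped (>= 1 bp) by the subject's CNVs.

    Coordinates are 0-based half-open in both inputs.  A gene counts once per
    subject no matter how many of that subject's CNVs hit it.  Duplicate call
    records collapse.  Calls on chromosomes absent from the annotation are
    skipped with a warning.

    ``subjects``, if given, pre-registers subject ids so that subjects without
    any overlapping call still appear with an empty set.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for a in annot:
        trees[a.chrom][a.start:a.end] = a.gene

    out: dict[str, set] = {}
    if subjects is not None:
        for sid in subjects:
            out[sid] = set()

    skipped_chroms: set[str] = set()
    for call in set(calls):
        out.setdefault(call.subject_id, set())
        if call.chrom not in trees:
            skipped_chroms.add(call.chrom)
            continue
        for iv in trees[call.chrom][call.start:call.end]:
            out[call.subject_id].add(iv.data)
    if skipped_chroms:
        warnings.warn(
            "CNV calls on chromosomes absent from the gene annotation were "
            f"skipped: {sorted(skipped_chroms)}", stacklevel=2)
    return {sid: frozenset(genes) for sid, genes in out.items()}


def filter_rare(gene_sets: Mapping[str, frozenset],
                threshold: float = 0.01) -> dict[str, frozenset]:
    """Drop genes affected in >= ``threshold`` of subjects (gene-level rarity).

    This is the gene-level surrogate for keeping CNVs "present in less than
    threshold of the sample": a gene is removed from every subject when the
    fraction of subjects carrying it affected reaches the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = len(gene_sets)
    if n == 0:
        return {}
    if threshold == 1.0:  # "less than 100%" excludes nothing
        return {sid: frozenset(genes) for sid, genes in gene_sets.items()}
    counts: dict[str, int] = defaultdict(int)
    for genes in gene_sets.values():
        for g in genes:
            counts[g] += 1
    common = {g for g, c in counts.items() if c / n >= threshold}
    return {sid: frozenset(genes - common) for sid, genes in gene_sets.items()}


def restrict_to_pathway(gene_sets: Mapping[str, frozenset],
                        phenotypes: Mapping[str, str],
                        graph: PathwayGraph,
                        verbose: bool = False) -> Cohort:
    """Drop off-pathway genes and assemble the Cohort.

    Subjects whose genes are all off-pathway remain in the cohort with empty
    sets: they still carry information through the group sizes and through the
    permutation labels.
    """
    dropped = 0
    subject_ids = list(gene_sets.keys())
    affected = []
    for sid in subject_ids:
        genes = gene_sets[sid]
        kept = frozenset(g for g in genes if g in graph)
        dropped += len(genes) - len(kept)
        affected.append(kept)
    if verbose and dropped:  # pragma: no cover
        warnings.warn(f"dropped {dropped} off-pathway affected-gene incidences",
                      stacklevel=2)
    return Cohort(subject_ids, [phenotypes[s] for s in subject_ids], affected)
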