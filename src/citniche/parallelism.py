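"""Genomic parallelism within and between selective environments.

Clones evolved in two media (citrate-only DM0 vs glucose+citrate DM25)
are compared through their sets of genes carrying "qualifying"
mutations: nonsynonymous SNPs, deletions, duplications/amplifications
and IS insertions that unambiguously affect a single gene (coding
region, or promoter within a configurable upstream window). Pairwise
parallelism is measured by Dice's similarity coefficient
S = 2|X∩Y| / (|X|+|Y|); the grand mean S_m, within-treatment mean S_w
and between-treatment mean S_b are compared by permuting treatment
labels across clones. Per-gene treatment specificity uses the
two-tailed Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2, fisher_exact_two_tailed, rng_for

__all__ = [
    "GeneLink",
    "MutationRecord",
    "GeneHitMatrix",
    "ParallelismReport",
    "QUALIFYING_TYPES",
    "qualifying_mutations",
    "hit_matrix",
    "dice",
    "similarity_summary",
    "permutation_test_sw_sb",
    "gene_treatment_fisher",
    "rank_genes",
]

logger = logging.getLogger(__name__)

MUTATION_TYPES = frozenset(
    {
        "snp_nonsynonymous",
        "snp_synonymous",
        "snp_nonsense",
        "snp_intergenic",
        "indel",
        "deletion",
        "duplication_amplification",
        "is_insertion",
        "multiple_base",
        "pseudogene",
    }
)

#: Mutation classes counted in the parallelism analyses.
QUALIFYING_TYPES = frozenset(
    {"snp_nonsynonymous", "deletion", "duplication_amplification", "is_insertion"}
)


@dataclass(frozen=True)
class GeneLink:
    """One gene touched by a mutation.

    relation is "coding" (inside the gene), "promoter" (upstream, with
    ``distance_bp`` base pairs 5' of the start) or "spanning" (the
    mutation extends over the gene and beyond).
    """

    gene: str
    relation: str  # coding | promoter | spanning
    distance_bp: Optional[int] = None


@dataclass(frozen=True)
class MutationRecord:
    clone_id: str
    treatment: str  # DM0 | DM25
    position: int
    type: str
    element: str = ""  # IS family for is_insertion records
    genes_affected: tuple[GeneLink, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be 1-based (>= 1)")
        if self.type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.type!r}")
        if self.type == "is_insertion" and not self.element:
            raise ValueError("is_insertion records must carry an IS element name")
        object.__setattr__(self, "genes_affected", tuple(self.genes_affected))


def qualifying_mutations(
    records: Iterable[MutationRecord], promoter_window_bp: int = 150
) -> list[tuple[MutationRecord, str]]:
    """Filter to qualifying mutations, each assigned to exactly one gene.

    Keeps only nonsynonymous SNPs, deletions, duplications/amplifications
    and IS insertions; a record qualifies when, after dropping promoter
    links farther than ``promoter_window_bp`` upstream, exactly one gene
    remains, affected via its coding region or promoter. Multi-gene
    deletions, spanning links and ambiguous intergenic events are
    excluded. Returns (record, gene) pairs.
    """
    kept: list[tuple[MutationRecord, str]] = []
    for rec in records:
        if rec.type not in QUALIFYING_TYPES:
            continue
        if not rec.genes_affected:
            logger.warning(
                "qualifying-type record at %d in %s has no gene annotation; excluded",
                rec.position,
                rec.clone_id,
            )
            continue
        eligible_genes: set[str] = set()
        all_genes: set[str] = set()
        for link in rec.genes_affected:
            if link.relation == "promoter" and (
                link.distance_bp is not None and link.distance_bp > promoter_window_bp
            ):
                continue  # out-of-window promoter link: does not implicate the gene
            all_genes.add(link.gene)
            if link.relation in ("coding", "promoter"):
                eligible_genes.add(link.gene)
        if len(all_genes) == 1 and len(eligible_genes) == 1:
            kept.append((rec, next(iter(eligible_genes))))
    return kept


@dataclass
class GeneHitMatrix:
    """Clone x gene counts of qualifying mutations, with treatment labels."""

    counts: pd.DataFrame  # index = clone ids, columns = genes, int counts
    treatments: pd.Series  # index = clone ids, values in {DM0, DM25}

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.treatments.index):
            self.treatments = self.treatments.reindex(self.counts.index)
        if self.treatments.isna().any():
            raise ValueError("every clone needs a treatment label")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def clones(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    def gene_sets(self) -> list[frozenset[str]]:
        """Per-clone set of genes with at least one qualifying mutation."""
        arr = self.counts.to_numpy() >= 1
        cols = np.asarray(self.counts.columns)
        return [frozenset(cols[row]) for row in arr]


def hit_matrix(
    qualified: Sequence[tuple[MutationRecord, str]],
    clones: Optional[Sequence[tuple[str, str]]] = None,
) -> GeneHitMatrix:
    """Build the clone x gene hit matrix from qualifying (record, gene) pairs.

    ``clones`` optionally fixes the (clone_id, treatment) roster so that
    clones with zero qualifying mutations still appear as all-zero rows.
    """
    rows = [
        {"clone_id": rec.clone_id, "treatment": rec.treatment, "gene": gene}
        for rec, gene in qualified
    ]
    df = pd.DataFrame(rows, columns=["clone_id", "treatment", "gene"])
    if clones is None:
        roster = df[["clone_id", "treatment"]].drop_duplicates().set_index("clone_id")
        treatments = roster["treatment"]
    else:
        treatments = pd.Series(
            {cid: trt for cid, trt in clones}, name="treatment", dtype=object
        )
    counts = (
        df.groupby(["clone_id", "gene"]).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame(index=treatments.index)
    )
    counts = counts.reindex(index=treatments.index, fill_value=0).astype(int)
    counts = counts.sort_index(axis=1)
    return GeneHitMatrix(counts=counts, treatments=treatments)


def dice(x: Iterable[str], y: Iterable[str]) -> float:
    """Dice similarity S = 2|x∩y| / (|x| + |y|) between two gene sets.

    Both sets empty is degenerate: S is defined as 0 (and such pairs are
    excluded from the mean similarities).
    """
    xs, ys = set(x), set(y)
    if not xs and not ys:
        logger.warning("Dice of two empty gene sets; defined as 0")
        return 0.0
    return 2.0 * len(xs & ys) / (len(xs) + len(ys))


def _pairwise_dice(sets: Sequence[frozenset[str]]) -> np.ndarray:
    n = len(sets)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dice(sets[i], sets[j])
    return d


def _mean_similarities(
    d: np.ndarray, same_treatment: np.ndarray, valid_pair: np.ndarray
) -> tuple[float, float, float]:
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = d[iu]
    same = same_treatment[iu]
    ok = valid_pair[iu]
    s_m = float(vals[ok].mean())
    s_w = float(vals[ok & same].mean())
    s_b = float(vals[ok & ~same].mean())
    return s_m, s_w, s_b


def _pair_masks(matrix: GeneHitMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sets = matrix.gene_sets()
    d = _pairwise_dice(sets)
    labels = matrix.treatments.to_numpy()
    same = labels[:, None] == labels[None, :]
    nonempty = np.array([len(s) > 0 for s in sets])
    valid = nonempty[:, None] | nonempty[None, :]  # exclude both-empty pairs
    return d, same, valid


def similarity_summary(matrix: GeneHitMatrix) -> tuple[float, float, float]:
    """Grand, within-treatment and between-treatment mean Dice similarity.

    Returns (S_m, S_w, S_b): the mean over all unordered clone pairs,
    over same-treatment pairs, and over cross-treatment pairs.
    """
    for trt, grp in matrix.treatments.groupby(matrix.treatments):
        if len(grp) < 2:
            raise ValueError(f"treatment {trt!r} needs at least 2 clones")
    d, same, valid = _pair_masks(matrix)
    return _mean_similarities(d, same, valid)


def permutation_test_sw_sb(
    matrix: GeneHitMatrix, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Permutation p-value for S_w - S_b > 0.

    Treatment labels are shuffled across clones (group sizes preserved);
    the statistic S_w - S_b is recomputed per permutation, and
    p = (1 + #{permuted >= observed}) / (1 + n_perm), which is never
    exactly zero. The pairwise Dice matrix depends only on the gene
    sets, so it is computed once and re-averaged under each labelling.
    """
    labels = matrix.treatments.to_numpy()
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("permutation test requires exactly 2 non-empty treatments")
    d, same, valid = _pair_masks(matrix)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    vals, ok = d[iu], valid[iu]

    def stat(lab: np.ndarray) -> float:
        same_u = (lab[:, None] == lab[None, :])[iu]
        return float(vals[ok & same_u].mean() - vals[ok & ~same_u].mean())

    observed = stat(labels)
    rng = rng_for(seed, "parallelism-permutation")
    exceed = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if stat(lab) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def gene_treatment_fisher(matrix: GeneHitMatrix, gene: str) -> float:
    """Two-tailed Fisher p for treatment specificity of one gene.

    The 2x2 table counts clones with vs without at least one qualifying
    mutation in ``gene``, split by treatment.
    """
    if gene not in matrix.counts.columns:
        return 1.0
    hit = matrix.counts[gene] >= 1
    trts = sorted(matrix.treatments.unique())
    if len(trts) != 2:
        raise ValueError("gene_treatment_fisher requires exactly 2 treatments")
    cells = []
    for trt in trts:
        in_trt = matrix.treatments == trt
        cells.append((int((hit & in_trt).sum()), int((~hit & in_trt).sum())))
    (a, b), (c, d) = cells
    return fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))


def rank_genes(matrix: GeneHitMatrix, min_genomes: int = 2) -> pd.DataFrame:
    """Rank genes by treatment asymmetry of their qualifying mutations.

    Restricts to genes hit in at least ``min_genomes`` genomes, sorts
    descending by |total_DM0 - total_DM25| with ties broken by total
    count then gene name. Columns: gene, per-treatment totals,
    abs_difference, n_genomes.
    """
    if matrix.counts.shape[1] == 0:
        return pd.DataFrame(
            columns=["gene", "total_DM0", "total_DM25", "abs_difference", "n_genomes"]
        )
    trts = sorted(matrix.treatments.unique())
    totals = {
        f"total_{trt}": matrix.counts[matrix.treatments == trt].sum(axis=0)
        for trt in trts
    }
    df = pd.DataFrame(totals)
    for col in ("total_DM0", "total_DM25"):
        if col not in df:
            df[col] = 0
    df["n_genomes"] = (matrix.counts >= 1).sum(axis=0)
    df["abs_difference"] = (df["total_DM0"] - df["total_DM25"]).abs()
    df["total"] = df["total_DM0"] + df["total_DM25"]
    df = df[df["n_genomes"] >= min_genomes]
    df = df.rename_axis("gene").reset_index()
    df = df.sort_values(
        ["abs_difference", "total", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df[["gene", "total_DM0", "total_DM25", "abs_difference", "n_genomes"]]


@dataclass(frozen=True)
class ParallelismReport:
    """Bundle of the parallelism statistics for one clone set."""

    S_m: float
    S_w: float
    S_b: float
    permutation_p: float
    gene_fisher_p: dict[str, float] = field(default_factory=dict)
    ranking: Optional[pd.DataFrame] = None


def parallelism_report(
    matrix: GeneHitMatrix, n_perm: int = 10_000, seed: int = 0
) -> ParallelismReport:
    """Full parallelism analysis of a hit matrix."""
    s_m, s_w, s_b = similarity_summary(matrix)
    p = permutation_test_sw_sb(matrix, n_perm=n_perm, seed=seed)
    ranking = rank_genes(matrix)
    fisher = {g: gene_treatment_fisher(matrix, g) for g in ranking["gene"]}
    return ParallelismReport(
        S_m=s_m, S_w=s_w, S_b=s_b, permutation_p=p, gene_fisher_p=fisher, ranking=ranking
    )


__all__.append("parallelism_report")
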