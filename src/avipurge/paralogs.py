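"""Paralog duplication detection, percent identity and NJ phylograms.

Percent identity uses one auditable definition: global alignment with match
+1, mismatch 0 and linear gap -1, identity = 100 * matches / alignment
columns (gap columns included in the denominator).  Phylograms are built by
neighbour joining on ``100 - identity`` distances with negative branch
lengths clamped to zero, after deterministic alphabetical ordering and
truncation to the first ``max_sequences`` labels, so figure-style outputs
are stable.  Paralog clusters are single-linkage components at a percent-
identity cutoff.

Neighbour joining is used rather than a clock-assuming method because
paralog pairs typically show unequal rates (a conserved copy next to a
rapidly evolving one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from skbio.tree import nj


@dataclass(frozen=True)
class ParalogParams:
    """Phylogram / clustering parameters.

    ``max_sequences``: deterministic truncation after alphabetical ordering
    (default 100, i.e. 2-3 paralogs for each of a few dozen species);
    ``cluster_cutoff``: percent identity at or above which sequences join a
    single-linkage cluster (default 80); ``min_paralogs``: paralog count at
    which a species counts as duplicated (default 2).
    """

    max_sequences: int = 100
    cluster_cutoff: float = 80.0
    min_paralogs: int = 2

    def __post_init__(self) -> None:
        if self.max_sequences < 3:
            raise ValueError("max_sequences must be >= 3")
        if not 0 < self.cluster_cutoff <= 100:
            raise ValueError("cluster_cutoff must lie in (0, 100]")


DEFAULT_PARAMS = ParalogParams()


def _aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity between two amino-acid sequences.

    Global alignment (match +1, mismatch 0, linear gap -1); identity is
    100 * matched columns / total alignment columns, so ``"A"`` vs ``"AA"``
    gives 50.  Symmetric by construction; empty sequences are rejected.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    aln = _aligner().align(a, b)[0]
    return 100.0 * aln.counts().identities / aln.length


def identity_matrix(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Symmetric percent-identity matrix (diagonal 100) over labelled sequences."""
    labels = list(sequences)
    n = len(labels)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(
                sequences[labels[i]], sequences[labels[j]]
            )
    return pd.DataFrame(mat, index=labels, columns=labels)


def detect_duplications(
    hits: pd.DataFrame, params: ParalogParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Per-gene paralog counts in the focal clade.

    For every gene, counts distinct paralog indices with a hit per Neoave
    species; reports the median count over species carrying the gene and
    flags the gene as duplicated in Neoaves when that median reaches
    ``params.min_paralogs``.  Returns columns ``gene,
    median_neoave_paralogs, duplicated_in_neoaves`` (empty input gives an
    empty frame).
    """
    neo = hits[(hits["clade"] == "neoaves") & hits["hit_length"].notna()]
    if neo.empty:
        return pd.DataFrame(
            columns=["gene", "median_neoave_paralogs", "duplicated_in_neoaves"]
        )
    counts = (
        neo.groupby(["gene", "species"], observed=True)["paralog_index"]
        .nunique()
        .rename("n_paralogs")
        .reset_index()
    )
    med = counts.groupby("gene", observed=True)["n_paralogs"].median()
    out = med.rename("median_neoave_paralogs").reset_index()
    out["duplicated_in_neoaves"] = out["median_neoave_paralogs"] >= params.min_paralogs
    return out


def single_linkage_clusters(
    idm: pd.DataFrame, cutoff: float = DEFAULT_PARAMS.cluster_cutoff
) -> list[frozenset]:
    """Single-linkage partition at a percent-identity cutoff.

    Two sequences share a cluster when a chain of pairs with identity >=
    ``cutoff`` connects them.  Clusters are returned sorted by their
    lexicographically smallest member.
    """
    labels = list(idm.index)
    if len(labels) == 1:
        return [frozenset(labels)]
    dist = squareform(100.0 - idm.values, checks=False)
    assignment = fcluster(linkage(dist, method="single"), t=100.0 - cutoff,
                          criterion="distance")
    groups: dict[int, set] = {}
    for label, cl in zip(labels, assignment):
        groups.setdefault(cl, set()).add(label)
    return sorted((frozenset(g) for g in groups.values()), key=lambda g: min(g))


def select_sequences(
    sequences: Mapping[str, str], max_sequences: int = DEFAULT_PARAMS.max_sequences
) -> dict[str, str]:
    """Alphabetical ordering by label, truncated to the first ``max_sequences``."""
    return {k: sequences[k] for k in sorted(sequences)[:max_sequences]}


def nj_tree(distances: pd.DataFrame) -> str:
    """Neighbour-joining newick from a symmetric distance matrix.

    Ties are resolved deterministically by the (alphabetically sorted) label
    order of the matrix; negative branch lengths are clamped to zero.
    """
    ids = list(distances.index)
    if len(ids) < 3:
        raise ValueError("need >= 3 taxa for neighbour joining")
    dm = DistanceMatrix(distances.values, ids=ids)
    return str(nj(dm, neg_as_zero=True)).strip()


@dataclass(frozen=True)
class Phylogram:
    """NJ phylogram over a paralog family with its identity structure."""

    newick: str
    identity: pd.DataFrame
    clusters: list


def build_phylogram(
    sequences: Mapping[str, str], params: ParalogParams = DEFAULT_PARAMS
) -> Phylogram:
    """Neighbour-joining phylogram from pairwise identities.

    Sequences are ordered alphabetically by label and truncated to
    ``params.max_sequences``; distances are ``100 - identity``; negative NJ
    branch lengths are clamped to zero.  Returns the newick string (with
    branch lengths), the identity matrix and the single-linkage clusters at
    ``params.cluster_cutoff``.  Fewer than three sequences are rejected —
    use :func:`pairwise_identity` directly for a pair.
    """
    chosen = select_sequences(sequences, params.max_sequences)
    if len(chosen) < 3:
        raise ValueError(
            "need >= 3 sequences for a phylogram; use pairwise_identity for pairs"
        )
    idm = identity_matrix(chosen)
    newick = nj_tree(100.0 - idm)
    clusters = single_linkage_clusters(idm, params.cluster_cutoff)
    return Phylogram(newick=newick, identity=idm, clusters=clusters)
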