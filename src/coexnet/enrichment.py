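"""Log-odds-ratio over-representation of annotation terms in clusters.

For a cluster and a term, the 2x2 table over the background gene set is

    a = genes in both cluster and term      b = cluster only
    c = term only                           d = neither

and the score is the natural-log odds ratio ln[(a*d)/(b*c)], with the
Haldane–Anscombe correction (add epsilon, default 0.5, to every cell) applied
only when some cell is zero. Positive values mean the term is relatively
more abundant in the cluster than in the background; 0 means no enrichment.
Terms are ranked by log-odds magnitude alone — no multiple-testing
machinery is applied by default, though Fisher exact p-values with
Benjamini–Hochberg adjustment can be switched on for exploratory use.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import ComputationError, ConfigurationError
from .mcl import ClusterSet
from .synthetic import GeneSetCollection

__all__ = [
    "EnrichmentParams",
    "log_odds",
    "enrich_clusters",
    "term_frequency",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentParams:
    """Enrichment filters and background choice.

    max_term_size:
        Terms with at least this many genes are excluded — applied only to
        collections flagged as GO-BP (broad biological-process terms; the
        default keeps terms with < 1500 genes). KEGG-style collections are
        never size-filtered.
    min_cluster_size:
        Clusters below this size are skipped (default 10).
    background:
        "network_genes" scores each term against the analyzed network's
        gene set; "universe_genes" uses the collection's universe.
    zero_cell_correction:
        Epsilon added to all four cells when any cell is zero.
    compute_pvalues:
        Optionally adds Fisher exact p-values and Benjamini–Hochberg
        q-values to the table.
    """

    max_term_size: int = 1500
    min_cluster_size: int = 10
    background: str = "network_genes"
    zero_cell_correction: float = 0.5
    compute_pvalues: bool = False

    def __post_init__(self) -> None:
        if self.max_term_size < 1:
            raise ConfigurationError("max_term_size must be >= 1")
        if self.zero_cell_correction < 0:
            raise ConfigurationError("zero_cell_correction must be >= 0")
        if self.background not in ("network_genes", "universe_genes"):
            raise ConfigurationError(
                f"unknown background mode {self.background!r}"
            )


def log_odds(a: int, b: int, c: int, d: int, correction: float = 0.5) -> float:
    """Natural-log odds ratio of a 2x2 contingency table.

    ln[(a*d)/(b*c)]; when any cell is zero, ``correction`` is added to all
    four cells first, keeping the value finite.
    """
    if min(a, b, c, d) < 0:
        raise ComputationError("contingency counts must be non-negative")
    if a == b == c == d == 0:
        raise ComputationError("all four contingency cells are zero")
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + correction for x in (a, b, c, d))
        if min(a, b, c, d) == 0:
            raise ComputationError("zero cell with zero correction")
    return math.log((a * d) / (b * c))


def _contingency(
    cluster: set, term: set, background: set
) -> tuple[int, int, int, int]:
    term_bg = term & background
    a = len(cluster & term_bg)
    b = len(cluster) - a
    c = len(term_bg) - a
    d = len(background) - a - b - c
    return a, b, c, d


def enrich_clusters(
    cs: ClusterSet,
    annot: GeneSetCollection,
    params: EnrichmentParams | None = None,
    background_genes: set | None = None,
) -> pd.DataFrame:
    """Score every (cluster, term) pair by log-odds over-representation.

    Returns one row per retained pair with the 2x2 counts, the term's total
    size, the log-odds ratio and an ``is_top_term`` flag marking each
    cluster's highest-scoring term (ties broken by term id). Clusters below
    ``min_cluster_size`` are skipped; for GO-BP collections terms with
    >= ``max_term_size`` genes are excluded. The background defaults to the
    union of all cluster genes (the analyzed network) unless
    ``background_genes`` or the universe mode overrides it.
    """
    params = params or EnrichmentParams()
    if params.background == "universe_genes":
        if annot.universe is None:
            raise ConfigurationError(
                "background='universe_genes' needs a collection universe"
            )
        background = set(annot.universe)
    elif background_genes is not None:
        background = set(background_genes)
    else:
        background = {g for c in cs.clusters for g in c}
    if not background:
        raise ConfigurationError("empty background gene set")

    is_gobp = (annot.category or "").upper().replace("_", "-") == "GO-BP"
    rows = []
    for ci, cluster in enumerate(cs.clusters):
        if len(cluster) < params.min_cluster_size:
            continue
        cset = set(cluster) & background
        if not cset:
            continue
        for term_id in sorted(annot.terms):
            genes = annot.terms[term_id]
            if is_gobp and len(genes) >= params.max_term_size:
                continue
            a, b, c, d = _contingency(cset, set(genes), background)
            if a + c == 0:
                continue  # term absent from background entirely
            if b == 0 and d == 0:
                # term covers the whole background: proportions are 1 on
                # both sides, so there is no enrichment by definition
                lor = 0.0
            else:
                lor = log_odds(a, b, c, d, params.zero_cell_correction)
            row = {
                "cluster": ci,
                "cluster_size": len(cluster),
                "term": term_id,
                "term_size": len(genes),
                "a": a, "b": b, "c": c, "d": d,
                "log_odds": lor,
            }
            if params.compute_pvalues:
                row["p_value"] = stats.fisher_exact(
                    [[a, b], [c, d]], alternative="greater"
                )[1]
            rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    if params.compute_pvalues:
        from statsmodels.stats.multitest import multipletests

        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table.sort_values(
        ["cluster", "log_odds", "term"], ascending=[True, False, True]
    ).reset_index(drop=True)
    table["is_top_term"] = False
    top_idx = table.groupby("cluster").head(1).index
    table.loc[top_idx, "is_top_term"] = True
    return table


def term_frequency(
    genes: set, annot: GeneSetCollection, top_k: int = 10
) -> pd.DataFrame:
    """Top-k terms by how many of the given genes they annotate.

    Counts, per term, the input genes belonging to it (a gene annotated to
    several terms counts once per term), sorts descending with ties broken
    by term id, and returns the first ``top_k`` rows as columns
    (term, description, count).
    """
    genes = set(genes)
    counts = []
    for term_id in sorted(annot.terms):
        n = len(genes & annot.terms[term_id])
        if n > 0:
            counts.append(
                {
                    "term": term_id,
                    "description": annot.descriptions.get(term_id, ""),
                    "count": n,
                }
            )
    table = pd.DataFrame(counts, columns=["term", "description", "count"])
    if table.empty:
        return table
    table = table.sort_values(
        ["count", "term"], ascending=[False, True]
    ).reset_index(drop=True)
    return table.head(top_k)
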