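"""Pre-network cleaning of probe-level expression tables.

Consumes already-normalized (log-scale) probe x sample matrices with a
probe-to-gene map, removes low-expression probes, and collapses multiple
probes per gene to the single probe with the highest mean intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, EmptyResultError

__all__ = ["ProbeTable", "filter_low_expression", "collapse_probes",
           "default_low_expression_threshold"]

log = logging.getLogger(__name__)


@dataclass
class ProbeTable:
    """Probe-level expression with a many-to-one probe -> gene map.

    ``values`` is probes x samples (index = probe ids); ``gene_map`` maps
    every probe id to exactly one gene id. Probes missing from the map are
    rejected at construction (callers flag/drop unmapped probes upstream).
    """

    values: pd.DataFrame
    gene_map: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ConfigurationError(f"duplicate probe ids: {list(dupes)[:5]}")
        unmapped = self.values.index.difference(self.gene_map.index)
        if len(unmapped) > 0:
            raise ConfigurationError(
                f"{len(unmapped)} probes lack a gene id, e.g. {list(unmapped[:5])}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.values)


def default_low_expression_threshold(table: ProbeTable, quantile: float = 0.20) -> float:
    """Quantile of per-probe mean intensities used as the default cutoff.

    "Very low expression" has no universal number on a log-intensity scale;
    the 20th percentile of per-probe means is the package default and is
    fully configurable.
    """
    return float(table.values.mean(axis=1).quantile(quantile))


def filter_low_expression(table: ProbeTable, min_mean_intensity: float) -> ProbeTable:
    """Drop probes whose mean intensity across all samples is below the cutoff.

    Keeps probes with mean >= ``min_mean_intensity``, preserving input order.
    Raises :class:`EmptyResultError` if nothing survives.
    """
    if table.n_probes == 0:
        raise EmptyResultError("probe table is empty")
    means = table.values.mean(axis=1)
    keep = means >= min_mean_intensity
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise EmptyResultError(
            f"threshold {min_mean_intensity} removed all {table.n_probes} probes"
        )
    log.info("low-expression filter: kept %d / %d probes", n_kept, table.n_probes)
    kept = table.values.loc[keep]
    return ProbeTable(values=kept, gene_map=table.gene_map.loc[kept.index])


def collapse_probes(table: ProbeTable) -> pd.DataFrame:
    """Collapse to one row per gene: the probe with the highest mean intensity.

    Ties in mean intensity are broken by the lexicographically smallest probe
    id, so the result is deterministic and independent of input row order.
    Returns a genes x samples matrix indexed by gene id.
    """
    if table.n_probes == 0:
        raise EmptyResultError("probe table is empty")
    means = table.values.mean(axis=1)
    # sort by (gene, -mean, probe id): first row per gene is the winner
    tmp = pd.DataFrame(
        {
            "probe": table.values.index,
            "gene": table.gene_map.loc[table.values.index].values,
            "mean": means.values,
        }
    )
    tmp = tmp.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    winners = tmp.drop_duplicates("gene", keep="first")
    out = table.values.loc[winners["probe"].values]
    out.index = pd.Index(winners["gene"].values, name="gene")
    return out.sort_index()
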