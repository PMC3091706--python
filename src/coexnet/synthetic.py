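"""Synthetic multi-dataset expression data with planted co-expression modules.

The generator emulates the statistical setting of a multi-cohort microarray
co-expression study: several independent datasets (differing sample counts)
that share a set of co-regulated gene modules, plus modules private to a
single dataset, on a background of uncorrelated genes.

Each module in each dataset is driven by a single Gaussian latent factor:

    x_g = sqrt(rho / (1 - rho)) * sigma * f  +  sigma * eps_g

with ``f ~ N(0,1)`` per sample, ``eps_g ~ N(0,1)`` i.i.d. per gene and sample,
``sigma = noise_sd``. The expected Pearson correlation between two genes of
the same module is then exactly ``rho`` (within_module_corr). Background
genes are i.i.d. ``N(0, sigma^2)``, so the false-edge rate of a thresholded
correlation network is analytically checkable from the null PCC distribution.

Shared modules reuse the same member genes in every dataset but draw an
independent factor realization per dataset: the *co-expression structure* is
conserved across datasets, the expression values themselves are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SyntheticSpec",
    "GeneSetCollection",
    "simulate_datasets",
    "matched_gene_sets",
    "fixture_graph",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-module simulation.

    Attributes
    ----------
    n_genes:
        Total genes per dataset (module genes plus background).
    n_datasets:
        Number of datasets to generate.
    samples_per_dataset:
        One sample count per dataset; each must be >= 4 so Pearson
        correlation has at least 3 degrees of freedom.
    shared_modules:
        Sizes of modules planted in *every* dataset.
    private_modules_per_dataset:
        One list of module sizes per dataset; each such module is planted
        in that dataset only.
    within_module_corr:
        Target pairwise Pearson correlation of genes in the same module,
        in [0, 1).
    noise_sd:
        Standard deviation of the per-gene independent noise (and of
        background genes).
    seed:
        Master seed; all randomness derives from it.
    """

    n_genes: int = 1000
    n_datasets: int = 3
    samples_per_dataset: tuple[int, ...] = (30, 30, 30)
    shared_modules: tuple[int, ...] = (20, 20, 20, 20, 20)
    private_modules_per_dataset: tuple[tuple[int, ...], ...] = ((20,), (20,), (20,))
    within_module_corr: float = 0.85
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ConfigurationError("n_datasets must be >= 1")
        if len(self.samples_per_dataset) != self.n_datasets:
            raise ConfigurationError(
                "samples_per_dataset must have one entry per dataset"
            )
        if len(self.private_modules_per_dataset) != self.n_datasets:
            raise ConfigurationError(
                "private_modules_per_dataset must have one entry per dataset"
            )
        if any(n < 4 for n in self.samples_per_dataset):
            raise ConfigurationError("each dataset needs >= 4 samples")
        if not (0.0 <= self.within_module_corr < 1.0):
            raise ConfigurationError("within_module_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        total = sum(self.shared_modules) + sum(
            s for mods in self.private_modules_per_dataset for s in mods
        )
        if total > self.n_genes:
            raise ConfigurationError(
                f"module sizes sum to {total} > n_genes={self.n_genes}"
            )
        if any(s < 2 for s in self.shared_modules) or any(
            s < 2 for mods in self.private_modules_per_dataset for s in mods
        ):
            raise ConfigurationError("modules need >= 2 genes")


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (GMT-style annotation stand-in).

    ``terms`` maps term id -> set of gene ids; ``descriptions`` carries the
    GMT description column. ``category`` may be set to "GO-BP" or "KEGG" to
    drive category-specific enrichment filters; ``universe`` is an optional
    background gene set.
    """

    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ConfigurationError(f"term {term!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)

    def annotated_genes(self) -> frozenset[str]:
        """Union of all term gene sets."""
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_datasets(
    spec: SyntheticSpec,
) -> tuple[list[pd.DataFrame], dict[str, str]]:
    """Generate one genes x samples expression matrix per dataset.

    Returns the matrices (pandas DataFrames indexed by gene id, columns are
    sample ids unique to each dataset) and the ground-truth module map
    ``{gene_id: module_label}``; background genes are absent from the map.
    Module labels are ``shared_<k>`` and ``ds<d>_private_<k>``.

    Fully reproducible from ``spec.seed``.
    """
    rho = spec.within_module_corr
    sigma = spec.noise_sd
    # factor loading so that corr(x_g, x_h) == rho for genes sharing a factor
    loading = sigma * math.sqrt(rho / (1.0 - rho))

    genes = _gene_ids(spec.n_genes)
    module_map: dict[str, str] = {}
    cursor = 0
    shared_members: list[list[int]] = []
    for k, size in enumerate(spec.shared_modules):
        idx = list(range(cursor, cursor + size))
        shared_members.append(idx)
        for i in idx:
            module_map[genes[i]] = f"shared_{k}"
        cursor += size
    private_members: list[list[list[int]]] = []
    for d, mods in enumerate(spec.private_modules_per_dataset):
        per_ds: list[list[int]] = []
        for k, size in enumerate(mods):
            idx = list(range(cursor, cursor + size))
            per_ds.append(idx)
            for i in idx:
                module_map[genes[i]] = f"ds{d}_private_{k}"
            cursor += size
        private_members.append(per_ds)

    master = np.random.default_rng(spec.seed)
    streams = master.spawn(spec.n_datasets)
    matrices: list[pd.DataFrame] = []
    for d in range(spec.n_datasets):
        rng = streams[d]
        n_samp = spec.samples_per_dataset[d]
        values = sigma * rng.standard_normal((spec.n_genes, n_samp))
        planted = shared_members + private_members[d]
        for idx in planted:
            factor = rng.standard_normal(n_samp)
            values[idx, :] += loading * factor
        samples = [f"D{d}S{j:03d}" for j in range(n_samp)]
        matrices.append(pd.DataFrame(values, index=genes, columns=samples))
    return matrices, module_map


def matched_gene_sets(
    module_map: dict[str, str],
    n_decoy_terms: int,
    decoy_size_range: tuple[int, int],
    seed: int,
    all_genes: list[str] | None = None,
    category: str | None = None,
) -> GeneSetCollection:
    """Build an annotation collection matched to planted modules.

    One term per planted module containing exactly its genes, plus
    ``n_decoy_terms`` decoy terms of random genes drawn from the background
    (genes not in any module) when ``all_genes`` is given, otherwise from
    the module genes' complement is impossible, so ``all_genes`` is required
    whenever decoys are requested.
    """
    if not module_map:
        raise ConfigurationError("module map is empty")
    modules: dict[str, set[str]] = {}
    for gene, label in module_map.items():
        modules.setdefault(label, set()).add(gene)
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for label in sorted(modules):
        tid = f"TERM_{label}"
        terms[tid] = frozenset(modules[label])
        descriptions[tid] = f"planted module {label}"

    if n_decoy_terms > 0:
        if all_genes is None:
            raise ConfigurationError("decoy terms require the full gene list")
        background = sorted(set(all_genes) - set(module_map))
        lo, hi = decoy_size_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("invalid decoy_size_range")
        if hi > len(background):
            raise ConfigurationError(
                f"decoy size {hi} exceeds available background ({len(background)})"
            )
        rng = np.random.default_rng(seed)
        for k in range(n_decoy_terms):
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(background, size=size, replace=False)
            tid = f"DECOY_{k:03d}"
            terms[tid] = frozenset(members.tolist())
            descriptions[tid] = "decoy term of random background genes"
    return GeneSetCollection(
        terms=terms,
        descriptions=descriptions,
        universe=frozenset(all_genes) if all_genes is not None else None,
        category=category,
    )


def fixture_graph(kind: str, seed: int = 0, **params) -> nx.Graph:
    """Construct an oracle fixture graph of a standard family.

    Supported kinds: ``path``, ``star``, ``cycle``, ``complete`` (param
    ``n``), ``two_cliques`` (params ``n1``, ``n2``, ``bridge``),
    ``preferential_attachment`` (params ``n``, ``m``) and ``erdos_renyi``
    (params ``n`` and either ``p`` or ``mean_degree``).
    """
    try:
        if kind == "path":
            g = nx.path_graph(int(params["n"]))
        elif kind == "star":
            # star with n nodes total -> n-1 leaves
            g = nx.star_graph(int(params["n"]) - 1)
        elif kind == "cycle":
            g = nx.cycle_graph(int(params["n"]))
        elif kind == "complete":
            g = nx.complete_graph(int(params["n"]))
        elif kind == "two_cliques":
            n1, n2 = int(params["n1"]), int(params["n2"])
            bridge = int(params.get("bridge", 1))
            if n1 < 1 or n2 < 1 or bridge < 0 or bridge > min(n1, n2):
                raise ConfigurationError("invalid two_cliques sizes")
            g = nx.complete_graph(n1)
            g.add_edges_from(
                (i + n1, j + n1) for i in range(n2) for j in range(i + 1, n2)
            )
            for b in range(bridge):
                g.add_edge(b, n1 + b)
        elif kind == "preferential_attachment":
            g = nx.barabasi_albert_graph(
                int(params["n"]), int(params["m"]), seed=seed
            )
        elif kind == "erdos_renyi":
            n = int(params["n"])
            if "p" in params:
                p = float(params["p"])
            else:
                p = float(params["mean_degree"]) / (n - 1)
            g = nx.gnp_random_graph(n, p, seed=seed)
        else:
            raise ConfigurationError(f"unknown fixture kind {kind!r}")
    except (KeyError, ValueError) as exc:  # missing/invalid size params
        raise ConfigurationError(f"invalid parameters for {kind!r}: {exc}") from exc
    if g.number_of_nodes() < 1:
        raise ConfigurationError(f"fixture {kind!r} produced an empty graph")
    return nx.Graph(g)
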