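"""PPI-network loading and DIAMOnD seed-connector module expansion.

DIAMOnD grows a module from a set of seed genes by repeatedly adding the
network node whose links into the current module are most statistically
surprising: for a node of degree k with k_s links into a module of size s
in a network of N nodes, the connectivity p-value is the hypergeometric
tail P(X >= k_s). Tail probabilities are evaluated in log space so that
networks of tens of thousands of nodes cause no underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import ValidationError


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def log_hypergeom_tail(k_s, n: int, s: int, k) -> np.ndarray:
    """log P(X >= k_s) for X ~ Hypergeometric(population n, successes s, draws k).

    Vectorized over ``k_s`` and ``k``. The tail is accumulated in log
    space from the pmf at k_s using the term ratio recurrence, so the
    result does not underflow even for networks of tens of thousands of
    nodes and degrees in the thousands.
    """
    k_s = np.atleast_1d(np.asarray(k_s, dtype=float))
    k = np.broadcast_to(np.asarray(k, dtype=float), k_s.shape).copy()
    upper = np.minimum(k, float(s))
    out = np.full(k_s.shape, -np.inf)
    trivial = k_s <= np.maximum(0.0, k + s - n)  # tail includes all support
    out[trivial] = 0.0

    active = ~trivial & (k_s <= upper)
    if not active.any():
        return out
    i = k_s.copy()
    logpmf = _log_comb(s, i) + _log_comb(n - s, k - i) - _log_comb(n, k)
    tail = np.where(active, logpmf, -np.inf)
    mode = (k + 1.0) * (s + 1.0) / (n + 2.0)
    while active.any():
        nxt = active & (i < upper)
        if not nxt.any():
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            step = (
                np.log(s - i)
                + np.log(k - i)
                - np.log(i + 1.0)
                - np.log(n - s - k + i + 1.0)
            )
        logpmf = np.where(nxt, logpmf + step, logpmf)
        i = np.where(nxt, i + 1.0, i)
        tail = np.where(nxt, np.logaddexp(tail, logpmf), tail)
        # once past the mode the terms decrease; stop when negligible
        converged = nxt & (i > mode) & (logpmf < tail - 60.0)
        active = active & ~converged & (i < upper)
    out[~trivial & (k_s <= upper)] = tail[~trivial & (k_s <= upper)]
    return np.minimum(out, 0.0)


@dataclass
class ModuleResult:
    """Seeds plus genes added by DIAMOnD, in order of addition.

    ``added`` has one row per added gene with columns iteration, k
    (degree), k_s (links into the module at addition time) and p
    (hypergeometric connectivity p-value).
    """

    seeds: set[str]
    seeds_missing: set[str]
    added: pd.DataFrame

    @property
    def module_genes(self) -> set[str]:
        return self.seeds | set(self.added.index)

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene": g, "origin": "seed", "iteration": 0, "k": np.nan, "k_s": np.nan, "p": np.nan}
            for g in sorted(self.seeds)
        ]
        for gene, row in self.added.iterrows():
            rows.append(
                {
                    "gene": gene,
                    "origin": "added",
                    "iteration": int(row["iteration"]),
                    "k": int(row["k"]),
                    "k_s": int(row["k_s"]),
                    "p": row["p"],
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_ppi(edge_file: str | Path, min_score: int = 700) -> nx.Graph:
    """Load a STRING-dialect edge list keeping high-confidence edges.

    The file is whitespace-separated with a header line and columns
    protein1, protein2, combined_score. Edges with score < ``min_score``
    are dropped, symmetric duplicates are merged (keeping the higher
    score) and self-loops are discarded.
    """
    graph = nx.Graph()
    path = Path(edge_file)
    with open(path) as fh:
        header = fh.readline()
        if header.strip() == "":
            raise ValidationError(f"{path}: empty edge file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, score_str = parts
            try:
                score = int(float(score_str))
            except ValueError as err:
                raise ValidationError(f"{path}:{lineno}: bad score {score_str!r}") from err
            if not 0 <= score <= 1000:
                raise ValidationError(f"{path}:{lineno}: score {score} outside [0, 1000]")
            if a == b or score < min_score:
                continue
            if graph.has_edge(a, b):
                graph[a][b]["score"] = max(graph[a][b]["score"], score)
            else:
                graph.add_edge(a, b, score=score)
    return graph


def diamond_expand(
    graph: nx.Graph, seeds, n_added: int = 200, alpha: int = 1
) -> ModuleResult:
    """Iterative seed-connector expansion of a module in a PPI network.

    At every step, each node outside the module with at least one link
    into it is scored by the hypergeometric tail probability of its
    module links; the node with the smallest p-value joins the module.
    Seed nodes and links to them can be up-weighted by an integer
    ``alpha`` >= 1 (alpha = 1 is the plain algorithm). Ties are broken
    toward the smaller degree, then the lexicographically smaller gene
    id, so the expansion is fully deterministic.
    """
    if alpha < 1 or int(alpha) != alpha:
        raise ValidationError(f"alpha must be an integer >= 1, got {alpha}")
    seeds = set(seeds)
    in_graph = {s for s in seeds if s in graph}
    missing = seeds - in_graph
    if not in_graph:
        raise ValidationError("no seed gene is present in the network")
    if missing:
        import warnings

        warnings.warn(
            f"{len(missing)} seed genes absent from the network: "
            f"{sorted(missing)[:10]}",
            stacklevel=2,
        )

    n_nodes = graph.number_of_nodes()
    n_seeds_in_graph = len(in_graph)
    # alpha > 1 counts every seed as alpha nodes
    n_eff = n_nodes + (alpha - 1) * n_seeds_in_graph

    module = set(in_graph)
    is_seed = dict.fromkeys(graph.nodes, False)
    for s in in_graph:
        is_seed[s] = True

    # per-candidate counts of links into the module, split by seed status
    links: dict[str, int] = {}
    seed_links: dict[str, int] = {}
    for m in module:
        for nb in graph.neighbors(m):
            if nb in module:
                continue
            links[nb] = links.get(nb, 0) + 1
            seed_links[nb] = seed_links.get(nb, 0) + 1  # module == seeds initially

    rows = []
    for iteration in range(1, n_added + 1):
        candidates = [g for g in links if g not in module]
        if not candidates:
            break
        s_eff = len(module) + (alpha - 1) * sum(1 for g in module if is_seed[g])
        ks = np.array(
            [links[g] + (alpha - 1) * seed_links[g] for g in candidates], dtype=int
        )
        kk = np.array(
            [graph.degree(g) + (alpha - 1) * seed_links[g] for g in candidates],
            dtype=int,
        )
        logp = log_hypergeom_tail(ks, n_eff, int(s_eff), kk)
        order = sorted(
            range(len(candidates)),
            key=lambda i: (logp[i], kk[i], candidates[i]),
        )
        best = order[0]
        gene = candidates[best]
        rows.append(
            {
                "gene": gene,
                "iteration": iteration,
                "k": int(graph.degree(gene)),
                "k_s": int(links[gene]),
                "p": float(np.exp(logp[best])),
            }
        )
        module.add(gene)
        links.pop(gene, None)
        seed_links.pop(gene, None)
        for nb in graph.neighbors(gene):
            if nb in module:
                continue
            links[nb] = links.get(nb, 0) + 1
            seed_links.setdefault(nb, 0)

    added = pd.DataFrame(
        rows, columns=["gene", "iteration", "k", "k_s", "p"]
    ).set_index("gene")
    return ModuleResult(seeds=in_graph, seeds_missing=missing, added=added)


def intersect_modules(
    module_a: ModuleResult, module_b: ModuleResult, universe
) -> tuple[set[str], "EnrichmentResult"]:
    """Common genes of two modules plus Fisher overlap statistics.

    The overlap of the two final module gene sets is tested for
    enrichment against ``universe`` (typically the analyzed network's
    node set) with a one-sided Fisher exact test.
    """
    from .enrichment import fisher_enrichment

    genes_a = module_a.module_genes
    genes_b = module_b.module_genes
    common = genes_a & genes_b
    stats_ = fisher_enrichment(genes_a, genes_b, set(universe))
    return common, stats_


def export_viz_subgraph(
    graph: nx.Graph, genes, min_score: int = 950
) -> pd.DataFrame:
    """Induced subgraph edge list restricted to high-confidence edges.

    Intended for external rendering; returns a DataFrame with columns
    gene_a, gene_b, score.
    """
    genes = set(genes)
    unknown = genes - set(graph.nodes)
    if unknown:
        raise ValidationError(f"genes absent from the network: {sorted(unknown)[:5]}")
    rows = []
    for a, b, data in graph.subgraph(genes).edges(data=True):
        if data.get("score", 0) >= min_score:
            lo, hi = sorted((a, b))
            rows.append({"gene_a": lo, "gene_b": hi, "score": data["score"]})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).sort_values(
        ["gene_a", "gene_b"], ignore_index=True
    )


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a STRING-dialect edge list (protein1 protein2 combined_score)."""
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b, data in graph.edges(data=True):
            lo, hi = sorted((a, b))
            fh.write(f"{lo} {hi} {data.get('score', 1000)}\n")
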