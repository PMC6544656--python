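"""Hub-gene selection and stress centrality on thresholded module graphs.

Per-gene module statistics (module membership MM, gene-trait significance
GS, intramodule connectivity kIM) feed a threshold rule selecting hub
genes, split by correlation sign into down-in-case and up-in-case sets.
A module's adjacency submatrix thresholded at >0.2 yields an unweighted
graph on which Shimbel stress centrality (shortest-path counts through a
node) ranks gene importance; results export to SIF and GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "gene_module_statistics",
    "select_hub_genes",
    "HubSelection",
    "threshold_graph",
    "stress_centrality",
    "export_network",
]


def gene_module_statistics(
    expr: pd.DataFrame,
    modules: pd.Series,
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    adj: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene MM, GS, kIM and normalized kIM.

    MM is the signed Pearson correlation of a gene with its own module's
    eigengene (NaN for unassigned genes); GS the correlation with the
    binary case indicator; kIM the summed adjacency to same-module
    partners, normalized per module by its maximum (0 for singleton
    modules).
    """
    genes = list(expr.index)
    groups = traits.loc[list(expr.columns), "group"]
    indicator = (groups == "case").astype(float).to_numpy()
    x = expr.to_numpy(dtype=float)

    gs = np.array([np.corrcoef(x[i], indicator)[0, 1] for i in range(len(genes))])

    mm = np.full(len(genes), np.nan)
    kim = np.zeros(len(genes))
    labels = modules.loc[genes].to_numpy()
    a = adj.loc[genes, genes].to_numpy(dtype=float)
    for m in sorted(set(labels) - {0}):
        idx = np.flatnonzero(labels == m)
        if m in eigengenes.columns:
            me = eigengenes[m].loc[list(expr.columns)].to_numpy()
            for i in idx:
                mm[i] = np.corrcoef(x[i], me)[0, 1]
        if len(idx) > 1:
            sub = a[np.ix_(idx, idx)]
            kim[idx] = sub.sum(axis=1) - 1.0  # exclude self-adjacency
    kim_norm = np.zeros_like(kim)
    for m in sorted(set(labels) - {0}):
        idx = np.flatnonzero(labels == m)
        mmax = kim[idx].max()
        if mmax > 0:
            kim_norm[idx] = kim[idx] / mmax
    return pd.DataFrame(
        {"module": labels, "MM": mm, "GS": gs, "kIM": kim, "kIM_norm": kim_norm},
        index=genes,
    )


@dataclass
class HubSelection:
    """Hub genes split by trait-correlation sign, plus top-10 rankings."""

    hubs: pd.DataFrame
    negative: pd.DataFrame  # down in case (GS < 0)
    positive: pd.DataFrame  # up in case (GS > 0)
    top10_negative: pd.DataFrame
    top10_positive: pd.DataFrame


def select_hub_genes(
    stats: pd.DataFrame,
    mm_min: float = 0.8,
    gs_min: float = 0.5,
    kim_min: float = 0.5,
) -> HubSelection:
    """Select hubs by strict thresholds |MM| > mm_min, |GS| > gs_min,
    kIM_norm > kim_min, split by the sign of GS.

    Within each signed subset, genes are ranked by the mean of |MM| and
    |GS| (descending), then by normalized intramodule connectivity, and
    the top 10 reported.
    """
    assigned = stats[stats["module"] > 0].copy()
    mask = (
        (assigned["MM"].abs() > mm_min)
        & (assigned["GS"].abs() > gs_min)
        & (assigned["kIM_norm"] > kim_min)
    )
    hubs = assigned[mask].copy()
    hubs["mean_cor"] = (hubs["MM"].abs() + hubs["GS"].abs()) / 2.0
    negative = hubs[hubs["GS"] < 0]
    positive = hubs[hubs["GS"] > 0]

    def top10(df: pd.DataFrame) -> pd.DataFrame:
        return df.sort_values(
            ["mean_cor", "kIM_norm"], ascending=[False, False]
        ).head(10)

    return HubSelection(
        hubs=hubs,
        negative=negative,
        positive=positive,
        top10_negative=top10(negative),
        top10_positive=top10(positive),
    )


def threshold_graph(
    adj: pd.DataFrame, module_genes, edge_cutoff: float = 0.2
) -> nx.Graph:
    """Unweighted graph on module genes with edges where adjacency > cutoff.

    Isolated nodes are retained; the stored ``adjacency`` edge attribute
    is for export only and plays no role in shortest paths.
    """
    module_genes = list(module_genes)
    missing = set(module_genes) - set(adj.index)
    if missing:
        raise ValueError(f"genes absent from adjacency: {sorted(missing)[:5]}")
    g = nx.Graph(edge_cutoff=edge_cutoff)
    g.add_nodes_from(module_genes)
    sub = adj.loc[module_genes, module_genes].to_numpy(dtype=float)
    n = len(module_genes)
    for i in range(n):
        for j in range(i + 1, n):
            if sub[i, j] > edge_cutoff:
                g.add_edge(module_genes[i], module_genes[j], adjacency=float(sub[i, j]))
    return g


def stress_centrality(g: nx.Graph) -> pd.DataFrame:
    """Shimbel stress centrality: shortest s-t paths through each node.

    For every node v, counts over unordered pairs {s, t} (s != v != t) the
    number of shortest s-t paths on which v lies as an intermediate;
    computed from all-pairs BFS distances and path counts via the
    composition sigma_sv * sigma_vt where d(s,v) + d(v,t) = d(s,t).
    Disconnected pairs contribute 0.  Also reports node degree.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    index = {u: i for i, u in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    adj_list = {index[u]: [index[w] for w in g.neighbors(u)] for u in nodes}
    for s in nodes:
        si = index[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        # BFS with path counting
        frontier = [si]
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj_list[u]:
                    if np.isinf(dist[si, w]):
                        dist[si, w] = d + 1
                        nxt.append(w)
                    if dist[si, w] == d + 1:
                        sigma[si, w] += sigma[si, u]
            frontier = nxt
            d += 1

    stress = np.zeros(n, dtype=np.int64)
    for vi in range(n):
        on_path = dist[:, vi][:, None] + dist[vi, :][None, :] == dist
        counts = sigma[:, vi][:, None] * sigma[vi, :][None, :]
        counts[~on_path] = 0
        counts[vi, :] = 0
        counts[:, vi] = 0
        np.fill_diagonal(counts, 0)
        counts[~np.isfinite(dist)] = 0
        stress[vi] = int(round(counts.sum() / 2.0))  # unordered pairs

    return pd.DataFrame(
        {"stress": stress, "degree": [g.degree(u) for u in nodes]},
        index=pd.Index(nodes, name="gene"),
    )


def export_network(
    g: nx.Graph,
    centrality: pd.DataFrame,
    stats: pd.DataFrame,
    out_dir: str | Path,
    basename: str = "network",
) -> tuple[Path, Path]:
    """Write the module graph as SIF and GraphML with node/edge attributes.

    SIF lines are ``node<TAB>co<TAB>node``, one per unordered edge
    (isolated nodes written as bare node lines).  GraphML carries node
    attributes stress, degree, MM, GS and the adjacency edge attribute;
    reading the GraphML back yields an identical graph.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sif_path = out_dir / f"{basename}.sif"
    graphml_path = out_dir / f"{basename}.graphml"

    try:
        with open(sif_path, "w") as fh:
            written = set()
            for u, v in g.edges:
                fh.write(f"{u}\tco\t{v}\n")
                written.update((u, v))
            for u in g.nodes:
                if u not in written:
                    fh.write(f"{u}\n")
    except OSError as exc:
        raise OSError(f"failed writing SIF to {sif_path}: {exc}") from exc

    export = g.copy()
    for u in export.nodes:
        export.nodes[u]["stress"] = int(centrality.loc[u, "stress"]) if u in centrality.index else 0
        export.nodes[u]["degree"] = int(export.degree(u))
        if u in stats.index:
            mm, gs = stats.loc[u, "MM"], stats.loc[u, "GS"]
            export.nodes[u]["MM"] = float(mm) if pd.notna(mm) else 0.0
            export.nodes[u]["GS"] = float(gs) if pd.notna(gs) else 0.0
    try:
        nx.write_graphml(export, graphml_path)
    except OSError as exc:
        raise OSError(f"failed writing GraphML to {graphml_path}: {exc}") from exc
    return sif_path, graphml_path
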