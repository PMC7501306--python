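"""Enrichment-map construction: Jaccard gene-set graph, Louvain communities,
modularity, tf-idf cluster titling and multi-source annotation.

Significantly overrepresented sets (one direction at a time) become nodes of
an undirected graph whose edges carry the Jaccard similarity of the member
sets; edges are kept when both the similarity and the absolute overlap clear
inclusive thresholds (J >= 0.15 and >= 5 shared genes by default). Louvain
community detection on the Jaccard-weighted graph yields clusters, which are
titled by the ten highest tf-idf words of their set names and annotated only
when they span more than one collection source.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .genesets import GeneSet, SetCollection
from .stopwords import DEFAULT_STOPWORDS

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """Intersection over union of two gene sets."""
    if not a or not b:
        raise ValueError("Jaccard similarity is undefined for empty sets")
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def build_graph(sets: SetCollection | list[GeneSet], j_min: float = 0.15,
                k_min: int = 5, direction: str | None = None) -> nx.Graph:
    """All-pairs Jaccard graph over the given sets, trimmed by inclusive
    thresholds on similarity and overlap size.

    Up- and downregulated results are meant to be clustered separately; pass
    one direction's sets per invocation (`direction` is recorded on nodes).
    """
    graph = nx.Graph()
    sets = list(sets)
    for s in sets:
        graph.add_node(s.name, source=s.source, size=len(s.members),
                       direction=direction or "")
    for a, b in combinations(sets, 2):
        overlap = len(a.members & b.members)
        if overlap < k_min:
            continue
        j = jaccard(a.members, b.members)
        if j >= j_min:
            graph.add_edge(a.name, b.name, jaccard=j, overlap=overlap)
    return graph


@dataclass
class Partition:
    """A community assignment with optional titles and annotation flags."""

    membership: dict[str, int]
    seed: int | None = None
    resolution: float = 1.0
    titles: dict[int, list[str]] = field(default_factory=dict)
    tfidf_scores: dict[int, dict[str, float]] = field(default_factory=dict)
    annotated: dict[int, bool] = field(default_factory=dict)

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(nodes) for cid, nodes in sorted(out.items())}

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def louvain(graph: nx.Graph, seed: int = 0, resolution: float = 1.0,
            weighted: bool = True, n_restarts: int = 16) -> Partition:
    """Louvain community detection on the Jaccard-weighted graph.

    Standard two-phase greedy modularity optimization (local moving +
    aggregation to convergence). The greedy sweep is restarted `n_restarts`
    times with node visit orders derived from `seed` and the
    highest-modularity partition is kept (single-run Louvain is easily
    trapped in local optima on small unstructured graphs); the whole
    procedure is deterministic for a fixed seed. Community ids are
    relabelled contiguously from 0 in order of each community's
    lexicographically smallest member.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    weight = "jaccard" if weighted else None
    best_q, best = -math.inf, None
    for r in range(max(1, n_restarts)):
        comms = nx.community.louvain_communities(
            graph, weight=weight, resolution=resolution, seed=seed + 7919 * r)
        membership = {node: cid for cid, nodes in enumerate(comms) for node in nodes}
        q = modularity(graph, membership, weight=weight or "__unit__")
        if q > best_q + 1e-12:
            best_q, best = q, comms
    comms = sorted((sorted(c) for c in best), key=lambda c: c[0])
    membership = {node: cid for cid, nodes in enumerate(comms) for node in nodes}
    return Partition(membership=membership, seed=seed, resolution=resolution)


def modularity(graph: nx.Graph, partition: Partition | dict[str, int],
               weight: str = "jaccard") -> float:
    """Weighted Newman modularity Q = sum_c [S_in/2m - (S_tot/2m)^2]."""
    membership = partition.membership if isinstance(partition, Partition) else partition
    uncovered = set(graph.nodes) - set(membership)
    if uncovered:
        raise ValueError(f"partition does not cover nodes: {sorted(uncovered)[:5]}")
    two_m = sum(d.get(weight, 1.0) for _, _, d in graph.edges(data=True)) * 2.0
    if two_m == 0:
        return 0.0
    s_in: Counter = Counter()
    s_tot: Counter = Counter()
    for u, v, d in graph.edges(data=True):
        w = d.get(weight, 1.0)
        if membership[u] == membership[v]:
            s_in[membership[u]] += 2.0 * w
        s_tot[membership[u]] += w
        s_tot[membership[v]] += w
    return sum(s_in[c] / two_m - (s_tot[c] / two_m) ** 2
               for c in set(membership.values()))


def tokenize(name: str) -> list[str]:
    """Lower-case and split on any non-alphanumeric run (numerals kept)."""
    return [t for t in _TOKEN_RE.split(name.lower()) if t]


def title_clusters(partition: Partition, stop_words: frozenset | set | None = None,
                   top_n: int = 10) -> Partition:
    """Title each cluster with its `top_n` highest tf-idf set-name words.

    Each cluster's token multiset (over its member set names, stop-words
    removed) is one document: tf = count / cluster token total, idf =
    ln(C / clusters-containing-word) with C the number of clusters, no
    smoothing. Ties break by raw frequency, then alphabetically. With a
    single cluster every idf is ln(1) = 0; the title then falls back to the
    most frequent words (scores stay 0).
    """
    stop = DEFAULT_STOPWORDS if stop_words is None else frozenset(stop_words)
    communities = partition.communities()
    docs = {}
    for cid, nodes in communities.items():
        tokens = [t for node in nodes for t in tokenize(node) if t not in stop]
        docs[cid] = Counter(tokens)
    n_clusters = len(docs)
    df: Counter = Counter()
    for counts in docs.values():
        df.update(set(counts))
    titles, scores = {}, {}
    for cid, counts in docs.items():
        total = sum(counts.values())
        if total == 0:
            warnings.warn(f"cluster {cid} has no tokens after stop-wording", stacklevel=2)
            titles[cid], scores[cid] = [], {}
            continue
        tfidf = {w: (c / total) * math.log(n_clusters / df[w]) for w, c in counts.items()}
        ranked = sorted(tfidf, key=lambda w: (-tfidf[w], -counts[w], w))
        titles[cid] = ranked[:top_n]
        scores[cid] = {w: tfidf[w] for w in titles[cid]}
    partition.titles = titles
    partition.tfidf_scores = scores
    return partition


def annotate_clusters(partition: Partition, sources: dict[str, str] | nx.Graph) -> Partition:
    """Flag clusters spanning >= 2 collection sources; single-source clusters
    keep their titles and scores but are marked not-annotated (NA)."""
    if isinstance(sources, nx.Graph):
        sources = {n: d.get("source", "") for n, d in sources.nodes(data=True)}
    annotated = {}
    for cid, nodes in partition.communities().items():
        annotated[cid] = len({sources[n] for n in nodes}) >= 2
    partition.annotated = annotated
    return partition


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def edges_frame(graph: nx.Graph) -> pd.DataFrame:
    rows = [{"set_a": u, "set_b": v, "jaccard": d["jaccard"], "overlap": d["overlap"]}
            for u, v, d in graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["set_a", "set_b", "jaccard", "overlap"]) \
             .sort_values(["set_a", "set_b"]).reset_index(drop=True)


def write_edges_tsv(graph: nx.Graph, path: str | Path) -> None:
    edges_frame(graph).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def clusters_frame(graph: nx.Graph, partition: Partition) -> pd.DataFrame:
    rows = []
    for node in sorted(graph.nodes):
        cid = partition.membership[node]
        rows.append({
            "set": node,
            "direction": graph.nodes[node].get("direction", ""),
            "community": cid,
            "source": graph.nodes[node].get("source", ""),
            "annotated": partition.annotated.get(cid, False),
        })
    return pd.DataFrame(rows)


def titles_frame(partition: Partition) -> pd.DataFrame:
    rows = []
    for cid in sorted(partition.titles):
        for rank, word in enumerate(partition.titles[cid], start=1):
            rows.append({"community": cid, "rank": rank, "word": word,
                         "tfidf": partition.tfidf_scores[cid][word]})
    return pd.DataFrame(rows, columns=["community", "rank", "word", "tfidf"])


def enrichment_map(oa: pd.DataFrame, collection: SetCollection, direction: str = "up",
                   fdr_cut: float = 0.01, j_min: float = 0.15, k_min: int = 5,
                   seed: int = 0, resolution: float = 1.0,
                   drop_singletons: bool = False) -> tuple[nx.Graph, Partition]:
    """Full stage for one direction: screen by FDR, build, cluster, title,
    annotate. ``drop_singletons`` removes single-node communities (a
    presentation option; keeps the analysis intact by default)."""
    sig = oa[(oa["direction"] == direction) & (oa["fdr"] < fdr_cut)]
    names = [n for n in sig["name"] if n in collection]
    graph = build_graph(collection.subset(names), j_min=j_min, k_min=k_min,
                        direction=direction)
    partition = louvain(graph, seed=seed, resolution=resolution)
    if drop_singletons:
        keep = {n for nodes in partition.communities().values() if len(nodes) > 1 for n in nodes}
        graph = graph.subgraph(keep).copy()
        partition = louvain(graph, seed=seed, resolution=resolution) if keep else Partition({})
    if graph.number_of_nodes():
        partition = title_clusters(partition)
        partition = annotate_clusters(partition, graph)
    return graph, partition
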