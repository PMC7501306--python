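"""Self-validation benchmarks: oracle comparisons and planted-truth recovery.

Each function here re-runs a pipeline stage on generated data and measures
either agreement with an independent oracle (exhaustive enumeration, brute
force, hand computation) or recovery of the generator's planted truth. The
oracles are deliberately written as naive, direct computations so they share
no code with the implementations they check.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import assay as assay_mod
from . import de as de_mod
from . import enrichment as en_mod
from . import screen as screen_mod
from . import setnet as sn_mod
from . import synthetic as syn_mod
from .genesets import GeneSet


def _subseed(seed: int, i: int) -> int:
    return (seed * 100_003 + i) % (2**31 - 1)


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

def _hypergeom_tail(k: int, n: int, m: int, N: int) -> float:
    total = 0.0
    for j in range(k, min(n, m) + 1):
        total += math.comb(m, j) * math.comb(N - m, n - j) / math.comb(N, n)
    return total


def fisher_vs_hypergeom(max_n: int = 12) -> dict:
    """Max |p difference| between the overrepresentation test and exhaustive
    hypergeometric tail summation over every 2x2 table with N <= max_n."""
    worst, count = 0.0, 0
    for N in range(1, max_n + 1):
        universe = [f"U{i:02d}" for i in range(N)]
        for n in range(0, N + 1):
            gene_list = universe[:n]
            for m in range(1, N + 1):
                for k in range(max(0, n + m - N), min(n, m) + 1):
                    members = gene_list[:k] + universe[n:n + (m - k)]
                    gs = GeneSet("S", frozenset(members))
                    res = en_mod.overrep_test(gene_list, gs, universe)
                    assert res.k == k and res.m == m
                    worst = max(worst, abs(res.p - _hypergeom_tail(k, n, m, N)))
                    count += 1
    return {"max_abs_err": worst, "n_tables": count}


def _bh_bruteforce(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    for pos, i in enumerate(order, start=1):
        adj[i] = min(1.0, min(n * p[order[j - 1]] / j for j in range(pos, n + 1)))
    return adj


def bh_vs_bruteforce(n_vectors: int = 1000, seed: int = 0) -> dict:
    """Max |difference| between the step-up implementation and the textbook
    definition on random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 80))
        p = rng.uniform(0, 1, n)
        if rng.random() < 0.3:  # inject ties
            p = np.round(p, 2)
        worst = max(worst, float(np.max(np.abs(de_mod.bh_adjust(p) - _bh_bruteforce(p)))))
    return {"max_abs_err": worst, "n_vectors": n_vectors}


def graph_vs_bruteforce(seed: int = 0, n_sets: int = 100) -> dict:
    """Edge mismatches between build_graph and a brute-force double loop on a
    random collection of <= n_sets sets."""
    rng = np.random.default_rng(seed)
    universe = [f"G{i:04d}" for i in range(400)]
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(10, 80))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        sets.append(GeneSet(f"SET{i:03d}", members))
    graph = sn_mod.build_graph(sets)
    expected = set()
    for a, b in itertools.combinations(sets, 2):
        inter = len(a.members & b.members)
        union = len(a.members) + len(b.members) - inter
        if inter >= 5 and inter / union >= 0.15:
            expected.add(frozenset((a.name, b.name)))
    got = {frozenset(e) for e in graph.edges}
    return {"edge_mismatches": len(expected ^ got), "n_edges": len(expected),
            "n_sets": n_sets}


def _set_partitions(items: list):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def louvain_vs_exhaustive(seed: int = 0, sizes=(4, 5, 6, 7, 8), graphs_per_size: int = 2) -> dict:
    """Worst modularity shortfall of Louvain vs the exhaustive optimum over
    seeded random weighted graphs with <= 8 nodes."""
    worst_gap, n_graphs = 0.0, 0
    for n in sizes:
        for g_idx in range(graphs_per_size):
            g_seed = _subseed(seed, 97 * n + g_idx)
            graph = nx.gnp_random_graph(n, 0.5, seed=g_seed)
            rng = np.random.default_rng(g_seed)
            for u, v in graph.edges:
                graph.edges[u, v]["jaccard"] = float(rng.uniform(0.15, 1.0))
            if graph.number_of_edges() == 0:
                graph.add_edge(0, 1, jaccard=0.5)
            nodes = list(graph.nodes)
            best = max(
                sn_mod.modularity(graph, {node: cid
                                          for cid, block in enumerate(part)
                                          for node in block})
                for part in _set_partitions(nodes)
            )
            part = sn_mod.louvain(graph, seed=g_seed)
            q = sn_mod.modularity(graph, part)
            gap = (best - q) / abs(best) if best > 1e-12 else max(0.0, best - q)
            worst_gap = max(worst_gap, gap)
            n_graphs += 1
    return {"max_rel_gap": worst_gap, "n_graphs": n_graphs}


def tfidf_vs_hand() -> dict:
    """Title scores on a fixture small enough to compute by hand: 4 clusters,
    'alpha' unique to cluster 0 with frequency 2/10 -> tf-idf = 0.2 ln 4."""
    groups = [
        ["ALPHA_W1_W2_W3_W4", "ALPHA_W5_W6_W7_W8"],
        ["BETA_X1_X2_X3_X4"],
        ["GAMMA_Y1_Y2_Y3_Y4"],
        ["DELTA_Z1_Z2_Z3_Z4"],
    ]
    membership = {name: cid for cid, names in enumerate(groups) for name in names}
    part = sn_mod.title_clusters(sn_mod.Partition(membership=membership),
                                 stop_words=frozenset())
    expected = 0.2 * math.log(4)
    err = abs(part.tfidf_scores[0]["alpha"] - expected)
    # every unique filler word: 1/10 * ln 4 in cluster 0, 1/5 * ln 4 elsewhere
    err = max(err, abs(part.tfidf_scores[1]["beta"] - 0.2 * math.log(4)))
    return {"max_abs_err": err, "expected_alpha": expected}


# ---------------------------------------------------------------------------
# screen recovery
# ---------------------------------------------------------------------------

def screen_recovery(seed: int = 0, n_seeds: int = 100) -> dict:
    """Hit sensitivity / false-positive rate on the default planted screen,
    plus scrambled-well z calibration on matched null screens."""
    hit_truth = syn_mod.default_screen_truth()
    null_truth = syn_mod.default_screen_truth(hit_genes=frozenset())
    n_hits_called = n_planted = n_fp = n_null_genes = 0
    z_scrambled: list[np.ndarray] = []
    for i in range(n_seeds):
        s = _subseed(seed, i)
        screen = syn_mod.gen_screen(hit_truth, n_genes=296, seed=s)
        hits = screen_mod.call_screen(screen)
        called = set(hits.loc[hits["is_hit"], "gene"])
        n_planted += len(hit_truth.hit_genes)
        n_hits_called += len(called & hit_truth.hit_genes)
        non_hits = set(hits["gene"]) - hit_truth.hit_genes
        n_fp += len(called - hit_truth.hit_genes)
        n_null_genes += len(non_hits)

        null_screen = syn_mod.gen_screen(null_truth, n_genes=296, seed=s)
        wells = screen_mod.summarize_wells(null_screen)
        z = screen_mod.zscore(wells)
        z_scrambled.append(z.loc[z["role"] == "scrambled", "z"].to_numpy())
    z_all = np.concatenate(z_scrambled)
    return {
        "sensitivity": n_hits_called / n_planted,
        "false_positive_rate": n_fp / n_null_genes,
        "scrambled_z_mean": float(z_all.mean()),
        "scrambled_z_sd": float(z_all.std(ddof=1)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# DE calibration and recovery
# ---------------------------------------------------------------------------

def de_null_calibration(seed: int = 0, n_seeds: int = 50, n_genes: int = 2000,
                        alpha: float = 0.05) -> dict:
    """Fraction of null genes with p < alpha, pooled over seeded replicates."""
    below = total = 0
    for i in range(n_seeds):
        s = _subseed(seed, 500 + i)
        truth = syn_mod.make_de_truth(n_genes=n_genes, n_pairs=3, de_frac=0.0, seed=s)
        cm = syn_mod.gen_counts(truth, seed=s)
        tab = de_mod.run_de(cm)
        below += int((tab["p"] < alpha).sum())
        total += len(tab)
    return {"fraction_below": below / total, "alpha": alpha,
            "band_3se": 3 * math.sqrt(alpha * (1 - alpha) / n_genes),
            "n_tests": total, "n_seeds": n_seeds}


def de_lfc_recovery(seed: int = 0, n_seeds: int = 5) -> dict:
    """Spearman correlation of estimated vs planted log2 fold changes over the
    planted-DE genes (lfc +-1.5 on 10% of 2000 genes, 3 pairs)."""
    rs = []
    for i in range(n_seeds):
        s = _subseed(seed, 900 + i)
        truth = syn_mod.make_de_truth(n_genes=2000, n_pairs=3, de_frac=0.10,
                                      lfc=1.5, seed=s)
        cm = syn_mod.gen_counts(truth, seed=s)
        tab = de_mod.run_de(cm).set_index("gene")
        planted = truth.true_lfc[truth.true_lfc != 0]
        shared = planted.index.intersection(tab.index)
        r, _ = sp_stats.spearmanr(tab.loc[shared, "log2fc"], planted.loc[shared])
        rs.append(float(r))
    return {"spearman_mean": float(np.mean(rs)), "spearman_min": float(np.min(rs)),
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# enrichment-map recovery
# ---------------------------------------------------------------------------

def map_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Planted 4-cluster collection: cross-cluster edge count, Louvain ARI vs
    planted truth, and planted-vocabulary coverage of multi-source titles."""
    from sklearn.metrics import adjusted_rand_score
    between_edges = 0
    aris, vocab_hits, vocab_total = [], 0, 0
    for i in range(n_seeds):
        s = _subseed(seed, 1300 + i)
        truth = syn_mod.make_cluster_truth(seed=s)
        coll = syn_mod.gen_genesets(truth, seed=s)
        graph = sn_mod.build_graph(coll)
        between_edges += sum(
            1 for u, v in graph.edges
            if truth.cluster_of_set[u] != truth.cluster_of_set[v])
        part = sn_mod.louvain(graph, seed=s)
        nodes = sorted(graph.nodes)
        aris.append(adjusted_rand_score(
            [truth.cluster_of_set[n] for n in nodes],
            [part.membership[n] for n in nodes]))
        part = sn_mod.title_clusters(part)
        part = sn_mod.annotate_clusters(part, graph)
        for cid, nodes_c in part.communities().items():
            if not part.annotated.get(cid, False):
                continue
            vocab_total += 1
            planted_cluster = truth.cluster_of_set[nodes_c[0]]
            vocab = set(truth.vocab_of_cluster[planted_cluster])
            vocab_hits += bool(vocab & set(part.titles[cid]))
    return {"between_cluster_edges": between_edges,
            "ari_min": float(np.min(aris)), "ari_mean": float(np.mean(aris)),
            "title_vocab_coverage": vocab_hits / max(vocab_total, 1),
            "n_multi_source_clusters": vocab_total, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# assay recovery
# ---------------------------------------------------------------------------

def assay_recovery(seed: int = 0, n_cells: int = 5000) -> dict:
    """Gating accuracy, dNHEJ condition ratio and population-fraction errors
    on the default planted assay scenario."""
    truth = syn_mod.default_cell_truth()
    cells = pd.concat(
        [syn_mod.gen_cells(truth, n_cells=n_cells, condition=c, seed=_subseed(seed, 1700))
         for c in ("control", "treated")],
        ignore_index=True)
    phases = assay_mod.gate_phases(cells)
    merged = cells.merge(phases, on="cell_id")
    accuracy = float((merged["phase"] == merged["true_phase"]).mean())

    scores = assay_mod.dnhej_score(cells, phases)
    d = scores[scores["metric"] == "dnhej"].set_index("condition")
    ratio = float(d.loc["treated", "mean"] / d.loc["control", "mean"])
    ratio_se = ratio * math.sqrt(
        (d.loc["treated", "sem"] / d.loc["treated", "mean"]) ** 2 +
        (d.loc["control", "sem"] / d.loc["control", "mean"]) ** 2)

    control = cells[cells["condition"] == "control"]
    fractions, frac_errors_se = {}, {}
    for name, predicate, planted in (
            ("edu", "edu_pos", truth.phase_fractions["S"]),
            ("mitotic", "h3s10_pos", truth.phase_fractions["M"]),
            ("polyploid", "polyploid", truth.phase_fractions["polyploid"])):
        pct = assay_mod.population_fraction(control, predicate)
        se = 100 * math.sqrt(planted * (1 - planted) / n_cells)
        fractions[name] = pct
        frac_errors_se[name] = abs(pct - 100 * planted) / se
    return {"gating_accuracy": accuracy, "dnhej_ratio": ratio,
            "dnhej_ratio_se": float(ratio_se), "fractions_pct": fractions,
            "fraction_errors_se": frac_errors_se, "n_cells": n_cells}
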