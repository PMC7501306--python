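"""Gene-set overrepresentation testing and keyword-based set curation.

Overrepresentation of a gene list in a set is assessed with a one-sided
(greater) Fisher exact test on the 2x2 table

    [[k, n - k], [m - k, N - n - m + k]]

where k is the overlap, n the list size, m the set size (after intersecting
with the universe) and N the universe size. The reported odds ratio is the
sample odds ratio k(N - n - m + k) / ((n - k)(m - k)), with 0/0 -> NaN and
x/0 -> inf. p-values are Benjamini-Hochberg corrected within each direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .genesets import GeneSet, SetCollection

KEYWORD_RULES: Mapping[str, Mapping[str, Sequence[str]]] = {
    "dna_repair": {
        "include": ("repair", "homologous", "nonhomologous", "non_homologous"),
        "exclude": (),
    },
    "stem_cell": {
        "include": ("stem_cell",),
        "exclude": ("hematopo", "mammary", "leukemic", "lymphoid"),
    },
}


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    direction: str
    k: int
    n: int
    m: int
    N: int
    odds_ratio: float
    p: float
    fdr: float | None = None


def _sample_odds_ratio(k: int, n: int, m: int, N: int) -> float:
    a, b, c, d = k, n - k, m - k, N - n - m + k
    if a * d == 0 and b * c == 0:
        return float("nan")
    if b * c == 0:
        return float("inf")
    return (a * d) / (b * c)


def overrep_test(gene_list: Iterable[str], gene_set: GeneSet,
                 universe: Iterable[str], direction: str = "up") -> EnrichmentResult:
    """One-sided Fisher exact overrepresentation of `gene_list` in `gene_set`.

    Set members are intersected with the universe before testing; the list
    must be a subset of the universe.
    """
    uni = frozenset(str(g).upper() for g in universe)
    if not uni:
        raise ValueError("empty universe")
    lst = frozenset(str(g).upper() for g in gene_list)
    if not lst <= uni:
        missing = sorted(lst - uni)[:5]
        raise ValueError(f"gene list is not a subset of the universe (e.g. {missing})")
    members = gene_set.members & uni
    k = len(lst & members)
    n, m, N = len(lst), len(members), len(uni)
    table = np.array([[k, n - k], [m - k, N - n - m + k]])
    _, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(name=gene_set.name, direction=direction, k=k, n=n, m=m,
                            N=N, odds_ratio=_sample_odds_ratio(k, n, m, N), p=float(p))


def run_oa(up_list: Iterable[str], down_list: Iterable[str],
           collection: SetCollection, universe: Iterable[str],
           fdr_cut: float = 0.05) -> pd.DataFrame:
    """Overrepresentation of the up and down lists in every set.

    BH correction runs within each direction separately; the `significant`
    flag applies `fdr_cut` to the within-direction FDR.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    up = frozenset(str(g).upper() for g in up_list)
    down = frozenset(str(g).upper() for g in down_list)
    if up & down:
        raise ValueError("up and down lists must be disjoint")
    rows = []
    for direction, lst in (("up", up), ("down", down)):
        results = [overrep_test(lst, s, universe, direction=direction) for s in collection]
        fdr = bh_adjust([r.p for r in results])
        for r, q in zip(results, fdr):
            rows.append({
                "name": r.name, "direction": r.direction, "k": r.k, "n": r.n,
                "m": r.m, "N": r.N, "odds_ratio": r.odds_ratio, "p": r.p,
                "fdr": float(q), "significant": bool(q < fdr_cut),
            })
    return pd.DataFrame(rows)


def select_keyword_sets(collection: SetCollection,
                        rule: str | Mapping[str, Sequence[str]] = "dna_repair") -> SetCollection:
    """Curate sets by substring keywords on lower-cased names.

    `rule` is either a built-in rule name ("dna_repair", "stem_cell") or a
    mapping with "include"/"exclude" word lists. Matching is substring, not
    word-boundary (so e.g. "non_homologous" matches inside longer names);
    exclusion is applied after inclusion. Exclusion words are matched against
    the set name (plain GMT dialects carry no reliable description field).
    """
    if isinstance(rule, str):
        if rule not in KEYWORD_RULES:
            raise ValueError(f"unknown curation rule {rule!r}")
        rule = KEYWORD_RULES[rule]
    include = [w.lower() for w in rule.get("include", ())]
    exclude = [w.lower() for w in rule.get("exclude", ())]
    if not include:
        raise ValueError("curation rule needs at least one include word")
    selected = []
    for s in collection:
        name = s.name.lower()
        if any(w in name for w in include) and not any(w in name for w in exclude):
            selected.append(s.name)
    return collection.subset(selected)


def filter_go_level(collection: SetCollection, level: int = 6) -> SetCollection:
    """Keep GO-source sets only at the given ontology level; others pass through.

    GO sets with missing level metadata are excluded with a warning.
    """
    keep = []
    for s in collection:
        if s.source != "go":
            keep.append(s.name)
        elif s.go_level is None:
            warnings.warn(f"GO set {s.name!r} has no level metadata; excluded", stacklevel=2)
        elif s.go_level == level:
            keep.append(s.name)
    return collection.subset(keep)


def write_oa_tsv(oa: pd.DataFrame, path: str | Path) -> None:
    oa.to_csv(path, sep="\t", index=False)


def read_oa_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
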