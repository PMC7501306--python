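"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions the pipeline was built for:

* a high-content siRNA screen over ~296 chromatin-remodeling genes in two
  matched populations (stem-like GSCs and differentiated DGCs), read out as
  per-cell gamma-H2AX mean intensity (MI);
* a paired two-condition RNA-seq design with negative-binomial counts;
* MSigDB-style gene-set collections with planted overlap clusters and
  vocabulary words in the set names;
* per-cell microscopy/flow tables with cell-cycle phases, intensity
  channels, repair-reporter channels and foci counts.

Each truth object records the planted parameters so that recovery can be
scored exactly. All randomness flows from one root seed via labelled child
streams (:mod:`stemscreen._rng`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .de import CountMatrix
from .genesets import GeneSet, SetCollection

POPULATIONS = ("GSC", "DGC")
PHASES = ("G1", "S", "G2", "M", "polyploid")
SCREEN_COLUMNS = ["plate", "well", "gene", "role", "population", "cell_id", "mi"]
CELL_CHANNELS = ("edu", "cyclin_a", "dna_content", "h3s10", "gfp", "bfp")
FOCI_MARKERS = ("gh2ax", "53bp1", "brca1")


def _lognormal_meanone(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    if cv < 0:
        raise ValueError("coefficient of variation must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    """Planted configuration of the siRNA screen.

    ``effect_gsc``/``effect_dgc`` are multiplicative gamma-H2AX-MI effects of
    knocking down a hit gene in the respective population (scalar applied to
    every hit, or per-gene mapping). ``plate_cv`` is the well-to-well noise
    CV; ``cell_cv`` the per-cell intensity CV within a well.
    """

    hit_genes: frozenset = field(default_factory=frozenset)
    effect_gsc: float | Mapping[str, float] = 1.4
    effect_dgc: float | Mapping[str, float] = 1.0
    plate_cv: float = 0.05
    cell_cv: float = 0.30
    cells_per_well: int = 200

    def __post_init__(self) -> None:
        self.hit_genes = frozenset(self.hit_genes)
        if self.cells_per_well < 1:
            raise ValueError("cells_per_well must be >= 1")
        for eff in (self.effect_gsc, self.effect_dgc):
            vals = eff.values() if isinstance(eff, Mapping) else [eff]
            if any(v <= 0 for v in vals):
                raise ValueError("effects must be > 0")

    def effect(self, gene: str, population: str) -> float:
        if gene not in self.hit_genes:
            return 1.0
        eff = self.effect_gsc if population == "GSC" else self.effect_dgc
        if isinstance(eff, Mapping):
            return float(eff.get(gene, 1.0))
        return float(eff)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "hit_genes": sorted(self.hit_genes),
            "effect_gsc": self.effect_gsc if not isinstance(self.effect_gsc, Mapping) else dict(self.effect_gsc),
            "effect_dgc": self.effect_dgc if not isinstance(self.effect_dgc, Mapping) else dict(self.effect_dgc),
            "plate_cv": self.plate_cv,
            "cell_cv": self.cell_cv,
            "cells_per_well": self.cells_per_well,
        }
        Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def default_screen_truth(**overrides) -> ScreenTruth:
    """The default screen scenario: three planted GSC-specific hits at 1.4x."""
    kwargs = dict(hit_genes=frozenset({"SPT6", "BRCA1", "WEE1"}), effect_gsc=1.4,
                  effect_dgc=1.0, plate_cv=0.05, cell_cv=0.30, cells_per_well=200)
    kwargs.update(overrides)
    return ScreenTruth(**kwargs)


def screen_library(truth: ScreenTruth, n_genes: int) -> list[str]:
    """Gene library: planted hits first, then filler symbols up to n_genes."""
    hits = sorted(truth.hit_genes)
    if len(hits) > n_genes:
        raise ValueError("more hit genes than library slots")
    fillers = [f"GENE{i:03d}" for i in range(1, n_genes - len(hits) + 1)]
    return hits + fillers


def gen_screen(truth: ScreenTruth, n_genes: int = 296,
               populations: Sequence[str] = POPULATIONS,
               n_scrambled: int = 16, n_positive: int = 4,
               baseline: float = 1000.0, positive_effect: float = 2.0,
               seed: int = 0, plate: str = "P1") -> pd.DataFrame:
    """Per-cell gamma-H2AX MI table for one screen run.

    One sample well per gene per population, plus scrambled-control and
    positive-control wells per population. Per-cell MI is log-normal around
    plate baseline x well noise x planted gene effect.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    unknown = set(populations) - set(POPULATIONS)
    if unknown:
        raise ValueError(f"unknown population label(s): {sorted(unknown)}")
    rng = derive_rng(seed, "screen")
    genes = screen_library(truth, n_genes)
    ncell = truth.cells_per_well
    cell_suffix = np.array([f"-c{j:04d}" for j in range(1, ncell + 1)])
    frames = []
    for pop in populations:
        wells: list[tuple[str, str]] = [(g, "sample") for g in genes]
        wells += [(f"SCRAMBLED{i:02d}", "scrambled") for i in range(1, n_scrambled + 1)]
        wells += [(f"INCENP{i:02d}", "positive") for i in range(1, n_positive + 1)]
        n_wells = len(wells)
        effects = np.array([
            truth.effect(label, pop) if role == "sample"
            else (positive_effect if role == "positive" else 1.0)
            for label, role in wells
        ])
        well_means = baseline * effects * _lognormal_meanone(rng, truth.plate_cv, n_wells)
        mi = (well_means[:, None] *
              _lognormal_meanone(rng, truth.cell_cv, (n_wells, ncell))).ravel()
        well_ids = np.array([f"{pop}-W{i:03d}" for i in range(1, n_wells + 1)])
        frames.append(pd.DataFrame({
            "plate": plate,
            "well": np.repeat(well_ids, ncell),
            "gene": np.repeat([label for label, _ in wells], ncell),
            "role": np.repeat([role for _, role in wells], ncell),
            "population": pop,
            "cell_id": np.char.add(np.repeat(well_ids, ncell), np.tile(cell_suffix, n_wells)),
            "mi": mi,
        }))
    return pd.concat(frames, ignore_index=True)


def write_screen_tsv(screen: pd.DataFrame, path: str | Path) -> None:
    screen.to_csv(path, sep="\t", index=False)


def read_screen_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SCREEN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# paired counts
# ---------------------------------------------------------------------------

@dataclass
class DETruth:
    """Planted paired RNA-seq design.

    ``true_lfc`` holds the log2 fold change of condition B over A per gene
    (0 for non-differential genes); ``dispersion`` the per-gene NB dispersion;
    ``lib_sizes`` the nominal per-sample sequencing depths; ``pairing`` maps
    sample name to pair id; ``half_life`` per-gene mRNA half-life in hours.
    """

    genes: list[str]
    true_lfc: pd.Series
    dispersion: pd.Series
    lib_sizes: pd.Series
    pairing: dict[str, str]
    half_life: pd.Series
    pair_cv: float = 0.10

    def __post_init__(self) -> None:
        if (self.dispersion < 0).any():
            raise ValueError("dispersions must be >= 0")
        if (self.lib_sizes < 0).any():
            raise ValueError("library sizes must be >= 0")
        if (self.half_life <= 0).any():
            raise ValueError("half-lives must be > 0 hours")

    @property
    def de_genes(self) -> frozenset:
        return frozenset(self.true_lfc.index[self.true_lfc != 0])

    def to_json(self, path: str | Path) -> None:
        obj = {
            "true_lfc": {g: float(v) for g, v in self.true_lfc.items() if v != 0},
            "dispersion_mean": float(self.dispersion.mean()),
            "lib_sizes": {s: float(v) for s, v in self.lib_sizes.items()},
            "pairing": dict(self.pairing),
            "pair_cv": self.pair_cv,
        }
        Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def make_de_truth(n_genes: int = 2000, n_pairs: int = 3, de_frac: float = 0.10,
                  lfc: float = 1.5, dispersion: float = 0.10,
                  lib_size: float = 2e6, seed: int = 0) -> DETruth:
    """Default paired design: `de_frac` of genes at +-`lfc`, NB dispersion ~0.1.

    Signs of the planted fold changes are split evenly so the composition of
    the library stays roughly balanced.
    """
    rng = derive_rng(seed, "de_truth")
    genes = [f"GENE{i:05d}" for i in range(1, n_genes + 1)]
    true_lfc = pd.Series(0.0, index=genes)
    n_de = int(round(de_frac * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.permuted(np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0))
    true_lfc.iloc[de_idx] = lfc * signs
    disp = pd.Series(dispersion * np.exp(rng.normal(0, 0.2, n_genes)), index=genes)
    samples = [f"P{p}_{c}" for p in range(1, n_pairs + 1) for c in ("A", "B")]
    lib = pd.Series(lib_size * np.exp(rng.normal(0, 0.05, len(samples))), index=samples)
    pairing = {s: s.split("_")[0] for s in samples}
    half_life = pd.Series(np.exp(rng.normal(np.log(8.0), 0.8, n_genes)), index=genes)
    return DETruth(genes=genes, true_lfc=true_lfc, dispersion=disp,
                   lib_sizes=lib, pairing=pairing, half_life=half_life)


def gen_counts(truth: DETruth, n_genes: int | None = None, n_pairs: int | None = None,
               seed: int = 0) -> CountMatrix:
    """Negative-binomial paired counts with a shared per-pair baseline.

    Condition-B means are scaled by 2^true_lfc. Gene lengths are drawn once
    per gene so RPKM is computable. Dispersion below 1e-12 collapses to the
    Poisson limit.
    """
    rng = derive_rng(seed, "counts")
    genes = truth.genes if n_genes is None else truth.genes[:n_genes]
    samples = list(truth.lib_sizes.index)
    if n_pairs is not None:
        keep_pairs = sorted(set(truth.pairing.values()))[:n_pairs]
        samples = [s for s in samples if truth.pairing[s] in keep_pairs]
    pair_ids = sorted({truth.pairing[s] for s in samples})
    if len(pair_ids) < 2:
        raise ValueError("need at least two pairs")
    if (truth.lib_sizes.loc[samples] < 0).any():
        raise ValueError("library sizes must be >= 0")

    n = len(genes)
    rel = np.exp(rng.normal(0, 1.0, n))
    rel /= rel.sum()
    lengths = pd.Series(
        np.round(np.exp(rng.normal(np.log(1500.0), 0.5, n))).astype(int) + 200,
        index=genes, name="length_bp",
    )
    lfc = truth.true_lfc.loc[genes].to_numpy()
    disp = truth.dispersion.loc[genes].to_numpy()
    pair_base = {p: _lognormal_meanone(rng, truth.pair_cv, n) for p in pair_ids}

    counts = {}
    for s in samples:
        cond = "B" if s.endswith("_B") else "A"
        mu = truth.lib_sizes[s] * rel * pair_base[truth.pairing[s]]
        if cond == "B":
            mu = mu * np.power(2.0, lfc)
        poisson_like = disp < 1e-12
        c = np.empty(n, dtype=np.int64)
        if poisson_like.any():
            c[poisson_like] = rng.poisson(mu[poisson_like])
        if (~poisson_like).any():
            r = 1.0 / disp[~poisson_like]
            p = r / (r + mu[~poisson_like])
            c[~poisson_like] = rng.negative_binomial(r, p)
        counts[s] = c
    counts_df = pd.DataFrame(counts, index=genes)
    sample_meta = pd.DataFrame({
        "condition": ["B" if s.endswith("_B") else "A" for s in samples],
        "pair": [truth.pairing[s] for s in samples],
    }, index=pd.Index(samples, name="sample"))
    return CountMatrix(counts_df, lengths, sample_meta)


# ---------------------------------------------------------------------------
# gene-set collections
# ---------------------------------------------------------------------------

@dataclass
class ClusterTruth:
    """Planted enrichment-map structure for a gene-set collection."""

    cluster_of_set: dict[str, int]
    vocab_of_cluster: dict[int, list[str]]
    sources: dict[str, str]

    def __post_init__(self) -> None:
        for cid, vocab in self.vocab_of_cluster.items():
            if not vocab:
                raise ValueError(f"cluster {cid} has an empty vocabulary")
        if set(self.cluster_of_set) != set(self.sources):
            raise ValueError("cluster_of_set and sources must cover the same set names")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "cluster_of_set": self.cluster_of_set,
            "vocab_of_cluster": {str(k): v for k, v in self.vocab_of_cluster.items()},
            "sources": self.sources,
        }
        Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


DEFAULT_VOCAB = [
    ["mitochondrial", "respiration"],
    ["cycle", "mitotic"],
    ["interferon", "immune"],
    ["axon", "synapse"],
]


def make_cluster_truth(n_clusters: int = 4, sets_per_cluster: int = 8,
                       vocab: Sequence[Sequence[str]] | None = None,
                       sources: Sequence[str] = ("hallmark", "curated", "go"),
                       seed: int = 0) -> ClusterTruth:
    """Name the sets of a planted clustering: source word + cluster vocabulary
    + a per-set filler token. Sources cycle within a cluster so every cluster
    spans more than one collection."""
    rng = derive_rng(seed, "cluster_truth")
    if vocab is None:
        vocab = [DEFAULT_VOCAB[i % len(DEFAULT_VOCAB)] for i in range(n_clusters)]
    cluster_of_set: dict[str, int] = {}
    sources_of: dict[str, str] = {}
    vocab_of: dict[int, list[str]] = {}
    for c in range(n_clusters):
        words = [w.upper() for w in vocab[c]]
        vocab_of[c] = [w.lower() for w in vocab[c]]
        if not words:
            raise ValueError("cluster vocabulary must be nonempty")
        for j in range(sets_per_cluster):
            source = sources[j % len(sources)]
            filler = f"V{rng.integers(0, 10_000):04d}"
            name = "_".join([source.upper(), *words, f"SET{j + 1:02d}", filler])
            cluster_of_set[name] = c
            sources_of[name] = source
    return ClusterTruth(cluster_of_set=cluster_of_set, vocab_of_cluster=vocab_of,
                        sources=sources_of)


def gen_genesets(truth: ClusterTruth, universe_size: int = 2000,
                 set_size_range: tuple[int, int] = (40, 60),
                 pool_factor: float = 1.5, seed: int = 0) -> SetCollection:
    """Collection with disjoint per-cluster gene pools.

    Sets in a cluster draw their members from a shared pool of
    ``ceil(pool_factor * max_set_size)`` genes, which puts the expected
    within-cluster Jaccard at r/(2-r) with r = set_size/pool_size (~0.5 at
    the default 1.5x pool). Between-cluster overlap is exactly zero.
    """
    rng = derive_rng(seed, "genesets")
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid set size range")
    clusters = sorted(set(truth.cluster_of_set.values()))
    pool_size = int(math.ceil(pool_factor * hi))
    if universe_size < pool_size * len(clusters):
        raise ValueError("universe too small for disjoint cluster pools")
    if universe_size < hi:
        raise ValueError("universe smaller than the largest set size")
    universe = [f"G{i:05d}" for i in range(1, universe_size + 1)]
    pools = {c: universe[i * pool_size:(i + 1) * pool_size] for i, c in enumerate(clusters)}
    collection = SetCollection()
    for name in sorted(truth.cluster_of_set):
        c = truth.cluster_of_set[name]
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(pools[c], size=min(size, len(pools[c])), replace=False)
        collection.add(GeneSet(name=name, members=frozenset(members),
                               source=truth.sources[name]))
    return collection


# ---------------------------------------------------------------------------
# per-cell assay tables
# ---------------------------------------------------------------------------

@dataclass
class CellTruth:
    """Planted per-cell assay model.

    ``phase_fractions`` gives the cell-cycle mixture; ``foci_rate`` maps
    (marker, phase-or-group, condition) to a Poisson mean, where the group
    "SG2" covers both S and G2 ("*" wildcards are allowed for condition).
    Intensity channels are two-component log-normal mixtures whose positive
    mode sits ``channel_separation`` natural-log units above the negative
    mode. Nuclear area (arbitrary units) is log-normal with the given mean
    and SD. ``repair_rate`` is the per-condition fraction of reporter-
    transduced (BFP+) cells that resolved the reporter break (GFP+).
    """

    phase_fractions: dict[str, float]
    foci_rate: dict[tuple[str, str, str], float]
    na_mean: float = 100.0
    na_sd: float = 20.0
    channel_separation: float = 2.0
    transduced_frac: float = 0.6
    repair_rate: dict[str, float] = field(default_factory=lambda: {"*": 0.25})

    def __post_init__(self) -> None:
        if abs(sum(self.phase_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1 within 1e-9")
        unknown = set(self.phase_fractions) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases: {sorted(unknown)}")
        if any(rate < 0 for rate in self.foci_rate.values()):
            raise ValueError("foci rates must be >= 0")

    def rate(self, marker: str, phase: str, condition: str) -> float:
        group = "SG2" if phase in ("S", "G2") else phase
        for ph in (phase, group):
            for cond in (condition, "*"):
                if (marker, ph, cond) in self.foci_rate:
                    return self.foci_rate[(marker, ph, cond)]
        return 0.0

    def to_json(self, path: str | Path) -> None:
        obj = {
            "phase_fractions": self.phase_fractions,
            "foci_rate": {"|".join(k): v for k, v in self.foci_rate.items()},
            "na_mean": self.na_mean, "na_sd": self.na_sd,
            "channel_separation": self.channel_separation,
            "transduced_frac": self.transduced_frac,
            "repair_rate": self.repair_rate,
        }
        Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def default_cell_truth(**overrides) -> CellTruth:
    """Default assay scenario: an asynchronous population whose treated arm
    doubles the S/G2 53BP1 rate (the de-regulated end-joining readout)."""
    kwargs = dict(
        phase_fractions={"G1": 0.55, "S": 0.25, "G2": 0.12, "M": 0.03, "polyploid": 0.05},
        foci_rate={
            ("53bp1", "G1", "*"): 5.0,
            ("53bp1", "SG2", "control"): 2.0,
            ("53bp1", "SG2", "treated"): 4.0,
            ("53bp1", "M", "*"): 1.0,
            ("53bp1", "polyploid", "*"): 6.0,
            ("brca1", "SG2", "control"): 6.0,
            ("brca1", "SG2", "treated"): 3.0,
            ("brca1", "G1", "*"): 0.5,
            ("brca1", "M", "*"): 0.5,
            ("brca1", "polyploid", "*"): 1.0,
            ("gh2ax", "G1", "*"): 3.0,
            ("gh2ax", "SG2", "*"): 4.0,
            ("gh2ax", "M", "*"): 2.0,
            ("gh2ax", "polyploid", "*"): 8.0,
        },
        na_mean=100.0, na_sd=20.0, channel_separation=2.0,
        transduced_frac=0.6, repair_rate={"control": 0.25, "treated": 0.10},
    )
    kwargs.update(overrides)
    return CellTruth(**kwargs)


_DNA_MODES = {"G1": 2.0, "G2": 4.0, "M": 4.0, "polyploid": 8.0}


def gen_cells(truth: CellTruth, n_cells: int = 5000, condition: str = "control",
              seed: int = 0, base_log_intensity: float = math.log(100.0),
              channel_sigma: float = 0.30) -> pd.DataFrame:
    """Per-cell assay table for one condition.

    Columns: cell_id, condition, true_phase (generator ground truth, ignored
    by the scoring code), nuclear_area, the intensity channels, and
    foci_<marker> counts.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = derive_rng(seed, f"cells:{condition}")
    phases = np.array(PHASES)
    probs = np.array([truth.phase_fractions.get(p, 0.0) for p in PHASES])
    phase = rng.choice(phases, size=n_cells, p=probs / probs.sum())

    # nuclear area: log-normal matched to the requested mean/SD
    cv = truth.na_sd / truth.na_mean
    sigma = math.sqrt(math.log(1 + cv * cv))
    mu = math.log(truth.na_mean) - 0.5 * sigma * sigma
    nuclear_area = np.exp(rng.normal(mu, sigma, n_cells))

    def channel(positive_mask: np.ndarray) -> np.ndarray:
        shift = np.where(positive_mask, truth.channel_separation, 0.0)
        return np.exp(base_log_intensity + shift + rng.normal(0, channel_sigma, n_cells))

    is_s = phase == "S"
    is_g2 = phase == "G2"
    is_m = phase == "M"
    is_poly = phase == "polyploid"
    edu = channel(is_s)
    cyclin_a = channel(is_s | is_g2)
    h3s10 = channel(is_m)

    dna = np.empty(n_cells)
    for ph, mode in _DNA_MODES.items():
        mask = phase == ph
        jitter = 0.08 if ph == "polyploid" else 0.04
        dna[mask] = mode * np.exp(rng.normal(0, jitter, mask.sum()))
    s_mask = phase == "S"
    dna[s_mask] = rng.uniform(2.3, 3.7, s_mask.sum()) * np.exp(rng.normal(0, 0.02, s_mask.sum()))

    # repair reporter: BFP marks transduction; GFP among BFP+ marks repair
    rep = truth.repair_rate.get(condition, truth.repair_rate.get("*", 0.0))
    bfp_pos = rng.random(n_cells) < truth.transduced_frac
    gfp_pos = bfp_pos & (rng.random(n_cells) < rep)
    bfp = channel(bfp_pos)
    gfp = channel(gfp_pos)

    out = pd.DataFrame({
        "cell_id": [f"{condition}-c{i:05d}" for i in range(1, n_cells + 1)],
        "condition": condition,
        "true_phase": phase,
        "nuclear_area": nuclear_area,
        "edu": edu, "cyclin_a": cyclin_a, "dna_content": dna,
        "h3s10": h3s10, "gfp": gfp, "bfp": bfp,
    })
    for marker in FOCI_MARKERS:
        lam = np.array([truth.rate(marker, ph, condition) for ph in phase])
        out[f"foci_{marker}"] = rng.poisson(lam)
    return out


def write_cells_tsv(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_cells_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
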