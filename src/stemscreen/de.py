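"""Paired RNA-seq differential-expression post-processing.

Implements the expression workflow used downstream of read counting:
RPKM-based expression filtering, TMM library normalization, log2-CPM
transformation, a paired two-sided t-test on within-pair log-CPM differences
(a documented approximation of a negative-binomial GLM with a pairing
covariate), Benjamini-Hochberg correction, MA summaries, top-n signature
extraction, cross-dataset Spearman concordance with a sliding-window trend,
and an mRNA half-life confounding check.

Externally produced differential tables with the same column contract
(gene, log2fc, mean_log2cpm, p, fdr) are accepted by every downstream step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DE_COLUMNS = ["gene", "log2fc", "mean_log2cpm", "p", "fdr"]


@dataclass
class CountMatrix:
    """Integer gene x sample counts with gene lengths and paired sample metadata.

    ``samples`` is indexed by sample name with columns ``condition`` (one of
    {"A", "B"}) and ``pair``; every pair id must map to exactly one A and one
    B sample.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise ValueError(f"missing gene lengths for: {sorted(missing)[:10]}")
        if not set(self.counts.columns) <= set(self.samples.index):
            raise ValueError("every count column needs a samples-table row")
        for pair, grp in self.samples.loc[self.counts.columns].groupby("pair"):
            conds = sorted(grp["condition"])
            if conds != ["A", "B"]:
                raise ValueError(f"pair {pair!r} is not a complete A/B pair (got {conds})")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def pairs(self) -> list[tuple[str, str, str]]:
        """Return (pair_id, sample_A, sample_B) triples in sorted pair order."""
        meta = self.samples.loc[self.counts.columns]
        out = []
        for pair, grp in sorted(meta.groupby("pair"), key=lambda kv: str(kv[0])):
            a = grp.index[grp["condition"] == "A"][0]
            b = grp.index[grp["condition"] == "B"][0]
            out.append((pair, a, b))
        return out


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million, on raw library sizes."""
    lib = cm.library_sizes.astype(float)
    lengths = cm.lengths.loc[cm.counts.index].astype(float)
    return cm.counts * 1e9 / np.outer(lengths, lib)


def filter_expressed(cm: CountMatrix, rpkm_min: float = 1.0, min_samples: int = 3,
                     use_effective: bool = False) -> CountMatrix:
    """Keep genes strictly above `rpkm_min` RPKM in at least `min_samples` samples.

    The filter runs before normalization on raw library sizes by default;
    ``use_effective=True`` switches to TMM-effective sizes.
    """
    lib = cm.library_sizes.astype(float)
    if use_effective:
        lib = lib * tmm_factors(cm.counts)
    lengths = cm.lengths.loc[cm.counts.index].astype(float)
    r = cm.counts * 1e9 / np.outer(lengths, lib)
    keep = (r > rpkm_min).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts.loc[keep], cm.lengths.loc[keep], cm.samples)


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                     trim_m: float, trim_a: float) -> float:
    """Trimmed mean of M-values for one sample against the reference.

    Follows the published TMM recipe: log-ratios (M) and average log
    expression (A) over genes nonzero in both samples, double-trimmed (30% on
    M, 5% on A by default), combined with inverse-asymptotic-variance
    weights, then exponentiated.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        keep = (obs > 0) & (ref > 0)
        m = np.log2(p_obs[keep] / p_ref[keep])
        a = 0.5 * np.log2(p_obs[keep] * p_ref[keep])
        # inverse asymptotic (delta-method binomial) variance weights
        v = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (lib_ref * ref[keep])
        w = 1.0 / v
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[fin], a[fin], w[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM scale factors (geometric mean normalized to 1).

    The reference sample is the one whose 75th count-fraction percentile is
    closest to the mean over samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"samples with all-zero counts: {bad}")
    f75 = (counts / lib).quantile(0.75, axis=0)
    ref_name = (f75 - f75.mean()).abs().idxmin()
    ref = counts[ref_name].to_numpy(dtype=float)
    factors = {}
    for name in counts.columns:
        factors[name] = _tmm_pair_factor(
            counts[name].to_numpy(dtype=float), ref, lib[name], lib[ref_name], trim_m, trim_a
        )
    out = pd.Series(factors, name="tmm_factor")
    out /= np.exp(np.log(out).mean())
    return out


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None,
            pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount), CPM on TMM-effective library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.loc[counts.columns]
    cpm = counts * 1e6 / lib
    return np.log2(cpm + pseudocount)


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def paired_de(expr: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-gene paired two-sided t-test on within-pair log-CPM differences.

    log2fc is the mean within-pair (B - A) difference. Degenerate genes where
    every pair difference is identical get p = 1 when the common difference is
    zero and p = 0 otherwise.
    """
    meta = samples.loc[expr.columns]
    pairs = []
    for pair, grp in sorted(meta.groupby("pair"), key=lambda kv: str(kv[0])):
        a = grp.index[grp["condition"] == "A"]
        b = grp.index[grp["condition"] == "B"]
        if len(a) != 1 or len(b) != 1:
            raise ValueError(f"pair {pair!r} is not a complete A/B pair")
        pairs.append((a[0], b[0]))
    if len(pairs) < 2:
        raise ValueError("need at least two complete pairs")
    diffs = np.column_stack([expr[b].to_numpy() - expr[a].to_numpy() for a, b in pairs])
    k = diffs.shape[1]
    mean_d = diffs.mean(axis=1)
    sd_d = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(k))
    p = 2.0 * stats.t.sf(np.abs(t), df=k - 1)
    degenerate = sd_d == 0
    p[degenerate & (mean_d == 0)] = 1.0
    p[degenerate & (mean_d != 0)] = 0.0
    out = pd.DataFrame({
        "gene": expr.index,
        "log2fc": mean_d,
        "mean_log2cpm": expr.mean(axis=1).to_numpy(),
        "p": p,
    })
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out.reset_index(drop=True)


def run_de(cm: CountMatrix, rpkm_min: float = 1.0, min_samples: int = 3,
           pseudocount: float = 1.0) -> pd.DataFrame:
    """filter -> TMM -> log-CPM -> paired test, returning a DE table."""
    kept = filter_expressed(cm, rpkm_min=rpkm_min, min_samples=min_samples)
    factors = tmm_factors(kept.counts)
    expr = log_cpm(kept.counts, factors, pseudocount=pseudocount)
    return paired_de(expr, kept.samples)


# ---------------------------------------------------------------------------
# summaries and signatures
# ---------------------------------------------------------------------------

def ma_summary(de: pd.DataFrame, fdr_cut: float = 0.05) -> dict:
    """Counts of significantly up/down genes plus MA-plot coordinates."""
    sig = de["fdr"] < fdr_cut
    n_up = int((sig & (de["log2fc"] > 0)).sum())
    n_down = int((sig & (de["log2fc"] < 0)).sum())
    coords = de[["gene", "mean_log2cpm", "log2fc"]].copy()
    coords["significant"] = sig.to_numpy()
    return {"n_up": n_up, "n_down": n_down, "ma": coords}


def _top_by_p(de: pd.DataFrame, direction: str, n: int) -> list[str]:
    if direction == "up":
        sub = de[de["log2fc"] > 0]
    elif direction == "down":
        sub = de[de["log2fc"] < 0]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    sub = sub.assign(_abs=sub["log2fc"].abs())
    sub = sub.sort_values(["p", "_abs", "gene"], ascending=[True, False, True], kind="mergesort")
    return sub["gene"].head(n).tolist()


def extract_signature(de: pd.DataFrame, n: int = 500) -> tuple[list[str], list[str]]:
    """Top `n` up- and downregulated genes ranked by p-value.

    Ties across the n boundary break deterministically by |log2fc| descending,
    then gene symbol. If a direction has fewer than n genes, all are returned.
    """
    return _top_by_p(de, "up", n), _top_by_p(de, "down", n)


def top_up_set(de: pd.DataFrame, n: int = 250) -> list[str]:
    """Top `n` upregulated genes ranked by p-value (e.g. a derived stem-cell set)."""
    return _top_by_p(de, "up", n)


def concordance(de_a: pd.DataFrame, de_b: pd.DataFrame, window_frac: float = 0.05,
                density_bins: int = 40) -> dict:
    """Spearman concordance of two DE tables over their gene intersection.

    Also returns a trend curve: genes sorted by the A-table log2fc, sliding
    mean +- SE of the B-table log2fc with a window of ceil(window_frac * n)
    genes stepping one gene (symmetric windows truncated at the ends), plus
    2D bin counts for density plotting.
    """
    merged = de_a.merge(de_b, on="gene", suffixes=("_a", "_b"))
    n = len(merged)
    if n < 10:
        raise ValueError(f"need >= 10 shared genes, got {n}")
    x = merged["log2fc_a"].to_numpy()
    y = merged["log2fc_b"].to_numpy()
    r_s, p = stats.spearmanr(x, y)
    window = int(np.ceil(window_frac * n))
    order = np.argsort(x, kind="mergesort")
    ys = pd.Series(y[order])
    roll = ys.rolling(window, center=True, min_periods=1)
    trend = pd.DataFrame({
        "x": x[order],
        "mean": roll.mean().to_numpy(),
        "se": (roll.std(ddof=1) / np.sqrt(roll.count())).to_numpy(),
    })
    counts, xedges, yedges = np.histogram2d(x, y, bins=density_bins)
    return {"r_s": float(r_s), "p": float(p), "n": n, "trend": trend,
            "density": {"counts": counts, "xedges": xedges, "yedges": yedges}}


def halflife_bias(de: pd.DataFrame, half_life: pd.Series, limit: float = 0.3) -> dict:
    """Check whether fold changes correlate with mRNA half-life.

    A strong (|r_s| > limit) correlation would indicate that the differential
    signal merely tracks transcript stability under a global transcription
    decline, rather than gene-specific regulation.
    """
    hl = half_life.dropna()
    merged = de.set_index("gene").join(hl.rename("half_life"), how="inner").dropna(subset=["half_life"])
    if len(merged) == 0:
        raise ValueError("no genes overlap between DE table and half-life table")
    if len(merged) < 50:
        raise ValueError(f"need half-life for >= 50 genes, got {len(merged)}")
    r_s, p = stats.spearmanr(merged["log2fc"], merged["half_life"])
    quartile = pd.qcut(merged["half_life"], 4, labels=["Q1", "Q2", "Q3", "Q4"], duplicates="drop")
    summary = merged.groupby(quartile, observed=True)["log2fc"].agg(["mean", "count"])
    return {
        "r_s": float(r_s),
        "p": float(p),
        "n": int(len(merged)),
        "quartile_means": summary,
        "bias_flag": bool(abs(r_s) > limit),
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return de


def read_counts(counts_path, samples_path, lengths_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts, lengths, samples)


def write_counts(cm: CountMatrix, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / "counts.tsv",
        "samples": out_dir / "samples.tsv",
        "lengths": out_dir / "lengths.tsv",
    }
    cm.counts.to_csv(paths["counts"], sep="\t")
    cm.samples.to_csv(paths["samples"], sep="\t")
    cm.lengths.rename("length_bp").to_frame().to_csv(paths["lengths"], sep="\t")
    return paths
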