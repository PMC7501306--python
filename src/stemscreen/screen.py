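"""siRNA-screen hit calling on per-cell gamma-H2AX mean intensities.

Wells are summarized to mean MI, converted to fold change over the
scrambled-control mean of the same plate and population, z-scored against
the sample wells of that plate/population, and called as hits when the
knockdown induces the DSB marker in the stem-like population (fold change at
or above the threshold in GSCs) but not in the differentiated one (below the
threshold in DGCs).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

WELL_KEY = ["plate", "well", "gene", "role", "population"]


def summarize_wells(screen: pd.DataFrame, min_cells: int = 50) -> pd.DataFrame:
    """Aggregate per-cell MI to per-well mean with a cell-count QC flag.

    Wells with fewer than `min_cells` cells are flagged qc_pass=False and
    excluded from every downstream statistic.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if len(screen) == 0:
        raise ValueError("empty screen dataset")
    grouped = screen.groupby(WELL_KEY, as_index=False, sort=True).agg(
        n_cells=("mi", "size"), mean_mi=("mi", "mean"))
    grouped["qc_pass"] = grouped["n_cells"] >= min_cells
    return grouped


def control_fold_change(wells: pd.DataFrame) -> pd.DataFrame:
    """Fold change of each sample well over the scrambled-control mean.

    The reference is the mean of qc-passing scrambled-well means on the same
    plate and population.
    """
    ok = wells[wells["qc_pass"]]
    ref = (ok[ok["role"] == "scrambled"]
           .groupby(["plate", "population"])["mean_mi"].mean()
           .rename("scrambled_mean"))
    sample = ok[ok["role"] == "sample"].copy()
    for key in sample[["plate", "population"]].drop_duplicates().itertuples(index=False):
        if (key.plate, key.population) not in ref.index:
            raise ValueError(
                f"no qc-passing scrambled controls on plate {key.plate!r} "
                f"(population {key.population!r})")
    sample = sample.merge(ref.reset_index(), on=["plate", "population"], how="left")
    sample["fc"] = sample["mean_mi"] / sample["scrambled_mean"]
    return sample[["plate", "gene", "population", "fc"]]


def zscore(wells: pd.DataFrame, robust: bool = False) -> pd.DataFrame:
    """z-scores of qc-passing wells against the sample wells of the plate.

    The reference distribution is all qc-passing sample (non-control) wells
    of the same plate and population: hits are rare, so sample wells
    approximate a null. Population (ddof=0) SD by default; ``robust=True``
    uses median and scaled MAD instead. sigma = 0 yields z = 0.
    """
    ok = wells[wells["qc_pass"]].copy()
    stats_rows = {}
    for key, grp in ok[ok["role"] == "sample"].groupby(["plate", "population"]):
        if len(grp) < 3:
            raise ValueError(f"fewer than 3 qc-passing sample wells for {key}")
        x = grp["mean_mi"].to_numpy()
        if robust:
            mu = float(np.median(x))
            sigma = 1.4826 * float(np.median(np.abs(x - mu)))
        else:
            mu = float(np.mean(x))
            sigma = float(np.std(x))  # population SD
        stats_rows[key] = (mu, sigma)
    mus = ok.apply(lambda r: stats_rows.get((r["plate"], r["population"]), (np.nan, np.nan))[0], axis=1)
    sigmas = ok.apply(lambda r: stats_rows.get((r["plate"], r["population"]), (np.nan, np.nan))[1], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ok["mean_mi"] - mus) / sigmas
    ok["z"] = np.where(sigmas == 0, 0.0, z)
    return ok[["plate", "well", "gene", "role", "population", "mean_mi", "z"]]


def call_hits(fc: pd.DataFrame, z: pd.DataFrame | None = None,
              hit_threshold: float = 1.20,
              target: str = "GSC", reference: str = "DGC") -> pd.DataFrame:
    """Differential hit call: fc >= threshold in `target` AND < threshold in
    `reference`. The threshold is inclusive on the target side only.

    Genes missing either population are dropped with a warning. z-scores, if
    provided, are carried along for ranking context.
    """
    wide = fc.pivot_table(index="gene", columns="population", values="fc", aggfunc="mean")
    for pop in (target, reference):
        if pop not in wide.columns:
            raise ValueError(f"population {pop!r} absent from fold-change table")
    incomplete = wide.index[wide[[target, reference]].isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(f"excluding {len(incomplete)} gene(s) missing one population: "
                      f"{sorted(incomplete)[:5]}...", stacklevel=2)
        wide = wide.drop(index=incomplete)
    out = pd.DataFrame({
        "gene": wide.index,
        f"fc_{target.lower()}": wide[target].to_numpy(),
        f"fc_{reference.lower()}": wide[reference].to_numpy(),
    })
    if z is not None:
        zw = (z[z["role"] == "sample"]
              .pivot_table(index="gene", columns="population", values="z", aggfunc="mean"))
        out[f"z_{target.lower()}"] = out["gene"].map(zw.get(target, pd.Series(dtype=float)))
        out[f"z_{reference.lower()}"] = out["gene"].map(zw.get(reference, pd.Series(dtype=float)))
    out["is_hit"] = (out[f"fc_{target.lower()}"] >= hit_threshold) & \
                    (out[f"fc_{reference.lower()}"] < hit_threshold)
    return out.reset_index(drop=True)


def rank_hits(hits: pd.DataFrame, by: str = "fc_gsc") -> pd.DataFrame:
    """Rank called hits descending by `by`, ties broken by gene symbol.

    Non-hits keep a missing rank; ranks over the hits are 1..n_hits.
    """
    if by not in hits.columns:
        raise ValueError(f"unknown ranking key {by!r}")
    if not hits["is_hit"].any():
        raise ValueError("no hits to rank")
    out = hits.copy()
    called = out[out["is_hit"]].sort_values([by, "gene"], ascending=[False, True],
                                            kind="mergesort")
    ranks = pd.Series(np.arange(1, len(called) + 1), index=called.index)
    out["rank"] = ranks.reindex(out.index).astype("Int64")
    out["_order"] = out["rank"].astype(float).fillna(np.inf)
    out = out.sort_values(["_order", by, "gene"], ascending=[True, False, True],
                          kind="mergesort").drop(columns="_order")
    return out.reset_index(drop=True)


def call_screen(screen: pd.DataFrame, min_cells: int = 50, hit_threshold: float = 1.20,
                rank_by: str = "fc_gsc", robust_z: bool = False,
                target: str = "GSC", reference: str = "DGC") -> pd.DataFrame:
    """Full stage: summarize -> fold change + z -> differential call -> rank."""
    wells = summarize_wells(screen, min_cells=min_cells)
    fc = control_fold_change(wells)
    z = zscore(wells, robust=robust_z)
    hits = call_hits(fc, z, hit_threshold=hit_threshold, target=target, reference=reference)
    if hits["is_hit"].any():
        hits = rank_hits(hits, by=rank_by)
    else:
        hits["rank"] = pd.array([pd.NA] * len(hits), dtype="Int64")
    return hits


def write_hits_tsv(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False)
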