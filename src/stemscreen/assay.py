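"""Per-cell assay scoring: cell-cycle gating, nuclear-area-normalized foci
densities, DSB repair-pathway-choice scores, population fractions, reporter
repair rates, qPCR arithmetic and two-group comparison.

Cell-cycle phases are called from intensity channels with deterministic,
data-driven gates: each channel's log intensity is split at the midpoint of
a two-component Gaussian-mixture fit (with a conservative upper-quantile
fallback when the channel is effectively unimodal). Phase precedence is
polyploid > M > S > G2 > G1, which resolves double-positive cells
deterministically.

Foci counts are normalized to nuclear area (NA) per cell before averaging,
so populations with different nuclear sizes stay comparable. The
de-regulated end-joining score (dNHEJ) is the 53BP1 foci density restricted
to S/G2 cells; its companions are the HR proxy (BRCA1 density in S/G2) and
the NHEJ proxy (53BP1 density in G1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

PHASE_ORDER = ("polyploid", "M", "S", "G2", "G1")


@dataclass(frozen=True)
class GateConfig:
    """Gating parameters. ``poly_factor`` multiplies the G1 DNA-content mode
    (anchored at 2N) to place the polyploid cut at poly_factor x 2N; the
    default 2.25 puts it at 4.5N. ``min_modes_gap`` (natural-log units) is
    the smallest mixture-mean separation accepted as bimodal."""

    poly_factor: float = 2.25
    min_modes_gap: float = 0.5
    unimodal_sigmas: float = 3.0


def split_threshold(values: np.ndarray, min_modes_gap: float = 0.5,
                    unimodal_sigmas: float = 3.0) -> float:
    """Positivity threshold for one intensity channel.

    Midpoint (in log space) between the two means of a two-component
    Gaussian mixture; when the fitted modes are closer than `min_modes_gap`
    the channel is treated as unimodal-negative and the threshold falls back
    to mean + `unimodal_sigmas` * SD of the log intensities.
    """
    logx = np.log(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(logx)):
        raise ValueError("intensities must be positive and finite")
    gm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(logx.reshape(-1, 1))
    means = np.sort(gm.means_.ravel())
    if means[1] - means[0] < min_modes_gap:
        return float(np.exp(logx.mean() + unimodal_sigmas * logx.std()))
    return float(np.exp(means.mean()))


def _g1_mode(dna: np.ndarray) -> float:
    """DNA-content G1 mode via kernel density over the sub-median range."""
    if np.std(dna) < 1e-12:
        return float(dna[0])
    kde = stats.gaussian_kde(dna)
    lo, hi = np.quantile(dna, [0.001, 0.999])
    grid = np.linspace(lo, hi, 512)
    dens = kde(grid)
    # G1 is the dominant peak at or below 1.2x the median in a population
    # that is not heavily arrested; restrict the argmax accordingly.
    mask = grid <= 1.2 * np.median(dna)
    if not mask.any():
        mask = np.ones_like(grid, dtype=bool)
    return float(grid[mask][np.argmax(dens[mask])])


def gate_phases(cells: pd.DataFrame, mode: str = "edu_cyclin",
                config: GateConfig | None = None,
                thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Call one cell-cycle phase per cell.

    ``mode`` selects the S/G2 channels: "edu_cyclin" uses the EdU pulse for S
    and cyclin A for G2; "dna" gates S as intermediate DNA content between
    the G1 and G2 modes. Precedence: polyploid > M > S > G2 > G1. Explicit
    `thresholds` (channel -> cutoff) override the fitted gates.
    """
    config = config or GateConfig()
    required = {"edu_cyclin": ("edu", "cyclin_a", "h3s10", "dna_content"),
                "dna": ("dna_content", "h3s10")}
    if mode not in required:
        raise ValueError(f"unknown gating mode {mode!r}")
    missing = [c for c in required[mode] if c not in cells.columns]
    if missing:
        raise ValueError(f"missing channel(s) for mode {mode!r}: {missing}")

    thresholds = dict(thresholds or {})
    dna = cells["dna_content"].to_numpy(dtype=float)
    if "dna_content" in thresholds and mode != "dna":
        g1_mode = thresholds["dna_content"] / config.poly_factor
        poly_cut = thresholds["dna_content"]
    else:
        g1_mode = _g1_mode(dna)
        poly_cut = thresholds.get("dna_content", config.poly_factor * g1_mode)

    def thr(channel: str) -> float:
        if channel not in thresholds:
            thresholds[channel] = split_threshold(
                cells[channel].to_numpy(), config.min_modes_gap, config.unimodal_sigmas)
        return thresholds[channel]

    n = len(cells)
    phase = np.full(n, "G1", dtype=object)
    if mode == "edu_cyclin":
        s_mask = cells["edu"].to_numpy() > thr("edu")
        g2_mask = (cells["cyclin_a"].to_numpy() > thr("cyclin_a")) & ~s_mask
    else:
        s_mask = (dna > 1.25 * g1_mode) & (dna < 1.75 * g1_mode)
        g2_mask = (dna >= 1.75 * g1_mode) & (dna <= poly_cut)
    m_mask = cells["h3s10"].to_numpy() > thr("h3s10")
    poly_mask = dna > poly_cut
    phase[g2_mask] = "G2"
    phase[s_mask] = "S"
    phase[m_mask] = "M"
    phase[poly_mask] = "polyploid"
    out = pd.DataFrame({"cell_id": cells["cell_id"].to_numpy(), "phase": phase})
    out.attrs["thresholds"] = {**thresholds, "poly_cut": float(poly_cut),
                               "g1_mode": g1_mode}
    return out


def foci_density(cells: pd.DataFrame, marker: str,
                 group_by: str | list[str] = "condition") -> tuple[pd.Series, pd.DataFrame]:
    """Foci count per nucleus normalized to nuclear area, plus group mean +- SEM."""
    col = f"foci_{marker}" if f"foci_{marker}" in cells.columns else marker
    if col not in cells.columns:
        raise ValueError(f"marker {marker!r} not present")
    na = cells["nuclear_area"].to_numpy(dtype=float)
    if (na <= 0).any():
        raise ValueError("nuclear_area must be > 0")
    density = pd.Series(cells[col].to_numpy(dtype=float) / na,
                        index=cells.index, name=f"{marker}_density")
    grouped = density.groupby([cells[g] for g in ([group_by] if isinstance(group_by, str) else group_by)])
    summary = grouped.agg(["mean", "sem", "count"]).rename(columns={"count": "n"})
    return density, summary


def dnhej_score(cells: pd.DataFrame, phases: pd.DataFrame,
                group_by: str = "condition") -> pd.DataFrame:
    """Repair-pathway-choice scores per condition.

    dnhej: 53BP1 foci density in S/G2 cells (end-joining engaged when HR
    should operate); hr_proxy: BRCA1 density in S/G2; nhej_proxy: 53BP1
    density in G1.
    """
    merged = cells.merge(phases, on="cell_id")
    sg2 = merged[merged["phase"].isin(["S", "G2"])]
    g1 = merged[merged["phase"] == "G1"]
    if len(sg2) == 0:
        raise ValueError("no S/G2 cells after gating")
    rows = []
    for metric, marker, sub in (("dnhej", "53bp1", sg2), ("hr_proxy", "brca1", sg2),
                                ("nhej_proxy", "53bp1", g1)):
        if len(sub) == 0:
            continue
        _, summary = foci_density(sub, marker, group_by=group_by)
        for key, row in summary.iterrows():
            rows.append({group_by: key, "metric": metric, "mean": row["mean"],
                         "sem": row["sem"], "n": int(row["n"])})
    return pd.DataFrame(rows)


_PREDICATE_CHANNEL = {"edu_pos": "edu", "h3s10_pos": "h3s10",
                      "annexin_pos": "annexin", "casp3_pos": "casp3",
                      "gfp_pos": "gfp", "bfp_pos": "bfp"}


def population_fraction(cells: pd.DataFrame, predicate: str,
                        threshold: float | None = None,
                        config: GateConfig | None = None) -> float:
    """Percentage of cells satisfying a positivity predicate.

    Predicates: channel positivity ("edu_pos", "h3s10_pos", "annexin_pos",
    "casp3_pos", "gfp_pos", "bfp_pos") or "polyploid" (DNA content above the
    polyploid cut).
    """
    if len(cells) == 0:
        raise ValueError("zero cells")
    config = config or GateConfig()
    if predicate == "polyploid":
        dna = cells["dna_content"].to_numpy(dtype=float)
        cut = threshold if threshold is not None else config.poly_factor * _g1_mode(dna)
        mask = dna > cut
    elif predicate in _PREDICATE_CHANNEL:
        channel = _PREDICATE_CHANNEL[predicate]
        if channel not in cells.columns:
            raise ValueError(f"channel {channel!r} needed for {predicate!r} is missing")
        x = cells[channel].to_numpy(dtype=float)
        cut = threshold if threshold is not None else split_threshold(
            x, config.min_modes_gap, config.unimodal_sigmas)
        mask = x > cut
    else:
        raise ValueError(f"unknown predicate {predicate!r}")
    return 100.0 * float(mask.sum()) / len(cells)


def repair_rate(cells: pd.DataFrame, gfp_threshold: float | None = None,
                bfp_threshold: float | None = None,
                config: GateConfig | None = None) -> float:
    """Reporter repair rate: % of transduced (BFP+) cells that are also GFP+."""
    for ch in ("gfp", "bfp"):
        if ch not in cells.columns:
            raise ValueError(f"channel {ch!r} missing")
    config = config or GateConfig()
    bfp = cells["bfp"].to_numpy(dtype=float)
    gfp = cells["gfp"].to_numpy(dtype=float)
    bcut = bfp_threshold if bfp_threshold is not None else split_threshold(
        bfp, config.min_modes_gap, config.unimodal_sigmas)
    gcut = gfp_threshold if gfp_threshold is not None else split_threshold(
        gfp, config.min_modes_gap, config.unimodal_sigmas)
    bfp_pos = bfp > bcut
    if not bfp_pos.any():
        raise ValueError("no BFP-positive (transduced) cells")
    double = bfp_pos & (gfp > gcut)
    return 100.0 * float(double.sum()) / float(bfp_pos.sum())


# ---------------------------------------------------------------------------
# qPCR arithmetic
# ---------------------------------------------------------------------------

def ddct(ct_table: pd.DataFrame, housekeeping_gene: str = "HPRT1",
         reference_condition: str = "control") -> pd.DataFrame:
    """Relative expression by the delta-delta-CT method.

    `ct_table` columns: sample, condition, gene, ct. CT values are averaged
    within (condition, gene); delta-CT subtracts the housekeeping gene,
    delta-delta-CT subtracts the reference condition, fold = 2^(-ddCT).
    """
    mean_ct = ct_table.groupby(["condition", "gene"])["ct"].mean().unstack("gene")
    if housekeeping_gene not in mean_ct.columns or mean_ct[housekeeping_gene].isna().any():
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} missing in some condition")
    if reference_condition not in mean_ct.index:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    dct = mean_ct.sub(mean_ct[housekeeping_gene], axis=0)
    ddct_mat = dct.sub(dct.loc[reference_condition], axis=1)
    fold = np.power(2.0, -ddct_mat)
    out = fold.drop(columns=[housekeeping_gene]).stack().rename("fold").reset_index()
    return out


def chip_enrichment(ct_ip: float, ct_igg: float, ct_input: float,
                    input_fraction: float = 0.10) -> dict[str, float]:
    """ChIP-qPCR fold enrichment of the IP over the IgG control.

    The input CT is first adjusted for the fraction of chromatin it
    represents (CT' = ct_input - log2(1/fraction)); percent-input of a
    sample x is 100 * 2^(CT' - ct_x); fold enrichment is the IP/IgG ratio of
    percent-input values.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must lie in (0, 1]")
    for v in (ct_ip, ct_igg, ct_input):
        if not math.isfinite(v):
            raise ValueError("CT values must be finite")
    ct_adj = ct_input - math.log2(1.0 / input_fraction)
    pct_ip = 100.0 * 2.0 ** (ct_adj - ct_ip)
    pct_igg = 100.0 * 2.0 ** (ct_adj - ct_igg)
    return {"percent_input_ip": pct_ip, "percent_input_igg": pct_igg,
            "fold_enrichment": pct_ip / pct_igg}


def compare_groups(sample_a, sample_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test (Student by default, Welch with equal_var=False)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    return float(t), float(p)
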