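"""Per-window divergence statistics and outgroup-calibrated dating.

Implements the window statistics used to compare inverted and collinear
regions of a genome between two sister taxa:

* ``d_xy`` — mean pairwise substitutions per site between two groups,
  ``sum_sites[p1(1-p2) + p2(1-p1)] / n_callable``;
* Nei's ``D_A`` — allele-frequency distance
  ``1 - mean_sites[sqrt(p1 p2) + sqrt(q1 q2)]``, suited to tree building;
* Hudson-type ``F_ST`` as a ratio of window sums,
  ``1 - sum(p1 q1 + p2 q2) / sum(p1 q2 + p2 q1)``;
* relative node depth ``RND = d_xy(pair) / mean(d_xy(g1, out), d_xy(g2, out))``,
  which cancels local mutation-rate variation;
* the divergence-time transform ``T = -log(1 - F_ST)`` scaled per window so a
  calibration pair (here the outgroup comparison) equals a fixed age.

Summaries over partitions use window bootstrap percentile CIs; distribution
contrasts use the Mann-Whitney rank-sum test and a 2x2 outlier-enrichment
chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("ancinv")

FST_CLAMP = 1.0 - 1e-12


def _pair_freqs(table, pair, mask=None):
    p1 = table.freqs(pair[0])
    p2 = table.freqs(pair[1])
    if mask is not None:
        p1, p2 = p1[mask], p2[mask]
    usable = ~np.isnan(p1) & ~np.isnan(p2)
    return p1[usable], p2[usable]


def dxy(table, pair, window=None, n_callable=None):
    """Absolute divergence per site over a window.

    ``window`` is (chrom, start, end) 0-based half-open or None for all sites.
    ``n_callable`` defaults to the window length (or the site count when no
    window is given), which biases d_xy down when invariant sites were not
    callable; the default is logged by the scan driver.
    """
    mask = table.window_mask(*window) if window is not None else None
    p1, p2 = _pair_freqs(table, pair, mask)
    if n_callable is None:
        n_callable = (window[2] - window[1]) if window is not None else len(p1)
    if n_callable < 1:
        raise ValueError("n_callable must be >= 1")
    return float(np.sum(p1 * (1 - p2) + p2 * (1 - p1)) / n_callable)


def nei_da(table, pair, window=None):
    """Nei's D_A distance in [0, 1] over the usable biallelic sites."""
    mask = table.window_mask(*window) if window is not None else None
    p1, p2 = _pair_freqs(table, pair, mask)
    return da_from_freqs(p1, p2)


def da_from_freqs(p1, p2):
    if len(p1) == 0:
        raise ValueError("no usable sites for D_A")
    share = np.sqrt(p1 * p2) + np.sqrt((1 - p1) * (1 - p2))
    return float(1.0 - share.mean())


def fst(table, pair, window=None):
    """Hudson-type F_ST as a ratio of window sums, clamped to [0, 1)."""
    mask = table.window_mask(*window) if window is not None else None
    p1, p2 = _pair_freqs(table, pair, mask)
    return fst_from_freqs(p1, p2)


def fst_from_freqs(p1, p2):
    within = np.sum(p1 * (1 - p1) + p2 * (1 - p2))
    between = np.sum(p1 * (1 - p2) + p2 * (1 - p1))
    if between == 0:
        raise ValueError("between-group heterozygosity is 0 across the window")
    val = 1.0 - within / between
    if val >= 1.0:
        log.warning("F_ST clamped to 1 - 1e-12")
        return FST_CLAMP
    return float(max(val, 0.0))


def rnd(dxy_pair, dxy_g1_out, dxy_g2_out):
    """Relative node depth: pair divergence over mean outgroup divergence."""
    denom = 0.5 * (dxy_g1_out + dxy_g2_out)
    if denom <= 0:
        raise ValueError("zero outgroup divergence; window should be flagged missing")
    return float(dxy_pair / denom)


def cs_time(fst_value, fst_calib, calib_years=2_000_000.0):
    """Cavalli-Sforza transform T = -log(1 - F_ST), scaled so the calibration
    pair's transform equals ``calib_years`` (natural log)."""
    if not (0 <= fst_value < 1):
        raise ValueError("fst must be in [0, 1)")
    if not (0 < fst_calib < 1):
        raise ValueError("fst_calib must be in (0, 1); scaling undefined otherwise")
    return float(calib_years * (-np.log1p(-fst_value)) / (-np.log1p(-fst_calib)))


def segregating_mask(table, groups, mask=None):
    """Sites carrying variation among ``groups``: any within-group polymorphism
    or any two groups fixed for different alleles."""
    freqs = np.column_stack([table.freqs(g) for g in groups])
    if mask is not None:
        freqs = freqs[mask]
    with np.errstate(invalid="ignore"):
        poly = np.nanmax(freqs, axis=1) > np.nanmin(freqs, axis=1)
        within = ((freqs > 0) & (freqs < 1)).any(axis=1)
    return poly | within


def iter_windows(table, window_len):
    """Yield (chrom, start, end) tiles covering each chromosome's sites."""
    for chrom, sub in table.df.groupby("chrom", sort=True):
        last = int(sub["pos"].max())
        for start in range(0, last, window_len):
            yield chrom, start, start + window_len


def window_scan(
    table,
    pairs,
    outgroup,
    window_len=10_000,
    min_segregating=10,
    n_callable=None,
    calibration_pair=None,
    calib_years=2_000_000.0,
):
    """Compute WindowStats for every window and taxon pair.

    Returns a tidy DataFrame with one row per (window, pair): d_xy, D_A, F_ST,
    RND, T_raw and calibrated time in years (when ``calibration_pair`` is
    given, e.g. the ingroup-outgroup comparison pinned to 2 Mya), plus counts
    of segregating and callable sites.  Windows with fewer than
    ``min_segregating`` segregating sites are excluded from the output, the
    same rule the tree builder uses.
    """
    if n_callable is None:
        log.warning("n_callable defaults to the window length; d_xy is biased down on real data")
    all_groups = sorted({g for p in pairs for g in p} | {outgroup})
    rows = []
    for chrom, start, end in iter_windows(table, window_len):
        mask = table.window_mask(chrom, start, end)
        if not mask.any():
            continue
        n_seg = int(segregating_mask(table, all_groups, mask).sum())
        callable_here = n_callable if n_callable is not None else end - start
        if n_seg < min_segregating:
            continue
        calib_fst = None
        if calibration_pair is not None:
            try:
                calib_fst = fst(table, calibration_pair, (chrom, start, end))
            except ValueError:
                calib_fst = None
        for pair in pairs:
            win = (chrom, start, end)
            try:
                d_pair = dxy(table, pair, win, callable_here)
                d1o = dxy(table, (pair[0], outgroup), win, callable_here)
                d2o = dxy(table, (pair[1], outgroup), win, callable_here)
                da = nei_da(table, pair, win)
                f = fst(table, pair, win)
            except ValueError as exc:
                log.debug("window %s:%d-%d pair %s skipped: %s", chrom, start, end, pair, exc)
                continue
            row = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "pair": f"{pair[0]}-{pair[1]}",
                "dxy": d_pair,
                "da": da,
                "fst": f,
                "n_segregating": n_seg,
                "n_callable": callable_here,
            }
            try:
                row["rnd"] = rnd(d_pair, d1o, d2o)
            except ValueError:
                row["rnd"] = np.nan
            row["t_raw"] = float(-np.log1p(-min(f, FST_CLAMP)))
            if calib_fst is not None and calib_fst > 0:
                row["time_years"] = cs_time(min(f, FST_CLAMP), calib_fst, calib_years)
            else:
                row["time_years"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PartitionSummary:
    partition: str
    pair: str
    n_windows: int
    mean: float
    median: float
    ci_low: float
    ci_high: float
    mean_time_years: float
    time_ci_low: float
    time_ci_high: float
    n_top_outliers: int


def partition_summary(windows, partition, pair, n_boot=1000, seed=0, value="rnd", top_quantile=0.99):
    """Mean/median of a window statistic inside a partition with a 95%
    percentile bootstrap CI over windows (resampled with replacement)."""
    sub = windows[windows["pair"] == pair]
    member = partition.window_membership(sub)
    vals = sub.loc[member, value].dropna().to_numpy()
    if len(vals) < 2:
        raise ValueError(f"partition {partition.name!r} holds fewer than 2 usable windows")
    times = sub.loc[member, "time_years"].dropna().to_numpy() if "time_years" in sub else np.array([])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    boot_means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    if len(times) >= 2:
        tidx = rng.integers(0, len(times), size=(n_boot, len(times)))
        tmeans = times[tidx].mean(axis=1)
        tlo, thi = np.percentile(tmeans, [2.5, 97.5])
        tmean = float(times.mean())
    else:
        tmean, tlo, thi = np.nan, np.nan, np.nan
    threshold = np.nanquantile(windows.loc[windows["pair"] == pair, value], top_quantile)
    return PartitionSummary(
        partition=partition.name,
        pair=pair,
        n_windows=int(len(vals)),
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        ci_low=float(lo),
        ci_high=float(hi),
        mean_time_years=tmean,
        time_ci_low=float(tlo),
        time_ci_high=float(thi),
        n_top_outliers=int((vals > threshold).sum()),
    )


def compare_distributions(x, y, alternative="two-sided"):
    """Mann-Whitney rank-sum test; exact enumeration when both n <= 8 and the
    data are tie-free, tie-corrected normal approximation otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EnrichmentResult:
    statistic: float
    pvalue: float
    table: np.ndarray
    flagged: bool


def outlier_enrichment(windows, partition, pair, threshold_quantile=0.99, value="rnd"):
    """Pearson chi-square (1 df, no continuity correction) for enrichment of
    genome-wide top-(1-q) windows inside the partition."""
    sub = windows[windows["pair"] == pair].dropna(subset=[value])
    if len(sub) == 0:
        raise ValueError("no windows to classify")
    threshold = np.quantile(sub[value], threshold_quantile)
    outlier = sub[value].to_numpy() > threshold
    inside = partition.window_membership(sub)
    tab = np.array(
        [
            [(outlier & inside).sum(), (~outlier & inside).sum()],
            [(outlier & ~inside).sum(), (~outlier & ~inside).sum()],
        ],
        dtype=float,
    )
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        log.warning("outlier_enrichment: degenerate 2x2 margin; statistic undefined")
        return EnrichmentResult(np.nan, np.nan, tab, True)
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return EnrichmentResult(float(chi2), float(p), tab, False)


def time_prior_to_species_divergence(region_time, collinear_time):
    """Age of a region's divergence relative to the species split: region time
    minus collinear-region time (negative values are reported as-is)."""
    return region_time - collinear_time
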