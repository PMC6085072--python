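"""Pipeline orchestration: simulate -> scan -> date -> iimfit -> report.

A single declarative YAML config drives every stage; unknown keys are errors
(silent-typo protection), the seed is mandatory for any stochastic step, and
every output file carries a header recording the config hash and seed so reruns
are verifiably identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import divergence, iim, phylogeny, simulate
from .io import (
    GenomePartition,
    SiteTable,
    config_hash,
    read_sites,
    write_table,
)

log = logging.getLogger("ancinv")


@dataclass
class RunConfig:
    seed: int
    sites: str = ""  # site-table path (tsv) for scan/date
    format: str = "tsv"
    roles: dict = field(
        default_factory=lambda: dict(simulate.DEFAULT_ROLES)
    )
    window_len: int = 10_000
    min_segregating: int = 10
    n_boot: int = 10_000
    support_threshold: float = 0.75
    min_run: int = 3
    calib_years: float = 2_000_000.0
    calibration_group: str = "DpseST"  # paired with roles['outgroup'] per window
    partitions: dict = field(default_factory=dict)  # name -> BED path
    # simulate stage
    n_windows: int = 60
    breakpoint_windows: list = field(default_factory=list)
    n_per_group: int = 4
    mut_rate: float = 3.0
    scenario: dict = field(default_factory=dict)
    # iimfit stage
    loci_table: str = ""  # TSV with columns cls, s, r (else simulated)
    iim_truth: dict = field(default_factory=dict)  # ModelParams kwargs for simulation
    n_loci_per_class: int = 500
    x_scale: float = 1.0
    n_restarts: int = 3

    def validate(self):
        errors = []
        if self.window_len <= 0:
            errors.append("window_len must be > 0")
        if not (0 <= self.support_threshold <= 1):
            errors.append("support_threshold must be in [0, 1]")
        if self.min_segregating < 0:
            errors.append("min_segregating must be >= 0")
        if self.n_boot < 1:
            errors.append("n_boot must be >= 1")
        if self.calib_years <= 0:
            errors.append("calib_years must be > 0")
        if self.x_scale <= 0:
            errors.append("x_scale must be > 0")
        missing_roles = [r for r in phylogeny.ROLE_NAMES if r not in self.roles]
        if missing_roles:
            errors.append(f"roles missing: {missing_roles}")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        return self

    def hash(self):
        return config_hash(asdict(self))

    def header(self, stage):
        return [f"ancinv {stage}", f"seed={self.seed}", f"config={self.hash()}"]


def load_config(path):
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    return RunConfig(**raw).validate()


def _load_sites(cfg, outdir):
    path = cfg.sites or str(Path(outdir) / "sites.tsv")
    return read_sites(path, format=cfg.format)


def run_simulate(cfg, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = simulate.InversionScenario(**cfg.scenario)
    table, truth = simulate.make_window_dataset(
        scenario,
        n_windows=cfg.n_windows,
        breakpoint_windows=cfg.breakpoint_windows,
        window_len=cfg.window_len,
        n_per_group=cfg.n_per_group,
        mut_rate=cfg.mut_rate,
        seed=cfg.seed,
    )
    table.to_tsv(outdir / "sites.tsv")
    write_table(truth, outdir / "truth.tsv", cfg.header("simulate"))
    log.info("simulate: %d windows, %d sites", cfg.n_windows, table.n_sites)
    return table, truth


def run_scan(cfg, outdir):
    """data_io -> divergence -> window_phylogeny over the configured inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _load_sites(cfg, outdir)
    roles = cfg.roles
    groups = [roles[r] for r in phylogeny.ROLE_NAMES]
    ingroups = groups[:3]
    pairs = [(a, b) for i, a in enumerate(ingroups) for b in ingroups[i + 1 :]]
    windows = divergence.window_scan(
        table,
        pairs,
        outgroup=roles["outgroup"],
        window_len=cfg.window_len,
        min_segregating=cfg.min_segregating,
        calibration_pair=(cfg.calibration_group, roles["outgroup"]),
        calib_years=cfg.calib_years,
    )
    write_table(windows, outdir / "windows.tsv", cfg.header("scan"))
    trees = phylogeny.tree_scan(
        table,
        roles,
        window_len=cfg.window_len,
        min_segregating=cfg.min_segregating,
        n_boot=cfg.n_boot,
        support_threshold=cfg.support_threshold,
        seed=cfg.seed,
    )
    write_table(trees, outdir / "window_trees.tsv", cfg.header("scan"))
    with open(outdir / "trees.nwk", "w") as fh:
        for row in trees.itertuples():
            if row.newick:
                fh.write(f"[{row.chrom}:{row.start}-{row.end}] {row.newick}\n")
    blocks = phylogeny.blocks_to_frame(phylogeny.call_blocks(trees, min_run=cfg.min_run))
    write_table(blocks, outdir / "blocks.bed", cfg.header("scan"))
    return windows, trees, blocks


def run_date(cfg, outdir, windows=None):
    """Partition summaries of RND and calibrated times with bootstrap CIs."""
    outdir = Path(outdir)
    if windows is None:
        windows = pd.read_csv(outdir / "windows.tsv", sep="\t", comment="#")
    rows = []
    for name, bed in cfg.partitions.items():
        part = GenomePartition.from_bed(bed, name)
        for pair in windows["pair"].unique():
            try:
                s = divergence.partition_summary(windows, part, pair, seed=cfg.seed)
            except ValueError as exc:
                log.warning("partition %s pair %s skipped: %s", name, pair, exc)
                continue
            rows.append(s.__dict__)
    summary = pd.DataFrame(rows)
    write_table(summary, outdir / "partition_summary.tsv", cfg.header("date"))
    return summary


def run_iimfit(cfg, outdir):
    """Fit Iso/IM/IIM per partition and emit the model-comparison table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.loci_table:
        loci = pd.read_csv(cfg.loci_table, sep="\t", comment="#")
        partitioned = {name: sub for name, sub in loci.groupby("partition")} if "partition" in loci else {"all": loci}
    else:
        truth = dict(cfg.iim_truth) or dict(theta1=2.0, theta2=2.0, theta_anc=2.0, t0=1.5, t1=0.6, m1=0.5, m2=0.0)
        params = iim.ModelParams.iim(**truth)
        loci, _ = simulate.make_locus_dataset(params, cfg.n_loci_per_class, seed=cfg.seed)
        partitioned = {"all": loci}
    if not partitioned:
        raise ValueError("no partitions with loci to fit")
    rows = []
    fits = {}
    for i, (name, sub) in enumerate(partitioned.items()):
        row = {"partition": name, "n_loci": len(sub)}
        for model in iim.MODELS:
            res = iim.fit_model(sub, model, n_restarts=cfg.n_restarts, seed=cfg.seed + i)
            fits[(name, model)] = res
            row[f"lnl_{model}"] = res.lnl
        for null in ("iso", "im"):
            df_diff = iim.n_free_params("iim") - iim.n_free_params(null)
            try:
                stat, p = iim.scaled_lrt(row[f"lnl_{null}"], row["lnl_iim"], x=cfg.x_scale, df=df_diff)
            except ValueError:
                stat, p = np.nan, np.nan
            row[f"lrt_{null}_vs_iim"] = stat
            row[f"p_{null}_vs_iim"] = p
        rows.append(row)
    comparison = pd.DataFrame(rows)
    write_table(comparison, outdir / "model_comparison.tsv", cfg.header("iimfit"))
    report_lines = [fits[k].summary() for k in sorted(fits)]
    hier = None
    if len(partitioned) >= 2:
        free_fits, lnl_free, shared, lnl_shared, df = iim.hierarchical_fit(
            partitioned, "iim", n_restarts=cfg.n_restarts, seed=cfg.seed
        )
        stat, p = iim.scaled_lrt(lnl_shared, lnl_free, x=cfg.x_scale, df=df)
        hier = {"lnl_free": lnl_free, "lnl_shared": lnl_shared, "stat": stat, "p": p, "df": df}
        report_lines.append(
            f"hierarchical free-vs-shared: lnL_free={lnl_free:.3f} lnL_shared={lnl_shared:.3f} "
            f"LRT={stat:.3f} (df={df}, p={p:.3g}, x={cfg.x_scale})"
        )
    (outdir / "iim_report.txt").write_text("\n\n".join(report_lines) + "\n")
    return comparison, hier


def run_report(cfg, outdir):
    """Human-readable summary: per-region times, time prior to species
    divergence (region minus collinear), distribution contrasts, blocks."""
    outdir = Path(outdir)
    summary_path = outdir / "partition_summary.tsv"
    windows_path = outdir / "windows.tsv"
    blocks_path = outdir / "blocks.bed"
    for p in (summary_path, windows_path):
        if not p.exists():
            raise FileNotFoundError(f"missing artifact: {p}")
    summary = pd.read_csv(summary_path, sep="\t", comment="#")
    windows = pd.read_csv(windows_path, sep="\t", comment="#")
    lines = [f"# ancinv report seed={cfg.seed} config={cfg.hash()}"]
    collinear = summary[summary["partition"] == "collinear"]
    for _, row in summary.iterrows():
        line = (
            f"{row['partition']} / {row['pair']}: mean RND {row['mean']:.3f} "
            f"(95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f}; median {row['median']:.3f}), "
            f"{row['n_windows']} windows"
        )
        if np.isfinite(row.get("mean_time_years", np.nan)):
            line += f"; mean time {row['mean_time_years'] / 1e6:.2f} Mya"
            ref = collinear[collinear["pair"] == row["pair"]]
            if len(ref) and np.isfinite(ref.iloc[0]["mean_time_years"]):
                prior = divergence.time_prior_to_species_divergence(
                    row["mean_time_years"], ref.iloc[0]["mean_time_years"]
                )
                line += f"; time prior to species divergence {prior / 1e6:.2f} Mya"
        lines.append(line)
    # distribution contrasts between partitions, per pair
    for pair in summary["pair"].unique():
        parts = summary[summary["pair"] == pair]["partition"].tolist()
        for i, a in enumerate(parts):
            for b in parts[i + 1 :]:
                pa = GenomePartition.from_bed(cfg.partitions[a], a) if a in cfg.partitions else None
                pb = GenomePartition.from_bed(cfg.partitions[b], b) if b in cfg.partitions else None
                if pa is None or pb is None:
                    continue
                sub = windows[windows["pair"] == pair]
                xa = sub.loc[pa.window_membership(sub), "rnd"].dropna()
                xb = sub.loc[pb.window_membership(sub), "rnd"].dropna()
                if len(xa) and len(xb):
                    _, p = divergence.compare_distributions(xa, xb)
                    lines.append(f"Wilcoxon rank-sum RND {a} vs {b} ({pair}): P = {p:.3g}")
    if blocks_path.exists():
        blocks = pd.read_csv(blocks_path, sep="\t", comment="#")
        lines.append(f"{len(blocks)} discordance block(s) called")
        for _, b in blocks.iterrows():
            lines.append(f"  {b['chrom']}:{b['start']}-{b['end']} {b['cls']} ({b['n_windows']} windows)")
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return text
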