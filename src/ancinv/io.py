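"""Site-level variant I/O, filtering, and coordinate normalization.

The central container is :class:`SiteTable`: a per-site table of biallelic
allele counts for several population groups (e.g. pooled sequencing of
``DpseST``, ``DperST``, ``DperSR`` and an outgroup), sorted by chromosome and
1-based position.  Interval annotations (inversion spans, breakpoint flanks,
intergenic regions) are 0-based half-open :class:`GenomePartition` objects, the
BED convention.  Scaffold-to-chromosome maps allow lifting scaffold-level
coordinates onto assembled chromosome arms.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("ancinv")

#: per-group column suffixes: ref allele count, alt allele count, depth, genotype quality
GROUP_SUFFIXES = ("ref", "alt", "dp", "gq")
CORE_COLUMNS = ["chrom", "pos", "ref", "alt"]


def group_columns(groups):
    return [f"{g}_{suf}" for g in groups for suf in GROUP_SUFFIXES]


@dataclass
class SiteTable:
    """Sorted per-site, per-group allele count table.

    ``df`` holds columns ``chrom pos ref alt`` plus, for every group ``g``,
    ``g_ref g_alt g_dp g_gq``.  Positions are 1-based (VCF convention) and
    unique within a chromosome.
    """

    df: pd.DataFrame
    groups: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in CORE_COLUMNS + group_columns(self.groups) if c not in self.df.columns]
        if missing:
            raise ValueError(f"SiteTable missing columns: {missing}")
        self.sort()

    def sort(self):
        self.df = self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        dup = self.df.duplicated(["chrom", "pos"])
        if dup.any():
            row = self.df[dup].iloc[0]
            raise ValueError(f"duplicate site at {row['chrom']}:{row['pos']}")
        if len(self.df) and (self.df["pos"] < 1).any():
            raise ValueError("positions must be >= 1")

    @property
    def n_sites(self):
        return len(self.df)

    def freqs(self, group):
        """Alt-allele frequency per site; NaN where the group has no reads."""
        r = self.df[f"{group}_ref"].to_numpy(float)
        a = self.df[f"{group}_alt"].to_numpy(float)
        denom = r + a
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, a / np.maximum(denom, 1), np.nan)

    def window_mask(self, chrom, start, end):
        """Boolean mask of sites in the 0-based half-open window [start, end)."""
        pos = self.df["pos"].to_numpy()
        return (self.df["chrom"].to_numpy() == chrom) & (pos > start) & (pos <= end)

    def subset(self, mask):
        return SiteTable(self.df[mask].reset_index(drop=True), list(self.groups), dict(self.meta))

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("# ancinv site table; pos is 1-based\n")
            fh.write(f"# groups: {','.join(self.groups)}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    def __eq__(self, other):
        return (
            isinstance(other, SiteTable)
            and self.groups == other.groups
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )


def _groups_from_header(columns):
    groups = []
    for c in columns:
        if c.endswith("_ref") and c not in ("ref",):
            g = c[: -len("_ref")]
            if all(f"{g}_{suf}" in columns for suf in GROUP_SUFFIXES):
                groups.append(g)
    return groups


def read_sites(path, format="tsv", group_spec=None, multiallelic="reject"):
    """Read a site table from a TSV or a VCF.

    For VCF input ``group_spec`` maps each sample name to a group; per-group
    allele counts are summed over the samples in the group, depths are summed
    and the group genotype quality is the minimum over its samples (the
    conservative choice for a "every group passes" filter).  Multi-allelic
    records are handled per ``multiallelic``: ``"reject"`` drops them and
    counts the drops in ``meta["n_multiallelic_dropped"]``.
    """
    if format == "tsv":
        return _read_sites_tsv(path)
    if format == "vcf":
        return _read_sites_vcf(path, group_spec, multiallelic)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'vcf'")


def _read_sites_tsv(path):
    df = pd.read_csv(path, sep="\t", comment="#")
    groups = _groups_from_header(df.columns)
    if not groups:
        raise ValueError(f"{path}: no per-group columns (<g>_ref/_alt/_dp/_gq) found")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        if d["pos"] < 1:
            raise ValueError(f"{path} line {i}: position {d['pos']} < 1")
        for g in groups:
            if d[f"{g}_ref"] + d[f"{g}_alt"] > d[f"{g}_dp"]:
                raise ValueError(f"{path} line {i}: {g} allele counts exceed depth")
    return SiteTable(df, groups, {"source": str(path), "format": "tsv"})


def _read_sites_vcf(path, group_spec, multiallelic):
    from cyvcf2 import VCF

    if group_spec is None:
        raise ValueError("VCF input requires group_spec mapping sample -> group")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in group_spec:
            raise ValueError(f"sample {s!r} missing from group_spec")
    groups = list(dict.fromkeys(group_spec[s] for s in samples))
    rows = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            if multiallelic == "reject":
                n_multi += 1
                continue
            raise ValueError(f"multi-allelic record at {v.CHROM}:{v.POS} under policy {multiallelic!r}")
        rec = {"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0]}
        counts = {g: [0, 0, 0, np.inf] for g in groups}  # ref, alt, dp, min gq
        try:
            dps = v.format("DP")
        except KeyError:
            dps = None
        try:
            gqs = v.format("GQ")
        except KeyError:
            gqs = None
        for i, s in enumerate(samples):
            g = group_spec[s]
            alleles = [a for a in v.genotypes[i][:-1] if a >= 0]
            counts[g][0] += sum(1 for a in alleles if a == 0)
            counts[g][1] += sum(1 for a in alleles if a == 1)
            if dps is not None:
                counts[g][2] += int(dps[i][0]) if dps[i][0] >= 0 else 0
            if gqs is not None:
                counts[g][3] = min(counts[g][3], float(np.ravel(gqs[i])[0]))
        for g in groups:
            if counts[g][2] == 0:  # no DP field: fall back to allele count total
                counts[g][2] = counts[g][0] + counts[g][1]
            if not np.isfinite(counts[g][3]):
                counts[g][3] = 99.0
            rec[f"{g}_ref"], rec[f"{g}_alt"] = counts[g][0], counts[g][1]
            rec[f"{g}_dp"], rec[f"{g}_gq"] = counts[g][2], counts[g][3]
        rows.append(rec)
    df = pd.DataFrame(rows, columns=CORE_COLUMNS + group_columns(groups))
    return SiteTable(df, groups, {"source": str(path), "format": "vcf", "n_multiallelic_dropped": n_multi})


def filter_sites(table, min_gq=30.0, cov_low=1, cov_high_sd=3.0):
    """Apply genotype-quality and coverage filters.

    Keeps sites where, in *every* group, GQ >= ``min_gq``, depth > ``cov_low``,
    and depth < group mean + ``cov_high_sd`` x group SD, with mean and SD taken
    from the unfiltered input.  A degenerate SD of 0 keeps sites whose depth
    equals the mean (uniform-coverage data would otherwise vanish).
    """
    if min_gq < 0 or cov_high_sd <= 0:
        raise ValueError("min_gq must be >= 0 and cov_high_sd > 0")
    if table.n_sites == 0:
        raise ValueError("cannot filter an empty site table")
    keep = np.ones(table.n_sites, dtype=bool)
    for g in table.groups:
        dp = table.df[f"{g}_dp"].to_numpy(float)
        gq = table.df[f"{g}_gq"].to_numpy(float)
        mean, sd = dp.mean(), dp.std(ddof=0)
        keep &= gq >= min_gq
        keep &= dp > cov_low
        if sd == 0:
            keep &= dp == mean
        elif np.isfinite(cov_high_sd):
            keep &= dp < mean + cov_high_sd * sd
    out = table.subset(keep)
    out.meta["filters"] = {"min_gq": min_gq, "cov_low": cov_low, "cov_high_sd": cov_high_sd}
    n_dropped = table.n_sites - out.n_sites
    log.info("filter_sites: dropped %d of %d sites", n_dropped, table.n_sites)
    return out


@dataclass
class ScaffoldMap:
    """Rows of (scaffold, chromosome, chromosome offset, orientation, length)."""

    df: pd.DataFrame

    REQUIRED = ("scaffold", "chrom", "offset", "orientation", "length")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"scaffold map missing columns: {missing}")
        bad = ~self.df["orientation"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"orientation must be '+' or '-', got {self.df['orientation'][bad].iloc[0]!r}")
        # mapped intervals must not overlap on a chromosome
        for chrom, sub in self.df.groupby("chrom"):
            iv = sorted((r.offset, r.offset + r.length) for r in sub.itertuples())
            for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
                if s2 < e1:
                    raise ValueError(f"scaffold intervals overlap on {chrom}")

    @classmethod
    def from_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t", comment="#"))


def remap_coordinates(table, scaffold_map):
    """Rewrite scaffold coordinates to chromosome coordinates.

    Forward scaffolds: pos -> offset + pos.  Reverse-oriented scaffolds:
    pos -> offset + (length - pos + 1), so the scaffold's last base lands at
    offset + 1.  The output is re-sorted; coordinate collisions raise.
    """
    m = scaffold_map.df.set_index("scaffold")
    chroms = table.df["chrom"]
    unknown = set(chroms) - set(m.index)
    if unknown:
        raise KeyError(f"scaffold(s) absent from map: {sorted(unknown)}")
    sub = m.loc[chroms]
    offset = sub["offset"].to_numpy()
    length = sub["length"].to_numpy()
    reverse = (sub["orientation"] == "-").to_numpy()
    pos = table.df["pos"].to_numpy()
    new_pos = np.where(reverse, offset + (length - pos + 1), offset + pos)
    df = table.df.copy()
    df["chrom"] = sub["chrom"].to_numpy()
    df["pos"] = new_pos
    out = SiteTable(df, list(table.groups), dict(table.meta))  # sort + collision check
    return out


@dataclass
class GenomePartition:
    """Named set of sorted, non-overlapping 0-based half-open intervals."""

    name: str
    df: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self):
        need = [c for c in ("chrom", "start", "end") if c not in self.df.columns]
        if need:
            raise ValueError(f"partition missing columns: {need}")
        self.df = self.df.sort_values(["chrom", "start"]).reset_index(drop=True)
        if (self.df["end"] <= self.df["start"]).any():
            raise ValueError("partition intervals must have end > start")
        for chrom, sub in self.df.groupby("chrom"):
            e = sub["end"].to_numpy()
            s = sub["start"].to_numpy()
            if (s[1:] < e[:-1]).any():
                raise ValueError(f"partition {self.name!r}: overlapping intervals on {chrom}")

    @classmethod
    def from_bed(cls, path, name=None):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
        )
        return cls(name or str(path), df)

    def to_bed(self, path):
        with open(path, "w") as fh:
            fh.write(f"# partition {self.name}; 0-based half-open\n")
            self.df.to_csv(fh, sep="\t", index=False, header=False)

    def overlaps_window(self, chrom, start, end):
        sub = self.df[self.df["chrom"] == chrom]
        return bool(((sub["start"] < end) & (sub["end"] > start)).any())

    def window_membership(self, windows):
        """Boolean array: does each (chrom, start, end) row of ``windows`` overlap."""
        return np.array(
            [self.overlaps_window(r.chrom, r.start, r.end) for r in windows.itertuples()], dtype=bool
        )

    @property
    def total_span(self):
        return int((self.df["end"] - self.df["start"]).sum())


def config_hash(obj):
    """Stable short hash of a config-like nested structure, for output headers."""
    return hashlib.sha256(repr(sorted_items(obj)).encode()).hexdigest()[:12]


def sorted_items(obj):
    if isinstance(obj, dict):
        return tuple((k, sorted_items(v)) for k, v in sorted(obj.items()))
    if isinstance(obj, (list, tuple)):
        return tuple(sorted_items(v) for v in obj)
    return obj


def write_table(df, path, header_lines=()):
    """Write a DataFrame as TSV with '#' header lines and stable float format."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
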