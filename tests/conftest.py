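import numpy as np
import pandas as pd
import pytest

from ancinv.io import SiteTable


def make_table(rows, groups):
    """Build a SiteTable from compact row dicts; missing per-group fields get
    full-depth, high-quality defaults."""
    full = []
    for row in rows:
        rec = {"chrom": row.get("chrom", "chr1"), "pos": row["pos"], "ref": "A", "alt": "T"}
        for g in groups:
            rec[f"{g}_ref"] = row.get(f"{g}_ref", 10)
            rec[f"{g}_alt"] = row.get(f"{g}_alt", 0)
            rec[f"{g}_dp"] = row.get(f"{g}_dp", rec[f"{g}_ref"] + rec[f"{g}_alt"])
            rec[f"{g}_gq"] = row.get(f"{g}_gq", 99)
        full.append(rec)
    return SiteTable(pd.DataFrame(full), list(groups))


def freq_table(freqs_by_group, n=10, start_pos=1, chrom="chr1"):
    """SiteTable whose per-site alt frequencies equal the given arrays, using
    depth ``n`` per group (frequencies must be multiples of 1/n)."""
    groups = list(freqs_by_group)
    length = len(next(iter(freqs_by_group.values())))
    rows = []
    for i in range(length):
        row = {"pos": start_pos + i, "chrom": chrom}
        for g in groups:
            alt = int(round(freqs_by_group[g][i] * n))
            row[f"{g}_alt"] = alt
            row[f"{g}_ref"] = n - alt
        rows.append(row)
    return make_table(rows, groups)


@pytest.fixture
def four_group_names():
    return ["DpseST", "DperST", "DperSR", "outgroup"]


@pytest.fixture
def roles():
    return {
        "ingroup_A": "DpseST",
        "ingroup_B": "DperST",
        "ingroup_C": "DperSR",
        "outgroup": "outgroup",
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
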