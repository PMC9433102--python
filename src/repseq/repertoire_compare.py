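"""Repertoire overlap, longitudinal retention and public/private TCRs.

Two complementary overlap readings are computed between clonotype tables:

* unique overlap — set overlap of clonotype keys, reflecting sharing at
  the repertoire-richness level. Default metric is the Jaccard
  percentage 100·|A∩B|/|A∪B|; the Sørensen percentage
  100·2|A∩B|/(|A|+|B|) is selectable.
* total overlap — UMI-weighted overlap, reflecting sharing at the cell
  level (sensitive to clonal expansion). Default (symmetric) reading is
  100·(UMI_A(shared)+UMI_B(shared))/(UMI_A+UMI_B); a one-sided mean
  reading is available.

Overlap keys default to the nucleotide-level clonotype
(chain, V, J, CDR3aa, CDR3nt). Every result records which metric and key
produced it.

Publicity pools a donor's visits: a clonotype seen only in one donor
(either visit) is private; seen in ≥2 donors it is public, with the
publicity level the number of donors sharing it. Abundance-by-publicity
reports, per publicity level, the median across carrying donors of each
TCR's within-donor UMI percentage (donor repertoires cumulated across
that donor's tables first), log10-transformed for reporting.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .umi_pipeline import ClonotypeTable

DEFAULT_KEY_LEVEL = "nt"


class CompareError(ValueError):
    pass


@dataclass(frozen=True)
class OverlapResult:
    percent: float
    level: str  # "unique" | "total"
    metric: str
    key_level: str
    n_shared: int


def _check_pair(a: ClonotypeTable, b: ClonotypeTable) -> None:
    if a.n_clonotypes == 0 or b.n_clonotypes == 0:
        raise CompareError("overlap of an empty table is undefined")
    if a.sample.chain != b.sample.chain:
        raise CompareError("overlap requires tables of the same chain")


def unique_overlap(a: ClonotypeTable, b: ClonotypeTable,
                   metric: str = "jaccard",
                   key_level: str = DEFAULT_KEY_LEVEL) -> OverlapResult:
    """Percent overlap of unique clonotypes (symmetric in A and B)."""
    _check_pair(a, b)
    ka, kb = a.keys(key_level), b.keys(key_level)
    shared = len(ka & kb)
    if metric == "jaccard":
        pct = 100.0 * shared / len(ka | kb)
    elif metric == "sorensen":
        pct = 100.0 * 2 * shared / (len(ka) + len(kb))
    else:
        raise CompareError(f"unknown metric {metric!r}")
    return OverlapResult(pct, "unique", metric, key_level, shared)


def total_overlap(a: ClonotypeTable, b: ClonotypeTable,
                  metric: str = "symmetric",
                  key_level: str = DEFAULT_KEY_LEVEL) -> OverlapResult:
    """Percent of UMIs belonging to shared clonotypes."""
    _check_pair(a, b)
    ca, cb = a.counts(key_level), b.counts(key_level)
    shared = set(ca) & set(cb)
    umi_a = sum(ca[k] for k in shared)
    umi_b = sum(cb[k] for k in shared)
    if metric == "symmetric":
        pct = 100.0 * (umi_a + umi_b) / (a.total_umi + b.total_umi)
    elif metric == "one_sided_mean":
        pct = 50.0 * (umi_a / a.total_umi + umi_b / b.total_umi)
    else:
        raise CompareError(f"unknown metric {metric!r}")
    return OverlapResult(pct, "total", metric, key_level, len(shared))


def retention(visit1: ClonotypeTable, visit2: ClonotypeTable,
              key_level: str = DEFAULT_KEY_LEVEL) -> dict:
    """Longitudinal retention between a donor's two visits.

    Returns the unique and total overlap percentages plus the set of
    retained clonotype keys.
    """
    uniq = unique_overlap(visit1, visit2, key_level=key_level)
    tot = total_overlap(visit1, visit2, key_level=key_level)
    retained = visit1.keys(key_level) & visit2.keys(key_level)
    return {"unique_percent": uniq.percent, "total_percent": tot.percent,
            "retained_keys": retained}


# ---------------------------------------------------------------------------
# publicity
# ---------------------------------------------------------------------------

def publicity(donor_tables: Mapping[str, Sequence[ClonotypeTable]],
              key_level: str = "aa") -> pd.DataFrame:
    """Per-clonotype donor count and private/public label.

    ``donor_tables`` maps donor id → that donor's clonotype tables (both
    visits, any subsets). A clonotype is private iff exactly one donor
    carries it, regardless of visit.
    """
    if len(donor_tables) < 2:
        raise CompareError("publicity requires >= 2 donors")
    donors_by_key: dict[tuple, set] = defaultdict(set)
    for donor, tables in donor_tables.items():
        for table in tables:
            for key in table.keys(key_level):
                donors_by_key[key].add(donor)
    rows = [(key, len(donors), len(donors) == 1)
            for key, donors in donors_by_key.items()]
    df = pd.DataFrame(rows, columns=["key", "n_donors", "private"])
    return df.sort_values("key", kind="mergesort").reset_index(drop=True)


def abundance_by_publicity(donor_tables: Mapping[str,
                                                 Sequence[ClonotypeTable]],
                           key_level: str = "aa") -> pd.DataFrame:
    """Median within-donor UMI%% per publicity level.

    Per donor, UMI counts are cumulated over that donor's tables and each
    TCR's UMI percentage computed; per TCR, the median percentage across
    the donors carrying it; per publicity level, the median over its
    TCRs. Returned with a log10 column for reporting.
    """
    pub = publicity(donor_tables, key_level=key_level)
    per_donor_pct: dict[str, dict] = {}
    for donor, tables in donor_tables.items():
        cum: dict[tuple, int] = defaultdict(int)
        for table in tables:
            for key, n in table.counts(key_level).items():
                cum[key] += n
        total = sum(cum.values())
        per_donor_pct[donor] = {k: 100.0 * n / total
                                for k, n in cum.items()}
    median_pct = {}
    for key in pub["key"]:
        vals = [pct[key] for pct in per_donor_pct.values() if key in pct]
        median_pct[key] = float(np.median(vals))
    pub = pub.assign(median_umi_pct=[median_pct[k] for k in pub["key"]])
    grouped = (pub.groupby("n_donors")["median_umi_pct"].median()
               .reset_index()
               .rename(columns={"median_umi_pct": "median_umi_pct"}))
    grouped["log10_median_umi_pct"] = np.log10(grouped["median_umi_pct"])
    grouped["n_tcrs"] = pub.groupby("n_donors").size().values
    return grouped
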