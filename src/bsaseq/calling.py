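"""Per-CpG methylation calling from aligned bisulfite reads.

The core statistic is the per-individual, per-site C/(C+T) proportion:
reads showing C at a CpG position escaped conversion (methylated), reads
showing T were converted (unmethylated). A/G/N calls at the site carry no
bisulfite information and are excluded from the denominator.

Filtering follows the per-locus read-depth threshold rule: an individual's
values at *all* sites of a locus are dropped when the number of aligned
reads for that locus falls below the locus threshold (>= passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads import AlignedRead
from .reference import ReferenceLocus

__all__ = [
    "SiteCounts",
    "MethylationMatrix",
    "pileup_cpg_counts",
    "percent_methylation",
    "apply_depth_thresholds",
    "depth_histogram_report",
]


@dataclass
class SiteCounts:
    individual: str
    locus: str
    tss_position: int
    n_C: int = 0
    n_T: int = 0
    n_other: int = 0

    @property
    def depth(self) -> int:
        return self.n_C + self.n_T + self.n_other

    @property
    def informative_depth(self) -> int:
        return self.n_C + self.n_T


def pileup_cpg_counts(alignments: list[AlignedRead], locus: ReferenceLocus, individual: str = "") -> list[SiteCounts]:
    """Tally C/T/other base calls per CpG site across all covering reads."""
    counts = {
        s.seq_index: SiteCounts(individual, locus.name, s.tss_position)
        for s in locus.cpg_sites
    }
    for aln in alignments:
        if aln.locus != locus.name:
            raise ValueError(f"alignment on {aln.locus!r} passed to pileup of {locus.name!r}")
        for seq_index, base in aln.cpg_calls.items():
            sc = counts[seq_index]
            if base == "C":
                sc.n_C += 1
            elif base == "T":
                sc.n_T += 1
            else:
                sc.n_other += 1
    return [counts[s.seq_index] for s in locus.cpg_sites]


def percent_methylation(counts: SiteCounts) -> float | None:
    """100 * C/(C+T), or None when no informative calls cover the site."""
    denom = counts.n_C + counts.n_T
    if denom == 0:
        return None
    return 100.0 * counts.n_C / denom


@dataclass
class MethylationMatrix:
    """Individuals x CpG-site percent methylation, with depth bookkeeping.

    ``values``: percent in [0, 100], NaN where missing. Columns are
    "locus:tss_position" labels (e.g. "CRF:-101"), rows individual ids.
    ``site_depth``: informative (C+T) calls per cell, same shape.
    ``locus_depth``: aligned reads per individual per locus — the quantity
    the per-locus thresholds apply to.
    """

    values: pd.DataFrame
    site_depth: pd.DataFrame
    locus_depth: pd.DataFrame
    site_locus: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.site_locus:
            self.site_locus = {c: c.split(":")[0] for c in self.values.columns}
        if list(self.values.columns) != list(self.site_depth.columns):
            raise ValueError("values and site_depth columns differ")

    @property
    def individuals(self) -> list[str]:
        return list(self.values.index)

    @property
    def sites(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(
            self.values.copy(), self.site_depth.copy(), self.locus_depth.copy(), dict(self.site_locus)
        )

    def to_tsv(self, values_path, depth_path=None) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="individual", float_format="%.6f")
        if depth_path is not None:
            self.site_depth.to_csv(depth_path, sep="\t", index_label="individual")

    @classmethod
    def from_counts(
        cls, all_counts: list[SiteCounts], locus_depth: pd.DataFrame, site_order: list[str]
    ) -> "MethylationMatrix":
        rows: dict[str, dict[str, float]] = {}
        depths: dict[str, dict[str, int]] = {}
        for sc in all_counts:
            label = f"{sc.locus}:{sc.tss_position}"
            pct = percent_methylation(sc)
            rows.setdefault(sc.individual, {})[label] = np.nan if pct is None else pct
            depths.setdefault(sc.individual, {})[label] = sc.informative_depth
        individuals = list(locus_depth.index)
        values = pd.DataFrame(rows).T.reindex(index=individuals, columns=site_order)
        site_depth = pd.DataFrame(depths).T.reindex(index=individuals, columns=site_order).fillna(0).astype(int)
        return cls(values, site_depth, locus_depth)


def apply_depth_thresholds(
    matrix: MethylationMatrix,
    thresholds: dict[str, int],
    per_site: bool = False,
) -> MethylationMatrix:
    """Mask cells of individuals whose locus read depth misses the threshold.

    Depth >= threshold is retained. With ``per_site=True`` the informative
    per-site depth is compared instead of the per-locus aligned-read count.
    """
    known = set(matrix.locus_depth.columns) | {loc for loc in matrix.site_locus.values()}
    for locus in thresholds:
        if locus not in known:
            raise ValueError(f"threshold given for unknown locus {locus!r}")
    out = matrix.copy()
    for label in out.sites:
        locus = out.site_locus[label]
        if locus not in thresholds:
            continue
        thr = thresholds[locus]
        if thr < 0:
            raise ValueError(f"negative threshold for {locus!r}")
        if per_site:
            fail = out.site_depth[label] < thr
        else:
            fail = out.locus_depth[locus] < thr
        out.values.loc[fail, label] = np.nan
    return out


def depth_histogram_report(locus_depth: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Per-locus histogram of read depth across individuals.

    Deterministic equal-width binning from 0 to each locus's maximum depth;
    used to choose per-locus minimum depth thresholds by eye, as the
    upstream study did.
    """
    records = []
    for locus in locus_depth.columns:
        depths = locus_depth[locus].dropna().to_numpy()
        if depths.size == 0:
            continue
        top = max(float(depths.max()), 1.0)
        edges = np.linspace(0.0, top, n_bins + 1)
        hist, _ = np.histogram(depths, bins=edges)
        for k in range(n_bins):
            records.append(
                {
                    "locus": locus,
                    "bin_low": edges[k],
                    "bin_high": edges[k + 1],
                    "count": int(hist[k]),
                }
            )
    return pd.DataFrame(records, columns=["locus", "bin_low", "bin_high", "count"])
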