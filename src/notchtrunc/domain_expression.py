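"""Per-exon normalized coverage and the intracellular/extracellular
domain expression ratio, with rank-based group comparisons.

Normalized coverage is per-base depth per million mapped reads:
``(count_e / length_e) / (library_size / 1e6)``. The domain ratio divides
the mean normalized value over the intracellular exons (29-34 by default)
by the mean over the extracellular exons (1-27). A pooled mode (summed
base counts per domain, length-weighted) is available behind a flag; the
unweighted per-exon mean is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, rank_sum_test

__all__ = [
    "ExonCoverageTrack",
    "DomainRatio",
    "normalize_exon_coverage",
    "domain_ratio",
    "compare_ratio_groups",
    "ICD_EXONS",
    "ECD_EXONS",
]

ICD_EXONS = tuple(range(29, 35))
ECD_EXONS = tuple(range(1, 28))


@dataclass
class ExonCoverageTrack:
    """Read-base counts per exon of one gene in one sample."""

    gene: str
    counts: np.ndarray  # transcript order; read-bases per exon
    lengths: np.ndarray  # bp per exon
    library_size: int
    sample: str = "sample"
    group: str = "group"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.counts.shape != self.lengths.shape:
            raise ValueError("counts and lengths must have matching shapes")
        if (self.counts < 0).any():
            raise ValueError("negative exon counts")
        if (self.lengths <= 0).any():
            raise ValueError("non-positive exon lengths")

    @property
    def n_exons(self) -> int:
        return self.counts.size


@dataclass
class DomainRatio:
    sample: str
    group: str
    ratio: float
    infinite: bool = False  # zero extracellular coverage sentinel


def normalize_exon_coverage(track: ExonCoverageTrack) -> np.ndarray:
    """Per-base depth per million mapped reads, one value per exon."""
    if track.library_size <= 0:
        raise ValueError(f"track {track.sample!r}: library size must be positive")
    per_base = track.counts / track.lengths
    return per_base / (track.library_size / 1e6)


def domain_ratio(
    track: ExonCoverageTrack,
    icd_exons=ICD_EXONS,
    ecd_exons=ECD_EXONS,
    pooled: bool = False,
) -> DomainRatio:
    """Intracellular / extracellular normalized-coverage ratio.

    ``icd_exons``/``ecd_exons`` are 1-based exon indices into the
    transcript-ordered track. Zero extracellular coverage returns an
    explicit infinite-ratio sentinel rather than raising or dividing
    silently.
    """
    icd = np.asarray(icd_exons, dtype=int) - 1
    ecd = np.asarray(ecd_exons, dtype=int) - 1
    if set(icd) & set(ecd):
        raise ValueError("ICD and ECD exon sets must be disjoint")
    for idx in (icd, ecd):
        if idx.size == 0 or idx.min() < 0 or idx.max() >= track.n_exons:
            raise ValueError("exon indices outside the track")
    values = normalize_exon_coverage(track)
    if pooled:
        num = track.counts[icd].sum() / track.lengths[icd].sum()
        den = track.counts[ecd].sum() / track.lengths[ecd].sum()
    else:
        num = values[icd].mean()
        den = values[ecd].mean()
    if den == 0:
        return DomainRatio(track.sample, track.group, math.inf, infinite=True)
    return DomainRatio(track.sample, track.group, float(num / den))


def compare_ratio_groups(
    ratios: list[DomainRatio] | pd.DataFrame,
    reference: str,
) -> pd.DataFrame:
    """Two-sided rank-sum of the reference group against every other
    group, Benjamini-Hochberg adjusted across the comparisons."""
    if isinstance(ratios, pd.DataFrame):
        df = ratios
    else:
        df = pd.DataFrame(
            {"group": [r.group for r in ratios], "ratio": [r.ratio for r in ratios]}
        )
    groups = df["group"].unique().tolist()
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ref_vals = df.loc[df["group"] == reference, "ratio"].to_numpy()
    rows = []
    for grp in groups:
        if grp == reference:
            continue
        vals = df.loc[df["group"] == grp, "ratio"].to_numpy()
        if vals.size == 0 or ref_vals.size == 0:
            raise ValueError(f"group {grp!r} or reference is empty")
        res = rank_sum_test(ref_vals, vals)
        rows.append(
            {
                "group": grp,
                "reference": reference,
                "n_ref": ref_vals.size,
                "n_group": vals.size,
                "statistic": res.statistic,
                "pvalue": res.pvalue,
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = benjamini_hochberg(out["pvalue"].to_numpy())
    return out
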