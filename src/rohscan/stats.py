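"""ROH length classification, F_ROH inbreeding coefficients, group tests.

F_ROH = sum(L_ROH) / Lauto: the fraction of the SNP-covered autosomal
genome lying inside an individual's ROH segments.  Lauto is the sum over
autosomes of the span from first to last retained SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detect import ROHSegment
from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

MB = 1_000_000


@dataclass
class LengthBins:
    """Half-open [lower, upper) length bins in Mb plus short/medium/long
    classes.  A segment of exactly 2 Mb falls in "2-4" and class medium.
    Segments below the first edge are collected in a separate "<0.5" bin
    outside the proportion denominator."""

    edges_mb: tuple[float, ...] = (0.5, 1, 2, 4, 8, 16)
    labels: tuple[str, ...] = ("0.5-1", "1-2", "2-4", "4-8", "8-16", ">16")
    class_edges_mb: tuple[float, ...] = (0.5, 2, 8)
    class_labels: tuple[str, ...] = ("short", "medium", "long")
    under_label: str = "<0.5"

    def bin_of(self, length_bp: int) -> str:
        mb = length_bp / MB
        if mb < self.edges_mb[0]:
            return self.under_label
        idx = int(np.searchsorted(self.edges_mb, mb, side="right")) - 1
        return self.labels[idx]

    def class_of(self, length_bp: int) -> str | None:
        mb = length_bp / MB
        if mb < self.class_edges_mb[0]:
            return None
        idx = int(np.searchsorted(self.class_edges_mb, mb, side="right")) - 1
        return self.class_labels[idx]

    @property
    def all_bins(self) -> tuple[str, ...]:
        return (self.under_label,) + self.labels


def classify_lengths(
    segments: list[ROHSegment],
    sample_groups: dict[str, str] | None = None,
    bins: LengthBins | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count segments per length bin, per sample and per group.

    Returns ``(per_sample, per_group)``.  Group proportions are computed
    over segments >= the first bin edge (the "<0.5" bin is reported but
    excluded from the proportion denominator).
    """
    bins = bins or LengthBins()
    rows = [
        {
            "sample": s.sample_id,
            "bin": bins.bin_of(s.length_bp),
            "cls": bins.class_of(s.length_bp) or bins.under_label,
        }
        for s in segments
    ]
    df = pd.DataFrame(rows, columns=["sample", "bin", "cls"])
    per_sample = (
        df.groupby(["sample", "bin"]).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame()
    )
    per_sample = per_sample.reindex(columns=list(bins.all_bins), fill_value=0)

    if sample_groups is None:
        sample_groups = {s: "all" for s in df["sample"].unique()}
    df["group"] = df["sample"].map(sample_groups)
    counts = (
        df.groupby(["group", "bin"]).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame()
    )
    counts = counts.reindex(columns=list(bins.all_bins), fill_value=0)
    denom = counts[list(bins.labels)].sum(axis=1)
    props = counts[list(bins.labels)].div(denom.replace(0, np.nan), axis=0)
    per_group = pd.concat(
        {"count": counts, "proportion": props}, axis=1
    )
    return per_sample, per_group


# ----------------------------------------------------------------------
@dataclass
class FrohResult:
    sample_id: str
    sum_roh_bp: int
    l_auto_bp: int
    froh: float = field(init=False)

    def __post_init__(self) -> None:
        self.froh = self.sum_roh_bp / self.l_auto_bp


def compute_l_auto(gm: GenotypeMatrix, autosome_labels: list[str] | None = None) -> int:
    """Lauto: summed first-to-last SNP span per (autosomal) chromosome."""
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    allowed = set(autosome_labels) if autosome_labels is not None else None
    pos = gm.sites["pos"].to_numpy()
    total = 0
    for chrom, a, b in gm.chrom_blocks():
        if allowed is not None and chrom not in allowed:
            continue
        if b - a < 2:
            log.warning("chromosome %s has <2 SNPs; contributes 0 bp to Lauto", chrom)
            continue
        total += int(pos[b - 1] - pos[a] + 1)
    return total


def compute_froh(
    segments: list[ROHSegment],
    l_auto_bp: int,
    sample_id: str | None = None,
    autosome_labels: list[str] | None = None,
) -> FrohResult:
    """F_ROH for one sample: total segment bp over the autosomal denominator.

    ``segments`` must belong to a single sample; segments on chromosomes
    outside ``autosome_labels`` (when given) are excluded with a warning.
    """
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    ids = {s.sample_id for s in segments}
    if sample_id is None:
        if len(ids) > 1:
            raise ValueError("segments from multiple samples; pass sample_id")
        sample_id = next(iter(ids)) if ids else "NA"
    else:
        segments = [s for s in segments if s.sample_id == sample_id]
    if autosome_labels is not None:
        allowed = set(autosome_labels)
        dropped = [s for s in segments if s.chrom not in allowed]
        if dropped:
            log.warning(
                "%d segment(s) outside the autosome list excluded from F_ROH",
                len(dropped),
            )
        segments = [s for s in segments if s.chrom in allowed]
    return FrohResult(
        sample_id=sample_id,
        sum_roh_bp=sum(s.length_bp for s in segments),
        l_auto_bp=int(l_auto_bp),
    )


def froh_table(
    segments: list[ROHSegment],
    gm: GenotypeMatrix,
    sample_groups: dict[str, str] | None = None,
    autosome_labels: list[str] | None = None,
    l_auto_bp: int | None = None,
) -> pd.DataFrame:
    """Per-sample F_ROH table over all samples of ``gm``.

    ``l_auto_bp`` overrides the SNP-span denominator for users with a fixed
    assembly-based Lauto.
    """
    if l_auto_bp is None:
        l_auto_bp = compute_l_auto(gm, autosome_labels)
    by_sample: dict[str, list[ROHSegment]] = {sid: [] for sid in gm.sample_ids}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    rows = []
    for sid in gm.sample_ids:
        res = compute_froh(by_sample[sid], l_auto_bp, sample_id=sid,
                           autosome_labels=autosome_labels)
        rows.append(
            {
                "sample": sid,
                "n_segments": len(by_sample[sid]),
                "sum_roh_bp": res.sum_roh_bp,
                "l_auto_bp": res.l_auto_bp,
                "froh": res.froh,
            }
        )
    df = pd.DataFrame(rows)
    if sample_groups is not None:
        df.insert(1, "group", df["sample"].map(sample_groups))
    return df


# ----------------------------------------------------------------------
def compare_froh_groups(froh_by_group: dict[str, "np.ndarray | list[float]"]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of F_ROH across groups.

    Returns ``(F statistic, p value)``; requires >= 2 groups with >= 2
    samples each.
    """
    if len(froh_by_group) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = []
    for g, vals in froh_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 2:
            raise ValueError(f"group {g} has fewer than two samples")
        arrays.append(arr)
    f_stat, p = sps.f_oneway(*arrays)
    return float(f_stat), float(p)
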