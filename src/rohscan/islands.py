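"""ROH incidence, island calling and gene annotation.

The per-SNP incidence is the fraction of individuals whose ROH segments
cover the SNP.  Candidate island SNPs must lie in the top quantile of the
incidence distribution (ties at the cutoff included) AND be covered in at
least ``min_sample_frac`` of individuals; consecutive candidates within
``merge_gap_bp`` merge into one island spanning first to last candidate.
All interval overlap arithmetic is 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from gffutils import feature as gff_feature
from intervaltree import IntervalTree

from .detect import ROHSegment
from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class ROHIsland:
    """One called island: the span of a merged run of candidate SNPs.

    ``n_snps`` counts candidate SNPs; ``n_snps_total`` counts every retained
    SNP inside the span (the two can differ when non-candidate SNPs are
    interleaved)."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_snps_total: int
    peak_incidence: float
    gene_list: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def compute_incidence(segments: list[ROHSegment], gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP count and fraction of individuals with a covering ROH.

    The denominator is the total number of individuals in ``gm``,
    irrespective of missingness at the SNP.
    """
    pos = gm.sites["pos"].to_numpy()
    n_cov = np.zeros(gm.n_sites, dtype=np.int64)
    offsets = {chrom: (a, b) for chrom, a, b in gm.chrom_blocks()}
    for s in segments:
        if s.chrom not in offsets:
            continue
        a, b = offsets[s.chrom]
        i0 = a + int(np.searchsorted(pos[a:b], s.start_bp, side="left"))
        i1 = a + int(np.searchsorted(pos[a:b], s.end_bp, side="right"))
        n_cov[i0:i1] += 1
    return pd.DataFrame(
        {
            "chrom": gm.sites["chrom"].to_numpy(),
            "pos": pos,
            "n_covered": n_cov,
            "incidence": n_cov / gm.n_samples,
        }
    )


def call_islands(
    track: pd.DataFrame,
    top_quantile: float = 0.001,
    min_sample_frac: float = 0.5,
    merge_gap_bp: int = 1_000_000,
) -> list[ROHIsland]:
    """Call ROH islands from an incidence track.

    Candidates are SNPs whose incidence reaches the empirical
    ``1 - top_quantile`` quantile (computed with the ``higher`` method so
    the cutoff is an observed value; all ties at the cutoff qualify) and is
    at least ``min_sample_frac``.  Runs of candidates on one chromosome
    separated by at most ``merge_gap_bp`` become one island.
    """
    if len(track) == 0:
        raise ValueError("empty incidence track")
    inc = track["incidence"].to_numpy()
    cutoff = float(np.quantile(inc, 1.0 - top_quantile, method="higher"))
    candidate = (inc >= cutoff) & (inc >= min_sample_frac)
    if not candidate.any():
        log.info("no candidate SNPs above incidence cutoff %.4f", cutoff)
        return []

    islands: list[ROHIsland] = []
    cand = track.loc[candidate]
    pos_all = track["pos"].to_numpy()
    chrom_all = track["chrom"].to_numpy()
    for chrom in cand["chrom"].unique():
        sub = cand[cand["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        inc_sub = sub["incidence"].to_numpy()
        split = np.flatnonzero(np.diff(pos) > merge_gap_bp)
        starts = np.concatenate(([0], split + 1))
        stops = np.concatenate((split + 1, [len(pos)]))
        for a, b in zip(starts, stops):
            lo, hi = int(pos[a]), int(pos[b - 1])
            in_span = (chrom_all == chrom) & (pos_all >= lo) & (pos_all <= hi)
            islands.append(
                ROHIsland(
                    chrom=str(chrom),
                    start_bp=lo,
                    end_bp=hi,
                    n_snps=int(b - a),
                    n_snps_total=int(in_span.sum()),
                    peak_incidence=float(inc_sub[a:b].max()),
                )
            )
    islands.sort(key=lambda r: (r.chrom, r.start_bp))
    return islands


# ----------------------------------------------------------------------
def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from GFF3 (feature type ``gene``) or BED4.

    Returns a frame with columns ``chrom, start, end, name`` in 0-based
    half-open coordinates.  Unparseable GFF3 lines are skipped with a
    warning and counted.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "name"],
            dtype={"chrom": str, "name": str},
        )
        return df
    rows = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gff_feature.feature_from_line(line)
            except Exception:
                n_bad += 1
                continue
            if feat.featuretype != "gene":
                continue
            name = (
                feat.attributes.get("Name", [None])[0]
                or feat.attributes.get("ID", [None])[0]
                or f"{feat.seqid}:{feat.start}-{feat.end}"
            )
            # GFF3 is 1-based inclusive; convert to 0-based half-open
            rows.append((feat.seqid, feat.start - 1, feat.end, name))
    if n_bad:
        log.warning("skipped %d unparseable annotation line(s)", n_bad)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def annotate_islands(islands: list[ROHIsland], gene_models: pd.DataFrame) -> list[ROHIsland]:
    """Attach overlapping genes (>= 1 bp, half-open arithmetic) to islands.

    Gene lists are sorted by gene start; islands are modified in place and
    returned.
    """
    trees: dict[str, IntervalTree] = {}
    for r in gene_models.itertuples():
        if r.end <= r.start:
            continue
        trees.setdefault(str(r.chrom), IntervalTree()).addi(
            int(r.start), int(r.end), str(r.name)
        )
    for isl in islands:
        tree = trees.get(isl.chrom)
        if tree is None:
            isl.gene_list = []
            continue
        # island to 0-based half-open
        hits = tree.overlap(isl.start_bp - 1, isl.end_bp)
        isl.gene_list = [h.data for h in sorted(hits, key=lambda h: (h.begin, h.end))]
    return islands


# ----------------------------------------------------------------------
def islands_to_frame(islands: list[ROHIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in islands],
            "start_bp": [r.start_bp for r in islands],
            "end_bp": [r.end_bp for r in islands],
            "n_candidate_snps": [r.n_snps for r in islands],
            "n_total_snps": [r.n_snps_total for r in islands],
            "peak_incidence": [r.peak_incidence for r in islands],
            "genes": [",".join(r.gene_list) for r in islands],
        }
    )


def write_islands_tsv(islands: list[ROHIsland], path: str | Path) -> None:
    islands_to_frame(islands).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_islands_bed(islands: list[ROHIsland], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(islands, key=lambda r: (r.chrom, r.start_bp)):
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\n")


def write_incidence_tsv(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.6f")
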