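"""Run-of-homozygosity calling under five segment-level constraints.

A candidate run is any interval of consecutive SNPs, beginning and ending on
a homozygous call, that satisfies all of:

1. physical length >= ``min_length_bp``;
2. at most ``max_missing`` missing and ``max_het`` heterozygous genotypes;
3. at least ``min_snps`` consecutive SNPs;
4. SNP density >= ``min_density_snp_per_kb``;
5. no gap between adjacent SNPs inside the run above ``max_gap_bp``.

Missing calls are neutral: they count against the missing allowance but
never terminate a run by themselves.  From the candidate set we keep runs
not strictly contained in another candidate, then resolve overlaps greedily:
emit the candidate with the leftmost start (longest wins ties), drop
candidates overlapping it, repeat.  ``detect_roh`` computes this with a
linear scan; ``oracle_detect_roh`` enumerates every interval and exists so
the scan can be verified against a definitionally-correct reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix


@dataclass
class ROHParams:
    """Thresholds of the five run constraints (defaults: 50 kb minimum
    length, 50 SNPs, <=3 het, <=5 missing, 0.05 SNP/kb, 1 Mb maximum gap)."""

    min_length_bp: int = 50_000
    min_snps: int = 50
    max_het: int = 3
    max_missing: int = 5
    min_density_snp_per_kb: float = 0.05
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0 or self.min_snps <= 0:
            raise ValueError("min_length_bp and min_snps must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("max_het and max_missing must be >= 0")
        if self.min_density_snp_per_kb <= 0 or self.max_gap_bp <= 0:
            raise ValueError("density and gap thresholds must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run for one sample.

    ``start_bp``/``end_bp`` are the positions of the first and last SNP of
    the run (1-based inclusive); ``length_bp = end_bp - start_bp + 1``.
    """

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


# ----------------------------------------------------------------------
def _per_chrom_arrays(gm: GenotypeMatrix):
    """Yield (chrom, positions, per-sample call slice range) per chromosome."""
    pos = gm.sites["pos"].to_numpy()
    for chrom, a, b in gm.chrom_blocks():
        yield chrom, pos[a:b], a, b


def _scan_chromosome(
    calls: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[tuple[int, int]]:
    """Emit the greedy-resolved maximal runs for one sample/chromosome.

    Returns SNP-index pairs (i, j) inclusive.  A candidate [i, jmax(i)] is
    maximal iff jmax(i) exceeds jmax(i') for every earlier start i', so a
    single left-to-right pass tracking the best end seen suffices; emission
    additionally requires the run not to overlap the previously emitted one.
    """
    n = len(pos)
    if n == 0:
        return []
    hom = (calls == HOM_REF) | (calls == HOM_ALT)
    het = calls == HET
    miss = calls == MISSING

    het_cum = np.concatenate(([0], np.cumsum(het)))
    miss_cum = np.concatenate(([0], np.cumsum(miss)))
    het_idx = np.flatnonzero(het)
    miss_idx = np.flatnonzero(miss)

    gaps = np.diff(pos)
    breaks = np.flatnonzero(gaps > params.max_gap_bp)  # break between k and k+1

    min_snps = params.min_snps
    min_len = params.min_length_bp
    dens = params.min_density_snp_per_kb

    out: list[tuple[int, int]] = []
    best_j = -1
    emitted_end = -1
    bi = 0  # pointer into breaks

    for i in np.flatnonzero(hom):
        # furthest end allowed by the het budget
        h0 = het_cum[i] + params.max_het
        j_het = het_idx[h0] - 1 if h0 < len(het_idx) else n - 1
        m0 = miss_cum[i] + params.max_missing
        j_miss = miss_idx[m0] - 1 if m0 < len(miss_idx) else n - 1
        while bi < len(breaks) and breaks[bi] < i:
            bi += 1
        j_gap = breaks[bi] if bi < len(breaks) else n - 1
        J = min(j_het, j_miss, j_gap)
        lo = max(i + min_snps - 1, best_j + 1)
        if J < lo:
            continue
        lengths = pos[lo : J + 1] - pos[i] + 1
        n_snps = np.arange(lo, J + 1) - i + 1
        ok = hom[lo : J + 1] & (lengths >= min_len) & (n_snps * 1000.0 >= dens * lengths)
        if not ok.any():
            continue
        j_star = lo + (len(ok) - 1 - int(np.argmax(ok[::-1])))
        best_j = j_star
        if i > emitted_end:
            out.append((int(i), int(j_star)))
            emitted_end = j_star
    return out


def _build_segment(
    sample_id: str, chrom: str, calls: np.ndarray, pos: np.ndarray, i: int, j: int
) -> ROHSegment:
    window = calls[i : j + 1]
    return ROHSegment(
        sample_id=sample_id,
        chrom=chrom,
        start_bp=int(pos[i]),
        end_bp=int(pos[j]),
        n_snps=j - i + 1,
        n_het=int((window == HET).sum()),
        n_missing=int((window == MISSING).sum()),
    )


def detect_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH segments for every sample of ``gm``.

    The genotype matrix must be sorted by chromosome and position (enforced
    by :class:`~rohscan.genotypes.GenotypeMatrix`); segments are returned
    sorted by sample, chromosome block and start.
    """
    params = params or ROHParams()
    gm.validate()
    segments: list[ROHSegment] = []
    for chrom, pos, a, b in _per_chrom_arrays(gm):
        for s_idx, sid in enumerate(gm.sample_ids):
            calls = gm.calls[s_idx, a:b]
            for i, j in _scan_chromosome(calls, pos, params):
                segments.append(_build_segment(sid, chrom, calls, pos, i, j))
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start_bp))
    return segments


# ----------------------------------------------------------------------
ORACLE_MAX_SNPS = 2_000


def _oracle_chromosome(
    calls: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[tuple[int, int]]:
    """Exhaustive O(n^2) enumeration + maximality filter + greedy resolve."""
    n = len(pos)
    if n == 0:
        return []
    hom = (calls == HOM_REF) | (calls == HOM_ALT)
    het_cum = np.concatenate(([0], np.cumsum(calls == HET)))
    miss_cum = np.concatenate(([0], np.cumsum(calls == MISSING)))
    gaps = np.diff(pos)

    candidates: list[tuple[int, int]] = []
    for i in range(n):
        if not hom[i]:
            continue
        js = np.arange(i, n)
        lengths = pos[i:] - pos[i] + 1
        n_snps = js - i + 1
        n_het = het_cum[js + 1] - het_cum[i]
        n_miss = miss_cum[js + 1] - miss_cum[i]
        # running maximum gap inside [i, j]
        maxg = np.zeros(n - i, dtype=np.int64)
        if n - i > 1:
            maxg[1:] = np.maximum.accumulate(gaps[i : n - 1])
        ok = (
            hom[i:]
            & (n_snps >= params.min_snps)
            & (lengths >= params.min_length_bp)
            & (n_het <= params.max_het)
            & (n_miss <= params.max_missing)
            & (n_snps * 1000.0 >= params.min_density_snp_per_kb * lengths)
            & (maxg <= params.max_gap_bp)
        )
        for j in np.flatnonzero(ok):
            candidates.append((i, i + int(j)))

    # drop candidates strictly contained in another candidate
    candidates.sort(key=lambda c: (c[0], -c[1]))
    maximal: list[tuple[int, int]] = []
    best_end = -1
    for i, j in candidates:
        if j > best_end:
            maximal.append((i, j))
            best_end = j

    # greedy: leftmost start first, discard overlaps
    out: list[tuple[int, int]] = []
    emitted_end = -1
    for i, j in maximal:
        if i > emitted_end:
            out.append((i, j))
            emitted_end = j
    return out


def oracle_detect_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Brute-force reference caller (guard: <= 2000 SNPs per chromosome)."""
    params = params or ROHParams()
    gm.validate()
    segments: list[ROHSegment] = []
    for chrom, pos, a, b in _per_chrom_arrays(gm):
        if len(pos) > ORACLE_MAX_SNPS:
            raise ValueError(
                f"oracle guard: {len(pos)} SNPs on {chrom} exceeds {ORACLE_MAX_SNPS}"
            )
        for s_idx, sid in enumerate(gm.sample_ids):
            calls = gm.calls[s_idx, a:b]
            for i, j in _oracle_chromosome(calls, pos, params):
                segments.append(_build_segment(sid, chrom, calls, pos, i, j))
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start_bp))
    return segments


# ----------------------------------------------------------------------
def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Tabulate segments with PLINK .hom-style columns."""
    return pd.DataFrame(
        {
            "FID": [s.sample_id for s in segments],
            "IID": [s.sample_id for s in segments],
            "CHR": [s.chrom for s in segments],
            "SNP1": [f"{s.chrom}:{s.start_bp}" for s in segments],
            "SNP2": [f"{s.chrom}:{s.end_bp}" for s in segments],
            "POS1": [s.start_bp for s in segments],
            "POS2": [s.end_bp for s in segments],
            "KB": [s.length_bp / 1000.0 for s in segments],
            "NSNP": [s.n_snps for s in segments],
            "NHET": [s.n_het for s in segments],
            "NMISS": [s.n_missing for s in segments],
        }
    )


def frame_to_segments(df: pd.DataFrame) -> list[ROHSegment]:
    """Rebuild segments from a table written by :func:`write_segments_tsv`."""
    return [
        ROHSegment(
            sample_id=str(r.IID),
            chrom=str(r.CHR),
            start_bp=int(r.POS1),
            end_bp=int(r.POS2),
            n_snps=int(r.NSNP),
            n_het=int(r.NHET),
            n_missing=int(r.NMISS),
        )
        for r in df.itertuples()
    ]


def write_segments_tsv(segments: list[ROHSegment], path: str | Path) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_segments_tsv(path: str | Path) -> list[ROHSegment]:
    return frame_to_segments(pd.read_csv(path, sep="\t", dtype={"CHR": str, "IID": str}))


def write_segments_bed(segments: list[ROHSegment], path: str | Path) -> None:
    """BED4 of segments (0-based half-open, name = sample id)."""
    rows = sorted(
        ((s.chrom, s.start_bp - 1, s.end_bp, s.sample_id) for s in segments),
        key=lambda r: (r[0], r[1], r[2], r[3]),
    )
    with open(path, "w") as fh:
        for c, a, b, sid in rows:
            fh.write(f"{c}\t{a}\t{b}\t{sid}\n")
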