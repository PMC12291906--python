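"""Diploid genotype simulator with planted autozygous segments.

The simulator emulates a multi-generation inbreeding gradient: each group of
individuals receives planted homozygous-by-descent intervals until a target
fraction of the genome (``target_F``) is covered, over a Hardy-Weinberg
background drawn from Beta-distributed per-site allele frequencies.  Planted
intervals are the ground truth against which ROH detection, F_ROH estimation
and island calling are validated.

Randomness is organised as one root seed with fixed sub-streams: a site
stream (SNP positions and allele frequencies) and one stream per individual,
so that adding individuals to a config never perturbs the data of earlier
individuals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix

# group presets mirroring the observed generation gradient of autozygosity
# (F1 backcross lowest, third backcross generation highest)
STUDY_GROUPS: list[tuple[str, int, float]] = [
    ("F1", 20, 0.09428),
    ("F2", 20, 0.119657),
    ("CY", 20, 0.1435),
    ("F3", 20, 0.149666),
]

_SITE_STREAM = 0
_INDIV_STREAM = 1

#: forced-island validation region (chrom, start, end, carrier fraction)
ISLAND_REGION: tuple[str, int, int, float] = ("chr3", 30_000_001, 30_800_000, 0.8)


def island_validation_config(seed: int = 0, carrier_fraction: float = 0.8) -> "SimConfig":
    """Scenario for validating island recovery: one 30-individual group at a
    background autozygosity of 0.1 on a 1 Gb genome, with an 800 kb forced
    island carried by ``carrier_fraction`` of individuals.

    The region holds ~80 SNPs at the default 10 kb spacing: comfortably
    above the 50-SNP run minimum, yet below the ~100-SNP top-0.1% candidate
    budget of a 1 Gb genome, so the >=50 %-of-samples rule, not the
    quantile, delimits the island."""
    c, s, e, _ = ISLAND_REGION
    return SimConfig(
        chrom_lengths=[(f"chr{i}", 100_000_000) for i in range(1, 11)],
        groups=[("G", 30, 0.1)],
        forced_islands=[(c, s, e, carrier_fraction)],
        seed=seed,
    )


@dataclass
class SimConfig:
    """Configuration of one simulated population.

    Attributes
    ----------
    chrom_lengths
        ``(label, length_bp)`` per autosome.
    snp_spacing_mean
        Mean bp between adjacent SNPs; spacings are exponential (Poisson
        process), so a 10 kb mean puts ~50 SNPs in 0.5 Mb.
    groups
        ``(label, n_individuals, target_F)`` per group; ``target_F`` is the
        planted autozygous fraction of the genome, in ``[0, 1)``.
    segment_length_mean, segment_length_min
        Planted segment lengths are exponential with this mean, floored at
        the minimum; the final segment of an individual is truncated to the
        remaining deficit (never below the floor) so realized coverage
        tracks the target closely.
    allele_freq_beta
        ``(a, b)`` shape of the per-site allele-frequency Beta; frequencies
        are redrawn until the folded MAF is at least ``maf_floor`` so default
        simulations survive a MAF >= 0.05 site filter.
    het_error_rate
        Probability a genotype inside a planted segment is rendered
        heterozygous (genotyping error).
    missing_rate
        Probability any genotype is set missing, applied last.
    forced_islands
        ``(chrom, start_bp, end_bp, carrier_fraction)`` regions planted
        population-wide: each individual carries the full interval with
        probability ``carrier_fraction``.
    """

    chrom_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"chr{i}", 20_000_000) for i in range(1, 6)]
    )
    snp_spacing_mean: float = 10_000.0
    groups: list[tuple[str, int, float]] = field(
        default_factory=lambda: list(STUDY_GROUPS)
    )
    segment_length_mean: float = 1_500_000.0
    segment_length_min: float = 500_000.0
    allele_freq_beta: tuple[float, float] = (0.8, 0.8)
    maf_floor: float = 0.05
    het_error_rate: float = 0.001
    missing_rate: float = 0.01
    forced_islands: list[tuple[str, int, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        labels = [c for c, _ in self.chrom_lengths]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate chromosome labels")
        if not self.chrom_lengths:
            raise ValueError("at least one chromosome required")
        for c, length in self.chrom_lengths:
            if length <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")
        if self.snp_spacing_mean <= 0:
            raise ValueError("snp_spacing_mean must be > 0")
        if self.segment_length_mean <= 0 or self.segment_length_min <= 0:
            raise ValueError("segment lengths must be > 0")
        for g, n, f in self.groups:
            if not (0.0 <= f < 1.0):
                raise ValueError(f"group {g}: target_F must be in [0, 1)")
            if n < 0:
                raise ValueError(f"group {g}: negative group size")
            if f > 0 and self.segment_length_mean >= max(
                length for _, length in self.chrom_lengths
            ):
                raise ValueError(
                    f"group {g}: mean segment length >= longest chromosome; "
                    "target_F unreachable"
                )
        for rate, name in (
            (self.het_error_rate, "het_error_rate"),
            (self.missing_rate, "missing_rate"),
            (self.maf_floor, "maf_floor"),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        chrom_len = dict(self.chrom_lengths)
        for c, s, e, cf in self.forced_islands:
            if c not in chrom_len:
                raise ValueError(f"forced island on unknown chromosome {c}")
            if not (1 <= s <= e <= chrom_len[c]):
                raise ValueError(f"forced island {c}:{s}-{e} out of bounds")
            if not (0.0 <= cf <= 1.0):
                raise ValueError("carrier_fraction must be in [0, 1]")

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chrom_lengths)

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        """Load a config from a YAML mapping of the dataclass fields."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "chrom_lengths" in raw:
            raw["chrom_lengths"] = [(str(c), int(l)) for c, l in raw["chrom_lengths"]]
        if "groups" in raw:
            raw["groups"] = [(str(g), int(n), float(f)) for g, n, f in raw["groups"]]
        if "forced_islands" in raw:
            raw["forced_islands"] = [
                (str(c), int(s), int(e), float(cf))
                for c, s, e, cf in raw["forced_islands"]
            ]
        if "allele_freq_beta" in raw:
            a, b = raw["allele_freq_beta"]
            raw["allele_freq_beta"] = (float(a), float(b))
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimTruth:
    """Ground truth of a simulation: planted intervals per individual.

    ``intervals[sample_id]`` is a list of ``(chrom, start_bp, end_bp)``
    tuples, 1-based inclusive, non-overlapping within an individual.
    ``realized_f[sample_id]`` is planted bp divided by total genome bp.
    """

    intervals: dict[str, list[tuple[str, int, int]]]
    realized_f: dict[str, float]
    total_bp: int

    def planted_bp(self, sample_id: str) -> int:
        return sum(e - s + 1 for _, s, e in self.intervals[sample_id])


# ----------------------------------------------------------------------
def _site_positions(rng: np.random.Generator, length: int, spacing: float) -> np.ndarray:
    """SNP positions on one chromosome from a Poisson spacing process."""
    n_expected = int(length / spacing * 1.3) + 10
    pos: list[int] = []
    cur = 0
    while True:
        gaps = np.maximum(1, np.round(rng.exponential(spacing, n_expected))).astype(np.int64)
        for g in gaps:
            cur += int(g)
            if cur > length:
                return np.asarray(pos, dtype=np.int64)
            pos.append(cur)


def _place_for_target(
    rng: np.random.Generator,
    config: SimConfig,
    target_bp: float,
    existing: list[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    chrom_labels = [c for c, _ in config.chrom_lengths]
    chrom_len = dict(config.chrom_lengths)
    weights = np.array([chrom_len[c] for c in chrom_labels], dtype=float)
    weights /= weights.sum()

    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_labels}
    for c, s, e in existing:
        by_chrom[c].append((s, e))
    intervals = list(existing)
    covered = sum(e - s + 1 for _, s, e in existing)

    min_len = int(config.segment_length_min)
    while covered < target_bp:
        deficit = target_bp - covered
        length = max(min_len, int(round(rng.exponential(config.segment_length_mean))))
        if length > deficit:
            # truncate the final segment so realized F tracks the target
            length = max(min_len, int(round(deficit)))
        placed = False
        for _ in range(1000):
            c = chrom_labels[rng.choice(len(chrom_labels), p=weights)]
            if length > chrom_len[c]:
                continue
            start = int(rng.integers(1, chrom_len[c] - length + 2))
            end = start + length - 1
            if any(s <= end and start <= e for s, e in by_chrom[c]):
                continue
            by_chrom[c].append((start, end))
            intervals.append((c, start, end))
            covered += length
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place planted segment after 1000 attempts; "
                "genome too saturated for target_F"
            )
    return intervals


def simulate_population(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Simulate genotypes for all groups of ``config``.

    Returns
    -------
    gm
        Genotype matrix over all individuals (groups concatenated).
    sample_map
        Two-column frame ``sample`` / ``group``.
    truth
        Planted intervals and realized autozygous fractions per individual.
    """
    seed = int(config.seed)
    site_rng = np.random.default_rng([seed, _SITE_STREAM])

    # --- sites: positions and allele frequencies ----------------------
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for c, length in config.chrom_lengths:
        pos = _site_positions(site_rng, length, config.snp_spacing_mean)
        positions.append(pos)
        chroms.extend([c] * len(pos))
    pos_all = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    n_sites = len(pos_all)

    a, b = config.allele_freq_beta
    freq = site_rng.beta(a, b, n_sites)
    if config.maf_floor > 0:
        bad = np.minimum(freq, 1 - freq) < config.maf_floor
        while bad.any():
            freq[bad] = site_rng.beta(a, b, int(bad.sum()))
            bad = np.minimum(freq, 1 - freq) < config.maf_floor

    sites = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "pos": pos_all,
            "ref": "A",
            "alt": "G",
            "n_alleles": 2,
        }
    )

    # per-chromosome site index ranges for interval -> site lookup
    site_ranges: dict[str, tuple[int, int, np.ndarray]] = {}
    offset = 0
    for (c, _), pos in zip(config.chrom_lengths, positions):
        site_ranges[c] = (offset, offset + len(pos), pos)
        offset += len(pos)

    # --- individuals --------------------------------------------------
    sample_ids: list[str] = []
    group_of: list[str] = []
    targets: list[float] = []
    for g, n, f in config.groups:
        for k in range(n):
            sample_ids.append(f"{g}_{k + 1:03d}")
            group_of.append(g)
            targets.append(f)

    n_ind = len(sample_ids)
    calls = np.empty((n_ind, n_sites), dtype=np.int8)
    truth_intervals: dict[str, list[tuple[str, int, int]]] = {}
    realized_f: dict[str, float] = {}
    total_bp = config.total_bp

    p = freq  # alt-allele frequency per site
    hw = np.stack([(1 - p) ** 2, 2 * p * (1 - p)], axis=0).cumsum(axis=0)

    for idx, sid in enumerate(sample_ids):
        rng = np.random.default_rng([seed, _INDIV_STREAM, idx])

        # forced islands first (carrier status), then random planted segments
        forced: list[tuple[str, int, int]] = []
        for c, s, e, cf in config.forced_islands:
            if rng.random() < cf:
                forced.append((c, s, e))
        target_bp = targets[idx] * total_bp
        intervals = _place_for_target(rng, config, max(target_bp, 0.0), forced)
        intervals.sort(key=lambda iv: (iv[0], iv[1]))
        truth_intervals[sid] = intervals
        realized_f[sid] = sum(e - s + 1 for _, s, e in intervals) / total_bp

        # background Hardy-Weinberg genotypes
        u = rng.random(n_sites)
        g = np.full(n_sites, HOM_ALT, dtype=np.int8)
        g[u < hw[1]] = HET
        g[u < hw[0]] = HOM_REF

        # overwrite planted intervals: homozygous, allele by frequency
        for c, s, e in intervals:
            lo, hi, pos = site_ranges[c]
            i0 = lo + int(np.searchsorted(pos, s, side="left"))
            i1 = lo + int(np.searchsorted(pos, e, side="right"))
            span = i1 - i0
            if span <= 0:
                continue
            hom = np.where(rng.random(span) < p[i0:i1], HOM_ALT, HOM_REF).astype(np.int8)
            if config.het_error_rate > 0:
                err = rng.random(span) < config.het_error_rate
                hom[err] = HET
            g[i0:i1] = hom

        # missingness last, independent of everything else
        if config.missing_rate > 0:
            g[rng.random(n_sites) < config.missing_rate] = MISSING
        calls[idx] = g

    gm = GenotypeMatrix(sample_ids=sample_ids, sites=sites, calls=calls)
    sample_map = pd.DataFrame({"sample": sample_ids, "group": group_of})
    truth = SimTruth(intervals=truth_intervals, realized_f=realized_f, total_bp=total_bp)
    return gm, sample_map, truth


# ----------------------------------------------------------------------
def write_truth_bed(truth: SimTruth, path: str | Path) -> None:
    """Write planted intervals as BED4 (0-based half-open, name = sample)."""
    rows = []
    for sid, ivs in truth.intervals.items():
        for c, s, e in ivs:
            rows.append((c, s - 1, e, sid))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        for c, s, e, sid in rows:
            fh.write(f"{c}\t{s}\t{e}\t{sid}\n")


def write_sample_map(sample_map: pd.DataFrame, path: str | Path) -> None:
    """Write the two-column sample -> group TSV."""
    sample_map.to_csv(path, sep="\t", index=False, header=False)


def read_sample_map(path: str | Path) -> pd.DataFrame:
    """Read a headerless two-column sample -> group TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    return df
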