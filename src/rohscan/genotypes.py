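"""Core genotype container shared by the simulator, IO and ROH calling.

Genotype calls are stored as a dense ``int8`` matrix (samples x sites) using
the four-code scheme below.  Sites carry 1-based VCF-style positions; any BED
written downstream converts to 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# call codes
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

#: columns required in :attr:`GenotypeMatrix.sites`
SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "n_alleles")


@dataclass
class GenotypeMatrix:
    """Samples x SNP sites diploid genotype matrix.

    Parameters
    ----------
    sample_ids
        Sample identifiers, one per matrix row.
    sites
        Per-site table with columns ``chrom`` (str), ``pos`` (1-based bp,
        int), ``ref``, ``alt`` (comma-joined for multiallelic records) and
        ``n_alleles``.  Sites must be grouped by chromosome with strictly
        increasing positions inside each chromosome.
    calls
        ``int8`` array of shape ``(n_samples, n_sites)`` holding
        ``HOM_REF``/``HET``/``HOM_ALT``/``MISSING`` codes.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        for col in SITE_COLUMNS:
            if col not in self.sites.columns:
                raise ValueError(f"sites table missing column {col!r}")
        if self.calls.shape != (self.n_samples, self.n_sites):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.n_samples} samples x {self.n_sites} sites"
            )
        if len(set(self.sample_ids)) != self.n_samples:
            raise ValueError("duplicate sample ids")
        chroms = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        seen: set[str] = set()
        for start, stop in iter_chrom_blocks(chroms):
            c = chroms[start]
            if c in seen:
                raise ValueError(f"sites for chromosome {c} are not contiguous")
            seen.add(c)
            p = pos[start:stop]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------
    def chrom_blocks(self) -> list[tuple[str, int, int]]:
        """Return ``(chrom, start_index, stop_index)`` per chromosome block."""
        chroms = self.sites["chrom"].to_numpy()
        return [(chroms[a], a, b) for a, b in iter_chrom_blocks(chroms)]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask].copy(),
        )


def iter_chrom_blocks(chroms: np.ndarray):
    """Yield ``(start, stop)`` index pairs of runs of equal chromosome label."""
    n = len(chroms)
    if n == 0:
        return
    start = 0
    for i in range(1, n):
        if chroms[i] != chroms[start]:
            yield start, i
            start = i
    yield start, n


def allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt allele count, called allele count) from coded calls."""
    het = (calls == HET).sum(axis=0)
    hom_alt = (calls == HOM_ALT).sum(axis=0)
    non_missing = (calls != MISSING).sum(axis=0)
    return 2 * hom_alt + het, 2 * non_missing


def minor_allele_freq(calls: np.ndarray) -> np.ndarray:
    """Per-site MAF over non-missing genotypes; NaN where no calls."""
    alt, total = allele_counts(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    return np.where(np.isnan(af), np.nan, np.minimum(af, 1.0 - af))


def call_rate(calls: np.ndarray) -> np.ndarray:
    """Per-site fraction of non-missing genotypes."""
    return (calls != MISSING).sum(axis=0) / calls.shape[0]
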