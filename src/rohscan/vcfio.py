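"""VCF reading/writing and VCFtools-style site filtering.

Filtering semantics follow the common resequencing-QC recipe: keep biallelic
autosomal SNPs with call rate >= 0.8 and minor allele frequency >= 0.05,
computed over non-missing genotypes only.  Comparisons are inclusive (the
``--max-missing 0.8`` / ``--maf 0.05`` flag semantics of VCFtools).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    call_rate,
    minor_allele_freq,
)

log = logging.getLogger(__name__)


def read_vcf(path: str | Path, autosome_labels: list[str] | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Diploid GT fields are parsed to the four-code scheme; a genotype with any
    missing allele (``./.``, ``./1`` ...) is coded ``MISSING``.  Multiallelic
    records are retained with ``n_alleles > 2`` so the filter stage can drop
    them.  Non-diploid genotypes are a hard error.

    Parameters
    ----------
    autosome_labels
        If given, only records on these chromosomes are loaded (an early
        restriction; the authoritative autosome filter lives in
        :func:`filter_sites`).
    """
    path = str(path)
    keep = set(autosome_labels) if autosome_labels is not None else None
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} has no samples")

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    n_alleles: list[int] = []
    rows: list[np.ndarray] = []
    n = len(samples)
    for var in vcf:
        if keep is not None and var.CHROM not in keep:
            continue
        codes = np.empty(n, dtype=np.int8)
        gts = var.genotypes
        if len(gts) != n:
            raise ValueError(f"{path}: truncated genotype row at {var.CHROM}:{var.POS}")
        for i, g in enumerate(gts):
            if len(g) != 3:  # [a1, a2, phased] for diploid calls
                raise ValueError(
                    f"{path}: non-diploid GT for sample {samples[i]} "
                    f"at {var.CHROM}:{var.POS}"
                )
            a1, a2 = g[0], g[1]
            if a1 < 0 or a2 < 0:
                codes[i] = MISSING
            elif a1 == a2:
                codes[i] = HOM_REF if a1 == 0 else HOM_ALT
            else:
                codes[i] = HET
        chroms.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(",".join(var.ALT) if var.ALT else ".")
        n_alleles.append(1 + len(var.ALT))
        rows.append(codes)

    sites = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": ref,
            "alt": alt,
            "n_alleles": np.asarray(n_alleles, dtype=np.int64),
        }
    )
    calls = (
        np.vstack(rows).T.copy()
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids=samples, sites=sites, calls=calls)


_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as a plain-text VCF v4.2 with GT only."""
    contig_lengths = contig_lengths or {}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen: list[str] = []
        for c in gm.sites["chrom"]:
            if c not in seen:
                seen.append(c)
        for c in seen:
            if c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        chrom = gm.sites["chrom"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        ref = gm.sites["ref"].to_numpy()
        alt = gm.sites["alt"].to_numpy()
        calls = gm.calls
        for j in range(gm.n_sites):
            gts = "\t".join(_GT_STRING[int(calls[i, j])] for i in range(gm.n_samples))
            fh.write(f"{chrom[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


# ----------------------------------------------------------------------
@dataclass
class FilterSpec:
    """Site-filter thresholds (inclusive comparisons)."""

    min_call_rate: float = 0.8
    min_maf: float = 0.05
    biallelic_only: bool = True
    autosomes_only: bool = True
    autosome_labels: list[str] | None = None

    def __post_init__(self) -> None:
        for v, name in ((self.min_call_rate, "min_call_rate"), (self.min_maf, "min_maf")):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.autosomes_only and self.autosome_labels is None:
            # with no explicit list every chromosome present is treated as
            # autosomal; the flag only bites when a list is supplied
            self.autosomes_only = False


@dataclass
class FilterReport:
    """Counts of sites removed per criterion, attributed in priority order
    biallelic -> autosome -> call rate -> MAF (first failing criterion wins)."""

    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("retained", self.n_retained))
        return pd.DataFrame(rows, columns=["criterion", "n_sites"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_sites(gm: GenotypeMatrix, spec: FilterSpec | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply site filters, preserving site order.

    Returns the filtered matrix and a report of per-criterion removal counts.
    A site failing several criteria is counted once, under the first failing
    criterion in the order biallelic, autosome, call rate, MAF.
    """
    spec = spec or FilterSpec()
    n = gm.n_sites
    keep = np.ones(n, dtype=bool)
    assigned = np.zeros(n, dtype=bool)
    removed: dict[str, int] = {}

    def apply(name: str, fail: np.ndarray) -> None:
        newly = fail & ~assigned
        removed[name] = int(newly.sum())
        assigned[newly] = True
        keep[fail] = False

    if spec.biallelic_only:
        apply("multiallelic", gm.sites["n_alleles"].to_numpy() != 2)
    if spec.autosomes_only and spec.autosome_labels is not None:
        allowed = set(spec.autosome_labels)
        apply("non_autosome", ~gm.sites["chrom"].isin(allowed).to_numpy())
    apply("call_rate", call_rate(gm.calls) < spec.min_call_rate)
    maf = minor_allele_freq(gm.calls)
    apply("maf", ~(maf >= spec.min_maf))  # NaN (no calls) fails

    out = gm.subset_sites(keep)
    if out.n_sites == 0:
        log.warning("no sites survive filtering")
    report = FilterReport(n_input=n, n_retained=out.n_sites, removed=removed)
    return out, report
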