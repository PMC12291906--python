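"""End-to-end pipeline: simulate/ingest -> filter -> detect -> stats -> islands.

Each stage writes plain TSV/BED/VCF files so stages can be re-run
independently; a machine-readable manifest (parameters, input hashes,
package version, seed) is written alongside the outputs.  The manifest
deliberately contains no timestamps so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .detect import ROHParams, detect_roh, write_segments_bed, write_segments_tsv
from .islands import (
    annotate_islands,
    call_islands,
    compute_incidence,
    read_gene_models,
    write_incidence_tsv,
    write_islands_bed,
    write_islands_tsv,
)
from .simulate import SimConfig, simulate_population, write_sample_map, write_truth_bed
from .stats import classify_lengths, compare_froh_groups, froh_table
from .vcfio import FilterSpec, filter_sites, read_vcf, write_vcf

log = logging.getLogger(__name__)


@dataclass
class IslandParams:
    top_quantile: float = 0.001
    min_sample_frac: float = 0.5
    merge_gap_bp: int = 1_000_000


@dataclass
class RunConfig:
    """Full pipeline configuration.

    Exactly one of ``sim`` (simulate the input) or ``vcf_path`` (analyse an
    existing VCF, with ``sample_map_path`` for group labels) must be set.
    """

    outdir: str | Path = "rohscan_out"
    sim: SimConfig | None = None
    vcf_path: str | Path | None = None
    sample_map_path: str | Path | None = None
    gene_models_path: str | Path | None = None
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    roh_params: ROHParams = field(default_factory=ROHParams)
    island_params: IslandParams = field(default_factory=IslandParams)
    seed: int = 0
    make_plots: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Raises before any output is written if the declared inputs are missing;
    a stage failure propagates as an exception naming the stage.
    """
    if (config.sim is None) == (config.vcf_path is None):
        raise ValueError("exactly one of sim config or vcf_path must be given")
    for p in (config.vcf_path, config.sample_map_path, config.gene_models_path):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "filter": dataclasses.asdict(config.filter_spec),
            "roh": dataclasses.asdict(config.roh_params),
            "islands": dataclasses.asdict(config.island_params),
        },
        "inputs": {},
        "stages": [],
    }

    # --- stage: simulate or ingest ------------------------------------
    sample_groups: dict[str, str] | None = None
    if config.sim is not None:
        stage = "simulate"
        sim = dataclasses.replace(config.sim, seed=config.seed)
        gm, sample_map, truth = simulate_population(sim)
        write_vcf(gm, outdir / "simulated.vcf", dict(sim.chrom_lengths))
        write_sample_map(sample_map, outdir / "samples.tsv")
        write_truth_bed(truth, outdir / "truth.bed")
        sample_groups = dict(zip(sample_map["sample"], sample_map["group"]))
        manifest["parameters"]["sim"] = sim.to_dict()
        manifest["stages"].append(stage)
    else:
        stage = "ingest"
        vcf_path = Path(config.vcf_path)
        manifest["inputs"]["vcf"] = {"path": str(vcf_path), "sha256": _sha256(vcf_path)}
        gm = read_vcf(vcf_path)
        if config.sample_map_path is not None:
            from .simulate import read_sample_map

            smp = Path(config.sample_map_path)
            manifest["inputs"]["sample_map"] = {"path": str(smp), "sha256": _sha256(smp)}
            sm = read_sample_map(smp)
            sample_groups = dict(zip(sm["sample"], sm["group"]))
        manifest["stages"].append(stage)

    # --- stage: filter -------------------------------------------------
    gm_f, report = filter_sites(gm, config.filter_spec)
    report.write_tsv(outdir / "filter_report.tsv")
    write_vcf(gm_f, outdir / "filtered.vcf")
    manifest["stages"].append("filter")
    if gm_f.n_sites == 0:
        raise RuntimeError("stage filter: no sites survive; aborting downstream stages")

    # --- stage: detect -------------------------------------------------
    segments = detect_roh(gm_f, config.roh_params)
    write_segments_tsv(segments, outdir / "roh_segments.tsv")
    write_segments_bed(segments, outdir / "roh_segments.bed")
    manifest["stages"].append("detect")

    # --- stage: stats --------------------------------------------------
    froh = froh_table(segments, gm_f, sample_groups=sample_groups)
    froh.to_csv(outdir / "froh.tsv", sep="\t", index=False, float_format="%.6f")
    per_sample, per_group = classify_lengths(segments, sample_groups)
    per_sample.to_csv(outdir / "length_bins_per_sample.tsv", sep="\t")
    per_group.to_csv(outdir / "length_bins_per_group.tsv", sep="\t", float_format="%.6f")
    if sample_groups is not None and "group" in froh.columns:
        by_group = {
            g: sub["froh"].to_numpy()
            for g, sub in froh.groupby("group")
            if len(sub) >= 2
        }
        if len(by_group) >= 2:
            f_stat, p = compare_froh_groups(by_group)
            with open(outdir / "anova.tsv", "w") as fh:
                fh.write("statistic\tvalue\n")
                fh.write(f"F\t{f_stat:.6g}\np\t{p:.6g}\n")
    if config.make_plots:
        from .plots import plot_bin_proportions, plot_froh_violin

        plot_bin_proportions(per_group, outdir / "length_bins.png")
        if "group" in froh.columns:
            plot_froh_violin(froh, outdir / "froh_violin.png")
    manifest["stages"].append("stats")

    # --- stage: islands ------------------------------------------------
    track = compute_incidence(segments, gm_f)
    write_incidence_tsv(track, outdir / "incidence.tsv")
    islands = call_islands(
        track,
        top_quantile=config.island_params.top_quantile,
        min_sample_frac=config.island_params.min_sample_frac,
        merge_gap_bp=config.island_params.merge_gap_bp,
    )
    manifest["stages"].append("islands")

    # --- stage: annotate ------------------------------------------------
    if config.gene_models_path is not None:
        gmp = Path(config.gene_models_path)
        manifest["inputs"]["gene_models"] = {"path": str(gmp), "sha256": _sha256(gmp)}
        genes = read_gene_models(gmp)
        islands = annotate_islands(islands, genes)
        manifest["stages"].append("annotate")
    write_islands_tsv(islands, outdir / "islands.tsv")
    write_islands_bed(islands, outdir / "islands.bed")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
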