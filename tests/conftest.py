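import numpy as np
import pandas as pd
import pytest

from rohscan.genotypes import GenotypeMatrix


def make_gm(calls, pos, chrom="chr1", sample_ids=None, n_alleles=2):
    """Build a GenotypeMatrix from a call array and positions on one or more
    chromosomes.  ``calls`` is (n_samples, n_sites); ``chrom`` may be a
    single label or a per-site sequence; ``n_alleles`` likewise scalar or
    per-site."""
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[None, :]
    n_samples, n_sites = calls.shape
    if isinstance(chrom, str):
        chrom = [chrom] * n_sites
    if np.isscalar(n_alleles):
        n_alleles = [n_alleles] * n_sites
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": "A",
            "alt": "G",
            "n_alleles": np.asarray(n_alleles, dtype=np.int64),
        }
    )
    return GenotypeMatrix(sample_ids=list(sample_ids), sites=sites, calls=calls)


def random_instance(rng, n_snps=None, hom_bias=None):
    """A random single-sample genotype track exercising het/missing
    placement, gap structure and density variation."""
    n = n_snps or int(rng.integers(30, 120))
    spacing = rng.integers(1, 40_000, n)
    # occasional huge gap to exercise the gap constraint
    big = rng.random(n) < 0.03
    spacing[big] = rng.integers(200_000, 1_500_000, int(big.sum()))
    pos = np.cumsum(spacing) + 1
    p_hom = hom_bias if hom_bias is not None else rng.uniform(0.55, 0.95)
    rest = 1.0 - p_hom
    calls = rng.choice(
        [0, 2, 1, -1],
        size=n,
        p=[p_hom / 2, p_hom / 2, rest * 0.6, rest * 0.4],
    ).astype(np.int8)
    return calls, pos


def random_params(rng):
    from rohscan.detect import ROHParams

    return ROHParams(
        min_length_bp=int(rng.integers(10_000, 120_000)),
        min_snps=int(rng.integers(3, 16)),
        max_het=int(rng.integers(0, 4)),
        max_missing=int(rng.integers(0, 4)),
        min_density_snp_per_kb=float(rng.uniform(0.01, 0.2)),
        max_gap_bp=int(rng.integers(50_000, 600_000)),
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated population shared across tests (read-only)."""
    from rohscan.simulate import SimConfig, simulate_population

    cfg = SimConfig(
        chrom_lengths=[("chr1", 8_000_000), ("chr2", 6_000_000)],
        groups=[("A", 3, 0.12), ("B", 3, 0.0)],
        seed=7,
    )
    gm, sample_map, truth = simulate_population(cfg)
    return cfg, gm, sample_map, truth
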