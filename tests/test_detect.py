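"""ROH calling: constraint semantics, oracle equivalence, monotonicity,
planted-segment recovery and order invariance."""

import numpy as np
import pytest

from rohscan.detect import (
    ORACLE_MAX_SNPS,
    ROHParams,
    ROHSegment,
    detect_roh,
    oracle_detect_roh,
)
from rohscan.genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix

from conftest import make_gm, random_instance, random_params


def _seg_keys(segments):
    return {
        (s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.n_het, s.n_missing)
        for s in segments
    }


def test_clean_sixty_snp_run_is_one_segment():
    pos = np.arange(1, 61) * 10_000  # 60 SNPs spanning 590 kb, 10 kb gaps
    gm = make_gm(np.full(60, HOM_REF), pos)
    segs = detect_roh(gm, ROHParams())
    assert len(segs) == 1
    (s,) = segs
    assert (s.n_snps, s.n_het, s.n_missing) == (60, 0, 0)
    assert (s.start_bp, s.end_bp) == (10_000, 600_000)


def test_forty_nine_snps_is_no_segment():
    pos = np.arange(1, 50) * 10_000
    gm = make_gm(np.full(49, HOM_ALT), pos)
    assert detect_roh(gm, ROHParams()) == []


def test_gap_above_one_megabase_splits_runs():
    # two 60-SNP runs separated by a 1.2 Mb gap: must be two segments
    pos = np.concatenate([np.arange(1, 61) * 10_000,
                          1_800_000 + np.arange(60) * 10_000])
    gm = make_gm(np.full(120, HOM_REF), pos)
    segs = detect_roh(gm, ROHParams())
    assert len(segs) == 2
    assert segs[0].end_bp == 600_000 and segs[1].start_bp == 1_800_000


def test_het_budget_case_matches_oracle():
    # 120 hom SNPs with 4 het spread so no 50-SNP window holds <= 3
    rng = np.random.default_rng(0)
    calls = np.full(120, HOM_REF, dtype=np.int8)
    for i in (20, 50, 80, 110):
        calls[i] = HET
    pos = np.arange(1, 121) * 10_000
    gm = make_gm(calls, pos)
    params = ROHParams()
    assert _seg_keys(detect_roh(gm, params)) == _seg_keys(oracle_detect_roh(gm, params))


def test_missing_calls_are_neutral_not_terminating():
    # missing inside a run counts against the allowance but does not split it
    calls = np.full(60, HOM_REF, dtype=np.int8)
    calls[25] = MISSING
    calls[35] = MISSING
    gm = make_gm(calls, np.arange(1, 61) * 10_000)
    segs = detect_roh(gm, ROHParams())
    assert len(segs) == 1 and segs[0].n_missing == 2


def test_run_boundaries_are_homozygous():
    rng = np.random.default_rng(5)
    for _ in range(30):
        calls, pos = random_instance(rng, hom_bias=0.9)
        gm = make_gm(calls, pos)
        params = random_params(rng)
        for s in detect_roh(gm, params):
            i = int(np.searchsorted(pos, s.start_bp))
            j = int(np.searchsorted(pos, s.end_bp))
            assert calls[i] in (HOM_REF, HOM_ALT)
            assert calls[j] in (HOM_REF, HOM_ALT)


def test_all_het_input_yields_nothing():
    gm = make_gm(np.full(100, HET), np.arange(1, 101) * 10_000)
    assert oracle_detect_roh(gm, ROHParams()) == []
    assert detect_roh(gm, ROHParams()) == []


def test_all_hom_chromosome_single_full_span():
    pos = np.arange(1, 101) * 10_000  # 100 SNPs over ~1 Mb
    gm = make_gm(np.full(100, HOM_ALT), pos)
    segs = oracle_detect_roh(gm, ROHParams())
    assert len(segs) == 1
    assert (segs[0].start_bp, segs[0].end_bp, segs[0].n_snps) == (10_000, 1_000_000, 100)


def test_empty_matrix_empty_output():
    gm = make_gm(np.empty((1, 0), dtype=np.int8), [])
    assert detect_roh(gm, ROHParams()) == []


def test_unsorted_positions_rejected():
    import pandas as pd

    with pytest.raises(ValueError, match="strictly increasing"):
        make_gm(np.full(3, HOM_REF), [300, 200, 100])


def test_oracle_guard():
    n = ORACLE_MAX_SNPS + 1
    gm = make_gm(np.full(n, HOM_REF), np.arange(1, n + 1) * 100)
    with pytest.raises(ValueError, match="guard"):
        oracle_detect_roh(gm)


def test_segment_invariants_hold(seed=3):
    rng = np.random.default_rng(seed)
    for _ in range(40):
        calls, pos = random_instance(rng)
        params = random_params(rng)
        gm = make_gm(calls, pos)
        prev_end = -1
        for s in detect_roh(gm, params):
            assert s.n_snps >= params.min_snps
            assert s.length_bp >= params.min_length_bp
            assert s.n_het <= params.max_het
            assert s.n_missing <= params.max_missing
            assert s.n_snps * 1000.0 >= params.min_density_snp_per_kb * s.length_bp
            i = int(np.searchsorted(pos, s.start_bp))
            j = int(np.searchsorted(pos, s.end_bp))
            assert np.diff(pos[i : j + 1]).max(initial=0) <= params.max_gap_bp
            assert s.start_bp > prev_end  # non-overlapping, sorted
            prev_end = s.end_bp


def test_oracle_equivalence_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(60):
        calls, pos = random_instance(rng)
        params = random_params(rng)
        gm = make_gm(calls, pos)
        assert _seg_keys(detect_roh(gm, params)) == _seg_keys(
            oracle_detect_roh(gm, params)
        ), f"divergence for params {params}"


def _covered_bp(segments):
    return sum(s.length_bp for s in segments)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.sampled_from([HOM_REF, HOM_ALT, HET, MISSING]),
            st.integers(min_value=1, max_value=60_000),
        ),
        min_size=2,
        max_size=70,
    ),
    min_snps=st.integers(2, 10),
    max_het=st.integers(0, 3),
    max_missing=st.integers(0, 3),
)
def test_scan_equals_oracle_property(data, min_snps, max_het, max_missing):
    """The linear scan and the exhaustive oracle are the same function."""
    calls = np.array([c for c, _ in data], dtype=np.int8)
    pos = np.cumsum([g for _, g in data])
    params = ROHParams(
        min_length_bp=30_000, min_snps=min_snps, max_het=max_het,
        max_missing=max_missing, min_density_snp_per_kb=0.03,
        max_gap_bp=300_000,
    )
    gm = make_gm(calls, pos)
    assert _seg_keys(detect_roh(gm, params)) == _seg_keys(oracle_detect_roh(gm, params))


def _candidate_union_bp(calls, pos, params):
    """bp covered by the union of ALL constraint-satisfying intervals,
    enumerated brute-force (independent of the caller's pruning)."""
    n = len(pos)
    hom = np.isin(calls, [HOM_REF, HOM_ALT])
    covered = np.zeros(n, dtype=bool)
    for i in range(n):
        if not hom[i]:
            continue
        n_het = n_miss = 0
        for j in range(i, n):
            if calls[j] == HET:
                n_het += 1
            if calls[j] == MISSING:
                n_miss += 1
            if n_het > params.max_het or n_miss > params.max_missing:
                break
            if j > i and pos[j] - pos[j - 1] > params.max_gap_bp:
                break
            length = pos[j] - pos[i] + 1
            if (
                hom[j]
                and j - i + 1 >= params.min_snps
                and length >= params.min_length_bp
                and (j - i + 1) * 1000.0 >= params.min_density_snp_per_kb * length
            ):
                covered[i : j + 1] = True
    idx = np.flatnonzero(covered)
    if len(idx) == 0:
        return 0
    # sum bp over maximal covered index runs
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    return sum(int(pos[r[-1]] - pos[r[0]] + 1) for r in runs)


def test_monotonicity_of_candidate_coverage():
    """Raising the het/missing allowances can only enlarge the set of
    satisfying intervals (and hence covered bp); raising the SNP-count or
    length minima can only shrink it.  (The greedy overlap resolution is
    deliberately excluded: a newly affordable early candidate may preempt a
    longer one, so post-resolution coverage is not monotone.)"""
    import dataclasses

    rng = np.random.default_rng(19)
    for _ in range(15):
        calls, pos = random_instance(rng, hom_bias=0.85)
        base = ROHParams(min_length_bp=20_000, min_snps=8, max_het=1,
                         max_missing=1, min_density_snp_per_kb=0.02,
                         max_gap_bp=400_000)
        cov = _candidate_union_bp(calls, pos, base)
        more_het = dataclasses.replace(base, max_het=3)
        more_miss = dataclasses.replace(base, max_missing=3)
        stricter_snps = dataclasses.replace(base, min_snps=15)
        stricter_len = dataclasses.replace(base, min_length_bp=80_000)
        assert _candidate_union_bp(calls, pos, more_het) >= cov
        assert _candidate_union_bp(calls, pos, more_miss) >= cov
        assert _candidate_union_bp(calls, pos, stricter_snps) <= cov
        assert _candidate_union_bp(calls, pos, stricter_len) <= cov


def test_output_invariant_to_sample_and_chrom_order(small_sim):
    _, gm, _, _ = small_sim
    segs = _seg_keys(detect_roh(gm))

    # reversed sample order
    order = list(range(gm.n_samples))[::-1]
    gm_rev = GenotypeMatrix(
        sample_ids=[gm.sample_ids[i] for i in order],
        sites=gm.sites.copy(),
        calls=gm.calls[order],
    )
    assert _seg_keys(detect_roh(gm_rev)) == segs

    # reversed chromosome block order
    blocks = gm.chrom_blocks()
    idx = np.concatenate([np.arange(a, b) for _, a, b in reversed(blocks)])
    gm_cr = GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        sites=gm.sites.iloc[idx].reset_index(drop=True),
        calls=gm.calls[:, idx],
    )
    assert _seg_keys(detect_roh(gm_cr)) == segs


def test_planted_segment_recovery_on_clean_sim():
    """On an error-free simulation with long planted segments, called bp and
    planted bp must reciprocally cover each other at >= 95%."""
    from rohscan.simulate import SimConfig, simulate_population

    cfg = SimConfig(
        chrom_lengths=[(f"chr{i}", 50_000_000) for i in range(1, 4)],
        groups=[("G", 8, 0.12)],
        segment_length_mean=3_000_000,
        segment_length_min=1_500_000,
        het_error_rate=0.0,
        missing_rate=0.0,
        seed=23,
    )
    gm, _, truth = simulate_population(cfg)
    segs = detect_roh(gm)
    pos = gm.sites["pos"].to_numpy()
    blocks = {c: (a, b) for c, a, b in gm.chrom_blocks()}

    def site_mask(intervals):
        m = np.zeros(gm.n_sites, dtype=bool)
        for c, s, e in intervals:
            a, b = blocks[c]
            i0 = a + np.searchsorted(pos[a:b], s, side="left")
            i1 = a + np.searchsorted(pos[a:b], e, side="right")
            m[i0:i1] = True
        return m

    spacing_bp = np.diff(pos).clip(max=100_000).mean()
    tot_called = tot_planted = tot_inter = 0.0
    for i, sid in enumerate(gm.sample_ids):
        called = site_mask(
            [(s.chrom, s.start_bp, s.end_bp) for s in segs if s.sample_id == sid]
        )
        planted = site_mask(truth.intervals[sid])
        tot_called += called.sum()
        tot_planted += planted.sum()
        tot_inter += (called & planted).sum()
    assert tot_inter / tot_planted >= 0.95   # recall in SNP-weighted bp
    assert tot_inter / tot_called >= 0.95    # precision
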