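"""Additive scoring, LD clumping, P+T and the threshold search."""

import numpy as np
import pandas as pd
import pytest

from stackprs.gwas import assoc_quantitative, make_split
from stackprs.io_formats import MISSING, GenotypeMatrix, SummaryStats, VariantInfo
from stackprs.prs_linear import (
    AlleleMismatchError,
    clump,
    pairwise_r2,
    prsice_search,
    pt_prs,
    score_prs,
)
from stackprs.simdata import TrueEffects, simulate_genotypes, simulate_phenotype
from conftest import stats_for, toy_matrix


# -- scoring -----------------------------------------------------------------


def test_worked_scoring_example():
    # one sample with dosages (0, 1, 2) across three variants
    g = toy_matrix(np.array([[0, 1, 2]], dtype=np.int8))
    stats = stats_for(g, beta=np.array([0.5, -0.2, 0.1]), p=np.full(3, 0.5))
    scores = score_prs(g, stats, g.vids)
    assert scores[0] == pytest.approx(0.0, abs=1e-15)


def test_zero_betas_zero_scores(rng):
    g = simulate_genotypes(30, 8, seed=1)
    stats = stats_for(g, beta=np.zeros(8))
    assert np.all(score_prs(g, stats, g.vids) == 0.0)


def test_scoring_additive_over_partitions(rng):
    g = simulate_genotypes(40, 10, seed=2)
    stats = stats_for(g, beta=rng.normal(size=10))
    vids = g.vids
    a, b = vids[:4], vids[4:]
    np.testing.assert_allclose(
        score_prs(g, stats, a) + score_prs(g, stats, b),
        score_prs(g, stats, vids), rtol=1e-12,
    )


def test_scoring_linear_in_betas(rng):
    g = simulate_genotypes(25, 5, seed=3)
    beta = rng.normal(size=5)
    s1 = score_prs(g, stats_for(g, beta=beta), g.vids)
    s2 = score_prs(g, stats_for(g, beta=2 * beta), g.vids)
    np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)


def test_swapped_alleles_count_other_dosage():
    g = toy_matrix(np.array([[0], [1], [2]], dtype=np.int8))
    t = stats_for(g, beta=np.array([1.0]), p=np.array([0.5])).table.copy()
    t.loc[0, ["a1", "a2"]] = ["G", "A"]  # swapped relative to the genotype A/G
    stats = SummaryStats(table=t)
    np.testing.assert_allclose(score_prs(g, stats, g.vids), [2.0, 1.0, 0.0])


def test_allele_mismatch_raises():
    g = toy_matrix(np.array([[0], [1]], dtype=np.int8))
    t = stats_for(g, beta=np.array([1.0]), p=np.array([0.5])).table.copy()
    t.loc[0, ["a1", "a2"]] = ["C", "T"]
    with pytest.raises(AlleleMismatchError, match="v0"):
        score_prs(g, SummaryStats(table=t), g.vids)


def test_missing_dosage_uses_fill(rng):
    g = toy_matrix(np.array([[MISSING], [2], [0]], dtype=np.int8))
    stats = stats_for(g, beta=np.array([1.0]), p=np.array([0.5]))
    scores = score_prs(g, stats, g.vids, missing_fill={"v0": 1.5})
    np.testing.assert_allclose(scores, [1.5, 2.0, 0.0])


# -- pairwise r² -------------------------------------------------------------


def test_r2_self_and_duplicate():
    g = simulate_genotypes(200, 2, block_size=1, seed=4)
    assert pairwise_r2(g, "snp000000", "snp000000") == pytest.approx(1.0)
    dup = GenotypeMatrix(
        np.repeat(g.genotypes[:, :1], 2, axis=1),
        [g.variants[0], VariantInfo("1", 999, "copy", "A", "G")],
        g.sample_ids,
    )
    assert pairwise_r2(dup, "snp000000", "copy") == pytest.approx(1.0)


def test_r2_independent_variants_small():
    g = simulate_genotypes(5000, 2, block_size=1, within_block_r=0.0, seed=5)
    assert pairwise_r2(g, "snp000000", "snp000001") < 0.01


# -- clumping ----------------------------------------------------------------


def clump_oracle(g, stats, idx, r2_threshold=0.1, window_kb=250.0):
    """Brute-force reference of the greedy rule, written independently."""
    srows = stats.indexed()
    remaining = sorted(
        g.vids,
        key=lambda v: (srows.loc[v, "p"], g.variants[g.vid_index()[v]].chrom,
                       g.variants[g.vid_index()[v]].pos, v),
    )
    vinfo = {v.vid: v for v in g.variants}
    retained = []
    removed = set()
    for vid in remaining:
        if vid in removed:
            continue
        retained.append(vid)
        for other in remaining:
            if other == vid or other in removed or other in retained:
                continue
            va, vb = vinfo[vid], vinfo[other]
            if va.chrom != vb.chrom or abs(va.pos - vb.pos) >= window_kb * 1000:
                continue
            if pairwise_r2(g, vid, other, idx) >= r2_threshold:
                removed.add(other)
    return retained


def test_clump_correlated_trio_keeps_best_p():
    g = simulate_genotypes(500, 3, block_size=3, within_block_r=0.95, seed=6)
    stats = stats_for(g, p=np.array([1e-10, 1e-9, 1e-12]))
    res = clump(g, stats)
    assert res.retained == [g.vids[2]]
    assert set(res.absorbed) == {g.vids[0], g.vids[1]}
    for removed, (index_vid, r2) in res.absorbed.items():
        assert index_vid == g.vids[2] and r2 >= 0.1


def test_clump_window_respected():
    # two perfectly correlated variants 300 kb apart -> both retained
    geno = np.repeat(np.random.default_rng(0).choice([0, 1, 2], (300, 1)), 2, axis=1).astype(np.int8)
    variants = [VariantInfo("1", 100_000, "a", "A", "G"), VariantInfo("1", 400_000, "b", "C", "T")]
    g = GenotypeMatrix(geno, variants, [f"s{i}" for i in range(300)])
    stats = stats_for(g, p=np.array([1e-8, 1e-6]))
    assert set(clump(g, stats).retained) == {"a", "b"}


def test_clump_matches_bruteforce_oracle(rng):
    for trial in range(15):
        g = simulate_genotypes(
            300, int(rng.integers(10, 60)), block_size=int(rng.integers(2, 8)),
            within_block_r=float(rng.uniform(0.3, 0.95)), seed=int(rng.integers(1e6)),
        )
        stats = stats_for(g, p=rng.uniform(1e-12, 1, g.n_variants))
        assert clump(g, stats).retained == clump_oracle(g, stats, None)


# -- P+T and threshold search ------------------------------------------------


def _additive_sim(seed, n=3000, m=120):
    g = simulate_genotypes(n, m, block_size=10, within_block_r=0.7, seed=seed)
    rng = np.random.default_rng(seed + 1)
    strong = [f"snp{j:06d}" for j in (m // 8, m // 3, m // 2, 2 * m // 3, 7 * m // 8)]
    weak = [f"snp{j:06d}" for j in range(0, m, 7) if f"snp{j:06d}" not in strong][:10]
    betas = {v: 1.0 for v in strong} | {v: 0.15 for v in weak}
    y, _, _ = simulate_phenotype(g, TrueEffects(additive_betas=betas, h2_target=0.5),
                                 "quantitative", noise_seed=seed + 2)
    split = make_split(y, "quantitative", seed=seed)
    stats = assoc_quantitative(g, y, split.train_idx)
    return g, y, split, stats, strong


def test_pt_empty_model_warns():
    g = simulate_genotypes(200, 10, seed=7)
    stats = stats_for(g, p=np.full(10, 0.5))
    y = np.random.default_rng(0).standard_normal(200)
    split = make_split(y, "quantitative", seed=0)
    with pytest.warns(UserWarning, match="all zero"):
        res = pt_prs(g, stats, split)
    assert res.retained == [] and np.all(res.scores == 0.0)


def test_pt_recovers_strong_blocks():
    g, y, split, stats, strong = _additive_sim(seed=31)
    res = pt_prs(g, stats, split, p_threshold=5e-8)
    # every strong causal's block contributes an index SNP
    retained_blocks = {int(v[3:]) // 10 for v in res.retained}
    strong_blocks = {int(v[3:]) // 10 for v in strong}
    assert strong_blocks <= retained_blocks


def test_pt_invariant_to_sample_order():
    g, y, split, stats, _ = _additive_sim(seed=13, n=800, m=60)
    res1 = pt_prs(g, stats, split, p_threshold=1e-4)
    perm = np.random.default_rng(3).permutation(g.n_samples)
    g2 = g.subset_samples(perm)
    res2 = pt_prs(g2, stats, split, p_threshold=1e-4)
    assert res1.retained == res2.retained
    np.testing.assert_allclose(res2.scores, res1.scores[perm])


def test_prsice_singleton_grid_equals_pt():
    g, y, split, stats, _ = _additive_sim(seed=17, n=1500, m=80)
    res = prsice_search(g, stats, split, y, "quantitative", grid=np.array([5e-8]))
    pt = pt_prs(g, stats, split, p_threshold=5e-8)
    assert res.retained == pt.retained
    np.testing.assert_allclose(res.test_scores, pt.scores[split.test_idx])


def test_prsice_returns_grid_maximum():
    g, y, split, stats, _ = _additive_sim(seed=23, n=1500, m=80)
    res = prsice_search(g, stats, split, y, "quantitative")
    best_metric = res.curve[res.best_threshold][1]
    assert best_metric == max(m for _, m in res.curve.values())


def test_prsice_all_empty_raises():
    g = simulate_genotypes(200, 10, seed=8)
    stats = stats_for(g, p=np.full(10, 0.9))
    y = np.random.default_rng(1).standard_normal(200)
    split = make_split(y, "quantitative", seed=1)
    with pytest.raises(ValueError, match="empty"):
        prsice_search(g, stats, split, y, "quantitative", grid=np.array([1e-8, 1e-6]))
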