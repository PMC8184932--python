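"""Union atlas, distance size factors, shrinkage NB Wald test."""

import numpy as np
import pandas as pd
import pytest

from hicnb import simulate
from hicnb.differential import (
    assemble_counts,
    build_union_atlas,
    distance_size_factors,
    filter_differential,
    nb_wald_test,
)


def make_calls(pairs, sig_mask):
    df = pd.DataFrame(pairs, columns=["chrom", "bin_i", "bin_j"])
    df["distance"] = (df["bin_j"] - df["bin_i"]) * 5000
    df["qvalue"] = np.where(sig_mask, 0.01, 0.9)
    return df


PAIRS = [("c", 0, 1), ("c", 0, 2), ("c", 1, 3), ("c", 2, 5)]


class TestUnionAtlas:
    def test_set_union(self):
        a = make_calls(PAIRS, [True, True, False, False])
        b = make_calls(PAIRS, [False, True, True, False])
        atlas = build_union_atlas({"A": a, "B": b})
        got = set(map(tuple, atlas[["bin_i", "bin_j"]].to_numpy()))
        assert got == {(0, 1), (0, 2), (1, 3)}

    def test_symmetric_in_condition_order(self):
        a = make_calls(PAIRS, [True, False, False, False])
        b = make_calls(PAIRS, [False, False, False, True])
        ab = build_union_atlas({"A": a, "B": b})
        ba = build_union_atlas({"B": b, "A": a})
        pd.testing.assert_frame_equal(ab, ba)

    def test_empty_atlas_warns(self):
        a = make_calls(PAIRS, [False] * 4)
        b = make_calls(PAIRS, [False] * 4)
        with pytest.warns(UserWarning, match="empty"):
            atlas = build_union_atlas({"A": a, "B": b})
        assert len(atlas) == 0

    def test_binning_mismatch_raises(self):
        a = make_calls(PAIRS, [True] * 4)
        b = make_calls(PAIRS[:3], [True] * 3)
        with pytest.raises(ValueError, match="universe"):
            build_union_atlas({"A": a, "B": b})


class TestSizeFactors:
    def test_doubled_sample_factor_ratio(self, replicate_sets):
        tables, cond_of, truth = replicate_sets
        s0 = next(iter(tables))
        doubled = {k: v.copy() for k, v in tables.items()}
        doubled[s0] = doubled[s0].copy()
        doubled[s0]["count"] = doubled[s0]["count"] * 2
        sf1 = distance_size_factors(tables).set_index(["sample", "distance"])
        sf2 = distance_size_factors(doubled).set_index(["sample", "distance"])
        ratio = (sf2["s_hat"] / sf1["s_hat"]).loc[s0]
        np.testing.assert_allclose(ratio.to_numpy(), 2.0)

    def test_identical_samples_identical_factors(self, replicate_sets):
        tables, _, _ = replicate_sets
        t = next(iter(tables.values()))
        sf = distance_size_factors({"a": t, "b": t.copy()})
        wide = sf.pivot(index="distance", columns="sample", values="s_hat")
        np.testing.assert_array_equal(wide["a"], wide["b"])

    def test_normalized_medians_agree_across_samples(self, replicate_sets):
        """Per-distance medians of normalized counts match across samples
        (definitional: each sample's median is divided out up to the common
        per-distance center)."""
        tables, _, _ = replicate_sets
        sf = distance_size_factors(tables)
        lut = sf.set_index(["sample", "distance"])["rel"]
        base = next(iter(tables.values()))
        d = base["distance"].to_numpy()
        meds = {}
        nz = None
        counts = {s: t["count"].to_numpy(float) for s, t in tables.items()}
        any_nz = np.logical_or.reduce([c > 0 for c in counts.values()])
        for s, c in counts.items():
            f = lut.loc[list(zip([s] * len(d), d))].to_numpy(float)
            norm = c / f
            med_d = pd.Series(norm[any_nz]).groupby(d[any_nz]).median()
            meds[s] = med_d
        ref = meds[next(iter(meds))]
        for s, m in meds.items():
            assert np.max(np.abs(m.to_numpy() - ref.to_numpy())) <= 1.0

    def test_all_zero_stratum_falls_back(self):
        # two samples with an empty long-range stratum
        rows = []
        for d, c in [(5000, 4), (10000, 2), (15000, 0)]:
            for i in range(6):
                rows.append(("c", i, i + d // 5000, d, c))
        t = pd.DataFrame(rows, columns=["chrom", "bin_i", "bin_j", "distance", "count"])
        sf = distance_size_factors({"a": t, "b": t.copy()})
        far = sf[(sf["sample"] == "a") & (sf["distance"] == 15000)]
        assert far["flagged"].item()
        assert far["s_hat"].item() == 2.0  # nearest valid shorter distance


@pytest.fixture(scope="module")
def wald_setup():
    tables, cond_of, truth, diff = simulate.simulate_replicates(
        seed=55, n_replicates=3, n_bins=400, d_max=400_000,
        n_diff=80, diff_log2fc=1.0, min_diff_mu=20.0)
    base = next(iter(tables.values()))
    rng = np.random.default_rng(1)
    pick = np.sort(rng.choice(len(base), 6000, replace=False))
    atlas = base.iloc[pick][["chrom", "bin_i", "bin_j", "distance"]]
    extra = diff[["chrom", "bin_i", "bin_j"]].merge(
        base[["chrom", "bin_i", "bin_j", "distance"]], on=["chrom", "bin_i", "bin_j"])
    atlas = (pd.concat([atlas, extra]).drop_duplicates(subset=["chrom", "bin_i", "bin_j"])
             .reset_index(drop=True))
    sf = distance_size_factors(tables)
    counts, samples = assemble_counts(tables, atlas)
    res = nb_wald_test(atlas, counts, samples, cond_of, sf)
    return tables, cond_of, atlas, sf, counts, samples, res, diff


class TestWald:
    def test_label_swap_negates_log2fc_exactly(self, wald_setup):
        tables, cond_of, atlas, sf, counts, samples, res, _ = wald_setup
        swapped = {s: ("cond2" if c == "cond1" else "cond1") for s, c in cond_of.items()}
        res2 = nb_wald_test(atlas, counts, samples, swapped, sf)
        np.testing.assert_allclose(res2["log2FC"].to_numpy(), -res["log2FC"].to_numpy(),
                                   atol=1e-9)

    def test_replicate_order_invariance(self, wald_setup):
        tables, cond_of, atlas, sf, counts, samples, res, _ = wald_setup
        order = [samples[1], samples[0]] + samples[2:]
        counts2 = counts[:, [samples.index(s) for s in order]]
        res2 = nb_wald_test(atlas, counts2, order, cond_of, sf)
        np.testing.assert_allclose(res2["stat"].to_numpy(), res["stat"].to_numpy(),
                                   atol=1e-9)

    def test_planted_changes_found_with_correct_sign(self, wald_setup):
        *_, res, diff = wald_setup
        key = set(map(tuple, diff[["bin_i", "bin_j"]].to_numpy()))
        is_p = np.array([(i, j) in key for i, j in zip(res["bin_i"], res["bin_j"])])
        disc = (res["qvalue"] < 0.05).to_numpy()
        assert disc[is_p].mean() > 0.7
        assert (res.loc[is_p & disc, "log2FC"] > 0).all()

    def test_single_pair_matches_statsmodels_oracle(self, wald_setup):
        import statsmodels.api as sm

        tables, cond_of, atlas, sf, counts, samples, res, _ = wald_setup
        labels = sorted(set(cond_of.values()))
        cvec = np.array([1.0 if cond_of[s] == labels[1] else 0.0 for s in samples])
        lut = sf.set_index(["sample", "distance"])["rel"]
        rng = np.random.default_rng(0)
        tested_rows = np.flatnonzero(res["tested"].to_numpy() &
                                     (res["baseMean"].to_numpy() > 5))
        for g in rng.choice(tested_rows, 5, replace=False):
            d = atlas["distance"].iloc[g]
            f = np.array([lut.loc[(s, d)] for s in samples])
            ynorm = counts[g] / f
            one = nb_wald_test(atlas.iloc[[g]], counts[[g]], samples, cond_of, sf,
                               shrink=False)
            alpha = one["dispersion"].item()
            X = np.column_stack([np.ones_like(cvec), cvec])
            fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-8))
            glm = sm.GLM(ynorm, X, family=fam).fit()
            z_oracle = glm.params[1] / glm.bse[1]
            assert one["stat"].item() == pytest.approx(z_oracle, abs=1e-6)

    def test_fewer_than_two_replicates_raises(self, wald_setup):
        tables, cond_of, atlas, sf, counts, samples, *_ = wald_setup
        bad = dict(cond_of)
        solo = samples[0]
        bad = {s: ("solo" if s == solo else "rest") for s in samples}
        with pytest.raises(ValueError, match="fewer than 2"):
            nb_wald_test(atlas, counts, samples, bad, sf)

    def test_all_zero_pairs_flagged_not_tested(self, wald_setup):
        tables, cond_of, atlas, sf, counts, samples, res, _ = wald_setup
        zero_rows = counts.sum(axis=1) == 0
        if zero_rows.any():
            assert res.loc[zero_rows, "pvalue"].isna().all()
            assert (~res.loc[zero_rows, "tested"]).all()


class TestFilter:
    def test_identity_thresholds(self, wald_setup):
        *_, res, _ = wald_setup
        full = filter_differential(res, fdr=1.0, min_abs_log2fc=0.0)
        assert len(full) == int(np.isfinite(res["qvalue"]).sum())

    def test_fold_change_threshold(self, wald_setup):
        *_, res, _ = wald_setup
        cut = np.log2(1.5)
        f = filter_differential(res, fdr=0.05, min_abs_log2fc=cut)
        assert (np.abs(f["log2FC"]) >= cut).all()
        assert (f["qvalue"] < 0.05).all()

    def test_idempotent(self, wald_setup):
        *_, res, _ = wald_setup
        once = filter_differential(res, fdr=0.1, min_abs_log2fc=0.3)
        twice = filter_differential(once, fdr=0.1, min_abs_log2fc=0.3)
        pd.testing.assert_frame_equal(once, twice)
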