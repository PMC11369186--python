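"""Alpha values, region statistics, DMR calling, ranking, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methylfrac import (
    ConfigError,
    MethylRead,
    Region,
    SimConfig,
    call_dmrs,
    cluster_samples,
    compute_alpha,
    filter_specific,
    region_auc,
    region_statistics,
    select_top_n,
    simulate_study,
)
from methylfrac.io import DataError
from methylfrac.regions import DMRCall, read_dmr_calls, write_dmr_calls


def mk_read(states, sample_id="s1"):
    """A read whose CpG states are given; sequence built to match."""
    seq = "".join("CGA" for _ in states) or "AAA"
    return MethylRead(
        "chr1", 0, "+", seq, [3 * i for i in range(len(states))], states, sample_id
    )


def mk_call(rid, delta, q=0.01, called=True, direction=None, chrom="chr1", start=0):
    region = Region(chrom, start, start + 100, rid)
    return DMRCall(
        region=region,
        kind="pDMR",
        statistic="p_hypo",
        direction=direction or ("hypo" if delta > 0 else "hyper"),
        delta=delta,
        p_value=q / 2,
        q_value=q,
        called=called,
        specific=True,
    )


class TestAlpha:
    def test_alpha_arithmetic(self):
        assert compute_alpha(mk_read([1, 0, 1, 1])).alpha == 0.75
        assert compute_alpha(mk_read([0, 0, 0])).alpha == 0.0

    def test_too_few_cpgs_excluded_not_zero_filled(self):
        assert compute_alpha(mk_read([1, 0]), min_cpgs=3) is None


class TestRegionStatistics:
    def test_proportion_of_hypo_reads(self):
        reads = [mk_read([0, 0, 0])] * 3 + [mk_read([1, 1, 1])] * 7
        stats = region_statistics({"r1": reads}, alpha_lo=0.2, min_reads=1)
        row = stats.iloc[0]
        assert row["p_hypo"] == pytest.approx(0.3)
        assert row["p_hyper"] == pytest.approx(0.7)

    def test_zero_reads_all_statistics_missing(self):
        stats = region_statistics({"r1": []}, samples=["s1"])
        row = stats.iloc[0]
        assert row["n_reads"] == 0
        assert np.isnan(row["mean_meth"]) and np.isnan(row["p_hypo"])

    def test_matches_brute_force_recomputation(self, small_study):
        from methylfrac import assign_reads_to_regions

        reads = [r for rs in small_study.reads.values() for r in rs]
        by_region = assign_reads_to_regions(reads, small_study.candidate_regions())
        stats = region_statistics(by_region, min_reads=1)
        for _, row in stats.sample(40, random_state=0).iterrows():
            sreads = [
                r for r in by_region[row["region_id"]] if r.sample_id == row["sample_id"]
            ]
            alphas = [
                sum(r.cpg_states) / len(r.cpg_states)
                for r in sreads
                if len(r.cpg_states) >= 3
            ]
            assert row["n_reads"] == len(alphas)
            assert row["p_hypo"] == pytest.approx(
                np.mean([a <= 0.2 for a in alphas])
            )
            assert row["p_hyper"] == pytest.approx(
                np.mean([a >= 0.8 for a in alphas])
            )
            total = sum(len(r.cpg_states) for r in sreads)
            meth = sum(sum(r.cpg_states) for r in sreads)
            assert row["mean_meth"] == pytest.approx(meth / total)

    def test_p_hypo_nondecreasing_in_alpha_lo(self, rng):
        reads = [
            mk_read(list(rng.integers(0, 2, size=rng.integers(3, 8))))
            for _ in range(300)
        ]
        values = [
            region_statistics({"r": reads}, alpha_lo=lo, alpha_hi=0.99, min_reads=1)
            .iloc[0]["p_hypo"]
            for lo in (0.1, 0.2, 0.4, 0.6)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestCallDmrs:
    @staticmethod
    def stats_from(case_vals, ctrl_vals, region_id="r1"):
        rows = []
        for i, v in enumerate(case_vals):
            rows.append(dict(region_id=region_id, sample_id=f"case{i}", p_hypo=v))
        for i, v in enumerate(ctrl_vals):
            rows.append(dict(region_id=region_id, sample_id=f"ctrl{i}", p_hypo=v))
        return pd.DataFrame(rows)

    @staticmethod
    def manifest_for(n_case, n_ctrl):
        return pd.DataFrame(
            dict(
                sample_id=[f"case{i}" for i in range(n_case)]
                + [f"ctrl{i}" for i in range(n_ctrl)],
                group=["tumor_tissue"] * n_case + ["normal_tissue"] * n_ctrl,
            )
        )

    def test_identical_groups_give_p_one_and_no_calls(self):
        stats = self.stats_from([0.5] * 5, [0.5] * 5)
        calls = call_dmrs(
            stats, self.manifest_for(5, 5), "tumor_tissue", "normal_tissue"
        )
        assert len(calls) == 1
        assert calls[0].p_value == 1.0 and not calls[0].called

    def test_missing_statistic_drops_sample_from_that_region_only(self):
        stats = self.stats_from([0.9, 0.8, np.nan, 0.85], [0.1, 0.2, 0.15, 0.1])
        calls = call_dmrs(
            stats, self.manifest_for(4, 4), "tumor_tissue", "normal_tissue",
            min_abs_delta=0.2, q_threshold=0.2,
        )
        assert len(calls) == 1  # region still tested on 3 vs 4 samples
        assert calls[0].delta == pytest.approx(np.mean([0.9, 0.8, 0.85]) - 0.1375)

    def test_absent_group_is_configuration_error(self):
        stats = self.stats_from([0.5], [0.5])
        with pytest.raises(ConfigError, match="pca_urine"):
            call_dmrs(stats, self.manifest_for(1, 1), "pca_urine", "normal_tissue")

    def test_planted_regions_recovered_with_direction(self):
        cfg = SimConfig(
            n_regions=40, n_informative=8, tissue_depth_x=8.0,
            n_tumor_tissue=8, n_normal_tissue=8, seed=31,
        )
        study = simulate_study(cfg, seed=31, cohorts=("tissue",))
        from methylfrac import assign_reads_to_regions

        reads = [r for rs in study.reads.values() for r in rs]
        by_region = assign_reads_to_regions(reads, study.candidate_regions())
        stats = region_statistics(by_region, samples=study.manifest["sample_id"].tolist())
        calls = call_dmrs(stats, study.manifest, "tumor_tissue", "normal_tissue")
        called = {c.region.id for c in calls if c.called}
        assert called == set(study.informative_ids)
        assert all(
            c.direction == "hypo" for c in calls if c.called
        )  # tumor-hypo is the planted direction


class TestSpecificity:
    def test_called_in_one_contrast_only_is_not_specific(self):
        a = [mk_call("r1", 0.5), mk_call("r2", 0.5)]
        b = [mk_call("r1", 0.4), mk_call("r2", 0.4, called=False)]
        specific = filter_specific(a, b)
        assert [c.region.id for c in specific] == ["r1"]

    def test_direction_conflict_is_not_specific(self):
        a = [mk_call("r1", 0.5, direction="hypo")]
        b = [mk_call("r1", -0.5, direction="hyper")]
        assert filter_specific(a, b) == []

    def test_conservative_delta_is_minimum_magnitude(self):
        (merged,) = filter_specific([mk_call("r1", 0.5)], [mk_call("r1", 0.3)])
        assert merged.delta == 0.3 and merged.specific

    def test_mismatched_universe_rejected(self):
        with pytest.raises(DataError):
            filter_specific([mk_call("r1", 0.5)], [mk_call("r2", 0.5)])


class TestSelection:
    def test_top_n_by_absolute_delta(self):
        calls = [mk_call(f"r{i}", d) for i, d in enumerate([0.3, 0.5, 0.1, 0.4, 0.2])]
        top = select_top_n(calls, "hypo", 3)
        assert [r.id for r in top] == ["r1", "r3", "r0"]

    def test_ties_break_by_q_then_coordinate(self):
        calls = [
            mk_call("b", 0.4, q=0.02, start=200),
            mk_call("a", 0.4, q=0.01, start=300),
            mk_call("c", 0.4, q=0.02, start=100),
        ]
        top = select_top_n(calls, "hypo", 3)
        assert [r.id for r in top] == ["a", "c", "b"]

    def test_shortfall_returns_available_with_warning(self):
        calls = [mk_call(f"r{i}", 0.3 + 0.01 * i) for i in range(3)]
        with pytest.warns(UserWarning, match="only 3 available"):
            top = select_top_n(calls, "hypo", 2000)
        assert len(top) == 3


class TestRegionAuc:
    @staticmethod
    def auc_by_pair_counting(case, ctrl):
        wins = sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in case for y in ctrl
        )
        return wins / (len(case) * len(ctrl))

    def test_perfect_separation_and_ties(self):
        stats = TestCallDmrs.stats_from([0.9, 0.8], [0.1, 0.2])
        manifest = TestCallDmrs.manifest_for(2, 2)
        assert region_auc(stats, manifest, "tumor_tissue", "normal_tissue")["r1"] == 1.0
        stats_tied = TestCallDmrs.stats_from([0.5, 0.5], [0.5, 0.5])
        assert (
            region_auc(stats_tied, manifest, "tumor_tissue", "normal_tissue")["r1"]
            == 0.5
        )

    def test_matches_exhaustive_pair_counting(self, rng):
        for _ in range(30):
            case = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=8)
            ctrl = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=8)
            stats = TestCallDmrs.stats_from(case, ctrl)
            auc = region_auc(
                stats, TestCallDmrs.manifest_for(8, 8), "tumor_tissue", "normal_tissue"
            )["r1"]
            assert auc == pytest.approx(self.auc_by_pair_counting(case, ctrl))


class TestClustering:
    def test_identical_samples_merge_at_zero_distance(self):
        m = pd.DataFrame(
            [[0.1, 0.2, 0.3], [0.1, 0.2, 0.3], [0.9, 0.8, 0.7]],
            index=["a", "b", "c"],
        )
        Z, labels = cluster_samples(m)
        assert Z[0, 2] == 0.0  # first merge at distance 0
        assert labels["a"] == labels["b"] != labels["c"]

    def test_planted_two_group_structure_recovered(self, rng):
        tumor = rng.normal(0.8, 0.03, size=(6, 12))
        normal = rng.normal(0.1, 0.03, size=(6, 12))
        m = pd.DataFrame(
            np.vstack([tumor, normal]),
            index=[f"t{i}" for i in range(6)] + [f"n{i}" for i in range(6)],
        )
        _, labels = cluster_samples(m, top_fraction=1.0)
        t_labels = set(labels[:6])
        n_labels = set(labels[6:])
        assert len(t_labels) == 1 and len(n_labels) == 1 and t_labels != n_labels

    def test_sample_order_does_not_change_tree(self, rng):
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        m = pd.DataFrame(rng.random((8, 10)), index=[f"s{i}" for i in range(8)])
        Z1, _ = cluster_samples(m)
        perm = rng.permutation(8)
        Z2, _ = cluster_samples(m.iloc[perm])
        d1 = pd.DataFrame(squareform(cophenet(Z1)), index=m.index, columns=m.index)
        permuted_index = m.index[perm]
        d2 = pd.DataFrame(
            squareform(cophenet(Z2)), index=permuted_index, columns=permuted_index
        )
        d2 = d2.loc[m.index, m.index]
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-10)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(DataError):
            cluster_samples(pd.DataFrame([[1.0, 2.0]], index=["only"]))


class TestSignalMonotonicity:
    def test_group_separation_grows_with_methylation_difference(self):
        seps = []
        for p_tumor in (0.6, 0.35, 0.1):  # widening gap below p_normal=0.9
            cfg = SimConfig(
                n_regions=12, n_informative=12, p_meth_tumor=p_tumor,
                tissue_depth_x=8.0, n_tumor_tissue=6, n_normal_tissue=6, seed=13,
            )
            study = simulate_study(cfg, seed=13, cohorts=("tissue",))
            from methylfrac import assign_reads_to_regions

            reads = [r for rs in study.reads.values() for r in rs]
            by_region = assign_reads_to_regions(reads, study.candidate_regions())
            stats = region_statistics(by_region)
            groups = dict(zip(study.manifest["sample_id"], study.manifest["group"]))
            stats["group"] = stats["sample_id"].map(groups)
            means = stats.groupby("group")["p_hypo"].mean()
            seps.append(means["tumor_tissue"] - means["normal_tissue"])
        assert seps[0] > 0 and seps[0] < seps[1] < seps[2]


class TestCallIO:
    def test_bed6plus_roundtrip(self, tmp_path):
        calls = [mk_call("r1", 0.42, q=0.003), mk_call("r2", -0.3, q=0.04)]
        path = tmp_path / "calls.tsv"
        write_dmr_calls(calls, path)
        back = read_dmr_calls(path)
        assert [c.region.id for c in back] == ["r1", "r2"]
        assert back[0].delta == pytest.approx(0.42)
        assert back[1].direction == "hyper"
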