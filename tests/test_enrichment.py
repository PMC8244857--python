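import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tissuelens as tl
from tissuelens.containers import ValidationError
from tissuelens.enrichment import DOWN, UP, QQReport


@pytest.fixture
def random_stats():
    rng = np.random.default_rng(12)
    return pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])


class TestGmt:
    def test_basic_parse(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SETA\tdesc\tg1\tg2\tg3\nSETB\tother\tg4\tg5\n")
        sets = tl.read_gmt(path)
        assert sets == {"SETA": ["g1", "g2", "g3"], "SETB": ["g4", "g5"]}

    def test_duplicate_set_name_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("SETA\td\tg1\tg2\tg3\nSETA\td\tg4\tg5\tg6\n")
        with pytest.raises(ValidationError, match="SETA"):
            tl.read_gmt(path)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("SETA\td\tg1\tg2\nonlyname\n")
        with pytest.raises(ValidationError, match=":2"):
            tl.read_gmt(path)

    def test_roundtrip_identity(self, tmp_path):
        sets = {"A": ["g1", "g2"], "B": ["g9", "g3", "g5"]}
        tl.write_gmt(sets, tmp_path / "rt.gmt")
        assert tl.read_gmt(tmp_path / "rt.gmt") == sets

    def test_duplicate_members_deduplicated(self, tmp_path):
        path = tmp_path / "dupm.gmt"
        path.write_text("SETA\td\tg1\tg1\tg2\n")
        assert tl.read_gmt(path)["SETA"] == ["g1", "g2"]


class TestCameraPr:
    def test_zero_correlation_reduces_to_two_sample_t(self, random_stats):
        members = list(random_stats.index[:30])
        res = tl.camera_pr(random_stats, {"S": members}, inter_gene_corr=0.0)
        inset = random_stats.loc[members]
        outset = random_stats.drop(members)
        t, p = stats.ttest_ind(inset, outset, equal_var=True)
        assert res.loc["S", "t"] == pytest.approx(t, abs=1e-10)
        assert res.loc["S", "p"] == pytest.approx(p, abs=1e-10)

    def test_top_block_has_smallest_p_among_rank_windows(self):
        """On a 50-gene toy, the set of the m largest statistics beats every
        contiguous rank window of the same size."""
        rng = np.random.default_rng(13)
        vals = pd.Series(np.sort(rng.normal(size=50)), index=[f"g{i}" for i in range(50)])
        m = 8
        windows = {
            f"W{k}": list(vals.index[k : k + m]) for k in range(0, 50 - m + 1)
        }
        res = tl.directionalize(tl.camera_pr(vals, windows, inter_gene_corr=0.01), UP)
        # the last window holds the m largest values
        assert res["directional_p"].idxmin() == f"W{50 - m}"

    def test_monotone_linear_invariance(self, random_stats):
        sets = {"S": list(random_stats.index[10:60])}
        res = tl.camera_pr(random_stats, sets)
        res2 = tl.camera_pr(3.0 * random_stats + 7.0, sets)
        assert res.loc["S", "p"] == pytest.approx(res2.loc["S", "p"], abs=1e-12)
        assert res.loc["S", "direction"] == res2.loc["S", "direction"]

    def test_vif_monotonicity(self, random_stats):
        sets = {"S": list(random_stats.index[:40])}
        ps = [
            tl.camera_pr(random_stats, sets, inter_gene_corr=rho).loc["S", "p"]
            for rho in (0.0, 0.01, 0.05, 0.2)
        ]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_small_sets_skipped(self, random_stats):
        res = tl.camera_pr(random_stats, {"tiny": ["g0"], "ok": list(random_stats.index[:5])})
        assert list(res.index) == ["ok"]

    def test_matches_limma_camerapr(self, tmp_path, random_stats):
        """Independent oracle: Bioconductor limma's pre-ranked camera."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(14)
        sets = {
            f"S{k}": list(rng.choice(random_stats.index, int(rng.integers(5, 50)), replace=False))
            for k in range(6)
        }
        random_stats.to_csv(tmp_path / "stats.tsv", sep="\t", header=["stat"])
        tl.write_gmt(sets, tmp_path / "sets.gmt")
        script = tmp_path / "camera.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            st <- read.delim(args[1], row.names=1)
            stat <- setNames(st$stat, rownames(st))
            lines <- strsplit(readLines(args[2]), "\\t")
            sets <- lapply(lines, function(x) x[-(1:2)])
            names(sets) <- sapply(lines, `[`, 1)
            idx <- ids2indices(sets, names(stat))
            res <- cameraPR(stat, idx, inter.gene.cor=0.01, sort=FALSE)
            write.table(data.frame(set=rownames(res), p=res$PValue, dir=res$Direction),
                        args[3], sep="\\t", row.names=FALSE, quote=FALSE)
            """
        )
        out = tmp_path / "r_res.tsv"
        subprocess.run(
            ["Rscript", str(script), str(tmp_path / "stats.tsv"),
             str(tmp_path / "sets.gmt"), str(out)],
            check=True, capture_output=True,
        )
        r_res = pd.read_csv(out, sep="\t").set_index("set")
        py_res = tl.camera_pr(random_stats, sets, inter_gene_corr=0.01)
        for name in sets:
            assert py_res.loc[name, "p"] == pytest.approx(r_res.loc[name, "p"], rel=1e-6)
            assert py_res.loc[name, "direction"] == r_res.loc[name, "dir"].lower()


class TestDirectionalize:
    def test_masks_only_opposite_direction(self):
        res = pd.DataFrame(
            {"direction": [UP, DOWN, UP], "p": [0.01, 0.02, 0.03]},
            index=["A", "B", "C"],
        )
        out = tl.directionalize(res, UP)
        assert list(out["directional_p"]) == [0.01, 1.0, 0.03]
        out_all = tl.directionalize(res.assign(direction=UP), UP)
        assert list(out_all["directional_p"]) == [0.01, 0.02, 0.03]
        out_none = tl.directionalize(res.assign(direction=DOWN), UP)
        assert (out_none["directional_p"] == 1.0).all()


class TestSpecificityFilter:
    def test_order_statistics(self):
        spec = pd.Series(np.arange(1.0, 11.0), index=[f"g{i}" for i in range(10)])
        kept = tl.filter_by_specificity(spec, 0.2, "remove_most_specific")
        assert set(spec.index) - set(kept) == {"g8", "g9"}
        kept_low = tl.filter_by_specificity(spec, 0.2, "remove_least_specific")
        assert set(spec.index) - set(kept_low) == {"g0", "g1"}

    def test_ceiling_drops_at_least_one(self):
        spec = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        kept = tl.filter_by_specificity(spec, 0.001, "remove_most_specific")
        assert len(kept) == 9

    def test_both_tails_leave_sixty_percent(self):
        spec = pd.Series(np.arange(100.0), index=[f"g{i}" for i in range(100)])
        kept = tl.filter_by_specificity(spec, 0.2, "remove_most_specific")
        kept2 = tl.filter_by_specificity(spec.loc[kept], 0.25, "remove_least_specific")
        assert len(kept2) == 60

    def test_invalid_fraction(self):
        spec = pd.Series([1.0, 2.0])
        for frac in (0.0, 1.0, -0.5):
            with pytest.raises(ValidationError):
                tl.filter_by_specificity(spec, frac)


class TestTissueDeFilter:
    def test_all_neutral(self):
        nm = pd.DataFrame({"a": [2.0, 3.0], "b": [2.0, 3.0]}, index=["g1", "g2"])
        assert len(tl.filter_by_tissue_de(nm, "a", "b", keep="neutral")) == 2
        with pytest.raises(ValidationError):
            tl.filter_by_tissue_de(nm, "a", "b", keep="extreme")

    def test_threshold_example(self):
        nm = pd.DataFrame(
            {"a": [0.4, 1.0, 3.0], "b": [1.0, 1.0, 1.0]}, index=["g1", "g2", "g3"]
        )
        kept = tl.filter_by_tissue_de(nm, "a", "b", keep="neutral")
        assert list(kept) == ["g2"]
        kept_x = tl.filter_by_tissue_de(nm, "a", "b", keep="extreme")
        assert list(kept_x) == ["g1", "g3"]

    def test_top_sets_diverge_after_neutral_filter(self, default_cohort, default_stats):
        """Comparative-cancer rankings: without filtering, the top gene sets
        for cancer-a-vs-cancer-b mirror the tissue-a-vs-tissue-b sets; after
        removing normal-DE genes the overlap shrinks."""
        truth = default_cohort[4]
        cm = default_stats["cancer_means"]
        nm = default_stats["normal_means"]
        ca, cb = cm.values.columns[:2]
        ta, tb = default_stats["pairing"][ca], default_stats["pairing"][cb]
        sets = tl.generate_gene_sets(truth, list(cm.gene_ids), seed=21)
        cancer_fc = pd.Series(
            np.log2(cm.values[ca] / cm.values[cb]), index=cm.gene_ids
        )
        normal_fc = pd.Series(
            np.log2(nm.values[ta] / nm.values[tb]), index=nm.gene_ids
        )
        kept = tl.filter_by_tissue_de(nm.values, ta, tb, keep="neutral")

        def top10(stats_col):
            res = tl.camera_pr(stats_col, sets)
            return set(res["p"].nsmallest(10).index)

        unfiltered, tissue_ranked = top10(cancer_fc), top10(normal_fc)
        filtered = top10(cancer_fc.loc[kept])
        assert len(filtered & tissue_ranked) < len(unfiltered & tissue_ranked)


class TestQqCompare:
    def test_identical_lists(self):
        p = np.linspace(0.01, 1.0, 50)
        report = tl.qq_compare(p, p)
        assert report.improvement_fraction == 0.0
        np.testing.assert_allclose(report.quantiles_all, report.quantiles_filtered)

    def test_halved_p_values_dominate(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(0.01, 1, 100)
        report = tl.qq_compare(p, p / 2)
        assert report.improvement_fraction == 1.0

    def test_null_improvement_near_half(self):
        rng = np.random.default_rng(16)
        fracs = [
            tl.qq_compare(rng.uniform(size=1000), rng.uniform(size=1000)).improvement_fraction
            for _ in range(50)
        ]
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_unequal_lengths_interpolated(self):
        report = tl.qq_compare(np.linspace(0.1, 1, 10), np.linspace(0.05, 0.5, 7))
        assert isinstance(report, QQReport)
        assert len(report.quantiles_all) == len(report.quantiles_filtered) == 10
        assert (np.diff(report.quantiles_all) >= 0).all()
        assert (np.diff(report.quantiles_filtered) >= 0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            tl.qq_compare([0.5, 0.0], [0.5])
        with pytest.raises(ValidationError):
            tl.qq_compare([], [0.5])
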