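import hashlib

import numpy as np
import pandas as pd
import pytest

from selprof import (CutConfig, SelectivityConfig, build_matrices,
                     compute_selectivities, curate, run_profile,
                     score_clusters, select_pair_subset,
                     select_selective_clusters, simulate, sr_envelope,
                     ti_sr_table, write_fixture)
from selprof.datamodel import ClusterReport, LigandEntry
from selprof.selectivity import LigandClass, LigandSelectivity, selectivity_ratio
from selprof.synthetic import SimScenario, generate_scaffold_series


def entry(cid, ki):
    return LigandEntry(cid, "NS(=O)(=O)c1ccccc1", ki)


class TestSelectPairSubset:
    def test_only_dually_measured_survive(self, ix_ii_config):
        dual = [entry(f"D{i}", {"hCA IX": 5.0, "hCA II": 50.0})
                for i in range(10)]
        single = [entry(f"S{i}", {"hCA IX": 5.0}) for i in range(5)]
        subset = select_pair_subset(dual + single, ix_ii_config)
        assert [e.cid for e in subset] == [e.cid for e in dual]

    def test_identity_when_all_dual(self, ix_ii_config):
        dual = [entry(f"D{i}", {"hCA IX": 5.0, "hCA II": 50.0})
                for i in range(4)]
        assert select_pair_subset(dual, ix_ii_config) == dual

    def test_double_mode_requires_secondary_ki(self):
        cfg = SelectivityConfig(on_target="hCA IX", off_target="hCA II",
                                secondary_on_target="hCA XII")
        triple = entry("T", {"hCA IX": 1.0, "hCA II": 1.0, "hCA XII": 1.0})
        dual = entry("D", {"hCA IX": 1.0, "hCA II": 1.0})
        other = entry("T2", {"hCA IX": 1.0, "hCA II": 1.0, "hCA XII": 2.0})
        assert [e.cid for e in select_pair_subset([triple, dual, other], cfg)] \
            == ["T", "T2"]

    def test_too_few_survivors_is_error(self, ix_ii_config):
        with pytest.raises(ValueError, match="nothing to cluster"):
            select_pair_subset([entry("S", {"hCA IX": 1.0})], ix_ii_config)


class TestTiSrTable:
    def _subset(self, n=4):
        return [entry(f"C{i}", {"hCA IX": 1.0 + i, "hCA II": 50.0})
                for i in range(n)]

    def test_pair_count(self, ix_ii_config):
        subset = self._subset(4)
        sim, _ = build_matrices(subset, "keys")
        assert len(ti_sr_table(subset, sim, ix_ii_config)) == 6

    def test_uniform_si_means_zero_sr(self, ix_ii_config):
        subset = [entry(f"C{i}", {"hCA IX": 2.0, "hCA II": 50.0})
                  for i in range(4)]
        sim, _ = build_matrices(subset, "keys")
        assert (ti_sr_table(subset, sim, ix_ii_config).sr == 0.0).all()

    def test_rows_match_direct_double_loop(self, default_dataset,
                                           ix_ii_config):
        records, _ = default_dataset
        entries, _ = curate(records)
        subset = select_pair_subset(entries, ix_ii_config)
        sim, _ = build_matrices(subset, "path")
        table = ti_sr_table(subset, sim, ix_ii_config)
        sel = compute_selectivities(subset, ix_ii_config)
        idx = {e.cid: i for i, e in enumerate(subset)}
        for row in table.itertuples():
            assert row.ti == pytest.approx(
                sim.values[idx[row.cid_a], idx[row.cid_b]])
            assert row.sr == pytest.approx(
                selectivity_ratio(sel[row.cid_a].si, sel[row.cid_b].si))


class TestSrEnvelope:
    def test_high_similarity_bin_with_zero_sr(self):
        table = pd.DataFrame({"cid_a": ["a"] * 3, "cid_b": ["b"] * 3,
                              "ti": [0.9, 0.95, 0.85], "sr": [0.0, 0.0, 0.0]})
        env = sr_envelope(table)
        hi = env[env.ti_lo == 0.8].iloc[0]
        assert hi["count"] == 3 and hi.max_abs_sr == 0.0

    def test_empty_bin_marked_undefined(self):
        table = pd.DataFrame({"cid_a": ["a"], "cid_b": ["b"],
                              "ti": [0.9], "sr": [1.0]})
        env = sr_envelope(table)
        low = env[env.ti_lo == 0.0].iloc[0]
        assert low["count"] == 0 and np.isnan(low.max_abs_sr)

    def test_funnel_property_on_planted_data(self, fixture_csv):
        result = run_profile(fixture_csv, scheme="path")
        env = sr_envelope(result.pair_table)
        low, hi = env.iloc[0], env.iloc[-1]
        assert hi.max_abs_sr <= low.max_abs_sr

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            sr_envelope(pd.DataFrame(columns=["ti", "sr"]))


def _sel(cids, klass, si):
    return {c: LigandSelectivity(c, si, klass) for c in cids}


class TestScoreClusters:
    def test_pure_on_cluster_scores_100(self):
        cids = [f"C{i}" for i in range(41)]
        reports = score_clusters([cids], _sel(cids, LigandClass.L_ON, 40.0))
        assert reports[0].s_score == 100.0
        assert reports[0].counts == (41, 0, 0)

    def test_even_split_scores_zero(self):
        cids = [f"C{i}" for i in range(6)]
        sel = _sel(cids[:3], LigandClass.L_ON, 10.0)
        sel.update(_sel(cids[3:], LigandClass.L_OFF, 0.1))
        assert score_clusters([cids], sel)[0].s_score == 0.0

    def test_double_mode_sums_scores(self):
        cids = [f"C{i}" for i in range(5)]
        sel = _sel(cids, LigandClass.L_ON, 40.0)
        reports = score_clusters([cids], sel, sel)
        assert reports[0].double_s_score == 200.0

    def test_member_without_si_is_named(self):
        with pytest.raises(KeyError, match="GHOST"):
            score_clusters([["GHOST"]], {})


class TestSelectSelectiveClusters:
    def _report(self, cid, score, double=None):
        n = 10
        n_on = int(round(n * (score + 100) / 200))
        counts = (n_on, n - n_on, 0)
        from selprof.selectivity import s_score
        return ClusterReport(cid, [f"x{cid}_{i}" for i in range(n)], counts,
                             s_score(*counts),
                             s_score_secondary=None if double is None
                             else double - s_score(*counts),
                             double_s_score=double)

    def test_strict_cutoff(self):
        cfg = SelectivityConfig(on_target="a", off_target="b")
        reports = [self._report(i + 1, s)
                   for i, s in enumerate([100, 80, 60, -100])]
        kept = select_selective_clusters(reports, cfg)
        assert [r.s_score for r in kept] == [100.0, 80.0]

    def test_cutoff_zero_keeps_positive_scores(self):
        cfg = SelectivityConfig(on_target="a", off_target="b",
                                s_score_cutoff=0.0)
        reports = [self._report(i + 1, s) for i, s in enumerate([40, -20, 0])]
        kept = select_selective_clusters(reports, cfg)
        assert [r.s_score for r in kept] == [40.0]

    def test_double_mode_uses_twice_the_cutoff(self):
        cfg = SelectivityConfig(on_target="a", off_target="b",
                                secondary_on_target="c")
        reports = [self._report(1, 100, double=200.0),
                   self._report(2, 80, double=150.0),
                   self._report(3, 60, double=120.0)]
        kept = select_selective_clusters(reports, cfg)
        assert [r.double_s_score for r in kept] == [200.0, 150.0]


class TestRunProfile:
    def test_planted_on_selective_family_is_the_selective_cluster(
            self, fixture_csv):
        result = run_profile(fixture_csv)
        series = generate_scaffold_series(SimScenario())
        on_cids = {c for s in series if s.klass == "on_selective"
                   for c in s.cids}
        prom_cids = {c for s in series if s.klass == "promiscuous"
                     for c in s.cids}
        assert len(result.selective) == 1
        top = result.selective[0]
        assert top.s_score == 100.0
        assert set(top.members) <= on_cids
        selective_members = {c for r in result.selective for c in r.members}
        assert not selective_members & prom_cids

    def test_only_nonselective_ligands_give_empty_report(self, tmp_path):
        scenario = SimScenario(
            scaffold_classes=("promiscuous",), noise_sd=1e-6,
            outlier_rate=0.0, decoy_rate=0.0, seed=1)
        records, _ = simulate(scenario)
        p = tmp_path / "prom.csv"
        write_fixture(records, p)
        result = run_profile(p)
        assert result.selective == []

    def test_cluster_members_cover_the_subset(self, fixture_csv):
        result = run_profile(fixture_csv, cut_config=CutConfig(
            height_ratio=0.3, min_cluster_size=1))
        member_count = sum(len(c) for c in result.clusters)
        assert member_count == len(result.subset)

    def test_rerun_is_byte_identical(self, fixture_csv, tmp_path):
        digests = []
        for run in ("a", "b"):
            outdir = tmp_path / run
            run_profile(fixture_csv, outdir=outdir)
            h = hashlib.sha256()
            for f in sorted(outdir.iterdir()):
                h.update(f.name.encode())
                h.update(f.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_double_mode_end_to_end(self, tmp_path):
        scenario = SimScenario(secondary_on_target="hCA XII", seed=5)
        records, _ = simulate(scenario)
        p = tmp_path / "double.csv"
        write_fixture(records, p)
        cfg = SelectivityConfig(on_target="hCA IX", off_target="hCA II",
                                secondary_on_target="hCA XII")
        result = run_profile(p, selectivity_config=cfg, outdir=tmp_path / "o")
        assert result.pair_table is None  # SR only defined for single pairs
        assert all(r.double_s_score is not None for r in result.reports)
        assert any(r.double_s_score == 200.0 for r in result.selective)
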