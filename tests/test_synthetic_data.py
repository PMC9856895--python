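"""Seeded generators: determinism, planted structure, count-model calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riplab.behavior_stats import courtship_index, learning_index
from riplab.cpe_scan import DEFAULT_MOTIFS, census, scan_motifs
from riplab.errors import ConfigurationError, GenerationError
from riplab.synthetic_data import (
    BehaviorSimConfig,
    RipSimConfig,
    UtrSimConfig,
    WesternSimConfig,
    _nb_counts,
    simulate_courtship,
    simulate_ripseq,
    simulate_utr,
    simulate_western,
)


class TestDeterminism:
    def test_ripseq_same_seed_byte_identical(self):
        cfg = RipSimConfig(n_genes=200, n_targets=20, seed=7)
        counts_a, truth_a = simulate_ripseq(cfg)
        counts_b, truth_b = simulate_ripseq(cfg)
        pd.testing.assert_frame_equal(counts_a, counts_b)
        assert truth_a.target_ids == truth_b.target_ids

    def test_ripseq_different_seed_differs(self):
        a, _ = simulate_ripseq(RipSimConfig(n_genes=200, n_targets=20, seed=1))
        b, _ = simulate_ripseq(RipSimConfig(n_genes=200, n_targets=20, seed=2))
        assert not a.equals(b)

    def test_courtship_and_western_and_utr_deterministic(self):
        bc = BehaviorSimConfig(n_per_group=5, seed=3)
        assert [o.bouts for o in simulate_courtship(bc)] == [
            o.bouts for o in simulate_courtship(bc)
        ]
        wc = WesternSimConfig(seed=3)
        pd.testing.assert_frame_equal(simulate_western(wc), simulate_western(wc))
        uc = UtrSimConfig(length=500, planted=(("TTTTAT", 2),), seed=3)
        assert simulate_utr(uc) == simulate_utr(uc)


class TestSimulateRipseq:
    def test_library_sizes_within_sampling_error(self):
        cfg = RipSimConfig(n_genes=1000, n_targets=50, seed=11)
        counts, _ = simulate_ripseq(cfg)
        for col, lib in zip(("input", "ip", "mock_ip"), cfg.library_sizes):
            # the column total is a sum of independent NB draws around lib
            assert abs(counts[col].sum() - lib) < 0.05 * lib

    def test_no_planted_signal_when_enrichments_are_one(self):
        cfg = RipSimConfig(
            n_genes=800, n_targets=0, control_enrichment=1.0,
            dispersion=0.0, seed=13,
        )
        counts, truth = simulate_ripseq(cfg)
        assert truth.target_ids == frozenset()
        # Poisson counts, equal libraries: per-gene IP/Input ratio centred on 1
        big = counts[(counts["input"] > 200) & (counts["ip"] > 0)]
        ratios = big["ip"] / big["input"]
        assert abs(np.log(ratios).mean()) < 0.05

    def test_poisson_limit_recovers_planted_fold_change(self):
        # dispersion 0, equal libraries, enrichment 4.  The IP library total
        # is inflated by the enriched mass, which deflates every gene's
        # IP/Input CPM ratio by the same factor, so the target-over-nontarget
        # ratio of mean CPM ratios is exactly the planted fold-change.
        gaps = []
        for seed in range(20):
            cfg = RipSimConfig(
                n_genes=500, n_targets=50, target_enrichment_ip=4.0,
                control_enrichment=1.0, dispersion=0.0, seed=seed,
            )
            counts, truth = simulate_ripseq(cfg)
            cpm = 1e6 * counts[["input", "ip"]] / counts[["input", "ip"]].sum(axis=0)
            big = counts["input"] > 50
            is_tgt = counts.index.isin(truth.target_ids)
            log_ratio = np.log(cpm["ip"] / cpm["input"])
            gaps.append(
                log_ratio[big & is_tgt].mean() - log_ratio[big & ~is_tgt].mean()
            )
        assert np.exp(np.mean(gaps)) == pytest.approx(4.0, rel=0.03)

    def test_truth_roles_and_disjointness(self):
        counts, truth = simulate_ripseq(RipSimConfig(n_genes=300, n_targets=30, seed=5))
        assert truth.target_ids.isdisjoint(truth.negative_control_ids)
        assert truth.positive_control_ids == {"orb2", "act5C", "tub56D"}
        assert counts.loc["28S", "biotype"] == "other"
        assert counts.loc["RplP0", "biotype"] == "protein_coding"
        assert all(counts.loc[sorted(truth.target_ids), "biotype"] == "protein_coding")

    def test_negative_binomial_mean_variance_calibration(self):
        # chi-square dispersion test on a 1000-gene batch of equal means:
        # sum((x - mu)^2 / (mu + d mu^2)) ~ chi2(n) under the NB model
        rng = np.random.default_rng(17)
        mu, d, n = 150.0, 0.1, 1000
        draws = _nb_counts(rng, np.full(n, mu), d)
        statistic = np.sum((draws - mu) ** 2 / (mu + d * mu**2))
        p = stats.chi2.sf(statistic, df=n)
        assert 0.01 < p  # not rejected at alpha = 0.01
        assert stats.chi2.cdf(statistic, df=n) > 0.01

    def test_invalid_configs_name_the_field(self):
        with pytest.raises(ConfigurationError, match="n_targets"):
            RipSimConfig(n_genes=10, n_targets=8)
        with pytest.raises(ConfigurationError, match="library_sizes"):
            RipSimConfig(library_sizes=(0, 1, 1))
        with pytest.raises(ConfigurationError, match="enrichment"):
            RipSimConfig(target_enrichment_ip=0.5)
        with pytest.raises(ConfigurationError, match="dispersion"):
            RipSimConfig(dispersion=-1.0)


class TestSimulateCourtship:
    def test_counts_and_bounds(self):
        obs = simulate_courtship(BehaviorSimConfig(n_per_group=20, seed=2))
        assert len(obs) == 40
        assert {o.group for o in obs} == {"naive", "trained"}
        for o in obs:
            for start, end in o.bouts:
                assert 0.0 <= start < end <= 300.0

    def test_noise_free_limit_gives_li_fifty(self):
        obs = simulate_courtship(
            BehaviorSimConfig(
                ci_mean_naive=0.6, ci_mean_trained=0.3,
                ci_concentration=float("inf"), seed=1,
            )
        )
        naive = [courtship_index(o) for o in obs if o.group == "naive"]
        trained = [courtship_index(o) for o in obs if o.group == "trained"]
        res = learning_index([naive], [trained])
        assert res.LI == pytest.approx(50.0)

    def test_null_simulation_li_centred_on_zero(self):
        lis = []
        for seed in range(500):
            obs = simulate_courtship(
                BehaviorSimConfig(
                    n_per_group=10, ci_mean_naive=0.45, ci_mean_trained=0.45,
                    seed=seed,
                )
            )
            naive = [courtship_index(o) for o in obs if o.group == "naive"]
            trained = [courtship_index(o) for o in obs if o.group == "trained"]
            lis.append(learning_index([naive], [trained]).LI)
        assert abs(np.mean(lis)) < 3.0  # percentage points

    def test_invalid_mean_rejected(self):
        with pytest.raises(ConfigurationError, match="ci_mean_trained"):
            BehaviorSimConfig(ci_mean_trained=1.2)


class TestSimulateWestern:
    def test_noise_free_signals_proportional_to_load(self):
        table = simulate_western(WesternSimConfig(true_level_wt=2.0, cv=0.0, seed=0))
        wt = table[table["genotype"] == "wt"]
        assert np.allclose(wt["chemi_signal"], 2.0 * wt["relative_load"])
        assert np.allclose(wt["total_protein_signal"], wt["relative_load"])

    def test_default_ladder_is_one_over_2_4_6(self):
        table = simulate_western(WesternSimConfig(seed=0))
        one_series = table[
            (table["genotype"] == "wt") & (table["replicate"] == 1)
        ]
        assert list(one_series["relative_load"]) == [1 / 2, 1 / 4, 1 / 6]
        assert len(one_series) == 3

    def test_replicate_count(self):
        table = simulate_western(WesternSimConfig(n_replicates=4, seed=0))
        assert table.groupby("genotype")["replicate"].nunique().tolist() == [4, 4]

    def test_invalid_configs(self):
        with pytest.raises(ConfigurationError, match="loads"):
            WesternSimConfig(loads=(0.5, 0.0))
        with pytest.raises(ConfigurationError, match="n_replicates"):
            WesternSimConfig(n_replicates=1)
        with pytest.raises(ConfigurationError, match="cv"):
            WesternSimConfig(cv=-0.1)


class TestSimulateUtr:
    def test_planted_counts_found_exactly(self):
        seq, placements = simulate_utr(
            UtrSimConfig(length=1000, planted=(("TTTTAT", 3),), seed=4)
        )
        assert len(seq) == 1000
        hits = scan_motifs(seq, DEFAULT_MOTIFS)
        assert [h.start for h in hits] == [p for p, _ in placements]
        assert census(seq, DEFAULT_MOTIFS).n_canonical == 3

    def test_empty_plant_is_motif_free(self):
        seq, placements = simulate_utr(UtrSimConfig(length=2000, planted=(), seed=9))
        assert placements == []
        assert census(seq, DEFAULT_MOTIFS).n_total == 0

    def test_background_screen_verified_by_naive_substring_scan(self):
        seq, placements = simulate_utr(
            UtrSimConfig(length=3000, planted=(("TTTTAT", 5), ("TTTTGT", 4)), seed=6)
        )
        expected = {p for p, _ in placements}
        for pattern in DEFAULT_MOTIFS.all_patterns():
            found = {
                i for i in range(len(seq) - len(pattern) + 1)
                if seq[i : i + len(pattern)] == pattern
            }
            assert found <= expected

    def test_isoform_scale_census_replica(self):
        # a synthetic 5794-nt 3'UTR carrying 22 canonical + 15 noncanonical
        # planted sites, the scale of the longest natural isoform
        seq, _ = simulate_utr(
            UtrSimConfig(length=5794, planted=(("TTTTAT", 22), ("TTTTGT", 15)), seed=8)
        )
        c = census(seq, DEFAULT_MOTIFS)
        assert (c.n_canonical, c.n_noncanonical, c.n_total) == (22, 15, 37)

    def test_unplaceable_motifs_error(self):
        from riplab.synthetic_data import _place_motifs

        with pytest.raises(ConfigurationError, match="length"):
            UtrSimConfig(length=10, planted=(("TTTTAT", 3),))
        # three 6-mers cannot coexist in 12 nt however they are drawn
        with pytest.raises(GenerationError, match="overlap"):
            _place_motifs(
                np.random.default_rng(0), 12, ["TTTTAT"] * 3, max_attempts=50
            )

    def test_nested_planted_motif_is_rejected_not_looped(self):
        # TTTTTAT contains a TTTTAT occurrence at offset 1, which can never
        # be screened away
        with pytest.raises(GenerationError, match="nested"):
            simulate_utr(
                UtrSimConfig(length=400, planted=(("TTTTTAT", 1),), seed=0,
                             max_attempts=200)
            )
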