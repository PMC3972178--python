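"""Rank-sum aggregation, BH-FDR and the promoter calling rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medipdiff import (
    AnalysisConfig,
    bh_fdr,
    call_promoters,
    promoter_enrichment,
    promoter_pipeline,
    rank_sum,
)

from conftest import make_annotation
from oracles import enum_ranksum_p, stepup_bh


def probe_frame(t_by_promoter: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for pid, ts in t_by_promoter.items():
        for j, t in enumerate(ts):
            rows.append((f"{pid}_probe{j}", t))
    return pd.DataFrame(rows, columns=["probe_id", "moderated_t"])


class TestRankSum:
    def test_spec_toy_example_exact(self):
        assert rank_sum([2, 3], [-1, 0, 1], "greater") == pytest.approx(0.1)

    def test_identical_samples_two_sided_p_is_one(self):
        assert rank_sum([1, 2, 3], [1, 2, 3], "two-sided") == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum([], [1.0])

    def test_exact_matches_enumeration_for_all_small_no_tie_cases(self):
        """One-sided and two-sided p equal full rank-assignment enumeration."""
        rng = np.random.default_rng(21)
        for n1 in range(1, 6):
            for n2 in range(1, 13 - n1):
                a, b = rng.normal(size=n1), rng.normal(size=n2)
                for alt in ("greater", "less", "two-sided"):
                    assert rank_sum(a, b, alt) == pytest.approx(
                        enum_ranksum_p(a, b, alt), abs=1e-12
                    ), (n1, n2, alt)

    def test_approximation_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(22)
        a, b = rng.normal(size=12), rng.normal(size=18)  # n=30: asymptotic path
        from scipy import stats

        exact = stats.mannwhitneyu(a, b, alternative="greater", method="exact").pvalue
        assert rank_sum(a, b, "greater") == pytest.approx(exact, abs=0.01)

    def test_ties_fall_back_to_corrected_approximation(self):
        p = rank_sum([1, 1, 2], [1, 2, 2], "two-sided")
        assert 0 < p <= 1


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_executed_step_up(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_ps_unchanged(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_longhand_oracle_and_is_monotone(self, ps):
        out = bh_fdr(ps)
        assert np.allclose(out, stepup_bh(np.array(ps)), atol=1e-12)
        assert (out <= 1.0 + 1e-12).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()


class TestPromoterEnrichment:
    def test_top_k_probes_give_minimal_exact_p(self):
        # 4 promoters x 4 probes = 16 probes (exact path); promoter "top"
        # holds the 4 largest t: p_up = 1 / C(16, 4).
        ts = {
            "top": [10.0, 9.0, 8.0, 7.0],
            "a": [0.1, -0.2, 0.3, -0.4],
            "b": [0.5, -0.6, 0.7, -0.8],
            "c": [0.9, -1.0, 1.1, -1.2],
        }
        ann = make_annotation(
            [(pid, "chr1", 5000 + 10_000 * i, "+") for i, pid in enumerate(ts)],
            probes_per_promoter=4,
        )
        res = promoter_enrichment(probe_frame(ts), ann)
        top = res.set_index("promoter_id").loc["top"]
        assert top["p_up"] == pytest.approx(1 / math.comb(16, 4), abs=1e-12)
        assert top["direction"] == "up_in_cpa"
        assert top["promoter_p"] == top["p_up"]

    def test_vectorized_path_matches_scipy_per_promoter(self):
        from scipy import stats

        rng = np.random.default_rng(33)
        ts = {f"prom{i}": list(rng.normal(size=5)) for i in range(30)}  # 150 probes
        ann = make_annotation(
            [(pid, "chr1", 5000 + 10_000 * i, "+") for i, pid in enumerate(ts)],
            probes_per_promoter=5,
        )
        res = promoter_enrichment(probe_frame(ts), ann).set_index("promoter_id")
        all_t = np.concatenate(list(ts.values()))
        for pid in ["prom0", "prom7", "prom29"]:
            own = np.array(ts[pid])
            rest = np.concatenate([v for k, v in ts.items() if k != pid])
            ref_up = stats.mannwhitneyu(
                own, rest, alternative="greater", method="asymptotic",
                use_continuity=True,
            ).pvalue
            ref_down = stats.mannwhitneyu(
                own, rest, alternative="less", method="asymptotic",
                use_continuity=True,
            ).pvalue
            assert res.loc[pid, "p_up"] == pytest.approx(ref_up, abs=1e-10)
            assert res.loc[pid, "p_down"] == pytest.approx(ref_down, abs=1e-10)
        assert len(all_t) == 150

    def test_null_promoter_pvalues_uniform_over_seeds(self):
        from scipy import stats

        pvals = []
        for seed in range(3):
            rng = np.random.default_rng(50 + seed)
            ts = {f"prom{i}": list(rng.normal(size=4)) for i in range(300)}
            ann = make_annotation(
                [(pid, "chr1", 5000 + 5_000 * i, "+") for i, pid in enumerate(ts)],
                probes_per_promoter=4,
                chrom_length=10_000_000,
            )
            res = promoter_enrichment(probe_frame(ts), ann)
            pvals.append(res["p_up"].to_numpy())
        ks = stats.kstest(np.concatenate(pvals), "uniform")
        assert ks.pvalue > 0.01

    def test_single_promoter_background_is_an_error(self):
        ts = {"only": [1.0, 2.0, 3.0]}
        ann = make_annotation([("only", "chr1", 5000, "+")])
        with pytest.raises(ValueError, match="background"):
            promoter_enrichment(probe_frame(ts), ann)

    def test_promoter_without_probes_excluded_with_warning(self):
        ts = {"prom_a": [1.0, 0.5, -0.5], "prom_b": [0.2, -0.2, 0.4]}
        ann = make_annotation(
            [
                ("prom_a", "chr1", 5000, "+"),
                ("prom_b", "chr1", 50_000, "+"),
                ("prom_empty", "chr1", 100_000, "+"),
            ]
        )
        frame = probe_frame(ts)
        with pytest.warns(UserWarning, match="no probes"):
            res = promoter_enrichment(frame, ann)
        assert set(res["promoter_id"]) == {"prom_a", "prom_b"}


class TestCallPromoters:
    def _setup(self, fdr_target: float):
        ts = {
            "hit": [8.0, 9.0, 10.0],
            "mid": [1.0, -1.0, 0.5],
            "low": [-0.3, 0.2, -0.1],
            "neg": [-8.0, -9.0, -10.0],
        }
        ann = make_annotation(
            [(pid, "chr1", 5000 + 10_000 * i, "+") for i, pid in enumerate(ts)]
        )
        enrich = promoter_enrichment(probe_frame(ts), ann)
        return ts, ann, enrich

    def _probe_calls(self, ts, calls: dict[str, str]) -> pd.DataFrame:
        frame = probe_frame(ts)
        frame["probe_call"] = "none"
        for pid, call in calls.items():
            frame.loc[frame["probe_id"].str.startswith(pid), "probe_call"] = call
        return frame

    def test_supported_low_fdr_promoter_called(self):
        ts, ann, enrich = self._setup(0.19)
        probes = self._probe_calls(ts, {"hit": "up_in_cpa"})
        out = call_promoters(enrich, probes, ann).set_index("promoter_id")
        assert bool(out.loc["hit", "dm_call"])
        assert out.loc["hit", "n_called_probes"] == 3

    def test_low_fdr_without_supporting_probe_not_called(self):
        ts, ann, enrich = self._setup(0.19)
        probes = self._probe_calls(ts, {})
        out = call_promoters(enrich, probes, ann).set_index("promoter_id")
        assert not out["dm_call"].any()

    def test_high_fdr_with_probes_not_called(self):
        ts, ann, enrich = self._setup(0.25)
        probes = self._probe_calls(ts, {"mid": "up_in_cpa"})
        out = call_promoters(enrich, probes, ann).set_index("promoter_id")
        assert not bool(out.loc["mid", "dm_call"])  # fdr ~ 1 for mid

    def test_wrong_direction_probe_does_not_support_call(self):
        ts, ann, enrich = self._setup(0.19)
        probes = self._probe_calls(ts, {"hit": "down_in_cpa"})
        out = call_promoters(enrich, probes, ann).set_index("promoter_id")
        assert not bool(out.loc["hit", "dm_call"])

    def test_bonferroni_direction_adjustment_doubles_min_p(self):
        ts, ann, enrich = self._setup(0.19)
        probes = self._probe_calls(ts, {"hit": "up_in_cpa"})
        pooled = call_promoters(enrich, probes, ann, AnalysisConfig())
        doubled = call_promoters(
            enrich, probes, ann, AnalysisConfig(direction_adjust="bonferroni")
        )
        assert (doubled["fdr"] >= pooled["fdr"] - 1e-12).all()


class TestRecoveryProperties:
    def test_calls_partition_into_directions(self, small_dataset, default_config):
        from medipdiff import probe_pipeline

        annotation, matrix, _ = small_dataset
        probes, _ = probe_pipeline(matrix, default_config)
        res = promoter_pipeline(probes, annotation, default_config)
        dm = res[res["dm_call"]]
        n_up = (dm["direction"] == "up_in_cpa").sum()
        n_down = (dm["direction"] == "down_in_cpa").sum()
        assert n_up + n_down == len(dm)

    def test_planted_promoters_recovered_with_correct_direction(self):
        """Sensitivity, FDP and sign recovery under the study's design."""
        from medipdiff import SyntheticConfig, generate_annotation, generate_matrix, probe_pipeline

        sens, fdps, dir_acc = [], [], []
        for seed in (1, 2, 3):
            cfg = SyntheticConfig(
                n_chromosomes=3, chromosome_length=10_000_000, n_promoters=1000,
                probes_per_promoter=(3, 6), planted_fraction=0.05,
                effect_log2=1.0, effect_sd=0.15, noise_sd=0.25, seed=seed,
            )
            ann = generate_annotation(cfg)
            matrix, truth = generate_matrix(cfg, ann)
            probes, _ = probe_pipeline(matrix)
            res = promoter_pipeline(probes, ann).merge(truth, on="promoter_id")
            called = res[res["dm_call"]]
            tp = called["planted"].sum()
            sens.append(tp / res["planted"].sum())
            fdps.append((len(called) - tp) / max(len(called), 1))
            hits = called[called["planted"]]
            dir_acc.append((hits["direction_x"] == hits["direction_y"]).mean())
        assert min(sens) >= 0.9
        assert max(fdps) <= 0.25
        assert min(dir_acc) >= 0.99

    def test_false_call_rate_controlled_on_null(self):
        """Over repeated null simulations the FDP among calls stays small."""
        from medipdiff import SyntheticConfig, generate_annotation, generate_matrix, probe_pipeline

        fdp = []
        for seed in range(20):
            cfg = SyntheticConfig(
                n_chromosomes=2, chromosome_length=10_000_000, n_promoters=1000,
                probes_per_promoter=(3, 5), planted_fraction=0.0, seed=300 + seed,
            )
            ann = generate_annotation(cfg)
            matrix, _ = generate_matrix(cfg, ann)
            probes, _ = probe_pipeline(matrix)
            res = promoter_pipeline(probes, ann)
            n_calls = int(res["dm_call"].sum())
            fdp.append(0.0 if n_calls == 0 else 1.0)  # any null call is false
        assert np.mean(fdp) <= 0.25
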