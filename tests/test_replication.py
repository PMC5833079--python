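"""Meta-analysis, genomic control and the discovery->replication screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtlab import (
    PValueError,
    TwoSetStudyConfig,
    generate_two_set_study,
    genomic_control,
    meta_fixed,
    replication_screen,
    select_index,
)


def _study(ids, effects, ses, study="s"):
    return pd.DataFrame({"study_id": study, "feature_id": ids, "effect": effects, "se": ses})


class TestMetaFixed:
    def test_equal_weight_average(self):
        res = meta_fixed([_study(["a"], [0.0], [1.0]), _study(["a"], [2.0], [1.0])])
        row = res.table.iloc[0]
        assert row.effect == pytest.approx(1.0)
        assert row.se == pytest.approx(1 / np.sqrt(2))

    def test_single_study_identity(self):
        res = meta_fixed([_study(["a"], [0.5], [0.25])])
        row = res.table.iloc[0]
        assert (row.effect, row.se) == (0.5, 0.25)
        assert row.z == pytest.approx(2.0)

    def test_hand_weights(self):
        res = meta_fixed([_study(["a"], [1.0], [1.0]),
                          _study(["a"], [1.0], [2.0]),
                          _study(["a"], [1.0], [2.0])])
        row = res.table.iloc[0]
        assert row.effect == pytest.approx(1.0)
        assert row.se == pytest.approx(1 / np.sqrt(1.5))

    def test_pooled_se_below_min_input_se(self, rng):
        studies = [
            _study(["a", "b"], rng.normal(size=2), rng.uniform(0.1, 1, 2), f"s{k}")
            for k in range(4)
        ]
        res = meta_fixed(studies)
        min_se = pd.concat(studies).groupby("feature_id")["se"].min()
        assert (res.table.set_index("feature_id")["se"] <= min_se + 1e-12).all()

    def test_order_and_split_invariance(self):
        s1 = _study(["a"], [1.0], [0.5])
        s2 = _study(["a"], [-0.5], [0.8])
        direct = meta_fixed([s1, s2]).table
        swapped = meta_fixed([s2, s1]).table
        pd.testing.assert_frame_equal(direct, swapped)
        # splitting a study into two half-weight copies changes nothing
        half = _study(["a"], [1.0], [0.5 * np.sqrt(2)])
        split = meta_fixed([half, half.copy(), s2]).table
        np.testing.assert_allclose(split[["effect", "se", "z", "p"]],
                                   direct[["effect", "se", "z", "p"]])

    def test_nonpositive_se_named(self):
        with pytest.raises(PValueError, match="feat_bad"):
            meta_fixed([_study(["feat_bad"], [1.0], [0.0])])


class TestGenomicControl:
    def test_lambda_two_rescales(self):
        z_target = np.sqrt(0.90988)
        tbl = pd.DataFrame({"feature_id": ["a"], "effect": [z_target], "se": [1.0]})
        meta = meta_fixed([tbl[["feature_id", "effect", "se"]]])
        corrected = genomic_control(meta)
        assert corrected.lambda_gc == pytest.approx(2.0, abs=1e-4)
        assert corrected.table.se.iloc[0] == pytest.approx(np.sqrt(2), rel=1e-4)

    def test_no_deflation(self, rng):
        tbl = _study([f"f{i}" for i in range(100)], rng.normal(0, 0.1, 100), np.ones(100))
        meta = meta_fixed([tbl])
        out = genomic_control(meta)
        assert out.lambda_gc < 1
        pd.testing.assert_frame_equal(out.table, meta.table)

    def test_null_lambda_near_one(self, rng):
        tbl = _study([f"f{i}" for i in range(5000)], rng.normal(0, 1, 5000), np.ones(5000))
        out = genomic_control(meta_fixed([tbl]))
        assert out.lambda_gc == pytest.approx(1.0, abs=0.1)

    def test_scale_self_consistency(self, rng):
        """Inflating all z by c multiplies lambda by c^2 and correction undoes it."""
        c = 1.7
        base = _study([f"f{i}" for i in range(2000)], rng.normal(0, 1, 2000), np.ones(2000))
        inflated = base.assign(effect=base.effect * c)
        lam_base = np.median(meta_fixed([base]).table.z ** 2) / stats.chi2.ppf(0.5, 1)
        out = genomic_control(meta_fixed([inflated]))
        assert out.lambda_gc == pytest.approx(c**2 * lam_base, rel=1e-9)
        np.testing.assert_allclose(
            np.abs(out.table.z), np.abs(meta_fixed([base]).table.z) * c / np.sqrt(out.lambda_gc)
        )


class TestSelectIndex:
    def test_strict_threshold(self):
        tbl = _study(["a", "b"], [1.0, 1.0], [1.0, 1.0])
        meta = meta_fixed([tbl])
        meta.table.loc[:, "p"] = [1e-7, 1e-5]
        assert select_index(meta, 1e-6) == ["a"]

    def test_empty_selection(self):
        meta = meta_fixed([_study(["a"], [0.1], [1.0])])
        assert select_index(meta, 1e-6) == []

    def test_ordered_by_p(self):
        meta = meta_fixed([_study(["a", "b"], [1.0, 2.0], [0.1, 0.1])])
        assert select_index(meta, 0.999) == ["b", "a"]


class TestGenerator:
    def test_deterministic(self):
        a = generate_two_set_study(seed=3)
        b = generate_two_set_study(seed=3)
        for x, y in zip(a[0] + a[1], b[0] + b[1]):
            pd.testing.assert_frame_equal(x, y)

    def test_null_config_gives_uniform_discovery_p(self):
        cfg = TwoSetStudyConfig(n_true=0)
        disc, _, truth = generate_two_set_study(cfg, seed=9)
        assert truth.all()
        p = meta_fixed(disc).table["p"]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_strong_effects_all_selected(self):
        cfg = TwoSetStudyConfig(effect_size=0.1)
        disc, _, truth = generate_two_set_study(cfg, seed=2)
        selected = select_index(genomic_control(meta_fixed(disc)), 1e-6)
        true_ids = {f"feat{j:04d}" for j in np.flatnonzero(~truth)}
        assert true_ids <= set(selected)


@pytest.fixture(scope="module")
def screen_report():
    disc, repl, _ = generate_two_set_study(TwoSetStudyConfig(effect_size=0.02), seed=7)
    discovery = genomic_control(meta_fixed(disc))
    replication = meta_fixed(repl)
    return replication_screen(discovery, replication)


class TestScreen:
    def test_nesting_chains(self, screen_report):
        ids = screen_report.significant_ids
        for weaker, stronger in [
            ("bonferroni", "hommel"),
            ("by", "bh"),
            ("bh", "qvalue-storey"),
        ]:
            assert set(ids[weaker]) <= set(ids[stronger])

    def test_counts_match_id_lists(self, screen_report):
        for name, n in screen_report.counts.items():
            assert n == len(screen_report.significant_ids[name])

    def test_direction_consistency_flags_cover_selection(self, screen_report):
        assert set(screen_report.direction_consistent) == set(screen_report.selected)

    def test_empty_selection_reports_zeros(self):
        disc, repl, _ = generate_two_set_study(TwoSetStudyConfig(n_true=0), seed=1)
        report = replication_screen(meta_fixed(disc), meta_fixed(repl))
        assert all(v == 0 for v in report.counts.values())

    def test_report_frame_sorted_by_count(self, screen_report):
        frame = screen_report.to_frame()
        assert (frame["n_significant"].diff().dropna() >= 0).all()
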