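"""Sub-dataset drawing, trial fold changes, labeling, scoring, and calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exomode.caller import (
    CallerConfig,
    call_exons,
    gene_directions,
    label_exons,
    make_subdatasets,
    run_comparison,
    trial_fold_changes,
)
from exomode.density import KDEConfig
from exomode.io import filter_unexpressed_exons, normalize_log
from exomode.simulate import SyntheticSpec, generate


class TestMakeSubdatasets:
    def test_size_follows_fraction(self):
        cfg = CallerConfig(subsample_fraction=0.6, n_subdatasets=100, seed=1)
        subs = make_subdatasets([f"s{i}" for i in range(10)], cfg)
        assert len(subs) == 100
        assert all(len(s) == 6 for s in subs)
        assert all(len(set(s)) == 6 for s in subs)  # without replacement

    def test_deterministic_and_order_insensitive(self):
        cfg = CallerConfig(seed=11, n_subdatasets=5)
        ids = [f"s{i}" for i in range(8)]
        a = make_subdatasets(ids, cfg)
        b = make_subdatasets(list(reversed(ids)), cfg)
        assert a == b

    def test_fraction_one_returns_full_class(self):
        cfg = CallerConfig(subsample_fraction=1.0, n_subdatasets=3, seed=0)
        subs = make_subdatasets(["a", "b", "c", "d"], cfg)
        assert all(sorted(s) == ["a", "b", "c", "d"] for s in subs)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            make_subdatasets(["a", "b", "c"], CallerConfig())


class TestTrialFoldChanges:
    def test_direct_subtraction(self):
        cfg = CallerConfig()
        a = np.array([2.0, 2, 2, 2, 2, 8])
        b = np.array([2.0, 2, 2, 2, 2, 2])
        fc = trial_fold_changes(a, b, cfg)
        assert np.array_equal(fc, [0, 0, 0, 0, 0, 6])

    def test_near_zero_both_excluded(self):
        cfg = CallerConfig(near_zero_epsilon=1.0)
        fc = trial_fold_changes(np.array([0.2, 5.0]), np.array([0.2, 5.0]), cfg)
        assert np.isnan(fc[0]) and fc[1] == 0.0

    def test_near_zero_one_side_kept(self):
        cfg = CallerConfig(near_zero_epsilon=1.0)
        fc = trial_fold_changes(np.array([0.2]), np.array([6.0]), cfg)
        assert fc[0] == pytest.approx(-5.8)

    def test_invalid_mode_propagates(self):
        cfg = CallerConfig()
        fc = trial_fold_changes(np.array([np.nan, 3.0]), np.array([2.0, 2.0]), cfg)
        assert np.isnan(fc[0]) and fc[1] == 1.0


class TestLabelExons:
    def test_tight_cluster_all_zero(self):
        lab = label_exons(np.array([-0.1, 0.0, 0.05, 0.1, -0.05]))
        assert (lab.labels == 0).all()

    def test_minority_right_peak_plus_one(self):
        fc = np.array([1.0] * 8 + [4.0] * 2)
        lab = label_exons(fc)
        assert list(lab.labels) == [0] * 8 + [1] * 2
        assert lab.peak_x == pytest.approx(1.0, abs=0.2)

    def test_minority_left_peak_minus_one(self):
        fc = np.array([-0.5] * 9 + [-5.0] * 3)
        lab = label_exons(fc)
        assert list(lab.labels) == [0] * 9 + [-1] * 3

    def test_degenerate_all_equal_all_zero(self):
        lab = label_exons(np.array([2.0] * 6))
        assert (lab.labels == 0).all() and lab.peak_x == 2.0

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mirror_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        fc = rng.normal(0, 1, size=12)
        fc[rng.integers(0, 12)] += rng.choice([-4.0, 4.0])
        fwd = label_exons(fc)
        rev = label_exons(-fc)
        assert np.array_equal(rev.labels, -fwd.labels)
        assert rev.peak_x == pytest.approx(-fwd.peak_x, abs=1e-9)


class TestCallExons:
    def tallies(self, scores, n_trials=100):
        n = len(scores)
        plus = np.where(np.array(scores) > 0, scores, 0)
        minus = np.where(np.array(scores) < 0, -np.array(scores), 0)
        return pd.DataFrame(
            {
                "gene_id": ["G"] * n,
                "n_plus": plus,
                "n_minus": minus,
                "n_zero": n_trials - plus - minus,
                "n_excluded": np.zeros(n, dtype=int),
            },
            index=[f"chr1:{10 * i + 1}-{10 * i + 5}" for i in range(n)],
        )

    def test_hand_computed_three_sd_cut(self):
        # 98 zeros plus +80/-80: mean 0, population SD sqrt(12800/100) ~ 11.31
        scores = [0] * 98 + [80, -80]
        out, mu, sd = call_exons(self.tallies(scores), CallerConfig(n_subdatasets=10))
        assert mu == 0.0
        assert sd == pytest.approx(np.sqrt(2 * 80**2 / 100), abs=1e-12)
        assert out["final_call"].sum() == 0  # +1 and -1 balance
        assert out.loc[out["score"] == 80, "final_call"].item() == 1
        assert out.loc[out["score"] == -80, "final_call"].item() == -1
        assert (out.loc[out["score"] == 0, "final_call"] == 0).all()

    def test_zero_spread_makes_no_calls(self):
        out, _, sd = call_exons(self.tallies([5] * 10), CallerConfig(n_subdatasets=10))
        assert sd == 0.0 and (out["final_call"] == 0).all()

    def test_threshold_zero_calls_every_nonzero_score(self):
        scores = [0, 0, 3, -3, 0]  # symmetric: mean score 0
        cfg = CallerConfig(n_subdatasets=10, sd_threshold=0.0)
        out, _, _ = call_exons(self.tallies(scores), cfg)
        assert list(out["final_call"]) == [0, 0, 1, -1, 0]

    def test_never_valid_exons_uncallable(self):
        t = self.tallies([0, 0, 50])
        t.iloc[0] = ["G", 0, 0, 0, 100]  # excluded in every trial
        cfg = CallerConfig(n_subdatasets=10)
        out, mu, sd = call_exons(t, cfg)
        assert out["final_call"].iloc[0] == 0
        # mean/sd computed over the two analyzable exons only
        assert mu == pytest.approx(25.0)


class TestGeneDirections:
    def table(self, n_up, n_down, n_sim):
        return pd.DataFrame(
            {"n_up": [n_up], "n_down": [n_down], "n_similar": [n_sim]},
            index=pd.Index(["G1"], name="gene_id"),
        )

    def test_majority_up(self):
        out = gene_directions(self.table(90, 0, 10))
        assert out.loc["G1", "direction"] == "up"
        assert out.loc["G1", "consistency"] == pytest.approx(0.9)

    def test_all_similar(self):
        out = gene_directions(self.table(0, 0, 100))
        assert out.loc["G1", "direction"] == "similar"

    def test_down_with_sixty_percent(self):
        out = gene_directions(self.table(0, 60, 40))
        assert out.loc["G1", "direction"] == "down"

    def test_no_majority_is_similar(self):
        out = gene_directions(self.table(50, 50, 0))
        assert out.loc["G1", "direction"] == "similar"


@pytest.fixture(scope="module")
def small_run():
    """A fast full comparison: 20 genes x 10 exons, 12 samples per class."""
    spec = SyntheticSpec(
        seed=21,
        n_genes=20,
        exons_per_gene=10,
        class_sizes={"ER-HER2-": 12, "ER+HER2-": 12},
        de_fraction=0.0,
        dropout_rate=0.0,
        silent_exon_rate=0.0,
    )
    ds = generate(spec)
    matrix = normalize_log(filter_unexpressed_exons(ds.matrix))
    cfg = CallerConfig(n_subdatasets=4, seed=3)
    cs = run_comparison(matrix, ds.classes, "ER-HER2-", "ER+HER2-", cfg)
    return ds, matrix, cfg, cs


class TestRunComparison:
    def test_tally_conservation(self, small_run):
        _, _, cfg, cs = small_run
        t = cs.exon_table
        total = t["n_plus"] + t["n_minus"] + t["n_zero"] + t["n_excluded"]
        assert (total == cfg.n_trials).all()
        assert (t["score"].abs() <= cfg.n_trials).all()

    def test_determinism(self, small_run):
        ds, matrix, cfg, cs = small_run
        again = run_comparison(matrix, ds.classes, "ER-HER2-", "ER+HER2-", cfg)
        pd.testing.assert_frame_equal(cs.exon_table, again.exon_table)
        pd.testing.assert_frame_equal(cs.gene_table, again.gene_table)

    def test_shift_invariance_of_labels(self, small_run):
        # adding a constant to all exons of a gene in one class shifts that
        # gene's FCs but leaves exon labels (hence tallies) unchanged
        ds, matrix, cfg, cs = small_run
        gene = "G0003"
        rows = matrix.gene_ids[matrix.gene_ids == gene].index
        cls = ds.classes["class"]
        shifted_values = matrix.values.copy()
        cols = [s for s in matrix.samples if cls[s] == "ER-HER2-"]
        shifted_values.loc[rows, cols] += 2.5
        from exomode.io import ExonExpressionMatrix

        shifted = ExonExpressionMatrix(
            exons=matrix.exons, values=shifted_values, scale_state="normalized_log"
        )
        cs2 = run_comparison(shifted, ds.classes, "ER-HER2-", "ER+HER2-", cfg)
        cols_t = ["n_plus", "n_minus", "n_zero", "n_excluded"]
        pd.testing.assert_frame_equal(
            cs.exon_table.loc[rows, cols_t], cs2.exon_table.loc[rows, cols_t]
        )
        # and the gene's per-trial direction moves up
        assert cs2.gene_table.loc[gene, "direction"] == "up"

    def test_unanalyzable_exon_counted_excluded(self, small_run):
        ds, matrix, cfg, _ = small_run
        # silence one gene below the min-exon rule: only 4 of its exons keep
        # valid fold changes => the gene is excluded from every trial
        values = matrix.values.copy()
        gene = "G0001"
        rows = matrix.gene_ids[matrix.gene_ids == gene].index
        values.loc[rows[:6]] = 0.0  # near-zero modes on both sides
        from exomode.io import ExonExpressionMatrix

        crippled = ExonExpressionMatrix(
            exons=matrix.exons, values=values, scale_state="normalized_log"
        )
        cs = run_comparison(crippled, ds.classes, "ER-HER2-", "ER+HER2-", cfg)
        t = cs.exon_table.loc[rows]
        assert (t["n_excluded"] == cfg.n_trials).all()
        assert (t["final_call"] == 0).all()

    def test_trial_count_is_square(self, small_run):
        _, _, cfg, _ = small_run
        assert cfg.n_trials == cfg.n_subdatasets**2

    def test_missing_class_rejected(self, small_run):
        ds, matrix, cfg, _ = small_run
        with pytest.raises(ValueError, match="no samples"):
            run_comparison(matrix, ds.classes, "HER2+", "ER+HER2-", cfg)


class TestCallSetOutputs:
    def test_write_outputs_round_trip(self, small_run, tmp_path):
        _, _, _, cs = small_run
        paths = cs.write(str(tmp_path / "out"))
        assert len(paths) == 4
        calls = pd.read_csv(paths[0], sep="\t", index_col="exon_id")
        pd.testing.assert_frame_equal(calls, cs.exon_table, check_dtype=False)
        genes = pd.read_csv(paths[1], sep="\t", index_col="gene_id")
        assert list(genes.index) == list(cs.gene_table.index)
        import json

        manifest = json.loads((tmp_path / "out.manifest.json").read_text())
        assert manifest["comparison"] == ["ER-HER2-", "ER+HER2-"]

    def test_rerun_byte_identical_files(self, small_run, tmp_path):
        _, _, _, cs = small_run
        p1 = cs.write(str(tmp_path / "a"))
        p2 = cs.write(str(tmp_path / "b"))
        for a, b in zip(p1, p2):
            assert open(a, "rb").read() == open(b, "rb").read()
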