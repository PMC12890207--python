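"""Bias measurement against ground truth: origin-age inflation, ASR error, rates."""

import math

import numpy as np
import pytest

import phylobias as pb
from phylobias.simulate import SimulationRecord

GRID = pb.IntervalGrid((0.0, 5.0, 10.0))


def _record_from_trees(full, sampled, traits=None, states=None, params=None):
    return SimulationRecord(
        complete_tree=full,
        reconstructed_tree=full,
        sampled_tree=sampled,
        sampled_labels=tuple(sampled.tip_labels),
        true_origin_age=full.parent_ages(),
        node_states=states or {},
        tip_traits=traits or {},
        params=params,
    )


class TestOriginAgeBias:
    def test_complete_sampling_no_inflation(self, fig2_tree):
        record = _record_from_trees(fig2_tree, fig2_tree)
        report = pb.origin_age_bias(record)
        assert report.mean_percent_older == pytest.approx(0.0)
        assert report.percent_older_of_means == pytest.approx(0.0)
        assert report.loglog_r2 == pytest.approx(1.0)
        assert report.n == 4

    def test_constant_doubling_gives_100_percent(self):
        # same topology, every parent node twice as old
        full = pb.parse_newick("((A:1,B:1):1,C:2);")
        doubled = pb.parse_newick("((A:2,B:2):2,C:4);")
        record = SimulationRecord(
            complete_tree=full, reconstructed_tree=full,
            sampled_tree=doubled, sampled_labels=("A", "B", "C"),
            true_origin_age=full.parent_ages(),
            node_states={}, tip_traits={},
        )
        report = pb.origin_age_bias(record)
        assert report.mean_percent_older == pytest.approx(100.0)
        assert report.percent_older_of_means == pytest.approx(100.0)
        assert report.loglog_r2 == pytest.approx(1.0)

    def test_inflation_nonnegative_every_replicate(self):
        done, s = 0, 0
        while done < 30:
            tree = pb.simulate_birth_death(pb.SimParams(lam=0.1, t_max=40, seed=6000 + s))
            s += 1
            if tree is None or tree.n_tips < 20:
                continue
            sub, _ = pb.apply_sampling(
                tree, pb.SamplingScheme(kind="uniform", f=0.05, seed=s)
            )
            if sub.n_tips < 2:
                continue
            report = pb.origin_age_bias(_record_from_trees(tree, sub))
            assert report.mean_percent_older >= 0
            done += 1

    def test_nonpositive_true_age_rejected(self, fig2_tree):
        record = _record_from_trees(fig2_tree, fig2_tree)
        record.true_origin_age["A"] = 0.0
        with pytest.raises(ValueError):
            pb.origin_age_bias(record)


class TestTrueLineageMeans:
    def test_constant_states(self, fig2_record):
        record = fig2_record
        record.node_states = {k: 1.7 for k in record.node_states}
        means = pb.true_lineage_means(record, GRID)
        assert means["true_mean"].to_numpy() == pytest.approx([1.7, 1.7])

    def test_single_branch_linear_interpolation(self):
        import dendropy

        tns = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)
        dtree.seed_node.label = "root"
        child = dtree.seed_node.new_child(edge_length=10.0)
        child.taxon = tns.new_taxon("A")
        tree = pb.Phylogeny(dtree)
        record = SimulationRecord(
            complete_tree=tree, reconstructed_tree=tree, sampled_tree=tree,
            sampled_labels=("A",), true_origin_age={},
            node_states={"A": 10.0, "root": 0.0}, tip_traits={"A": 10.0},
        )
        means = pb.true_lineage_means(record, pb.IntervalGrid((0.0, 10.0)))
        assert means.loc[0, "true_mean"] == pytest.approx(5.0)  # bridge mean at m=5

    def test_fig2_old_interval_counts_two_basal_lineages(self, fig2_record):
        means = pb.true_lineage_means(fig2_record, GRID)
        assert means.loc[1, "n_lineages"] == 2
        assert means.loc[0, "n_lineages"] == 4
        # basal-branch interpolation of the placeholder states at m = 7.5-5 range
        assert not math.isnan(means.loc[1, "true_mean"])

    def test_midpoint_beyond_root_absent(self, fig2_record):
        grid = pb.IntervalGrid((0.0, 5.0, 10.0, 20.0))
        means = pb.true_lineage_means(fig2_record, grid)
        assert means.loc[2, "n_lineages"] == 0
        assert math.isnan(means.loc[2, "true_mean"])


class TestAsrBias:
    def test_equal_traits_zero_error(self):
        tree = pb.parse_newick("(A:4,B:4);")
        tree.root.label = "r"
        record = SimulationRecord(
            complete_tree=tree, reconstructed_tree=tree, sampled_tree=tree,
            sampled_labels=("A", "B"), true_origin_age={"A": 4.0, "B": 4.0},
            node_states={"A": 3.0, "B": 3.0, "r": 3.0},
            tip_traits={"A": 3.0, "B": 3.0},
        )
        report = pb.asr_bias(record, pb.IntervalGrid((0.0, 5.0)))
        assert report.table.loc[0, "abs_error"] == pytest.approx(0.0)

    def test_fig2_drop_d_fills_old_interval(self, fig2_record):
        origins_full = pb.naive_origin_ages(fig2_record.reconstructed_tree, GRID)
        full = pb.interval_median_states(origins_full, fig2_record.tip_traits, GRID)
        origins_drop = pb.naive_origin_ages(fig2_record.sampled_tree, GRID)
        drop = pb.interval_median_states(origins_drop, fig2_record.tip_traits, GRID)
        assert math.isnan(full.loc[1, "median"])
        assert drop.loc[1, "median"] == pytest.approx(3.0)

    def test_sensitivity_probe_flags_changed_intervals(self, fig2_record):
        report = pb.asr_bias(fig2_record, GRID, drop_seed=1)
        assert report.dropped_tip in fig2_record.sampled_tree.tip_labels
        assert set(report.sensitivity.columns) >= {
            "median_full", "median_dropped", "changed"
        }

    def test_sparser_sampling_worsens_interval_errors(self):
        """Mean absolute ASR error across defined intervals grows as f drops:
        misassigned (inflated) origins corrupt the whole median series."""
        errs = {0.1: [], 1.0: []}
        done, s = 0, 0
        while done < 30:
            s += 1
            try:
                record = pb.simulate_record(
                    pb.SimParams(lam=0.12, mu=0.0, t_max=35, seed=7000 + s),
                    pb.SamplingScheme(kind="uniform", f=1.0, seed=s),
                    pb.TraitModel(sigma2=1.0, seed=s),
                    require_min_tips=20,
                )
            except pb.TreeError:
                continue
            grid = pb.IntervalGrid.regular(5.0, record.complete_tree.crown_age + 5)
            for f in errs:
                sub, kept = pb.apply_sampling(
                    record.reconstructed_tree,
                    pb.SamplingScheme(kind="uniform", f=f, seed=s),
                )
                rec = SimulationRecord(
                    complete_tree=record.complete_tree,
                    reconstructed_tree=record.reconstructed_tree,
                    sampled_tree=sub, sampled_labels=kept,
                    true_origin_age=record.true_origin_age,
                    node_states=record.node_states, tip_traits=record.tip_traits,
                )
                table = pb.asr_bias(rec, grid).table.dropna(subset=["abs_error"])
                if not table.empty:
                    errs[f].append(table["abs_error"].mean())
            done += 1
        assert np.mean(errs[0.1]) > np.mean(errs[1.0])


class TestRateBiasCurve:
    def test_truth_is_net_rate(self, fig2_tree):
        record = _record_from_trees(
            fig2_tree, fig2_tree,
            params=pb.SimParams(lam=0.3, mu=0.1, t_max=10, seed=0),
        )
        record.sampled_tree.stem_age = 10.0
        curve = pb.rate_bias_curve(record, pb.IntervalGrid((0.0, 5.0)))
        assert np.allclose(curve["true_rate"], 0.2)
        assert list(curve["boundary"]) == [0.0, 5.0]

    def test_complete_yule_rate_near_lambda(self):
        """With full sampling ln(n)/t is a coarse but calibrated rate estimate."""
        rates = []
        done, s = 0, 0
        while done < 60:
            tree = pb.simulate_birth_death(pb.SimParams(lam=0.1, t_max=50, seed=8000 + s))
            s += 1
            if tree is None or tree.n_tips < 40:
                continue
            record = _record_from_trees(
                tree, tree, params=pb.SimParams(lam=0.1, t_max=50, seed=0)
            )
            curve = pb.rate_bias_curve(record, pb.IntervalGrid((0.0, 5.0)))
            rates.append(curve.loc[0, "naive_rate"])
            done += 1
        assert abs(np.mean(rates) - 0.1) < 0.025

    def test_missing_params_rejected(self, fig2_tree):
        record = _record_from_trees(fig2_tree, fig2_tree)
        with pytest.raises(ValueError):
            pb.rate_bias_curve(record, GRID)


class TestSamplingFraction:
    def test_published_style_percentages(self):
        assert pb.sampling_fraction(232, 359208)[1] == pytest.approx(0.065)
        assert pb.sampling_fraction(31389, 359208)[1] == pytest.approx(8.7)

    def test_full_sampling_and_errors(self):
        exact, rounded = pb.sampling_fraction(7, 7)
        assert exact == 100.0 and rounded == 100.0
        with pytest.raises(ValueError):
            pb.sampling_fraction(8, 7)
        with pytest.raises(ValueError):
            pb.sampling_fraction(0, 7)

    def test_exact_rational_before_formatting(self):
        exact, _ = pb.sampling_fraction(1, 3)
        assert exact == pytest.approx(100 / 3, rel=1e-15)
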