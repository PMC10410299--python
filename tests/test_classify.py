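"""Dual-control classifier: cutoffs, precedence, brute-force agreement, recovery."""

import numpy as np
import pandas as pd
import pytest

from coldclock.classify import (
    classify_gene,
    classify_table,
    fold_change,
    split_static,
)
from coldclock.de import call_degs, dispersion_trend, nb_two_group_test
from coldclock.normalize import cpm, tmm_factors
from coldclock.simulate import make_design, random_panel, simulate_counts


def brute_force_classify(fc4, fc24, timepoint):
    """Independent transcription of the classification procedure.

    Written as literal prose-to-code, separate from the package's
    implementation: evaluate the cold fold-change against the timepoint's
    cutoffs, then the ambient one, then give up.
    """
    if timepoint == "30min":
        up, down = 1.5, 2.0 / 3.0
    elif timepoint == "3h":
        up, down = 2.0, 1.0 / 2.0
    else:
        raise ValueError(timepoint)
    if fc4 >= up:
        return "induced"
    elif fc4 <= down:
        return "repressed"
    elif fc24 >= up or fc24 <= down:
        return "static"
    else:
        return "indeterminate"


class TestFoldChange:
    def test_simple_ratio(self):
        assert fold_change([10, 10, 10], [5, 5, 5], pseudocount=0) == pytest.approx(2.0)

    def test_identity(self):
        assert fold_change([7, 9], [7, 9]) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fold_change([-1.0], [2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fold_change([], [1.0])


class TestClassifyGene:
    @pytest.mark.parametrize("fc4,fc24,tp,expected", [
        (2.0, 1.0, "3h", "induced"),          # at the 3 h induced cutoff
        (1.0, 0.4, "3h", "static"),           # ambient fell, cold flat
        (1.2, 1.1, "3h", "indeterminate"),    # both folds mild
        (1.5, 1.0, "30min", "induced"),       # boundary inclusive
        (0.6, 3.0, "30min", "repressed"),     # cold check takes precedence
        (2.0 / 3.0, 1.0, "30min", "repressed"),
        (0.5, 1.0, "3h", "repressed"),
        (1.0, 2.0, "3h", "static"),
        (1.99, 1.0, "3h", "indeterminate"),
        (1.49, 0.1, "30min", "static"),
    ])
    def test_worked_examples(self, fc4, fc24, tp, expected):
        assert classify_gene(fc4, fc24, tp) == expected

    def test_numeric_timepoints_use_hour_rule(self):
        assert classify_gene(1.7, 1.0, 0.5) == "induced"       # 30 min cutoffs
        assert classify_gene(1.7, 1.0, 3.0) == "indeterminate"  # 3 h cutoffs

    def test_unknown_timepoint_rejected(self):
        with pytest.raises(ValueError):
            classify_gene(2.0, 1.0, "7h")

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            classify_gene(0.0, 1.0, "3h")

    def test_agrees_with_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        fc = np.exp(rng.uniform(np.log(0.1), np.log(10.0), (10_000, 2)))
        tps = rng.choice(["30min", "3h"], 10_000)
        for (fc4, fc24), tp in zip(fc, tps):
            assert classify_gene(fc4, fc24, tp) == brute_force_classify(fc4, fc24, tp)

    def test_monotone_in_cold_fold(self):
        # raising FC4 can only move repressed -> (static|indeterminate) -> induced
        order = {"repressed": 0, "static": 1, "indeterminate": 1, "induced": 2}
        rng = np.random.default_rng(7)
        for _ in range(200):
            fc24 = float(np.exp(rng.uniform(np.log(0.2), np.log(5.0))))
            tp = str(rng.choice(["30min", "3h"]))
            grid = np.exp(np.linspace(np.log(0.2), np.log(5.0), 60))
            levels = [order[classify_gene(f, fc24, tp)] for f in grid]
            assert (np.diff(levels) >= 0).all()


class TestSplitStatic:
    def test_ambient_fall_is_static_induced(self):
        assert split_static("static", 0.3, "3h") == "static_induced"

    def test_ambient_rise_is_static_repressed(self):
        assert split_static("static", 3.0, "3h") == "static_repressed"

    def test_non_static_rejected(self):
        with pytest.raises(ValueError):
            split_static("induced", 3.0, "3h")


def run_shoot_pipeline(n_genes, fractions, seed, timepoints=("T0", "T3")):
    panel = random_panel(n_genes, fractions, seed=seed)
    design = make_design("shoot", timepoints, seed=seed)
    counts, truth = simulate_counts(panel, design, seed=seed + 1)
    factors = tmm_factors(counts)
    groups = (design["timepoint"] + "_" + design["condition"]).to_numpy()
    disp = dispersion_trend(counts, groups)
    deg_sets = {}
    for tp in timepoints:
        if tp == "T0":
            continue
        sub = design[design["timepoint"] == tp]
        amb = sub.loc[sub["condition"] == "ambient", "sample_id"].tolist()
        cold = sub.loc[sub["condition"] == "cold", "sample_id"].tolist()
        res = nb_two_group_test(counts, amb, cold, dispersions=disp, factors=factors)
        deg_sets[("shoot", tp)] = call_degs(res, 0.01)
    table, summary = classify_table(deg_sets, cpm(counts, factors), design)
    return table, summary, truth


class TestClassifyTable:
    def test_truth_recovery_at_default_noise(self):
        fractions = {"induced": 0.2, "repressed": 0.2, "static": 0.2, "none": 0.4}
        table, _, truth = run_shoot_pipeline(1000, fractions, seed=5)
        sub = table[table["timepoint"] == "T3"].set_index("gene_id")
        for category in ("induced", "repressed", "static"):
            truth_genes = truth.index[truth["category"] == category]
            called = sub.reindex(truth_genes)["category"]
            recovery = (called == category).mean()  # missing DEG counts as a miss
            assert recovery >= 0.8, f"{category}: {recovery:.2f}"

    def test_null_simulation_classifies_nothing(self):
        fractions = {"induced": 0.0, "repressed": 0.0, "static": 0.0, "none": 1.0}
        table, _, _ = run_shoot_pipeline(300, fractions, seed=11)
        assert len(table) == 0

    def test_monotone_genes_stay_in_same_category_across_timepoints(self):
        fractions = {"induced": 0.25, "repressed": 0.25, "static": 0.0, "none": 0.5}
        table, summary, truth = run_shoot_pipeline(
            400, fractions, seed=21, timepoints=("T0", "T0.5", "T3"))
        overlaps = summary["overlaps"]
        same = overlaps["shoot:T0.5:induced|shoot:T3:induced"]
        crossed = overlaps["shoot:T0.5:induced|shoot:T3:repressed"]
        assert same > 0
        assert crossed == 0

    def test_missing_t0_rejected(self):
        fractions = {"induced": 0.0, "repressed": 0.0, "static": 0.0, "none": 1.0}
        panel = random_panel(50, fractions, seed=0)
        design = make_design("shoot", ("T0", "T3"), seed=0)
        counts, _ = simulate_counts(panel, design, seed=1)
        no_t0 = design[design["timepoint"] != "T0"]
        with pytest.raises(ValueError, match="T0"):
            classify_table({("shoot", "T3"): {counts.index[0]}},
                           cpm(counts[no_t0["sample_id"]]), no_t0)
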