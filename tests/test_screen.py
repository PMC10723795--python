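import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from nucleoscore.screen import (
    aggregate_wells,
    call_hits,
    hit_category,
    hit_percentages,
    target_enrichment,
    vehicle_stats,
)
from nucleoscore.synthetic import generate_plate


def make_layout(wells, compound="CMP", conc=10.0, vehicle=False):
    return pd.DataFrame(
        {
            "well_id": wells,
            "compound_id": [compound] * len(wells),
            "concentration_uM": [conc] * len(wells),
            "is_vehicle": [vehicle] * len(wells),
        }
    )


class TestAggregateWells:
    def test_two_stage_field_then_well_mean(self):
        per_cell = pd.DataFrame(
            {
                "well_id": ["W1"] * 4,
                "field_id": ["f1", "f1", "f2", "f2"],
                "normality_score": [0.9, 1.1, 0.7, 0.9],  # field means 1.0 and 0.8
            }
        )
        wells = aggregate_wells(per_cell, make_layout(["W1"]))
        assert wells.loc[0, "mean_score"] == pytest.approx(0.9)
        assert wells.loc[0, "n_fields"] == 2
        assert wells.loc[0, "cell_count"] == 4

    def test_unscored_field_excluded_and_counted(self):
        per_cell = pd.DataFrame(
            {
                "well_id": ["W1"] * 4,
                "field_id": ["f1", "f1", "f2", "f2"],
                "normality_score": [1.0, 1.0, np.nan, np.nan],
            }
        )
        wells = aggregate_wells(per_cell, make_layout(["W1"]))
        assert wells.loc[0, "mean_score"] == pytest.approx(1.0)
        assert wells.loc[0, "n_fields"] == 1
        assert wells.loc[0, "n_unscored_cells"] == 2

    def test_well_missing_from_layout_raises(self):
        per_cell = pd.DataFrame(
            {"well_id": ["W1"], "field_id": ["f1"], "normality_score": [1.0]}
        )
        with pytest.raises(ValueError, match="absent from layout"):
            aggregate_wells(per_cell, make_layout(["W2"]))

    def test_matches_brute_force_two_stage_oracle(self):
        cells, layout, _ = generate_plate(
            n_compounds=6, hit_fraction=0.5, cells_per_well=12, n_fields=3,
            n_vehicle_wells=4, seed=5,
        )
        wells = aggregate_wells(cells, layout).set_index("well_id")
        for well_id, group in cells.groupby("well_id"):
            field_means = [
                fg["normality_score"].mean() for _, fg in group.groupby("field_id")
            ]
            assert wells.loc[well_id, "mean_score"] == pytest.approx(
                sum(field_means) / len(field_means)
            )

    def test_normalized_score_vehicle_mean_is_one(self):
        cells, layout, _ = generate_plate(
            n_compounds=4, cells_per_well=10, n_vehicle_wells=6, seed=2
        )
        wells = aggregate_wells(cells, layout)
        vehicle = wells[wells["is_vehicle"].astype(bool)]
        assert vehicle["normalized_score"].mean() == pytest.approx(1.0)


class TestVehicleStats:
    def test_sample_mean_and_sd(self):
        wells = pd.DataFrame(
            {"mean_score": [0.9, 1.0, 1.1], "is_vehicle": [True] * 3}
        )
        mean, sd = vehicle_stats(wells)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.1)

    def test_fewer_than_two_wells_raises(self):
        wells = pd.DataFrame({"mean_score": [1.0], "is_vehicle": [True]})
        with pytest.raises(ValueError, match="at least 2 vehicle wells"):
            vehicle_stats(wells)

    def test_zero_sd_fails_loudly_downstream(self):
        wells = pd.DataFrame(
            {"mean_score": [1.0, 1.0, 1.0], "is_vehicle": [True] * 3}
        )
        mean, sd = vehicle_stats(wells)
        assert sd == 0.0
        with pytest.raises(ValueError, match="SD must be positive"):
            call_hits(make_layout(["W1"]).assign(mean_score=0.5), mean, sd)

    def test_monte_carlo_recovery(self, rng):
        scores = rng.normal(1.0, 0.05, 1000)
        wells = pd.DataFrame({"mean_score": scores, "is_vehicle": True})
        mean, sd = vehicle_stats(wells)
        assert abs(mean - 1.0) < 3 * 0.05 / math.sqrt(1000)
        assert abs(sd - 0.05) < 3 * 0.05 / math.sqrt(2 * 1000)


class TestCallHits:
    def _wells(self, scores_by_conc):
        rows = []
        for compound, by_conc in scores_by_conc.items():
            for conc, score in by_conc.items():
                rows.append(
                    {
                        "well_id": f"{compound}_{conc}",
                        "compound_id": compound,
                        "concentration_uM": conc,
                        "mean_score": score,
                        "is_vehicle": False,
                    }
                )
        return pd.DataFrame(rows)

    def test_three_sd_below_is_hit(self):
        wells = self._wells({"A": {10.0: 0.85}})
        (call,) = call_hits(wells, 1.0, 0.05)
        assert call.hit_at == frozenset({10.0})
        assert call.z_like_deviation[10.0] == pytest.approx(-3.0)

    def test_one_sd_below_is_not_hit(self):
        wells = self._wells({"A": {10.0: 0.95}})
        (call,) = call_hits(wells, 1.0, 0.05)
        assert call.category == "none"

    def test_categories_from_concentration_sets(self):
        wells = self._wells(
            {
                "both": {1.0: 0.8, 10.0: 0.8},
                "high": {1.0: 0.99, 10.0: 0.8},
                "low": {1.0: 0.8, 10.0: 0.99},
                "none": {1.0: 0.99, 10.0: 0.99},
            }
        )
        categories = {c.compound_id: c.category for c in call_hits(wells, 1.0, 0.05)}
        assert categories == {
            "both": "both",
            "high": "10_only",
            "low": "1_only",
            "none": "none",
        }

    def test_above_mean_not_hit_one_sided_but_hit_two_sided(self):
        wells = self._wells({"A": {10.0: 1.5}})
        (below,) = call_hits(wells, 1.0, 0.05, direction="below")
        (two,) = call_hits(wells, 1.0, 0.05, direction="two_sided")
        assert below.category == "none"
        assert two.category == "10_only"

    def test_affine_invariance(self):
        cells, layout, _ = generate_plate(
            n_compounds=40, hit_fraction=0.3, cells_per_well=20, n_vehicle_wells=8, seed=9
        )
        wells = aggregate_wells(cells, layout)
        mean, sd = vehicle_stats(wells)
        base = {c.compound_id: c.category for c in call_hits(wells, mean, sd)}
        a, b = 3.7, 11.0
        rescaled = wells.assign(mean_score=wells["mean_score"] * a + b)
        shifted = {
            c.compound_id: c.category
            for c in call_hits(rescaled, mean * a + b, sd * a)
        }
        assert base == shifted

    def test_category_partition_covers_library(self):
        cells, layout, truth = generate_plate(
            n_compounds=50, hit_fraction=0.2, cells_per_well=10, n_vehicle_wells=8, seed=3
        )
        wells = aggregate_wells(cells, layout)
        calls = call_hits(wells, *vehicle_stats(wells))
        counts = pd.Series([c.category for c in calls]).value_counts()
        assert counts.sum() == 50

    def test_null_hit_rate_matches_normal_tail(self):
        # one test per compound (10 uM well); planted effect zero
        cells, layout, _ = generate_plate(
            n_compounds=10_000, hit_fraction=0.0, cells_per_well=1, cell_sd=0.0,
            n_vehicle_wells=16, vehicle_sd=0.05, seed=11,
        )
        wells = aggregate_wells(cells, layout)
        treated = wells[(~wells["is_vehicle"].astype(bool)) & (wells["concentration_uM"] == 10.0)]
        rate = float((treated["mean_score"] < 1.0 - 2 * 0.05).mean())
        p = norm.cdf(-2)
        bound = 2.576 * math.sqrt(p * (1 - p) / len(treated))
        assert abs(rate - p) < bound

    def test_strong_effects_fully_recovered(self):
        fprs = []
        for seed in (21, 22, 23):
            cells, layout, truth = generate_plate(
                n_compounds=200, hit_fraction=0.15, effect_size_sd=6.0,
                cells_per_well=30, cell_sd=0.1, n_vehicle_wells=128, seed=seed,
            )
            wells = aggregate_wells(cells, layout)
            calls = call_hits(wells, *vehicle_stats(wells))
            by_compound = {c.compound_id: c for c in calls}
            truth = truth.set_index("compound_id")
            planted = truth[truth["category"] != "none"].index
            nulls = truth[truth["category"] == "none"].index
            recall = np.mean([by_compound[c].category != "none" for c in planted])
            assert recall == 1.0
            # false-positive rate per concentration test on null compounds
            fprs.append(sum(len(by_compound[c].hit_at) for c in nulls) / (2 * len(nulls)))
        assert np.mean(fprs) <= 0.05


def exact_hypergeom_upper_tail(M, K, n, k):
    """Exact tail by combinatorial enumeration over class counts."""
    total = math.comb(M, n)
    return sum(
        math.comb(K, j) * math.comb(M - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestTargetEnrichment:
    def _annotation(self, counts):
        rows = []
        i = 0
        for cls, n in counts.items():
            for _ in range(n):
                rows.append({"compound_id": f"c{i}", "target_class": cls})
                i += 1
        return pd.DataFrame(rows)

    def test_worked_example_matches_enumeration(self):
        # library 100, 10 in class, 20 hits of which 6 in class
        annotation = self._annotation({"kinase": 10, "other": 90})
        hits = [f"c{i}" for i in range(6)] + [f"c{i}" for i in range(10, 24)]
        result = target_enrichment(hits, annotation).set_index("target_class")
        expected_p = exact_hypergeom_upper_tail(100, 10, 20, 6)
        assert result.loc["kinase", "p_value"] == pytest.approx(expected_p, rel=1e-9)
        assert result.loc["kinase", "fold_enrichment"] == pytest.approx(
            (6 / 20) / (10 / 100)
        )
        assert result.loc["kinase", "significant"]

    def test_class_absent_from_hits(self):
        annotation = self._annotation({"rare": 2, "other": 48})
        hits = [f"c{i}" for i in range(2, 8)]  # none from 'rare'
        result = target_enrichment(hits, annotation).set_index("target_class")
        assert result.loc["rare", "fold_enrichment"] == 0.0
        assert result.loc["rare", "p_value"] == pytest.approx(1.0)

    def test_saturated_single_class(self):
        annotation = self._annotation({"only": 8})
        hits = [f"c{i}" for i in range(8)]
        result = target_enrichment(hits, annotation)
        assert result.loc[0, "fold_enrichment"] == pytest.approx(1.0)
        assert result.loc[0, "p_value"] == pytest.approx(1.0)

    def test_missing_annotation_raises(self):
        annotation = self._annotation({"a": 3})
        with pytest.raises(ValueError, match="missing annotation"):
            target_enrichment(["ghost"], annotation)

    def test_small_libraries_match_enumeration_oracle(self, rng):
        # random instances over every library size up to 25
        for M in range(2, 26):
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            annotation = self._annotation({"cls": K, "other": M - K})
            in_class = [f"c{i}" for i in range(K)]
            out_class = [f"c{i}" for i in range(K, M)]
            rng.shuffle(in_class)
            rng.shuffle(out_class)
            k = int(rng.integers(0, min(K, n) + 1))
            hits = in_class[:k] + out_class[: n - k]
            if len(hits) != n:
                continue  # infeasible draw for this (K, n, k)
            result = target_enrichment(hits, annotation).set_index("target_class")
            expected = exact_hypergeom_upper_tail(M, K, n, k)
            assert result.loc["cls", "p_value"] == pytest.approx(expected, rel=1e-9)


class TestHitPercentages:
    def test_screen_counts_arithmetic(self):
        pct = hit_percentages(83, 69, 1180)
        assert pct["pct_both"] == pytest.approx(100 * 83 / 1180)
        assert pct["pct_high_only"] == pytest.approx(100 * 69 / 1180)
        assert pct["pct_total"] == pytest.approx(100 * 152 / 1180)

    def test_rejects_empty_library(self):
        with pytest.raises(ValueError):
            hit_percentages(1, 1, 0)


def test_hit_category_pure_function():
    assert hit_category(frozenset({1.0, 10.0})) == "both"
    assert hit_category(frozenset({10.0})) == "10_only"
    assert hit_category(frozenset({1.0})) == "1_only"
    assert hit_category(frozenset()) == "none"
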