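"""Lineage aggregation, controls, rarefaction and the saturation estimator."""

import numpy as np
import pandas as pd
import pytest

from tagem.barcode_calling import BarcodeCall, CallStatus
from tagem.lineage_analysis import (
    LineageTable,
    estimate_true_integrations,
    rarefaction_curve,
    summarize_lineages,
    validate_controls,
)
from tagem.pipeline import (
    call_simulated_experiment,
    run_simulated_experiment,
    sample_sheet_frame,
)
from tagem.synthetic_data import GermlineSimConfig, simulate_germline_experiment

B1 = "A" * 14
B2 = "C" * 14


def _call(sample_id, status, barcode=None, n=600):
    comp = np.zeros((5, 14), dtype=int)
    if barcode:
        for pos, base in enumerate(barcode):
            comp["ACGT".index(base), pos] = n
    return BarcodeCall(
        sample_id=sample_id,
        status=status,
        barcode=barcode,
        n_reads_total=n,
        n_reads_trimmed=n if status is not CallStatus.INSUFFICIENT_READS else 0,
        composition=comp,
    )


def _sheet(rows):
    return pd.DataFrame(rows, columns=["sample_id", "lineage_id", "role"])


class TestSummarizeLineages:
    def test_repeated_barcode_counts_once(self):
        calls = [_call(f"s{i}", CallStatus.CALLED, B1) for i in range(3)]
        table = LineageTable.from_calls(
            calls, _sheet([(f"s{i}", "L1", "progeny") for i in range(3)])
        )
        summary = summarize_lineages(table)
        assert summary.unique_barcode_counts == {"L1": 1}
        assert summary.total_unique_insertions == 1

    def test_non_called_samples_excluded(self):
        calls = [
            _call("s0", CallStatus.CALLED, B1),
            _call("s1", CallStatus.MIXED),
            _call("s2", CallStatus.CALLED, B2),
            _call("s3", CallStatus.INSUFFICIENT_READS),
        ]
        table = LineageTable.from_calls(
            calls, _sheet([(f"s{i}", "L1", "progeny") for i in range(4)])
        )
        assert summarize_lineages(table).unique_barcode_counts == {"L1": 2}

    def test_cross_lineage_collision_deduplicated_globally(self):
        calls = [
            _call("a", CallStatus.CALLED, B1),
            _call("b", CallStatus.CALLED, B1),
            _call("c", CallStatus.CALLED, B2),
        ]
        table = LineageTable.from_calls(
            calls,
            _sheet([("a", "L1", "progeny"), ("b", "L2", "progeny"), ("c", "L2", "progeny")]),
        )
        summary = summarize_lineages(table)
        assert summary.unique_barcode_counts == {"L1": 1, "L2": 2}
        assert summary.total_unique_insertions == 2
        assert summary.cross_lineage_collisions == {B1: ["L1", "L2"]}
        assert summary.total_unique_insertions <= sum(
            summary.unique_barcode_counts.values()
        )

    def test_histogram_and_mean(self):
        calls = [
            _call("a", CallStatus.CALLED, B1),
            _call("b", CallStatus.CALLED, B1),
            _call("c", CallStatus.CALLED, B2),
        ]
        table = LineageTable.from_calls(
            calls,
            _sheet([("a", "L1", "progeny"), ("b", "L2", "progeny"), ("c", "L2", "progeny")]),
        )
        summary = summarize_lineages(table)
        assert summary.histogram == {1: 1, 2: 1}
        assert summary.mean_insertions_per_embryo == pytest.approx(1.5)

    def test_exhaustive_sampling_recovers_truth_exactly(self, small_library):
        # with progeny far outnumbering the true set and no sequencing
        # error, per-lineage unique counts equal the simulated truth
        cfg = GermlineSimConfig(
            library=small_library,
            n_embryos=120,
            per_base_error_rate=0.0,
            progeny_sampled_max=120,
            read_depth_mean=600,
            read_depth_dispersion=1e9,
            n_blanks=0,
            n_duplicate_controls=0,
            seed=17,
        )
        truth, _, _, summary = run_simulated_experiment(cfg)
        assert summary.unique_barcode_counts == truth.true_set_sizes()


class TestValidateControls:
    def test_matching_pair_and_blank_pass(self):
        calls = [
            _call("c_a", CallStatus.CALLED, B1),
            _call("c_b", CallStatus.CALLED, B1),
            _call("blank0", CallStatus.INSUFFICIENT_READS),
        ]
        table = LineageTable.from_calls(
            calls,
            _sheet(
                [
                    ("c_a", "CTRL0", "duplicate_control"),
                    ("c_b", "CTRL0", "duplicate_control"),
                    ("blank0", "BLANK", "blank"),
                ]
            ),
        )
        report = validate_controls(table)
        assert report.n_matching_duplicates == report.n_duplicate_pairs == 1
        assert report.n_blanks == 1 and report.n_blanks_called == 0

    def test_discordant_pair_not_matching(self):
        calls = [_call("c_a", CallStatus.CALLED, B1), _call("c_b", CallStatus.CALLED, B2)]
        table = LineageTable.from_calls(
            calls,
            _sheet(
                [("c_a", "CTRL0", "duplicate_control"), ("c_b", "CTRL0", "duplicate_control")]
            ),
        )
        assert validate_controls(table).n_matching_duplicates == 0

    def test_unpaired_duplicate_control_rejected(self):
        table = LineageTable.from_calls(
            [_call("c_a", CallStatus.CALLED, B1)],
            _sheet([("c_a", "CTRL0", "duplicate_control")]),
        )
        with pytest.raises(ValueError, match="pair"):
            validate_controls(table)

    def test_simulated_blanks_are_never_called(self, small_library, layout, params):
        # mixture-mode blanks at full depth: no single barcode can pass
        # the consensus rule
        cfg = GermlineSimConfig(
            library=small_library,
            n_embryos=30,
            n_blanks=16,
            n_duplicate_controls=0,
            blank_mode="mixture",
            read_depth_mean=1000,
            read_depth_dispersion=1e9,
            seed=23,
        )
        truth = simulate_germline_experiment(cfg)
        calls = call_simulated_experiment(truth, cfg, layout, params)
        table = LineageTable.from_calls(calls, sample_sheet_frame(truth))
        report = validate_controls(table)
        assert report.n_blanks == 16
        assert report.n_blanks_called == 0


class TestRarefaction:
    def test_zero_level_gives_zero_unique(self):
        curve = rarefaction_curve([B1] * 10, levels=[0], n_reps=3, seed=1)
        assert curve["mean_unique"].tolist() == [0.0]

    def test_full_depth_on_error_free_pool_counts_all(self, small_library):
        reads = [b for b in small_library.entries for _ in range(3)]
        curve = rarefaction_curve(reads, levels=[len(reads)], n_reps=2, seed=1)
        assert curve["mean_unique"].tolist() == [float(len(small_library))]

    def test_monotone_in_level(self, small_library):
        reads = [b for b in small_library.entries for _ in range(4)]
        curve = rarefaction_curve(
            reads, levels=[0, 50, 200, 800, 2000], n_reps=5, seed=2
        )
        means = curve["mean_unique"].tolist()
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_matches_occupancy_closed_form(self):
        # 1,000 equally frequent barcodes subsampled at depth 1,000:
        # expected uniques 1000*(1-(1-1/1000)^1000) ~ 632.3
        from tagem.synthetic_data import generate_library

        lib = generate_library(1000, 14, seed=5)
        reads = [b for b in lib.entries for _ in range(200)]
        n_reps = 50
        curve = rarefaction_curve(reads, levels=[1000], n_reps=n_reps, seed=6)
        expected = 1000 * (1 - (1 - 1 / 1000) ** 1000)
        se = curve["sd_unique"][0] / np.sqrt(n_reps)
        assert abs(curve["mean_unique"][0] - expected) < 3 * se

    def test_oversized_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            rarefaction_curve([B1] * 10, levels=[11], n_reps=1, seed=0)

    def test_one_mismatch_collapse_merges_error_neighbours(self):
        major = ["ACGTACGTACGTAC"] * 50
        neighbour = ["ACGTACGTACGTAA"] * 3  # 1 mismatch from major
        distinct = ["TTTTGGGGCCCCAA"] * 20
        reads = major + neighbour + distinct
        raw = rarefaction_curve(reads, levels=[len(reads)], n_reps=1, seed=0)
        collapsed = rarefaction_curve(
            reads, levels=[len(reads)], n_reps=1, seed=0, collapse_1mm=True
        )
        assert raw["mean_unique"][0] == 3.0
        assert collapsed["mean_unique"][0] == 2.0


class TestEstimator:
    def test_single_unique_is_fixed_point(self):
        assert estimate_true_integrations(1, 10) == 1.0

    def test_all_distinct_boundary_is_infinite(self):
        assert estimate_true_integrations(10, 10) == float("inf")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_true_integrations(11, 10)

    def test_inverts_known_expectation(self):
        # K=15, n=10: E[U] = 15*(1-(14/15)^10); inverting E[U] recovers K
        expected_u = 15 * (1 - (14 / 15) ** 10)
        assert expected_u == pytest.approx(7.48, abs=0.01)
        assert estimate_true_integrations(expected_u, 10) == pytest.approx(15, abs=1e-6)

    def test_monte_carlo_oracle_recovery(self):
        # oracle: simulate U directly, feed its mean to the estimator
        rng = np.random.default_rng(31)
        k, n, reps = 15, 10, 4000
        us = [len(set(rng.integers(0, k, size=n))) for _ in range(reps)]
        k_hat = estimate_true_integrations(float(np.mean(us)), n)
        assert k_hat == pytest.approx(k, rel=0.08)

    def test_monotone_and_bounded_below(self):
        prev = 0.0
        for u in [1, 2, 3, 4.5, 6, 7.9, 9]:
            k_hat = estimate_true_integrations(u, 10)
            assert k_hat >= u
            assert k_hat >= prev
            prev = k_hat


class TestLineageTableConstruction:
    def test_missing_sheet_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            LineageTable.from_calls([], pd.DataFrame({"sample_id": []}))

    def test_call_absent_from_sheet_rejected(self):
        with pytest.raises(ValueError, match="not in sample sheet"):
            LineageTable.from_calls(
                [_call("ghost", CallStatus.CALLED, B1)], _sheet([("s0", "L1", "progeny")])
            )

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="unknown roles"):
            LineageTable.from_calls([], _sheet([("s0", "L1", "mystery")]))
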