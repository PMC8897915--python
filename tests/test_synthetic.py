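import numpy as np
import pandas as pd
import pytest

from exondepth.synthetic import (
    CnvEvent,
    ReadPlacement,
    SimulationError,
    SimulationSpec,
    emit_fixture_bams,
    evaluate_calls,
    read_truth_tsv,
    simulate_coverage,
    write_truth_tsv,
)


class TestSimulateCoverage:
    def test_null_model_moments(self):
        spec = SimulationSpec(
            n_regions=80, n_samples=40, seed=0, depth_mean=100.0,
            libsize_sd=0.0, gc_bias_strength=0.0, K_true=0,
        )
        sim = simulate_coverage(spec)
        assert sim.truth.empty
        np.testing.assert_allclose(sim.lam_true, sim.lam_cnv)
        # with N_j = 1 and no GC bias, lambda rows are constant at beta_i
        assert np.allclose(sim.lam_true, sim.lam_true[:, :1])
        # column means of Y concentrate near the corresponding row means
        row_mean = sim.matrix.counts.mean(axis=1)
        se = np.sqrt(sim.lam_true[:, 0] / 40)
        assert np.mean(np.abs(row_mean - sim.lam_true[:, 0]) < 4 * se) > 0.95

    def test_carrier_bookkeeping(self):
        spec = SimulationSpec(
            n_regions=50, n_samples=100, seed=1,
            cnv_events=(CnvEvent("DEL", 1, 3, 0.02),),
        )
        sim = simulate_coverage(spec)
        assert len(sim.truth) == 2
        assert set(sim.truth["population_frequency"]) == {0.02}
        assert sim.truth["sample_id"].nunique() == 2

    def test_poisson_moment_check(self):
        # mean of Y over replicate draws of one cell ~= its stored lambda
        draws = []
        base = SimulationSpec(n_regions=10, n_samples=5, seed=0, depth_mean=80.0)
        lam = simulate_coverage(base).lam_cnv[3, 2]
        for seed in range(1000):
            spec = SimulationSpec(n_regions=10, n_samples=5, seed=0, depth_mean=80.0)
            rng = np.random.default_rng(seed)
            draws.append(rng.poisson(lam))
        se = np.sqrt(lam / 1000)
        assert abs(np.mean(draws) - lam) < 3 * se

    def test_reproducible_from_seed(self):
        spec = SimulationSpec(n_regions=30, n_samples=10, seed=5)
        a = simulate_coverage(spec)
        b = simulate_coverage(spec)
        np.testing.assert_array_equal(a.matrix.counts, b.matrix.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_deletion_scales_lambda(self):
        spec = SimulationSpec(
            n_regions=40, n_samples=20, seed=3,
            cnv_events=(CnvEvent("DEL", 1, 4, 0.05),),
        )
        sim = simulate_coverage(spec)
        carrier = sim.truth.iloc[0]
        j = sim.matrix.sample_ids.index(carrier["sample_id"])
        rows = [
            i for i, r in enumerate(sim.regions)
            if r.start >= carrier["start"] and r.end <= carrier["end"]
        ]
        assert len(rows) == 4
        np.testing.assert_allclose(
            sim.lam_cnv[rows, j], 0.5 * sim.lam_true[rows, j]
        )

    def test_event_longer_than_regions_error(self):
        spec = SimulationSpec(
            n_regions=5, n_samples=10, seed=0,
            cnv_events=(CnvEvent("DEL", 1, 10, 0.5),),
        )
        with pytest.raises(SimulationError):
            simulate_coverage(spec)

    def test_invalid_event_rejected(self):
        with pytest.raises(ValueError):
            CnvEvent("DEL", 3, 2, 0.1)  # type/CN mismatch
        with pytest.raises(ValueError):
            CnvEvent("DUP", 4, 2, 0.0)  # zero carrier fraction


class TestFixtureBams:
    def test_single_read_counts_once(self, tmp_path, small_regions):
        from exondepth.io_coverage import ReadFilter, count_region_coverage

        placements = [ReadPlacement("s", "chr1", 120, 180)]
        paths = emit_fixture_bams(small_regions, placements, tmp_path)
        counts = count_region_coverage(paths["s"], small_regions, ReadFilter(min_mapq=0))
        assert counts.tolist() == [1, 0, 0, 0]

    def test_duplicate_flag_respected(self, tmp_path, small_regions):
        from exondepth.io_coverage import ReadFilter, count_region_coverage

        placements = [ReadPlacement("s", "chr1", 120, 180, is_duplicate=True)]
        paths = emit_fixture_bams(small_regions, placements, tmp_path)
        counts = count_region_coverage(paths["s"], small_regions, ReadFilter(min_mapq=0))
        assert counts.sum() == 0

    def test_off_contig_placement_error(self, tmp_path, small_regions):
        with pytest.raises(SimulationError, match="chrZ"):
            emit_fixture_bams(
                small_regions, [ReadPlacement("s", "chrZ", 0, 50)], tmp_path
            )


def call_row(sample, start, end, type_, n_exons, chrom="chr1"):
    return {
        "sample_id": sample, "chrom": chrom, "start": start, "end": end,
        "type": type_, "copy_number": 1 if type_ == "DEL" else 3,
        "n_exons": n_exons, "raw_sum": 100.0, "norm_sum": 200.0,
        "ratio": 0.5, "lratio": 10.0,
    }


def truth_row(sample, start, end, type_, n_exons, freq, chrom="chr1"):
    return {
        "sample_id": sample, "chrom": chrom, "start": start, "end": end,
        "type": type_, "copy_number": 1 if type_ == "DEL" else 3,
        "n_exons": n_exons, "population_frequency": freq,
    }


class TestEvaluateCalls:
    def test_perfect_calls(self):
        truth = pd.DataFrame([
            truth_row("s1", 0, 1000, "DEL", 2, 0.01),
            truth_row("s2", 5000, 9000, "DUP", 5, 0.5),
        ])
        calls = pd.DataFrame([
            call_row("s1", 0, 1000, "DEL", 2),
            call_row("s2", 5000, 9000, "DUP", 5),
        ])
        report = evaluate_calls(calls, truth, n_samples=100)
        top = report[(report.frequency == "all") & (report.length == "all")].iloc[0]
        assert (top.tp, top.fp, top.fn) == (2, 0, 0)
        assert top.precision == 1.0 and top.sensitivity == 1.0

    def test_empty_call_set(self):
        truth = pd.DataFrame([truth_row("s1", 0, 1000, "DEL", 2, 0.01)])
        calls = pd.DataFrame(columns=list(call_row("x", 0, 1, "DEL", 1)))
        report = evaluate_calls(calls, truth, n_samples=100)
        top = report[(report.frequency == "all") & (report.length == "all")].iloc[0]
        assert (top.tp, top.fp, top.fn) == (0, 0, 1)
        assert top.sensitivity == 0.0

    def test_hand_enumerated_fixture(self):
        # 3 truth events; 4 calls: 2 true matches, 1 wrong-type, 1 spurious
        truth = pd.DataFrame([
            truth_row("s1", 0, 1000, "DEL", 2, 0.01),
            truth_row("s2", 5000, 9000, "DUP", 5, 0.5),
            truth_row("s3", 20_000, 21_000, "DEL", 2, 0.01),
        ])
        calls = pd.DataFrame([
            call_row("s1", 0, 900, "DEL", 2),        # TP (overlaps truth 1)
            call_row("s2", 5000, 9000, "DUP", 5),    # TP (truth 2)
            call_row("s3", 20_000, 21_000, "DUP", 2),  # wrong type -> FP
            call_row("s1", 50_000, 51_000, "DEL", 1),  # spurious -> FP
        ])
        report = evaluate_calls(calls, truth, n_samples=100)
        top = report[(report.frequency == "all") & (report.length == "all")].iloc[0]
        assert (top.tp, top.fp, top.fn) == (2, 2, 1)
        assert top.precision == pytest.approx(0.5)
        assert top.sensitivity == pytest.approx(2 / 3)
        rare = report[(report.frequency == "rare") & (report.length == "all")].iloc[0]
        assert rare.tp == 1 and rare.fn == 1

    def test_one_truth_matches_at_most_one_call(self):
        truth = pd.DataFrame([truth_row("s1", 0, 5000, "DEL", 5, 0.01)])
        calls = pd.DataFrame([
            call_row("s1", 0, 2000, "DEL", 2),
            call_row("s1", 3000, 5000, "DEL", 2),
        ])
        report = evaluate_calls(calls, truth, n_samples=100)
        top = report[(report.frequency == "all") & (report.length == "all")].iloc[0]
        assert (top.tp, top.fp, top.fn) == (1, 1, 0)

    def test_strata_additivity(self):
        truth = pd.DataFrame([
            truth_row("s1", 0, 1000, "DEL", 2, 0.01),
            truth_row("s2", 5000, 9000, "DUP", 5, 0.5),
            truth_row("s3", 20_000, 21_000, "DEL", 7, 0.002),
        ])
        calls = pd.DataFrame([
            call_row("s1", 0, 900, "DEL", 2),
            call_row("s9", 40_000, 41_000, "DEL", 1),
        ])
        report = evaluate_calls(calls, truth, n_samples=500)
        r = report.set_index(["frequency", "length"])
        for col in ("tp", "fn"):
            assert (
                r.loc[("all", "all"), col]
                == r.loc[("rare", "all"), col] + r.loc[("common", "all"), col]
            )
            assert (
                r.loc[("all", "all"), col]
                == r.loc[("all", "short"), col] + r.loc[("all", "long"), col]
            )

    def test_sample_relabeling_symmetry(self):
        truth = pd.DataFrame([
            truth_row("s1", 0, 1000, "DEL", 2, 0.01),
            truth_row("s2", 5000, 9000, "DUP", 5, 0.5),
        ])
        calls = pd.DataFrame([
            call_row("s1", 0, 1000, "DEL", 2),
            call_row("s2", 5000, 9000, "DUP", 5),
        ])
        relabel = {"s1": "x9", "s2": "x7"}
        truth2 = truth.assign(sample_id=truth["sample_id"].map(relabel))
        calls2 = calls.assign(sample_id=calls["sample_id"].map(relabel))
        a = evaluate_calls(calls, truth, n_samples=100)
        b = evaluate_calls(calls2, truth2, n_samples=100)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_sample_error(self):
        truth = pd.DataFrame([truth_row("s1", 0, 1000, "DEL", 2, 0.01)])
        calls = pd.DataFrame([call_row("ghost", 0, 1000, "DEL", 2)])
        with pytest.raises(SimulationError, match="ghost"):
            evaluate_calls(calls, truth, n_samples=10, sample_ids=["s1", "s2"])


def test_truth_tsv_round_trip(tmp_path):
    spec = SimulationSpec(
        n_regions=50, n_samples=40, seed=2,
        cnv_events=(CnvEvent("DEL", 1, 3, 0.05), CnvEvent("DUP", 3, 2, 0.1)),
    )
    sim = simulate_coverage(spec)
    path = tmp_path / "truth.tsv"
    write_truth_tsv(sim.truth, path)
    loaded = read_truth_tsv(path)
    assert len(loaded) == len(sim.truth)
    assert list(loaded["sample_id"]) == list(sim.truth["sample_id"])
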