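"""Pipeline orchestration, file round trips, comparison, CLI smoke."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from srmeth import (
    AnalysisConfig,
    analyze,
    compare_samples,
    fit_pattern_model,
    run_pipeline,
    simulate_dataset,
    simulate_reads,
)
from srmeth.cli import main


@pytest.fixture(scope="module")
def small_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_ds")
    return simulate_dataset(
        out_dir=out, length=20_000, min_regions=40, coverage=10, seed=5
    )


class TestAnalysisConfig:
    def test_round_trip_through_file(self, tmp_path):
        config = AnalysisConfig(n_sites=10, max_span=100, min_meth=0.2, seed=7)
        path = tmp_path / "config.txt"
        config.to_file(path)
        assert AnalysisConfig.from_file(path) == config

    def test_overrides(self, tmp_path):
        AnalysisConfig().to_file(tmp_path / "c.txt")
        config = AnalysisConfig.from_file(tmp_path / "c.txt", min_reads=2)
        assert config.min_reads == 2

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            AnalysisConfig(min_meth=1.5)
        with pytest.raises(ValueError):
            AnalysisConfig(n_sites=1)


class TestRunPipeline:
    def test_outputs_parse_and_respect_schemas(self, small_dataset, tmp_path):
        paths = small_dataset.paths
        result = run_pipeline(
            paths["fasta"], paths["gff"], paths["sam"], out_dir=tmp_path / "out"
        )
        regions = pd.read_csv(tmp_path / "out" / "regions.tsv", sep="\t")
        features = pd.read_csv(tmp_path / "out" / "region_features.tsv", sep="\t")
        elements = pd.read_csv(tmp_path / "out" / "elements.tsv", sep="\t")
        vectors = pd.read_csv(tmp_path / "out" / "read_vectors.tsv", sep="\t")
        assert len(regions) == len(small_dataset.regions)
        assert set(features.region_id) <= set(regions.region_id)
        assert (features.n_reads >= 1).all()
        assert elements.n_regions_used.min() >= result.config.min_regions
        assert vectors.score.between(0, 5).all()
        assert (tmp_path / "out" / "checksums.txt").exists()

    def test_rerun_is_byte_identical(self, small_dataset, tmp_path):
        paths = small_dataset.paths
        for name in ("a", "b"):
            run_pipeline(
                paths["fasta"], paths["gff"], paths["sam"], out_dir=tmp_path / name
            )
        for filename in ("regions.tsv", "region_features.tsv", "elements.tsv"):
            assert (tmp_path / "a" / filename).read_bytes() == (
                tmp_path / "b" / filename
            ).read_bytes()

    def test_min_reads_filter_is_monotone(self, small_dataset):
        ds = small_dataset
        genome = {ds.genome.name: ds.genome}
        loose = analyze(genome, ds.elements, ds.reads, AnalysisConfig(min_reads=1))
        strict = analyze(genome, ds.elements, ds.reads, AnalysisConfig(min_reads=4))
        assert (
            strict.counts["regions_passing_filters"]
            <= loose.counts["regions_passing_filters"]
        )

    def test_chrom_mismatch_names_offender(self, small_dataset, tmp_path):
        paths = small_dataset.paths
        bad_gff = tmp_path / "bad.gff3"
        bad_gff.write_text(
            "##gff-version 3\nchrMISSING\t.\tTE\t1\t500\t.\t.\t.\tID=x\n"
        )
        with pytest.raises(ValueError, match="chrMISSING"):
            run_pipeline(paths["fasta"], bad_gff, paths["sam"])


class TestCompareSamples:
    def test_identical_samples_have_zero_deltas(self, small_dataset):
        ds = small_dataset
        genome = {ds.genome.name: ds.genome}
        result = analyze(genome, ds.elements, ds.reads)
        comparison = compare_samples(result, result)
        assert (comparison.region_deltas.delta_meth == 0).all()
        assert comparison.hypermethylated == set()
        assert comparison.counts["regions_only_a"] == 0

    def test_regime_swap_shifts_scores_consistently(self, small_dataset):
        """Swapping each region's regime between samples moves element
        pattern scores in the direction of the new regime."""
        ds = small_dataset
        genome = {ds.genome.name: ds.genome}
        result_a = analyze(genome, ds.elements, ds.reads)

        from srmeth import CMT2_LIKE, DRM2_LIKE

        swapped = {
            rid: (DRM2_LIKE if spec.regime == "cmt2_like" else CMT2_LIKE)
            for rid, spec in ds.regime_of.items()
        }
        reads_b, _ = simulate_reads(
            ds.genome, ds.regions, swapped, coverage=ds.coverage, seed=99
        )
        result_b = analyze(genome, ds.elements, reads_b)

        truth = ds.truth.regions
        regime = dict(zip(truth.region_id, truth.regime))
        passing = result_a.passing_features()
        model = fit_pattern_model(
            [f for f in passing if regime[f.region_id] == "drm2_like"],
            [f for f in passing if regime[f.region_id] == "cmt2_like"],
        )
        comparison = compare_samples(result_a, result_b, model=model)
        shift = comparison.element_shift.set_index("element_id")["shift"]
        for element_id, direction in ds.element_regime.items():
            if element_id not in shift.index:
                continue
            if direction == "cmt2_like":  # swapped to drm2 -> score drops
                assert shift[element_id] < 0
            else:
                assert shift[element_id] > 0

    def test_element_present_in_one_sample_only_is_excluded(self, small_dataset):
        ds = small_dataset
        genome = {ds.genome.name: ds.genome}
        result_a = analyze(genome, ds.elements, ds.reads)
        half_elements = ds.elements[: len(ds.elements) // 2]
        result_b = analyze(genome, half_elements, ds.reads)
        comparison = compare_samples(result_a, result_b)
        only_a = comparison.counts["regions_only_a"]
        assert only_a > 0
        assert comparison.counts["regions_shared"] + only_a == len(result_a.features)


class TestCli:
    def test_simulate_run_fit_score_peaks(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        result = runner.invoke(
            main,
            ["simulate", "--out-dir", str(sim_dir), "--length", "20000", "--seed", "5"],
        )
        assert result.exit_code == 0, result.output

        out_dir = tmp_path / "out"
        result = runner.invoke(
            main,
            [
                "run",
                str(sim_dir / "genome.fa"),
                str(sim_dir / "elements.gff3"),
                str(sim_dir / "reads.sam"),
                "--out-dir",
                str(out_dir),
            ],
        )
        assert result.exit_code == 0, result.output

        # split the feature table by true regime to fit a model
        features = pd.read_csv(out_dir / "region_features.tsv", sep="\t")
        truth = pd.read_csv(sim_dir / "truth_regions.tsv", sep="\t")
        merged = features.merge(truth[["region_id", "regime"]], on="region_id")
        merged = merged[(merged.n_reads >= 4) & (merged.mean_read_meth >= 0.10)]
        f0 = merged[merged.regime == "drm2_like"].drop(columns="regime")
        f1 = merged[merged.regime == "cmt2_like"].drop(columns="regime")
        f0.to_csv(tmp_path / "class0.tsv", sep="\t", index=False)
        f1.to_csv(tmp_path / "class1.tsv", sep="\t", index=False)
        model_file = tmp_path / "model.txt"
        result = runner.invoke(
            main,
            ["fit", str(tmp_path / "class0.tsv"), str(tmp_path / "class1.tsv"),
             "--out", str(model_file)],
        )
        assert result.exit_code == 0, result.output

        scored = tmp_path / "scored.tsv"
        result = runner.invoke(
            main,
            ["score", str(model_file), str(out_dir / "region_features.tsv"),
             "--out", str(scored)],
        )
        assert result.exit_code == 0, result.output
        frame = pd.read_csv(scored, sep="\t")
        assert frame.pattern_score.between(0, 1).all()

        result = runner.invoke(main, ["peaks", str(scored)])
        assert result.exit_code == 0, result.output
        assert result.output.startswith("n_peaks")

    def test_data_error_exit_code(self, tmp_path):
        bad = tmp_path / "empty.fa"
        bad.write_text("")
        gff = tmp_path / "a.gff3"
        gff.write_text("chr1\t.\tTE\t1\t10\t.\t.\t.\tID=x\n")
        runner = CliRunner()
        result = runner.invoke(main, ["sites", str(bad), str(gff), "--out", str(tmp_path / 'o.tsv')])
        assert result.exit_code == 1
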