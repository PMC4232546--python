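"""Synthetic data generator: determinism, planted contrast, NB moments."""

import numpy as np
import pandas as pd
import pytest

from gonadspec import io
from gonadspec.simulate import (
    GeneModel,
    SampleLayout,
    SimConfig,
    generate_gene_models,
    plant_signal,
    sample_table,
    simulate_counts,
    simulate_dataset,
    write_dataset,
)
from gonadspec.types import ConfigError, InputError


def test_empty_gene_set_gives_empty_model_list():
    assert generate_gene_models(SimConfig(n_genes=0)) == []


def test_same_seed_reproduces_models_exactly():
    cfg = SimConfig(n_genes=50, n_ovary_specific=5, n_testis_specific=5, seed=7)
    assert generate_gene_models(cfg) == generate_gene_models(cfg)


def test_degenerate_length_range_pins_every_length():
    cfg = SimConfig(n_genes=20, length_range=(500, 500))
    assert all(m.length_bp == 500 for m in generate_gene_models(cfg))


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_genes=5, n_ovary_specific=4, n_testis_specific=3),
        dict(n_genes=10, length_range=(800, 200)),
        dict(n_genes=10, effect_fold=0.5),
        dict(n_genes=10, dispersion=0.0),
        dict(n_genes=10, library_sizes=[1000] * 5),
    ],
)
def test_invalid_configuration_rejected(kwargs):
    with pytest.raises(ConfigError):
        SimConfig(**kwargs)


def test_truth_labels_partition_genes_and_match_config():
    cfg = SimConfig(n_genes=200, n_ovary_specific=30, n_testis_specific=20, seed=3)
    _, truth = plant_signal(generate_gene_models(cfg), cfg)
    counts = truth.labels.value_counts()
    assert counts["ovary_specific"] == 30
    assert counts["testis_specific"] == 20
    assert counts["background"] == 150


def test_planted_mean_ratio_equals_effect_fold_exactly():
    cfg = SimConfig(n_genes=100, n_ovary_specific=10, n_testis_specific=10,
                    effect_fold=7.0, seed=11)
    means, truth = plant_signal(generate_gene_models(cfg), cfg)
    groups = sample_table(cfg.layout)["group"]
    for label, target in (("ovary_specific", "ovary"), ("testis_specific", "testis")):
        sub = means.loc[truth.genes_with_label(label)]
        t = sub.loc[:, groups == target].to_numpy()
        o = sub.loc[:, groups != target].to_numpy()
        assert np.allclose(t.min(1) / o.max(1), 7.0, rtol=1e-12)
        assert np.allclose(o.max(1), o.min(1), rtol=1e-12)


def test_null_effect_fold_means_are_tissue_independent():
    cfg = SimConfig(n_genes=50, n_ovary_specific=10, n_testis_specific=10,
                    effect_fold=1.0, seed=2)
    means, truth = plant_signal(generate_gene_models(cfg), cfg)
    assert np.allclose(means.to_numpy().min(1), means.to_numpy().max(1))
    assert len(truth.genes_with_label("ovary_specific")) == 10


def test_planted_mean_arithmetic_from_baseline():
    # baseline_mean 20, L = 1000 bp, N = 1e6: non-ovary mean 20, ovary 200
    models = [GeneModel("g1", 1000, (), (), "ovary_specific")]
    cfg = SimConfig(n_genes=1, n_ovary_specific=1, effect_fold=10.0,
                    baseline_mean=20.0, library_sizes=[1_000_000] * 13)
    means, _ = plant_signal(models, cfg)
    groups = sample_table(cfg.layout)["group"]
    assert np.allclose(means.loc["g1", groups == "ovary"], 200.0)
    assert np.allclose(means.loc["g1", groups != "ovary"], 20.0)


def test_stage_samples_receive_background_means_only():
    cfg = SimConfig(n_genes=40, n_ovary_specific=10, effect_fold=9.0,
                    layout=SampleLayout(stage=4),
                    library_sizes=[2_000_000] * 17, seed=5)
    means, truth = plant_signal(generate_gene_models(cfg), cfg)
    groups = sample_table(cfg.layout)["group"]
    planted = truth.genes_with_label("ovary_specific")
    stage = means.loc[planted, groups == "stage"].to_numpy()
    somatic = means.loc[planted, groups == "somatic"].to_numpy()
    assert np.allclose(stage.mean(1), somatic.mean(1), rtol=1e-12)


def test_expected_column_sums_track_configured_library_sizes():
    lib = [3_000_000, 5_000_000, 8_000_000] + [4_000_000] * 10
    cfg = SimConfig(n_genes=1000, library_sizes=lib, seed=9)
    means, _ = plant_signal(generate_gene_models(cfg), cfg)
    ratio = means.sum(axis=0).to_numpy() / np.asarray(lib, dtype=float)
    assert ratio.max() / ratio.min() < 1.01


def test_counts_zero_mean_yields_zero_counts():
    means = pd.DataFrame(np.zeros((3, 4)), index=list("abc"), columns=list("wxyz"))
    cm = simulate_counts(means, dispersion=5.0, seed=0)
    assert (cm.counts.to_numpy() == 0).all()


def test_counts_negative_mean_rejected():
    means = pd.DataFrame([[-1.0]], index=["a"], columns=["s"])
    with pytest.raises(InputError):
        simulate_counts(means, dispersion=5.0, seed=0)


def test_nb_moments_match_specification():
    # one gene, 10,000 replicate columns
    cols = [f"s{i}" for i in range(10_000)]
    means = pd.DataFrame(np.full((1, 10_000), 100.0), index=["g"], columns=cols)
    # near-Poisson limit: empirical mean within 2% of the target
    draws = simulate_counts(means, dispersion=1e6, seed=42).counts.to_numpy().ravel()
    assert abs(draws.mean() - 100.0) / 100.0 < 0.02
    # overdispersed: variance approaches m + m^2/r and exceeds m
    m, r = 50.0, 5.0
    means = pd.DataFrame(np.full((1, 10_000), m), index=["g"], columns=cols)
    draws = simulate_counts(means, dispersion=r, seed=42).counts.to_numpy().ravel()
    expected_var = m + m * m / r
    assert draws.var() > m
    assert abs(draws.var() - expected_var) / expected_var < 0.10


def test_library_size_recorded_as_column_totals():
    cfg = SimConfig(n_genes=100, seed=1)
    counts, *_ = simulate_dataset(cfg)
    assert (counts.library_size == counts.counts.sum(axis=0)).all()


def test_dataset_round_trips_through_readers(tmp_path):
    cfg = SimConfig(n_genes=30, n_ovary_specific=5, n_testis_specific=5, seed=4)
    counts, models, metadata, truth = simulate_dataset(cfg)
    paths = write_dataset(counts, models, metadata, truth, tmp_path)

    back = io.read_counts(paths["counts"])
    pd.testing.assert_frame_equal(back.counts, counts.counts)
    models_df = io.read_models(paths["models"])
    assert list(models_df.index) == [m.gene_id for m in models]
    assert models_df["length_bp"].tolist() == [m.length_bp for m in models]
    go_map, _ = io.read_term_map(paths["go_map"])
    assert go_map == {m.gene_id: set(m.go_terms) for m in models if m.go_terms}
    meta = io.read_metadata(paths["metadata"])
    assert list(meta.index) == list(metadata.index)
    truth_back = io.read_truth(paths["truth"])
    assert len(truth_back) == cfg.n_genes
    assert (truth_back == truth.labels).all()


def test_write_dataset_empty_gene_set(tmp_path):
    cfg = SimConfig(n_genes=0)
    counts, models, metadata, truth = simulate_dataset(cfg)
    paths = write_dataset(counts, models, metadata, truth, tmp_path)
    assert io.read_counts(paths["counts"]).counts.shape[0] == 0
    assert len(io.read_truth(paths["truth"])) == 0


def test_same_seed_writes_byte_identical_datasets(tmp_path):
    cfg = SimConfig(n_genes=60, n_ovary_specific=8, n_testis_specific=8, seed=13)
    outs = []
    for sub in ("a", "b"):
        counts, models, metadata, truth = simulate_dataset(cfg)
        outs.append(write_dataset(counts, models, metadata, truth, tmp_path / sub))
    for key in outs[0]:
        a = open(outs[0][key], "rb").read()
        b = open(outs[1][key], "rb").read()
        assert a == b, f"{key} differs between identical-seed runs"
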