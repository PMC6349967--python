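import dataclasses

import numpy as np
import pytest

from mlenz.hierarchy_pipeline import (
    Annotation,
    PartialFailure,
    PipelineConfig,
    annotate_records,
    encode_dataset,
    evaluate,
    predict_is_multifunctional,
    predict_main_classes,
    run_pipeline,
    split_indices,
    train_binary,
    train_multilabel,
    write_annotations_tsv,
)
from mlenz.net_core import ModelConfig, build_model, save_model
from mlenz.rank_loss import LabelSet
from mlenz.synthetic_data import SimSpec, generate, write_dataset
from mlenz.threshold_calibration import ThresholdModel

TINY = ModelConfig(
    q_classes=6, conv_filters=((4, 8), (8, 8)), fc_widths=(16, 32),
    dropout=0.0, epochs=2, seed=0,
)


@pytest.fixture(scope="module")
def encoded(small_dataset):
    return encode_dataset(small_dataset)


@pytest.fixture(scope="module")
def binary_model(encoded, small_dataset):
    return train_binary(
        encoded, small_dataset.multi_flags,
        dataclasses.replace(TINY, q_classes=1), weighted=True,
    )


@pytest.fixture(scope="module")
def multilabel_with_threshold(encoded, small_dataset):
    return train_multilabel(encoded, small_dataset.labels, TINY)


class TestBinaryLevel:
    def test_decision_rule_and_score(self, encoded, binary_model):
        decision, score = predict_is_multifunctional(encoded[0], binary_model)
        assert isinstance(decision, bool)
        assert 0 < score < 1
        assert decision == (score > 0.5)

    def test_cutoff_is_strict(self, encoded, binary_model):
        _, score = predict_is_multifunctional(encoded[0], binary_model)
        decision, _ = predict_is_multifunctional(encoded[0], binary_model, cutoff=score)
        assert decision is False

    def test_wrong_arity_model_rejected(self, encoded, multilabel_with_threshold):
        model, _ = multilabel_with_threshold
        with pytest.raises(ValueError, match="q_classes=1"):
            predict_is_multifunctional(encoded[0], model)


class TestMultilabelLevel:
    def test_never_empty_and_deterministic(self, encoded, multilabel_with_threshold):
        model, tmodel = multilabel_with_threshold
        for x in encoded[:10]:
            a = predict_main_classes(x, model, tmodel)
            b = predict_main_classes(x, model, tmodel)
            assert len(a.members) >= 1
            assert a.members == b.members

    def test_worked_example_threshold_composition(self, worked_example):
        scores, _ = worked_example
        tmodel = ThresholdModel(w=np.zeros(6), b=0.55)
        from mlenz.threshold_calibration import apply_threshold

        assert apply_threshold(scores, tmodel).members == frozenset({1, 2})


class TestSplits:
    def test_split_is_pure_function_of_inputs(self):
        ids = [f"s{i}" for i in range(40)]
        a = split_indices(ids, seed=3, run_index=1, train_fraction=0.7)
        b = split_indices(ids, seed=3, run_index=1, train_fraction=0.7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_runs_and_seeds_vary_the_split(self):
        ids = [f"s{i}" for i in range(40)]
        base = split_indices(ids, 3, 0, 0.7)
        other_run = split_indices(ids, 3, 1, 0.7)
        other_seed = split_indices(ids, 4, 0, 0.7)
        assert not np.array_equal(base[0], other_run[0])
        assert not np.array_equal(base[0], other_seed[0])

    def test_partition_is_exhaustive_and_disjoint(self):
        ids = [f"s{i}" for i in range(33)]
        train, test = split_indices(ids, 0, 0, 0.7)
        combined = np.sort(np.concatenate([train, test]))
        np.testing.assert_array_equal(combined, np.arange(33))
        assert len(train) == round(0.7 * 33)


class TestEvaluate:
    def test_repeated_splits_reproducible(self, small_dataset):
        _, summary_a = evaluate(small_dataset, TINY, r_splits=2, seed=5)
        _, summary_b = evaluate(small_dataset, TINY, r_splits=2, seed=5)
        assert summary_a == summary_b

    def test_summary_shape(self, small_dataset):
        reports, summary = evaluate(small_dataset, TINY, r_splits=2, seed=5)
        assert len(reports) == 2
        assert set(summary) == set(reports[0].as_dict())
        for mean, sd in summary.values():
            assert 0 <= mean <= 1 and sd >= 0

    def test_tiny_dataset_rejected(self):
        ds = generate(SimSpec(n=5, seed=1))
        with pytest.raises(ValueError, match="too small"):
            evaluate(ds, TINY, r_splits=1)


class TestAnnotation:
    def test_main_classes_present_iff_multifunctional(self):
        with pytest.raises(ValueError, match="iff"):
            Annotation(id="x", is_multifunctional=True, score=0.9, main_classes=None)

    def test_routing_exhaustive(self, small_dataset, binary_model,
                                multilabel_with_threshold, tmp_path):
        model, tmodel = multilabel_with_threshold
        config = PipelineConfig()
        annotations = annotate_records(
            small_dataset.records[:20], binary_model, model, tmodel, config
        )
        assert len(annotations) == 20
        for ann in annotations:
            if ann.is_multifunctional:
                assert len(ann.main_classes.members) >= 1
            else:
                assert ann.main_classes is None
        out = tmp_path / "annotations.tsv"
        write_annotations_tsv(annotations, out)
        assert len(out.read_text().splitlines()) == 21


class TestRunPipeline:
    def _write_models(self, tmp_path, binary_model, multilabel_with_threshold):
        model, tmodel = multilabel_with_threshold
        bpath = tmp_path / "binary.npz"
        mpath = tmp_path / "multi.npz"
        save_model(binary_model, bpath)
        save_model(model, mpath, threshold=tmodel)
        return bpath, mpath

    def test_end_to_end_annotation(self, tmp_path, small_dataset, binary_model,
                                   multilabel_with_threshold):
        bpath, mpath = self._write_models(tmp_path, binary_model, multilabel_with_threshold)
        ds = generate(SimSpec(n=10, seed=77, multi_fraction=0.5))
        data_dir = tmp_path / "data"
        write_dataset(ds, data_dir)
        config = PipelineConfig(
            binary_model_path=bpath, multilabel_model_path=mpath,
            domains_dir=data_dir / "domains",
        )
        annotations = run_pipeline(data_dir / "sequences.fasta", config)
        assert [a.id for a in annotations] == [r.id for r in ds.records]

    def test_rerun_is_identical(self, tmp_path, small_dataset, binary_model,
                                multilabel_with_threshold):
        bpath, mpath = self._write_models(tmp_path, binary_model, multilabel_with_threshold)
        ds = generate(SimSpec(n=8, seed=78))
        data_dir = tmp_path / "data"
        write_dataset(ds, data_dir)
        config = PipelineConfig(
            binary_model_path=bpath, multilabel_model_path=mpath,
            domains_dir=data_dir / "domains",
        )
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_annotations_tsv(run_pipeline(data_dir / "sequences.fasta", config), out1)
        write_annotations_tsv(run_pipeline(data_dir / "sequences.fasta", config), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_partial_failure_isolates_bad_record(self, tmp_path, binary_model,
                                                 multilabel_with_threshold):
        model, tmodel = multilabel_with_threshold
        bpath, mpath = self._write_models(tmp_path, binary_model, multilabel_with_threshold)
        ds = generate(SimSpec(n=9, seed=79))
        data_dir = tmp_path / "data"
        write_dataset(ds, data_dir, pssm_fixtures=True)
        # corrupt one record's PSSM so parsing fails for it alone
        bad_id = ds.records[4].id
        pssm_dir = data_dir / "pssm"
        (pssm_dir / f"{bad_id}.pssm").write_text("1 M garbage\n")
        config = PipelineConfig(
            binary_model_path=bpath, multilabel_model_path=mpath,
            pssm_mode="parsed", pssm_dir=pssm_dir,
            domains_dir=data_dir / "domains",
        )
        with pytest.raises(PartialFailure) as err:
            run_pipeline(data_dir / "sequences.fasta", config)
        assert set(err.value.errors) == {bad_id}
        assert len(err.value.annotations) == 8

    def test_missing_threshold_rejected(self, tmp_path, binary_model,
                                        multilabel_with_threshold):
        model, _ = multilabel_with_threshold
        bpath = tmp_path / "binary.npz"
        mpath = tmp_path / "multi.npz"
        save_model(binary_model, bpath)
        save_model(model, mpath)  # no threshold embedded
        config = PipelineConfig(binary_model_path=bpath, multilabel_model_path=mpath)
        ds = generate(SimSpec(n=3, seed=80))
        data_dir = tmp_path / "data"
        write_dataset(ds, data_dir)
        with pytest.raises(ValueError, match="threshold"):
            run_pipeline(data_dir / "sequences.fasta", config)


def test_pipeline_config_validation():
    with pytest.raises(ValueError, match="split"):
        PipelineConfig(split=1.5)
    with pytest.raises(ValueError, match="pssm_mode"):
        PipelineConfig(pssm_mode="magic")
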