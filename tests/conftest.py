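import numpy as np
import pytest

from marrowdet.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Width-scaled detector config small enough for CPU unit tests."""
    return ModelConfig(width_scale=0.125, input_size=192)


@pytest.fixture(scope="session")
def smear_dataset_16(tmp_path_factory):
    """16 synthetic smear images at the study defaults (session-cached)."""
    from marrowdet.synth import SmearSpec, generate_dataset

    out = tmp_path_factory.mktemp("smears16")
    return generate_dataset(SmearSpec(), 16, out, seed=1)


@pytest.fixture(scope="session")
def overfit_smoke(smear_dataset_16, tmp_path_factory):
    """Overfit a width-scaled detector on 16 synthetic smears (200 epochs).

    Anchors are clustered from the 16 images' labels; the loss weights and
    focal alpha follow the desk-scale smoke configuration documented in
    docs/methods.md.  Returns the training summary plus the mAP@0.5 of the
    final model re-evaluated on the training images at confidence 0.1.
    """
    from marrowdet.anchors import anchors_from_labels
    from marrowdet.data import DetectionDataset, read_yolo_labels
    from marrowdet.losses import FocalParams, LossWeights
    from marrowdet.model import ModelConfig, load_checkpoint
    from marrowdet.postprocess import NMSConfig
    from marrowdet.train import TrainConfig, evaluate_model, train

    index = smear_dataset_16
    input_size = 128
    wh = np.asarray(
        [(a.w, a.h) for p in index.label_paths for a in read_yolo_labels(p)]
    )
    model_cfg = ModelConfig(
        width_scale=0.125, input_size=input_size,
        anchors=anchors_from_labels(wh, input_size, rng_seed=0).for_model_config(),
    )
    train_cfg = TrainConfig(
        epochs=200, batch_size=4, lr0=0.15, lr_final_frac=0.05,
        warmup_epochs=6, seed=0, mosaic=False, eval_every=200,
    )
    out = tmp_path_factory.mktemp("smoke_run")
    summary = train(
        train_cfg, model_cfg, index, out,
        loss_weights=LossWeights(w_box=0.5, w_cls=2.0, w_obj=0.7),
        focal=FocalParams(alpha=0.75, gamma=2.0),
        soft_obj=False,
    )
    model, _ = load_checkpoint(out / "last.npz")
    val = evaluate_model(
        model, DetectionDataset(index, input_size, mosaic=False),
        NMSConfig(conf_threshold=0.1),
    )
    summary["train_map50"] = val["map50"]
    return summary
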