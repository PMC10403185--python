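import numpy as np
import pytest

from massfuse.data_io import ModalityVolume, SegmentationMask
from massfuse.nn import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_volume(rng):
    vox = rng.normal(100.0, 10.0, size=(10, 10, 10)).astype(np.float32)
    return ModalityVolume(voxels=vox, spacing=(1.0, 1.0, 1.0), modality="d2",
                          case_id="case0")


@pytest.fixture
def ball_mask():
    """Solid ball of radius 3 centered in a 10^3 grid, drawn on d2."""
    idx = np.indices((10, 10, 10))
    dist = np.sqrt(((idx - 4.5) ** 2).sum(axis=0))
    return SegmentationMask(voxels=(dist <= 3.0).astype(np.uint8),
                            case_id="case0", reference_modality="d2")


@pytest.fixture
def small_net_config():
    """Down-scaled network for fast functional tests."""
    return NetworkConfig(in_channels=2, stage_plan=((1, 4, 8), (1, 8, 4)),
                         fc_widths=(8 * 4 ** 3, 16), spatial_kernel=3,
                         reduction=2)


def make_phantom_dataset(tmp_path, n=12, difficulty=5.0, seed=0, side=16,
                         modalities=("t2wi", "nonfs_t1wi", "d1", "d2"),
                         include_sobel=True, contrast_means=None,
                         morphology_by_class=True, contrast_sampler=None):
    """Generate a phantom cohort on disk and preprocess it into a TensorDataset."""
    from massfuse.data_io import load_mask, load_volume
    from massfuse.phantoms import generate_cohort
    from massfuse.preprocessing import preprocess_case
    from massfuse.training import TensorDataset

    manifest = generate_cohort(n=n, prevalence=0.5, difficulty=difficulty,
                               seed=seed, out_dir=tmp_path,
                               modalities=modalities,
                               contrast_means=contrast_means,
                               morphology_by_class=morphology_by_class,
                               contrast_sampler=contrast_sampler)
    ids, xs, ys = [], [], []
    for rec in manifest.records:
        ref = load_volume(rec.paths[rec.reference_modality],
                          rec.reference_modality, rec.case_id)
        mask = load_mask(rec.mask_path, ref)
        vols = [load_volume(rec.paths[m], m, rec.case_id) for m in modalities]
        tensor, _, _ = preprocess_case(ref, mask, vols, label=rec.label,
                                       target_side=side,
                                       include_sobel=include_sobel)
        ids.append(rec.case_id)
        xs.append(tensor.channels)
        ys.append(1 if rec.label == "malignant" else 0)
    return manifest, TensorDataset(ids, np.stack(xs), np.array(ys))


# ---------------------------------------------------------------------------
# Heavy, session-scoped end-to-end training fixtures (shared by module
# invariant tests and the acceptance suite). All runs are scaled down:
# n=60 phantoms, 16^3 tensors, the proportionally reduced network from
# default_config_for, <=10 epochs. Seeds are fixed throughout.
# ---------------------------------------------------------------------------

HEAVY_N = 60
HEAVY_SIZES = (50, 10, 0)      # folds rotate over all 60; no fixed test set


def run_heavy_cv(dataset, seed=0):
    from massfuse.nn import default_config_for
    from massfuse.training import Hyperparams, make_split, run_cv

    labels = {c: ("malignant" if y else "benign")
              for c, y in zip(dataset.case_ids, dataset.y)}
    split = make_split(labels, HEAVY_SIZES, seed=seed)
    config = default_config_for(dataset.x.shape[1], side=dataset.x.shape[2])
    hyper = Hyperparams(lr=3e-3, batch_size=8, max_epochs=10, patience=3,
                        seed=seed)
    return run_cv(dataset, split, config, hyper)


def oof_auc(result):
    from massfuse.evaluation import auc_mann_whitney
    return auc_mann_whitney(result.oof.labels, result.oof.scores)


@pytest.fixture(scope="session")
def separable_run(tmp_path_factory):
    """Difficulty-5 default (morphology + intensity) cohort and its CV result."""
    tmp = tmp_path_factory.mktemp("separable")
    _, ds = make_phantom_dataset(tmp, n=HEAVY_N, difficulty=5.0, seed=42)
    return ds, run_heavy_cv(ds, seed=0)


@pytest.fixture(scope="session")
def shuffled_label_auc(separable_run):
    """Pooled out-of-fold AUC after permuting the labels of the separable cohort."""
    from massfuse.training import TensorDataset
    ds, _ = separable_run
    y = np.random.default_rng(777).permutation(ds.y)
    shuffled = TensorDataset(ds.case_ids, ds.x, y)
    return oof_auc(run_heavy_cv(shuffled, seed=0))


@pytest.fixture(scope="session")
def intensity_sweep_aucs(tmp_path_factory):
    """Pooled OOF AUC per difficulty with intensity-only class signal."""
    out = {}
    for difficulty in (0.0, 1.0, 3.0, 5.0):
        tmp = tmp_path_factory.mktemp(f"sweep{int(difficulty)}")
        _, ds = make_phantom_dataset(tmp, n=HEAVY_N, difficulty=difficulty,
                                     seed=42, morphology_by_class=False)
        out[difficulty] = oof_auc(run_heavy_cv(ds, seed=0))
    return out


def complementary_contrast_sampler(label, rng):
    """Each malignant case is conspicuous in exactly one of t2wi / d2.

    A single-modal model is blind to half the positives (AUC ceiling ~0.75);
    the fused model sees every case's signal. d1 never carries signal.
    """
    base = {"t2wi": 25.0, "d1": 7.5, "d2": 25.0}
    if label == "malignant":
        hot = "t2wi" if rng.random() < 0.5 else "d2"
        base[hot] += 30.0
    return base


@pytest.fixture(scope="session")
def complementary_aucs(tmp_path_factory):
    """Fused (t2wi+d2) vs single-modal models on a split-signal cohort."""
    out = {}
    for name, mods, sobel in [("fused", ("t2wi", "d2"), True),
                              ("t2wi", ("t2wi",), False),
                              ("d2", ("d2",), False),
                              ("d1", ("d1",), False)]:
        tmp = tmp_path_factory.mktemp(f"comp_{name}")
        _, ds = make_phantom_dataset(tmp, n=HEAVY_N, difficulty=0.0, seed=42,
                                     modalities=mods, include_sobel=sobel,
                                     morphology_by_class=False,
                                     contrast_sampler=complementary_contrast_sampler)
        out[name] = oof_auc(run_heavy_cv(ds, seed=0))
    return out
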