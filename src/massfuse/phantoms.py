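"""Co-registered multi-modal 3D lesion phantoms.

Benign lesions are smoothed ellipsoids; malignant lesions carry radial
spikes (spiculation). Each modality is rendered on its own grid from the
same physical shape, so the modalities are co-registered by construction.
Class separation is controlled by a single ``difficulty`` scale: the
class-conditional lesion-contrast means differ by ``difficulty`` times the
noise standard deviation (two-Gaussian Bayes AUC = Phi(difficulty / sqrt 2)).
Intensity profiles give the pipeline learnable structure; they make no claim
of radiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import (CaseRecord, CohortManifest, ModalityVolume,
                      SegmentationMask, save_volume, write_manifest)

#: per-modality (grid shape, mm spacing); T2WI deliberately coarse through-plane
DEFAULT_GRIDS: dict[str, tuple[tuple[int, int, int], tuple[float, float, float]]] = {
    "t2wi": ((40, 40, 14), (1.0, 1.0, 3.0)),
    "nonfs_t1wi": ((40, 40, 30), (1.0, 1.0, 1.4)),
    "d1": ((40, 40, 36), (1.0, 1.0, 1.2)),
    "d2": ((40, 40, 36), (1.0, 1.0, 1.2)),
    "d4": ((40, 40, 36), (1.0, 1.0, 1.2)),
    "d6": ((40, 40, 36), (1.0, 1.0, 1.2)),
}

REFERENCE_MODALITY = "d2"


@dataclass
class ModalityProfile:
    lesion_contrast: float   # lesion mean minus background mean
    background: float = 100.0
    noise_sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class PhantomSpec:
    class_label: str                     # "benign" | "malignant"
    base_radius: float = 7.0             # mm
    spike_count: int = 0
    spike_length: float = 4.0            # mm beyond the ellipsoid surface
    smoothness: float = 1.0              # Gaussian blur sigma (benign rendering)
    modality_profiles: dict[str, ModalityProfile] = field(default_factory=dict)
    grids: dict[str, tuple[tuple[int, int, int], tuple[float, float, float]]] = \
        field(default_factory=lambda: dict(DEFAULT_GRIDS))
    seed: int = 0
    case_id: str = "case"

    def __post_init__(self) -> None:
        if self.class_label not in ("benign", "malignant"):
            raise ValueError(f"bad class label {self.class_label!r}")
        if not self.modality_profiles:
            self.modality_profiles = {m: ModalityProfile(40.0) for m in self.grids}
        for mod, (shape, spacing) in self.grids.items():
            half_extent = min(dim * sp for dim, sp in zip(shape, spacing)) / 2.0
            if self.base_radius + self.spike_length + 2.0 * max(spacing) > half_extent:
                raise ValueError(
                    f"lesion (r={self.base_radius}, spikes {self.spike_length}) "
                    f"does not fit the {mod} grid with a 2-voxel margin")


@dataclass
class PhantomCase:
    volumes: dict[str, ModalityVolume]
    mask: SegmentationMask
    label: str
    spec: PhantomSpec


def _lesion_indicator(shape: tuple[int, int, int], spacing: tuple[float, float, float],
                      center_phys: np.ndarray, radii_phys: np.ndarray,
                      spike_dirs: np.ndarray, spike_length: float,
                      spike_radius: float = 1.2) -> np.ndarray:
    """Binary lesion support on one grid: ellipsoid plus radial spike segments."""
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    pts = np.stack(grids, axis=-1) - center_phys  # physical offsets from center
    inside = (np.sum((pts / radii_phys) ** 2, axis=-1) <= 1.0)
    r_mean = float(radii_phys.mean())
    for d in spike_dirs:
        t = pts @ d  # signed distance along the spike axis
        radial = np.linalg.norm(pts - t[..., None] * d, axis=-1)
        taper = np.clip(1.0 - t / (r_mean + spike_length), 0.0, 1.0)
        on_spike = (t >= 0) & (t <= r_mean + spike_length) \
            & (radial <= spike_radius * (0.4 + 0.6 * taper))
        inside |= on_spike
    return inside.astype(np.uint8)


def render_lesion(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom on every modality grid; deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    ref_shape, ref_spacing = spec.grids[REFERENCE_MODALITY]
    fov = np.array([n * s for n, s in zip(ref_shape, ref_spacing)])
    center = fov / 2.0 + rng.uniform(-1.5, 1.5, size=3)
    radii = spec.base_radius * rng.uniform(0.85, 1.05, size=3)
    if spec.spike_count > 0:
        dirs = rng.normal(size=(spec.spike_count, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    else:
        dirs = np.zeros((0, 3))
    mask_vox = _lesion_indicator(ref_shape, ref_spacing, center, radii, dirs,
                                 spec.spike_length)
    if mask_vox.sum() == 0:
        raise ValueError("rendered lesion has empty support")
    mask = SegmentationMask(voxels=mask_vox, case_id=spec.case_id,
                            reference_modality=REFERENCE_MODALITY)
    volumes: dict[str, ModalityVolume] = {}
    for mod, profile in spec.modality_profiles.items():
        shape, spacing = spec.grids[mod]
        indicator = _lesion_indicator(shape, spacing, center, radii, dirs,
                                      spec.spike_length).astype(float)
        if spec.smoothness > 0:
            sigma_vox = [spec.smoothness / s for s in spacing]
            indicator = ndimage.gaussian_filter(indicator, sigma=sigma_vox)
        vox = profile.background + profile.lesion_contrast * indicator
        vox = vox + rng.normal(0.0, profile.noise_sigma, size=shape)
        volumes[mod] = ModalityVolume(voxels=vox.astype(np.float32),
                                      spacing=spacing, modality=mod,
                                      case_id=spec.case_id)
    return PhantomCase(volumes=volumes, mask=mask, label=spec.class_label,
                       spec=spec)


def class_contrast_means(difficulty: float, noise_sigma: float = 10.0,
                         base_contrast: float = 25.0) -> dict[str, dict[str, float]]:
    """Class-conditional lesion-contrast means per modality.

    Malignant lesions get a larger early-enhancement jump (d2 - d1) and their
    means exceed the benign means by ``difficulty * noise_sigma``.
    """
    delta = difficulty * noise_sigma
    benign = {"t2wi": base_contrast, "nonfs_t1wi": base_contrast,
              "d1": 0.3 * base_contrast, "d2": base_contrast,
              "d4": base_contrast, "d6": base_contrast}
    # pre-contrast d1 carries no class signal; the post-contrast phases do,
    # so the malignant d2 - d1 enhancement jump exceeds the benign one
    malignant = {m: (c if m == "d1" else c + delta) for m, c in benign.items()}
    return {"benign": benign, "malignant": malignant}


def generate_cohort(n: int, prevalence: float, difficulty: float, seed: int,
                    out_dir: str | Path,
                    modalities: tuple[str, ...] = ("t2wi", "nonfs_t1wi", "d1", "d2"),
                    noise_sigma: float = 10.0,
                    contrast_means: dict[str, dict[str, float]] | None = None,
                    morphology_by_class: bool = True,
                    contrast_sampler=None,
                    ) -> CohortManifest:
    """Write a phantom cohort (NIfTI volumes + masks + manifest CSV) to disk.

    ``contrast_means`` overrides the class-conditional lesion-contrast means
    per modality, e.g. to put signal in only one modality. With
    ``morphology_by_class=False`` both classes are rendered as smooth
    ellipsoids so intensity profiles are the only class signal.
    ``contrast_sampler(label, rng) -> {modality: contrast}``, when given,
    draws per-case contrasts instead (e.g. complementary-information cohorts
    where each malignant case is conspicuous in only one modality).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be strictly between 0 and 1")
    n_mal = int(round(n * prevalence))
    n_ben = n - n_mal
    if n_mal < 1 or n_ben < 1:
        raise ValueError(f"n={n} too small for both classes at prevalence {prevalence}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if contrast_means is None:
        contrast_means = class_contrast_means(difficulty, noise_sigma)
    rng = np.random.default_rng(seed)
    labels = ["malignant"] * n_mal + ["benign"] * n_ben
    rng.shuffle(labels)
    records = []
    # the reference modality is always rendered: its grid defines the mask
    # and the bounding cube even when it is not an input channel
    rendered = tuple(dict.fromkeys(modalities + (REFERENCE_MODALITY,)))
    for i, label in enumerate(labels):
        case_id = f"phantom_{i:04d}"
        case_means = contrast_sampler(label, rng) if contrast_sampler \
            else contrast_means[label]
        profiles = {m: ModalityProfile(case_means[m], noise_sigma=noise_sigma)
                    for m in rendered}
        spiculated = morphology_by_class and label == "malignant"
        smooth = (not morphology_by_class) or label == "benign"
        spec = PhantomSpec(
            class_label=label,
            base_radius=float(rng.uniform(6.0, 8.5)),
            spike_count=int(rng.integers(8, 14)) if spiculated else 0,
            spike_length=4.0 if spiculated else 0.0,
            smoothness=1.2 if smooth else 0.0,
            modality_profiles=profiles,
            grids={m: DEFAULT_GRIDS[m] for m in rendered},
            seed=int(rng.integers(0, 2 ** 31)),
            case_id=case_id,
        )
        case = render_lesion(spec)
        paths = {}
        for mod, vol in case.volumes.items():
            p = out_dir / f"{case_id}_{mod}.nii"
            save_volume(vol, p)
            paths[mod] = p
        mask_path = out_dir / f"{case_id}_mask.nii"
        save_volume(ModalityVolume(voxels=case.mask.voxels,
                                   spacing=spec.grids[REFERENCE_MODALITY][1],
                                   modality=REFERENCE_MODALITY, case_id=case_id),
                    mask_path)
        records.append(CaseRecord(case_id=case_id, label=label, paths=paths,
                                  mask_path=mask_path,
                                  reference_modality=REFERENCE_MODALITY))
    manifest = CohortManifest(records=records)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
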