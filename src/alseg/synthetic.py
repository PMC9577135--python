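"""Synthetic histology ROI cohorts with the structure of an annotated
oral-cavity-cancer dataset.

Each ROI is a label map built from layered, spatially correlated random
blobs — a stroma background, tumor nests (optionally with keratin-pearl
cores), lymphocytic infiltrates that hug tumor borders, occasional
background/adipose margins, and rare small patches of mucosa, blood, muscle,
nerves, necrosis, and junk — rendered to an RGB image by per-class H&E-like
color distributions plus correlated noise whose amplitude grows with a
``hardness`` knob. Class prevalence is highly imbalanced (tumor, stroma, and
lymphocytes dominate; mucosa, blood, and muscle are rare and appear in only a
fraction of ROIs), so ROIs differ in which structures they contain and an
informed sample-selection strategy has signal to exploit. A configurable
fraction of labeled pixels is re-masked to the avoid class, emulating
annotators labeling only regions of high confidence. ROIs are grouped by
patient, with one shared appearance offset per patient so patient-level
splitting is consequential. Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .legend import ClassLegend, LabelMap, RoiSample, table1_legend

__all__ = ["CohortConfig", "generate_cohort", "paper_like_preset", "desk_preset"]


# Target prevalence of each class when it occurs in a ROI, and the probability
# that it occurs at all. Tumor/stroma/lymphocytes dominate; mucosa, blood,
# muscle and the other rare classes appear only in a minority of ROIs.
DEFAULT_PREVALENCE = {
    "Tumor": 0.22,
    "Lymphocytes": 0.12,
    "Background/Adipose": 0.08,
    "Mucosa": 0.05,
    "Muscle": 0.05,
    "Necrosis": 0.03,
    "Nerves": 0.02,
    "Junk": 0.02,
    "Blood": 0.015,
    # Keratin Pearl is a fraction of the tumor area, not of the image
}
DEFAULT_PRESENCE = {
    "Tumor": 1.0,
    "Lymphocytes": 0.9,
    "Background/Adipose": 0.7,
    "Mucosa": 0.25,
    "Muscle": 0.25,
    "Necrosis": 0.25,
    "Nerves": 0.3,
    "Junk": 0.3,
    "Blood": 0.3,
}
KERATIN_FRACTION_OF_TUMOR = 0.15
KERATIN_PRESENCE = 0.5

# Gaussian blob scale per class, in microns (converted by each config's mpp).
SIGMA_UM = {
    "Background/Adipose": 26.0,
    "Tumor": 18.0,
    "Lymphocytes": 13.0,
    "Mucosa": 16.0,
    "Muscle": 16.0,
    "Necrosis": 13.0,
    "Nerves": 9.0,
    "Junk": 11.0,
    "Blood": 8.0,
}

# H&E-like mean RGB per class: pink stroma, purple tumor, dark lymphocyte
# infiltrate, near-white background/adipose, bright eosinophilic keratin.
CLASS_COLOR_MEANS = {
    "Stroma": (232, 178, 192),
    "Tumor": (126, 94, 166),
    "Lymphocytes": (88, 62, 130),
    "Mucosa": (206, 150, 200),
    "Background/Adipose": (244, 243, 245),
    "Blood": (186, 48, 56),
    "Nerves": (222, 188, 158),
    "Necrosis": (168, 146, 122),
    "Keratin Pearl": (240, 154, 160),
    "Muscle": (202, 110, 122),
    "Junk": (148, 150, 152),
}

# Layering order: later entries overwrite earlier ones.
_LAYER_ORDER = [
    "Background/Adipose",
    "Mucosa",
    "Muscle",
    "Necrosis",
    "Nerves",
    "Junk",
    "Tumor",
    "Lymphocytes",
    "Blood",
]


class GenerationError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Study-condition knobs for a synthetic cohort.

    ``hardness`` in [0, 1] scales the correlated appearance noise: 0 gives
    nearly noiseless class colors, 1 makes classes hard to separate.
    ``n_extra_rois`` patients (taken from the front) contribute a second ROI.
    """

    n_patients: int = 23
    rois_per_patient: int = 1
    n_extra_rois: int = 1
    image_size: int = 128
    mpp: float = 2.0
    class_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    presence_prob: dict = field(default_factory=lambda: dict(DEFAULT_PRESENCE))
    avoid_fraction: float = 0.1
    hardness: float = 0.35
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_prevalence.values())
        if total > 1.0:
            raise GenerationError(f"class prevalences sum to {total} > 1")
        if self.image_size < 16:
            raise GenerationError("image_size too small to host the blob grammar")
        if not 0 <= self.avoid_fraction < 1:
            raise GenerationError("avoid_fraction must be in [0, 1)")
        if not 0 <= self.hardness <= 1:
            raise GenerationError("hardness must be in [0, 1]")


def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    f = ndi.gaussian_filter(rng.standard_normal((size, size)), sigma=sigma)
    return (f - f.mean()) / (f.std() + 1e-9)


def _threshold_mask(fld: np.ndarray, fraction: float) -> np.ndarray:
    if fraction <= 0:
        return np.zeros_like(fld, dtype=bool)
    return fld >= np.quantile(fld, 1.0 - fraction)


def _build_label_map(cfg: CohortConfig, legend: ClassLegend, rng: np.random.Generator):
    s = cfg.image_size
    labels = np.full((s, s), legend.index_of("Stroma"), dtype=np.int16)

    present = {
        name: rng.random() < cfg.presence_prob.get(name, 0.0) for name in _LAYER_ORDER
    }
    keratin_here = present["Tumor"] and rng.random() < KERATIN_PRESENCE

    # structure scale is fixed in microns (a tumor nest does not grow with
    # the ROI), so larger ROIs average over more independent blobs and the
    # realized class fractions tighten around their targets
    sigmas = {name: um / cfg.mpp for name, um in SIGMA_UM.items()}

    tumor_mask = np.zeros((s, s), dtype=bool)
    for name in _LAYER_ORDER:
        if not present[name]:
            continue
        prev = cfg.class_prevalence.get(name, 0.0)
        if prev <= 0:
            continue
        fld = _smooth_field(rng, s, sigmas[name])
        if name == "Tumor":
            # oversample so the keratin carve-out leaves ~prev of tumor
            eff = prev / (1 - KERATIN_FRACTION_OF_TUMOR) if keratin_here else prev
            tumor_fld = fld
            mask = _threshold_mask(fld, min(eff, 0.95))
            tumor_mask = mask
        elif name == "Lymphocytes":
            # infiltrates favor the band just outside tumor nests
            band_px = max(2, int(8.0 / cfg.mpp))
            band = ndi.binary_dilation(tumor_mask, iterations=band_px) & ~tumor_mask
            mask = _threshold_mask(fld + 1.5 * band, prev)
        else:
            mask = _threshold_mask(fld, prev)
        labels[mask] = legend.index_of(name)

    if keratin_here and tumor_mask.sum() > 4:
        # pearls sit at the cores of tumor nests: highest tumor-field values
        core = np.where(tumor_mask, tumor_fld, -np.inf)
        n_core = int(KERATIN_FRACTION_OF_TUMOR * tumor_mask.sum())
        if n_core > 0:
            thresh = np.partition(core.ravel(), -n_core)[-n_core]
            pearl = (core >= thresh) & (labels == legend.index_of("Tumor"))
            labels[pearl] = legend.index_of("Keratin Pearl")
    return labels


def _avoid_overlay(labels: np.ndarray, cfg: CohortConfig, legend: ClassLegend, rng):
    """Mask ~avoid_fraction of labeled pixels, preferring class boundaries."""
    target = int(cfg.avoid_fraction * labels.size)
    if target == 0:
        return labels
    boundary = np.zeros_like(labels, dtype=bool)
    boundary[:-1] |= labels[:-1] != labels[1:]
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary = ndi.binary_dilation(boundary, iterations=1)
    out = labels.copy()
    idx = np.flatnonzero(boundary)
    if idx.size > target:
        idx = rng.choice(idx, size=target, replace=False)
    out.flat[idx] = legend.avoid_index
    deficit = target - idx.size
    if deficit > 0:
        rest = np.flatnonzero(out.ravel() != legend.avoid_index)
        extra = rng.choice(rest, size=min(deficit, rest.size), replace=False)
        out.flat[extra] = legend.avoid_index
    return out


def _render_image(
    labels_full: np.ndarray,
    cfg: CohortConfig,
    legend: ClassLegend,
    rng: np.random.Generator,
    patient_offset: np.ndarray,
) -> np.ndarray:
    s = cfg.image_size
    means = np.zeros((legend.n_classes, 3))
    for name, color in CLASS_COLOR_MEANS.items():
        means[legend.index_of(name)] = color
    img = means[labels_full].astype(np.float64)
    img += patient_offset
    corr_amp = 4.0 + 30.0 * cfg.hardness
    for c in range(3):
        img[..., c] += corr_amp * ndi.gaussian_filter(rng.standard_normal((s, s)), sigma=3)
    img += (3.0 + 10.0 * cfg.hardness) * rng.standard_normal((s, s, 3))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_cohort(config: CohortConfig):
    """Generate the full synthetic cohort; returns ``(samples, legend)``.

    The image is rendered from the label map *before* the avoid overlay, so
    avoided pixels still look like the tissue beneath them — the annotation
    is withheld, not the tissue.
    """
    legend = table1_legend()
    samples = []
    for p in range(config.n_patients):
        patient_id = f"P{p:02d}"
        p_ss, offset_ss = np.random.SeedSequence([config.seed, p]).spawn(2)
        patient_offset = np.random.default_rng(offset_ss).normal(0, 6.0, size=3)
        n_rois = config.rois_per_patient + (1 if p < config.n_extra_rois else 0)
        roi_streams = p_ss.spawn(n_rois)
        for r in range(n_rois):
            rng = np.random.default_rng(roi_streams[r])
            labels_full = _build_label_map(config, legend, rng)
            labels = _avoid_overlay(labels_full, config, legend, rng)
            image = _render_image(labels_full, config, legend, rng, patient_offset)
            samples.append(
                RoiSample(
                    roi_id=f"{patient_id}R{r}",
                    patient_id=patient_id,
                    image=image,
                    labels=LabelMap(labels, legend),
                    microns_per_pixel=config.mpp,
                )
            )
    return samples, legend


def paper_like_preset(seed: int = 0) -> CohortConfig:
    """23 patients / 24 ROIs (one patient contributes two), 11 classes,
    skewed prevalence with rare mucosa/blood/muscle; 3 of the patients are
    meant for holdout via :func:`alseg.legend.split_by_patient`."""
    return CohortConfig(n_patients=23, rois_per_patient=1, n_extra_rois=1,
                        image_size=256, seed=seed)


def desk_preset(seed: int = 0) -> CohortConfig:
    """The paper-like cohort at desk scale (64 x 64 ROIs) for CPU runs."""
    return CohortConfig(n_patients=23, rois_per_patient=1, n_extra_rois=1,
                        image_size=64, seed=seed)
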