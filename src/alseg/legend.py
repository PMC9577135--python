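"""Color-legend label maps, cohort manifests, and patient-level splits.

Ground truth arrives as RGB PNG label maps in which each tissue class owns one
exact color; pixels the annotator did not label belong to a reserved *avoid*
class that is excluded from training loss and from every metric. This module
converts between the RGB encoding and integer index maps, applies class merges
(e.g. slide background + adipose into one super-class), and manages the cohort
manifest with leakage-free patient-level train/holdout splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ClassLegend",
    "LabelMap",
    "RoiSample",
    "CohortSplit",
    "AVOID_COLOR",
    "table1_legend",
    "premerge_legend",
    "decode_label_png",
    "encode_label_png",
    "merge_classes",
    "split_by_patient",
    "save_cohort",
    "load_cohort",
]

#: Reserved color for unlabeled (avoid) pixels; deliberately absent from the
#: tissue palette so round-trips are unambiguous.
AVOID_COLOR = (255, 255, 255)

# Canonical RGB values for the named annotation colors.  The legend names
# colors, not values, so these are a repository convention written into every
# manifest.
_NAMED_COLORS = {
    "Red": (255, 0, 0),
    "Blue": (0, 0, 255),
    "Yellow": (255, 255, 0),
    "Sky blue": (135, 206, 235),
    "Gray": (128, 128, 128),
    "Green": (0, 128, 0),
    "Orange": (255, 165, 0),
    "Black": (0, 0, 0),
    "Dark blue": (0, 0, 139),
    "Olive": (128, 128, 0),
    "Pink": (255, 192, 203),
    "Light gray": (211, 211, 211),
}

# Post-merge tissue classes and their annotation colors (11 classes).
_TABLE1 = [
    ("Stroma", "Red"),
    ("Tumor", "Blue"),
    ("Lymphocytes", "Yellow"),
    ("Mucosa", "Sky blue"),
    ("Background/Adipose", "Gray"),
    ("Blood", "Green"),
    ("Nerves", "Orange"),
    ("Necrosis", "Black"),
    ("Keratin Pearl", "Dark blue"),
    ("Muscle", "Olive"),
    ("Junk", "Pink"),
]


class LegendError(ValueError):
    """Raised for malformed legends, unknown colors, or bad indices."""


@dataclass(frozen=True)
class ClassLegend:
    """Bidirectional map between class names, RGB colors, and indices.

    ``entries`` is an ordered list of ``(name, (r, g, b), index)`` with indices
    contiguous from 0; ``avoid_index`` (== ``len(entries)``) is reserved for
    unlabeled pixels and is not a tissue class.
    """

    entries: tuple = ()
    avoid_index: int = field(default=0)

    def __post_init__(self):
        names = [e[0] for e in self.entries]
        colors = [tuple(e[1]) for e in self.entries]
        indices = [e[2] for e in self.entries]
        if len(set(names)) != len(names):
            raise LegendError("duplicate class names in legend")
        if len(set(colors)) != len(colors):
            raise LegendError("duplicate colors in legend")
        if tuple(AVOID_COLOR) in colors:
            raise LegendError("avoid color reserved; cannot assign to a tissue class")
        if sorted(indices) != list(range(len(indices))):
            raise LegendError("class indices must be contiguous from 0")
        if self.avoid_index in indices:
            raise LegendError("avoid_index collides with a tissue class index")

    @classmethod
    def from_names(cls, names_and_colors) -> "ClassLegend":
        entries = tuple(
            (name, tuple(color), i) for i, (name, color) in enumerate(names_and_colors)
        )
        return cls(entries=entries, avoid_index=len(entries))

    @property
    def n_classes(self) -> int:
        return len(self.entries)

    @property
    def class_names(self) -> list:
        return [e[0] for e in sorted(self.entries, key=lambda e: e[2])]

    def index_of(self, name: str) -> int:
        for n, _, i in self.entries:
            if n == name:
                return i
        raise LegendError(f"unknown class name: {name!r}")

    def color_of(self, name: str):
        for n, c, _ in self.entries:
            if n == name:
                return c
        raise LegendError(f"unknown class name: {name!r}")

    def name_of(self, index: int) -> str:
        for n, _, i in self.entries:
            if i == index:
                return n
        raise LegendError(f"no class with index {index}")

    def palette(self) -> np.ndarray:
        """(n_classes + 1, 3) uint8 array; row ``avoid_index`` is the avoid color."""
        pal = np.zeros((self.n_classes + 1, 3), dtype=np.uint8)
        for _, color, i in self.entries:
            pal[i] = color
        pal[self.avoid_index] = AVOID_COLOR
        return pal

    def to_dict(self) -> dict:
        return {
            "classes": [
                {"name": n, "color": list(c), "index": i} for n, c, i in self.entries
            ],
            "avoid_index": self.avoid_index,
            "avoid_color": list(AVOID_COLOR),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassLegend":
        entries = tuple(
            (e["name"], tuple(e["color"]), e["index"]) for e in d["classes"]
        )
        return cls(entries=entries, avoid_index=d["avoid_index"])


def table1_legend() -> ClassLegend:
    """The canonical 11-class tissue legend (post background/adipose merge)."""
    return ClassLegend.from_names(
        [(name, _NAMED_COLORS[color]) for name, color in _TABLE1]
    )


def premerge_legend() -> ClassLegend:
    """The 12-class legend with Background and Adipose still separate."""
    entries = []
    for name, color in _TABLE1:
        if name == "Background/Adipose":
            entries.append(("Background", _NAMED_COLORS["Gray"]))
            entries.append(("Adipose", _NAMED_COLORS["Light gray"]))
        else:
            entries.append((name, _NAMED_COLORS[color]))
    return ClassLegend.from_names(entries)


@dataclass
class LabelMap:
    """A 2-D grid of legend indices paired with the legend that defines them."""

    indices: np.ndarray
    legend: ClassLegend

    def __post_init__(self):
        self.indices = np.asarray(self.indices)
        if self.indices.ndim != 2:
            raise LegendError("label map must be 2-D")
        legal = set(range(self.legend.n_classes)) | {self.legend.avoid_index}
        present = set(np.unique(self.indices).tolist())
        if not present <= legal:
            raise LegendError(f"illegal indices in label map: {sorted(present - legal)}")

    @property
    def shape(self):
        return self.indices.shape


@dataclass
class RoiSample:
    """One annotated region of interest: image, label map, patient, resolution."""

    roi_id: str
    patient_id: str
    image: np.ndarray  # (H, W, 3) uint8 or float
    labels: LabelMap
    microns_per_pixel: float

    def __post_init__(self):
        if self.image.shape[:2] != self.labels.shape:
            raise LegendError(
                f"image {self.image.shape[:2]} and labels {self.labels.shape} differ"
            )
        if self.microns_per_pixel <= 0:
            raise LegendError("microns_per_pixel must be positive")


@dataclass
class CohortSplit:
    """Patient-disjoint partition of a cohort into training pool and holdout."""

    train_pool_ids: set
    holdout_ids: set


def _pack(rgb: np.ndarray) -> np.ndarray:
    rgb = rgb.astype(np.int64)
    return (rgb[..., 0] << 16) | (rgb[..., 1] << 8) | rgb[..., 2]


def decode_label_png(raster: np.ndarray, legend: ClassLegend, strict: bool = False) -> LabelMap:
    """Decode an RGB raster into class indices by exact color match.

    Pixels whose color matches no legend entry (and is not the avoid color)
    become ``avoid_index`` when ``strict`` is False, and raise otherwise.
    """
    raster = np.asarray(raster)
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise LegendError(f"expected an (H, W, 3) raster, got shape {raster.shape}")
    packed = _pack(raster)
    lut = {int(_pack(np.array(c))): i for _, c, i in legend.entries}
    lut[int(_pack(np.array(AVOID_COLOR)))] = legend.avoid_index

    out = np.full(packed.shape, legend.avoid_index, dtype=np.int16)
    known = np.zeros(packed.shape, dtype=bool)
    for color, idx in lut.items():
        m = packed == color
        out[m] = idx
        known |= m
    if strict and not known.all():
        n_bad = int((~known).sum())
        bad = np.argwhere(~known)[0]
        color = tuple(int(v) for v in raster[bad[0], bad[1]])
        raise LegendError(
            f"{n_bad} pixel(s) with colors absent from the legend (e.g. {color})"
        )
    return LabelMap(indices=out, legend=legend)


def encode_label_png(labels: LabelMap, legend: ClassLegend | None = None) -> np.ndarray:
    """Render a label map back to its RGB encoding (exact inverse of decode)."""
    legend = legend or labels.legend
    idx = labels.indices
    legal = set(range(legend.n_classes)) | {legend.avoid_index}
    present = set(np.unique(idx).tolist())
    if not present <= legal:
        raise LegendError(f"indices outside legend: {sorted(present - legal)}")
    pal = legend.palette()
    # avoid_index may exceed n_classes; remap it onto the last palette row
    remapped = np.where(idx == legend.avoid_index, legend.n_classes, idx)
    return pal[remapped.astype(np.int64)]


def merge_classes(labels: LabelMap, legend: ClassLegend, from_names, to_name: str):
    """Merge two classes into a super-class, reindexing the legend contiguously.

    Returns ``(new_labels, new_legend)``. The super-class takes the first
    source class's color and position; all other pixels are unchanged.
    """
    a, b = from_names
    ia, ib = legend.index_of(a), legend.index_of(b)
    new_entries = []
    for name, color, idx in sorted(legend.entries, key=lambda e: e[2]):
        if idx == ia:
            new_entries.append((to_name, color))
        elif idx == ib:
            continue
        else:
            new_entries.append((name, color))
    new_legend = ClassLegend.from_names(new_entries)

    # old index -> new index
    mapping = np.zeros(legend.n_classes + 1, dtype=np.int16)
    for name, _, old_idx in legend.entries:
        if old_idx == ia or old_idx == ib:
            mapping[old_idx] = new_legend.index_of(to_name)
        else:
            mapping[old_idx] = new_legend.index_of(name)
    mapping[legend.avoid_index] = new_legend.avoid_index
    return LabelMap(indices=mapping[labels.indices], legend=new_legend), new_legend


def split_by_patient(cohort, n_holdout_patients: int, seed: int) -> CohortSplit:
    """Hold out every ROI of ``n_holdout_patients`` randomly chosen patients.

    The split is at patient level: no patient contributes ROIs to both sides.
    Deterministic for a fixed seed.
    """
    patients = sorted({s.patient_id for s in cohort})
    if n_holdout_patients >= len(patients):
        raise LegendError(
            f"n_holdout_patients={n_holdout_patients} >= {len(patients)} patients"
        )
    rng = np.random.default_rng(seed)
    holdout_patients = set(
        rng.choice(patients, size=n_holdout_patients, replace=False).tolist()
    )
    holdout = {s.roi_id for s in cohort if s.patient_id in holdout_patients}
    train = {s.roi_id for s in cohort} - holdout
    return CohortSplit(train_pool_ids=train, holdout_ids=holdout)


# ---------------------------------------------------------------------------
# Manifest I/O: PNG images + PNG label maps + one JSON manifest per cohort.

def save_cohort(cohort, legend: ClassLegend, out_dir) -> Path:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        img_path = f"images/{s.roi_id}.png"
        lab_path = f"labels/{s.roi_id}.png"
        Image.fromarray(np.asarray(s.image, dtype=np.uint8)).save(out / img_path)
        Image.fromarray(encode_label_png(s.labels, legend)).save(out / lab_path)
        rows.append(
            {
                "roi_id": s.roi_id,
                "patient_id": s.patient_id,
                "image": img_path,
                "labels": lab_path,
                "microns_per_pixel": s.microns_per_pixel,
            }
        )
    manifest = {"legend": legend.to_dict(), "rois": rows}
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_cohort(manifest_path):
    """Load a cohort saved by :func:`save_cohort`; returns (samples, legend)."""
    path = Path(manifest_path)
    if path.is_dir():
        path = path / "manifest.json"
    manifest = json.loads(path.read_text())
    legend = ClassLegend.from_dict(manifest["legend"])
    root = path.parent
    samples = []
    for row in manifest["rois"]:
        image = np.asarray(Image.open(root / row["image"]).convert("RGB"))
        raster = np.asarray(Image.open(root / row["labels"]).convert("RGB"))
        labels = decode_label_png(raster, legend, strict=True)
        samples.append(
            RoiSample(
                roi_id=row["roi_id"],
                patient_id=row["patient_id"],
                image=image,
                labels=labels,
                microns_per_pixel=row["microns_per_pixel"],
            )
        )
    return samples, legend
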