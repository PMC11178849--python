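"""NIfTI volume I/O and input-preparation operators.

Implements the preprocessing surface that sits between skull-stripped,
co-registered T1-weighted volumes (plus aseg-style label maps) and the
networks: intensity z-scoring, center crop/pad to a cube, anatomical region
extraction by label, hemisphere splitting, and zero-margin trimming. No
resampling or reorientation happens here — inputs are assumed preprocessed
to a common grid upstream (e.g. by FreeSurfer's recon-all), and every
operator conserves voxel values exactly (masking and cropping only, no
interpolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml


class AlignmentError(ValueError):
    """Volume and label map do not share a grid."""


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    empty_region: bool = False  # set by extract_region when no voxel matched

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"Volume must be 3D, got {self.values.ndim}D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class LabelMap:
    """An integer 3D label image aligned to a Volume."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"LabelMap must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap requires an integer dtype")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class RegionSpec:
    """A named set of label codes, optionally split by hemisphere.

    Built-in specs follow the FreeSurfer aseg convention: hippocampus 17/53,
    amygdala 18/54 (left/right).
    """

    name: str
    labels: frozenset[int]
    left_labels: frozenset[int] = field(default_factory=frozenset)
    right_labels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        self.labels = frozenset(int(v) for v in self.labels)
        self.left_labels = frozenset(int(v) for v in self.left_labels)
        self.right_labels = frozenset(int(v) for v in self.right_labels)
        if not self.labels:
            raise ValueError("RegionSpec.labels must be non-empty")
        if self.left_labels & self.right_labels:
            raise ValueError("left and right label sets must be disjoint")
        if not (self.left_labels | self.right_labels) <= self.labels:
            raise ValueError("left/right labels must be subsets of labels")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            name=d["name"],
            labels=frozenset(d["labels"]),
            left_labels=frozenset(d.get("left_labels", ())),
            right_labels=frozenset(d.get("right_labels", ())),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "name": self.name,
                    "labels": sorted(self.labels),
                    "left_labels": sorted(self.left_labels),
                    "right_labels": sorted(self.right_labels),
                },
                fh,
            )
        return path


HIPPOCAMPUS = RegionSpec("HA", frozenset({17, 53}), frozenset({17}), frozenset({53}))
AMYGDALA = RegionSpec("AM", frozenset({18, 54}), frozenset({18}), frozenset({54}))
HIPPOCAMPUS_AMYGDALA = RegionSpec(
    "HA+AM", frozenset({17, 53, 18, 54}), frozenset({17, 18}), frozenset({53, 54})
)

BUILTIN_REGIONS = {"HA": HIPPOCAMPUS, "AM": AMYGDALA, "HA+AM": HIPPOCAMPUS_AMYGDALA}


# -- NIfTI I/O ----------------------------------------------------------------

def _load_nifti(path: str | Path):
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format errors
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(path: str | Path) -> Volume:
    data, spacing = _load_nifti(path)
    return Volume(data.astype(np.float32), spacing)


def read_labelmap(path: str | Path) -> LabelMap:
    data, spacing = _load_nifti(path)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-3):
            raise ValueError(f"{path}: label map contains non-integer values")
        data = rounded
    return LabelMap(data.astype(np.int16), spacing)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(v: Volume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(v.values.astype(np.float32), _affine(v.spacing))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
    return path


def write_labelmap(m: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(m.labels.astype(np.int16), _affine(m.spacing))
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))
    return path


# -- preprocessing operators --------------------------------------------------

def normalize_intensity(v: Volume, mask: LabelMap | None = None) -> Volume:
    """Z-score the volume over in-mask voxels (whole grid without a mask)."""
    if mask is not None:
        if mask.shape != v.shape:
            raise AlignmentError(f"mask shape {mask.shape} != volume shape {v.shape}")
        sel = mask.labels > 0
        if not sel.any():
            raise ValueError("mask selects no voxels")
        vals = v.values[sel]
    else:
        sel = None
        vals = v.values.reshape(-1)
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd == 0.0:
        raise ValueError("zero intensity variance in the normalization region")
    out = (v.values - mu) / sd
    return Volume(out.astype(np.float32), v.spacing)


def crop_or_pad_center(v: Volume, edge: int) -> Volume:
    """Center-crop or zero-pad each axis to ``edge`` voxels.

    On odd size differences the extra voxel goes to the high-index side, for
    both cropping and padding, so the operation is its own partial inverse:
    padding back to the original size restores every retained voxel.
    """
    if edge < 1:
        raise ValueError("edge must be >= 1")
    out = v.values
    for axis in range(3):
        size = out.shape[axis]
        if size > edge:
            start = (size - edge) // 2
            sl = [slice(None)] * 3
            sl[axis] = slice(start, start + edge)
            out = out[tuple(sl)]
        elif size < edge:
            lo = (edge - size) // 2
            hi = edge - size - lo
            pads = [(0, 0)] * 3
            pads[axis] = (lo, hi)
            out = np.pad(out, pads)
    return Volume(np.ascontiguousarray(out), v.spacing)


def extract_region(v: Volume, m: LabelMap, spec: RegionSpec,
                   labels: frozenset[int] | None = None) -> Volume:
    """Mask the volume to the voxels whose label is in the region spec.

    The output keeps the full grid shape; out-of-region voxels are zeroed
    and in-region values are conserved exactly. If no voxel matches, a
    warning is raised and the result carries ``empty_region=True``.
    """
    if m.shape != v.shape:
        raise AlignmentError(f"label map shape {m.shape} != volume shape {v.shape}")
    wanted = labels if labels is not None else spec.labels
    sel = np.isin(m.labels, list(wanted))
    out = np.where(sel, v.values, np.float32(0.0))
    empty = not bool(sel.any())
    if empty:
        warnings.warn(
            f"region '{spec.name}' matched no voxels (labels {sorted(wanted)})",
            stacklevel=2,
        )
    return Volume(out.astype(np.float32), v.spacing, empty_region=empty)


def split_left_right(v: Volume, m: LabelMap, spec: RegionSpec) -> tuple[Volume, Volume]:
    """Extract the left- and right-hemisphere parts of a region separately.

    Returns two masked volumes with disjoint nonzero supports (label sets
    are disjoint by RegionSpec construction).
    """
    if not spec.left_labels or not spec.right_labels:
        raise ValueError(f"region '{spec.name}' has no left/right label split")
    left = extract_region(v, m, spec, labels=spec.left_labels)
    right = extract_region(v, m, spec, labels=spec.right_labels)
    return left, right


def trim_zero_margins(v: Volume, pad: int = 0) -> Volume:
    """Crop to the tight bounding box of nonzero voxels, expanded by ``pad``.

    The counterpart of region masking: region inputs carry large all-zero
    margins, and trimming them is the suggested remedy for the extra zero
    "noise" they introduce.
    """
    nz = np.nonzero(v.values)
    if nz[0].size == 0:
        raise ValueError("cannot trim an all-zero volume")
    sl = []
    for axis in range(3):
        lo = max(int(nz[axis].min()) - pad, 0)
        hi = min(int(nz[axis].max()) + 1 + pad, v.shape[axis])
        sl.append(slice(lo, hi))
    return Volume(np.ascontiguousarray(v.values[tuple(sl)]), v.spacing)
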