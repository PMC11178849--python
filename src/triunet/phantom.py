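"""Synthetic aging-brain phantom generator.

Produces T1-like 3D volumes with paired integer label maps and known ages,
emulating the structure of a healthy-aging cohort (ages 18-89) at desk
scale. The phantom is a geometric cartoon, not an MRI simulation: a brain
ellipsoid with an age-dependent cortex intensity, a central CSF ventricle
whose volume fraction grows linearly with age (the dominant, analytically
invertible age signal), and four subcortical blobs (left/right hippocampus
and amygdala, FreeSurfer-style label codes) whose radii shrink with age.
Disease-like groups (MCI-like, AD-like) apply the atrophy of an older
effective age while keeping the chronological age label, creating a positive
brain-age gap by construction.

All geometry is deterministic given (age, group, params); only the additive
Gaussian intensity noise consumes the seed, so label maps are noise-free.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .volume_io import LabelMap, Volume, write_labelmap, write_volume

GROUPS = ("HC", "MCI-like", "AD-like")

DEFAULT_LABEL_CODES = {
    "brain": 1,
    "ventricle": 4,
    "hippocampus_left": 17,
    "hippocampus_right": 53,
    "amygdala_left": 18,
    "amygdala_right": 54,
}

# blob centers as fractions of the brain semi-axes (x, y, z); hippocampi
# and amygdalae sit in the axial plane, clear of the ventricle at max age,
# and scale with the brain so smaller grids keep a valid geometry
_REGION_OFFSETS = {
    "hippocampus_left": (-0.57, -0.40, 0.0),
    "hippocampus_right": (0.57, -0.40, 0.0),
    "amygdala_left": (-0.57, 0.40, 0.0),
    "amygdala_right": (0.57, 0.40, 0.0),
}


@dataclass
class PhantomParams:
    """Generative parameters of the aging-brain phantom.

    Rates are per year of *effective* age (chronological age plus the
    disease-group offset). Defaults are chosen so that, on the default
    32-voxel grid, the ventricle-fraction age signal is an order of
    magnitude larger than the voxelization error of ellipsoid rasterization,
    and so that every structure stays strictly inside the brain mask at the
    maximum effective age (89 + the AD-like offset).
    """

    grid_edge: int = 32
    brain_radii: tuple[float, float, float] = (14.0, 15.0, 13.0)
    ventricle_base_fraction: float = 0.045
    ventricle_growth_per_year: float = 0.04
    ventricle_shape: tuple[float, float, float] = (4.5, 4.5, 7.0)
    cortex_intensity_at_18: float = 100.0
    cortex_intensity_slope: float = -0.3
    region_intensity_factor: float = 0.8
    region_base_radius: float = 2.5
    region_shrink_per_year: float = 0.0125
    noise_sd: float = 5.0
    age_min: float = 18.0
    age_max: float = 89.0
    group_age_offsets: dict = field(
        default_factory=lambda: {"HC": 0.0, "MCI-like": 5.0, "AD-like": 10.0}
    )
    label_codes: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_CODES))

    def __post_init__(self):
        self.validate()

    # -- derived geometry -----------------------------------------------------
    def effective_age(self, age: float, group: str) -> float:
        if group not in self.group_age_offsets:
            raise ValueError(f"unknown group '{group}' (expected one of {GROUPS})")
        return age + self.group_age_offsets[group]

    def ventricle_fraction(self, effective_age: float) -> float:
        return self.ventricle_base_fraction * (
            1.0 + self.ventricle_growth_per_year * (effective_age - 18.0)
        )

    def ventricle_semi_axes(self, effective_age: float) -> np.ndarray:
        """Semi-axes of the ventricle ellipsoid realizing the target fraction."""
        shape = np.asarray(self.ventricle_shape, dtype=float)
        brain_vol = float(np.prod(self.brain_radii))  # up to the common 4/3*pi
        frac = self.ventricle_fraction(effective_age)
        u = (frac * brain_vol / float(np.prod(shape))) ** (1.0 / 3.0)
        return u * shape

    def region_radius(self, effective_age: float) -> float:
        return self.region_base_radius - self.region_shrink_per_year * (effective_age - 18.0)

    def cortex_intensity(self, effective_age: float) -> float:
        return self.cortex_intensity_at_18 + self.cortex_intensity_slope * (effective_age - 18.0)

    def max_effective_age(self) -> float:
        return self.age_max + max(self.group_age_offsets.values())

    def validate(self) -> None:
        for name in (
            "ventricle_base_fraction", "ventricle_growth_per_year",
            "cortex_intensity_at_18", "cortex_intensity_slope",
            "region_base_radius", "region_shrink_per_year", "noise_sd",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0 < self.ventricle_base_fraction < 1):
            raise ValueError("ventricle_base_fraction must lie in (0, 1)")
        if self.ventricle_growth_per_year < 0 or self.region_shrink_per_year < 0:
            raise ValueError("atrophy rates must be >= 0")
        if self.cortex_intensity_slope > 0:
            raise ValueError("cortex_intensity_slope must be <= 0 (intensity declines with age)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        max_eff = self.max_effective_age()
        if self.region_radius(max_eff) < 1.0:
            raise ValueError(
                "region_shrink_per_year too large: region radius falls below 1 voxel "
                f"at effective age {max_eff:.1f}"
            )
        axes = self.ventricle_semi_axes(max_eff)
        if np.any(axes >= np.asarray(self.brain_radii)):
            raise ValueError(
                "ventricle_growth_per_year too large: ventricle reaches the brain "
                f"surface at effective age {max_eff:.1f}"
            )
        half = (self.grid_edge - 1) / 2.0
        if np.any(np.asarray(self.brain_radii) > half + 1.5):
            raise ValueError("brain_radii do not fit the grid")

    # -- (de)serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["brain_radii"] = list(self.brain_radii)
        d["ventricle_shape"] = list(self.ventricle_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown phantom parameter(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("brain_radii", "ventricle_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _ellipsoid_mask(coords: tuple[np.ndarray, np.ndarray, np.ndarray],
                    center: tuple[float, float, float],
                    semi_axes: np.ndarray | tuple[float, float, float]) -> np.ndarray:
    cx, cy, cz = coords
    ax, ay, az = semi_axes
    x0, y0, z0 = center
    return (
        ((cx - x0) / ax) ** 2 + ((cy - y0) / ay) ** 2 + ((cz - z0) / az) ** 2
    ) <= 1.0


def sample_phantom(age: float, group: str, params: PhantomParams, seed: int) -> tuple[Volume, LabelMap]:
    """Generate one phantom volume and its label map.

    The geometry is fully determined by (age, group, params); ``seed`` only
    drives the additive Gaussian intensity noise, which is clipped at zero.
    """
    if not (params.age_min <= age <= params.age_max):
        raise ValueError(
            f"age {age} outside the configured range [{params.age_min}, {params.age_max}]"
        )
    eff = params.effective_age(age, group)
    radius = params.region_radius(eff)
    if radius < 1.0:
        raise ValueError(
            f"region radius {radius:.2f} < 1 voxel at effective age {eff:.1f}: "
            "region_shrink_per_year too large for this age"
        )
    e = params.grid_edge
    half = (e - 1) / 2.0
    ax = np.arange(e, dtype=np.float64)
    cx, cy, cz = np.meshgrid(ax, ax, ax, indexing="ij")
    center = (half, half, half)

    brain = _ellipsoid_mask((cx, cy, cz), center, params.brain_radii)
    ventricle = _ellipsoid_mask((cx, cy, cz), center, params.ventricle_semi_axes(eff))

    codes = params.label_codes
    labels = np.zeros((e, e, e), dtype=np.int16)
    labels[brain] = codes["brain"]
    labels[ventricle] = codes["ventricle"]

    cortex = params.cortex_intensity(eff)
    values = np.zeros((e, e, e), dtype=np.float32)
    values[brain] = cortex
    values[ventricle] = 0.0

    for name, offset in _REGION_OFFSETS.items():
        blob_center = tuple(half + f * r for f, r in zip(offset, params.brain_radii))
        blob = _ellipsoid_mask((cx, cy, cz), blob_center, (radius, radius, radius))
        labels[blob] = codes[name]
        values[blob] = cortex * params.region_intensity_factor

    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, params.noise_sd, size=values.shape)
        values = np.clip(values, 0.0, None).astype(np.float32)

    spacing = (1.0, 1.0, 1.0)
    return Volume(values.astype(np.float32), spacing), LabelMap(labels, spacing)


@dataclass
class CohortManifest:
    """Subject table of a generated cohort plus its provenance."""

    records: pd.DataFrame  # subject_id, age, group, volume_path, labelmap_path
    seed: int
    params: PhantomParams

    COLUMNS = ("subject_id", "age", "group", "volume_path", "labelmap_path")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.records["subject_id"].duplicated().any():
            raise ValueError("subject_ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.records.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = 0,
                 params: PhantomParams | None = None) -> "CohortManifest":
        df = pd.read_csv(path)
        return cls(df, seed=seed, params=params or PhantomParams())

    def subset(self, group: str) -> "CohortManifest":
        df = self.records[self.records["group"] == group].reset_index(drop=True)
        return CohortManifest(df, seed=self.seed, params=self.params)


def generate_cohort(n: int, age_low: float, age_high: float, group: str,
                    params: PhantomParams, seed: int, out_dir: str | Path) -> CohortManifest:
    """Write ``n`` phantom volume/label-map pairs and a CSV manifest.

    Ages are drawn uniformly on [age_low, age_high] from the seeded stream;
    each subject's noise seed is derived from the same stream, so the whole
    cohort is reproducible from (n, ages, group, params, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not age_low < age_high:
        raise ValueError("age_low must be < age_high")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_low, age_high, size=n)
    noise_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    tag = group.replace("-like", "").lower()
    rows = []
    for i, (age, sub_seed) in enumerate(zip(ages, noise_seeds)):
        sid = f"{tag}{i:04d}"
        vol, lab = sample_phantom(float(age), group, params, int(sub_seed))
        vpath = write_volume(vol, out_dir / f"{sid}_T1w.nii.gz")
        lpath = write_labelmap(lab, out_dir / f"{sid}_aseg.nii.gz")
        rows.append((sid, float(age), group, str(vpath), str(lpath)))
    df = pd.DataFrame(rows, columns=list(CohortManifest.COLUMNS))
    manifest = CohortManifest(df, seed=seed, params=params)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


@dataclass
class OracleReport:
    """In-sample linear-oracle age recovery from the ventricle fraction."""

    predictions: pd.DataFrame  # subject_id, age, ventricle_fraction, predicted_age
    mae: float
    slope: float
    intercept: float


def ventricle_fraction_from_labels(lab: LabelMap, params: PhantomParams) -> float:
    """Ventricle voxel count over total brain (nonzero-label) voxel count."""
    vcode = params.label_codes["ventricle"]
    total = int(np.count_nonzero(lab.labels))
    if total == 0:
        raise ValueError("label map contains no brain voxels")
    return float(np.count_nonzero(lab.labels == vcode)) / total


def oracle_age_estimate(manifest: CohortManifest) -> OracleReport:
    """Least-squares line of age on ventricle-volume fraction.

    This is the "signal exists" reference: if a closed-form feature of the
    label map recovers age, a network failing to beat the mean-age predictor
    points at the model or training, not at the data.
    """
    from .volume_io import read_labelmap

    if len(manifest) < 10:
        raise ValueError(f"oracle needs >= 10 subjects, got {len(manifest)}")
    ages = manifest.records["age"].to_numpy(dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("degenerate cohort: all subjects have the same age")
    fractions = np.array([
        ventricle_fraction_from_labels(read_labelmap(p), manifest.params)
        for p in manifest.records["labelmap_path"]
    ])
    slope, intercept = np.polyfit(fractions, ages, deg=1)
    predicted = slope * fractions + intercept
    mae = float(np.mean(np.abs(predicted - ages)))
    df = pd.DataFrame({
        "subject_id": manifest.records["subject_id"],
        "age": ages,
        "ventricle_fraction": fractions,
        "predicted_age": predicted,
    })
    return OracleReport(df, mae=mae, slope=float(slope), intercept=float(intercept))
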