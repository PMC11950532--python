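"""Synthetic brain phantoms with known ageing and disease effects.

Real brain-age studies combine an anatomical atlas, a demographics table
and per-subject 3-D image channels.  This module generates all three with
a fully known ground truth, so every downstream stage (model training,
BrainAGE, saliency, ROI statistics) can be validated against the effects
that were actually injected.

The generative model, per voxel of region ``r`` in channel ``c``::

    value = mixing[c] * ( baseline[r]
                          + age_slope[r] * (age - age_ref)
                          + disease_offset[r] * 1[patient]
                          + subject_intercept
                          + region_intercept[r] )          + N(0, voxel_sd)

Background voxels carry only the voxel noise.  ``age_slope`` is negative
for age-sensitive regions (intensity decline with age, emulating grey
matter loss); ``disease_offset`` is an extra negative shift confined to
designated disease regions, so patient brains look "older" exactly where
the pathology lives.  The subject intercept is a shared random effect
(scanner/biology), drawn once per subject; the per-(subject, region)
intercept adds region-specific variability, without which all regions
would be perfectly collinear given age — a degeneracy real brains do not
have.

Channels emulate imaging modalities by scalar mixing of the single latent
atrophy field — the analysis structure (one model per modality) is
preserved without modelling tissue segmentation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import LabeledVolume, as_array, load_nifti, read_json, save_nifti, write_json

__all__ = [
    "AtlasSpec",
    "EffectModel",
    "GroundTruthManifest",
    "build_atlas",
    "sample_cohort",
    "render_subject",
    "subject_intercept",
    "subject_random_effects",
    "write_dataset",
    "read_dataset",
]

DEFAULT_AGE_MIN = 18.0
DEFAULT_AGE_MAX = 88.0


@dataclass(frozen=True)
class AtlasSpec:
    """Parameters of the synthetic parcellation."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_regions: int = 24
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise ValueError(f"bad grid_shape {self.grid_shape}")


@dataclass
class EffectModel:
    """Ground-truth effect sizes driving the phantom intensities."""

    baseline: np.ndarray            # (K,) mean intensity per region, arbitrary units
    age_slope: np.ndarray           # (K,) units per year
    age_sensitive_set: tuple[int, ...]
    disease_offset: np.ndarray      # (K,) additive units, patients only
    disease_set: tuple[int, ...]
    subject_sd: float = 0.05
    region_sd: float = 0.03
    voxel_sd: float = 0.05
    n_channels: int = 2
    channel_mixing: tuple[float, ...] = (1.0, 0.7)
    age_ref: float = DEFAULT_AGE_MIN

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.age_slope = np.asarray(self.age_slope, dtype=float)
        self.disease_offset = np.asarray(self.disease_offset, dtype=float)
        k = len(self.baseline)
        if not (len(self.age_slope) == len(self.disease_offset) == k):
            raise ValueError("baseline, age_slope, disease_offset must share length K")
        for name, s in (("disease_set", self.disease_set),
                        ("age_sensitive_set", self.age_sensitive_set)):
            if not set(s) <= set(range(1, k + 1)):
                raise ValueError(f"{name} must be a subset of 1..{k}")
        if self.subject_sd < 0 or self.voxel_sd < 0 or self.region_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if len(self.channel_mixing) != self.n_channels:
            raise ValueError("channel_mixing length must equal n_channels")

    @property
    def n_regions(self) -> int:
        return len(self.baseline)

    @classmethod
    def default(cls, n_regions: int = 24, n_disease: int = 6,
                n_channels: int = 2, seed: int = 0,
                disease_extra_years: float = 40.0,
                expanding_fraction: float = 0.25,
                subject_sd: float = 0.05, region_sd: float = 0.03,
                voxel_sd: float = 0.05,
                age_ref: float = DEFAULT_AGE_MIN) -> "EffectModel":
        """Study-condition defaults.

        Every region is age-sensitive with a heterogeneous slope of 0.4 to
        1.2 % of baseline per year; most decline (grey/white-matter-like
        atrophy) while ``expanding_fraction`` of regions grow with age
        (CSF/ventricle-like expansion).  ``n_disease`` regions additionally
        carry a patient-only offset equal to ``disease_extra_years`` of
        extra ageing along that region's own slope — accelerated ageing
        confined to the disease regions, in either tissue direction.
        """
        rng = np.random.default_rng([int(seed), 0xEFFEC7])
        baseline = rng.uniform(0.9, 1.1, n_regions)
        slopes = rng.uniform(0.004, 0.012, n_regions)
        n_expand = int(round(expanding_fraction * n_regions))
        sign = np.full(n_regions, -1.0)
        sign[rng.choice(n_regions, size=n_expand, replace=False)] = 1.0
        slopes = slopes * sign
        disease_regions = tuple(
            sorted(rng.choice(np.arange(1, n_regions + 1),
                              size=min(n_disease, n_regions), replace=False)))
        offsets = np.zeros(n_regions)
        for r in disease_regions:
            offsets[r - 1] = slopes[r - 1] * disease_extra_years
        mixing = (1.0, 0.7, 1.3, 0.5, 0.85)[:n_channels]
        return cls(baseline=baseline, age_slope=slopes,
                   age_sensitive_set=tuple(range(1, n_regions + 1)),
                   disease_offset=offsets, disease_set=disease_regions,
                   subject_sd=subject_sd, region_sd=region_sd, voxel_sd=voxel_sd,
                   n_channels=n_channels, channel_mixing=mixing,
                   age_ref=age_ref)

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.tolist(),
            "age_slope": self.age_slope.tolist(),
            "age_sensitive_set": list(self.age_sensitive_set),
            "disease_offset": self.disease_offset.tolist(),
            "disease_set": list(self.disease_set),
            "subject_sd": self.subject_sd,
            "region_sd": self.region_sd,
            "voxel_sd": self.voxel_sd,
            "n_channels": self.n_channels,
            "channel_mixing": list(self.channel_mixing),
            "age_ref": self.age_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectModel":
        d = dict(d)
        d["age_sensitive_set"] = tuple(d["age_sensitive_set"])
        d["disease_set"] = tuple(d["disease_set"])
        d["channel_mixing"] = tuple(d["channel_mixing"])
        return cls(**d)


@dataclass
class GroundTruthManifest:
    """Everything needed to re-render any subject volume bit-exactly."""

    effects: EffectModel
    atlas_spec: AtlasSpec
    seed: int
    intercepts: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "effects": self.effects.to_dict(),
            "atlas_spec": {"grid_shape": list(self.atlas_spec.grid_shape),
                           "n_regions": self.atlas_spec.n_regions,
                           "seed": self.atlas_spec.seed},
            "seed": self.seed,
            "intercepts": self.intercepts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        a = d["atlas_spec"]
        return cls(effects=EffectModel.from_dict(d["effects"]),
                   atlas_spec=AtlasSpec(tuple(a["grid_shape"]), a["n_regions"], a["seed"]),
                   seed=d["seed"], intercepts=dict(d["intercepts"]))


# ---------------------------------------------------------------------------
# atlas construction


def _lattice_dims(k: int) -> tuple[int, int, int]:
    """Smallest near-cubic integer lattice with at least k cells."""
    nx = int(np.ceil(k ** (1.0 / 3.0)))
    ny = int(np.ceil(np.sqrt(k / nx)))
    nz = int(np.ceil(k / (nx * ny)))
    return nx, ny, nz


def build_atlas(spec: AtlasSpec) -> tuple[LabeledVolume, pd.DataFrame]:
    """Seed K disjoint ellipsoidal regions on a jittered lattice.

    Voxels claimed by several ellipsoids go to the nearest region center
    (ties to the lowest label); voxels claimed by none are background (0).
    Deterministic for a fixed spec.

    Returns the integer label volume and a region table
    (label, name, voxel_count).
    """
    k = spec.n_regions
    shape = np.asarray(spec.grid_shape, dtype=float)
    dims = np.asarray(_lattice_dims(k))
    cell = shape / dims
    if np.any(cell < 2.0):
        raise ValueError(
            f"grid {spec.grid_shape} too small to seat {k} disjoint regions "
            f"(needs >= 2 voxels per lattice cell, lattice {tuple(dims)})")

    rng = np.random.default_rng([int(spec.seed), 0xA71A5])
    cells = np.stack(np.meshgrid(*[np.arange(d) for d in dims], indexing="ij"),
                     axis=-1).reshape(-1, 3)
    chosen = cells[rng.permutation(len(cells))[:k]]
    centers = (chosen + 0.5) * cell + rng.uniform(-0.25, 0.25, (k, 3)) * cell
    semi = np.maximum(rng.uniform(0.35, 0.50, (k, 3)) * cell, 1.0)

    coords = np.stack(np.meshgrid(*[np.arange(n) for n in spec.grid_shape],
                                  indexing="ij"), axis=-1).astype(float)  # (D,H,W,3)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    best_dist = np.full(spec.grid_shape, np.inf)
    for r in range(k):
        delta = coords - centers[r]
        inside = np.sum((delta / semi[r]) ** 2, axis=-1) <= 1.0
        dist = np.sum(delta ** 2, axis=-1)
        # nearest center wins; strict < keeps the lowest label on exact ties
        take = inside & (dist < best_dist)
        labels[take] = r + 1
        best_dist[take] = dist[take]

    # guarantee every region holds at least one voxel (its center voxel)
    for r in range(k):
        if not np.any(labels == r + 1):
            c = tuple(np.clip(np.round(centers[r]).astype(int), 0,
                              np.asarray(spec.grid_shape) - 1))
            labels[c] = r + 1

    counts = np.bincount(labels.ravel(), minlength=k + 1)
    table = pd.DataFrame({
        "label": np.arange(1, k + 1),
        "name": [f"region_{r:03d}" for r in range(1, k + 1)],
        "voxel_count": counts[1:],
    })
    return LabeledVolume(data=labels), table


# ---------------------------------------------------------------------------
# cohorts and rendering


def sample_cohort(n: int, group_fraction: float,
                  age_min: float = DEFAULT_AGE_MIN,
                  age_max: float = DEFAULT_AGE_MAX,
                  seed: int = 0, id_prefix: str = "sub") -> pd.DataFrame:
    """Sample a demographics table: uniform ages, balanced sex, fixed split.

    Exactly ``round(n * group_fraction)`` subjects are patients, placed at
    seeded-random positions in the table.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= group_fraction <= 1.0:
        raise ValueError("group_fraction must be in [0, 1]")
    if age_min >= age_max:
        raise ValueError("age_min must be < age_max")
    rng = np.random.default_rng([int(seed), 0xC0407])
    ages = rng.uniform(age_min, age_max, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    n_pat = int(np.rint(n * group_fraction))
    group = np.array(["control"] * n, dtype=object)
    group[rng.permutation(n)[:n_pat]] = "patient"
    ids = [f"{id_prefix}-{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame({"participant_id": ids, "age": ages,
                         "sex": sex, "group": group})


def _subject_streams(subject_id: str, seed: int):
    h = zlib.crc32(subject_id.encode("utf-8"))
    return (np.random.default_rng([int(seed), h, 0]),
            np.random.default_rng([int(seed), h, 1]))


def subject_random_effects(subject_id: str, seed: int,
                           effects: EffectModel) -> tuple[float, np.ndarray]:
    """Realized (global intercept, per-region intercepts) for a subject.

    Deterministic per (id, seed): standard-normal draws from the subject's
    own stream, scaled by subject_sd and region_sd.
    """
    rng, _ = _subject_streams(subject_id, seed)
    intercept = float(rng.standard_normal() * effects.subject_sd)
    region = rng.standard_normal(effects.n_regions) * effects.region_sd
    return intercept, region


def subject_intercept(subject_id: str, seed: int, subject_sd: float) -> float:
    """The subject's realized global random intercept."""
    rng, _ = _subject_streams(subject_id, seed)
    return float(rng.standard_normal() * subject_sd)


def render_subject(record, atlas, effects: EffectModel, seed: int = 0) -> np.ndarray:
    """Render a subject's multi-channel volume stack, shape (C, D, H, W).

    ``record`` is a mapping/row with participant_id, age and group.
    Deterministic per (participant_id, seed).
    """
    labels = as_array(atlas)
    k = effects.n_regions
    present = set(np.unique(labels)) - {0}
    referenced = set(range(1, k + 1))
    missing = sorted(referenced - present)
    if missing:
        raise ValueError(f"atlas is missing region labels referenced by the "
                         f"effect model: {missing}")

    sid = str(record["participant_id"])
    age = float(record["age"])
    is_patient = str(record["group"]) == "patient"

    intercept, region_intercepts = subject_random_effects(sid, seed, effects)
    _, noise_rng = _subject_streams(sid, seed)

    lut = np.zeros(k + 1)
    lut[1:] = (effects.baseline
               + effects.age_slope * (age - effects.age_ref)
               + (effects.disease_offset if is_patient else 0.0)
               + intercept
               + region_intercepts)
    latent = lut[labels]
    background = labels == 0
    latent[background] = 0.0

    stack = np.empty((effects.n_channels,) + labels.shape)
    for c in range(effects.n_channels):
        noise = (noise_rng.normal(0.0, effects.voxel_sd, labels.shape)
                 if effects.voxel_sd > 0 else 0.0)
        stack[c] = effects.channel_mixing[c] * latent + noise
    return stack


# ---------------------------------------------------------------------------
# dataset round-trip


def write_dataset(cohort: pd.DataFrame, volumes: dict[str, np.ndarray],
                  atlas, region_table: pd.DataFrame,
                  manifest: GroundTruthManifest, out_dir: str | Path) -> Path:
    """Write a self-contained dataset tree.

    Layout: ``atlas.nii.gz``, ``regions.tsv``, ``participants.tsv`` (with
    one path column per channel), ``manifest.json`` and per-subject
    ``sub-XXXX/chan-C.nii.gz`` files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    missing = [sid for sid in cohort["participant_id"] if sid not in volumes]
    if missing:
        raise ValueError(f"missing volumes for subjects: {missing}")

    save_nifti(out / "atlas.nii.gz", atlas)
    region_table.to_csv(out / "regions.tsv", sep="\t", index=False)

    n_channels = manifest.effects.n_channels
    path_cols: dict[str, list[str]] = {f"path_chan{c}": [] for c in range(n_channels)}
    for sid in cohort["participant_id"]:
        stack = volumes[sid]
        if stack.shape[0] != n_channels:
            raise ValueError(f"{sid}: expected {n_channels} channels, "
                             f"got {stack.shape[0]}")
        for c in range(n_channels):
            rel = f"{sid}/chan-{c}.nii.gz"
            save_nifti(out / rel, stack[c])
            path_cols[f"path_chan{c}"].append(rel)

    table = cohort.copy()
    for col, paths in path_cols.items():
        table[col] = paths
    table.to_csv(out / "participants.tsv", sep="\t", index=False)
    write_json(out / "manifest.json", manifest.to_dict())
    return out


def read_dataset(out_dir: str | Path):
    """Read back a dataset tree written by :func:`write_dataset`.

    Returns (cohort, volumes, atlas, region_table, manifest).
    """
    out = Path(out_dir)
    cohort = pd.read_csv(out / "participants.tsv", sep="\t")
    atlas = load_nifti(out / "atlas.nii.gz")
    region_table = pd.read_csv(out / "regions.tsv", sep="\t")
    manifest = GroundTruthManifest.from_dict(read_json(out / "manifest.json"))
    path_cols = sorted(c for c in cohort.columns if c.startswith("path_chan"))
    volumes = {}
    for _, row in cohort.iterrows():
        stack = np.stack([load_nifti(out / row[c]).data for c in path_cols])
        volumes[row["participant_id"]] = stack
    return cohort, volumes, atlas, region_table, manifest
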