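"""Synthetic multi-subject cohorts for connectivity-based parcellation.

Real inputs to the pipeline are per-subject track-density volumes: for each
seed voxel of the pallidum (or a relay nucleus) and each remote target, a
nonnegative scalar measuring streamline density. Those volumes are produced
by probabilistic tractography, which is outside the scope of this package.
This module emulates their statistical structure with a known ground truth:

* a shared ellipsoidal seed ROI on a common template grid;
* per-target density profiles that are Gaussian bumps along one spatial
  axis, with strictly increasing peak positions — reproducing the
  anterior-limbic / intermediate-associative / posterior-sensorimotor
  topographic ordering of pallidal afferents and efferents;
* per-subject rigid jitter of the profile (template-registration error) and
  multiplicative log-normal voxel noise (count-like tractography noise);
* the noiseless per-voxel argmax of the profiles as the ground-truth label
  field, against which label recovery can be scored exactly.

All randomness flows from ``CohortConfig.rng_seed``; two calls with the same
config produce bit-identical cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cbp_engine import LabelParcellation

DEFAULT_LABELS = ("limbic", "associative", "sensorimotor", "other")

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic hemisphere cohort.

    Parameters
    ----------
    n_subjects:
        Number of subjects to simulate.
    grid_shape:
        Template grid in voxels; every dimension must be >= 5.
    voxel_size_mm:
        Isotropic voxel edge length in mm (1.25 mm matches high-quality
        diffusion acquisitions).
    n_targets:
        Number of remote targets (functional territories); >= 2.
    gradient_axis:
        Spatial axis ("x", "y" or "z") along which target dominance is
        topographically ordered. "y" is the anteroposterior axis in RAS.
    gradient_centers:
        Normalized peak position in [0, 1] of each target's density profile
        along ``gradient_axis``; strictly increasing, one per target.
    gradient_width:
        Normalized standard deviation of each Gaussian profile.
    noise_cv:
        Coefficient of variation of the multiplicative log-normal voxel
        noise; 0 disables noise.
    jitter_sd_mm:
        Standard deviation in mm of the per-subject rigid translation of
        the density profiles along ``gradient_axis``; 0 disables jitter.
    label_center_shift:
        Optional per-target additive shift (normalized axis units) of the
        profile peak, used to plant a hemispheric effect: shifting one
        target's peak toward its posterior neighbour moves their shared
        boundary by about half the shift, so that target's parcel — hence
        its density index — is genuinely larger. A territory change of
        this kind survives the pipeline's per-map mean normalization,
        which cancels any purely multiplicative density gain.
    rng_seed:
        Seed for all randomness in the cohort.

    The per-target profiles are mean-equalized over the seed ROI (each has
    in-ROI mean 1 before noise), so the pipeline's mean normalization is
    the identity on noiseless data and the ground-truth argmax is exactly
    what a noiseless winner-takes-all recovers.
    """

    n_subjects: int = 20
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 1.25
    n_targets: int = 4
    gradient_axis: str = "y"
    gradient_centers: tuple[float, ...] = (0.15, 0.4, 0.65, 0.9)
    gradient_width: float = 0.10
    noise_cv: float = 0.3
    jitter_sd_mm: float = 0.625
    label_center_shift: tuple[float, ...] | None = None
    label_names: tuple[str, ...] = DEFAULT_LABELS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        if len(self.grid_shape) != 3 or any(d < 5 for d in self.grid_shape):
            raise ConfigurationError(
                f"degenerate grid {self.grid_shape}: every dimension must be >= 5"
            )
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel_size_mm must be positive")
        if self.n_targets < 2:
            raise ConfigurationError("n_targets must be >= 2")
        if self.gradient_axis not in _AXIS_INDEX:
            raise ConfigurationError(f"gradient_axis must be one of x,y,z, got {self.gradient_axis!r}")
        if len(self.gradient_centers) != self.n_targets:
            raise ConfigurationError("need one gradient center per target")
        centers = np.asarray(self.gradient_centers, dtype=float)
        if np.any(np.diff(centers) <= 0):
            raise ConfigurationError("gradient_centers must be strictly increasing")
        if np.any(centers < 0) or np.any(centers > 1):
            raise ConfigurationError("gradient_centers must lie in [0, 1]")
        if self.gradient_width <= 0:
            raise ConfigurationError("gradient_width must be positive")
        if self.noise_cv < 0 or self.jitter_sd_mm < 0:
            raise ConfigurationError("noise_cv and jitter_sd_mm must be nonnegative")
        if len(self.label_names) != self.n_targets:
            raise ConfigurationError("need one label name per target")
        if self.label_center_shift is not None:
            if len(self.label_center_shift) != self.n_targets:
                raise ConfigurationError("label_center_shift needs one value per target")
            shifted = centers + np.asarray(self.label_center_shift, dtype=float)
            if np.any(np.diff(shifted) <= 0) or np.any(shifted < 0) or np.any(shifted > 1):
                raise ConfigurationError(
                    "label_center_shift must keep centers strictly increasing within [0, 1]"
                )

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-mm RAS affine placing the grid center at the origin."""
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        center = (np.asarray(self.grid_shape, dtype=float) - 1) / 2.0
        aff[:3, 3] = -center * self.voxel_size_mm
        return aff


@dataclass
class SubjectBundle:
    """One subject's simulated data: ROI, per-target densities, ground truth."""

    subject_id: str
    seed_roi: np.ndarray
    densities: dict[str, np.ndarray]
    truth: LabelParcellation


def make_seed_roi(config: CohortConfig) -> np.ndarray:
    """Build an ellipsoidal binary seed ROI centered in the grid.

    The ellipsoid's half-axes span 40% of each grid dimension, so the ROI is
    connected, reflection-symmetric through the grid center, and comfortably
    inside the volume.
    """
    shape = np.asarray(config.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    half_axes = 0.4 * shape
    idx = np.indices(config.grid_shape, dtype=float)
    dist2 = sum(
        ((idx[a] - center[a]) / half_axes[a]) ** 2 for a in range(3)
    )
    roi = dist2 <= 1.0
    if roi.sum() < 100:
        raise ConfigurationError(
            f"grid {config.grid_shape} too small: ellipsoid has {int(roi.sum())} voxels (< 100)"
        )
    return roi


def _axis_coordinate(config: CohortConfig) -> np.ndarray:
    """Normalized [0,1] coordinate of each voxel along the gradient axis."""
    ax = _AXIS_INDEX[config.gradient_axis]
    n = config.grid_shape[ax]
    coord = np.arange(n, dtype=float) / (n - 1)
    shape = [1, 1, 1]
    shape[ax] = n
    return np.broadcast_to(coord.reshape(shape), config.grid_shape)


def _bumps(config: CohortConfig, shift: float = 0.0) -> np.ndarray:
    """Raw Gaussian bumps, shape (n_targets, *grid_shape).

    ``shift`` translates the voxel coordinate (in normalized units) before
    evaluating the profiles — the subject-level jitter.
    """
    pos = _axis_coordinate(config) + shift
    centers = np.asarray(config.gradient_centers, dtype=float)
    if config.label_center_shift is not None:
        centers = centers + np.asarray(config.label_center_shift, dtype=float)
    w = config.gradient_width
    return np.exp(-0.5 * ((pos[None] - centers[:, None, None, None]) / w) ** 2)


def _profiles(config: CohortConfig, seed_roi: np.ndarray, shift: float = 0.0) -> np.ndarray:
    """Generating profiles: Gaussian bumps mean-equalized over the seed ROI.

    Each bump is divided by its unshifted in-ROI mean, so every profile has
    in-ROI mean 1 and the pipeline's mean normalization is the identity on
    noiseless data. Jitter is a pure translation of this fixed profile
    (the normalization constants do not move with the subject).
    """
    roi_means = _bumps(config)[:, seed_roi].mean(axis=1)
    return _bumps(config, shift=shift) / roi_means[:, None, None, None]


def truth_parcellation(config: CohortConfig, seed_roi: np.ndarray | None = None) -> LabelParcellation:
    """Ground-truth labels: noiseless per-voxel argmax of the profiles."""
    if seed_roi is None:
        seed_roi = make_seed_roi(config)
    prof = _profiles(config, seed_roi)
    labels = np.where(seed_roi, np.argmax(prof, axis=0) + 1, 0).astype(np.int32)
    return LabelParcellation(labels=labels, label_names=list(config.label_names), seed_roi=seed_roi)


def simulate_cohort(config: CohortConfig) -> list[SubjectBundle]:
    """Simulate all subjects of one cohort.

    Density of target ``t`` at voxel ``v`` is ``G_t(pos(v) + jitter) * eps(v)``
    where ``G_t`` is the target's Gaussian profile, ``jitter`` a per-subject
    normal translation (SD ``jitter_sd_mm``, expressed in normalized axis
    units), and ``eps`` i.i.d. log-normal with unit mean and coefficient of
    variation ``noise_cv``. Densities are zero outside the seed ROI. The
    ground truth shared by all subjects is the noiseless, unjittered argmax.
    """
    rng = np.random.default_rng(config.rng_seed)
    seed_roi = make_seed_roi(config)
    truth = truth_parcellation(config, seed_roi)

    ax = _AXIS_INDEX[config.gradient_axis]
    axis_extent_mm = (config.grid_shape[ax] - 1) * config.voxel_size_mm
    jitter_sd_norm = config.jitter_sd_mm / axis_extent_mm

    # lognormal with mean 1 and CV c: sigma^2 = ln(1+c^2), mu = -sigma^2/2
    if config.noise_cv > 0:
        sigma2 = np.log1p(config.noise_cv**2)
        mu = -sigma2 / 2.0
        sigma = np.sqrt(sigma2)
    subjects: list[SubjectBundle] = []
    for s in range(config.n_subjects):
        shift = rng.normal(0.0, jitter_sd_norm) if jitter_sd_norm > 0 else 0.0
        prof = _profiles(config, seed_roi, shift=shift)
        if config.noise_cv > 0:
            eps = rng.lognormal(mean=mu, sigma=sigma, size=prof.shape)
            prof = prof * eps
        prof = prof * seed_roi[None]
        densities = {
            name: prof[t] for t, name in enumerate(config.label_names)
        }
        subjects.append(
            SubjectBundle(
                subject_id=f"sub-{s:03d}",
                seed_roi=seed_roi,
                densities=densities,
                truth=truth,
            )
        )
    return subjects


def make_site_table(
    config: CohortConfig,
    labels: list[str] | tuple[str, ...] | None = None,
    offset_mm: tuple[float, float, float] = (3.0, 4.0, 0.0),
) -> pd.DataFrame:
    """Synthetic stimulation-site table: one point at each truth-parcel COG
    plus one point displaced ``offset_mm`` from the first COG.

    Returns a DataFrame with columns ``name, x, y, z, source`` (mm template
    coordinates); empty truth parcels are omitted with a warning.
    """
    if labels is None:
        labels = list(config.label_names)
    if not labels:
        raise ConfigurationError("labels must be nonempty")
    truth = truth_parcellation(config)
    aff = config.affine
    rows = []
    first_cog = None
    for name in labels:
        t = list(config.label_names).index(name) + 1
        voxels = np.argwhere(truth.labels == t)
        if voxels.size == 0:
            warnings.warn(f"truth parcel {name!r} is empty; site omitted")
            continue
        centroid_vox = voxels.mean(axis=0)
        cog = aff[:3, :3] @ centroid_vox + aff[:3, 3]
        if first_cog is None:
            first_cog = cog
        rows.append({"name": f"site_{name}", "x": cog[0], "y": cog[1], "z": cog[2], "source": "synthetic"})
    if first_cog is not None:
        off = first_cog + np.asarray(offset_mm, dtype=float)
        rows.append({"name": "site_offset", "x": off[0], "y": off[1], "z": off[2], "source": "synthetic"})
    return pd.DataFrame(rows, columns=["name", "x", "y", "z", "source"])


def hemisphere_pair(
    config: CohortConfig,
    left_shift: tuple[float, ...] | None = None,
    right_shift: tuple[float, ...] | None = None,
) -> tuple[list[SubjectBundle], list[SubjectBundle]]:
    """Simulate paired left/right cohorts as two independent cohorts.

    Both hemispheres share `config` except for an optional per-label
    profile-center shift (the plantable lateralization effect) and a
    derived seed for the right side so the noise draws are independent.
    """
    left_cfg = replace(config, label_center_shift=left_shift)
    right_cfg = replace(
        config,
        label_center_shift=right_shift,
        rng_seed=(config.rng_seed * 2 + 1) % (2**31 - 1),
    )
    return simulate_cohort(left_cfg), simulate_cohort(right_cfg)
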