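"""Hemispheric asymmetry statistics on parcel volumes.

Per-subject parcel size is summarized as the streamline density index
SDI = 100 * v / V_ROI (parcel voxels over seed-ROI voxels, in percent).
Left-right asymmetry is assessed two ways:

* a paired sign-flip permutation test on the per-subject left-right SDI
  differences, with family-wise error controlled by the t-max method:
  each permutation flips whole subjects' difference vectors (preserving
  the correlation across variables) and records the maximum |t| over the
  variable family, so corrected p-values are valid jointly;
* a per-subject lateralization index LI = (Left - Right)/(Left + Right),
  classified as left-dominant when LI > 0.1 and right-dominant when
  LI < -0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class LateralityRecord:
    li: float
    category: str  # left_lateralized | right_lateralized | not_lateralized


@dataclass
class PermutationResult:
    variable_keys: list
    t_obs: np.ndarray           # NaN where the t statistic is undefined
    p_corrected: np.ndarray     # t-max corrected, two-sided
    p_uncorrected: np.ndarray
    n_perm: int
    rng_seed: int
    alpha: float

    def significant(self) -> np.ndarray:
        return self.p_corrected < self.alpha


def sdi(v: int | float, V_ROI: int | float) -> float:
    """Streamline density index: 100 * parcel voxels / seed-ROI voxels."""
    if V_ROI <= 0:
        raise ValueError("seed-ROI voxel count must be positive")
    if not 0 <= v <= V_ROI:
        raise ValueError(f"parcel count {v} outside [0, {V_ROI}]")
    return 100.0 * v / V_ROI


def lateralization_index(left_sdi: float, right_sdi: float, cutoff: float = 0.1) -> LateralityRecord:
    """LI = (Left - Right)/(Left + Right), categorized at the ±cutoff."""
    total = left_sdi + right_sdi
    if total <= 0:
        raise ValueError("LI undefined: left + right must be positive")
    li = (left_sdi - right_sdi) / total
    if li > cutoff:
        category = "left_lateralized"
    elif li < -cutoff:
        category = "right_lateralized"
    else:
        category = "not_lateralized"
    return LateralityRecord(li=li, category=category)


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t statistic per column.

    Zero-variance columns have no finite t: all-zero differences give t = 0
    (the null coincides with the observation), nonzero constant differences
    give NaN (undefined).
    """
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = 0.0
    t[(sd == 0) & (mean != 0)] = np.nan
    return t


def paired_permutation_tmax(
    left: np.ndarray,
    right: np.ndarray,
    n_perm: int = 50_000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    variable_keys: list | None = None,
) -> PermutationResult:
    """Paired sign-flip permutation test with t-max multiplicity correction.

    ``left`` and ``right`` are subjects x variables matrices of SDI values.
    The null distribution is built by randomly negating each subject's
    whole difference vector (the same flips applied across variables within
    a permutation); for each permutation the maximum |t| over variables is
    recorded, and the two-sided corrected p-value of variable j is

        p_j = (1 + #{permutations with t-max >= |t_obs_j|}) / (n_perm + 1).

    Variables whose differences have zero variance have no t statistic;
    they are reported as NaN and excluded from the max with a warning.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError(f"shape mismatch: left {left.shape} vs right {right.shape}")
    if left.ndim != 2 or left.shape[0] < 3:
        raise ValueError("need a subjects x variables matrix with >= 3 subjects")
    if np.any(~np.isfinite(left)) or np.any(~np.isfinite(right)):
        raise ValueError("missing or non-finite values are not supported")
    n_sub, n_var = left.shape
    if variable_keys is None:
        variable_keys = list(range(n_var))

    diffs = left - right
    t_obs = _paired_t(diffs)
    valid = ~np.isnan(t_obs)
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} variable(s) with zero-variance differences: "
            "t undefined, excluded from the t-max family"
        )
    if not valid.any():
        return PermutationResult(
            variable_keys=variable_keys,
            t_obs=t_obs,
            p_corrected=np.full(n_var, np.nan),
            p_uncorrected=np.full(n_var, np.nan),
            n_perm=n_perm,
            rng_seed=rng_seed,
            alpha=alpha,
        )

    rng = np.random.default_rng(rng_seed)
    d = diffs[:, valid]
    abs_t_obs = np.abs(t_obs[valid])

    t_max = np.empty(n_perm)
    abs_t_perm_ge = np.zeros(d.shape[1])   # per-variable uncorrected counts
    # batch the permutations to bound memory at ~ batch x subjects doubles
    batch = max(1, min(n_perm, 2_000_000 // max(1, n_sub * d.shape[1])))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(b, n_sub))
        flipped = signs[:, :, None] * d[None, :, :]        # b x subjects x vars
        mean = flipped.mean(axis=1)
        sd = flipped.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(mean / (sd / np.sqrt(n_sub)))
        t = np.nan_to_num(t, nan=0.0, posinf=np.inf)
        t_max[done : done + b] = t.max(axis=1)
        abs_t_perm_ge += (t >= abs_t_obs[None, :]).sum(axis=0)
        done += b

    p_corr_valid = (1.0 + (t_max[:, None] >= abs_t_obs[None, :]).sum(axis=0)) / (n_perm + 1)
    p_unc_valid = (1.0 + abs_t_perm_ge) / (n_perm + 1)

    p_corrected = np.full(n_var, np.nan)
    p_uncorrected = np.full(n_var, np.nan)
    p_corrected[valid] = p_corr_valid
    p_uncorrected[valid] = p_unc_valid
    return PermutationResult(
        variable_keys=variable_keys,
        t_obs=t_obs,
        p_corrected=p_corrected,
        p_uncorrected=p_uncorrected,
        n_perm=n_perm,
        rng_seed=rng_seed,
        alpha=alpha,
    )


def exhaustive_sign_flip_pvalues(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Exact t-max corrected p-values by enumerating all 2^n sign patterns.

    Feasible only for small cohorts; serves as the exact reference for the
    Monte-Carlo estimator. Uses the same (1+b)/(1+m) convention with m = 2^n
    enumerated patterns (the identity pattern contributes the +1 in b).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    diffs = left - right
    n_sub, n_var = diffs.shape
    if n_sub > 20:
        raise ValueError("exhaustive enumeration limited to <= 20 subjects")
    t_obs = _paired_t(diffs)
    valid = ~np.isnan(t_obs)
    abs_t_obs = np.abs(t_obs[valid])
    d = diffs[:, valid]

    patterns = np.array(
        [[1.0 if (i >> s) & 1 else -1.0 for s in range(n_sub)] for i in range(2**n_sub)]
    )
    flipped = patterns[:, :, None] * d[None, :, :]
    mean = flipped.mean(axis=1)
    sd = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean / (sd / np.sqrt(n_sub)))
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf)
    t_max = t.max(axis=1)
    p_valid = (t_max[:, None] >= abs_t_obs[None, :]).mean(axis=0)
    p = np.full(n_var, np.nan)
    p[valid] = p_valid
    return p
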