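"""End-to-end orchestration: simulate/ingest, parcellate, aggregate, report.

Two entry points:

* :func:`run_synthetic_study` drives the whole analysis on simulated
  cohorts — per-subject winner-takes-all parcellation of GPi (3 pathways)
  and GPe (2 pathways) in both hemispheres, 50%-thresholded maximum
  probability maps with volumes and centers of gravity, Dice between
  pathway pairs, OBL/TAO reproducibility, SDI lateralization with the
  t-max permutation test, and stimulation-site proximity;
* :func:`validate_manifest` / :func:`run_manifest_parcellation` consume a
  YAML manifest of NIfTI density volumes on disk for real data arriving
  pre-registered on one template grid.

NIfTI I/O goes through nibabel throughout.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cbp_engine import DensityMap, LabelParcellation, parcellate_subject
from .group_maps import (
    MPMask,
    build_probability_map,
    center_of_gravity,
    mask_volume_mm3,
    threshold_mpm,
)
from .laterality_stats import lateralization_index, paired_permutation_tmax, sdi
from .similarity_metrics import dice, overlap_by_label, total_accumulated_overlap
from .stim_proximity import cogs_from_masks, load_site_table, proximity_report
from .synthetic_cohort import CohortConfig, make_site_table, simulate_cohort

GPI_PATHWAYS = ("striatopallidal", "subthalamopallidal", "pallidothalamic")
GPE_PATHWAYS = ("striatopallidal", "subthalamopallidal")
NUCLEI = {"GPi": GPI_PATHWAYS, "GPe": GPE_PATHWAYS}
HEMISPHERES = ("left", "right")


# --------------------------------------------------------------------------
# NIfTI helpers

def save_volume(path: Path | str, data: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def save_labels(path: Path | str, parcel: LabelParcellation, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(parcel.labels.astype(np.int16), affine)
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    sidecar.write_text(
        json.dumps({"label_names": parcel.label_names, "provenance": parcel.provenance}, indent=2)
    )


def load_volume(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_cohort(config: CohortConfig, out_dir: Path | str) -> dict:
    """Simulate a cohort and write it to disk as NIfTI + CSV.

    One density volume per subject x target, plus the shared seed ROI, the
    ground-truth label field, and the synthetic stimulation-site table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = simulate_cohort(config)
    aff = config.affine
    n_files = 0
    for sub in subjects:
        for label, dens in sub.densities.items():
            save_volume(out_dir / f"{sub.subject_id}_target-{label}_density.nii.gz", dens, aff)
            n_files += 1
    save_volume(out_dir / "seed_roi.nii.gz", subjects[0].seed_roi.astype(np.float32), aff)
    save_labels(out_dir / "truth_labels.nii.gz", subjects[0].truth, aff)
    make_site_table(config).to_csv(out_dir / "sites.csv", index=False)
    return {"n_subjects": len(subjects), "density_volumes": n_files, "out_dir": str(out_dir)}


# --------------------------------------------------------------------------
# Manifest-driven runs (real data arriving on a common template grid)

@dataclass
class RunManifest:
    """File map for a manifest-driven parcellation run.

    ``density_files`` maps (subject, nucleus, pathway, label, hemisphere)
    to a NIfTI path; ``roi_files`` maps (nucleus, hemisphere) to the seed
    ROI path shared by that nucleus's maps.
    """

    density_files: dict[tuple[str, str, str, str, str], str]
    roi_files: dict[tuple[str, str], str]
    threshold_fraction: float = 0.5
    out_dir: str = "."
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunManifest":
        raw = yaml.safe_load(Path(path).read_text())
        density = {
            (e["subject"], e["nucleus"], e["pathway"], e["label"], e["hemisphere"]): e["file"]
            for e in raw["densities"]
        }
        rois = {(e["nucleus"], e["hemisphere"]): e["file"] for e in raw["rois"]}
        return cls(
            density_files=density,
            roi_files=rois,
            threshold_fraction=raw.get("threshold_fraction", 0.5),
            out_dir=raw.get("out_dir", "."),
            rng_seed=raw.get("rng_seed", 0),
        )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_manifest(manifest: RunManifest) -> ValidationReport:
    """Check file existence, label completeness, grid agreement, all-zero maps."""
    report = ValidationReport()
    for key, f in {**manifest.density_files, **{k: v for k, v in manifest.roi_files.items()}}.items():
        if not Path(f).exists():
            report.errors.append(f"missing file for {key}: {f}")
    if report.errors:
        return report

    # label completeness: every (subject, nucleus, pathway, hemisphere) needs
    # the same label set
    groups: dict[tuple, set] = {}
    for (subject, nucleus, pathway, label, hemi) in manifest.density_files:
        groups.setdefault((subject, nucleus, pathway, hemi), set()).add(label)
    all_labels = set().union(*groups.values()) if groups else set()
    for key, labels in groups.items():
        for absent in sorted(all_labels - labels):
            report.errors.append(f"missing target map: subject={key[0]} nucleus={key[1]} pathway={key[2]} label={absent} hemisphere={key[3]}")

    shape_ref: tuple | None = None
    for key, f in manifest.density_files.items():
        data, _ = load_volume(f)
        if shape_ref is None:
            shape_ref = data.shape
        elif data.shape != shape_ref:
            report.errors.append(f"grid mismatch for {key}: {data.shape} != {shape_ref}")
        if not np.any(data > 0):
            report.warnings.append(f"all-zero density volume for {key}")
    return report


def run_manifest_parcellation(manifest: RunManifest) -> dict:
    """Parcellate every (subject, nucleus, pathway, hemisphere) in a manifest."""
    report = validate_manifest(manifest)
    if not report.ok:
        raise ValueError("manifest validation failed:\n" + "\n".join(report.errors))
    out_dir = Path(manifest.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups: dict[tuple, dict[str, str]] = {}
    for (subject, nucleus, pathway, label, hemi), f in manifest.density_files.items():
        groups.setdefault((subject, nucleus, pathway, hemi), {})[label] = f
    n_maps = 0
    for (subject, nucleus, pathway, hemi), files in sorted(groups.items()):
        roi, affine = load_volume(manifest.roi_files[(nucleus, hemi)])
        roi = roi > 0
        maps = []
        for label in sorted(files):
            data, _ = load_volume(files[label])
            maps.append(
                DensityMap(values=np.where(roi, data, 0.0), seed_roi=roi,
                           target_label=label, subject_id=subject)
            )
        parcel = parcellate_subject(maps)
        parcel.provenance = {"nucleus": nucleus, "pathway": pathway, "hemisphere": hemi}
        save_labels(out_dir / f"{subject}_{nucleus}_{pathway}_{hemi}_labels.nii.gz", parcel, affine)
        n_maps += 1
    return {"parcellations_written": n_maps, "out_dir": str(out_dir), "version": __version__}


# --------------------------------------------------------------------------
# Synthetic end-to-end study

@dataclass(frozen=True)
class StudyConfig:
    """Study-level knobs for the synthetic end-to-end run.

    ``left_shift`` plants the hemispheric effect: a per-label shift of the
    profile peaks applied to the left cohorts only. Shifting the limbic
    peak posteriorly enlarges the left limbic territory, so its density
    index is reliably higher on the left and the permutation test has a
    true positive to find.
    """

    rng_seed: int = 0
    n_subjects: int = 20
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 1.25
    noise_cv: float = 0.3
    jitter_sd_mm: float = 0.625
    threshold_fraction: float = 0.5
    n_perm: int = 50_000
    left_shift: tuple[float, ...] = (0.05, 0.0, 0.0, 0.0)


@dataclass
class StudySummary:
    """All tables produced by one synthetic study run."""

    n_subjects: int
    rng_seed: int
    mpm_counts: dict[str, int]                # nucleus -> thresholded MPMs per hemisphere
    volumes: pd.DataFrame                      # nucleus,pathway,label,hemisphere,volume_mm3,cog_x/y/z
    dice_table: pd.DataFrame                   # nucleus,pathway_pair,label,hemisphere,dice
    reproducibility: pd.DataFrame              # nucleus,pathway,hemisphere,label(or TAO),value
    sdi_table: pd.DataFrame                    # subject,nucleus,pathway,label,hemisphere,sdi
    permutation: pd.DataFrame                  # nucleus,pathway,label,t_obs,p_corrected,p_uncorrected
    laterality: pd.DataFrame                   # nucleus,pathway,label,pct_left,pct_right,pct_none
    proximity_distances: pd.DataFrame
    proximity_membership: pd.DataFrame
    label_recovery: float                      # mean per-subject truth-recovery fraction
    version: str = __version__


def _derived_seed(base: int, *idx: int) -> int:
    return int(np.random.SeedSequence([base, *idx]).generate_state(1)[0] % (2**31 - 1))


def _cohort_config(study: StudyConfig, nucleus_i: int, pathway_i: int, hemi_i: int) -> CohortConfig:
    shift = study.left_shift if hemi_i == 0 else None
    return CohortConfig(
        n_subjects=study.n_subjects,
        grid_shape=study.grid_shape,
        voxel_size_mm=study.voxel_size_mm,
        noise_cv=study.noise_cv,
        jitter_sd_mm=study.jitter_sd_mm,
        label_center_shift=shift,
        rng_seed=_derived_seed(study.rng_seed, nucleus_i, pathway_i, hemi_i),
    )


def run_synthetic_study(study: StudyConfig, out_dir: Path | str | None = None) -> StudySummary:
    """Run the full pipeline on synthetic cohorts and collect every table.

    For each nucleus (GPi against 3 pathways, GPe against 2), hemisphere
    and pathway, a cohort of subjects is simulated, each subject is
    parcellated by normalized winner-takes-all, subject parcels are
    aggregated into thresholded MPMs, and the statistical surface (Dice,
    OBL/TAO, SDI + permutation laterality, site proximity) is computed.
    """
    vol_rows, dice_rows, repro_rows, sdi_rows, perm_rows, lat_rows = [], [], [], [], [], []
    mpm_counts: dict[str, int] = {}
    recovery: list[float] = []
    # (nucleus, pathway, hemi) -> per-subject parcels / thresholded MPMs by label
    parcels_by_run: dict[tuple[str, str, str], list[LabelParcellation]] = {}
    mpm_by_run: dict[tuple[str, str, str], dict[str, MPMask]] = {}

    base_cfg = None
    for ni, (nucleus, pathways) in enumerate(NUCLEI.items()):
        n_mpm = 0
        for pi, pathway in enumerate(pathways):
            for hi, hemi in enumerate(HEMISPHERES):
                cfg = _cohort_config(study, ni, pi, hi)
                if base_cfg is None:
                    base_cfg = cfg
                subjects = simulate_cohort(cfg)
                truth = subjects[0].truth
                roi_count = int(subjects[0].seed_roi.sum())
                parcels = []
                for sub in subjects:
                    maps = [
                        DensityMap(values=sub.densities[name], seed_roi=sub.seed_roi,
                                   target_label=name, subject_id=sub.subject_id)
                        for name in cfg.label_names
                    ]
                    parcel = parcellate_subject(maps)
                    parcel.provenance = {"nucleus": nucleus, "pathway": pathway, "hemisphere": hemi}
                    parcels.append(parcel)
                    inroi = sub.seed_roi
                    recovery.append(float((parcel.labels[inroi] == truth.labels[inroi]).mean()))
                    for li, label in enumerate(cfg.label_names, start=1):
                        sdi_rows.append({
                            "subject": sub.subject_id, "nucleus": nucleus, "pathway": pathway,
                            "label": label, "hemisphere": hemi,
                            "sdi": sdi(int((parcel.labels == li).sum()), roi_count),
                        })
                parcels_by_run[(nucleus, pathway, hemi)] = parcels

                mpms: dict[str, MPMask] = {}
                for label in cfg.label_names:
                    pmap = build_probability_map(parcels, label)
                    mpm = threshold_mpm(pmap, study.threshold_fraction, affine=cfg.affine)
                    mpm.label_name = f"{nucleus}_{pathway}_{label}_{hemi}"
                    mpms[label] = mpm
                    n_mpm += 1 if hemi == "left" else 0
                    if mpm.mask.any():
                        cog = center_of_gravity(mpm)
                        vol_rows.append({
                            "nucleus": nucleus, "pathway": pathway, "label": label,
                            "hemisphere": hemi, "volume_mm3": mask_volume_mm3(mpm),
                            "cog_x": cog[0], "cog_y": cog[1], "cog_z": cog[2],
                        })
                mpm_by_run[(nucleus, pathway, hemi)] = mpms

                for label in cfg.label_names:
                    masks = [p.mask(label) for p in parcels]
                    repro_rows.append({
                        "nucleus": nucleus, "pathway": pathway, "hemisphere": hemi,
                        "measure": "OBL", "label": label,
                        "value": overlap_by_label(masks),
                    })
                repro_rows.append({
                    "nucleus": nucleus, "pathway": pathway, "hemisphere": hemi,
                    "measure": "TAO", "label": "",
                    "value": total_accumulated_overlap(parcels),
                })
        mpm_counts[nucleus] = n_mpm

    labels = list(base_cfg.label_names)

    # Dice between functionally homologous MPMs of different pathways
    for nucleus, pathways in NUCLEI.items():
        for pa, pb in itertools.combinations(pathways, 2):
            for hemi in HEMISPHERES:
                for label in labels:
                    A = mpm_by_run[(nucleus, pa, hemi)][label].mask
                    B = mpm_by_run[(nucleus, pb, hemi)][label].mask
                    dice_rows.append({
                        "nucleus": nucleus, "pathway_pair": f"{pa}/{pb}", "label": label,
                        "hemisphere": hemi, "dice": dice(A, B),
                    })

    # SDI laterality: permutation test per (nucleus, pathway) family + LI
    sdi_df = pd.DataFrame(sdi_rows)
    for ni, (nucleus, pathways) in enumerate(NUCLEI.items()):
        for pi, pathway in enumerate(pathways):
            sub = sdi_df[(sdi_df.nucleus == nucleus) & (sdi_df.pathway == pathway)]
            left = sub[sub.hemisphere == "left"].pivot(index="subject", columns="label", values="sdi")[labels]
            right = sub[sub.hemisphere == "right"].pivot(index="subject", columns="label", values="sdi")[labels]
            res = paired_permutation_tmax(
                left.to_numpy(), right.to_numpy(), n_perm=study.n_perm,
                rng_seed=_derived_seed(study.rng_seed, 100 + ni, pi), variable_keys=labels,
            )
            for j, label in enumerate(labels):
                perm_rows.append({
                    "nucleus": nucleus, "pathway": pathway, "label": label,
                    "t_obs": res.t_obs[j], "p_corrected": res.p_corrected[j],
                    "p_uncorrected": res.p_uncorrected[j],
                    "mean_sdi_left": left[label].mean(), "sd_sdi_left": left[label].std(ddof=1),
                    "mean_sdi_right": right[label].mean(), "sd_sdi_right": right[label].std(ddof=1),
                })
                cats = [
                    lateralization_index(l, r).category
                    for l, r in zip(left[label], right[label])
                    if l + r > 0
                ]
                n = max(len(cats), 1)
                lat_rows.append({
                    "nucleus": nucleus, "pathway": pathway, "label": label,
                    "pct_left": 100.0 * sum(c == "left_lateralized" for c in cats) / n,
                    "pct_right": 100.0 * sum(c == "right_lateralized" for c in cats) / n,
                    "pct_none": 100.0 * sum(c == "not_lateralized" for c in cats) / n,
                })

    # Proximity: GPi sensorimotor COGs per pathway vs synthetic sites (left)
    sm_masks = []
    for pathway in GPI_PATHWAYS:
        m = mpm_by_run[("GPi", pathway, "left")]["sensorimotor"]
        m = MPMask(mask=m.mask, label_name=f"{pathway}_sensorimotor",
                   threshold_fraction=m.threshold_fraction, affine=m.affine)
        sm_masks.append(m)
    site_cfg = replace(_cohort_config(study, 0, 0, 0), label_center_shift=None)
    sites = load_site_table(make_site_table(site_cfg))
    prox = proximity_report(cogs_from_masks(sm_masks), sites, masks=sm_masks)

    summary = StudySummary(
        n_subjects=study.n_subjects,
        rng_seed=study.rng_seed,
        mpm_counts=mpm_counts,
        volumes=pd.DataFrame(vol_rows),
        dice_table=pd.DataFrame(dice_rows),
        reproducibility=pd.DataFrame(repro_rows),
        sdi_table=sdi_df,
        permutation=pd.DataFrame(perm_rows),
        laterality=pd.DataFrame(lat_rows),
        proximity_distances=prox.distances,
        proximity_membership=prox.membership,
        label_recovery=float(np.mean(recovery)),
    )
    if out_dir is not None:
        write_summary(summary, Path(out_dir))
    return summary


def write_summary(summary: StudySummary, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary.volumes.to_csv(out_dir / "mpm_volumes_cog.csv", index=False)
    summary.dice_table.to_csv(out_dir / "dice_pathway_pairs.csv", index=False)
    summary.reproducibility.to_csv(out_dir / "reproducibility_obl_tao.csv", index=False)
    summary.sdi_table.to_csv(out_dir / "sdi_per_subject.csv", index=False)
    summary.permutation.to_csv(out_dir / "laterality_permutation.csv", index=False)
    summary.laterality.to_csv(out_dir / "laterality_li_percent.csv", index=False)
    summary.proximity_distances.to_csv(out_dir / "proximity_distances_mm.csv")
    summary.proximity_membership.to_csv(out_dir / "proximity_membership.csv")
    (out_dir / "run_summary.json").write_text(json.dumps({
        "n_subjects": summary.n_subjects,
        "rng_seed": summary.rng_seed,
        "mpm_counts_per_hemisphere": summary.mpm_counts,
        "label_recovery": summary.label_recovery,
        "version": summary.version,
    }, indent=2))
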