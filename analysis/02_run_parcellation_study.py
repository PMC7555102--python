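"""Run the full two-hemisphere parcellation study on synthetic cohorts.

Simulates 20 subjects per (nucleus, pathway, hemisphere), parcellates each
subject by normalized winner-takes-all, aggregates 50%-thresholded maximum
probability maps (12 for GPi, 8 for GPe per hemisphere), and computes the
complete statistical surface: Dice between pathway pairs, OBL/TAO
reproducibility, SDI lateralization with 50,000-permutation t-max testing,
and stimulation-site proximity. All tables land in results/study/.

    python analysis/02_run_parcellation_study.py
"""

from pathlib import Path

from pallidoparc.io_pipeline import StudyConfig, run_synthetic_study

OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    study = StudyConfig(rng_seed=1, n_subjects=20, n_perm=50_000)
    summary = run_synthetic_study(study, out_dir=OUT)
    print(f"thresholded MPMs per hemisphere: {summary.mpm_counts} "
          "(4 functional territories x 3 GPi / 2 GPe pathways)")
    print(f"mean truth-label recovery across all runs: {summary.label_recovery:.3f}")
    print(f"tables written to {OUT}")
    print("Finding: the planted left limbic enlargement is visible in the SDI "
          "table and will be tested in 04; the sensorimotor MPMs of all three "
          "GPi pathways nearly coincide (see 03).")


if __name__ == "__main__":
    main()
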