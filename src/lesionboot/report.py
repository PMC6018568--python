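"""End-to-end study orchestration and report-table rendering.

`run_full_study` wires the stages together: synthetic cohort -> exact
in-sample calibration -> (optionally) lesion volumes, overlap mask,
voxelwise GLM and ROI discovery -> ROI lesion-load effect size with
credible interval -> bootstrap reproducibility study -> tables and
figures. Every output directory gets a provenance JSON (config hash, seed,
package version, warning counts) and the run is deterministic given the
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig
from .effects import credible_interval_r2
from .glm import (
    build_design_matrix,
    extract_lesion_load,
    fit_voxelwise_glm,
    fwe_threshold,
)
from .lesion_io import build_overlap_map, make_analysis_mask, save_volume
from .model import LesionDeficitModel
from .bootstrap import (
    classify_against_interval,
    select_decile_resamples,
    summarize_by_significance,
)
from .synthetic import (
    calibrate_generator,
    fix_sample_partial_r2,
    generate_cohort,
    write_cohort,
)
from .volumes import generate_lesion_volumes

__all__ = ["run_full_study", "write_report_tables"]

log = logging.getLogger("lesionboot")

_DASH = "–"  # en dash for empty table cells


def _fmt2(v) -> str:
    return _DASH if (v is None or (isinstance(v, float) and np.isnan(v))) else f"{v:.2f}"


def write_report_tables(summaries: pd.DataFrame, classification: pd.DataFrame,
                        deciles: pd.DataFrame, out_dir) -> dict:
    """Render the three study tables as CSV files.

    * ``table_deciles.csv`` — per size, the resample at each decile of the
      R² distribution (R² and p).
    * ``table_significance.csv`` — mean/median/min/max R² of significant
      and non-significant resamples per size, one row block per alpha.
    * ``table_interval.csv`` — counts of resamples above / within / below
      the full-cohort credible interval, split by significance.

    Values are displayed at 2 decimals; empty cells render as a dash.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    sizes = sorted(summaries["size"].unique())

    rows = []
    for alpha in sorted(summaries["alpha"].unique(), reverse=True):
        sub = summaries[summaries["alpha"] == alpha]
        for stat in ("count", "mean_r2", "median_r2", "min_r2", "max_r2"):
            row = {"alpha": alpha, "statistic": stat}
            for size in sizes:
                for group, tag in (("significant", "s"), ("not_significant", "ns")):
                    cell = sub[(sub["size"] == size) & (sub["group"] == group)]
                    val = cell[stat].iloc[0] if len(cell) else np.nan
                    if stat == "count":
                        row[f"{size}_{tag}"] = int(val) if np.isfinite(val) else _DASH
                    else:
                        row[f"{size}_{tag}"] = _fmt2(val)
            rows.append(row)
    sig_path = out_dir / "table_significance.csv"
    pd.DataFrame(rows).to_csv(sig_path, index=False)
    paths["significance"] = sig_path

    cls_path = out_dir / "table_interval.csv"
    classification.to_csv(cls_path, index=False)
    paths["interval"] = cls_path

    dec = deciles.copy()
    dec["r2"] = dec["r2"].map(_fmt2)
    dec["p"] = dec["p"].map(lambda v: f"{v:.3f}")
    dec_path = out_dir / "table_deciles.csv"
    dec.pivot(index="percentile", columns="size", values=["r2", "p"]).to_csv(dec_path)
    paths["deciles"] = dec_path
    return paths


def _config_hash(config: StudyConfig) -> str:
    gen = config.generator.to_dict()
    gen.pop("calibration", None)
    blob = json.dumps({**gen, "study": {
        "sizes": list(config.sizes), "n_boot": config.n_boot,
        "alphas": list(config.alphas), "seed": config.seed,
        "fwe_method": config.fwe_method, "n_perm": config.n_perm,
        "alpha_voxel": config.alpha_voxel, "min_overlap": config.min_overlap,
        "with_replacement": config.with_replacement,
        "skip_imaging": config.skip_imaging,
    }}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_full_study(config: StudyConfig, write_volumes: bool = False) -> dict:
    """Run the whole pipeline into ``config.output_dir``.

    With ``config.skip_imaging`` the latent lesion load is used directly
    (tabular mode); otherwise lesion volumes are rendered, the ROI is
    discovered by the FWE-corrected voxelwise GLM, and lesion load is the
    mean fuzzy abnormality over that ROI.

    Returns a dict of the key result objects and output paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    warning_counts = {}
    stage = "setup"
    try:
        seed_sq = np.random.SeedSequence(config.seed)
        s_cohort, s_volumes, s_roi, s_boot = (
            int(s.generate_state(1)[0] >> 1) for s in seed_sq.spawn(4))

        stage = "cohort"
        gcfg = calibrate_generator(config.generator.target_partial_r2,
                                   config.generator)
        cohort, load = generate_cohort(gcfg, seed=s_cohort)
        load = fix_sample_partial_r2(cohort, load,
                                     gcfg.target_partial_r2,
                                     sign=gcfg.effect_sign)
        write_cohort(cohort, out / "cohort.csv")
        log.info("cohort of %d patients written", len(cohort))

        roi = None
        if config.skip_imaging:
            lesion_load = load
        else:
            stage = "volumes"
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fuzzies, binaries, vol_diag = generate_lesion_volumes(
                    gcfg, cohort, load, seed=s_volumes)
            warning_counts["volumes"] = len(caught)
            stage = "roi"
            mask = make_analysis_mask(build_overlap_map(binaries),
                                      config.min_overlap)
            design = build_design_matrix(cohort)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                stat_map = fit_voxelwise_glm(fuzzies, design, mask)
            warning_counts["glm_capped_t"] = stat_map.n_capped
            roi = fwe_threshold(
                stat_map, design, fuzzies, mask,
                alpha=config.alpha_voxel, method=config.fwe_method,
                n_perm=config.n_perm, seed=s_roi)
            if roi.n_voxels == 0:
                raise RuntimeError("no voxels survived FWE correction")
            lesion_load = extract_lesion_load(fuzzies, roi)
            save_volume(mask, out / "analysis_mask.nii.gz")
            roi_img = type(mask)(in_mask=roi.as_volume().astype(bool),
                                 min_patients=config.min_overlap,
                                 voxel_size_mm=gcfg.voxel_size_mm)
            save_volume(roi_img, out / "roi.nii.gz")
            (out / "roi_settings.json").write_text(json.dumps({
                "method": roi.method, "threshold": roi.threshold_used,
                "alpha": roi.alpha, "n_voxels": roi.n_voxels,
                "mask_voxels": mask.n_voxels,
            }, indent=2))
            if write_volumes:
                vdir = out / "volumes"
                vdir.mkdir(exist_ok=True)
                for f, b in zip(fuzzies, binaries):
                    save_volume(f, vdir / f"{f.patient_id}_fuzzy.nii.gz")
                    save_volume(b, vdir / f"{b.patient_id}_binary.nii.gz")
            log.info("ROI: %d voxels (%s, threshold %.2f)",
                     roi.n_voxels, roi.method, roi.threshold_used)

        stage = "effect"
        model = LesionDeficitModel.from_dataframe(cohort, lesion_load=lesion_load)
        res = model.fit()
        ci = res.credible_interval()
        (out / "effect_size.json").write_text(json.dumps({
            "r_partial": res.r_partial, "r2": res.r2, "t": res.t_stat,
            "df": res.df, "p_two_sided": res.p_value,
            "ci_lower_r2": ci.lower_r2, "ci_upper_r2": ci.upper_r2,
            "ci_level": ci.level,
        }, indent=2))

        stage = "bootstrap"
        study = res.bootstrap_study(
            sizes=config.sizes, B=config.n_boot,
            with_replacement=config.with_replacement, seed=s_boot,
            alphas=config.alphas)
        study.records.to_csv(out / "resample_records.csv", index=False)
        summaries = summarize_by_significance(study.records, config.alphas)
        classification = classify_against_interval(study.records, ci)
        deciles = select_decile_resamples(study.records)
        write_report_tables(summaries, classification, deciles, out)
        summaries.to_json(out / "summaries.json", orient="records", indent=2)

        stage = "figures"
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        ax = study.plot_effect_distributions()
        ax.figure.savefig(out / "fig_effect_distributions.png", dpi=120)
        plt.close(ax.figure)
        ax = study.plot_significance_histogram(size=min(config.sizes))
        ax.figure.savefig(out / "fig_significance_histogram.png", dpi=120)
        plt.close(ax.figure)

        provenance = {
            "package_version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "n_records": int(len(study.records)),
            "warnings": warning_counts,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        return {
            "cohort": cohort, "lesion_load": lesion_load, "roi": roi,
            "results": res, "study": study, "output_dir": out,
            "provenance": provenance,
        }
    except Exception as err:
        raise RuntimeError(f"study failed at stage {stage!r}: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()
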