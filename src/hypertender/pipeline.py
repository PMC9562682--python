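"""End-to-end orchestration: calibration -> artifact repair -> segmentation ->
ROI -> unfolding -> trimming -> pre-processing -> PLS-DA -> evaluation.

Two entry points cover the two ways the pipeline is used:

* :func:`assemble_cohort` runs the image-processing stages over an in-memory
  synthetic cohort and returns the stacked calibration / prediction pixel
  matrices (calibration samples contribute their central ROI, prediction
  samples their full lean mask);
* :func:`run_pipeline` is the config-driven disk variant used by the command
  line: it reads ENVI cubes and the reference WBSF table from a simulation
  directory, runs the same stages, and writes metrics tables, VIP scores,
  classification maps, the model archive and a log into a run directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import segment as seg
from .evaluate import (ModelReport, classification_map, compare_models,
                       split_calibration)
from .hypercube import (Hypercube, ReferencePair, calibrate_reflectance,
                        detect_dead_pixels, read_cube, remove_spikes,
                        repair_dead_pixels)
from .plsda import CVSpec, vip_scores, vip_select
from .preprocess import (FIRST_DER_MC, SMOOTH_2ND_DER_MC, SMOOTH_SNV_MC,
                         PreprocessSpec, run_chain)
from .segment import SpectraMatrix, segment_sample, select_roi_ring, stack_matrices

log = logging.getLogger("hypertender")

DEFAULT_CHAINS = (FIRST_DER_MC, SMOOTH_2ND_DER_MC, SMOOTH_SNV_MC)


@dataclass
class PipelineConfig:
    """Configuration of a full classification run."""

    data_dir: str = "."
    out_dir: str = "run"
    band_nm: float = seg.DEFAULT_SEGMENT_BAND_NM
    threshold_low: float = seg.DEFAULT_LOW_THRESHOLD
    threshold_high: float = seg.DEFAULT_HIGH_THRESHOLD
    roi_fraction: float = seg.DEFAULT_ROI_FRACTION
    trim_leading: int = seg.DEFAULT_TRIM_LEADING
    split_fraction: float = 0.70
    split_seed: int = 0
    cv_splits: int = 10
    max_lv: int = 20
    blocking_unit: str = "sample"
    vip_threshold: float = 1.0
    dead_pixel_k: float = 3.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def cv_spec(self) -> CVSpec:
        return CVSpec(n_splits=self.cv_splits, max_lv=self.max_lv,
                      blocking_unit=self.blocking_unit)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and sample names."""

    def __init__(self, stage: str, sample_id: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed on sample '{sample_id}': {cause}")
        self.stage = stage
        self.sample_id = sample_id


def process_sample(cube: Hypercube, refs: ReferencePair,
                   config: PipelineConfig = PipelineConfig(),
                   group: int | None = None):
    """Image-processing stages for one sample.

    Calibrates, repairs dead pixels and spikes, segments, and returns the
    trimmed full-lean matrix, the trimmed ROI matrix, and the mask set.
    """
    sid = cube.sample_id
    try:
        calibrated = calibrate_reflectance(cube, refs)
    except Exception as e:  # noqa: BLE001 - rewrap with stage context
        raise StageError("calibration", sid, e) from e
    try:
        dead = detect_dead_pixels(cube, refs, k=config.dead_pixel_k)
        repaired = repair_dead_pixels(calibrated, dead)
        repaired = remove_spikes(repaired)
    except Exception as e:
        raise StageError("artifact-repair", sid, e) from e
    try:
        masks = segment_sample(repaired, band_nm=config.band_nm,
                               low=config.threshold_low,
                               high=config.threshold_high)
        roi = select_roi_ring(masks.lean_mask, fraction=config.roi_fraction)
    except Exception as e:
        raise StageError("segmentation", sid, e) from e
    lean_matrix = seg.trim_bands(seg.unfold(repaired, masks.lean_mask, group=group),
                                 config.trim_leading)
    roi_matrix = seg.trim_bands(seg.unfold(repaired, roi, group=group),
                                config.trim_leading)
    return lean_matrix, roi_matrix, masks


@dataclass
class CohortDataset:
    """Stacked pixel matrices for one calibration/prediction split."""

    calibration: SpectraMatrix  # ROI pixels of calibration samples
    prediction: SpectraMatrix  # full lean pixels of prediction samples
    cal_ids: list[str]
    test_ids: list[str]
    shapes: dict[str, tuple[int, int]] = field(default_factory=dict)
    lean_matrices: dict[str, SpectraMatrix] = field(default_factory=dict)


def assemble_cohort(cohort, config: PipelineConfig = PipelineConfig(),
                    keep_lean_matrices: bool = False) -> CohortDataset:
    """Render + process every cohort sample and assemble the two pixel blocks."""
    groups = cohort.groups
    cal_ids, test_ids = split_calibration(groups, fraction=config.split_fraction,
                                          seed=config.split_seed)
    cal_parts, pred_parts = [], []
    shapes: dict[str, tuple[int, int]] = {}
    lean_matrices: dict[str, SpectraMatrix] = {}
    for sample in cohort.samples:
        cube, refs, _truth = cohort.render(sample)
        lean_m, roi_m, _ = process_sample(cube, refs, config, group=sample.group)
        shapes[sample.sample_id] = cube.shape[:2]
        if sample.sample_id in cal_ids:
            cal_parts.append(roi_m)
        else:
            pred_parts.append(lean_m)
            if keep_lean_matrices:
                lean_matrices[sample.sample_id] = lean_m
    return CohortDataset(calibration=stack_matrices(cal_parts),
                         prediction=stack_matrices(pred_parts),
                         cal_ids=cal_ids, test_ids=test_ids, shapes=shapes,
                         lean_matrices=lean_matrices)


# ---------------------------------------------------------------------------
# Disk-based run
# ---------------------------------------------------------------------------

def _read_reference_table(path: Path) -> dict[str, dict]:
    if not path.exists():
        raise FileNotFoundError(f"reference table not found: {path}")
    rows = {}
    lines = path.read_text().strip().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        rows[rec["sample_id"]] = {"wbsf_n": float(rec["wbsf_n"]),
                                  "group": int(rec["group"])}
    return rows


def _load_sample(data_dir: Path, sid: str):
    raw = read_cube(data_dir / f"{sid}_raw")
    for kind in ("white", "black"):
        if not (data_dir / f"{sid}_{kind}.hdr").exists():
            raise StageError("calibration", sid, FileNotFoundError(
                f"missing {kind} reference frame: {data_dir / f'{sid}_{kind}.hdr'}"))
    white = read_cube(data_dir / f"{sid}_white")
    black = read_cube(data_dir / f"{sid}_black")
    return raw, ReferencePair(white=white.values, black=black.values)


def _write_metrics_table(reports: list[ModelReport], path: Path) -> None:
    """Confusion blocks for every chain, in the printed-table layout."""
    lines = ["chain,set,estimated_group,real_group_1_pct,real_group_2_pct,"
             "mean_percent_cc,n_lv,explained_x_variance_pct"]
    for rep in reports:
        for set_name, summ in (("CV", rep.cv_summary),
                               ("Pred", rep.prediction_summary)):
            cp = summ.column_percent
            for i, est in enumerate((1, 2)):
                lines.append(
                    f"{rep.label},{set_name},{est},{cp[i, 0]:.2f},{cp[i, 1]:.2f},"
                    f"{summ.mean_percent_cc:.2f},{rep.n_lv},"
                    f"{rep.explained_x_variance:.2f}")
    path.write_text("\n".join(lines) + "\n")


def _write_sensitivity_table(reports: list[ModelReport], path: Path) -> None:
    lines = ["chain,set,group,sensitivity,specificity"]
    for rep in reports:
        for set_name, summ in (("CV", rep.cv_summary),
                               ("Pred", rep.prediction_summary)):
            for g in (1, 2):
                lines.append(f"{rep.label},{set_name},{g},"
                             f"{summ.sensitivity[g]:.3f},{summ.specificity[g]:.3f}")
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig,
                 chains: tuple[PreprocessSpec, ...] = DEFAULT_CHAINS) -> Path:
    """Run the full disk-based pipeline and return the run directory."""
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        table = _read_reference_table(data_dir / "reference_table.tsv")
        groups = {sid: rec["group"] for sid, rec in table.items()}
        cal_ids, test_ids = split_calibration(groups, config.split_fraction,
                                              config.split_seed)
        log.info("split: %d calibration, %d prediction samples",
                 len(cal_ids), len(test_ids))
        cal_parts, pred_parts = [], []
        shapes, lean_matrices = {}, {}
        for sid in sorted(table):
            raw, refs = _load_sample(data_dir, sid)
            lean_m, roi_m, _ = process_sample(raw, refs, config,
                                              group=groups[sid])
            shapes[sid] = raw.shape[:2]
            if sid in cal_ids:
                cal_parts.append(roi_m)
            else:
                pred_parts.append(lean_m)
                lean_matrices[sid] = lean_m
            log.info("processed %s: %d lean px, %d roi px", sid,
                     lean_m.n_pixels, roi_m.n_pixels)
        X_cal = stack_matrices(cal_parts)
        X_pred = stack_matrices(pred_parts)
        reports = compare_models(list(chains), X_cal.X, X_cal.group_labels,
                                 X_cal.sample_ids, X_pred.X,
                                 X_pred.group_labels, cv=config.cv_spec,
                                 wavelengths=X_cal.wavelengths)
        _write_metrics_table(reports, out_dir / "metrics.csv")
        _write_sensitivity_table(reports, out_dir / "sensitivity.csv")

        best = reports[0]
        vip = vip_scores(best.model)
        selected = vip_select(vip, X_cal.wavelengths, config.vip_threshold)
        vip_lines = ["wavelength_nm,vip"] + [
            f"{w:.2f},{v:.4f}" for w, v in zip(X_cal.wavelengths, vip)]
        (out_dir / "vip.csv").write_text("\n".join(vip_lines) + "\n")
        log.info("best chain %s: %d LVs, %d VIP-selected wavelengths",
                 best.label, best.n_lv, len(selected))

        maps_dir = out_dir / "maps"
        maps_dir.mkdir(exist_ok=True)
        for sid, lean_m in lean_matrices.items():
            _, Xp = run_chain(best.chain, X_cal.X, lean_m.X)
            proc = SpectraMatrix(X=Xp, wavelengths=lean_m.wavelengths,
                                 sample_ids=lean_m.sample_ids,
                                 pixel_rows=lean_m.pixel_rows,
                                 pixel_cols=lean_m.pixel_cols,
                                 group_labels=lean_m.group_labels)
            cmap = classification_map(best.model, proc, shapes[sid],
                                      true_group=groups[sid])
            np.savetxt(maps_dir / f"{sid}_categories.txt",
                       cmap.categories, fmt="%d")
            try:
                import matplotlib
                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(3, 3))
                ax.imshow(cmap.to_rgb())
                ax.set_title(f"{sid} (group {groups[sid]})")
                ax.axis("off")
                fig.savefig(maps_dir / f"{sid}_map.png", dpi=120,
                            bbox_inches="tight")
                plt.close(fig)
            except Exception as e:  # pragma: no cover - plotting is best-effort
                log.warning("map figure for %s skipped: %s", sid, e)

        np.savez(out_dir / "model.npz", W=best.model.W, P=best.model.P,
                 Q=best.model.Q, B=best.model.B, x_mean=best.model.x_mean,
                 y_mean=best.model.y_mean,
                 wavelengths=X_cal.wavelengths, n_lv=best.n_lv)
        (out_dir / "config.json").write_text(
            json.dumps(asdict(config), indent=2) + "\n")
        log.info("run complete: best %s mean CV %%CC %.2f",
                 best.label, best.cv_summary.mean_percent_cc)
        return out_dir
    finally:
        log.removeHandler(handler)
        handler.close()
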