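#!/usr/bin/env python
"""VIP wavelength ranking and pixel classification maps.

Fits the 1st der + MC model on the default cohort's calibration ROI pixels,
ranks wavelengths by variable importance in projection, and renders
TP/FN/TN/FP classification maps for the prediction-set samples.  Writes
results/vip_scores.csv, results/vip_selected_wavelengths.csv and map figures
under results/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from hypertender import (SceneSpec, assemble_cohort, classification_map,
                         cross_validate, fit, make_cohort, select_n_lv,
                         vip_scores, vip_select)
from hypertender.pipeline import PipelineConfig
from hypertender.preprocess import FIRST_DER_MC, run_chain
from hypertender.segment import SpectraMatrix

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIGURES = RESULTS / "figures"


def main() -> None:
    cohort = make_cohort(SceneSpec(seed=1))
    ds = assemble_cohort(cohort, PipelineConfig(), keep_lean_matrices=True)
    summaries = cross_validate(ds.calibration.X, ds.calibration.group_labels,
                               ds.calibration.sample_ids,
                               preprocess=FIRST_DER_MC)
    n_lv = select_n_lv(summaries)
    Xc, _ = run_chain(FIRST_DER_MC, ds.calibration.X)
    model = fit(Xc, ds.calibration.group_labels, max(n_lv, 3),
                wavelengths=ds.calibration.wavelengths)

    vip = vip_scores(model)
    wl = ds.calibration.wavelengths
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame({"wavelength_nm": wl.round(2), "vip": vip.round(4)}).to_csv(
        RESULTS / "vip_scores.csv", index=False)
    selected = vip_select(vip, wl)
    pd.DataFrame({"wavelength_nm": selected.round(2)}).to_csv(
        RESULTS / "vip_selected_wavelengths.csv", index=False)
    print(f"{len(selected)} wavelengths above the VIP threshold 1.0, "
          f"spanning {selected.min():.1f}-{selected.max():.1f} nm "
          f"(injected class window: 1000-1100 nm)")

    FIGURES.mkdir(exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(wl, vip, lw=1)
    ax.axhline(1.0, color="r", ls="--", lw=0.8)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("VIP score")
    fig.savefig(FIGURES / "vip_scores.png", dpi=150, bbox_inches="tight")
    plt.close(fig)

    groups = cohort.groups
    frac_rows = []
    show = [sid for sid in ds.test_ids if groups[sid] == 1][:2] + \
           [sid for sid in ds.test_ids if groups[sid] == 2][:2]
    for sid in show:
        lean_m = ds.lean_matrices[sid]
        _, Xp = run_chain(FIRST_DER_MC, ds.calibration.X, lean_m.X)
        proc = SpectraMatrix(X=Xp, wavelengths=lean_m.wavelengths,
                             sample_ids=lean_m.sample_ids,
                             pixel_rows=lean_m.pixel_rows,
                             pixel_cols=lean_m.pixel_cols)
        cmap = classification_map(model, proc, ds.shapes[sid], groups[sid])
        frac = cmap.fractions()
        frac_rows.append({"sample_id": sid, "true_group": groups[sid]} |
                         {k: round(v, 4) for k, v in frac.items()})
        fig, ax = plt.subplots(figsize=(3, 3))
        ax.imshow(cmap.to_rgb())
        ax.set_title(f"{sid} (group {groups[sid]})", fontsize=9)
        ax.axis("off")
        fig.savefig(FIGURES / f"map_{sid}.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
    df = pd.DataFrame(frac_rows)
    df.to_csv(RESULTS / "map_fractions.csv", index=False)
    print("\nPer-sample map category fractions (prediction set):")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
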