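"""Predict the test animals and measure segmentation agreement.

The selected network labels every ED/ES frame of the three test animals; its
masks are exported as CON-TXT contour files (the text dialect standing in
for clinical contour containers). Agreement is quantified per image (Dice
for cavity and myocardium, Hausdorff distance between boundaries) for three
comparisons: observer one vs repeat, vs observer two, and vs the model.
Predictions are also tallied as correct / incorrect / missing.
"""

import json

import pandas as pd

from cinefunc import contours as ct
from cinefunc import metrics as met
from cinefunc.pipeline import compare_labelings, stage_predict
from common import RESULTS, SCRATCH, STUDY, cohort, trained_model


def main():
    scans, split, labelings = cohort()
    net, _ = trained_model(scans, split, labelings)
    labelings["model"] = stage_predict(STUDY, scans, split, net)

    contour_dir = RESULTS / "contours"
    contour_dir.mkdir(parents=True, exist_ok=True)
    for scan_id, masks in labelings["model"].items():
        cf = ct.masks_to_contour_file(
            masks, scan_id, (STUDY.pixel_spacing_mm,) * 2, STUDY.slice_thickness_mm)
        ct.write_contour_file(cf, contour_dir / f"{scan_id}.contxt")

    phases = {s.scan_id: (s.gt.ed_phase, s.gt.es_phase) for s in scans}
    rows = []
    for ref, other in (("observer1", "repeat"), ("observer1", "observer2"),
                       ("observer1", "model")):
        df, agg = compare_labelings(labelings[ref], labelings[other], STUDY,
                                    phases_by_scan=phases)
        df.insert(0, "comparison", f"{ref}_vs_{other}")
        rows.append(df)
        print(f"{ref} vs {other}: mean Dice LV {agg.mean_dice_lv:.3f}, "
              f"MY {agg.mean_dice_my:.3f}; median HD LV {agg.median_hd_lv:.2f}, "
              f"MY {agg.median_hd_my:.2f} px ({agg.n_pairs} image pairs)")
    pd.concat(rows, ignore_index=True).to_csv(
        RESULTS / "agreement_per_image.csv", index=False)

    classes = []
    for s in scans:
        if s.scan_id not in labelings["model"]:
            continue
        for k in range(s.gt.masks.shape[0]):
            for p in (s.gt.ed_phase, s.gt.es_phase):
                classes.append(met.classify_prediction(
                    labelings["model"][s.scan_id][k, p],
                    labelings["observer1"][s.scan_id][k, p], STUDY.tau))
    tally = met.status_tally(classes)
    tally["tau"] = STUDY.tau
    (RESULTS / "prediction_tally.json").write_text(json.dumps(tally, indent=2))
    print(f"test-set frames: {tally['correct_percent']:.1f}% correct, "
          f"{tally['incorrect_percent']:.1f}% incorrect, "
          f"{tally['missing_percent']:.1f}% missing "
          f"(tau = {STUDY.tau}, n = {tally['n']})")


if __name__ == "__main__":
    main()
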