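"""Split the cohort animal-wise and transfer-train the segmentation network.

The eleven animals go 6/2/3 into train/validation/test with group
stratification. A small encoder-decoder pretrained on clean phantoms is then
fine-tuned on the training animals' ED/ES labels with the two-step schedule:
a frozen phase that trains only the classification head, then an unfrozen
phase over all parameters, checkpointing throughout and selecting the
checkpoint with the highest validation Dice.
"""

import pandas as pd

from common import MODEL_CACHE, RESULTS, STUDY, cohort, trained_model


def main():
    scans, split, labelings = cohort()
    print("animal-wise split:")
    for name in ("train", "validation", "test"):
        print(f"  {name}: {sorted(getattr(split, name))}")

    if MODEL_CACHE.exists():
        MODEL_CACHE.unlink()  # always retrain in this script
    net, records = trained_model(scans, split, labelings)
    df = pd.DataFrame([{"phase": r.phase, "epoch": r.epoch,
                        "validation_dice": round(r.validation_dice, 4)}
                       for r in records])
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "training_checkpoints.csv", index=False)
    best = df.loc[df.validation_dice.idxmax()]
    print(df.to_string(index=False))
    print(f"selected checkpoint: {best.phase} epoch {best.epoch} "
          f"(validation Dice {best.validation_dice:.3f}); weights cached at {MODEL_CACHE}")


if __name__ == "__main__":
    main()
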