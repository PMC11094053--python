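"""End-to-end study orchestration on synthetic cine stacks.

``run_study`` realizes the whole design on phantoms: generate one short-axis
cine scan per animal (infarcted animals get sector wall thinning and reduced
contraction), rate and degrade image quality, split the cohort animal-wise,
synthesize observer readings (a repeat reading and a second observer via
boundary jitter of the ground truth), pretrain a small segmentation network
on a clean phantom distribution, transfer-train it on the study's training
animals with the frozen/unfrozen schedule, predict the test animals, and
compare all labelings: per-image Dice/Hausdorff agreement, scan-level
cardiac function, and reproducibility statistics (bias, limits of agreement,
ICC, CoV, Pearson r, paired t-tests with Bonferroni threshold).

By default only end-diastolic and end-systolic frames are labeled and
evaluated; ED/ES phases are pinned to the ground-truth phases for every
labeling so all readers use identical phases.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as met
from . import model as mdl
from . import phantom as ph
from . import stats as st
from . import volumetry as vol

logger = logging.getLogger(__name__)

PARAMETERS = ("EF", "SV", "LV mass", "EDV", "ESV")
_PARAM_COLS = {"EF": "ef_percent", "SV": "sv_ml", "LV mass": "lv_mass_g",
               "EDV": "edv_ml", "ESV": "esv_ml"}


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one study run."""

    n_infarct: int = 7
    n_sham: int = 4
    split_counts: tuple[int, int, int] = (6, 2, 3)
    n_slices: int = 6
    n_phases: int = 30
    image_size: int = 64
    pixel_spacing_mm: float = 0.4
    slice_thickness_mm: float = 6.0
    empty_slice_margin: int = 1
    repeat_jitter_px: float = 0.5
    observer2_jitter_px: float = 1.0
    model_channels: int = 8
    # shift-only normalization: per-frame contrast stretching would blow blank
    # basal/apical frames' noise up to full scale and the model would
    # hallucinate tissue there
    normalization: str = "center"
    pretrain_epochs: int = 8
    schedule: mdl.TrainSchedule = field(
        default_factory=lambda: mdl.TrainSchedule(
            frozen_epochs=10, frozen_max_lr=1e-2,
            unfrozen_epochs=30, unfrozen_max_lr=1e-2,
            checkpoint_every=10, batch_size=8))
    augment: mdl.AugmentPolicy | None = None
    hd_units: str = "px"  # "px" | "mm"
    tau: float = 0.5
    icc_form: str = "A,1"
    overall_alpha: float = 0.05
    n_hypotheses: int = 4
    seed: int = 0
    out_dir: str = "results/study"

    def __post_init__(self) -> None:
        n = self.n_infarct + self.n_sham
        if sum(self.split_counts) != n:
            raise ValueError("split counts must sum to the number of animals")
        if min(self.split_counts) < 1:
            raise ValueError("train, validation and test sets must each hold >= 1 animal")
        if self.hd_units not in ("px", "mm"):
            raise ValueError("hd_units must be 'px' or 'mm'")
        if not (0 <= self.tau <= 1):
            raise ValueError("tau must lie in [0, 1]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


@dataclass
class StudyReport:
    function_table: pd.DataFrame
    agreement_table: pd.DataFrame
    stats_table: pd.DataFrame
    prediction_tally: dict
    out_dir: Path


@dataclass
class Scan:
    scan_id: str
    animal: str
    group: str
    stack: ph.CineStack
    gt: ph.GroundTruth
    quality: ph.QualityScore


def _child_seed(root: int, *salt: int) -> int:
    return int(np.random.SeedSequence([root, *salt]).generate_state(1)[0] % (2**31))


def stage_generate(cfg: RunConfig) -> list[Scan]:
    """One degraded cine scan per animal, infarct morphology in the infarct group."""
    scans: list[Scan] = []
    animals = [(f"I{i+1:02d}", "infarct") for i in range(cfg.n_infarct)] + \
              [(f"S{i+1:02d}", "sham") for i in range(cfg.n_sham)]
    for idx, (animal, group) in enumerate(animals):
        rng = np.random.default_rng(_child_seed(cfg.seed, 1, idx))
        base_r = rng.uniform(0.14, 0.19) * cfg.image_size
        labeled = cfg.n_slices - 2 * cfg.empty_slice_margin
        # mild apical taper of the cavity radius
        radii = base_r * np.linspace(1.0, 0.75, labeled)
        wall = rng.uniform(0.055, 0.075) * cfg.image_size
        if group == "infarct":
            contraction = rng.uniform(0.18, 0.26)
            sector0 = rng.uniform(0, 360)
            infarct = ph.InfarctSpec(
                sector_start_deg=sector0,
                sector_end_deg=sector0 + rng.uniform(70, 110),
                thinning_fraction=rng.uniform(0.3, 0.5),
                affected_slices=tuple(range(cfg.empty_slice_margin + 1,
                                            cfg.n_slices - cfg.empty_slice_margin)),
            )
        else:
            contraction = rng.uniform(0.30, 0.38)
            infarct = None
        pcfg = ph.PhantomConfig(
            n_slices=cfg.n_slices, n_phases=cfg.n_phases,
            image_size=cfg.image_size,
            pixel_spacing_mm=cfg.pixel_spacing_mm,
            slice_thickness_mm=cfg.slice_thickness_mm,
            endo_radius_px=radii, wall_thickness_px=wall,
            contraction_fraction=contraction, infarct=infarct,
            empty_slice_margin=cfg.empty_slice_margin,
            seed=_child_seed(cfg.seed, 2, idx))
        stack, gt = ph.generate_phantom_stack(pcfg)
        q = ph.QualityScore(
            artefacts=int(rng.choice([2, 3], p=[0.4, 0.6])),
            noise=int(rng.choice([1, 2, 3], p=[0.3, 0.5, 0.2])),
            general=int(rng.choice([1, 2, 3], p=[0.25, 0.5, 0.25])))
        stack = ph.inject_degradation(stack, q, seed=_child_seed(cfg.seed, 3, idx))
        scans.append(Scan(f"{animal}_MRI1", animal, group, stack, gt, q))
    return scans


def stage_split(cfg: RunConfig, scans: list[Scan]) -> ph.DatasetSplit:
    animals = sorted({(s.animal, s.group) for s in scans})
    return ph.split_animals(animals, cfg.split_counts,
                            seed=_child_seed(cfg.seed, 4))


def _edes_masks(scan: Scan) -> np.ndarray:
    """Ground-truth masks restricted to the ED and ES phases (zeros elsewhere)."""
    out = np.zeros_like(scan.gt.masks)
    for p in (scan.gt.ed_phase, scan.gt.es_phase):
        out[:, p] = scan.gt.masks[:, p]
    return out


def stage_observers(cfg: RunConfig, scans: list[Scan]) -> dict[str, dict[str, np.ndarray]]:
    """Observer-one, repeat, and observer-two labelings of the ED/ES frames.

    Observer one is the ground truth; the repeat reading and the second
    observer jitter the region boundaries with increasing magnitude
    (intra-observer variability is smaller than inter-observer variability).
    """
    labelings: dict[str, dict[str, np.ndarray]] = {
        "observer1": {}, "repeat": {}, "observer2": {}}
    for i, scan in enumerate(scans):
        ref = _edes_masks(scan)
        labelings["observer1"][scan.scan_id] = ref
        labelings["repeat"][scan.scan_id] = ph.perturb_masks(
            ref, cfg.repeat_jitter_px, seed=_child_seed(cfg.seed, 5, i))
        labelings["observer2"][scan.scan_id] = ph.perturb_masks(
            ref, cfg.observer2_jitter_px, seed=_child_seed(cfg.seed, 6, i))
    return labelings


def _frames(scan: Scan, masks: np.ndarray,
            normalization: str = "none") -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for s in range(masks.shape[0]):
        for p in (scan.gt.ed_phase, scan.gt.es_phase):
            img = mdl.preprocess(scan.stack.data[s, p], input_size=masks.shape[-1],
                                 normalization=normalization)
            out.append((img, masks[s, p]))
    return out


def stage_pretrain(cfg: RunConfig) -> mdl.SegNet:
    """Pretrain on a clean phantom distribution (the transfer-learning source)."""
    net = mdl.SegNet(channels=cfg.model_channels, input_size=cfg.image_size,
                     seed=_child_seed(cfg.seed, 7), normalization=cfg.normalization)
    pre_sched = mdl.TrainSchedule(frozen_epochs=cfg.pretrain_epochs,
                                  frozen_max_lr=1e-2,
                                  unfrozen_epochs=cfg.pretrain_epochs,
                                  unfrozen_max_lr=1e-2,
                                  checkpoint_every=cfg.pretrain_epochs,
                                  batch_size=cfg.schedule.batch_size)
    frames: list[tuple[np.ndarray, np.ndarray]] = []
    for j in range(4):
        pcfg = ph.PhantomConfig(
            n_slices=4, n_phases=6, image_size=cfg.image_size,
            endo_radius_px=np.random.default_rng(
                _child_seed(cfg.seed, 8, j)).uniform(0.12, 0.20) * cfg.image_size,
            wall_thickness_px=0.06 * cfg.image_size,
            contraction_fraction=0.3, empty_slice_margin=1,
            seed=_child_seed(cfg.seed, 9, j))
        stack, gt = ph.generate_phantom_stack(pcfg)
        for s in range(pcfg.n_slices):
            for p in (gt.ed_phase, gt.es_phase):
                frames.append((mdl.preprocess(stack.data[s, p],
                                              input_size=cfg.image_size,
                                              normalization=cfg.normalization),
                               gt.masks[s, p]))
    net, _ = mdl.train_transfer(net, frames[:-4], frames[-4:], pre_sched,
                                seed=_child_seed(cfg.seed, 10))
    return net


def stage_train(cfg: RunConfig, scans: list[Scan], split: ph.DatasetSplit,
                labelings: dict[str, dict[str, np.ndarray]],
                run_dir: Path | None = None
                ) -> tuple[mdl.SegNet, list[mdl.CheckpointRecord]]:
    """Transfer-train on the training animals' observer-one ED/ES labels."""
    net = stage_pretrain(cfg)
    train_frames, val_frames = [], []
    for scan in scans:
        frames = _frames(scan, labelings["observer1"][scan.scan_id],
                         cfg.normalization)
        subset = split.subset_of(scan.animal)
        if subset == "train":
            train_frames.extend(frames)
        elif subset == "validation":
            val_frames.extend(frames)
    return mdl.train_transfer(net, train_frames, val_frames, cfg.schedule,
                              augment_policy=cfg.augment,
                              seed=_child_seed(cfg.seed, 11), run_dir=run_dir)


def stage_predict(cfg: RunConfig, scans: list[Scan], split: ph.DatasetSplit,
                  net: mdl.SegNet) -> dict[str, np.ndarray]:
    """Model labelings of the test animals' ED/ES frames."""
    out: dict[str, np.ndarray] = {}
    for scan in scans:
        if split.subset_of(scan.animal) != "test":
            continue
        masks = np.zeros_like(scan.gt.masks)
        for s in range(masks.shape[0]):
            for p in (scan.gt.ed_phase, scan.gt.es_phase):
                masks[s, p] = mdl.predict(net, scan.stack.data[s, p])
        out[scan.scan_id] = masks
    return out


def stage_function(cfg: RunConfig, scans: list[Scan],
                   labelings: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    """Cardiac function per scan and labeling, ED/ES pinned to the ground truth."""
    vcfg = vol.VolumetryConfig((cfg.pixel_spacing_mm, cfg.pixel_spacing_mm),
                               cfg.slice_thickness_mm)
    rows = []
    for scan in scans:
        for name, masks_by_scan in labelings.items():
            if scan.scan_id not in masks_by_scan:
                continue
            f = vol.compute_function(masks_by_scan[scan.scan_id], vcfg,
                                     ed_phase=scan.gt.ed_phase,
                                     es_phase=scan.gt.es_phase)
            rows.append({"scan": scan.scan_id, "animal": scan.animal,
                         "group": scan.group, "labeling": name,
                         "EF": f.ef_percent, "SV": f.sv_ml,
                         "LV mass": f.lv_mass_g, "EDV": f.edv_ml,
                         "ESV": f.esv_ml,
                         "missing_label_slices": f.missing_label_slices,
                         "analytic_EF": scan.gt.analytic_ef_percent,
                         "analytic_EDV": scan.gt.analytic_edv_ml})
    return pd.DataFrame(rows)


def compare_labelings(ref_masks: dict[str, np.ndarray],
                      other_masks: dict[str, np.ndarray],
                      cfg: RunConfig | None = None,
                      phases_by_scan: dict[str, tuple[int, int]] | None = None
                      ) -> tuple[pd.DataFrame, met.AggregateAgreement]:
    """Per-image agreement of two labelings plus the aggregate.

    Compares every frame (optionally restricted to given phases per scan)
    where at least one labeling marks tissue; both-absent frames are
    excluded. HD is reported in pixels, or millimeters when the config asks
    for it.
    """
    common = sorted(set(ref_masks) & set(other_masks))
    if not common:
        raise ValueError("no common scan keys between the two labelings")
    hd_scale = 1.0
    if cfg is not None and cfg.hd_units == "mm":
        hd_scale = cfg.pixel_spacing_mm
    rows = []
    pairs = []
    for scan_id in common:
        ref = ref_masks[scan_id]
        other = other_masks[scan_id]
        if ref.shape != other.shape:
            raise ValueError(f"mask shapes differ for scan {scan_id}")
        phases = range(ref.shape[1]) if phases_by_scan is None \
            else phases_by_scan[scan_id]
        for s in range(ref.shape[0]):
            for p in phases:
                if not ref[s, p].any() and not other[s, p].any():
                    continue
                pa = met.pairwise_agreement(other[s, p], ref[s, p])
                if pa.hd_lv is not None:
                    pa.hd_lv *= hd_scale
                if pa.hd_my is not None:
                    pa.hd_my *= hd_scale
                pairs.append(pa)
                rows.append({"scan": scan_id, "slice": s, "phase": p,
                             "status": pa.status.value,
                             "dice_lv": pa.dice_lv, "dice_my": pa.dice_my,
                             "hd_lv": pa.hd_lv, "hd_my": pa.hd_my})
    return pd.DataFrame(rows), met.aggregate(pairs)


def stage_agreement(cfg: RunConfig, scans: list[Scan],
                    labelings: dict[str, dict[str, np.ndarray]]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dice/HD agreement for every comparison: per-image rows and aggregates."""
    phases = {s.scan_id: (s.gt.ed_phase, s.gt.es_phase) for s in scans}
    comparisons = [("observer1", "repeat"), ("observer1", "observer2")]
    if "model" in labelings:
        comparisons.append(("observer1", "model"))
    img_rows, agg_rows = [], []
    for ref_name, other_name in comparisons:
        df, agg = compare_labelings(labelings[ref_name], labelings[other_name],
                                    cfg, phases_by_scan=phases)
        df.insert(0, "comparison", f"{ref_name}_vs_{other_name}")
        img_rows.append(df)
        agg_rows.append({"comparison": f"{ref_name}_vs_{other_name}",
                         "mean_dice_lv": agg.mean_dice_lv,
                         "mean_dice_my": agg.mean_dice_my,
                         "median_hd_lv": agg.median_hd_lv,
                         "median_hd_my": agg.median_hd_my,
                         "n_pairs": agg.n_pairs})
    return pd.concat(img_rows, ignore_index=True), pd.DataFrame(agg_rows)


def stage_stats(cfg: RunConfig, function_df: pd.DataFrame) -> pd.DataFrame:
    """Reproducibility statistics per comparison and cardiac parameter."""
    rows = []
    comparisons = [("observer1", "repeat"), ("observer1", "observer2")]
    if "model" in set(function_df["labeling"]):
        comparisons.append(("observer1", "model"))
    for ref_name, other_name in comparisons:
        a_df = function_df[function_df.labeling == ref_name].set_index("scan")
        b_df = function_df[function_df.labeling == other_name].set_index("scan")
        common = sorted(set(a_df.index) & set(b_df.index))
        for param in PARAMETERS:
            series = st.PairedSeries(param,
                                     a_df.loc[common, param].to_numpy(),
                                     b_df.loc[common, param].to_numpy())
            res = st.agreement_stats(series, cfg.overall_alpha,
                                     cfg.n_hypotheses, cfg.icc_form)
            rows.append({"comparison": f"{ref_name}_vs_{other_name}",
                         "parameter": param, "n": res.n, "bias": res.bias,
                         "loa_low": res.loa_low, "loa_high": res.loa_high,
                         "icc": res.icc, "icc_band": res.icc_band,
                         "cov_percent": res.cov_percent,
                         "pearson_r": res.pearson_r,
                         "t_p_value": res.t_p_value,
                         "threshold": st.bonferroni_threshold(
                             cfg.overall_alpha, cfg.n_hypotheses)})
    return pd.DataFrame(rows)


def _function_summary(function_df: pd.DataFrame) -> pd.DataFrame:
    obs1 = function_df[function_df.labeling == "observer1"]
    return obs1.groupby("group")[list(PARAMETERS)].agg(["mean", "std"])


def run_study(cfg: RunConfig) -> StudyReport:
    """Execute all stages in order, persisting every table under ``cfg.out_dir``.

    Identical config and seed give an identical report; any stage failure
    aborts with a stage-tagged error while earlier outputs stay on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(cfg.to_json())

    stage = "generate"
    try:
        scans = stage_generate(cfg)
        quality = pd.DataFrame(
            [{"scan": s.scan_id, "group": s.group,
              "artefacts": s.quality.artefacts, "noise": s.quality.noise,
              "general": s.quality.general,
              "total": ph.total_quality_score(s.quality)} for s in scans])
        quality.to_csv(out / "image_quality.csv", index=False)

        stage = "split"
        split = stage_split(cfg, scans)
        (out / "split.json").write_text(json.dumps(
            {k: sorted(getattr(split, k)) for k in ("train", "validation", "test")},
            indent=2))

        stage = "observers"
        labelings = stage_observers(cfg, scans)

        stage = "train"
        net, records = stage_train(cfg, scans, split, labelings)
        pd.DataFrame([{"phase": r.phase, "epoch": r.epoch,
                       "validation_dice": r.validation_dice}
                      for r in records]).to_csv(out / "checkpoints.csv", index=False)

        stage = "predict"
        labelings["model"] = stage_predict(cfg, scans, split, net)
        tally_classes = []
        for scan in scans:
            if scan.scan_id not in labelings["model"]:
                continue
            ref = labelings["observer1"][scan.scan_id]
            pred = labelings["model"][scan.scan_id]
            for s in range(ref.shape[0]):
                for p in (scan.gt.ed_phase, scan.gt.es_phase):
                    tally_classes.append(
                        met.classify_prediction(pred[s, p], ref[s, p], cfg.tau))
        tally = met.status_tally(tally_classes)
        tally["tau"] = cfg.tau
        (out / "prediction_tally.json").write_text(json.dumps(tally, indent=2))

        stage = "function"
        function_df = stage_function(cfg, scans, labelings)
        function_df.to_csv(out / "cardiac_function.csv", index=False)
        _function_summary(function_df).to_csv(out / "function_by_group.csv")

        stage = "agreement"
        per_image, agg = stage_agreement(cfg, scans, labelings)
        per_image.to_csv(out / "agreement_per_image.csv", index=False)
        agg.to_csv(out / "agreement_aggregate.csv", index=False)

        stage = "stats"
        stats_df = stage_stats(cfg, function_df)
        stats_df.to_csv(out / "agreement_stats.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"study stage {stage!r} failed: {exc}") from exc

    logger.info("study complete: %d scans, %d evaluated predictions",
                len(scans), tally["n"])
    return StudyReport(function_df, agg, stats_df, tally, out)
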