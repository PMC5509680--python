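"""End-to-end experiment driver composing every pipeline stage.

Sequence per run: phantom cohort -> per-sequence standardization ->
(optional registration) -> region decomposition and stratified patch
sampling on discovery subjects -> 80/20 patch split -> CNN training with
early stopping -> per-voxel probability maps on validation subjects ->
threshold + largest-component segmentation -> DSC/AUC metrics (and,
optionally, an ICC stability report over repeated runs).
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .evaluate import MetricsReport, StabilityReport, icc_agreement, dsc, metrics_report, voxel_auc
from .infer import predict_volume, threshold_and_select
from .model import ConvNet, NetworkSpec, TrainConfig, build_network, split_discovery, train
from .phantom import Distractor, PhantomConfig, generate_cohort, generate_phantom
from .preprocess import RegistrationConfig, register_volume, standardize_volume
from .sampling import PatchSet, decompose, sample_patches
from .volume import LabelMap, MpVolume

log = logging.getLogger("patchseg")


@dataclass(frozen=True)
class SamplingConfig:
    N: int = 500  # patches per class per subject
    M: int = 21
    radius_mm: float = 10.0
    threshold: float = 2.0


@dataclass(frozen=True)
class InferConfig:
    threshold: float = 0.5
    connectivity: int = 26
    batch: int = 256


@dataclass(frozen=True)
class ExperimentConfig:
    n_subjects: int = 30
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    registration: RegistrationConfig | None = None  # None = channels generated aligned
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    infer: InferConfig = field(default_factory=InferConfig)
    split_rule: str = "parity"  # parity | random | sequential
    n_discovery: int | None = None  # used by the sequential rule
    seed: int = 7

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        if "phantom" in raw and isinstance(raw["phantom"], dict):
            ph = dict(raw["phantom"])
            for key in ("grid_shape", "spacing", "tumour_offsets"):
                if key in ph and ph[key] is not None:
                    ph[key] = tuple(ph[key])
            if ph.get("tumour_centre") is not None:
                ph["tumour_centre"] = tuple(ph["tumour_centre"])
            if "distractors" in ph:
                ph["distractors"] = tuple(
                    Distractor(
                        centre=tuple(d["centre"]),
                        radius=d["radius"],
                        offsets=tuple(d["offsets"]),
                    )
                    for d in ph["distractors"]
                )
            raw["phantom"] = PhantomConfig(**ph)
        if raw.get("registration"):
            raw["registration"] = RegistrationConfig(**raw["registration"])
        if "sampling" in raw and isinstance(raw["sampling"], dict):
            raw["sampling"] = SamplingConfig(**raw["sampling"])
        if "network" in raw and isinstance(raw["network"], dict):
            net = dict(raw["network"])
            for key in ("conv_filters", "conv_kernels"):
                if key in net:
                    net[key] = tuple(net[key])
            raw["network"] = NetworkSpec(**net)
        if "train" in raw and isinstance(raw["train"], dict):
            raw["train"] = TrainConfig(**raw["train"])
        if "infer" in raw and isinstance(raw["infer"], dict):
            raw["infer"] = InferConfig(**raw["infer"])
        return cls(**raw)


def desk_scale_config(seed: int = 7) -> ExperimentConfig:
    """Scaled-down single-CPU experiment configuration.

    20 discovery + 10 validation phantom subjects at 64x64x16 voxels with
    2x2x5 mm spacing, 500 patches per class per subject, at most 30 epochs.
    The classifier keeps the 9-layer doubling architecture at reduced width
    (4, 8, 16, 32 filters) with 7x7 patches so the run fits a desk budget;
    the full-width 21x21 network remains the package default.
    """
    base = PhantomConfig(
        grid_shape=(64, 64, 16),
        spacing=(2.0, 2.0, 5.0),
        tumour_radius=10.0,
        distractors=(
            Distractor(centre=(30.0, 30.0, 40.0), radius=7.0, offsets=(-0.8, 0.5, 3.0)),
        ),
    )
    return ExperimentConfig(
        n_subjects=30,
        phantom=base,
        sampling=SamplingConfig(N=500, M=7),
        network=NetworkSpec(conv_filters=(4, 8, 16, 32), fc_width=32),
        train=TrainConfig(lr=1.0, batch_size=128, max_epochs=12, seed=seed),
        infer=InferConfig(batch=2048),
        split_rule="sequential",
        n_discovery=20,
        seed=seed,
    )


def failure_mode_phantom(base: PhantomConfig, seed: int = 99):
    """Phantom reproducing the documented failure mode: a distractor with the
    tumour's intensity signature but larger than the tumour, so that largest-
    component selection picks the wrong structure."""
    cfg = replace(
        base,
        tumour_radius=8.0,
        distractors=(
            Distractor(
                centre=(30.0, 30.0, 40.0), radius=14.0, offsets=base.tumour_offsets
            ),
        ),
        seed=seed,
    )
    vol, label = generate_phantom(cfg)
    vol.subject_id = "failure-mode"
    return vol, label


def split_cohort(cohort, rule: str = "parity", n_discovery: int | None = None,
                 seed: int = 0):
    """Subject-level split into (discovery, validation) lists.

    ``parity`` mirrors the identifier rule: subjects whose numeric id is
    even go to discovery, odd to validation.
    """
    if rule == "parity":
        discovery = [s for s in cohort if _numeric_id(s[0].subject_id) % 2 == 0]
        validation = [s for s in cohort if _numeric_id(s[0].subject_id) % 2 == 1]
    elif rule == "sequential":
        if n_discovery is None:
            raise ValueError("sequential split requires n_discovery")
        discovery, validation = list(cohort[:n_discovery]), list(cohort[n_discovery:])
    elif rule == "random":
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(cohort))
        n_disc = n_discovery if n_discovery is not None else len(cohort) // 2
        discovery = [cohort[i] for i in sorted(idx[:n_disc])]
        validation = [cohort[i] for i in sorted(idx[n_disc:])]
    else:
        raise ValueError(f"unknown split rule {rule!r}")
    if not discovery or not validation:
        raise ValueError("split produced an empty discovery or validation set")
    return discovery, validation


def _numeric_id(subject_id: str) -> int:
    digits = "".join(ch for ch in subject_id if ch.isdigit())
    if not digits:
        raise ValueError(f"subject id {subject_id!r} carries no numeric identifier")
    return int(digits)


def preprocess_subject(volume: MpVolume, registration: RegistrationConfig | None):
    vol = standardize_volume(volume)
    if registration is not None:
        vol = register_volume(vol, registration)
        vol = standardize_volume(vol)
    return vol


def build_patchset(
    discovery, cfg: ExperimentConfig, seed: int
) -> PatchSet:
    """Standardize, decompose and sample every discovery subject."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0]) for c in ss.spawn(len(discovery))]
    sets = []
    for (volume, label), subj_seed in zip(discovery, seeds):
        std = preprocess_subject(volume, cfg.registration)
        regions = decompose(
            std.dwi_high_b,
            label,
            std.spacing,
            radius_mm=cfg.sampling.radius_mm,
            threshold=cfg.sampling.threshold,
        )
        sets.append(
            sample_patches(std, regions, N=cfg.sampling.N, M=cfg.sampling.M, seed=subj_seed)
        )
    return PatchSet.concatenate(sets)


def predict_subject(model: ConvNet, volume: MpVolume, cfg: ExperimentConfig):
    std = preprocess_subject(volume, cfg.registration)
    pmap = predict_volume(model, std, M=cfg.sampling.M, batch=cfg.infer.batch)
    seg = threshold_and_select(pmap, t=cfg.infer.threshold, connectivity=cfg.infer.connectivity)
    return pmap, seg


def run_pipeline(
    discovery, validation, cfg: ExperimentConfig, seed: int | None = None
):
    """Train on discovery subjects and evaluate on validation subjects.

    Returns (model, history, MetricsReport, per-subject predictions) where
    predictions maps subject_id -> (ProbabilityMap, SegMask).
    """
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    sample_seed, init_seed, train_seed = (
        int(c.generate_state(1)[0]) for c in ss.spawn(3)
    )

    t0 = time.time()
    patchset = build_patchset(discovery, cfg, sample_seed)
    log.info("sampled %d patches from %d subjects in %.1fs",
             len(patchset), len(discovery), time.time() - t0)

    train_set, test_set = split_discovery(
        patchset, train_fraction=cfg.train.train_fraction, seed=train_seed
    )
    model = build_network(cfg.network, cfg.sampling.M, seed=init_seed)
    t0 = time.time()
    model, history = train(model, train_set, test_set,
                           replace(cfg.train, seed=train_seed))
    log.info("trained for %d epochs (%s) in %.1fs",
             len(history.test_cost), history.stop_reason, time.time() - t0)

    rows, predictions = [], {}
    for volume, label in validation:
        pmap, seg = predict_subject(model, volume, cfg)
        rows.append(
            {
                "subject_id": volume.subject_id,
                "dsc": dsc(seg, label),
                "auc": voxel_auc(pmap, label),
            }
        )
        predictions[volume.subject_id] = (pmap, seg)
    report = metrics_report(rows)
    return model, history, report, predictions


def run_stability(
    discovery, validation, cfg: ExperimentConfig, n_runs: int = 4,
    seeds: list[int] | None = None,
) -> StabilityReport:
    """Repeat sampling + training + prediction ``n_runs`` times; ICC of DSC."""
    if seeds is None:
        ss = np.random.SeedSequence(cfg.seed)
        seeds = [int(c.generate_state(1)[0]) for c in ss.spawn(n_runs)]
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    columns = []
    subject_ids = [v.subject_id for v, _ in validation]
    for r, run_seed in enumerate(seeds):
        try:
            _, _, report, _ = run_pipeline(discovery, validation, cfg, seed=run_seed)
        except Exception:
            log.exception("stability run %d (seed %d) failed", r, run_seed)
            raise
        columns.append(report.table["dsc"].to_numpy())
    matrix = np.column_stack(columns)
    est, ci = icc_agreement(matrix)
    return StabilityReport(
        dsc_matrix=matrix,
        icc=est,
        ci95=ci,
        n_runs=n_runs,
        subject_ids=subject_ids,
        run_seeds=list(seeds),
    )


def run_experiment(cfg: ExperimentConfig, out_dir, stability_runs: int = 0) -> Path:
    """Full on-disk experiment: cohort, checkpoint, maps, masks, reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    cohort = generate_cohort(cfg.n_subjects, cfg.phantom, seed=cfg.seed)
    discovery, validation = split_cohort(
        cohort, cfg.split_rule, cfg.n_discovery, seed=cfg.seed
    )
    split_of = {v.subject_id: "discovery" for v, _ in discovery}
    split_of.update({v.subject_id: "validation" for v, _ in validation})
    rows = []
    for volume, label in cohort:
        sdir = out / "cohort" / volume.subject_id
        pio.write_subject(sdir, volume, label)
        rows.append(
            {
                "subject_id": volume.subject_id,
                "directory": str(sdir.relative_to(out)),
                "split": split_of[volume.subject_id],
            }
        )
    pio.write_manifest(out / "manifest.tsv", rows)

    model, history, report, predictions = run_pipeline(discovery, validation, cfg)
    pio.save_checkpoint(out / "model.npz", model, history, cfg.train)
    pio.export_history(out / "history.tsv", history)

    maps_dir = out / "maps"
    masks_dir = out / "masks"
    maps_dir.mkdir(exist_ok=True)
    masks_dir.mkdir(exist_ok=True)
    for sid, (pmap, seg) in predictions.items():
        pio.save_nifti(pmap.p, pmap.spacing, maps_dir / f"{sid}_prob.nii")
        pio.save_nifti(seg.mask, pmap.spacing, masks_dir / f"{sid}_seg.nii")

    report.table.to_csv(out / "metrics.tsv", sep="\t", index=False)
    summary = {"seed": cfg.seed, **report.summary()}

    if stability_runs >= 2:
        sreport = run_stability(discovery, validation, cfg, n_runs=stability_runs)
        sreport.to_table().to_csv(out / "stability.tsv", sep="\t", index=False)
        summary["stability"] = {
            "icc": sreport.icc,
            "ci95": list(sreport.ci95),
            "n_runs": sreport.n_runs,
            "icc_form": sreport.icc_form,
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
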