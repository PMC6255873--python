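"""End-to-end workflow: synthesize/ingest -> tissue -> sample -> train ->
predict -> score -> evaluate.

Every stage reads and writes plain files (PNG slides and masks, CSV tables,
YAML config, JSON sidecars) so the CLI subcommands compose via the file
system; :func:`run_pipeline` chains them in memory for speed and stamps
every artifact directory with the config hash and root seed.  All
randomness derives from one root seed, expanded deterministically per
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import patches as patching
from . import synthetic as syn
from . import tissue as tissue_mod
from .acgan import ACGANSpec, save_checkpoint
from .classes import collapse_to_reduced, default_scheme, reduced_scheme
from .concordance import (ScoreTable, evaluate_table, leave_one_out_median,
                          pairwise_reports, restricted_concordance,
                          restricted_to_dataframe)
from .scoring import score_slide
from .training import TrainConfig, TrainData, patches_to_float, train

log = logging.getLogger("pdl1tps")


@dataclass
class PipelineConfig:
    """One YAML-serializable configuration for the whole workflow."""

    out_dir: str = "runs/demo"
    seed: int = 0

    # synthetic study
    n_slides: int = 10
    n_annotated: int = 5  # slides whose masks feed patch sampling
    slide_width: int = 384
    slide_height: int = 384
    blob_sigma: float = 36.0
    n_raters: int = 3
    rater_noise_sd: float = 5.0
    annotator_disagreement: float = 0.1

    # patch sampling (strides are desk-scale: slides here are ~10x smaller
    # than clinical scans, so the grids are proportionally denser)
    patch_size: int = 32
    labeled_stride: int = 10
    unlabeled_stride: int = 10
    purity_threshold: float = 0.9
    # 4-fold rotation augmentation of the labeled training pool (protocol
    # default; controlled experiments with a fixed labeled-patch budget
    # turn it off so the pool size stays exactly n_labeled_per_class)
    augment_rotations: bool = True

    # model / training
    reduced_classes: bool = True
    base_width: int = 16
    d_z: int = 100
    mode: str = "ssl_acgan"
    iterations: int = 2000
    batch_labeled: int | None = None
    batch_unlabeled: int | None = None
    lr: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.999
    eval_every: int = 100
    n_labeled_per_class: int = 50
    n_unlabeled: int = 5000
    n_eval_per_class: int = 100

    # prediction / scoring
    predict_window: int | None = None  # default: patch_size
    predict_stride: int = 32
    cutoff: float = 25.0
    delta_grid: list[float] = field(default_factory=lambda: [0, 10, 20, 30, 40, 60, 80, 100])

    def scheme(self):
        return reduced_scheme() if self.reduced_classes else default_scheme()

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def demo_config(out_dir: str = "runs/demo", seed: int = 0) -> PipelineConfig:
    """A desk-scale configuration that exercises every stage in well under
    a minute: small slides, 16-px patches, a narrow network, few
    iterations."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        n_slides=5,
        n_annotated=3,
        slide_width=192,
        slide_height=192,
        blob_sigma=24.0,
        patch_size=16,
        labeled_stride=12,
        unlabeled_stride=24,
        base_width=8,
        iterations=60,
        eval_every=20,
        n_labeled_per_class=40,
        n_unlabeled=300,
        n_eval_per_class=40,
        predict_stride=16,
    )


def _stage_seed(root_seed: int, stage: int) -> int:
    return int((root_seed * 1_000_003 + 7919 * stage) % (2**31 - 1))


# ---------------------------------------------------------------------------
# Stage: synthesize the study

def synthesize_study(config: PipelineConfig):
    """Generate slides, ground truth and simulated visual scores."""
    study = syn.make_study(
        config.n_slides,
        seed=_stage_seed(config.seed, 1),
        width=config.slide_width,
        height=config.slide_height,
        n_raters=config.n_raters,
        rater_noise_sd=config.rater_noise_sd,
        blob_sigma=config.blob_sigma,
    )
    log.info("synth: %d slides of %dx%d", len(study), config.slide_width, config.slide_height)
    return study


# ---------------------------------------------------------------------------
# Stage: patch datasets

def build_patch_data(config: PipelineConfig, study) -> TrainData:
    """Labeled, unlabeled and held-out evaluation patch pools.

    The ground-truth mask plays the role of annotator A; a simulated
    second annotator (controlled disagreement rate) provides mask B, and
    labeled patches are sampled from the concordant region of the two, as
    in the consolidation protocol.  Unlabeled patches come from the
    detected tissue of every slide.  Evaluation patches are sampled from
    the last annotated slide, which contributes no training patches.
    """
    scheme = config.scheme()
    rng = np.random.default_rng(_stage_seed(config.seed, 2))
    annotated = study[: config.n_annotated]
    if len(annotated) < 2:
        raise ValueError("need at least 2 annotated slides (train + eval)")
    train_sl, eval_sl = annotated[:-1], annotated[-1:]

    def labeled_from(subset):
        imgs, labels = [], []
        for slide_id, img, truth, _scores in subset:
            annot_b = syn.generate_rater_annotations(
                truth, config.annotator_disagreement,
                seed=int(rng.integers(2**31 - 1)),
            )
            concordant = patching.concordant_mask(truth.label_mask, annot_b)
            plist = patching.sample_labeled(
                img, concordant, config.patch_size, config.labeled_stride,
                config.purity_threshold, slide_id=slide_id,
            )
            for p in plist:
                imgs.append(p.image)
                labels.append(p.label)
        if not imgs:
            raise ValueError("no labeled patches sampled; check strides/sizes")
        x = np.stack(imgs)
        y = np.asarray(labels)
        if config.reduced_classes:
            y = collapse_to_reduced(y)
        return x, y

    def cap_per_class(x, y, n_per_class):
        keep = []
        for cid in scheme.class_ids:
            idx = np.flatnonzero(y == cid)
            if len(idx) == 0:
                warnings.warn(f"no patches for class {scheme.name_of(cid)}")
                continue
            rng.shuffle(idx)
            keep.append(idx[:n_per_class])
        keep = np.concatenate(keep)
        rng.shuffle(keep)
        return x[keep], y[keep]

    x_tr, y_tr = cap_per_class(*labeled_from(train_sl), config.n_labeled_per_class)
    if config.augment_rotations:
        # 4-fold rotations on the training pool only; eval stays raw
        x_tr = np.concatenate([np.rot90(x_tr, k, axes=(1, 2)) for k in range(4)])
        y_tr = np.tile(y_tr, 4)
        perm = rng.permutation(len(x_tr))
        x_tr, y_tr = x_tr[perm], y_tr[perm]
    x_ev, y_ev = cap_per_class(*labeled_from(eval_sl), config.n_eval_per_class)

    unl = []
    for slide_id, img, truth, _scores in study:
        mask = tissue_mod.detect_tissue(img)
        for p in patching.sample_unlabeled(
            img, mask, config.patch_size, config.unlabeled_stride, slide_id=slide_id
        ):
            unl.append(p.image)
    if len(unl) > config.n_unlabeled:
        idx = rng.choice(len(unl), size=config.n_unlabeled, replace=False)
        unl = [unl[i] for i in idx]
    x_unl = np.stack(unl) if unl else None

    index_of = {cid: i for i, cid in enumerate(scheme.class_ids)}
    to_idx = np.vectorize(index_of.get)
    log.info(
        "sample: %d labeled, %d unlabeled, %d eval patches",
        len(x_tr), 0 if x_unl is None else len(x_unl), len(x_ev),
    )
    return TrainData(
        x_labeled=patches_to_float(x_tr),
        y_labeled=to_idx(y_tr),
        x_eval=patches_to_float(x_ev),
        y_eval=to_idx(y_ev),
        x_unlabeled=patches_to_float(x_unl) if x_unl is not None else None,
    )


# ---------------------------------------------------------------------------
# Stage: train

def train_model(config: PipelineConfig, data: TrainData):
    spec = ACGANSpec(
        patch_size=config.patch_size,
        n_classes=config.scheme().n_classes,
        d_z=config.d_z,
        base_width=config.base_width,
    )
    tc = TrainConfig(
        mode=config.mode,
        batch_labeled=config.batch_labeled,
        batch_unlabeled=config.batch_unlabeled,
        iterations=config.iterations,
        lr=config.lr,
        beta1=config.beta1,
        beta2=config.beta2,
        eval_every=config.eval_every,
        seed=_stage_seed(config.seed, 3),
    )
    model, history = train(spec, data, tc)
    log.info(
        "train[%s]: best accuracy %.3f at iteration %d",
        config.mode, history.best_accuracy, history.best_iteration,
    )
    return model, history


# ---------------------------------------------------------------------------
# Stage: predict + score

def score_study(config: PipelineConfig, study, model) -> tuple[ScoreTable, pd.DataFrame]:
    """Automated TPS for every slide plus the simulated visual scores."""
    scheme = config.scheme()
    window = config.predict_window or config.patch_size
    rows = []
    slide_ids, visual, automated = [], [], []
    for slide_id, img, truth, scores in study:
        mask = tissue_mod.detect_tissue(img)
        result, _pred_mask = score_slide(
            img, mask, model, scheme,
            window=window, stride=min(config.predict_stride, window),
            cutoff=config.cutoff,
        )
        rows.append(
            {
                "slide_id": slide_id,
                "tps": np.nan if result.tps is None else result.tps,
                "n_pos": result.n_pos_pixels,
                "n_neg": result.n_neg_pixels,
                "status": result.status,
                "true_tps": np.nan if truth.true_tps is None else truth.true_tps,
            }
        )
        if scores is not None:
            slide_ids.append(slide_id)
            visual.append(scores)
            automated.append(np.nan if result.tps is None else result.tps)
    table = ScoreTable(slide_ids=slide_ids, visual=np.asarray(visual), automated=np.asarray(automated))
    return table, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage: evaluate

def evaluate_study(config: PipelineConfig, table: ScoreTable) -> dict[str, pd.DataFrame]:
    report = evaluate_table(table, cutoff=config.cutoff)
    restricted = restricted_to_dataframe(
        restricted_concordance(table, config.delta_grid, cutoff=config.cutoff)
    )
    loo = pd.DataFrame(
        {name: rep.as_dict() for name, rep in leave_one_out_median(table, config.cutoff).items()}
    ).T.rename_axis("source").reset_index()
    pairwise = pairwise_reports(table, cutoff=config.cutoff)
    return {
        "report": pd.DataFrame([report.as_dict()]),
        "restricted": restricted,
        "loo": loo,
        "pairwise": pairwise,
    }


# ---------------------------------------------------------------------------
# Orchestration

def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages, persisting artifacts under ``config.out_dir``.

    Outputs: slides/ and masks/ (PNG), patches summary, checkpoint +
    history.csv, scores.csv, report/*.csv, run.json (config hash, seed,
    stage timings).  Any stage failure aborts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    timings: dict[str, float] = {}

    def run_stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    study = run_stage("synth", synthesize_study, config)
    slides_dir = out / "slides"
    masks_dir = out / "masks"
    slides_dir.mkdir(exist_ok=True)
    masks_dir.mkdir(exist_ok=True)
    truth_rows = []
    for slide_id, img, truth, scores in study:
        syn.write_slide(slides_dir / f"{slide_id}.png", img)
        syn.write_mask(masks_dir / f"{slide_id}.png", truth.label_mask)
        row = {"slide_id": slide_id, "true_tps": truth.true_tps}
        if scores is not None:
            row.update({f"rater_{j + 1}": s for j, s in enumerate(scores)})
        truth_rows.append(row)
    syn.write_truth_table(truth_rows, out / "truth.csv")

    data = run_stage("sample", build_patch_data, config, study)
    model, history = run_stage("train", train_model, config, data)
    history.to_csv(out / "history.csv")
    save_checkpoint(out / "checkpoint.npz", model, extra={"config_hash": config.config_hash()})

    table, scores_df = run_stage("score", score_study, config, study, model)
    scores_df.to_csv(out / "scores.csv", index=False)
    table.to_csv(out / "score_table.csv")

    reports = run_stage("evaluate", evaluate_study, config, table)
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    for name, df in reports.items():
        df.to_csv(report_dir / f"{name}.csv", index=False)

    (out / "run.json").write_text(
        json.dumps(
            {"config_hash": config.config_hash(), "seed": config.seed, "timings_s": timings},
            indent=2,
        )
    )
    log.info("pipeline done: %s (stages %s)", out, timings)
    return out


# ---------------------------------------------------------------------------
# Comparative study used by the evaluation scripts: semi-supervised AC-GAN
# vs fully-supervised baseline on the same labeled patches.

def comparative_study(
    seeds=(0, 1, 2),
    *,
    config: PipelineConfig | None = None,
    modes=("ssl_acgan", "fully_supervised"),
) -> dict:
    """Train each mode on identical data across seeds; report best held-out
    accuracy and slide-level TPS concordance against ground truth.

    The default configuration keeps the labeled pool at exactly
    ``n_labeled_per_class`` patches per class (no rotation augmentation),
    so the label budget of the comparison is the stated one.

    Returns ``{mode: {"accuracy": [...], "lcc_vs_true": [...], "tables": [...]}}``.
    """
    from .concordance import lin_ccc

    base = config or PipelineConfig(augment_rotations=False)
    results: dict = {mode: {"accuracy": [], "lcc_vs_true": [], "tables": []} for mode in modes}
    for seed in seeds:
        cfg = PipelineConfig(**{**asdict(base), "seed": int(seed)})
        study = synthesize_study(cfg)
        data = build_patch_data(cfg, study)
        for mode in modes:
            mcfg = PipelineConfig(**{**asdict(cfg), "mode": mode})
            model, history = train_model(mcfg, data)
            table, scores_df = score_study(mcfg, study, model)
            valid = np.isfinite(scores_df["tps"]) & np.isfinite(scores_df["true_tps"])
            lcc = lin_ccc(scores_df.loc[valid, "true_tps"], scores_df.loc[valid, "tps"])
            results[mode]["accuracy"].append(history.best_accuracy)
            results[mode]["lcc_vs_true"].append(lcc)
            results[mode]["tables"].append(table)
            log.info("study seed=%s mode=%s acc=%.3f lcc=%.3f",
                     seed, mode, history.best_accuracy, lcc)
    return results
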