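"""End-to-end orchestration: standardize -> segment -> features -> heatmap
-> stats -> classify, with QC bookkeeping and reproducible seeds.

The in-memory entry points (:func:`process_specimen`,
:func:`analyze_dataset`) run the whole chain on loaded images;
:func:`run_pipeline` is the file-based wrapper that persists every stage's
artifacts plus a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import heatmap as hm
from . import spot_features as sf
from . import standardize as std
from . import stats as st
from .io import AbdomenROI, RawImage, load_image, load_roi, save_image, save_json
from .segmentation import BinaryMask, LabeledSpots, SegmentationParams, segment_image

logger = logging.getLogger(__name__)

#: Fixed float formatting keeps every CSV byte-reproducible across runs.
CSV_FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    images_dir: str | None = None
    rois_dir: str | None = None
    labels_csv: str | None = None
    out_dir: str = "spotmorph_out"
    ref_width: int = 800
    central_band: float = 0.15
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    f_enter: float = 4.0
    f_remove: float = 3.9
    train_frac: float = 0.6
    hidden_grid: tuple[int, ...] = (5, 10, 15, 20, 25)
    hidden_activation: str = "tanh"
    mlp_loss: str = "cross_entropy"
    max_epochs: int = 300
    split_seed: int = 0
    mlp_seed: int = 0
    importance_reps: int = 30
    allow_empty_lda: bool = False

    @classmethod
    def from_json(cls_, path: str | Path) -> "PipelineConfig":
        import json

        with open(path) as fh:
            raw = json.load(fh)
        seg = raw.pop("segmentation", None)
        cfg = cls_(**raw)
        if seg is not None:
            cfg.segmentation = SegmentationParams(**seg)
        if isinstance(cfg.hidden_grid, list):
            cfg.hidden_grid = tuple(cfg.hidden_grid)
        return cfg


@dataclass
class SpecimenResult:
    specimen_id: str
    group: str
    standardized: std.StandardizedImage
    spots: LabeledSpots
    mask: BinaryMask
    records: list[sf.SpotRecord]


@dataclass
class PipelineResult:
    specimens: list[SpecimenResult]
    features: pd.DataFrame
    qc: dict
    heatmaps: dict
    descriptives: pd.DataFrame
    kruskal: pd.DataFrame
    lda: cls.LDAModel | None
    split: cls.SplitPlan | None
    mlp: cls.MLPModel | None
    leaderboard: pd.DataFrame | None
    importance: cls.ImportanceReport | None


def process_specimen(
    image: RawImage | np.ndarray,
    roi: AbdomenROI,
    ref_width: int = 800,
    seg_params: SegmentationParams | None = None,
    central_band: float = 0.15,
    specimen_id: str = "",
    group: str = "",
) -> SpecimenResult:
    """Run one specimen through standardization, segmentation and measurement."""
    pixels = image.pixels if isinstance(image, RawImage) else np.asarray(image)
    if not specimen_id and isinstance(image, RawImage):
        specimen_id = image.source_id
    gray = std.desaturate(pixels)
    # histogram stretch over the whole frame: the light background anchors
    # the upper quantile so the cuticle/spot contrast survives the clip
    stretched = std.stretch_levels(gray)
    simg = std.standardize_geometry(stretched, roi, ref_width=ref_width)
    simg.source_id = specimen_id
    spots, mask = segment_image(simg.pixels, simg.roi_mask, seg_params)
    records = sf.classify_and_number(spots, roi_mask=simg.roi_mask, central_band=central_band)
    for rec in records:
        sf.spot_metrics(rec, spots.Ta)
    return SpecimenResult(
        specimen_id=specimen_id,
        group=group,
        standardized=simg,
        spots=spots,
        mask=mask,
        records=records,
    )


def analyze_dataset(
    items: list[tuple[str, str, RawImage, AbdomenROI]],
    config: PipelineConfig | None = None,
    run_classification: bool = True,
) -> PipelineResult:
    """Run the full analysis on (specimen_id, group, image, roi) tuples."""
    config = config or PipelineConfig()
    results: list[SpecimenResult] = []
    qc: dict = {"excluded": [], "spot_count_flags": []}
    expected = config.segmentation.expected_spot_count
    for specimen_id, group, image, roi in items:
        try:
            res = process_specimen(
                image,
                roi,
                ref_width=config.ref_width,
                seg_params=config.segmentation,
                central_band=config.central_band,
                specimen_id=specimen_id,
                group=group,
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("specimen %s excluded: %s", specimen_id, exc)
            qc["excluded"].append({"specimen_id": specimen_id, "reason": str(exc)})
            continue
        if expected is not None and len(res.records) != expected:
            qc["spot_count_flags"].append(
                {"specimen_id": specimen_id, "count": len(res.records), "expected": expected}
            )
        results.append(res)
    if not results:
        raise RuntimeError("no specimens survived QC")

    specimens = [
        sf.SpecimenSpots(specimen_id=r.specimen_id, group=r.group, Ta=r.spots.Ta, records=r.records)
        for r in results
    ]
    features = sf.build_feature_table(specimens)

    heatmaps = {}
    for grp in sorted({r.group for r in results}):
        masks = [r.mask for r in results if r.group == grp]
        heatmaps[grp] = hm.accumulate_heatmap(masks, group=grp)

    desc = st.descriptives_table(features, "group", columns=sf.FEATURE_COLUMNS)
    kw = st.kruskal_wallis_table(features, "group", columns=sf.FEATURE_COLUMNS)

    lda = split = mlp = importance = None
    leaderboard = None
    if run_classification and features["group"].nunique() >= 2:
        usable = [c for c in sf.FEATURE_COLUMNS if not features[c].isna().all()]
        lda = cls.stepwise_lda(
            features,
            features["group"],
            f_enter=config.f_enter,
            f_remove=config.f_remove,
            allow_empty=config.allow_empty_lda,
            feature_columns=usable,
        )
        split = cls.make_split(
            features["group"],
            train_frac=config.train_frac,
            forced_validation_ids=lda.misclassified_resub,
            seed=config.split_seed,
        )
        complete = features[usable + ["group"]].dropna()
        if len(config.hidden_grid) > 1:
            mlp, leaderboard = cls.search_topology(
                complete,
                complete["group"],
                split,
                hidden_grid=config.hidden_grid,
                activations=(config.hidden_activation,),
                losses=(config.mlp_loss,),
                max_epochs=config.max_epochs,
                seed=config.mlp_seed,
                feature_columns=usable,
            )
        else:
            mlp = cls.train_mlp(
                complete,
                complete["group"],
                split,
                cls.MLPConfig(
                    hidden_units=config.hidden_grid[0],
                    hidden_activation=config.hidden_activation,
                    loss=config.mlp_loss,
                    max_epochs=config.max_epochs,
                    seed=config.mlp_seed,
                ),
                feature_columns=usable,
            )
        importance = cls.permutation_importance(
            mlp,
            complete,
            complete["group"],
            reps=config.importance_reps,
            seed=config.mlp_seed + 1,
        )
    return PipelineResult(
        specimens=results,
        features=features,
        qc=qc,
        heatmaps=heatmaps,
        descriptives=desc,
        kruskal=kw,
        lda=lda,
        split=split,
        mlp=mlp,
        leaderboard=leaderboard,
        importance=importance,
    )


def _features_csv(features: pd.DataFrame, path: Path) -> None:
    features.sort_index().to_csv(path, float_format=CSV_FLOAT_FORMAT)


def load_items(
    images_dir: str | Path, rois_dir: str | Path, labels_csv: str | Path
) -> tuple[list[tuple[str, str, RawImage, AbdomenROI]], list[dict]]:
    """Load (id, group, image, roi) tuples from disk; missing ROIs are reported."""
    labels = pd.read_csv(labels_csv).set_index("specimen_id")["group"]
    items, missing = [], []
    for specimen_id, group in labels.sort_index().items():
        img_path = None
        for ext in (".png", ".tif", ".tiff"):
            candidate = Path(images_dir) / f"{specimen_id}{ext}"
            if candidate.exists():
                img_path = candidate
                break
        roi_path = Path(rois_dir) / f"{specimen_id}.json"
        if img_path is None or not roi_path.exists():
            missing.append(
                {"specimen_id": str(specimen_id), "reason": "missing image" if img_path is None else "missing ROI"}
            )
            continue
        items.append((str(specimen_id), str(group), load_image(img_path), load_roi(roi_path)))
    return items, missing


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based pipeline run: reads images/ROIs/labels, writes all artifacts."""
    if not (config.images_dir and config.rois_dir and config.labels_csv):
        raise ValueError("run_pipeline needs images_dir, rois_dir and labels_csv")
    out = Path(config.out_dir)
    (out / "standardized").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "heatmaps").mkdir(exist_ok=True)

    items, missing = load_items(config.images_dir, config.rois_dir, config.labels_csv)
    result = analyze_dataset(items, config)
    result.qc["excluded"].extend(missing)

    for r in result.specimens:
        save_image(out / "standardized" / f"{r.specimen_id}.png", r.standardized.pixels)
        save_json(
            out / "standardized" / f"{r.specimen_id}.transform.json",
            r.standardized.transform.to_dict(),
        )
        save_image(out / "masks" / f"{r.specimen_id}.png", r.mask.grid.astype(np.uint8) * 255)

    spot_rows = []
    for r in result.specimens:
        for rec in r.records:
            spot_rows.append(
                {
                    "specimen_id": r.specimen_id,
                    "group": r.group,
                    "number": rec.number,
                    "cls": rec.cls,
                    "side": rec.side,
                    "area_px": rec.area_px,
                    "centroid_x": rec.centroid[0],
                    "centroid_y": rec.centroid[1],
                    "Ra": rec.Ra,
                    "MaxFd": rec.MaxFd,
                    "MinFd": rec.MinFd,
                    "Fa": rec.Fa,
                    "Fa_folded": rec.Fa_folded,
                    "Ar": rec.Ar,
                }
            )
    pd.DataFrame(spot_rows).to_csv(out / "spots.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    _features_csv(result.features, out / "features.csv")
    save_json(out / "features.units.json", sf.FEATURE_UNITS)
    save_json(out / "qc.json", result.qc)

    for grp, heat in result.heatmaps.items():
        hm.render_heatmap(heat, out / "heatmaps" / f"{grp}.png")
        hm.save_heatmap_csv(heat, out / "heatmaps" / f"{grp}.csv")

    result.descriptives.to_csv(out / "descriptives.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    result.kruskal.to_csv(out / "kruskal_wallis.csv", index=False, float_format=CSV_FLOAT_FORMAT)

    if result.lda is not None:
        result.lda.step_trace.to_csv(out / "lda_steps.csv", index=False, float_format=CSV_FLOAT_FORMAT)
        result.lda.scores.to_csv(out / "lda_scores.csv", float_format=CSV_FLOAT_FORMAT)
        result.lda.confusion_resub.to_csv(out / "lda_confusion_resub.csv")
        result.lda.confusion_loo.to_csv(out / "lda_confusion_loo.csv")
        save_json(
            out / "lda_summary.json",
            {
                "selected_vars": result.lda.selected_vars,
                "wilks_lambda": result.lda.wilks,
                "wilks_F": result.lda.wilks_f,
                "wilks_df": list(result.lda.wilks_df),
                "wilks_p": result.lda.wilks_p,
                "accuracy_resubstitution_pct": result.lda.accuracy_resub,
                "accuracy_leave_one_out_pct": result.lda.accuracy_loo,
                "misclassified": [str(i) for i in result.lda.misclassified_resub],
            },
        )
        _ordination_plot(result.lda, out / "lda_ordination.png")
    if result.mlp is not None:
        save_json(
            out / "mlp_summary.json",
            {
                "hidden_units": result.mlp.config.hidden_units,
                "activation": result.mlp.config.hidden_activation,
                "loss": result.mlp.config.loss,
                "n_iter": result.mlp.n_iter,
                "accuracy_train_pct": result.mlp.accuracy_train,
                "accuracy_validation_pct": result.mlp.accuracy_validation,
                "split": {
                    "train_ids": [str(i) for i in result.split.train_ids],
                    "validation_ids": [str(i) for i in result.split.validation_ids],
                    "forced_validation_ids": [str(i) for i in result.split.forced_validation_ids],
                    "seed": result.split.seed,
                },
            },
        )
        if result.leaderboard is not None:
            result.leaderboard.to_csv(out / "mlp_leaderboard.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    if result.importance is not None:
        result.importance.importance.rename("importance_ratio").to_csv(
            out / "importance.csv", float_format=CSV_FLOAT_FORMAT
        )

    manifest = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "segmentation"},
            "segmentation": asdict(config.segmentation),
        },
        "n_specimens": len(result.specimens),
        "n_excluded": len(result.qc["excluded"]),
        "n_spot_count_flags": len(result.qc["spot_count_flags"]),
        "groups": sorted({r.group for r in result.specimens}),
    }
    save_json(out / "manifest.json", manifest)
    return result


def _ordination_plot(lda: cls.LDAModel, path: Path) -> None:
    if lda.scores.shape[1] < 2:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    groups = lda.fit_labels
    for grp in sorted(groups.unique()):
        sub = lda.scores.loc[groups[groups == grp].index]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=str(grp), s=18, alpha=0.8)
    ax.set_xlabel("canonical axis 1")
    ax.set_ylabel("canonical axis 2")
    ax.legend(title="group")
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": "spotmorph"})
    plt.close(fig)
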