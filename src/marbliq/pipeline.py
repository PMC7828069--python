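"""End-to-end orchestration: simulate → extract → assemble → model → report.

A single :class:`RunConfig` fully determines a run: the same config and
seed reproduce byte-identical report files. The pipeline mirrors the
study workflow — cutlet images are generated (in place of the camera),
image-analysis features are extracted from them, spectrophotometer-style
color triplicates are aggregated, carcass weight joins the table, the
known smooth link produces the "chemical" IMF% ground truth, samples are
grouped semi-quantitatively, and the four learners are compared under
one shared repeated k-fold CV scheme.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .color import aggregate_replicates
from .dataset import PREDICTOR_COLUMNS, assign_groups, scale_center
from .evaluation import (
    classification_report,
    cross_validate,
    lda_spec,
    make_cv_scheme,
    mda_spec,
    mlr_spec,
    regression_report,
    svr_spec,
    variable_importance,
)
from .imaging import anchored_threshold, extract_marbling, measure_morphometry, otsu_threshold
from .synthetic import POPULATION_RANGES, TableGroundTruth, generate_cutlet_image

log = logging.getLogger("marbliq")

__all__ = ["RunConfig", "run_full_pipeline"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    seed: int = 0
    n_samples: int = 39
    # image generation
    image_width_px: int = 360
    image_height_px: int = 400
    mm_per_px: float = 0.4
    noise_sd: float = 0.0
    muscle_gray: int = 120
    fleck_gray: int = 220
    # feature extraction
    threshold_mode: str = "otsu"  # 'otsu' | 'anchored'
    anchor_margin: int = 0
    min_particle_px: int = 10
    # grouping
    group_mode: str = "strict"  # 'strict' | 'lenient'
    # cross-validation
    cv_k: int = 7
    cv_repeats: int = 5
    stratified: bool = True
    # model hyperparameters
    mda_subclasses: int = 3
    svr_degree: int = 3
    svr_scale: float = 0.1
    svr_offset: float = 1.0
    svr_cost: float = 1.0
    svr_epsilon: float = 0.1
    # response link
    imf_noise_sd: float = 0.05
    link_params: dict = field(
        default_factory=lambda: {"b0": 0.45, "b1": 0.12, "b2": 0.10, "b3": 0.10}
    )
    importance_permutations: int = 20

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            log.info("stage: %s", name)
            return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


class PipelineError(RuntimeError):
    pass


def _simulate_and_extract(config: RunConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate per-sample cutlet images and extract the 7 IA variables."""
    rows = []
    lo_np, hi_np = POPULATION_RANGES["NOParticles"]
    for i in range(config.n_samples):
        image_seed = int(rng.integers(2**31))
        n_flecks = int(rng.integers(int(lo_np), int(hi_np) + 1))
        band_px = int(rng.integers(10, 140))
        image, truth = generate_cutlet_image(
            width_px=config.image_width_px,
            height_px=config.image_height_px,
            mm_per_px=config.mm_per_px,
            n_flecks=n_flecks,
            fleck_area_px_mean=float(rng.uniform(15, 35)),
            muscle_gray=config.muscle_gray,
            fleck_gray=config.fleck_gray,
            noise_sd=config.noise_sd,
            seed=image_seed,
            band_thickness_px=band_px,
        )
        if config.threshold_mode == "anchored":
            fleck_px = np.argwhere(truth.fleck_mask)
            picks = fleck_px[rng.choice(len(fleck_px), size=5, replace=False)]
            thr = anchored_threshold(image, truth.roi_mask, picks, margin=config.anchor_margin)
        elif config.threshold_mode == "otsu":
            thr = otsu_threshold(image, truth.roi_mask)
        else:
            raise ValueError(f"unknown threshold_mode {config.threshold_mode!r}")
        marb = extract_marbling(
            image, truth.roi_mask, thr, min_particle_px=config.min_particle_px
        )
        morpho = measure_morphometry(truth.roi_mask, truth.fat_band_mask, config.mm_per_px)
        rows.append(
            {
                "sample_id": f"S{i + 1:03d}",
                "image_seed": image_seed,
                "threshold": marb.threshold,
                "Width": morpho.width_cm,
                "Height": morpho.height_cm,
                "REA": morpho.rea_cm2,
                "BFT": morpho.bft_cm,
                "NOParticles": marb.n_particles,
                "Marb_area": marb.marb_area_mm2,
                "Marb_area%": marb.marb_area_pct,
            }
        )
    return pd.DataFrame(rows)


def _simulate_color(config: RunConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Simulate triplicate spectrophotometer readings and aggregate them."""
    R = POPULATION_RANGES
    rows = []
    for i in range(config.n_samples):
        L = rng.uniform(*R["L*"])
        while True:
            a = rng.uniform(*R["a*"])
            b = rng.uniform(*R["b*"])
            C = float(np.hypot(a, b))
            H = float(np.degrees(np.arctan2(b, a)))
            if R["C*"][0] <= C <= R["C*"][1] and R["H*"][0] <= H <= R["H*"][1]:
                break
        # replicate scatter: ~2% of the reading, occasionally larger
        reps = np.column_stack(
            [
                L + rng.normal(0, 0.02 * L, 3),
                a + rng.normal(0, 0.03 * max(abs(a), 1.0), 3),
                b + rng.normal(0, 0.02 * abs(b), 3),
            ]
        )
        agg = aggregate_replicates(reps)
        row = {"sample_id": f"S{i + 1:03d}"}
        row.update(agg.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and write the report bundle to ``outdir``.

    Returns a dictionary with the assembled table and all in-memory
    report objects; the on-disk bundle (JSON/CSV/TXT) is reproducible
    byte-for-byte from the config alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if config.cv_k > config.n_samples:
        raise PipelineError(
            f"config invalid: cv_k={config.cv_k} exceeds n_samples={config.n_samples}"
        )

    with _stage("simulate-images + extract-features"):
        ia = _simulate_and_extract(config, rng)
    with _stage("simulate-color"):
        color = _simulate_color(config, rng)
    with _stage("assemble-table"):
        table = ia.merge(color[["sample_id", "L*", "a*", "b*", "C*", "H*"]], on="sample_id")
        table["CW"] = rng.uniform(*POPULATION_RANGES["CW"], size=len(table))
        link = TableGroundTruth(
            link_params=dict(config.link_params), noise_sd=config.imf_noise_sd
        )
        imf = link.evaluate(table["BFT"], table["CW"], table["Marb_area%"])
        if config.imf_noise_sd > 0:
            imf = imf + rng.normal(0, config.imf_noise_sd, size=len(table))
        table["IMF%"] = np.maximum(np.asarray(imf), 0.05)
        table["group"] = assign_groups(table, mode=config.group_mode)
        n_unassigned = int(table["group"].isna().sum())
        modeling = table.dropna(subset=["group"]).reset_index(drop=True)
        log.info("%d samples; %d unassigned IMF values dropped", len(table), n_unassigned)

    with _stage("cross-validation"):
        scheme = make_cv_scheme(
            len(modeling), k=config.cv_k, repeats=config.cv_repeats,
            seed=config.seed,
            strata=modeling["group"].to_numpy() if config.stratified else None,
        )
        specs = {
            "LDA": lda_spec(),
            "MDA": mda_spec(subclasses_per_class=config.mda_subclasses, seed=config.seed),
            "MLR": mlr_spec(column_names=PREDICTOR_COLUMNS),
            "SVMR-Poly": svr_spec(
                degree=config.svr_degree, scale=config.svr_scale,
                offset=config.svr_offset, cost=config.svr_cost,
                epsilon=config.svr_epsilon,
            ),
        }
        cv_results = {}
        for name, spec in specs.items():
            target = "group" if spec.task == "classification" else "IMF%"
            cv_results[name] = cross_validate(spec, modeling, scheme, target=target)

    with _stage("best-model-reports"):
        reports = {}
        for name, spec in specs.items():
            res = cv_results[name]
            best = res.best_split()
            train_idx = np.setdiff1d(
                np.arange(len(modeling)), best.val_idx, assume_unique=False
            )
            train = modeling.iloc[train_idx]
            fm = scale_center(train, columns=PREDICTOR_COLUMNS)
            target = "group" if spec.task == "classification" else "IMF%"
            model = spec.fit(fm.values, train[target].to_numpy())
            pred_all = np.asarray(spec.predict(model, fm.transform(modeling)))
            if spec.task == "classification":
                reports[name] = classification_report(
                    modeling["group"].to_numpy(), pred_all
                )
            else:
                reports[name] = regression_report(
                    modeling["IMF%"].to_numpy(), pred_all.astype(float),
                    n_predictors=len(PREDICTOR_COLUMNS),
                )

    with _stage("variable-importance"):
        fm_full = scale_center(modeling, columns=PREDICTOR_COLUMNS)
        importance = {}
        for name, metric, target in (
            ("MDA", "accuracy", "group"),
            ("SVMR-Poly", "r2", "IMF%"),
        ):
            spec = specs[name]
            model = spec.fit(fm_full.values, modeling[target].to_numpy())
            predict_fn = lambda frame, _s=spec, _m=model, _fm=fm_full: _s.predict(
                _m, _fm.transform(frame)
            )
            importance[name] = variable_importance(
                predict_fn,
                modeling.loc[:, list(PREDICTOR_COLUMNS)],
                modeling[target].to_numpy(),
                metric=metric,
                n_permutations=config.importance_permutations,
                seed=config.seed,
            )

    with _stage("write-bundle"):
        def dump(obj, name):
            with open(outdir / name, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True)
                fh.write("\n")

        dump({"config": config.to_dict(), "package_version": __version__}, "config.json")
        table.to_csv(outdir / "features.csv", index=False)
        color.to_csv(outdir / "color.csv", index=False)
        for name, res in cv_results.items():
            slug = name.lower().replace("-", "_")
            dump(
                {
                    "model": name,
                    "task": res.task,
                    "n_splits_scheme": res.scheme.n_splits,
                    "n_splits_evaluated": len(res.splits),
                    "n_degenerate": res.n_degenerate,
                    "mean": res.mean,
                    "sd": res.sd,
                    "per_split": [
                        {"repeat": s.repeat, "fold": s.fold, **s.metrics}
                        for s in res.splits
                    ],
                },
                f"cv_{slug}.json",
            )
            dump(reports[name].to_dict(), f"report_{slug}.json")
            (outdir / f"report_{slug}.txt").write_text(reports[name].to_text() + "\n")
        for name, imp in importance.items():
            slug = name.lower().replace("-", "_")
            imp.to_csv(outdir / f"importance_{slug}.csv", index=False)
        dump(
            {
                "n_samples": int(len(table)),
                "n_modeling": int(len(modeling)),
                "n_unassigned": n_unassigned,
                "group_counts": modeling["group"].value_counts().to_dict(),
                "cv": {"k": config.cv_k, "repeats": config.cv_repeats,
                       "n_splits": scheme.n_splits, "stratified": config.stratified},
            },
            "provenance.json",
        )

    return {
        "table": table,
        "modeling": modeling,
        "scheme": scheme,
        "cv_results": cv_results,
        "reports": reports,
        "importance": importance,
    }
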