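"""End-to-end pipeline: phantom -> calibrate -> segment -> classify -> quantify -> stats.

The processing order mirrors the acquisition-to-index chain the method
defines: flat-field correction, 1075 nm threshold segmentation,
morphological cleanup, connected components, calyx exclusion, pixel
classification with the library-trained SVM, per-berry bruise ratio
index, and the treatment-level statistical comparison.  Every artifact
is written with a manifest recording the effective configuration and
content hashes, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import flat_field_correct
from .classify import train_classifier, cross_validate, classify_image
from .cube import band_index
from .library import (
    balance_library,
    extract_roi_spectra,
    merge_libraries,
    normalize_library,
)
from .phantom import PhantomConfig, make_scene, simulate_human_assessment
from .quantify import bruise_ratio, call_bruised, two_side_ratio
from .segment import calyx_exclusion_mask, label_components, refine_mask, threshold_mask
from .stats import kw_multcomp, kruskal_wallis, linreg_index_vs_human

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, serializable configuration for a full pipeline run."""

    out_dir: str = "pipeline_out"
    seed: int = 7
    treatments: tuple[str, ...] = (
        "control",
        "pad120",
        "steel60",
        "steel120",
        "fully_bruised",
    )
    n_berries: int = 25
    threshold_dn: float = 942.0
    segment_band_nm: float = 1075.0
    roi_band_nm: float = 1200.0
    min_object_px: int = 50
    calyx_radius_px: int = 5
    normalization: str = "mean"
    svm_cost: float = 1.0
    cv_folds: int = 10
    cv_repeats: int = 2
    bruise_threshold: float = 0.2
    library_per_class: int = 800
    balance_seed: int = 17

    _RANGES = {
        "threshold_dn": (0, 4095),
        "segment_band_nm": (950, 1650),
        "roi_band_nm": (950, 1650),
        "min_object_px": (0, 10_000),
        "calyx_radius_px": (0, 50),
        "cv_folds": (2, 50),
        "cv_repeats": (1, 50),
        "bruise_threshold": (0.0, 1.0),
        "library_per_class": (20, 1_000_000),
        "n_berries": (1, 500),
        "svm_cost": (1e-6, 1e6),
    }

    def __post_init__(self) -> None:
        if isinstance(self.treatments, str):
            self.treatments = tuple(
                t.strip() for t in self.treatments.split(",") if t.strip()
            )
        else:
            self.treatments = tuple(self.treatments)
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside documented range [{lo}, {hi}]")
        if self.normalization not in ("mean", "snv"):
            raise ValueError("normalization must be 'mean' or 'snv'")

    # flat key = value config file (TOML-compatible scalars)
    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            if f.name.startswith("_"):
                continue
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ", ".join(v)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            else:
                lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _segment(cube_raw, cfg: PipelineConfig):
    band = cube_raw.band(cfg.segment_band_nm)
    mask = refine_mask(threshold_mask(band, cfg.threshold_dn), cfg.min_object_px)
    labelmap = label_components(mask)
    exclusion = calyx_exclusion_mask(labelmap, cfg.calyx_radius_px)
    return labelmap, exclusion


def _subsample(lib, n_rows: int, seed: int):
    if len(lib) <= n_rows:
        return lib
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(lib), size=n_rows, replace=False))
    return lib.subset(keep)


def run_pipeline(cfg: PipelineConfig, phantom_cfg: PhantomConfig | None = None) -> dict:
    """Execute the full chain on generated phantom scenes.

    Returns a summary dict (also written to ``manifest.json``); the
    per-berry report goes to ``report.csv`` and treatment statistics to
    ``stats.json`` inside ``cfg.out_dir``.
    """
    t0 = time.time()
    pcfg = phantom_cfg or PhantomConfig(n_berries=cfg.n_berries)
    pcfg = dataclasses.replace(pcfg, n_berries=cfg.n_berries)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ---- training library from dedicated control / fully_bruised scenes
        stage = "library"
        libs = []
        for label, treatment, sub_seed in (
            ("healthy", "control", 1),
            ("bruised", "fully_bruised", 2),
        ):
            scene = make_scene(pcfg, treatment, seed=cfg.seed * 1000 + sub_seed)
            refl = flat_field_correct(scene.raw, scene.white, scene.dark)
            labelmap, exclusion = _segment(scene.raw, cfg)
            roi = (labelmap.labels > 0) & ~exclusion
            lib = extract_roi_spectra(refl, roi, label, source_tag=treatment)
            libs.append(_subsample(lib, cfg.library_per_class, cfg.balance_seed))
        lib = balance_library(merge_libraries(libs[0], libs[1]), seed=cfg.balance_seed)
        lib = normalize_library(lib, cfg.normalization)
        log.info("library: %d spectra (%s)", len(lib), lib.class_counts())

        stage = "train"
        cv_mean, cv_sd = cross_validate(
            lib, k=cfg.cv_folds, repeats=cfg.cv_repeats, seed=cfg.seed, C=cfg.svm_cost
        )
        model = train_classifier(lib, C=cfg.svm_cost)
        log.info("cv accuracy %.2f +/- %.2f %%", cv_mean, cv_sd)

        # ---- per-treatment scenes, both sides
        stage = "classify"
        rows = []
        ratios_by_treatment: dict[str, list[float]] = {}
        human_all: list[float] = []
        index_all: list[float] = []
        for ti, treatment in enumerate(cfg.treatments):
            per_side = {}
            for si, side in enumerate(("stem", "calyx")):
                scene = make_scene(
                    pcfg, treatment, seed=cfg.seed * 1000 + 10 + 2 * ti + si
                )
                refl = flat_field_correct(scene.raw, scene.white, scene.dark)
                labelmap, exclusion = _segment(scene.raw, cfg)
                classified = classify_image(
                    model, refl, labelmap, exclusion, cfg.normalization
                )
                ratios = {
                    bid: bruise_ratio(classified, bid)
                    for bid in labelmap.berry_ids()
                }
                human = simulate_human_assessment(
                    scene.truth, pcfg.assessment_noise_sd, seed=cfg.seed * 1000 + 50 + ti
                )
                per_side[side] = (ratios, scene.truth, human)
            stem_ratios, stem_truth, stem_human = per_side["stem"]
            calyx_ratios, _, _ = per_side["calyx"]
            ids_s = sorted(stem_ratios)
            ids_c = sorted(calyx_ratios)
            treatment_indices = []
            for bid_s, bid_c in zip(ids_s, ids_c):
                idx = two_side_ratio(stem_ratios[bid_s], calyx_ratios[bid_c])
                treatment_indices.append(idx)
                for side, ratio in (("stem", stem_ratios[bid_s]), ("calyx", calyx_ratios[bid_c])):
                    rows.append(
                        {
                            "treatment": treatment,
                            "berry_id": bid_s,
                            "side": side,
                            "side_ratio": ratio,
                            "bruise_ratio_index": idx,
                            "bruised": call_bruised(idx, cfg.bruise_threshold),
                            "firmness": stem_truth.firmness.get(bid_s),
                            "human_assessment": stem_human.get(bid_s),
                            "true_fraction": stem_truth.fractions.get(bid_s),
                        }
                    )
                index_all.append(idx)
                human_all.append(stem_human.get(bid_s, 0.0))
            ratios_by_treatment[treatment] = treatment_indices
        report = pd.DataFrame(rows)
        report_path = out / "report.csv"
        report.to_csv(report_path, index=False, float_format="%.6f")

        # ---- statistics across treatments
        stage = "stats"
        stats_out: dict = {"cv_accuracy_pct": cv_mean, "cv_accuracy_sd_pct": cv_sd}
        if len(cfg.treatments) >= 2:
            groups = {t: np.array(v) for t, v in ratios_by_treatment.items()}
            try:
                kw = kruskal_wallis(list(groups.values()))
                stats_out["kruskal_wallis"] = {
                    "H": kw.statistic,
                    "df": kw.df,
                    "p": kw.pvalue,
                }
                stats_out["letters"] = kw_multcomp(groups).letters
            except ValueError as err:
                stats_out["kruskal_wallis"] = {"error": str(err)}
        if np.ptp(human_all) > 0:
            stats_out["index_vs_human"] = linreg_index_vs_human(human_all, index_all)
        stats_path = out / "stats.json"
        stats_path.write_text(json.dumps(stats_out, indent=2, default=list))

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": {
                f.name: list(v) if isinstance(v := getattr(cfg, f.name), tuple) else v
                for f in dataclasses.fields(cfg)
            },
            "outputs": {
                p.name: _sha256(p) for p in (report_path, stats_path)
            },
            "n_report_rows": int(len(report)),
            "elapsed_s": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return {"report": report, "stats": stats_out, "manifest": manifest}
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
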