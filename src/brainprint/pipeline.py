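"""End-to-end experiment driver: smooth -> match -> verify -> identify.

One :class:`ExperimentConfig` fully determines an experiment: the dataset
(a manifest of normalized GM maps, or a synthetic phantom config), the
smoothing FWHM, the distance metric, the protocols to run, and the
selectors.  :func:`run_experiment` executes the requested protocols and
writes score tables, ROC/EER summaries, score histograms and the
identification report under one output directory.  Everything in the JSON
summary is recomputable from the emitted score CSVs alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from .identification import build_gallery, identification_report
from .matching import Metric, normalize_scores, pairwise_distances
from .phantoms import PhantomConfig, build_dataset
from .verification import (
    DEFAULT_SELECTOR,
    GenuineMode,
    enumerate_genuine_pairs,
    enumerate_imposter_pairs,
    eer,
    roc_curve,
    score_histogram,
    separation_gap,
)
from .volumes import DatasetIndex, load_dataset, smooth_dataset

logger = logging.getLogger("brainprint")

VERIFICATION_PROTOCOLS: tuple[GenuineMode, ...] = ("same_visit", "different_visit")
ALL_PROTOCOLS = VERIFICATION_PROTOCOLS + ("identification",)

DEFAULT_FWHM_MM = 8.0
DEFAULT_HISTOGRAM_BIN_WIDTH = 2.5


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment.

    Exactly one of ``manifest`` (path to a dataset manifest CSV) or
    ``phantom`` (synthetic generator config) supplies the dataset.  ``seed``
    overrides the phantom's master seed so one flag controls all randomness.
    """

    manifest: str | None = None
    phantom: PhantomConfig | None = None
    fwhm_mm: float = DEFAULT_FWHM_MM
    metric: Metric = "l1"
    protocols: tuple[str, ...] = ALL_PROTOCOLS
    imposter_selector: tuple[int, int] = DEFAULT_SELECTOR
    gallery_selector: tuple[int, int] = DEFAULT_SELECTOR
    probe_selector: tuple[int, int] = (2, 2)
    histogram_bin_width: float = DEFAULT_HISTOGRAM_BIN_WIDTH
    out_dir: str = "brainprint_out"
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.phantom is None):
            raise ValueError("exactly one of manifest or phantom must be set")
        if not self.protocols:
            raise ValueError("at least one protocol must be requested")
        unknown = set(self.protocols) - set(ALL_PROTOCOLS)
        if unknown:
            raise ValueError(f"unknown protocols: {sorted(unknown)}")
        self.protocols = tuple(self.protocols)
        if self.seed is not None and self.phantom is not None:
            self.phantom = PhantomConfig(
                **{**self.phantom.__dict__, "master_seed": self.seed}
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "phantom" in raw and raw["phantom"] is not None:
            raw["phantom"] = PhantomConfig(**raw["phantom"])
        for key in ("protocols", "imposter_selector", "gallery_selector",
                    "probe_selector"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _load_index(config: ExperimentConfig) -> DatasetIndex:
    if config.manifest is not None:
        logger.info("loading dataset from manifest %s", config.manifest)
        return load_dataset(config.manifest)
    assert config.phantom is not None
    logger.info(
        "generating phantom dataset: %d subjects x %d visits x %d scans, seed %d",
        config.phantom.n_subjects,
        config.phantom.visits_per_subject,
        config.phantom.scans_per_visit,
        config.phantom.master_seed,
    )
    return build_dataset(config.phantom)


def run_verification_protocol(
    index: DatasetIndex,
    mode: GenuineMode,
    metric: Metric = "l1",
    imposter_selector: tuple[int, int] = DEFAULT_SELECTOR,
) -> dict[str, Any]:
    """Run one verification protocol on a (smoothed) index.

    Genuine and imposter distances are pooled before score normalization, so
    the min-max extremes span the whole experiment.  Returns the normalized
    pool, the ROC, and the summary statistics.
    """
    genuine = enumerate_genuine_pairs(index, mode)
    if not genuine:
        raise ValueError(f"protocol {mode!r}: dataset yields no genuine pairs")
    imposter = enumerate_imposter_pairs(index, imposter_selector)
    logger.info(
        "%s: %d genuine pairs, %d imposter pairs", mode, len(genuine), len(imposter)
    )
    pool = normalize_scores(pairwise_distances(genuine + imposter, index, metric))
    logger.info("%s: d_min=%.6g d_max=%.6g", mode, pool.d_min, pool.d_max)
    g = pool.scores("genuine")
    i = pool.scores("imposter")
    curve = roc_curve(g, i)
    eer_res = eer(curve)
    max_imp, min_gen, separable = separation_gap(g, i)
    return {
        "pool": pool,
        "roc": curve,
        "summary": {
            "protocol": mode,
            "n_genuine": len(genuine),
            "n_imposter": len(imposter),
            "d_min": pool.d_min,
            "d_max": pool.d_max,
            "eer": eer_res.eer,
            "threshold_at_eer": eer_res.threshold_at_eer,
            "exact_crossing": eer_res.exact_crossing,
            "max_imposter": max_imp,
            "min_genuine": min_gen,
            "separable": separable,
        },
    }


def run_identification_protocol(
    index: DatasetIndex,
    metric: Metric = "l1",
    gallery_selector: tuple[int, int] = DEFAULT_SELECTOR,
    probe_selector: tuple[int, int] = (2, 2),
) -> dict[str, Any]:
    """Closed-set identification: one gallery entry and one probe per subject."""
    gallery = build_gallery(index, gallery_selector)
    pv, ps = probe_selector
    probes = [index.get(s, pv, ps) for s in index.subjects]
    logger.info(
        "identification: gallery N=%d (visit %d, scan %d), %d probes (visit %d, scan %d)",
        gallery.N, *gallery_selector, len(probes), pv, ps,
    )
    report = identification_report(probes, gallery, metric)
    n_correct = int(report["correct"].sum())
    return {
        "report": report,
        "summary": {
            "protocol": "identification",
            "n_probes": len(report),
            "n_correct": n_correct,
            "identification_ratio": 100.0 * n_correct / len(report),
            "n_ties": int(report["tie"].sum()),
        },
    }


def run_experiment(config: ExperimentConfig) -> dict[str, Any]:
    """Run every requested protocol and write the experiment report.

    Output layout under ``config.out_dir``:
    ``scores_<protocol>.csv``, ``roc_<protocol>.csv``,
    ``histogram_<protocol>.csv``, ``identification_report.csv`` and a single
    ``summary.json``.  Deterministic given the config (and seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = _load_index(config)
    smoothed = smooth_dataset(index, config.fwhm_mm)
    logger.info(
        "dataset: %d volumes, %d subjects, smoothed at FWHM %.3g mm",
        len(smoothed), len(smoothed.subjects), config.fwhm_mm,
    )
    summary: dict[str, Any] = {
        "config": {
            "metric": config.metric,
            "fwhm_mm": config.fwhm_mm,
            "protocols": list(config.protocols),
            "score_tie_convention": (
                "score == threshold counts as accepted-genuine and "
                "correctly-rejected-imposter (strict FAR/FRR inequalities)"
            ),
            "normalization_pool": "per-experiment (genuine + imposter combined)",
            "n_volumes": len(smoothed),
            "n_subjects": len(smoothed.subjects),
            "n_visits_histogram": smoothed.n_visits_histogram(),
            "seed": (
                config.phantom.master_seed if config.phantom is not None else None
            ),
        },
        "protocols": {},
    }
    for mode in VERIFICATION_PROTOCOLS:
        if mode not in config.protocols:
            continue
        res = run_verification_protocol(
            smoothed, mode, config.metric, config.imposter_selector
        )
        res["pool"].to_csv(out / f"scores_{mode}.csv")
        res["roc"].to_frame().to_csv(out / f"roc_{mode}.csv", index=False)
        hist_rows = []
        for label in ("genuine", "imposter"):
            for center, pct in score_histogram(
                res["pool"].scores(label), config.histogram_bin_width
            ):
                hist_rows.append(f"{label},{center},{pct}")
        (out / f"histogram_{mode}.csv").write_text(
            "label,bin_center,percentage\n" + "\n".join(hist_rows) + "\n"
        )
        summary["protocols"][mode] = res["summary"]
    if "identification" in config.protocols:
        res = run_identification_protocol(
            smoothed, config.metric, config.gallery_selector, config.probe_selector
        )
        res["report"].to_csv(out / "identification_report.csv", index=False)
        summary["protocols"]["identification"] = res["summary"]
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
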