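"""End-to-end orchestration: simulate -> train -> segment -> quantify ->
classify groups -> statistics -> report.

Every stage writes plain CSV/PNG/TIFF/JSON artifacts into a run directory
so any stage can be replaced by external tooling (e.g. real slide
segmentations dropped in at the measurements interface), and the run
directory is a self-describing provenance record (config, seeds, stage
logs).  ``from-measurements`` mode skips the imaging stages and starts from
existing subjects.csv + measurements.csv.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import depositseg, groupstats, grouping, synthcohort
from .regions import load_registry

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGE_SEED_OFFSETS = {"tiles": 11, "cohort": 23, "classifier": 37, "stats": 53}


@dataclass
class PipelineConfig:
    seed: int = 0
    preset: str = "easy"               # easy | realistic
    tile_size: int = 4096              # production tiling of annotations
    sim_tile_px: int = 192             # synthetic tile edge for train/test
    n_train_tiles: int = 10
    n_test_tiles: int = 10
    n_trees: int = 100
    pixels_per_class: int = 20_000     # training subsample budget per class
    classifier_threshold: float = 0.7
    positivity_threshold_pct: float = 0.3
    deposit_fraction_range: tuple[float, float] = (0.01, 0.12)
    registry_path: str | None = None
    cluster_overrides: dict = field(default_factory=dict)
    out_dir: str = "runs/latest"

    def __post_init__(self) -> None:
        if not (0 < self.classifier_threshold < 1):
            raise ValueError("classifier threshold must lie in (0, 1)")
        if self.positivity_threshold_pct <= 0:
            raise ValueError("positivity threshold must be positive")
        if self.preset not in ("easy", "realistic"):
            raise ValueError("preset must be 'easy' or 'realistic'")

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "deposit_fraction_range" in payload:
            payload["deposit_fraction_range"] = tuple(payload["deposit_fraction_range"])
        return cls(**payload)


def _cohort_config(config: PipelineConfig):
    maker = (synthcohort.easy_cohort_config if config.preset == "easy"
             else synthcohort.realistic_cohort_config)
    return maker(seed=config.stage_seed("cohort"))


def _tile_specs(config: PipelineConfig, n: int, seed0: int) -> list[synthcohort.TileSpec]:
    rng = np.random.default_rng(seed0)
    lo, hi = config.deposit_fraction_range
    specs = []
    for i in range(n):
        specs.append(synthcohort.TileSpec(
            width=config.sim_tile_px, height=config.sim_tile_px,
            deposit_fraction_target=float(rng.uniform(lo, hi)),
            seed=int(rng.integers(2**31 - 1)),
        ))
    return specs


def simulate_tiles(config: PipelineConfig) -> tuple[list, list]:
    """Generate the train and test tile sets (with ground-truth masks)."""
    seed = config.stage_seed("tiles")
    train = [synthcohort.generate_tile(s) for s in _tile_specs(config, config.n_train_tiles, seed)]
    test = [synthcohort.generate_tile(s) for s in _tile_specs(config, config.n_test_tiles, seed + 1)]
    return train, test


def train_and_validate(config: PipelineConfig, train_tiles, test_tiles):
    """Train the deposit classifier and validate on independent tiles."""
    labeled = [(depositseg.preprocess_tile(t.image), t.truth_mask) for t in train_tiles]
    model = depositseg.train_classifier(
        labeled, n_trees=config.n_trees, seed=config.stage_seed("classifier"),
        threshold=config.classifier_threshold, pixels_per_class=config.pixels_per_class,
    )
    report = depositseg.validate_model(model, test_tiles)
    return model, report


def run_pipeline(
    config: PipelineConfig,
    mode: str = "synthetic",
    measurements: pd.DataFrame | None = None,
    subjects: pd.DataFrame | None = None,
) -> Path:
    """Execute the full pipeline; returns the run directory.

    ``synthetic`` mode simulates tiles and a cohort; ``from-measurements``
    mode requires ``measurements`` and ``subjects`` tables (or CSVs already
    in the run directory written by an external tool).
    """
    if mode not in ("synthetic", "from-measurements"):
        raise ValueError("mode must be 'synthetic' or 'from-measurements'")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry(config.registry_path, config.cluster_overrides or None)
    timings: dict[str, float] = {}

    def _stage(name):
        timings[name] = time.perf_counter()

    def _done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    validation = None
    if mode == "synthetic":
        _stage("imaging")
        train_tiles, test_tiles = simulate_tiles(config)
        model, validation = train_and_validate(config, train_tiles, test_tiles)
        depositseg.save_model(model, out / "classifier.joblib")
        pd.DataFrame({
            "tile_id": validation.tile_ids,
            "prediction_accuracy": validation.prediction_accuracies,
            "area_accuracy": validation.area_accuracies,
            "predicted_area_pct": validation.predicted_areas,
            "reference_area_pct": validation.reference_areas,
        }).to_csv(out / "segmentation_validation.csv", index=False)
        _done("imaging")

        _stage("cohort")
        subject_records, measurements = synthcohort.generate_cohort(_cohort_config(config), registry)
        subjects = synthcohort.subjects_to_frame(subject_records)
        _done("cohort")
    else:
        if measurements is None or subjects is None:
            m_path, s_path = out / "measurements.csv", out / "subjects.csv"
            if not (m_path.exists() and s_path.exists()):
                raise FileNotFoundError(
                    "from-measurements mode needs measurements/subjects tables or CSVs in the run directory"
                )
            measurements = pd.read_csv(m_path)
            subjects = pd.read_csv(s_path)

    subjects.to_csv(out / "subjects.csv", index=False)
    measurements.to_csv(out / "measurements.csv", index=False)

    _stage("grouping")
    thresholds = grouping.GroupThresholds(positivity_pct=config.positivity_threshold_pct)
    assignments = grouping.assign_groups(measurements, thresholds, registry)
    assignments.to_csv(out / "groups.csv", index=False)
    _done("grouping")

    _stage("stats")
    frame = groupstats.build_frame(measurements, subjects, assignments, registry)
    frame.to_csv(out / "analysis_frame.csv", index=False)

    stains = sorted(frame["stain"].unique())
    stat_tables = []
    for stain in stains:
        for cov in ("none", "age_sex"):
            stat_tables.append(groupstats.run_contrast_analysis(
                frame, stain, ("alpha_syn_negative", "alpha_syn_positive"), covariates=cov))
        subgroups = [s for s in ("A", "B", "C")
                     if (frame["subgroup"] == s).any()]
        pairs = [("negative", s) for s in subgroups] + [
            (a, b) for i, a in enumerate(subgroups) for b in subgroups[i + 1:]
        ]
        for a, b in pairs:
            stat_tables.append(groupstats.run_contrast_analysis(
                frame, stain, (a, b), covariates="age_sex", label_col="subgroup"))
    stats = pd.concat(stat_tables, ignore_index=True)
    stats.to_csv(out / "stats.csv", index=False)

    summary = groupstats.summarize_clusters(frame, group_col="group")
    summary.to_csv(out / "cluster_summary.csv", index=False)
    _done("stats")

    provenance = {
        "config": {**asdict(config), "deposit_fraction_range": list(config.deposit_fraction_range)},
        "mode": mode,
        "stage_seeds": {k: config.stage_seed(k) for k in _STAGE_SEED_OFFSETS},
        "stage_timings_s": timings,
        "n_subjects": int(subjects.shape[0]),
        "n_measurements": int(measurements.shape[0]),
    }
    (out / "run.json").write_text(json.dumps(provenance, indent=2))

    _write_report(out, assignments, stats, summary, validation)
    return out


def _write_report(out: Path, assignments, stats, summary, validation) -> None:
    lines = ["# Pipeline report", ""]
    counts = assignments.groupby(["group", "subgroup"]).size()
    lines += ["## Group assignment", "", counts.to_string(), ""]
    if validation is not None:
        lines += [
            "## Segmentation validation",
            "",
            f"mean prediction accuracy: {validation.mean_prediction_accuracy:.4f}",
            f"mean area accuracy: {validation.mean_area_accuracy:.4f}",
            "",
        ]
    sig = stats[(stats["flag"] == "") & (stats["p_fdr"] < 0.05)]
    lines += ["## Significant contrasts (FDR < 0.05)", "",
              sig.to_string(index=False) if len(sig) else "none", ""]
    lines += ["## Cluster summary (median covered area, %)", "", summary.to_string(index=False), ""]
    (out / "report.md").write_text("\n".join(lines))
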