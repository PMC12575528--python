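"""Synthetic histology tiles and synthetic cohorts with known ground truth.

The study cohort (DAB-stained sections of 28 brain regions in advanced-stage
Alzheimer cases) is available only on request, so this module generates
stand-ins with the statistical structure the downstream analysis assumes:

* :func:`generate_tile` renders an H-DAB brightfield tile by composing
  hematoxylin and DAB optical-density maps (nuclei, diffuse low-intensity
  physiological staining, and dense deposits shaped like Lewy bodies,
  neurites and plaques) through the Beer-Lambert forward model, together
  with a per-pixel ground-truth label mask.  It is the exact forward model
  that :func:`lewyquant.stainsep.deconvolve` inverts, so segmentation and
  deconvolution can be validated against known truth.

* :func:`generate_cohort` draws per-subject demographics and per-region
  covered-area measurements for the three stains, with subgroup-specific
  regional load profiles (negative / amygdala-predominant / brainstem-
  predominant / cortical), log-normal loads on the percent scale, optional
  covariate effects on the log-linear predictor, and missing regions.

All randomness flows from explicit integer seeds; identical specs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import regions as _regions
from . import stainsep

__all__ = [
    "TileSpec",
    "SyntheticTile",
    "CovariateEffects",
    "SubgroupProfile",
    "CohortConfig",
    "SubjectRecord",
    "generate_tile",
    "generate_cohort",
    "easy_cohort_config",
    "realistic_cohort_config",
    "default_tile_spec",
]

STAINS = ("alpha_syn", "tau", "abeta")
SUBGROUPS = ("negative", "A", "B", "C")

# truth_mask label codes
BACKGROUND, NUCLEUS, DIFFUSE_STAIN, DENSE_DEPOSIT = 0, 1, 2, 3
TRUTH_LABELS = {
    BACKGROUND: "background",
    NUCLEUS: "nucleus",
    DIFFUSE_STAIN: "diffuse_stain",
    DENSE_DEPOSIT: "dense_deposit",
}


# ---------------------------------------------------------------------------
# tiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TileSpec:
    """Parameters of one synthetic tile.

    ``deposit_mix`` gives the proportions of blob-like (Lewy-body),
    curvilinear (Lewy-neurite) and plaque-like elements and must sum to 1.
    ``diffuse_background_level`` is the mean OD of diffuse physiological
    staining, deliberately well below dense-deposit OD.
    """

    width: int = 256
    height: int = 256
    pixel_size: float = 0.22  # um / px
    stain: str = "alpha_syn"
    deposit_fraction_target: float = 0.05
    deposit_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)
    diffuse_background_level: float = 0.08
    nucleus_density: float = 1500.0  # per mm^2
    noise_od: float = 0.03           # per-pixel OD noise SD on the DAB channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("tile dimensions must be positive")
        if not (0.0 <= self.deposit_fraction_target <= 0.5):
            raise ValueError("deposit_fraction_target must lie in [0, 0.5]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.stain not in STAINS:
            raise ValueError(f"stain must be one of {STAINS}")
        mix = np.asarray(self.deposit_mix, dtype=float)
        if mix.size != 3 or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
            raise ValueError("deposit_mix must be three non-negative proportions summing to 1")
        if self.diffuse_background_level < 0:
            raise ValueError("diffuse_background_level must be non-negative")


@dataclass(frozen=True)
class SyntheticTile:
    image: np.ndarray       # H x W x 3 uint8
    truth_mask: np.ndarray  # H x W uint8, codes in TRUTH_LABELS
    od_hematoxylin: np.ndarray
    od_dab: np.ndarray
    spec: TileSpec

    @property
    def deposit_fraction(self) -> float:
        return float((self.truth_mask == DENSE_DEPOSIT).mean())


def default_tile_spec(**kwargs) -> TileSpec:
    return TileSpec(**kwargs)


def _paint_disk(mask: np.ndarray, cy: float, cx: float, ry: float, rx: float, theta: float) -> None:
    """Paint a filled (rotated) ellipse into a boolean mask, clipped to bounds."""
    h, w = mask.shape
    rmax = max(ry, rx)
    y0, y1 = int(max(0, cy - rmax - 1)), int(min(h, cy + rmax + 2))
    x0, x1 = int(max(0, cx - rmax - 1)), int(min(w, cx + rmax + 2))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = (c * dx + s * dy) / rx
    v = (-s * dx + c * dy) / ry
    mask[y0:y1, x0:x1] |= (u * u + v * v) <= 1.0


def _paint_blob(mask: np.ndarray, rng: np.random.Generator, px: float, max_area: float) -> None:
    # Lewy-body analog: filled disc/ellipse, 5-25 um diameter.
    r_um = rng.uniform(2.5, 12.5)
    r = r_um / px
    if np.pi * r * r > max_area:
        r = max(2.0, np.sqrt(max_area / np.pi))
    ecc = rng.uniform(0.7, 1.0)
    cy = rng.uniform(0, mask.shape[0])
    cx = rng.uniform(0, mask.shape[1])
    _paint_disk(mask, cy, cx, r, r * ecc, rng.uniform(0, np.pi))


def _paint_curvilinear(mask: np.ndarray, rng: np.random.Generator, px: float, max_area: float) -> None:
    # Lewy-neurite analog: random-walk tube 1-3 um wide, 15-60 um long.
    width_um = rng.uniform(1.0, 3.0)
    length_um = rng.uniform(15.0, 60.0)
    half_w = max(1.0, 0.5 * width_um / px)
    n_steps = int(length_um / px)
    est_area = 2 * half_w * n_steps
    if est_area > max_area:
        n_steps = max(4, int(max_area / (2 * half_w)))
    y = rng.uniform(0, mask.shape[0])
    x = rng.uniform(0, mask.shape[1])
    theta = rng.uniform(0, 2 * np.pi)
    step = max(1.0, half_w)  # paint overlapping disks along the walk
    for _ in range(max(1, int(n_steps / step))):
        _paint_disk(mask, y, x, half_w, half_w, 0.0)
        theta += rng.normal(0.0, 0.25)
        y += step * np.sin(theta)
        x += step * np.cos(theta)


def _paint_plaque(mask: np.ndarray, rng: np.random.Generator, px: float, max_area: float) -> None:
    # Plaque/tangle analog: annulus plus dense core.
    r_um = rng.uniform(5.0, 12.5)
    r = r_um / px
    if np.pi * r * r > max_area:
        r = max(3.0, np.sqrt(max_area / np.pi))
    cy = rng.uniform(0, mask.shape[0])
    cx = rng.uniform(0, mask.shape[1])
    outer = np.zeros_like(mask)
    _paint_disk(outer, cy, cx, r, r, 0.0)
    inner = np.zeros_like(mask)
    _paint_disk(inner, cy, cx, 0.65 * r, 0.65 * r, 0.0)
    ring = outer & ~inner
    core = np.zeros_like(mask)
    _paint_disk(core, cy, cx, 0.3 * r, 0.3 * r, 0.0)
    mask |= ring | core


_PAINTERS = (_paint_blob, _paint_curvilinear, _paint_plaque)


def generate_tile(spec: TileSpec) -> SyntheticTile:
    """Render one synthetic H-DAB tile with its ground-truth label mask.

    Dense deposits are placed until their realized pixel fraction reaches
    ``deposit_fraction_target``; individual shapes are capped so the
    realized fraction stays within +/-30% of the target (and exactly 0 for a
    zero target).  Deposit pixels carry DAB OD in [0.7, 1.3], at least
    ~9x the default diffuse background level, satisfying the contract that
    dense deposits are composed above the diffuse level.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    total_px = h * w

    # --- hematoxylin: nuclei over faint cytoplasmic background
    od_h = rng.normal(0.02, 0.005, size=(h, w)).clip(0)
    area_mm2 = total_px * (spec.pixel_size * 1e-3) ** 2
    n_nuclei = rng.poisson(spec.nucleus_density * area_mm2)
    nucleus_mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_nuclei):
        r = rng.uniform(2.5, 4.0) / spec.pixel_size  # 5-8 um diameter
        _paint_disk(nucleus_mask, rng.uniform(0, h), rng.uniform(0, w), r, r * rng.uniform(0.8, 1.0), rng.uniform(0, np.pi))
    od_h = od_h + nucleus_mask * rng.uniform(0.5, 0.9)

    # --- DAB: diffuse physiological staining (low OD, spatially smooth)
    od_d = np.zeros((h, w))
    diffuse_mask = np.zeros((h, w), dtype=bool)
    if spec.diffuse_background_level > 0:
        noise = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=8.0)
        noise = (noise - noise.min()) / max(np.ptp(noise), 1e-12)
        # squared field: mean ~= level, hotspots up to 3x the level, so the
        # brightest diffuse staining approaches the dimmest deposit texture
        diffuse = noise**2 * 3.0 * spec.diffuse_background_level
        od_d += diffuse
        diffuse_mask = diffuse > spec.diffuse_background_level

    # --- dense deposits, placed until the realized fraction hits the target
    deposit_mask = np.zeros((h, w), dtype=bool)
    target_px = spec.deposit_fraction_target * total_px
    if target_px > 0:
        mix = np.asarray(spec.deposit_mix, dtype=float)
        for _ in range(10_000):
            done = deposit_mask.sum()
            if done >= target_px:
                break
            remaining = target_px - done
            painter = _PAINTERS[rng.choice(3, p=mix)]
            painter(deposit_mask, rng, spec.pixel_size, max_area=max(remaining * 1.3, 30.0))
    if deposit_mask.any():
        # Deposits are internally textured: a smooth multiplicative field in
        # [0.35, 1] modulates a 0.7-1.3 base OD, so parts of each deposit dip
        # toward the diffuse-background range.  A per-pixel threshold cannot
        # label such pixels without also labeling diffuse hotspots; context
        # features can.
        base = ndimage.gaussian_filter(rng.uniform(0.7, 1.3, size=(h, w)), 1.0)
        texture = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=3.0)
        texture = (texture - texture.min()) / max(np.ptp(texture), 1e-12)
        deposit_od = base * (0.18 + 0.82 * texture)
        floor = spec.diffuse_background_level + 0.05
        od_d = np.where(deposit_mask, np.maximum(deposit_od, floor), od_d)
    if spec.noise_od > 0:
        od_d = np.clip(od_d + rng.normal(0.0, spec.noise_od, size=(h, w)), 0.0, None)

    truth = np.full((h, w), BACKGROUND, dtype=np.uint8)
    truth[diffuse_mask] = DIFFUSE_STAIN
    truth[nucleus_mask] = NUCLEUS
    truth[deposit_mask] = DENSE_DEPOSIT

    od_stack = np.stack([od_h, od_d, np.zeros_like(od_d)], axis=-1)
    image = stainsep.od_to_rgb(od_stack, stainsep.StainVectorSet())
    return SyntheticTile(image=image, truth_mask=truth, od_hematoxylin=od_h, od_dab=od_d, spec=spec)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateEffects:
    """Additive effects on the log-load linear predictor."""

    age_per_year: float = 0.0   # per year of age, centered at the cohort mean
    female: float = 0.0         # female vs male offset
    apoe4: float = 0.0          # >=1 epsilon-4 allele vs none


@dataclass(frozen=True)
class SubgroupProfile:
    """Log-normal covered-area parameters (percent scale) per region cluster.

    ``medians`` maps cluster -> median covered area in percent; ``sigma`` is
    the common log-scale SD.  Regions inherit their cluster's parameters;
    the olfactory bulb uses the ``unassigned`` entry.
    """

    medians: dict[str, float]
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for cluster, m in self.medians.items():
            if m <= 0:
                raise ValueError(f"median for {cluster} must be positive")


@dataclass(frozen=True)
class CohortConfig:
    n_per_subgroup: dict[str, int]
    profiles: dict[str, dict[str, SubgroupProfile]]  # stain -> subgroup -> profile
    effects: dict[str, CovariateEffects] = field(default_factory=dict)  # per stain
    age_mean: float = 72.8
    age_sd: float = 11.5
    female_fraction: float = 0.56
    apoe4_fraction: float = 0.58
    braak_probs: tuple[float, float, float] = (8 / 72, 14 / 72, 50 / 72)   # IV:V:VI
    thal_probs: tuple[float, float, float] = (2 / 69, 7 / 69, 60 / 69)     # 3:4:5
    tdp43_probs: tuple[float, float, float] = (25 / 72, 24 / 72, 23 / 72)  # neg:pos:unknown
    missingness: float = 0.0
    annotation_sigma: float = 0.1  # log-scale SD between duplicate annotations
    seed: int = 0

    def __post_init__(self) -> None:
        for sg, n in self.n_per_subgroup.items():
            if sg not in SUBGROUPS:
                raise ValueError(f"unknown subgroup {sg!r}")
            if n < 0:
                raise ValueError("subgroup sizes must be >= 0")
        if not (0.0 <= self.missingness <= 1.0):
            raise ValueError("missingness must lie in [0, 1]")
        for stain in self.profiles:
            if stain not in STAINS:
                raise ValueError(f"unknown stain {stain!r}")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age_at_death: float
    sex: str                      # female | male
    apoe_alleles: tuple[int, int]
    braak_stage: str              # IV | V | VI
    thal_phase: int               # 3 | 4 | 5
    tdp43: str                    # negative | positive | unknown
    truth_subgroup: str

    @property
    def apoe4_carrier(self) -> bool:
        return 4 in self.apoe_alleles

    def __post_init__(self) -> None:
        if self.age_at_death <= 0:
            raise ValueError("age must be positive")
        if self.braak_stage not in ("IV", "V", "VI"):
            raise ValueError("Braak stage must be IV, V or VI")


def _draw_subject(rng: np.random.Generator, idx: int, subgroup: str, cfg: CohortConfig) -> SubjectRecord:
    age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 40.0, 100.0))
    sex = "female" if rng.random() < cfg.female_fraction else "male"
    if rng.random() < cfg.apoe4_fraction:
        alleles = (4, 4) if rng.random() < 0.25 else (3, 4)
    else:
        alleles = (2, 3) if rng.random() < 0.15 else (3, 3)
    braak = ("IV", "V", "VI")[rng.choice(3, p=cfg.braak_probs)]
    thal = (3, 4, 5)[rng.choice(3, p=cfg.thal_probs)]
    tdp = ("negative", "positive", "unknown")[rng.choice(3, p=cfg.tdp43_probs)]
    return SubjectRecord(
        subject_id=f"S{idx:03d}", age_at_death=age, sex=sex, apoe_alleles=alleles,
        braak_stage=braak, thal_phase=thal, tdp43=tdp, truth_subgroup=subgroup,
    )


def generate_cohort(
    config: CohortConfig,
    registry: _regions.RegionRegistry | None = None,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Draw a synthetic cohort and its region-level covered-area table.

    Returns subjects plus a long measurements table with one row per
    subject x stain x region x annotation (two annotations for substantia
    nigra and locus coeruleus, one elsewhere).  Loads are log-normal on the
    percent scale: ``log load = log median(cluster, subgroup) + effects +
    N(0, sigma)``, with covariate effects applied on the log-linear
    predictor.  Region records are dropped missing-completely-at-random at
    ``config.missingness``, except that subjects intended alpha-syn-negative
    always keep their amygdala alpha-syn measurement (the eligibility
    requirement for calling a case negative).
    """
    registry = registry or _regions.load_registry()
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectRecord] = []
    idx = 0
    for subgroup in SUBGROUPS:
        for _ in range(config.n_per_subgroup.get(subgroup, 0)):
            subjects.append(_draw_subject(rng, idx, subgroup, config))
            idx += 1

    rows: list[dict] = []
    for subj in subjects:
        for stain, by_subgroup in config.profiles.items():
            profile = by_subgroup[subj.truth_subgroup]
            eff = config.effects.get(stain, CovariateEffects())
            shift = (
                eff.age_per_year * (subj.age_at_death - config.age_mean)
                + (eff.female if subj.sex == "female" else 0.0)
                + (eff.apoe4 if subj.apoe4_carrier else 0.0)
            )
            for region in registry.regions:
                cluster = registry.cluster_of(region)
                median = profile.medians.get(cluster)
                if median is None:
                    continue
                keep_always = (
                    subj.truth_subgroup == "negative"
                    and stain == "alpha_syn"
                    and region == "amygdala"
                )
                if not keep_always and rng.random() < config.missingness:
                    continue
                latent = np.log(median) + shift + rng.normal(0.0, profile.sigma)
                for annot in range(1, registry.n_annotations(region) + 1):
                    log_val = latent + (
                        rng.normal(0.0, config.annotation_sigma)
                        if registry.n_annotations(region) > 1 else 0.0
                    )
                    rows.append({
                        "subject_id": subj.subject_id,
                        "stain": stain,
                        "region": region,
                        "annotation_index": annot,
                        "covered_area_pct": float(np.clip(np.exp(log_val), 0.0, 100.0)),
                        "qc_flag": "pass",
                    })
    measurements = pd.DataFrame(
        rows,
        columns=["subject_id", "stain", "region", "annotation_index", "covered_area_pct", "qc_flag"],
    )
    return subjects, measurements


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records (the subjects.csv schema)."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age_at_death": [s.age_at_death for s in subjects],
            "sex": [s.sex for s in subjects],
            "apoe_allele_1": [s.apoe_alleles[0] for s in subjects],
            "apoe_allele_2": [s.apoe_alleles[1] for s in subjects],
            "braak_stage": [s.braak_stage for s in subjects],
            "thal_phase": [s.thal_phase for s in subjects],
            "tdp43": [s.tdp43 for s in subjects],
            "truth_subgroup": [s.truth_subgroup for s in subjects],
        }
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_DEFAULT_N = {"negative": 29, "A": 15, "B": 5, "C": 22}

# Alpha-syn regional medians (percent) per subgroup, qualitatively matching
# the observed distribution patterns: negative near zero everywhere; A high
# in amygdala-entorhinal only; B high in brainstem; C cortical spread with
# the highest amygdala load and moderate brainstem involvement.
_ALPHA_MEDIANS = {
    "negative": {"cortical": 0.002, "subcortical": 0.002, "hippocampal": 0.002,
                 "amygdala_entorhinal": 0.003, "brainstem": 0.004, "unassigned": 0.002},
    "A": {"cortical": 0.01, "subcortical": 0.01, "hippocampal": 0.05,
          "amygdala_entorhinal": 0.7, "brainstem": 0.02, "unassigned": 0.05},
    "B": {"cortical": 0.01, "subcortical": 0.01, "hippocampal": 0.02,
          "amygdala_entorhinal": 0.08, "brainstem": 1.0, "unassigned": 0.05},
    "C": {"cortical": 0.8, "subcortical": 0.1, "hippocampal": 0.4,
          "amygdala_entorhinal": 1.5, "brainstem": 0.5, "unassigned": 0.3},
}

# Tau and abeta medians (percent) shared across alpha-syn subgroups, set to
# the magnitude ordering reported for advanced AD: tau highest in the
# amygdala-entorhinal and hippocampal clusters, abeta highest cortically.
_TAU_MEDIANS = {"cortical": 14.0, "subcortical": 1.6, "hippocampal": 19.0,
                "amygdala_entorhinal": 24.0, "brainstem": 2.2, "unassigned": 1.0}
_ABETA_MEDIANS = {"cortical": 4.5, "subcortical": 0.8, "hippocampal": 1.0,
                  "amygdala_entorhinal": 2.0, "brainstem": 0.7, "unassigned": 0.5}


def _flat_profiles(sigma_alpha: float, sigma_other: float) -> dict:
    profiles = {
        "alpha_syn": {sg: SubgroupProfile(medians=_ALPHA_MEDIANS[sg], sigma=sigma_alpha)
                      for sg in SUBGROUPS},
        "tau": {sg: SubgroupProfile(medians=_TAU_MEDIANS, sigma=sigma_other)
                for sg in SUBGROUPS},
        "abeta": {sg: SubgroupProfile(medians=_ABETA_MEDIANS, sigma=sigma_other)
                  for sg in SUBGROUPS},
    }
    return profiles


def easy_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Well-separated preset: tight load scales, no missingness, no covariate
    effects.  Downstream subgroup assignment recovers the generating truth
    for every subject."""
    kwargs = dict(
        n_per_subgroup=dict(_DEFAULT_N),
        profiles=_flat_profiles(sigma_alpha=0.25, sigma_other=0.5),
        effects={},
        missingness=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def realistic_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Noisier preset: broader load scales, 15% missing regions, and modest
    covariate effects in the directions reported for advanced AD (higher
    abeta in women and ApoE4 carriers, higher tau in men)."""
    kwargs = dict(
        n_per_subgroup=dict(_DEFAULT_N),
        profiles=_flat_profiles(sigma_alpha=0.6, sigma_other=0.8),
        effects={
            "abeta": CovariateEffects(female=0.3, apoe4=0.3),
            "tau": CovariateEffects(female=-0.25, age_per_year=-0.01),
            "alpha_syn": CovariateEffects(apoe4=0.2),
        },
        missingness=0.15,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def null_cohort_config(seed: int = 0, n_per_group: int = 20, sigma: float = 0.5) -> CohortConfig:
    """Two-arm null cohort for type-I-error simulations: the 'negative' and
    'A' arms share identical load distributions and zero covariate effects."""
    flat = {c: 0.05 for c in _regions.CLUSTERS}
    profile = SubgroupProfile(medians=flat, sigma=sigma)
    profiles = {"alpha_syn": {sg: profile for sg in SUBGROUPS}}
    return CohortConfig(
        n_per_subgroup={"negative": n_per_group, "A": n_per_group, "B": 0, "C": 0},
        profiles=profiles,
        effects={},
        missingness=0.0,
        seed=seed,
    )
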