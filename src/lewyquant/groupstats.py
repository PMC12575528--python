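"""Cluster-level statistics for covered-area analyses.

The analysis unit is the region cluster: within one cluster, covered area
(regressed on the fraction scale, percent/100) is modeled by ordinary least
squares as

    covered_area ~ label + region + sex + age

for one pairwise label contrast at a time, with region as a categorical
fixed effect.  Control variants drop the age/sex covariates, add ApoE4
carriage, or add a per-subject random intercept (linear mixed model, REML).
Demographic tables are compared with chi-squared tests (Yates continuity
correction for 2x2 tables, plain Pearson otherwise), Mann-Whitney U,
Kruskal-Wallis and Wilcoxon signed-rank tests.  p-values are adjusted by
Benjamini-Hochberg FDR within one analysis family (by default the set of
cluster-level p-values of one contrast analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .regions import RegionRegistry, load_registry

__all__ = [
    "RegressionResult",
    "ContingencyResult",
    "RankTestResult",
    "build_frame",
    "fit_pairwise_cluster_regression",
    "fit_mixed_control",
    "predictor_regression",
    "chisq_test",
    "mann_whitney",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "fdr_adjust",
    "summarize_clusters",
    "run_contrast_analysis",
]

ANALYSIS_CLUSTERS = ("cortical", "subcortical", "hippocampal", "amygdala_entorhinal", "brainstem")

COVARIATE_SETS = {
    "none": "",
    "age_sex": " + C(sex) + age_at_death",
    "age_sex_apoe4": " + C(sex) + age_at_death + C(apoe4_carrier)",
}


@dataclass(frozen=True)
class RegressionResult:
    contrast: tuple[str, str]
    cluster: str
    stain: str
    beta: float
    se: float
    p: float
    p_adjusted: float | None
    n_rows: int
    variant: str  # plain | covariates | apoe4 | mixed
    flag: str = ""

    @property
    def ok(self) -> bool:
        return self.flag == ""


@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    statistic: float
    dof: int
    p: float
    continuity_correction: bool


@dataclass(frozen=True)
class RankTestResult:
    test: str
    statistic: float
    p: float
    group_sizes: tuple[int, ...]


def age_group(age: float) -> str:
    """Age-at-death bands: < 65, 65 to < 75, >= 75 years."""
    if age < 65:
        return "<65"
    if age < 75:
        return "65-75"
    return ">=75"


def build_frame(
    measurements: pd.DataFrame,
    subjects: pd.DataFrame,
    assignments: pd.DataFrame,
    registry: RegionRegistry | None = None,
) -> pd.DataFrame:
    """Join aggregated measurements, demographics and group labels.

    One row per subject x stain x region with cluster label, group and
    subgroup, derived age band, and ApoE4 carriage (>= one epsilon-4
    allele).  Regions mapped to the ``unassigned`` cluster (olfactory bulb
    by default) are excluded from the analysis frame.
    """
    from .grouping import aggregate_loads

    registry = registry or load_registry()
    orphans = set(measurements["subject_id"]) - set(subjects["subject_id"])
    if orphans:
        raise ValueError(f"measurements reference unknown subjects: {sorted(orphans)}")
    agg = aggregate_loads(measurements, registry)
    agg["cluster"] = agg["region"].map(registry.cluster_of)
    agg = agg[agg["cluster"] != "unassigned"].copy()

    subj = subjects.copy()
    subj["apoe4_carrier"] = (subj["apoe_allele_1"] == 4) | (subj["apoe_allele_2"] == 4)
    subj["age_group"] = subj["age_at_death"].map(age_group)
    keep = ["subject_id", "age_at_death", "sex", "apoe4_carrier", "age_group"]
    frame = agg.merge(subj[keep], on="subject_id", how="left")
    frame = frame.merge(
        assignments[["subject_id", "group", "subgroup", "eligible"]],
        on="subject_id", how="left",
    )
    frame = frame[frame["eligible"].fillna(False)].drop(columns="eligible")
    # eligible negatives get an explicit subgroup level so subgroup contrasts
    # read "negative vs A" rather than "none vs A"
    frame.loc[frame["group"] == "alpha_syn_negative", "subgroup"] = "negative"
    return frame.reset_index(drop=True)


def _fit_ols(data: pd.DataFrame, formula: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return smf.ols(formula, data=data).fit()


def _design_is_deficient(model_fit) -> bool:
    return bool(model_fit.df_model + 1 > np.linalg.matrix_rank(model_fit.model.exog))


def _contrast_subset(
    frame: pd.DataFrame, cluster: str, stain: str, labels: tuple[str, str], label_col: str
) -> pd.DataFrame:
    sub = frame[
        (frame["cluster"] == cluster)
        & (frame["stain"] == stain)
        & (frame[label_col].isin(labels))
    ].copy()
    sub["response"] = sub["covered_area_pct"] / 100.0  # fraction scale
    sub["label"] = pd.Categorical(sub[label_col], categories=list(labels))
    return sub


def fit_pairwise_cluster_regression(
    frame: pd.DataFrame,
    cluster: str,
    stain: str,
    labels: tuple[str, str],
    covariates: str = "age_sex",
    label_col: str = "group",
) -> RegressionResult:
    """OLS contrast of two labels within one cluster and stain.

    Only rows of the two labels enter the fit; region is a categorical
    fixed effect; beta is the coefficient of the second label versus the
    first on the response (fraction) scale, with a two-sided p-value.
    Rank-deficient designs (e.g. a label confined to a single region) are
    returned flagged rather than silently dropped.
    """
    if covariates not in COVARIATE_SETS:
        raise ValueError(f"covariates must be one of {sorted(COVARIATE_SETS)}")
    sub = _contrast_subset(frame, cluster, stain, labels, label_col)
    variant = {"none": "plain", "age_sex": "covariates", "age_sex_apoe4": "apoe4"}[covariates]

    def _flagged(flag: str) -> RegressionResult:
        return RegressionResult(labels, cluster, stain, np.nan, np.nan, np.nan, None,
                                len(sub), variant, flag=flag)

    present = set(sub["label"].dropna().unique())
    if len(present) < 2:
        return _flagged("fewer than two labels present")

    # a single region degenerates gracefully: C(region) contributes no
    # columns and the no-covariate beta is the plain difference of means
    formula = "response ~ label + C(region)" + COVARIATE_SETS[covariates]
    fit = _fit_ols(sub, formula)
    term = f"label[T.{labels[1]}]"
    if term not in fit.params.index or _design_is_deficient(fit):
        return _flagged("rank-deficient design")
    if fit.df_resid <= 0 or not np.isfinite(fit.pvalues[term]):
        return _flagged("no residual degrees of freedom")
    return RegressionResult(
        contrast=labels, cluster=cluster, stain=stain,
        beta=float(fit.params[term]), se=float(fit.bse[term]),
        p=float(fit.pvalues[term]), p_adjusted=None,
        n_rows=len(sub), variant=variant,
    )


def fit_mixed_control(
    frame: pd.DataFrame,
    cluster: str,
    stain: str,
    labels: tuple[str, str],
    label_col: str = "group",
) -> RegressionResult:
    """The mixed-effects control: same fixed effects as the covariate OLS
    plus a random intercept per subject, fitted by REML.

    With zero between-subject variance the variance component sits at the
    boundary and the fixed-effect estimate coincides with OLS.  Convergence
    problems are flagged, not raised.
    """
    sub = _contrast_subset(frame, cluster, stain, labels, label_col)
    variant = "mixed"

    def _flagged(flag: str) -> RegressionResult:
        return RegressionResult(labels, cluster, stain, np.nan, np.nan, np.nan, None,
                                len(sub), variant, flag=flag)

    present = set(sub["label"].dropna().unique())
    if len(present) < 2:
        return _flagged("fewer than two labels present")
    for lab in labels:
        if sub.loc[sub["label"] == lab, "subject_id"].nunique() < 2:
            return _flagged(f"fewer than two subjects with label {lab!r}")

    formula = "response ~ label + C(region) + C(sex) + age_at_death"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=sub, groups=sub["subject_id"])
            fit = model.fit(reml=True)
    except (np.linalg.LinAlgError, ValueError) as exc:
        return _flagged(f"mixed model failed: {exc}")
    term = f"label[T.{labels[1]}]"
    if term not in fit.params.index:
        return _flagged("rank-deficient design")
    flag = "" if fit.converged else "did not converge"
    return RegressionResult(
        contrast=labels, cluster=cluster, stain=stain,
        beta=float(fit.params[term]), se=float(fit.bse[term]),
        p=float(fit.pvalues[term]), p_adjusted=None,
        n_rows=len(sub), variant=variant, flag=flag,
    )


_PREDICTOR_LEVELS = {
    "sex": ("male", "female"),
    "apoe4": (False, True),
    "age_group": ("<65", "65-75", ">=75"),
}
_PREDICTOR_COLS = {"sex": "sex", "apoe4": "apoe4_carrier", "age_group": "age_group"}


def predictor_regression(
    frame: pd.DataFrame,
    cluster: str,
    stain: str,
    predictor: str,
    adjust: str = "none",
) -> list[RegressionResult]:
    """Covered area regressed on a demographic predictor within one cluster.

    ``predictor`` is sex, apoe4, or age_group (age groups compared
    pairwise); region always enters as a fixed effect; ``adjust`` optionally
    adds the remaining demographic covariates ('none', 'sex', 'age',
    'age_sex').
    """
    if predictor not in _PREDICTOR_LEVELS:
        raise ValueError(f"predictor must be one of {sorted(_PREDICTOR_LEVELS)}")
    col = _PREDICTOR_COLS[predictor]
    adjust_terms = {
        "none": "",
        "sex": " + C(sex)",
        "age": " + age_at_death",
        "age_sex": " + C(sex) + age_at_death",
    }
    if adjust not in adjust_terms:
        raise ValueError(f"adjust must be one of {sorted(adjust_terms)}")

    levels = _PREDICTOR_LEVELS[predictor]
    present = [lv for lv in levels if (frame[col] == lv).any()]
    if len(present) < 2:
        raise ValueError(f"predictor {predictor!r} has fewer than two levels present")

    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1:]]
    results = []
    for a, b in pairs:
        sub = frame[
            (frame["cluster"] == cluster) & (frame["stain"] == stain) & (frame[col].isin([a, b]))
        ].copy()
        sub["response"] = sub["covered_area_pct"] / 100.0
        sub["predictor"] = pd.Categorical(sub[col], categories=[a, b])
        formula = "response ~ predictor + C(region)" + adjust_terms[adjust]
        # drop the adjustment term that coincides with the predictor itself
        if predictor == "sex":
            formula = formula.replace(" + C(sex)", "")
        if predictor == "age_group":
            formula = formula.replace(" + age_at_death", "")
        fit = _fit_ols(sub, formula)
        term = f"predictor[T.{b}]"
        if term not in fit.params.index:
            results.append(RegressionResult((str(a), str(b)), cluster, stain, np.nan,
                                            np.nan, np.nan, None, len(sub),
                                            f"{predictor}:{adjust}", flag="rank-deficient design"))
            continue
        results.append(RegressionResult(
            contrast=(str(a), str(b)), cluster=cluster, stain=stain,
            beta=float(fit.params[term]), se=float(fit.bse[term]),
            p=float(fit.pvalues[term]), p_adjusted=None,
            n_rows=len(sub), variant=f"{predictor}:{adjust}",
        ))
    return results


def chisq_test(table) -> ContingencyResult:
    """Pearson chi-squared test of an r x c contingency table.

    Yates continuity correction is applied iff the table is 2x2 (the policy
    that reproduces the published demographic comparisons); larger tables
    use the plain Pearson statistic.
    """
    observed = np.asarray(table)
    if observed.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if (observed < 0).any():
        raise ValueError("counts must be non-negative")
    correction = observed.shape == (2, 2)
    res = sps.chi2_contingency(observed, correction=correction)
    return ContingencyResult(
        observed=observed, statistic=float(res.statistic), dof=int(res.dof),
        p=float(res.pvalue), continuity_correction=correction,
    )


def mann_whitney(x, y) -> RankTestResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return RankTestResult("mann_whitney_U", float(res.statistic), float(res.pvalue),
                          (x.size, y.size))


def kruskal_wallis(*groups) -> RankTestResult:
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    res = sps.kruskal(*arrays)
    return RankTestResult("kruskal_wallis_K", float(res.statistic), float(res.pvalue),
                          tuple(a.size for a in arrays))


def wilcoxon_signed_rank(x, y) -> RankTestResult:
    """Paired signed-rank test (duplicate-annotation reproducibility check).

    All-zero differences carry no evidence against symmetry; p is 1 by
    convention in that degenerate case.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("signed-rank test requires paired samples")
    if x.size == 0:
        raise ValueError("empty input")
    diffs = x - y
    if np.all(diffs == 0):
        return RankTestResult("wilcoxon_signed_rank", 0.0, 1.0, (x.size, y.size))
    res = sps.wilcoxon(x, y, zero_method="wilcox")
    return RankTestResult("wilcoxon_signed_rank", float(res.statistic), float(res.pvalue),
                          (x.size, y.size))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one analysis family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def summarize_clusters(frame: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Median [IQR] covered area (percent) per group x cluster with row counts."""
    if frame.empty:
        raise ValueError("empty analysis frame")
    out = (
        frame.groupby([group_col, "cluster", "stain"])["covered_area_pct"]
        .agg(n="size", median="median",
             q25=lambda v: float(np.percentile(v, 25)),
             q75=lambda v: float(np.percentile(v, 75)))
        .reset_index()
    )
    return out


def run_contrast_analysis(
    frame: pd.DataFrame,
    stain: str,
    labels: tuple[str, str],
    covariates: str = "age_sex",
    label_col: str = "group",
    clusters: tuple[str, ...] = ANALYSIS_CLUSTERS,
) -> pd.DataFrame:
    """One full contrast analysis: one OLS fit per cluster, BH-FDR across
    the cluster-level p-values (the analysis family)."""
    results = [
        fit_pairwise_cluster_regression(frame, cluster, stain, labels,
                                        covariates=covariates, label_col=label_col)
        for cluster in clusters
    ]
    rows = pd.DataFrame({
        "cluster": [r.cluster for r in results],
        "stain": stain,
        "contrast": [f"{r.contrast[0]} vs {r.contrast[1]}" for r in results],
        "variant": [r.variant for r in results],
        "beta": [r.beta for r in results],
        "se": [r.se for r in results],
        "p": [r.p for r in results],
        "n_rows": [r.n_rows for r in results],
        "flag": [r.flag for r in results],
    })
    ok = rows["flag"] == ""
    rows["p_fdr"] = np.nan
    if ok.any():
        rows.loc[ok, "p_fdr"] = fdr_adjust(rows.loc[ok, "p"].to_numpy())
    return rows


def _simulation_frame(
    rng: np.random.Generator,
    offset: float,
    n_subjects_per_arm: int = 20,
    n_regions: int = 4,
    baseline: float = 0.01,
    noise_sd: float = 0.005,
) -> pd.DataFrame:
    """One synthetic two-arm cluster dataset on the fraction scale.

    Demographics follow the cohort generator's marginals; arm 'g1' carries
    an additive covered-area offset (fraction scale) on top of the shared
    baseline.  Used by the calibration simulations below.
    """
    rows = []
    for i in range(2 * n_subjects_per_arm):
        arm = "g0" if i < n_subjects_per_arm else "g1"
        age = float(np.clip(rng.normal(72.8, 11.5), 40, 100))
        sex = "female" if rng.random() < 0.56 else "male"
        for r in range(n_regions):
            y = baseline + (offset if arm == "g1" else 0.0) + rng.normal(0, noise_sd)
            rows.append(dict(subject_id=f"s{i}", stain="alpha_syn", region=f"r{r}",
                             cluster="cortical", covered_area_pct=max(y, 0.0) * 100,
                             sex=sex, age_at_death=age, arm=arm))
    return pd.DataFrame(rows)


def type_one_error_simulation(
    n_replicates: int = 200, seed: int = 0, alpha: float = 0.05
) -> float:
    """Rejection rate of the pairwise cluster regression under a true null.

    Each replicate draws an independent two-arm dataset with zero effect
    (child streams spawned from one seed) and fits the age/sex-adjusted
    contrast; the rate should sit inside the binomial band around alpha.
    """
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rejections = 0
    for child in children:
        frame = _simulation_frame(np.random.default_rng(child), offset=0.0)
        res = fit_pairwise_cluster_regression(frame, "cortical", "alpha_syn",
                                              ("g0", "g1"), "age_sex", "arm")
        rejections += res.p < alpha
    return rejections / n_replicates


def effect_recovery_simulation(
    n_replicates: int = 100, seed: int = 0, offset: float = 0.01
) -> tuple[float, float]:
    """Sign and +/-2 SE coverage rates for a known additive effect.

    Returns (fraction with positive beta-hat, fraction with |beta-hat -
    offset| <= 2 SE) over seeded replicates.
    """
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    sign_hits = cover_hits = 0
    for child in children:
        frame = _simulation_frame(np.random.default_rng(child), offset=offset)
        res = fit_pairwise_cluster_regression(frame, "cortical", "alpha_syn",
                                              ("g0", "g1"), "age_sex", "arm")
        sign_hits += res.beta > 0
        cover_hits += abs(res.beta - offset) <= 2 * res.se
    return sign_hits / n_replicates, cover_hits / n_replicates


def significance_tier(p: float) -> str:
    """Significance marks at p < 0.05 (*), < 0.01 (**), < 0.001 (***)."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
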