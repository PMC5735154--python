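"""Group-, trial- and lesion-level statistics for choice-consistency studies.

The stages mirror a clinical lesion study's analysis plan:

* a linear mixed model of log-transformed intransitivity percentages on
  orthogonal group contrasts × task, with a random intercept per subject —
  the focal test is the (MTL vs both control groups) × task interaction;
* trial-level logistic regressions probing alternative accounts: does the
  position of a triple's last trial, or the spread (variance) of its trial
  positions, predict intransitivity, and do those effects differ for the
  lesion group;
* response-time analyses testing a speed-accuracy account: are trials that
  participate in intransitive triples faster or slower, and do groups differ
  in mean response time;
* an item-heterogeneity test (are specific items over-involved in cycles);
* the lesion stage: a lateral damage index LDI = |V_L − V_R| / (V_L + V_R)
  of left/right structure volumes, rank-correlated (Spearman) with each
  subject's intransitivity percentage.

Model fitting is delegated to statsmodels; design-matrix construction is
owned (and unit-tested) here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .transitivity import item_involvement

__all__ = [
    "LesionRecord",
    "ContrastScheme",
    "ModelResult",
    "CorrelationResult",
    "compute_ldi",
    "ldi_behavior_correlation",
    "laterality_comparison",
    "DEFAULT_LOG_OFFSET",
    "half_triplet_offset",
    "log_transform_scores",
    "variance_homogeneity_check",
    "build_contrasts",
    "build_group_task_design",
    "fit_group_task_model",
    "triplet_level_regressions",
    "rt_analyses",
    "item_involvement_counts",
    "item_involvement_test",
]


@dataclass(frozen=True)
class LesionRecord:
    """Left/right structure volumes and the derived lateral damage index."""

    subject_id: str
    vol_left: float
    vol_right: float
    ldi: float


@dataclass(frozen=True)
class ContrastScheme:
    """Orthogonal group contrasts: ETL vs CON, and MTL vs both controls."""

    codes: Mapping[str, tuple[float, float]]
    description: tuple[str, str] = (
        "ETL vs CON",
        "MTL vs mean(CON, ETL)",
    )


@dataclass(frozen=True)
class ModelResult:
    """One fitted model: one row per fixed-effect term.

    ``terms`` columns: term, estimate, stat, df, p.  ``description`` names
    the fitter and its statistic/df convention.
    """

    terms: pd.DataFrame
    description: str

    def estimate(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "estimate"])

    def p_value(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "p"])


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    stat: float
    p: float
    n: int


def compute_ldi(
    vol_left: float, vol_right: float, subject_id: str = ""
) -> LesionRecord:
    """Lateral damage index |V_L − V_R| / (V_L + V_R) of paired volumes.

    Symmetric under swapping sides; 0 iff the volumes are equal; < 1 for
    positive volumes.
    """
    if vol_left <= 0 or vol_right <= 0:
        raise ValueError(
            f"volumes must be positive, got left={vol_left}, right={vol_right}"
        )
    ldi = abs((vol_left - vol_right) / (vol_left + vol_right))
    return LesionRecord(
        subject_id=subject_id, vol_left=vol_left, vol_right=vol_right, ldi=ldi
    )


def _as_frames(
    records: Sequence[LesionRecord] | pd.DataFrame,
    scores: pd.DataFrame,
) -> pd.DataFrame:
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ for r in records])
    rec_ids = set(records["subject_id"])
    sc_ids = set(scores["subject_id"])
    orphans = sorted(rec_ids ^ (rec_ids & sc_ids))
    missing = sorted(rec_ids - sc_ids)
    if missing:
        raise KeyError(f"lesion records without matching scores: {missing}")
    return records.merge(
        scores[["subject_id", "pct_intransitive"]], on="subject_id", how="inner"
    )


def ldi_behavior_correlation(
    records: Sequence[LesionRecord] | pd.DataFrame,
    scores: pd.DataFrame,
) -> CorrelationResult:
    """Spearman rank correlation between LDI and intransitivity percentage.

    Two-tailed; ties handled by midranks.  ``scores`` must carry a matching
    row (subject_id, pct_intransitive) for every lesion record.
    """
    merged = _as_frames(records, scores)
    n = len(merged)
    if n < 4:
        raise ValueError(f"need at least 4 matched subjects, got {n}")
    rho, p = scipy.stats.spearmanr(merged["ldi"], merged["pct_intransitive"])
    rho = float(rho)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
    return CorrelationResult(rho=rho, stat=float(t), p=float(p), n=n)


def laterality_comparison(
    lesions: pd.DataFrame, scores: pd.DataFrame
) -> ModelResult:
    """Two-sample comparison of intransitivity by atrophied side (left/right).

    A generic Welch-free pooled t-test stage; with the small samples such
    subsets typically offer it is descriptive rather than confirmatory.
    """
    merged = lesions.merge(scores[["subject_id", "pct_intransitive"]], on="subject_id")
    left = merged.loc[merged["side"] == "left", "pct_intransitive"]
    right = merged.loc[merged["side"] == "right", "pct_intransitive"]
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need at least 2 subjects per side")
    t, p = scipy.stats.ttest_ind(left, right)
    df = len(left) + len(right) - 2
    terms = pd.DataFrame(
        {
            "term": ["left_minus_right"],
            "estimate": [float(left.mean() - right.mean())],
            "stat": [float(t)],
            "df": [float(df)],
            "p": [float(p)],
        }
    )
    return ModelResult(terms=terms, description="pooled two-sample t-test")


#: Default offset (percentage points) added before the log transform.
#: One full percentage point keeps zero scores finite *without* stretching
#: them into extreme outliers: with an offset near the statistic's
#: resolution (e.g. half a triple, ~0.04pp for 20 items), log(0 + c) sits
#: 3+ log-units below typical scores, and the transform amplifies the very
#: variance inequality it is meant to remove.
DEFAULT_LOG_OFFSET = 1.0


def half_triplet_offset(n_items: int = 20) -> float:
    """Alternative offset policy: half of one triple, 100 / (2·C(n, 3)).

    The smallest meaningful resolution of the statistic; available for
    sensitivity analyses via the ``offset`` argument of
    :func:`log_transform_scores`.
    """
    return 100.0 / (2 * comb(n_items, 3))


def log_transform_scores(
    pct: np.ndarray | pd.Series, offset: float | None = None
) -> tuple[np.ndarray, float]:
    """Natural log of (percentage + offset); returns (values, offset used)."""
    off = DEFAULT_LOG_OFFSET if offset is None else float(offset)
    vals = np.asarray(pct, dtype=float)
    if np.any(vals < 0):
        raise ValueError("percentages must be nonnegative")
    return np.log(vals + off), off


def variance_homogeneity_check(
    values_by_group: Mapping[str, np.ndarray | Sequence[float]],
) -> tuple[float, int, float]:
    """Bartlett's test of equal variances across groups: (K², df, p)."""
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        if np.var(arr) == 0:
            raise ValueError(f"group {name!r} has zero variance")
        arrays[name] = arr
    k2, p = scipy.stats.bartlett(*arrays.values())
    return float(k2), len(arrays) - 1, float(p)


def build_contrasts(groups: Sequence[str] = ("CON", "ETL", "MTL")) -> ContrastScheme:
    """Orthogonal contrasts: (ETL − CON) and (MTL − mean of CON, ETL).

    Each contrast's weights sum to zero and the two are orthogonal under
    equal weighting.
    """
    if sorted(groups) != ["CON", "ETL", "MTL"]:
        raise ValueError(f"expected groups CON, ETL, MTL; got {sorted(groups)}")
    return ContrastScheme(
        codes={"CON": (-1.0, -0.5), "ETL": (1.0, -0.5), "MTL": (0.0, 1.0)}
    )


def build_group_task_design(
    scores: pd.DataFrame, scheme: ContrastScheme | None = None
) -> pd.DataFrame:
    """Fixed-effects design matrix for the group × task model.

    Requires one row per subject×task with columns subject_id, group, task.
    Task is centered (+0.5 preference, −0.5 number), so contrast main effects
    are averages over tasks and interactions are task differences.
    """
    scheme = scheme or build_contrasts()
    unknown = set(scores["group"]) - set(scheme.codes)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    bad_task = set(scores["task"]) - {"preference", "number"}
    if bad_task:
        raise ValueError(f"unknown task label(s): {sorted(bad_task)}")
    per_subject = scores.groupby("subject_id")["task"].nunique()
    if (per_subject < 2).any():
        missing = per_subject[per_subject < 2].index.tolist()
        raise ValueError(
            f"each subject must contribute both tasks; incomplete: {missing}"
        )
    c1 = scores["group"].map({g: c[0] for g, c in scheme.codes.items()})
    c2 = scores["group"].map({g: c[1] for g, c in scheme.codes.items()})
    task = scores["task"].map({"preference": 0.5, "number": -0.5})
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "etl_vs_con": c1.astype(float),
            "mtl_vs_controls": c2.astype(float),
            "task": task.astype(float),
            "etl_vs_con:task": (c1 * task).astype(float),
            "mtl_vs_controls:task": (c2 * task).astype(float),
        },
        index=scores.index,
    )
    return design


def fit_group_task_model(
    scores: pd.DataFrame,
    offset: float | None = None,
) -> ModelResult:
    """Mixed model: log(pct + offset) ~ contrasts × task + (1 | subject).

    ``scores`` needs one row per subject×task with columns subject_id,
    group, task, pct_intransitive.  The focal term is
    ``mtl_vs_controls:task`` — whether the MTL group's preference-vs-control
    gap exceeds that of both control groups.  P-values use the large-sample
    Wald z of the mixed-model fitter.
    """
    endog, off = log_transform_scores(scores["pct_intransitive"], offset)
    exog = build_group_task_design(scores)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=scores["subject_id"])
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError:
            # near-zero random-intercept variance can defeat the default
            # optimizer; Powell is gradient-free and robust at the boundary
            res = model.fit(reml=True, method="powell")
    k = exog.shape[1]
    terms = pd.DataFrame(
        {
            "term": exog.columns,
            "estimate": res.fe_params.to_numpy(),
            "stat": res.tvalues.to_numpy()[:k],
            "df": np.nan,
            "p": res.pvalues.to_numpy()[:k],
        }
    )
    return ModelResult(
        terms=terms,
        description=(
            "linear mixed model (random intercept per subject), REML, "
            f"Wald z p-values; log offset {off:.6g} percentage points"
        ),
    )


def _zscore(x: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=0))
    if sd == 0:
        raise ZeroDivisionError(name)
    return (x - mu) / sd, mu, sd


def _cluster_logit(
    y: np.ndarray, X: pd.DataFrame, clusters: pd.Series, description: str
) -> ModelResult:
    if y.all() or not y.any():
        raise ValueError(
            "outcome is constant (complete separation); need both transitive "
            "and intransitive triples — enlarge the sample or raise the noise"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y.astype(float), X, family=sm.families.Binomial())
        res = model.fit(
            cov_type="cluster",
            cov_kwds={"groups": pd.Categorical(clusters).codes},
        )
    terms = pd.DataFrame(
        {
            "term": X.columns,
            "estimate": res.params.to_numpy(),
            "stat": res.tvalues.to_numpy(),
            "df": np.nan,
            "p": res.pvalues.to_numpy(),
        }
    )
    return ModelResult(terms=terms, description=description)


def triplet_level_regressions(
    triplets: pd.DataFrame,
    features: Sequence[str] = ("last_trial_index", "trial_index_variance"),
) -> dict[str, ModelResult]:
    """Logistic regressions of intransitivity on trial-position features.

    For each feature: is_intransitive ~ z(feature) + MTL + z(feature):MTL,
    with cluster-robust (by subject) standard errors.  ``triplets`` is the
    triple-level table from :func:`intransit.transitivity.triplet_table`
    with a ``group`` column.  Predictors are z-scored; the scaling is
    recorded in the result description.
    """
    out: dict[str, ModelResult] = {}
    y = triplets["is_intransitive"].to_numpy(dtype=bool)
    mtl = (triplets["group"] == "MTL").to_numpy(dtype=float)
    for feat in features:
        z, mu, sd = _zscore(triplets[feat].to_numpy(dtype=float), feat)
        X = pd.DataFrame(
            {"intercept": 1.0, feat: z, "mtl": mtl, f"{feat}:mtl": z * mtl},
            index=triplets.index,
        )
        out[feat] = _cluster_logit(
            y,
            X,
            triplets["subject_id"],
            description=(
                "logistic regression, cluster-robust (by subject) SE; "
                f"{feat} z-scored (mean {mu:.4g}, sd {sd:.4g})"
            ),
        )
    return out


def rt_analyses(
    trials: pd.DataFrame, scheme: ContrastScheme | None = None
) -> tuple[ModelResult, ModelResult]:
    """Response-time stages: involvement regression and group RT comparison.

    (a) logistic regression of intransitive-triple involvement on z-scored
    RT with a quadratic RT term and MTL/ETL interactions, cluster-robust by
    subject — a positive RT coefficient contradicts a speed-accuracy
    account; (b) OLS of subject-mean RT on the orthogonal group contrasts.
    ``trials`` must carry subject_id, group, rt and an ``involved`` flag
    (see :func:`intransit.transitivity.trial_involvement`).  Trials with
    missing RT are excluded with their count reported in the description.
    """
    scheme = scheme or build_contrasts()
    n_total = len(trials)
    trials = trials.dropna(subset=["rt"])
    n_dropped = n_total - len(trials)
    note = f"; {n_dropped} trial(s) without RT excluded" if n_dropped else ""
    y = trials["involved"].to_numpy(dtype=bool)
    mtl = (trials["group"] == "MTL").to_numpy(dtype=float)
    etl = (trials["group"] == "ETL").to_numpy(dtype=float)
    try:
        zrt, mu, sd = _zscore(trials["rt"].to_numpy(dtype=float), "rt")
    except ZeroDivisionError:
        warnings.warn(
            "response times are constant; RT coefficients degenerate to 0",
            stacklevel=2,
        )
        terms = pd.DataFrame(
            {
                "term": ["intercept", "rt", "rt2", "mtl", "rt:mtl", "rt2:etl"],
                "estimate": [float(np.log(y.mean() / (1 - y.mean()))), 0, 0, 0, 0, 0],
                "stat": np.nan,
                "df": np.nan,
                "p": np.nan,
            }
        )
        involvement = ModelResult(
            terms=terms, description="degenerate: zero RT variance" + note
        )
    else:
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "rt": zrt,
                "rt2": zrt**2,
                "mtl": mtl,
                "rt:mtl": zrt * mtl,
                "rt2:etl": zrt**2 * etl,
            },
            index=trials.index,
        )
        involvement = _cluster_logit(
            y,
            X,
            trials["subject_id"],
            description=(
                "logistic involvement regression, cluster-robust (by subject) "
                f"SE; rt z-scored (mean {mu:.4g} s, sd {sd:.4g} s)" + note
            ),
        )

    subj = (
        trials.groupby(["subject_id", "group"], as_index=False)["rt"].mean()
    )
    c1 = subj["group"].map({g: c[0] for g, c in scheme.codes.items()})
    c2 = subj["group"].map({g: c[1] for g, c in scheme.codes.items()})
    X2 = pd.DataFrame(
        {"intercept": 1.0, "etl_vs_con": c1.astype(float),
         "mtl_vs_controls": c2.astype(float)}
    )
    ols = sm.OLS(subj["rt"].to_numpy(), X2).fit()
    group_rt = ModelResult(
        terms=pd.DataFrame(
            {
                "term": X2.columns,
                "estimate": ols.params.to_numpy(),
                "stat": ols.tvalues.to_numpy(),
                "df": float(ols.df_resid),
                "p": ols.pvalues.to_numpy(),
            }
        ),
        description="OLS of subject-mean RT (s) on orthogonal group contrasts",
    )
    return involvement, group_rt


def item_involvement_counts(triplets: pd.DataFrame, n_items: int) -> pd.DataFrame:
    """Long table of per-subject×item intransitive-triple counts."""
    rows = []
    for sid, sub in triplets.groupby("subject_id", sort=True):
        counts = item_involvement(sub, n_items)
        rows.extend(
            {"subject_id": sid, "item": i + 1, "count": int(c)}
            for i, c in enumerate(counts)
        )
    return pd.DataFrame(rows)


def item_involvement_test(counts: pd.DataFrame) -> tuple[float, tuple[int, int], float]:
    """Item-heterogeneity F-test of intransitive-triple involvement.

    Randomized-block one-way ANOVA: counts ~ item + subject, F-testing the
    item factor against the residual with df = (I−1, (I−1)(S−1)).  Subjects
    are blocks, which absorbs between-subject differences in overall
    inconsistency.
    """
    items = counts["item"].unique()
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    wide = counts.pivot(index="subject_id", columns="item", values="count").to_numpy(
        dtype=float
    )
    S, I = wide.shape
    grand = wide.mean()
    item_means = wide.mean(axis=0)
    subj_means = wide.mean(axis=1)
    ss_item = S * ((item_means - grand) ** 2).sum()
    resid = wide - item_means[None, :] - subj_means[:, None] + grand
    ss_err = (resid**2).sum()
    df1, df2 = I - 1, (I - 1) * (S - 1)
    if ss_item == 0:  # identical item means: no heterogeneity by definition
        return 0.0, (df1, df2), 1.0
    f = (ss_item / df1) / (ss_err / df2)
    p = float(scipy.stats.f.sf(f, df1, df2))
    return float(f), (df1, df2), p
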