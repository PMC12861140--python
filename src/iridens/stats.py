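"""Association layer: correlations, mixed models and the pigmentation bias.

Study data arrive as one row per eye (a *study table*: ``subject_id``,
``eye_id``, ``cd``, artefact percentages, ``iris_color``,
``pigment_class``).  Because many participants contribute both eyes,
fellow-eye rows are correlated; plain Pearson correlations are therefore
paired with linear mixed-effects models (LMMs) carrying a per-subject
random intercept.  The fixed-effect coefficient beta is the expected change
in the response per unit of the predictor after absorbing between-subject
differences.  Estimation is by REML with Wald z p-values.

The light-vs-dark comparison reports per-group means and SDs, LMM p-values
per outcome, and the headline bias: the absolute light-minus-dark CD
difference and its size relative to the dark-group mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .errors import (
    DegenerateVariance,
    EmptyGroup,
    LengthMismatch,
    NonpositiveReference,
    TooFewSubjects,
)

__all__ = [
    "AssociationResult",
    "GroupComparison",
    "pearson_correlation",
    "fit_lmm",
    "compare_groups",
    "bias_summary",
    "association_table",
]

OUTCOMES = ("cd", "pct_iris", "pct_lateral", "pct_overall")


@dataclass(frozen=True)
class AssociationResult:
    """Pearson r and LMM slope for one response~predictor pair."""

    response: str
    predictor: str
    r: float
    p_r: float
    beta: float
    p_beta: float
    n: int
    n_subjects: int
    singular: bool  # random-intercept variance collapsed to ~0


@dataclass(frozen=True)
class GroupComparison:
    """Light-vs-dark group summary across the densitometry outcomes.

    ``means``/``sds`` map outcome -> {"light": x, "dark": y}; ``p_values``
    holds the LMM group-effect p per outcome.  ``delta_cd`` is the
    light-minus-dark difference of mean CD and ``relative_bias`` expresses
    it as a percentage of the dark-group mean (the reference group).
    """

    n_light: int
    n_dark: int
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    delta_cd: float = float("nan")
    relative_bias: float = float("nan")


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise LengthMismatch(f"lengths differ: {x.size} vs {y.size}")
    if x.size < 3:
        raise LengthMismatch("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateVariance("zero variance in a correlation input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _fit_mixedlm(records: pd.DataFrame, response: str, predictor: str):
    """REML MixedLM fit with subject random intercept; returns
    (beta, p_beta, singular)."""
    data = records[[response, predictor, "subject_id"]].dropna()
    if data["subject_id"].nunique() < 3:
        raise TooFewSubjects("need at least 3 subjects for a mixed model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            f"{response} ~ {predictor}", data, groups=data["subject_id"]
        )
        fit = model.fit(reml=True)
    beta = float(fit.params[predictor])
    p_beta = float(fit.pvalues[predictor])
    resid_var = float(fit.scale)
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    # a boundary fit: either variance component collapsed to ~0 (the
    # random intercept is redundant, or it absorbs all residual variance)
    total = max(resid_var + re_var, 1e-300)
    singular = min(resid_var, re_var) <= 1e-6 * total
    return beta, p_beta, singular


def fit_lmm(
    records: pd.DataFrame, response: str, predictor: str
) -> AssociationResult:
    """Mixed-model slope plus pooled Pearson r for one variable pair.

    Fits ``response ~ predictor`` with a per-subject random intercept
    (REML).  ``singular=True`` flags (non-fatally) that the intercept
    variance collapsed to zero, in which case the slope coincides with
    ordinary least squares.
    """
    beta, p_beta, singular = _fit_mixedlm(records, response, predictor)
    r, p_r = pearson_correlation(records[response], records[predictor])
    return AssociationResult(
        response=response,
        predictor=predictor,
        r=r,
        p_r=p_r,
        beta=beta,
        p_beta=p_beta,
        n=len(records),
        n_subjects=records["subject_id"].nunique(),
        singular=singular,
    )


def bias_summary(mean_light: float, mean_dark: float) -> tuple[float, float]:
    """Absolute and relative light-vs-dark CD bias.

    Returns ``(delta, relative)`` with ``delta = mean_light - mean_dark``
    (a.u.) and ``relative = 100 * delta / mean_dark`` (%), the dark-iris
    group serving as the reference.
    """
    if mean_dark <= 0:
        raise NonpositiveReference("dark-group mean must be positive")
    delta = mean_light - mean_dark
    return delta, 100.0 * delta / mean_dark


def compare_groups(
    records: pd.DataFrame, outcomes: tuple[str, ...] = OUTCOMES
) -> GroupComparison:
    """Light-vs-dark comparison of CD and artefact outcomes.

    Rows with ``pigment_class == "indeterminate"`` are excluded.  Per
    outcome: group mean and SD, plus the p-value of the group fixed effect
    in an LMM with subject random intercept.  The CD bias summary uses the
    group means directly.
    """
    data = records[records["pigment_class"].isin(["light", "dark"])].copy()
    n_light = int((data["pigment_class"] == "light").sum())
    n_dark = int((data["pigment_class"] == "dark").sum())
    if n_light == 0 or n_dark == 0:
        raise EmptyGroup(f"n_light={n_light}, n_dark={n_dark}")
    data["is_light"] = (data["pigment_class"] == "light").astype(float)

    means: dict = {}
    sds: dict = {}
    p_values: dict = {}
    for outcome in outcomes:
        grp = data.groupby("pigment_class")[outcome]
        means[outcome] = {
            "light": float(grp.mean()["light"]),
            "dark": float(grp.mean()["dark"]),
        }
        sds[outcome] = {
            "light": float(grp.std(ddof=1)["light"]),
            "dark": float(grp.std(ddof=1)["dark"]),
        }
        _, p, _ = _fit_mixedlm(data, outcome, "is_light")
        p_values[outcome] = p

    if "cd" in means:
        delta_cd, relative = bias_summary(means["cd"]["light"], means["cd"]["dark"])
    else:
        delta_cd, relative = float("nan"), float("nan")
    return GroupComparison(
        n_light=n_light,
        n_dark=n_dark,
        means=means,
        sds=sds,
        p_values=p_values,
        delta_cd=delta_cd,
        relative_bias=relative,
    )


def association_table(records: pd.DataFrame) -> pd.DataFrame:
    """The three headline associations as a tidy frame.

    CD ~ % iris brightness, % iris brightness ~ IrisColor and
    CD ~ IrisColor, each with pooled Pearson r and the mixed-model slope.
    """
    pairs = [
        ("cd", "pct_iris"),
        ("pct_iris", "iris_color"),
        ("cd", "iris_color"),
    ]
    rows = []
    for response, predictor in pairs:
        res = fit_lmm(records, response, predictor)
        rows.append(
            {
                "response": response,
                "predictor": predictor,
                "r": res.r,
                "p_r": res.p_r,
                "beta": res.beta,
                "p_beta": res.p_beta,
                "n": res.n,
                "singular": res.singular,
            }
        )
    return pd.DataFrame(rows)
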