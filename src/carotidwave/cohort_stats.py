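"""Longitudinal cohort statistics: mixed models, releveling, ROC screening.

Each vascular metric is modelled with a linear mixed-effects model —
genotype (control, dcr), biological sex, imaging age and arterial side as
fixed effects (interactions configurable) and a per-mouse random intercept
for the repeated measures.  Post-hoc simple effects are obtained by
releveling: refitting with a different reference level so the within-level
contrast of interest appears directly as a coefficient, leaving the fit
(log-likelihood) unchanged.

Fixed-effect p-values use the Wald normal approximation on the REML
estimates.  With cohort-scale mouse numbers this is mildly
anti-conservative; the simulation utilities in this package make that
calibration measurable rather than hidden.

ROC analysis evaluates every midpoint between sorted unique values (plus
±∞), computes empirical sensitivity/specificity, the trapezoidal AUC
(equal to the Mann–Whitney statistic), and the Youden-optimal cut-off
J = max(sensitivity + specificity − 1), ties broken toward the lower
cut-off.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "LmmResult",
    "RocResult",
    "fit_lmm",
    "relevel_posthoc",
    "genotype_effect",
    "roc_analysis",
    "day50_biomarker_screen",
    "correlation",
]

DEFAULT_FIXED_SPEC = "genotype * sex * age + side"
FACTOR_COLUMNS = {"genotype": "genotype", "sex": "sex", "age": "age_days",
                  "side": "side"}


@dataclass
class LmmResult:
    """A fitted linear mixed-effects model for one outcome."""

    outcome: str
    formula: str
    coefficients: pd.DataFrame  #: index term; columns estimate, se, z, p
    random_intercept_var: float
    llf: float
    n_obs: int
    n_groups: int
    converged: bool
    refs: dict = field(default_factory=dict)
    fixed_spec: str = DEFAULT_FIXED_SPEC
    categorical_age: bool = True
    table: pd.DataFrame | None = field(default=None, repr=False)

    def validate(self) -> None:
        p = self.coefficients["p"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        if self.n_obs < self.n_groups:
            raise ValueError("more mice than observations")
        if self.random_intercept_var < 0:
            raise ValueError("random-intercept variance must be non-negative")


def _default_refs(table: pd.DataFrame) -> dict:
    return {
        "genotype": "control",
        "sex": "F",
        "age": int(table["age_days"].min()),
        "side": "LCCA",
    }


def _build_formula(outcome, fixed_spec, refs, categorical_age):
    mapping = {
        "genotype": f"C(genotype, Treatment('{refs['genotype']}'))",
        "sex": f"C(sex, Treatment('{refs['sex']}'))",
        "side": f"C(side, Treatment('{refs['side']}'))",
        "age": (f"C(age_days, Treatment({refs['age']}))"
                if categorical_age else "age_days"),
    }
    rhs = fixed_spec
    for key, repl in mapping.items():
        rhs = re.sub(rf"\b{key}\b", repl, rhs)
    return f"Q('{outcome}') ~ {rhs}"


def fit_lmm(
    table: pd.DataFrame,
    outcome: str,
    fixed_spec: str = DEFAULT_FIXED_SPEC,
    refs: dict | None = None,
    categorical_age: bool = True,
    reml: bool = True,
) -> LmmResult:
    """Fit a per-mouse random-intercept model for one outcome.

    ``fixed_spec`` is a formula fragment over the factor names ``genotype``,
    ``sex``, ``age``, ``side`` (e.g. ``"genotype * sex * age + side"`` or the
    body-weight variant ``"genotype * sex * age"`` without side).  ``refs``
    sets the reference level per factor (releveling = refitting with a
    different ``refs``).  Rows with a missing outcome are dropped
    (complete-case analysis); Wald normal p-values are reported per
    coefficient.
    """
    refs = {**_default_refs(table), **(refs or {})}
    used_factors = [c for f, c in FACTOR_COLUMNS.items()
                    if re.search(rf"\b{f}\b", fixed_spec)]
    data = table.dropna(subset=[outcome, "mouse_id", *used_factors]).copy()
    for factor in ("genotype", "sex", "side"):
        col = FACTOR_COLUMNS[factor]
        if col in data.columns and re.search(rf"\b{factor}\b", fixed_spec):
            if data[col].nunique() < 2:
                raise ValueError(f"factor {factor!r} needs at least 2 levels")

    formula = _build_formula(outcome, fixed_spec, refs, categorical_age)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["mouse_id"])
        res = model.fit(reml=reml)

    est = res.fe_params
    se = res.bse_fe
    z = est / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    coefficients = pd.DataFrame(
        {"estimate": est, "se": se, "z": z, "p": p}
    )
    out = LmmResult(
        outcome=outcome,
        formula=formula,
        coefficients=coefficients,
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
        llf=float(res.llf),
        n_obs=int(res.nobs),
        n_groups=data["mouse_id"].nunique(),
        converged=bool(res.converged),
        refs=refs,
        fixed_spec=fixed_spec,
        categorical_age=categorical_age,
        table=table,
    )
    out.validate()
    return out


def relevel_posthoc(result: LmmResult, factor: str, new_ref) -> LmmResult:
    """Refit with ``factor``'s reference level changed.

    Simple (within-level) effects can then be read directly from the
    releveled coefficient table.  Releveling reparameterizes but does not
    change the fit: the log-likelihood is identical.
    """
    if result.table is None:
        raise ValueError("result does not carry its data; refit with fit_lmm")
    if factor not in FACTOR_COLUMNS:
        raise ValueError(f"unknown factor {factor!r}")
    refs = {**result.refs, factor: new_ref}
    return fit_lmm(
        result.table,
        result.outcome,
        fixed_spec=result.fixed_spec,
        refs=refs,
        categorical_age=result.categorical_age,
    )


def genotype_effect(result: LmmResult) -> pd.Series:
    """The genotype main-term coefficient row (the simple effect of dcr vs
    the genotype reference at the reference levels of the other factors)."""
    names = [n for n in result.coefficients.index
             if n.startswith("C(genotype") and ":" not in n]
    if len(names) != 1:
        raise ValueError(f"expected one genotype main term, found {names}")
    return result.coefficients.loc[names[0]]


# --------------------------------------------------------------------------
# ROC / Youden
# --------------------------------------------------------------------------


@dataclass
class RocResult:
    """Empirical ROC curve with trapezoidal AUC and Youden cut-off."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    orientation: str  #: 'greater' → positive class called at value ≥ cut-off
    positive_label: object = "dcr"

    def validate(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC out of [0, 1]")
        for a in (self.sensitivity, self.specificity):
            if ((a < -1e-12) | (a > 1 + 1e-12)).any():
                raise ValueError("sensitivity/specificity out of [0, 1]")


def _roc_curves(pos: np.ndarray, neg: np.ndarray, thresholds: np.ndarray,
                orientation: str):
    """Sensitivity/specificity per threshold for one orientation."""
    pos = np.sort(pos)
    neg = np.sort(neg)
    if orientation == "greater":  # call positive when value >= threshold
        sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / len(pos)
        spec = np.searchsorted(neg, thresholds, side="left") / len(neg)
    else:  # call positive when value <= threshold
        sens = np.searchsorted(pos, thresholds, side="right") / len(pos)
        spec = 1.0 - np.searchsorted(neg, thresholds, side="right") / len(neg)
    return sens, spec


def _trapezoid_auc(sens: np.ndarray, spec: np.ndarray, orientation: str) -> float:
    # traverse the curve in threshold order so that FPR is monotone
    # (descending thresholds for 'greater', ascending for 'less')
    fpr = 1.0 - spec
    if orientation == "greater":
        sens, fpr = sens[::-1], fpr[::-1]
    return float(np.trapezoid(sens, fpr))


def roc_analysis(values, labels, positive="dcr") -> RocResult:
    """Empirical ROC of ``values`` for discriminating ``positive`` cases.

    Thresholds are the midpoints between sorted unique values plus ±∞.  The
    orientation (whether the positive class lies above or below the
    cut-off) is chosen so AUC ≥ 0.5 and recorded.  The AUC is the
    trapezoidal area, which equals the Mann–Whitney U statistic divided by
    n₁·n₂ (ties counted half).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive
    if is_pos.all() or (~is_pos).all():
        raise ValueError("both classes must be non-empty")
    pos, neg = values[is_pos], values[~is_pos]

    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])

    sens_g, spec_g = _roc_curves(pos, neg, thresholds, "greater")
    auc_g = _trapezoid_auc(sens_g, spec_g, "greater")
    if auc_g >= 0.5:
        orientation, sens, spec, auc = "greater", sens_g, spec_g, auc_g
    else:
        sens, spec = _roc_curves(pos, neg, thresholds, "less")
        orientation = "less"
        auc = _trapezoid_auc(sens, spec, "less")

    j = sens + spec - 1.0
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])  # lower cut-off wins
    out = RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=float(thresholds[best]),
        youden_j=float(j[best]),
        orientation=orientation,
        positive_label=positive,
    )
    out.validate()
    return out


# --------------------------------------------------------------------------
# pre-symptomatic biomarker screen
# --------------------------------------------------------------------------


def day50_biomarker_screen(
    table: pd.DataFrame,
    metrics=None,
    alpha: float = 0.05,
    fixed_spec: str = DEFAULT_FIXED_SPEC,
    stratified: bool = False,
    positive: str = "dcr",
    fdr: bool = False,
) -> pd.DataFrame:
    """Screen metrics for pre-symptomatic (earliest-age) genotype differences.

    Per sex and metric, the genotype simple effect at the earliest imaging
    age is read from the releveled full model (or, with ``stratified=True``,
    from a per-sex refit of ``genotype * age + side``).  Metrics significant
    at ``alpha`` get an ROC analysis of the per-mouse earliest-age values
    (averaged across sides), yielding an AUC and Youden cut-off.

    No multiple-testing correction is applied by default; ``fdr=True``
    applies Benjamini–Hochberg across the screened tests before gating.
    """
    age0 = table["age_days"].min()
    if metrics is None:
        reserved = {"mouse_id", "genotype", "sex", "age_days", "side", "arrhythmic"}
        metrics = [c for c in table.columns
                   if c not in reserved and pd.api.types.is_numeric_dtype(table[c])]

    rows = []
    for metric in metrics:
        for sex in sorted(table["sex"].unique()):
            if stratified:
                sub = table[table["sex"] == sex]
                fit = fit_lmm(sub, metric, fixed_spec="genotype * age + side",
                              refs={"age": int(age0)})
            else:
                fit = fit_lmm(table, metric, fixed_spec=fixed_spec,
                              refs={"sex": sex, "age": int(age0)})
            eff = genotype_effect(fit)
            rows.append({
                "metric": metric,
                "sex": sex,
                "estimate": float(eff["estimate"]),
                "p_value": float(eff["p"]),
                "converged": fit.converged,
            })
    report = pd.DataFrame(rows)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        report["p_adjusted"] = multipletests(report["p_value"],
                                             method="fdr_bh")[1]
    else:
        report["p_adjusted"] = report["p_value"]
    report["significant"] = (report["p_adjusted"] < alpha) & report["converged"]
    report["direction"] = np.where(report["estimate"] > 0, "increase",
                                   "decrease")
    report["auc"] = np.nan
    report["youden_cutoff"] = np.nan
    report["orientation"] = ""
    for i, row in report[report["significant"]].iterrows():
        day0 = table[(table["age_days"] == age0) & (table["sex"] == row["sex"])]
        per_mouse = day0.groupby(["mouse_id", "genotype"], observed=True)[
            row["metric"]].mean().reset_index()
        roc = roc_analysis(per_mouse[row["metric"]], per_mouse["genotype"],
                           positive=positive)
        report.loc[i, ["auc", "youden_cutoff", "orientation"]] = (
            roc.auc, roc.youden_cutoff, roc.orientation)
    return report


def correlation(table: pd.DataFrame, x: str, y: str):
    """Pearson correlation between two metric columns (complete cases)."""
    data = table.dropna(subset=[x, y])
    r, p = sps.pearsonr(data[x], data[y])
    return float(r), float(p)
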