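"""Association statistics for response analyses.

Univariable logistic regression odds ratios with Wald confidence intervals and
Benjamini-Hochberg FDR, proportional-odds (ordinal logistic) trend tests over
the ordered residual-cancer-burden classes, and two-sided Wilcoxon rank-sum
comparisons against the complete-response group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.discrete.discrete_model import Logit
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

#: Ordered response classes, best to worst.
RCB_ORDER = ("pCR", "RCB-I", "RCB-II", "RCB-III")


@dataclass
class AssociationResult:
    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float | None = None
    separated: bool = False

    @property
    def direction(self) -> str:
        return "toward_pCR" if self.odds_ratio > 1 else "toward_residual_disease"


@dataclass
class OrdinalTrendResult:
    feature: str
    coefficient: float
    se: float
    p_value: float  # likelihood-ratio test vs intercept-only


def univariable_logistic(
    feature: np.ndarray | pd.Series, outcome: np.ndarray | pd.Series, name: str = ""
) -> AssociationResult:
    """Maximum-likelihood logistic fit of a binary outcome on one feature.

    Returns the odds ratio per unit of the feature with a Wald 95% CI and
    two-sided p-value.  Complete or quasi-complete separation (or a constant
    feature) yields a flagged result with infinite OR and NaN p, which is
    excluded from FDR adjustment by default.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.std(x) == 0:
        return AssociationResult(name, np.inf, np.nan, np.nan, np.nan, separated=True)
    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = Logit(y, X).fit(disp=False, maxiter=200)
        except Exception:
            return AssociationResult(name, np.inf, np.nan, np.nan, np.nan,
                                     separated=True)
    coef, se = fit.params[1], fit.bse[1]
    # quasi-separation blows up the SE; judge on the standardized scale so
    # features measured in tiny units are not misflagged
    if not np.isfinite(se) or se * np.std(x) > 50:
        return AssociationResult(name, np.inf, np.nan, np.nan, np.nan, separated=True)
    z = sps.norm.ppf(0.975)
    return AssociationResult(
        feature=name,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_value=float(fit.pvalues[1]),
    )


def multivariable_logistic(
    X: pd.DataFrame, outcome: np.ndarray | pd.Series
) -> list[AssociationResult]:
    """Single multiple-logistic fit; per-covariate ORs with Wald CIs."""
    y = np.asarray(outcome, dtype=float)
    mat = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float) for c in X.columns])
    fit = Logit(y, mat).fit(disp=False, maxiter=200)
    z = sps.norm.ppf(0.975)
    out = []
    for i, c in enumerate(X.columns, start=1):
        coef, se = fit.params[i], fit.bse[i]
        out.append(
            AssociationResult(
                feature=c,
                odds_ratio=float(np.exp(coef)),
                ci_low=float(np.exp(coef - z * se)),
                ci_high=float(np.exp(coef + z * se)),
                p_value=float(fit.pvalues[i]),
            )
        )
    return out


def encode_rcb(labels: pd.Series | np.ndarray, order: tuple[str, ...] = RCB_ORDER):
    """Map RCB class labels to ordinal codes 0 (pCR, best) .. 3 (RCB-III)."""
    mapping = {cls: i for i, cls in enumerate(order)}
    codes = pd.Series(labels).map(mapping)
    if codes.isna().any():
        bad = sorted(set(pd.Series(labels)[codes.isna()]))
        raise ValueError(f"unknown RCB label(s): {bad}")
    return codes.to_numpy(int)


def ordinal_trend(
    feature: np.ndarray | pd.Series,
    rcb: np.ndarray | pd.Series,
    name: str = "",
) -> OrdinalTrendResult:
    """Proportional-odds trend test of a feature against ordered RCB classes.

    ``rcb`` may be string labels (pCR/RCB-I/II/III) or integer codes where
    larger means more residual disease.  The model is an ordinal logistic
    regression (logit link); the p-value is from the likelihood-ratio test
    against the intercept-only model.  A positive coefficient means the
    feature increases with residual disease; negative means it tracks pCR.
    """
    x = np.asarray(feature, dtype=float)
    codes = (
        encode_rcb(rcb)
        if not np.issubdtype(np.asarray(rcb).dtype, np.number)
        else np.asarray(rcb, dtype=int)
    )
    if len(np.unique(codes)) < 2:
        raise ValueError("need at least 2 response classes")
    endog = pd.Series(pd.Categorical(codes, ordered=True))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(endog, x[:, None], distr="logit")
        fit = model.fit(method="bfgs", disp=False, maxiter=1000, gtol=1e-8)
        null = OrderedModel(endog, np.empty((len(x), 0)), distr="logit").fit(
            method="bfgs", disp=False, maxiter=1000, gtol=1e-8
        )
    grad_norm = float(np.max(np.abs(model.score(fit.params))))
    if not fit.mle_retvals.get("converged", True) and grad_norm > 1e-4 * len(x):
        raise RuntimeError(f"ordinal model failed to converge for {name!r}")
    lr = 2.0 * (fit.llf - null.llf)
    p = float(sps.chi2.sf(max(lr, 0.0), df=1))
    return OrdinalTrendResult(
        feature=name,
        coefficient=float(np.asarray(fit.params)[0]),
        se=float(np.asarray(fit.bse)[0]),
        p_value=max(p, np.finfo(float).tiny),
    )


def ranksum_by_class(
    feature: pd.Series | np.ndarray,
    classes: pd.Series | np.ndarray,
    reference: str = "pCR",
    exact_max_n: int = 20,
) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum p-value for each class versus the
    reference (complete-response) group.

    Exact enumeration when the combined sample size is <= 20, normal
    approximation with continuity correction otherwise.  Empty classes are
    skipped with a warning.
    """
    feat = pd.Series(np.asarray(feature, dtype=float))
    cls = pd.Series(np.asarray(classes, dtype=object))
    ref_vals = feat[cls == reference].dropna()
    if len(ref_vals) == 0:
        raise ValueError(f"reference class {reference!r} is empty")
    out: dict[str, float] = {}
    for c in pd.unique(cls):
        if c == reference:
            continue
        vals = feat[cls == c].dropna()
        if len(vals) == 0:
            warnings.warn(f"class {c!r} empty; skipped")
            continue
        method = "exact" if len(vals) + len(ref_vals) <= exact_max_n else "asymptotic"
        res = sps.mannwhitneyu(
            ref_vals, vals, alternative="two-sided", method=method
        )
        out[str(c)] = float(res.pvalue)
    return out


def fdr_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p, bounded by 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def association_table(
    features: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    subgroup: pd.Series | None = None,
) -> pd.DataFrame:
    """Univariable logistic OR for every feature column, with BH FDR over
    non-separated fits; optionally repeated within subgroups (e.g. HER2+/-)."""

    def _one(block: pd.DataFrame, y, label) -> pd.DataFrame:
        results = [univariable_logistic(block[c], y, name=c) for c in block.columns]
        df = pd.DataFrame(
            {
                "feature": [r.feature for r in results],
                "odds_ratio": [r.odds_ratio for r in results],
                "ci_low": [r.ci_low for r in results],
                "ci_high": [r.ci_high for r in results],
                "p_value": [r.p_value for r in results],
                "separated": [r.separated for r in results],
            }
        )
        df["q_value"] = np.nan
        ok = ~df["separated"]
        if ok.any():
            df.loc[ok, "q_value"] = fdr_adjust(df.loc[ok, "p_value"].to_numpy())
        df["direction"] = np.where(
            df["odds_ratio"] > 1, "toward_pCR", "toward_residual_disease"
        )
        df.insert(0, "subgroup", label)
        return df

    y = np.asarray(outcome, dtype=float)
    tables = [_one(features, y, "all")]
    if subgroup is not None:
        for g in pd.unique(subgroup):
            mask = (subgroup == g).to_numpy()
            if len(np.unique(y[mask])) == 2:
                tables.append(_one(features[mask], y[mask], str(g)))
    return pd.concat(tables, ignore_index=True)


def therapy_exposure_filter(
    clinical: pd.DataFrame,
    min_chemo_cycles: int = 1,
    min_her2_cycles: int = 1,
) -> pd.Series:
    """Inclusion mask for association analyses: at least one chemotherapy
    cycle, and at least one anti-HER2 cycle when the tumour is HER2+."""
    ok = clinical["chemo_cycles"] >= min_chemo_cycles
    if "her2_status" in clinical.columns and "her2_cycles" in clinical.columns:
        her2_pos = clinical["her2_status"].astype(bool)
        ok &= ~her2_pos | (clinical["her2_cycles"] >= min_her2_cycles)
    return ok
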