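"""Multinomial propensity model and covariate-balance diagnostics.

The propensity model is a multinomial logistic regression of the ten-level
NSAID exposure on the combined covariate matrix (prespecified + hdPS);
each subject gets a predicted probability vector over the exposure groups.

Balance is quantified per covariate and comparator-vs-referent pair by the
standardized difference (mean difference in units of the pooled standard
deviation) and, conditional on the propensity score, by the weighted
conditional standardized difference (WCSD): subjects of the pair are
stratified into quantile strata of the comparator-group propensity, the
within-stratum standardized differences are averaged with weights
proportional to stratum size, and strata with an empty arm are skipped with
their weight renormalized.  Values above 0.1 conventionally flag meaningful
imbalance; flagged covariates enter the outcome models directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from clopnsaid.data_model import REFERENT_NSAID

BALANCE_THRESHOLD = 0.1


@dataclass
class PropensityModel:
    """Fitted multinomial propensity model with per-subject probabilities."""

    covariate_names: list[str]
    classes: list[str]
    coefficients: np.ndarray  # (n_classes, n_covariates), standardized scale
    probabilities: pd.DataFrame  # subjects x classes, rows sum to 1
    ridge_fallback: bool = False
    log: list[str] = field(default_factory=list)


def fit_propensity(
    matrix: pd.DataFrame,
    exposure: pd.Series,
    max_iter: int = 500,
) -> PropensityModel:
    """Maximum-likelihood multinomial logit of exposure on covariates.

    Covariates are internally standardized.  If the unpenalized fit fails to
    converge or shows runaway coefficients (separation), the model is refit
    with an l2 (ridge) penalty and the fallback is logged.

    Raises if a covariate has zero variance or any exposure group is empty.
    """
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(matrix.columns, sd) if s == 0]
        raise ValueError(f"zero-variance covariates: {bad[:5]}")
    counts = exposure.value_counts()
    if (counts == 0).any() or exposure.nunique() < 2:
        raise ValueError("every exposure group must be non-empty")
    Xs = (X - X.mean(axis=0)) / sd

    log: list[str] = []
    ridge = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter)
            clf.fit(Xs, exposure.to_numpy())
            # |coef| > 8 per SD of a covariate implies an implausible odds
            # ratio (> e^8): treat as (quasi-)separation
            if np.abs(clf.coef_).max() > 8:
                raise ConvergenceWarning("separation suspected")
        except (ConvergenceWarning, Exception) as exc:  # noqa: BLE001 - fall back to ridge
            ridge = True
            log.append(f"ridge fallback engaged: {type(exc).__name__}: {exc}")
            clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=max_iter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(Xs, exposure.to_numpy())

    probs = pd.DataFrame(
        clf.predict_proba(Xs), index=matrix.index, columns=list(clf.classes_)
    )
    return PropensityModel(
        covariate_names=list(matrix.columns),
        classes=list(clf.classes_),
        coefficients=clf.coef_,
        probabilities=probs,
        ridge_fallback=ridge,
        log=log,
    )


def standardized_difference(values_a, values_b, coding: str | None = None) -> float:
    """Absolute standardized difference between two groups.

    Binary: ``|p_a - p_b| / sqrt((p_a(1-p_a) + p_b(1-p_b)) / 2)``;
    continuous: ``|mean_a - mean_b| / sqrt((var_a + var_b) / 2)``.
    Returns ``inf`` (flagged) when the pooled variance is zero but the means
    differ; 0.0 when the groups are momentwise identical.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if coding is None:
        coding = "binary" if set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0} else "continuous"
    if coding == "binary":
        pa, pb = a.mean(), b.mean()
        denom = np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2)
        num = abs(pa - pb)
    else:
        denom = np.sqrt((a.var(ddof=1) if a.size > 1 else 0.0) / 2
                        + (b.var(ddof=1) if b.size > 1 else 0.0) / 2)
        num = abs(a.mean() - b.mean())
    if denom == 0:
        return 0.0 if num == 0 else float("inf")
    return float(num / denom)


def sdiff_from_proportions(p_a: float, p_b: float) -> float:
    """Standardized difference of a binary covariate from group proportions."""
    denom = np.sqrt((p_a * (1 - p_a) + p_b * (1 - p_b)) / 2)
    if denom == 0:
        return 0.0 if p_a == p_b else float("inf")
    return float(abs(p_a - p_b) / denom)


def wcsd(
    values,
    in_comparator,
    propensity,
    n_strata: int = 10,
    coding: str | None = None,
) -> float:
    """Weighted conditional standardized difference within one pair.

    Subjects (comparator + referent arms only) are cut into ``n_strata``
    quantile strata of the comparator-group propensity; the within-stratum
    standardized difference is averaged with weights proportional to the
    stratum's pair-total size.  Strata where either arm is empty are skipped
    and the remaining weights renormalized.  With ``n_strata = 1`` this
    equals the unconditional standardized difference exactly.
    """
    v = np.asarray(values, dtype=float)
    grp = np.asarray(in_comparator, dtype=bool)
    ps = np.asarray(propensity, dtype=float)
    if v.shape != grp.shape or v.shape != ps.shape:
        raise ValueError("values, group mask and propensity must align")
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    uniq = np.unique(ps)
    if len(uniq) <= n_strata:
        # few distinct scores: one stratum per value (quantile cuts would merge)
        strata = np.searchsorted(uniq, ps)
    else:
        cut = np.unique(np.quantile(ps, np.linspace(0, 1, n_strata + 1)[1:-1]))
        strata = np.searchsorted(cut, ps, side="right")

    diffs, weights = [], []
    for s in np.unique(strata):
        m = strata == s
        a, b = v[m & grp], v[m & ~grp]
        if a.size == 0 or b.size == 0:
            continue  # skipped stratum; weight renormalized below
        d = standardized_difference(a, b, coding=coding)
        if np.isfinite(d):
            diffs.append(d)
            weights.append(m.sum())
    if not diffs:
        raise ValueError("all propensity strata degenerate for this pair")
    w = np.asarray(weights, dtype=float)
    return float(np.average(diffs, weights=w / w.sum()))


def balance_table(
    matrix: pd.DataFrame,
    exposure: pd.Series,
    model: PropensityModel,
    referent: str = REFERENT_NSAID,
    n_strata: int = 10,
    threshold: float = BALANCE_THRESHOLD,
) -> pd.DataFrame:
    """Standardized difference and WCSD per covariate x comparator pair.

    Returns one row per (covariate, comparator) with ``s_diff``, ``wcsd`` and
    ``flag`` (wcsd > threshold); flagged covariates enter the adjusted
    outcome models directly.
    """
    exp_arr = exposure.to_numpy()
    ref_mask = exp_arr == referent
    rows = []
    comparators = [c for c in model.classes if c != referent]
    for comp in comparators:
        comp_mask = exp_arr == comp
        pair = comp_mask | ref_mask
        ps = model.probabilities[comp].to_numpy()[pair]
        in_comp = comp_mask[pair]
        for cov in matrix.columns:
            v = matrix[cov].to_numpy(dtype=float)
            coding = "continuous" if matrix[cov].nunique() > 2 else "binary"
            s = standardized_difference(v[comp_mask], v[ref_mask], coding=coding)
            try:
                w = wcsd(v[pair], in_comp, ps, n_strata=n_strata, coding=coding)
            except ValueError:
                w = float("nan")
            rows.append({"covariate": cov, "comparator": comp,
                         "s_diff": s, "wcsd": w,
                         "flag": bool(np.isfinite(w) and w > threshold)})
    return pd.DataFrame(rows)
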