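"""Multivariable logistic-regression baseline on clinical covariates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = ["clinical_lr", "ClinicalModel"]

_DUMMIES = {
    "sex": ("sex", {"M": ["sex_M"]}),
}


def _design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "age":
            cols["age"] = df["age"].astype(float)
        elif cov == "sex":
            cols["sex_M"] = (df["sex"] == "M").astype(float)
        elif cov == "cT":
            cols["cT_3"] = (df["cT"].astype(str) == "3").astype(float)
            cols["cT_4"] = (df["cT"].astype(str) == "4").astype(float)
        elif cov == "cN":
            cols["cN_1"] = (df["cN"].astype(int) == 1).astype(float)
            cols["cN_2"] = (df["cN"].astype(int) == 2).astype(float)
        else:
            cols[cov] = df[cov].astype(float)
    X = pd.DataFrame(cols, index=df.index)
    if X.isna().any().any():
        raise ValueError("missing covariate values")
    # drop levels absent from this cohort (zero-variance dummies)
    X = X.loc[:, X.std(axis=0) > 0]
    return sm.add_constant(X, has_constant="add")


@dataclass
class ClinicalModel:
    params: pd.Series
    conf_int: pd.DataFrame
    covariates: tuple[str, ...]
    target: str

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = _design(df, self.covariates)
        X = X.reindex(columns=self.params.index, fill_value=0.0)
        eta = X.values @ self.params.values
        return 1.0 / (1.0 + np.exp(-eta))


def clinical_lr(development, external=None, covariates=("age", "sex", "cT", "cN"),
                target: str = "emvi"):
    """Fit a maximum-likelihood logistic model on the development cohort and
    score the external cohort.

    Inputs are CaseRecord lists or cohort-table DataFrames. Returns
    (ScoreSet, ClinicalModel); the ScoreSet holds external probabilities
    (development probabilities when no external cohort is given). Perfect
    separation is reported as an error rather than silently fitted.
    """
    from ..phantom.summary import cohort_table
    from ..classification.scores import ScoreSet

    dev = cohort_table(development)
    ext = cohort_table(external) if external is not None else dev
    y = dev[target].astype(int).values
    if len(np.unique(y)) < 2:
        raise ValueError("target must contain both classes in the development cohort")
    X = _design(dev, covariates)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(f"logistic fit failed (perfect separation?): {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic regression did not converge "
                         "(possible separation or collinearity)")
    model = ClinicalModel(
        params=res.params,
        conf_int=res.conf_int(),
        covariates=tuple(covariates),
        target=target,
    )
    probs = model.predict(ext)
    ids = (
        ext["patient_id"].astype(str).tolist()
        if "patient_id" in ext.columns
        else [str(i) for i in range(len(ext))]
    )
    scores = ScoreSet(
        patient_ids=ids,
        scores=np.asarray(probs, dtype=np.float64),
        labels=ext[target].astype(int).values,
    )
    return scores, model
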