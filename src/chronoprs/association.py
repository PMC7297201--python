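"""Case-only association of GRPS with chronicity markers.

Chronicity markers are annualized by follow-up time (count / years of
follow-up), variance-stabilized with log1p, and z-scored; the resulting
outcome is regressed on the standardized GRPS with ordinary least squares,
adjusting for ancestry principal components, genotyping batch, age at
diagnosis, and sex. Sex-stratified fits drop the sex covariate; the
moderation analysis adds a GRPS x sex product term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import CHRONICITY_MARKERS
from .errors import CollinearityError, DegenerateOutcomeError, ValidationError
from .scoring import GRPSVector

DEFAULT_ADJUST = ("pcs", "batch", "age_at_diagnosis", "sex")


@dataclass
class OutcomeVector:
    """Transformed per-case outcome for one chronicity marker."""

    individual_ids: np.ndarray
    values: np.ndarray
    marker: str
    transform: str

    def __post_init__(self) -> None:
        if len(self.individual_ids) != len(self.values):
            raise ValidationError("one outcome value per case required")


@dataclass
class RegressionResult:
    outcome: str
    stratum: str
    term: str
    B: float
    se: float
    P: float
    n: int


def make_outcome(
    pheno: pd.DataFrame,
    marker: str,
    transform: str = "rate_log1p_z",
) -> OutcomeVector:
    """Annualize and transform one chronicity marker over cases.

    ``rate_log1p_z`` (default): z(log1p(marker / follow_up_years)).
    ``raw_z``: z(marker), no follow-up weighting.
    """
    if marker not in CHRONICITY_MARKERS:
        raise ValidationError(
            f"unknown marker {marker!r}; expected one of {CHRONICITY_MARKERS}"
        )
    cases = pheno.loc[pheno["case_status"] == 1]
    if cases.empty:
        raise ValidationError("phenotype table contains no cases")
    values = cases[marker].to_numpy(dtype=float)
    if np.isnan(values).any() or (values < 0).any():
        raise ValidationError(f"marker {marker} must be nonnegative and present for all cases")

    if transform == "rate_log1p_z":
        fu = cases["follow_up_years"].to_numpy(dtype=float)
        bad = ~(fu > 0)
        if bad.any():
            ids = cases["individual_id"].to_numpy()[bad]
            raise ValidationError(
                f"nonpositive follow_up_years for cases: {', '.join(map(str, ids[:10]))}"
            )
        t = np.log1p(values / fu)
    elif transform == "raw_z":
        t = values.astype(float)
    else:
        raise ValidationError(f"unknown transform {transform!r}")

    sd = float(np.std(t, ddof=1)) if len(t) > 1 else 0.0
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateOutcomeError(f"outcome for {marker} has zero variance after transform")
    z = (t - float(np.mean(t))) / sd
    return OutcomeVector(
        individual_ids=cases["individual_id"].to_numpy(),
        values=z,
        marker=marker,
        transform=transform,
    )


def _assemble(
    outcome: OutcomeVector,
    grps: GRPSVector,
    covars: pd.DataFrame | None,
    pheno: pd.DataFrame,
    adjust: tuple[str, ...],
) -> pd.DataFrame:
    df = pd.DataFrame({"individual_id": outcome.individual_ids, "_y": outcome.values})
    df = df.merge(grps.to_frame()[["individual_id", "score"]], on="individual_id", validate="one_to_one")
    df = df.merge(
        pheno[["individual_id", "sex", "age_at_diagnosis"]], on="individual_id", validate="one_to_one"
    )
    if covars is not None and ({"pcs", "batch"} & set(adjust)):
        df = df.merge(covars, on="individual_id", validate="one_to_one")
    return df


def _design(df: pd.DataFrame, adjust: tuple[str, ...], with_sex: bool, sex_ref: str = "F") -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["grps"] = df["score"].to_numpy()
    if "pcs" in adjust:
        for col in [c for c in df.columns if c.startswith("pc_")]:
            X[col] = df[col].to_numpy()
    if "batch" in adjust and "batch" in df.columns:
        dummies = pd.get_dummies(df["batch"], prefix="batch", drop_first=True, dtype=float)
        for col in dummies.columns:
            X[col] = dummies[col].to_numpy()
    if "age_at_diagnosis" in adjust:
        X["age_at_diagnosis"] = df["age_at_diagnosis"].to_numpy()
    if with_sex and "sex" in adjust:
        other = "M" if sex_ref == "F" else "F"
        X[f"sex_{other}"] = (df["sex"] == other).astype(float).to_numpy()
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name aliased columns via pivoted QR: small trailing R diagonals
        from scipy.linalg import qr

        _q, r, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [X.columns[j] for j in piv[len(diag):]]
        raise CollinearityError(
            f"rank-deficient design (rank {rank} < {arr.shape[1]}); aliased: {aliased}",
            aliased=[str(a) for a in aliased],
        )


def _ols_term(y: np.ndarray, X: pd.DataFrame, term: str) -> tuple[float, float, float]:
    _check_rank(X)
    fit = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    j = list(X.columns).index(term)
    return float(fit.params[j]), float(fit.bse[j]), float(fit.pvalues[j])


def fit_case_only(
    outcome: OutcomeVector,
    grps: GRPSVector,
    covars: pd.DataFrame | None,
    pheno: pd.DataFrame,
    stratum: str = "all",
    adjust: tuple[str, ...] = DEFAULT_ADJUST,
) -> RegressionResult:
    """OLS of the transformed outcome on GRPS plus covariates.

    ``stratum`` selects all cases or one sex; stratified fits automatically
    drop sex from the adjustment set. Returns the GRPS term.
    """
    if stratum not in ("all", "female", "male"):
        raise ValidationError("stratum must be 'all', 'female' or 'male'")
    df = _assemble(outcome, grps, covars, pheno, adjust)
    if stratum != "all":
        df = df.loc[df["sex"] == ("F" if stratum == "female" else "M")]
        if df.empty:
            raise ValidationError(f"no cases in stratum {stratum!r}")
    X = _design(df, adjust, with_sex=(stratum == "all"))
    if len(df) < X.shape[1] + 1:
        raise ValidationError(f"n={len(df)} too small for {X.shape[1]} model terms")
    b, se, p = _ols_term(df["_y"].to_numpy(), X, "grps")
    return RegressionResult(
        outcome=outcome.marker, stratum=stratum, term="grps", B=b, se=se, P=p, n=len(df)
    )


def fit_interaction(
    outcome: OutcomeVector,
    grps: GRPSVector,
    covars: pd.DataFrame | None,
    pheno: pd.DataFrame,
    adjust: tuple[str, ...] = DEFAULT_ADJUST,
    sex_ref: str = "F",
) -> RegressionResult:
    """Add a GRPS x sex product term; returns that term's coefficient."""
    df = _assemble(outcome, grps, covars, pheno, adjust)
    if df["sex"].nunique() < 2:
        raise ValidationError("interaction model requires both sexes among cases")
    X = _design(df, adjust, with_sex=True, sex_ref=sex_ref)
    other = "M" if sex_ref == "F" else "F"
    if f"sex_{other}" not in X.columns:
        X[f"sex_{other}"] = (df["sex"] == other).astype(float).to_numpy()
    X["grps_x_sex"] = X["grps"].to_numpy() * X[f"sex_{other}"].to_numpy()
    b, se, p = _ols_term(df["_y"].to_numpy(), X, "grps_x_sex")
    return RegressionResult(
        outcome=outcome.marker, stratum="interaction", term="grps_x_sex",
        B=b, se=se, P=p, n=len(df),
    )
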