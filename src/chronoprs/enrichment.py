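"""Case-control prediction accuracy, chronicity enrichment, and sex gap.

The prediction statistic is the incremental Nagelkerke pseudo-R2 of the
GRPS: the Nagelkerke R2 of the logistic model case ~ PCs + GRPS minus that
of case ~ PCs, each measured against the intercept-only model. Chronicity
enrichment keeps only cases at or above a marker threshold (controls are
never filtered) and asks, via a matched-size permutation test, whether the
enriched subsample's incremental R2 exceeds what random case subsets of the
same size achieve. The sex gap test compares male-only and female-only
incremental R2 and builds its null by permuting sex labels.

Logistic models are fit by an internal Newton-Raphson maximum-likelihood
routine (a few microseconds per fit at these design sizes), which keeps the
thousands of refits inside a permutation test cheap; its log-likelihoods are
validated against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CHRONICITY_MARKERS
from .errors import (
    ConvergenceError,
    NestingError,
    SeparationError,
    ValidationError,
)
from .scoring import GRPSVector

#: the published above-average chronicity inclusion thresholds
DEFAULT_FILTERS = {
    "n_total": 27,
    "n_inpatient": 12,
    "n_outpatient": 19,
    "hosp_length_days": 640,
}


@dataclass(frozen=True)
class ChronicityFilter:
    """Inclusive lower bound on one chronicity marker (cases only)."""

    marker: str
    threshold: float

    def __post_init__(self) -> None:
        if self.marker not in CHRONICITY_MARKERS:
            raise ValidationError(
                f"unknown marker {self.marker!r}; expected one of {CHRONICITY_MARKERS}"
            )
        if self.threshold < 0:
            raise ValidationError("filter threshold must be nonnegative")


@dataclass
class EnrichmentResult:
    filter: ChronicityFilter | None
    n_selected_cases: int
    observed_nkr2: float
    baseline_nkr2: float
    perm_values: np.ndarray
    p_perm: float
    n_perm: int
    seed: int
    alternative: str = "greater"
    extras: dict = field(default_factory=dict)


def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Cox-Snell R2 rescaled by its maximum attainable value.

    ``CS = 1 - exp(2 (ll_null - ll_full) / n)``; the Nagelkerke value is
    CS / (1 - exp(2 ll_null / n)), reaching 1 for a saturated fit.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if ll_full < ll_null - 1e-8:
        raise NestingError(
            f"ll_full ({ll_full}) < ll_null ({ll_null}); models are not nested"
        )
    ll_full = max(ll_full, ll_null)
    cs = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    cs_max = 1.0 - np.exp(2.0 * ll_null / n)
    if cs_max <= 0:
        return 0.0
    return float(cs / cs_max)


# -- internal logistic maximum likelihood ------------------------------


def _logit_loglik(X: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-12) -> float:
    """Log-likelihood at the MLE of a logistic regression via Newton-Raphson."""
    n, p = X.shape
    beta = np.zeros(p)
    ybar = y.mean()
    if ybar <= 0 or ybar >= 1:
        raise ValidationError("response is constant; logistic model undefined")
    beta[0] = np.log(ybar / (1.0 - ybar))  # assumes an intercept in column 0
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(y @ eta - np.sum(np.log1p(np.exp(eta))))
    for _ in range(max_iter):
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian in logistic fit: {exc}") from exc
        # step-halving line search on the log-likelihood
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            eta_c = X @ cand
            ll_c = float(y @ eta_c - np.sum(np.log1p(np.exp(np.clip(eta_c, None, 500)))))
            if ll_c >= ll - 1e-14:
                break
            scale *= 0.5
        improvement = ll_c - ll
        beta, eta, ll = cand, eta_c, ll_c
        mu = 1.0 / (1.0 + np.exp(-eta))
        if np.max(np.abs(eta)) > 30 and improvement > 1e-6:
            raise SeparationError(
                "complete or quasi-complete separation detected (unbounded linear predictor)"
            )
        if abs(improvement) < tol * (abs(ll) + 1.0):
            return ll
    raise ConvergenceError(
        f"logistic fit did not converge in {max_iter} iterations (last ll change {improvement:.3e})"
    )


def _intercept_loglik(y: np.ndarray) -> float:
    n1 = y.sum()
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("response is constant; logistic model undefined")
    p = n1 / len(y)
    return float(n1 * np.log(p) + n0 * np.log(1.0 - p))


def _incremental_from_arrays(
    y: np.ndarray, x_null: np.ndarray, score: np.ndarray
) -> tuple[float, float, float]:
    """(incremental, nk_full, nk_null) on prebuilt arrays."""
    n = len(y)
    ll0 = _intercept_loglik(y)
    ll_null = _logit_loglik(x_null, y)
    if float(np.std(score)) <= 1e-12:
        nk_null = nagelkerke_r2(ll0, ll_null, n)
        return 0.0, nk_null, nk_null  # aliased score contributes nothing
    x_full = np.column_stack([x_null, score])
    ll_full = _logit_loglik(x_full, y)
    nk_null = nagelkerke_r2(ll0, ll_null, n)
    nk_full = nagelkerke_r2(ll0, ll_full, n)
    return nk_full - nk_null, nk_full, nk_null


def _build_arrays(
    pheno: pd.DataFrame,
    grps: GRPSVector,
    covars: pd.DataFrame | None,
    include_batch: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-aligned (y, x_null, score, sex, case_mask) for the full sample."""
    df = pheno[["individual_id", "case_status", "sex"]].merge(
        grps.to_frame()[["individual_id", "score"]], on="individual_id", validate="one_to_one"
    )
    cols = [np.ones(len(df))]
    if covars is not None:
        df = df.merge(covars, on="individual_id", validate="one_to_one")
        cols += [df[c].to_numpy(dtype=float) for c in df.columns if c.startswith("pc_")]
        if include_batch and "batch" in df.columns:
            dummies = pd.get_dummies(df["batch"], drop_first=True, dtype=float)
            cols += [dummies[c].to_numpy() for c in dummies.columns]
    x_null = np.column_stack(cols)
    return (
        df["case_status"].to_numpy(dtype=float),
        x_null,
        df["score"].to_numpy(dtype=float),
        df["sex"].to_numpy(),
        df["case_status"].to_numpy() == 1,
    )


def incremental_nkr2(
    pheno: pd.DataFrame,
    grps: GRPSVector,
    covars: pd.DataFrame | None,
    case_ids: np.ndarray | None = None,
    include_batch: bool = False,
) -> float:
    """Incremental Nagelkerke R2 of the GRPS over the PC-only null model.

    ``case_ids`` restricts the cases entering the fit (all controls are
    always included); by default all cases are used.
    """
    y, x_null, score, _sex, case_mask = _build_arrays(pheno, grps, covars, include_batch)
    if case_ids is not None:
        ids = pheno["individual_id"].to_numpy()
        selected = np.isin(ids, np.asarray(case_ids))
        if (selected & ~case_mask).any():
            raise ValidationError("case_ids must refer to cases only")
        rows = np.flatnonzero(selected | ~case_mask)
        y, x_null, score = y[rows], x_null[rows], score[rows]
    inc, _full, _null = _incremental_from_arrays(y, x_null, score)
    return inc


def apply_chronicity_filter(pheno: pd.DataFrame, filt: ChronicityFilter) -> np.ndarray:
    """Ids of cases whose marker is >= the threshold; controls never filtered."""
    cases = pheno.loc[pheno["case_status"] == 1]
    if cases.empty:
        raise ValidationError("phenotype table contains no cases")
    keep = cases[filt.marker].to_numpy(dtype=float) >= filt.threshold
    return cases["individual_id"].to_numpy()[keep]


def permutation_enrichment_test(
    pheno: pd.DataFrame,
    grps: GRPSVector,
    covars: pd.DataFrame | None,
    filt: ChronicityFilter,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
    include_batch: bool = False,
) -> EnrichmentResult:
    """Matched-subsample permutation test of chronicity enrichment.

    The observed statistic is the incremental Nagelkerke R2 with cases
    restricted to the filtered subset; each permutation draw replaces the
    filtered cases with a uniform random case subset of the same size
    (without replacement) and recomputes the statistic. The empirical
    p-value uses the add-one convention (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError("alternative must be 'greater', 'less' or 'two-sided'")
    selected = apply_chronicity_filter(pheno, filt)
    if len(selected) == 0:
        raise ValidationError(f"filter {filt} selects zero cases")

    y, x_null, score, _sex, case_mask = _build_arrays(pheno, grps, covars, include_batch)
    ids = pheno["individual_id"].to_numpy()
    case_rows = np.flatnonzero(case_mask)
    control_rows = np.flatnonzero(~case_mask)
    sel_rows = np.flatnonzero(np.isin(ids, selected))

    def stat(case_subset_rows: np.ndarray) -> float:
        rows = np.sort(np.concatenate([control_rows, case_subset_rows]))
        inc, _f, _n = _incremental_from_arrays(y[rows], x_null[rows], score[rows])
        return inc

    observed = stat(sel_rows)
    baseline, _f, _n0 = _incremental_from_arrays(y, x_null, score)

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    k = len(sel_rows)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        draw = rng.choice(case_rows, size=k, replace=False)
        perm[b] = stat(draw)

    if alternative == "greater":
        extreme = int(np.sum(perm >= observed))
    elif alternative == "less":
        extreme = int(np.sum(perm <= observed))
    else:
        center = float(np.mean(perm))
        extreme = int(np.sum(np.abs(perm - center) >= abs(observed - center)))
    p_perm = (1 + extreme) / (n_perm + 1)

    return EnrichmentResult(
        filter=filt,
        n_selected_cases=int(len(selected)),
        observed_nkr2=observed,
        baseline_nkr2=baseline,
        perm_values=perm,
        p_perm=float(p_perm),
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
    )


def sex_prediction_gap_test(
    pheno: pd.DataFrame,
    grps: GRPSVector,
    covars: pd.DataFrame | None,
    n_perm: int = 1000,
    seed: int = 0,
    include_batch: bool = False,
) -> EnrichmentResult:
    """Male-minus-female gap in incremental Nagelkerke R2, sex-label permutation null.

    Each sex's incremental R2 is computed on that sex's cases and controls;
    the null distribution permutes sex labels across all individuals and the
    two-sided empirical p uses the add-one convention.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    y, x_null, score, sex, case_mask = _build_arrays(pheno, grps, covars, include_batch)

    def gap(labels: np.ndarray) -> tuple[float, float, float]:
        out = {}
        for s in ("M", "F"):
            rows = np.flatnonzero(labels == s)
            ys = y[rows]
            if ys.sum() == 0 or ys.sum() == len(ys):
                raise ValidationError(f"sex stratum {s!r} lacks cases or controls")
            inc, _f, _n = _incremental_from_arrays(ys, x_null[rows], score[rows])
            out[s] = inc
        return out["M"] - out["F"], out["M"], out["F"]

    observed, nk_m, nk_f = gap(sex)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b], _m, _f = gap(rng.permutation(sex))
    extreme = int(np.sum(np.abs(perm) >= abs(observed)))
    p_perm = (1 + extreme) / (n_perm + 1)

    return EnrichmentResult(
        filter=None,
        n_selected_cases=int(case_mask.sum()),
        observed_nkr2=observed,
        baseline_nkr2=0.0,
        perm_values=perm,
        p_perm=float(p_perm),
        n_perm=n_perm,
        seed=seed,
        alternative="two-sided",
        extras={"nkr2_male": nk_m, "nkr2_female": nk_f},
    )
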