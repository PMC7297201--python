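"""End-to-end orchestration: simulate -> score -> associate -> enrich -> report.

Produces a :class:`ReportBundle` whose four tables mirror the standard
presentation of this analysis: cohort descriptives by sex, case-only GRPS
association per marker and threshold, sex-stratified association with the
interaction term at the primary threshold, and case-control enrichment
(incremental Nagelkerke R2 with permutation p-values) plus the sex gap.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import fit_case_only, fit_interaction, make_outcome
from .config import CHRONICITY_MARKERS, SimulationConfig
from .enrichment import (
    DEFAULT_FILTERS,
    ChronicityFilter,
    incremental_nkr2,
    permutation_enrichment_test,
    sex_prediction_gap_test,
)
from .io import _write_tsv
from .scoring import GRPSVector, align_variants, compute_grps, standardize
from .simulate import GenotypeMatrix, simulate_cohort, simulate_summary_stats

logger = logging.getLogger("chronoprs")


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the analysis stages downstream of the simulator."""

    pt_thresholds: tuple[float, ...] = (0.05, 0.1, 0.01)
    primary_pt: float = 0.05  # the threshold all enrichment analyses use
    n_perm: int = 1000
    filters: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FILTERS))
    drop_ambiguous: bool = True
    include_batch: bool = False
    outcome_transform: str = "rate_log1p_z"


@dataclass
class ReportBundle:
    descriptives: pd.DataFrame
    association: pd.DataFrame
    association_by_sex: pd.DataFrame
    enrichment: pd.DataFrame
    perm_distributions: dict[str, list[float]]
    metadata: dict


def describe_chronicity(pheno: pd.DataFrame) -> pd.DataFrame:
    """Case chronicity means and sds, total and by sex."""
    cases = pheno.loc[pheno["case_status"] == 1]
    rows = []
    for marker in CHRONICITY_MARKERS:
        row: dict = {"marker": marker}
        for label, sub in (
            ("total", cases),
            ("female", cases.loc[cases["sex"] == "F"]),
            ("male", cases.loc[cases["sex"] == "M"]),
        ):
            vals = sub[marker].to_numpy(dtype=float)
            row[f"{label}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
            row[f"{label}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: SimulationConfig,
    analysis: AnalysisConfig | None = None,
    seed: int | None = None,
) -> ReportBundle:
    """Run every stage and collect the report tables.

    Deterministic given ``(config, analysis, seed)``; ``seed`` overrides
    ``config.seed`` for all stages including the permutation draws.
    """
    analysis = analysis or AnalysisConfig()
    base_seed = config.seed if seed is None else seed
    t0 = time.perf_counter()

    sumstats = simulate_summary_stats(config, seed=base_seed)
    genotypes, pheno, covars = simulate_cohort(config, sumstats, seed=base_seed)
    logger.info("simulated cohort n=%d in %.1fs", len(pheno), time.perf_counter() - t0)

    panel = align_variants(genotypes, sumstats, drop_ambiguous=analysis.drop_ambiguous)
    scores: dict[float, GRPSVector] = {
        pt: standardize(compute_grps(panel, pt=pt)) for pt in analysis.pt_thresholds
    }
    primary = scores[analysis.primary_pt]

    # case-only association: all strata at the primary PT, all-cases at every PT
    assoc_rows, sex_rows = [], []
    for marker in CHRONICITY_MARKERS:
        outcome = make_outcome(pheno, marker, transform=analysis.outcome_transform)
        for pt, grps in scores.items():
            res = fit_case_only(outcome, grps, covars, pheno, stratum="all")
            assoc_rows.append(
                {"marker": marker, "pt": pt, "B": res.B, "se": res.se, "P": res.P, "n": res.n}
            )
        for stratum in ("female", "male"):
            res = fit_case_only(outcome, primary, covars, pheno, stratum=stratum)
            sex_rows.append(
                {"marker": marker, "stratum": stratum, "B": res.B, "se": res.se,
                 "P": res.P, "n": res.n}
            )
        res = fit_interaction(outcome, primary, covars, pheno)
        sex_rows.append(
            {"marker": marker, "stratum": "interaction", "B": res.B, "se": res.se,
             "P": res.P, "n": res.n}
        )
    logger.info("associations done at %.1fs", time.perf_counter() - t0)

    # enrichment: four chronicity filters plus the sex gap
    baseline = incremental_nkr2(pheno, primary, covars, include_batch=analysis.include_batch)
    enr_rows = [{"subsample": "full", "n_cases": int((pheno["case_status"] == 1).sum()),
                 "nkr2": baseline, "p_perm": np.nan}]
    perm_dists: dict[str, list[float]] = {}
    for marker, threshold in analysis.filters.items():
        res = permutation_enrichment_test(
            pheno, primary, covars, ChronicityFilter(marker, threshold),
            n_perm=analysis.n_perm, seed=base_seed, include_batch=analysis.include_batch,
        )
        enr_rows.append(
            {"subsample": marker, "n_cases": res.n_selected_cases,
             "nkr2": res.observed_nkr2, "p_perm": res.p_perm}
        )
        perm_dists[marker] = [float(v) for v in res.perm_values]
    sexgap = sex_prediction_gap_test(
        pheno, primary, covars, n_perm=analysis.n_perm, seed=base_seed,
        include_batch=analysis.include_batch,
    )
    enr_rows.append({"subsample": "females", "n_cases": int(((pheno.case_status == 1) & (pheno.sex == "F")).sum()),
                     "nkr2": sexgap.extras["nkr2_female"], "p_perm": sexgap.p_perm})
    enr_rows.append({"subsample": "males", "n_cases": int(((pheno.case_status == 1) & (pheno.sex == "M")).sum()),
                     "nkr2": sexgap.extras["nkr2_male"], "p_perm": sexgap.p_perm})
    perm_dists["sex_gap"] = [float(v) for v in sexgap.perm_values]
    logger.info("enrichment done at %.1fs", time.perf_counter() - t0)

    metadata = {
        "config_hash": config.hash(),
        "seed": base_seed,
        "n_perm": analysis.n_perm,
        "primary_pt": analysis.primary_pt,
        "n_variants_used": {str(pt): s.n_variants_used for pt, s in scores.items()},
        "alignment": panel.action_counts,
        "runtime_s": round(time.perf_counter() - t0, 2),
    }
    return ReportBundle(
        descriptives=describe_chronicity(pheno),
        association=pd.DataFrame(assoc_rows),
        association_by_sex=pd.DataFrame(sex_rows),
        enrichment=pd.DataFrame(enr_rows),
        perm_distributions=perm_dists,
        metadata=metadata,
    )


def write_report(bundle: ReportBundle, outdir) -> None:
    """Write the bundle as TSVs plus a JSON sidecar of permutation draws."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": bundle.metadata["config_hash"], "seed": bundle.metadata["seed"]}
    _write_tsv(bundle.descriptives, outdir / "descriptives.tsv", meta)
    _write_tsv(bundle.association, outdir / "association.tsv", meta)
    _write_tsv(bundle.association_by_sex, outdir / "association_by_sex.tsv", meta)
    _write_tsv(bundle.enrichment, outdir / "enrichment.tsv", meta)
    with open(outdir / "permutations.json", "w") as fh:
        json.dump({"metadata": bundle.metadata, "distributions": bundle.perm_distributions}, fh)
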