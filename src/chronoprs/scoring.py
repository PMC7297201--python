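"""Genomic risk profile scores (GRPS / polygenic scores).

A GRPS is the weighted allele sum ``score_i = sum_j beta_j * dosage_ij``
over the discovery variants whose p-value falls below the threshold PT;
dosages are first harmonized so they count the summary-statistic effect
allele. Scores are standardized within the analysis sample before they enter
any regression, so coefficients are per standard deviation of the score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateScoreError, EmptyPanelError, ThresholdError, ValidationError
from .simulate import GenotypeMatrix

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GRPSVector:
    """Per-individual polygenic score at one p-value threshold."""

    individual_ids: np.ndarray
    score: np.ndarray
    pt_threshold: float
    n_variants_used: int
    standardized: bool = False

    def __post_init__(self) -> None:
        if len(self.individual_ids) != len(self.score):
            raise ValidationError("one score per individual required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual_id": self.individual_ids, "score": self.score, "pt": self.pt_threshold}
        )


@dataclass
class AlignedPanel:
    """Genotypes recoded to count each matched variant's effect allele.

    ``actions`` records one row per genotype variant with its harmonization
    action (keep / flip / drop) and reason; ``variants`` and ``dosage``
    retain only the kept and flipped variants, joined with their summary
    statistics, with flipped dosages recoded as ``2 - g``.
    """

    individual_ids: np.ndarray
    variants: pd.DataFrame  # variant_id, effect_allele, other_allele, beta, p, eaf
    dosage: np.ndarray
    actions: pd.DataFrame  # variant_id, action, reason
    action_counts: dict[str, int]


def align_variants(
    genotypes: GenotypeMatrix,
    sumstats: pd.DataFrame,
    drop_ambiguous: bool = True,
) -> AlignedPanel:
    """Harmonize genotype allele coding with the summary statistics.

    Variants are matched by id. A variant is kept as-is when the counted
    allele equals the effect allele, flipped (dosage recoded to ``2 - g``)
    when it equals the other allele, and dropped when the allele pairs do
    not match or, with ``drop_ambiguous``, when the pair is strand-ambiguous
    (A/T or C/G).
    """
    if genotypes.n_variants == 0 or len(sumstats) == 0:
        raise EmptyPanelError("empty genotype panel or summary statistics")

    ss = sumstats.set_index("variant_id")
    actions = []
    keep_cols: list[int] = []
    flip_cols: list[int] = []
    for j, row in enumerate(genotypes.variants.itertuples(index=False)):
        vid, counted, other = row.variant_id, row.counted_allele, row.other_allele
        if vid not in ss.index:
            actions.append((vid, "drop", "unmatched-id"))
            continue
        eff = ss.at[vid, "effect_allele"]
        oth = ss.at[vid, "other_allele"]
        if drop_ambiguous and (eff, oth) in _AMBIGUOUS_PAIRS:
            actions.append((vid, "drop", "strand-ambiguous"))
            continue
        if counted == eff and other == oth:
            actions.append((vid, "keep", "matched"))
            keep_cols.append(j)
        elif counted == oth and other == eff:
            actions.append((vid, "flip", "counted-other-allele"))
            flip_cols.append(j)
        else:
            actions.append((vid, "drop", "allele-mismatch"))

    if not keep_cols and not flip_cols:
        raise EmptyPanelError("no variants survived allele harmonization")

    cols = sorted(keep_cols + flip_cols)
    dosage = genotypes.dosage[:, cols].astype(float).copy()
    flip_set = set(flip_cols)
    for local_j, j in enumerate(cols):
        if j in flip_set:
            dosage[:, local_j] = 2.0 - dosage[:, local_j]

    kept_ids = genotypes.variants["variant_id"].to_numpy()[cols]
    variants = (
        pd.DataFrame({"variant_id": kept_ids})
        .merge(sumstats, on="variant_id", how="left", validate="one_to_one")
        .reset_index(drop=True)
    )
    actions_df = pd.DataFrame(actions, columns=["variant_id", "action", "reason"])
    counts = actions_df["action"].value_counts().to_dict()
    counts = {k: int(counts.get(k, 0)) for k in ("keep", "flip", "drop")}
    return AlignedPanel(
        individual_ids=genotypes.individual_ids,
        variants=variants,
        dosage=dosage,
        actions=actions_df,
        action_counts=counts,
    )


def compute_grps(
    panel: AlignedPanel,
    sumstats: pd.DataFrame | None = None,
    pt: float = 0.05,
    missing_policy: str = "target_freq",
) -> GRPSVector:
    """Weighted allele sum over variants with discovery ``p < pt`` (strict).

    Missing dosages are imputed as twice the target-sample effect-allele
    frequency at that variant (``missing_policy='target_freq'``) or left to
    zero out the variant's contribution (``'zero'``).
    """
    if not 0 < pt <= 1:
        raise ValidationError("pt must lie in (0, 1]")
    stats_df = panel.variants
    if sumstats is not None:
        stats_df = (
            stats_df[["variant_id"]]
            .merge(sumstats, on="variant_id", how="left", validate="one_to_one")
        )
        if stats_df["beta"].isna().any():
            raise ValidationError("provided sumstats do not cover the aligned panel")
    mask = stats_df["p"].to_numpy() < pt
    if not mask.any():
        raise ThresholdError(f"p-value threshold {pt} selects zero variants")

    dosage = panel.dosage[:, mask]
    beta = stats_df["beta"].to_numpy()[mask]
    if np.isnan(dosage).any():
        if missing_policy == "target_freq":
            col_mean = np.nanmean(dosage, axis=0)  # = 2 * target-sample EAF
            fill = np.broadcast_to(col_mean, dosage.shape)
        elif missing_policy == "zero":
            fill = np.zeros_like(dosage)
        else:
            raise ValidationError(f"unknown missing_policy {missing_policy!r}")
        dosage = np.where(np.isnan(dosage), fill, dosage)
    score = dosage @ beta
    return GRPSVector(
        individual_ids=panel.individual_ids,
        score=score,
        pt_threshold=pt,
        n_variants_used=int(mask.sum()),
        standardized=False,
    )


def standardize(grps: GRPSVector) -> GRPSVector:
    """Z-score the score vector (sample sd, ddof=1)."""
    if len(grps.score) < 2:
        raise DegenerateScoreError("need at least two individuals to standardize")
    sd = float(np.std(grps.score, ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateScoreError("score vector has zero variance")
    z = (grps.score - float(np.mean(grps.score))) / sd
    return replace(grps, score=z, standardized=True)


def score_genotypes(
    genotypes: GenotypeMatrix,
    sumstats: pd.DataFrame,
    pt: float = 0.05,
    drop_ambiguous: bool = True,
    standardized: bool = True,
) -> GRPSVector:
    """Convenience wrapper: align, score at one threshold, standardize."""
    panel = align_variants(genotypes, sumstats, drop_ambiguous=drop_ambiguous)
    grps = compute_grps(panel, pt=pt)
    return standardize(grps) if standardized else grps
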