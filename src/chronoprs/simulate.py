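"""Liability-threshold synthetic data: discovery GWAS and ascertained cohort.

The generative model
--------------------
Each of M independent biallelic variants has an effect-allele frequency p_j
drawn uniformly from the configured range. True standardized effects are
``beta_std_j ~ N(0, h2/M)`` so the genetic value ``G_i = sum_j beta_std_j *
z_ij`` (z = standardized dosage) has variance ``h2_liability``. Liability is
``G + E`` with ``E ~ N(0, 1 - h2)``; the female environmental variance may
be inflated by a configurable factor, modelling a weaker genetic
determination of disease in women. An individual is a case when liability
exceeds the upper-prevalence quantile of the base N(0,1) liability
distribution.

The discovery GWAS is emulated on the summary level: the estimated
per-allele effect is the true per-allele effect plus Gaussian noise with the
standard error ``1 / sqrt(2 p (1-p) n_discovery)`` of a per-allele
regression coefficient on a standardized trait, and the p-value is the
two-sided Wald p.

Case chronicity markers (total / inpatient / outpatient health-care
contacts, cumulative hospitalization length) are drawn conditionally on the
standardized genetic value: counts are negative binomial with log-mean
``a + b * g_std (+ sex shift)``, length is log-normal likewise. Outpatient
contacts are genetically decoupled (b = 0) by default. All randomness flows
from a single seed through per-stage child streams, so e.g. enlarging the
variant panel does not perturb the phenotype draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CHRONICITY_MARKERS, SimulationConfig
from .errors import SamplingBudgetError, ValidationError

_BASES = np.array(list("ACGT"))

# stable indices into the spawned seed-sequence children
_STREAM_SUMSTATS = 0
_STREAM_GENO = 1
_STREAM_CHRONICITY = 2
_STREAM_DEMOGRAPHICS = 3
_STREAM_COVARIATES = 4
_STREAM_ORIENTATION = 5
_STREAM_MISSING = 6


@dataclass
class GenotypeMatrix:
    """Individual x variant effect-allele dosage matrix.

    ``dosage[i, j]`` counts copies of ``variants.counted_allele[j]`` carried
    by individual i, in [0, 2], NaN where missing.
    """

    individual_ids: np.ndarray
    variants: pd.DataFrame  # columns: variant_id, counted_allele, other_allele
    dosage: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.individual_ids):
            raise ValidationError("dosage rows do not match individual_ids")
        if m != len(self.variants):
            raise ValidationError("dosage columns do not match variant table")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]


def _rng(config_seed: int, seed: int | None, stream: int) -> np.random.Generator:
    root = np.random.SeedSequence(config_seed if seed is None else seed)
    return np.random.Generator(np.random.PCG64(root.spawn(stream + 1)[stream]))


def simulate_summary_stats(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Emulate a discovery GWAS over independent variants.

    Returns a table with columns ``variant_id, effect_allele, other_allele,
    beta, p, eaf, true_effect``; ``beta`` and ``true_effect`` are per-allele
    (raw dosage scale) effects.
    """
    config.validate()
    rng = _rng(config.seed, seed, _STREAM_SUMSTATS)
    m = config.n_variants
    lo, hi = config.maf_range
    eaf = rng.uniform(lo, hi, size=m)

    # alleles: ordered distinct pair per variant
    a1 = rng.integers(0, 4, size=m)
    a2 = (a1 + rng.integers(1, 4, size=m)) % 4

    var_scale = 2.0 * eaf * (1.0 - eaf)
    if config.h2_liability > 0:
        beta_std = rng.normal(0.0, np.sqrt(config.h2_liability / m), size=m)
    else:
        beta_std = np.zeros(m)
        rng.normal(0.0, 1.0, size=m)  # keep stream alignment across h2 settings
    true_pa = beta_std / np.sqrt(var_scale)

    se = 1.0 / np.sqrt(var_scale * config.n_discovery)
    beta_hat = true_pa + rng.normal(0.0, se)
    z = beta_hat / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    width = max(6, len(str(m)))
    return pd.DataFrame(
        {
            "variant_id": [f"var{str(i).zfill(width)}" for i in range(m)],
            "effect_allele": _BASES[a1],
            "other_allele": _BASES[a2],
            "beta": beta_hat,
            "p": p,
            "eaf": eaf,
            "true_effect": true_pa,
        }
    )


def _draw_chronicity(
    config: SimulationConfig,
    g_std: np.ndarray,
    sex: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for marker in CHRONICITY_MARKERS:
        link = config.chronicity_links[marker]
        log_mu = link.intercept + link.slope * g_std
        if marker in config.sex_shifts:
            shifted_sex, shift = config.sex_shifts[marker]
            log_mu = log_mu + shift * (sex == shifted_sex)
        if marker == "hosp_length_days":
            out[marker] = np.exp(rng.normal(log_mu, link.dispersion))
        else:
            k = link.dispersion
            mu = np.exp(log_mu)
            out[marker] = rng.negative_binomial(k, k / (k + mu)).astype(float)
    return out


def simulate_cohort(
    config: SimulationConfig,
    sumstats: pd.DataFrame,
    seed: int | None = None,
    ascertain: bool = True,
    randomize_counted_allele: bool = True,
    return_liability: bool = False,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw an ascertained case-control cohort under the liability model.

    Rejection sampling fills four quotas (case/control x female/male) set by
    the configured totals and sex proportions; with ``ascertain=False`` the
    first ``n_cases + n_controls`` population draws are returned regardless
    of status (useful for checking that the case fraction converges to the
    prevalence). Genotypes, phenotypes (with chronicity markers for cases),
    and covariates (PCs, batch) are returned; all draws are deterministic
    given ``(config, seed)``.
    """
    config.validate()
    if "true_effect" not in sumstats.columns:
        raise ValidationError("sumstats must carry the simulator's true_effect column")

    base_seed = config.seed if seed is None else seed
    rng_geno = _rng(base_seed, None, _STREAM_GENO)

    eaf = sumstats["eaf"].to_numpy()
    true_pa = sumstats["true_effect"].to_numpy()
    m = len(sumstats)
    # G = dosage @ true_pa - const has the standardized-scale variance h2
    g_offset = float(np.sum(2.0 * eaf * true_pa))

    n_total = config.n_cases + config.n_controls
    env_sd_m = np.sqrt(max(1.0 - config.h2_liability, 0.0))
    env_sd_f = env_sd_m * np.sqrt(config.female_noise_inflation)
    tau = stats.norm.ppf(1.0 - config.prevalence)

    # quotas: (case, F), (case, M), (control, F), (control, M)
    n_case_f = int(round(config.n_cases * config.prop_female_cases))
    n_ctrl_f = int(round(config.n_controls * config.prop_female_controls))
    quotas = {
        (1, "F"): n_case_f,
        (1, "M"): config.n_cases - n_case_f,
        (0, "F"): n_ctrl_f,
        (0, "M"): config.n_controls - n_ctrl_f,
    }

    kept_dos: list[np.ndarray] = []
    kept_g: list[np.ndarray] = []
    kept_liab: list[np.ndarray] = []
    kept_sex: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    drawn = 0
    remaining = dict(quotas)

    while any(v > 0 for v in remaining.values()):
        if not ascertain:
            chunk = n_total
        else:
            need_cases = remaining[(1, "F")] + remaining[(1, "M")]
            exp_case = max(config.prevalence * 0.5, 1e-9)
            chunk = int(min(50_000, max(2_048, 1.3 * need_cases / exp_case)))
        if drawn + chunk > config.draw_budget:
            chunk = config.draw_budget - drawn
            if chunk <= 0:
                raise SamplingBudgetError(
                    f"draw budget {config.draw_budget} exhausted with quotas still open: "
                    f"{ {k: v for k, v in remaining.items() if v > 0} }"
                )
        # exact Binomial(2, p) via single-uniform quantile inversion (fast path)
        u = rng_geno.random((chunk, m))
        q_zero = (1.0 - eaf) ** 2
        q_one = q_zero + 2.0 * eaf * (1.0 - eaf)
        dos = np.add(u > q_zero, u > q_one, dtype=np.float64)
        del u
        g = dos @ true_pa - g_offset
        sex = np.where(rng_geno.random(chunk) < 0.5, "F", "M")
        env = rng_geno.normal(0.0, 1.0, size=chunk) * np.where(sex == "F", env_sd_f, env_sd_m)
        liab = g + env
        status = (liab > tau).astype(int)
        drawn += chunk

        if not ascertain:
            take = np.arange(min(chunk, n_total))
            kept_dos.append(dos[take])
            kept_g.append(g[take])
            kept_liab.append(liab[take])
            kept_sex.append(sex[take])
            kept_status.append(status[take])
            break

        for key in remaining:
            if remaining[key] <= 0:
                continue
            st, sx = key
            idx = np.flatnonzero((status == st) & (sex == sx))[: remaining[key]]
            if idx.size:
                kept_dos.append(dos[idx])
                kept_g.append(g[idx])
                kept_liab.append(liab[idx])
                kept_sex.append(sex[idx])
                kept_status.append(status[idx])
                remaining[key] -= idx.size

    dosage = np.concatenate(kept_dos) if kept_dos else np.empty((0, m))
    g_value = np.concatenate(kept_g) if kept_g else np.empty(0)
    liab_all = np.concatenate(kept_liab) if kept_liab else np.empty(0)
    sex = np.concatenate(kept_sex) if kept_sex else np.empty(0, dtype="U1")
    status = np.concatenate(kept_status) if kept_status else np.empty(0, dtype=int)

    # stable ordering: cases first, controls after (each in acceptance order)
    order = np.argsort(-status, kind="stable")
    dosage, g_value, sex, status = dosage[order], g_value[order], sex[order], status[order]
    liab_all = liab_all[order]
    n = len(status)
    ids = np.array([f"ind{str(i).zfill(6)}" for i in range(n)])

    if config.h2_liability > 0:
        g_std = g_value / np.sqrt(config.h2_liability)
    else:
        g_std = np.zeros(n)

    # phenotypes
    rng_chron = _rng(base_seed, None, _STREAM_CHRONICITY)
    rng_demo = _rng(base_seed, None, _STREAM_DEMOGRAPHICS)
    is_case = status == 1
    chron = {marker: np.full(n, np.nan) for marker in CHRONICITY_MARKERS}
    if is_case.any():
        drawn_chron = _draw_chronicity(config, g_std[is_case], sex[is_case], rng_chron)
        for marker in CHRONICITY_MARKERS:
            chron[marker][is_case] = drawn_chron[marker]

    followup = np.full(n, np.nan)
    age = np.full(n, np.nan)
    n_cases_out = int(is_case.sum())
    if n_cases_out:
        fu_a = (1.0 - config.followup_mean_years) / config.followup_sd_years
        followup[is_case] = stats.truncnorm.rvs(
            fu_a, np.inf, loc=config.followup_mean_years, scale=config.followup_sd_years,
            size=n_cases_out, random_state=rng_demo,
        )
        age_a = (13.0 - config.age_mean) / config.age_sd
        age[is_case] = stats.truncnorm.rvs(
            age_a, np.inf, loc=config.age_mean, scale=config.age_sd,
            size=n_cases_out, random_state=rng_demo,
        )

    pheno = pd.DataFrame(
        {
            "individual_id": ids,
            "case_status": status,
            "sex": sex,
            "age_at_diagnosis": age,
            "follow_up_years": followup,
            **{marker: chron[marker] for marker in CHRONICITY_MARKERS},
        }
    )
    if return_liability:
        pheno["liability"] = liab_all

    # covariates: pure-noise PCs, uniform batches
    rng_cov = _rng(base_seed, None, _STREAM_COVARIATES)
    pcs = rng_cov.normal(0.0, 1.0, size=(n, config.n_pcs))
    batch = rng_cov.integers(1, config.n_batches + 1, size=n)
    covars = pd.DataFrame(
        {"individual_id": ids}
        | {f"pc_{k + 1}": pcs[:, k] for k in range(config.n_pcs)}
        | {"batch": [f"batch_{b}" for b in batch]}
    )

    # genotype orientation: the file may count either allele
    variants = sumstats[["variant_id", "effect_allele", "other_allele"]].copy()
    variants.columns = ["variant_id", "counted_allele", "other_allele"]
    if randomize_counted_allele:
        rng_orient = _rng(base_seed, None, _STREAM_ORIENTATION)
        flip = rng_orient.random(m) < 0.5
        dosage[:, flip] = 2.0 - dosage[:, flip]
        counted = variants["counted_allele"].to_numpy().copy()
        other = variants["other_allele"].to_numpy().copy()
        variants["counted_allele"] = np.where(flip, other, counted)
        variants["other_allele"] = np.where(flip, counted, other)

    if config.missing_rate > 0:
        rng_miss = _rng(base_seed, None, _STREAM_MISSING)
        dosage[rng_miss.random(dosage.shape) < config.missing_rate] = np.nan

    genotypes = GenotypeMatrix(individual_ids=ids, variants=variants, dosage=dosage)
    return genotypes, pheno, covars
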