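"""Synthetic biobank cohort generator.

Emulates the statistical structure the MR-PheWAS analysis assumes about
an individual-level cohort: Hardy-Weinberg genotypes at the instrument
SNPs, four standardized iron biomarkers with the concordant sign
pattern (serum iron, log10 ferritin, and transferrin saturation rise
with the iron-raising allele; transferrin falls), hospital ICD events
drawn from per-phecode logistic disease models with configurable causal
iron effects and direct (pleiotropic) SNP effects, and related pairs
above or below the 0.0884 kinship-pruning threshold.

Everything is seeded: each stage draws from its own stream keyed by
``(seed, stage_name)``, so a fixed seed yields a byte-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .instruments import BIOMARKERS

#: Loadings of the three secondary biomarkers on standardized serum iron.
#: Signs encode the concordant iron-status pattern; transferrin opposes it.
BIOMARKER_LOADINGS: Dict[str, float] = {
    "log10_ferritin": 0.45,
    "transferrin": -0.60,
    "transferrin_saturation": 0.75,
}

#: Kinship coefficient above which one member of a pair is pruned
#: (~second-degree relatives).
KINSHIP_THRESHOLD: float = 0.0884

COVARIATE_COLUMNS = ("age", "sex", "array", "pc1", "pc2", "pc3", "pc4")


@dataclass
class SnpDef:
    """One simulated instrument SNP: allele labels, frequency, iron effect."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta_iron_sd_units: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eaf) and 0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.rsid}: EAF must be finite and in (0,1), got {self.eaf}")
        if not np.isfinite(self.beta_iron_sd_units):
            raise ValueError(f"{self.rsid}: non-finite iron effect")


@dataclass
class PhecodeScenario:
    """Disease model for one phecode.

    ``causal_log_or_per_sd_iron`` acts through serum iron;
    ``direct_snp_log_ors`` inject pleiotropy (SNP -> outcome paths that
    bypass iron).  ``sex_ratio`` is the expected female fraction among
    cases in a 50/50 population, implemented as a female log-odds shift
    of logit(sex_ratio).
    """

    phecode_id: str
    baseline_prevalence: float
    causal_log_or_per_sd_iron: float = 0.0
    direct_snp_log_ors: Dict[str, float] = field(default_factory=dict)
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ValueError(
                f"{self.phecode_id}: baseline prevalence must be in (0,1), "
                f"got {self.baseline_prevalence}"
            )
        if not (0.0 < self.sex_ratio < 1.0):
            raise ValueError(f"{self.phecode_id}: sex_ratio must be in (0,1)")


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic cohort."""

    n_individuals: int
    snps: List[SnpDef]
    phecode_scenarios: List[PhecodeScenario]
    biomarker_noise_sd: float = 0.981  # sqrt(1 - 0.038): unit-variance serum iron
    n_related_pairs: int = 0
    kinship_range: Tuple[float, float] = (0.09, 0.25)
    age_log_or_per_year: float = 0.02  # modest default so adjustment is exercised
    female_fraction: float = 0.54
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (np.isfinite(self.biomarker_noise_sd) and self.biomarker_noise_sd >= 0):
            raise ValueError("biomarker_noise_sd must be a nonnegative finite number")
        if self.n_related_pairs < 0:
            raise ValueError("n_related_pairs must be nonnegative")
        if self.n_related_pairs > self.n_individuals // 2:
            raise ValueError("n_related_pairs may not exceed n_individuals/2")
        lo, hi = self.kinship_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("kinship_range must satisfy 0 <= low <= high <= 0.5")
        seen = set()
        for sc in self.phecode_scenarios:
            if sc.phecode_id in seen:
                raise ValueError(f"duplicate phecode scenario {sc.phecode_id}")
            seen.add(sc.phecode_id)

    @property
    def rsids(self) -> List[str]:
        return [s.rsid for s in self.snps]


@dataclass
class SyntheticCohort:
    """Individual-level tables of one simulated cohort."""

    genotypes: pd.DataFrame  # person_id index, one dosage column per rsid
    covariates: pd.DataFrame  # person_id index, COVARIATE_COLUMNS
    biomarkers: pd.DataFrame  # person_id index, BIOMARKERS columns
    icd_events: pd.DataFrame  # long: person_id, icd_version, code
    kinship: pd.DataFrame  # id_a, id_b, coefficient
    config: ScenarioConfig


def generate_genotypes(config: ScenarioConfig) -> pd.DataFrame:
    """Sample HWE dosages: column j ~ Binomial(2, eaf_j), independent SNPs."""
    rng = stage_rng(config.seed, "genotypes")
    n = config.n_individuals
    cols = {}
    for snp in config.snps:
        cols[snp.rsid] = rng.binomial(2, snp.eaf, size=n).astype(np.int8)
    df = pd.DataFrame(cols, index=pd.RangeIndex(n, name="person_id"))
    return df


def generate_covariates(config: ScenarioConfig) -> pd.DataFrame:
    """Age (years, 40-70), sex (1=female), genotyping array, 4 PCs."""
    rng = stage_rng(config.seed, "covariates")
    n = config.n_individuals
    df = pd.DataFrame(
        {
            "age": rng.uniform(40.0, 70.0, size=n),
            "sex": (rng.random(n) < config.female_fraction).astype(np.int8),
            "array": (rng.random(n) < 0.10).astype(np.int8),
            "pc1": rng.normal(size=n),
            "pc2": rng.normal(size=n),
            "pc3": rng.normal(size=n),
            "pc4": rng.normal(size=n),
        },
        index=pd.RangeIndex(n, name="person_id"),
    )
    return df


def generate_biomarkers(genotypes: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Serum iron = sum_j dosage_j * beta_j + Normal(0, noise_sd^2).

    The other three biomarkers are fixed linear loadings on serum iron
    plus independent noise sized so every biomarker has unit marginal
    variance when serum iron does; transferrin's loading is negative.
    """
    if list(genotypes.columns) != config.rsids:
        raise ValueError("genotype columns do not match config.snps")
    rng = stage_rng(config.seed, "biomarkers")
    n = len(genotypes)
    betas = np.array([s.beta_iron_sd_units for s in config.snps])
    iron = genotypes.to_numpy(dtype=float) @ betas + rng.normal(
        0.0, config.biomarker_noise_sd, size=n
    )
    out = {"serum_iron": iron}
    for name, loading in BIOMARKER_LOADINGS.items():
        resid_sd = math.sqrt(max(1.0 - loading**2, 0.0))
        out[name] = loading * iron + rng.normal(0.0, resid_sd, size=n)
    df = pd.DataFrame(out, index=genotypes.index)
    return df[list(BIOMARKERS)]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def generate_phenome(
    genotypes: pd.DataFrame,
    biomarkers: pd.DataFrame,
    covariates: pd.DataFrame,
    config: ScenarioConfig,
    phecode_map: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Draw case status per phecode and emit one ICD event per case.

    logit P(case) = logit(prevalence) + causal_effect * serum_iron
                    + sum_j direct_effect_j * dosage_j
                    + age and sex terms.
    Null phecodes have all genetic and causal terms zero.
    """
    if phecode_map is None:
        phecode_map = synthetic_scenario_map(config)
    from .phecodes import _normalize_code  # local import to avoid a cycle

    code_for: Dict[str, Tuple[int, str]] = {}
    for _, r in phecode_map.iterrows():
        pid = str(r["phecode"])
        if pid not in code_for:
            code_for[pid] = (int(r["icd_version"]), _normalize_code(str(r["icd_code"])))
    missing = [sc.phecode_id for sc in config.phecode_scenarios if sc.phecode_id not in code_for]
    if missing:
        raise ValueError(f"phecodes with no mapped ICD code: {missing}")

    rng = stage_rng(config.seed, "phenome")
    iron = biomarkers["serum_iron"].to_numpy()
    age_c = covariates["age"].to_numpy() - 55.0
    sex = covariates["sex"].to_numpy()
    dosages = genotypes.to_numpy(dtype=float)
    rsid_index = {r: j for j, r in enumerate(config.rsids)}
    person_ids = genotypes.index.to_numpy()

    frames = []
    for sc in config.phecode_scenarios:
        eta = np.full(len(iron), _logit(sc.baseline_prevalence))
        if sc.causal_log_or_per_sd_iron != 0.0:
            eta = eta + sc.causal_log_or_per_sd_iron * iron
        for rsid, lor in sc.direct_snp_log_ors.items():
            if rsid not in rsid_index:
                raise ValueError(f"{sc.phecode_id}: direct effect on unknown SNP {rsid}")
            if lor != 0.0:
                eta = eta + lor * dosages[:, rsid_index[rsid]]
        eta = eta + config.age_log_or_per_year * age_c
        if sc.sex_ratio != 0.5:
            eta = eta + _logit(sc.sex_ratio) * sex
        p = 1.0 / (1.0 + np.exp(-eta))
        case = rng.random(len(p)) < p
        version, code = code_for[sc.phecode_id]
        ids = person_ids[case]
        frames.append(
            pd.DataFrame(
                {
                    "person_id": ids,
                    "icd_version": np.full(len(ids), version, dtype=np.int8),
                    "code": code,
                }
            )
        )
    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = pd.DataFrame(columns=["person_id", "icd_version", "code"])
    return events


def generate_kinship(config: ScenarioConfig) -> pd.DataFrame:
    """Emit disjoint related pairs with coefficients from kinship_range."""
    rng = stage_rng(config.seed, "kinship")
    k = config.n_related_pairs
    if k == 0:
        return pd.DataFrame(columns=["id_a", "id_b", "coefficient"])
    # Disjoint by construction: pair up a random draw of 2k individuals.
    chosen = rng.choice(config.n_individuals, size=2 * k, replace=False)
    lo, hi = config.kinship_range
    coef = rng.uniform(lo, hi, size=k)
    return pd.DataFrame(
        {"id_a": chosen[0::2], "id_b": chosen[1::2], "coefficient": coef}
    )


def generate_cohort(
    config: ScenarioConfig, phecode_map: Optional[pd.DataFrame] = None
) -> SyntheticCohort:
    """Run all four generator stages under one seed."""
    genotypes = generate_genotypes(config)
    covariates = generate_covariates(config)
    biomarkers = generate_biomarkers(genotypes, config)
    icd_events = generate_phenome(genotypes, biomarkers, covariates, config, phecode_map)
    kinship = generate_kinship(config)
    return SyntheticCohort(genotypes, covariates, biomarkers, icd_events, kinship, config)


# ---------------------------------------------------------------------------
# Scenario builders


def calibrated_snps(
    instruments: Optional[Sequence] = None, target_r2: float = 0.038
) -> List[SnpDef]:
    """Instrument SNPs with iron effects rescaled so that, under HWE,
    they explain exactly ``target_r2`` of unit-variance serum iron."""
    from .instruments import instrument_r2_serum_iron, load_instruments

    if instruments is None:
        instruments = load_instruments()
    raw_r2 = instrument_r2_serum_iron(list(instruments))
    scale = math.sqrt(target_r2 / raw_r2)
    return [
        SnpDef(
            rsid=s.rsid,
            effect_allele=s.effect_allele,
            other_allele=s.other_allele,
            eaf=s.eaf,
            beta_iron_sd_units=s.beta["serum_iron"] * scale,
        )
        for s in instruments
    ]


def noise_sd_for_unit_variance(snps: Sequence[SnpDef]) -> float:
    """Residual SD giving serum iron unit marginal variance under HWE."""
    genetic_var = sum(2 * s.eaf * (1 - s.eaf) * s.beta_iron_sd_units**2 for s in snps)
    if genetic_var >= 1.0:
        raise ValueError("genetic variance alone exceeds the unit target")
    return math.sqrt(1.0 - genetic_var)


def null_scenario(
    n_individuals: int = 20_000,
    n_phecodes: int = 100,
    prevalence: float = 0.05,
    seed: int = 0,
    n_related_pairs: int = 0,
) -> ScenarioConfig:
    """Global-null phenome: no causal iron effects, no pleiotropy."""
    snps = calibrated_snps()
    scenarios = [
        PhecodeScenario(phecode_id=f"{100 + i}.1", baseline_prevalence=prevalence)
        for i in range(n_phecodes)
    ]
    return ScenarioConfig(
        n_individuals=n_individuals,
        snps=snps,
        phecode_scenarios=scenarios,
        biomarker_noise_sd=noise_sd_for_unit_variance(snps),
        n_related_pairs=n_related_pairs,
        seed=seed,
    )


#: Disease-category vocabulary used for synthetic phenome maps.
CATEGORIES = (
    "Circulatory system", "Congenital anomalies", "Dermatologic", "Digestive",
    "Endocrine/metabolic", "Genitourinary", "Hematopoietic", "Infectious diseases",
    "Injuries and poisonings", "Mental disorders", "Musculoskeletal", "Neoplasms",
    "Neurological", "Pregnancy complications", "Respiratory", "Sense organs",
    "Symptoms",
)


def paper_like_scenario(
    n_individuals: int = 50_000,
    n_phecodes: int = 904,
    n_causal: int = 10,
    n_pleiotropic: int = 4,
    causal_log_or: float = math.log(0.72),
    pleiotropic_log_or: float = math.log(1.5),
    signal_prevalence: float = 0.08,
    seed: int = 0,
    n_related_pairs: int = 500,
) -> ScenarioConfig:
    """Phenome-scale scenario: mostly null phecodes, a block of causal
    outcomes at the iron-deficiency-anemia effect size (OR 0.72 per SD
    serum iron), and a block of single-SNP pleiotropic outcomes that
    Cochran Q should flag.  Null prevalences spread log-uniformly
    (seeded) so the 200-case filter is exercised realistically; the
    non-null blocks are common outcomes (``signal_prevalence``),
    mirroring the fact that detectable phenome-scan signals are
    common diagnoses, which keeps the scan powered at cohort sizes far
    below biobank scale.
    """
    snps = calibrated_snps()
    rng = stage_rng(seed, "scenario-prevalences")
    prevalences = np.exp(rng.uniform(math.log(0.008), math.log(0.10), size=n_phecodes))
    prevalences[: n_causal + n_pleiotropic] = signal_prevalence
    scenarios = []
    for i in range(n_phecodes):
        # one integer root per phecode: outcomes are distinct diseases, so
        # no cross-exclusion couples their control pools
        pid = f"{100 + i}.1"
        causal = 0.0
        direct: Dict[str, float] = {}
        if i < n_causal:
            causal = causal_log_or
        elif i < n_causal + n_pleiotropic:
            direct = {snps[0].rsid: pleiotropic_log_or}
        scenarios.append(
            PhecodeScenario(
                phecode_id=pid,
                baseline_prevalence=float(prevalences[i]),
                causal_log_or_per_sd_iron=causal,
                direct_snp_log_ors=direct,
            )
        )
    return ScenarioConfig(
        n_individuals=n_individuals,
        snps=snps,
        phecode_scenarios=scenarios,
        biomarker_noise_sd=noise_sd_for_unit_variance(snps),
        n_related_pairs=n_related_pairs,
        seed=seed,
    )


def synthetic_scenario_map(config: ScenarioConfig) -> pd.DataFrame:
    """Build a synthetic one-code-per-phecode ICD-10 map for a scenario.

    Codes are 'Y' + phecode digits (dot removed); exclusion root is the
    integer part of the phecode, so sibling phecodes (same integer part)
    exclude each other's cases from controls.
    """
    rows = []
    for i, sc in enumerate(config.phecode_scenarios):
        pid = sc.phecode_id
        rows.append(
            {
                "icd_version": 10,
                "icd_code": "Y" + pid.replace(".", ""),
                "phecode": pid,
                "exclusion_root": pid.split(".")[0],
                "description": f"Synthetic phenotype {pid}",
                "category": CATEGORIES[i % len(CATEGORIES)],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O

_TABLES = ("genotypes", "covariates", "biomarkers", "icd_events", "kinship")


def write_cohort(cohort: SyntheticCohort, out_dir: Path | str) -> None:
    """Write the five cohort tables as UTF-8 tab-delimited files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.genotypes.to_csv(out / "genotypes.tsv", sep="\t")
    cohort.covariates.to_csv(out / "covariates.tsv", sep="\t", float_format="%.10g")
    cohort.biomarkers.to_csv(out / "biomarkers.tsv", sep="\t", float_format="%.10g")
    cohort.icd_events.to_csv(out / "icd_events.tsv", sep="\t", index=False)
    cohort.kinship.to_csv(out / "kinship.tsv", sep="\t", index=False, float_format="%.10g")


def read_cohort(in_dir: Path | str, config: Optional[ScenarioConfig] = None) -> SyntheticCohort:
    """Read tables written by :func:`write_cohort`."""
    p = Path(in_dir)
    genotypes = pd.read_csv(p / "genotypes.tsv", sep="\t", index_col="person_id")
    covariates = pd.read_csv(p / "covariates.tsv", sep="\t", index_col="person_id")
    biomarkers = pd.read_csv(p / "biomarkers.tsv", sep="\t", index_col="person_id")
    icd_events = pd.read_csv(
        p / "icd_events.tsv", sep="\t", dtype={"code": str}
    )
    kinship = pd.read_csv(p / "kinship.tsv", sep="\t")
    return SyntheticCohort(genotypes, covariates, biomarkers, icd_events, kinship, config)
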