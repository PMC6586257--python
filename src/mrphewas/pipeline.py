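"""Phenome-scan orchestration: FDR, heterogeneity screening, reporting.

Runs the full chain - relatedness pruning, ICD -> phecode case/control
construction, the 200-case filter, per-SNP logistic PheWAS, summary MR
per phecode (ratio, IVW, Cochran Q, weighted median) - then applies
Benjamini-Hochberg FDR at 5% across the IVW p-values and splits the
significant outcomes into those with consistent evidence across
instruments and those excluded for heterogeneity (Q p < 0.05).
Sex-stratified estimates and rescaling to the other iron biomarkers are
computed for the consistent outcomes only.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import BIOMARKERS, InstrumentSNP, load_instruments
from .mr import (
    IVWResult,
    RatioEstimate,
    WeightedMedianResult,
    ivw_meta,
    ratios_for_biomarker,
    weighted_median_from_ratios,
)
from .phecodes import (
    CaseControlSet,
    build_case_control,
    filter_min_cases,
    load_phecode_map,
    map_icd_to_phecodes,
    phecode_defs,
    prune_related,
)
from .phewas import AssociationEstimate, associations_to_frame, run_phewas
from .simulate import KINSHIP_THRESHOLD, SyntheticCohort


@dataclass
class RunConfig:
    """Thresholds and sizes governing one discovery run."""

    min_cases: int = 200
    fdr_q: float = 0.05
    fdr_method: str = "bh"
    q_alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    sd_serum_iron: float = 6.1
    kinship_threshold: float = KINSHIP_THRESHOLD
    stratify_sex: bool = True
    rescale_biomarkers: bool = True
    instrument_r2: float = 0.038  # advisory power column only

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        for name in ("fdr_q", "q_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.fdr_method not in ("bh", "by"):
            raise ValueError(f"fdr_method must be 'bh' or 'by', got {self.fdr_method!r}")


@dataclass
class PhewasMrRow:
    """One phenotype's full MR-PheWAS record."""

    phecode_id: str
    description: str
    category: str
    n_cases: int
    n_controls: int
    ratios: List[RatioEstimate]
    ivw: IVWResult
    wm: Optional[WeightedMedianResult]
    fdr_significant: bool = False
    heterogeneous: bool = False
    sex_stratum: str = "all"


@dataclass
class PipelineResult:
    """Everything a discovery run produces."""

    rows: List[PhewasMrRow]
    consistent: List[PhewasMrRow]
    heterogeneous_excluded: List[PhewasMrRow]
    associations: List[AssociationEstimate]
    stratified: Dict[str, List[PhewasMrRow]] = field(default_factory=dict)
    rescaled: Dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: Dict = field(default_factory=dict)
    realized_threshold: float = float("nan")


def bh_fdr(
    p_values: Sequence[float], q: float = 0.05, method: str = "bh"
) -> Tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up (default) or Benjamini-Yekutieli.

    Flags p_(i) <= (i/m) q for every i up to the largest index where
    the condition holds.  Returns (flags in input order, realized
    threshold (k/m) q for k flags; 0.0 when nothing is flagged).
    ``method='by'`` divides q by the harmonic sum H_m for FDR control
    under arbitrary dependence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr needs at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method not in ("bh", "by"):
        raise ValueError(f"method must be 'bh' or 'by', got {method!r}")
    m = p.size
    if method == "by":
        q = q / np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(ranked <= crit)[0]
    flags = np.zeros(m, dtype=bool)
    if passing.size == 0:
        return flags, 0.0
    k = passing[-1] + 1
    flags[order[:k]] = True
    return flags, float(k / m * q)


def classify_outcomes(
    rows: Sequence[PhewasMrRow],
) -> Tuple[List[PhewasMrRow], List[PhewasMrRow]]:
    """Split FDR-significant rows into consistent (homogeneous) evidence
    and those excluded for between-instrument heterogeneity."""
    consistent = [r for r in rows if r.fdr_significant and not r.heterogeneous]
    excluded = [r for r in rows if r.fdr_significant and r.heterogeneous]
    return consistent, excluded


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV in percent, 100*sd/mean (descriptive; e.g. serum iron spread)."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def approximate_power(
    log_or: float,
    n_cases: int,
    n_controls: int,
    r2: float = 0.038,
    alpha: float = 0.05,
) -> float:
    """Normal-approximation power of an IVW MR test.

    Advisory only (never used to filter): with case fraction phi and
    total N, the non-centrality is |b| sqrt(N r2 phi (1-phi)).
    """
    n = n_cases + n_controls
    phi = n_cases / n
    ncp = abs(log_or) * np.sqrt(n * r2 * phi * (1 - phi))
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))


def _wm_seed(run_seed: int, phecode_id: str, stratum: str) -> int:
    return (int(run_seed) ^ zlib.crc32(f"{stratum}:{phecode_id}".encode())) & 0x7FFFFFFF


def _mr_rows(
    instruments: Sequence[InstrumentSNP],
    associations: Sequence[AssociationEstimate],
    defs: Dict,
    config: RunConfig,
    stratum: str = "all",
    with_wm: bool = True,
) -> List[PhewasMrRow]:
    """Group converged per-SNP associations by phecode and run the MR chain."""
    by_phecode: Dict[str, Dict[str, AssociationEstimate]] = {}
    for a in associations:
        by_phecode.setdefault(a.phecode_id, {})[a.rsid] = a
    inst_by_rsid = {i.rsid: i for i in instruments}
    rows: List[PhewasMrRow] = []
    for pid in sorted(by_phecode):
        ests = by_phecode[pid]
        if set(ests) != set(inst_by_rsid) or not all(e.converged for e in ests.values()):
            continue  # MR needs every instrument; failures are in the manifest
        ordered_inst = [inst_by_rsid[i.rsid] for i in instruments]
        ordered_out = [ests[i.rsid] for i in instruments]
        ratios = ratios_for_biomarker(ordered_inst, ordered_out, "serum_iron")
        ivw = ivw_meta(ratios)
        wm = None
        if with_wm:
            wm = weighted_median_from_ratios(
                ordered_inst,
                ordered_out,
                "serum_iron",
                n_boot=config.n_boot,
                seed=_wm_seed(config.seed, pid, stratum),
            )
        d = defs.get(pid)
        rows.append(
            PhewasMrRow(
                phecode_id=pid,
                description=d.description if d else "",
                category=d.category if d else "",
                n_cases=min(e.n_cases for e in ests.values()),
                n_controls=min(e.n_controls for e in ests.values()),
                ratios=ratios,
                ivw=ivw,
                wm=wm,
                heterogeneous=bool(ivw.q_p < config.q_alpha),
                sex_stratum=stratum,
            )
        )
    return rows


def run_full_pipeline(
    cohort: SyntheticCohort,
    instruments: Optional[Sequence[InstrumentSNP]] = None,
    phecode_map: Optional[pd.DataFrame] = None,
    config: Optional[RunConfig] = None,
    out_dir: Optional[Path | str] = None,
) -> PipelineResult:
    """Execute the full MR-PheWAS discovery chain on a cohort.

    Deterministic under a fixed ``config.seed``.  When ``out_dir`` is
    given, writes tab-delimited result tables, scatter-plot data, and a
    JSON run manifest.
    """
    config = config or RunConfig()
    if instruments is None:
        instruments = load_instruments()
    if phecode_map is None:
        from .simulate import synthetic_scenario_map

        phecode_map = (
            synthetic_scenario_map(cohort.config)
            if cohort.config is not None
            else load_phecode_map()
        )
    defs = phecode_defs(phecode_map)
    manifest: Dict = {
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if not k.startswith("_")
        },
        "counts": {},
    }
    counts = manifest["counts"]
    counts["n_individuals"] = int(len(cohort.covariates))

    retained = prune_related(
        cohort.covariates.index,
        cohort.kinship,
        threshold=config.kinship_threshold,
        seed=config.seed,
    )
    counts["n_retained"] = len(retained)
    counts["n_pruned"] = counts["n_individuals"] - len(retained)

    incidence = map_icd_to_phecodes(cohort.icd_events, phecode_map)
    counts["n_unmapped_events"] = int(incidence.attrs.get("n_unmapped", 0))
    counts["n_phecodes_mapped"] = int(incidence.shape[1])

    sets = [
        build_case_control(pid, incidence, phecode_map, cohort_ids=retained, defs=defs)
        for pid in incidence.columns
    ]
    kept = filter_min_cases(sets, minimum=config.min_cases)
    counts["n_phecodes_pass_case_filter"] = len(kept)
    counts["n_phecodes_dropped_by_case_filter"] = len(sets) - len(kept)

    effect_alleles = {i.rsid: i.effect_allele for i in instruments}
    genotypes = cohort.genotypes.loc[sorted(retained)]
    associations = run_phewas(
        genotypes,
        kept,
        cohort.covariates,
        effect_alleles=effect_alleles,
        sex_filter="all",
        min_cases=config.min_cases,
    )
    counts["n_fits"] = len(associations)
    counts["n_failed_fits"] = sum(not a.converged for a in associations)

    rows = _mr_rows(instruments, associations, defs, config, "all", with_wm=True)
    counts["n_phecodes_analyzed"] = len(rows)

    result = PipelineResult(
        rows=rows,
        consistent=[],
        heterogeneous_excluded=[],
        associations=associations,
        manifest=manifest,
    )
    if rows:
        flags, threshold = bh_fdr(
            [r.ivw.p for r in rows], q=config.fdr_q, method=config.fdr_method
        )
        for r, f in zip(rows, flags):
            r.fdr_significant = bool(f)
        result.realized_threshold = threshold
        manifest["realized_fdr_threshold"] = threshold
    result.consistent, result.heterogeneous_excluded = classify_outcomes(rows)
    counts["n_fdr_significant"] = sum(r.fdr_significant for r in rows)
    counts["n_consistent"] = len(result.consistent)
    counts["n_heterogeneous_excluded"] = len(result.heterogeneous_excluded)

    # Follow-up analyses for the consistent outcomes only.
    keep_ids = {r.phecode_id for r in result.consistent}
    keep_sets = [s for s in kept if s.phecode_id in keep_ids]
    if config.stratify_sex and keep_sets:
        for stratum in ("male", "female"):
            assoc_s = run_phewas(
                genotypes,
                keep_sets,
                cohort.covariates,
                effect_alleles=effect_alleles,
                sex_filter=stratum,
                min_cases=config.min_cases,
            )
            result.stratified[stratum] = _mr_rows(
                instruments, assoc_s, defs, config, stratum, with_wm=False
            )
    if config.rescale_biomarkers and result.consistent:
        assoc_by_pid: Dict[str, Dict[str, AssociationEstimate]] = {}
        for a in associations:
            assoc_by_pid.setdefault(a.phecode_id, {})[a.rsid] = a
        for biomarker in BIOMARKERS[1:]:
            recs = []
            for r in result.consistent:
                ordered_out = [assoc_by_pid[r.phecode_id][i.rsid] for i in instruments]
                ivw_b = ivw_meta(ratios_for_biomarker(instruments, ordered_out, biomarker))
                recs.append(
                    {
                        "phecode": r.phecode_id,
                        "biomarker": biomarker,
                        "beta": ivw_b.beta,
                        "se": ivw_b.se,
                        "ci_low": ivw_b.ci_low,
                        "ci_high": ivw_b.ci_high,
                        "p": ivw_b.p,
                    }
                )
            result.rescaled[biomarker] = pd.DataFrame(recs)

    if out_dir is not None:
        write_results(result, instruments, out_dir)
    return result


# ---------------------------------------------------------------------------
# Summary-statistics-only entry point


def mr_from_summary_tables(
    instruments: Sequence[InstrumentSNP],
    association_tables: Dict[str, pd.DataFrame],
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Run the MR stage directly from per-SNP summary tables.

    ``association_tables`` maps rsid -> a table shaped like the per-SNP
    PheWAS exports (columns: phecode, effect_allele, beta, se, p,
    n_cases, n_controls).  No individual-level data are touched: this
    is the path by which published per-SNP PheWAS results feed the MR
    chain.  Returns one row per phecode present for every instrument,
    with IVW, Q, weighted-median, and BH-FDR columns.
    """
    config = config or RunConfig()
    inst_rsids = [i.rsid for i in instruments]
    missing = set(inst_rsids) - set(association_tables)
    if missing:
        raise ValueError(f"no association table for instruments: {sorted(missing)}")
    per_snp: Dict[str, Dict[str, AssociationEstimate]] = {}
    for rsid in inst_rsids:
        t = association_tables[rsid]
        if "converged" in t.columns:
            t = t[t["converged"].astype(bool)]
        for _, r in t.iterrows():
            est = AssociationEstimate(
                rsid=rsid,
                phecode_id=str(r["phecode"]),
                beta=float(r["beta"]),
                se=float(r["se"]),
                p=float(r.get("p", 1.0)) if np.isfinite(r.get("p", 1.0)) else 1.0,
                n_cases=int(r.get("n_cases", 0)),
                n_controls=int(r.get("n_controls", 0)),
                effect_allele=str(r.get("effect_allele", "")),
            )
            per_snp.setdefault(est.phecode_id, {})[rsid] = est
    associations = [
        e for pid in sorted(per_snp) for e in per_snp[pid].values()
        if set(per_snp[pid]) == set(inst_rsids)
    ]
    defs: Dict = {}
    rows = _mr_rows(instruments, associations, defs, config, "all", with_wm=True)
    if rows:
        flags, threshold = bh_fdr(
            [r.ivw.p for r in rows], q=config.fdr_q, method=config.fdr_method
        )
        for r, f in zip(rows, flags):
            r.fdr_significant = bool(f)
    return rows_to_frame(rows, config)


# ---------------------------------------------------------------------------
# Reporting


def rows_to_frame(rows: Sequence[PhewasMrRow], config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Flatten result rows into the per-phecode results table."""
    config = config or RunConfig()
    recs = []
    for r in rows:
        rec = {
            "phecode": r.phecode_id,
            "description": r.description,
            "category": r.category,
            "sex_stratum": r.sex_stratum,
            "n_cases": r.n_cases,
            "n_controls": r.n_controls,
        }
        for ratio in r.ratios:
            rec[f"beta_{ratio.rsid}"] = ratio.beta_mr
            rec[f"se_{ratio.rsid}"] = ratio.se_mr
        rec.update(
            {
                "ivw_beta": r.ivw.beta,
                "ivw_se": r.ivw.se,
                "ivw_or": float(np.exp(r.ivw.beta)),
                "ivw_ci_low_or": float(np.exp(r.ivw.ci_low)),
                "ivw_ci_high_or": float(np.exp(r.ivw.ci_high)),
                "ivw_p": r.ivw.p,
                "q_stat": r.ivw.q_stat,
                "q_df": r.ivw.q_df,
                "q_p": r.ivw.q_p,
                "fdr_significant": r.fdr_significant,
                "heterogeneous": r.heterogeneous,
                "approx_power": approximate_power(
                    r.ivw.beta, r.n_cases, r.n_controls, r2=config.instrument_r2
                )
                if r.n_cases
                else np.nan,
            }
        )
        if r.wm is not None:
            rec.update(
                {
                    "wm_beta": r.wm.beta,
                    "wm_se": r.wm.se_boot,
                    "wm_or": float(np.exp(r.wm.beta)),
                    "wm_ci_low_or": float(np.exp(r.wm.ci_low)),
                    "wm_ci_high_or": float(np.exp(r.wm.ci_high)),
                    "wm_p": r.wm.p,
                }
            )
        recs.append(rec)
    return pd.DataFrame(recs)


def scatter_data(
    instruments: Sequence[InstrumentSNP],
    rows: Sequence[PhewasMrRow],
    associations: Sequence[AssociationEstimate],
) -> pd.DataFrame:
    """(gamma, Gamma) pairs with SEs per outcome, for scatter/forest plots."""
    inst = {i.rsid: i for i in instruments}
    assoc = {(a.phecode_id, a.rsid): a for a in associations}
    recs = []
    for r in rows:
        for rsid, i in inst.items():
            a = assoc.get((r.phecode_id, rsid))
            if a is None or not a.converged:
                continue
            sign = 1.0 if a.effect_allele in ("", i.effect_allele) else -1.0
            recs.append(
                {
                    "phecode": r.phecode_id,
                    "rsid": rsid,
                    "gamma": i.beta["serum_iron"],
                    "se_gamma": i.se["serum_iron"],
                    "Gamma": sign * a.beta,
                    "se_Gamma": a.se,
                }
            )
    return pd.DataFrame(recs)


def summarize_cohort(
    cohort: SyntheticCohort,
    case_control_sets: Optional[Iterable[CaseControlSet]] = None,
    phecode_map: Optional[pd.DataFrame] = None,
) -> Dict[str, pd.DataFrame]:
    """Descriptive tables: participant characteristics, and per-disease-
    category phenotype counts with case-count min/median/mean/max."""
    cov = cohort.covariates
    n = len(cov)
    participants = pd.DataFrame(
        [
            {"characteristic": "N", "value": float(n), "dispersion": np.nan},
            {
                "characteristic": "Age, years (SD)",
                "value": float(cov["age"].mean()),
                "dispersion": float(cov["age"].std()),
            },
            {
                "characteristic": "Sex, female (%)",
                "value": float(cov["sex"].sum()),
                "dispersion": float(100.0 * cov["sex"].mean()),
            },
            {
                "characteristic": "Genotyping array (%)",
                "value": float(cov["array"].sum()),
                "dispersion": float(100.0 * cov["array"].mean()),
            },
        ]
    )
    categories = pd.DataFrame(
        columns=["category", "phenotypes", "min", "median", "mean", "max"]
    )
    if case_control_sets is not None:
        if phecode_map is None:
            raise ValueError("phecode_map required to categorize phecodes")
        defs = phecode_defs(phecode_map)
        recs: Dict[str, List[int]] = {}
        for s in case_control_sets:
            cat = defs[s.phecode_id].category if s.phecode_id in defs else ""
            recs.setdefault(cat, []).append(s.n_cases)
        categories = pd.DataFrame(
            [
                {
                    "category": cat,
                    "phenotypes": len(v),
                    "min": int(np.min(v)),
                    "median": float(np.median(v)),
                    "mean": float(np.mean(v)),
                    "max": int(np.max(v)),
                }
                for cat, v in sorted(recs.items())
            ]
        )
    return {"participants": participants, "categories": categories}


def write_results(
    result: PipelineResult,
    instruments: Sequence[InstrumentSNP],
    out_dir: Path | str,
) -> None:
    """Write tab-delimited result tables plus the JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = RunConfig(**{
        k: v for k, v in result.manifest.get("config", {}).items()
    }) if result.manifest.get("config") else RunConfig()
    rows_to_frame(result.rows, config).to_csv(out / "results.tsv", sep="\t", index=False)
    rows_to_frame(result.consistent, config).to_csv(
        out / "results_consistent.tsv", sep="\t", index=False
    )
    assoc = associations_to_frame(result.associations)
    for rsid, grp in assoc.groupby("rsid"):
        grp.to_csv(out / f"phewas_{rsid}.tsv", sep="\t", index=False)
    scatter_data(instruments, result.rows, result.associations).to_csv(
        out / "scatter.tsv", sep="\t", index=False
    )
    for stratum, rows in result.stratified.items():
        rows_to_frame(rows, config).to_csv(
            out / f"results_{stratum}.tsv", sep="\t", index=False
        )
    for biomarker, df in result.rescaled.items():
        df.to_csv(out / f"rescaled_{biomarker}.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
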