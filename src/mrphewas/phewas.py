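"""Per-SNP, per-phecode covariate-adjusted logistic regression.

Each instrument SNP is regressed against each phecode's case/control
outcome with an additive dosage coding, adjusting for age, sex,
genotyping array, and the first four genetic principal components.
The fitted log odds ratio (per copy of the effect allele), its Wald
standard error, and a two-sided normal p-value form the SNP-outcome
summary statistic consumed by the MR stage.

Fits use plain maximum likelihood (Newton, coefficient tolerance
1e-10, 100 iterations).  Non-convergence or separation produces a
flagged failure record rather than an exception, so a phenome scan
never aborts on a single pathological phecode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phecodes import CaseControlSet

P_FLOOR = 1e-300


@dataclass
class AssociationEstimate:
    """Summary association of one SNP with one phecode (log-OR units)."""

    rsid: str
    phecode_id: str
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    effect_allele: str
    converged: bool = True
    failure_reason: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if not np.isfinite(self.beta):
                raise ValueError(f"{self.rsid}/{self.phecode_id}: non-finite beta")
            if not (np.isfinite(self.se) and self.se > 0):
                raise ValueError(f"{self.rsid}/{self.phecode_id}: SE must be positive")
            if not (0.0 < self.p <= 1.0):
                raise ValueError(f"{self.rsid}/{self.phecode_id}: p outside (0,1]")


_COVARIATES_FULL = ["age", "sex", "array", "pc1", "pc2", "pc3", "pc4"]
_COVARIATES_STRATIFIED = ["age", "array", "pc1", "pc2", "pc3", "pc4"]


def _firth_logit(y: np.ndarray, x: np.ndarray, maxiter: int = 500, tol: float = 1e-10):
    """Firth-penalized logistic regression (Jeffreys-prior score).

    The score is augmented with the hat-diagonal correction
    U*_j = sum_i (y_i - p_i + h_i (1/2 - p_i)) x_ij, which keeps
    estimates finite under separation.  Newton steps with step-halving
    on the penalized log-likelihood.  Returns (params, bse, converged).
    """
    n, k = x.shape

    def _state(beta):
        eta = np.clip(x @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        info = x.T @ (x * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return p, w, info, -np.inf
        pll = np.sum(y * eta - np.log1p(np.exp(eta))) + 0.5 * logdet
        return p, w, info, pll

    beta = np.zeros(k)
    p, w, info, pll = _state(beta)
    for _ in range(maxiter):
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return beta, np.full(k, np.nan), False
        xw = x * w[:, None]
        h = np.einsum("ij,jk,ik->i", xw, cov, x)
        score = x.T @ (y - p + h * (0.5 - p))
        # the penalized score vanishes at the (always finite) optimum;
        # the step criterion alone stalls on flat separated likelihoods
        if np.max(np.abs(score)) < 1e-4:
            return beta, np.sqrt(np.diag(cov)), True
        step = cov @ score
        # step-halving: the penalized likelihood must not decrease
        for _ in range(25):
            cand = beta + step
            p_c, w_c, info_c, pll_c = _state(cand)
            if pll_c >= pll - 1e-12:
                break
            step = step / 2.0
        beta, p, w, info, pll = cand, p_c, w_c, info_c, pll_c
        if np.max(np.abs(step)) < tol:
            try:
                cov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                return beta, np.full(k, np.nan), False
            return beta, np.sqrt(np.diag(cov)), True
    return beta, np.full(k, np.nan), False


def fit_snp_phecode(
    dosage: pd.Series,
    case_control: CaseControlSet,
    covariates: pd.DataFrame,
    rsid: str = "",
    effect_allele: str = "",
    covariate_columns: Optional[List[str]] = None,
    firth: bool = False,
) -> AssociationEstimate:
    """MLE logistic fit of one phecode's outcome on one SNP's dosage.

    The excluded set (related-phecode carriers) is omitted entirely;
    the model is fit on cases union controls.  ``firth=True`` applies
    the Jeffreys-prior penalty, useful for rare outcomes prone to
    separation.
    """
    if case_control.n_cases == 0 or case_control.n_controls == 0:
        raise ValueError(
            f"{case_control.phecode_id}: needs >=1 case and >=1 control"
        )
    ids = sorted(case_control.case_ids | case_control.control_ids)
    idx = pd.Index(ids)
    cols = _COVARIATES_FULL if covariate_columns is None else covariate_columns
    missing = covariates.loc[idx, cols].isna().any(axis=None)
    if missing:
        raise ValueError(f"{case_control.phecode_id}: incomplete covariates")
    x = np.column_stack(
        [
            np.ones(len(idx)),
            dosage.loc[idx].to_numpy(dtype=float),
            covariates.loc[idx, cols].to_numpy(dtype=float),
        ]
    )
    y = np.fromiter((i in case_control.case_ids for i in ids), dtype=bool, count=len(ids))
    rsid = rsid or (dosage.name or "snp")
    try:
        if firth:
            params, bse, converged = _firth_logit(y.astype(float), x)
            beta, se = float(params[1]), float(bse[1])
        else:
            fit = sm.Logit(y, x).fit(disp=0, method="newton", maxiter=100, tol=1e-10)
            converged = bool(fit.mle_retvals.get("converged", False))
            beta = float(fit.params[1])
            se = float(fit.bse[1])
        ok = converged and np.isfinite(beta) and np.isfinite(se) and se > 0
        reason = "" if ok else "non-convergence or unstable standard error"
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        ok, beta, se, reason = False, np.nan, np.nan, f"{type(e).__name__}: {e}"
    if not ok:
        return AssociationEstimate(
            rsid=rsid,
            phecode_id=case_control.phecode_id,
            beta=np.nan,
            se=np.nan,
            p=np.nan,
            n_cases=case_control.n_cases,
            n_controls=case_control.n_controls,
            effect_allele=effect_allele,
            converged=False,
            failure_reason=reason or "did not converge",
        )
    z = beta / se
    p = max(2.0 * stats.norm.sf(abs(z)), P_FLOOR)
    return AssociationEstimate(
        rsid=rsid,
        phecode_id=case_control.phecode_id,
        beta=beta,
        se=se,
        p=float(p),
        n_cases=case_control.n_cases,
        n_controls=case_control.n_controls,
        effect_allele=effect_allele,
    )


def run_phewas(
    genotypes: pd.DataFrame,
    case_control_sets: Iterable[CaseControlSet],
    covariates: pd.DataFrame,
    effect_alleles: Optional[Dict[str, str]] = None,
    sex_filter: str = "all",
    min_cases: int = 200,
) -> List[AssociationEstimate]:
    """Scan every (SNP, phecode) pair; collect estimates and failures.

    ``sex_filter`` restricts to one genetic sex ('male'/'female'); the
    sex covariate is then dropped and the minimum-case filter is
    re-applied within the stratum.  Output order is (phecode, SNP),
    deterministic given inputs.
    """
    if sex_filter not in ("all", "male", "female"):
        raise ValueError(f"sex_filter must be all/male/female, got {sex_filter!r}")
    effect_alleles = effect_alleles or {}
    if sex_filter == "all":
        stratum_ids = None
        cols = _COVARIATES_FULL
    else:
        want = 1 if sex_filter == "female" else 0
        stratum_ids = set(covariates.index[covariates["sex"] == want].astype(int))
        cols = _COVARIATES_STRATIFIED
    out: List[AssociationEstimate] = []
    for cc in case_control_sets:
        if stratum_ids is not None:
            cc = CaseControlSet(
                cc.phecode_id,
                cc.case_ids & stratum_ids,
                cc.control_ids & stratum_ids,
                cc.excluded_ids & stratum_ids,
            )
            if cc.n_cases < min_cases:
                continue
        if cc.n_cases == 0 or cc.n_controls == 0:
            continue
        for rsid in genotypes.columns:
            out.append(
                fit_snp_phecode(
                    genotypes[rsid],
                    cc,
                    covariates,
                    rsid=rsid,
                    effect_allele=effect_alleles.get(rsid, ""),
                    covariate_columns=cols,
                )
            )
    return out


def associations_to_frame(estimates: Iterable[AssociationEstimate]) -> pd.DataFrame:
    """Tabulate estimates in the per-SNP summary-table shape
    (phecode, beta in log-OR units, se, p, case/control counts)."""
    return pd.DataFrame(
        [
            {
                "rsid": e.rsid,
                "phecode": e.phecode_id,
                "effect_allele": e.effect_allele,
                "beta": e.beta,
                "se": e.se,
                "p": e.p,
                "n_cases": e.n_cases,
                "n_controls": e.n_controls,
                "converged": e.converged,
                "failure_reason": e.failure_reason,
            }
            for e in estimates
        ]
    )
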