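"""Two-sample summary-data Mendelian randomization.

For each instrument SNP j with exposure association gamma_j (SD units
of serum iron) and outcome association Gamma_j (log-OR per effect
allele), the causal effect of a 1 SD increase in serum iron on the
outcome is estimated by the ratio (Wald) method:

    beta_j = Gamma_j / gamma_j

with a second-order delta-method standard error that retains the
uncertainty of the SNP-exposure association (zero exposure-outcome
covariance, as the two samples are independent):

    se_j^2 = se_Gamma^2 / gamma^2 + Gamma^2 * se_gamma^2 / gamma^4

Per-SNP ratios are pooled by fixed-effect inverse-variance-weighted
(IVW) meta-analysis; heterogeneity between instruments (a signature of
pleiotropy) is screened with Cochran's Q; and the precision-weighted
median provides a sensitivity estimate that stays consistent when
instruments carrying more than half the weight are valid, with its
standard error obtained by parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats

from ._rng import stage_rng
from .instruments import BIOMARKERS, InstrumentSNP
from .phewas import AssociationEstimate, P_FLOOR

Z975 = 1.959963984540054  # normal 97.5% quantile; CIs are beta +/- 1.96*se


@dataclass
class RatioEstimate:
    """Per-instrument causal estimate, log-OR per 1 SD of the exposure."""

    rsid: str
    beta_mr: float
    se_mr: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta_mr):
            raise ValueError(f"{self.rsid}: non-finite ratio estimate")
        if not (np.isfinite(self.se_mr) and self.se_mr > 0):
            raise ValueError(f"{self.rsid}: ratio SE must be positive")

    @property
    def weight(self) -> float:
        return 1.0 / self.se_mr**2


@dataclass
class IVWResult:
    """Fixed-effect IVW pooled estimate with Cochran Q heterogeneity."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q_stat: float = np.nan
    q_df: int = 0
    q_p: float = np.nan


@dataclass
class WeightedMedianResult:
    """Precision-weighted median estimate with bootstrap SE."""

    beta: float
    se_boot: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    seed: int


def harmonize(
    instrument: InstrumentSNP, outcome: AssociationEstimate
) -> Tuple[InstrumentSNP, AssociationEstimate]:
    """Align the outcome association to the instrument's effect allele.

    If the outcome was coded on the instrument's other allele, its beta
    is negated and allele labels swapped.  Allele pairs that do not
    match as an unordered pair are a hard data error: the iron
    instruments are non-palindromic, so no strand-flip inference is
    attempted.
    """
    if instrument.rsid != outcome.rsid:
        raise ValueError(
            f"rsid mismatch: instrument {instrument.rsid} vs outcome {outcome.rsid}"
        )
    inst_pair = {instrument.effect_allele, instrument.other_allele}
    if not outcome.effect_allele:
        raise ValueError(f"{outcome.rsid}: outcome record lacks an effect allele")
    if outcome.effect_allele == instrument.effect_allele:
        return instrument, outcome
    if outcome.effect_allele == instrument.other_allele:
        flipped = AssociationEstimate(
            rsid=outcome.rsid,
            phecode_id=outcome.phecode_id,
            beta=-outcome.beta,
            se=outcome.se,
            p=outcome.p,
            n_cases=outcome.n_cases,
            n_controls=outcome.n_controls,
            effect_allele=instrument.effect_allele,
            converged=outcome.converged,
            failure_reason=outcome.failure_reason,
        )
        return instrument, flipped
    raise ValueError(
        f"{outcome.rsid}: outcome effect allele {outcome.effect_allele!r} "
        f"incompatible with instrument alleles {sorted(inst_pair)}"
    )


def ratio_estimate(
    gamma: float, se_gamma: float, big_gamma: float, se_big_gamma: float, rsid: str = ""
) -> RatioEstimate:
    """Wald ratio with the two-term second-order standard error."""
    if gamma == 0 or not np.isfinite(gamma):
        raise ValueError(f"{rsid}: exposure association must be nonzero and finite")
    if not (se_gamma >= 0 and se_big_gamma > 0):
        raise ValueError(f"{rsid}: need se_gamma >= 0 and se_Gamma > 0")
    beta = big_gamma / gamma
    var = se_big_gamma**2 / gamma**2 + big_gamma**2 * se_gamma**2 / gamma**4
    return RatioEstimate(rsid=rsid, beta_mr=beta, se_mr=float(np.sqrt(var)))


def _two_sided_p(beta: float, se: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(beta) / se), P_FLOOR))


def ivw_meta(ratios: Sequence[RatioEstimate]) -> IVWResult:
    """Fixed-effect inverse-variance-weighted pooling of ratio estimates."""
    if len(ratios) < 2:
        raise ValueError("IVW pooling needs at least 2 instruments")
    beta_j = np.array([r.beta_mr for r in ratios])
    w = np.array([r.weight for r in ratios])
    beta = float(np.sum(w * beta_j) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    res = IVWResult(
        beta=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        p=_two_sided_p(beta, se),
    )
    res.q_stat, res.q_df, res.q_p = cochran_q(ratios, res)
    return res


def cochran_q(
    ratios: Sequence[RatioEstimate], ivw: IVWResult
) -> Tuple[float, int, float]:
    """Cochran's Q about the IVW estimate: Q = sum_j w_j (beta_j - beta)^2,
    df = k - 1, upper-tail chi-square p."""
    beta_j = np.array([r.beta_mr for r in ratios])
    w = np.array([r.weight for r in ratios])
    q = float(np.sum(w * (beta_j - ivw.beta) ** 2))
    df = len(ratios) - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return q, df, p


def _weighted_median_point(beta_j: np.ndarray, w: np.ndarray) -> float:
    """Precision-weighted median by interpolation of the weighted CDF.

    Estimates are sorted ascending; normalized weights w' define
    breakpoints s_j = cumsum(w') - w'/2; the estimate interpolates
    (s_j, beta_(j)) linearly at 0.5, clamping to the extreme estimate
    when 0.5 falls outside [s_1, s_k].
    """
    order = np.argsort(beta_j)
    b = beta_j[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - wn / 2.0
    if 0.5 <= s[0]:
        return float(b[0])
    if 0.5 >= s[-1]:
        return float(b[-1])
    return float(np.interp(0.5, s, b))


def _weighted_median_rows(b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of an (m, k) batch (bootstrap hot path).

    Same interpolation rule as :func:`_weighted_median_point`,
    vectorized over rows.
    """
    order = np.argsort(b, axis=1)
    bs = np.take_along_axis(b, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    wn = ws / ws.sum(axis=1, keepdims=True)
    s = np.cumsum(wn, axis=1) - wn / 2.0
    m, k = b.shape
    idx = (s < 0.5).sum(axis=1)  # first breakpoint >= 0.5
    out = np.empty(m)
    low = idx == 0
    high = idx == k
    out[low] = bs[low, 0]
    out[high] = bs[high, -1]
    mid = ~(low | high)
    j = idx[mid]
    rows = np.nonzero(mid)[0]
    s0 = s[rows, j - 1]
    s1 = s[rows, j]
    b0 = bs[rows, j - 1]
    b1 = bs[rows, j]
    out[mid] = b0 + (b1 - b0) * (0.5 - s0) / (s1 - s0)
    return out


def weighted_median(
    gammas: Sequence[float],
    se_gammas: Sequence[float],
    big_gammas: Sequence[float],
    se_big_gammas: Sequence[float],
    rsids: Sequence[str] = (),
    n_boot: int = 1000,
    seed: int = 0,
) -> WeightedMedianResult:
    """Weighted-median MR estimate with parametric-bootstrap SE.

    The point estimate is the precision-weighted median of the per-SNP
    ratios.  For the SE, both the outcome and exposure associations are
    re-drawn (Gamma* ~ N(Gamma, se_Gamma^2), gamma* ~ N(gamma,
    se_gamma^2)), the weighted median recomputed per resample, and the
    SD over ``n_boot`` resamples taken.  Seeded, hence reproducible.
    """
    g = np.asarray(gammas, dtype=float)
    sg = np.asarray(se_gammas, dtype=float)
    G = np.asarray(big_gammas, dtype=float)
    sG = np.asarray(se_big_gammas, dtype=float)
    k = len(g)
    if k < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if np.any(g == 0):
        raise ValueError("exposure associations must be nonzero")
    rsids = list(rsids) or [f"snp{i}" for i in range(k)]
    ratios = [
        ratio_estimate(g[j], sg[j], G[j], sG[j], rsid=rsids[j]) for j in range(k)
    ]
    beta_j = np.array([r.beta_mr for r in ratios])
    w = np.array([r.weight for r in ratios])
    est = _weighted_median_point(beta_j, w)

    rng = stage_rng(seed, "weighted-median-bootstrap")
    G_star = rng.normal(G, sG, size=(n_boot, k))
    g_star = rng.normal(g, sg, size=(n_boot, k))
    # Degenerate resampled denominators are astronomically unlikely for
    # strong instruments; guard anyway.
    g_star[g_star == 0] = np.finfo(float).tiny
    b_star = G_star / g_star
    var_star = sG**2 / g_star**2 + G_star**2 * sg**2 / g_star**4
    w_star = 1.0 / var_star
    boots = _weighted_median_rows(b_star, w_star)
    se_boot = float(np.std(boots, ddof=1))
    if se_boot == 0:
        se_boot = np.finfo(float).tiny
    return WeightedMedianResult(
        beta=est,
        se_boot=se_boot,
        ci_low=est - Z975 * se_boot,
        ci_high=est + Z975 * se_boot,
        p=_two_sided_p(est, se_boot),
        n_boot=n_boot,
        seed=seed,
    )


def weighted_median_from_ratios(
    instruments: Sequence[InstrumentSNP],
    outcomes: Sequence[AssociationEstimate],
    biomarker: str = "serum_iron",
    n_boot: int = 1000,
    seed: int = 0,
) -> WeightedMedianResult:
    """Convenience wrapper: harmonize then bootstrap the weighted median."""
    pairs = [harmonize(i, o) for i, o in zip(instruments, outcomes)]
    return weighted_median(
        gammas=[i.beta[biomarker] for i, _ in pairs],
        se_gammas=[i.se[biomarker] for i, _ in pairs],
        big_gammas=[o.beta for _, o in pairs],
        se_big_gammas=[o.se for _, o in pairs],
        rsids=[i.rsid for i, _ in pairs],
        n_boot=n_boot,
        seed=seed,
    )


def ratios_for_biomarker(
    instruments: Sequence[InstrumentSNP],
    outcomes: Sequence[AssociationEstimate],
    biomarker: str = "serum_iron",
) -> List[RatioEstimate]:
    """Harmonize each instrument/outcome pair and form per-SNP ratios
    scaled to 1 SD of the chosen biomarker."""
    if biomarker not in BIOMARKERS:
        raise ValueError(f"unknown biomarker {biomarker!r}; expected one of {BIOMARKERS}")
    out = []
    for inst, assoc in zip(instruments, outcomes):
        inst, assoc = harmonize(inst, assoc)
        out.append(
            ratio_estimate(
                inst.beta[biomarker],
                inst.se[biomarker],
                assoc.beta,
                assoc.se,
                rsid=inst.rsid,
            )
        )
    return out


def rescale_to_biomarker(
    instruments: Sequence[InstrumentSNP],
    outcomes: Sequence[AssociationEstimate],
    biomarker: str,
) -> IVWResult:
    """IVW estimate per 1 SD of another iron biomarker.

    Recomputes the ratio denominators with that biomarker's per-SNP
    associations.  Because transferrin moves opposite to iron status,
    transferrin-scaled estimates flip sign relative to iron-scaled
    ones.
    """
    for inst in instruments:
        if biomarker not in inst.beta:
            raise ValueError(f"{inst.rsid}: no {biomarker!r} association available")
    return ivw_meta(ratios_for_biomarker(instruments, outcomes, biomarker))
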