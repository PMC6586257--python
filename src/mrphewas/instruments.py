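"""Genetic instruments for systemic iron status.

An instrument SNP carries its summary association (beta, SE, in SD
units) with each of the four iron-status biomarkers: serum iron,
log10 ferritin, transferrin, and transferrin saturation.  A valid
iron-status instrument shows the concordant sign pattern - raising
serum iron, ferritin, and transferrin saturation while lowering
transferrin (higher transferrin reflects lower iron status).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

#: Biomarker column order used throughout the package.
BIOMARKERS: Tuple[str, ...] = (
    "serum_iron",
    "log10_ferritin",
    "transferrin",
    "transferrin_saturation",
)

#: SD of serum iron in the exposure GWAS population, micromol/L.
SD_SERUM_IRON_UMOL_L: float = 6.1


@dataclass
class InstrumentSNP:
    """Summary associations of one instrument SNP with the 4 biomarkers.

    ``beta`` and ``se`` map biomarker name -> per-effect-allele
    association in SD units of that biomarker.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: Dict[str, float] = field(default_factory=dict)
    se: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.rsid}: EAF must lie in (0,1), got {self.eaf}")
        missing = [b for b in BIOMARKERS if b not in self.beta or b not in self.se]
        if missing:
            raise ValueError(f"{self.rsid}: missing biomarker associations {missing}")
        for b in BIOMARKERS:
            if not np.isfinite(self.beta[b]):
                raise ValueError(f"{self.rsid}: non-finite beta for {b}")
            if not (np.isfinite(self.se[b]) and self.se[b] > 0):
                raise ValueError(f"{self.rsid}: SE for {b} must be positive")
        iron_sign = np.sign(self.beta["serum_iron"])
        if iron_sign == 0:
            raise ValueError(f"{self.rsid}: serum iron beta must be nonzero")
        for b in ("log10_ferritin", "transferrin_saturation"):
            if np.sign(self.beta[b]) != iron_sign:
                raise ValueError(
                    f"{self.rsid}: {b} beta must share the serum iron sign "
                    "(concordant iron-status pattern)"
                )
        if np.sign(self.beta["transferrin"]) != -iron_sign:
            raise ValueError(
                f"{self.rsid}: transferrin beta must oppose the serum iron sign"
            )


def scale_to_sd(
    beta_absolute: float,
    se_absolute: float,
    sd_serum_iron: float = SD_SERUM_IRON_UMOL_L,
) -> Tuple[float, float]:
    """Convert a per-allele effect in micromol/L to SD units of serum iron.

    The SD used by default is the 6.1 micromol/L of the exposure GWAS
    population.  SEs scale identically.
    """
    if not (np.isfinite(sd_serum_iron) and sd_serum_iron > 0):
        raise ValueError(f"sd_serum_iron must be positive, got {sd_serum_iron}")
    return beta_absolute / sd_serum_iron, se_absolute / sd_serum_iron


def _instrument_frame(snps: List[InstrumentSNP]) -> pd.DataFrame:
    rows = []
    for s in snps:
        row = {
            "rsid": s.rsid,
            "effect_allele": s.effect_allele,
            "other_allele": s.other_allele,
            "eaf": s.eaf,
        }
        for b in BIOMARKERS:
            row[f"beta_{b}"] = s.beta[b]
            row[f"se_{b}"] = s.se[b]
        rows.append(row)
    return pd.DataFrame(rows)


def write_instruments(snps: List[InstrumentSNP], path: Path | str) -> None:
    """Write an instrument table (tab-delimited, one row per SNP)."""
    _instrument_frame(snps).to_csv(path, sep="\t", index=False)


def load_instruments(path: Optional[Path | str] = None) -> List[InstrumentSNP]:
    """Load an instrument summary-statistic table.

    With no path, loads the packaged synthetic re-entry of the 3 iron
    instruments (rs1800562, rs1799945 in HFE; rs855791 in TMPRSS6).
    The packaged values are a synthetic stand-in with realistic
    magnitudes and the concordant sign pattern; they are not the
    published consortium estimates.
    """
    if path is None:
        ref = resources.files("mrphewas").joinpath("data/instruments_synthetic.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"rsid", "effect_allele", "other_allele", "eaf"} | {
        f"{kind}_{b}" for b in BIOMARKERS for kind in ("beta", "se")
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"instrument table missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            InstrumentSNP(
                rsid=str(r["rsid"]),
                effect_allele=str(r["effect_allele"]),
                other_allele=str(r["other_allele"]),
                eaf=float(r["eaf"]),
                beta={b: float(r[f"beta_{b}"]) for b in BIOMARKERS},
                se={b: float(r[f"se_{b}"]) for b in BIOMARKERS},
            )
        )
    return out


def instrument_r2_serum_iron(snps: List[InstrumentSNP]) -> float:
    """Variance in standardized serum iron explained by the instruments.

    Under HWE and no LD, each SNP contributes 2*p*(1-p)*beta^2; the
    biomarker being in SD units makes the sum an R^2 directly.
    """
    return float(
        sum(2.0 * s.eaf * (1.0 - s.eaf) * s.beta["serum_iron"] ** 2 for s in snps)
    )
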