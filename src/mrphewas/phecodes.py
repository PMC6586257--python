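"""ICD -> phecode mapping and case/control construction.

Phecodes group ICD-9/10 diagnosis codes into clinically meaningful case
definitions.  For a target phecode, cases are individuals with at least
one mapped hospital event; individuals carrying a *related* phecode
(one sharing the target's exclusion root) are removed from the control
pool; controls are the remainder.  Relatedness pruning keeps one member
of every pair above the 0.0884 kinship coefficient.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .simulate import KINSHIP_THRESHOLD

logger = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^[A-Z0-9]{2,7}$")

MAP_COLUMNS = ("icd_version", "icd_code", "phecode", "exclusion_root", "description", "category")


@dataclass
class PhecodeDef:
    """One phecode: identity, control-exclusion root, and its ICD codes."""

    phecode_id: str
    description: str = ""
    exclusion_root: str = ""
    category: str = ""
    icd_codes: List[Tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        try:
            float(self.phecode_id)
        except ValueError:
            raise ValueError(f"phecode_id {self.phecode_id!r} does not parse as a decimal")
        if not self.exclusion_root:
            self.exclusion_root = self.phecode_id.split(".")[0]


@dataclass
class CaseControlSet:
    """Analysis-ready partition of the retained cohort for one phecode."""

    phecode_id: str
    case_ids: Set[int]
    control_ids: Set[int]
    excluded_ids: Set[int]

    def __post_init__(self) -> None:
        if self.case_ids & self.control_ids or self.case_ids & self.excluded_ids or (
            self.control_ids & self.excluded_ids
        ):
            raise ValueError(f"{self.phecode_id}: case/control/excluded sets overlap")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)


def _normalize_code(code: str) -> str:
    """Normalize an ICD code: strip dots/whitespace, uppercase."""
    return code.replace(".", "").strip().upper()


def load_phecode_map(path: Optional[Path | str] = None) -> pd.DataFrame:
    """Load a tab-delimited phecode map.

    Expected columns: icd_version, icd_code, phecode, exclusion_root,
    description, category.  With no path, loads the small packaged
    synthetic-dialect map (a hand-built stand-in, not the published
    phecode map).
    """
    if path is None:
        ref = resources.files("mrphewas").joinpath("data/phecode_map_synthetic.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phecode map missing columns: {sorted(missing)}")
    df = df.copy()
    df["icd_version"] = df["icd_version"].astype(int)
    df["icd_code"] = df["icd_code"].map(_normalize_code)
    bad_version = ~df["icd_version"].isin([9, 10])
    if bad_version.any():
        raise ValueError("icd_version must be 9 or 10 for every map row")
    df.loc[df["exclusion_root"].isna(), "exclusion_root"] = (
        df.loc[df["exclusion_root"].isna(), "phecode"].str.split(".").str[0]
    )
    return df


def phecode_defs(phecode_map: pd.DataFrame) -> Dict[str, PhecodeDef]:
    """Collapse a map table into one PhecodeDef per phecode."""
    defs: Dict[str, PhecodeDef] = {}
    for _, r in phecode_map.iterrows():
        pid = str(r["phecode"])
        d = defs.get(pid)
        if d is None:
            d = PhecodeDef(
                phecode_id=pid,
                description=str(r.get("description", "")),
                exclusion_root=str(r["exclusion_root"]),
                category=str(r.get("category", "")),
            )
            defs[pid] = d
        d.icd_codes.append((int(r["icd_version"]), str(r["icd_code"])))
    return defs


def prune_related(
    individual_ids: Iterable[int],
    kinship: pd.DataFrame,
    threshold: float = KINSHIP_THRESHOLD,
    seed: int = 0,
) -> Set[int]:
    """Drop one member (seeded uniform choice) of every related pair.

    Pairs with coefficient > ``threshold`` are resolved greedily in
    table order: if both members are still retained, one is excluded at
    random.  Guarantees no retained pair remains above the threshold.
    """
    ids = set(int(i) for i in individual_ids)
    if len(kinship) == 0:
        return ids
    coef = kinship["coefficient"].to_numpy(dtype=float)
    if not np.all(np.isfinite(coef)) or np.any(coef < 0):
        raise ValueError("kinship coefficients must be finite and nonnegative")
    unknown = (set(kinship["id_a"].astype(int)) | set(kinship["id_b"].astype(int))) - ids
    if unknown:
        raise ValueError(f"kinship pairs reference unknown ids: {sorted(unknown)[:5]}")
    rng = stage_rng(seed, "prune-related")
    retained = set(ids)
    for a, b, c in zip(
        kinship["id_a"].astype(int), kinship["id_b"].astype(int), coef
    ):
        if c > threshold and a in retained and b in retained:
            retained.discard(a if rng.random() < 0.5 else b)
    return retained


def map_icd_to_phecodes(
    icd_events: pd.DataFrame, phecode_map: pd.DataFrame
) -> pd.DataFrame:
    """Flag each person for each phecode with >= 1 mapped event.

    Returns a boolean person x phecode incidence table (index =
    person_id).  Events whose (version, code) pair has no map entry are
    counted and logged, never fatal; malformed code strings are skipped
    with a warning.
    """
    phecodes = sorted(set(str(p) for p in phecode_map["phecode"]))
    persons = pd.Index(
        sorted(set(int(p) for p in icd_events["person_id"])), name="person_id"
    )
    arr = np.zeros((len(persons), len(phecodes)), dtype=bool)
    if len(icd_events):
        ev = pd.DataFrame(
            {
                "person_id": icd_events["person_id"].astype(int),
                "icd_version": icd_events["icd_version"].astype(int),
                "code": icd_events["code"].astype(str).map(_normalize_code),
            }
        )
        ok = ev["code"].str.match(_CODE_RE)
        n_malformed = int((~ok).sum())
        ev = ev[ok]
        lut = phecode_map[["icd_version", "icd_code", "phecode"]].copy()
        lut["icd_version"] = lut["icd_version"].astype(int)
        merged = ev.merge(
            lut, left_on=["icd_version", "code"], right_on=["icd_version", "icd_code"],
            how="left",
        )
        n_unmapped = int(merged["phecode"].isna().sum())
        hits = merged.dropna(subset=["phecode"])
        row = persons.get_indexer(hits["person_id"].to_numpy())
        col = pd.Index(phecodes).get_indexer(hits["phecode"].astype(str).to_numpy())
        arr[row, col] = True
    else:
        n_malformed = n_unmapped = 0
    if n_malformed:
        logger.warning("skipped %d malformed ICD code strings", n_malformed)
    if n_unmapped:
        logger.info("%d events carried codes absent from the phecode map", n_unmapped)
    table = pd.DataFrame(arr, index=persons, columns=phecodes)
    table.attrs["n_unmapped"] = n_unmapped
    table.attrs["n_malformed"] = n_malformed
    return table


def build_case_control(
    phecode_id: str,
    incidence: pd.DataFrame,
    phecode_map: pd.DataFrame,
    cohort_ids: Optional[Iterable[int]] = None,
    defs: Optional[Dict[str, PhecodeDef]] = None,
) -> CaseControlSet:
    """Partition the cohort into cases / excluded / controls for one phecode.

    Cases carry the target phecode.  Excluded individuals are non-cases
    carrying any phecode that shares the target's exclusion root (the
    'related phecodes' removed from the control pool).  Controls are
    everyone else in the cohort, including individuals with no hospital
    events at all.
    """
    if defs is None:
        defs = phecode_defs(phecode_map)
    if phecode_id not in defs:
        raise ValueError(f"phecode {phecode_id} absent from the supplied map")
    if cohort_ids is None:
        cohort = set(int(i) for i in incidence.index)
    else:
        cohort = set(int(i) for i in cohort_ids)
    if not cohort:
        raise ValueError("empty cohort")
    root = defs[phecode_id].exclusion_root
    related = [
        p for p, d in defs.items() if p != phecode_id and d.exclusion_root == root
    ]
    present = incidence.index.intersection(list(cohort))
    if phecode_id in incidence.columns:
        cases = set(int(i) for i in present[incidence.loc[present, phecode_id]])
    else:
        cases = set()
    excluded: Set[int] = set()
    for p in related:
        if p in incidence.columns:
            excluded |= set(int(i) for i in present[incidence.loc[present, p]])
    excluded -= cases
    controls = cohort - cases - excluded
    return CaseControlSet(phecode_id, cases, controls, excluded)


def filter_min_cases(
    sets: Iterable[CaseControlSet], minimum: int = 200
) -> List[CaseControlSet]:
    """Keep exactly the phecodes with at least ``minimum`` cases."""
    return [s for s in sets if s.n_cases >= minimum]
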