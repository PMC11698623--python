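"""Module eigengene vs progression-trait screening.

Clinical stage and the TNM axes are encoded as ordinal numeric codes and
correlated (Pearson) with every module eigengene; a module is "important"
when it clears |r| and p-value thresholds on at least a minimum number of
traits.  No multiple-testing correction is applied at this screening step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_COLUMNS = ("stage", "T", "N", "M")

_STAGE_RE = re.compile(r"^(IV|III|II|I)[A-C]?$")
_STAGE_CODE = {"I": 1, "II": 2, "III": 3, "IV": 4}
_TNM_RE = re.compile(r"^([TNM])?(\d+)[a-c]?$", re.IGNORECASE)


class TraitError(ValueError):
    pass


def _parse_stage(label: str, sample: str) -> int:
    match = _STAGE_RE.match(str(label).strip().upper().replace("STAGE", "").strip())
    if not match:
        raise TraitError(f"sample {sample!r}: unparseable stage label {label!r}")
    return _STAGE_CODE[match.group(1)]


def _parse_tnm(label: str, sample: str, fieldname: str) -> int:
    match = _TNM_RE.match(str(label).strip())
    if not match:
        raise TraitError(f"sample {sample!r}: unparseable {fieldname} label {label!r}")
    return int(match.group(2))


def encode_traits(clinical: pd.DataFrame, *, unparseable: str = "error") -> pd.DataFrame:
    """Ordinal numeric codes for stage and TNM, one row per sample.

    Stage sub-letters (IIA, IIIB, ...) collapse to the Roman numeral; T/N/M
    labels map to their numeric component (T3 -> 3, N0 -> 0).  A label that
    cannot be parsed (e.g. "MX") raises by default; with
    ``unparseable="drop"`` the sample is excluded instead.
    """
    if unparseable not in ("error", "drop"):
        raise TraitError("unparseable must be 'error' or 'drop'")
    rows = {}
    for _, row in clinical.iterrows():
        sid = row["sample_id"]
        try:
            rows[sid] = {
                "stage": _parse_stage(row["stage"], sid),
                "T": _parse_tnm(row["T"], sid, "T"),
                "N": _parse_tnm(row["N"], sid, "N"),
                "M": _parse_tnm(row["M"], sid, "M"),
            }
        except TraitError:
            if unparseable == "error":
                raise
    traits = pd.DataFrame.from_dict(rows, orient="index")
    traits.index.name = "sample_id"
    return traits[list(TRAIT_COLUMNS)]


@dataclass
class ModuleTraitResult:
    """Pearson r and two-sided p per (module, trait) pair."""

    r: pd.DataFrame  # modules x traits
    p: pd.DataFrame  # modules x traits


def correlate_eigengene_traits(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, *, drop_constant: bool = False
) -> ModuleTraitResult:
    """Pearson correlation of each eigengene with each ordinal trait code.

    The p-value comes from the t statistic r*sqrt((n-2)/(1-r^2)) on n-2
    degrees of freedom, two-sided.  A constant trait raises by default;
    with ``drop_constant=True`` it is silently excluded instead (a rare
    metastasis code can be uniform in a small cohort).
    """
    shared = [s for s in eigengenes.columns if s in traits.index]
    if len(shared) < 4:
        raise TraitError("need at least 4 samples shared by eigengenes and traits")
    tmat = traits.loc[shared]
    constant = [c for c in tmat.columns if tmat[c].nunique() < 2]
    if constant and not drop_constant:
        raise TraitError(f"trait {constant[0]!r} is constant across samples")
    tmat = tmat.drop(columns=constant)
    if tmat.shape[1] == 0:
        raise TraitError("all traits are constant across samples")
    r = pd.DataFrame(index=eigengenes.index, columns=tmat.columns, dtype=float)
    p = pd.DataFrame(index=eigengenes.index, columns=tmat.columns, dtype=float)
    for module in eigengenes.index:
        eg = eigengenes.loc[module, shared].to_numpy(dtype=float)
        for trait in tmat.columns:
            res = stats.pearsonr(eg, tmat[trait].to_numpy(dtype=float))
            r.loc[module, trait] = res.statistic
            p.loc[module, trait] = res.pvalue
    return ModuleTraitResult(r=r, p=p)


def select_important_modules(
    result: ModuleTraitResult,
    *,
    cor_thr: float = 0.2,
    p_thr: float = 0.05,
    min_traits: int = 2,
) -> list[str]:
    """Modules with |r| > cor_thr and p < p_thr on >= min_traits traits.

    Both inequalities are strict, so a module sitting exactly on a threshold
    does not qualify.
    """
    hits = (result.r.abs() > cor_thr) & (result.p < p_thr)
    selected = hits.sum(axis=1) >= min_traits
    return [str(m) for m in result.r.index[selected]]
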