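"""miRNA target over-representation in progression-associated modules.

For every (miRNA, important module) pair the upper-tail hypergeometric
probability of the observed target overlap is computed against the full
network gene universe, p-values are Benjamini-Hochberg adjusted across the
test family, and a candidate regulator must additionally be negatively
correlated (Pearson r below a threshold, default -0.3) with the module's
eigengene, reflecting the predominantly repressive action of miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpression import UNASSIGNED
from .preprocessing import TargetMap


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentRecord:
    """One (miRNA, module) over-representation test.

    ``x`` is the module size, ``n`` the miRNA's target count in the
    universe, ``z`` their overlap and ``N`` the universe size.  ``r_me`` is
    the Pearson correlation between the miRNA's normalized expression and
    the module eigengene; ``evaluable`` is False when that correlation is
    undefined (constant profile), in which case the record can never be
    selected.
    """

    mirna: str
    module: str
    x: int
    n: int
    z: int
    N: int
    p_ht: float
    fdr: float | None = None
    r_me: float | None = None
    selected: bool = False
    evaluable: bool = True


def hypergeom_upper(x: int, n: int, z: int, N: int) -> float:
    """P(overlap >= z) drawing n targets from a universe of N with x module genes.

    Equals sum_{k=z}^{min(x,n)} C(x,k) C(N-x,n-k) / C(N,n); terms with k > x
    vanish, so summing to min(x, n) is identical to summing to n.
    """
    if not (0 <= x <= N and 0 <= n <= N and 0 <= z <= min(x, n)):
        raise EnrichmentError(f"infeasible arguments x={x}, n={n}, z={z}, N={N}")
    if z == 0:
        return 1.0
    p = float(stats.hypergeom.sf(z - 1, N, x, n))
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def enrich_mirnas(
    targets: TargetMap,
    partition: pd.Series,
    important: list[str],
) -> list[EnrichmentRecord]:
    """One record per (miRNA, important module).

    The universe ``N`` counts every network gene including unassigned ones;
    module size ``x`` counts only assigned members of that module.
    """
    universe = set(partition.index)
    if universe != set(targets.universe):
        raise EnrichmentError("partition gene set differs from target-map universe")
    N = len(universe)
    module_genes: dict[str, set[str]] = {}
    for module in important:
        members = set(partition.index[partition == module]) - {UNASSIGNED}
        if partition.eq(module).sum() == 0:
            raise EnrichmentError(f"important module {module!r} absent from partition")
        module_genes[module] = members
    records = []
    for mirna in targets.mirnas:
        tset = targets.targets[mirna]
        n = len(tset)
        for module in important:
            members = module_genes[module]
            z = len(tset & members)
            x = len(members)
            records.append(
                EnrichmentRecord(
                    mirna=mirna,
                    module=module,
                    x=x,
                    n=n,
                    z=z,
                    N=N,
                    p_ht=hypergeom_upper(x, n, z, N),
                )
            )
    return records


def bh_adjust(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise EnrichmentError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(records: list[EnrichmentRecord], *, family: str = "joint") -> None:
    """Attach BH-adjusted p-values in place.

    ``family="joint"`` corrects across the full miRNA x module record list;
    ``family="per_module"`` corrects each module's tests separately.
    """
    if family == "joint":
        groups = {None: records}
    elif family == "per_module":
        groups = {}
        for rec in records:
            groups.setdefault(rec.module, []).append(rec)
    else:
        raise EnrichmentError("family must be 'joint' or 'per_module'")
    for group in groups.values():
        fdrs = bh_adjust([rec.p_ht for rec in group])
        for rec, fdr in zip(group, fdrs):
            rec.fdr = float(fdr)


def mirna_module_correlation(
    mirna_expr: pd.DataFrame, eigengenes: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between each miRNA's profile and each module eigengene.

    Rows are miRNAs, columns modules.  A constant miRNA profile yields NaN
    (the correlation is undefined) and the corresponding records are marked
    unevaluable downstream.
    """
    shared = [s for s in mirna_expr.columns if s in eigengenes.columns]
    if len(shared) < 4:
        raise EnrichmentError("need at least 4 shared samples")
    M = mirna_expr[shared].to_numpy(dtype=float)
    E = eigengenes[shared].to_numpy(dtype=float)
    Mc = M - M.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=1, keepdims=True)
    msd = np.sqrt((Mc**2).sum(axis=1))
    esd = np.sqrt((Ec**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Mc @ Ec.T) / np.outer(msd, esd)
    r[:, esd == 0] = np.nan
    r[msd == 0, :] = np.nan
    return pd.DataFrame(
        np.clip(r, -1.0, 1.0), index=mirna_expr.index, columns=eigengenes.index
    )


def attach_correlations(
    records: list[EnrichmentRecord], correlations: pd.DataFrame
) -> None:
    """Copy the matching (miRNA, module) correlation into each record."""
    for rec in records:
        if rec.mirna in correlations.index and rec.module in correlations.columns:
            r = correlations.loc[rec.mirna, rec.module]
            if pd.isna(r):
                rec.r_me = None
                rec.evaluable = False
            else:
                rec.r_me = float(r)
        else:
            rec.r_me = None
            rec.evaluable = False


def select_significant(
    records: list[EnrichmentRecord],
    *,
    fdr_thr: float = 0.05,
    cor_thr: float = -0.3,
) -> list[EnrichmentRecord]:
    """Flag and return records with FDR < fdr_thr and r_me < cor_thr (strict)."""
    selected = []
    for rec in records:
        if rec.fdr is None:
            raise EnrichmentError("records lack FDR values; run apply_fdr first")
        rec.selected = (
            rec.evaluable
            and rec.r_me is not None
            and rec.fdr < fdr_thr
            and rec.r_me < cor_thr
        )
        if rec.selected:
            selected.append(rec)
    return selected


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": r.mirna,
                "module": r.module,
                "x": r.x,
                "n": r.n,
                "z": r.z,
                "N": r.N,
                "p": r.p_ht,
                "fdr": r.fdr,
                "r_me": r.r_me,
                "selected": r.selected,
            }
            for r in records
        ]
    )


def run_enrichment(
    targets: TargetMap,
    partition: pd.Series,
    important: list[str],
    mirna_expr: pd.DataFrame,
    eigengenes: pd.DataFrame,
    *,
    fdr_thr: float = 0.05,
    cor_thr: float = -0.3,
    family: str = "joint",
) -> list[EnrichmentRecord]:
    """Full screen: tests, FDR, eigengene correlations and dual selection."""
    records = enrich_mirnas(targets, partition, important)
    apply_fdr(records, family=family)
    cors = mirna_module_correlation(mirna_expr, eigengenes.loc[important])
    attach_correlations(records, cors)
    select_significant(records, fdr_thr=fdr_thr, cor_thr=cor_thr)
    return records
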