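"""Sample selection, count filtering, normalisation and target-map handling.

The pipeline starts from raw count matrices (features x samples), a clinical
table and one or more miRNA->target interaction tables.  Samples must be
treatment-naive, staged and profiled on both assays; lowly expressed features
are dropped before library-size normalisation; the co-expression analysis is
restricted to genes that appear in the merged target map, which fixes the
universe size ``N`` used by every downstream over-representation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


class PreprocessingError(ValueError):
    """Raised when an input violates a preprocessing contract."""


# ---------------------------------------------------------------------------
# Target maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetMap:
    """miRNA -> target-gene sets restricted to a stated gene universe.

    Parameters
    ----------
    targets
        Mapping from miRNA identifier to the set of its annotated target
        genes.  Every target must belong to ``universe``.
    universe
        The gene universe against which over-representation is assessed
        (``N`` in the hypergeometric test).
    """

    targets: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        targets = {m: frozenset(g) for m, g in self.targets.items()}
        universe = frozenset(self.universe)
        for mirna, genes in targets.items():
            stray = genes - universe
            if stray:
                raise PreprocessingError(
                    f"targets of {mirna!r} outside the universe: {sorted(stray)[:5]}"
                )
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "universe", universe)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.targets)

    def n_pairs(self) -> int:
        return sum(len(g) for g in self.targets.values())

    def restricted_to(self, genes: Iterable[str]) -> "TargetMap":
        """Intersect the universe (and every target set) with ``genes``."""
        keep = frozenset(genes) & self.universe
        return TargetMap(
            targets={m: g & keep for m, g in self.targets.items()},
            universe=keep,
        )

    def to_pairs(self) -> pd.DataFrame:
        rows = [(m, g) for m in sorted(self.targets) for g in sorted(self.targets[m])]
        return pd.DataFrame(rows, columns=["mirna", "gene"])


def merge_target_maps(maps: Sequence[TargetMap]) -> TargetMap:
    """Pair-level union of several interaction databases.

    The merged universe is the union of the input universes and each miRNA's
    target set is the deduplicated union of its sets across inputs.
    """
    if len(maps) == 0:
        raise PreprocessingError("merge_target_maps requires at least one map")
    universe: frozenset[str] = frozenset()
    targets: dict[str, frozenset[str]] = {}
    for tm in maps:
        universe |= tm.universe
        for mirna, genes in tm.targets.items():
            targets[mirna] = targets.get(mirna, frozenset()) | genes
    return TargetMap(targets=targets, universe=universe)


# ---------------------------------------------------------------------------
# Sample selection
# ---------------------------------------------------------------------------

_TREATMENT_COLUMNS = ("pharmaceutical_treatment", "radiation_treatment")


def _is_missing(value) -> bool:
    return pd.isna(value) or str(value).strip() == ""


def select_samples(
    clinical: pd.DataFrame,
    gene_samples: Iterable[str],
    mirna_samples: Iterable[str],
    *,
    unknown_treatment_is_treated: bool = True,
) -> list[str]:
    """Treatment-naive samples with both assays and non-missing stage.

    Order is stable by the row order of ``clinical``.  Treatment flags are
    tri-state (yes/no/unknown); by default an unknown flag is read
    conservatively as treated and the sample is excluded.
    """
    gene_set = set(gene_samples)
    mirna_set = set(mirna_samples)
    treated_values = {"yes"}
    if unknown_treatment_is_treated:
        treated_values.add("unknown")

    kept: list[str] = []
    for _, row in clinical.iterrows():
        sid = row["sample_id"]
        if sid not in gene_set or sid not in mirna_set:
            continue
        flags = []
        for col in _TREATMENT_COLUMNS:
            val = row.get(col)
            flags.append("unknown" if _is_missing(val) else str(val).strip().lower())
        if any(f in treated_values for f in flags):
            continue
        if _is_missing(row.get("stage")):
            continue
        kept.append(sid)
    if not kept:
        raise PreprocessingError("no samples survive filters")
    return kept


# ---------------------------------------------------------------------------
# Count filtering and normalisation
# ---------------------------------------------------------------------------


def filter_low_counts(matrix: pd.DataFrame, min_total: int) -> pd.DataFrame:
    """Drop features whose total count across samples is below ``min_total``.

    The threshold is strict in the "removed" direction: a feature with a row
    total exactly equal to ``min_total`` is kept.
    """
    values = matrix.to_numpy()
    if (values < 0).any():
        raise PreprocessingError("count matrix contains negative values")
    keep = values.sum(axis=1) >= min_total
    return matrix.loc[keep]


def normalize_log2(matrix: pd.DataFrame, *, scale: float = 1e6) -> pd.DataFrame:
    """Counts-per-million library-size normalisation followed by log2(x+1)."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise PreprocessingError("count matrix contains negative values")
    totals = values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise PreprocessingError(
            f"sample {matrix.columns[zero[0]]!r} has an all-zero library"
        )
    cpm = values / totals * scale
    return pd.DataFrame(np.log2(cpm + 1.0), index=matrix.index, columns=matrix.columns)


def restrict_universe(
    expr: pd.DataFrame, targets: TargetMap
) -> tuple[pd.DataFrame, TargetMap]:
    """Restrict expression and target map to their common gene set.

    The resulting gene count defines the universe size ``N`` for all
    enrichment tests.  The operation is idempotent.
    """
    common = [g for g in expr.index if g in targets.universe]
    if not common:
        raise PreprocessingError("expression matrix and target universe are disjoint")
    return expr.loc[common], targets.restricted_to(common)


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------


@dataclass
class SampleDendrogram:
    """Average-linkage clustering of samples with optional outlier flags."""

    linkage_matrix: np.ndarray
    samples: list[str]
    flagged: list[str] = field(default_factory=list)


def sample_qc_dendrogram(
    expr: pd.DataFrame, *, height_threshold: float | None = None
) -> SampleDendrogram:
    """Hierarchical sample clustering on Euclidean distance for QC.

    When ``height_threshold`` is given, the tree is cut at that height and
    every sample outside the largest resulting cluster is flagged as an
    outlier; with the threshold unset no sample is flagged.
    """
    if expr.shape[1] < 3:
        raise PreprocessingError("sample QC requires at least 3 samples")
    dist = pdist(expr.to_numpy(dtype=float).T, metric="euclidean")
    Z = linkage(dist, method="average")
    samples = list(expr.columns)
    flagged: list[str] = []
    if height_threshold is not None:
        labels = fcluster(Z, t=height_threshold, criterion="distance")
        counts = pd.Series(labels).value_counts()
        main = counts.idxmax()
        flagged = [s for s, lab in zip(samples, labels) if lab != main]
    return SampleDendrogram(linkage_matrix=Z, samples=samples, flagged=flagged)
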