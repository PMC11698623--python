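"""Seeded generator for datasets with planted co-expression structure.

The generator emulates the data a tumour-cohort study of this kind consumes:
a gene count matrix with block-correlated modules driven by shared latent
factors, ordinal stage/TNM clinical traits that covary with some of those
factors, miRNA counts where designated "regulator" miRNAs are anticorrelated
with the module they target, and a miRNA->target map in which each
regulator's targets are over-represented in its module against a
genome-scale universe.  Every planted feature is recorded so downstream
stages can be scored against ground truth.

Counts are produced by mapping the latent Gaussian signal through an
exponential link to Poisson means whose per-sample totals are scaled to the
expected library size, which yields realistically skewed counts that survive
the low-count filters at the default depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import io as mio
from .preprocessing import TargetMap

UNASSIGNED = "unassigned"


class SimConfigError(ValueError):
    """A SimConfig field is inconsistent; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic dataset.

    ``module_sizes`` and ``background_genes`` must sum to ``n_genes``.
    ``trait_modules`` entries are ``(module index, sign, effect size)``:
    the ordinal progression traits covary with that module's latent factor
    at the stated signed effect size.  ``regulators`` entries are
    ``(miRNA index, module index, target overlap fraction, anticorrelation
    strength)``.  ``decoy_target_fraction`` is the fraction of the gene
    universe targeted by each non-regulator miRNA (regulators receive the
    same expected target count, part planted in their module).
    """

    seed: int = 0
    n_samples: int = 100
    n_genes: int = 350
    module_sizes: tuple[int, ...] = (50, 50, 50, 50, 50)
    background_genes: int = 100
    module_cor: float = 0.8
    trait_modules: tuple[tuple[int, int, float], ...] = ((0, 1, 0.5), (1, -1, 0.5))
    n_mirnas: int = 40
    regulators: tuple[tuple[int, int, float, float], ...] = (
        (0, 0, 0.6, 0.7),
        (1, 0, 0.6, 0.7),
        (2, 1, 0.6, 0.7),
    )
    decoy_target_fraction: float = 0.15
    count_depth: float = 1e6
    noise_sd: float = 0.6
    # extra samples appended to exercise the clinical filters: they carry a
    # treatment flag or a missing stage and are removed by sample selection
    n_treated_extra: int = 4
    n_unstaged_extra: int = 2

    def validate(self) -> None:
        if sum(self.module_sizes) + self.background_genes != self.n_genes:
            raise SimConfigError(
                "module_sizes + background_genes must sum to n_genes "
                f"({sum(self.module_sizes)} + {self.background_genes} != {self.n_genes})"
            )
        if not 0 < self.module_cor < 1:
            raise SimConfigError("module_cor must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise SimConfigError("noise_sd must be positive")
        if not 0 <= self.decoy_target_fraction <= 1:
            raise SimConfigError("decoy_target_fraction must lie in [0, 1]")
        if self.count_depth <= 0:
            raise SimConfigError("count_depth must be positive")
        for m, _sign, effect in self.trait_modules:
            if not 0 <= m < len(self.module_sizes):
                raise SimConfigError(f"trait_modules references module {m} out of range")
            if not 0 < effect < 1:
                raise SimConfigError("trait_modules effect size must lie in (0, 1)")
        if sum(e * e for _, _, e in self.trait_modules) > 1:
            raise SimConfigError("trait_modules squared effects must sum to <= 1")
        for i, m, overlap, strength in self.regulators:
            if not 0 <= i < self.n_mirnas:
                raise SimConfigError(f"regulators references miRNA {i} out of range")
            if not 0 <= m < len(self.module_sizes):
                raise SimConfigError(f"regulators references module {m} out of range")
            if not 0 < overlap <= 1:
                raise SimConfigError("regulator overlap fraction must lie in (0, 1]")
            if not 0 < strength < 1:
                raise SimConfigError("regulator anticorrelation strength must lie in (0, 1)")


@dataclass
class Truth:
    """Planted structure of a synthetic dataset."""

    partition: pd.Series  # gene -> planted module label (or "unassigned")
    regulators: list[tuple[str, str]]  # (miRNA id, planted module label)
    trait_modules: list[tuple[str, int, float]]  # (module label, sign, effect)
    factors: pd.DataFrame  # module label x sample latent factors


@dataclass
class SyntheticDataset:
    gene_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    clinical: pd.DataFrame
    target_map: TargetMap
    truth: Truth
    config: SimConfig


# marginal level proportions for the ordinal clinical codes; chosen to give
# a stage distribution close to an early-majority tumour cohort
_T_PROPS = (0.35, 0.45, 0.14, 0.06)  # T1..T4
_N_PROPS = (0.50, 0.30, 0.12, 0.08)  # N0..N3
_M1_RATE = 0.04
_TRAIT_LOADING = 0.8  # loading of each TNM latent on the progression latent
_STAGE_SUBLETTERS = {"II": ("A", "B"), "III": ("A", "B", "C")}


def _ordinal_from_latent(latent: np.ndarray, props: tuple[float, ...]) -> np.ndarray:
    cuts = norm.ppf(np.cumsum(props[:-1]))
    return np.searchsorted(cuts, latent, side="right")


def _counts_from_latent(
    latent: np.ndarray, depth: float, rng: np.random.Generator
) -> np.ndarray:
    """Exponential link, per-sample totals scaled to the expected depth."""
    baseline = rng.normal(0.0, 1.0, size=latent.shape[0])
    mu = np.exp(baseline[:, None] + latent)
    mu *= depth / mu.sum(axis=0, keepdims=True)
    return rng.poisson(mu)


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate one dataset with planted modules, traits and regulators.

    The same ``config`` (including its seed) always produces byte-identical
    matrices; all randomness flows from one generator in a fixed order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_mod = len(config.module_sizes)
    n_extra = config.n_treated_extra + config.n_unstaged_extra
    n_total = config.n_samples + n_extra
    samples = [f"S{i + 1:04d}" for i in range(n_total)]
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    mirnas = [f"miR-{i + 1:04d}" for i in range(config.n_mirnas)]
    module_labels = [f"M{m + 1}" for m in range(n_mod)]

    # --- module latent factors and gene expression signal -----------------
    factors = rng.normal(size=(n_mod, n_total))
    latent = np.empty((config.n_genes, n_total))
    partition_labels = []
    start = 0
    for m, size in enumerate(config.module_sizes):
        eps = rng.normal(size=(size, n_total))
        latent[start : start + size] = (
            config.module_cor * factors[m] + config.noise_sd * eps
        )
        partition_labels.extend([module_labels[m]] * size)
        start += size
    latent[start:] = rng.normal(size=(config.background_genes, n_total))
    partition_labels.extend([UNASSIGNED] * config.background_genes)

    gene_counts = pd.DataFrame(
        _counts_from_latent(latent, config.count_depth, rng),
        index=genes,
        columns=samples,
    )

    # --- clinical traits ---------------------------------------------------
    effect_var = sum(e * e for _, _, e in config.trait_modules)
    progression = sum(
        sign * e * factors[m] for m, sign, e in config.trait_modules
    ) + np.sqrt(max(0.0, 1.0 - effect_var)) * rng.normal(size=n_total)

    resid = np.sqrt(1.0 - _TRAIT_LOADING**2)
    t_latent = _TRAIT_LOADING * progression + resid * rng.normal(size=n_total)
    n_latent = _TRAIT_LOADING * progression + resid * rng.normal(size=n_total)
    m_latent = _TRAIT_LOADING * progression + resid * rng.normal(size=n_total)
    t_code = _ordinal_from_latent(t_latent, _T_PROPS) + 1  # T1..T4
    n_code = _ordinal_from_latent(n_latent, _N_PROPS)  # N0..N3
    m_code = (m_latent > norm.ppf(1.0 - _M1_RATE)).astype(int)  # M0/M1

    # overall stage follows the TNM codes the way clinical staging does:
    # metastasis dominates, then locally advanced disease, then early disease
    stage_code = np.where(
        m_code == 1,
        4,
        np.where((t_code == 4) | (n_code >= 2), 3, np.where((t_code >= 2) | (n_code >= 1), 2, 1)),
    )
    romans = {1: "I", 2: "II", 3: "III", 4: "IV"}
    stage_labels = []
    for code in stage_code:
        roman = romans[int(code)]
        letters = _STAGE_SUBLETTERS.get(roman)
        if letters is not None:
            roman = roman + letters[rng.integers(len(letters))]
        stage_labels.append(roman)

    age = rng.integers(30, 91, size=n_total)
    pharm = np.array(["no"] * n_total, dtype=object)
    radiation = np.array(["no"] * n_total, dtype=object)
    stage_out = np.array(stage_labels, dtype=object)
    for k in range(config.n_treated_extra):
        idx = config.n_samples + k
        if rng.random() < 0.5:
            pharm[idx] = "yes"
        else:
            radiation[idx] = "yes"
    for k in range(config.n_unstaged_extra):
        idx = config.n_samples + config.n_treated_extra + k
        stage_out[idx] = ""

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "stage": stage_out,
            "T": [f"T{c}" for c in t_code],
            "N": [f"N{c}" for c in n_code],
            "M": [f"M{c}" for c in m_code],
            "pharmaceutical_treatment": pharm,
            "radiation_treatment": radiation,
            "age": age,
        }
    )

    # --- miRNA expression ---------------------------------------------------
    regulator_of = {i: (m, overlap, strength) for i, m, overlap, strength in config.regulators}
    mirna_latent = np.empty((config.n_mirnas, n_total))
    for i in range(config.n_mirnas):
        eps = rng.normal(size=n_total)
        if i in regulator_of:
            m, _overlap, strength = regulator_of[i]
            mirna_latent[i] = -strength * factors[m] + np.sqrt(1 - strength**2) * eps
        else:
            mirna_latent[i] = eps
    mirna_counts = pd.DataFrame(
        _counts_from_latent(mirna_latent, config.count_depth / 10.0, rng),
        index=mirnas,
        columns=samples,
    )

    # --- target map ---------------------------------------------------------
    universe = np.array(genes)
    module_members = {
        m: [genes[g] for g in range(config.n_genes) if partition_labels[g] == module_labels[m]]
        for m in range(n_mod)
    }
    n_targets = int(round(config.decoy_target_fraction * config.n_genes))
    targets: dict[str, frozenset[str]] = {}
    for i in range(config.n_mirnas):
        if i in regulator_of:
            m, overlap, _strength = regulator_of[i]
            members = module_members[m]
            k_in = int(round(overlap * len(members)))
            planted = rng.choice(members, size=k_in, replace=False)
            outside = np.array(sorted(set(genes) - set(members)))
            k_out = max(0, n_targets - k_in)
            extra = rng.choice(outside, size=min(k_out, outside.size), replace=False)
            targets[mirnas[i]] = frozenset(planted) | frozenset(extra)
        else:
            targets[mirnas[i]] = frozenset(
                rng.choice(universe, size=n_targets, replace=False)
            )
    target_map = TargetMap(targets=targets, universe=frozenset(genes))

    truth = Truth(
        partition=pd.Series(partition_labels, index=genes, name="module"),
        regulators=[(mirnas[i], module_labels[m]) for i, m, _o, _s in config.regulators],
        trait_modules=[(module_labels[m], sign, e) for m, sign, e in config.trait_modules],
        factors=pd.DataFrame(factors, index=module_labels, columns=samples),
    )
    return SyntheticDataset(
        gene_counts=gene_counts,
        mirna_counts=mirna_counts,
        clinical=clinical,
        target_map=target_map,
        truth=truth,
        config=config,
    )


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> list[Path]:
    """Write the dataset as TSV/JSON files; returns the five-file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = [
        directory / "genes.tsv",
        directory / "mirnas.tsv",
        directory / "clinical.tsv",
        directory / "targets.tsv",
        directory / "truth.json",
    ]
    mio.write_expression(dataset.gene_counts, manifest[0])
    mio.write_expression(dataset.mirna_counts, manifest[1])
    mio.write_clinical(dataset.clinical, manifest[2])
    mio.write_target_map(dataset.target_map, manifest[3])
    mio.write_json(
        {
            "partition": dataset.truth.partition.to_dict(),
            "regulators": [list(pair) for pair in dataset.truth.regulators],
            "trait_modules": [list(t) for t in dataset.truth.trait_modules],
            "seed": dataset.config.seed,
        },
        manifest[4],
    )
    return manifest
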