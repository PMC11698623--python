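"""End-to-end orchestration: preprocess -> network -> traits -> enrichment -> GSVA.

Every stage writes its artifact to the output directory so a run can be
resumed or audited from any point, and the run report collects the counts,
thresholds and results of each stage.  A demo mode generates a seeded
synthetic dataset with planted regulators and reports how well the pipeline
recovers them.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpression as cx
from . import enrichment as en
from . import gsva as gv
from . import io as mio
from . import module_trait as mt
from . import preprocessing as pp
from .synthetic import SimConfig, SyntheticDataset, simulate_dataset, write_fixture

log = logging.getLogger("modulemir")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and a remediation hint."""


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults follow the reference workflow: low-count cutoffs of
    50 (genes) and 10 (miRNAs), soft threshold chosen automatically at
    scale-free fit R^2 > 0.9, minimum module size 30, eigengene merge cut
    height 0.25, deep split 2, kME thresholds 0.3 / 0.5 / 10, trait screen
    |r| > 0.2 with p < 0.05 on >= 2 traits, FDR < 0.05 and miRNA-eigengene
    correlation < -0.3.
    """

    out_dir: str = "modulemir_run"
    seed: int = 0
    demo: bool = False
    genes: str | None = None
    mirnas: str | None = None
    clinical: str | None = None
    targets: str | None = None
    min_gene_total: int = 50
    min_mirna_total: int = 10
    beta: int | None = None  # None: choose automatically
    target_r2: float = 0.9
    powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    deep_split: int = 2
    min_kme_to_stay: float = 0.3
    min_core_kme: float = 0.5
    min_core_kme_size: int = 10
    trait_cor: float = 0.2
    trait_p: float = 0.05
    min_traits: int = 2
    fdr: float = 0.05
    mirna_cor: float = -0.3
    fdr_family: str = "joint"
    gsva_method: str = "kernel"
    sim: dict = field(default_factory=dict)  # SimConfig overrides for demo mode

    def validate(self) -> None:
        checks = [
            ("min_gene_total", self.min_gene_total >= 0),
            ("min_mirna_total", self.min_mirna_total >= 0),
            ("beta", self.beta is None or self.beta >= 1),
            ("target_r2", 0 < self.target_r2 <= 1),
            ("powers", len(self.powers) > 0),
            ("min_module_size", self.min_module_size >= 2),
            ("merge_cut_height", 0 <= self.merge_cut_height < 1),
            ("min_kme_to_stay", 0 <= self.min_kme_to_stay <= 1),
            ("min_core_kme", 0 <= self.min_core_kme <= 1),
            ("min_core_kme_size", self.min_core_kme_size >= 1),
            ("trait_cor", 0 <= self.trait_cor < 1),
            ("trait_p", 0 < self.trait_p <= 1),
            ("min_traits", 1 <= self.min_traits <= len(mt.TRAIT_COLUMNS)),
            ("fdr", 0 < self.fdr <= 1),
            ("mirna_cor", -1 <= self.mirna_cor <= 1),
            ("fdr_family", self.fdr_family in ("joint", "per_module")),
            ("gsva_method", self.gsva_method in ("kernel", "ecdf")),
        ]
        for name, ok in checks:
            if not ok:
                raise PipelineError(f"[config] invalid value for {name!r}")
        if not self.demo:
            for name in ("genes", "mirnas", "clinical", "targets"):
                if getattr(self, name) is None:
                    raise PipelineError(
                        f"[config] input path {name!r} is required unless demo=True"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"[config] unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _stage(name: str, hint: str):
    """Decorator-free stage guard: re-raise with stage name and hint."""

    class _Guard:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}; {hint}") from exc
            return False

    return _Guard()


def _match_modules_to_truth(
    partition: pd.Series, truth_partition: pd.Series
) -> dict[str, str]:
    """Best-overlap mapping from detected module labels to planted labels."""
    mapping = {}
    for module in pd.unique(partition):
        if module == cx.UNASSIGNED:
            continue
        genes = partition.index[partition == module]
        counts = truth_partition.loc[genes].value_counts()
        counts = counts[counts.index != cx.UNASSIGNED]
        mapping[module] = str(counts.idxmax()) if len(counts) else cx.UNASSIGNED
    return mapping


def run_pipeline(
    config: RunConfig, dataset: SyntheticDataset | None = None
) -> dict:
    """Execute the full analysis; returns (and writes) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "thresholds": _threshold_dict(config)}

    with _stage("load", "check the input paths and TSV formats"):
        if dataset is None and config.demo:
            sim = SimConfig(**{"seed": config.seed, **config.sim})
            dataset = simulate_dataset(sim)
            write_fixture(dataset, out / "fixtures")
        if dataset is not None:
            gene_counts = dataset.gene_counts
            mirna_counts = dataset.mirna_counts
            clinical = dataset.clinical
            target_map = dataset.target_map
        else:
            gene_counts = mio.read_expression(config.genes)
            mirna_counts = mio.read_expression(config.mirnas)
            clinical = mio.read_clinical(config.clinical)
            target_map = mio.read_target_map(config.targets)
        report["input"] = {
            "genes": gene_counts.shape[0],
            "mirnas": mirna_counts.shape[0],
            "samples": int(len(clinical)),
            "target_pairs": target_map.n_pairs(),
        }

    with _stage("preprocess", "verify clinical columns and count matrices"):
        samples = pp.select_samples(clinical, gene_counts.columns, mirna_counts.columns)
        genes_f = pp.filter_low_counts(gene_counts[samples], config.min_gene_total)
        mirnas_f = pp.filter_low_counts(mirna_counts[samples], config.min_mirna_total)
        genes_norm = pp.normalize_log2(genes_f)
        mirnas_norm = pp.normalize_log2(mirnas_f)
        genes_net, targets_net = pp.restrict_universe(genes_norm, target_map)
        qc = pp.sample_qc_dendrogram(genes_norm)
        clinical_kept = clinical[clinical["sample_id"].isin(samples)]
        report["preprocess"] = {
            "samples_kept": len(samples),
            "qc_outliers_flagged": len(qc.flagged),
            "genes_after_count_filter": genes_f.shape[0],
            "mirnas_after_count_filter": mirnas_f.shape[0],
            "universe_size": genes_net.shape[0],
        }
        mio.write_expression(genes_norm, out / "genes_norm.tsv")
        mio.write_expression(mirnas_norm, out / "mirnas_norm.tsv")
        mio.write_clinical(clinical_kept, out / "clinical_kept.tsv")

    with _stage("network", "inspect the soft-threshold report; data may lack structure"):
        if config.beta is not None:
            beta = config.beta
            report["network"] = {"beta": beta, "beta_source": "fixed"}
        else:
            sft = cx.pick_soft_threshold(
                genes_net, config.powers, target_r2=config.target_r2
            )
            sft.table.to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
            if sft.chosen is not None:
                beta = sft.chosen
                source = "auto"
            else:
                beta = int(
                    sft.table.loc[sft.table["r_squared"].idxmax(), "power"]
                )
                source = "fallback_best_fit"
            row = sft.table[sft.table["power"] == beta].iloc[0]
            report["network"] = {
                "beta": beta,
                "beta_source": source,
                "scale_free_r2": float(row["r_squared"]),
                "mean_connectivity": float(row["mean_connectivity"]),
            }
        adj = cx.signed_adjacency(cx.pearson_matrix(genes_net), beta)
        tom = cx.tom_similarity(adj)
        partition = cx.detect_modules(
            tom, config.min_module_size, config.deep_split
        )
        partition = cx.merge_close_modules(
            genes_net, partition, cut_height=config.merge_cut_height
        )
        eigengenes = cx.module_eigengenes(genes_net, partition)
        partition = cx.apply_kme_filters(
            genes_net,
            partition,
            eigengenes,
            min_kme_to_stay=config.min_kme_to_stay,
            min_core_kme=config.min_core_kme,
            min_core_size=config.min_core_kme_size,
        )
        eigengenes = cx.module_eigengenes(genes_net, partition)
        sizes = partition[partition != cx.UNASSIGNED].value_counts()
        report["network"].update(
            {
                "n_modules": int(len(sizes)),
                "module_sizes": {str(k): int(v) for k, v in sizes.items()},
                "unassigned": int((partition == cx.UNASSIGNED).sum()),
            }
        )
        mio.write_partition(partition, out / "modules.tsv")
        eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")

    with _stage("traits", "check stage/TNM labels in the clinical table"):
        traits = mt.encode_traits(clinical_kept)
        mt_result = mt.correlate_eigengene_traits(eigengenes, traits, drop_constant=True)
        important = mt.select_important_modules(
            mt_result,
            cor_thr=config.trait_cor,
            p_thr=config.trait_p,
            min_traits=config.min_traits,
        )
        long = mt_result.r.stack().rename("r").to_frame()
        long["p"] = mt_result.p.stack()
        long.index.names = ["module", "trait"]
        long.reset_index().to_csv(out / "module_trait.tsv", sep="\t", index=False)
        report["traits"] = {
            "important_modules": important,
            "correlations": {
                m: {t: round(float(mt_result.r.loc[m, t]), 6) for t in mt_result.r.columns}
                for m in map(str, mt_result.r.index)
            },
        }

    selected: list[en.EnrichmentRecord] = []
    records: list[en.EnrichmentRecord] = []
    with _stage("enrichment", "requires at least one important module"):
        if important:
            records = en.run_enrichment(
                targets_net,
                partition,
                important,
                mirnas_norm,
                eigengenes,
                fdr_thr=config.fdr,
                cor_thr=config.mirna_cor,
                family=config.fdr_family,
            )
            selected = [r for r in records if r.selected]
            en.records_to_frame(records).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
        report["enrichment"] = {
            "tested_mirnas": len({r.mirna for r in records}),
            "records": len(records),
            "fdr_pass": sum(
                1 for r in records if r.fdr is not None and r.fdr < config.fdr
            ),
            "selected": [
                {
                    "mirna": r.mirna,
                    "module": r.module,
                    "z": r.z,
                    "n": r.n,
                    "x": r.x,
                    "fdr": float(r.fdr),
                    "r_me": round(float(r.r_me), 6),
                }
                for r in sorted(selected, key=lambda r: (r.mirna, r.module))
            ],
        }

    with _stage("gsva", "selected target sets need >= 2 genes in the matrix"):
        gsva_rows = []
        for rec in sorted(selected, key=lambda r: (r.mirna, r.module)):
            gene_set = targets_net.targets[rec.mirna] & set(
                partition.index[partition == rec.module]
            )
            if len(gene_set) < 2:
                continue
            scores = gv.gsva_scores(genes_net, gene_set, method=config.gsva_method)
            r, p = gv.correlate_scores_stage(scores, traits)
            gsva_rows.append(
                {
                    "mirna": rec.mirna,
                    "module": rec.module,
                    "set_size": len(gene_set),
                    "stage_r": round(r, 6),
                    "stage_p": p,
                }
            )
        if gsva_rows:
            pd.DataFrame(gsva_rows).to_csv(out / "gsva.tsv", sep="\t", index=False)
        report["gsva"] = gsva_rows

    if dataset is not None:
        with _stage("truth", "demo-only ground-truth comparison"):
            mapping = _match_modules_to_truth(partition, dataset.truth.partition)
            planted = {tuple(p) for p in dataset.truth.regulators}
            predicted = {(r.mirna, mapping.get(r.module, "?")) for r in selected}
            tp = planted & predicted
            report["truth"] = {
                "module_mapping": mapping,
                "planted_regulators": sorted(map(list, planted)),
                "recovered_regulators": sorted(map(list, tp)),
                "precision": len(tp) / len(predicted) if predicted else 0.0,
                "recall": len(tp) / len(planted) if planted else 0.0,
            }

    mio.write_json(report, out / "report.json")
    return report


def _threshold_dict(config: RunConfig) -> dict:
    keys = [
        "min_gene_total", "min_mirna_total", "beta", "target_r2",
        "min_module_size", "merge_cut_height", "deep_split",
        "min_kme_to_stay", "min_core_kme", "min_core_kme_size",
        "trait_cor", "trait_p", "min_traits", "fdr", "mirna_cor",
        "fdr_family", "gsva_method",
    ]
    return {k: getattr(config, k) for k in keys}
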