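"""End-to-end orchestration: simulate -> map -> quantify -> classify.

Runs the stages on real FASTA/FASTQ inputs or on synthetic data with planted
truth, writes the per-stage TSV tables (counts, expression, enrichment,
Z scores, category summary) plus a machine-readable run manifest, and
produces truth-recovery reports for synthetic runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import enrich as enrich_mod
from . import quant as quant_mod
from . import readmap as readmap_mod
from . import synthio as synthio_mod
from .enrich import EnrichmentParams
from .errors import ConfigurationError, InputError
from .readmap import LIBRARIES, CountMatrix, MapParams
from .synthio import SyntheticConfig

logger = logging.getLogger(__name__)

#: planted class -> expected enrichment category
TRUTH_TO_CATEGORY: Mapping[str, str] = {
    "female_sg_enriched": "female_enriched",
    "male_sg_enriched": "male_enriched",
    "shared_sg": "shared",
    "background": "not_sg_enriched",
}


@dataclass
class RunConfig:
    """Single configuration object for a full pipeline run."""

    out_dir: str = "sialoquant_run"
    synthetic: bool = True
    reference_fasta: Optional[str] = None
    fastq: Dict[str, str] = field(default_factory=dict)  # label -> path
    trim_threshold: int = 13
    trim_mode: str = "trim"
    map_params: MapParams = field(default_factory=MapParams)
    enrich_params: EnrichmentParams = field(default_factory=EnrichmentParams)
    ei_reference: str = "FSG"
    multimap_policy: str = "whole"
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.trim_threshold <= 0:
            raise ConfigurationError("trim_threshold must be positive")
        if not self.synthetic:
            if not self.reference_fasta:
                raise ConfigurationError("reference_fasta required without synthetic mode")
            if set(self.fastq) != set(LIBRARIES):
                raise ConfigurationError(
                    f"fastq labels must be exactly {set(LIBRARIES)}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "map_params":
                cfg.map_params = MapParams(**value)
            elif key == "enrich_params":
                cfg.enrich_params = EnrichmentParams(**value)
            elif key == "synth":
                for k, v in value.items():
                    if k in ("cds_length_range",):
                        v = tuple(v)
                    if k == "fold_ranges":
                        v = {
                            cls_: (tuple(map(tuple, ranges)))
                            for cls_, ranges in v.items()
                        }
                    setattr(cfg.synth, k, v)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)


@dataclass
class RunResult:
    out_dir: Path
    counts: CountMatrix
    expression: pd.DataFrame
    enrichment: pd.DataFrame
    zscores: pd.DataFrame
    summary: pd.DataFrame
    truth: Optional[pd.DataFrame] = None
    recovery: Optional[Tuple[pd.DataFrame, pd.DataFrame]] = None


def category_summary(
    expr: pd.DataFrame, calls: pd.DataFrame
) -> pd.DataFrame:
    """Per-category counts and TPM summaries.

    Emits, per enrichment category, the CDS count, the mean TPM in each
    library, and the female/male TPM comparison both as a mean of per-CDS
    pseudocounted ratios and as a ratio of the mean TPMs (the two disagree
    whenever per-CDS ratios are heterogeneous, so both are labeled).
    """
    joined = expr.join(calls[["category", "fsg_msg_fold", "msg_fsg_fold"]])
    rows = []
    for cat in enrich_mod.CATEGORIES:
        sub = joined[joined["category"] == cat]
        row = {"category": cat, "n": len(sub)}
        for lib in LIBRARIES:
            row[f"mean_tpm_{lib}"] = sub[f"tpm_{lib}"].mean() if len(sub) else np.nan
        if len(sub):
            row["mean_of_ratios_FSG_over_MSG"] = sub["fsg_msg_fold"].mean()
            row["ratio_of_means_FSG_over_MSG"] = quant_mod.tpm_ratio(
                sub["tpm_FSG"].mean(), sub["tpm_MSG"].mean()
            )
            row["mean_of_ratios_MSG_over_FSG"] = sub["msg_fsg_fold"].mean()
            row["ratio_of_means_MSG_over_FSG"] = quant_mod.tpm_ratio(
                sub["tpm_MSG"].mean(), sub["tpm_FSG"].mean()
            )
        else:
            for c in (
                "mean_of_ratios_FSG_over_MSG",
                "ratio_of_means_FSG_over_MSG",
                "mean_of_ratios_MSG_over_FSG",
                "ratio_of_means_MSG_over_FSG",
            ):
                row[c] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_report(
    truth: pd.DataFrame, calls: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion matrix and per-class sensitivity/specificity.

    ``truth`` carries cds_id and class_label; ``calls`` is the enrichment
    table indexed by cds_id with a category column.
    """
    truth_idx = truth.set_index("cds_id")["class_label"]
    if set(truth_idx.index) != set(calls.index):
        raise InputError("truth and calls identifiers do not match")
    expected = truth_idx.map(TRUTH_TO_CATEGORY)
    observed = calls.loc[expected.index, "category"]
    confusion = pd.crosstab(
        truth_idx.rename("planted_class"), observed.rename("called_category")
    )
    rows = []
    for cls, cat in TRUTH_TO_CATEGORY.items():
        mask = truth_idx == cls
        n_class = int(mask.sum())
        tp = int((observed[mask] == cat).sum())
        fp = int((observed[~mask] == cat).sum())
        n_rest = int((~mask).sum())
        rows.append(
            {
                "class_label": cls,
                "category": cat,
                "n": n_class,
                "sensitivity": tp / n_class if n_class else np.nan,
                "specificity": (n_rest - fp) / n_rest if n_rest else np.nan,
            }
        )
    return confusion, pd.DataFrame(rows)


def _stage(name: str, t0: float, n: int) -> None:
    logger.info("stage %-10s %6.1fs  %d records", name, time.perf_counter() - t0, n)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write all output tables.

    Deterministic for a fixed seed: running twice with the same config
    produces byte-identical tables.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {"stages": []}

    try:
        t0 = time.perf_counter()
        truth = None
        if config.synthetic:
            config.synth.rng_seed = config.rng_seed
            cds_set, truth = synthio_mod.generate_cds_set(config.synth)
            reads_by_lib, expected = synthio_mod.synthesize_reads(
                cds_set, truth, config.synth, out_dir=out_dir / "reads"
            )
            synthio_mod.write_fasta(cds_set, out_dir / "reference.fasta")
            truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
            expected.to_csv(out_dir / "expected_counts.tsv", sep="\t", index=False)
            _stage("simulate", t0, sum(len(v) for v in reads_by_lib.values()))

            def read_stream():
                for lib in LIBRARIES:
                    yield from reads_by_lib.get(lib, [])

        else:
            cds_set = readmap_mod.read_reference_fasta(config.reference_fasta)
            _stage("load_ref", t0, len(cds_set))

            def read_stream():
                for lib in LIBRARIES:
                    yield from readmap_mod.read_fastq(config.fastq[lib], lib)

    except Exception as exc:  # pragma: no cover - abort path
        raise RuntimeError(f"stage input failed: {exc}") from exc

    t0 = time.perf_counter()
    index = readmap_mod.ReferenceIndex(cds_set, config.map_params.word_size)
    assignments = readmap_mod.map_reads(
        read_stream(),
        index,
        config.map_params,
        trim_threshold=config.trim_threshold,
        trim_mode=config.trim_mode,
    )
    matrix = readmap_mod.build_count_matrix(
        assignments,
        [r.cds_id for r in cds_set],
        policy=config.multimap_policy,
    )
    readmap_mod.write_counts_tsv(matrix, out_dir / "counts.tsv")
    _stage("map", t0, int(matrix.counts.to_numpy().sum()))

    t0 = time.perf_counter()
    lengths = pd.Series(
        [r.length for r in cds_set], index=[r.cds_id for r in cds_set]
    )
    expr = quant_mod.build_expression_table(
        matrix, lengths, ei_reference=config.ei_reference
    )
    quant_mod.write_expression_tsv(expr, out_dir / "expression.tsv")
    _stage("quant", t0, len(expr))

    t0 = time.perf_counter()
    calls = enrich_mod.call_enrichment(expr, matrix.totals, config.enrich_params)
    calls.reset_index().to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    zscores = enrich_mod.zscore_table(expr)
    zscores.reset_index().to_csv(out_dir / "zscores.tsv", sep="\t", index=False)
    summary = category_summary(expr, calls)
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    _stage("enrich", t0, len(calls))

    recovery = None
    if truth is not None and len(truth):
        recovery = recovery_report(truth, calls)
        recovery[0].to_csv(out_dir / "recovery_confusion.tsv", sep="\t")
        recovery[1].to_csv(out_dir / "recovery_metrics.tsv", sep="\t", index=False)

    manifest["n_cds"] = len(cds_set)
    manifest["totals"] = {k: int(v) for k, v in matrix.totals.items()}
    manifest["category_counts"] = calls["category"].value_counts().to_dict()
    manifest["seed"] = config.rng_seed
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)

    return RunResult(
        out_dir=out_dir,
        counts=matrix,
        expression=expr,
        enrichment=calls,
        zscores=zscores,
        summary=summary,
        truth=truth,
        recovery=recovery,
    )
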