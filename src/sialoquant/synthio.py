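"""Seeded synthetic CDS sets and four-library FASTQ read simulation.

The generator plants a per-CDS enrichment class (female salivary-gland
enriched, male salivary-gland enriched, shared salivary, or background) and
builds target molar fractions (expected TPM) for the four libraries FSG,
MSG, FWB, MWB so that the planted salivary-gland-versus-whole-body and
female-versus-male fold values hold exactly in expected TPM.  Salivary-
associated CDS receive a fixed small molar level in the whole-body
libraries (``enriched_wb_tpm``); their salivary level is that level scaled
by the planted fold and split between the sexes by the planted sex fold;
background CDS absorb the remaining molar mass of each library.  Reads are
then drawn per library by multinomial allocation proportional to molar
fraction x CDS length (longer templates yield more reads), from uniform
start positions on either strand, with independent per-base substitution
errors and an optional injected low-quality 3' tail.

The default library depths keep the 3:1 female-to-male salivary-gland
molar pooling imbalance of the study design; read length defaults to 101 nt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .readmap import LIBRARIES, CdsRecord, ReadRecord

logger = logging.getLogger(__name__)

CLASSES: Tuple[str, ...] = (
    "female_sg_enriched",
    "male_sg_enriched",
    "shared_sg",
    "background",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_depths() -> Dict[str, int]:
    return {"FSG": 90_000, "MSG": 30_000, "FWB": 25_000, "MWB": 25_000}


def _default_proportions() -> Dict[str, float]:
    return {
        "female_sg_enriched": 0.10,
        "male_sg_enriched": 0.10,
        "shared_sg": 0.05,
        "background": 0.75,
    }


def _default_fold_ranges() -> Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]]:
    # per class: (sg_vs_wb fold interval, sex fold interval)
    return {
        "female_sg_enriched": ((25.0, 40.0), (25.0, 40.0)),
        "male_sg_enriched": ((25.0, 40.0), (25.0, 40.0)),
        "shared_sg": ((25.0, 40.0), (1.0, 1.0)),
        "background": ((1.0, 1.0), (1.0, 1.0)),
    }


@dataclass
class SyntheticConfig:
    n_cds: int = 500
    cds_length_range: Tuple[int, int] = (150, 400)
    library_depths: Dict[str, int] = field(default_factory=_default_depths)
    read_length: int = 101
    per_base_error_rate: float = 0.005
    class_proportions: Dict[str, float] = field(default_factory=_default_proportions)
    fold_ranges: Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]] = field(
        default_factory=_default_fold_ranges
    )
    enriched_wb_tpm: float = 150.0  # molar ppm of each SG-associated CDS in WB
    low_quality_tail_prob: float = 0.02
    low_quality_tail_phred: int = 2
    low_quality_tail_max_len: int = 15
    n_duplicate_cds: int = 0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_cds < 0:
            raise ConfigurationError("n_cds must be >= 0")
        lo, hi = self.cds_length_range
        if lo < 3 or hi < lo:
            raise ConfigurationError("cds_length_range must satisfy 3 <= lo <= hi")
        if set(self.library_depths) != set(LIBRARIES):
            raise ConfigurationError(
                f"library_depths labels must be exactly {set(LIBRARIES)}"
            )
        for lib, depth in self.library_depths.items():
            if depth <= 0:
                raise ConfigurationError(f"library_depths[{lib}] must be > 0")
        if not 0.0 <= self.per_base_error_rate < 0.05:
            raise ConfigurationError("per_base_error_rate must be in [0, 0.05)")
        if self.read_length < 26:
            raise ConfigurationError("read_length must be >= 26")
        if set(self.class_proportions) != set(CLASSES):
            raise ConfigurationError(
                f"class_proportions keys must be exactly {set(CLASSES)}"
            )
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_proportions must sum to 1 (got {total!r})"
            )
        if any(p < 0 for p in self.class_proportions.values()):
            raise ConfigurationError("class_proportions must be non-negative")
        if set(self.fold_ranges) != set(CLASSES):
            raise ConfigurationError(f"fold_ranges keys must be exactly {set(CLASSES)}")
        for cls, (sg, sex) in self.fold_ranges.items():
            if sg[0] < 1 or sg[1] < sg[0] or sex[0] < 1 or sex[1] < sex[0]:
                raise ConfigurationError(
                    f"fold_ranges[{cls}] intervals must satisfy 1 <= lo <= hi"
                )
        if self.enriched_wb_tpm <= 0:
            raise ConfigurationError("enriched_wb_tpm must be > 0")
        if not 0 <= self.n_duplicate_cds < max(self.n_cds, 1):
            raise ConfigurationError("n_duplicate_cds must be in [0, n_cds)")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, stream])


# ---------------------------------------------------------------------------
# CDS set and truth
# ---------------------------------------------------------------------------


def _allocate_classes(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of class counts, then a seeded shuffle."""
    n = config.n_cds
    fracs = np.array([config.class_proportions[c] for c in CLASSES])
    base = np.floor(fracs * n).astype(int)
    remainder = fracs * n - base
    short = n - base.sum()
    for idx in np.argsort(-remainder)[:short]:
        base[idx] += 1
    labels = np.repeat(np.array(CLASSES, dtype=object), base)
    rng.shuffle(labels)
    return labels


def generate_cds_set(
    config: SyntheticConfig,
) -> Tuple[List[CdsRecord], pd.DataFrame]:
    """Generate a random CDS set plus its planted-truth table.

    The truth table has one row per CDS with the class label, the planted
    salivary-gland/whole-body and sex fold values, and the expected TPM
    (molar parts per million) of the CDS in each library.  For background
    CDS the recorded salivary fold is the realised expected-TPM fold implied
    by the residual-mass construction (typically below 1).
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_cds
    if n == 0:
        truth = pd.DataFrame(
            columns=["cds_id", "class_label", "true_sg_fold", "true_sex_fold"]
            + [f"true_tpm_{lib}" for lib in LIBRARIES]
        )
        return [], truth

    width = max(5, len(str(n)))
    ids = [f"CDS{i:0{width}d}" for i in range(1, n + 1)]
    lo, hi = config.cds_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    seqs: List[str] = []
    seen = set()
    for length in lengths:
        while True:
            seq = bytes(_BASES[rng.integers(0, 4, size=int(length))]).decode("ascii")
            if seq not in seen:
                seen.add(seq)
                break
        seqs.append(seq)
    # optional duplicated CDS for multi-mapping tests: the last k records
    # become exact copies of the first
    for j in range(config.n_duplicate_cds):
        seqs[n - 1 - j] = seqs[0]

    labels = _allocate_classes(config, rng)

    sg_fold = np.empty(n)
    sex_fold = np.empty(n)
    for i, cls in enumerate(labels):
        (sg_lo, sg_hi), (sex_lo, sex_hi) = config.fold_ranges[cls]
        sg_fold[i] = rng.uniform(sg_lo, sg_hi)
        sex_fold[i] = rng.uniform(sex_lo, sex_hi)

    # target molar fractions (ppm) per library
    delta = config.enriched_wb_tpm
    tpm = {lib: np.zeros(n) for lib in LIBRARIES}
    is_bg = labels == "background"
    for i in range(n):
        if is_bg[i]:
            continue
        tpm["FWB"][i] = delta
        tpm["MWB"][i] = delta
        pooled_sg = sg_fold[i] * 2.0 * delta
        if labels[i] == "female_sg_enriched":
            s = sex_fold[i]
            tpm["FSG"][i] = pooled_sg * s / (s + 1.0)
            tpm["MSG"][i] = pooled_sg / (s + 1.0)
        elif labels[i] == "male_sg_enriched":
            s = sex_fold[i]
            tpm["MSG"][i] = pooled_sg * s / (s + 1.0)
            tpm["FSG"][i] = pooled_sg / (s + 1.0)
        else:  # shared_sg
            tpm["FSG"][i] = pooled_sg / 2.0
            tpm["MSG"][i] = pooled_sg / 2.0

    n_bg = int(is_bg.sum())
    for lib in LIBRARIES:
        used = tpm[lib].sum()
        if used >= 1e6:
            raise ConfigurationError(
                f"planted molar mass exceeds library {lib}: lower enriched_wb_tpm "
                "or the enriched class proportions"
            )
        if n_bg:
            tpm[lib][is_bg] = (1e6 - used) / n_bg
        elif used > 0:
            tpm[lib] *= 1e6 / used

    # realised folds for background rows (residual-mass construction)
    if n_bg:
        bg_fold = (tpm["FSG"][is_bg] + tpm["MSG"][is_bg]) / (
            tpm["FWB"][is_bg] + tpm["MWB"][is_bg]
        )
        sg_fold[is_bg] = bg_fold

    records = [CdsRecord(cid, seq) for cid, seq in zip(ids, seqs)]
    truth = pd.DataFrame(
        {
            "cds_id": ids,
            "class_label": labels,
            "true_sg_fold": sg_fold,
            "true_sex_fold": sex_fold,
            **{f"true_tpm_{lib}": tpm[lib] for lib in LIBRARIES},
        }
    )
    return records, truth


# ---------------------------------------------------------------------------
# read synthesis
# ---------------------------------------------------------------------------

_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b


def expected_counts(
    cds_set: Sequence[CdsRecord], truth: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Multinomial expected read counts per CDS and library.

    Sampling weight is molar fraction x CDS length; CDS shorter than the
    read length carry zero weight (they cannot be sampled).
    """
    lengths = np.array([r.length for r in cds_set], dtype=float)
    sampleable = lengths >= config.read_length
    out = {"cds_id": [r.cds_id for r in cds_set]}
    truth = truth.set_index("cds_id").loc[out["cds_id"]]
    for lib in LIBRARIES:
        w = truth[f"true_tpm_{lib}"].to_numpy() * lengths * sampleable
        total = w.sum()
        out[f"expected_{lib}"] = (
            config.library_depths[lib] * w / total if total > 0 else w
        )
    return pd.DataFrame(out)


def _simulate_library(
    cds_set: Sequence[CdsRecord],
    weights: np.ndarray,
    depth: int,
    label: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> List[ReadRecord]:
    L = config.read_length
    total = weights.sum()
    if total <= 0:
        return []
    n_per_cds = rng.multinomial(depth, weights / total)
    reads: List[ReadRecord] = []
    serial = 0
    err = config.per_base_error_rate
    hi_q = 40
    for idx, n_reads in enumerate(n_per_cds):
        if n_reads == 0:
            continue
        arr = np.frombuffer(cds_set[idx].sequence.encode("ascii"), dtype=np.uint8)
        starts = rng.integers(0, arr.size - L + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for start, minus in zip(starts, strands):
            frag = arr[start : start + L].copy()
            if minus:
                frag = _COMP[frag[::-1]]
            if err > 0:
                n_err = rng.binomial(L, err)
                if n_err:
                    pos = rng.choice(L, size=n_err, replace=False)
                    shift = rng.integers(1, 4, size=n_err)
                    cur = np.searchsorted(_BASES, frag[pos])
                    frag[pos] = _BASES[(cur + shift) % 4]
            quals = [hi_q] * L
            if (
                config.low_quality_tail_prob > 0
                and rng.random() < config.low_quality_tail_prob
            ):
                tail = int(rng.integers(1, config.low_quality_tail_max_len + 1))
                quals[L - tail :] = [config.low_quality_tail_phred] * tail
            serial += 1
            reads.append(
                ReadRecord(
                    f"{label}:{serial:07d}",
                    bytes(frag).decode("ascii"),
                    quals,
                    label,
                )
            )
    return reads


def synthesize_reads(
    cds_set: Sequence[CdsRecord],
    truth: pd.DataFrame,
    config: SyntheticConfig,
    out_dir: Optional[Path] = None,
) -> Tuple[Dict[str, List[ReadRecord]], pd.DataFrame]:
    """Draw the four read libraries; optionally write them as FASTQ.

    Returns the reads per library plus the multinomial expected-count table.
    Raises InputError if the truth table does not cover every CDS.
    """
    config.validate()
    ids = [r.cds_id for r in cds_set]
    missing = set(ids) - set(truth["cds_id"])
    if missing:
        raise InputError(f"truth table missing CDS: {sorted(missing)[:5]} ...")
    lengths = np.array([r.length for r in cds_set], dtype=float)
    short = lengths < config.read_length
    if short.any():
        logger.warning(
            "%d CDS shorter than the read length are excluded from sampling",
            int(short.sum()),
        )
    truth_idx = truth.set_index("cds_id").loc[ids]
    expected = expected_counts(cds_set, truth, config)
    rng = _rng(config, 1)
    libraries: Dict[str, List[ReadRecord]] = {}
    for lib in LIBRARIES:
        w = truth_idx[f"true_tpm_{lib}"].to_numpy() * lengths * (~short)
        libraries[lib] = _simulate_library(
            cds_set, w, config.library_depths[lib], lib, config, rng
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for lib, reads in libraries.items():
            write_fastq(reads, out_dir / f"{lib}.fastq")
    return libraries, expected


def write_fastq(reads: Sequence[ReadRecord], path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def write_fasta(cds_set: Sequence[CdsRecord], path) -> None:
    with open(path, "w") as handle:
        for rec in cds_set:
            handle.write(f">{rec.cds_id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# matched qPCR assay simulation
# ---------------------------------------------------------------------------


def simulate_qpcr_assay(
    truth: pd.DataFrame,
    genes: Sequence[str],
    config: SyntheticConfig,
    groups: Tuple[str, str] = ("FSG", "MSG"),
    n_bio: int = 3,
    n_tech: int = 2,
    ct_noise_sd: float = 0.15,
    reference_gene: str = "S7",
) -> pd.DataFrame:
    """Tidy Ct table whose expected fold changes match the planted truth.

    For each selected gene the between-group difference of delta-Ct means is
    set to -log2 of the planted expected-TPM ratio, with Gaussian replicate
    noise, three biological replicates and technical duplicates by default.
    """
    rng = _rng(config, 2)
    truth_idx = truth.set_index("cds_id")
    rows = []
    for gene in genes:
        ratio = (truth_idx.at[gene, f"true_tpm_{groups[0]}"]) / (
            truth_idx.at[gene, f"true_tpm_{groups[1]}"]
        )
        d_ct = {groups[0]: 5.0 - np.log2(ratio), groups[1]: 5.0}
        for group in groups:
            for bio in range(1, n_bio + 1):
                ref_ct = 16.0 + rng.normal(0, ct_noise_sd)
                tgt_ct = ref_ct + d_ct[group] + rng.normal(0, ct_noise_sd)
                for tech in range(1, n_tech + 1):
                    rows.append(
                        (reference_gene, "reference", group, bio, tech,
                         ref_ct + rng.normal(0, ct_noise_sd / 2))
                    )
                    rows.append(
                        (gene, "target", group, bio, tech,
                         tgt_ct + rng.normal(0, ct_noise_sd / 2))
                    )
    return pd.DataFrame(
        rows, columns=["gene", "role", "group", "bio_rep", "tech_rep", "ct"]
    )
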