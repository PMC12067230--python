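"""Read processing: trimming, quality filtering, variant counting, QC.

Converts raw amplicon reads (or pre-tabulated counts) into a filtered
count table. Reads are fixed-length amplicons of the form
``flank5 + variable region + flank3``; flanks are matched at fixed offsets
with a mismatch tolerance, no indel alignment. The per-base Phred filter
applies to the variable region, whose bases determine variant identity.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from nucleation_dms.simulate import PHASES

REJECT_REASONS = ("too_short", "flank5_fail", "flank3_fail", "low_quality", "not_designed", "bad_length")


@dataclass(frozen=True)
class ProcessingConfig:
    """Trimming, quality and abundance filters for one library.

    ``min_input_reads`` defaults to the designed-library threshold (200);
    random-extension libraries use 100. ``min_input_mode`` controls the
    input filter: ``all`` removes a variant only when its input count is
    below threshold in *every* replicate (literal reading), ``any`` when it
    is below threshold in at least one.
    """

    flank5: str
    flank3: str
    max_flank_mismatch_frac: float = 0.20
    min_phred: int = 30
    min_input_reads: int = 200
    min_input_mode: str = "all"
    designed_whitelist: frozenset[str] | None = None
    expected_length: int | None = None  # random mode: required interior length

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_flank_mismatch_frac <= 1.0:
            raise ValueError("max_flank_mismatch_frac must be in [0, 1]")
        if not 0 <= self.min_phred <= 41:
            raise ValueError("min_phred must be in [0, 41]")
        if self.min_input_mode not in {"all", "any"}:
            raise ValueError("min_input_mode must be 'all' or 'any'")

    @property
    def max_mismatches_5(self) -> int:
        return int(self.max_flank_mismatch_frac * len(self.flank5))

    @property
    def max_mismatches_3(self) -> int:
        return int(self.max_flank_mismatch_frac * len(self.flank3))


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def trim_constant_regions(read: str, cfg: ProcessingConfig) -> tuple[str | None, str]:
    """Strip the constant flanks off a read.

    Returns ``(interior, "ok")`` when both flanks match within the mismatch
    tolerance (at most ``floor(frac · flank_len)`` mismatches each),
    otherwise ``(None, reason)`` with reason in ``too_short``,
    ``flank5_fail``, ``flank3_fail``.
    """
    n5, n3 = len(cfg.flank5), len(cfg.flank3)
    if len(read) <= n5 + n3:
        return None, "too_short"
    read = read.upper()
    if _mismatches(read[:n5], cfg.flank5.upper()) > cfg.max_mismatches_5:
        return None, "flank5_fail"
    if n3 and _mismatches(read[-n3:], cfg.flank3.upper()) > cfg.max_mismatches_3:
        return None, "flank3_fail"
    return read[n5 : len(read) - n3], "ok"


def quality_filter(qualities: Iterable[int], cfg: ProcessingConfig) -> bool:
    """True when every (variable-region) base meets the Phred threshold."""
    quals = list(qualities)
    if not quals:
        raise ValueError("read has no base qualities")
    return min(quals) >= cfg.min_phred


def process_fastq(path: str | Path, cfg: ProcessingConfig) -> tuple[Counter, Counter]:
    """Count accepted variable regions in one FASTQ file.

    Returns ``(interior counts, reject tally by reason)``. Whitelist /
    length screening is left to :func:`count_variants` so the reject tally
    here covers only trimming and quality.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    accepted: Counter = Counter()
    rejected: Counter = Counter()
    with opener(path, "rt") as handle:
        for _title, seq, qual in FastqGeneralIterator(handle):
            interior, reason = trim_constant_regions(seq, cfg)
            if interior is None:
                rejected[reason] += 1
                continue
            n5 = len(cfg.flank5)
            interior_quals = [ord(c) - 33 for c in qual[n5 : n5 + len(interior)]]
            if not quality_filter(interior_quals, cfg):
                rejected["low_quality"] += 1
                continue
            accepted[interior] += 1
    return accepted, rejected


def count_variants(
    accepted: Mapping[str, int], cfg: ProcessingConfig
) -> tuple[Counter, Counter]:
    """Screen accepted interiors into a per-variant count vector.

    Designed mode (whitelist set): interiors off the whitelist are
    discarded and tallied. Random mode: every distinct interior of the
    expected length becomes a variant. Returns ``(counts, discards)``.
    """
    counts: Counter = Counter()
    discards: Counter = Counter()
    for interior, n in accepted.items():
        if cfg.designed_whitelist is not None:
            if interior in cfg.designed_whitelist:
                counts[interior] += n
            else:
                discards["not_designed"] += n
        elif cfg.expected_length is not None and len(interior) != cfg.expected_length:
            discards["bad_length"] += n
        else:
            counts[interior] += n
    return counts, discards


def input_read_filter(counts: pd.DataFrame, cfg: ProcessingConfig) -> pd.DataFrame:
    """Drop variants with insufficient input coverage.

    Under ``min_input_mode='all'`` a variant is removed only when its input
    count is below ``min_input_reads`` in every replicate; under ``'any'``
    when it falls below the threshold in at least one replicate.
    """
    inputs = counts.xs("input", axis=1, level="phase")
    below = inputs < cfg.min_input_reads
    remove = below.all(axis=1) if cfg.min_input_mode == "all" else below.any(axis=1)
    return counts.loc[~remove]


def process_fastq_pair(
    fastq_paths: Mapping[tuple[int, str], str | Path],
    cfg: ProcessingConfig,
    variant_index: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process a set of per-sample FASTQ files into a count table.

    ``fastq_paths`` maps ``(replicate, phase)`` to a file. Returns the
    count table (rows = variants, columns = (replicate, phase)) and a QC
    report with per-sample totals and rejects by reason. When
    ``variant_index`` is given (e.g. the simulated or designed library) the
    table is reindexed to it so absent variants keep zero rows.
    """
    per_sample: dict[tuple[int, str], Counter] = {}
    qc_rows = []
    for (rep, phase), path in sorted(fastq_paths.items()):
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        accepted, rejected = process_fastq(path, cfg)
        counts, discards = count_variants(accepted, cfg)
        per_sample[(rep, phase)] = counts
        row = {"replicate": rep, "phase": phase,
               "total_reads": sum(accepted.values()) + sum(rejected.values()),
               "accepted": sum(counts.values())}
        for reason in REJECT_REASONS:
            row[reason] = rejected.get(reason, 0) + discards.get(reason, 0)
        qc_rows.append(row)
    all_variants = sorted(set().union(*(c.keys() for c in per_sample.values())))
    table = pd.DataFrame(
        {key: pd.Series(c, dtype="int64") for key, c in per_sample.items()},
        index=all_variants,
    ).fillna(0).astype(int)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["replicate", "phase"])
    if variant_index is not None:
        table = table.reindex(list(variant_index)).fillna(0).astype(int)
    table.index.name = "variant"
    return table, pd.DataFrame(qc_rows)


def process_experiment(
    fastq_paths: Mapping[tuple[int, str], str | Path],
    cfg: ProcessingConfig,
    variant_index: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full chain: FASTQ → trim/quality → count → input-read filter."""
    table, qc = process_fastq_pair(fastq_paths, cfg, variant_index=variant_index)
    filtered = input_read_filter(table, cfg)
    qc["variants_before_input_filter"] = len(table)
    qc["variants_after_input_filter"] = len(filtered)
    return filtered, qc
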