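"""Synthetic selection-experiment generator.

Emulates the statistical structure of the nucleation selection assay: a
library of variants with uneven (log-normal) input representation is put
through one round of selection in which each variant's abundance is
multiplied by exp(true nucleation score); input and output pools are then
sequenced to finite depth, modelled as multinomial draws. Variant dropout
arises naturally from the finite depth.

True effects follow a two-component model mirroring the bimodal
nucleator / non-nucleator structure of random-extension libraries: with
probability ``p_nucleator`` a variant is a nucleator and its true score is
drawn from a positive distribution (default gamma with shape 2, scale 1.5
on the natural-log scale); otherwise its true score is 0 up to an optional
Gaussian jitter.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

PHASES = ("input", "output")


@dataclass(frozen=True)
class TrueEffectModel:
    """Two-component true-effect distribution for a variant library."""

    p_nucleator: float = 0.3
    nucleator_dist: str = "gamma"
    nucleator_params: tuple[float, ...] = (2.0, 1.5)  # shape, scale
    null_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_nucleator <= 1.0:
            raise ValueError("p_nucleator must be in [0, 1]")
        if self.null_noise_sd < 0:
            raise ValueError("null_noise_sd must be >= 0")
        if self.nucleator_dist not in {"gamma", "point"}:
            raise ValueError("nucleator_dist must be 'gamma' or 'point'")


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling configuration for one simulated selection experiment."""

    replicates: int = 3
    input_depth: int = 2_000_000
    output_depth: int = 2_000_000
    abundance_dispersion: float = 0.5  # SD of log input abundances
    hard_dropout_rate: float = 0.0  # optional: force output absence
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.input_depth < 1 or self.output_depth < 1:
            raise ValueError("sequencing depths must be >= 1")
        if not 0.0 <= self.hard_dropout_rate < 1.0:
            raise ValueError("hard_dropout_rate must be in [0, 1)")


def assign_true_scores(
    variant_ids, model: TrueEffectModel, seed: int | np.random.Generator
) -> pd.Series:
    """Draw a true nucleation score per variant (natural-log scale).

    Nucleator status is Bernoulli(``p_nucleator``) per variant; nucleator
    scores come from the configured positive distribution, non-nucleator
    scores are N(0, ``null_noise_sd``) (exactly 0 when the SD is 0).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = list(variant_ids)
    n = len(ids)
    is_nuc = rng.random(n) < model.p_nucleator
    scores = np.zeros(n)
    if model.null_noise_sd > 0:
        scores = rng.normal(0.0, model.null_noise_sd, size=n)
    n_nuc = int(is_nuc.sum())
    if n_nuc:
        if model.nucleator_dist == "gamma":
            shape, scale = model.nucleator_params
            scores[is_nuc] = rng.gamma(shape, scale, size=n_nuc)
        else:  # point mass
            scores[is_nuc] = model.nucleator_params[0]
    return pd.Series(scores, index=pd.Index(ids, name="variant"), name="true_ns")


def simulate_counts(true_scores: pd.Series, cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate input/output read counts for every replicate.

    Per replicate: input frequencies are log-normal draws renormalised to
    sum to 1; output frequencies are input × exp(true score), renormalised;
    counts are multinomial at the configured depths. Columns are a
    MultiIndex (replicate, phase); every variant keeps a row even when all
    its counts are zero.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = true_scores.index
    n = len(ids)
    mult = np.exp(true_scores.to_numpy(float))
    cols = {}
    for rep in range(1, cfg.replicates + 1):
        w = rng.lognormal(mean=0.0, sigma=cfg.abundance_dispersion, size=n)
        p_in = w / w.sum()
        p_out = p_in * mult
        if cfg.hard_dropout_rate > 0:
            drop = rng.random(n) < cfg.hard_dropout_rate
            p_out = np.where(drop, 0.0, p_out)
        if p_out.sum() == 0:
            raise ValueError("all output frequencies are zero")
        p_out = p_out / p_out.sum()
        cols[(rep, "input")] = rng.multinomial(cfg.input_depth, p_in)
        cols[(rep, "output")] = rng.multinomial(cfg.output_depth, p_out)
    counts = pd.DataFrame(cols, index=ids)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["replicate", "phase"])
    if (counts.sum(axis=1) == 0).all():
        warnings.warn("sequencing depth so low that every variant has zero counts")
    return counts


def _quality_char(phred: int) -> str:
    if not 0 <= phred <= 41:
        raise ValueError("phred must be in [0, 41]")
    return chr(phred + 33)


def emit_fastq(
    counts: pd.DataFrame,
    nt_seqs: Mapping[str, str],
    flank5: str,
    flank3: str,
    out_dir: str | Path,
    phred: int = 37,
    base_error_rate: float = 0.0,
    low_quality_rate: float = 0.0,
    low_quality_phred: int = 20,
    seed: int = 0,
    gzipped: bool = False,
) -> dict[tuple[int, str], Path]:
    """Write one FASTQ file per (replicate, phase) sample.

    Each count becomes one read ``flank5 + variant nt + flank3`` with a
    uniform Phred quality. Optional corruption for stress-testing the read
    filters: ``base_error_rate`` substitutes bases (qualities untouched),
    ``low_quality_rate`` drops single-base qualities to
    ``low_quality_phred``.
    """
    missing = [v for v in counts.index if v not in nt_seqs]
    if missing:
        raise ValueError(f"variants without nucleotide sequence: {missing[:3]}...")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[tuple[int, str], Path] = {}
    bases = np.array(list("ACGT"))
    for rep, phase in counts.columns:
        suffix = "fastq.gz" if gzipped else "fastq"
        path = out_dir / f"rep{rep}_{phase}.{suffix}"
        opener = gzip.open if gzipped else open
        with opener(path, "wt") as fh:
            sample = counts[(rep, phase)]
            read_no = 0
            for variant, count in sample.items():
                seq0 = flank5 + nt_seqs[variant] + flank3
                for _ in range(int(count)):
                    read_no += 1
                    seq = seq0
                    qual = [phred] * len(seq)
                    if base_error_rate > 0:
                        hit = rng.random(len(seq)) < base_error_rate
                        if hit.any():
                            arr = np.array(list(seq))
                            arr[hit] = bases[rng.integers(0, 4, size=int(hit.sum()))]
                            seq = "".join(arr)
                    if low_quality_rate > 0:
                        hit = rng.random(len(seq)) < low_quality_rate
                        qual = [low_quality_phred if h else phred for h in hit]
                    fh.write(
                        f"@rep{rep}_{phase}_{read_no}\n{seq}\n+\n"
                        + "".join(_quality_char(q) for q in qual)
                        + "\n"
                    )
        paths[(rep, phase)] = path
    return paths
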