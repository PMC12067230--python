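"""Nucleation-score estimation from input/output count tables.

Per replicate, the enrichment of a variant between the input and
post-selection output pools is

    ES_i = ln(F_i,output) − ln(F_i,input)

with F the within-sample frequencies. Nucleation scores are enrichments
relative to a reference: for designed libraries the wild-type variant
(NS_i = ES_i − ES_wt, applied per replicate), for random-extension
libraries the mode of the merged score distribution (most sequences do not
nucleate, so the distribution's bulk defines zero).

Per-replicate errors use the Poisson delta method,
sigma² = 1/c_in + 1/c_out (+ the reference's two terms under wild-type
centering), on pseudocounted counts; replicates are combined with the
inverse-variance (error-weighted) mean. Sequences present in the input but
absent from every output are imputed at the distribution mode, carrying
the largest observed error so they can never be called significant.

Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nucleation_dms.simulate import PHASES


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring options.

    ``pseudocount`` is added to every count before frequencies (0 allowed;
    the default 0.5 keeps zero output counts finite). ``centering`` is
    ``'wt'`` (requires ``reference_id``) or ``'mode'``.
    """

    pseudocount: float = 0.5
    centering: str = "wt"
    reference_id: str | None = None
    mode_grid_points: int = 512
    min_entries_for_mode: int = 50

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.centering not in {"wt", "mode"}:
            raise ValueError("centering must be 'wt' or 'mode'")
        if self.centering == "wt" and self.reference_id is None:
            raise ValueError("wt centering requires reference_id")


def _replicate_frames(counts: pd.DataFrame) -> list[int]:
    reps = sorted(set(counts.columns.get_level_values("replicate")))
    for rep in reps:
        for phase in PHASES:
            if (rep, phase) not in counts.columns:
                raise ValueError(f"missing sample (replicate {rep}, {phase})")
    return reps


def per_replicate_scores(counts: pd.DataFrame, cfg: ScoreConfig) -> pd.DataFrame:
    """Per-replicate scores and delta-method errors.

    Returns a frame indexed like ``counts`` with columns ``ns_rep{r}`` and
    ``sigma_rep{r}``. Under wild-type centering the reference's enrichment
    (and its error contribution) is subtracted within each replicate; under
    mode centering the raw enrichments are returned and centred later.
    """
    reps = _replicate_frames(counts)
    pc = cfg.pseudocount
    out = pd.DataFrame(index=counts.index)
    for rep in reps:
        c_in = counts[(rep, "input")].to_numpy(float)
        c_out = counts[(rep, "output")].to_numpy(float)
        if c_in.sum() == 0 or c_out.sum() == 0:
            raise ValueError(f"replicate {rep} has a sample with zero total reads")
        f_in = (c_in + pc) / (c_in + pc).sum()
        f_out = (c_out + pc) / (c_out + pc).sum()
        with np.errstate(divide="ignore"):
            es = np.log(f_out) - np.log(f_in)
            var = 1.0 / (c_in + pc) + 1.0 / (c_out + pc)
        if cfg.centering == "wt":
            if cfg.reference_id not in counts.index:
                raise ValueError(f"reference {cfg.reference_id!r} not in count table")
            ref = counts.index.get_loc(cfg.reference_id)
            es = es - es[ref]
            ref_var = var[ref].copy()
            var = var + ref_var
            var[ref] = ref_var  # the reference's own score is exactly 0 by construction
        out[f"ns_rep{rep}"] = es
        out[f"sigma_rep{rep}"] = np.sqrt(var)
    return out


def merge_replicates(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance (error-weighted) mean across replicates.

    ns = Σ(ns_r/σ_r²) / Σ(1/σ_r²), sigma = sqrt(1/Σ(1/σ_r²)). Replicates
    with non-finite score or error are ignored per variant; variants with
    no usable replicate are flagged ``unmeasured``.
    """
    ns_cols = sorted(c for c in per_rep.columns if c.startswith("ns_rep"))
    sig_cols = [c.replace("ns_", "sigma_") for c in ns_cols]
    ns = per_rep[ns_cols].to_numpy(float)
    sig = per_rep[sig_cols].to_numpy(float)
    usable = np.isfinite(ns) & np.isfinite(sig) & (sig > 0)
    w = np.where(usable, 1.0 / np.where(usable, sig, 1.0) ** 2, 0.0)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        merged_ns = (w * np.where(usable, ns, 0.0)).sum(axis=1) / wsum
        merged_sigma = np.sqrt(1.0 / wsum)
    out = per_rep.copy()
    out["ns"] = merged_ns
    out["sigma"] = merged_sigma
    out["unmeasured"] = wsum == 0
    return out


def kde_mode(values: np.ndarray, grid_points: int = 512) -> float:
    """Mode of a sample via Gaussian KDE (Silverman bandwidth, grid argmax)."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size < 2 or np.ptp(values) == 0:
        return float(values[0]) if values.size else float("nan")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])


def center_scores(entries: pd.DataFrame, cfg: ScoreConfig) -> pd.DataFrame:
    """Shift merged (and per-replicate) scores so the reference is 0.

    Wild-type centering subtracts the reference's merged score (a no-op
    when per-replicate scores were already reference-subtracted, making
    centering idempotent). Mode centering subtracts the kernel-density mode
    of the merged score distribution.
    """
    out = entries.copy()
    if cfg.centering == "wt":
        if cfg.reference_id not in entries.index:
            raise ValueError(f"reference {cfg.reference_id!r} not scored")
        if entries.loc[cfg.reference_id].get("unmeasured", False):
            raise ValueError("reference variant is unmeasured; cannot centre")
        shift = float(entries.loc[cfg.reference_id, "ns"])
    else:
        if "unmeasured" in entries.columns:
            measured = entries.loc[~entries["unmeasured"].astype(bool), "ns"]
        else:
            measured = entries["ns"]
        if len(measured) < cfg.min_entries_for_mode:
            raise ValueError(
                f"mode centering needs >= {cfg.min_entries_for_mode} scored entries"
            )
        shift = kde_mode(measured.to_numpy(), cfg.mode_grid_points)
    ns_cols = [c for c in out.columns if c == "ns" or c.startswith("ns_rep")]
    out[ns_cols] = out[ns_cols] - shift
    out["centered_to"] = cfg.centering
    return out


def impute_dropouts(entries: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Impute output-dropout sequences at the (centred) distribution mode.

    A sequence with input reads in some replicate but zero output reads in
    *all* replicates is assigned the mode score (0 after centering) and the
    largest observed sigma among measured entries, and flagged ``imputed``.
    Sequences with output reads in any replicate are scored normally.
    """
    out = entries.copy()
    if "imputed" not in out.columns:
        out["imputed"] = False
    inputs = counts.xs("input", axis=1, level="phase")
    outputs = counts.xs("output", axis=1, level="phase")
    dropouts = (inputs.sum(axis=1) > 0) & (outputs == 0).all(axis=1)
    idx = counts.index[dropouts]
    if len(idx):
        max_sigma = out.loc[~out["imputed"], "sigma"].replace([np.inf], np.nan).max()
        out.loc[idx, "ns"] = 0.0
        out.loc[idx, "sigma"] = max_sigma
        out.loc[idx, "imputed"] = True
        if "unmeasured" in out.columns:
            out.loc[idx, "unmeasured"] = False
    return out


def score_counts(counts: pd.DataFrame, cfg: ScoreConfig) -> pd.DataFrame:
    """Full scoring chain: per-replicate scores → merge → centre → impute."""
    entries = merge_replicates(per_replicate_scores(counts, cfg))
    entries = center_scores(entries, cfg)
    if cfg.centering == "mode":
        entries = impute_dropouts(entries, counts)
    return entries
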