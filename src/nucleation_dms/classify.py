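"""FDR-controlled variant classification and library bookkeeping.

Designed libraries: each variant's merged score is tested against the
wild type with a Z-test (z = ns/sigma, two-sided) and Benjamini–Hochberg
correction at FDR 0.1, yielding NS_inc / NS_dec / WT_like labels; WT_like
variants with an unreliable error (sigma normalised to the score
interquartile range above 0.2) are excluded.

Random-extension libraries: a one-sided Z-test against 0 at FDR 0.05
separates nucleators from nonnucleators; imputed dropouts are always
nonnucleators; the strongest decile by score forms the top-10% tier.
Duplicate protein sequences are merged (mean score, modal status, ties
conservatively to nonnucleator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ClassificationConfig:
    design_fdr: float = 0.1
    random_fdr: float = 0.05
    iqr_sigma_cutoff: float = 0.2
    top_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in ("design_fdr", "random_fdr", "top_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _zp(entries: pd.DataFrame, sided: str) -> tuple[np.ndarray, np.ndarray]:
    ns = entries["ns"].to_numpy(float)
    sigma = entries["sigma"].to_numpy(float)
    if np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
        raise ValueError("every entry needs a finite positive sigma")
    z = ns / sigma
    if sided == "two_sided":
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif sided == "one_sided_greater":
        p = stats.norm.sf(z)
    else:
        raise ValueError(sided)
    return z, np.minimum(p, 1.0)


def sigma_iqr_filter(
    entries: pd.DataFrame, cfg: ClassificationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop WT_like entries whose IQR-normalised sigma exceeds the cutoff.

    Sigma values are normalised to the interquartile range of the merged
    score distribution; only WT_like labels are filtered (significant calls
    keep their label regardless of error). Returns ``(kept, dropped)``.
    """
    if len(entries) < 4:
        raise ValueError("need >= 4 entries for a defined interquartile range")
    q75, q25 = np.percentile(entries["ns"].to_numpy(float), [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        raise ValueError("interquartile range of scores is zero")
    norm_sigma = entries["sigma"] / iqr
    drop = (entries["label"] == "WT_like") & (norm_sigma > cfg.iqr_sigma_cutoff)
    out = entries.copy()
    out["norm_sigma"] = norm_sigma
    return out.loc[~drop], out.loc[drop]


def classify_designed(
    entries: pd.DataFrame, cfg: ClassificationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label designed-library variants NS_inc / NS_dec / WT_like.

    Two-sided Z-test of each wild-type-centred score against 0, BH
    correction at ``design_fdr``; significant positive scores are NS_inc,
    significant negative NS_dec, the rest WT_like. The sigma/IQR filter
    then removes unreliable WT_like entries. Returns ``(kept, dropped)``.
    """
    cfg = cfg or ClassificationConfig()
    out = entries.copy()
    z, p = _zp(out, "two_sided")
    out["z"] = z
    out["p"] = p
    out["p_adj"] = bh_adjust(p)
    sig = out["p_adj"] <= cfg.design_fdr
    out["label"] = np.where(
        sig & (out["ns"] > 0), "NS_inc", np.where(sig & (out["ns"] < 0), "NS_dec", "WT_like")
    )
    return sigma_iqr_filter(out, cfg)


def classify_random(
    entries: pd.DataFrame, cfg: ClassificationConfig | None = None
) -> pd.DataFrame:
    """Label random-extension sequences nucleator / nonnucleator.

    One-sided (greater) Z-test of each mode-centred score against 0, BH at
    ``random_fdr``. Imputed entries are nonnucleators by rule and are not
    part of the tested family (their p and p_adj are NaN). The top
    ``top_fraction`` of the library by score is flagged ``top10`` after
    intersection with the nucleator set.
    """
    cfg = cfg or ClassificationConfig()
    out = entries.copy()
    z, p = _zp(out, "one_sided_greater")
    imputed = out["imputed"].to_numpy(bool) if "imputed" in out.columns else np.zeros(len(out), bool)
    out["z"] = z
    out["p"] = np.where(imputed, np.nan, p)
    p_adj = np.full(len(out), np.nan)
    p_adj[~imputed] = bh_adjust(p[~imputed])
    out["p_adj"] = p_adj
    nucleator = ~imputed & (p_adj <= cfg.random_fdr)
    out["label"] = np.where(nucleator, "nucleator", "nonnucleator")
    n_top = int(round(cfg.top_fraction * len(out)))
    top_ids = out["ns"].nlargest(n_top).index
    out["top10"] = False
    out.loc[top_ids, "top10"] = True
    out["top10"] &= out["label"] == "nucleator"
    return out


def merge_duplicates(
    classified: pd.DataFrame, cfg: ClassificationConfig | None = None
) -> pd.DataFrame:
    """Merge entries sharing a protein sequence.

    Mean score, mean sigma, modal nucleator status (ties conservatively to
    nonnucleator). Afterwards, nonnucleators with unreliable errors
    (IQR-normalised sigma above the cutoff) and a mean score above the
    minimum nucleator score are discarded. ``top10`` is re-derived as
    "any duplicate was top10" intersected with nucleator status.
    """
    cfg = cfg or ClassificationConfig()
    if "protein_seq" not in classified.columns:
        raise ValueError("need a protein_seq column to merge duplicates")

    def _merge(group: pd.DataFrame) -> pd.Series:
        n_nuc = (group["label"] == "nucleator").sum()
        label = "nucleator" if n_nuc > len(group) - n_nuc else "nonnucleator"
        return pd.Series(
            {
                "ns": group["ns"].mean(),
                "sigma": group["sigma"].mean(),
                "label": label,
                "top10": bool(group.get("top10", pd.Series(False)).any()) and label == "nucleator",
                "n_merged": len(group),
                "imputed": bool(group.get("imputed", pd.Series(False)).all()),
            }
        )

    merged = classified.groupby("protein_seq", sort=True).apply(_merge, include_groups=False)
    merged.index.name = "protein_seq"
    q75, q25 = np.percentile(merged["ns"].to_numpy(float), [75, 25])
    iqr = q75 - q25
    nucleators = merged.loc[merged["label"] == "nucleator", "ns"]
    if iqr > 0 and len(nucleators):
        min_nuc = nucleators.min()
        bad = (
            (merged["label"] == "nonnucleator")
            & (merged["sigma"] / iqr > cfg.iqr_sigma_cutoff)
            & (merged["ns"] > min_nuc)
        )
        merged = merged.loc[~bad]
    return merged


def count_gatekeepers(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-position counts of nucleation-increasing / -decreasing variants.

    A position is a *gatekeeper* when mutations there more often increase
    than decrease nucleation (n_inc > n_dec). Expects designed-library
    labels and a ``position`` column.
    """
    if "position" not in classified.columns:
        raise ValueError("need a position column")
    rows = []
    for pos, group in classified.groupby("position", sort=True):
        n_inc = int((group["label"] == "NS_inc").sum())
        n_dec = int((group["label"] == "NS_dec").sum())
        rows.append(
            {"position": int(pos), "n_inc": n_inc, "n_dec": n_dec,
             "gatekeeper": n_inc > n_dec}
        )
    return pd.DataFrame(rows).set_index("position")


def heatmap_matrix(classified: pd.DataFrame) -> pd.DataFrame:
    """Position × mutant-residue matrix of merged scores (stops as '*')."""
    needed = {"position", "mut_aa", "ns"}
    if not needed <= set(classified.columns):
        raise ValueError(f"need columns {sorted(needed)}")
    return classified.pivot_table(index="mut_aa", columns="position", values="ns")


def class_fractions(counts: dict[str, int]) -> pd.Series:
    """Percentages per class from raw per-class counts (sums to 100)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return pd.Series({k: 100.0 * v / total for k, v in counts.items()}, name="percent")
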