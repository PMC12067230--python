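"""Sequence-composition enrichment and predictor evaluation.

Compares nucleating against non-nucleating peptide sets: per-residue
composition differences (Welch t-test, Cohen's d, frequency difference in
percentage points), position-wise physicochemical-class tests (2×2
chi-square without continuity correction), length-stratified class
fractions, per-sequence property scales (Kyte–Doolittle hydropathy,
Kanehisa–Tsong beta-sheet propensity), cross-peptide score correlations
under different alignments, and a rank-based AUC harness for externally
computed predictor scores.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from nucleation_dms.peptides import CANONICAL_AA, load_scales

#: default physicochemical grouping; the scheme is an argument everywhere
AA_CLASS_SCHEME: dict[str, str] = {
    **{aa: "aliphatic" for aa in "AVLIM"},
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "polar" for aa in "STNQ"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "special" for aa in "CGP"},
}

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for level, mark in STAR_LEVELS:
        if p < level:
            return mark
    return ""


def composition_percent(sequence: str) -> pd.Series:
    """Percent composition over the 20 canonical residues (sums to 100)."""
    if len(sequence) == 0:
        raise ValueError("cannot compute composition of an empty sequence")
    counts = pd.Series(0.0, index=list(CANONICAL_AA))
    for aa in sequence:
        if aa not in counts.index:
            raise ValueError(f"non-canonical residue {aa!r}")
        counts[aa] += 1
    return 100.0 * counts / len(sequence)


def _composition_matrix(seqs: Sequence[str]) -> np.ndarray:
    return np.vstack([composition_percent(s).to_numpy() for s in seqs])


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardised mean difference with the pooled standard deviation."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    diff = float(np.mean(x) - np.mean(y))
    if pooled == 0:
        return 0.0
    return diff / float(np.sqrt(pooled))


def group_composition_test(
    nucleators: Sequence[str], nonnucleators: Sequence[str]
) -> pd.DataFrame:
    """Per-residue composition comparison between the two groups.

    Welch t-test on per-sequence composition percentages; Cohen's d with
    pooled SD; ``freq_difference`` = mean(nucleators) − mean(nonnucleators)
    in percentage points.
    """
    if len(nucleators) < 2 or len(nonnucleators) < 2:
        raise ValueError("both groups need >= 2 sequences")
    a = _composition_matrix(nucleators)
    b = _composition_matrix(nonnucleators)
    rows = []
    for j, aa in enumerate(CANONICAL_AA):
        x, y = a[:, j], b[:, j]
        if np.var(x) == 0 and np.var(y) == 0:
            t, p = (np.inf, 0.0) if np.mean(x) != np.mean(y) else (0.0, 1.0)
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append(
            {
                "aa": aa,
                "mean_nucleator": float(np.mean(x)),
                "mean_nonnucleator": float(np.mean(y)),
                "t": float(t),
                "p": float(p),
                "cohens_d": cohens_d(x, y),
                "freq_difference": float(np.mean(x) - np.mean(y)),
            }
        )
    return pd.DataFrame(rows).set_index("aa")


def positionwise_class_test(
    nucleators: Sequence[str],
    nonnucleators: Sequence[str],
    scheme: Mapping[str, str] | None = None,
    positions: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per-position, per-class 2×2 chi-square between the groups.

    Positions are 1-based over the full peptide; sequences shorter than a
    position are excluded there. The 2×2 table crosses group membership
    with "residue at this position belongs to the class". Tests with any
    expected cell below 1 are skipped (``skipped`` flag). No continuity
    correction.
    """
    scheme = dict(scheme or AA_CLASS_SCHEME)
    classes = sorted(set(scheme.values()))
    if positions is None:
        longest = max(len(s) for s in list(nucleators) + list(nonnucleators))
        positions = range(1, longest + 1)
    rows = []
    for pos in positions:
        nuc_here = [s[pos - 1] for s in nucleators if len(s) >= pos]
        non_here = [s[pos - 1] for s in nonnucleators if len(s) >= pos]
        if not nuc_here or not non_here:
            continue
        for cls in classes:
            in_nuc = sum(1 for aa in nuc_here if scheme[aa] == cls)
            in_non = sum(1 for aa in non_here if scheme[aa] == cls)
            table = np.array(
                [[in_nuc, len(nuc_here) - in_nuc], [in_non, len(non_here) - in_non]]
            )
            row = {
                "position": pos,
                "class": cls,
                "nucleator_with": in_nuc,
                "nucleator_without": len(nuc_here) - in_nuc,
                "nonnucleator_with": in_non,
                "nonnucleator_without": len(non_here) - in_non,
                "freq_difference": in_nuc / len(nuc_here) - in_non / len(non_here),
            }
            if in_nuc + in_non == 0:
                row.update(chi2=np.nan, p=np.nan, stars="", skipped=True)
            else:
                expected = stats.contingency.expected_freq(table)
                if (expected < 1).any():
                    row.update(chi2=np.nan, p=np.nan, stars="", skipped=True)
                else:
                    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                    row.update(chi2=float(chi2), p=float(p), stars=_stars(p), skipped=False)
            rows.append(row)
    return pd.DataFrame(rows)


def length_stratify(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide-length class fractions for a classified random library.

    Expects the merged classification frame indexed by protein sequence
    with ``label`` and ``top10`` columns. Fractions of nonnucleators,
    nucleators and top-10% nucleators are reported per length (top10 is a
    sub-tier of nucleators, so the first two sum to 1).
    """
    lengths = classified.index.str.len()
    rows = []
    for length, group in classified.groupby(lengths):
        n = len(group)
        n_nuc = int((group["label"] == "nucleator").sum())
        rows.append(
            {
                "length": int(length),
                "n": n,
                "frac_nonnucleator": (n - n_nuc) / n,
                "frac_nucleator": n_nuc / n,
                "frac_top10": float(group["top10"].sum()) / n if "top10" in group else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("length")


def sequence_properties(
    sequences: Sequence[str],
    scales: pd.DataFrame | None = None,
    region_start: int = 1,
) -> pd.DataFrame:
    """Mean per-residue scale values per sequence.

    ``region_start`` restricts the calculation to positions >= that 1-based
    position (e.g. 23 for the extension region of Bri2-based peptides);
    sequences shorter than the region are reported as NaN.
    """
    scales = load_scales() if scales is None else scales
    rows = []
    for seq in sequences:
        region = seq[region_start - 1 :]
        if not region:
            rows.append({c: np.nan for c in scales.columns})
        else:
            rows.append({c: float(scales.loc[list(region), c].mean()) for c in scales.columns})
    return pd.DataFrame(rows, index=pd.Index(sequences, name="sequence"))


def cross_peptide_correlation(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    alignment: str | Mapping[int, int] = "n_anchor",
    aggregation: str = "by_position",
) -> tuple[float, float, int]:
    """Pearson correlation of aggregated scores between two peptides.

    ``scores_a``/``scores_b`` carry columns ``position``, ``wt_aa``,
    ``mut_aa`` and ``ns``. Aggregation averages scores ``by_position``,
    ``by_wt_aa`` (mutations *of* the same residue) or ``by_mut_aa``
    (mutations *to* the same residue). For positional aggregation the
    peptides are paired ``n_anchor`` (i ↔ i), ``c_anchor``
    (i ↔ i + L_b − L_a) or through an explicit position map (e.g. from an
    external multiple-sequence alignment). Returns ``(r, p, n_pairs)``.
    """
    key = {"by_position": "position", "by_wt_aa": "wt_aa", "by_mut_aa": "mut_aa"}[aggregation]
    mean_a = scores_a.groupby(key)["ns"].mean()
    mean_b = scores_b.groupby(key)["ns"].mean()
    if aggregation == "by_position":
        if isinstance(alignment, str):
            if alignment == "n_anchor":
                offset = 0
            elif alignment == "c_anchor":
                len_a = int(scores_a["position"].max())
                len_b = int(scores_b["position"].max())
                offset = len_b - len_a
            else:
                raise ValueError(f"unknown alignment {alignment!r}")
            mapping = {int(i): int(i) + offset for i in mean_a.index}
        else:
            mapping = {int(k): int(v) for k, v in alignment.items()}
        pairs = [
            (mean_a[i], mean_b[j])
            for i, j in mapping.items()
            if i in mean_a.index and j in mean_b.index
        ]
    else:
        shared = mean_a.index.intersection(mean_b.index)
        pairs = [(mean_a[k], mean_b[k]) for k in shared]
    if len(pairs) < 3:
        raise ValueError("need >= 3 paired observations")
    x, y = map(np.asarray, zip(*pairs))
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(pairs)


def predictor_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """AUC of a per-sequence predictor against nucleator labels.

    Rank-based (Mann–Whitney) AUC with a bootstrap standard deviation over
    ``n_boot`` resamples. Returns ``(auc, sd)``.
    """
    y = np.asarray(labels, bool)
    x = np.asarray(scores, float)
    if y.all() or not y.any():
        raise ValueError("need both nucleator and nonnucleator labels")
    auc = float(roc_auc_score(y, x))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(y), size=len(y))
        if y[idx].all() or not y[idx].any():
            continue
        boots.append(roc_auc_score(y[idx], x[idx]))
    sd = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
    return auc, sd
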