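"""Library enumeration and NNK random-extension sequence space.

Two library designs are modelled:

* a *designed* library holding every single amino-acid substitution and
  every truncation (stop codon) of a wild-type peptide — for a peptide of
  length L that is 19·L missense plus L nonsense records;
* a *random-extension* library where a base peptide is extended by a run of
  NNK degenerate codons (N = A/C/G/T at the first two positions, K = G/T at
  the third). The 32 NNK codons encode all 20 amino acids and exactly one
  stop (TAG), so premature stops truncate the extension and the library
  spans every extension length from 0 to the number of codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

from nucleation_dms.peptides import CANONICAL_AA, STOP, Peptide

_STANDARD = _BioCodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with stops mapped to "*"
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: STOP for c in _STANDARD.stop_codons})

#: the 32 NNK codons, lexicographic
NNK_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "GT"
)


def translate_codons(nt: str) -> str:
    """Translate a codon string, stopping at (and excluding) the first stop."""
    if len(nt) % 3:
        raise ValueError("nucleotide sequence length must be a multiple of 3")
    out = []
    for i in range(0, len(nt), 3):
        aa = CODON_TO_AA[nt[i : i + 3].upper()]
        if aa == STOP:
            break
        out.append(aa)
    return "".join(out)


@dataclass(frozen=True)
class VariantRecord:
    """One library member relative to its parent peptide.

    ``position`` is 1-based; ``None`` for the wild type itself. Nonsense
    records truncate the parent just before ``position``; missense records
    differ from the parent at exactly ``position``.
    """

    parent_id: str
    position: int | None
    wt_aa: str | None
    mut_aa: str | None
    variant_class: str  # synonymous | missense | nonsense
    protein_seq: str
    snv_reachable: bool | None = None

    @property
    def id(self) -> str:
        if self.position is None:
            return f"{self.parent_id}_WT"
        return f"{self.parent_id}_{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class NNKExtensionSpec:
    """Random C-terminal extension of ``base_peptide`` by ``n_codons`` NNK codons."""

    base_peptide: Peptide
    n_codons: int = 12
    codon_set: tuple[str, ...] = field(default=NNK_CODONS)

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        stops = [c for c in self.codon_set if CODON_TO_AA[c] == STOP]
        if len(set(self.codon_set)) != len(self.codon_set):
            raise ValueError("codon_set contains duplicates")
        if len(stops) != 1:
            raise ValueError("codon_set must contain exactly one stop codon")


def enumerate_substitutions_and_truncations(wt: Peptide) -> list[VariantRecord]:
    """All single substitutions and truncations of ``wt``.

    Returns 19·L missense + L nonsense records in a deterministic order:
    position-major, mutant residue alphabetical, with the stop (truncation)
    record last at each position.
    """
    records: list[VariantRecord] = []
    seq = wt.residues
    for pos in range(1, len(seq) + 1):
        wt_aa = seq[pos - 1]
        for mut in sorted(set(CANONICAL_AA) - {wt_aa}):
            protein = seq[: pos - 1] + mut + seq[pos:]
            records.append(
                VariantRecord(wt.id, pos, wt_aa, mut, "missense", protein)
            )
        records.append(
            VariantRecord(wt.id, pos, wt_aa, STOP, "nonsense", seq[: pos - 1])
        )
    return records


def sample_nnk_extensions(
    spec: NNKExtensionSpec, n: int, seed: int | np.random.Generator
) -> list[tuple[str, str]]:
    """Draw ``n`` random NNK extensions.

    Each extension is ``n_codons`` codons drawn uniformly (with replacement)
    from the codon set. Returns ``(nucleotide_extension, full_peptide)``
    pairs where the peptide is the base extended by the translation up to
    the first stop codon.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = np.asarray(spec.codon_set)
    draws = rng.integers(0, len(codons), size=(n, spec.n_codons))
    out = []
    base = spec.base_peptide.residues
    for row in draws:
        nt = "".join(codons[row])
        out.append((nt, base + translate_codons(nt)))
    return out


def nnk_codon_probability(aa: str, codon_set: Sequence[str] = NNK_CODONS) -> float:
    """Probability that a single uniform draw from the codon set encodes ``aa``.

    ``aa`` may be a residue or ``"*"`` for stop. Computed by exhaustive
    enumeration of the codon set.
    """
    hits = sum(1 for c in codon_set if CODON_TO_AA[c] == aa)
    return hits / len(codon_set)


def _snv_neighbor_aas(codon: str) -> set[str]:
    """Amino acids (or stop) reachable from ``codon`` by exactly one nt change."""
    reachable = set()
    for i in range(3):
        for nt in "ACGT":
            if nt == codon[i]:
                continue
            reachable.add(CODON_TO_AA[codon[:i] + nt + codon[i + 1 :]])
    return reachable


def annotate_snv_reachability(
    wt_nt: str, variants: Iterable[VariantRecord]
) -> list[VariantRecord]:
    """Flag variants whose target residue is one nucleotide change away.

    ``wt_nt`` is the parent coding sequence (no stop codon required). A
    missense or nonsense record is flagged ``True`` when its mutant amino
    acid (or stop) is encoded by some single-nucleotide neighbor of the
    wild-type codon at that position. Records with ``mut_aa`` equal to the
    wild-type residue, and wild-type records, are flagged ``False``.
    """
    wt_nt = wt_nt.upper()
    variants = list(variants)
    protein = translate_codons(wt_nt)
    lengths = {len(v.protein_seq) for v in variants if v.variant_class == "missense"}
    if lengths and lengths != {len(protein)}:
        raise ValueError(
            "wild-type nucleotide sequence does not translate to the variants' parent"
        )
    out = []
    for v in variants:
        if v.position is None or v.mut_aa is None or v.mut_aa == v.wt_aa:
            out.append(replace(v, snv_reachable=False))
            continue
        codon = wt_nt[3 * (v.position - 1) : 3 * v.position]
        if len(codon) != 3:
            raise ValueError("nucleotide sequence shorter than variant positions")
        if protein[v.position - 1] != v.wt_aa:
            raise ValueError(
                f"codon at position {v.position} encodes {protein[v.position - 1]}, "
                f"variant expects {v.wt_aa}"
            )
        flag = v.mut_aa in _snv_neighbor_aas(codon)
        out.append(replace(v, snv_reachable=flag))
    return out


def subset_abri_like(peptides: Iterable[str], base_length: int = 22) -> list[str]:
    """Extended peptides with Ser at the first extension position.

    For the Bri2 base (22 residues) that is position 23 — the position where
    the British-dementia stop-loss mutation inserts a Ser. Unextended
    peptides are excluded.
    """
    return [p for p in peptides if len(p) > base_length and p[base_length] == "S"]


def variants_to_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    """Tabulate variant records (one row per variant, indexed by id)."""
    rows = [
        {
            "id": v.id,
            "parent": v.parent_id,
            "position": v.position,
            "wt_aa": v.wt_aa,
            "mut_aa": v.mut_aa,
            "class": v.variant_class,
            "protein_seq": v.protein_seq,
            "snv_reachable": v.snv_reachable,
        }
        for v in variants
    ]
    return pd.DataFrame(rows).set_index("id")
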