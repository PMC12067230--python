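"""Peptide container, reference sequences and residue property scales.

The reference peptides are the 22-residue furin-released Bri2 peptide and
its two 34-residue dementia-associated C-terminal extension products, ADan
(Danish dementia) and ABri (British dementia). They ship as editable FASTA
fixtures under ``data/``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio import SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

_DATA_PACKAGE = "nucleation_dms.data"


@dataclass(frozen=True)
class Peptide:
    """A short peptide: an id and a 1-based-indexed residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"peptide {self.id!r} is empty")
        bad = set(self.residues) - set(CANONICAL_AA)
        if bad:
            raise ValueError(
                f"peptide {self.id!r} contains non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]


def load_peptide(path_or_handle) -> Peptide:
    """Read the first record of a FASTA file as a Peptide."""
    record = next(SeqIO.parse(path_or_handle, "fasta"))
    return Peptide(id=record.id, residues=str(record.seq).upper())


def _data_path(name: str):
    return resources.files(_DATA_PACKAGE).joinpath(name)


def reference_peptide(name: str) -> Peptide:
    """Load a bundled reference peptide: 'bri2', 'adan' or 'abri'."""
    name = name.lower()
    if name not in {"bri2", "adan", "abri"}:
        raise ValueError(f"unknown reference peptide {name!r}")
    with _data_path(f"{name}.fasta").open() as handle:
        return load_peptide(handle)


def reference_nucleotide(name: str) -> str:
    """Load a bundled coding sequence (synthetic back-translation) for a peptide."""
    with _data_path(f"{name.lower()}_nt_synthetic.fasta").open() as handle:
        record = next(SeqIO.parse(handle, "fasta"))
    return str(record.seq).upper()


def load_scales() -> pd.DataFrame:
    """Per-residue property scales, indexed by one-letter amino acid code.

    Columns: ``kyte_doolittle`` (hydropathy) and ``kanehisa_tsong``
    (beta-sheet propensity).
    """
    with _data_path("scales.tsv").open() as handle:
        scales = pd.read_csv(handle, sep="\t", comment="#").set_index("aa")
    if sorted(scales.index) != sorted(CANONICAL_AA):
        raise ValueError("scale table must cover exactly the 20 canonical residues")
    return scales
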