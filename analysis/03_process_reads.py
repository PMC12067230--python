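"""Round-trip a slice of the simulated experiment through raw reads.

Emits FASTQ for a 150-variant slice of the random-library counts (constant
flanks attached, uniform Q37), reprocesses the reads with the trimming /
quality / counting chain, and verifies the recovered count table is
identical. A second pass with base errors and low-quality bases shows the
QC filters engaging. FASTQ goes to scratch/, the QC report to results/.
"""

from pathlib import Path

import pandas as pd

import nucleation_dms as nd
from nucleation_dms.experiments import FLANK5, FLANK3

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "fastq"
SEED = 20240903


def load_counts() -> pd.DataFrame:
    flat = pd.read_csv(RESULTS / "random_counts.tsv", sep="\t", index_col=0)
    cols = [(int(c.split("_")[0][3:]), c.split("_")[1]) for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples(cols, names=["replicate", "phase"])
    return flat


def main() -> None:
    counts = load_counts().iloc[:150]
    nt_seqs = {v: v for v in counts.index}

    clean = nd.emit_fastq(counts, nt_seqs, FLANK5, FLANK3, SCRATCH / "clean",
                          phred=37, seed=SEED)
    cfg = nd.ProcessingConfig(flank5=FLANK5, flank3=FLANK3, expected_length=36,
                              min_input_reads=100)
    table, qc = nd.process_fastq_pair(clean, cfg, variant_index=counts.index)
    identical = table.equals(counts.astype(int))
    print(f"clean round trip over {int(counts.to_numpy().sum()):,} reads: "
          f"{'identical' if identical else 'MISMATCH'}")

    noisy = nd.emit_fastq(counts, nt_seqs, FLANK5, FLANK3, SCRATCH / "noisy",
                          phred=37, base_error_rate=0.01, low_quality_rate=0.005,
                          seed=SEED + 1)
    _table_n, qc_n = nd.process_fastq_pair(noisy, cfg, variant_index=counts.index)
    qc_n.to_csv(RESULTS / "read_qc_report.tsv", sep="\t", index=False)
    lost = 100 * (1 - qc_n["accepted"].sum() / qc_n["total_reads"].sum())
    print(f"with 1% base errors + 0.5% low-quality bases: "
          f"{lost:.1f}% of reads rejected by the QC chain "
          f"(see results/read_qc_report.tsv)")

    filtered = nd.input_read_filter(table, cfg)
    print(f"input-read filter (>=100 reads in at least one input replicate): "
          f"{len(table) - len(filtered)} of {len(table)} variants removed")


if __name__ == "__main__":
    main()
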