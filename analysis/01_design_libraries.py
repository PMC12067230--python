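"""Enumerate the designed libraries and sample the random-extension library.

Builds (i) every single amino-acid substitution and truncation of the two
34-residue extension peptides (680 variants each), annotated for
single-nucleotide-variant reachability against the bundled synthetic
coding sequences, and (ii) three NNK random-extension libraries of the
22-residue base peptide, scaled down from the experimental library sizes.

Writes results/designed_variants.tsv and results/nnk_library.tsv.
"""

from pathlib import Path

import pandas as pd

import nucleation_dms as nd
from nucleation_dms.peptides import reference_nucleotide

RESULTS = Path(__file__).resolve().parents[1] / "results"
# scaled-down counterparts of the three experimental libraries
EXPERIMENT_SIZES = {1: 3000, 2: 2200, 3: 1800}
SEED = 20240901


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    frames = []
    for name in ("adan", "abri"):
        peptide = nd.reference_peptide(name)
        records = nd.enumerate_substitutions_and_truncations(peptide)
        records = nd.annotate_snv_reachability(reference_nucleotide(name), records)
        frame = nd.variants_to_frame(records)
        frames.append(frame)
        n_snv = int(frame["snv_reachable"].sum())
        print(f"{name}: {len(frame)} designed variants "
              f"({(frame['class'] == 'missense').sum()} substitutions, "
              f"{(frame['class'] == 'nonsense').sum()} truncations); "
              f"{n_snv} reachable by a single nucleotide change")
    designed = pd.concat(frames)
    designed.to_csv(RESULTS / "designed_variants.tsv", sep="\t")

    base = nd.reference_peptide("bri2")
    spec = nd.NNKExtensionSpec(base)
    rows = []
    for experiment, size in EXPERIMENT_SIZES.items():
        seen = set()
        pairs = nd.sample_nnk_extensions(spec, 2 * size, seed=SEED + experiment)
        for nt, pep in pairs:
            if nt in seen:
                continue
            seen.add(nt)
            rows.append({"experiment": experiment, "nt_extension": nt,
                         "protein_seq": pep, "extension_length": len(pep) - len(base)})
            if len(seen) == size:
                break
    library = pd.DataFrame(rows)
    library.to_csv(RESULTS / "nnk_library.tsv", sep="\t", index=False)
    abri_like = nd.subset_abri_like(library["protein_seq"])
    print(f"random library: {len(library)} unique extensions across "
          f"{len(EXPERIMENT_SIZES)} experiments; "
          f"{100 * len(abri_like) / len(library):.1f}% carry Ser at position 23 "
          f"(expected {100 * 3 / 32:.1f}% from the NNK code)")


if __name__ == "__main__":
    main()
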