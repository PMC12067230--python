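"""Compare the sequence composition of nucleators and nonnucleators.

On the classified random library: per-residue composition enrichment over
the extension region (Welch t, Cohen's d, frequency difference),
position-wise physicochemical-class chi-square tests, length-stratified
class fractions, hydropathy / beta-propensity summaries, the ABri-like
(Ser-23) subset, a hydropathy-as-predictor AUC, and the cross-peptide
score correlation between the two simulated designed libraries.

Writes results/composition_stats.tsv, position_tests.tsv,
length_strata.tsv, properties.tsv.
"""

from pathlib import Path

import pandas as pd

import nucleation_dms as nd

RESULTS = Path(__file__).resolve().parents[1] / "results"
BASE_LEN = 22


def main() -> None:
    merged = pd.read_csv(RESULTS / "random_classes.tsv", sep="\t", index_col=0)
    extended = merged.loc[merged.index.str.len() > BASE_LEN]
    nuc = [s[BASE_LEN:] for s in extended.index[extended["label"] == "nucleator"]]
    non = [s[BASE_LEN:] for s in extended.index[extended["label"] == "nonnucleator"]]

    comp = nd.group_composition_test(nuc, non)
    comp.to_csv(RESULTS / "composition_stats.tsv", sep="\t")
    top = comp.reindex(comp["p"].sort_values().index).head(3)
    print(f"composition (extension region), {len(nuc)} nucleators vs "
          f"{len(non)} nonnucleators; largest differences:")
    for aa, row in top.iterrows():
        print(f"  {aa}: diff {row['freq_difference']:+.2f} points, "
              f"d = {row['cohens_d']:+.2f}, p = {row['p']:.2e}")

    pos = nd.positionwise_class_test(
        [s for s in extended.index[extended["label"] == "nucleator"]],
        [s for s in extended.index[extended["label"] == "nonnucleator"]],
        positions=range(BASE_LEN + 1, BASE_LEN + 13),
    )
    pos.to_csv(RESULTS / "position_tests.tsv", sep="\t", index=False)
    starred = pos.loc[pos["stars"] != ""]
    print(f"position-wise class tests: {len(starred)} of {len(pos)} "
          "(position, class) pairs significant at p < 0.05")

    strata = nd.length_stratify(merged)
    strata.to_csv(RESULTS / "length_strata.tsv", sep="\t")
    print("nucleator fraction by peptide length:",
          {int(k): round(v, 2) for k, v in strata["frac_nucleator"].items()})

    props = nd.sequence_properties(list(extended.index), region_start=BASE_LEN + 1)
    props["label"] = extended["label"].to_numpy()
    props.to_csv(RESULTS / "properties.tsv", sep="\t")
    means = props.groupby("label")[["kyte_doolittle", "kanehisa_tsong"]].mean()
    print("mean extension hydropathy / beta-propensity by class:")
    print(means.round(3).to_string())

    abri_like = nd.subset_abri_like(list(extended.index))
    sub = extended.loc[abri_like]
    print(f"ABri-like (Ser-23) subset: {len(sub)} sequences "
          f"({100 * len(sub) / len(extended):.1f}% of extended), "
          f"{100 * (sub['label'] == 'nucleator').mean():.1f}% nucleators")

    auc, sd = nd.predictor_auc(
        props["kyte_doolittle"].to_numpy(),
        (props["label"] == "nucleator").to_numpy(),
        seed=5,
    )
    print(f"extension hydropathy as a nucleation predictor: "
          f"AUC = {auc:.3f} +/- {sd:.3f} "
          "(near 0.5: hydropathy alone does not separate the simulated classes)")

    for stem in ("designed_classes",):
        a = pd.read_csv(RESULTS / f"{stem}.tsv", sep="\t", index_col=0)
        adan_scores = a[["position", "wt_aa", "mut_aa", "ns"]].dropna()
        half = adan_scores.sample(frac=0.5, random_state=0)
        rest = adan_scores.drop(half.index)
        r, p, n = nd.cross_peptide_correlation(half, rest, aggregation="by_mut_aa")
        print(f"split-half correlation of mean scores by mutant residue: "
              f"r = {r:.2f} (p = {p:.1e}, n = {n})")


if __name__ == "__main__":
    main()
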