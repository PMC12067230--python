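"""Simulate selection experiments for the designed and random libraries.

Designed library: true effects follow a three-way mixture (a quarter of
substitutions increase nucleation, somewhat under half decrease it, the
rest are wild-type-like), with the wild-type entry fixed at 0 so scoring
can centre on it. Random library: 30% nucleators with gamma-distributed
positive effects, the generator's default.

Sequencing depth is set to ~1,000 reads per variant per sample, matching
the coverage regime of real runs of this assay.

Writes results/{designed,random}_counts.tsv and matching *_truth.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import nucleation_dms as nd

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20240902
COVERAGE = 1000  # reads per variant per sample


def designed_truth(ids, seed: int) -> pd.Series:
    """Mixture of increasing / decreasing / neutral single-mutant effects."""
    rng = np.random.default_rng(seed)
    u = rng.random(len(ids))
    effects = np.zeros(len(ids))
    inc = u < 0.25
    dec = (u >= 0.25) & (u < 0.70)
    effects[inc] = rng.gamma(2.0, 0.75, inc.sum())
    effects[dec] = -rng.gamma(2.0, 1.0, dec.sum())
    return pd.Series(effects, index=pd.Index(ids, name="variant"), name="true_ns")


def save(counts: pd.DataFrame, truth: pd.Series, stem: str) -> None:
    flat = counts.copy()
    flat.columns = [f"rep{r}_{phase}" for r, phase in counts.columns]
    flat.to_csv(RESULTS / f"{stem}_counts.tsv", sep="\t")
    truth.to_csv(RESULTS / f"{stem}_truth.tsv", sep="\t")


def main() -> None:
    designed = pd.read_csv(RESULTS / "designed_variants.tsv", sep="\t", index_col=0)
    adan = designed.loc[designed["parent"] == "adan"]
    ids = ["adan_WT"] + list(adan.index)
    truth = designed_truth(ids, seed=SEED)
    truth.loc["adan_WT"] = 0.0
    depth = COVERAGE * len(truth)
    cfg = nd.SimulationConfig(input_depth=depth, output_depth=depth, seed=SEED + 1)
    counts = nd.simulate_counts(truth, cfg)
    save(counts, truth, "designed")
    print(f"designed library: {len(truth)} variants x 3 replicates at "
          f"{depth:,} reads per sample; true effects "
          f"{(truth > 0).mean() * 100:.0f}% increasing / "
          f"{(truth < 0).mean() * 100:.0f}% decreasing")

    library = pd.read_csv(RESULTS / "nnk_library.tsv", sep="\t")
    exp1 = library.loc[library["experiment"] == 1].set_index("nt_extension")
    truth_r = nd.assign_true_scores(exp1.index, nd.TrueEffectModel(), seed=SEED + 2)
    depth_r = COVERAGE * len(truth_r)
    counts_r = nd.simulate_counts(
        truth_r, nd.SimulationConfig(input_depth=depth_r, output_depth=depth_r,
                                     seed=SEED + 3)
    )
    save(counts_r, truth_r, "random")
    dropped = (counts_r.xs("output", axis=1, level="phase") == 0).all(axis=1).sum()
    print(f"random library (experiment 1): {len(truth_r)} sequences; "
          f"{dropped} with no output reads in any replicate (dropout)")


if __name__ == "__main__":
    main()
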