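"""End-to-end benchmark experiments on the synthetic generator.

Canned experiments that exercise the whole chain — library →  simulated
selection → (optionally FASTQ → read processing) → scoring →
classification — and report how well the pipeline recovers the generating
truth. Used by the analysis drivers and the acceptance script.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from nucleation_dms.library import NNKExtensionSpec, sample_nnk_extensions
from nucleation_dms.peptides import Peptide
from nucleation_dms.classify import (
    ClassificationConfig,
    classify_random,
    merge_duplicates,
)
from nucleation_dms.reads import ProcessingConfig, process_fastq_pair
from nucleation_dms.scoring import ScoreConfig, score_counts
from nucleation_dms.simulate import (
    SimulationConfig,
    TrueEffectModel,
    assign_true_scores,
    emit_fastq,
    simulate_counts,
)

#: constant amplicon flanks used by the simulated sequencing runs
#: (25 nt upstream, 21 nt downstream, mirroring the cloning design)
FLANK5 = "ACTAGTGGATCCAGCTGTACAAGTA"
FLANK3 = "TAAGCTTGATATCGAATTCCT"


def recovery_experiment(
    seed: int,
    n_variants: int = 2000,
    model: TrueEffectModel | None = None,
    sim: SimulationConfig | None = None,
) -> dict:
    """Simulate a random-extension-style selection and score it back.

    Default study conditions: 2,000 variants, 3 replicates, 2×10⁶ reads per
    sample, 30% nucleators with true scores ~ gamma(shape 2, scale 1.5).
    Reports the Pearson correlation between true and estimated scores over
    measured variants and the recovered nucleator fraction at FDR 0.05.
    """
    model = model or TrueEffectModel()
    rng = np.random.default_rng(seed)
    ids = [f"v{i:05d}" for i in range(n_variants)]
    true = assign_true_scores(ids, model, rng)
    sim = sim or SimulationConfig(seed=int(rng.integers(2**31)))
    counts = simulate_counts(true, sim)
    entries = score_counts(counts, ScoreConfig(centering="mode"))
    classified = classify_random(entries, ClassificationConfig())
    # final reliability step: duplicate merging is a no-op for unique ids,
    # but the discard of unreliable high-scoring nonnucleators applies
    final = classified.copy()
    final["protein_seq"] = final.index
    final = merge_duplicates(final)
    measured = ~classified["unmeasured"] & ~classified["imputed"]
    r, _ = stats.pearsonr(true[measured], classified.loc[measured, "ns"])
    nuc_measured = measured & (true > 0)
    r_nuc = (
        stats.pearsonr(true[nuc_measured], classified.loc[nuc_measured, "ns"])[0]
        if nuc_measured.sum() >= 3
        else float("nan")
    )
    return {
        "pearson_r": float(r),
        "pearson_r_nucleators": float(r_nuc),
        "true_nucleator_fraction": float((true > 0).mean()),
        "estimated_nucleator_fraction": float((final["label"] == "nucleator").mean()),
        "prefilter_nucleator_fraction": float((classified["label"] == "nucleator").mean()),
        "n_variants": n_variants,
        "truth": true,
        "classified": classified,
    }


def null_fdr_experiment(
    seeds,
    n_variants: int = 1000,
    depth: int = 200_000,
    replicates: int = 3,
) -> dict:
    """Global-null calibration: all true scores 0, classify at FDR 0.05.

    Returns the per-seed and mean fractions of variants falsely flagged as
    nucleators.
    """
    fractions = []
    ids = [f"v{i:05d}" for i in range(n_variants)]
    model = TrueEffectModel(p_nucleator=0.0)
    for seed in seeds:
        true = assign_true_scores(ids, model, seed)
        counts = simulate_counts(
            true,
            SimulationConfig(replicates=replicates, input_depth=depth,
                             output_depth=depth, seed=int(seed)),
        )
        entries = score_counts(counts, ScoreConfig(centering="mode"))
        classified = classify_random(entries)
        fractions.append(float((classified["label"] == "nucleator").mean()))
    return {
        "fractions": fractions,
        "mean_flagged_fraction": float(np.mean(fractions)),
        "n_variants": n_variants,
    }


def roundtrip_experiment(
    seed: int,
    n_variants: int = 100,
    depth: int = 20_000,
    out_dir: str | Path | None = None,
) -> dict:
    """Counts → FASTQ (no corruption) → read processing → counts identity."""
    base = Peptide("base", "EASNCFAIRHFENKFAVETLIC")
    pairs = sample_nnk_extensions(NNKExtensionSpec(base), 3 * n_variants, seed)
    nt_seqs: dict[str, str] = {}
    for nt, _pep in pairs:
        if nt not in nt_seqs:
            nt_seqs[nt] = nt
        if len(nt_seqs) == n_variants:
            break
    true = assign_true_scores(list(nt_seqs), TrueEffectModel(), seed + 1)
    counts = simulate_counts(
        true, SimulationConfig(replicates=2, input_depth=depth,
                               output_depth=depth, seed=seed + 2)
    )
    cfg = ProcessingConfig(flank5=FLANK5, flank3=FLANK3, expected_length=36,
                           min_input_reads=100)
    with tempfile.TemporaryDirectory() as tmp:
        target = Path(out_dir) if out_dir is not None else Path(tmp)
        paths = emit_fastq(counts, nt_seqs, FLANK5, FLANK3, target, phred=37)
        table, qc = process_fastq_pair(paths, cfg, variant_index=counts.index)
    exact = bool(table.equals(counts.astype(int)))
    return {"exact": exact, "n_variants": n_variants,
            "total_reads": int(counts.to_numpy().sum()), "qc": qc}
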