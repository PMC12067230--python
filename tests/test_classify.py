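"""FDR classification, quality filtering, duplicate merging, gatekeepers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nucleation_dms as nd


def bh_oracle(pvals):
    """Naive O(m^2) step-up BH adjustment."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_from_top in range(m):
        i = m - 1 - rank_from_top
        idx = order[i]
        value = p[idx] * m / (i + 1)
        if rank_from_top == 0:
            adj[idx] = min(value, 1.0)
        else:
            adj[idx] = min(value, adj[order[i + 1]], 1.0)
    return adj


class TestBHAdjust:
    def test_step_up_hand_example(self):
        p = [0.01, 0.02, 0.04, 0.5]
        adj = nd.bh_adjust(p)
        # thresholds i*q/m: reject first two at FDR 0.05
        assert (adj <= 0.05).tolist() == [True, True, False, False]

    def test_degenerate_cases(self):
        assert nd.bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]
        assert nd.bh_adjust([0.123]).tolist() == [0.123]

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            nd.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_naive_oracle(self, pvals):
        assert np.allclose(nd.bh_adjust(pvals), bh_oracle(pvals), atol=1e-12)


def entries_frame(ns, sigma, **extra):
    frame = pd.DataFrame({"ns": ns, "sigma": sigma})
    for k, v in extra.items():
        frame[k] = v
    frame.index = [f"v{i}" for i in range(len(frame))]
    return frame


class TestClassifyDesigned:
    def test_planted_five_sigma_shifts_recovered(self, rng):
        n_null = 200
        ns = np.concatenate([rng.normal(0, 0.1, n_null), [1.0, -1.0]])
        entries = entries_frame(ns, 0.2)  # shifted variants sit at +-5 sigma
        kept, dropped = nd.classify_designed(entries)
        labels = pd.concat([kept, dropped])["label"]
        assert labels.loc["v200"] == "NS_inc"
        assert labels.loc["v201"] == "NS_dec"
        null_labels = labels.iloc[:n_null]
        assert (null_labels == "WT_like").mean() > 0.95

    def test_zero_score_is_wt_like(self):
        entries = entries_frame([0.0, 0.0, 0.1, -0.1, 0.05], [0.5, 5.0, 0.4, 0.4, 0.4])
        kept, dropped = nd.classify_designed(entries)
        labels = pd.concat([kept, dropped])["label"]
        assert labels.loc["v0"] == "WT_like"
        assert labels.loc["v1"] == "WT_like"

    def test_tiny_z_never_rejected(self, rng):
        ns = np.concatenate([rng.normal(0, 0.1, 100), [0.02]])
        entries = entries_frame(ns, 0.2)
        kept, dropped = nd.classify_designed(entries)
        assert pd.concat([kept, dropped]).loc["v100", "label"] == "WT_like"

    def test_nonpositive_sigma_raises(self):
        entries = entries_frame([0.1, 0.2, 0.3, 0.4], [0.1, 0.0, 0.1, 0.1])
        with pytest.raises(ValueError):
            nd.classify_designed(entries)


class TestSigmaIQRFilter:
    def make(self, sigmas, labels, ns=None):
        # scores engineered so IQR == 1 exactly: quartiles at -0.5 and 0.5
        base_ns = [-1.5, -0.5, 0.5, 1.5] * 2 if ns is None else ns
        frame = pd.DataFrame({
            "ns": base_ns[: len(sigmas)], "sigma": sigmas, "label": labels,
        })
        frame.index = [f"v{i}" for i in range(len(frame))]
        return frame

    def test_cutoff_boundary(self):
        sigmas = [0.01, 0.01, 0.01, 0.01, 0.21, 0.19, 0.01, 0.01]
        labels = ["WT_like"] * 8
        frame = self.make(sigmas, labels)
        iqr = np.subtract(*np.percentile(frame["ns"], [75, 25]))
        kept, dropped = nd.sigma_iqr_filter(frame, nd.ClassificationConfig())
        assert set(dropped.index) == {f"v{i}" for i, s in enumerate(sigmas)
                                      if s / iqr > 0.2}
        assert "v5" in kept.index

    def test_significant_labels_immune(self):
        frame = self.make([5.0, 0.01, 0.01, 0.01], ["NS_inc"] + ["WT_like"] * 3)
        kept, dropped = nd.sigma_iqr_filter(frame, nd.ClassificationConfig())
        assert "v0" in kept.index and dropped.empty

    def test_zero_sigma_always_retained(self):
        frame = self.make([0.0, 0.01, 0.01, 0.01], ["WT_like"] * 4)
        kept, _ = nd.sigma_iqr_filter(frame, nd.ClassificationConfig())
        assert "v0" in kept.index

    def test_zero_iqr_raises(self):
        frame = self.make([0.1] * 4, ["WT_like"] * 4, ns=[1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            nd.sigma_iqr_filter(frame, nd.ClassificationConfig())


class TestClassifyRandom:
    def test_power_on_separated_nucleators(self, rng):
        n = 2000
        is_nuc = rng.random(n) < 0.3
        ns = np.where(is_nuc, 3.0, 0.0) + rng.normal(0, 0.2, n)
        entries = entries_frame(ns, 0.2, imputed=False)
        out = nd.classify_random(entries)
        frac = (out["label"] == "nucleator").mean()
        assert abs(frac - is_nuc.mean()) < 0.03

    def test_imputed_forced_nonnucleator(self):
        entries = entries_frame([5.0, 0.1, 6.0], [0.1, 0.1, 0.1],
                                imputed=[True, False, False])
        out = nd.classify_random(entries)
        assert out.loc["v0", "label"] == "nonnucleator"
        assert out.loc["v2", "label"] == "nucleator"

    def test_top10_subset_of_nucleators_and_size(self, rng):
        n = 500
        ns = np.concatenate([rng.normal(0, 0.05, 350), rng.normal(4, 1, 150)])
        entries = entries_frame(ns, 0.1, imputed=False)
        out = nd.classify_random(entries)
        top = out.loc[out["top10"]]
        assert (top["label"] == "nucleator").all()
        assert abs(len(top) - round(0.10 * n)) <= 1

    def test_monotonicity_in_ns(self, rng):
        """Raising a score (fixed sigma) can never demote a nucleator."""
        base = np.concatenate([rng.normal(0, 0.1, 300), rng.normal(2, 0.5, 100)])
        entries = entries_frame(base, 0.15, imputed=False)
        out1 = nd.classify_random(entries)
        bumped = entries.copy()
        bumped.loc[out1["label"] == "nucleator", "ns"] += 1.0
        out2 = nd.classify_random(bumped)
        was_nuc = out1.index[out1["label"] == "nucleator"]
        assert (out2.loc[was_nuc, "label"] == "nucleator").all()

    def test_labels_partition(self, rng):
        entries = entries_frame(rng.normal(0, 1, 100), 0.5, imputed=False)
        out = nd.classify_random(entries)
        assert set(out["label"]) <= {"nucleator", "nonnucleator"}
        assert out["label"].notna().all()


class TestEmpiricalFDR:
    def test_global_null_false_flag_rate(self):
        """All-null library: flagged fraction stays near the nominal FDR."""
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            sigma = rng.uniform(0.1, 0.5, 800)
            ns = rng.normal(0, 1, 800) * sigma
            entries = entries_frame(ns, sigma, imputed=False)
            out = nd.classify_random(entries)
            fracs.append((out["label"] == "nucleator").mean())
        assert np.mean(fracs) <= 0.05 + 0.02


class TestMergeDuplicates:
    def make(self, rows):
        frame = pd.DataFrame(rows)
        frame.index = [f"v{i}" for i in range(len(frame))]
        return frame

    def test_majority_status_and_mean_ns(self):
        frame = self.make([
            {"protein_seq": "PEP", "ns": 1.0, "sigma": 0.1, "label": "nucleator", "top10": False},
            {"protein_seq": "PEP", "ns": 2.0, "sigma": 0.1, "label": "nucleator", "top10": False},
            {"protein_seq": "PEP", "ns": 3.0, "sigma": 0.1, "label": "nonnucleator", "top10": False},
            {"protein_seq": "OTH", "ns": 0.0, "sigma": 0.1, "label": "nonnucleator", "top10": False},
        ])
        merged = nd.merge_duplicates(frame)
        assert merged.loc["PEP", "label"] == "nucleator"
        assert merged.loc["PEP", "ns"] == pytest.approx(2.0)
        assert merged.loc["PEP", "n_merged"] == 3

    def test_tie_breaks_to_nonnucleator(self):
        frame = self.make([
            {"protein_seq": "PEP", "ns": 1.0, "sigma": 0.1, "label": "nucleator", "top10": False},
            {"protein_seq": "PEP", "ns": 1.0, "sigma": 0.1, "label": "nonnucleator", "top10": False},
            {"protein_seq": "A", "ns": 0.0, "sigma": 0.1, "label": "nonnucleator", "top10": False},
            {"protein_seq": "B", "ns": 0.5, "sigma": 0.1, "label": "nonnucleator", "top10": False},
        ])
        merged = nd.merge_duplicates(frame)
        assert merged.loc["PEP", "label"] == "nonnucleator"

    def test_unreliable_high_scoring_nonnucleator_discarded(self):
        rows = [
            {"protein_seq": f"N{i}", "ns": x, "sigma": 0.01,
             "label": "nonnucleator", "top10": False}
            for i, x in enumerate([-1.5, -0.5, 0.5, 1.5])
        ]
        rows.append({"protein_seq": "NUC", "ns": 2.0, "sigma": 0.01,
                     "label": "nucleator", "top10": False})
        rows.append({"protein_seq": "BAD", "ns": 3.0, "sigma": 5.0,
                     "label": "nonnucleator", "top10": False})
        merged = nd.merge_duplicates(self.make(rows))
        assert "BAD" not in merged.index
        assert "NUC" in merged.index


class TestGatekeepers:
    def test_counts_match_bruteforce_tally(self, rng):
        labels = rng.choice(["NS_inc", "NS_dec", "WT_like"], size=400)
        positions = rng.integers(1, 21, size=400)
        frame = pd.DataFrame({"position": positions, "label": labels})
        table = nd.count_gatekeepers(frame)
        for pos in np.unique(positions):
            mask = positions == pos
            assert table.loc[pos, "n_inc"] == (labels[mask] == "NS_inc").sum()
            assert table.loc[pos, "n_dec"] == (labels[mask] == "NS_dec").sum()
            assert table.loc[pos, "gatekeeper"] == (
                table.loc[pos, "n_inc"] > table.loc[pos, "n_dec"]
            )

    def test_twelve_vs_two_is_gatekeeper(self):
        frame = pd.DataFrame({
            "position": [6] * 14 + [7] * 2,
            "label": ["NS_inc"] * 12 + ["NS_dec"] * 2 + ["WT_like"] * 2,
        })
        table = nd.count_gatekeepers(frame)
        assert bool(table.loc[6, "gatekeeper"])
        assert not bool(table.loc[7, "gatekeeper"])


class TestBookkeeping:
    def test_class_fractions(self):
        frac = nd.class_fractions({"nucleator": 1, "nonnucleator": 3})
        assert frac["nucleator"] == pytest.approx(25.0)
        assert frac.sum() == pytest.approx(100.0)

    def test_heatmap_matrix_layout(self, adan):
        records = nd.enumerate_substitutions_and_truncations(adan)
        frame = nd.variants_to_frame(records)
        frame["ns"] = np.arange(len(frame), dtype=float)
        matrix = nd.heatmap_matrix(frame)
        assert matrix.shape == (21, 34)  # 20 residues + stop, 34 positions
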