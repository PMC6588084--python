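"""Directional Running Fisher scoring and cutoff calibration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tgxddi import (
    DDI,
    NON_DDI,
    DirectionalSignature,
    calibrate_cutoff,
    fit_nsc,
    make_signature,
    rf_call,
    running_fisher_score,
)
from tgxddi.running_fisher import prefix_tail_pvalues

from conftest import make_panel, make_profile
from oracles import hypergeom_tail_bruteforce, zero_fn_cutoff_bruteforce


def signature(entries, universe):
    return DirectionalSignature(entries=tuple(entries), universe_size=universe)


class TestMakeSignature:
    def test_directions_follow_centroid_difference_and_zeros_drop(self):
        panel = make_panel(
            {
                "d1": [2.0, -1.0, 0.5], "d2": [2.0, -1.0, 0.5],
                "n1": [0.0, 0.0, 0.5], "n2": [0.0, 0.0, 0.5],
            },
            {"d1": DDI, "d2": DDI, "n1": NON_DDI, "n2": NON_DDI},
        )
        model = fit_nsc(panel, s0=1.0)
        with pytest.warns(UserWarning, match="G3"):
            sig = make_signature(model)
        assert [(g, d) for g, d, _ in sig.entries] == [("G1", 1), ("G2", -1)]
        assert sig.universe_size == 3

    def test_equal_weights_ordered_alphabetically(self):
        panel = make_panel(
            {"d1": [1.0, 1.0], "d2": [1.0, 1.0], "n1": [-1.0, -1.0], "n2": [-1.0, -1.0]},
            {"d1": DDI, "d2": DDI, "n1": NON_DDI, "n2": NON_DDI},
        )
        sig = make_signature(fit_nsc(panel, s0=1.0))
        assert [g for g, _, _ in sig.entries] == ["G1", "G2"]

    def test_directions_match_sign_oracle(self, rng):
        cols = {f"d{j}": rng.normal(1, 1, 6).tolist() for j in range(3)}
        cols.update({f"n{j}": rng.normal(-1, 1, 6).tolist() for j in range(3)})
        labels = {c: (DDI if c.startswith("d") else NON_DDI) for c in cols}
        panel = make_panel(cols, labels)
        model = fit_nsc(panel)
        sig = make_signature(model)
        diff = panel.matrix[["d0", "d1", "d2"]].mean(axis=1) - panel.matrix[
            ["n0", "n1", "n2"]
        ].mean(axis=1)
        for g, d, w in sig.entries:
            assert d == (1 if diff[g] > 0 else -1)
            assert w == pytest.approx(abs(diff[g]))


class TestPrefixPvalues:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_match_exhaustive_hypergeometric_tails(self, seed):
        rng = np.random.default_rng(seed)
        universe = 30
        genes = [f"G{i}" for i in range(universe)]
        sig_genes = frozenset(rng.choice(genes, size=5, replace=False).tolist())
        query = rng.choice(genes, size=8, replace=False).tolist()
        p = prefix_tail_pvalues(sig_genes, query, universe)
        overlap = 0
        for k, g in enumerate(query, start=1):
            overlap += g in sig_genes
            expected = hypergeom_tail_bruteforce(overlap, universe, len(sig_genes), k)
            assert p[k - 1] == pytest.approx(expected, abs=1e-12)


class TestScore:
    def concordant_query(self, sig):
        vals = {}
        for rank, (g, d, _) in enumerate(sig.entries):
            vals[g] = d * (10.0 - rank)  # strong, correctly signed
        return make_profile("q", vals)

    def five_gene_signature(self):
        return signature(
            [("G1", 1, 5.0), ("G2", 1, 4.0), ("G3", -1, 3.0), ("G4", -1, 2.0), ("G5", 1, 1.0)],
            universe=20,
        )

    def test_maximal_concordance_is_positive(self):
        sig = self.five_gene_signature()
        res = running_fisher_score(sig, self.concordant_query(sig))
        assert res.direction == "positive"
        assert res.signed_score > 0
        assert 0 < res.p_value < 1

    def test_antisymmetry_under_global_sign_flip(self):
        sig = self.five_gene_signature()
        q = self.concordant_query(sig)
        flipped = make_profile("qf", {g: -v for g, v in q.log2fc.items()})
        r1 = running_fisher_score(sig, q)
        r2 = running_fisher_score(sig, flipped)
        assert r2.direction == "negative"
        assert r2.signed_score == pytest.approx(-r1.signed_score, abs=1e-12)
        assert r2.p_value == pytest.approx(r1.p_value, abs=1e-15)

    def test_component_pvalues_match_bruteforce(self, rng):
        # 5-gene signature, 8-gene query, universe 20: every pair P equals
        # min over prefixes of the exhaustive tail, Bonferroni-corrected
        universe = 20
        genes = [f"G{i}" for i in range(universe)]
        sig = signature(
            [(g, 1 if i < 3 else -1, float(5 - i)) for i, g in enumerate(genes[:5])],
            universe=universe,
        )
        q_genes = rng.choice(genes, size=8, replace=False).tolist()
        q = make_profile("q", {g: float(v) for g, v in zip(q_genes, rng.normal(0, 2, 8))})
        res = running_fisher_score(sig, q)

        up_sig = {g for g, d, _ in sig.entries if d == 1}
        down_sig = {g for g, d, _ in sig.entries if d == -1}
        for s_name, s_genes in (("up", up_sig), ("down", down_sig)):
            for q_name, q_sign in (("up", 1), ("down", -1)):
                part = sorted(
                    (g for g, v in q.log2fc.items() if np.sign(v) == q_sign),
                    key=lambda g: (-abs(q.log2fc[g]), g),
                )
                if not part:
                    expected = 1.0
                else:
                    overlap, best = 0, 1.0
                    for k, g in enumerate(part, start=1):
                        overlap += g in s_genes
                        best = min(
                            best, hypergeom_tail_bruteforce(overlap, universe, len(s_genes), k)
                        )
                    expected = min(1.0, best * len(part))
                assert res.component_pvalues[f"{s_name}_{q_name}"] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_zero_overlap_gives_unit_p_and_zero_score(self):
        sig = signature([("S1", 1, 1.0), ("S2", -1, 1.0)], universe=20)
        q = make_profile("q", {"Q1": 0.0, "Q2": 0.0})  # zero log2fc: no direction
        res = running_fisher_score(sig, q)
        assert res.p_value == 1.0
        assert res.direction == "positive"
        assert res.signed_score == 0.0

    def test_universe_too_small_rejected(self):
        sig = self.five_gene_signature()
        q = self.concordant_query(sig)
        with pytest.raises(ValueError):
            running_fisher_score(sig, q, universe_size=3)

    def test_monotone_under_concordant_enrichment(self):
        # appending ever-stronger concordant signature genes to the query
        # never decreases the positive score
        universe = 100
        sig = signature(
            [(f"S{i}", 1 if i % 2 == 0 else -1, float(20 - i)) for i in range(10)],
            universe=universe,
        )
        base = {f"Q{i}": (0.5 + 0.01 * i) * (1 if i % 2 == 0 else -1) for i in range(6)}
        prev = running_fisher_score(sig, make_profile("q", dict(base)), universe).signed_score
        vals = dict(base)
        strength = 50.0
        for g, d, _ in sig.entries:
            vals[g] = d * strength  # enters at the top of its part
            strength += 1.0
            score = running_fisher_score(sig, make_profile("q", dict(vals)), universe).signed_score
            assert score >= prev - 1e-9
            prev = score


class TestCalibration:
    def test_worked_example(self):
        scores = {"d1": 30.0, "d2": 25.0, "d3": 22.0, "n1": 18.0, "n2": 5.0, "n3": -10.0, "n4": 21.0}
        labels = {c: (DDI if c.startswith("d") else NON_DDI) for c in scores}
        cutoff = calibrate_cutoff(scores, labels)
        assert cutoff == 22.0
        fp = [c for c in scores if labels[c] == NON_DDI and scores[c] >= cutoff]
        assert fp == []
        # one false positive appears only once the threshold drops to <= 21
        assert [c for c in scores if labels[c] == NON_DDI and scores[c] >= 21.0] == ["n4"]

    @pytest.mark.parametrize("seed", range(5))
    def test_largest_zero_fn_threshold_by_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        scores = {f"c{i}": float(rng.normal(10, 15)) for i in range(12)}
        labels = {c: (DDI if rng.random() < 0.5 else NON_DDI) for c in scores}
        if DDI not in labels.values():
            labels["c0"] = DDI
        cutoff = calibrate_cutoff(scores, labels)
        assert cutoff == zero_fn_cutoff_bruteforce(scores, labels)
        fn = [c for c in scores if labels[c] == DDI and scores[c] < cutoff]
        assert fn == []

    def test_perfectly_separated_scores_give_zero_fp(self):
        scores = {"d1": 40.0, "d2": 35.0, "n1": 2.0, "n2": -3.0}
        labels = {"d1": DDI, "d2": DDI, "n1": NON_DDI, "n2": NON_DDI}
        cutoff = calibrate_cutoff(scores, labels)
        assert not [c for c in scores if labels[c] == NON_DDI and scores[c] >= cutoff]

    def test_high_scoring_nonddi_is_false_positive_at_any_zero_fn_cutoff(self):
        scores = {"d1": 25.0, "d2": 20.0, "n_hot": 30.0, "n2": 1.0}
        labels = {"d1": DDI, "d2": DDI, "n_hot": NON_DDI, "n2": NON_DDI}
        cutoff = calibrate_cutoff(scores, labels)
        assert scores["n_hot"] >= cutoff  # inevitably misclassified

    def test_empty_ddi_set_rejected(self):
        with pytest.raises(ValueError):
            calibrate_cutoff({"a": 1.0}, {"a": NON_DDI})


class TestRFCall:
    @pytest.mark.parametrize(
        "score,cutoff,expected",
        [(25.0, 19.0, DDI), (18.9, 19.0, NON_DDI), (19.0, 19.0, DDI)],
    )
    def test_threshold_rule_with_ge_convention(self, score, cutoff, expected):
        call = rf_call(score, cutoff)
        assert call.verdict == expected
        assert call.score == score
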