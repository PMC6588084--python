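"""The ddCq chain: reference-gene stability ranking, expression filtering,
and fold-change computation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tgxddi import (
    compute_fold_changes,
    filter_unexpressed_genes,
    rank_reference_genes,
)

from conftest import make_cq


def simple_sheet(sample_ids, roles=None, chemicals=None, vehicle="H2O"):
    rows = []
    for i, sid in enumerate(sample_ids):
        rows.append(
            {
                "sample_id": sid,
                "chemical": (chemicals or ["chemA"] * len(sample_ids))[i],
                "role": (roles or ["treatment"] * len(sample_ids))[i],
                "vehicle": vehicle,
                "replicate": 1,
            }
        )
    return rows


def two_sample_cq(gene_values: dict[str, tuple[float, float]]):
    """Two samples s1 (control) and s2 (treatment) with given per-gene Cq."""
    values = {
        "s1": {g: v[0] for g, v in gene_values.items()},
        "s2": {g: v[1] for g, v in gene_values.items()},
    }
    sheet = simple_sheet(["s1", "s2"], roles=["control", "treatment"])
    return make_cq(values, sheet)


class TestReferenceRanking:
    def test_zero_variance_gene_ranks_first_with_exact_zero(self):
        cq = two_sample_cq({"A": (20.0, 20.0), "B": (18.0, 25.0)})
        ranked = rank_reference_genes(cq, ["A", "B"])
        assert ranked[0] == ("A", 0.0)
        assert ranked[1][0] == "B"

    def test_ordering_matches_spreadsheet_sds(self, rng):
        genes = ["HPRT1", "GUSB", "GAPDH", "CASC3", "GENE18S", "EIF2B1"]
        base = rng.uniform(18, 28, size=6)
        sds = {g: 0.1 * (i + 1) for i, g in enumerate(rng.permutation(genes))}
        n = 40
        values = {
            f"s{j}": {g: base[i] + rng.normal(0, sds[g]) for i, g in enumerate(genes)}
            for j in range(n)
        }
        sheet = simple_sheet(
            [f"s{j}" for j in range(n)],
            roles=["control"] + ["treatment"] * (n - 1),
            chemicals=["veh"] + [f"c{j}" for j in range(n - 1)],
        )
        cq = make_cq(values, sheet)
        ranked = rank_reference_genes(cq, genes)
        # spreadsheet-style oracle: per-gene sample SD, ascending
        frame = pd.DataFrame(values)
        expected = sorted(
            ((g, float(np.std(frame.loc[g].to_numpy(), ddof=1))) for g in genes),
            key=lambda t: (t[1], t[0]),
        )
        assert [g for g, _ in ranked] == [g for g, _ in expected]
        top2 = {g for g, _ in ranked[:2]}
        assert top2 == {g for g, _ in expected[:2]}

    def test_tie_broken_alphabetically(self):
        cq = two_sample_cq({"ZZZ": (20.0, 22.0), "AAA": (25.0, 27.0)})
        ranked = rank_reference_genes(cq, ["ZZZ", "AAA"])
        assert [g for g, _ in ranked] == ["AAA", "ZZZ"]

    def test_missing_candidate_named_in_error(self):
        cq = two_sample_cq({"A": (20.0, 20.0)})
        with pytest.raises(KeyError, match="NOPE"):
            rank_reference_genes(cq, ["A", "NOPE"])

    def test_mostly_undetermined_candidate_excluded_with_warning(self):
        values = {
            "s1": {"A": 20.0, "B": np.nan},
            "s2": {"A": 20.5, "B": np.nan},
            "s3": {"A": 20.2, "B": 30.0},
        }
        sheet = simple_sheet(
            ["s1", "s2", "s3"],
            roles=["control", "treatment", "treatment"],
            chemicals=["veh", "c1", "c2"],
        )
        cq = make_cq(values, sheet)
        with pytest.warns(UserWarning, match="B"):
            ranked = rank_reference_genes(cq, ["A", "B"])
        assert [g for g, _ in ranked] == ["A"]

    def test_sample_order_invariance(self, rng):
        n = 10
        values = {f"s{j}": {"A": rng.uniform(18, 30), "B": rng.uniform(18, 30)} for j in range(n)}
        sheet = simple_sheet(
            list(values),
            roles=["control"] + ["treatment"] * (n - 1),
            chemicals=["veh"] + [f"c{j}" for j in range(n - 1)],
        )
        cq = make_cq(values, sheet)
        shuffled_ids = list(values)[::-1]
        cq2 = make_cq({k: values[k] for k in shuffled_ids}, sheet)
        assert rank_reference_genes(cq, ["A", "B"]) == rank_reference_genes(cq2, ["A", "B"])


class TestFoldChange:
    def test_treatment_equal_to_control_gives_all_zero(self):
        cq = two_sample_cq({"REF": (20.0, 20.0), "T1": (24.0, 24.0), "T2": (31.0, 31.0)})
        (profile,) = compute_fold_changes(cq, ["REF"], ["T1", "T2"])
        assert profile.chemical == "chemA"
        assert (profile.log2fc == 0.0).all()

    def test_ddcq_minus_two_gives_fold_change_four(self):
        # control dCq = 24-20 = 4; treatment dCq = 22-20 = 2; ddCq = -2
        cq = two_sample_cq({"REF": (20.0, 20.0), "T": (24.0, 22.0)})
        (profile,) = compute_fold_changes(cq, ["REF"], ["T"])
        assert profile.log2fc["T"] == pytest.approx(2.0)
        assert 2.0 ** profile.log2fc["T"] == pytest.approx(4.0)

    def test_hand_computed_chain(self):
        # ref 20/20; target control 24, treatment 21 -> ddCq = 1 - 4 = -3 -> log2fc +3
        cq = two_sample_cq({"REF": (20.0, 20.0), "T": (24.0, 21.0)})
        (profile,) = compute_fold_changes(cq, ["REF"], ["T"])
        assert profile.log2fc["T"] == pytest.approx(3.0)

    def test_replicates_averaged_on_dcq_scale(self):
        # treatment replicate dCq values 1 and 3 must average to 2 (log2fc -2),
        # not to the linear-scale mean log2((2^-1 + 2^-3)/2)
        values = {
            "ctrl": {"REF": 20.0, "T": 20.0},
            "t_r1": {"REF": 20.0, "T": 21.0},
            "t_r2": {"REF": 20.0, "T": 23.0},
        }
        sheet = [
            {"sample_id": "ctrl", "chemical": "veh", "role": "control", "vehicle": "H2O", "replicate": 1},
            {"sample_id": "t_r1", "chemical": "X", "role": "treatment", "vehicle": "H2O", "replicate": 1},
            {"sample_id": "t_r2", "chemical": "X", "role": "treatment", "vehicle": "H2O", "replicate": 2},
        ]
        cq = make_cq(values, sheet)
        (profile,) = compute_fold_changes(cq, ["REF"], ["T"])
        assert profile.log2fc["T"] == pytest.approx(-2.0)

    def test_missing_control_names_chemical(self):
        values = {
            "c1": {"REF": 20.0, "T": 20.0},
            "t1": {"REF": 20.0, "T": 21.0},
        }
        sheet = [
            {"sample_id": "c1", "chemical": "veh", "role": "control", "vehicle": "DMSO", "replicate": 1},
            {"sample_id": "t1", "chemical": "X", "role": "treatment", "vehicle": "EtOH", "replicate": 1},
        ]
        with pytest.raises(ValueError, match="EtOH"):
            make_cq(values, sheet)

    def test_undetermined_in_retained_gene_directs_to_filter(self):
        cq = two_sample_cq({"REF": (20.0, 20.0), "T": (np.nan, 21.0)})
        with pytest.raises(ValueError, match="filter"):
            compute_fold_changes(cq, ["REF"], ["T"])

    def test_log2fc_is_exactly_minus_ddcq(self, rng):
        # fold change strictly positive, log2(fold change) = -ddCq exactly
        genes = {f"T{i}": (rng.uniform(18, 32), rng.uniform(18, 32)) for i in range(8)}
        genes["REF"] = (20.0, 20.0)
        cq = two_sample_cq(genes)
        (profile,) = compute_fold_changes(cq, ["REF"], [g for g in genes if g != "REF"])
        for g in profile.genes:
            ddcq = (genes[g][1] - 20.0) - (genes[g][0] - 20.0)
            assert profile.log2fc[g] == pytest.approx(-ddcq, abs=1e-12)
            assert 2.0 ** profile.log2fc[g] > 0


class TestFiltering:
    def _cq_with_fraction(self, frac_above: float, n_samples: int = 10):
        n_above = int(round(frac_above * n_samples))
        values = {
            f"s{j}": {
                "BAD": 41.0 if j < n_above else 35.0,
                "GOOD": 30.0 + 0.1 * j,
            }
            for j in range(n_samples)
        }
        sheet = simple_sheet(
            list(values),
            roles=["control"] + ["treatment"] * (n_samples - 1),
            chemicals=["veh"] + [f"c{j}" for j in range(n_samples - 1)],
        )
        return make_cq(values, sheet)

    def test_majority_above_ceiling_excluded(self):
        cq = self._cq_with_fraction(0.6)
        retained, excluded = filter_unexpressed_genes(cq, ["BAD", "GOOD"])
        assert excluded == ["BAD"]
        assert retained == ["GOOD"]

    def test_all_expressed_nothing_excluded(self):
        cq = self._cq_with_fraction(0.0)
        retained, excluded = filter_unexpressed_genes(cq, ["BAD", "GOOD"])
        assert excluded == []
        assert retained == ["BAD", "GOOD"]

    def test_exactly_half_is_retained(self):
        # rule is strict 'greater than the majority fraction'
        cq = self._cq_with_fraction(0.5)
        retained, excluded = filter_unexpressed_genes(cq, ["BAD", "GOOD"])
        assert excluded == []

    def test_filtering_is_idempotent(self):
        cq = self._cq_with_fraction(0.8)
        retained, excluded = filter_unexpressed_genes(cq, ["BAD", "GOOD"])
        retained2, excluded2 = filter_unexpressed_genes(cq, retained)
        assert retained2 == retained
        assert excluded2 == []

    def test_all_unexpressed_raises(self):
        cq = self._cq_with_fraction(1.0)
        with pytest.raises(ValueError):
            filter_unexpressed_genes(cq, ["BAD"])
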