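"""Combinatorial barcodes: codes, categories, enumeration, frequency tables."""

import itertools
from collections import Counter

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peepbarcode.barcode import (
    BarcodePattern,
    barcode_cohort,
    categorize,
    category_frequencies,
    enumerate_patterns,
    make_combination,
)
from peepbarcode.peep import DOWN, NORM, UP

#: The published 15-row pattern table for a 4-gene panel: code -> category.
FOUR_GENE_TABLE = [
    ("4U0N0D", "4-Up"),
    ("3U1N0D", "3-Up"),
    ("2U2N0D", "2-Up"),
    ("1U3N0D", "1-Up"),
    ("0U4N0D", "Others"),
    ("3U0N1D", "Others"),
    ("2U1N1D", "Others"),
    ("1U2N1D", "1-Up-1-Down"),
    ("0U3N1D", "Others"),
    ("2U0N2D", "Others"),
    ("1U1N2D", "Others"),
    ("0U2N2D", "Others"),
    ("1U0N3D", "Others"),
    ("0U1N3D", "Others"),
    ("0U0N4D", "Others"),
]


def brute_force_patterns(n: int) -> set[tuple[int, int, int]]:
    """Oracle: collapse all 3^n ordered status tuples to count triples."""
    out = set()
    for combo in itertools.product((UP, NORM, DOWN), repeat=n):
        c = Counter(combo)
        out.add((c[UP], c[NORM], c[DOWN]))
    return out


class TestMakeCombination:
    @pytest.mark.parametrize(
        "statuses,code",
        [
            ((UP, UP, UP, UP), "4U0N0D"),
            ((UP, NORM, UP, UP), "3U1N0D"),
            ((NORM, DOWN, DOWN, NORM), "0U2N2D"),
        ],
    )
    def test_published_examples(self, statuses, code):
        assert make_combination(statuses).code == code

    def test_order_invariance(self):
        a = make_combination((UP, DOWN, NORM, UP))
        b = make_combination((UP, UP, NORM, DOWN))
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            make_combination(())

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_combination(("Up", "Sideways"))


class TestCategorize:
    @pytest.mark.parametrize(
        "counts,category",
        [
            ((2, 2, 0), "2-Up"),
            ((2, 1, 1), "Others"),
            ((1, 2, 1), "1-Up-1-Down"),
            ((4, 0, 0), "4-Up"),
            ((0, 4, 0), "Others"),
            ((0, 0, 4), "Others"),
        ],
    )
    def test_category_rule(self, counts, category):
        assert categorize(BarcodePattern(*counts)) == category


class TestEnumeratePatterns:
    def test_four_gene_table_row_for_row(self):
        got = [(p.code, p.category) for p in enumerate_patterns(4)]
        assert got == FOUR_GENE_TABLE

    @pytest.mark.parametrize("n,count", [(0, 1), (1, 3), (4, 15), (8, 45)])
    def test_counts(self, n, count):
        assert len(enumerate_patterns(n)) == count

    @pytest.mark.parametrize("n", range(9))
    def test_equals_brute_force_oracle(self, n):
        got = {(p.n_up, p.n_norm, p.n_down) for p in enumerate_patterns(n)}
        assert got == brute_force_patterns(n)

    def test_four_gene_category_partition(self):
        cats = Counter(p.category for p in enumerate_patterns(4))
        assert cats == {
            "4-Up": 1, "3-Up": 1, "2-Up": 1, "1-Up": 1, "1-Up-1-Down": 1, "Others": 10
        }

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            enumerate_patterns(-1)


PANEL = ("NELL2", "ITM2C", "AKAP12", "IL13RA1")


def _peep_from(printed_donors: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        [list(s) for s in printed_donors["statuses"]],
        index=list(printed_donors["donor_id"]),
        columns=list(PANEL),
    )


class TestBarcodeCohort:
    def test_published_donor_barcodes(self, printed_donors):
        peep = _peep_from(printed_donors)
        barcodes = barcode_cohort(peep, PANEL)
        assert [b.pattern.code for b in barcodes] == list(printed_donors["code"])
        assert [b.pattern.category for b in barcodes] == list(printed_donors["category"])

    def test_empty_cohort(self):
        peep = pd.DataFrame(columns=list(PANEL))
        assert barcode_cohort(peep, PANEL) == []

    def test_missing_panel_gene_rejected(self, printed_donors):
        peep = _peep_from(printed_donors)
        with pytest.raises(ValueError, match="CALB2"):
            barcode_cohort(peep, PANEL + ("CALB2",))

    def test_every_pattern_is_enumerable(self, small_cohort):
        from peepbarcode.peep import build_peep, fit_control_stats

        labels = dict(zip(small_cohort.donors["donor_id"], small_cohort.donors["label"]))
        controls = [d for d, l in labels.items() if l != "High"]
        peep = build_peep(
            small_cohort.true_log2, fit_control_stats(small_cohort.true_log2, controls)
        )
        universe = {p.code for p in enumerate_patterns(len(PANEL))}
        for b in barcode_cohort(peep, PANEL):
            assert b.pattern.code in universe

    @given(perm=st.permutations(list(PANEL)))
    @settings(deadline=None, max_examples=24)
    def test_panel_order_invariance(self, perm):
        peep = pd.DataFrame(
            [["Up", "Norm", "Down", "Up"], ["Norm"] * 4],
            index=["D1", "D2"],
            columns=list(PANEL),
        )
        base = barcode_cohort(peep, PANEL)
        permuted = barcode_cohort(peep, perm)
        assert [b.pattern for b in base] == [b.pattern for b in permuted]


class TestCategoryFrequencies:
    def test_published_headline_fractions(self):
        """6/17 High donors in 4-Up -> ~35%; 43/63 Average in Others -> ~68%."""
        barcodes, labels = [], {}
        i = 0

        def add(group, code_counts):
            nonlocal i
            for (u, n, d), k in code_counts.items():
                for _ in range(k):
                    did = f"D{i}"
                    statuses = (UP,) * u + (NORM,) * n + (DOWN,) * d
                    barcodes.append(
                        next(
                            b
                            for b in barcode_cohort(
                                pd.DataFrame([list(statuses)], index=[did], columns=PANEL),
                                PANEL,
                            )
                        )
                    )
                    labels[did] = group
                    i += 1

        add("High", {(4, 0, 0): 6, (3, 1, 0): 5, (2, 2, 0): 3, (1, 3, 0): 1, (0, 4, 0): 2})
        add("Ave", {(0, 4, 0): 30, (0, 2, 2): 13, (1, 3, 0): 10, (2, 2, 0): 6, (1, 2, 1): 4})
        add("Low", {(0, 4, 0): 8, (1, 3, 0): 4, (2, 2, 0): 2})
        freq = category_frequencies(barcodes, labels)
        by = {(r["group"], r["category"]): r for _, r in freq.iterrows()}
        assert by[("High", "4-Up")]["count"] == 6
        assert round(100 * by[("High", "4-Up")]["fraction"]) == 35
        assert by[("Ave", "Others")]["count"] == 43
        assert round(100 * by[("Ave", "Others")]["fraction"]) == 68
        # fractions sum to 1 within each group; zero cells present
        sums = freq.groupby("group")["fraction"].sum()
        assert sums.loc[["High", "Ave", "Low"]].tolist() == pytest.approx([1, 1, 1])
        assert by[("Low", "4-Up")]["count"] == 0

    def test_identical_statuses_single_category(self):
        peep = pd.DataFrame([["Up"] * 4] * 3, index=["a", "b", "c"], columns=PANEL)
        barcodes = barcode_cohort(peep, PANEL)
        freq = category_frequencies(barcodes, {"a": "High", "b": "High", "c": "High"})
        nonzero = freq[freq["count"] > 0]
        assert len(nonzero) == 1
        assert nonzero.iloc[0]["category"] == "4-Up"
        assert nonzero.iloc[0]["fraction"] == pytest.approx(1.0)

    def test_unlabelled_rejected(self, printed_donors):
        peep = _peep_from(printed_donors)
        barcodes = barcode_cohort(peep, PANEL)
        with pytest.raises(ValueError, match="unlabelled"):
            category_frequencies(barcodes, {})


def test_synthetic_four_up_enrichment_confined_to_high():
    """With 3-SD up-shifts on all panel genes, 4-Up is frequent in High
    donors and essentially absent in controls."""
    import numpy as np

    from peepbarcode.peep import build_peep, fit_control_stats
    from peepbarcode.simulate import GeneSpec, SimConfig, simulate_cohort

    specs = tuple(GeneSpec(g, 0.0, 1.5) for g in PANEL)
    cohort = simulate_cohort(
        SimConfig(n_donors=400, gene_specs=specs, noise_sd=0.5, seed=31)
    )
    labels = dict(zip(cohort.donors["donor_id"], cohort.donors["label"]))
    controls = [d for d, l in labels.items() if l != "High"]
    peep = build_peep(cohort.true_log2, fit_control_stats(cohort.true_log2, controls))
    barcodes = barcode_cohort(peep, PANEL)
    freq = category_frequencies(barcodes, labels)
    by = {(r["group"], r["category"]): r["fraction"] for _, r in freq.iterrows()}
    assert by[("High", "4-Up")] > 0.5
    # per-tail null rate ~15.9% -> 4-Up in controls ~ 0.159**4 ~ 0.06%
    assert by[("Ave", "4-Up")] < 0.02
    assert by[("Low", "4-Up")] < 0.02
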