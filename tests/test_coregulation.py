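import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import fet_tail_enumeration
from conftest import ANCHOR, PSOP, make_calls, make_registry
from phoscoreg import (
    ContingencyTable,
    SiteKey,
    ThresholdConfig,
    UsageError,
    ValidationError,
    apply_high_confidence_filter,
    benjamini_hochberg,
    build_contingency,
    coregulation_scan,
    fisher_exact_one_sided,
    shared_psops,
)


class TestContingency:
    def test_ten_dataset_fixture(self, coreg_fixture):
        calls, universe = coreg_fixture
        t = build_contingency(ANCHOR, PSOP, calls, universe)
        assert (t.a, t.b, t.c, t.d) == (3, 3, 1, 3)
        assert t.n == 10

    def test_anchor_never_regulated_gives_empty_both_row(self, coreg_fixture):
        calls, universe = coreg_fixture
        calls = calls.copy()
        mask = calls["gene_symbol"] == ANCHOR.gene_symbol
        calls.loc[mask, "direction"] = "NR"
        t = build_contingency(ANCHOR, PSOP, calls, universe)
        assert t.c == t.d == 0

    def test_detected_mode_counts_presence_for_a(self, coreg_fixture):
        calls, universe = coreg_fixture
        t = build_contingency(ANCHOR, PSOP, calls, universe, cell_mode="detected")
        # only ds10 has neither site measured
        assert t.a == 1 and t.n == 10 and (t.c, t.d) == (1, 3)

    def test_identical_sites_rejected(self, coreg_fixture):
        calls, universe = coreg_fixture
        with pytest.raises(UsageError):
            build_contingency(ANCHOR, ANCHOR, calls, universe)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_cells_always_partition_the_universe(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"ds{i}" for i in range(rng.integers(1, 15))]
        rows = []
        for ds in universe:
            for site in (ANCHOR, PSOP):
                state = rng.choice(["U", "D", "NR", "absent"])
                if state != "absent":
                    rows.append((ds, site.gene_symbol, site.residue, site.position, state))
        t = build_contingency(ANCHOR, PSOP, make_calls(rows), universe)
        assert t.n == len(universe)


class TestFisherExact:
    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(1, 2, -1, 0)

    def test_empty_concordant_row_gives_p_one(self):
        assert fisher_exact_one_sided(ContingencyTable(4, 6, 0, 0), "concordant") == 1.0

    def test_matches_enumeration_on_small_tables(self):
        for a in range(5):
            for b in range(5):
                for c in range(4):
                    for d in range(4):
                        t = ContingencyTable(a, b, c, d)
                        for tail in ("concordant", "discordant"):
                            assert fisher_exact_one_sided(t, tail) == pytest.approx(
                                fet_tail_enumeration(a, b, c, d, tail), abs=1e-9
                            )

    def test_heavy_concordant_table_matches_enumeration(self):
        # all five both-regulated datasets concordant against balanced rest
        t = ContingencyTable(5, 5, 0, 5)
        assert fisher_exact_one_sided(t, "concordant") == pytest.approx(
            fet_tail_enumeration(5, 5, 0, 5, "concordant"), abs=1e-12
        )

    def test_matches_reference_implementation(self):
        import scipy.stats as st_sp

        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, size=4))
            t = ContingencyTable(a, b, c, d)
            ref_pos = st_sp.fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
            ref_neg = st_sp.fisher_exact([[a, b], [d, c]], alternative="greater").pvalue
            assert fisher_exact_one_sided(t, "concordant") == pytest.approx(ref_pos, abs=1e-9)
            assert fisher_exact_one_sided(t, "discordant") == pytest.approx(ref_neg, abs=1e-9)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_label_swap_duality(self, cells):
        """U<->D on the second site exchanges c and d and the two tails."""
        a, b, c, d = cells
        t, swapped = ContingencyTable(a, b, c, d), ContingencyTable(a, b, d, c)
        assert fisher_exact_one_sided(t, "concordant") == pytest.approx(
            fisher_exact_one_sided(swapped, "discordant"), abs=1e-12
        )


def _planted_registry(n_regulated=12, n_null=8, discordant=False):
    """Universe where the PsOP tracks (or opposes) the anchor perfectly in
    the regulated datasets, with additional all-NR datasets for contrast."""
    n = n_regulated + n_null
    ids = [f"ds{i}" for i in range(1, n + 1)]
    reg = make_registry(ids, studies=[f"st{i}" for i in range(1, n + 1)],
                        conditions=[f"c{i}" for i in range(1, n + 1)])
    rows = []
    for i, ds in enumerate(ids):
        if i < n_regulated:
            a_dir = "U" if i % 2 else "D"
            p_dir = ("D" if a_dir == "U" else "U") if discordant else a_dir
        else:
            a_dir = p_dir = "NR"
        rows.append((ds, ANCHOR.gene_symbol, ANCHOR.residue, ANCHOR.position, a_dir))
        rows.append((ds, PSOP.gene_symbol, PSOP.residue, PSOP.position, p_dir))
    return reg, make_calls(rows)


class TestScan:
    def test_perfect_concordance_classified_positive(self):
        reg, calls = _planted_registry()
        stats = coregulation_scan(ANCHOR, calls, reg, universe="all")
        row = stats[stats["psop_gene"] == PSOP.gene_symbol].iloc[0]
        assert row["classification"] == "positive"
        assert row["high_confidence"]
        assert row["d"] == 12 and row["c"] == 0

    def test_perfect_discordance_classified_negative(self):
        reg, calls = _planted_registry(discordant=True)
        stats = coregulation_scan(ANCHOR, calls, reg, universe="all")
        row = stats[stats["psop_gene"] == PSOP.gene_symbol].iloc[0]
        assert row["classification"] == "negative"
        assert row["fet_p_neg"] < 0.05

    def test_all_discordant_matches_enumeration_decision(self):
        """0 concordant, 8 discordant in a universe of 20: negative iff the
        enumeration oracle puts the discordant tail below alpha."""
        ids = [f"ds{i}" for i in range(1, 21)]
        reg = make_registry(ids, studies=[f"st{i}" for i in ids],
                            conditions=[f"c{i}" for i in ids])
        rows = []
        for i, ds in enumerate(ids):
            a_dir = "U" if i % 2 else "D"
            rows.append((ds, ANCHOR.gene_symbol, ANCHOR.residue, ANCHOR.position,
                         a_dir if i < 8 else "NR"))
            if i < 8:
                rows.append((ds, PSOP.gene_symbol, PSOP.residue, PSOP.position,
                             "D" if a_dir == "U" else "U"))
        stats = coregulation_scan(ANCHOR, make_calls(rows), reg, universe="all")
        row = stats[stats["psop_gene"] == PSOP.gene_symbol].iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (12, 0, 8, 0)
        p_oracle = fet_tail_enumeration(12, 0, 8, 0, "discordant")
        assert row["fet_p_neg"] == pytest.approx(p_oracle, abs=1e-9)
        assert (row["classification"] == "negative") == (p_oracle < 0.05)

    def test_unregulated_anchor_yields_empty_result(self):
        ids = ["ds1", "ds2"]
        reg = make_registry(ids)
        rows = [(ds, ANCHOR.gene_symbol, ANCHOR.residue, ANCHOR.position, "NR") for ds in ids]
        rows += [(ds, PSOP.gene_symbol, PSOP.residue, PSOP.position, "U") for ds in ids]
        stats = coregulation_scan(ANCHOR, make_calls(rows), reg, universe="all")
        assert len(stats) == 0


def _stat_row(p=0.049, frac=0.10, conditions=3, studies=3, ratio=4.0, classification="positive"):
    return pd.DataFrame(
        [
            {
                "anchor": "MAPT:S519",
                "psop_gene": "NUCKS1",
                "psop_site": "S214",
                "nUU": 4, "nUD": 1, "nDU": 0, "nDD": 0,
                "a": 5, "b": 0, "c": 1, "d": 4,
                "pos_ratio": ratio, "neg_ratio": 1 / ratio if ratio else math.inf,
                "fet_p_pos": p, "fet_p_neg": 1.0,
                "support_fraction": frac,
                "n_conditions": conditions, "n_studies": studies,
                "classification": classification, "high_confidence": False, "flags": "",
            }
        ]
    )


class TestHighConfidenceFilter:
    def test_all_boundary_inclusive_values_pass(self):
        out = apply_high_confidence_filter(_stat_row(), anchor_total_detections=40)
        assert out.loc[0, "high_confidence"]

    @pytest.mark.parametrize(
        "kw",
        [
            {"studies": 2},          # needs three distinct studies
            {"conditions": 2},       # needs three distinct conditions
            {"frac": 0.09},          # support below ten percent
            {"p": 0.05},             # p gate is strict
            {"classification": "none"},
        ],
    )
    def test_single_failing_layer_blocks(self, kw):
        out = apply_high_confidence_filter(_stat_row(**kw), anchor_total_detections=40)
        assert not out.loc[0, "high_confidence"]

    def test_zero_anchor_detections_rejected(self):
        with pytest.raises(ValidationError):
            apply_high_confidence_filter(_stat_row(), anchor_total_detections=0)

    def test_strengthening_thresholds_never_adds_pairs(self):
        frame = pd.concat(
            [_stat_row(), _stat_row(frac=0.15, studies=5, conditions=5, p=0.001)],
            ignore_index=True,
        )
        base = ThresholdConfig()
        n_base = apply_high_confidence_filter(frame, 40, base)["high_confidence"].sum()
        for strict in (
            ThresholdConfig(min_support_fraction=0.2),
            ThresholdConfig(min_studies=5),
            ThresholdConfig(min_conditions=5),
            ThresholdConfig(alpha=0.01),
        ):
            n = apply_high_confidence_filter(frame, 40, strict)["high_confidence"].sum()
            assert n <= n_base


class TestSharedPsops:
    def test_pairwise_intersection(self):
        table, excl = shared_psops({"A": {"x", "y", "z"}, "B": {"y", "z", "w"}})
        row = table.iloc[0]
        assert row["n_shared"] == 2 and set(row["shared"].split("|")) == {"y", "z"}
        assert excl["A"] == {"x"} and excl["B"] == {"w"}

    def test_disjoint_and_identical_sets(self):
        table, _ = shared_psops({"A": {"x"}, "B": {"y"}})
        assert table.iloc[0]["n_shared"] == 0
        table, _ = shared_psops({"A": {"x", "y"}, "B": {"x", "y"}})
        assert table.iloc[0]["n_shared"] == 2

    def test_single_anchor_rejected(self):
        with pytest.raises(UsageError):
            shared_psops({"A": {"x"}})


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.8, 0.04])
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()
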