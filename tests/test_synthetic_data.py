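import math

import numpy as np
import pandas as pd
import pytest

from phoscoreg import (
    PlantedPair,
    SiteKey,
    SyntheticCorpusConfig,
    ValidationError,
    call_registry,
    coregulation_scan,
    generate_corpus,
    pair_pattern_counts,
    truth_eval,
    write_corpus,
)
from phoscoreg.synthetic_data import DEFAULT_ANCHOR_SITES, default_planted_pairs

SMALL = dict(n_studies=5, conditions_per_study=2, n_background_sites=60, n_proteins=20)


class TestDeterminism:
    def test_same_seed_same_corpus(self):
        cfg = SyntheticCorpusConfig(**SMALL, seed=5)
        r1, t1 = generate_corpus(cfg)
        r2, t2 = generate_corpus(cfg)
        pd.testing.assert_frame_equal(r1.measurements, r2.measurements)
        pd.testing.assert_frame_equal(r1.detections, r2.detections)
        pd.testing.assert_frame_equal(t1.true_calls, t2.true_calls)

    def test_different_seed_differs(self):
        r1, _ = generate_corpus(SyntheticCorpusConfig(**SMALL, seed=1))
        r2, _ = generate_corpus(SyntheticCorpusConfig(**SMALL, seed=2))
        assert not r1.measurements["fold_change"].equals(r2.measurements["fold_change"])

    def test_written_corpus_byte_identical(self, tmp_path):
        cfg = SyntheticCorpusConfig(**SMALL, seed=5)
        for sub in ("a", "b"):
            reg, truth = generate_corpus(cfg)
            write_corpus(reg, truth, tmp_path / sub)
        for name in ("differential.tsv", "profiling.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


class TestPlantedStructure:
    def test_perfect_positive_pair_has_no_discordant_patterns(self):
        pair = PlantedPair(
            anchor_site=DEFAULT_ANCHOR_SITES[0],
            partner_site=SiteKey("PLNT001", "S", 100),
            polarity="positive",
            concordance=1.0,
            co_measurement_rate=1.0,
        )
        cfg = SyntheticCorpusConfig(**SMALL, planted_pairs=(pair,), class1_fail_rate=0.0, seed=3)
        reg, _ = generate_corpus(cfg)
        calls, _ = call_registry(reg)
        c = pair_pattern_counts(pair.anchor_site, pair.partner_site, calls)
        assert c.nUD == c.nDU == 0
        assert c.concordant > 0

    def test_zero_rates_give_only_nr_calls(self):
        cfg = SyntheticCorpusConfig(**SMALL, p_up=0.0, p_down=0.0, seed=3)
        reg, _ = generate_corpus(cfg)
        calls, _ = call_registry(reg)
        assert set(calls["direction"]) == {"NR"}

    def test_calls_match_planted_truth(self):
        """The regulation caller recovers exactly the generator's intended
        directions for every Class-1 row (fold changes are unambiguous)."""
        cfg = SyntheticCorpusConfig(**SMALL, class1_fail_rate=0.0, seed=9)
        reg, truth = generate_corpus(cfg)
        calls, _ = call_registry(reg)
        key = ["dataset_id", "gene_symbol", "residue", "position"]
        merged = calls.merge(truth.true_calls, on=key, suffixes=("_called", "_true"))
        assert len(merged) == len(calls)
        assert (merged["direction_called"] == merged["direction_true"]).all()

    def test_infeasible_rates_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticCorpusConfig(p_up=0.7, p_down=0.5)

    def test_boundary_fraction_plants_gate_exact_values(self):
        cfg = SyntheticCorpusConfig(**SMALL, boundary_fraction=1.0, seed=2)
        reg, truth = generate_corpus(cfg)
        regulated = truth.true_calls["direction"].isin(["U", "D"])
        key = ["dataset_id", "gene_symbol", "residue", "position"]
        merged = reg.measurements.merge(truth.true_calls, on=key)
        fc = merged.loc[merged["direction"].isin(["U", "D"]), "fold_change"]
        assert set(np.round(fc, 10)) <= {1.3, 0.76}
        calls, _ = call_registry(reg)
        cm = calls.merge(truth.true_calls, on=key, suffixes=("_called", "_true"))
        # gate-exact values are still regulated: boundaries are inclusive
        reg_rows = cm[cm["direction_true"].isin(["U", "D"])]
        assert (reg_rows["direction_called"] == reg_rows["direction_true"]).all()


class TestCalibration:
    def test_background_regulation_rate_matches_pi(self):
        cfg = SyntheticCorpusConfig(n_studies=10, conditions_per_study=2,
                                    n_background_sites=500, seed=4, class1_fail_rate=0.0)
        _, truth = generate_corpus(cfg)
        bg = truth.true_calls[~truth.true_calls["gene_symbol"].str.startswith("MAPT")]
        n = len(bg)
        frac = bg["direction"].isin(["U", "D"]).mean()
        pi = cfg.p_up + cfg.p_down
        se = math.sqrt(pi * (1 - pi) / n)
        assert abs(frac - pi) <= 3 * se

    def test_planted_concordance_matches_rho(self):
        rho = 0.8
        pair = PlantedPair(
            anchor_site=DEFAULT_ANCHOR_SITES[0],
            partner_site=SiteKey("PLNT001", "S", 100),
            polarity="positive",
            concordance=rho,
            co_measurement_rate=1.0,
        )
        cfg = SyntheticCorpusConfig(
            n_studies=60, conditions_per_study=3, n_background_sites=1,
            planted_pairs=(pair,), p_up=0.25, p_down=0.25, class1_fail_rate=0.0, seed=6,
        )
        reg, truth = generate_corpus(cfg)
        calls, _ = call_registry(reg)
        c = pair_pattern_counts(pair.anchor_site, pair.partner_site, calls)
        total = c.total
        se = math.sqrt(rho * (1 - rho) / total)
        assert abs(c.concordant / total - rho) <= 3 * se


class TestTruthEval:
    def test_all_recovered_gives_sensitivity_one(self):
        pairs = default_planted_pairs(2, 0)
        truth_calls = pd.DataFrame(columns=["dataset_id", "gene_symbol", "residue", "position", "direction"])
        truth = _truth(pairs, truth_calls)
        stats = pd.DataFrame(
            [
                {"anchor": str(p.anchor_site), "psop_gene": p.partner_site.gene_symbol,
                 "psop_site": f"{p.partner_site.residue}{p.partner_site.position}",
                 "classification": p.polarity, "high_confidence": True}
                for p in pairs
            ]
        )
        rep = truth_eval(stats, truth)
        assert rep.sensitivity == 1.0 and rep.n_background_high_confidence == 0

    def test_wrong_polarity_not_counted(self):
        pairs = default_planted_pairs(1, 0)
        truth = _truth(pairs, pd.DataFrame())
        p = pairs[0]
        stats = pd.DataFrame(
            [{"anchor": str(p.anchor_site), "psop_gene": p.partner_site.gene_symbol,
              "psop_site": f"{p.partner_site.residue}{p.partner_site.position}",
              "classification": "negative", "high_confidence": True}]
        )
        rep = truth_eval(stats, truth)
        assert rep.n_recovered == 0

    def test_no_planted_pairs_gives_undefined_sensitivity(self):
        truth = _truth((), pd.DataFrame())
        stats = pd.DataFrame(
            [{"anchor": "MAPT:S519", "psop_gene": "G1", "psop_site": "S10",
              "classification": "positive", "high_confidence": True}]
        )
        rep = truth_eval(stats, truth)
        assert rep.sensitivity is None
        assert rep.n_background_high_confidence == 1


def _truth(pairs, calls):
    from phoscoreg import GroundTruth

    return GroundTruth(planted_pairs=tuple(pairs), true_calls=calls,
                       config=SyntheticCorpusConfig())
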