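import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from exomestrat.catalog import (
    align_risk_allele,
    load_catalog,
    map_to_catalog,
    parse_risk_allele,
    random_set_enrichment,
    risk_stratify,
    trait_enrichment,
)
from exomestrat.io import Variant

from conftest import make_matrix


def catalog_frame(rows):
    return pd.DataFrame(rows, columns=["SNPS", "DISEASE/TRAIT", "PARENT_TERM", "RISK_ALLELE", "RAF"])


class TestMapping:
    def test_join_semantics_one_row_per_trait(self):
        cat = catalog_frame(
            [
                ("rs1", "T1", "P1", "A", 0.3),
                ("rs2", "T1", "P1", "G", 0.4),
                ("rs2", "T2", "P2", "G", 0.4),
                ("rs9", "T3", "P1", "C", 0.5),
            ]
        )
        matches = map_to_catalog({"rs1", "rs2", "rs3"}, cat)
        assert len(matches) == 3
        assert sorted(matches["SNPS"]) == ["rs1", "rs2", "rs2"]

    def test_empty_catalog(self):
        assert len(map_to_catalog({"rs1"}, catalog_frame([]))) == 0

    def test_risk_allele_dialect_parsing(self):
        assert parse_risk_allele("rs123-A") == "A"
        assert parse_risk_allele("T") == "T"

    def test_load_catalog_roundtrip(self, tmp_path):
        cat = catalog_frame([("rs1", "T1", "P1", "rs1-A", "0.3"), ("rs2", "T2", "P2", "G", "NR")])
        path = tmp_path / "cat.tsv"
        cat.to_csv(path, sep="\t", index=False)
        loaded = load_catalog(path)
        assert loaded["RISK_ALLELE"].tolist() == ["A", "G"]
        assert np.isnan(loaded["RAF"].iloc[1])
        assert loaded["RAF_raw"].iloc[1] == "NR"


class TestAlignRiskAllele:
    VAR = Variant("1", 100, "rs1", "A", "G")

    def test_alt_risk_keeps_alt_frequency(self):
        assert align_risk_allele(self.VAR, "G", {"V": 0.36})["V"] == 0.36

    def test_ref_risk_takes_complement(self):
        raf = align_risk_allele(self.VAR, "A", {"V": 0.36, "K": 0.5})
        assert raf["V"] == pytest.approx(0.64)
        assert raf["K"] == pytest.approx(0.5)

    def test_complement_identity(self, rng):
        for f in rng.uniform(0, 1, size=20):
            raf = align_risk_allele(self.VAR, "A", {"V": f})
            assert raf["V"] + f == pytest.approx(1.0)

    def test_unalignable_is_error(self):
        with pytest.raises(ValueError):
            align_risk_allele(Variant("1", 5, "rs2", "A", "T"), "G", {"V": 0.2})


class TestRandomSetEnrichment:
    def _setup(self, q=0.1, pool_size=4000, draw=200, seed=0):
        pool = [f"rs{i}" for i in range(pool_size)]
        cat_ids = pool[: int(q * pool_size)]
        cat = catalog_frame([(s, "T1", "P1", "A", 0.3) for s in cat_ids])
        return pool, cat_ids, cat, draw

    def test_null_median_matches_coverage_fraction(self):
        pool, cat_ids, cat, draw = self._setup()
        rng = np.random.default_rng(8)
        diff = list(rng.choice(pool, size=draw, replace=False))
        enr = random_set_enrichment(pool, diff, cat, n_iter=500, seed=4)
        expected = 0.1 * draw
        sd = np.sqrt(draw * 0.1 * 0.9)
        assert abs(enr.null_median - expected) <= 3 * sd / np.sqrt(500) * 1.25 + 1.0

    def test_observed_equal_median_gives_null_chi_square(self):
        pool, cat_ids, cat, draw = self._setup()
        probe = random_set_enrichment(pool, pool[:draw], cat, n_iter=200, seed=9)
        med = int(probe.null_median)
        # build a diff set with exactly `med` catalog hits
        diff = cat_ids[:med] + [p for p in pool if p not in set(cat_ids)][: draw - med]
        enr = random_set_enrichment(pool, diff, cat, n_iter=200, seed=9)
        assert enr.observed_count == med == enr.null_median
        assert enr.chi_square == 0.0
        assert enr.p == 1.0

    def test_planted_overrepresentation_detected(self):
        pool, cat_ids, cat, draw = self._setup(q=0.02)
        # diff set hits the catalog 10x more often than a random draw would
        diff = cat_ids[: int(0.2 * draw)] + [p for p in pool if p not in set(cat_ids)][: int(0.8 * draw)]
        enr = random_set_enrichment(pool, diff, cat, n_iter=500, seed=3)
        assert enr.p < 0.05

    def test_determinism_and_errors(self):
        pool, _, cat, draw = self._setup()
        e1 = random_set_enrichment(pool, pool[:draw], cat, n_iter=100, seed=7)
        e2 = random_set_enrichment(pool, pool[:draw], cat, n_iter=100, seed=7)
        assert e1.null_median == e2.null_median
        assert np.array_equal(e1.null_counts, e2.null_counts)
        with pytest.raises(ValueError):
            random_set_enrichment(pool, ["not_in_pool"], cat, n_iter=10, seed=0)

    def test_zero_median_reported_as_undefined(self):
        pool = [f"rs{i}" for i in range(1000)]
        cat = catalog_frame([("rs0", "T1", "P1", "A", 0.1)])
        enr = random_set_enrichment(pool, pool[10:15], cat, n_iter=50, seed=1)
        assert enr.null_median == 0
        assert enr.chi_square is None and enr.p is None


class TestTraitEnrichment:
    def test_matches_hypergeometric_oracle(self):
        cat_rows = [(f"rs{i}", "Rare", "P1", "A", 0.1) for i in range(10)]
        cat_rows += [(f"rs{i}", "Common", "P2", "A", 0.1) for i in range(10, 1000)]
        cat = catalog_frame(cat_rows)
        gm = pd.DataFrame(
            {
                "group": "V",
                "SNPS": [f"rs{i}" for i in range(8)] + ["rs500", "rs501"],
                "DISEASE/TRAIT": ["Rare"] * 8 + ["Common"] * 2,
            }
        )
        res = trait_enrichment(gm, cat)
        row = res[res["DISEASE/TRAIT"] == "Rare"].iloc[0]
        expected = fisher_exact([[8, 2], [10, 990]])[1]
        assert row["p"] == pytest.approx(expected, abs=1e-9)
        assert row["p"] < 0.05
        assert row["PARENT_TERM"] == "P1"

    def test_background_rate_hits_not_enriched(self):
        cat_rows = [(f"rs{i}", "T1" if i % 2 else "T2", "P1", "A", 0.1) for i in range(400)]
        cat = catalog_frame(cat_rows)
        gm = pd.DataFrame(
            {
                "group": "V",
                "SNPS": [f"rs{i}" for i in range(40)],
                "DISEASE/TRAIT": ["T1" if i % 2 else "T2" for i in range(40)],
            }
        )
        res = trait_enrichment(gm, cat)
        assert (res["p"] > 0.5).all()

    def test_unknown_trait_is_error(self):
        cat = catalog_frame([("rs1", "T1", "P1", "A", 0.1)])
        gm = pd.DataFrame({"group": ["V"], "SNPS": ["rs9"], "DISEASE/TRAIT": ["T9"]})
        with pytest.raises(ValueError):
            trait_enrichment(gm, cat)


class TestRiskStratify:
    def _scenario(self):
        # 4 groups x 18; variant rs0: K high, P low, control near P.
        rng = np.random.default_rng(12)
        blocks = [
            rng.binomial(2, f, size=(18, 2)) for f in (0.30, 0.08, 0.45, 0.10)
        ]  # V, P, K, C; second variant is null at 0.3
        g = np.vstack(blocks).astype(np.int8)
        g[:, 1] = np.vstack([rng.binomial(2, 0.3, size=(72, 1))]).ravel()
        m, d = make_matrix(g, groups={"V": 18, "P": 18, "K": 18, "C": 18})
        from exomestrat.association import pairwise_scan
        from exomestrat.replication import background_contrasts_all

        diff = pairwise_scan(m, d)
        bg = background_contrasts_all(m, d, [v.id for v in m.variants])
        return m, d, diff, bg

    def test_conjunction_rule_and_marks(self):
        m, d, diff, bg = self._scenario()
        cat = catalog_frame(
            [("rs0", "T1", "P1", "G", 0.2), ("rs1", "T2", "P2", "G", 0.9)]
        )
        table = risk_stratify(m, d, diff, bg, cat)
        assert set(table["variant_id"]) <= {"rs0"}
        if len(table):
            row = table.iloc[0]
            assert "K" in row["high_group"]
            assert "P" in row["low_group"]
            assert row["raf_K"] > row["raf_P"]
            assert row["exceeds_catalog"] in (True, False)

    def test_group_only_significance_excluded(self):
        m, d, diff, bg = self._scenario()
        # empty background significance: nothing passes the conjunction
        bg_none = bg.copy()
        bg_none["p"] = 1.0
        cat = catalog_frame([("rs0", "T1", "P1", "G", 0.2)])
        table = risk_stratify(m, d, diff, bg_none, cat)
        assert len(table) == 0

    def test_nr_catalog_raf_keeps_row_with_undefined_flag(self):
        m, d, diff, bg = self._scenario()
        cat = catalog_frame([("rs0", "T1", "P1", "G", np.nan)])
        table = risk_stratify(m, d, diff, bg, cat)
        if len(table):
            assert table.iloc[0]["exceeds_catalog"] is None

    def test_marked_pair_reproduces_significance(self):
        from exomestrat import fisher

        m, d, diff, bg = self._scenario()
        cat = catalog_frame([("rs0", "T1", "P1", "G", 0.2)])
        table = risk_stratify(m, d, diff, bg, cat)
        for _, row in table.iterrows():
            for pair in row["sig_group_pairs"].split(";"):
                sub = diff[(diff["variant_id"] == row["variant_id"]) & (diff["pair"] == pair)]
                r = sub.iloc[0]
                assert fisher.fisher_two_sided(int(r.a), int(r.b), int(r.c), int(r.d)) < 0.05
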