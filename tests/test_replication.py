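import numpy as np
import pandas as pd
import pytest

from exomestrat.replication import background_contrast, background_contrasts_all, replicate

from conftest import make_matrix


def frame(rows):
    return pd.DataFrame(rows, columns=["variant_id", "gene", "pair", "profile"])


class TestReplicate:
    def test_three_levels_and_containment(self):
        A = frame(
            [
                ("rs1", "G1", "V-K", "V+K-"),   # level 3
                ("rs2", "G2", "V-K", "V+K-"),   # level 2 only (direction flips in B)
                ("rs3", "G3", "P-K", "P+K-"),   # cohort A only
                ("rs4", None, "V-K", "V+K-"),   # no gene: excluded from level 1
            ]
        )
        B = frame(
            [
                ("rs1", "G1", "V-K", "V+K-"),
                ("rs2", "G2", "V-K", "V-K+"),
                ("rs5", "G1", "P-K", "P-K+"),
                ("rs4", None, "V-K", "V+K-"),
            ]
        )
        rep = replicate(A, B)
        assert rep.level1_genes == {"G1", "G2"}
        assert rep.level2_ids == {"rs1", "rs2", "rs4"}
        assert rep.level3_ids == {"rs1", "rs4"}
        rep.check_containment()

    def test_tie_profiles_never_match(self):
        A = frame([("rs1", "G1", "V-K", "V=K=")])
        rep = replicate(A, A)
        assert rep.level2_ids == {"rs1"}
        assert rep.level3_ids == set()

    def test_symmetry(self):
        A = frame([("rs1", "G1", "V-K", "V+K-"), ("rs2", "G2", "P-K", "P-K+")])
        B = frame([("rs1", "G1", "V-K", "V+K-"), ("rs3", "G2", "P-K", "P+K-")])
        ab, ba = replicate(A, B), replicate(B, A)
        assert ab.level1_genes == ba.level1_genes
        assert ab.level2_ids == ba.level2_ids
        assert ab.level3_ids == ba.level3_ids

    def test_same_pair_option(self):
        A = frame([("rs1", "G1", "V-K", "V+K-")])
        B = frame([("rs1", "G1", "P-K", "P+K-")])
        assert replicate(A, B).level2_ids == {"rs1"}
        assert replicate(A, B, same_pair=True).level2_ids == set()

    def test_recall_on_simulated_replication_pair(self):
        from exomestrat.association import scan_pair
        from exomestrat.permutation import PermutationConfig, permute_scan
        from exomestrat.simulate import SimulationConfig, simulate_replication_pair

        cfg = SimulationConfig(n_variants=400, frac_planted=0.1, seed=19)
        (mA, dA), (mB, dB), truth = simulate_replication_pair(cfg, labels=("A", "B"))
        retained = {}
        for label, m, d in (("A", mA, dA), ("B", mB, dB)):
            scan = scan_pair(m, d, ("V", "K"))
            perm = permute_scan(
                m, d, ("V", "K"), PermutationConfig(n_perm=400, seed=3), observed=scan
            )
            keep = perm.loc[perm["retained"], "variant_id"]
            retained[label] = scan[scan["variant_id"].isin(keep)]
        rep = replicate(retained["A"], retained["B"])
        planted_ids = set(truth.loc[truth.planted, "variant_id"])
        recall = len(planted_ids & rep.level3_ids) / len(planted_ids)
        assert recall >= 0.8
        rep.check_containment()


class TestBackgroundContrast:
    def _matrix_with_freqs(self, rng, f_group, f_ctrl, n=18):
        g_grp = rng.binomial(2, f_group, size=(n, 1))
        g_ctl = rng.binomial(2, f_ctrl, size=(n, 1))
        g = np.vstack([g_grp, g_ctl]).astype(np.int8)
        return make_matrix(g, groups={"V": n, "C": n})

    def test_strong_difference_is_flagged(self, rng):
        flagged = 0
        reps = 60
        for _ in range(reps):
            m, d = self._matrix_with_freqs(rng, 0.9, 0.3)
            res = background_contrast(m, d, "V", ["rs0"])
            flagged += bool(res.iloc[0]["significant"])
        assert flagged / reps >= 0.9

    def test_identical_counts_not_flagged(self):
        g = np.vstack([np.ones((18, 1)), np.ones((18, 1))]).astype(np.int8)
        m, d = make_matrix(g, groups={"V": 18, "C": 18})
        res = background_contrast(m, d, "V", ["rs0"])
        assert res.iloc[0]["p"] == pytest.approx(1.0, abs=1e-9)
        assert not res.iloc[0]["significant"]

    def test_reports_all_groups(self, small_cohort):
        _, m, d, _ = small_cohort
        ids = [m.variants[i].id for i in range(5)]
        res = background_contrasts_all(m, d, ids)
        assert set(res["pair"]) == {"V-C", "P-C", "K-C"}
        assert len(res) == 15

    def test_missing_variant_is_error(self, small_cohort):
        _, m, d, _ = small_cohort
        with pytest.raises(KeyError):
            background_contrast(m, d, "V", ["rs_absent"])
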