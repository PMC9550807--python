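"""Weighted/unweighted sum scores, proxy substitution, PRS normalization."""

import numpy as np
import pandas as pd
import pytest

from famburden.scores import (compute_prs, risk_allele_dosage,
                              substitute_proxies, unweighted_sum_score,
                              weighted_sum_score)
from tests.conftest import make_genotype_matrix


def rtab(snps, ors, mhc=None, risk=None):
    n = len(snps)
    return pd.DataFrame({
        "snp_id": snps,
        "chrom": ["6" if (mhc or [False] * n)[k] else "1" for k in range(n)],
        "pos": [1000 * (k + 1) for k in range(n)],
        "risk_allele": risk or ["G"] * n,
        "odds_ratio": ors,
        "is_mhc": mhc or [False] * n,
    })


def dframe(data, index):
    return pd.DataFrame(data, index=index)


class TestWeightedSum:
    def test_zero_dosages(self):
        table = rtab(["s1", "s2"], [2.0, 1.5])
        d = dframe({"s1": [0.0], "s2": [0.0]}, ["i1"])
        assert weighted_sum_score(d, table).iloc[0] == 0.0

    def test_closed_forms(self):
        table = rtab(["s1"], [10.0])
        d = dframe({"s1": [2.0]}, ["i1"])
        assert weighted_sum_score(d, table).iloc[0] == pytest.approx(2.0)
        table3 = rtab(["s1", "s2", "s3"], [2.0, 1.5, 1.2])
        d3 = dframe({"s1": [2.0], "s2": [1.0], "s3": [0.0]}, ["i1"])
        expected = 2 * np.log10(2) + np.log10(1.5)
        assert weighted_sum_score(d3, table3).iloc[0] == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(0.77815, abs=5e-6)

    def test_unweighted_and_identity_at_or10(self):
        table = rtab(["s1", "s2", "s3"], [10.0, 10.0, 10.0])
        d = dframe({"s1": [2.0], "s2": [1.0], "s3": [0.0]}, ["i1"])
        assert unweighted_sum_score(d, table).iloc[0] == 3.0
        assert weighted_sum_score(d, table).iloc[0] == pytest.approx(3.0)

    def test_mhc_decomposition_exact(self):
        rng = np.random.default_rng(5)
        n = 20
        mhc = [k < 6 for k in range(n)]
        table = rtab([f"s{k}" for k in range(n)],
                     rng.uniform(1.05, 2.0, n), mhc=mhc)
        d = dframe({f"s{k}": rng.integers(0, 3, 4).astype(float)
                    for k in range(n)}, list("abcd"))
        total = weighted_sum_score(d, table, "all")
        non = weighted_sum_score(d, table, "non_mhc")
        mhc_part = weighted_sum_score(d, table[table.is_mhc], "all")
        np.testing.assert_allclose(total - non, mhc_part, atol=1e-12)

    def test_snp_order_invariance(self):
        rng = np.random.default_rng(6)
        table = rtab([f"s{k}" for k in range(10)], rng.uniform(1.1, 2, 10))
        d = dframe({f"s{k}": rng.integers(0, 3, 3).astype(float)
                    for k in range(10)}, list("xyz"))
        shuffled = table.sample(frac=1, random_state=1).reset_index(drop=True)
        np.testing.assert_allclose(
            weighted_sum_score(d, table), weighted_sum_score(d, shuffled)
        )

    def test_additivity(self):
        table = rtab(["s1", "s2"], [1.3, 1.8])
        d = dframe({"s1": [1.0, 1.0, 2.0], "s2": [0.0, 1.0, 1.0]},
                   ["g1", "g2", "sum"])
        s = weighted_sum_score(d, table)
        assert s["sum"] == pytest.approx(s["g1"] + s["g2"], abs=1e-12)


class TestRiskAlleleDosage:
    def test_orientation_flip(self):
        gm = make_genotype_matrix(["i1", "i2"],
                                  np.array([[2, 0], [1, 1]], dtype=np.int8))
        table = rtab(["v0", "v1"], [1.5, 1.5], risk=["G", "A"])
        # v0 risk allele = alt (G): dosage as-is; v1 risk = ref (A): flipped
        d = risk_allele_dosage(gm, table)
        assert list(d["v0"]) == [2, 1]
        assert list(d["v1"]) == [2, 1]

    def test_unresolvable_allele(self):
        gm = make_genotype_matrix(["i1"], np.array([[1]], dtype=np.int8))
        table = rtab(["v0"], [1.5], risk=["T"])
        with pytest.raises(ValueError, match="neither"):
            risk_allele_dosage(gm, table)

    def test_missing_imputed_to_mean(self):
        calls = np.array([[2], [0], [-1]], dtype=np.int8)
        gm = make_genotype_matrix(["a", "b", "c"], calls)
        d = risk_allele_dosage(gm, rtab(["v0"], [1.5]))
        assert d.loc["c", "v0"] == pytest.approx(1.0)  # mean of (2, 0)


class TestProxySubstitution:
    def ld(self, rows):
        return pd.DataFrame(rows, columns=["index_snp", "proxy_snp", "r2",
                                           "risk_allele"])

    def test_substitution_and_boundary(self):
        table = rtab(["kept", "subbed", "weak"], [1.2, 1.3, 1.4])
        ld = self.ld([("subbed", "proxyA", 0.95, "T"),
                      ("weak", "proxyB", 0.79, "C")])
        out, log = substitute_proxies(
            table, ["kept", "proxyA", "proxyB"], ld, r2_min=0.8
        )
        assert list(out["snp_id"]) == ["kept", "proxyA"]
        assert out.set_index("snp_id").loc["proxyA", "risk_allele"] == "T"
        acts = dict(zip(log["index_snp"], log["action"]))
        assert acts == {"subbed": "substituted", "weak": "dropped_no_proxy"}

    def test_r2_boundary_inclusive(self):
        table = rtab(["x"], [1.2])
        ld = self.ld([("x", "p", 0.8, "T")])
        out, _ = substitute_proxies(table, ["p"], ld)
        assert list(out["snp_id"]) == ["p"]

    def test_tie_break_lexicographic(self):
        table = rtab(["x"], [1.2])
        ld = self.ld([("x", "pB", 0.9, "T"), ("x", "pA", 0.9, "C")])
        out, _ = substitute_proxies(table, ["pA", "pB"], ld)
        assert list(out["snp_id"]) == ["pA"]

    def test_ambiguous_mapping_dropped(self):
        table = rtab(["x"], [1.2])
        ld = self.ld([("x", "p", 0.9, "")])
        out, log = substitute_proxies(table, ["p"], ld)
        assert out.empty
        assert log.iloc[0]["action"] == "dropped_ambiguous_alleles"


class TestPRS:
    def test_hand_z_scores(self):
        d = dframe({"s1": [0.0, 1.0, 2.0]}, ["a", "b", "c"])
        beta = pd.Series({"s1": 0.5})
        raw, z = compute_prs(d, beta)
        np.testing.assert_allclose(raw, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(z, [-1.2247448, 0.0, 1.2247448],
                                   atol=1e-6)

    def test_scale_invariance_of_z(self):
        rng = np.random.default_rng(8)
        d = dframe({f"s{k}": rng.uniform(0, 2, 10) for k in range(5)},
                   [f"i{k}" for k in range(10)])
        beta = pd.Series(rng.normal(size=5), index=[f"s{k}" for k in range(5)])
        _, z1 = compute_prs(d, beta)
        _, z2 = compute_prs(d, 2.0 * beta)
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_zero_beta_degenerate(self):
        d = dframe({"s1": [0.0, 1.0]}, ["a", "b"])
        with pytest.raises(ValueError, match="zero SD"):
            compute_prs(d, pd.Series({"s1": 0.0}))

    def test_reference_subset(self):
        d = dframe({"s1": [0.0, 2.0, 4.0]}, ["a", "b", "c"])
        raw, z = compute_prs(d, pd.Series({"s1": 1.0}),
                             reference_ids=["a", "b"])
        # mean 1, sd 1 over the reference -> z = (raw - 1) / 1
        np.testing.assert_allclose(z, [-1.0, 1.0, 3.0])

    def test_z_normalization_invariant(self):
        rng = np.random.default_rng(9)
        d = dframe({f"s{k}": rng.uniform(0, 2, 50) for k in range(4)},
                   [f"i{k}" for k in range(50)])
        beta = pd.Series(rng.normal(size=4), index=[f"s{k}" for k in range(4)])
        _, z = compute_prs(d, beta)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert np.std(z.to_numpy()) == pytest.approx(1.0, abs=1e-9)
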