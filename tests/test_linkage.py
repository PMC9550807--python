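"""Exact single-point NPL, Kong-Cox LOD, and candidate-region extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from famburden.linkage import (BitCapExceeded, InheritanceVectors,
                               candidate_linkage_regions, kong_cox_lod,
                               npl_single_point)
from famburden.pedigree import Individual, Pedigree


def oracle_npl(ped, genotypes, allele_freqs):
    """Independent brute-force oracle: enumerate inheritance vectors by
    explicit transmission recursion and founder-allele assignments by
    itertools; returns (E[S|data], mu0, sigma0, per-vector S array).

    ``genotypes`` maps id -> unordered allele pair (indices into
    ``allele_freqs``).
    """
    founders = sorted(m.id for m in ped.founders())
    nonf = [m.id for m in ped.nonfounders()]
    affected = sorted(m.id for m in ped.members.values()
                      if m.affection == "affected")
    n_slots = 2 * len(founders)
    slot = {f: (2 * k, 2 * k + 1) for k, f in enumerate(founders)}
    k_alleles = len(allele_freqs)

    def share_count(a, b):
        # IBD alleles shared between two (slot, slot) pairs: max matching
        best = 0
        for perm in ((0, 1), (1, 0)):
            c = (a[0] == b[perm[0]]) + (a[1] == b[perm[1]])
            best = max(best, c)
        return best

    s_list, lik_list = [], []
    for bits in itertools.product((0, 1), repeat=2 * len(nonf)):
        slots = dict(slot)
        for k, nid in enumerate(nonf):
            ind = ped[nid]
            slots[nid] = (
                slots[ind.father_id][bits[2 * k]],
                slots[ind.mother_id][bits[2 * k + 1]],
            )
        s = sum(
            share_count(slots[i], slots[j])
            for i, j in itertools.combinations(affected, 2)
        )
        lik = 0.0
        for assign in itertools.product(range(k_alleles), repeat=n_slots):
            ok = True
            for i, pair in genotypes.items():
                got = (assign[slots[i][0]], assign[slots[i][1]])
                if tuple(sorted(got)) != tuple(sorted(pair)):
                    ok = False
                    break
            if ok:
                p = 1.0
                for a in assign:
                    p *= allele_freqs[a]
                lik += p
        s_list.append(s)
        lik_list.append(lik)
    s = np.array(s_list, dtype=float)
    lik = np.array(lik_list)
    e_s = (s * lik).sum() / lik.sum() if lik.sum() > 0 else np.nan
    return e_s, s.mean(), s.std(), s


class TestNPLSinglePoint:
    def test_fully_informative_sib_pair(self, sib_pair_ped):
        """Parents 1/2 x 3/4, sibs identical: both alleles IBD, Z=(2-1)/sigma0."""
        iv = InheritanceVectors(sib_pair_ped)
        genos = {"f": (0, 1), "m": (2, 3), "s1": (0, 2), "s2": (0, 2)}
        res = iv.score_marker_alleles(genos, [0.25] * 4)
        sigma0 = iv.s_pairs.std()
        assert res.expected_sharing == pytest.approx(2.0, abs=1e-12)
        assert res.z == pytest.approx((2 - 1) / sigma0, abs=1e-12)

    def test_uninformative_marker_skipped(self, sib_pair_ped):
        res = npl_single_point(sib_pair_ped,
                               {"f": 0, "m": 0, "s1": 0, "s2": 0}, 0.3)
        assert not res.informative
        assert res.reason == "uninformative"

    @pytest.mark.parametrize("genos", [
        {"f": 1, "m": 1, "s1": 2, "s2": 2},
        {"f": 1, "m": 0, "s1": 1, "s2": 0},
        {"s1": 2, "s2": 1},
        {"f": 2, "m": 1, "s1": 2, "s2": 2, "s3": 1},
    ])
    def test_posterior_matches_oracle_sib_trio(self, sib_trio_ped, genos):
        iv = InheritanceVectors(sib_trio_ped)
        p = 0.35
        res = iv.score_marker(genos, p)
        pairs = {i: {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g]
                 for i, g in genos.items()}
        e_s, mu0, sd0, _ = oracle_npl(sib_trio_ped, pairs, [1 - p, p])
        assert res.null_mean == pytest.approx(mu0, abs=1e-10)
        assert res.null_sd == pytest.approx(sd0, abs=1e-10)
        if res.informative:
            assert res.expected_sharing == pytest.approx(e_s, abs=1e-10)

    def test_posterior_matches_oracle_consanguineous(self, first_cousin_ped):
        # add a second affected child to give an affected pair
        ped = first_cousin_ped
        members = list(ped.members.values()) + [
            Individual("d", "a", "b", "female", "affected", 25)
        ]
        ped2 = Pedigree("FC2", [Individual(
            m.id, m.father_id, m.mother_id, m.sex, m.affection, m.age_years
        ) for m in members])
        iv = InheritanceVectors(ped2)
        genos = {"gf": 1, "gm": 0, "s1": 1, "s2": 0, "c": 1, "d": 1}
        p = 0.2
        res = iv.score_marker(genos, p)
        pairs = {i: {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g]
                 for i, g in genos.items()}
        e_s, mu0, sd0, _ = oracle_npl(ped2, pairs, [1 - p, p])
        assert res.expected_sharing == pytest.approx(e_s, abs=1e-10)
        assert res.null_mean == pytest.approx(mu0, abs=1e-10)

    def test_fast_and_graph_paths_agree(self, sib_trio_ped):
        iv = InheritanceVectors(sib_trio_ped)
        rng = np.random.default_rng(0)
        for _ in range(10):
            genos = {i: int(g) for i, g in
                     zip(iv.ped.members, rng.integers(0, 3, len(iv.ped.members)))}
            p = float(rng.uniform(0.1, 0.9))
            np.testing.assert_allclose(
                iv._likelihoods_assignment(genos, p),
                iv._likelihoods_graph(genos, p),
                rtol=1e-10,
            )

    def test_inconsistent_genotypes_flagged(self, sib_pair_ped):
        res = npl_single_point(sib_pair_ped,
                               {"f": 0, "m": 0, "s1": 2, "s2": 2}, 0.3)
        assert not res.informative
        assert res.reason == "inconsistent genotypes"

    def test_bit_cap(self, sib_pair_ped):
        with pytest.raises(BitCapExceeded):
            InheritanceVectors(sib_pair_ped, bit_cap=3)

    def test_null_calibration(self, sib_trio_ped):
        """Mean Z over unlinked markers is ~0 (markers independent of status)."""
        iv = InheritanceVectors(sib_trio_ped)
        rng = np.random.default_rng(42)
        zs = []
        p = 0.5
        for _ in range(500):
            haps = {f: rng.integers(0, 2, 2) for f in ("f", "m")}
            s_haps = {}
            for s in ("s1", "s2", "s3"):
                s_haps[s] = np.array([haps["f"][rng.integers(0, 2)],
                                      haps["m"][rng.integers(0, 2)]])
            genos = {"f": int(haps["f"].sum()), "m": int(haps["m"].sum())}
            genos.update({s: int(h.sum()) for s, h in s_haps.items()})
            res = iv.score_marker(genos, p)
            if res.informative:
                zs.append(res.z)
        se = np.std(zs) / np.sqrt(len(zs))
        assert abs(np.mean(zs)) < 3 * se + 0.05


class TestKongCox:
    def test_zero_and_negative(self):
        assert kong_cox_lod([0.0]) == 0.0
        assert kong_cox_lod([-1.0, -2.5]) == 0.0

    def test_single_positive_matches_grid_oracle(self):
        z = 2.0
        cap = 10.0
        grid = np.linspace(0, cap, 2_000_001)
        oracle = np.log10(1 + grid * z).max()
        assert kong_cox_lod([z], delta_cap=cap) == pytest.approx(oracle,
                                                                 abs=1e-5)

    def test_mixed_signs_matches_grid_oracle(self):
        zs = np.array([2.0, -1.2, 0.7])
        hi = 1 / 1.2 * (1 - 1e-9)
        grid = np.linspace(0, hi, 1_000_001)
        obj = np.log10(1 + grid[:, None] * zs[None, :]).sum(axis=1)
        assert kong_cox_lod(zs) == pytest.approx(obj.max(), abs=1e-6)

    def test_support_bound(self):
        # support minimum tightens the feasible range below the observed Z
        lod_b = kong_cox_lod([2.0], z_support_min=[-0.5])
        assert lod_b == pytest.approx(np.log10(1 + 2.0 / 0.5), abs=1e-6)

    def test_dominant_cosegregation_power(self):
        """Perfect sharing among 4 affected (>=4 informative meioses)
        exceeds the LOD 1.2 candidate threshold."""
        members = [Individual("f", sex="male", affection="affected",
                              age_years=60),
                   Individual("m", sex="female", affection="unaffected",
                              age_years=58)]
        for k in range(4):
            members.append(Individual(f"c{k}", "f", "m", "male", "affected",
                                      30))
        ped = Pedigree("DOM", members)
        iv = InheritanceVectors(ped)
        # marker tagging the dominant haplotype: father het, carriers het
        genos = {"f": 1, "m": 0}
        genos.update({f"c{k}": 1 for k in range(4)})
        res = iv.score_marker(genos, 0.05)
        assert res.informative
        assert kong_cox_lod([res.z]) > 1.2


class TestCandidateRegions:
    def test_hand_trace(self):
        track = pd.DataFrame({
            "chrom": ["1"] * 5,
            "pos": [100, 200, 300, 400, 500],
            "lod": [1.0, 1.3, 1.25, 0.9, 1.21],
        })
        regions = candidate_linkage_regions(track, 1.2)
        assert [(r.start, r.end) for r in regions] == [(200, 300), (500, 500)]

    def test_all_below_threshold(self):
        track = pd.DataFrame({"chrom": ["1"] * 3, "pos": [1, 2, 3],
                              "lod": [1.2, 0.5, 1.0]})
        assert candidate_linkage_regions(track, 1.2) == []

    def test_boundary_is_strict(self):
        track = pd.DataFrame({"chrom": ["1"], "pos": [10], "lod": [1.2]})
        assert candidate_linkage_regions(track, 1.2) == []

    def test_unsorted_rejected(self):
        track = pd.DataFrame({"chrom": ["1", "1"], "pos": [200, 100],
                              "lod": [2.0, 2.0]})
        with pytest.raises(ValueError, match="sorted"):
            candidate_linkage_regions(track)
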