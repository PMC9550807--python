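"""Synthetic-data generator: determinism, Mendelian consistency, and the
statistical structure downstream stages rely on."""

import numpy as np
import pandas as pd
import pytest

from famburden.genotypes import MISSING
from famburden.pedigree import Individual, Pedigree
from famburden.simulate import (DiseaseModel, GeneticMap, assign_affection,
                                autozygous_segments, default_marker_panel,
                                default_risk_panel, family_templates,
                                inject_missingness, inject_rare_variant,
                                simulate_family_set, simulate_unrelated,
                                true_ibd_sharing)


@pytest.fixture(scope="module")
def panel():
    return default_marker_panel(1500, seed=3)


@pytest.fixture(scope="module")
def family_sim(panel):
    variants, freqs = panel
    return simulate_family_set(family_templates(), variants, freqs, seed=17)


class TestPanels:
    def test_marker_panel_shape(self, panel):
        variants, freqs = panel
        assert len(variants) == len(freqs)
        assert set(variants["chrom"]) == {str(c) for c in range(1, 23)}
        for _, sub in variants.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing

    def test_risk_panel_structure(self, panel):
        variants, freqs = panel
        risk = default_risk_panel(variants, freqs, seed=4)
        assert len(risk) == 174
        assert int(risk["is_mhc"].sum()) == 9
        mhc = risk[risk.is_mhc]
        assert (mhc["chrom"] == "6").all()
        assert mhc["pos"].between(25_000_000, 34_000_000).all()
        assert (risk["odds_ratio"] > 0).all()

    def test_haldane_map(self, panel):
        variants, _ = panel
        gmap = GeneticMap.uniform(variants)
        for th in gmap.thetas().values():
            assert np.all(th >= 0) and np.all(th <= 0.5)


class TestGeneDrop:
    def test_deterministic_from_seed(self, panel):
        variants, freqs = panel
        _, gm1, _ = simulate_family_set(family_templates(), variants, freqs,
                                        seed=8)
        _, gm2, _ = simulate_family_set(family_templates(), variants, freqs,
                                        seed=8)
        assert gm1.samples == gm2.samples
        np.testing.assert_array_equal(gm1.calls, gm2.calls)

    def test_mendelian_consistent_everywhere(self, family_sim):
        peds, gm, _ = family_sim
        for ped in peds:
            for nf in ped.nonfounders():
                fa = gm.calls[gm.sample_index([nf.father_id])[0]]
                mo = gm.calls[gm.sample_index([nf.mother_id])[0]]
                ch = gm.calls[gm.sample_index([nf.id])[0]]
                bad = (
                    ((fa == 0) & (ch == 2)) | ((fa == 2) & (ch == 0))
                    | ((mo == 0) & (ch == 2)) | ((mo == 2) & (ch == 0))
                    | ((fa == 0) & (mo == 0) & (ch != 0))
                    | ((fa == 2) & (mo == 2) & (ch != 2))
                )
                assert not bad.any()

    def test_founder_frequency(self):
        variants = pd.DataFrame({
            "variant_id": ["v0"], "chrom": ["1"], "pos": [1000],
            "ref": ["A"], "alt": ["G"],
        })
        gm = simulate_unrelated(5000, variants, np.array([0.3]), seed=1)
        freq = gm.calls.mean() / 2
        assert freq == pytest.approx(0.3, abs=0.02)  # 3 sigma binomial bound

    def test_sib_true_ibd_half(self, panel):
        variants, freqs = panel
        peds = []
        for k in range(30):
            f = f"S{k}"
            peds.append(Pedigree(f, [
                Individual(f + "_f", sex="male"),
                Individual(f + "_m", sex="female"),
                Individual(f + "_c1", f + "_f", f + "_m", "male"),
                Individual(f + "_c2", f + "_f", f + "_m", "female"),
            ]))
        _, _, truth = simulate_family_set(peds, variants, freqs, seed=23)
        vals = [true_ibd_sharing(truth, f"S{k}_c1", f"S{k}_c2")
                for k in range(30)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)


class TestAffection:
    def test_nobody_affected_at_infinite_threshold(self, family_sim):
        _, gm, _ = family_sim
        model = DiseaseModel(threshold=np.inf)
        out = assign_affection(gm, model, seed=2)
        assert (out["affection"] == "unaffected").all()

    def test_dominant_carrier_always_affected(self, family_sim):
        _, gm, _ = family_sim
        carrier = pd.Series(0, index=gm.samples)
        carrier.iloc[:5] = 1
        model = DiseaseModel(threshold=np.inf,
                             rare_variant_effect="dominant_full")
        out = assign_affection(gm, model, seed=2, rare_carrier_dosage=carrier)
        assert (out["affection"].iloc[:5] == "affected").all()
        assert (out["affection"].iloc[5:] == "unaffected").all()

    def test_liability_separates_groups(self, panel):
        variants, freqs = panel
        gm = simulate_unrelated(1000, variants, freqs, seed=31)
        weights = pd.Series(0.3, index=variants["variant_id"][:50])
        model = DiseaseModel(weights=weights, threshold=float(
            (2 * freqs[:50] * 0.3).sum()
        ))
        out = assign_affection(gm, model, seed=5)
        aff = out[out.affection == "affected"]
        un = out[out.affection == "unaffected"]
        assert len(aff) > 10 and len(un) > 10
        assert aff["liability"].mean() > un["liability"].mean()

    def test_age_distributions(self, panel):
        variants, freqs = panel
        gm = simulate_unrelated(2000, variants[:5], freqs[:5], seed=37)
        model = DiseaseModel(threshold=0.0)  # ~half affected
        out = assign_affection(gm, model, seed=7)
        aff_ages = out.loc[out.affection == "affected", "age_years"]
        un_ages = out.loc[out.affection == "unaffected", "age_years"]
        assert aff_ages.mean() == pytest.approx(42, abs=2)
        assert un_ages.mean() == pytest.approx(55.4, abs=2)


class TestInjectRareVariant:
    def test_het_injection(self, family_sim):
        peds, gm, truth = family_sim
        row, gts = inject_rare_variant(peds[0], truth, "het", 0.0234,
                                       seed=41)
        for m in peds[0].members.values():
            expected = 1 if m.affection == "affected" else 0
            assert gts[m.id] == expected
        assert row["zygosity"] == "heterozygous"

    def test_hom_injection_inside_autozygosity(self, panel):
        # fresh simulation: carving mutates genotypes and truth in place
        variants, freqs = panel
        peds, gm, truth = simulate_family_set(family_templates()[:3],
                                              variants, freqs, seed=61)
        ped = peds[1]
        row, gts = inject_rare_variant(ped, truth, "hom", 0.0206, seed=43,
                                       genotypes=gm, carve_bp=20_000_000)
        affected = [m.id for m in ped.members.values()
                    if m.affection == "affected"]
        for a in affected:
            assert gts[a] == 2
            segs = autozygous_segments(truth, a)
            assert any(c == row["chrom"] and s <= row["pos"] <= e
                       for c, s, e in segs)
        # no unaffected member is homozygous
        for m in ped.members.values():
            if m.affection != "affected":
                assert gts[m.id] < 2

    def test_hom_warns_without_consanguinity(self, family_sim):
        peds, gm, truth = family_sim
        nuclear = [p for p in peds if not p.consanguineous_unions()][0]
        with pytest.warns(UserWarning, match="non-consanguineous"):
            inject_rare_variant(nuclear, truth, "hom", 0.01, seed=47)

    def test_requires_affected(self, panel):
        ped = Pedigree("E", [Individual("x", sex="male",
                                        affection="unaffected")])
        with pytest.raises(ValueError, match="no affected"):
            inject_rare_variant(ped, None, "het")


class TestInjectMissingness:
    def test_rate_zero_unchanged(self, family_sim):
        _, gm, _ = family_sim
        out = inject_missingness(gm, 0.0, 0.0, seed=1)
        np.testing.assert_array_equal(out.calls, gm.calls)

    def test_rate_one_all_missing(self, family_sim):
        _, gm, _ = family_sim
        out = inject_missingness(gm, 1.0, 0.0, seed=1)
        assert (out.calls == MISSING).all()

    def test_sample_rate_recovered(self, panel):
        variants, freqs = panel
        gm = simulate_unrelated(1, variants, freqs, seed=51)
        rates = np.array([0.06])
        out = inject_missingness(gm, rates, 0.0, seed=3)
        cr = out.sample_call_rate()[0]
        assert cr == pytest.approx(0.94, abs=0.02)

    def test_invalid_rate(self, family_sim):
        _, gm, _ = family_sim
        with pytest.raises(ValueError):
            inject_missingness(gm, 1.5, 0.0)

    def test_reproducible(self, family_sim):
        _, gm, _ = family_sim
        a = inject_missingness(gm, 0.05, 0.02, seed=9)
        b = inject_missingness(gm, 0.05, 0.02, seed=9)
        np.testing.assert_array_equal(a.calls, b.calls)


class TestFrequencyEmulation:
    def test_population_divergence_correlation_high(self, panel):
        variants, freqs = panel
        risk = default_risk_panel(variants, freqs, seed=6)
        r = np.corrcoef(risk["study_freq"], risk["reference_freq"])[0, 1]
        assert r > 0.8  # Fst ~ 0.01 divergence keeps frequencies tightly coupled
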