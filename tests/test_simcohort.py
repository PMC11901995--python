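"""Synthetic cohort generator: moments, bookkeeping, determinism."""

import numpy as np
import pandas as pd
import pytest

from metaprs_kit import (
    AncestryModel,
    EhrNoise,
    TraitArchitecture,
    compute_pcs,
    simulate_ehr,
    simulate_frequencies,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_weight_panels,
)
from metaprs_kit.phenotype import phenotype_cohort
from metaprs_kit.scoring import score_panel
from metaprs_kit.simcohort import DEFAULT_CODE_SETS

from conftest import make_genotypes


class TestSimulateFrequencies:
    def test_zero_divergence_limit(self):
        model = AncestryModel(
            group_names=("A",), fst=(1e-7,), group_sizes=(10,)
        )
        freqs = simulate_frequencies(model, 100, seed=0)
        assert np.abs(freqs["A"] - freqs["base"]).max() < 1e-3

    def test_balding_nichols_variance(self):
        # at base p = 0.5, the group-frequency variance should be fst*p*(1-p)
        model = AncestryModel(
            group_names=("A", "B"), fst=(0.1, 0.1), group_sizes=(10, 10)
        )
        freqs = simulate_frequencies(
            model, 5000, seed=3, base_freqs=np.full(5000, 0.5)
        )
        expected = 0.1 * 0.25
        for g in ("A", "B"):
            var = freqs[g].var()
            assert abs(var - expected) / expected < 0.2

    def test_deterministic_under_seed(self):
        model = AncestryModel(
            group_names=("A", "B"), fst=(0.05, 0.2), group_sizes=(5, 5)
        )
        f1 = simulate_frequencies(model, 200, seed=42)
        f2 = simulate_frequencies(model, 200, seed=42)
        pd.testing.assert_frame_equal(f1, f2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AncestryModel(group_names=("A",), fst=(1.5,), group_sizes=(5,))
        model = AncestryModel(group_names=("A",), fst=(0.1,), group_sizes=(5,))
        with pytest.raises(ValueError):
            simulate_frequencies(model, 10, seed=0, base_freqs=np.full(10, 0.999))
        with pytest.raises(ValueError):
            simulate_frequencies(model, 0, seed=0)


class TestSimulateGenotypes:
    def test_degenerate_frequency_gives_zero_column(self):
        model = AncestryModel(group_names=("A",), fst=(0.1,), group_sizes=(50,))
        freqs = pd.DataFrame({"base": [0.5, 0.5], "A": [0.0, 0.5]})
        geno, _ = simulate_genotypes(freqs, model, seed=0)
        assert (geno.dosages[:, 0] == 0).all()

    def test_binomial_mean(self):
        model = AncestryModel(group_names=("A",), fst=(0.1,), group_sizes=(2000,))
        freqs = pd.DataFrame({"base": [0.3], "A": [0.3]})
        geno, _ = simulate_genotypes(freqs, model, seed=1)
        assert abs(geno.dosages[:, 0].mean() - 0.6) < 0.03

    def test_labels_partition_group_sizes(self, two_group_model):
        freqs = simulate_frequencies(two_group_model, 20, seed=5)
        geno, labels = simulate_genotypes(freqs, two_group_model, seed=6)
        counts = labels.value_counts()
        assert counts["GRP1"] == 400 and counts["GRP2"] == 400
        assert len(labels) == geno.n_samples


class TestWeightPanels:
    def test_full_density(self, small_cohort):
        arch = TraitArchitecture(causal_fraction=1.0)
        geno = small_cohort["genotypes"]
        panels = simulate_weight_panels(arch, geno, seed=0)
        for p in panels.values():
            assert p.n_variants == geno.n_variants
            assert (p.entries["effect_weight"] != 0).all()

    def test_panel_isolation(self, small_cohort):
        panels = simulate_weight_panels(
            TraitArchitecture(), small_cohort["genotypes"], seed=1
        )
        before = panels["HDL"].entries["effect_weight"].copy()
        panels["LDL"].entries.loc[:, "effect_weight"] = 0.0
        pd.testing.assert_series_equal(
            panels["HDL"].entries["effect_weight"], before
        )


class TestSimulatePhenotypes:
    def test_prevalence_calibration(self):
        model = AncestryModel(
            group_names=("A", "B"), fst=(0.05, 0.05), group_sizes=(10000, 10000)
        )
        arch = TraitArchitecture(prevalence={"HT": 0.25, "T2DM": 0.12, "AF": 0.04, "CAD": 0.10})
        freqs = simulate_frequencies(model, 100, seed=2)
        geno, labels = simulate_genotypes(freqs, model, seed=3)
        panels = simulate_weight_panels(arch, geno, seed=4)
        truth = simulate_phenotypes(geno, panels, labels, arch, seed=5)
        prev = truth["cad"].mean()
        assert 0.08 <= prev <= 0.12
        # within each ancestry too (the thresholds are per-group)
        for g in ("A", "B"):
            assert abs(truth.loc[truth["ancestry"] == g, "cad"].mean() - 0.10) < 0.01

    def test_zero_direct_share_partial_correlation(self):
        model = AncestryModel(group_names=("A",), fst=(0.05,), group_sizes=(20000,))
        arch = TraitArchitecture(cad_direct_share=0.0, cad_mediated_share=0.30)
        freqs = simulate_frequencies(model, 100, seed=6)
        geno, labels = simulate_genotypes(freqs, model, seed=7)
        panels = simulate_weight_panels(arch, geno, seed=8)
        truth = simulate_phenotypes(geno, panels, labels, arch, seed=9)
        # residualize CAD liability and the direct CAD score on the
        # risk-factor scores; the partial correlation should vanish
        rf = truth[[f"z_{p}" for p in ("LDL", "HDL", "TG", "LPA", "HT", "T2DM", "AF")]]
        x = np.column_stack([np.ones(len(rf)), rf.to_numpy()])
        def resid(y):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return y - x @ beta
        r = np.corrcoef(
            resid(truth["liab_CAD"].to_numpy()), resid(truth["z_CAD"].to_numpy())
        )[0, 1]
        assert abs(r) < 0.02

    def test_noiseless_direct_liability_thresholds_exactly(self, small_cohort):
        arch = TraitArchitecture(
            cad_mediated_share=0.0, cad_direct_share=1.0, prevalence={
                "HT": 0.25, "T2DM": 0.12, "AF": 0.04, "CAD": 0.08}
        )
        truth = simulate_phenotypes(
            small_cohort["genotypes"],
            small_cohort["panels"],
            small_cohort["labels"],
            arch,
            seed=10,
        )
        for g, sub in truth.groupby("ancestry"):
            n_cases = int(sub["cad"].sum())
            top = sub["z_CAD"].nlargest(n_cases).index
            assert set(sub.index[sub["cad"] == 1]) == set(top)

    def test_unreachable_prevalence_rejected(self):
        with pytest.raises(ValueError):
            TraitArchitecture(prevalence={"CAD": 0.0})


class TestSimulateEhr:
    def test_zero_noise_round_trip(self, small_cohort):
        """With noise off and two lab repeats, phenotyping recovers truth."""
        truth = small_cohort["truth"]
        noise = EhrNoise(
            false_negative_rate=0.0,
            control_code_rate=0.0,
            min_lab_repeats=2,
            max_lab_repeats=2,
            lab_jitter_frac=0.0,
            outlier_rate=0.0,
            medicated_fraction=0.0,
        )
        ehr = simulate_ehr(truth, seed=20, noise=noise)
        # no censoring events in the stream -> use lab rules without them
        from metaprs_kit.phenotype import DEFAULT_LAB_RULES, LabRule

        rules = {
            k: LabRule(v.analyte, v.lower, v.upper)
            for k, v in DEFAULT_LAB_RULES.items()
        }
        phenos = phenotype_cohort(ehr, DEFAULT_CODE_SETS, lab_rules=rules)
        for col in ("cad", "ht", "t2dm", "af"):
            assert (phenos[col] == truth[col].reindex(phenos.index)).all(), col
        for col in ("ldl_160", "ldl_190", "tg_175", "hdl_40"):
            assert (
                phenos[col].astype(int) == truth[col].reindex(phenos.index)
            ).all(), col

    def test_outlier_switch_off(self, small_cohort):
        noise = EhrNoise(outlier_rate=0.0)
        ehr = simulate_ehr(small_cohort["truth"], seed=21, noise=noise)
        for analyte in ("LDL", "TG"):
            vals = ehr.labs.loc[ehr.labs["analyte"] == analyte, "value"]
            assert ((vals > 20) & (vals < 500)).all()

    def test_deterministic_stream(self, small_cohort):
        e1 = simulate_ehr(small_cohort["truth"], seed=22)
        e2 = simulate_ehr(small_cohort["truth"], seed=22)
        for name in ("diagnoses", "labs", "medications", "enrollment"):
            pd.testing.assert_frame_equal(getattr(e1, name), getattr(e2, name))


class TestComputePcs:
    def test_pc1_separates_divergent_groups(self):
        from sklearn.metrics import roc_auc_score

        model = AncestryModel(
            group_names=("A", "B"), fst=(0.2, 0.2), group_sizes=(200, 200)
        )
        freqs = simulate_frequencies(model, 500, seed=30)
        geno, labels = simulate_genotypes(freqs, model, seed=31)
        pcs = compute_pcs(geno, 4)
        auc = roc_auc_score((labels == "B").astype(int), pcs["PC1"])
        assert max(auc, 1 - auc) > 0.95

    def test_orthogonal_components(self, small_cohort):
        pcs = small_cohort["pcs"]
        corr = np.corrcoef(pcs.to_numpy(), rowvar=False)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 1e-8

    def test_permutation_equivariance(self, small_cohort):
        geno = small_cohort["genotypes"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(geno.n_samples)
        from metaprs_kit import GenotypeMatrix

        permuted = GenotypeMatrix(
            samples=geno.samples[perm],
            variants=geno.variants,
            dosages=geno.dosages[perm],
        )
        p1 = compute_pcs(geno, 4)
        p2 = compute_pcs(permuted, 4)
        np.testing.assert_allclose(
            p1.loc[p2.index].to_numpy(), p2.to_numpy(), atol=1e-8
        )

    def test_constant_columns_dropped(self):
        dosages = np.column_stack(
            [np.zeros(30), np.random.default_rng(1).binomial(2, 0.5, 30)]
        )
        geno = make_genotypes(dosages)
        pcs = compute_pcs(geno, 1)
        assert pcs.shape == (30, 1)


def test_raw_score_group_shift(two_group_model):
    """Allele-frequency divergence shifts raw PRS group means (the
    phenomenon ancestry adjustment exists to remove)."""
    model = AncestryModel(
        group_names=("A", "B"), fst=(0.1, 0.1), group_sizes=(500, 500)
    )
    freqs = simulate_frequencies(model, 5000, seed=40)
    geno, labels = simulate_genotypes(freqs, model, seed=41)
    panels = simulate_weight_panels(
        TraitArchitecture(causal_fraction=1.0), geno, seed=42
    )
    scores = score_panel(geno, panels["CAD"]).scores
    a = scores[labels == "A"]
    b = scores[labels == "B"]
    pooled_se = np.sqrt(a.var() / len(a) + b.var() / len(b))
    assert abs(a.mean() - b.mean()) > 3 * pooled_se
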