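"""Scoring-file I/O, allele matching and raw PRS computation."""

import numpy as np
import pandas as pd
import pytest

from metaprs_kit import (
    GenotypeMatrix,
    TraitArchitecture,
    WeightPanel,
    read_scoring_file,
    simulate_weight_panels,
    write_scoring_file,
)
from metaprs_kit.scoring import (
    ScoringFileError,
    compute_raw_prs,
    match_variants,
    score_panel,
)

from conftest import make_genotypes


def make_panel(weights, effect="G", other="A", chrom="1", start_pos=100):
    entries = pd.DataFrame(
        {
            "rsID": [f"rs{j + 1}" for j in range(len(weights))],
            "chr_name": [chrom] * len(weights),
            "chr_position": [start_pos + 100 * j for j in range(len(weights))],
            "effect_allele": [effect] * len(weights),
            "other_allele": [other] * len(weights),
            "effect_weight": list(weights),
        }
    )
    return WeightPanel(name="toy", entries=entries)


class TestScoringFileIO:
    def test_happy_path(self, tmp_path):
        path = tmp_path / "panel.txt"
        path.write_text(
            "### PGS scoring file\n#pgs_name=demo\n"
            "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"
            "rs1\t1\t100\tA\tG\t0.12\n"
            "rs2\t1\t200\tC\tT\t-0.05\n"
            "rs3\t2\t150\tG\tA\t0.33\n"
        )
        panel = read_scoring_file(path)
        assert panel.n_variants == 3
        assert panel.n_dropped_rows == 0

    def test_malformed_weight_dropped_and_counted(self, tmp_path):
        path = tmp_path / "panel.txt"
        path.write_text(
            "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"
            "rs1\t1\t100\tA\tG\t0.12\n"
            "rs2\t1\t200\tC\tT\tNA\n"
            "rs3\t2\t150\tG\tA\t0.33\n"
        )
        panel = read_scoring_file(path)
        assert panel.n_variants == 2
        assert panel.n_dropped_rows == 1

    def test_no_parsable_rows_errors(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"
            "rs1\t1\t100\tA\tG\tNA\n"
        )
        with pytest.raises(ScoringFileError):
            read_scoring_file(path)

    def test_duplicate_id_errors_naming_id(self, tmp_path):
        path = tmp_path / "dup.txt"
        path.write_text(
            "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"
            "rs1\t1\t100\tA\tG\t0.1\n"
            "rs1\t1\t200\tC\tT\t0.2\n"
        )
        with pytest.raises(ScoringFileError, match="rs1"):
            read_scoring_file(path)

    def test_round_trip_preserves_weights(self, tmp_path, small_cohort):
        panels = simulate_weight_panels(
            TraitArchitecture(), small_cohort["genotypes"], seed=50
        )
        for name, panel in panels.items():
            path = tmp_path / f"{name}.txt"
            write_scoring_file(panel, path)
            back = read_scoring_file(path, name=name)
            np.testing.assert_allclose(
                back.entries["effect_weight"].to_numpy(),
                panel.entries["effect_weight"].to_numpy(),
                rtol=0,
                atol=1e-12,
            )


class TestMatchVariants:
    def test_identity_no_flips(self):
        geno = make_genotypes(np.zeros((2, 3)), ref="A", alt="G")
        panel = make_panel([0.1, 0.2, 0.3], effect="G", other="A")
        matched = match_variants(panel, geno)
        assert not matched.flipped.any()
        assert matched.n_matched == 3

    def test_flip_algebra_on_one_variant_panel(self):
        # effect allele == ref: contribution is w*(2-d); the difference from
        # ignoring the flip is w*(2-2d) per sample
        d = np.array([[0.0], [1.0], [2.0]])
        geno = make_genotypes(d, ref="A", alt="G")
        panel = make_panel([0.7], effect="A", other="G")
        matched = match_variants(panel, geno, policy="allow_flip")
        assert matched.flipped.all()
        flipped_scores = compute_raw_prs(geno, matched).scores.to_numpy()
        unflipped = (d @ np.array([0.7])).ravel()
        np.testing.assert_allclose(
            flipped_scores - unflipped, 0.7 * (2 - 2 * d.ravel()), atol=1e-12
        )

    def test_strict_drops_flip_candidates(self):
        geno = make_genotypes(np.zeros((2, 1)), ref="A", alt="G")
        panel = make_panel([0.7], effect="A", other="G")
        with pytest.raises(ValueError, match="zero variants"):
            match_variants(panel, geno, policy="strict")

    def test_ambiguous_pair_dropped_with_reason(self):
        geno = make_genotypes(np.zeros((2, 2)), ref="A", alt="G")
        geno.variants.loc[0, ["ref", "alt"]] = ["A", "T"]
        panel = make_panel([0.1, 0.2], effect="G", other="A")
        panel.entries.loc[0, ["effect_allele", "other_allele"]] = ["T", "A"]
        matched = match_variants(panel, geno, policy="drop_ambiguous")
        assert matched.n_matched == 1
        report = matched.drop_report
        assert (report["reason"] == "ambiguous").sum() == 1

    def test_unmatched_position_counted(self):
        geno = make_genotypes(np.zeros((2, 1)), start_pos=100)
        panel = make_panel([0.1, 0.2], start_pos=100)  # second entry at 200
        matched = match_variants(panel, geno)
        assert matched.n_matched == 1
        assert (matched.drop_report["reason"] == "unmatched_position").sum() == 1


class TestComputeRawPrs:
    def test_null_panel_gives_zero_scores(self):
        geno = make_genotypes(np.random.default_rng(0).binomial(2, 0.4, (10, 5)))
        panel = make_panel([0.0] * 5)
        scores = score_panel(geno, panel).scores
        assert (scores == 0).all()

    def test_hand_computed_dot_product(self):
        geno = make_genotypes(np.array([[0.0, 1.0, 2.0]]))
        panel = make_panel([0.1, -0.2, 0.3])
        scores = score_panel(geno, panel).scores
        assert scores.iloc[0] == pytest.approx(0.4, abs=1e-12)

    def test_matches_accumulation_loop_oracle(self):
        rng = np.random.default_rng(7)
        dosages = rng.binomial(2, 0.4, size=(50, 100)).astype(float)
        weights = rng.normal(0, 0.3, size=100)
        geno = make_genotypes(dosages)
        panel = make_panel(weights)
        scores = score_panel(geno, panel).scores.to_numpy()
        oracle = np.zeros(50)
        for v in range(100):
            for i in range(50):
                oracle[i] += weights[v] * dosages[i, v]
        np.testing.assert_allclose(scores, oracle, atol=1e-10)

    def test_missing_dosage_mean_imputed(self):
        d = np.array([[0.0], [2.0], [np.nan]])
        geno = make_genotypes(d)
        panel = make_panel([1.0])
        scores = score_panel(geno, panel).scores
        # AF = mean(0,2)/2 = 0.5 -> imputed dosage 1.0
        assert scores.iloc[2] == pytest.approx(1.0)

    def test_all_missing_variant_dropped_with_warning(self):
        d = np.array([[np.nan, 1.0], [np.nan, 2.0]])
        geno = make_genotypes(d)
        panel = make_panel([0.5, 0.5])
        matched = match_variants(panel, geno)
        with pytest.warns(UserWarning, match="all-missing"):
            rv = compute_raw_prs(geno, matched)
        assert rv.n_variants_used == 1
        assert rv.n_variants_used + rv.n_variants_dropped == panel.n_variants

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        dosages = rng.binomial(2, 0.3, size=(20, 30)).astype(float)
        geno = make_genotypes(dosages)
        panel = make_panel(rng.normal(size=30))
        base = score_panel(geno, panel).scores
        perm = rng.permutation(20)
        permuted = GenotypeMatrix(
            samples=geno.samples[perm], variants=geno.variants,
            dosages=geno.dosages[perm],
        )
        shuffled = score_panel(permuted, panel).scores
        pd.testing.assert_series_equal(
            base.loc[shuffled.index], shuffled, check_names=False
        )

    def test_additivity_over_disjoint_panels(self):
        rng = np.random.default_rng(5)
        dosages = rng.binomial(2, 0.4, size=(30, 20)).astype(float)
        geno = make_genotypes(dosages)
        weights = rng.normal(size=20)
        full = make_panel(weights)
        half_a = WeightPanel(name="A", entries=full.entries.iloc[:10].copy())
        half_b = WeightPanel(name="B", entries=full.entries.iloc[10:].copy())
        total = score_panel(geno, full).scores
        split = score_panel(geno, half_a).scores + score_panel(geno, half_b).scores
        np.testing.assert_allclose(total.to_numpy(), split.to_numpy(), atol=1e-10)


def test_vcf_and_dosage_tsv_paths_agree(tmp_path, small_cohort):
    """Reading the same cohort back from VCF and from dosage TSV yields
    identical raw scores."""
    geno = small_cohort["genotypes"]
    panel = small_cohort["panels"]["LDL"]
    geno.to_vcf(tmp_path / "g.vcf")
    geno.to_dosage_tsv(tmp_path / "g.tsv")
    from_vcf = GenotypeMatrix.from_vcf(tmp_path / "g.vcf")
    from_tsv = GenotypeMatrix.from_dosage_tsv(tmp_path / "g.tsv")
    s_vcf = score_panel(from_vcf, panel).scores
    s_tsv = score_panel(from_tsv, panel).scores
    np.testing.assert_allclose(
        s_vcf.to_numpy(), s_tsv.loc[s_vcf.index].to_numpy(), atol=1e-6
    )
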