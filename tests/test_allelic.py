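"""Dosage model, bias rules and reciprocal-cross origin classification."""

import numpy as np
import pandas as pd
import pytest

from seedimprint import allelic
from seedimprint.allelic import (
    MixtureModel,
    add_parental_counts,
    classify_origin,
    collect_snp_counts,
    expected_maternal_fraction,
    rule_no_maternal,
    rule_paternal_ratio,
    tissue_maternal_fraction,
)


class TestDosageModel:
    @pytest.mark.parametrize("tissue,status,expected", [
        ("endosperm", "biallelic", 2 / 3),  # 2:1 maternal:paternal copies
        ("embryo", "biallelic", 1 / 2),     # 1:1
        ("seed_coat", "biallelic", 1.0),    # maternal sporophyte
        ("seed_coat", "PEG", 1.0),
        ("embryo", "PEG", 1 / 2),           # imprinting is endosperm-only
        ("endosperm", "PEG", 0.02),
        ("endosperm", "MEG", 0.98),
    ])
    def test_tissue_fractions(self, tissue, status, expected):
        assert tissue_maternal_fraction(tissue, status) == pytest.approx(expected)

    def test_ase_depends_on_direction(self):
        # line A favoured 4:1; endosperm has 2 maternal : 1 paternal copies
        f_ab = tissue_maternal_fraction("endosperm", "ASE_lineA", direction="AxB")
        f_ba = tissue_maternal_fraction("endosperm", "ASE_lineA", direction="BxA")
        assert f_ab == pytest.approx(8 / 9)
        assert f_ba == pytest.approx(2 / 6)

    @pytest.mark.parametrize("mix,expected", [
        ({8: (0, 0, 1)}, 2 / 3),
        ({8: (0, 1, 0)}, 1 / 2),
        ({8: (1, 0, 0)}, 1.0),
    ])
    def test_pure_tissue_mixtures(self, mix, expected):
        model = MixtureModel(mix)
        assert expected_maternal_fraction(model, "biallelic", 8) == pytest.approx(expected)

    def test_monotone_in_seed_coat_proportion(self):
        fracs = [
            expected_maternal_fraction(MixtureModel({8: (p, (1 - p) / 2, (1 - p) / 2)}),
                                       "biallelic", 8)
            for p in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a < b for a, b in zip(fracs, fracs[1:]))

    def test_tissue_weights_reweight_mixture(self):
        model = MixtureModel({8: (0.45, 0.15, 0.40)})
        f_endo_dom = expected_maternal_fraction(
            model, "PEG", 8, tissue_weights=(0.05, 0.05, 0.9))
        f_equal = expected_maternal_fraction(model, "PEG", 8)
        assert f_endo_dom < f_equal  # endosperm-dominant PEG looks more paternal

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tissue_maternal_fraction("root", "biallelic")
        with pytest.raises(ValueError):
            tissue_maternal_fraction("embryo", "odd_status")
        with pytest.raises(ValueError):
            MixtureModel({0: (0.5, 0.25, 0.25)})  # DAP0 must be all maternal
        with pytest.raises(ValueError):
            expected_maternal_fraction(MixtureModel({8: (0, 0, 1)}), "biallelic", 4)


def _table(rows, direction="AxB", tissue="whole_seed", dap=8):
    recs = []
    for gene, snp, rep, la, lb in rows:
        recs.append({"gene_id": gene, "snp_chrom": "chr1", "snp_pos": 100 + snp,
                     "sample": f"s{rep}", "dap": dap, "replicate": rep,
                     "lineA_count": la, "lineB_count": lb,
                     "tissue": tissue, "direction": direction})
    return pd.DataFrame(recs)


class TestRuleNoMaternal:
    def test_called_when_maternal_absent_everywhere(self):
        rows = [("g1", s, r, 0, 30) for s in (1, 2) for r in (1, 2, 3)]
        out = rule_no_maternal(_table(rows), "AxB", 8)
        assert out.set_index("gene_id").loc["g1", "called"]

    def test_single_maternal_read_disqualifies(self):
        rows = [("g1", s, r, 0, 30) for s in (1, 2) for r in (1, 2, 3)]
        rows[3] = ("g1", 2, 1, 1, 30)
        out = rule_no_maternal(_table(rows), "AxB", 8)
        assert not out.set_index("gene_id").loc["g1", "called"]

    def test_low_expression_removed(self):
        rows = [("g1", 1, r, 0, c) for r, c in ((1, 1), (2, 2), (3, 1.5))]
        out = rule_no_maternal(_table(rows), "AxB", 8).set_index("gene_id")
        assert out.loc["g1", "mean_total"] == pytest.approx(1.5)
        assert not out.loc["g1", "called"]

    def test_high_variability_removed(self):
        rows = [("g1", 1, 1, 0, 100), ("g1", 1, 2, 0, 0), ("g1", 1, 3, 0, 0)]
        out = rule_no_maternal(_table(rows), "AxB", 8).set_index("gene_id")
        assert out.loc["g1", "sd_total"] > out.loc["g1", "mean_total"]
        assert not out.loc["g1", "called"]


class TestRulePaternalRatio:
    def test_hand_arithmetic_called(self):
        """Three SNPs with mean paternal/maternal ratios 3.1, 4.0, 2.5:
        majority > 2, SD < mean, four expressed replicates -> called."""
        rows = []
        for snp, ratio in ((1, 3.1), (2, 4.0), (3, 2.5)):
            for rep in range(1, 5):
                rows.append(("g1", snp, rep, 10, int(10 * ratio)))
        out = rule_paternal_ratio(_table(rows), "AxB", 8).set_index("gene_id")
        assert out.loc["g1", "called"]
        assert out.loc["g1", "n_snps_over"] == 3
        assert out.loc["g1", "replicates_expressed"] == 4

    def test_majority_failure(self):
        rows = []
        for snp, ratio in ((1, 3.1), (2, 0.4), (3, 0.5)):
            for rep in range(1, 4):
                rows.append(("g1", snp, rep, 10, int(10 * ratio)))
        out = rule_paternal_ratio(_table(rows), "AxB", 8).set_index("gene_id")
        assert not out.loc["g1", "called"]

    def test_variance_filter(self):
        """Mean ratios (2.5, 2.5, 40): SD ~ 21.7 exceeds mean 15 -> not
        called despite every SNP clearing the ratio threshold."""
        rows = []
        for snp, ratio in ((1, 2.5), (2, 2.5), (3, 40.0)):
            for rep in range(1, 4):
                rows.append(("g1", snp, rep, 10, int(10 * ratio)))
        out = rule_paternal_ratio(_table(rows), "AxB", 8).set_index("gene_id")
        means = np.array([2.5, 2.5, 40.0])
        assert out.loc["g1", "sd_ratio"] == pytest.approx(means.std(ddof=1))
        assert not out.loc["g1", "called"]

    def test_min_replicates(self):
        rows = [("g1", 1, 1, 10, 50)]
        out = rule_paternal_ratio(_table(rows), "AxB", 8).set_index("gene_id")
        assert not out.loc["g1", "called"]  # expressed in only one replicate

    def test_zero_denominator_modes(self):
        rows = [("g1", 1, 1, 0, 50), ("g1", 1, 2, 10, 50)]
        excl = rule_paternal_ratio(_table(rows), "AxB", 8).set_index("gene_id")
        assert excl.loc["g1", "mean_ratio"] == pytest.approx(5.0)
        pc = rule_paternal_ratio(_table(rows), "AxB", 8,
                                 zero_denominator="pseudocount").set_index("gene_id")
        assert pc.loc["g1", "mean_ratio"] == pytest.approx(
            (50.5 / 0.5 + 50.5 / 10.5) / 2)

    def test_direction_controls_numerator(self):
        # same line counts, opposite direction: paternal line flips
        rows = [("g1", 1, r, 10, 40) for r in (1, 2, 3)]
        ab = rule_paternal_ratio(_table(rows, "AxB"), "AxB", 8).set_index("gene_id")
        ba = rule_paternal_ratio(_table(rows, "BxA"), "BxA", 8).set_index("gene_id")
        assert ab.loc["g1", "mean_ratio"] == pytest.approx(4.0)
        assert ba.loc["g1", "mean_ratio"] == pytest.approx(0.25)


class TestCollectSnpCounts:
    def test_reads_increment_their_parent_line(self):
        assignments = pd.DataFrame([
            {"read_id": "r1", "chosen_parent": "maternal", "chrom": "chr1", "pos": 95},
            {"read_id": "r2", "chosen_parent": "paternal", "chrom": "chr1", "pos": 100},
            {"read_id": "r3", "chosen_parent": "maternal", "chrom": "chr1", "pos": 400},
        ])
        sites = pd.DataFrame([
            {"gene_id": "g1", "snp_chrom": "chr1", "snp_pos": 120,
             "lineA_allele": "A", "lineB_allele": "T"},
        ])
        out = collect_snp_counts(assignments, sites, read_length=150, direction="AxB")
        row = out.iloc[0]
        assert row["lineA_count"] == 1 and row["lineB_count"] == 1  # r3 misses the site

    def test_non_divergent_site_excluded(self):
        sites = pd.DataFrame([
            {"gene_id": "g1", "snp_chrom": "chr1", "snp_pos": 10,
             "lineA_allele": "A", "lineB_allele": "A"},
        ])
        with pytest.warns(UserWarning, match="non-divergent"):
            out = collect_snp_counts(pd.DataFrame(columns=["read_id", "chosen_parent", "chrom", "pos"]), sites)
        assert len(out) == 0


def _endo_counts(gene, frac_a, coverage, direction, n_rep=4, n_snp=3, seed=0):
    """Endosperm rows with line-A fraction frac_a at every SNP."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_rep + 1):
        for snp in range(n_snp):
            la = rng.binomial(coverage, frac_a)
            rows.append({"gene_id": gene, "snp_chrom": "chr1", "snp_pos": 100 + snp,
                         "sample": f"e{rep}", "dap": 8, "replicate": rep,
                         "lineA_count": la, "lineB_count": coverage - la,
                         "tissue": "endosperm", "direction": direction})
    return pd.DataFrame(rows)


class TestClassifyOrigin:
    def test_peg_ase_biallelic_separation(self):
        """PEG: paternal-active in both directions; cis-ASE: line-A-active
        in both; biallelic: activity ~1 (the 2:1 count ratio is dosage)."""
        eps = 0.02
        tables = [
            # PEG, maternal fraction ~ eps in both directions
            _endo_counts("peg", eps, 60, "AxB", seed=1),            # A maternal
            _endo_counts("peg", 1 - eps, 60, "BxA", seed=2),        # B maternal, A paternal
            # ASE favouring line A 4:1
            _endo_counts("ase", 8 / 9, 60, "AxB", seed=3),
            _endo_counts("ase", 4 / 6, 60, "BxA", seed=4),
            # biallelic
            _endo_counts("bi", 2 / 3, 60, "AxB", seed=5),
            _endo_counts("bi", 1 / 3, 60, "BxA", seed=6),
        ]
        out = classify_origin(pd.concat(tables)).set_index("gene_id")
        assert out.loc["peg", "classification"] == "imprinted_PEG"
        assert out.loc["ase", "classification"] == "allele_specific"
        assert out.loc["bi", "classification"] == "unbiased"

    def test_meg_detected(self):
        eps = 0.02
        tables = [_endo_counts("meg", 1 - eps, 60, "AxB", seed=7),
                  _endo_counts("meg", eps, 60, "BxA", seed=8)]
        out = classify_origin(pd.concat(tables)).set_index("gene_id")
        assert out.loc["meg", "classification"] == "imprinted_MEG"

    def test_missing_direction_unvalidated(self):
        out = classify_origin(_endo_counts("g", 0.1, 50, "AxB")).set_index("gene_id")
        assert out.loc["g", "classification"] == "unvalidated"

    def test_line_label_symmetry(self):
        """Relabelling lines A<->B (which also swaps the direction labels)
        must leave every classification unchanged."""
        eps = 0.02
        tables = pd.concat([
            _endo_counts("peg", eps, 60, "AxB", seed=1),
            _endo_counts("peg", 1 - eps, 60, "BxA", seed=2),
            _endo_counts("ase", 8 / 9, 60, "AxB", seed=3),
            _endo_counts("ase", 4 / 6, 60, "BxA", seed=4),
        ])
        swapped = tables.rename(columns={"lineA_count": "lineB_count",
                                         "lineB_count": "lineA_count"})
        swapped["direction"] = swapped["direction"].map({"AxB": "BxA", "BxA": "AxB"})
        a = classify_origin(tables).set_index("gene_id")["classification"]
        b = classify_origin(swapped).set_index("gene_id")["classification"]
        assert a.to_dict() == b.to_dict()


def test_add_parental_counts_roles():
    t = _table([("g1", 1, 1, 7, 3)], direction="AxB")
    out = add_parental_counts(t)
    assert out.iloc[0]["maternal_count"] == 7
    t = _table([("g1", 1, 1, 7, 3)], direction="BxA")
    out = add_parental_counts(t)
    assert out.iloc[0]["maternal_count"] == 3


def test_validation_errors():
    t = _table([("g1", 1, 1, 7, 3)])
    bad = t.drop(columns=["tissue"])
    with pytest.raises(ValueError):
        allelic.validate_allele_table(bad)
    neg = t.assign(lineA_count=-1)
    with pytest.raises(ValueError):
        allelic.validate_allele_table(neg)
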