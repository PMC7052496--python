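"""Hard filtering, pseudo-reference construction and coordinate liftover."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seedimprint import pseudoref
from seedimprint.pseudoref import (
    CoordinateMap,
    FilterThresholds,
    build_pseudoreference,
    coding_divergence,
    expected_residual_heterozygosity,
    hard_filter_variants,
    snv_differences,
)


def _variant_frame(rows):
    base = {"chrom": "chr1", "pos": 1, "ref": "A", "alt": "T", "genotype": "hom_alt",
            "QD": 25.0, "FS": 1.0, "MQ": 60.0, "MQRankSum": 0.0,
            "ReadPosRankSum": 0.0, "DP": 30.0}
    recs = []
    for i, r in enumerate(rows):
        rec = dict(base)
        rec.update(r)
        rec["pos"] = rec.get("pos", 10 * (i + 1))
        recs.append(rec)
    return pd.DataFrame(recs)


class TestHardFilter:
    def test_boundary_rejections(self):
        df = _variant_frame([{"QD": 1.9}, {"DP": 3.0}, {"QD": 2.0, "DP": 4.0}])
        passing, tally = hard_filter_variants(df)
        assert len(passing) == 1 and tally["QD"] == 1 and tally["DP_low"] == 1

    def test_hand_enumerated_fixture(self):
        """Ten hand-annotated variants against a by-hand rule walk."""
        df = _variant_frame([
            {},                            # pass
            {"QD": 0.5},                   # fail QD
            {"FS": 61.0},                  # fail FS
            {"MQ": 19.9},                  # fail MQ
            {"MQRankSum": -13.0},          # fail MQRankSum
            {"ReadPosRankSum": -8.5},      # fail ReadPosRankSum
            {"DP": 2.0},                   # fail DP low
            {"DP": 30.0},                  # pass
            {"QD": 2.0, "FS": 60.0},       # pass (inclusive boundaries)
            {"QD": 0.1, "DP": 1.0},        # fail, tallied under QD (first rule)
        ])
        passing, tally = hard_filter_variants(df)
        assert list(passing.index) == [0, 7, 8]
        assert tally == {"QD": 2, "FS": 1, "MQ": 1, "MQRankSum": 1,
                         "ReadPosRankSum": 1, "DP_low": 1, "DP_high": 0}
        assert sum(tally.values()) == len(df) - len(passing)

    def test_empty_input(self):
        passing, tally = hard_filter_variants(_variant_frame([]).iloc[:0])
        assert len(passing) == 0 and sum(tally.values()) == 0

    def test_idempotent_under_fixed_thresholds(self):
        """With a fixed depth ceiling the filter is idempotent (the
        adaptive mean+2SD ceiling shifts slightly on the filtered set)."""
        rng = np.random.default_rng(0)
        df = _variant_frame([{"DP": float(d), "QD": float(q)}
                             for d, q in zip(rng.normal(35, 8, 200).round(),
                                             rng.uniform(0, 30, 200))])
        th = FilterThresholds(dp_max=45.0)
        once, _ = hard_filter_variants(df, th)
        twice, tally = hard_filter_variants(once, th)
        assert len(twice) == len(once) and sum(tally.values()) == 0

    def test_missing_annotations_do_not_reject(self):
        df = _variant_frame([{"MQRankSum": np.nan, "ReadPosRankSum": np.nan}])
        passing, _ = hard_filter_variants(df)
        assert len(passing) == 1


class TestPseudoReference:
    def test_zero_variants_identity(self):
        ref = {"chr1": "ACGTACGTAC"}
        pseudo, cmap = build_pseudoreference(ref, _variant_frame([]).iloc[:0])
        assert pseudo == ref
        assert all(cmap.lift("chr1", x)[0] == x for x in range(10))

    def test_single_snv(self):
        ref = {"chr1": "ACGTACGTAC"}
        v = _variant_frame([{"pos": 3, "ref": "G", "alt": "T"}])
        pseudo, cmap = build_pseudoreference(ref, v)
        assert pseudo["chr1"] == "ACTTACGTAC"
        assert sum(a != b for a, b in zip(pseudo["chr1"], ref["chr1"])) == 1
        assert cmap.lift("chr1", 7) == (7, "exact")

    def test_deletion_shifts_downstream_snv(self):
        """A 2 bp deletion upstream shifts a later position left by 2."""
        ref = {"chr1": "ACGTACGTACGT"}
        v = _variant_frame([
            {"pos": 2, "ref": "CGT", "alt": "C"},     # delete 2 bp
            {"pos": 9, "ref": "A", "alt": "G"},       # SNV after the deletion
        ])
        pseudo, cmap = build_pseudoreference(ref, v)
        assert pseudo["chr1"] == "ACACGTGCGT"
        # 1-based ref position 9 lands at pseudo position 9-2=7 (0-based 6)
        assert cmap.lift("chr1", 8, "to_pseudo") == (6, "exact")

    def test_overlapping_variants_error(self):
        ref = {"chr1": "ACGTACGTAC"}
        v = _variant_frame([{"pos": 2, "ref": "CGT", "alt": "C"},
                            {"pos": 3, "ref": "G", "alt": "A"}])
        with pytest.raises(ValueError, match="overlap"):
            build_pseudoreference(ref, v)

    def test_het_variants_skipped_with_warning(self):
        ref = {"chr1": "ACGTACGTAC"}
        v = _variant_frame([{"pos": 3, "ref": "G", "alt": "T", "genotype": "het"}])
        with pytest.warns(UserWarning, match="heterozygous"):
            pseudo, _ = build_pseudoreference(ref, v)
        assert pseudo == ref

    def test_sequence_space_round_trip(self):
        """Applying an SNV set and diffing the sequences recovers it."""
        rng = np.random.default_rng(3)
        ref_seq = "".join(rng.choice(list("ACGT"), 500))
        pos = np.sort(rng.choice(np.arange(1, 501), 20, replace=False))
        rows = []
        for p in pos:
            r = ref_seq[p - 1]
            rows.append({"pos": int(p), "ref": r,
                         "alt": {"A": "C", "C": "G", "G": "T", "T": "A"}[r]})
        v = _variant_frame(rows)
        pseudo, _ = build_pseudoreference({"chr1": ref_seq}, v)
        diffs = snv_differences(ref_seq, pseudo["chr1"])
        assert [(p, r, a) for p, r, a in diffs] == \
            [(int(r["pos"]), r["ref"], r["alt"]) for _, r in v.iterrows()]


class TestLiftover:
    @pytest.fixture()
    def toy_map(self):
        rng = np.random.default_rng(5)
        ref_seq = "".join(rng.choice(list("ACGT"), 1000))
        v = _variant_frame([
            {"pos": 101, "ref": ref_seq[100:104], "alt": ref_seq[100]},     # 3 bp del
            {"pos": 400, "ref": ref_seq[399], "alt": ref_seq[399] + "TT"},  # 2 bp ins
            {"pos": 700, "ref": ref_seq[699:701], "alt": ref_seq[699]},     # 1 bp del
        ])
        pseudo, cmap = build_pseudoreference({"chr1": ref_seq}, v)
        return ref_seq, pseudo["chr1"], cmap

    def test_exhaustive_round_trip_outside_gaps(self, toy_map):
        ref_seq, pseudo_seq, cmap = toy_map
        deleted = set(range(101, 104)) | {700}
        for x in range(len(ref_seq)):
            y, status = cmap.lift("chr1", x, "to_pseudo")
            if x in deleted:
                assert status == "deleted_adjacent"
                continue
            assert status == "exact"
            back, st2 = cmap.lift("chr1", y, "to_reference")
            assert (back, st2) == (x, "exact")
            assert ref_seq[x] == pseudo_seq[y]

    def test_total_length_accounting(self, toy_map):
        ref_seq, pseudo_seq, cmap = toy_map
        ref_span, pseudo_span = cmap.total_lengths("chr1")
        assert ref_span == len(ref_seq)
        assert pseudo_span == len(pseudo_seq) == len(ref_seq) + 2 - 3 - 1

    def test_position_in_deleted_interval_flags_adjacent(self, toy_map):
        _, _, cmap = toy_map
        y, status = cmap.lift("chr1", 102, "to_pseudo")
        assert status == "deleted_adjacent"
        assert y == cmap.lift("chr1", 100, "to_pseudo")[0]

    def test_unknown_chromosome(self, toy_map):
        with pytest.raises(KeyError):
            toy_map[2].lift("chrX", 5)

    def test_chain_tsv_round_trip(self, toy_map, tmp_path):
        _, _, cmap = toy_map
        cmap.write_chain_tsv(tmp_path / "m.chain.tsv")
        back = CoordinateMap.read_chain_tsv(tmp_path / "m.chain.tsv")
        assert back.blocks == cmap.blocks

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_property_random_indels(self, seed):
        rng = np.random.default_rng(seed)
        ref_seq = "".join(rng.choice(list("ACGT"), 300))
        positions = np.sort(rng.choice(np.arange(1, 290, 10), 4, replace=False))
        rows = []
        for p in positions:
            p = int(p)
            if rng.random() < 0.5:
                rows.append({"pos": p, "ref": ref_seq[p - 1:p + 2], "alt": ref_seq[p - 1]})
            else:
                rows.append({"pos": p, "ref": ref_seq[p - 1],
                             "alt": ref_seq[p - 1] + "AC"})
        _, cmap = build_pseudoreference({"chr1": ref_seq}, _variant_frame(rows))
        for x in range(0, 300, 7):
            y, status = cmap.lift("chr1", x, "to_pseudo")
            if status == "exact":
                assert cmap.lift("chr1", y, "to_reference") == (x, "exact")


class TestCodingDivergence:
    intervals = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})

    def test_identical_sets_zero(self):
        v = _variant_frame([{"pos": 5}, {"pos": 50}])
        assert coding_divergence(v, v, self.intervals) == 0.0

    def test_exact_arithmetic(self):
        """28 divergent sites over 1000 covered coding sites -> 0.028."""
        a = _variant_frame([{"pos": p, "ref": "A", "alt": "T"} for p in range(10, 290, 10)])
        b = _variant_frame([]).iloc[:0]
        assert coding_divergence(a, b, self.intervals) == pytest.approx(0.028)

    def test_zero_covered_sites_signalled(self):
        v = _variant_frame([{"pos": 5}])
        empty = pd.DataFrame({"chrom": [], "start": [], "end": []})
        with pytest.raises(ValueError):
            coding_divergence(v, v, empty)

    def test_simulator_recovery_within_3se(self):
        from seedimprint import synthetic

        cfg = synthetic.SimulationConfig(n_genes=300, divergence_pi=0.05, rng_seed=9)
        _, gene_models, exons, variants, _ = synthetic.generate_genome_and_variants(cfg)
        coding = exons[["chrom", "start", "end"]]
        pi = coding_divergence(variants["A"], variants["B"], coding)
        total = (coding["end"] - coding["start"]).sum()
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(pi - 0.05) < 3 * se


def test_residual_heterozygosity_after_five_selfing_generations():
    """Five generations of selfing leave (1/2)^5 = 3.125% of the founder
    heterozygosity, i.e. about 3%."""
    h = expected_residual_heterozygosity(5)
    assert h == pytest.approx(0.03125)
    assert round(h * 100) == 3
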