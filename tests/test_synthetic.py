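"""Generator-level checks: divergence, count structure, allelic draws,
file round trips and seeded determinism."""

import numpy as np
import pandas as pd
import pytest

from seedimprint import allelic, synthetic
from seedimprint.synthetic import SimulationConfig


def test_zero_divergence_yields_no_diagnostic_snps():
    cfg = SimulationConfig(n_genes=30, divergence_pi=0.0, rng_seed=2)
    _, _, _, _, snps = synthetic.generate_genome_and_variants(cfg)
    assert len(snps) == 0


def test_snp_count_matches_poisson_expectation():
    """With pi=0.028 over ~1 kb coding length the mean diagnostic SNP
    count per gene should sit within 3 SE of pi * length."""
    cfg = SimulationConfig(n_genes=500, gene_length_mean=1000, rng_seed=3)
    _, gene_models, _, _, snps = synthetic.generate_genome_and_variants(cfg)
    per_gene = snps.groupby("gene_id").size().reindex(
        gene_models["gene_id"], fill_value=0)
    expected = 0.028 * gene_models["coding_length"].mean()
    se = np.sqrt(expected / len(gene_models))
    assert abs(per_gene.mean() - expected) < 3 * se


def test_diagnostic_sites_always_divergent(small_dataset):
    snps = small_dataset.truth.snps
    assert (snps["lineA_allele"] != snps["lineB_allele"]).all()


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=0)
    with pytest.raises(ValueError):
        SimulationConfig(n_chromosomes=0)
    with pytest.raises(ValueError):
        SimulationConfig(tissue_mixture_by_timepoint={0: (0.5, 0.3, 0.3)})
    with pytest.raises(ValueError):
        SimulationConfig(tissue_mixture_by_timepoint={0: (0.8, 0.1, 0.1)})


def test_counts_poisson_limit_and_batch_free_replicates():
    """phi -> 0 gives Poisson-like variance; with batch_sd = 0 replicate
    means within a DAP differ only through library size."""
    counts, design, _ = synthetic.simulate_timecourse_counts(
        n_genes=300, phi=0.0, mean_count=200.0, batch_sd=0.0, seed=4)
    x = counts.loc[:, design["dap"] == 4].to_numpy()
    ratio = x.var(axis=1, ddof=1).mean() / x.mean(axis=1).mean()
    assert 0.8 < ratio < 1.2
    lib = counts.sum(axis=0)
    norm = counts / lib
    d4 = norm.loc[:, design["dap"] == 4]
    rel = d4.mean(axis=1)
    assert np.allclose(d4.std(axis=1) / np.maximum(rel, 1e-12), 0, atol=1.0)


def test_not_de_gene_has_flat_means():
    """With fixed library size and no batch effect, the pooled per-DAP
    mean count of non-DE biallelic genes is flat across the series."""
    cfg = SimulationConfig(n_genes=300, rng_seed=5, batch_sd=0.0,
                           library_size_sigma=0.0)
    _, gene_models, _, _, snps = synthetic.generate_genome_and_variants(cfg)
    truth = synthetic.generate_truth(cfg, gene_models, snps)
    counts, design = synthetic.simulate_counts(cfg, truth, "AxB")
    genes = truth.genes
    flat_bi = genes[(~genes["is_de"]) & (genes["allelic_status"] == "biallelic")].index
    pooled = counts.loc[flat_bi].sum(axis=0)
    per_dap = pooled.groupby(design["dap"].to_numpy()).mean()
    # pooled NB noise with phi=0.1 and lognormal baselines leaves a few
    # percent of relative SD per DAP group; 15% bounds ~3 SE on max-min
    assert per_dap.max() / per_dap.min() - 1 < 0.15


def test_allele_counts_biallelic_endosperm_two_thirds(paperlike_dataset):
    ds = paperlike_dataset
    endo = allelic.add_parental_counts(ds.allele_counts[("endosperm", "AxB")])
    bi = ds.truth.genes.query("allelic_status == 'biallelic'").index
    sub = endo[endo["gene_id"].isin(bi)]
    m = sub["maternal_count"].sum()
    n = m + sub["paternal_count"].sum()
    se = np.sqrt(2 / 3 * 1 / 3 / n) * 4  # overdispersion widens the binomial SE
    assert abs(m / n - 2 / 3) < max(3 * se, 0.01)


def test_peg_complete_silencing_zero_maternal():
    cfg = SimulationConfig(n_genes=80, leakage=0.0, allelic_overdispersion=0.0,
                           rng_seed=6)
    ds = synthetic.simulate_dataset(cfg)
    endo = allelic.add_parental_counts(ds.allele_counts[("endosperm", "AxB")])
    pegs = ds.truth.genes.query("allelic_status == 'PEG'").index
    assert len(pegs) > 0
    assert endo[endo["gene_id"].isin(pegs)]["maternal_count"].eq(0).all()


def test_ase_line_fraction_invariant_to_cross_direction(paperlike_dataset):
    """A cis-ASE gene favours the same line in both cross directions."""
    ds = paperlike_dataset
    ase = ds.truth.genes.query("allelic_status == 'ASE_lineA'").index
    fracs = {}
    for direction in ("AxB", "BxA"):
        t = ds.allele_counts[("endosperm", direction)]
        sub = t[t["gene_id"].isin(ase)]
        fracs[direction] = sub["lineA_count"].sum() / (
            sub["lineA_count"].sum() + sub["lineB_count"].sum())
    # expected line-A fractions: 8/9 when A is maternal, 4/6 when paternal
    assert abs(fracs["AxB"] - 8 / 9) < 0.02
    assert abs(fracs["BxA"] - 4 / 6) < 0.02


def test_whole_seed_fraction_is_tissue_weighted_average(paperlike_dataset):
    """Law of total expectation: the whole-seed maternal fraction of
    biallelic genes matches the mixture-weighted per-tissue fractions."""
    ds = paperlike_dataset
    model = ds.config.mixture_model()
    bi = ds.truth.genes.query("allelic_status == 'biallelic'").index
    ws = allelic.add_parental_counts(ds.allele_counts[("whole_seed", "AxB")])
    for dap in (2, 8):
        sub = ws[(ws["dap"] == dap) & ws["gene_id"].isin(bi)]
        m, n = sub["maternal_count"].sum(), (sub["maternal_count"] + sub["paternal_count"]).sum()
        f_exp = allelic.expected_maternal_fraction(model, "biallelic", dap)
        assert abs(m / n - f_exp) < 0.01


def test_same_seed_reproduces_dataset_exactly():
    cfg = SimulationConfig(n_genes=40, rng_seed=11)
    a = synthetic.simulate_dataset(cfg)
    b = synthetic.simulate_dataset(cfg)
    assert a.reference == b.reference
    pd.testing.assert_frame_equal(a.counts["AxB"], b.counts["AxB"])
    pd.testing.assert_frame_equal(a.allele_counts[("whole_seed", "BxA")],
                                  b.allele_counts[("whole_seed", "BxA")])


def test_write_read_round_trip(tmp_path, small_dataset):
    ds = small_dataset
    synthetic.write_dataset(ds, tmp_path)
    counts = synthetic.read_counts_tsv(tmp_path / "counts_AxB.tsv")
    pd.testing.assert_frame_equal(counts, ds.counts["AxB"], check_names=False)
    table = synthetic.read_allele_table_tsv(tmp_path / "allele_counts_endosperm_AxB.tsv")
    assert len(table) == len(ds.allele_counts[("endosperm", "AxB")])
    ref = synthetic.read_fasta(tmp_path / "reference.fa")
    assert ref == ds.reference
    # VCF carries homozygous genotypes only
    vcf_lines = [l for l in (tmp_path / "lineA.vcf").read_text().splitlines()
                 if not l.startswith("#")]
    assert all(line.endswith(("1/1", "0/0")) for line in vcf_lines)
    # and reads back losslessly through the VCF loader
    from seedimprint.pseudoref import load_variants_vcf

    loaded = load_variants_vcf(tmp_path / "lineA.vcf")
    orig = ds.variants["A"].sort_values(["chrom", "pos"]).reset_index(drop=True)
    assert len(loaded) == len(orig)
    assert (loaded["pos"].to_numpy() == orig["pos"].to_numpy()).all()
    assert (loaded["alt"] == orig["alt"]).all()
    assert (loaded["genotype"] == orig["genotype"]).all()
    assert np.allclose(loaded["QD"], orig["QD"], atol=0.01)
    # GFF3 exon unions reproduce the truth coding lengths
    gene_models, exons = synthetic.read_gff3_genes(tmp_path / "annotation.gff3")
    from seedimprint.quantify import exon_union_lengths

    lengths = exon_union_lengths(exons)
    truth_len = ds.truth.genes["coding_length"]
    assert (lengths.reindex(truth_len.index) == truth_len).all()
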