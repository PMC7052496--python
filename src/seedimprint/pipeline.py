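"""End-to-end pipeline driver on a synthetic reciprocal-cross dataset.

Runs simulate -> pseudo-reference -> read arbitration -> quantification
-> time-course DE -> clustering -> expression classification -> allelic
bias calling, writes every stage's table under a run directory and
produces a machine-readable report that scores each stage against the
simulation truth. Every stage is a pure function of (inputs, config,
seed), so a rerun with the same seed reproduces the run byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import allelic, arbitration, classify, clustering, pseudoref, quantify, synthetic, timecourse
from ._rng import substream


@dataclass
class PipelineConfig:
    """All stage thresholds, defaulting to the study's printed settings
    (FDR 0.01, R^2 0.6, CPM > 1 in >= 3 samples, FPKM 1/5 rules,
    paternal ratio > 2, mismatch fraction 0.04, K-means with 100 starts
    and 25 iterations)."""

    simulation: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    fdr: float = 0.01
    r2_min: float = 0.6
    poly_degree: int = 4
    cpm_min: float = 1.0
    cpm_min_samples: int = 3
    kmeans_k: int | None = None  # None: choose by gap statistic
    gap_k_range: tuple[int, int] = (1, 8)
    kmeans_starts: int = 100
    kmeans_iters: int = 25
    gap_B: int = 50
    ratio_min: float = 2.0
    min_mean_count: float = 2.0
    min_replicates: int = 2
    max_mismatch_fraction: float = 0.04
    bias_timepoint: float = 8
    rules: classify.ClassificationRules = field(default_factory=classify.ClassificationRules)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = synthetic.SimulationConfig(**raw.pop("simulation", {}))
        rules = classify.ClassificationRules(**raw.pop("rules", {}))
        return cls(simulation=sim, rules=rules, **raw)


def _stage(report: dict, name: str):
    report.setdefault("stages", []).append(name)


def run_pipeline(config: PipelineConfig | None = None, out_dir=None) -> dict:
    """Run every stage; return (and optionally write) the run report."""
    config = config or PipelineConfig()
    t0 = time.time()
    report: dict = {"seed": config.seed}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------
    _stage(report, "simulate")
    ds = synthetic.simulate_dataset(config.simulation)
    truth = ds.truth
    if out is not None:
        synthetic.write_dataset(ds, out / "data")

    # --- pseudo-reference ---------------------------------------------
    _stage(report, "pseudoref")
    pseudo, cmaps, filter_tallies = {}, {}, {}
    for line in ("A", "B"):
        passing, tally = pseudoref.hard_filter_variants(ds.variants[line])
        pseudo[line], cmaps[line] = pseudoref.build_pseudoreference(ds.reference, passing)
        filter_tallies[line] = tally
    coding = ds.exons.rename(columns={"chrom": "chrom"})[["chrom", "start", "end"]]
    pi = pseudoref.coding_divergence(
        *(pseudoref.hard_filter_variants(ds.variants[l])[0] for l in ("A", "B")),
        coding_intervals=coding,
    )
    report["pseudoref"] = {"filter_tallies": filter_tallies, "coding_pi": pi}
    if out is not None:
        for line in ("A", "B"):
            synthetic.write_fasta(pseudo[line], out / f"pseudo_{line}.fa")
            cmaps[line].write_chain_tsv(out / f"pseudo_{line}.chain.tsv")

    # --- read arbitration (demonstration subset) ----------------------
    _stage(report, "arbitrate")
    f_expect = allelic.expected_maternal_fraction(
        config.simulation.mixture_model(), "biallelic", config.bias_timepoint)
    m_obs, p_obs, _ = synthetic.simulate_arbitration_observations(
        n_reads=20000, maternal_fraction=f_expect, divergence_pi=config.simulation.divergence_pi,
        read_length=config.simulation.read_length, seed=config.seed)
    n_total = len(m_obs)
    m_keep = arbitration.filter_alignments(m_obs, config.max_mismatch_fraction)
    p_keep = arbitration.filter_alignments(p_obs, config.max_mismatch_fraction)
    merged = arbitration.arbitrate(m_keep, p_keep, seed=config.seed)
    report["arbitration"] = arbitration.mapping_stats(
        merged, n_total, len(m_keep), len(p_keep))

    # --- quantification ------------------------------------------------
    _stage(report, "quantify")
    counts = ds.counts["AxB"]
    design = ds.design["AxB"]
    kept = quantify.cpm_filter(counts, config.cpm_min, config.cpm_min_samples)
    counts_f = counts.loc[kept]
    tmm = quantify.tmm_factors(counts_f)
    lengths = quantify.exon_union_lengths(ds.exons)
    fpkm_all = quantify.fpkm(counts, lengths)
    report["quantification"] = {
        "genes_total": int(len(counts)),
        "genes_after_cpm_filter": int(len(kept)),
        "tmm_range": [float(tmm.min()), float(tmm.max())],
    }

    # --- time-course DE -------------------------------------------------
    _stage(report, "timecourse_de")
    glm = timecourse.glm_lrt_stage(counts_f, design, fdr=config.fdr, tmm=tmm)
    poly = timecourse.polynomial_stage(
        counts_f, design, r2_min=config.r2_min, fdr=config.fdr,
        degree=config.poly_degree, tmm=tmm)
    de = timecourse.intersect_degs(glm, poly)
    degs = de.index[de["intersection_deg"]]
    truth_de = truth.genes.loc[counts_f.index, "is_temporally_changing"]
    tp = int((truth_de & de["intersection_deg"]).sum())
    report["timecourse_de"] = {
        "glm_degs": int(de["glm_deg"].sum()),
        "poly_degs": int(de["poly_deg"].sum()),
        "intersection_degs": int(len(degs)),
        "recall": tp / max(1, int(truth_de.sum())),
        "false_discovery_proportion": 1.0 - tp / max(1, len(degs)),
    }
    pca_coords, var_frac = timecourse.pca_samples(counts_f)
    report["pca_variance_explained"] = [float(v) for v in var_frac[:2]]
    if out is not None:
        de.to_csv(out / "de_results.tsv", sep="\t")
        pca_coords.to_csv(out / "pca_samples.tsv", sep="\t")

    # --- clustering -----------------------------------------------------
    _stage(report, "cluster")
    profiles = clustering.profile_matrix(fpkm_all.loc[degs], design)
    if len(profiles) >= 10:
        if config.kmeans_k is None:
            lo, hi = config.gap_k_range
            k, gap_curve = clustering.gap_statistic(
                profiles, range(lo, hi + 1), B=config.gap_B, seed=config.seed)
        else:
            k, gap_curve = config.kmeans_k, None
        result = clustering.kmeans_profiles(
            profiles, k, n_start=config.kmeans_starts,
            max_iter=config.kmeans_iters, seed=config.seed)
        ari = adjusted_rand_score(
            truth.genes.loc[result.labels.index, "cluster"], result.labels)
        report["clustering"] = {"chosen_k": int(k), "ari_vs_truth": float(ari)}
        if out is not None:
            result.labels.to_csv(out / "clusters.tsv", sep="\t")
            if gap_curve is not None:
                gap_curve.to_csv(out / "gap_curve.tsv", sep="\t", index=False)
    else:
        report["clustering"] = {"skipped": f"only {len(profiles)} DEGs"}

    # --- expression classes ---------------------------------------------
    _stage(report, "classify")
    means = classify.mean_fpkm_by_timepoint(fpkm_all, design)
    expressed = classify.classify_expressed(means, config.rules)
    stage_lab = classify.classify_stage_specific(means, config.rules)
    ext_rng = substream(config.seed, "external-panel")
    external = pd.DataFrame(
        {t: np.where(ext_rng.random(len(means)) < 0.2, 0.0,
                     ext_rng.lognormal(1.0, 1.0, len(means)))
         for t in ("calyx", "leaf", "petal", "stem")},
        index=means.index,
    )
    exclusive = classify.classify_exclusive(means, external, config.rules)
    report["expression_classes"] = {
        "expressed": int(expressed.sum()),
        "stage_specific": int(stage_lab.notna().sum()),
        "ovule_exclusive": int(exclusive["ovule_exclusive"].sum()),
        "seed_exclusive": int((exclusive["label"] == "seed_exclusive").sum()),
    }

    # --- allelic bias ----------------------------------------------------
    _stage(report, "biascall")
    whole = ds.allele_counts[("whole_seed", "AxB")]
    calls = allelic.call_biased_genes(
        whole, "AxB", config.bias_timepoint, config.ratio_min,
        config.min_mean_count, config.min_replicates)
    called = set(calls["gene_id"])
    evaluable = truth.genes[truth.genes["n_snps"] > 0]
    peg_genes = set(evaluable.index[evaluable["allelic_status"] == "PEG"])
    biallelic_genes = set(evaluable.index[evaluable["allelic_status"] == "biallelic"])
    peg_recall = len(called & peg_genes) / max(1, len(peg_genes))
    peg_precision = (len(called & peg_genes) / len(called)) if called else float("nan")
    endo = pd.concat([ds.allele_counts[("endosperm", "AxB")],
                      ds.allele_counts[("endosperm", "BxA")]])
    origin = allelic.classify_origin(endo, sorted(called), config.ratio_min)
    cls_by_gene = origin.set_index("gene_id")["classification"]
    report["allelic_bias"] = {
        "candidates": len(called),
        "peg_recall": peg_recall,
        "peg_precision": peg_precision,
        "biallelic_false_call_rate": len(called & biallelic_genes) / max(1, len(biallelic_genes)),
        "origin_classes": origin["classification"].value_counts().to_dict(),
        "peg_confirmed": int((cls_by_gene.reindex(sorted(called & peg_genes))
                              == "imprinted_PEG").sum()),
    }
    if out is not None:
        calls.to_csv(out / "bias_calls.tsv", sep="\t", index=False)
        origin.to_csv(out / "origin_classification.tsv", sep="\t", index=False)

    report["runtime_s"] = round(time.time() - t0, 2)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
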