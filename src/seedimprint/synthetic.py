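"""Synthetic reciprocal-cross seed transcriptome datasets.

Generates complete, seeded datasets with the statistical structure the
analysis assumes, so every downstream stage can be tested against known
ground truth without any external data:

* a random reference genome with non-overlapping gene models;
* two inbred parental lines diverged at ~pi substitutions per coding
  site (every diagnostic SNP homozygous within a line and divergent
  between lines), plus deliberately bad variant calls and intergenic
  indels to exercise hard filtering and liftover;
* negative-binomial count matrices for both cross directions over the
  0/2/4/6/8 DAP series with Table-style replicate numbers, library-size
  variation and lognormal maternal-plant (batch) effects;
* per-SNP allele-count tables (beta-binomial around the tissue-mixture
  maternal fraction) for whole seed and for isolated tissues in both
  cross directions;
* a truth table (cluster archetype, DE flag, allelic status, tissue
  weights) against which recovery is scored.

Imprinted (PEG/MEG) and cis-ASE genes are simulated as
endosperm-dominant, reflecting the endosperm-specific biology of
imprinting; this is also what makes them visible in whole-seed counts,
where seed-coat and embryo reads would otherwise swamp the signal.

All randomness flows from one master seed through independent named
substreams, so the same seed yields a byte-identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .allelic import (
    ALLELE_TABLE_COLUMNS,
    MixtureModel,
    tissue_maternal_fraction,
)

BASES = np.array(list("ACGT"))

#: temporal multiplier archetypes over the five DAP stages (0,2,4,6,8)
ARCHETYPES: dict[str, tuple[float, ...]] = {
    "flat": (1.0, 1.0, 1.0, 1.0, 1.0),
    "ovule_peak": (4.0, 2.0, 1.0, 0.5, 0.5),
    "mid_peak": (0.5, 0.8, 1.5, 4.0, 1.5),
    "late_rise": (0.4, 0.4, 0.8, 1.6, 4.0),
    "early_rise": (0.5, 4.0, 2.0, 1.0, 0.5),
    "decline": (4.0, 3.0, 2.0, 1.0, 0.4),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic reciprocal-cross dataset.

    Defaults mirror the study conditions: five time points at 0-8 DAP
    with 5/4/3/4/4 biological replicates, coding divergence pi = 0.028
    between the parental lines, NB dispersion 0.1, beta-binomial allelic
    overdispersion 0.02 and a seed-coat/embryo/endosperm mixture that
    starts all-maternal at 0 DAP and shifts toward endosperm by 8 DAP.
    Sizes (gene number, library size) are desk-scale.
    """

    n_genes: int = 800
    n_chromosomes: int = 2
    gene_length_mean: int = 1000
    divergence_pi: float = 0.028
    time_points: tuple[float, ...] = (0, 2, 4, 6, 8)
    replicates_per_timepoint: tuple[int, ...] = (5, 4, 3, 4, 4)
    library_size_mean: float = 400_000
    library_size_sigma: float = 0.2
    nb_dispersion: float = 0.1
    batch_sd: float = 0.1
    allelic_overdispersion: float = 0.02
    tissue_mixture_by_timepoint: dict[float, tuple[float, float, float]] = field(
        default_factory=lambda: {
            0: (1.00, 0.00, 0.00),
            2: (0.80, 0.05, 0.15),
            4: (0.70, 0.08, 0.22),
            6: (0.55, 0.12, 0.33),
            8: (0.45, 0.15, 0.40),
        }
    )
    n_clusters_true: int = 4
    frac_flat: float = 0.40
    frac_peg: float = 0.05
    frac_meg: float = 0.03
    frac_ase: float = 0.06
    leakage: float = 0.02
    ase_ratio: float = 4.0
    read_length: int = 150
    baseline_log_sd: float = 1.0
    fail_variant_rate: float = 0.10
    shared_variant_rate: float = 0.002
    indels_per_chromosome: int = 3
    isolated_dap: float = 8
    isolated_replicates: int = 4
    isolated_library_size: float = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one gene and one chromosome")
        if len(self.time_points) != len(self.replicates_per_timepoint):
            raise ValueError("one replicate count per time point required")
        if self.nb_dispersion < 0 or self.allelic_overdispersion < 0:
            raise ValueError("dispersions must be non-negative")
        if not 1 <= self.n_clusters_true <= len(ARCHETYPES):
            raise ValueError(f"n_clusters_true must be in [1, {len(ARCHETYPES)}]")
        if self.frac_peg + self.frac_meg + self.frac_ase > 1:
            raise ValueError("allelic-status fractions exceed 1")
        MixtureModel(dict(self.tissue_mixture_by_timepoint), self.leakage, self.ase_ratio)

    def mixture_model(self) -> MixtureModel:
        return MixtureModel(
            {k: tuple(v) for k, v in self.tissue_mixture_by_timepoint.items()},
            leakage=self.leakage,
            ase_ratio=self.ase_ratio,
        )


@dataclass
class TruthTable:
    """Ground truth: per-gene archetype/cluster, DE flag, allelic status,
    baseline and per-tissue expression weights, plus temporal multipliers
    and diagnostic SNP positions."""

    genes: pd.DataFrame
    temporal: pd.DataFrame  # genes x time points
    snps: pd.DataFrame      # gene_id, chrom, pos (1-based), ref, alts per line


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    reference: dict[str, str]
    gene_models: pd.DataFrame
    exons: pd.DataFrame
    variants: dict[str, pd.DataFrame]  # line -> VCF-like frame
    truth: TruthTable
    counts: dict[str, pd.DataFrame]    # direction -> genes x samples
    design: dict[str, pd.DataFrame]
    allele_counts: dict[tuple[str, str], pd.DataFrame]  # (tissue, direction)


# ---------------------------------------------------------------------------
# genome / variants

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _variant_annotations(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    return {
        "QD": rng.uniform(15, 35, n).round(2),
        "FS": rng.uniform(0, 5, n).round(2),
        "MQ": np.full(n, 60.0),
        "MQRankSum": rng.normal(0, 1, n).round(3),
        "ReadPosRankSum": rng.normal(0, 1, n).round(3),
        "DP": rng.normal(35, 3, n).round(0).clip(min=8),
    }


def generate_genome_and_variants(config: SimulationConfig):
    """Random reference, non-overlapping gene models and per-line variants.

    Returns (reference, gene_models, exons, variants-by-line, snps).
    Diagnostic SNP counts per gene are Poisson(pi * coding length); each
    SNP is a homozygous substitution in exactly one line, so the lines
    always differ there. A fraction of deliberately failing variant
    calls and a few intergenic indels per chromosome are added.
    """
    rng = substream(config.rng_seed, "genome")
    genes_per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    genes_per_chrom[: config.n_genes % config.n_chromosomes] += 1

    reference: dict[str, str] = {}
    gene_rows, exon_rows, snp_rows = [], [], []
    var_rows = {"A": [], "B": []}
    gene_idx = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = 200
        chrom_genes = []
        for _ in range(genes_per_chrom[ci]):
            gene_id = f"G{gene_idx + 1:05d}"
            gene_idx += 1
            length = int(np.clip(rng.gamma(4.0, config.gene_length_mean / 4.0),
                                 300, 4 * config.gene_length_mean))
            n_ex = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(1, length), size=n_ex - 1, replace=False)) \
                if n_ex > 1 else np.array([], dtype=int)
            ex_lens = np.diff(np.concatenate([[0], cuts, [length]]))
            start = cursor
            pos = start
            exon_offsets = []
            for k, el in enumerate(ex_lens):
                exon_rows.append({"gene_id": gene_id, "chrom": chrom,
                                  "start": pos, "end": pos + int(el)})
                exon_offsets.append((pos, pos + int(el)))
                pos += int(el)
                if k < n_ex - 1:
                    pos += 100  # intron
            end = pos
            gene_rows.append({"gene_id": gene_id, "chrom": chrom, "start": start,
                              "end": end, "strand": "+" if rng.random() < 0.5 else "-",
                              "coding_length": int(length)})
            chrom_genes.append((gene_id, exon_offsets, int(length)))
            cursor = end + 200
        chrom_len = cursor + 200
        seq = _random_seq(rng, chrom_len)
        reference[chrom] = seq

        used: set[int] = set()
        # diagnostic SNPs in exons
        for gene_id, exon_offsets, length in chrom_genes:
            exonic = np.concatenate([np.arange(s, e) for s, e in exon_offsets])
            n_snp = rng.poisson(config.divergence_pi * length)
            n_snp = min(n_snp, len(exonic))
            if n_snp == 0:
                continue
            positions = rng.choice(exonic, size=n_snp, replace=False)
            for p in np.sort(positions):
                p = int(p)
                if p in used:
                    continue
                used.add(p)
                ref_base = seq[p]
                alt = str(rng.choice(BASES[BASES != ref_base]))
                line = "A" if rng.random() < 0.5 else "B"
                var_rows[line].append({"chrom": chrom, "pos": p + 1, "ref": ref_base,
                                       "alt": alt, "genotype": "hom_alt"})
                snp_rows.append({"gene_id": gene_id, "chrom": chrom, "pos": p + 1,
                                 "ref": ref_base,
                                 "lineA_allele": alt if line == "A" else ref_base,
                                 "lineB_allele": alt if line == "B" else ref_base})
            # shared (non-divergent) exonic variants in both lines
            n_shared = rng.poisson(config.shared_variant_rate * length)
            for p in rng.choice(exonic, size=min(n_shared, len(exonic)), replace=False):
                p = int(p)
                if p in used:
                    continue
                used.add(p)
                ref_base = seq[p]
                alt = str(rng.choice(BASES[BASES != ref_base]))
                for line in ("A", "B"):
                    var_rows[line].append({"chrom": chrom, "pos": p + 1, "ref": ref_base,
                                           "alt": alt, "genotype": "hom_alt"})

        # intergenic indels (exercise liftover)
        genic = np.zeros(chrom_len, dtype=bool)
        for _, offs, _ in chrom_genes:
            for s, e in offs:
                genic[max(0, s - 10):min(chrom_len, e + 11)] = True
        near_used = np.zeros(chrom_len, dtype=bool)
        for u in used:
            near_used[max(0, u - 5):min(chrom_len, u + 6)] = True
        free = ~genic & ~near_used
        free[:50] = free[-50:] = False
        intergenic = np.nonzero(free)[0]
        if len(intergenic) and config.indels_per_chromosome > 0:
            picks = rng.choice(intergenic, size=min(config.indels_per_chromosome,
                                                    len(intergenic)), replace=False)
            for p in np.sort(picks):
                p = int(p)
                if any(abs(p - u) < 6 for u in used):
                    continue
                used.update(range(p, p + 5))
                size = int(rng.integers(1, 4))
                line = "A" if rng.random() < 0.5 else "B"
                if rng.random() < 0.5:  # deletion
                    ref_a = seq[p:p + 1 + size]
                    alt_a = seq[p]
                else:  # insertion
                    ref_a = seq[p]
                    alt_a = seq[p] + _random_seq(rng, size)
                var_rows[line].append({"chrom": chrom, "pos": p + 1, "ref": ref_a,
                                       "alt": alt_a, "genotype": "hom_alt"})

        # deliberately failing variant calls (intergenic SNVs)
        n_fail = rng.poisson(config.fail_variant_rate * max(1, len(used)))
        candidates = [p for p in intergenic if p not in used]
        fail_rules = ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP"]
        for k, p in enumerate(rng.choice(candidates, size=min(n_fail, len(candidates)),
                                         replace=False)):
            p = int(p)
            used.add(p)
            ref_base = seq[p]
            alt = str(rng.choice(BASES[BASES != ref_base]))
            row = {"chrom": chrom, "pos": p + 1, "ref": ref_base, "alt": alt,
                   "genotype": "hom_alt", "_fail": fail_rules[k % len(fail_rules)]}
            var_rows["A" if rng.random() < 0.5 else "B"].append(row)

    gene_models = pd.DataFrame(gene_rows)
    exons = pd.DataFrame(exon_rows)
    snps = pd.DataFrame(snp_rows, columns=["gene_id", "chrom", "pos", "ref",
                                           "lineA_allele", "lineB_allele"])
    variants = {}
    ann_rng = substream(config.rng_seed, "variant-annotations")
    for line in ("A", "B"):
        df = pd.DataFrame(var_rows[line])
        if df.empty:
            df = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "genotype"])
        ann = _variant_annotations(ann_rng, len(df))
        for key, vals in ann.items():
            df[key] = vals
        if "_fail" in df.columns:
            bad = df["_fail"].notna()
            df.loc[bad & (df["_fail"] == "QD"), "QD"] = 0.5
            df.loc[bad & (df["_fail"] == "FS"), "FS"] = 90.0
            df.loc[bad & (df["_fail"] == "MQ"), "MQ"] = 10.0
            df.loc[bad & (df["_fail"] == "MQRankSum"), "MQRankSum"] = -20.0
            df.loc[bad & (df["_fail"] == "ReadPosRankSum"), "ReadPosRankSum"] = -12.0
            df.loc[bad & (df["_fail"] == "DP"), "DP"] = 2.0
            df = df.drop(columns=["_fail"])
        variants[line] = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return reference, gene_models, exons, variants, snps


# ---------------------------------------------------------------------------
# truth

def generate_truth(config: SimulationConfig, gene_models: pd.DataFrame,
                   snps: pd.DataFrame) -> TruthTable:
    """Assign cluster archetypes, DE flags, allelic statuses, baselines and
    tissue weights to every gene."""
    rng = substream(config.rng_seed, "truth")
    n = len(gene_models)
    names = list(ARCHETYPES)[: config.n_clusters_true]
    if "flat" in names:
        probs = [config.frac_flat] + [(1 - config.frac_flat) / (len(names) - 1)] * (len(names) - 1) \
            if len(names) > 1 else [1.0]
    else:
        probs = [1.0 / len(names)] * len(names)
    archetype = rng.choice(names, size=n, p=probs)

    status = np.array(["biallelic"] * n, dtype=object)
    u = rng.random(n)
    status[u < config.frac_peg] = "PEG"
    status[(u >= config.frac_peg) & (u < config.frac_peg + config.frac_meg)] = "MEG"
    ase_hi = config.frac_peg + config.frac_meg + config.frac_ase
    is_ase = (u >= config.frac_peg + config.frac_meg) & (u < ase_hi)
    ase_line = rng.random(n) < 0.5
    status[is_ase & ase_line] = "ASE_lineA"
    status[is_ase & ~ase_line] = "ASE_lineB"

    baseline = rng.lognormal(0.0, config.baseline_log_sd, size=n)
    w = np.tile(np.array([1 / 3, 1 / 3, 1 / 3]), (n, 1))
    w[status != "biallelic"] = np.array([0.05, 0.05, 0.90])

    n_snps = snps.groupby("gene_id").size() if len(snps) else pd.Series(dtype=int)
    genes = pd.DataFrame({
        "gene_id": gene_models["gene_id"].to_numpy(),
        "cluster": [names.index(a) for a in archetype],
        "archetype": archetype,
        "is_de": archetype != "flat",
        "allelic_status": status,
        "baseline": baseline,
        "w_seed_coat": w[:, 0],
        "w_embryo": w[:, 1],
        "w_endosperm": w[:, 2],
    }).set_index("gene_id")
    genes["coding_length"] = gene_models.set_index("gene_id")["coding_length"]
    genes["n_snps"] = n_snps.reindex(genes.index).fillna(0).astype(int)
    # endosperm-dominant genes drift with the tissue mixture even under a
    # flat archetype, so they are temporal changers too
    genes["is_temporally_changing"] = genes["is_de"] | (genes["allelic_status"] != "biallelic")
    temporal = pd.DataFrame(
        [ARCHETYPES[a][: len(config.time_points)] for a in archetype],
        index=genes.index, columns=list(config.time_points),
    )
    return TruthTable(genes=genes, temporal=temporal, snps=snps)


# ---------------------------------------------------------------------------
# counts

def _make_design(config: SimulationConfig, direction: str) -> pd.DataFrame:
    """Sample sheet for one cross direction, with maternal-plant batches.

    Replicate r at any fertilized stage is maternal plant r; the ovule
    stage reuses plants 1-2 and adds pooled batches for the extra
    replicates, yielding seven batches under the default design.
    """
    rows = []
    for dap, nrep in zip(config.time_points, config.replicates_per_timepoint):
        for r in range(1, nrep + 1):
            if dap == config.time_points[0] and r > 2:
                batch = f"P{max(config.replicates_per_timepoint) + r - 2}"
            else:
                batch = f"P{r}"
            rows.append({"sample": f"{int(dap)}d_BR{r}_{direction}",
                         "dap": dap, "replicate": r, "batch": batch})
    return pd.DataFrame(rows).set_index("sample")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if phi < 1e-8:
        return rng.poisson(mean)
    return rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mean))


def simulate_counts(config: SimulationConfig, truth: TruthTable,
                    direction: str = "AxB") -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB count matrix and design for one cross direction.

    The expected count of gene g in sample s is the library size times
    the normalized product of baseline, temporal multiplier at the
    sample's DAP, tissue-mixture weight and the lognormal batch factor
    of the sample's maternal plant; counts are NB with dispersion phi.
    """
    rng = substream(config.rng_seed, f"counts-{direction}")
    design = _make_design(config, direction)
    genes = truth.genes
    n, daps = len(genes), design["dap"].to_numpy()
    mix = config.tissue_mixture_by_timepoint
    w = genes[["w_seed_coat", "w_embryo", "w_endosperm"]].to_numpy()

    mix_by_dap = {d: w @ np.asarray(mix[d]) for d in config.time_points}
    mult = truth.temporal
    batches = sorted(design["batch"].unique())
    bf = {b: rng.lognormal(0.0, config.batch_sd, size=n) if config.batch_sd > 0
          else np.ones(n) for b in batches}
    lib = np.round(rng.lognormal(np.log(config.library_size_mean),
                                 config.library_size_sigma, size=len(design)))

    base = genes["baseline"].to_numpy()
    weights = np.empty((n, len(design)))
    for j, (_, row) in enumerate(design.iterrows()):
        d = row["dap"]
        weights[:, j] = base * mult[d].to_numpy() * mix_by_dap[d] * bf[row["batch"]]
    # scale by one grand constant (not per sample) so a flat gene's expected
    # count tracks the nominal library size and stays flat across DAP;
    # realized library sizes then drift mildly with composition, as in
    # real libraries
    grand = weights.sum(axis=0).mean()
    mean = weights * (lib / grand)[None, :]
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    cdf = pd.DataFrame(counts, index=genes.index, columns=design.index)
    return cdf, design


# ---------------------------------------------------------------------------
# allele counts

def _beta_binomial(rng: np.random.Generator, n: np.ndarray, f: np.ndarray,
                   rho: float) -> np.ndarray:
    """Vectorized beta-binomial draws with per-element mean fraction."""
    n = np.asarray(n, dtype=np.int64)
    f = np.broadcast_to(np.asarray(f, dtype=float), n.shape)
    out = np.zeros_like(n)
    lo, hi = f <= 0.0, f >= 1.0
    mid = ~lo & ~hi
    if mid.any():
        if rho <= 0.0:
            p = f[mid]
        else:
            a = f[mid] * (1.0 - rho) / rho
            b = (1.0 - f[mid]) * (1.0 - rho) / rho
            p = rng.beta(a, b)
        out[mid] = rng.binomial(n[mid], p)
    out[hi] = n[hi]
    return out


def _maternal_fraction_vector(
    status: np.ndarray,
    tissue_weights: np.ndarray,
    proportions: tuple[float, float, float],
    direction: str,
    leakage: float,
    ase_ratio: float,
) -> np.ndarray:
    """Vectorized whole-seed maternal fraction per gene (see
    :func:`seedimprint.allelic.expected_maternal_fraction`)."""
    n = len(status)
    m = np.empty((n, 3))
    m[:, 0] = 1.0  # seed coat
    for col, (cm, cp) in ((1, (1, 1)), (2, (2, 1))):
        base = cm / (cm + cp)
        mt = np.full(n, base)
        if col == 2:
            mt[status == "PEG"] = leakage
            mt[status == "MEG"] = 1.0 - leakage
        maternal_line = "A" if direction == "AxB" else "B"
        fav_mat = status == f"ASE_line{maternal_line}"
        fav_pat = (status == "ASE_lineA") | (status == "ASE_lineB")
        fav_pat &= ~fav_mat
        mt[fav_mat] = cm * ase_ratio / (cm * ase_ratio + cp)
        mt[fav_pat] = cm / (cm + cp * ase_ratio)
        m[:, col] = mt
    p = np.asarray(proportions)
    num = (tissue_weights * p[None, :] * m).sum(axis=1)
    den = (tissue_weights * p[None, :]).sum(axis=1)
    return num / np.maximum(den, 1e-300)


def simulate_allele_counts(
    config: SimulationConfig,
    truth: TruthTable,
    counts: pd.DataFrame | None,
    design: pd.DataFrame | None,
    direction: str = "AxB",
    tissue: str = "whole_seed",
) -> pd.DataFrame:
    """Per-SNP line allele counts for one cross direction and tissue.

    SNP coverage is a binomial thinning of the gene's count by
    2*read_length/gene length (floor 1 when the gene is expressed); the
    maternal-line count is beta-binomial around the tissue (or
    whole-seed mixture) maternal fraction for the gene's allelic status.
    ``whole_seed`` uses the supplied count matrix at 2-8 DAP; isolated
    tissues draw their own counts at `config.isolated_dap`.
    """
    if tissue not in ("whole_seed", "seed_coat", "embryo", "endosperm"):
        raise ValueError(f"unknown tissue {tissue!r}")
    rng = substream(config.rng_seed, f"allele-{tissue}-{direction}")
    genes = truth.genes
    snps = truth.snps.sort_values(["gene_id", "chrom", "pos"]).reset_index(drop=True)
    if snps.empty:
        return pd.DataFrame(columns=ALLELE_TABLE_COLUMNS)

    gene_pos = pd.Series(np.arange(len(genes)), index=genes.index)
    snp_gene_idx = gene_pos[snps["gene_id"]].to_numpy()
    status = genes["allelic_status"].to_numpy()
    w = genes[["w_seed_coat", "w_embryo", "w_endosperm"]].to_numpy()
    p_cov = np.minimum(1.0, 2.0 * config.read_length
                       / np.maximum(genes["coding_length"].to_numpy(), 1))

    if tissue == "whole_seed":
        if counts is None or design is None:
            raise ValueError("whole-seed allele counts need the count matrix and design")
        sub = design[design["dap"] >= 2]
        counts_arr = counts.loc[genes.index, sub.index].to_numpy()
        sample_meta = [(s, row["dap"], row["replicate"]) for s, row in sub.iterrows()]
        f_by_dap = {
            d: _maternal_fraction_vector(
                status, w, config.tissue_mixture_by_timepoint[d],
                direction, config.leakage, config.ase_ratio)
            for d in sorted(sub["dap"].unique())
        }
        f_cols = [f_by_dap[d] for _, d, _ in sample_meta]
        names = [s for s, _, _ in sample_meta]
    else:
        d = config.isolated_dap
        tissue_col = {"seed_coat": 0, "embryo": 1, "endosperm": 2}[tissue]
        weight = (genes["baseline"].to_numpy() * truth.temporal[d].to_numpy()
                  * w[:, tissue_col])
        weight = np.maximum(weight, 1e-12)
        mean = config.isolated_library_size * weight / weight.sum()
        counts_arr = np.column_stack([
            _nb_draw(rng, mean, config.nb_dispersion)
            for _ in range(config.isolated_replicates)
        ])
        sample_meta = [(r, d, r) for r in range(1, config.isolated_replicates + 1)]
        f_tissue = np.array([
            tissue_maternal_fraction(tissue, st, direction=direction,
                                     leakage=config.leakage, ase_ratio=config.ase_ratio)
            for st in status
        ])
        f_cols = [f_tissue] * config.isolated_replicates
        names = [f"{tissue}_{int(d)}d_BR{r}_{direction}" for r, _, _ in sample_meta]

    frames = []
    for j, ((_, dap, rep), f_gene, name) in enumerate(zip(sample_meta, f_cols, names)):
        c = counts_arr[snp_gene_idx, j]
        cov = rng.binomial(c, p_cov[snp_gene_idx])
        cov = np.where(c > 0, np.maximum(cov, 1), 0)
        mat = _beta_binomial(rng, cov, f_gene[snp_gene_idx],
                             config.allelic_overdispersion)
        pat = cov - mat
        la, lb = (mat, pat) if direction == "AxB" else (pat, mat)
        frames.append(pd.DataFrame({
            "gene_id": snps["gene_id"], "snp_chrom": snps["chrom"],
            "snp_pos": snps["pos"], "sample": name, "dap": dap,
            "replicate": rep, "lineA_count": la, "lineB_count": lb,
            "tissue": tissue, "direction": direction,
        }))
    return pd.concat(frames, ignore_index=True)[ALLELE_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# full dataset and small special-purpose simulators

def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the complete dataset for both cross directions."""
    config = config or SimulationConfig()
    reference, gene_models, exons, variants, snps = generate_genome_and_variants(config)
    truth = generate_truth(config, gene_models, snps)
    counts, design, allele = {}, {}, {}
    for direction in ("AxB", "BxA"):
        counts[direction], design[direction] = simulate_counts(config, truth, direction)
        allele[("whole_seed", direction)] = simulate_allele_counts(
            config, truth, counts[direction], design[direction], direction, "whole_seed")
        allele[("endosperm", direction)] = simulate_allele_counts(
            config, truth, None, None, direction, "endosperm")
    return SyntheticDataset(config, reference, gene_models, exons, variants,
                            truth, counts, design, allele)


def simulate_timecourse_counts(
    n_genes: int = 2000,
    replicates: tuple[int, ...] = (4, 4, 4, 4, 4),
    time_points: tuple[float, ...] = (0, 2, 4, 6, 8),
    phi: float = 0.1,
    mean_count: float = 100.0,
    de_fraction: float = 0.0,
    fold: float = 4.0,
    step_at: float = 6,
    batch_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Small NB time-course simulator for DE calibration studies.

    Under the null every gene is flat; with `de_fraction` > 0 a random
    subset steps `fold`-fold up from `step_at` DAP onward. Returns
    (counts, design, is_de).
    """
    rng = substream(seed, "timecourse-sim")
    rows = []
    for dap, nrep in zip(time_points, replicates):
        for r in range(1, nrep + 1):
            rows.append({"sample": f"{int(dap)}d_R{r}", "dap": dap,
                         "replicate": r, "batch": f"P{r}"})
    design = pd.DataFrame(rows).set_index("sample")
    base = rng.lognormal(np.log(mean_count), 1.0, size=n_genes)
    is_de = pd.Series(rng.random(n_genes) < de_fraction,
                      index=[f"G{i + 1:05d}" for i in range(n_genes)], name="is_de")
    daps = design["dap"].to_numpy()
    mult = np.ones((n_genes, len(design)))
    mult[np.ix_(is_de.to_numpy(), daps >= step_at)] = fold
    bf = {b: rng.lognormal(0.0, batch_sd, size=n_genes) if batch_sd > 0 else np.ones(n_genes)
          for b in design["batch"].unique()}
    mean = base[:, None] * mult
    for j, (_, row) in enumerate(design.iterrows()):
        mean[:, j] = mean[:, j] * bf[row["batch"]]
    counts = _nb_draw(rng, mean, phi)
    return (pd.DataFrame(counts, index=is_de.index, columns=design.index),
            design, is_de)


def simulate_archetype_profiles(
    n_per_cluster: int = 100,
    archetypes: tuple[str, ...] = ("ovule_peak", "mid_peak", "late_rise", "flat"),
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Well-separated archetype profiles in z-score space, with truth labels."""
    rng = substream(seed, "archetype-profiles")
    rows, labels = [], []
    for k, name in enumerate(archetypes):
        prof = np.log2(np.asarray(ARCHETYPES[name]))
        sd = prof.std()
        z = (prof - prof.mean()) / (sd if sd > 0 else 1.0)
        for _ in range(n_per_cluster):
            rows.append(z + rng.normal(0.0, noise_sd, size=len(z)))
            labels.append(k)
    idx = [f"G{i + 1:05d}" for i in range(len(rows))]
    profiles = pd.DataFrame(rows, index=idx, columns=[0, 2, 4, 6, 8])
    return profiles, pd.Series(labels, index=idx, name="true_cluster")


def simulate_arbitration_observations(
    n_reads: int = 20000,
    maternal_fraction: float = 0.7,
    divergence_pi: float = 0.028,
    read_length: int = 150,
    error_rate: float = 0.01,
    max_mismatch_fraction: float = 0.04,
    seed: int = 0,
):
    """Read-level fixture for arbitration: mismatch counts of each read
    against both parental genomes.

    Each read originates from the maternal haplotype with probability
    `maternal_fraction`. Against its own parent it carries only
    sequencing errors (Poisson); against the other parent it adds the
    diagnostic-site mismatches (Poisson(pi * read length)). Returns the
    two observation frames plus the read count.
    """
    rng = substream(seed, "arbitration-reads")
    from_maternal = rng.random(n_reads) < maternal_fraction
    errors = rng.poisson(error_rate * read_length, size=n_reads)
    divergent = rng.poisson(divergence_pi * read_length, size=n_reads)
    mm_mat = errors + np.where(from_maternal, 0, divergent)
    mm_pat = errors + np.where(from_maternal, divergent, 0)
    frames = {}
    for name, mm in (("maternal", mm_mat), ("paternal", mm_pat)):
        frames[name] = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(n_reads)],
            "chrom": "chr1",
            "pos": rng.integers(0, 1_000_000, size=n_reads),
            "mismatches": mm,
            "read_length": read_length,
            "properly_paired": True,
            "unique": True,
        })
    return frames["maternal"], frames["paternal"], from_maternal


# ---------------------------------------------------------------------------
# I/O

def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write the dataset as FASTA / VCF / GFF3 / TSV / JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.reference, out / "reference.fa")
    for line, df in ds.variants.items():
        write_vcf(df, out / f"line{line}.vcf", sample=f"line{line}")
    write_gff3(ds.gene_models, ds.exons, out / "annotation.gff3")
    for direction in ds.counts:
        ds.counts[direction].to_csv(out / f"counts_{direction}.tsv", sep="\t")
        ds.design[direction].to_csv(out / f"design_{direction}.tsv", sep="\t")
    for (tissue, direction), table in ds.allele_counts.items():
        table.to_csv(out / f"allele_counts_{tissue}_{direction}.tsv", sep="\t", index=False)
    truth = {
        "genes": ds.truth.genes.reset_index().to_dict(orient="records"),
        "temporal": {g: list(map(float, row))
                     for g, row in ds.truth.temporal.iterrows()},
        "time_points": [float(t) for t in ds.config.time_points],
        "snps": ds.truth.snps.to_dict(orient="records"),
    }
    (out / "truth.json").write_text(json.dumps(truth))
    cfg = asdict(ds.config)
    cfg["tissue_mixture_by_timepoint"] = {str(k): list(v) for k, v in
                                          cfg["tissue_mixture_by_timepoint"].items()}
    (out / "config.json").write_text(json.dumps(cfg, default=float))


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_vcf(variants: pd.DataFrame, path, sample: str = "sample") -> None:
    """Minimal VCF v4.2 writer with the hard-filter INFO annotations and a
    homozygous GT field."""
    info_keys = ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP"]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for k in info_keys:
            typ = "Integer" if k == "DP" else "Float"
            fh.write(f'##INFO=<ID={k},Number=1,Type={typ},Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for _, v in variants.sort_values(["chrom", "pos"]).iterrows():
            info = ";".join(
                f"{k}={int(v[k])}" if k == "DP" else f"{k}={float(v[k]):g}"
                for k in info_keys if k in v and pd.notna(v[k])
            )
            gt = {"hom_alt": "1/1", "het": "0/1", "hom_ref": "0/0"}[v["genotype"]]
            fh.write(f"{v['chrom']}\t{int(v['pos'])}\t.\t{v['ref']}\t{v['alt']}\t"
                     f"50\tPASS\t{info}\tGT\t{gt}\n")


def write_gff3(gene_models: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    """GFF3 writer (1-based inclusive coordinates at the file boundary)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        exon_by_gene = dict(tuple(exons.groupby("gene_id")))
        for _, g in gene_models.iterrows():
            fh.write(f"{g['chrom']}\tsynthetic\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                     f"{g['strand']}\t.\tID={g['gene_id']}\n")
            for _, e in exon_by_gene[g["gene_id"]].iterrows():
                fh.write(f"{e['chrom']}\tsynthetic\texon\t{e['start'] + 1}\t{e['end']}\t.\t"
                         f"{g['strand']}\t.\tParent={g['gene_id']}\n")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_allele_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def read_gff3_genes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load gene models and exons back from GFF3 (to 0-based half-open)."""
    import pyranges

    df = pyranges.read_gff3(str(path), as_df=True)
    genes = df[df["Feature"] == "gene"]
    exons = df[df["Feature"] == "exon"]
    gene_models = pd.DataFrame({
        "gene_id": genes["ID"].to_numpy(),
        "chrom": genes["Chromosome"].astype(str).to_numpy(),
        "start": genes["Start"].to_numpy(),
        "end": genes["End"].to_numpy(),
        "strand": genes["Strand"].astype(str).to_numpy(),
    })
    exon_df = pd.DataFrame({
        "gene_id": exons["Parent"].to_numpy(),
        "chrom": exons["Chromosome"].astype(str).to_numpy(),
        "start": exons["Start"].to_numpy(),
        "end": exons["End"].to_numpy(),
    })
    return gene_models, exon_df
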