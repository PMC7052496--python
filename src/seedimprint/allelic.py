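"""Parent-of-origin and allele-of-origin analysis of per-SNP allele counts.

This module implements the core allelic-bias caller for a reciprocal cross
between two inbred lines (A and B). Seed RNA is a mixture of three tissues
with different parental genome dosages:

* seed coat — maternal sporophyte, all reads carry the maternal line's
  alleles;
* embryo — diploid, 1 maternal : 1 paternal genome copy;
* endosperm — triploid, 2 maternal : 1 paternal genome copies.

For an unimprinted, cis-neutral ("biallelic") gene the expected maternal
read fraction is therefore 1, 1/2 and 2/3 in the three tissues, and a
tissue-proportion-weighted average of those in whole seed. Imprinting
(PEG/MEG) perturbs only the endosperm fraction; cis-regulatory
allele-specific expression (ASE) multiplies one *line's* allele activity in
every tissue where both parental genomes are present.

Candidate biased genes are called from whole-seed allele-count tables with
two threshold rules (zero-maternal and paternal/maternal ratio > 2 at a
majority of SNPs), and candidates are resolved into imprinted vs
allele-specific classes using isolated-endosperm counts from both cross
directions: an imprinted gene favours the same *parent* in both directions
while a cis-ASE gene favours the same *line*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("seed_coat", "embryo", "endosperm")
#: maternal:paternal genome copy numbers per tissue
TISSUE_COPIES = {"seed_coat": (2, 0), "embryo": (1, 1), "endosperm": (2, 1)}

DIRECTIONS = ("AxB", "BxA")

#: columns required in an allele-count table
ALLELE_TABLE_COLUMNS = [
    "gene_id", "snp_chrom", "snp_pos", "sample", "dap", "replicate",
    "lineA_count", "lineB_count", "tissue", "direction",
]

ALLELIC_STATUSES = ("biallelic", "PEG", "MEG", "ASE_lineA", "ASE_lineB")


@dataclass
class MixtureModel:
    """Tissue-mixture dosage model for whole-seed allele counts.

    Parameters
    ----------
    proportions
        Mapping DAP -> (p_seed_coat, p_embryo, p_endosperm), each summing
        to 1. At 0 DAP (unfertilized ovule) the sample is 100% maternal
        tissue.
    leakage
        Residual expression of the silenced allele at an imprinted locus,
        as a fraction of full activity. Keeps ratio statistics finite.
    ase_ratio
        Allele-activity fold-change of the favoured line for cis-ASE genes.
    """

    proportions: dict[float, tuple[float, float, float]] = field(
        default_factory=lambda: {
            0: (1.00, 0.00, 0.00),
            2: (0.80, 0.05, 0.15),
            4: (0.70, 0.08, 0.22),
            6: (0.55, 0.12, 0.33),
            8: (0.45, 0.15, 0.40),
        }
    )
    leakage: float = 0.02
    ase_ratio: float = 4.0

    def __post_init__(self) -> None:
        for dap, p in self.proportions.items():
            p = tuple(float(x) for x in p)
            if len(p) != 3 or any(x < 0 or x > 1 for x in p):
                raise ValueError(f"invalid tissue proportions at DAP {dap}: {p}")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"tissue proportions at DAP {dap} sum to {sum(p)}, not 1")
            self.proportions[dap] = p
        if 0 in self.proportions and self.proportions[0] != (1.0, 0.0, 0.0):
            raise ValueError("at DAP 0 the mixture must be 100% maternal (seed coat) tissue")
        if not 0 <= self.leakage < 0.5:
            raise ValueError("leakage must be in [0, 0.5)")


def tissue_maternal_fraction(
    tissue: str,
    status: str = "biallelic",
    *,
    direction: str = "AxB",
    leakage: float = 0.02,
    ase_ratio: float = 4.0,
) -> float:
    """Expected maternal-line read fraction in one tissue.

    PEG/MEG modify only the endosperm (the maternal endosperm fraction
    collapses to `leakage` for a PEG and rises to ``1 - leakage`` for a
    MEG); a cis-ASE gene multiplies the favoured line's allele activity by
    `ase_ratio` in embryo and endosperm (the seed coat carries only
    maternal alleles, so ASE cannot move its fraction).
    """
    if tissue not in TISSUE_COPIES:
        raise ValueError(f"unknown tissue {tissue!r}")
    if status not in ALLELIC_STATUSES:
        raise ValueError(f"unknown allelic status {status!r}")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown cross direction {direction!r}")
    if tissue == "seed_coat":
        return 1.0
    cm, cp = TISSUE_COPIES[tissue]
    if status == "PEG":
        return leakage if tissue == "endosperm" else cm / (cm + cp)
    if status == "MEG":
        return 1.0 - leakage if tissue == "endosperm" else cm / (cm + cp)
    am = ap = 1.0  # allele activity of maternal / paternal copies
    if status in ("ASE_lineA", "ASE_lineB"):
        favoured = "A" if status == "ASE_lineA" else "B"
        maternal_line = "A" if direction == "AxB" else "B"
        if favoured == maternal_line:
            am = ase_ratio
        else:
            ap = ase_ratio
    num = cm * am
    return num / (num + cp * ap)


def expected_maternal_fraction(
    model: MixtureModel,
    status: str,
    timepoint: float,
    *,
    tissue_weights: tuple[float, float, float] | None = None,
    direction: str = "AxB",
) -> float:
    """Expected maternal read fraction in whole seed at a time point.

    f = sum_t p_t * mu_t * m_t / sum_t p_t * mu_t, where p_t are the tissue
    proportions at the time point, mu_t the gene's relative per-tissue
    expression (`tissue_weights`, default equal) and m_t the per-tissue
    maternal fractions for the gene's allelic status.
    """
    if timepoint not in model.proportions:
        raise ValueError(f"no tissue proportions defined for DAP {timepoint}")
    p = model.proportions[timepoint]
    mu = (1.0, 1.0, 1.0) if tissue_weights is None else tuple(tissue_weights)
    num = den = 0.0
    for tissue, p_t, mu_t in zip(TISSUES, p, mu):
        m = tissue_maternal_fraction(
            tissue, status, direction=direction,
            leakage=model.leakage, ase_ratio=model.ase_ratio,
        )
        num += p_t * mu_t * m
        den += p_t * mu_t
    if den == 0:
        raise ValueError("gene has zero expression weight in every tissue present")
    return num / den


# ---------------------------------------------------------------------------
# allele-count tables

def validate_allele_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ALLELE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allele-count table is missing columns {missing}")
    if (table[["lineA_count", "lineB_count"]] < 0).any().any():
        raise ValueError("negative allele counts")
    bad = set(table["direction"]) - set(DIRECTIONS)
    if bad:
        raise ValueError(f"unknown cross directions {bad}")
    return table


def add_parental_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Derive maternal/paternal counts from line counts and cross direction."""
    table = validate_allele_table(table).copy()
    a_maternal = table["direction"].to_numpy() == "AxB"
    la = table["lineA_count"].to_numpy()
    lb = table["lineB_count"].to_numpy()
    table["maternal_count"] = np.where(a_maternal, la, lb)
    table["paternal_count"] = np.where(a_maternal, lb, la)
    return table


def collect_snp_counts(
    assignments: pd.DataFrame,
    diagnostic_sites: pd.DataFrame,
    *,
    read_length: int = 150,
    sample: str = "S1",
    dap: float = 8,
    replicate: int = 1,
    tissue: str = "whole_seed",
    direction: str = "AxB",
) -> pd.DataFrame:
    """Aggregate arbitrated read assignments into per-SNP line counts.

    Each retained read (reference coordinates) overlapping a diagnostic
    site increments the count of the line corresponding to its arbitration
    parent. Sites that are not divergent between the lines are dropped
    with a warning; non-diagnostic positions never produce rows.
    """
    sites = diagnostic_sites.copy()
    same = sites["lineA_allele"] == sites["lineB_allele"]
    if same.any():
        warnings.warn(f"excluding {int(same.sum())} non-divergent site(s)")
        sites = sites[~same]
    rows = []
    maternal_line = "A" if direction == "AxB" else "B"
    for chrom, chrom_sites in sites.groupby("snp_chrom" if "snp_chrom" in sites else "chrom"):
        reads = assignments[assignments["chrom"] == chrom]
        if reads.empty:
            starts = np.array([], dtype=int)
        else:
            starts = np.sort(reads["pos"].to_numpy())
        parents = reads.sort_values("pos")["chosen_parent"].to_numpy() if not reads.empty else np.array([])
        pos_col = "snp_pos" if "snp_pos" in chrom_sites else "pos"
        for _, site in chrom_sites.iterrows():
            p = site[pos_col]
            lo = np.searchsorted(starts, p - read_length + 1, side="left")
            hi = np.searchsorted(starts, p, side="right")
            overlapping = parents[lo:hi]
            n_mat = int(np.sum(overlapping == "maternal"))
            n_pat = int(np.sum(overlapping == "paternal"))
            line_a = n_mat if maternal_line == "A" else n_pat
            line_b = n_pat if maternal_line == "A" else n_mat
            rows.append({
                "gene_id": site["gene_id"], "snp_chrom": chrom, "snp_pos": p,
                "sample": sample, "dap": dap, "replicate": replicate,
                "lineA_count": line_a, "lineB_count": line_b,
                "tissue": tissue, "direction": direction,
            })
    return pd.DataFrame(rows, columns=ALLELE_TABLE_COLUMNS)


def _restrict(table: pd.DataFrame, direction: str, timepoint: float | None) -> pd.DataFrame:
    table = add_parental_counts(table)
    table = table[table["direction"] == direction]
    if timepoint is not None:
        table = table[table["dap"] == timepoint]
    return table


def rule_no_maternal(
    table: pd.DataFrame,
    direction: str = "AxB",
    timepoint: float | None = None,
    min_mean_count: float = 2.0,
) -> pd.DataFrame:
    """Zero-maternal candidate rule.

    A gene is called when the maternal-line count is 0 at every SNP in
    every replicate. Genes with little overall allelic expression (mean
    per-replicate total count < `min_mean_count`) or highly variable
    expression (per-replicate SD > mean) are removed.

    Returns a per-gene frame with the intermediate statistics and a
    boolean ``called`` column; genes absent from the table are simply not
    evaluable and produce no row.
    """
    sub = _restrict(table, direction, timepoint)
    if sub.empty:
        return pd.DataFrame(columns=["gene_id", "no_maternal", "mean_total", "sd_total", "called"])
    sub = sub.assign(total=sub["maternal_count"] + sub["paternal_count"])
    per_rep = sub.groupby(["gene_id", "replicate"], sort=True)["total"].sum()
    stats = per_rep.groupby("gene_id").agg(mean_total="mean", sd_total=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
    no_mat = sub.groupby("gene_id")["maternal_count"].max().eq(0).rename("no_maternal")
    out = stats.join(no_mat).reset_index()
    out["called"] = (
        out["no_maternal"]
        & (out["mean_total"] >= min_mean_count)
        & (out["sd_total"] <= out["mean_total"])
    )
    return out


def rule_paternal_ratio(
    table: pd.DataFrame,
    direction: str = "AxB",
    timepoint: float | None = None,
    ratio_min: float = 2.0,
    min_replicates: int = 2,
    zero_denominator: str = "exclude",
) -> pd.DataFrame:
    """Paternal/maternal ratio candidate rule.

    Per SNP, the paternal/maternal count ratio is computed per replicate
    and averaged across replicates. A gene is called when (i) strictly
    more than half of its SNPs have a mean ratio > `ratio_min`, (ii) the
    SD of the per-SNP mean ratios is below their mean, and (iii) allelic
    counts are nonzero in at least `min_replicates` replicates.

    `zero_denominator` controls replicate-level ratios with a zero
    maternal count: ``"exclude"`` drops them from the across-replicate
    mean (the pure zero-maternal signal is the province of
    :func:`rule_no_maternal`); ``"pseudocount"`` uses (p+0.5)/(m+0.5).
    """
    if zero_denominator not in ("exclude", "pseudocount"):
        raise ValueError("zero_denominator must be 'exclude' or 'pseudocount'")
    sub = _restrict(table, direction, timepoint)
    cols = ["gene_id", "n_snps", "n_snps_over", "mean_ratio", "sd_ratio",
            "replicates_expressed", "called"]
    if sub.empty:
        return pd.DataFrame(columns=cols)
    m = sub["maternal_count"].to_numpy(dtype=float)
    p = sub["paternal_count"].to_numpy(dtype=float)
    if zero_denominator == "pseudocount":
        ratio = (p + 0.5) / (m + 0.5)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(m > 0, p / np.maximum(m, 1e-300), np.nan)
    sub = sub.assign(ratio=ratio, total=m + p)

    snp_mean = sub.groupby(["gene_id", "snp_chrom", "snp_pos"])["ratio"].mean()  # skipna
    per_gene = snp_mean.groupby("gene_id").agg(
        n_snps="count",
        n_snps_over=lambda x: int((x > ratio_min).sum()),
        mean_ratio="mean",
        sd_ratio=lambda x: x.std(ddof=1) if x.count() > 1 else 0.0,
    )
    reps = (
        sub.groupby(["gene_id", "replicate"])["total"].sum().gt(0)
        .groupby("gene_id").sum().rename("replicates_expressed")
    )
    out = per_gene.join(reps).reset_index()
    out["called"] = (
        (out["n_snps"] > 0)
        & (out["n_snps_over"] > out["n_snps"] / 2.0)
        & (out["sd_ratio"] < out["mean_ratio"])
        & (out["replicates_expressed"] >= min_replicates)
    )
    return out[cols]


def call_biased_genes(
    table: pd.DataFrame,
    direction: str = "AxB",
    timepoint: float | None = None,
    ratio_min: float = 2.0,
    min_mean_count: float = 2.0,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Union of the two candidate rules, tagged by the rule that fired."""
    nm = rule_no_maternal(table, direction, timepoint, min_mean_count)
    pr = rule_paternal_ratio(table, direction, timepoint, ratio_min, min_replicates)
    nm_called = set(nm.loc[nm["called"], "gene_id"])
    pr_called = set(pr.loc[pr["called"], "gene_id"])
    genes = sorted(nm_called | pr_called)
    rule = [
        "no_maternal" if g in nm_called else "paternal_ratio" for g in genes
    ]
    out = pd.DataFrame({"gene_id": genes, "rule": rule})
    return out.merge(pr[["gene_id", "mean_ratio", "n_snps"]], on="gene_id", how="left")


# ---------------------------------------------------------------------------
# reciprocal-cross classification

def _activity_ratio_lineA(line_a: float, line_b: float, direction: str) -> float:
    """Estimated allele-activity ratio A/B in isolated endosperm.

    Corrects the observed line-count ratio for the 2:1 maternal:paternal
    genome dosage: if line A is maternal the biallelic expectation of
    cA/cB is 2, if paternal it is 1/2. A pseudocount of 0.5 keeps the
    estimate finite at zero counts.
    """
    obs = (line_a + 0.5) / (line_b + 0.5)
    expected = 2.0 if direction == "AxB" else 0.5
    return obs / expected


def classify_origin(
    endosperm_table: pd.DataFrame,
    candidate_genes: list[str] | None = None,
    ratio_min: float = 2.0,
) -> pd.DataFrame:
    """Resolve candidate biased genes into imprinting vs cis-ASE classes.

    Uses isolated-endosperm allele counts from both cross directions. The
    per-direction bias statistic is the dosage-corrected allele-activity
    ratio (observed line ratio over the 2:1-dosage biallelic expectation);
    a gene whose *paternal* allele is > `ratio_min`-fold more active in
    both directions is an imprinted PEG (maternal: MEG), one whose same
    *line* is > `ratio_min`-fold more active in both directions shows
    allele-specific expression, discordant bias is ``inconsistent``, no
    bias is ``unbiased`` and a gene missing a direction is
    ``unvalidated``.
    """
    table = add_parental_counts(endosperm_table)
    table = table[table["tissue"] == "endosperm"]
    if candidate_genes is None:
        candidate_genes = sorted(table["gene_id"].unique())
    pooled = table.groupby(["gene_id", "direction"])[["lineA_count", "lineB_count"]].sum()
    rows = []
    for gene in candidate_genes:
        stats: dict[str, float] = {}
        for direction in DIRECTIONS:
            if (gene, direction) in pooled.index:
                la, lb = pooled.loc[(gene, direction)]
                stats[direction] = _activity_ratio_lineA(la, lb, direction)
        if len(stats) < 2:
            cls = "unvalidated"
            act_ab = stats.get("AxB", np.nan)
            act_ba = stats.get("BxA", np.nan)
        else:
            act_ab, act_ba = stats["AxB"], stats["BxA"]
            # paternal-line activity ratio per direction: paternal is B in AxB
            pat_ab, pat_ba = 1.0 / act_ab, act_ba
            mat_ab, mat_ba = act_ab, 1.0 / act_ba
            if pat_ab > ratio_min and pat_ba > ratio_min:
                cls = "imprinted_PEG"
            elif mat_ab > ratio_min and mat_ba > ratio_min:
                cls = "imprinted_MEG"
            elif act_ab > ratio_min and act_ba > ratio_min:
                cls = "allele_specific"  # favours line A
            elif act_ab < 1 / ratio_min and act_ba < 1 / ratio_min:
                cls = "allele_specific"  # favours line B
            elif max(act_ab, 1 / act_ab) <= ratio_min and max(act_ba, 1 / act_ba) <= ratio_min:
                cls = "unbiased"
            else:
                cls = "inconsistent"
        rows.append({
            "gene_id": gene,
            "activity_A_over_B_AxB": act_ab,
            "activity_A_over_B_BxA": act_ba,
            "classification": cls,
        })
    return pd.DataFrame(rows)
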