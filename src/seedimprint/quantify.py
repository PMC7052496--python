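"""Gene-level quantification and normalization.

Counts reads into union-exon gene models, applies the expression filter
(CPM > 1 in at least three samples), computes TMM normalization factors
(trimmed mean of M-values against a reference sample) and CPM/FPKM
expression matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def exon_union_lengths(exons: pd.DataFrame) -> pd.Series:
    """Union-exon length per gene from an exon table (0-based half-open)."""
    lengths = {}
    for gene, grp in exons.groupby("gene_id"):
        ivals = sorted(zip(grp["start"], grp["end"]))
        total = 0
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        lengths[gene] = total
    return pd.Series(lengths, name="length")


def count_genes(
    assignments: pd.DataFrame, exons: pd.DataFrame
) -> tuple[pd.Series, dict[str, int]]:
    """Count arbitrated read assignments into genes.

    A read increments exactly one gene when its (reference) position
    falls inside that gene's exon union; positions hitting the exons of
    more than one gene are discarded as ambiguous and positions hitting
    none (including unknown chromosomes) are tallied unassigned.
    """
    genes = sorted(exons["gene_id"].unique())
    counts = pd.Series(0, index=pd.Index(genes, name="gene_id"), dtype=int)
    stats = {"assigned": 0, "unassigned": 0, "ambiguous": 0}
    by_chrom = {}
    for chrom, grp in exons.groupby("chrom"):
        order = np.argsort(grp["start"].to_numpy())
        starts = grp["start"].to_numpy()[order]
        ends = grp["end"].to_numpy()[order]
        # running max of interval ends lets the back-scan stop early even
        # if intervals overlap arbitrarily
        by_chrom[chrom] = (starts, ends, grp["gene_id"].to_numpy()[order],
                           np.maximum.accumulate(ends))
    for chrom, grp in assignments.groupby("chrom"):
        if chrom not in by_chrom:
            stats["unassigned"] += len(grp)
            continue
        starts, ends, gene_ids, maxend = by_chrom[chrom]
        for pos in grp["pos"].to_numpy():
            i = np.searchsorted(starts, pos, side="right")
            hits = set()
            j = i - 1
            while j >= 0 and maxend[j] > pos:
                if starts[j] <= pos < ends[j]:
                    hits.add(gene_ids[j])
                j -= 1
            if len(hits) == 1:
                counts[hits.pop()] += 1
                stats["assigned"] += 1
            elif len(hits) > 1:
                stats["ambiguous"] += 1
            else:
                stats["unassigned"] += 1
    return counts, stats


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million; columns sum to 1e6 when sizes are column sums."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("non-positive library size")
    return counts * 1e6 / library_sizes


def cpm_filter(
    counts: pd.DataFrame, cpm_min: float = 1.0, min_samples: int = 3,
    library_sizes: pd.Series | None = None,
) -> pd.Index:
    """Genes with CPM > `cpm_min` in at least `min_samples` samples."""
    x = cpm(counts, library_sizes)
    keep = (x > cpm_min).sum(axis=1) >= min_samples
    return counts.index[keep]


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05,
) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the mean across samples. For each sample the factor is
    the weighted (inverse asymptotic variance) mean of the gene-wise
    log2-ratios against the reference, after rank-trimming `trim_m` of
    each tail of the M values and `trim_a` of each tail of the A values.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("sample with zero total count")
    y = counts.to_numpy(dtype=float)
    f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yj, nj = y[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        obs, refv = yj[ok] / nj, yr[ok] / nr
        logr = np.log2(obs / refv)
        abse = (np.log2(obs) + np.log2(refv)) / 2.0
        v = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        fin = np.isfinite(logr) & np.isfinite(abse)
        logr, abse, v = logr[fin], abse[fin], v[fin]
        n = len(logr)
        if n == 0:
            continue
        lo_l = np.floor(n * trim_m) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * trim_a) + 1
        hi_s = n + 1 - lo_s
        rl, ra = rankdata(logr), rankdata(abse)
        keep = (rl >= lo_l) & (rl <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        if keep.sum() == 0:
            continue
        w = 1.0 / v[keep]
        factors[j] = 2.0 ** (np.sum(w * logr[keep]) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (length * libsize)."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("missing or non-positive gene length")
    return counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)
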