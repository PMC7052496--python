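"""Variant hard-filtering and parental pseudo-reference construction.

An inbred parental line's filtered homozygous variants are substituted
into the reference to build a single-haplotype pseudo-reference genome,
together with an indel-aware bidirectional coordinate map (a chain of
gapless alignment blocks). Mapping RNA reads to each parental
pseudo-reference instead of the community reference reduces reference
mapping bias when the sequenced lines are diverged from it.

All coordinates are 0-based half-open internally; VCF/GFF3 I/O converts at
the boundary.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "genotype",
    "QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP",
]


def load_variants_vcf(path) -> pd.DataFrame:
    """Load a VCF into the package's variant frame.

    Keeps the first ALT allele of each record, derives the genotype class
    from the first sample's GT (hom_ref / het / hom_alt) and pulls the
    hard-filter annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum, DP)
    from INFO; absent annotations become NaN.
    """
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        if rec.gt_types is not None and len(rec.gt_types):
            gt = {0: "hom_ref", 1: "het", 3: "hom_alt"}.get(int(rec.gt_types[0]), "het")
        else:
            gt = "hom_alt"
        row = {
            "chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF,
            "alt": rec.ALT[0] if rec.ALT else rec.REF, "genotype": gt,
        }
        for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP"):
            val = rec.INFO.get(key)
            row[key] = float(val) if val is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


@dataclass
class FilterThresholds:
    """Hard-filter thresholds for called variants.

    Defaults follow common GATK germline hard-filter practice: reject
    when QD < 2, FS > 60, MQ < 20, MQRankSum < -12.5,
    ReadPosRankSum < -8, depth < 4 or depth more than `dp_high_sd`
    standard deviations above the mean depth of the input set.
    """

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 20.0
    mq_ranksum_min: float = -12.5
    readpos_ranksum_min: float = -8.0
    dp_min: float = 4
    dp_high_sd: float = 2.0
    #: fixed depth ceiling; None derives mean + dp_high_sd*SD from the input
    dp_max: float | None = None


def hard_filter_variants(
    variants: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply hard filters; return passing variants and a rejection tally.

    A variant passes iff every annotated statistic satisfies its
    threshold; missing (NaN) annotations do not reject. The depth upper
    bound is mean + `dp_high_sd`*SD computed over the input set itself.
    Each rejected variant is tallied under the first rule it fails, so
    the tally sums to the number rejected.
    """
    th = thresholds or FilterThresholds()
    df = variants
    n = len(df)
    tally_order = ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP_low", "DP_high"]
    tally = {k: 0 for k in tally_order}
    if n == 0:
        return df.copy(), tally

    def col(name):
        return pd.to_numeric(df.get(name, pd.Series(np.nan, index=df.index)), errors="coerce")

    dp = col("DP")
    if th.dp_max is not None:
        dp_hi = th.dp_max
    else:
        dp_hi = dp.mean() + th.dp_high_sd * dp.std(ddof=1) if dp.notna().any() else np.inf
    fails = {
        "QD": col("QD") < th.qd_min,
        "FS": col("FS") > th.fs_max,
        "MQ": col("MQ") < th.mq_min,
        "MQRankSum": col("MQRankSum") < th.mq_ranksum_min,
        "ReadPosRankSum": col("ReadPosRankSum") < th.readpos_ranksum_min,
        "DP_low": dp < th.dp_min,
        "DP_high": dp > dp_hi,
    }
    rejected = pd.Series(False, index=df.index)
    first_rule = pd.Series("", index=df.index)
    for rule in tally_order:
        f = fails[rule].fillna(False)
        newly = f & ~rejected
        first_rule[newly] = rule
        rejected |= f
    for rule in tally_order:
        tally[rule] = int((first_rule == rule).sum())
    return df[~rejected].copy(), tally


# ---------------------------------------------------------------------------
# coordinate map

@dataclass
class CoordinateMap:
    """Per-chromosome chain of gapless alignment blocks.

    Each block is (ref_start, pseudo_start, length) in 0-based half-open
    coordinates; gaps between consecutive blocks are deletions (reference
    bases absent from the pseudo genome) or insertions (pseudo bases
    absent from the reference).
    """

    blocks: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    def chromosomes(self) -> list[str]:
        return list(self.blocks)

    def lift(self, chrom: str, position: int, direction: str = "to_pseudo") -> tuple[int, str]:
        """Lift a position between coordinate systems.

        Returns ``(position, status)`` where status is ``"exact"`` for
        positions inside an alignment block and ``"deleted_adjacent"``
        for positions falling in a gap, in which case the nearest
        preceding conserved base is returned.
        """
        if chrom not in self.blocks:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if direction not in ("to_pseudo", "to_reference"):
            raise ValueError(f"unknown lift direction {direction!r}")
        blocks = self.blocks[chrom]
        src, dst = (0, 1) if direction == "to_pseudo" else (1, 0)
        starts = [b[src] for b in blocks]
        i = bisect_right(starts, position) - 1
        if i < 0:
            raise ValueError(f"position {position} precedes the first block on {chrom}")
        b = blocks[i]
        offset = position - b[src]
        if offset < b[2]:
            return b[dst] + offset, "exact"
        return b[dst] + b[2] - 1, "deleted_adjacent"

    def total_lengths(self, chrom: str) -> tuple[int, int]:
        """(reference span, pseudo span) covered by the chain, gaps included."""
        blocks = self.blocks[chrom]
        last = blocks[-1]
        return last[0] + last[2], last[1] + last[2]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "ref_start": r, "pseudo_start": p, "length": n}
            for c, bl in self.blocks.items()
            for r, p, n in bl
        ]
        return pd.DataFrame(rows, columns=["chrom", "ref_start", "pseudo_start", "length"])

    def write_chain_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_chain_tsv(cls, path) -> "CoordinateMap":
        df = pd.read_csv(path, sep="\t")
        blocks: dict[str, list[tuple[int, int, int]]] = {}
        for _, row in df.iterrows():
            blocks.setdefault(str(row["chrom"]), []).append(
                (int(row["ref_start"]), int(row["pseudo_start"]), int(row["length"]))
            )
        return cls(blocks)


def build_pseudoreference(
    reference: dict[str, str], variants: pd.DataFrame
) -> tuple[dict[str, str], CoordinateMap]:
    """Substitute homozygous-alt variants into the reference.

    SNVs replace bases in place; indels shift downstream coordinates and
    open gaps in the coordinate map. Variants are applied per chromosome
    in descending coordinate order so earlier edits cannot invalidate
    later coordinates. Heterozygous variants are skipped with a warning
    (a pseudo-reference is a single haplotype); overlapping variants are
    an error.
    """
    pseudo: dict[str, str] = {}
    cmap = CoordinateMap()
    if len(variants):
        het = variants["genotype"] == "het"
        if het.any():
            warnings.warn(f"skipping {int(het.sum())} heterozygous variant(s)")
            variants = variants[~het]
        hom_ref = variants["genotype"] == "hom_ref"
        variants = variants[~hom_ref]
    for chrom, seq in reference.items():
        vs = variants[variants["chrom"] == chrom].sort_values("pos") if len(variants) else variants
        records = []
        prev_end = -1
        prev_pos = None
        for _, v in vs.iterrows():
            pos0 = int(v["pos"]) - 1  # VCF is 1-based
            ref_a, alt_a = str(v["ref"]), str(v["alt"])
            if pos0 < 0 or pos0 + len(ref_a) > len(seq):
                raise ValueError(f"variant at {chrom}:{v['pos']} outside chromosome bounds")
            if seq[pos0:pos0 + len(ref_a)] != ref_a:
                raise ValueError(f"reference mismatch for variant at {chrom}:{v['pos']}")
            if pos0 < prev_end:
                raise ValueError(
                    f"overlapping variants on {chrom}: positions {prev_pos} and {v['pos']}"
                )
            prev_end = pos0 + len(ref_a)
            prev_pos = int(v["pos"])
            records.append((pos0, ref_a, alt_a))

        new_seq = seq
        for pos0, ref_a, alt_a in reversed(records):
            new_seq = new_seq[:pos0] + alt_a + new_seq[pos0 + len(ref_a):]
        pseudo[chrom] = new_seq

        # chain blocks: SNVs are length-preserving, only indels break blocks
        blocks = []
        ref_cur = pseudo_cur = 0
        for pos0, ref_a, alt_a in records:
            if len(ref_a) == len(alt_a):
                continue
            shared = min(len(ref_a), len(alt_a))
            seg_end = pos0 + shared
            length = seg_end - ref_cur
            blocks.append((ref_cur, pseudo_cur, length))
            ref_cur = seg_end
            pseudo_cur += length
            if len(ref_a) > len(alt_a):
                ref_cur += len(ref_a) - len(alt_a)  # deletion
            else:
                pseudo_cur += len(alt_a) - len(ref_a)  # insertion
        blocks.append((ref_cur, pseudo_cur, len(seq) - ref_cur))
        cmap.blocks[chrom] = blocks
        if len(new_seq) != pseudo_cur + (len(seq) - ref_cur):
            raise AssertionError("pseudo length inconsistent with coordinate map")
    return pseudo, cmap


def snv_differences(ref_seq: str, alt_seq: str) -> list[tuple[int, str, str]]:
    """Positions (1-based) where two equal-length sequences differ."""
    if len(ref_seq) != len(alt_seq):
        raise ValueError("sequences differ in length; SNV comparison only")
    a = np.frombuffer(ref_seq.encode(), dtype="S1")
    b = np.frombuffer(alt_seq.encode(), dtype="S1")
    idx = np.nonzero(a != b)[0]
    return [(int(i) + 1, ref_seq[i], alt_seq[i]) for i in idx]


def coding_divergence(
    lineA_variants: pd.DataFrame,
    lineB_variants: pd.DataFrame,
    coding_intervals: pd.DataFrame,
    covered_sites: int | None = None,
) -> float:
    """Pairwise per-site divergence between two lines over coding sites.

    pi = (# coding sites where the two lines carry different alleles) /
    (# covered coding sites). Only single-nucleotide substitutions are
    counted; `coding_intervals` has columns chrom/start/end (0-based
    half-open). When `covered_sites` is None every coding site is assumed
    covered.
    """
    if covered_sites is None:
        covered_sites = int((coding_intervals["end"] - coding_intervals["start"]).sum())
    if covered_sites <= 0:
        raise ValueError("zero covered coding sites: divergence undefined")

    def snv_alleles(df: pd.DataFrame) -> dict[tuple[str, int], str]:
        out = {}
        if not len(df):
            return out
        snv = df[(df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)]
        snv = snv[snv["genotype"] == "hom_alt"]
        for chrom, grp in snv.groupby("chrom"):
            ivals = coding_intervals[coding_intervals["chrom"] == chrom]
            if ivals.empty:
                continue
            starts = ivals["start"].to_numpy()
            ends = ivals["end"].to_numpy()
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            pos0 = grp["pos"].to_numpy() - 1
            idx = np.searchsorted(starts, pos0, side="right") - 1
            inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
            for p0, alt, ok in zip(pos0, grp["alt"], inside):
                if ok:
                    out[(chrom, int(p0))] = alt
        return out

    alle_a = snv_alleles(lineA_variants)
    alle_b = snv_alleles(lineB_variants)
    sites = set(alle_a) | set(alle_b)
    n_diff = sum(1 for s in sites if alle_a.get(s) != alle_b.get(s))
    return n_diff / covered_sites


def expected_residual_heterozygosity(generations: int = 5, initial: float = 1.0) -> float:
    """Expected heterozygosity remaining after `generations` of selfing.

    Each selfing generation halves heterozygosity, so a line formed by g
    generations of self-fertilization retains at most ``initial * 2**-g``
    of its founder's heterozygosity (as a fraction); five generations
    leave about 3%.
    """
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return initial * 0.5 ** generations
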