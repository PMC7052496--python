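"""Best-of-two-genomes read arbitration.

The same reads are aligned separately to the maternal and paternal
pseudo-references; alignments are filtered to properly-paired, uniquely
mapped reads within a mismatch budget, and each read is then assigned to
the parent in which it aligns with fewer mismatches ("mapping quality"
is operationalized strictly as the mismatch count). Reads mapping to
only one parent are retained as-is; ties follow a configurable policy.
Chosen coordinates can be lifted back to the community reference through
each parent's coordinate map.

Alignments are represented as plain DataFrames (one row per read per
parent) and can be loaded from SAM (NM tag = mismatches, flag 0x2 =
properly paired) or from a 7-column TSV observation format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .pseudoref import CoordinateMap

OBS_COLUMNS = [
    "read_id", "chrom", "pos", "mismatches", "read_length",
    "properly_paired", "unique",
]

TIE_POLICIES = ("random", "maternal", "drop")


def read_sam_observations(path, unique_mapq: int = 1) -> pd.DataFrame:
    """Load alignment observations from a SAM/BAM file.

    Mismatches come from the NM tag; ``properly_paired`` from flag 0x2;
    an alignment is ``unique`` when it is neither secondary nor
    supplementary and has MAPQ >= `unique_mapq`.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            rows.append({
                "read_id": aln.query_name,
                "chrom": aln.reference_name,
                "pos": aln.reference_start,
                "mismatches": aln.get_tag("NM") if aln.has_tag("NM") else 0,
                "read_length": aln.query_length or len(aln.query_sequence or ""),
                "properly_paired": aln.is_proper_pair,
                "unique": (not aln.is_secondary and not aln.is_supplementary
                           and aln.mapping_quality >= unique_mapq),
            })
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def read_observations_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns {missing}")
    return df


def filter_alignments(observations: pd.DataFrame, max_mismatch_fraction: float = 0.04) -> pd.DataFrame:
    """Retain properly-paired, unique alignments within the mismatch budget.

    A read of length L is retained when mismatches <= L * fraction
    (inclusive at the boundary, e.g. 6 mismatches in a 150 bp read at
    fraction 0.04).
    """
    obs = observations
    if (obs["read_length"] <= 0).any():
        raise ValueError("non-positive read length")
    keep = (
        obs["properly_paired"].astype(bool)
        & obs["unique"].astype(bool)
        & (obs["mismatches"] <= max_mismatch_fraction * obs["read_length"])
    )
    return obs[keep].copy()


def arbitrate(
    maternal_obs: pd.DataFrame,
    paternal_obs: pd.DataFrame,
    tie_policy: str = "random",
    seed: int = 0,
    maternal_map: CoordinateMap | None = None,
    paternal_map: CoordinateMap | None = None,
) -> pd.DataFrame:
    """Merge per-parent alignments into one assignment per read.

    A read present in only one parent keeps that parent; a read present
    in both goes to the parent with fewer mismatches. Equal mismatch
    counts follow `tie_policy`: ``"random"`` (seeded uniform),
    ``"maternal"``, or ``"drop"``. When coordinate maps are supplied the
    chosen position is lifted to reference coordinates.
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    for name, obs in (("maternal", maternal_obs), ("paternal", paternal_obs)):
        if obs["read_id"].duplicated().any():
            dup = obs.loc[obs["read_id"].duplicated(), "read_id"].iloc[0]
            raise ValueError(f"read {dup!r} appears twice in the {name} observations")

    m = maternal_obs.set_index("read_id")
    p = paternal_obs.set_index("read_id")
    merged = m.join(p, how="outer", lsuffix="_m", rsuffix="_p")
    mm = merged["mismatches_m"].to_numpy(dtype=float)
    mp = merged["mismatches_p"].to_numpy(dtype=float)
    has_m, has_p = ~np.isnan(mm), ~np.isnan(mp)

    choose_m = has_m & (~has_p | (mm < mp))
    choose_p = has_p & (~has_m | (mp < mm))
    tie = has_m & has_p & (mm == mp)
    if tie_policy == "maternal":
        choose_m |= tie
    elif tie_policy == "random":
        rng = substream(seed, "arbitration-ties")
        coin = rng.random(len(merged)) < 0.5
        choose_m |= tie & coin
        choose_p |= tie & ~coin
    # "drop": ties assigned to neither parent

    rows = []
    for i, (read_id, row) in enumerate(merged.iterrows()):
        if choose_m[i]:
            parent, cmap = "maternal", maternal_map
            chrom, pos = row["chrom_m"], row["pos_m"]
        elif choose_p[i]:
            parent, cmap = "paternal", paternal_map
            chrom, pos = row["chrom_p"], row["pos_p"]
        else:
            continue
        pos = int(pos)
        if cmap is not None:
            pos, _ = cmap.lift(chrom, pos, "to_reference")
        rows.append({
            "read_id": read_id,
            "chosen_parent": parent,
            "chrom": chrom,
            "pos": pos,
            "mismatches_maternal": mm[i] if has_m[i] else np.nan,
            "mismatches_paternal": mp[i] if has_p[i] else np.nan,
            "tie_flag": bool(tie[i]),
        })
    return pd.DataFrame(
        rows,
        columns=["read_id", "chosen_parent", "chrom", "pos",
                 "mismatches_maternal", "mismatches_paternal", "tie_flag"],
    )


def mapping_stats(
    merged: pd.DataFrame,
    n_total_reads: int,
    n_maternal_retained: int | None = None,
    n_paternal_retained: int | None = None,
) -> dict[str, float]:
    """Properly-paired uniquely-mapped fractions per parent and merged.

    Merging is best-of-two, so the merged rate is >= each single-parent
    rate whenever the tie policy does not drop reads.
    """
    if n_total_reads <= 0:
        raise ValueError("mapping rates undefined for zero reads")
    out = {"merged_rate": len(merged) / n_total_reads}
    if n_maternal_retained is not None:
        out["maternal_rate"] = n_maternal_retained / n_total_reads
    if n_paternal_retained is not None:
        out["paternal_rate"] = n_paternal_retained / n_total_reads
    return out
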