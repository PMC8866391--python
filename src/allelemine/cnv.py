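"""Copy-number estimation from capture read counts.

Read counts over a gene's captured coding region are normalised per kilobase
of target and per million mapped reads (rpkm), then expressed as a ratio to a
genotype known to carry a single copy of the locus.  Because the comparison is
within one locus across genotypes, no GC-bias correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CaptureTargetSet

DEFAULT_MULTI_COPY_THRESHOLD = 1.75
DEFAULT_ABSENCE_THRESHOLD = 0.1
DEFAULT_CONTROL_BOUNDS = (0.5, 1.75)


class CNVError(ValueError):
    pass


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    gene_id: str
    rpkm: float
    cn_ratio: float
    cn_class: int
    multi_copy: bool


def rpkm(raw_count: float, captured_len: int, total_mapped: int) -> float:
    """Reads per kilobase of captured target per million mapped reads."""
    if captured_len <= 0:
        raise CNVError("captured_len must be positive")
    if total_mapped <= 0:
        raise CNVError("empty library: total_mapped must be positive")
    return raw_count / ((captured_len / 1e3) * (total_mapped / 1e6))


def cn_ratio(sample_rpkm: float, reference_rpkm: float) -> float:
    """Copy number as rpkm relative to a single-copy reference genotype."""
    if reference_rpkm <= 0:
        raise CNVError("reference gene not captured (reference rpkm is 0)")
    return sample_rpkm / reference_rpkm


def classify_cn(ratio: float, multi_copy_threshold: float = DEFAULT_MULTI_COPY_THRESHOLD) -> tuple[int, bool]:
    """Discretise a continuous copy-number ratio.

    Round half up, floored at zero; ``multi_copy`` flags ratios at or above
    the threshold (default 1.75), i.e. genotypes carrying two or more copies.
    """
    if ratio < 0:
        raise CNVError("cn_ratio must be non-negative")
    cn_class = max(0, int(np.floor(ratio + 0.5)))
    return cn_class, ratio >= multi_copy_threshold


def presence_absence(
    sample_rpkm: float,
    reference_rpkm: float,
    absence_threshold: float = DEFAULT_ABSENCE_THRESHOLD,
) -> str:
    """Call a locus present or absent from its normalised read count.

    Used for loci whose major variation is complete deletion (the
    vernalization repressor locus): absence is a copy-number ratio below
    the threshold (default 0.1, far below single-copy noise).
    """
    return "absent" if cn_ratio(sample_rpkm, reference_rpkm) < absence_threshold else "present"


def aggregate_target_counts(
    counts: pd.DataFrame, targets: CaptureTargetSet
) -> pd.DataFrame:
    """Sum per-target read counts to per-gene counts.

    ``counts`` has columns sample_id, target_id, count.  Returns columns
    sample_id, gene_id, raw_count.  Counts are pooled over all capture
    targets of a gene before any normalisation.
    """
    gene_of = {t.target_id: t.gene_id for t in targets.targets}
    unknown = set(counts["target_id"]) - set(gene_of)
    if unknown:
        raise CNVError(f"counts reference unknown targets: {sorted(unknown)[:5]}")
    df = counts.copy()
    df["gene_id"] = df["target_id"].map(gene_of)
    out = (
        df.groupby(["sample_id", "gene_id"], as_index=False)["count"]
        .sum()
        .rename(columns={"count": "raw_count"})
    )
    return out


def gene_copy_number(
    counts: pd.DataFrame,
    targets: CaptureTargetSet,
    gene_id: str,
    reference_sample_id: str,
    total_mapped: pd.Series | dict,
    multi_copy_threshold: float = DEFAULT_MULTI_COPY_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample copy-number estimates for one gene.

    ``counts`` has columns sample_id, gene_id, raw_count (use
    :func:`aggregate_target_counts` for per-target input);  ``total_mapped``
    maps sample_id to library size.  Returns a DataFrame with columns
    sample_id, gene_id, raw_count, rpkm, cn_ratio, cn_class, multi_copy.
    """
    captured_len = targets.gene_length(gene_id)
    if captured_len == 0:
        raise CNVError(f"gene {gene_id!r} absent from capture target set")
    sub = counts[counts["gene_id"] == gene_id]
    if reference_sample_id not in set(sub["sample_id"]):
        raise CNVError(
            f"reference sample {reference_sample_id!r} has no counts for {gene_id}"
        )
    tm = dict(total_mapped) if not isinstance(total_mapped, dict) else total_mapped
    rows = []
    for rec in sub.itertuples():
        sample_rpkm = rpkm(rec.raw_count, captured_len, int(tm[rec.sample_id]))
        rows.append((rec.sample_id, gene_id, rec.raw_count, sample_rpkm))
    df = pd.DataFrame(rows, columns=["sample_id", "gene_id", "raw_count", "rpkm"])
    ref_rpkm = float(df.loc[df["sample_id"] == reference_sample_id, "rpkm"].iloc[0])
    if ref_rpkm <= 0:
        raise CNVError("reference gene not captured (reference rpkm is 0)")
    df["cn_ratio"] = df["rpkm"] / ref_rpkm
    classes = df["cn_ratio"].map(lambda r: classify_cn(r, multi_copy_threshold))
    df["cn_class"] = [c for c, _ in classes]
    df["multi_copy"] = [m for _, m in classes]
    return df


def rpkm_table(
    counts: pd.DataFrame,
    targets: CaptureTargetSet,
    gene_id: str,
    total_mapped: pd.Series | dict,
) -> pd.DataFrame:
    """Per-sample normalised read counts for one gene, without a reference
    ratio — for loci the reference genotype itself lacks."""
    captured_len = targets.gene_length(gene_id)
    if captured_len == 0:
        raise CNVError(f"gene {gene_id!r} absent from capture target set")
    tm = dict(total_mapped) if not isinstance(total_mapped, dict) else total_mapped
    sub = counts[counts["gene_id"] == gene_id]
    rows = [
        (r.sample_id, gene_id, r.raw_count,
         rpkm(r.raw_count, captured_len, int(tm[r.sample_id])))
        for r in sub.itertuples()
    ]
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "raw_count", "rpkm"])


def copy_number_table(
    counts: pd.DataFrame,
    targets: CaptureTargetSet,
    genes: list[str],
    reference_sample_id: str,
    total_mapped: pd.Series | dict,
    multi_copy_threshold: float = DEFAULT_MULTI_COPY_THRESHOLD,
) -> pd.DataFrame:
    """Copy-number estimates for several genes, concatenated long-form."""
    return pd.concat(
        [
            gene_copy_number(
                counts, targets, g, reference_sample_id, total_mapped,
                multi_copy_threshold,
            )
            for g in genes
        ],
        ignore_index=True,
    )


def control_gene_qc(
    cn_table: pd.DataFrame,
    control_gene_ids: list[str],
    bounds: tuple[float, float] = DEFAULT_CONTROL_BOUNDS,
) -> pd.DataFrame:
    """Flag samples whose single-copy control genes drift in copy number.

    Returns one row per sample with per-control max observed ratio and a
    ``flagged`` boolean; with an empty control list every sample passes and a
    ``no controls`` warning row is encoded via the ``note`` column.
    """
    samples = sorted(cn_table["sample_id"].unique())
    if not control_gene_ids:
        return pd.DataFrame(
            {
                "sample_id": samples,
                "max_control_ratio": np.nan,
                "flagged": False,
                "note": "no controls",
            }
        )
    lo, hi = bounds
    sub = cn_table[cn_table["gene_id"].isin(control_gene_ids)]
    missing = set(control_gene_ids) - set(sub["gene_id"])
    if missing:
        raise CNVError(f"control genes missing from table: {sorted(missing)}")
    per_sample = sub.groupby("sample_id")["cn_ratio"]
    stats = per_sample.agg(["max", "min"]).reindex(samples)
    flagged = (stats["max"] > hi) | (stats["min"] < lo)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "max_control_ratio": stats["max"].to_numpy(),
            "flagged": flagged.to_numpy(),
            "note": "",
        }
    )
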