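"""End-to-end allele-mining pipeline over a panel directory.

Wires the stages together on the standard input files (BED targets, VCF
calls, count TSV, deletion TSV, metadata TSV, frost TSV): copy-number
estimation with control-gene QC, VRN-H2 presence/absence, paralog
haplotyping at the collapsed CBF2 locus, deletion-haplotype classification
and growth-habit prediction at VRN-H1, diversity statistics, and the
frost-association regression.  Runs truth-blind; recovery scoring against a
synthetic truth tree is the caller's business.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv, diversity, paralogs, phenotype, svhap
from .io import (
    CaptureTargetSet,
    VariantTable,
    load_capture_targets,
    load_sample_metadata,
    load_variants,
)
from .simulate import (
    ALL_COUNT_GENES,
    CBF14_CONTIG,
    CBF2_CONTIG,
    CBF2_GENE_START,
    CBF2_PARALOG_GENE,
    CNV_GENES,
    CONTROL_GENES,
    REFERENCE_SAMPLE,
    VRN1_CONTIG,
    VRN1_CONTIG_LEN,
    VRN2_GENE,
    default_catalog,
    default_regions,
    default_signature,
)


def snp_haplotype_factor(variants: VariantTable, contig: str) -> pd.Series:
    """Haplotype labels from the allele combination at one locus's SNPs.

    Homozygous calls map to their allele code; a sample with any missing or
    heterozygous call at the locus is labelled "NA".
    """
    sub = variants.for_contig(contig)
    labels = []
    for j, sample in enumerate(sub.samples):
        col = sub.gt[:, j]
        if ((col != 0) & (col != 2)).any():
            labels.append("NA")
        else:
            labels.append("hap_" + "".join("01"[int(c == 2)] for c in col))
    return pd.Series(labels, index=pd.Index(sub.samples, name="sample_id"))


@dataclass
class PipelineResult:
    cn_table: pd.DataFrame
    qc: pd.DataFrame
    vrn2_status: dict[str, str]
    paralog_calls: pd.DataFrame
    vrn1_table: pd.DataFrame
    diversity_stats: dict
    sfs: pd.DataFrame
    singletons: pd.DataFrame
    association: dict = field(default_factory=dict)


def run_pipeline(
    panel_dir: str | Path,
    reference_sample: str = REFERENCE_SAMPLE,
    min_ab: float = paralogs.DEFAULT_MIN_AB,
    tolerance_bp: int = svhap.DEFAULT_BREAKPOINT_TOLERANCE,
    alpha: float = phenotype.DEFAULT_ALPHA,
) -> PipelineResult:
    """Run every stage on the files under ``panel_dir``/inputs."""
    inp = Path(panel_dir) / "inputs"
    targets = load_capture_targets(inp / "targets.bed")
    metadata = load_sample_metadata(inp / "samples.tsv")
    counts = pd.read_csv(inp / "counts.tsv", sep="\t")
    variants = load_variants(inp / "calls.vcf")
    deletions = svhap.load_deletion_calls(inp / "deletions.tsv")
    frost = pd.read_csv(inp / "frost.tsv", sep="\t")
    return run_stages(
        targets, metadata, counts, variants, deletions, frost,
        reference_sample=reference_sample, min_ab=min_ab,
        tolerance_bp=tolerance_bp, alpha=alpha,
    )


def run_stages(
    targets: CaptureTargetSet,
    metadata: pd.DataFrame,
    counts: pd.DataFrame,
    variants: VariantTable,
    deletions: list,
    frost: pd.DataFrame,
    reference_sample: str = REFERENCE_SAMPLE,
    min_ab: float = paralogs.DEFAULT_MIN_AB,
    tolerance_bp: int = svhap.DEFAULT_BREAKPOINT_TOLERANCE,
    alpha: float = phenotype.DEFAULT_ALPHA,
) -> PipelineResult:
    total_mapped = dict(
        zip(metadata["sample_id"], metadata["total_mapped_reads"])
    )
    sample_ids = list(metadata["sample_id"])

    # --- copy number -------------------------------------------------------
    gene_counts = cnv.aggregate_target_counts(counts, targets)
    ratio_genes = [g for g in ALL_COUNT_GENES if g != VRN2_GENE]
    cn_table = cnv.copy_number_table(
        gene_counts, targets, ratio_genes, reference_sample, total_mapped
    )
    qc = cnv.control_gene_qc(cn_table, list(CONTROL_GENES))

    # --- VRN-H2 presence/absence ------------------------------------------
    # the single-copy reference genotype itself lacks the repressor locus,
    # so the denominator is the panel median of positive rpkm values
    vrn2 = cnv.rpkm_table(gene_counts, targets, VRN2_GENE, total_mapped)
    positive = vrn2.loc[vrn2["rpkm"] > 0, "rpkm"]
    ref_rpkm = float(positive.median()) if len(positive) else 1.0
    vrn2_status = {
        str(r.sample_id): cnv.presence_absence(r.rpkm, ref_rpkm)
        for r in vrn2.itertuples()
    }

    # --- paralog haplotyping ----------------------------------------------
    signature = default_signature()
    depth_mult = {
        str(r.sample_id): float(r.cn_ratio)
        for r in cn_table[cn_table["gene_id"] == CBF2_PARALOG_GENE].itertuples()
    }
    patterns = paralogs.extract_patterns(
        variants, signature, CBF2_GENE_START, CBF2_CONTIG, depth_mult
    )
    calls = [
        paralogs.call_paralog_haplotype(p, signature, min_ab=min_ab)
        for p in patterns
    ]
    paralog_table = paralogs.paralog_call_table(calls)

    # --- VRN-H1 deletion haplotypes + growth habit ------------------------
    catalog = default_catalog()
    regions = default_regions()
    assignments = svhap.classify_panel(
        deletions, catalog, sample_ids, tolerance_bp=tolerance_bp
    )
    vrn1_table = svhap.growth_habit_table(assignments, regions, vrn2_status)

    # --- diversity on the vernalization locus -----------------------------
    vrn1_variants = variants.for_contig(VRN1_CONTIG)
    aln = diversity.alignment_from_variants(vrn1_variants, VRN1_CONTIG_LEN)
    pruned, prune_report = diversity.prune_missing(aln, "drop_sites")
    stats_all = diversity.diversity_stats(pruned)
    cats = dict(zip(metadata["sample_id"], metadata["biological_status"]))
    bins, singletons = diversity.site_frequency_spectrum(aln, cats)
    per_category = {}
    for cat in sorted(set(cats.values())):
        members = [s for s in aln.samples if cats.get(s) == cat]
        if len(members) < 2:
            continue
        sub = diversity.AlignmentMatrix(
            members,
            pruned.codes[[pruned.samples.index(s) for s in members]],
            pruned.sites,
            pruned.length,
        )
        per_category[cat] = diversity.diversity_stats(sub)
    ts = sum(
        diversity.classify_substitution(r, a) == "transition"
        for r, a in zip(vrn1_variants.sites["ref"], vrn1_variants.sites["alt"])
    )
    div = {
        "overall": stats_all,
        "by_category": per_category,
        "prune_report": prune_report,
        "n_transitions": int(ts),
        "n_transversions": int(len(vrn1_variants.sites) - ts),
    }

    # --- frost association -------------------------------------------------
    cbf14_factor = snp_haplotype_factor(variants, CBF14_CONTIG)
    association = {}
    for temperature in sorted(frost["temperature"].unique()):
        sub = frost[frost["temperature"] == temperature]
        means = phenotype.genotype_adjusted_means(sub)
        pred = _assemble_predictors(
            means.adjusted_means, cn_table, paralog_table, vrn1_table,
            cbf14_factor,
        )
        terms = [c for c in pred.columns if c != "mean_score"]
        result = phenotype.backward_elimination(pred, "mean_score", terms, alpha=alpha)
        association[temperature] = {
            "adjusted_means": means,
            "regression": result,
        }

    return PipelineResult(
        cn_table=cn_table,
        qc=qc,
        vrn2_status=vrn2_status,
        paralog_calls=paralog_table,
        vrn1_table=vrn1_table,
        diversity_stats=div,
        sfs=diversity.sfs_table(bins),
        singletons=singletons,
        association=association,
    )


def _assemble_predictors(
    adjusted_means: pd.Series,
    cn_table: pd.DataFrame,
    paralog_table: pd.DataFrame,
    vrn1_table: pd.DataFrame,
    cbf14_factor: pd.Series | None = None,
) -> pd.DataFrame:
    """Join genetic predictors onto the genotype-adjusted frost means."""
    df = adjusted_means.rename("mean_score").to_frame()
    for gene in CNV_GENES:
        sub = cn_table[cn_table["gene_id"] == gene].set_index("sample_id")
        df[f"cn_{gene}"] = sub["cn_ratio"].reindex(df.index)
    par = paralog_table.set_index("sample_id")["haplotype_label"].reindex(df.index)
    df["cbf2_paralogs"] = par.fillna("unresolved").astype(str)
    vrn1 = vrn1_table.set_index("sample_id")["haplotype"].reindex(df.index)
    df["vrn1_haplotype"] = vrn1.fillna("unknown").astype(str)
    if cbf14_factor is not None:
        df["cbf14_haplotype"] = (
            cbf14_factor.reindex(df.index).fillna("NA").astype(str)
        )
    # single-level factors carry no information and break the design matrix
    for col in ("cbf2_paralogs", "vrn1_haplotype", "cbf14_haplotype"):
        if col in df.columns and df[col].nunique() < 2:
            df = df.drop(columns=col)
    df = df.dropna()
    return df
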