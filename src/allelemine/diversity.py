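"""Population-genetic summaries of a biallelic SNP table.

Computes nucleotide diversity (π), Watterson's θ, haplotype number and
diversity, the site-frequency spectrum decomposed by germplasm category,
transition/transversion classification, missing-data pruning, and
codon-level effect annotation of coding SNPs.  Sequences from an inbred
panel are treated as haploid consensus haplotypes; statistics are computed
on complete (pruned) data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import GT_HET, GT_HOM_ALT, GT_HOM_REF, VariantTable

ALLELE_MISSING = -1

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class DiversityError(ValueError):
    pass


@dataclass
class AlignmentMatrix:
    """Haploid allele codes (0 ref, 1 alt, −1 missing), samples × sites."""

    samples: list[str]
    codes: np.ndarray  # int8, shape (n_samples, n_sites)
    sites: pd.DataFrame  # contig, pos, ref, alt (and optionally region_class)
    length: int  # alignment length L in bp (monomorphic sites included)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.sites)):
            raise DiversityError("alignment matrix dimensions inconsistent")
        if self.length <= 0:
            raise DiversityError("alignment length must be positive")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]


def alignment_from_variants(
    table: VariantTable, length: int, het_policy: str = "missing"
) -> AlignmentMatrix:
    """Collapse diploid genotype calls to haploid consensus codes.

    Homozygous calls map to their allele; heterozygous calls (paralog
    signal, not true heterozygosity in an inbred panel) become missing by
    default, or the alternative allele with ``het_policy='alt'``.
    """
    if het_policy not in ("missing", "alt"):
        raise DiversityError(f"unknown het_policy {het_policy!r}")
    codes = np.full(table.gt.T.shape, ALLELE_MISSING, dtype=np.int8)
    gt = table.gt.T  # samples × sites
    codes[gt == GT_HOM_REF] = 0
    codes[gt == GT_HOM_ALT] = 1
    if het_policy == "alt":
        codes[gt == GT_HET] = 1
    return AlignmentMatrix(list(table.samples), codes, table.sites.copy(), length)


@dataclass(frozen=True)
class DiversityStats:
    S: int
    n: int
    L: int
    pi: float
    theta_w: float
    n_hap: int
    Hd: float


def nucleotide_diversity(aln: AlignmentMatrix) -> float:
    """π: mean pairwise differences per site over all unordered pairs."""
    if aln.n < 2:
        raise DiversityError("nucleotide diversity requires at least 2 sequences")
    if (aln.codes == ALLELE_MISSING).any():
        raise DiversityError("alignment contains missing data; prune first")
    n = aln.n
    c = aln.codes.sum(axis=0)  # alt counts per site
    diff_pairs = float((c * (n - c)).sum())
    return diff_pairs / (n * (n - 1) / 2) / aln.length


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's estimator per site: S / (a·L), a = Σ_{i=1}^{n−1} 1/i."""
    if n < 2:
        raise DiversityError("Watterson's theta requires at least 2 sequences")
    if L <= 0:
        raise DiversityError("alignment length must be positive")
    a = sum(1.0 / i for i in range(1, n))
    return S / (a * L)


def haplotype_stats(aln: AlignmentMatrix) -> tuple[int, float]:
    """Distinct haplotype count and haplotype diversity.

    Hd = n/(n−1) · (1 − Σ p_i²): the small-sample-corrected probability
    that two randomly drawn haplotypes differ.
    """
    if aln.n < 2:
        raise DiversityError("haplotype statistics require at least 2 sequences")
    if (aln.codes == ALLELE_MISSING).any():
        raise DiversityError("alignment contains missing data; prune first")
    _, counts = np.unique(aln.codes, axis=0, return_counts=True)
    n = aln.n
    p = counts / n
    hd = (n / (n - 1)) * (1.0 - float((p**2).sum()))
    return len(counts), hd


def diversity_stats(aln: AlignmentMatrix) -> DiversityStats:
    """All summary statistics of one (complete) alignment."""
    c = aln.codes.sum(axis=0)
    S = int(((c > 0) & (c < aln.n)).sum())
    n_hap, hd = haplotype_stats(aln)
    return DiversityStats(
        S=S,
        n=aln.n,
        L=aln.length,
        pi=nucleotide_diversity(aln),
        theta_w=watterson_theta(S, aln.n, aln.length),
        n_hap=n_hap,
        Hd=hd,
    )


def prune_missing(
    aln: AlignmentMatrix,
    strategy: str = "drop_sites",
    max_missing: float = 0.2,
) -> tuple[AlignmentMatrix, dict]:
    """Remove missing data before diversity analysis.

    ``drop_sites`` removes every site with one or more missing calls (the
    prune-then-analyse order used for per-gene diversity);
    ``drop_samples_then_sites`` first drops samples whose missing fraction
    exceeds ``max_missing``, then drops remaining incomplete sites.
    Returns the pruned alignment and a report of removed ids.
    """
    if strategy not in ("drop_sites", "drop_samples_then_sites"):
        raise DiversityError(f"unknown pruning strategy {strategy!r}")
    miss = aln.codes == ALLELE_MISSING
    removed_samples: list[str] = []
    codes, samples = aln.codes, list(aln.samples)
    if strategy == "drop_samples_then_sites" and aln.n_sites > 0:
        frac = miss.mean(axis=1)
        keep = frac <= max_missing
        removed_samples = [s for s, k in zip(samples, keep) if not k]
        codes = codes[keep]
        samples = [s for s, k in zip(samples, keep) if k]
        miss = codes == ALLELE_MISSING
    site_keep = ~miss.any(axis=0) if len(samples) else np.zeros(aln.n_sites, bool)
    removed_sites = aln.sites.index[~site_keep].tolist()
    pruned = AlignmentMatrix(
        samples, codes[:, site_keep], aln.sites.loc[site_keep], aln.length
    )
    if pruned.n == 0 or (aln.n_sites > 0 and pruned.n_sites == 0 and miss.all()):
        raise DiversityError("no data survives pruning")
    report = {
        "removed_samples": removed_samples,
        "removed_sites": removed_sites,
        "n_sites_kept": pruned.n_sites,
    }
    return pruned, report


@dataclass
class SfsBin:
    low: float
    high: float
    count: int
    by_category: dict[str, float]


def site_frequency_spectrum(
    aln: AlignmentMatrix,
    categories: Mapping[str, str],
    bin_width: float = 0.05,
) -> tuple[list[SfsBin], pd.DataFrame]:
    """Alternative-allele frequency spectrum with category decomposition.

    Frequencies are computed over non-missing calls; monomorphic sites are
    excluded.  Bins are left-closed right-open ([0.95, 1.0] closed at the
    top).  Each polymorphic site contributes 1 to its bin, split across
    germplasm categories in proportion to the categories of the samples
    carrying the alternative allele.  Also returns a singleton report
    attributing each singleton (alt allele in exactly one sample) to its
    carrier's category.
    """
    cats = np.array([categories.get(s, "unknown") for s in aln.samples])
    cat_levels = sorted(set(cats))
    n_bins = int(round(1.0 / bin_width))
    bins = [
        SfsBin(i * bin_width, (i + 1) * bin_width, 0, {c: 0.0 for c in cat_levels})
        for i in range(n_bins)
    ]
    singleton_rows = []
    for j in range(aln.n_sites):
        col = aln.codes[:, j]
        known = col != ALLELE_MISSING
        n_known = int(known.sum())
        if n_known == 0:
            continue
        n_alt = int((col[known] == 1).sum())
        if n_alt == 0 or n_alt == n_known:
            continue
        freq = n_alt / n_known
        idx = min(int(freq / bin_width), n_bins - 1)
        bins[idx].count += 1
        carriers = cats[(col == 1)]
        for c in carriers:
            bins[idx].by_category[c] += 1.0 / len(carriers)
        if n_alt == 1:
            carrier_idx = int(np.flatnonzero(col == 1)[0])
            singleton_rows.append(
                {
                    "site_index": j,
                    "carrier": aln.samples[carrier_idx],
                    "category": cats[carrier_idx],
                }
            )
    singletons = pd.DataFrame(
        singleton_rows, columns=["site_index", "carrier", "category"]
    )
    return bins, singletons


def sfs_table(bins: Sequence[SfsBin]) -> pd.DataFrame:
    cats = sorted({c for b in bins for c in b.by_category})
    return pd.DataFrame(
        [
            {
                "freq_low": b.low,
                "freq_high": b.high,
                "count": b.count,
                **{c: b.by_category.get(c, 0.0) for c in cats},
            }
            for b in bins
        ]
    )


def classify_substitution(ref: str, alt: str) -> str:
    """Purine↔purine / pyrimidine↔pyrimidine changes are transitions."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise DiversityError(f"not a SNP: {ref}>{alt}")
    if ref == alt:
        raise DiversityError("ref and alt alleles are identical")
    return "transition" if (ref, alt) in TRANSITIONS else "transversion"


@dataclass
class CdsModel:
    """Spliced coding-sequence model for effect annotation."""

    contig: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, ascending
    strand: str = "+"
    gene_start: int | None = None  # gene span for up/downstream subclassing
    gene_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(tuple(e) for e in self.exons))
        if self.strand not in "+-":
            raise DiversityError(f"invalid strand {self.strand!r}")
        total = sum(e - s for s, e in self.exons)
        if total % 3 != 0:
            raise DiversityError(
                f"CDS length {total} not divisible by 3"
            )
        if self.gene_start is None:
            self.gene_start = self.exons[0][0]
        if self.gene_end is None:
            self.gene_end = self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_index(self, pos: int) -> int | None:
        """Map a genomic position to its 0-based index in the spliced CDS."""
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                fwd = offset + (pos - s)
                return fwd if self.strand == "+" else self.cds_length - 1 - fwd
            offset += e - s
        return None


@dataclass(frozen=True)
class EffectAnnotation:
    kind: str  # synonymous | missense | noncoding | unclassified
    subclass: str | None = None  # intron | upstream | downstream
    residue_index: int | None = None  # 1-based from the start codon
    aa_ref: str | None = None
    aa_alt: str | None = None

    @property
    def hgvs_p(self) -> str | None:
        if self.residue_index is None:
            return None
        return f"{self.aa_ref}{self.residue_index}{self.aa_alt}"


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def annotate_effect(
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    cds: CdsModel,
    reference: Mapping[str, str],
    codon_table: str | int = "Standard",
) -> EffectAnnotation:
    """Codon-level classification of one biallelic SNP.

    SNPs outside the CDS are noncoding with an intron/upstream/downstream
    subclass; SNPs inside have their reference and alternative codons
    translated and compared.  Indels are reported unclassified.
    """
    if len(ref) != 1 or len(alt) != 1:
        return EffectAnnotation(kind="unclassified")
    if contig != cds.contig:
        return EffectAnnotation(kind="noncoding", subclass="other_contig")
    seq = reference[contig]
    if seq[pos] != ref:
        raise DiversityError(
            f"reference mismatch at {contig}:{pos}: expected {ref}, "
            f"found {seq[pos]}"
        )
    idx = cds.cds_index(pos)
    if idx is None:
        if pos < cds.gene_start:
            sub = "upstream" if cds.strand == "+" else "downstream"
        elif pos >= cds.gene_end:
            sub = "downstream" if cds.strand == "+" else "upstream"
        else:
            sub = "intron"
        return EffectAnnotation(kind="noncoding", subclass=sub)
    # spliced CDS on the coding strand
    cds_seq = "".join(seq[s:e] for s, e in cds.exons)
    alt_seq = "".join(
        seq[s:pos] + alt + seq[pos + 1 : e] if s <= pos < e else seq[s:e]
        for s, e in cds.exons
    )
    if cds.strand == "-":
        cds_seq = cds_seq.translate(_COMPLEMENT)[::-1]
        alt_seq = alt_seq.translate(_COMPLEMENT)[::-1]
    codon_i = idx // 3
    ref_codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    alt_codon = alt_seq[3 * codon_i : 3 * codon_i + 3]
    aa_ref = str(Seq(ref_codon).translate(table=codon_table))
    aa_alt = str(Seq(alt_codon).translate(table=codon_table))
    kind = "synonymous" if aa_ref == aa_alt else "missense"
    return EffectAnnotation(
        kind=kind,
        residue_index=codon_i + 1,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
    )
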