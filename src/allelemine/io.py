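"""Readers, writers and the shared data model for the allele-mining pipeline.

All genomic intervals are 0-based half-open internally; the 1-based VCF
convention is converted at the I/O boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# genotype codes used throughout the package
GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2

BIOLOGICAL_STATUSES = ("cultivar", "landrace", "wild", "unknown")
GROWTH_HABITS = ("winter", "spring", "facultative", "unknown")

METADATA_COLUMNS = [
    "sample_id",
    "biological_status",
    "growth_habit",
    "latitude",
    "longitude",
    "total_mapped_reads",
]


class PanelIOError(ValueError):
    """Malformed or inconsistent pipeline input."""


@dataclass(frozen=True)
class CaptureTarget:
    """One hybridisation-capture interval (0-based half-open)."""

    contig: str
    start: int
    end: int
    target_id: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise PanelIOError(
                f"target {self.target_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CaptureTargetSet:
    """Capture design grouped by gene; the denominator of rpkm normalisation."""

    targets: list[CaptureTarget] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.targets:
            seen.setdefault(t.gene_id, None)
        return list(seen)

    def targets_of(self, gene_id: str) -> list[CaptureTarget]:
        return [t for t in self.targets if t.gene_id == gene_id]

    def gene_length(self, gene_id: str) -> int:
        """Total captured length (bp) of a gene, summed over its targets."""
        return sum(t.length for t in self.targets_of(gene_id))

    def gene_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.targets:
            out[t.gene_id] = out.get(t.gene_id, 0) + t.length
        return out

    def validate(self) -> None:
        """Reject overlapping targets within one gene."""
        by_gene: dict[str, list[CaptureTarget]] = {}
        for t in self.targets:
            by_gene.setdefault(t.gene_id, []).append(t)
        for gene, ts in by_gene.items():
            ts = sorted(ts, key=lambda t: (t.contig, t.start))
            for a, b in zip(ts, ts[1:]):
                if a.contig == b.contig and b.start < a.end:
                    raise PanelIOError(
                        f"gene {gene}: overlapping targets "
                        f"{a.target_id} [{a.start},{a.end}) and "
                        f"{b.target_id} [{b.start},{b.end})"
                    )

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.targets:
                fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.target_id}\n")


def load_capture_targets(
    path: str | Path,
    gene_map: Mapping[str, str] | None = None,
) -> CaptureTargetSet:
    """Read a 4+ column BED of capture targets.

    The gene of each target is taken from ``gene_map[target_id]`` when a
    mapping is supplied, otherwise derived from the BED name column by
    stripping a trailing ``_<n>`` target index (``HvCBF2a_1`` -> ``HvCBF2a``).
    """
    targets: list[CaptureTarget] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelIOError(f"{path}: malformed BED line {lineno}: {line!r}")
            contig, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PanelIOError(
                    f"{path}: malformed BED line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) >= 4 else None
            if gene_map is not None and name is not None and name in gene_map:
                gene_id = gene_map[name]
            elif name is not None:
                base, _, tail = name.rpartition("_")
                gene_id = base if base and tail.isdigit() else name
            else:
                raise PanelIOError(
                    f"{path}: line {lineno}: gene_id unresolvable "
                    "(no name column and no gene_map)"
                )
            target_id = name if name is not None else f"target_{lineno}"
            try:
                targets.append(
                    CaptureTarget(contig, start, end, target_id, gene_id)
                )
            except PanelIOError as exc:
                raise PanelIOError(f"{path}: line {lineno}: {exc}") from exc
    tset = CaptureTargetSet(targets)
    tset.validate()
    return tset


class VariantTable:
    """Biallelic SNP calls for a panel: genotypes plus allele depths.

    Attributes
    ----------
    samples : list of sample ids, in VCF column order.
    sites : DataFrame with columns contig, pos (0-based), ref, alt.
    gt : int8 array, shape (n_sites, n_samples); codes GT_* above.
    ad_ref, ad_alt : int32 arrays, same shape.
    """

    def __init__(
        self,
        samples: Sequence[str],
        sites: pd.DataFrame,
        gt: np.ndarray,
        ad_ref: np.ndarray,
        ad_alt: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.sites = sites.reset_index(drop=True)
        self.gt = np.asarray(gt, dtype=np.int8)
        self.ad_ref = np.asarray(ad_ref, dtype=np.int32)
        self.ad_alt = np.asarray(ad_alt, dtype=np.int32)
        n_sites, n_samples = self.gt.shape
        if len(self.sites) != n_sites or len(self.samples) != n_samples:
            raise PanelIOError("variant table dimensions inconsistent")
        if self.ad_ref.shape != self.gt.shape or self.ad_alt.shape != self.gt.shape:
            raise PanelIOError("allele-depth arrays do not match genotype matrix")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask)
        return VariantTable(
            self.samples,
            self.sites.loc[mask],
            self.gt[mask],
            self.ad_ref[mask],
            self.ad_alt[mask],
        )

    def subset_samples(self, keep: Sequence[str]) -> "VariantTable":
        idx = [self.samples.index(s) for s in keep]
        return VariantTable(
            [self.samples[i] for i in idx],
            self.sites,
            self.gt[:, idx],
            self.ad_ref[:, idx],
            self.ad_alt[:, idx],
        )

    def for_contig(self, contig: str) -> "VariantTable":
        return self.subset_sites((self.sites["contig"] == contig).to_numpy())

    def to_vcf(self, path: str | Path) -> None:
        """Write a plain-text VCF 4.2 with GT:AD for every sample."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths (ref,alt)">\n'
            )
            for contig in self.sites["contig"].unique():
                fh.write(f"##contig=<ID={contig}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            gt_str = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", GT_MISSING: "./."}
            for i, site in enumerate(self.sites.itertuples()):
                cells = [
                    f"{gt_str[int(self.gt[i, j])]}:{self.ad_ref[i, j]},{self.ad_alt[i, j]}"
                    for j in range(self.n_samples)
                ]
                fh.write(
                    f"{site.contig}\t{site.pos + 1}\t.\t{site.ref}\t{site.alt}"
                    "\t.\tPASS\t.\tGT:AD\t" + "\t".join(cells) + "\n"
                )


def load_variants(
    path: str | Path,
    split_multiallelic: bool = True,
) -> VariantTable:
    """Read a VCF with GT and AD into a :class:`VariantTable`.

    Only SNP alleles are kept.  Multiallelic records are split into biallelic
    rows (alt-by-alt, with non-focal alt reads excluded from AD) when
    ``split_multiallelic`` is true, and skipped otherwise.  A record without
    AD is retained with zero depths after a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)

    rows = []
    gts, adr, ada = [], [], []
    warned_ad = False
    for var in vcf:
        alts = [a for a in (var.ALT or [])]
        if len(var.REF) != 1:
            continue
        if len(alts) > 1 and not split_multiallelic:
            continue
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            if not warned_ad:
                warnings.warn(
                    f"{path}: AD field missing; allele depths set to 0",
                    stacklevel=2,
                )
                warned_ad = True
            ad = np.zeros((n, len(alts) + 1), dtype=np.int32)
        ad = np.asarray(ad)
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing AD as negative
        geno = np.array(var.genotypes, dtype=object)  # [a1, a2, phased] per sample
        for k, alt in enumerate(alts, start=1):
            if len(alt) != 1 or alt not in "ACGT":
                continue
            gt_row = np.full(n, GT_MISSING, dtype=np.int8)
            for j in range(n):
                a1, a2 = geno[j][0], geno[j][1]
                if a1 < 0 or a2 < 0:
                    continue
                n_alt = int(a1 == k) + int(a2 == k)
                n_ref = int(a1 == 0) + int(a2 == 0)
                if n_alt == 2:
                    gt_row[j] = GT_HOM_ALT
                elif n_alt == 1 and n_ref == 1:
                    gt_row[j] = GT_HET
                elif n_ref == 2:
                    gt_row[j] = GT_HOM_REF
                # genotypes involving a different alt stay missing in this split
            rows.append((var.CHROM, var.POS - 1, var.REF, alt))
            gts.append(gt_row)
            adr.append(ad[:, 0].astype(np.int32))
            ada.append(
                ad[:, k].astype(np.int32)
                if ad.shape[1] > k
                else np.zeros(n, dtype=np.int32)
            )
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    shape = (len(rows), n)
    return VariantTable(
        samples,
        sites,
        np.array(gts, dtype=np.int8).reshape(shape),
        np.array(adr, dtype=np.int32).reshape(shape),
        np.array(ada, dtype=np.int32).reshape(shape),
    )


@dataclass
class ReferenceEdit:
    contig: str
    start: int
    end: int
    original: str
    replacement: str


@dataclass
class CoordinateLift:
    """Maps positions on the original contig to the edited contig.

    Positions downstream of the edited region shift by
    ``len(replacement) − (end − start)``; positions inside it map to None.
    """

    start: int
    end: int
    shift: int

    def __call__(self, pos: int) -> int | None:
        if pos < self.start:
            return pos
        if pos < self.end:
            return None
        return pos + self.shift


@dataclass
class ReferenceSequenceSet:
    """Named contigs with a provenance trail of region edits."""

    sequences: dict[str, str]
    edits: list[ReferenceEdit] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise PanelIOError(
                    f"contig {name}: invalid characters {sorted(bad)}"
                )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSequenceSet":
        seqs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(seqs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def substitute_reference_allele(
    ref: ReferenceSequenceSet,
    contig: str,
    start: int,
    end: int,
    replacement: str,
) -> tuple[ReferenceSequenceSet, CoordinateLift]:
    """Swap a reference region for a different allele of the locus.

    This is how a reference assembled from a deletion-carrying genotype is
    repaired before structural-variant genotyping: the region carrying the
    deletion allele is excised and the full-length allele inserted, so that
    deletions in other samples become visible as missing coverage.  Returns
    the edited set and the coordinate lift for the contig.
    """
    if contig not in ref.sequences:
        raise PanelIOError(f"unknown contig {contig!r}")
    seq = ref.sequences[contig]
    if not (0 <= start < end <= len(seq)):
        raise PanelIOError(
            f"region [{start},{end}) out of bounds for contig {contig} "
            f"(length {len(seq)})"
        )
    if not replacement:
        raise PanelIOError("replacement sequence is empty")
    replacement = replacement.upper()
    bad = set(replacement) - set("ACGTN")
    if bad:
        raise PanelIOError(f"replacement has invalid characters {sorted(bad)}")
    new_seq = seq[:start] + replacement + seq[end:]
    shift = len(replacement) - (end - start)
    edited = ReferenceSequenceSet(
        {**ref.sequences, contig: new_seq},
        edits=ref.edits + [ReferenceEdit(contig, start, end, seq[start:end], replacement)],
    )
    return edited, CoordinateLift(start=start, end=end, shift=shift)


def load_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the panel metadata TSV.

    Returns a DataFrame with columns sample_id, biological_status,
    growth_habit, latitude, longitude, total_mapped_reads.  Unknown category
    labels are mapped to "unknown"; duplicate sample ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise PanelIOError(f"{path}: missing metadata columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise PanelIOError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    df = df.copy()
    df["biological_status"] = (
        df["biological_status"].astype(str).str.lower().where(
            df["biological_status"].astype(str).str.lower().isin(BIOLOGICAL_STATUSES),
            "unknown",
        )
    )
    df["growth_habit"] = (
        df["growth_habit"].astype(str).str.lower().where(
            df["growth_habit"].astype(str).str.lower().isin(GROWTH_HABITS),
            "unknown",
        )
    )
    df["latitude"] = pd.to_numeric(df["latitude"], errors="coerce")
    df["longitude"] = pd.to_numeric(df["longitude"], errors="coerce")
    bad_lat = df["latitude"].dropna().abs() > 90
    if bad_lat.any():
        raise PanelIOError(f"{path}: latitude outside [-90, 90]")
    df["total_mapped_reads"] = df["total_mapped_reads"].astype(np.int64)
    if (df["total_mapped_reads"] < 0).any():
        raise PanelIOError(f"{path}: negative total_mapped_reads")
    return df[METADATA_COLUMNS]


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)
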