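"""Deletion-haplotype classification at the vernalization locus VRN-H1.

Deletion calls made against a reference carrying the full-length winter
(recessive) allele are matched to a named haplotype catalog with a small
breakpoint tolerance, annotated for overlap with the first-intron regulatory
regions, and combined with VRN-H2 presence/absence into a growth-habit
prediction.  Insertions are out of model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_BREAKPOINT_TOLERANCE = 10
WILD_HAPLOTYPE = "VRN1-wild"


class SVError(ValueError):
    pass


@dataclass(frozen=True)
class DeletionCall:
    sample_id: str
    contig: str
    start: int  # 0-based half-open on the customised reference
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise SVError(
                f"{self.sample_id}: deletion [{self.start},{self.end}) "
                "has length < 1"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HaplotypeDefinition:
    """A named set of deletions; the wild haplotype has none."""

    name: str
    deletions: tuple[tuple[int, int], ...]  # sorted (start, end)
    source: str = "catalog"  # catalog | novel

    def __post_init__(self) -> None:
        self.deletions = tuple(sorted(tuple(d) for d in self.deletions))

    @property
    def is_wild(self) -> bool:
        return len(self.deletions) == 0


@dataclass
class RegionAnnotation:
    """Named functional intervals on the customised reference.

    The core regulatory region must lie within the 2.8 kb regulatory region,
    which must lie within the first intron.
    """

    regions: dict[str, tuple[int, int]]

    REQUIRED = ("promoter", "intron1", "regulatory_2_8kb", "core_region")

    def __post_init__(self) -> None:
        for name in self.REQUIRED:
            if name not in self.regions:
                raise SVError(f"region annotation missing {name!r}")
        for name, (s, e) in self.regions.items():
            if e <= s:
                raise SVError(f"region {name}: degenerate interval [{s},{e})")
        i1 = self.regions["intron1"]
        reg = self.regions["regulatory_2_8kb"]
        core = self.regions["core_region"]
        if not (i1[0] <= reg[0] and reg[1] <= i1[1]):
            raise SVError("regulatory_2_8kb must lie within intron1")
        if not (reg[0] <= core[0] and core[1] <= reg[1]):
            raise SVError("core_region must lie within regulatory_2_8kb")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionAnnotation":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                str(r.region_name): (int(r.start), int(r.end))
                for r in df.itertuples()
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(n, s, e) for n, (s, e) in self.regions.items()],
            columns=["region_name", "start", "end"],
        ).to_csv(path, sep="\t", index=False)


class HaplotypeCatalog:
    """Ordered collection of named deletion haplotypes."""

    def __init__(self, haplotypes: Sequence[HaplotypeDefinition]) -> None:
        names = [h.name for h in haplotypes]
        if len(set(names)) != len(names):
            raise SVError("duplicate haplotype names in catalog")
        self.haplotypes = list(haplotypes)
        if not any(h.is_wild for h in self.haplotypes):
            raise SVError("catalog must contain the wild (deletion-free) haplotype")

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    def get(self, name: str) -> HaplotypeDefinition:
        for h in self.haplotypes:
            if h.name == name:
                return h
        raise KeyError(name)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypeCatalog":
        """Load a catalog TSV: name, deletion_start, deletion_end.

        Multiple rows per name define multi-deletion haplotypes; the wild
        haplotype is a single row with empty start/end cells.
        """
        df = pd.read_csv(path, sep="\t")
        haps = []
        for name, sub in df.groupby("name", sort=False):
            dels = [
                (int(r.deletion_start), int(r.deletion_end))
                for r in sub.itertuples()
                if pd.notna(r.deletion_start)
            ]
            haps.append(HaplotypeDefinition(str(name), tuple(dels)))
        return cls(haps)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for h in self.haplotypes:
            if h.is_wild:
                rows.append((h.name, "", ""))
            else:
                rows.extend((h.name, s, e) for s, e in h.deletions)
        pd.DataFrame(rows, columns=["name", "deletion_start", "deletion_end"]).to_csv(
            path, sep="\t", index=False
        )


def _check_non_overlapping(dels: Sequence[tuple[int, int]], sample_id: str) -> None:
    dels = sorted(dels)
    for (s1, e1), (s2, e2) in zip(dels, dels[1:]):
        if s2 < e1:
            raise SVError(
                f"{sample_id}: overlapping deletions [{s1},{e1}) and [{s2},{e2}) "
                "— inconsistent call set"
            )


def match_deletion_haplotype(
    calls: Sequence[DeletionCall],
    catalog: HaplotypeCatalog,
    tolerance_bp: int = DEFAULT_BREAKPOINT_TOLERANCE,
) -> HaplotypeDefinition:
    """Match one sample's deletion set against the catalog.

    A sample matches a catalog haplotype iff a one-to-one pairing exists
    between its deletions and the haplotype's deletions with both breakpoints
    within ``tolerance_bp``.  An empty call set is the wild haplotype; an
    unmatched set becomes a novel haplotype.
    """
    sample_id = calls[0].sample_id if calls else ""
    dels = sorted((c.start, c.end) for c in calls)
    _check_non_overlapping(dels, sample_id)
    for hap in catalog:
        if len(hap.deletions) != len(dels):
            continue
        # non-overlapping sorted intervals: the only viable pairing is in order
        if all(
            abs(a[0] - b[0]) <= tolerance_bp and abs(a[1] - b[1]) <= tolerance_bp
            for a, b in zip(dels, hap.deletions)
        ):
            return hap
    return name_novel_haplotype(dels, catalog)


def name_novel_haplotype(
    deletions: Sequence[tuple[int, int]],
    catalog: HaplotypeCatalog,
    registry: dict[tuple[tuple[int, int], ...], str] | None = None,
) -> HaplotypeDefinition:
    """Deterministically name an uncatalogued deletion set.

    Names are NOVEL-k, ordered by (first deletion start, length); the same
    set always receives the same name.  Passing the same ``registry`` dict
    across calls keeps numbering consistent within a run.
    """
    dels = tuple(sorted(tuple(d) for d in deletions))
    if not dels:
        raise SVError("novel haplotype cannot be deletion-free (that is wild)")
    for hap in catalog:
        if hap.deletions == dels:
            raise SVError(
                f"deletion set equals catalog haplotype {hap.name}; not novel"
            )
    if registry is not None and dels in registry:
        return HaplotypeDefinition(registry[dels], dels, source="novel")
    k = (len(registry) + 1) if registry is not None else 1
    name = f"NOVEL-{k}"
    if registry is not None:
        registry[dels] = name
    return HaplotypeDefinition(name, dels, source="novel")


def classify_panel(
    calls: Iterable[DeletionCall],
    catalog: HaplotypeCatalog,
    sample_ids: Sequence[str],
    tolerance_bp: int = DEFAULT_BREAKPOINT_TOLERANCE,
) -> dict[str, HaplotypeDefinition]:
    """Haplotype every sample; samples without calls are wild.

    Novel haplotypes are numbered deterministically by (first start, length)
    across the whole panel, independent of sample order.
    """
    by_sample: dict[str, list[DeletionCall]] = {s: [] for s in sample_ids}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)

    wild = next(h for h in catalog if h.is_wild)
    out: dict[str, HaplotypeDefinition] = {}
    novel_sets: set[tuple[tuple[int, int], ...]] = set()
    matched: dict[str, HaplotypeDefinition | None] = {}
    for s, cs in by_sample.items():
        if not cs:
            out[s] = wild
            continue
        dels = sorted((c.start, c.end) for c in cs)
        _check_non_overlapping(dels, s)
        hap = None
        for cand in catalog:
            if len(cand.deletions) != len(dels):
                continue
            if all(
                abs(a[0] - b[0]) <= tolerance_bp and abs(a[1] - b[1]) <= tolerance_bp
                for a, b in zip(dels, cand.deletions)
            ):
                hap = cand
                break
        matched[s] = hap
        if hap is None:
            novel_sets.add(tuple(dels))
    # stable novel numbering across the panel
    ordered = sorted(novel_sets, key=lambda d: (d[0][0], d[0][1] - d[0][0], d))
    registry = {d: f"NOVEL-{k}" for k, d in enumerate(ordered, start=1)}
    for s, cs in by_sample.items():
        if s in out:
            continue
        hap = matched[s]
        if hap is None:
            dels = tuple(sorted((c.start, c.end) for c in cs))
            hap = HaplotypeDefinition(registry[dels], dels, source="novel")
        out[s] = hap
    return out


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def annotate_regulatory_overlap(
    hap: HaplotypeDefinition, regions: RegionAnnotation
) -> dict[str, bool]:
    """Half-open interval intersection of a haplotype with each named region."""
    reg = regions.regions["regulatory_2_8kb"]
    core = regions.regions["core_region"]
    prom = regions.regions["promoter"]
    flags = {
        "overlaps_regulatory": any(_overlaps(d, reg) for d in hap.deletions),
        "overlaps_core": any(_overlaps(d, core) for d in hap.deletions),
        "overlaps_promoter": any(_overlaps(d, prom) for d in hap.deletions),
    }
    # fully removed iff the union of deletions covers the region
    covered = 0
    for s, e in sorted(hap.deletions):
        s, e = max(s, reg[0]), min(e, reg[1])
        if e > s:
            covered += e - s
    flags["fully_removes_regulatory"] = covered == reg[1] - reg[0]
    return flags


@dataclass(frozen=True)
class GrowthHabitCall:
    sample_id: str
    vrn1_haplotype: str
    vrn2_status: str  # present | absent
    predicted_class: str  # winter | spring | facultative | uncertain


def predict_growth_habit(
    sample_id: str,
    hap: HaplotypeDefinition,
    flags: Mapping[str, bool],
    vrn2_status: str,
) -> GrowthHabitCall:
    """Joint growth-habit prediction from VRN-H1 haplotype and VRN-H2 status.

    Deletions hitting the first-intron regulatory region release the
    vernalization requirement (spring); a deletion-free winter allele with
    VRN-H2 present is winter and with VRN-H2 fully deleted is facultative.
    Deletions that miss the regulatory region have no established phenotype
    and are called uncertain.
    """
    if vrn2_status not in ("present", "absent"):
        raise SVError(f"invalid vrn2_status {vrn2_status!r}")
    if flags.get("overlaps_regulatory") or flags.get("overlaps_core"):
        cls = "spring"
    elif hap.is_wild:
        cls = "winter" if vrn2_status == "present" else "facultative"
    else:
        cls = "uncertain"
    return GrowthHabitCall(sample_id, hap.name, vrn2_status, cls)


def detect_deletions_from_depth(
    depth: np.ndarray,
    sample_id: str,
    contig: str,
    min_len: int = 500,
    drop_fraction: float = 0.2,
) -> list[DeletionCall]:
    """Depth-gap deletion detector (desk-scale stand-in for a split-read caller).

    Emits maximal runs of at least ``min_len`` consecutive positions whose
    depth falls below ``drop_fraction`` times the median depth.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.size == 0 or not np.any(depth > 0):
        raise SVError("no coverage: depth profile is all zero")
    threshold = drop_fraction * np.median(depth)
    low = depth < threshold
    calls = []
    # run-length scan over the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_len:
            calls.append(DeletionCall(sample_id, contig, int(s), int(e)))
    return calls


def load_deletion_calls(path: str | Path) -> list[DeletionCall]:
    """Read deletion calls from TSV (sample_id, contig, start, end; 0-based)
    or from a VCF with SVTYPE=DEL (POS/INFO END 1-based inclusive)."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        calls = []
        for var in vcf:
            if var.INFO.get("SVTYPE") != "DEL":
                continue
            end = var.INFO.get("END")
            if end is None:
                raise SVError(f"{path}: DEL record at {var.POS} lacks INFO/END")
            start0, end0 = var.POS - 1, int(end)  # 1-based inclusive -> half-open
            for j, s in enumerate(samples):
                a1, a2 = var.genotypes[j][0], var.genotypes[j][1]
                if a1 == 1 or a2 == 1:
                    calls.append(DeletionCall(s, var.CHROM, start0, end0))
        return calls
    df = pd.read_csv(path, sep="\t")
    return [
        DeletionCall(str(r.sample_id), str(r.contig), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def growth_habit_table(
    assignments: Mapping[str, HaplotypeDefinition],
    regions: RegionAnnotation,
    vrn2_status: Mapping[str, str],
) -> pd.DataFrame:
    rows = []
    for sample, hap in assignments.items():
        flags = annotate_regulatory_overlap(hap, regions)
        call = predict_growth_habit(sample, hap, flags, vrn2_status[sample])
        rows.append(
            {
                "sample_id": sample,
                "haplotype": hap.name,
                "haplotype_source": hap.source,
                **flags,
                "vrn2_status": call.vrn2_status,
                "predicted_class": call.predicted_class,
            }
        )
    return pd.DataFrame(rows)
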