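"""Paralog deconvolution from heterozygous SNPs, allele balance and depth.

Near-identical gene paralogs co-captured by exome probes all map onto the
single reference copy of the gene.  A genotype carrying two diverged copies
then shows (i) heterozygous calls exactly at the positions where the copies
differ, (ii) an allele balance close to the ratio of alternative to reference
copies, and (iii) an elevated normalised read count.  Given a signature
matrix of known paralog alleles at discriminating positions, this module
enumerates every multiset of paralog copies consistent with a sample's
observed pattern and ranks the hypotheses by agreement with depth and
allele balance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, VariantTable

DEFAULT_MIN_AB = 0.25
DEFAULT_MAX_TOTAL_COPIES = 4
# mean |log AB deviation| allowed between observed and predicted allele
# balance: a factor-1.5 deviation (log 1.5 ~ 0.405) passes, a factor-2
# deviation (log 2 ~ 0.693) is excluded
DEFAULT_AB_TOLERANCE = 0.6
DEFAULT_DEPTH_CONSISTENCY = 0.75
MAX_CONFLICT_FRACTION = 0.2


class ParalogError(ValueError):
    pass


def allele_balance(ad_ref: int, ad_alt: int) -> float:
    """Ratio of alternative-allele to reference-allele read depth.

    Undefined (NaN) when no reference reads support the site; a true
    heterozygote with both copies equally captured sits close to 1.
    """
    if ad_ref < 0 or ad_alt < 0:
        raise ParalogError("allele depths must be non-negative")
    if ad_ref == 0:
        return float("nan")
    return ad_alt / ad_ref


def allele_balance_flag(ad_ref: int, ad_alt: int) -> str:
    """Classify why an allele balance is (un)defined."""
    if ad_ref == 0 and ad_alt == 0:
        return "no-coverage"
    if ad_ref == 0:
        return "hom-alt-support"
    return "ok"


class ParalogSignature:
    """Allele matrix of known paralogs at their discriminating positions.

    Parameters
    ----------
    gene_id : name of the collapsed reference gene.
    positions : bp offsets of the variant positions relative to the start
        codon, ascending.
    alleles : mapping paralog name -> nucleotide string, one base per
        position.
    ref_paralog : the paralog identical to the reference assembly; its
        alleles define the reference base at every position.
    """

    def __init__(
        self,
        gene_id: str,
        positions: Sequence[int],
        alleles: Mapping[str, str],
        ref_paralog: str,
    ) -> None:
        self.gene_id = gene_id
        self.positions = list(positions)
        self.alleles = {name: row.upper() for name, row in alleles.items()}
        self.ref_paralog = ref_paralog
        if ref_paralog not in self.alleles:
            raise ParalogError(f"reference paralog {ref_paralog!r} not in matrix")
        npos = len(self.positions)
        for name, row in self.alleles.items():
            if len(row) != npos:
                raise ParalogError(
                    f"paralog {name}: {len(row)} alleles for {npos} positions"
                )
        # biallelic check and per-position ref/alt
        self.ref_allele = self.alleles[ref_paralog]
        alt = []
        for i in range(npos):
            obs = {row[i] for row in self.alleles.values()}
            if len(obs) > 2:
                raise ParalogError(
                    f"position {self.positions[i]}: more than two alleles {sorted(obs)}"
                )
            others = obs - {self.ref_allele[i]}
            alt.append(others.pop() if others else ".")
        self.alt_allele = "".join(alt)

    @property
    def paralogs(self) -> list[str]:
        return list(self.alleles)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def aliases(self) -> list[tuple[str, str]]:
        """Pairs of paralogs with identical allele rows (indistinguishable)."""
        out = []
        names = self.paralogs
        for a, b in itertools.combinations(names, 2):
            if self.alleles[a] == self.alleles[b]:
                out.append((a, b))
        return out

    @classmethod
    def from_tsv(
        cls, path: str | Path, gene_id: str, ref_paralog: str
    ) -> "ParalogSignature":
        """Load a long-format signature TSV: paralog, offset_bp, allele."""
        df = pd.read_csv(path, sep="\t")
        need = {"paralog", "offset_bp", "allele"}
        if not need <= set(df.columns):
            raise ParalogError(f"{path}: signature TSV needs columns {sorted(need)}")
        positions = sorted(df["offset_bp"].unique())
        alleles = {}
        for name, sub in df.groupby("paralog"):
            row = dict(zip(sub["offset_bp"], sub["allele"]))
            if set(row) != set(positions):
                raise ParalogError(f"{path}: paralog {name} misses positions")
            alleles[str(name)] = "".join(str(row[p]) for p in positions)
        return cls(gene_id, positions, alleles, ref_paralog)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (name, pos, row[i])
            for name, row in self.alleles.items()
            for i, pos in enumerate(self.positions)
        ]
        pd.DataFrame(rows, columns=["paralog", "offset_bp", "allele"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ObservedPattern:
    """One sample's calls at the signature positions.

    ``depth_multiplier`` is the copy-number ratio of the gene from read
    counts (None when unavailable); ``n_demoted`` counts heterozygous calls
    demoted to missing by the allele-balance filter.
    """

    sample_id: str
    calls: np.ndarray  # int8, codes from allelemine.io
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    depth_multiplier: float | None = None
    n_demoted: int = 0

    def allele_balances(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            ab = np.where(self.ad_ref > 0, self.ad_alt / np.maximum(self.ad_ref, 1), np.nan)
        return ab


def filter_het_calls(
    pattern: ObservedPattern,
    min_ab: float = DEFAULT_MIN_AB,
    symmetric: bool = False,
) -> ObservedPattern:
    """Demote low-allele-balance heterozygous calls to missing.

    A genuine het produced by two co-captured copies has balanced read
    support; a het with AB below ``min_ab`` (default 0.25) is more likely a
    mapping or sequencing artefact and is set to missing.  The filter is
    one-sided by default; ``symmetric=True`` also demotes AB > 1/min_ab.
    """
    if not (0 < min_ab <= 1):
        raise ParalogError("min_ab must be in (0, 1]")
    ab = pattern.allele_balances()
    calls = pattern.calls.copy()
    het = calls == GT_HET
    low = het & (np.isnan(ab) | (ab < min_ab))
    demote = low
    if symmetric:
        demote = demote | (het & (ab > 1.0 / min_ab))
    calls[demote] = GT_MISSING
    return replace(pattern, calls=calls, n_demoted=pattern.n_demoted + int(demote.sum()))


@dataclass
class CombinationHypothesis:
    """A multiset of paralog copies with its predicted observable pattern."""

    combo: tuple[tuple[str, int], ...]  # sorted (paralog, copies)
    total_copies: int
    predicted_calls: np.ndarray
    predicted_ab: np.ndarray
    score: float = 1.0
    depth_dev: float = 0.0
    ab_dev: float = 0.0
    ambiguous_with: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        return "+".join(
            name if k == 1 else f"{name}x{k}" for name, k in self.combo
        )


def _canonical_combo(combo: Mapping[str, int]) -> tuple[tuple[str, int], ...]:
    items = [(n, int(k)) for n, k in combo.items() if k > 0]
    if not items:
        raise ParalogError("combination is empty")
    return tuple(sorted(items))


def predict_pattern(
    combo: Mapping[str, int], signature: ParalogSignature
) -> CombinationHypothesis:
    """Predict the collapsed-mapping genotype pattern of a paralog multiset.

    At each position the call is heterozygous iff both the reference and the
    alternative base occur among the carried copies; the predicted allele
    balance is (alt copies)/(ref copies) and the predicted depth multiplier
    is the total copy count relative to a single-copy reference.
    """
    canon = _canonical_combo(combo)
    unknown = [n for n, _ in canon if n not in signature.alleles]
    if unknown:
        raise ParalogError(f"unknown paralog name(s): {unknown}")
    npos = signature.n_positions
    calls = np.empty(npos, dtype=np.int8)
    ab = np.full(npos, np.nan)
    for i in range(npos):
        ref_base = signature.ref_allele[i]
        n_ref = sum(k for n, k in canon if signature.alleles[n][i] == ref_base)
        n_alt = sum(k for n, k in canon if signature.alleles[n][i] != ref_base)
        if n_ref and n_alt:
            calls[i] = GT_HET
            ab[i] = n_alt / n_ref
        elif n_alt:
            calls[i] = GT_HOM_ALT
        else:
            calls[i] = GT_HOM_REF
    total = sum(k for _, k in canon)
    return CombinationHypothesis(
        combo=canon, total_copies=total, predicted_calls=calls, predicted_ab=ab
    )


def _iter_multisets(names: Sequence[str], max_total: int):
    for total in range(1, max_total + 1):
        for picks in itertools.combinations_with_replacement(sorted(names), total):
            combo: dict[str, int] = {}
            for n in picks:
                combo[n] = combo.get(n, 0) + 1
            yield combo


def enumerate_consistent_combinations(
    pattern: ObservedPattern,
    signature: ParalogSignature,
    max_total_copies: int = DEFAULT_MAX_TOTAL_COPIES,
    ab_tolerance: float = DEFAULT_AB_TOLERANCE,
) -> list[CombinationHypothesis]:
    """Rank every paralog multiset consistent with an observed pattern.

    A hypothesis is consistent when its predicted call equals the observed
    call at every non-missing position and its mean absolute log-ratio of
    observed to predicted allele balance over heterozygous positions is at
    most ``ab_tolerance``.  Hypotheses are scored by closeness of total
    copies to the read-depth multiplier and by the allele-balance deviation;
    hypotheses with identical predictions and tied scores are mutually
    flagged ambiguous.  Returns an empty list (and no exception) when no
    multiset fits.
    """
    if not (1 <= max_total_copies <= 6):
        raise ParalogError("max_total_copies must be in [1, 6]")
    observed = pattern.calls
    known = observed != GT_MISSING
    obs_ab = pattern.allele_balances()
    hyps: list[CombinationHypothesis] = []
    for combo in _iter_multisets(signature.paralogs, max_total_copies):
        hyp = predict_pattern(combo, signature)
        if not np.array_equal(hyp.predicted_calls[known], observed[known]):
            continue
        het = known & (observed == GT_HET)
        usable = het & np.isfinite(obs_ab) & np.isfinite(hyp.predicted_ab)
        if usable.any():
            dev = np.abs(np.log(obs_ab[usable] / hyp.predicted_ab[usable]))
            ab_dev = float(dev.mean())
        else:
            ab_dev = 0.0
        if ab_dev > ab_tolerance:
            continue
        depth_dev = (
            abs(hyp.total_copies - pattern.depth_multiplier)
            if pattern.depth_multiplier is not None
            else 0.0
        )
        hyp.ab_dev = ab_dev
        hyp.depth_dev = depth_dev
        hyp.score = 1.0 / (1.0 + depth_dev + ab_dev)
        hyps.append(hyp)

    # mutual ambiguity: identical predicted observables and tied score
    def pred_key(h: CombinationHypothesis):
        ab_key = tuple(
            None if not np.isfinite(v) else round(float(v), 9) for v in h.predicted_ab
        )
        return (h.predicted_calls.tobytes(), ab_key, h.total_copies)

    groups: dict[tuple, list[CombinationHypothesis]] = {}
    for h in hyps:
        groups.setdefault(pred_key(h), []).append(h)
    for group in groups.values():
        if len(group) > 1:
            for h in group:
                h.ambiguous_with = sorted(
                    o.label for o in group if o is not h
                )
    hyps.sort(key=lambda h: (-h.score, h.label, h.total_copies))
    return hyps


def mismatch_diagnostic(
    pattern: ObservedPattern,
    signature: ParalogSignature,
    max_total_copies: int = DEFAULT_MAX_TOTAL_COPIES,
) -> dict[str, list[int]]:
    """Per-hypothesis mismatching positions, for samples with no fit."""
    observed = pattern.calls
    known = observed != GT_MISSING
    out: dict[str, list[int]] = {}
    for combo in _iter_multisets(signature.paralogs, max_total_copies):
        hyp = predict_pattern(combo, signature)
        bad = known & (hyp.predicted_calls != observed)
        out[hyp.label] = [signature.positions[i] for i in np.flatnonzero(bad)]
    return out


def extract_patterns(
    variants: VariantTable,
    signature: ParalogSignature,
    gene_start: int,
    contig: str,
    depth_multipliers: Mapping[str, float] | None = None,
) -> list[ObservedPattern]:
    """Pull each sample's calls at the signature positions from a VCF table.

    Signature offsets are relative to the start codon; ``gene_start`` is the
    0-based position of the start codon on ``contig``.  Signature positions
    absent from the table are treated as missing.
    """
    table = variants.for_contig(contig)
    pos_index = {int(p): i for i, p in enumerate(table.sites["pos"])}
    rows = [pos_index.get(gene_start + off) for off in signature.positions]
    npos = signature.n_positions
    patterns = []
    for j, sample in enumerate(table.samples):
        calls = np.full(npos, GT_MISSING, dtype=np.int8)
        adr = np.zeros(npos, dtype=np.int32)
        ada = np.zeros(npos, dtype=np.int32)
        for i, r in enumerate(rows):
            if r is None:
                # a position with no variant record is homozygous reference
                calls[i] = GT_HOM_REF
                continue
            calls[i] = table.gt[r, j]
            adr[i] = table.ad_ref[r, j]
            ada[i] = table.ad_alt[r, j]
        dm = depth_multipliers.get(sample) if depth_multipliers else None
        patterns.append(
            ObservedPattern(sample, calls, adr, ada, depth_multiplier=dm)
        )
    return patterns


@dataclass
class ParalogCall:
    sample_id: str
    status: str  # resolved | ambiguous | unresolved
    haplotype_label: str | None
    combination: tuple[tuple[str, int], ...] | None
    total_copies: int | None
    score: float | None
    ambiguous_with: list[str]
    n_demoted: int


def call_paralog_haplotype(
    pattern: ObservedPattern,
    signature: ParalogSignature,
    min_ab: float = DEFAULT_MIN_AB,
    max_total_copies: int = DEFAULT_MAX_TOTAL_COPIES,
    ab_tolerance: float = DEFAULT_AB_TOLERANCE,
    depth_consistency: float = DEFAULT_DEPTH_CONSISTENCY,
) -> ParalogCall:
    """Assign a sample a stable paralog-combination haplotype label.

    The label is the canonical combination string of the top-ranked
    hypothesis, so identical filtered patterns always receive identical
    labels.  A sample is ``unresolved`` when every position is missing, when
    no combination fits, or when no fitting combination's total copy count
    is within ``depth_consistency`` of the read-depth multiplier (the read
    count does not support the extra paralogs).
    """
    filtered = filter_het_calls(pattern, min_ab=min_ab)
    known = filtered.calls != GT_MISSING
    if not known.any():
        return ParalogCall(
            pattern.sample_id, "unresolved", None, None, None, None, [],
            filtered.n_demoted,
        )
    hyps = enumerate_consistent_combinations(
        filtered, signature, max_total_copies, ab_tolerance
    )
    if filtered.depth_multiplier is not None:
        hyps = [h for h in hyps if h.depth_dev <= depth_consistency]
    if not hyps:
        return ParalogCall(
            pattern.sample_id, "unresolved", None, None, None, None, [],
            filtered.n_demoted,
        )
    top = hyps[0]
    status = "ambiguous" if top.ambiguous_with else "resolved"
    return ParalogCall(
        pattern.sample_id,
        status,
        top.label,
        top.combo,
        top.total_copies,
        top.score,
        top.ambiguous_with,
        filtered.n_demoted,
    )


def paralog_call_table(calls: Sequence[ParalogCall]) -> pd.DataFrame:
    """Long-form results table, one row per sample."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "status": [c.status for c in calls],
            "haplotype_label": [c.haplotype_label for c in calls],
            "total_copies": [c.total_copies for c in calls],
            "score": [c.score for c in calls],
            "ambiguous_with": [";".join(c.ambiguous_with) for c in calls],
            "n_demoted_het": [c.n_demoted for c in calls],
        }
    )
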