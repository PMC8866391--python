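"""Synthetic exome-capture panel with known truth.

Generates a barley-like diversity panel end to end: per-sample germplasm
category, true copy number of the co-duplicated CBF segment genes, paralog
combinations at the collapsed CBF2 locus, deletion haplotypes at the
vernalization locus, presence/absence of the vernalization repressor locus,
a rare-allele-heavy SNP matrix, capture read counts, allele depths,
per-base depth profiles and replicated 0–5 frost scores — everything the
pipeline consumes, plus the truth tables to score recovery against.
Observables are generated only from truth plus an explicit noise model, and
truth files live in a separate subtree so the pipeline runs truth-blind.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, VariantTable
from .paralogs import ParalogSignature
from .svhap import HaplotypeCatalog, RegionAnnotation

VRN1_CONTIG = "chr5H_VRN1"
VRN1_CONTIG_LEN = 15000
CBF2_CONTIG = "chr5H_CBF2"
CBF2_GENE_START = 500
CBF14_CONTIG = "chr5H_CBF14"
# two haplotype-tagging SNPs at the CBF14 locus; haplotypes are defined by
# the allele combination (ref/ref, alt/ref, ref/alt)
CBF14_SNPS = ((300, "C", "T"), (600, "G", "A"))
CBF14_HAPLOTYPE_CODES = {"hap1": (0, 0), "hap2": (1, 0), "hap3": (0, 1)}

CNV_GENES = ("HvCBF2a", "HvCBF4b")
CONTROL_GENES = ("HvNUD", "HvSAMDC")
VRN2_GENE = "HvVRN2"
CBF2_PARALOG_GENE = "HvCBF2"
ALL_COUNT_GENES = CNV_GENES + CONTROL_GENES + (VRN2_GENE, CBF2_PARALOG_GENE)

REFERENCE_SAMPLE = "Morex"


class SimulationError(ValueError):
    pass


def _data_path(name: str):
    return importlib.resources.files("allelemine.data").joinpath(name)


def default_signature() -> ParalogSignature:
    """The bundled CBF2 paralog signature (four rows, six positions)."""
    with importlib.resources.as_file(_data_path("cbf2_signature.tsv")) as p:
        return ParalogSignature.from_tsv(p, CBF2_PARALOG_GENE, "morex_CBF2a")


def default_catalog() -> HaplotypeCatalog:
    with importlib.resources.as_file(_data_path("vrn1_catalog.tsv")) as p:
        return HaplotypeCatalog.from_tsv(p)


def default_regions() -> RegionAnnotation:
    with importlib.resources.as_file(_data_path("vrn1_regions.tsv")) as p:
        return RegionAnnotation.from_tsv(p)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic panel.

    Defaults follow the panel this generator emulates: 403 accessions split
    188 cultivars / 185 landraces / 22 wild / 8 unknown, copy number of the
    duplicated segment up to 12 with roughly 11% of samples multi-copy,
    scores on a 0–5 scale at 0.5 granularity, and a rare-allele-heavy SNP
    frequency spectrum.
    """

    n_samples: int = 403
    category_counts: dict = field(
        default_factory=lambda: {
            "cultivar": 188,
            "landrace": 185,
            "wild": 22,
            "unknown": 8,
        }
    )
    # copy number of the co-duplicated two-gene segment
    cn_support: tuple = (1, 2, 3, 4, 5, 6, 8, 10, 12)
    cn_probs: tuple = (0.886, 0.05, 0.02, 0.015, 0.01, 0.006, 0.005, 0.004, 0.004)
    # paralog combination frequencies at the collapsed CBF2 locus
    combo_probs: tuple = (
        (("morex_CBF2a", 1), 0.70),
        ((("morex_CBF2a", 1), ("morex_CBF2a", 1)), 0.08),
        ((("nure_CBF2a", 1), ("nure_CBF2b", 1)), 0.06),
        ((("morex_CBF2a", 1), ("nure_CBF2b", 1)), 0.05),
        ((("CBF2ab_fusion", 1), ("morex_CBF2a", 1)), 0.04),
        (("CBF2ab_fusion", 1), 0.04),
        (("nure_CBF2b", 1), 0.03),
    )
    vrn2_absence_prob: float = 0.15
    vrn1_hap_probs: dict | None = None  # None -> built-in frequencies
    mean_target_coverage: float = 60.0
    read_len: int = 100
    overdispersion: float = 0.0  # NB dispersion; 0 = Poisson
    error_rate: float = 0.005
    snp_sites: int = 40
    # per-call missing rate; at panel scale this retains roughly a quarter
    # of sites under complete-case pruning, as observed in capture panels
    missing_rate: float = 0.003
    snp_depth: float = 50.0
    base_total_mapped: int = 20_000_000
    lib_sigma: float = 0.15
    breakpoint_jitter: int = 3
    # frost experiment
    n_frost_genotypes: int = 45
    n_boxes: int = 5
    n_replicates: int = 10
    frost_baseline: float = 2.5
    cbf14_effects: tuple = (0.0, 0.0, 1.0)  # per haplotype level
    cbf14_probs: tuple = (0.4, 0.35, 0.25)
    cn_frost_effect: float = 0.0
    box_effect_sd: float = 0.3
    residual_sd: float = 1.0
    score_granularity: float = 0.5

    def validate(self) -> None:
        if sum(self.category_counts.values()) != self.n_samples:
            raise SimulationError("category counts must sum to n_samples")
        for probs, what in (
            (self.cn_probs, "cn_probs"),
            ([p for _, p in self.combo_probs], "combo_probs"),
            (self.cbf14_probs, "cbf14_probs"),
        ):
            arr = np.asarray(probs, dtype=float)
            if (arr < 0).any() or (arr > 1).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise SimulationError(f"{what} must be probabilities summing to 1")
        if not (0 <= self.vrn2_absence_prob <= 1):
            raise SimulationError("vrn2_absence_prob must be in [0,1]")
        if self.mean_target_coverage <= 0:
            raise SimulationError("mean_target_coverage must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _vrn1_hap_probs(catalog: HaplotypeCatalog) -> dict[str, float]:
    """Built-in haplotype frequencies: the three most frequent haplotypes at
    their observed panel shares, remainder uniform."""
    names = [h.name for h in catalog]
    major = {"VRN1-4": 72 / 403, "VRN1-1": 63 / 403, "VRN1-wild": 62 / 403}
    rest = [n for n in names if n not in major]
    residual = 1.0 - sum(major.values())
    probs = {**major, **{n: residual / len(rest) for n in rest}}
    return probs


# capture design: two targets per gene, on a per-gene contig except the
# loci that live on the shared synthetic contigs
def default_targets_frame() -> pd.DataFrame:
    rows = []
    for gene in ALL_COUNT_GENES:
        if gene == CBF2_PARALOG_GENE:
            contig = CBF2_CONTIG
            spans = [(400, 1000, f"{gene}_1"), (1100, 1600, f"{gene}_2")]
        else:
            contig = f"ctg_{gene}"
            spans = [(100, 700, f"{gene}_1"), (900, 1800, f"{gene}_2")]
        for s, e, tid in spans:
            rows.append((contig, s, e, tid))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name"])


@dataclass
class SyntheticTruth:
    """Per-sample ground truth of a simulated panel."""

    samples: pd.DataFrame  # sample_id, category, cn per gene, combo, haps, ...
    snp_genotypes: pd.DataFrame  # sites × samples haploid truth (0/1)

    def to_dir(self, truth_dir: str | Path) -> None:
        truth_dir = Path(truth_dir)
        truth_dir.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(truth_dir / "samples.tsv", sep="\t", index=False)
        self.snp_genotypes.to_csv(truth_dir / "snp_genotypes.tsv", sep="\t")

    @classmethod
    def from_dir(cls, truth_dir: str | Path) -> "SyntheticTruth":
        truth_dir = Path(truth_dir)
        return cls(
            samples=pd.read_csv(truth_dir / "samples.tsv", sep="\t"),
            snp_genotypes=pd.read_csv(
                truth_dir / "snp_genotypes.tsv", sep="\t", index_col=0
            ),
        )


def simulate_read_counts(
    cn: np.ndarray,
    target_len: int,
    lib_factor: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-sample read counts for one capture target.

    Expected count is cn × coverage/read_len × target_len × lib_factor;
    Poisson by default, negative binomial at the configured overdispersion
    (variance = mean + overdispersion × mean²).
    """
    lam = (
        cn
        * (config.mean_target_coverage / config.read_len)
        * target_len
        * lib_factor
    )
    if config.overdispersion > 0:
        r = 1.0 / config.overdispersion
        p = r / (r + lam)
        return rng.negative_binomial(r, p)
    return rng.poisson(lam)


def simulate_allele_depths(
    combo: Mapping[str, int],
    signature: ParalogSignature,
    total_depth: int,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference/alternative depths at each signature position.

    Each read is drawn from one carried copy uniformly at random and reports
    that copy's allele, flipped with probability ``error_rate``.
    """
    if total_depth <= 0:
        raise SimulationError("total_depth must be positive")
    names = [n for n, k in combo.items() for _ in range(k)]
    npos = signature.n_positions
    adr = np.zeros(npos, dtype=np.int64)
    ada = np.zeros(npos, dtype=np.int64)
    copy_idx = rng.integers(0, len(names), size=(npos, total_depth))
    flips = rng.random((npos, total_depth)) < error_rate
    for i in range(npos):
        ref_base = signature.ref_allele[i]
        is_alt = np.array(
            [signature.alleles[names[c]][i] != ref_base for c in copy_idx[i]]
        )
        is_alt = np.logical_xor(is_alt, flips[i])
        ada[i] = int(is_alt.sum())
        adr[i] = total_depth - ada[i]
    return adr, ada


def simulate_depth_profile(
    deletions: Sequence[tuple[int, int]],
    contig_len: int,
    coverage: float,
    read_len: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Idealised per-base depth over the locus: ~coverage outside deletions,
    zero inside, linear ramps of one read length at the edges."""
    depth = np.full(contig_len, float(coverage))
    ramp = np.linspace(0.0, 1.0, read_len, endpoint=False)
    for s, e in deletions:
        depth[s:e] = 0.0
        lo = max(0, s - read_len)
        depth[lo:s] = np.minimum(depth[lo:s], coverage * ramp[::-1][: s - lo])
        hi = min(contig_len, e + read_len)
        depth[e:hi] = np.minimum(depth[e:hi], coverage * ramp[: hi - e])
    if rng is not None:
        depth = rng.poisson(np.maximum(depth, 0.0)).astype(float)
    return depth


def simulate_frost_phenotype(
    genotype_ids: Sequence[str],
    effects: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Replicated 0–5 frost scores from an additive genotype + box model.

    latent = baseline + genotype effect + box effect + N(0, residual_sd);
    the score is the latent value clipped to [0, 5] and rounded to the
    configured granularity, mimicking visual regrowth scoring.  Box
    assignment is randomized per replicate; both test temperatures are
    emitted with the same genotype effects.
    """
    rows = []
    boxes = [f"box{b + 1}" for b in range(config.n_boxes)]
    box_eff = rng.normal(0.0, config.box_effect_sd, size=config.n_boxes)
    g = config.score_granularity
    for temperature in (-6.0, -9.0):
        for gid in genotype_ids:
            box_of_rep = rng.integers(0, config.n_boxes, size=config.n_replicates)
            noise = rng.normal(0.0, config.residual_sd, size=config.n_replicates)
            for rep in range(config.n_replicates):
                b = int(box_of_rep[rep])
                latent = (
                    config.frost_baseline
                    + effects[gid]
                    + box_eff[b]
                    + noise[rep]
                )
                score = float(np.clip(np.round(latent / g) * g, 0.0, 5.0)) if g > 0 else float(
                    np.clip(latent, 0.0, 5.0)
                )
                rows.append(
                    {
                        "genotype_id": gid,
                        "box_id": boxes[b],
                        "replicate": rep + 1,
                        "temperature": temperature,
                        "score": score,
                    }
                )
    return pd.DataFrame(rows)


def _call_gt_from_depths(adr: int, ada: int) -> int:
    tot = adr + ada
    if tot == 0:
        return GT_MISSING
    frac = ada / tot
    if frac >= 0.9:
        return GT_HOM_ALT
    if frac <= 0.1:
        return GT_HOM_REF
    return GT_HET


def simulate_panel(
    config: SimulationConfig,
    seed: int,
    out_dir: str | Path | None = None,
    signature: ParalogSignature | None = None,
    catalog: HaplotypeCatalog | None = None,
) -> tuple[SyntheticTruth, dict]:
    """Generate the full panel; optionally write inputs/ and truth/ trees.

    Fully reproducible: identical (config, seed) produce byte-identical
    files.  Returns the truth object and a dict of the in-memory inputs
    (metadata, targets, counts, variants, deletions, frost scores).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    signature = signature or default_signature()
    catalog = catalog or default_catalog()

    # --- samples and categories -------------------------------------------
    n = config.n_samples
    categories = [
        c for c, k in sorted(config.category_counts.items()) for _ in range(k)
    ]
    rng.shuffle(categories)
    sample_ids = [REFERENCE_SAMPLE] + [f"WB-{i:03d}" for i in range(1, n)]
    # the reference genotype is a cultivar: swap one into first position
    if "cultivar" in categories and categories[0] != "cultivar":
        k = categories.index("cultivar")
        categories[0], categories[k] = categories[k], categories[0]

    lat_range = {
        "cultivar": (30.0, 62.0),
        "landrace": (22.0, 52.0),
        "wild": (28.0, 40.0),
        "unknown": (25.0, 55.0),
    }
    latitude = np.array(
        [rng.uniform(*lat_range[c]) for c in categories]
    ).round(3)
    longitude = rng.uniform(-10.0, 75.0, size=n).round(3)
    # a few formally bred cultivars without usable coordinates
    no_coord = rng.random(n) < 0.02
    latitude = np.where(no_coord, np.nan, latitude)
    longitude = np.where(no_coord, np.nan, longitude)

    lib_factor = rng.lognormal(0.0, config.lib_sigma, size=n)
    lib_factor[0] = 1.0
    total_mapped = np.round(config.base_total_mapped * lib_factor).astype(np.int64)

    # --- truth: copy numbers, combos, haplotypes --------------------------
    segment_cn = rng.choice(config.cn_support, size=n, p=config.cn_probs)
    segment_cn[0] = 1  # reference genotype is single copy

    combo_defs = []
    for combo, _p in config.combo_probs:
        items = combo if isinstance(combo[0], tuple) else (combo,)
        d: dict[str, int] = {}
        for name, k in items:
            d[name] = d.get(name, 0) + int(k)
        combo_defs.append(d)
    combo_idx = rng.choice(
        len(combo_defs), size=n, p=[p for _, p in config.combo_probs]
    )
    combo_idx[0] = next(
        i for i, d in enumerate(combo_defs) if d == {"morex_CBF2a": 1}
    )

    hap_probs = config.vrn1_hap_probs or _vrn1_hap_probs(catalog)
    hap_names = sorted(hap_probs)
    hap_p = np.array([hap_probs[h] for h in hap_names])
    hap_p = hap_p / hap_p.sum()
    vrn1_hap = rng.choice(hap_names, size=n, p=hap_p)
    vrn1_hap[0] = "VRN1-1"  # the reference genotype carries the 5154 bp allele

    vrn2_absent = rng.random(n) < config.vrn2_absence_prob
    vrn2_absent[0] = True  # the reference genotype lacks the repressor locus

    cbf14_hap = rng.choice(
        [f"hap{k + 1}" for k in range(len(config.cbf14_probs))],
        size=n,
        p=config.cbf14_probs,
    )

    targets = default_targets_frame()
    gene_cn = {
        "HvCBF2a": segment_cn.astype(float),
        "HvCBF4b": segment_cn.astype(float),
        "HvNUD": np.ones(n),
        "HvSAMDC": np.ones(n),
        VRN2_GENE: np.where(vrn2_absent, 0.0, 1.0),
        CBF2_PARALOG_GENE: np.array(
            [sum(combo_defs[i].values()) for i in combo_idx], dtype=float
        ),
    }

    # --- read counts per capture target -----------------------------------
    count_rows = []
    for t in targets.itertuples():
        gene = t.name.rsplit("_", 1)[0]
        counts = simulate_read_counts(
            gene_cn[gene], t.end - t.start, lib_factor, config, rng
        )
        for sid, c in zip(sample_ids, counts):
            count_rows.append((sid, t.name, int(c)))
    counts_df = pd.DataFrame(count_rows, columns=["sample_id", "target_id", "count"])

    # --- SNP matrix on the vernalization contig ---------------------------
    snp_pos = np.sort(
        rng.choice(np.arange(100, VRN1_CONTIG_LEN - 100), config.snp_sites, replace=False)
    )
    bases = np.array(list("ACGT"))
    ref_b = bases[rng.integers(0, 4, size=config.snp_sites)]
    alt_b = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in ref_b]
    )
    freq = np.clip(rng.beta(0.25, 2.5, size=config.snp_sites), 1.0 / n, 0.95)
    truth_geno = (rng.random((config.snp_sites, n)) < freq[:, None]).astype(np.int8)

    gt = np.where(truth_geno == 1, GT_HOM_ALT, GT_HOM_REF).astype(np.int8)
    depth = rng.poisson(config.snp_depth, size=gt.shape)
    err = config.error_rate
    ada = np.where(
        truth_geno == 1,
        rng.binomial(depth, 1 - err),
        rng.binomial(depth, err),
    )
    adr = depth - ada
    miss = rng.random(gt.shape) < config.missing_rate
    gt[miss] = GT_MISSING
    adr[miss] = 0
    ada[miss] = 0

    vrn1_sites = pd.DataFrame(
        {
            "contig": VRN1_CONTIG,
            "pos": snp_pos,
            "ref": ref_b,
            "alt": alt_b,
        }
    )

    # --- signature-position calls on the CBF2 contig ----------------------
    sig_npos = signature.n_positions
    sig_gt = np.zeros((sig_npos, n), dtype=np.int8)
    sig_adr = np.zeros((sig_npos, n), dtype=np.int32)
    sig_ada = np.zeros((sig_npos, n), dtype=np.int32)
    depth_per_copy = int(round(config.snp_depth))
    for j in range(n):
        combo = combo_defs[combo_idx[j]]
        total_depth = depth_per_copy * sum(combo.values())
        a_r, a_a = simulate_allele_depths(
            combo, signature, total_depth, config.error_rate, rng
        )
        sig_adr[:, j] = a_r
        sig_ada[:, j] = a_a
        sig_gt[:, j] = [_call_gt_from_depths(r, a) for r, a in zip(a_r, a_a)]
    sig_sites = pd.DataFrame(
        {
            "contig": CBF2_CONTIG,
            "pos": [CBF2_GENE_START + off for off in signature.positions],
            "ref": list(signature.ref_allele),
            "alt": [
                a if a != "." else ("A" if r != "A" else "C")
                for a, r in zip(signature.alt_allele, signature.ref_allele)
            ],
        }
    )

    # --- CBF14 haplotype-tagging SNPs -------------------------------------
    cbf14_truth = np.array(
        [CBF14_HAPLOTYPE_CODES[h] for h in cbf14_hap], dtype=np.int8
    ).T  # sites × samples
    c14_gt = np.where(cbf14_truth == 1, GT_HOM_ALT, GT_HOM_REF).astype(np.int8)
    c14_depth = rng.poisson(config.snp_depth, size=c14_gt.shape)
    c14_ada = np.where(
        cbf14_truth == 1,
        rng.binomial(c14_depth, 1 - err),
        rng.binomial(c14_depth, err),
    )
    c14_adr = c14_depth - c14_ada
    c14_miss = rng.random(c14_gt.shape) < config.missing_rate
    c14_gt[c14_miss] = GT_MISSING
    c14_adr[c14_miss] = 0
    c14_ada[c14_miss] = 0
    cbf14_sites = pd.DataFrame(
        {
            "contig": CBF14_CONTIG,
            "pos": [p for p, _, _ in CBF14_SNPS],
            "ref": [r for _, r, _ in CBF14_SNPS],
            "alt": [a for _, _, a in CBF14_SNPS],
        }
    )

    variants = VariantTable(
        sample_ids,
        pd.concat([vrn1_sites, sig_sites, cbf14_sites], ignore_index=True),
        np.vstack([gt, sig_gt, c14_gt]),
        np.vstack([adr, sig_adr, c14_adr]),
        np.vstack([ada, sig_ada, c14_ada]),
    )

    # --- deletion calls with breakpoint jitter ----------------------------
    del_rows = []
    jit = config.breakpoint_jitter
    for sid, hname in zip(sample_ids, vrn1_hap):
        hap = catalog.get(hname)
        for s, e in hap.deletions:
            js = s + int(rng.integers(-jit, jit + 1))
            je = e + int(rng.integers(-jit, jit + 1))
            del_rows.append((sid, VRN1_CONTIG, js, je))
    deletions_df = pd.DataFrame(
        del_rows, columns=["sample_id", "contig", "start", "end"]
    )

    # --- growth habit from truth ------------------------------------------
    regions = default_regions()
    reg = regions.regions["regulatory_2_8kb"]
    habit = []
    for hname, absent in zip(vrn1_hap, vrn2_absent):
        hap = catalog.get(hname)
        touches_reg = any(s < reg[1] and reg[0] < e for s, e in hap.deletions)
        if touches_reg:
            habit.append("spring")
        elif hap.is_wild:
            habit.append("facultative" if absent else "winter")
        else:
            # deletions outside the regulatory region have no established
            # phenotype; label by the vernalization-repressor status alone
            habit.append("winter" if not absent else "unknown")

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "biological_status": categories,
            "growth_habit": habit,
            "latitude": latitude,
            "longitude": longitude,
            "total_mapped_reads": total_mapped,
        }
    )

    # --- frost experiment on a spring subset ------------------------------
    spring_idx = [i for i, h in enumerate(habit) if h == "spring"]
    other_idx = [i for i in range(n) if i not in spring_idx]
    chosen = (spring_idx + other_idx)[: config.n_frost_genotypes]
    frost_ids = [sample_ids[i] for i in sorted(chosen)]
    eff_levels = dict(
        zip([f"hap{k + 1}" for k in range(len(config.cbf14_effects))],
            config.cbf14_effects)
    )
    gen_effects = {
        sample_ids[i]: eff_levels[cbf14_hap[i]]
        + config.cn_frost_effect * float(segment_cn[i])
        for i in sorted(chosen)
    }
    frost_df = simulate_frost_phenotype(frost_ids, gen_effects, config, rng)

    truth = SyntheticTruth(
        samples=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "category": categories,
                "cn_HvCBF2a": gene_cn["HvCBF2a"],
                "cn_HvCBF4b": gene_cn["HvCBF4b"],
                "cn_HvNUD": gene_cn["HvNUD"],
                "cn_HvSAMDC": gene_cn["HvSAMDC"],
                "paralog_combo": [
                    "+".join(
                        name if k == 1 else f"{name}x{k}"
                        for name, k in sorted(combo_defs[i].items())
                    )
                    for i in combo_idx
                ],
                "paralog_total_copies": gene_cn[CBF2_PARALOG_GENE].astype(int),
                "vrn1_haplotype": vrn1_hap,
                "vrn2_status": np.where(vrn2_absent, "absent", "present"),
                "cbf14_haplotype": cbf14_hap,
                "frost_effect": [
                    gen_effects.get(s, np.nan) for s in sample_ids
                ],
                "growth_habit": habit,
            }
        ),
        snp_genotypes=pd.DataFrame(
            truth_geno,
            index=[f"{VRN1_CONTIG}:{p}" for p in snp_pos],
            columns=sample_ids,
        ),
    )

    inputs = {
        "metadata": metadata,
        "targets": targets,
        "counts": counts_df,
        "variants": variants,
        "deletions": deletions_df,
        "frost": frost_df,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        inp = out_dir / "inputs"
        inp.mkdir(parents=True, exist_ok=True)
        with open(inp / "targets.bed", "w") as fh:
            for t in targets.itertuples():
                fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.name}\n")
        metadata.to_csv(inp / "samples.tsv", sep="\t", index=False)
        counts_df.to_csv(inp / "counts.tsv", sep="\t", index=False)
        variants.to_vcf(inp / "calls.vcf")
        deletions_df.to_csv(inp / "deletions.tsv", sep="\t", index=False)
        frost_df.to_csv(inp / "frost.tsv", sep="\t", index=False)
        truth.to_dir(out_dir / "truth")
    return truth, inputs
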