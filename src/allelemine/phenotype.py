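"""Frost-phenotype statistics: adjusted genotype means, backward-elimination
regression, and the small closed-form qPCR helpers.

Regrowth after freezing is scored 0 (death) to 5 (undamaged) per plant in a
replicated, sparsely populated genotype × box design.  Genotype means are
adjusted for box effects with an additive two-way fixed-effects model, then
related to genetic predictors (copy-number ratios, haplotype factors) by
multiple linear regression with backward elimination of non-significant
terms.  Scores are treated as numeric: genotype mean scores are close to
normally distributed at this replication level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05


class PhenotypeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# two-way additive model for genotype-adjusted means


def _connected_components(edges: Sequence[tuple[str, str]]) -> list[set[str]]:
    """Components of the bipartite genotype-box incidence graph.

    Genotype nodes are prefixed "g:" and box nodes "b:" so labels cannot
    collide.  A disconnected design makes genotype contrasts across
    components inestimable.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for g, b in edges:
        for node in (f"g:{g}", f"b:{b}"):
            parent.setdefault(node, node)
        union(f"g:{g}", f"b:{b}")
    comps: dict[str, set[str]] = {}
    for node in parent:
        comps.setdefault(find(node), set()).add(node)
    return list(comps.values())


@dataclass
class FrostScoreResults:
    """Fitted genotype and box effects of the two-way additive model."""

    adjusted_means: pd.Series  # per genotype
    box_effects: pd.Series  # per box, reference box at 0
    residual_sd: float
    n_obs: int

    def summary(self) -> str:
        lines = ["Two-way additive frost-score model", "=" * 40]
        lines.append(f"observations: {self.n_obs}")
        lines.append(f"residual SD:  {self.residual_sd:.4f}")
        lines.append("")
        lines.append("genotype  adjusted_mean")
        for g, m in self.adjusted_means.items():
            lines.append(f"{g:<12s} {m:8.3f}")
        return "\n".join(lines)


class FrostScoreModel:
    """Additive fixed-effects model score ~ genotype + box.

    The adjusted mean of a genotype is its fitted value averaged over the
    observed boxes, which makes the means invariant to box labelling.  With
    a balanced design they equal the arithmetic genotype means exactly.
    """

    def __init__(self, scores: pd.DataFrame) -> None:
        need = {"genotype_id", "box_id", "score"}
        if not need <= set(scores.columns):
            raise PhenotypeError(f"frost scores need columns {sorted(need)}")
        self.scores = scores.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path, temperature: float | None = None) -> "FrostScoreModel":
        df = pd.read_csv(path, sep="\t")
        if temperature is not None and "temperature" in df.columns:
            df = df[df["temperature"] == temperature]
        return cls(df)

    def fit(self) -> FrostScoreResults:
        df = self.scores
        genotypes = sorted(df["genotype_id"].astype(str).unique())
        boxes = sorted(df["box_id"].astype(str).unique())
        comps = _connected_components(
            list(zip(df["genotype_id"].astype(str), df["box_id"].astype(str)))
        )
        if len(comps) > 1:
            blocks = [
                sorted(n[2:] for n in comp if n.startswith("g:")) for comp in comps
            ]
            raise PhenotypeError(
                f"disconnected genotype × box design; blocks: {blocks}"
            )
        y = df["score"].to_numpy(dtype=float)
        n = len(y)
        g_idx = pd.Categorical(df["genotype_id"].astype(str), categories=genotypes).codes
        b_idx = pd.Categorical(df["box_id"].astype(str), categories=boxes).codes
        # intercept + drop-first dummies for genotype and box
        p = 1 + (len(genotypes) - 1) + (len(boxes) - 1)
        X = np.zeros((n, p))
        X[:, 0] = 1.0
        for i in range(n):
            if g_idx[i] > 0:
                X[i, g_idx[i]] = 1.0
            if b_idx[i] > 0:
                X[i, len(genotypes) - 1 + b_idx[i]] = 1.0
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            raise PhenotypeError(
                "design matrix is rank deficient after reference-level constraints"
            )
        beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        rss_val = float(((y - fitted) ** 2).sum())
        dof = n - p
        resid_sd = math.sqrt(rss_val / dof) if dof > 0 else float("nan")
        g_eff = np.concatenate(([0.0], beta[1 : len(genotypes)]))
        b_eff = np.concatenate(([0.0], beta[len(genotypes) :]))
        mean_box = float(b_eff.mean())
        adjusted = pd.Series(
            beta[0] + g_eff + mean_box, index=pd.Index(genotypes, name="genotype_id")
        )
        return FrostScoreResults(
            adjusted_means=adjusted,
            box_effects=pd.Series(b_eff, index=pd.Index(boxes, name="box_id")),
            residual_sd=resid_sd,
            n_obs=n,
        )


def genotype_adjusted_means(scores: pd.DataFrame) -> FrostScoreResults:
    """Convenience wrapper: fit the two-way model and return its results."""
    return FrostScoreModel(scores).fit()


# ---------------------------------------------------------------------------
# multiple linear regression with backward elimination


def _term_columns(data: pd.DataFrame, term: str) -> np.ndarray:
    col = data[term]
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.astype(str).unique())
        codes = pd.Categorical(col.astype(str), categories=levels).codes
        # drop-first indicator coding; a whole factor is one term
        X = np.zeros((len(col), len(levels) - 1))
        for i, c in enumerate(codes):
            if c > 0:
                X[i, c - 1] = 1.0
        return X
    return col.to_numpy(dtype=float).reshape(-1, 1)


def _fit_rss(y: np.ndarray, blocks: Sequence[np.ndarray]) -> tuple[np.ndarray, float, int]:
    X = np.hstack([np.ones((len(y), 1))] + list(blocks)) if blocks else np.ones(
        (len(y), 1)
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    return beta, rss, X.shape[1]


@dataclass
class EliminationStep:
    removed: str
    p_value: float
    remaining: tuple[str, ...]


@dataclass
class BackwardEliminationResults:
    """Final model after stepwise removal of non-significant terms."""

    retained: tuple[str, ...]
    coefficients: dict[str, np.ndarray]
    intercept: float
    p_values: dict[str, float]
    r_squared: float
    trace: list[EliminationStep] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA

    def summary(self) -> str:
        lines = ["Backward-elimination linear model", "=" * 40]
        lines.append(f"alpha = {self.alpha}")
        if self.trace:
            lines.append("removed (in order):")
            for step in self.trace:
                lines.append(f"  {step.removed:<20s} p = {step.p_value:.4f}")
        else:
            lines.append("removed: none")
        lines.append("")
        if self.retained:
            lines.append("retained term        partial-F p")
            for t in self.retained:
                lines.append(f"{t:<20s} {self.p_values[t]:.3e}")
        else:
            lines.append("no term retained (intercept-only model)")
        lines.append("")
        lines.append(f"R² = {self.r_squared:.4f}")
        return "\n".join(lines)


def backward_elimination(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> BackwardEliminationResults:
    """Multiple linear regression with backward elimination.

    Starting from the full additive model, the term with the largest
    partial-F p-value ≥ alpha is removed (categorical factors as a whole)
    and the model refitted, until every remaining term is significant.
    Removal is keyed on the p-value with a deterministic tie-break on the
    term name, so the retained set does not depend on predictor order.
    An intercept-only outcome is valid, not an error.
    """
    y = data[response].to_numpy(dtype=float)
    terms = sorted(terms)
    blocks = {t: _term_columns(data, t) for t in terms}
    n_cols = 1 + sum(b.shape[1] for b in blocks.values())
    if len(y) <= n_cols:
        raise PhenotypeError(
            f"n = {len(y)} observations for {n_cols} model columns"
        )

    def partial_p(current: list[str]) -> dict[str, float]:
        _, rss_full, p_full = _fit_rss(y, [blocks[t] for t in current])
        out = {}
        for t in current:
            others = [blocks[u] for u in current if u != t]
            _, rss_red, p_red = _fit_rss(y, others)
            q = p_full - p_red
            dof = len(y) - p_full
            if rss_full <= 0:
                out[t] = 0.0
                continue
            F = ((rss_red - rss_full) / q) / (rss_full / dof)
            out[t] = float(stats.f.sf(F, q, dof))
        return out

    current = list(terms)
    trace: list[EliminationStep] = []
    while current:
        pvals = partial_p(current)
        worst = max(current, key=lambda t: (pvals[t], t))
        if pvals[worst] < alpha:
            break
        current.remove(worst)
        trace.append(
            EliminationStep(worst, pvals[worst], tuple(current))
        )
    beta, rss, _ = _fit_rss(y, [blocks[t] for t in current])
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    coefs: dict[str, np.ndarray] = {}
    offset = 1
    for t in current:
        k = blocks[t].shape[1]
        coefs[t] = beta[offset : offset + k].copy()
        offset += k
    final_p = partial_p(current) if current else {}
    return BackwardEliminationResults(
        retained=tuple(current),
        coefficients=coefs,
        intercept=float(beta[0]),
        p_values=final_p,
        r_squared=r2,
        trace=trace,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# closed-form helpers


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise PhenotypeError("pearson correlation needs n >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise PhenotypeError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise PhenotypeError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def qpcr_efficiency(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope: E = 10^(−1/slope) − 1.

    A perfect doubling per cycle (slope = −1/log10 2 ≈ −3.32) gives E = 1.
    """
    if slope >= 0:
        raise PhenotypeError("invalid standard curve: slope must be negative")
    return 10.0 ** (-1.0 / slope) - 1.0


def ddct_fold_change(
    ct_target_treated: float,
    ct_hk_treated: float,
    ct_target_control: float,
    ct_hk_control: float,
) -> float:
    """Relative expression by the 2^−ΔΔCt method."""
    for v in (ct_target_treated, ct_hk_treated, ct_target_control, ct_hk_control):
        if not math.isfinite(v):
            raise PhenotypeError("Ct values must be finite")
    ddct = (ct_target_treated - ct_hk_treated) - (ct_target_control - ct_hk_control)
    return 2.0 ** (-ddct)


def cn_latitude_summary(
    cn_table: pd.DataFrame,
    metadata: pd.DataFrame,
    genes: Sequence[str] = ("HvCBF2a", "HvCBF4b"),
    band_width_deg: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of summed gene copy number by latitude band.

    Sums cn_ratio over ``genes`` per sample, joins sampling latitude, and
    reports n, median and max of the sum per band (bands are left-closed,
    keyed by their lower edge).  Samples without latitude are returned
    separately as unlocated.
    """
    sub = cn_table[cn_table["gene_id"].isin(genes)]
    summed = sub.groupby("sample_id")["cn_ratio"].sum().rename("cn_sum")
    merged = metadata.merge(summed, left_on="sample_id", right_index=True, how="inner")
    unlocated = merged[merged["latitude"].isna()][["sample_id", "cn_sum"]]
    located = merged.dropna(subset=["latitude"]).copy()
    located["band"] = (
        np.floor(located["latitude"] / band_width_deg) * band_width_deg
    )
    bands = (
        located.groupby("band")["cn_sum"]
        .agg(n="count", median="median", max="max")
        .reset_index()
    )
    return bands, unlocated.reset_index(drop=True)
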