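"""Self-contained differential-expression core for replicated RNA-seq counts.

Implements the minimal negative-binomial workflow needed by the stress-memory
analysis: median-of-ratios normalization, FPKM, method-of-moments dispersion
estimation, a Wald test on log2 fold changes between two conditions, and
Benjamini-Hochberg adjustment.  Differentially expressed genes (DEGs) are
called with the thresholds adjusted p < 0.05 and |log2 fold change| > 1.

The test is deliberately simple: per-condition normalized means with a
pseudocount, a delta-method standard error under the NB variance function
``var = mu + alpha * mu**2``, and a two-sided normal p-value.  It is not a
GLM and makes no claim of numerical parity with full DE packages; its test
surface is recovery of planted effects in simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# DEG thresholds: strict inequalities throughout.
PADJ_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0

#: pseudocount added to normalized condition means before forming ratios
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus a design mapping samples to
    (condition, replicate).

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integers, index = gene ids, columns = sample ids.
    design : pandas.DataFrame
        Index = sample ids, columns ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers in count matrix")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design map: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            c = self.design.loc[s, "condition"]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.samples if self.design.loc[s, "condition"] == condition]
        if not out:
            raise ValueError(f"unknown condition label: {condition!r}")
        return out

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(counts=counts, design=design)

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        self.design.to_csv(samples_path, sep="\t", index_label="sample")


@dataclass
class ContrastResult:
    """Per-gene result of one two-condition contrast.

    ``table`` has columns baseMean, log2fc, se, pvalue, padj, status
    (status in {"UP", "DOWN", "NS"}), indexed by gene.
    """

    condition_ref: str
    condition_alt: str
    table: pd.DataFrame = field(repr=False)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, condition_ref="ref", condition_alt="alt") -> "ContrastResult":
        return cls(condition_ref, condition_alt, pd.read_csv(path, sep="\t", index_col=0))


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    For each sample, the factor is the median over genes (restricted to
    genes with a positive geometric mean across samples) of
    count / geometric-mean.
    """
    mat = cm.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(mat).mean(axis=1)
    ok = np.isfinite(loggeo)
    if not ok.any():
        raise ValueError("no gene with all-positive counts; cannot normalize")
    ratios = mat[ok] / np.exp(loggeo[ok])[:, None]
    return pd.Series(np.median(ratios, axis=0), index=cm.samples, name="size_factor")


def normalized_counts(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(cm)
    return cm.counts / factors


def fpkm(cm: CountMatrix, gene_lengths: pd.Series | dict) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * total_counts[s]).
    """
    lengths = pd.Series(gene_lengths, dtype=float)
    missing = cm.genes.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for: {sorted(missing)[:5]}")
    lengths = lengths.reindex(cm.genes)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = cm.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("per-sample totals must be positive")
    return cm.counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def estimate_dispersion(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    shrink_weight: float = 0.3,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    Within each condition having >= 2 replicates, ``alpha = max(0,
    (s2 - mean) / mean**2)``; per-gene estimates are averaged across such
    conditions and optionally shrunk toward the trimmed mean of all
    estimates (weight ``shrink_weight``).
    """
    norm = normalized_counts(cm, factors)
    per_cond = []
    for cond in cm.conditions():
        cols = cm.samples_of(cond)
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy()
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (s2 - mu) / np.square(mu), 0.0)
        per_cond.append(np.maximum(a, 0.0))
    if not per_cond:
        raise ValueError("dispersion estimation needs >= 2 replicates in some condition")
    alpha = np.mean(per_cond, axis=0)
    if shrink_weight > 0:
        center = stats.trim_mean(alpha, 0.1)
        alpha = (1.0 - shrink_weight) * alpha + shrink_weight * center
    return pd.Series(alpha, index=cm.genes, name="dispersion")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def wald_contrast(
    cm: CountMatrix,
    factors: pd.Series,
    dispersions: pd.Series,
    condition_ref: str,
    condition_alt: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ContrastResult:
    """Wald test of alt vs ref on pseudocounted normalized condition means.

    log2fc = log2((m_alt + c) / (m_ref + c)); the standard error follows the
    delta method under var = mu + alpha mu**2:
    se = (1/ln 2) * sqrt((1/(m_alt+c) + alpha)/n_alt + (1/(m_ref+c) + alpha)/n_ref).
    """
    norm = normalized_counts(cm, factors)
    ref_cols = cm.samples_of(condition_ref)
    alt_cols = cm.samples_of(condition_alt)
    m_ref = norm[ref_cols].mean(axis=1).to_numpy()
    m_alt = norm[alt_cols].mean(axis=1).to_numpy()
    alpha = dispersions.reindex(cm.genes).to_numpy()
    c = pseudocount

    log2fc = np.log2((m_alt + c) / (m_ref + c))
    var = (1.0 / (m_alt + c) + alpha) / len(alt_cols) + (1.0 / (m_ref + c) + alpha) / len(ref_cols)
    se = np.sqrt(var) / np.log(2)
    with np.errstate(invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(pvalue)

    status = deg_status(log2fc, padj)

    table = pd.DataFrame(
        {
            "baseMean": norm[ref_cols + alt_cols].mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
            "padj": padj,
            "status": status,
        },
        index=cm.genes,
    )
    return ContrastResult(condition_ref, condition_alt, table)


def deg_status(log2fc, padj) -> np.ndarray:
    """UP / DOWN / NS per gene under the strict thresholds
    padj < 0.05 and |log2fc| > 1."""
    log2fc = np.atleast_1d(np.asarray(log2fc, dtype=float))
    padj = np.atleast_1d(np.asarray(padj, dtype=float))
    status = np.full(log2fc.shape, "NS", dtype=object)
    status[(padj < PADJ_THRESHOLD) & (log2fc > LFC_THRESHOLD)] = "UP"
    status[(padj < PADJ_THRESHOLD) & (log2fc < -LFC_THRESHOLD)] = "DOWN"
    return status


def call_degs(contrast: ContrastResult) -> tuple[set, set]:
    """Return the (UP, DOWN) DEG sets of a contrast."""
    t = contrast.table
    up = set(t.index[t["status"] == "UP"])
    down = set(t.index[t["status"] == "DOWN"])
    return up, down
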