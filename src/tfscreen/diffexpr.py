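"""Negative-binomial differential induction calling with BH selection.

The test is a two-condition likelihood-ratio test on NB(mu, alpha) counts:
under the null one common concentration q drives every sample through its
size factor (mu_j = s_j * q); under the alternative each condition has its
own rate. Dispersion alpha is fixed per gene from a method-of-moments
estimate, the statistic 2*(l_alt - l_null) is referred to chi-square(1),
and genes pass through Benjamini-Hochberg step-up selection at adjusted
P < alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

GENOTYPES = ("wt", "null")
TREATMENTS = ("untreated", "stimulated")


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    genotype: str
    treatment: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")


@dataclass
class CountMatrix:
    """Gene x sample integer counts under a genotype x treatment design."""

    counts: pd.DataFrame  # index gene_id, columns sample_id
    design: List[SampleDesign]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.design]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        if list(self.counts.columns) != ids:
            raise ValueError("count columns must match design sample_ids in order")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.counts.index)

    def subset_genotype(self, genotype: str) -> "CountMatrix":
        keep = [s for s in self.design if s.genotype == genotype]
        return CountMatrix(self.counts[[s.sample_id for s in keep]], keep)

    def treatment_labels(self) -> np.ndarray:
        return np.array([s.treatment for s in self.design])


@dataclass
class DEConfig:
    alpha: float = 0.05          # BH threshold on adjusted P
    alpha_min: float = 1e-8      # dispersion floor
    min_total_count: int = 1     # independent filter: total count across samples
    # guard against per-gene moment-estimate noise: use the larger of the
    # gene's own estimate and the across-genes median (cf. DESeq's
    # "maximum" dispersion sharing); raw per-gene estimates are
    # anticonservative at small replicate counts
    pool_dispersion: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.alpha_min <= 0:
            raise ValueError("alpha_min must be positive")


# ---------------------------------------------------------------------------
# Normalization and dispersion


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    factor_j = median over genes with all-positive rows of
    count_gj / geometric-mean_g. With ``pseudo_reference=True`` a half-count
    is added when no gene is positive in every sample.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        if not pseudo_reference:
            raise ValueError(
                "no gene has positive counts in every sample; "
                "re-run with pseudo_reference=True to use a half-count pseudo-reference"
            )
        arr = arr + 0.5
        positive = np.ones(arr.shape[0], dtype=bool)
    sub = arr[positive]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    condition: Sequence[str],
    factors: pd.Series,
    alpha_min: float = 1e-8,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    Within each condition: alpha_hat = (s^2 - m) / m^2 with m the mean and
    s^2 the sample variance of normalized counts; estimates are averaged
    across conditions (conditions with zero mean contribute nothing) and
    floored at ``alpha_min``. Genes with zero overall mean get the floor.
    """
    cond = np.asarray(condition)
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    per_cond: List[np.ndarray] = []
    for label in pd.unique(cond):
        block = norm[:, cond == label]
        m = block.mean(axis=1)
        if block.shape[1] >= 2:
            v = block.var(axis=1, ddof=1)
        else:
            v = np.zeros_like(m)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, np.nan)
        per_cond.append(a)
    stacked = np.vstack(per_cond)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        avg = np.nanmean(stacked, axis=0)
    avg = np.where(np.isfinite(avg), avg, alpha_min)
    return pd.Series(np.maximum(avg, alpha_min), index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorized across genes)


def _nb_loglik(k: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row sums of NB log-pmf; k, mu are (G, S); r is (G, 1) = 1/alpha."""
    mu = np.maximum(mu, 1e-300)
    return np.sum(
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1.0)
        + r * (np.log(r) - np.log(r + mu))
        + k * (np.log(mu) - np.log(r + mu)),
        axis=1,
    )


def _fit_rate(k: np.ndarray, s: np.ndarray, r: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """MLE of the common concentration q with mu_j = s_j * q, alpha fixed.

    Solves sum_j k_j / q = sum_j s_j (r + k_j) / (r + s_j q) by the
    monotone fixed-point iteration q <- sum(k) / sum(s_j (r+k_j)/(r+s_j q)),
    which reduces to q = sum(k)/sum(s) in the Poisson limit r -> inf.
    """
    total = k.sum(axis=1)
    q = total / s.sum()
    zero = total == 0
    q = np.where(zero, 0.0, np.maximum(q, 1e-300))
    for _ in range(200):
        denom = np.sum(s[None, :] * (r + k) / (r + s[None, :] * q[:, None]), axis=1)
        q_new = np.where(zero, 0.0, total / np.maximum(denom, 1e-300))
        if np.all(np.abs(q_new - q) <= tol * np.maximum(q, 1.0)):
            q = q_new
            break
        q = q_new
    return q


def nb_lrt_vectorized(
    counts: np.ndarray,
    factors: np.ndarray,
    is_b: np.ndarray,
    alpha: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """LRT p-values and log2 fold-changes (condition B over A) for all genes.

    Parameters are per-gene arrays except ``factors`` (per sample) and
    ``is_b`` (per-sample boolean, True for the second condition). All-zero
    genes get p-value 1 and log2fc 0.
    """
    k = np.asarray(counts, dtype=float)
    s = np.asarray(factors, dtype=float)
    r = (1.0 / np.asarray(alpha, dtype=float))[:, None]
    ka, sa = k[:, ~is_b], s[~is_b]
    kb, sb = k[:, is_b], s[is_b]

    q0 = _fit_rate(k, s, r)
    qa = _fit_rate(ka, sa, r)
    qb = _fit_rate(kb, sb, r)

    l0 = _nb_loglik(k, s[None, :] * q0[:, None], r)
    la = _nb_loglik(ka, sa[None, :] * qa[:, None], r)
    lb = _nb_loglik(kb, sb[None, :] * qb[:, None], r)
    lam = np.maximum(2.0 * (la + lb - l0), 0.0)
    pvalue = chi2.sf(lam, df=1)

    # half-count pseudo-rate when a fitted per-condition rate is zero
    qa_safe = np.where(qa > 0, qa, 0.5 / sa.sum())
    qb_safe = np.where(qb > 0, qb, 0.5 / sb.sum())
    log2fc = np.log2(qb_safe / qa_safe)

    untestable = k.sum(axis=1) == 0
    pvalue = np.where(untestable, 1.0, pvalue)
    log2fc = np.where(untestable, 0.0, log2fc)
    return pvalue, log2fc


def nb_lrt_test(
    gene_counts: Sequence[float],
    factors: Sequence[float],
    condition: Sequence[str],
    alpha_g: float,
) -> Tuple[float, float]:
    """Single-gene LRT; conditions taken in order of first appearance.

    Returns (pvalue, log2fc) with log2fc = log2(rate of second condition /
    rate of first).
    """
    cond = np.asarray(condition)
    labels = list(pd.unique(cond))
    if len(labels) != 2:
        raise ValueError(f"exactly two conditions required, got {labels}")
    is_b = cond == labels[1]
    p, lfc = nb_lrt_vectorized(
        np.asarray(gene_counts, dtype=float)[None, :],
        np.asarray(factors, dtype=float),
        is_b,
        np.asarray([alpha_g], dtype=float),
    )
    return float(p[0]), float(lfc[0])


# ---------------------------------------------------------------------------
# Multiple testing and the per-genotype driver


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_de(counts: CountMatrix, genotype: str, config: Optional[DEConfig] = None) -> pd.DataFrame:
    """Stimulated-vs-untreated calls for one genotype.

    Pipeline: size factors -> MoM dispersion -> per-gene NB LRT -> BH over
    the genes passing the independent filter. Returns a table with columns
    gene_id, base_mean, log2fc, dispersion, pvalue, padj, call, tested.
    """
    config = config or DEConfig()
    sub = counts.subset_genotype(genotype)
    treatments = sub.treatment_labels()
    present = set(treatments)
    if set(TREATMENTS) - present:
        missing = sorted(set(TREATMENTS) - present)
        raise ValueError(f"genotype {genotype!r}: missing treatment(s) {missing}")
    for t in TREATMENTS:
        if (treatments == t).sum() < 2:
            warnings.warn(
                f"genotype {genotype!r}, treatment {t!r}: fewer than 2 replicates",
                stacklevel=2,
            )

    # dispersion is shared across the whole design: estimated within every
    # genotype x treatment cell of the full matrix and averaged, which
    # stabilizes the moment estimator at small per-cell replicate counts
    all_factors = size_factors(counts.counts)
    cells = np.array([f"{s.genotype}:{s.treatment}" for s in counts.design])
    disp = estimate_dispersion(counts.counts, cells, all_factors, alpha_min=config.alpha_min)
    if config.pool_dispersion:
        disp = np.maximum(disp, float(np.median(disp)))

    keep = [s.genotype == genotype for s in counts.design]
    factors = all_factors[keep]
    is_stim = treatments == "stimulated"
    pvalue, log2fc = nb_lrt_vectorized(
        sub.counts.to_numpy(), factors.to_numpy(), is_stim, disp.to_numpy()
    )
    norm = sub.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    base_mean = norm.mean(axis=1)

    tested = sub.counts.to_numpy().sum(axis=1) >= config.min_total_count
    padj = np.full(pvalue.shape, np.nan)
    if tested.any():
        padj[tested] = bh_adjust(pvalue[tested])

    call = np.where(
        tested & (padj < config.alpha) & (log2fc > 0),
        "up",
        np.where(tested & (padj < config.alpha) & (log2fc < 0), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene_id": sub.gene_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "dispersion": disp.to_numpy(),
            "pvalue": pvalue,
            "padj": padj,
            "call": call,
            "tested": tested,
        }
    )


def genes_with_call(de: pd.DataFrame, call: str) -> set:
    return set(de.loc[de["call"] == call, "gene_id"])


# ---------------------------------------------------------------------------
# TSV I/O


def write_counts_tsv(cm: CountMatrix, path: str, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        cm.counts.rename_axis("gene_id").to_csv(fh, sep="\t")


def write_design_tsv(design: Iterable[SampleDesign], path: str, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        fh.write("sample_id\tgenotype\ttreatment\n")
        for s in design:
            fh.write(f"{s.sample_id}\t{s.genotype}\t{s.treatment}\n")


def read_counts_tsv(counts_path: str, design_path: str) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id", comment="#")
    # keep_default_na: the genotype label "null" must stay a string
    ddf = pd.read_csv(design_path, sep="\t", comment="#", keep_default_na=False)
    design = [
        SampleDesign(str(r.sample_id), str(r.genotype), str(r.treatment))
        for r in ddf.itertuples(index=False)
    ]
    counts = counts[[s.sample_id for s in design]]
    return CountMatrix(counts, design)
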