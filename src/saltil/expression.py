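"""Expression normalisation, differential-expression calling and the
cross-genotype salt-response overlap statistic.

Differential expression between two replicate groups is assessed with a
negative-binomial exact-style conditional test: group sums are modelled as
negative binomial with a common dispersion (pooled method-of-moments
estimate, or supplied), and the two-sided p-value is computed from the
conditional distribution of one group's sum given the total. Genes are then
called up-/down-regulated by the joint criteria |log2FC| > 0.5 (strict),
P <= 0.05 and mean FPKM >= 25 across the contrast's samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionError(ValueError):
    """Raised on invalid expression inputs."""


@dataclass(frozen=True)
class DGEConfig:
    """Thresholds for calling differentially expressed genes."""

    lfc_threshold: float = 0.5   # |log2FC| must exceed (strict)
    p_threshold: float = 0.05    # P <= (non-strict)
    fpkm_min: float = 25.0       # mean FPKM >= (non-strict)
    inclusive_lfc: bool = False  # if True, |log2FC| >= threshold qualifies
    bh_fdr: bool = False         # if True, apply Benjamini-Hochberg to p

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.p_threshold <= 0 or self.fpkm_min < 0:
            raise ExpressionError("thresholds must be positive")


def fpkm(
    counts: pd.DataFrame,
    gene_lengths_bp: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * libsize[s])``. Library
    sizes default to the column sums of ``counts``.
    """
    lengths = gene_lengths_bp.reindex(counts.index)
    if lengths.isna().any():
        raise ExpressionError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise ExpressionError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ExpressionError("library sizes must be positive for all samples")
    return (counts * 1e9).div(lengths, axis=0).div(library_sizes, axis=1)


def estimate_dispersion(group_a: pd.DataFrame, group_b: pd.DataFrame) -> float:
    """Pooled method-of-moments common NB dispersion.

    Under NB(mu, phi) the within-group sample variance has expectation
    ``mu + phi mu^2``; summing ``var - mean`` over genes and dividing by an
    unbiased estimate of ``sum(mu^2)`` (``mean^2 - var/n``) gives a shared
    dispersion that is close to unbiased even at 3 replicates. Clipped at 0
    when nothing exceeds Poisson noise.
    """
    num = 0.0
    den = 0.0
    for grp in (group_a, group_b):
        m = grp.mean(axis=1).to_numpy(dtype=float)
        v = grp.var(axis=1, ddof=1).to_numpy(dtype=float)
        num += float(np.sum(v - m))
        den += float(np.sum(np.square(m) - v / grp.shape[1]))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


#: Total count above which the conditional test switches to its normal limit.
_LARGE_TOTAL = 20_000


def _group_sum_logpmf(k: np.ndarray, mean: float, n: int,
                      dispersion: float) -> np.ndarray:
    """log pmf of a sum of ``n`` iid NB(mean, dispersion) counts."""
    if dispersion <= 1e-12:
        return stats.poisson.logpmf(k, n * mean)
    size = n / dispersion  # sum of n NB(size=1/phi) is NB(size=n/phi)
    p = size / (size + n * mean)
    return stats.nbinom.logpmf(k, size, p)


def _exact_test_one(sum_a: int, sum_b: int, n_a: int, n_b: int,
                    dispersion: float) -> float:
    """Two-sided conditional NB test for one gene.

    Conditions on the total t = sum_a + sum_b; p-value is the probability of
    outcomes no more likely than the observed split, mirroring the exact
    tests used for small-replicate RNA-seq.
    """
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    mu = t / (n_a + n_b)
    if t > _LARGE_TOTAL:
        # at large totals the conditional law is asymptotically normal;
        # enumeration would be slow and adds nothing at this resolution
        var_a = n_a * mu + dispersion * n_a * mu * mu
        var_b = n_b * mu + dispersion * n_b * mu * mu
        cond_mean = t * n_a / (n_a + n_b)
        cond_sd = np.sqrt(var_a * var_b / (var_a + var_b))
        z = (abs(sum_a - cond_mean) - 0.5) / cond_sd
        return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    if n_a == n_b:
        # symmetric conditional distribution around t/2: two-sided tail is
        # twice the lower tail of min(sum_a, t - sum_a)
        m = min(sum_a, t - sum_a)
        half = t // 2
        k = np.arange(0, half + 1)
        logp = (_group_sum_logpmf(k, mu, n_a, dispersion)
                + _group_sum_logpmf(t - k, mu, n_b, dispersion))
        # total mass over 0..t via symmetry: pairs (k, t-k), centre once
        if t % 2 == 0:
            if m == half:
                return 1.0  # observed the central split
            log_total = np.logaddexp(_logsumexp(logp[:-1]) + np.log(2.0),
                                     logp[-1])
        else:
            log_total = _logsumexp(logp) + np.log(2.0)
        tail = _logsumexp(logp[:m + 1])
        p = 2.0 * np.exp(tail - log_total)
        return float(min(1.0, p))
    # general (unbalanced) case: full enumeration
    k = np.arange(0, t + 1)
    logp = (_group_sum_logpmf(k, mu, n_a, dispersion)
            + _group_sum_logpmf(t - k, mu, n_b, dispersion))
    log_total = _logsumexp(logp)
    obs = logp[sum_a]
    mask = logp <= obs + 1e-12
    p = np.exp(_logsumexp(logp[mask]) - log_total)
    return float(min(1.0, p))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.sum(np.exp(x - m))))


def nb_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene two-group NB exact-style test.

    ``group_a`` and ``group_b`` are genes x replicates count matrices over
    the same genes. Returns a frame with the common dispersion used, per-gene
    p-values in [0, 1], and an ``all_zero`` flag (such genes get p = 1).
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ExpressionError("need at least two replicates per group")
    if not group_a.index.equals(group_b.index):
        raise ExpressionError("gene sets of the two groups differ")
    if dispersion is None:
        dispersion = estimate_dispersion(group_a, group_b)
    sums_a = group_a.sum(axis=1).to_numpy().astype(np.int64)
    sums_b = group_b.sum(axis=1).to_numpy().astype(np.int64)
    n_a, n_b = group_a.shape[1], group_b.shape[1]
    pvals = np.ones(len(sums_a))
    for i, (sa, sb) in enumerate(zip(sums_a, sums_b)):
        pvals[i] = _exact_test_one(int(sa), int(sb), n_a, n_b, dispersion)
    return pd.DataFrame(
        {"p": pvals, "all_zero": (sums_a + sums_b) == 0,
         "dispersion": dispersion},
        index=group_a.index)


def log2_fold_change(mean_a: pd.Series, mean_b: pd.Series,
                     pseudo: float = 0.01) -> pd.Series:
    """log2((mean_b + pseudo) / (mean_a + pseudo)); B relative to A."""
    return np.log2((mean_b + pseudo) / (mean_a + pseudo))


def dge_contrast(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_lengths_bp: pd.Series,
    genotype: str,
    cfg: DGEConfig = DGEConfig(),
    conditions: tuple[str, str] = ("control", "salt"),
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Salt-versus-control DEG table for one genotype.

    Builds FPKMs over the contrast's samples, runs the NB test and applies
    the calling thresholds. When the metadata carries a ``library_size``
    column (known effective depths) FPKMs use it and counts are rescaled to
    the common (geometric-mean) depth before the exact test, which assumes
    equal library sizes; otherwise column totals serve as library sizes.
    Returns per-gene log2FC (salt over control), p, mean FPKM and the call
    in {up, down, ns}.
    """
    meta = metadata.set_index("sample_id")
    samples_a = meta.index[(meta["genotype"] == genotype)
                           & (meta["condition"] == conditions[0])]
    samples_b = meta.index[(meta["genotype"] == genotype)
                           & (meta["condition"] == conditions[1])]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ExpressionError(
            f"genotype {genotype!r} lacks >= 2 replicates per condition")
    contrast = list(samples_a) + list(samples_b)
    if "library_size" in meta.columns:
        libsizes = meta.loc[contrast, "library_size"].astype(float)
    else:
        libsizes = counts[contrast].sum(axis=0).astype(float)
    fk = fpkm(counts[contrast], gene_lengths_bp, library_sizes=libsizes)
    common_depth = float(np.exp(np.log(libsizes).mean()))
    scaled = (counts[contrast] * (common_depth / libsizes)).round().astype(int)
    test = nb_test(scaled[list(samples_a)], scaled[list(samples_b)],
                   dispersion=dispersion)
    table = pd.DataFrame(index=counts.index)
    table["log2FC"] = log2_fold_change(
        fk[list(samples_a)].mean(axis=1), fk[list(samples_b)].mean(axis=1))
    table["p"] = test["p"]
    table["mean_fpkm"] = fk.mean(axis=1)
    return call_degs(table, cfg)


def call_degs(table: pd.DataFrame, cfg: DGEConfig = DGEConfig()) -> pd.DataFrame:
    """Apply the DEG thresholds to a table with log2FC, p and mean_fpkm.

    Fold change is strict (>0.5 or <-0.5), p and FPKM are non-strict
    (<= 0.05, >= 25), matching the printed operators of the criteria.
    """
    required = {"log2FC", "p", "mean_fpkm"}
    if not required.issubset(table.columns):
        raise ExpressionError(f"DEG table needs columns {required}")
    out = table.copy()
    p = out["p"]
    if cfg.bh_fdr:
        p = pd.Series(_bh_adjust(out["p"].to_numpy()), index=out.index)
        out["p_adj"] = p
    if cfg.inclusive_lfc:
        up_fc = out["log2FC"] >= cfg.lfc_threshold
        dn_fc = out["log2FC"] <= -cfg.lfc_threshold
    else:
        up_fc = out["log2FC"] > cfg.lfc_threshold
        dn_fc = out["log2FC"] < -cfg.lfc_threshold
    passing = (p <= cfg.p_threshold) & (out["mean_fpkm"] >= cfg.fpkm_min)
    out["call"] = "ns"
    out.loc[up_fc & passing, "call"] = "up"
    out.loc[dn_fc & passing, "call"] = "down"
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# overlap statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapSummary:
    """Venn counts of salt-responsive genes in two genotype contrasts."""

    n_a: int
    n_b: int
    common_up: int
    common_down: int
    union_size: int

    @property
    def n_common(self) -> int:
        return self.common_up + self.common_down

    @property
    def pct_common(self) -> float:
        """100 * (common up + common down) / union, one-decimal quantity."""
        if self.union_size == 0:
            return float("nan")
        return 100.0 * self.n_common / self.union_size


def overlap_summary(
    up_a, down_a, up_b, down_b,
) -> OverlapSummary:
    """Overlap of salt-responsive gene sets between two genotypes.

    Arguments are the up- and down-regulated gene sets per genotype; the
    union is exact, and a gene up in one genotype but down in the other
    stays in the union without joining the common pool. For published Venn
    totals without gene identities use :func:`overlap_from_counts`.
    """
    sets = [frozenset(s) for s in (up_a, down_a, up_b, down_b)]
    up_a, down_a, up_b, down_b = sets
    if up_a & down_a:
        raise ExpressionError("genes both up and down in genotype A")
    if up_b & down_b:
        raise ExpressionError("genes both up and down in genotype B")
    common_up = len(up_a & up_b)
    common_down = len(down_a & down_b)
    union = (up_a | down_a) | (up_b | down_b)
    return OverlapSummary(
        n_a=len(up_a | down_a),
        n_b=len(up_b | down_b),
        common_up=common_up,
        common_down=common_down,
        union_size=len(union),
    )


def overlap_from_counts(
    n_a: int, n_b: int, common_up: int, common_down: int,
) -> OverlapSummary:
    """Overlap summary from published totals.

    With only counts available the union is ``n_a + n_b - common``, which
    presumes no gene is up in one genotype and down in the other among the
    common pool.
    """
    common = common_up + common_down
    if min(n_a, n_b, common_up, common_down) < 0:
        raise ExpressionError("counts must be non-negative")
    if common > min(n_a, n_b):
        raise ExpressionError("common count exceeds a genotype total")
    return OverlapSummary(
        n_a=n_a, n_b=n_b, common_up=common_up, common_down=common_down,
        union_size=n_a + n_b - common,
    )


def deg_sets(table: pd.DataFrame) -> tuple[frozenset[str], frozenset[str]]:
    """(up, down) gene-id sets from a called DEG table."""
    return (frozenset(table.index[table["call"] == "up"]),
            frozenset(table.index[table["call"] == "down"]))
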