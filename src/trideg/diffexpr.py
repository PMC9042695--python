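"""Count normalization and negative-binomial differential testing.

Implements an edgeR-style, deliberately simplified pipeline:

* TMM (trimmed mean of M-values) scale factors — doubly trimmed (30% on
  M, 5% on A) weighted mean of per-gene log ratios against a reference
  sample, with inverse asymptotic-variance weights, normalized to
  geometric mean 1.
* An exact conditional NB test on library-size-equalized group sums: the
  two-sided p-value of group A's sum given the total, under NB with a
  common dispersion φ (variance μ + φμ²).  φ = 0 reduces to the exact
  binomial split test.
* A method-of-moments common-dispersion estimator.
* Per-contrast fold changes on TMM-normalized CPM with a pseudo-count,
  BH-adjusted FDRs, and the DEG rule |FC| > 1.5 (strict) and p < 0.05 on
  the raw p-value.

Exact numerical parity with edgeR is not promised: tagwise shrinkage,
quantile-adjusted pseudo-counts and GLM machinery are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import TierThresholds

__all__ = [
    "DegThresholds",
    "ContrastResult",
    "ContrastTriplet",
    "tmm_factors",
    "nb_exact_test",
    "estimate_dispersion",
    "run_contrast",
    "run_triplet",
    "call_degs",
    "bh_adjust",
    "cpm",
    "signed_fc",
    "CONTRAST_NAMES",
]

CONTRAST_NAMES = ("L3vNT", "L4vNT", "L4vL3")

#: numerator/denominator treatments for each named contrast
_CONTRAST_GROUPS = {
    "L3vNT": ("IFNL3", "NT"),
    "L4vNT": ("IFNL4", "NT"),
    "L4vL3": ("IFNL4", "IFNL3"),
}


@dataclass(frozen=True)
class DegThresholds:
    """DEG rule: strictly more than fc_thresh-fold change and p < p_thresh."""

    fc_thresh: float = 1.5
    p_thresh: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_thresh <= 0 or self.p_thresh <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ContrastResult:
    """Per-gene statistics for one comparison within one cell type."""

    cell_type: str
    name: str
    table: pd.DataFrame  # index gene; log2FC, signed_FC, mean_CPM, p_value, FDR, is_DEG
    thresholds: DegThresholds = field(default_factory=DegThresholds)


@dataclass
class ContrastTriplet:
    """The three comparisons of one cell type over a shared gene universe."""

    cell_type: str
    results: dict[str, ContrastResult]

    def __post_init__(self) -> None:
        idx = None
        for name in CONTRAST_NAMES:
            if name not in self.results:
                raise ValueError(f"triplet is missing contrast {name}")
            t = self.results[name].table
            if idx is None:
                idx = t.index
            elif not t.index.equals(idx):
                raise ValueError("triplet contrasts must share identical gene order")

    def to_classify_input(self) -> pd.DataFrame:
        """Flatten into the per-gene table the classification step consumes."""
        a = self.results["L3vNT"].table
        b = self.results["L4vNT"].table
        c = self.results["L4vL3"].table
        return pd.DataFrame(
            {
                "signed_fc_l3": a["signed_FC"],
                "p_l3": a["p_value"],
                "signed_fc_l4": b["signed_FC"],
                "p_l4": b["p_value"],
                "signed_fc_l4vl3": c["signed_FC"],
                "p_l4vl3": c["p_value"],
            }
        )


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene identifiers in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample identifiers in count matrix")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("count matrix contains negative entries")


def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million, against raw or effective library sizes."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    return counts / lib_sizes * 1e6


def signed_fc(log2fc: float | np.ndarray) -> float | np.ndarray:
    """Display convention: ratio if >= 1, else negative reciprocal.

    log2FC = -7.1175 maps to about -138.86 (a 138.9-fold down-regulation).
    """
    lf = np.asarray(log2fc, dtype=float)
    out = np.where(lf >= 0, 2.0 ** lf, -(2.0 ** (-lf)))
    return float(out) if np.isscalar(log2fc) else out


def tmm_factors(
    counts: pd.DataFrame,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM scale factors, one per sample, geometric mean 1.

    The reference is the sample whose upper-quartile CPM is closest to the
    mean upper quartile (unless named explicitly).  For each sample, genes
    with a zero count in either the sample or the reference are dropped;
    the per-gene log2 ratios M are doubly trimmed (``trim_m`` from each M
    tail, ``trim_a`` from each A tail) and averaged with inverse
    asymptotic-variance weights.
    """
    _check_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")

    y = counts.to_numpy(dtype=float)
    n_s = lib.to_numpy()

    if reference is None:
        uq = np.array([np.quantile(y[:, j] / n_s[j], 0.75) for j in range(y.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if reference not in counts.columns:
            raise ValueError(f"unknown reference sample {reference!r}")
        ref_j = counts.columns.get_loc(reference)

    log_f = np.zeros(y.shape[1])
    yr, nr = y[:, ref_j], n_s[ref_j]
    for j in range(y.shape[1]):
        if j == ref_j:
            continue
        ys, ns = y[:, j], n_s[j]
        keep = (ys > 0) & (yr > 0)
        if not keep.any():
            continue
        ps, pr = ys[keep] / ns, yr[keep] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = (ns - ys[keep]) / (ns * ys[keep]) + (nr - yr[keep]) / (nr * yr[keep])

        n = len(m)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if kept.any() and w[kept].sum() > 0:
            log_f[j] = np.sum(w[kept] * m[kept]) / np.sum(w[kept])

    log_f -= log_f.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_f, index=counts.columns, name="tmm_factor")


def _exact_conditional_p(s_a: int, total: int, n_a: int, n_b: int, dispersion: float) -> float:
    """Two-sided exact p of the split s_a | total under common-dispersion NB.

    Probabilities of all splits no more likely than the observed one are
    summed (the "minimum-likelihood" two-sided rule, matching the exact
    binomial test in the Poisson limit).
    """
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)

    if dispersion == 0:
        dist_a = stats.poisson(n_a * mu)
        dist_b = stats.poisson(n_b * mu)
    else:
        r_a, r_b = n_a / dispersion, n_b / dispersion
        dist_a = stats.nbinom(r_a, r_a / (r_a + n_a * mu))
        dist_b = stats.nbinom(r_b, r_b / (r_b + n_b * mu))

    if total <= 2000:
        ks = np.arange(total + 1)
    else:
        eps = 1e-15
        lo = max(0, int(dist_a.ppf(eps)), total - int(dist_b.isf(eps)))
        hi = min(total, int(dist_a.isf(eps)), total - int(dist_b.ppf(eps)))
        lo = min(lo, s_a)
        hi = max(hi, s_a)
        ks = np.arange(lo, hi + 1)

    logp = dist_a.logpmf(ks) + dist_b.logpmf(total - ks)
    logp -= logp.max()
    p = np.exp(logp)
    p_obs = p[ks == s_a][0]
    tail = p[p <= p_obs * (1 + 1e-7)].sum() / p.sum()
    return float(min(1.0, tail))


def nb_exact_test(
    group_a_counts: np.ndarray,
    group_b_counts: np.ndarray,
    lib_sizes_a: np.ndarray,
    lib_sizes_b: np.ndarray,
    dispersion: float,
) -> float:
    """Exact conditional NB test between two groups of one gene's counts.

    Counts are first equalized to the geometric-mean effective library
    size, then the groups' rounded sums are compared conditionally on
    their total.  Returns a two-sided p in (0, 1].
    """
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    a = np.asarray(group_a_counts, dtype=float)
    b = np.asarray(group_b_counts, dtype=float)
    la = np.asarray(lib_sizes_a, dtype=float)
    lb = np.asarray(lib_sizes_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one sample")
    if (la <= 0).any() or (lb <= 0).any():
        raise ValueError("library sizes must be positive")

    l_common = np.exp(np.mean(np.log(np.concatenate([la, lb]))))
    s_a = int(round((a * (l_common / la)).sum()))
    s_b = int(round((b * (l_common / lb)).sum()))
    return _exact_conditional_p(s_a, s_a + s_b, a.size, b.size, dispersion)


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    eff_lib_sizes: pd.Series | None = None,
    min_mean: float = 1.0,
) -> float:
    """Common NB dispersion by pooled method of moments.

    Counts are equalized to the geometric-mean effective library size;
    within every group with >= 2 replicates, per-gene means m and unbiased
    variances v are pooled into the ratio estimator
    φ = Σ(v − m) / Σ(m² − v/n), floored at 0 (the m² denominator is
    corrected for the sampling variance of the mean).
    """
    _check_counts(counts)
    if eff_lib_sizes is None:
        eff_lib_sizes = counts.sum(axis=0).astype(float)
    eff = eff_lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    l_common = np.exp(np.mean(np.log(eff)))
    scaled = counts.to_numpy(dtype=float) * (l_common / eff)

    num = 0.0
    den = 0.0
    any_replicated = False
    for g in pd.unique(groups):
        cols = np.flatnonzero((groups == g).to_numpy())
        if len(cols) < 2:
            continue
        any_replicated = True
        sub = scaled[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        keep = m > min_mean
        num += float((v[keep] - m[keep]).sum())
        den += float((m[keep] ** 2 - v[keep] / len(cols)).clip(min=0.0).sum())
    if not any_replicated:
        raise ValueError("dispersion estimation needs at least one group with replicates")
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    result: ContrastResult, fc_thresh: float = 1.5, p_thresh: float = 0.05
) -> set[str]:
    """Gene ids passing |signed FC| > fc_thresh (strict) and p < p_thresh."""
    if fc_thresh <= 0 or p_thresh <= 0:
        raise ValueError("thresholds must be positive")
    t = result.table
    mask = (t["signed_FC"].abs() > fc_thresh) & (t["p_value"] < p_thresh)
    return set(t.index[mask])


def filter_expressed(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 2
) -> pd.DataFrame:
    """Low-expression filter: keep genes with CPM > min_cpm in >= min_samples."""
    keep = (cpm(counts) > min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep]


def _group_samples(design: pd.DataFrame, cell_type: str, treatment: str) -> list[str]:
    mask = (design["cell_type"] == cell_type) & (design["treatment"] == treatment)
    return list(design.index[mask])


def _contrast_stats(
    counts: pd.DataFrame,
    eff_lib: pd.Series,
    num_samples: list[str],
    den_samples: list[str],
    dispersion: float,
    thresholds: DegThresholds,
    cell_type: str,
    name: str,
) -> ContrastResult:
    cpm_mat = cpm(counts, eff_lib)
    mean_num = cpm_mat[num_samples].mean(axis=1)
    mean_den = cpm_mat[den_samples].mean(axis=1)
    log2fc = np.log2((mean_num + 0.5) / (mean_den + 0.5))

    y_num = counts[num_samples].to_numpy(dtype=float)
    y_den = counts[den_samples].to_numpy(dtype=float)
    la = eff_lib[num_samples].to_numpy(dtype=float)
    lb = eff_lib[den_samples].to_numpy(dtype=float)
    l_common = np.exp(np.mean(np.log(np.concatenate([la, lb]))))
    s_num = np.rint((y_num * (l_common / la)).sum(axis=1)).astype(np.int64)
    s_den = np.rint((y_den * (l_common / lb)).sum(axis=1)).astype(np.int64)

    p = np.array(
        [
            _exact_conditional_p(sa, sa + sb, y_num.shape[1], y_den.shape[1], dispersion)
            for sa, sb in zip(s_num, s_den)
        ]
    )
    sfc = signed_fc(log2fc.to_numpy())
    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "signed_FC": sfc,
            "mean_CPM": cpm_mat[num_samples + den_samples].mean(axis=1),
            "p_value": p,
            "FDR": bh_adjust(p),
        },
        index=counts.index,
    )
    table["is_DEG"] = (table["signed_FC"].abs() > thresholds.fc_thresh) & (
        table["p_value"] < thresholds.p_thresh
    )
    return ContrastResult(cell_type=cell_type, name=name, table=table, thresholds=thresholds)


def run_contrast(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    numerator: tuple[str, str],
    denominator: tuple[str, str],
    thresholds: DegThresholds = DegThresholds(),
    dispersion: float | None = None,
    min_cpm: float = 1.0,
    min_samples: int = 2,
) -> ContrastResult:
    """One comparison: TMM-normalize the two groups, test every gene.

    numerator / denominator are (cell_type, treatment) pairs.  If
    ``dispersion`` is None a common dispersion is estimated from the two
    groups' replicates.
    """
    _check_counts(counts)
    num = _group_samples(design, *numerator)
    den = _group_samples(design, *denominator)
    if not num or not den:
        missing = numerator if not num else denominator
        raise ValueError(f"no samples for group {missing} in the design")

    sub = filter_expressed(counts[num + den], min_cpm, min_samples)
    factors = tmm_factors(sub)
    eff_lib = sub.sum(axis=0) * factors
    if dispersion is None:
        groups = pd.Series(["num"] * len(num) + ["den"] * len(den), index=num + den)
        dispersion = estimate_dispersion(sub, groups, eff_lib)
    name = f"{numerator[1]}v{denominator[1]}"
    return _contrast_stats(
        sub, eff_lib, num, den, dispersion, thresholds, numerator[0], name
    )


def run_triplet(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    cell_type: str,
    thresholds: DegThresholds = DegThresholds(),
    dispersion: float | None = None,
    min_cpm: float = 1.0,
    min_samples: int = 2,
) -> ContrastTriplet:
    """The three contrasts of one cell type over a shared gene universe.

    The expression filter, TMM factors and the common dispersion are
    computed once from all of the cell type's samples, so the three
    result tables share an identical gene order.
    """
    _check_counts(counts)
    ct_samples = list(design.index[design["cell_type"] == cell_type])
    if not ct_samples:
        raise ValueError(f"no samples for cell type {cell_type!r} in the design")
    sub = filter_expressed(counts[ct_samples], min_cpm, min_samples)
    factors = tmm_factors(sub)
    eff_lib = sub.sum(axis=0) * factors
    if dispersion is None:
        groups = design.loc[ct_samples, "treatment"]
        dispersion = estimate_dispersion(sub, groups, eff_lib)

    results = {}
    for name, (num_tr, den_tr) in _CONTRAST_GROUPS.items():
        num = _group_samples(design, cell_type, num_tr)
        den = _group_samples(design, cell_type, den_tr)
        if not num or not den:
            raise ValueError(f"contrast {name} needs treatments {num_tr} and {den_tr}")
        results[name] = _contrast_stats(
            sub, eff_lib, num, den, dispersion, thresholds, cell_type, name
        )
    return ContrastTriplet(cell_type=cell_type, results=results)


def deg_thresholds_from_tiers(tiers: TierThresholds) -> DegThresholds:
    """The DEG rule embedded in a set of tier thresholds."""
    return DegThresholds(fc_thresh=tiers.fc_thresh, p_thresh=tiers.p_thresh)
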