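"""Pairwise negative-binomial differential expression and the
cross-comparison consistency logic.

The test is a simplified exact-style NB comparison of group count sums
on size-factor-normalized data (median-of-ratios factors): per-gene
dispersions are estimated by method of moments, shrunk toward a fitted
mean-dispersion trend, and the two-sided p-value comes from the
conditional distribution of one group's sum given the total.  The
bespoke part of the workflow is downstream: a gene counts as a
consistent cold-responsive candidate only when it is significant in
every pairwise comparison between the low group and each high group.
Externally computed per-comparison p-value tables can be substituted
for the built-in test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coldacc.containers import CountMatrix, SampleDesign

log = logging.getLogger(__name__)


def size_factors(counts: pd.DataFrame | CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the gene-wise geometric mean across samples; each
    sample's factor is the median ratio of its counts to the reference
    over genes expressed in all samples.  With ``pseudo_reference`` the
    geometric mean is taken over positive counts only, allowing data
    where no gene is expressed everywhere.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    k = counts.to_numpy(dtype=float)
    if pseudo_reference:
        logk = np.full_like(k, np.nan)
        np.log(k, out=logk, where=k > 0)
        npos = np.sum(~np.isnan(logk), axis=1)
        usable = npos > 0
        ref = np.exp(np.nanmean(logk[usable], axis=1))
        ratios = k[usable] / ref[:, None]
        with np.errstate(invalid="ignore"):
            factors = np.nanmedian(np.where(k[usable] > 0, ratios, np.nan), axis=0)
    else:
        allpos = (k > 0).all(axis=1)
        if not allpos.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; "
                "rerun with pseudo_reference=True"
            )
        ref = np.exp(np.log(k[allpos]).mean(axis=1))
        factors = np.median(k[allpos] / ref[:, None], axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class DEResult:
    """One pairwise comparison (A over B)."""

    comparison: tuple[str, str]
    table: pd.DataFrame  # base_mean_A, base_mean_B, lfc, p_value, adj_p, significant, direction
    alpha: float = 0.05

    @property
    def significant_genes(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])

    def direction_of(self, gene: str) -> str:
        return str(self.table.loc[gene, "direction"])


def _fit_dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit disp ~ a0 + a1/mean on genes with informative raw estimates."""
    ok = (mean > 0) & (disp > 0)
    if ok.sum() < 10:
        med = float(np.median(disp[disp > 0])) if (disp > 0).any() else 0.1
        return max(med, 1e-6), 0.0
    x = 1.0 / mean[ok]
    y = disp[ok]
    # robust-ish: trimmed least squares, dropping the top/bottom 5% residuals once
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    lo, hi = np.quantile(resid, [0.05, 0.95])
    keep = (resid >= lo) & (resid <= hi)
    if keep.sum() >= 10:
        coef, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)
    a0, a1 = float(coef[0]), float(coef[1])
    return max(a0, 1e-6), max(a1, 0.0)


def _nb_logpmf(k: np.ndarray, mean: float, alpha: float) -> np.ndarray:
    if alpha <= 1e-10:
        return stats.poisson.logpmf(k, mean)
    size = 1.0 / alpha
    return stats.nbinom.logpmf(k, size, size / (size + mean))


def _exact_nb_p(ka: int, kb: int, mu_a: float, mu_b: float,
                var_a: float, var_b: float) -> float:
    """Two-sided conditional p for group sum ka given total ka + kb.

    Group sums are modelled NB with the given means/variances; the
    conditional law of ka given the total is enumerated over the region
    carrying essentially all mass, and the p-value sums the conditional
    probabilities not exceeding that of the observed split.
    """
    total = ka + kb
    if total == 0:
        return 1.0
    alpha_a = max((var_a - mu_a) / mu_a**2, 0.0) if mu_a > 0 else 0.0
    alpha_b = max((var_b - mu_b) / mu_b**2, 0.0) if mu_b > 0 else 0.0
    # window around the conditional mode; always include the observation
    frac = mu_a / (mu_a + mu_b)
    center = total * frac
    sd = np.sqrt(max(total * frac * (1 - frac) + alpha_a * center**2, 1.0))
    lo = int(max(0, min(center - 12 * sd, ka - 2)))
    hi = int(min(total, max(center + 12 * sd, ka + 2)))
    grid = np.arange(lo, hi + 1)
    logp = _nb_logpmf(grid, mu_a, alpha_a) + _nb_logpmf(total - grid, mu_b, alpha_b)
    logp -= logp.max()
    p = np.exp(logp)
    p_obs = p[ka - lo]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum() / p.sum()))


def test_pairwise(
    counts: CountMatrix,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    prior_df: float = 10.0,
) -> DEResult:
    """Exact-style NB test of group A versus group B for every gene.

    Dispersions are method-of-moments estimates pooled within groups,
    shrunk toward the fitted mean-dispersion trend with ``prior_df``
    prior degrees of freedom; with fewer than two replicates per group
    the trend alone is used (logged).  All-zero genes get p = 1 and are
    excluded from the BH adjustment.
    """
    design.validate_against(counts)
    samples_a = design.samples_in(group_a)
    samples_b = design.samples_in(group_b)
    if not samples_a or not samples_b:
        raise ValueError(f"empty group in comparison {group_a} vs {group_b}")

    sf = size_factors(counts.counts, pseudo_reference=True)
    k = counts.counts[samples_a + samples_b].to_numpy(dtype=float)
    sfv = sf[samples_a + samples_b].to_numpy()
    na, nb_ = len(samples_a), len(samples_b)
    q = k / sfv  # normalized counts
    q_a, q_b = q[:, :na], q[:, na:]
    qbar = q.mean(axis=1)

    # raw method-of-moments dispersion, pooled within groups
    n_rep = na + nb_
    if na >= 2 or nb_ >= 2:
        parts, dfs = [], 0
        for sub in (q_a, q_b):
            if sub.shape[1] >= 2:
                parts.append(sub.var(axis=1, ddof=1) * (sub.shape[1] - 1))
                dfs += sub.shape[1] - 1
        w = sum(parts) / dfs
        shot = qbar * np.mean(1.0 / sfv)
        raw = np.maximum((w - shot) / np.maximum(qbar, 1e-12) ** 2, 0.0)
        a0, a1 = _fit_dispersion_trend(qbar, raw)
        trend = a0 + a1 / np.maximum(qbar, 1e-12)
        disp = (dfs * raw + prior_df * trend) / (dfs + prior_df)
    else:
        log.warning(
            "comparison %s vs %s has no replicated group; "
            "using pooled dispersion trend only", group_a, group_b,
        )
        w = q.var(axis=1, ddof=1)
        shot = qbar * np.mean(1.0 / sfv)
        raw = np.maximum((w - shot) / np.maximum(qbar, 1e-12) ** 2, 0.0)
        a0, a1 = _fit_dispersion_trend(qbar, raw)
        disp = a0 + a1 / np.maximum(qbar, 1e-12)
    disp = np.clip(disp, 1e-8, 10.0)

    sa, sb = sfv[:na], sfv[na:]
    ka = k[:, :na].sum(axis=1).astype(np.int64)
    kb = k[:, na:].sum(axis=1).astype(np.int64)
    mu_a = qbar * sa.sum()
    mu_b = qbar * sb.sum()
    var_a = qbar * sa.sum() + disp * qbar**2 * np.sum(sa**2)
    var_b = qbar * sb.sum() + disp * qbar**2 * np.sum(sb**2)

    n_genes = k.shape[0]
    pvals = np.ones(n_genes)
    tested = (ka + kb) > 0
    for i in np.flatnonzero(tested):
        pvals[i] = _exact_nb_p(int(ka[i]), int(kb[i]), mu_a[i], mu_b[i], var_a[i], var_b[i])
    n_zero = int((~tested).sum())
    if n_zero:
        log.info("%d all-zero genes excluded from BH adjustment", n_zero)

    adj = np.ones(n_genes)
    if tested.any():
        adj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    lfc = np.log2(((ka + 0.5) / sa.sum()) / ((kb + 0.5) / sb.sum()))
    significant = tested & (adj < alpha)
    direction = np.where(
        significant & (lfc > 0), "up_in_A", np.where(significant & (lfc < 0), "down_in_A", "none")
    )
    table = pd.DataFrame(
        {
            "base_mean_A": q_a.mean(axis=1),
            "base_mean_B": q_b.mean(axis=1),
            "lfc": lfc,
            "p_value": pvals,
            "adj_p": adj,
            "significant": significant,
            "direction": direction,
        },
        index=counts.gene_ids,
    )
    return DEResult(comparison=(group_a, group_b), table=table, alpha=alpha)


def deresult_from_table(
    df: pd.DataFrame, comparison: tuple[str, str], alpha: float = 0.05
) -> DEResult:
    """Wrap an externally computed DE table (any engine) as a DEResult.

    Needs columns lfc and either adj_p or p_value (BH applied if only
    p_value is present); gene ids in the index.
    """
    tab = df.copy()
    if "adj_p" not in tab.columns:
        tab["adj_p"] = multipletests(tab["p_value"].to_numpy(), method="fdr_bh")[1]
    if "p_value" not in tab.columns:
        tab["p_value"] = tab["adj_p"]
    tab["significant"] = tab["adj_p"] < alpha
    tab["direction"] = np.where(
        tab["significant"] & (tab["lfc"] > 0),
        "up_in_A",
        np.where(tab["significant"] & (tab["lfc"] < 0), "down_in_A", "none"),
    )
    return DEResult(comparison=comparison, table=tab, alpha=alpha)


@dataclass
class ConsistentDEGSet:
    """Genes significant in every low-vs-high pairwise comparison."""

    low_group: str
    high_groups: list[str]
    #: gene -> {high_group: direction in the (low, high) comparison}
    directions: dict[str, dict[str, str]] = field(default_factory=dict)
    #: gene -> True when direction sign is identical across comparisons
    consistent_direction: dict[str, bool] = field(default_factory=dict)
    per_comparison_significant: dict[str, set[str]] = field(default_factory=dict)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.directions)

    def direction_of(self, gene: str) -> str:
        dirs = set(self.directions[gene].values())
        return dirs.pop() if len(dirs) == 1 else "mixed"


def consistent_degs(results: dict[str, DEResult], low_group: str) -> ConsistentDEGSet:
    """Intersect the significant sets of all low-vs-high comparisons.

    ``results`` maps each high group to the DEResult of (low, high).
    """
    if not results:
        raise ValueError("no comparisons given")
    universes = [frozenset(r.table.index) for r in results.values()]
    if len(set(universes)) != 1:
        raise ValueError("gene universes differ across comparisons")
    high_groups = list(results)
    sig_sets = {h: results[h].significant_genes for h in high_groups}
    common = set.intersection(*sig_sets.values())
    directions = {
        g: {h: results[h].direction_of(g) for h in high_groups} for g in sorted(common)
    }
    consistent = {g: len(set(d.values())) == 1 for g, d in directions.items()}
    return ConsistentDEGSet(
        low_group=low_group,
        high_groups=high_groups,
        directions=directions,
        consistent_direction=consistent,
        per_comparison_significant=sig_sets,
    )


def _venn_counts(sets: dict[str, set[str]]) -> dict[str, int]:
    names = list(sets)
    universe = set().union(*sets.values()) if sets else set()
    out: dict[str, int] = {}
    for gene in universe:
        key = "&".join(n for n in names if gene in sets[n])
        out[key] = out.get(key, 0) + 1
    return out


def overlap_analysis(
    set_low1: ConsistentDEGSet,
    set_low2: ConsistentDEGSet,
    de_direct: DEResult | None = None,
) -> dict:
    """Overlap report between two consistent DEG sets (e.g. T2 and T5).

    Includes the per-high-group Venn membership counts for each low
    group and, when the direct low1-vs-low2 comparison is supplied, how
    many genes of each set are also significant there.
    """
    g1, g2 = set_low1.gene_ids, set_low2.gene_ids
    report = {
        "low_groups": (set_low1.low_group, set_low2.low_group),
        "n_set1": len(g1),
        "n_set2": len(g2),
        "n_intersection": len(g1 & g2),
        "intersection": sorted(g1 & g2),
        "venn_set1": _venn_counts(set_low1.per_comparison_significant),
        "venn_set2": _venn_counts(set_low2.per_comparison_significant),
    }
    if de_direct is not None:
        direct = de_direct.significant_genes
        report["n_set1_also_direct"] = len(g1 & direct)
        report["n_set2_also_direct"] = len(g2 & direct)
    return report


def deg_fpkm_export(fpkm: pd.DataFrame, degs: set[str]) -> pd.DataFrame:
    """log10(FPKM + 1) matrix restricted to DEGs, for external heatmaps."""
    keep = [g for g in fpkm.index if g in degs]
    return np.log10(fpkm.loc[keep] + 1.0)
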