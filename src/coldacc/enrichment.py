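"""Resampling-based significance of GO functional groups among DEGs.

The observed number of DEGs in each functional group is compared with
the counts obtained by repeatedly drawing random gene sets of the same
size from the expressed-gene background (10000 draws by default).  The
empirical two-sided p-value is Bonferroni-corrected across the groups
tested.  Because draws are taken without replacement from a finite
background, the exact null for a single group is hypergeometric, which
serves as an independent validation oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

NAMESPACES = ("BP", "CC", "MF")


@dataclass
class GOAnnotationMap:
    """gene -> functional groups, plus per-group label/namespace."""

    gene_to_groups: dict[str, set[str]]
    group_info: pd.DataFrame = field(default_factory=pd.DataFrame)
    # group_info: index group_id, columns label, namespace

    def __post_init__(self) -> None:
        if self.group_info.empty:
            ids = sorted({g for gs in self.gene_to_groups.values() for g in gs})
            self.group_info = pd.DataFrame(
                {"label": ids, "namespace": "BP"}, index=pd.Index(ids, name="group_id")
            )
        referenced = {g for gs in self.gene_to_groups.values() for g in gs}
        unknown = referenced - set(self.group_info.index)
        if unknown:
            raise ValueError(f"genes reference unknown groups: {sorted(unknown)[:5]}")

    @property
    def group_ids(self) -> list[str]:
        return list(self.group_info.index)

    def members(self, group_id: str, universe: set[str] | None = None) -> set[str]:
        out = {g for g, gs in self.gene_to_groups.items() if group_id in gs}
        return out if universe is None else out & universe

    def to_tsv(self, path) -> None:
        rows = [
            (g, grp, self.group_info.loc[grp, "namespace"])
            for g, gs in sorted(self.gene_to_groups.items())
            for grp in sorted(gs)
        ]
        pd.DataFrame(rows, columns=["gene_id", "go_id", "namespace"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "GOAnnotationMap":
        df = pd.read_csv(path, sep="\t")
        g2g: dict[str, set[str]] = {}
        for gene, go in zip(df["gene_id"], df["go_id"]):
            g2g.setdefault(str(gene), set()).add(str(go))
        info = (
            df[["go_id", "namespace"]]
            .drop_duplicates("go_id")
            .set_index("go_id")
            .rename_axis("group_id")
        )
        info["label"] = info.index
        return cls(gene_to_groups=g2g, group_info=info[["label", "namespace"]])


@dataclass
class EnrichmentResult:
    group_id: str
    namespace: str
    observed: int
    null_mean: float
    null_sd: float
    emp_p: float
    bonferroni_alpha: float
    significant: bool
    direction: str  # higher | lower
    n_iter: int
    seed: int


def _membership_matrix(
    background: list[str], annotation: GOAnnotationMap, group_ids: list[str]
) -> np.ndarray:
    col = {g: j for j, g in enumerate(group_ids)}
    M = np.zeros((len(background), len(group_ids)), dtype=bool)
    for i, gene in enumerate(background):
        for grp in annotation.gene_to_groups.get(gene, ()):
            j = col.get(grp)
            if j is not None:
                M[i, j] = True
    return M


def resample_null(
    background: set[str] | list[str],
    annotation: GOAnnotationMap,
    sample_size: int,
    n_iter: int = 10000,
    seed: int = 0,
    with_replacement: bool = False,
) -> pd.DataFrame:
    """Null group-count samples from random gene draws.

    Each of ``n_iter`` iterations draws ``sample_size`` genes from the
    background (without replacement by default) and counts, per group,
    how many drawn genes belong to it.  Returns an (n_iter x n_groups)
    DataFrame of counts, columns in ``annotation.group_ids`` order.
    """
    genes = sorted(set(background))
    n = len(genes)
    if sample_size > n:
        raise ValueError(f"sample_size {sample_size} exceeds background size {n}")
    if sample_size <= 0:
        raise ValueError("sample_size must be positive")
    group_ids = annotation.group_ids
    M = _membership_matrix(genes, annotation, group_ids)

    # Genes with identical membership patterns are exchangeable under a
    # uniform draw, so the per-pattern counts of a without-replacement
    # draw follow a multivariate hypergeometric (multinomial for
    # with-replacement); group counts are a linear map of those.
    patterns, class_counts = np.unique(M, axis=0, return_counts=True)
    group_classes = [np.flatnonzero(patterns[:, j]) for j in range(len(group_ids))]
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_iter, len(group_ids)), dtype=np.int32)
    chunk = max(1, int(2e7 / max(len(class_counts), 1)))
    for lo in range(0, n_iter, chunk):
        c = min(chunk, n_iter - lo)
        if with_replacement:
            draws = rng.multinomial(sample_size, class_counts / n, size=c)
        else:
            draws = rng.multivariate_hypergeometric(
                class_counts, sample_size, size=c, method="count"
            )
        for j, cls in enumerate(group_classes):
            if len(cls):
                counts[lo : lo + c, j] = draws[:, cls].sum(axis=1)
    return pd.DataFrame(counts, columns=group_ids)


def empirical_two_sided_p(null_counts: np.ndarray, observed: int) -> float:
    """Add-one-smoothed two-sided empirical p from a null sample."""
    n = len(null_counts)
    lower = (np.count_nonzero(null_counts <= observed) + 1) / (n + 1)
    upper = (np.count_nonzero(null_counts >= observed) + 1) / (n + 1)
    return min(1.0, 2.0 * min(lower, upper))


def enrichment_test(
    deg_set: set[str],
    background: set[str],
    annotation: GOAnnotationMap,
    n_iter: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    with_replacement: bool = False,
) -> list[EnrichmentResult]:
    """Test each functional group for DEG over/under-representation.

    A group is significant when its smoothed two-sided empirical p
    falls below the Bonferroni level alpha/m, where m counts the groups
    with at least one background gene.
    """
    deg_set = set(deg_set)
    background = set(background)
    if not deg_set:
        raise ValueError("empty DEG set")
    if not background:
        raise ValueError("empty background")
    extra = deg_set - background
    if extra:
        raise ValueError(f"DEGs outside background: {sorted(extra)[:5]}")

    null = resample_null(
        background, annotation, len(deg_set), n_iter=n_iter, seed=seed,
        with_replacement=with_replacement,
    )
    genes = sorted(background)
    M = _membership_matrix(genes, annotation, annotation.group_ids)
    bg_counts = M.sum(axis=0)
    deg_mask = np.array([g in deg_set for g in genes])
    obs_counts = M[deg_mask].sum(axis=0)

    tested = [j for j, c in enumerate(bg_counts) if c > 0]
    m = len(tested)
    if m == 0:
        raise ValueError("no functional group has background genes")
    bonf = alpha / m

    results: list[EnrichmentResult] = []
    for j in tested:
        gid = annotation.group_ids[j]
        nc = null.iloc[:, j].to_numpy()
        mean = float(nc.mean())
        results.append(
            EnrichmentResult(
                group_id=gid,
                namespace=str(annotation.group_info.loc[gid, "namespace"]),
                observed=int(obs_counts[j]),
                null_mean=mean,
                null_sd=float(nc.std(ddof=1)) if n_iter > 1 else 0.0,
                emp_p=empirical_two_sided_p(nc, int(obs_counts[j])),
                bonferroni_alpha=bonf,
                significant=empirical_two_sided_p(nc, int(obs_counts[j])) < bonf,
                direction="higher" if obs_counts[j] > mean else "lower",
                n_iter=n_iter,
                seed=seed,
            )
        )
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("group_id")


def hypergeom_oracle(
    obs: int, group_size: int, background_size: int, sample_size: int
) -> float:
    """Exact two-sided p for the without-replacement null.

    Tail sums of Hypergeometric(background_size, group_size,
    sample_size); two-sided as twice the smaller tail, capped at 1.
    """
    if not (0 <= group_size <= background_size and 0 < sample_size <= background_size):
        raise ValueError("inconsistent sizes")
    if not 0 <= obs <= min(group_size, sample_size):
        raise ValueError(f"obs={obs} impossible for given sizes")
    hg = stats.hypergeom(background_size, group_size, sample_size)
    lower = float(hg.cdf(obs))
    upper = float(hg.sf(obs - 1))
    return min(1.0, 2.0 * min(lower, upper))


def binomial_oracle(
    obs: int, group_size: int, background_size: int, sample_size: int
) -> float:
    """Exact two-sided p for the with-replacement null (binomial)."""
    b = stats.binom(sample_size, group_size / background_size)
    lower = float(b.cdf(obs))
    upper = float(b.sf(obs - 1))
    return min(1.0, 2.0 * min(lower, upper))


def go_barchart_table(
    annotation: GOAnnotationMap,
    gene_sets: dict[str, set[str]],
    enrichment: dict[str, list[EnrichmentResult]] | None = None,
) -> pd.DataFrame:
    """Percent of each gene set annotated to each group, by namespace.

    Mirrors a classification bar chart: one row per functional group,
    one percentage column per named gene set, with a significance mark
    ('*higher'/'*lower') joined from enrichment results where given.
    """
    rows = []
    for gid in annotation.group_ids:
        members = annotation.members(gid)
        row: dict[str, object] = {
            "group_id": gid,
            "label": annotation.group_info.loc[gid, "label"],
            "namespace": annotation.group_info.loc[gid, "namespace"],
        }
        for name, genes in gene_sets.items():
            row[f"pct_{name}"] = 100.0 * len(members & set(genes)) / len(genes) if genes else 0.0
        if enrichment:
            for name, res in enrichment.items():
                mark = ""
                for r in res:
                    if r.group_id == gid and r.significant:
                        mark = f"*{r.direction}"
                row[f"star_{name}"] = mark
        rows.append(row)
    return pd.DataFrame(rows).set_index("group_id")
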