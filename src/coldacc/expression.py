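"""Expression quantification and depth diagnostics.

FPKM (fragments per kilobase of transcript per million mapped
fragments) is computed from gene-level fragment counts and transcript
lengths.  The saturation diagnostic asks at what fraction of
sequencing depth per-gene FPKM estimates stabilise to within a
tolerance (10% by default) of their full-depth values; depth reduction
is modelled as binomial thinning of per-gene counts, which is
distributionally identical to uniform subsampling of mapped reads at
the gene level.  Relative qPCR quantification follows 2^-ddCq.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from coldacc.containers import CountMatrix, SampleDesign


def compute_fpkm(counts: CountMatrix) -> pd.DataFrame:
    """FPKM[g, s] = count[g, s] * 1e9 / (length[g] * total_count[s])."""
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero)}")
    return counts.counts * 1e9 / np.outer(counts.lengths.to_numpy(), totals.to_numpy())


@dataclass
class SaturationCurve:
    sample_id: str
    percentages: np.ndarray
    fraction_within: np.ndarray
    fpkm_threshold: float
    n_genes_included: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"percent_reads": self.percentages, "fraction_within": self.fraction_within}
        )


def saturation_curve(
    counts: CountMatrix,
    sample_id: str,
    percentages: list[float] | np.ndarray = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100),
    tolerance: float = 0.10,
    fpkm_threshold: float = 0.0,
    n_reps: int = 50,
    seed: int = 0,
) -> SaturationCurve:
    """Fraction of genes whose thinned-depth FPKM is within ``tolerance``
    of the full-depth value, at each depth percentage.

    Per-gene counts are thinned Binomial(count, p/100) and FPKM is
    recomputed on the thinned library; the fraction is averaged over
    ``n_reps`` replicates.  Genes with full-depth FPKM <= the threshold
    are excluded when the threshold is positive.  At p = 100 the
    subsample is the full library, so the fraction is exactly 1.
    """
    pct = np.asarray(percentages, dtype=float)
    if not np.all(np.diff(pct) > 0):
        raise ValueError("percentages must be strictly increasing")
    if pct[0] <= 0 or pct[-1] > 100:
        raise ValueError("percentages must lie in (0, 100]")
    if sample_id not in counts.sample_ids:
        raise ValueError(f"unknown sample {sample_id}")

    k = counts.counts[sample_id].to_numpy(dtype=np.int64)
    lengths = counts.lengths.to_numpy(dtype=float)
    total = k.sum()
    if total == 0:
        raise ValueError(f"sample {sample_id} has zero total count")
    final = k * 1e9 / (lengths * total)
    include = final > fpkm_threshold if fpkm_threshold > 0 else np.ones_like(final, dtype=bool)
    if not include.any():
        raise ValueError("no gene passes the FPKM inclusion threshold")
    n_inc = int(include.sum())

    rng = np.random.default_rng(seed)
    fractions = np.empty(len(pct))
    for i, p in enumerate(pct):
        if p == 100.0:
            fractions[i] = 1.0
            continue
        acc = 0.0
        for _ in range(n_reps):
            thin = rng.binomial(k, p / 100.0)
            t_total = thin.sum()
            if t_total == 0:
                acc += float(np.mean(final[include] == 0.0))
                continue
            f = thin * 1e9 / (lengths * t_total)
            within = np.abs(f[include] - final[include]) <= tolerance * final[include]
            acc += float(within.mean())
        fractions[i] = acc / n_reps
    return SaturationCurve(
        sample_id=sample_id,
        percentages=pct,
        fraction_within=fractions,
        fpkm_threshold=fpkm_threshold,
        n_genes_included=n_inc,
    )


def density_summary(
    fpkm: pd.DataFrame,
    design: SampleDesign,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-group histogram of log10(group-mean FPKM) over expressed genes.

    A gene's group value is the mean FPKM over the group's samples;
    zeros are excluded before the log.  Histograms share a fixed grid
    and are normalised to unit area; the returned frame is indexed by
    bin midpoints with one column per group.
    """
    if bins is None:
        bins = np.linspace(-3.0, 5.0, 81)
    mids = 0.5 * (bins[:-1] + bins[1:])
    out = {}
    for group in design.groups:
        cols = design.samples_in(group)
        gmean = fpkm[cols].mean(axis=1)
        vals = np.log10(gmean[gmean > 0])
        hist, _ = np.histogram(np.clip(vals, bins[0], bins[-1]), bins=bins, density=True)
        out[group] = hist
    return pd.DataFrame(out, index=pd.Index(mids, name="log10_fpkm"))


REQUIRED_CQ_COLUMNS = {"sample_id", "gene_id", "Cq", "role", "condition"}


def ddcq(cq: pd.DataFrame, calibrator_condition: str = "calibrator") -> pd.DataFrame:
    """Relative expression per (target gene, sample) by 2^-ddCq.

    dCq = Cq_target - Cq_reference within a sample; ddCq subtracts the
    mean dCq of that gene over calibrator-condition samples.  The Cq
    table needs columns sample_id, gene_id, Cq, role (target|reference)
    and condition; every sample must carry a reference-gene Cq.
    """
    missing = REQUIRED_CQ_COLUMNS - set(cq.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    ref = cq[cq["role"] == "reference"]
    if ref.empty:
        raise ValueError("no reference-gene rows in Cq table")
    ref_cq = ref.groupby("sample_id")["Cq"].mean()
    targets = cq[cq["role"] == "target"].copy()
    no_ref = set(targets["sample_id"]) - set(ref_cq.index)
    if no_ref:
        raise ValueError(f"samples without reference Cq: {sorted(no_ref)}")
    targets["delta_cq"] = targets["Cq"].to_numpy() - ref_cq[targets["sample_id"]].to_numpy()
    cal = targets[targets["condition"] == calibrator_condition]
    if cal.empty:
        raise ValueError(f"no samples with calibrator condition {calibrator_condition!r}")
    cal_dcq = cal.groupby("gene_id")["delta_cq"].mean()
    no_cal = set(targets["gene_id"]) - set(cal_dcq.index)
    if no_cal:
        raise ValueError(f"target genes without calibrator entries: {sorted(no_cal)}")
    targets["ddcq"] = targets["delta_cq"].to_numpy() - cal_dcq[targets["gene_id"]].to_numpy()
    targets["relative_expression"] = 2.0 ** (-targets["ddcq"])
    return targets[
        ["gene_id", "sample_id", "condition", "delta_cq", "ddcq", "relative_expression"]
    ].reset_index(drop=True)
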