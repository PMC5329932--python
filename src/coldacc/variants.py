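"""Variant filtering, IUPAC genotype matrices and genetic structure.

Sites are filtered on call quality (QUAL/QD), reduced to biallelic
positions covered by at least six reads in every sample, and each
sample is genotyped with a single IUPAC letter: the two-allele
ambiguity code when both alleles reach the heterozygote fraction,
otherwise the majority base.  The samples x sites character matrix is
exported as FASTA / relaxed PHYLIP / NEXUS for external phylogenetic
inference; a built-in ambiguity-aware distance + neighbor-joining tree
serves as a desk-scale structure check.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from skbio import DistanceMatrix
from skbio.tree import nj

IUPAC_PAIR: dict[frozenset, str] = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
AMBIG_TO_BASES: dict[str, frozenset] = {v: k for k, v in IUPAC_PAIR.items()}
MISSING_CODES = {"N", "-", "?"}


@dataclass
class SiteTable:
    """Variant records with per-sample, per-allele read depths.

    ``meta`` is indexed by site id ("gene:pos") with columns gene_id,
    pos (1-based), ref, alt (comma-separated alternates), qual, qd.
    ``depths`` is an (n_sites, n_samples, n_allele_slots) integer array;
    allele slot 0 is the reference, slots 1.. follow the alt order.
    """

    meta: pd.DataFrame
    depths: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        if self.depths.shape[0] != len(self.meta) or self.depths.shape[1] != len(self.samples):
            raise ValueError("depths shape inconsistent with meta/samples")
        if (self.depths < 0).any():
            raise ValueError("read depths must be non-negative")

    def __len__(self) -> int:
        return len(self.meta)

    def alleles(self, i: int) -> list[str]:
        row = self.meta.iloc[i]
        alts = [a for a in str(row["alt"]).split(",") if a]
        return [str(row["ref"])] + alts

    def n_observed_alleles(self) -> np.ndarray:
        """Per site: alleles with nonzero total depth across samples."""
        totals = self.depths.sum(axis=1)  # sites x allele slots
        n_listed = np.array([len(self.alleles(i)) for i in range(len(self))])
        observed = np.zeros(len(self), dtype=int)
        for i in range(len(self)):
            observed[i] = int(np.count_nonzero(totals[i, : n_listed[i]]))
        return observed

    def subset(self, keep: np.ndarray) -> "SiteTable":
        return SiteTable(self.meta.iloc[keep].copy(), self.depths[keep], list(self.samples))

    def to_tsv(self, path) -> None:
        out = self.meta.copy()
        for j, s in enumerate(self.samples):
            col = []
            for i in range(len(self)):
                k = len(self.alleles(i))
                col.append(",".join(str(int(d)) for d in self.depths[i, j, :k]))
            out[s] = col
        out.to_csv(path, sep="\t", index_label="site_id")

    @classmethod
    def from_tsv(cls, path) -> "SiteTable":
        df = pd.read_csv(path, sep="\t", index_col="site_id")
        fixed = ["gene_id", "pos", "ref", "alt", "qual", "qd"]
        samples = [c for c in df.columns if c not in fixed]
        n_alleles = df["alt"].astype(str).map(lambda a: 1 + len([x for x in a.split(",") if x]))
        slots = int(n_alleles.max()) if len(df) else 1
        depths = np.zeros((len(df), len(samples), slots), dtype=np.int64)
        for j, s in enumerate(samples):
            for i, cell in enumerate(df[s]):
                vals = [int(v) for v in str(cell).split(",")]
                depths[i, j, : len(vals)] = vals
        return cls(df[fixed].copy(), depths, samples)


def quality_filter(sites: SiteTable, min_qual: float = 30.0, min_qd: float = 5.0) -> SiteTable:
    """Drop records failing either the QUAL or the QD threshold.

    Records lacking a QUAL/QD value pass with a warning.
    """
    qual = sites.meta["qual"].to_numpy(dtype=float)
    qd = sites.meta["qd"].to_numpy(dtype=float)
    n_missing = int((np.isnan(qual) | np.isnan(qd)).sum())
    if n_missing:
        warnings.warn(f"{n_missing} records lack QUAL/QD and pass unfiltered", stacklevel=2)
    keep = (np.isnan(qual) | (qual >= min_qual)) & (np.isnan(qd) | (qd >= min_qd))
    return sites.subset(np.flatnonzero(keep))


def select_sites(
    sites: SiteTable,
    max_alleles: int = 2,
    min_reads_per_sample: int = 6,
    min_samples_covered: int | None = None,
) -> SiteTable:
    """Keep sites with <= ``max_alleles`` observed alleles whose total
    depth reaches ``min_reads_per_sample`` in every sample.

    ``min_samples_covered`` relaxes the every-sample requirement to a
    minimum number of samples.
    """
    n_obs = sites.n_observed_alleles()
    sample_depth = sites.depths.sum(axis=2)  # sites x samples
    covered = (sample_depth >= min_reads_per_sample).sum(axis=1)
    need = len(sites.samples) if min_samples_covered is None else min_samples_covered
    keep = (n_obs <= max_alleles) & (covered >= need)
    return sites.subset(np.flatnonzero(keep))


def call_iupac(
    allele_a: str, allele_b: str, depth_a: int, depth_b: int, het_min_fraction: float = 0.2
) -> str:
    """Single-letter genotype for one sample at a biallelic site.

    Both alleles at fraction >= ``het_min_fraction`` of the site depth
    give the ambiguity code of the pair; otherwise the majority base.
    """
    total = depth_a + depth_b
    if total <= 0:
        raise ValueError("zero depth: site should have been filtered out")
    fa, fb = depth_a / total, depth_b / total
    if fa >= het_min_fraction and fb >= het_min_fraction and allele_a != allele_b:
        return IUPAC_PAIR[frozenset((allele_a, allele_b))]
    return allele_a if depth_a >= depth_b else allele_b


@dataclass
class GenotypeMatrix:
    """Samples x sites IUPAC characters."""

    table: pd.DataFrame  # index samples, columns site ids

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.table.columns)

    def sequence_of(self, sample: str) -> str:
        return "".join(self.table.loc[sample])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.sample_ids:
                fh.write(f">{s}\n{self.sequence_of(s)}\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.sample_ids)} {len(self.site_ids)}\n")
            for s in self.sample_ids:
                fh.write(f"{s}  {self.sequence_of(s)}\n")

    def to_nexus(self, path) -> None:
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={len(self.sample_ids)} NCHAR={len(self.site_ids)};",
            "  FORMAT DATATYPE=DNA MISSING=? GAP=-;",
            "  MATRIX",
        ]
        lines += [f"    {s}  {self.sequence_of(s)}" for s in self.sample_ids]
        lines += ["  ;", "END;", ""]
        with open(path, "w") as fh:
            fh.write("\n".join(lines))

    @classmethod
    def from_nexus(cls, path, site_ids: list[str] | None = None) -> "GenotypeMatrix":
        rows: dict[str, str] = {}
        in_matrix = False
        with open(path) as fh:
            for line in fh:
                t = line.strip()
                if t.upper() == "MATRIX":
                    in_matrix = True
                    continue
                if in_matrix:
                    if t == ";" or t.upper().startswith("END"):
                        break
                    if t:
                        name, seq = t.split(None, 1)
                        rows[name] = rows.get(name, "") + seq.replace(" ", "")
        n = len(next(iter(rows.values())))
        cols = site_ids if site_ids is not None else [f"site_{i}" for i in range(n)]
        return cls(pd.DataFrame({c: [rows[s][i] for s in rows] for i, c in enumerate(cols)},
                                index=list(rows)))


def build_matrix(
    sites: SiteTable,
    n_subsample: int | None = None,
    seed: int = 0,
    het_min_fraction: float = 0.2,
) -> GenotypeMatrix:
    """IUPAC genotype matrix from filtered biallelic sites.

    Optionally takes a uniform random subset of ``n_subsample`` sites
    (without replacement); columns are ordered by (gene_id, pos).
    Samples with zero depth at a site are coded '?' (missing).
    """
    idx = np.arange(len(sites))
    if n_subsample is not None:
        if n_subsample > len(sites):
            raise ValueError(f"n_subsample {n_subsample} exceeds {len(sites)} eligible sites")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(sites), size=n_subsample, replace=False)
    st = sites.subset(idx)
    order = np.lexsort((st.meta["pos"].to_numpy(), st.meta["gene_id"].to_numpy()))
    st = st.subset(order)

    codes = np.empty((len(st.samples), len(st)), dtype=object)
    for i in range(len(st)):
        alleles = st.alleles(i)
        totals = st.depths[:, :, : len(alleles)].sum(axis=1)[i]
        observed = [a for a, t in zip(alleles, totals) if t > 0]
        if len(observed) > 2:
            raise ValueError(f"site {st.meta.index[i]} has >2 observed alleles")
        if len(observed) == 1:
            observed = observed * 2
        elif len(observed) == 0:
            codes[:, i] = "?"
            continue
        ia = alleles.index(observed[0])
        ib = alleles.index(observed[1]) if observed[1] != observed[0] else ia
        for j in range(len(st.samples)):
            da = int(st.depths[i, j, ia])
            db = int(st.depths[i, j, ib]) if ib != ia else 0
            if da + db == 0:
                codes[j, i] = "?"
            else:
                codes[j, i] = call_iupac(observed[0], observed[1], da, db, het_min_fraction)
    return GenotypeMatrix(
        pd.DataFrame(codes, index=list(st.samples), columns=list(st.meta.index))
    )


@dataclass
class CodingEffect:
    site_id: str
    cds_id: str
    effect: str  # synonymous | non_synonymous | non_coding
    codon_before: str = ""
    codon_after: str = ""
    aa_before: str = ""
    aa_after: str = ""


def coding_effect(
    gene_id: str,
    pos: int,
    ref: str,
    alt: str,
    cds_annotation: pd.DataFrame,
    sequences: dict[str, str],
) -> CodingEffect:
    """Classify a SNP as synonymous / non-synonymous / non-coding.

    ``cds_annotation`` has columns gene_id, cds_id, start, end (1-based
    inclusive on the transcript), strand (+/-), frame (0-2).  The
    alternate base is substituted into its codon and both codons are
    translated with the standard genetic code; minus-strand CDS are
    reverse-complemented before codon lookup.  A trailing partial codon
    is ignored with a warning.
    """
    site_id = f"{gene_id}:{pos}"
    rows = cds_annotation[
        (cds_annotation["gene_id"] == gene_id)
        & (cds_annotation["start"] <= pos)
        & (cds_annotation["end"] >= pos)
    ]
    if rows.empty:
        return CodingEffect(site_id=site_id, cds_id="", effect="non_coding")
    cds = rows.iloc[0]
    seq = sequences[gene_id]
    sub = seq[int(cds["start"]) - 1 : int(cds["end"])]
    offset_in_cds = pos - int(cds["start"])
    if str(cds["strand"]) == "-":
        sub = str(Seq(sub).reverse_complement())
        offset_in_cds = len(sub) - 1 - offset_in_cds
        ref = str(Seq(ref).complement())
        alt = str(Seq(alt).complement())
    frame = int(cds.get("frame", 0))
    coding = sub[frame:]
    if len(coding) % 3:
        warnings.warn(
            f"CDS {cds.get('cds_id', gene_id)} length not divisible by 3; "
            "trailing partial codon ignored",
            stacklevel=2,
        )
    offset = offset_in_cds - frame
    codon_idx = offset // 3
    if offset < 0 or codon_idx >= len(coding) // 3:
        return CodingEffect(site_id=site_id, cds_id=str(cds.get("cds_id", "")), effect="non_coding")
    codon = coding[3 * codon_idx : 3 * codon_idx + 3]
    within = offset % 3
    if codon[within] != ref:
        warnings.warn(f"reference base mismatch at {site_id}", stacklevel=2)
    mutated = codon[:within] + alt + codon[within + 1 :]
    aa_before = str(Seq(codon).translate())
    aa_after = str(Seq(mutated).translate())
    return CodingEffect(
        site_id=site_id,
        cds_id=str(cds.get("cds_id", "")),
        effect="synonymous" if aa_before == aa_after else "non_synonymous",
        codon_before=codon,
        codon_after=mutated,
        aa_before=aa_before,
        aa_after=aa_after,
    )


def ratio_by_gene(effects: list[CodingEffect]) -> pd.Series:
    """Per-gene non-synonymous / synonymous SNP ratio.

    Genes with non-synonymous SNPs but no synonymous ones get +inf;
    genes with neither get NaN (undefined).
    """
    per_gene: dict[str, list[int]] = {}
    for e in effects:
        gene = e.site_id.split(":")[0]
        ns, s = per_gene.setdefault(gene, [0, 0])
        if e.effect == "non_synonymous":
            per_gene[gene][0] = ns + 1
        elif e.effect == "synonymous":
            per_gene[gene][1] = s + 1
    out = {}
    for gene, (ns, s) in per_gene.items():
        if s > 0:
            out[gene] = ns / s
        elif ns > 0:
            out[gene] = np.inf
        else:
            out[gene] = np.nan
    return pd.Series(out, name="nonsyn_syn_ratio").sort_index()


def _pair_score(a: str, b: str) -> float:
    if a == b:
        return 0.0
    sa, sb = AMBIG_TO_BASES.get(a), AMBIG_TO_BASES.get(b)
    if sa is not None and sb is None and b in sa:
        return 0.5
    if sb is not None and sa is None and a in sb:
        return 0.5
    return 1.0


_CODE_ORDER = "ACGTRYSWKM" + "".join(MISSING_CODES)
_SCORE_LUT = np.ones((len(_CODE_ORDER), len(_CODE_ORDER)))
for _i, _a in enumerate(_CODE_ORDER):
    for _j, _b in enumerate(_CODE_ORDER):
        if _a in MISSING_CODES or _b in MISSING_CODES:
            _SCORE_LUT[_i, _j] = np.nan
        else:
            _SCORE_LUT[_i, _j] = _pair_score(_a, _b)


def distance_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Mean per-site mismatch with ambiguity-aware scoring.

    Identical codes score 0; a two-base ambiguity versus a plain base it
    contains scores 0.5; anything else scores 1.  Sites where either
    sample is missing are skipped pairwise.
    """
    code_idx = {c: i for i, c in enumerate(_CODE_ORDER)}
    arr = np.array(
        [[code_idx[c] for c in matrix.table.loc[s]] for s in matrix.sample_ids], dtype=np.int8
    )
    n = len(matrix.sample_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            scores = _SCORE_LUT[arr[i], arr[j]]
            valid = ~np.isnan(scores)
            d[i, j] = d[j, i] = float(np.nanmean(scores)) if valid.any() else np.nan
    return pd.DataFrame(d, index=matrix.sample_ids, columns=matrix.sample_ids)


def nj_tree(distances: pd.DataFrame) -> str:
    """Unrooted neighbor-joining tree (newick) from a distance matrix."""
    if len(distances) < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    dm = DistanceMatrix(distances.to_numpy(), ids=list(distances.index))
    tree = nj(dm)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
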