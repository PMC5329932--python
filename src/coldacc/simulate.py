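"""Synthetic study generator.

Emulates the inputs of a five-temperature-group leaf transcriptome
experiment: negative-binomial fragment counts in which a fraction of
genes is up-regulated at chilling temperatures (below 10 degC), a GO
annotation with one or more groups enriched among the responsive genes,
biallelic SNP pileups from two diverged populations, and transcript
sequences carrying planted SSR runs and coding frames.  Everything is
driven by one top-level seed; each stage derives its own child stream
so stages are independently reproducible, and all planted structure is
recorded in a TruthSet for recovery tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from coldacc import ssr as ssr_mod
from coldacc.containers import (
    ConfigurationError,
    CountMatrix,
    SampleDesign,
    SimulationConfig,
    TruthSet,
)
from coldacc.enrichment import GOAnnotationMap
from coldacc.variants import SiteTable

# fixed child-stream tags so each stage has an independent, stable stream
_STAGE_COUNTS, _STAGE_ANNOT, _STAGE_PILEUP, _STAGE_TRANSCRIPT = 11, 23, 37, 53

_PLANTED_LABELS = {"GO:0022857": "transmembrane transporter activity"}


def _stage_rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def _sample_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    samples, groups = [], []
    for g in config.groups:
        for r in range(config.n_samples_per_group):
            samples.append(f"{g}_r{r + 1}")
            groups.append(g)
    return samples, groups


def generate_counts(config: SimulationConfig) -> tuple[CountMatrix, SampleDesign, TruthSet]:
    """Fragment counts, sample design and expression truth.

    Counts are negative-binomial around gene baselines scaled by the
    sample's log-normal library size; responsive genes have their mean
    multiplied by 2^lfc in groups colder than the chilling cutoff.  A
    configured fraction of responsive genes is down- instead of
    up-regulated, and another fraction responds only in the coldest
    group (mirroring the stronger response at the lowest temperature).
    """
    config.validate()
    rng = _stage_rng(config, _STAGE_COUNTS)
    n = config.n_genes
    gene_ids = [f"gene_{i + 1:05d}" for i in range(n)]
    lengths = np.clip(
        rng.lognormal(np.log(config.mean_gene_length), 0.4, size=n), 200, 20000
    ).astype(np.int64)
    weights = rng.lognormal(0.0, 1.2, size=n)
    weights /= weights.sum()

    n_resp = int(round(config.frac_responsive * n))
    resp_idx = rng.choice(n, size=n_resp, replace=False)
    down = rng.random(n_resp) < config.frac_down
    t2_only = rng.random(n_resp) < config.frac_t2_only
    lfc = rng.normal(config.lfc_mean, config.lfc_sd, size=n_resp)
    lfc = np.where(down, -np.abs(lfc), np.abs(lfc))

    coldest = min(config.groups, key=config.groups.get)
    cold_groups = [g for g, t in config.groups.items() if t < config.cold_cutoff_C]

    true_lfc: dict[str, dict[str, float]] = {}
    for j, gi in enumerate(resp_idx):
        per_group = {}
        for g in cold_groups:
            if t2_only[j] and g != coldest:
                continue
            per_group[g] = float(lfc[j])
        true_lfc[gene_ids[gi]] = per_group

    samples, sample_groups = _sample_names(config)
    sigma = np.sqrt(np.log(1.0 + config.library_size_cv**2))
    lib = rng.lognormal(np.log(config.library_size_mean) - sigma**2 / 2, sigma,
                        size=len(samples))

    fold = np.ones((n, len(samples)))
    for j, gi in enumerate(resp_idx):
        per_group = true_lfc[gene_ids[gi]]
        for s, g in enumerate(sample_groups):
            if g in per_group:
                fold[gi, s] = 2.0 ** per_group[g]
    mu = weights[:, None] * fold * lib[None, :]
    if config.nb_dispersion <= 1e-12:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))

    cm = CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=samples),
        lengths=pd.Series(lengths, index=gene_ids, name="length"),
    )
    design = SampleDesign(
        pd.DataFrame(
            {"group": sample_groups, "temperature_C": [config.groups[g] for g in sample_groups]},
            index=pd.Index(samples, name="sample"),
        )
    )
    truth = TruthSet(
        responsive_gene_ids={gene_ids[gi] for gi in resp_idx},
        true_lfc=true_lfc,
    )
    return cm, design, truth


def generate_annotation(
    gene_ids: list[str], truth: TruthSet, config: SimulationConfig
) -> GOAnnotationMap:
    """Gene -> GO-group annotation with planted enrichment.

    Each gene joins each group independently at that group's marginal
    probability; in planted groups the membership odds for responsive
    genes are multiplied by the configured enrichment odds.  Genes may
    end up in zero groups (annotated background only).
    """
    config.validate()
    for grp, odds in config.planted_enriched_groups.items():
        if odds <= 0:
            raise ConfigurationError(f"enrichment odds for {grp} must be positive")
    rng = _stage_rng(config, _STAGE_ANNOT)
    planted = list(config.planted_enriched_groups)
    n_extra = config.n_go_groups - len(planted)
    if n_extra < 0:
        raise ConfigurationError("more planted groups than n_go_groups")
    group_ids = planted + [f"GO:{i + 1:07d}" for i in range(n_extra)]
    info = pd.DataFrame(
        {
            "label": [_PLANTED_LABELS.get(g, g) for g in group_ids],
            "namespace": [("BP", "CC", "MF")[i % 3] for i in range(len(group_ids))],
        },
        index=pd.Index(group_ids, name="group_id"),
    )
    responsive = np.array([g in truth.responsive_gene_ids for g in gene_ids])
    g2g: dict[str, set[str]] = {g: set() for g in gene_ids}
    for grp in group_ids:
        p = float(rng.uniform(0.03, 0.15))
        odds = config.planted_enriched_groups.get(grp, 1.0)
        p_resp = odds * p / (1.0 - p + odds * p)
        probs = np.where(responsive, p_resp, p)
        member = rng.random(len(gene_ids)) < probs
        for g in np.asarray(gene_ids)[member]:
            g2g[str(g)].add(grp)
    truth.enriched_group_ids = {
        g for g, o in config.planted_enriched_groups.items() if o != 1.0
    }
    return GOAnnotationMap(gene_to_groups=g2g, group_info=info)


_BASES = np.array(list("ACGT"))


def generate_pileups(config: SimulationConfig) -> tuple[SiteTable, TruthSet]:
    """Biallelic SNP pileups from planted diploid populations.

    Samples are assigned to populations in contiguous blocks of the
    design's sample order.  A configured fraction of sites is fixed for
    different alleles between populations; the rest share a common
    alternate-allele frequency.  Per-sample coverage is Poisson and the
    alternate read count binomial at the genotype's allele fraction,
    perturbed by the per-read error rate.
    """
    config.validate()
    rng = _stage_rng(config, _STAGE_PILEUP)
    samples, _ = _sample_names(config)
    n_s = len(samples)
    pops = {s: (i * config.n_populations) // n_s for i, s in enumerate(samples)}

    n_sites = config.n_snp_sites
    seen: set[tuple[str, int]] = set()
    genes, positions = [], []
    while len(genes) < n_sites:
        g = f"gene_{int(rng.integers(config.n_genes)) + 1:05d}"
        p = int(rng.integers(1, config.mean_gene_length + 1))
        if (g, p) not in seen:
            seen.add((g, p))
            genes.append(g)
            positions.append(p)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    refs, alts = _BASES[ref_idx], _BASES[alt_idx]

    n_div = int(round(config.fst_like_divergence * n_sites))
    divergent = np.zeros(n_sites, dtype=bool)
    divergent[rng.choice(n_sites, size=n_div, replace=False)] = True
    shared_freq = rng.uniform(0.05, 0.95, size=n_sites)
    flip = rng.random(n_sites) < 0.5  # which population carries the alt allele

    depths = np.zeros((n_sites, n_s, 2), dtype=np.int64)
    true_genotypes: dict[str, dict[str, tuple[str, str]]] = {s: {} for s in samples}
    e = config.sequencing_error
    for j, s in enumerate(samples):
        pop = pops[s]
        p_alt = np.where(
            divergent,
            np.where(flip ^ (pop % 2 == 1), 1.0, 0.0),
            shared_freq,
        )
        n_alt_alleles = rng.binomial(2, p_alt)
        cov = rng.poisson(config.coverage_mean, size=n_sites)
        f = n_alt_alleles / 2.0
        f_eff = f * (1 - e) + (1 - f) * e
        alt_reads = rng.binomial(cov, f_eff)
        depths[:, j, 0] = cov - alt_reads
        depths[:, j, 1] = alt_reads
        for i in range(n_sites):
            a = [refs[i]] * (2 - n_alt_alleles[i]) + [alts[i]] * n_alt_alleles[i]
            true_genotypes[s][f"{genes[i]}:{positions[i]}"] = (a[0], a[1])

    meta = pd.DataFrame(
        {
            "gene_id": genes,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "qual": np.round(rng.uniform(30.0, 2000.0, size=n_sites), 2),
            "qd": np.round(rng.uniform(5.0, 40.0, size=n_sites), 2),
        },
        index=pd.Index([f"{g}:{p}" for g, p in zip(genes, positions)], name="site_id"),
    )
    truth = TruthSet(true_genotypes=true_genotypes, populations=pops)
    return SiteTable(meta=meta, depths=depths, samples=samples), truth


_STOPS = {"TAA", "TAG", "TGA"}


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(str(rng.choice(sorted(_STOPS))))
    return "".join(codons)


def _cap_background(
    seq: list[str],
    rng: np.random.Generator,
    planted: list[dict],
    cds: dict | None,
    min_repeats: dict[int, int],
) -> None:
    """Mutate bases until the scanner finds exactly the planted SSRs.

    Mutations avoid planted SSR spans and never create an in-frame stop
    codon inside a planted CDS (start and stop codons are untouched).
    """
    planted_spans = [(p["start"], p["end"]) for p in planted]

    def in_planted(pos1: int) -> bool:
        return any(s <= pos1 <= e for s, e in planted_spans)

    for _ in range(100):
        found = ssr_mod.find_ssrs("".join(seq), min_repeats=min_repeats)
        offending = [
            r
            for r in found
            if not any(
                r.kind == "perfect"
                and r.start == p["start"]
                and r.end == p["end"]
                and r.motif == p["motif"]
                for p in planted
            )
        ]
        if not offending:
            return
        for r in offending:
            cand = [p for p in range(r.start, r.end + 1) if not in_planted(p)]
            if not cand:
                continue
            pos1 = int(rng.choice(cand))
            for new in rng.permutation(_BASES):
                if new == seq[pos1 - 1]:
                    continue
                if cds is not None and cds["start"] + 3 <= pos1 <= cds["end"] - 3:
                    off = pos1 - cds["start"]
                    ci = off // 3
                    codon = list(seq[cds["start"] - 1 + 3 * ci : cds["start"] - 1 + 3 * ci + 3])
                    codon[off % 3] = new
                    if "".join(codon) in _STOPS:
                        continue
                elif cds is not None and cds["start"] <= pos1 <= cds["end"]:
                    continue  # keep start/stop codons intact
                seq[pos1 - 1] = str(new)
                break
    raise RuntimeError("could not cap background SSR runs")


def generate_transcripts(
    config: SimulationConfig,
    min_repeats: dict[int, int] | None = None,
) -> tuple[dict[str, str], TruthSet]:
    """Transcript sequences with planted SSRs and coding frames.

    Background is random sequence with accidental SSR runs broken below
    the detection thresholds, so the scanner recovers exactly the
    planted records.  Planted CDS regions are ATG..stop frames with no
    internal stop codon, placed clear of the planted SSR.
    """
    config.validate()
    if min_repeats is None:
        min_repeats = dict(ssr_mod.DEFAULT_MIN_REPEATS)
    rng = _stage_rng(config, _STAGE_TRANSCRIPT)
    sequences: dict[str, str] = {}
    truth = TruthSet()
    L = config.transcript_length
    for t in range(config.n_transcripts):
        seq_id = f"transcript_{t + 1:03d}"
        seq = list(rng.choice(_BASES, size=L))
        planted: list[dict] = []
        cds_rec: dict | None = None

        if rng.random() < config.frac_with_cds:
            n_codons = int(rng.integers(30, 80))
            start = int(rng.integers(50, L // 2 - 3 * n_codons))
            cds_seq = _random_cds(rng, n_codons)
            seq[start - 1 : start - 1 + len(cds_seq)] = list(cds_seq)
            cds_rec = {"start": start, "end": start + len(cds_seq) - 1,
                       "strand": "+", "frame": 0}
            truth.planted_cds[seq_id] = cds_rec

        if rng.random() < config.frac_with_ssr:
            k = int(rng.choice([1, 2, 2, 3, 3, 4, 5, 6]))
            while True:
                unit = "".join(rng.choice(_BASES, size=k))
                if ssr_mod._is_primitive(unit):
                    break
            reps = int(min_repeats[k] + rng.integers(0, 5))
            span = k * reps
            start = int(rng.integers(L // 2 + 10, L - span - 10))
            seq[start - 1 : start - 1 + span] = list(unit * reps)
            planted.append(
                {"motif": unit, "unit_size": k, "repeat_number": reps,
                 "start": start, "end": start + span - 1}
            )
            truth.planted_ssrs[seq_id] = planted

        _cap_background(seq, rng, planted, cds_rec, min_repeats)
        sequences[seq_id] = "".join(seq)
    return sequences, truth


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def cds_truth_to_frame(truth: TruthSet) -> pd.DataFrame:
    rows = [
        {"gene_id": sid, "cds_id": f"{sid}.cds", "start": c["start"], "end": c["end"],
         "strand": c["strand"], "frame": c["frame"]}
        for sid, c in truth.planted_cds.items()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "cds_id", "start", "end", "strand", "frame"])


def merge_truths(*truths: TruthSet) -> TruthSet:
    """Combine per-stage truth sets into one."""
    out = TruthSet()
    for t in truths:
        out.responsive_gene_ids |= t.responsive_gene_ids
        out.true_lfc.update(t.true_lfc)
        out.enriched_group_ids |= t.enriched_group_ids
        out.true_genotypes.update(t.true_genotypes)
        out.populations.update(t.populations)
        out.planted_ssrs.update(t.planted_ssrs)
        out.planted_cds.update(t.planted_cds)
    return out


def generate_all(config: SimulationConfig):
    """Run every generator stage; returns (counts, design, annotation,
    sites, sequences, merged truth)."""
    counts, design, truth_c = generate_counts(config)
    annotation = generate_annotation(list(counts.gene_ids), truth_c, config)
    sites, truth_p = generate_pileups(config)
    sequences, truth_t = generate_transcripts(config)
    truth = merge_truths(truth_c, truth_p, truth_t)
    return counts, design, annotation, sites, sequences, truth
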