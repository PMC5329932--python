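"""Core data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class CountMatrix:
    """Gene-level fragment counts with per-gene transcript lengths.

    Attributes
    ----------
    counts : pd.DataFrame
        Non-negative integer counts, genes (rows) x samples (columns).
    lengths : pd.Series
        Transcript length in bases, indexed like ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts index and lengths index differ")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lengths = df.pop("length")
        return cls(counts=df.astype(np.int64), lengths=lengths.astype(np.int64))


@dataclass
class SampleDesign:
    """Sample-to-temperature-group assignment.

    ``table`` has one row per sample with columns ``group`` and
    ``temperature_C``; the index is the sample id.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"group", "temperature_C"} - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in design")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.table["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def group_temperature(self, group: str) -> float:
        return float(self.table.loc[self.table["group"] == group, "temperature_C"].iloc[0])

    def validate_against(self, counts: CountMatrix) -> None:
        if set(self.sample_ids) != set(counts.sample_ids):
            raise ValueError("design samples do not match count matrix samples")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", index_col="sample"))


#: default temperature groups: label -> representative air temperature (degC)
DEFAULT_GROUPS: dict[str, float] = {"T2": 2.0, "T5": 5.0, "T10": 10.0, "T14": 14.0, "T18": 18.0}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study generator.

    The defaults emulate a five-temperature-group leaf transcriptome
    design in which a fraction of genes respond to chilling (air
    temperature below 10 degC) with log2 fold-changes drawn from a
    normal distribution, annotated GO groups of which a few are
    enriched among the responsive genes, and biallelic SNP pileups from
    two diverged populations.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 2
    groups: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    frac_responsive: float = 0.10
    frac_down: float = 0.05          # responsive genes down- instead of up-regulated
    frac_t2_only: float = 0.35       # responsive only at the coldest group
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    nb_dispersion: float = 0.05
    library_size_mean: int = 1_000_000
    library_size_cv: float = 0.2     # log-normal spread of library sizes
    mean_gene_length: int = 1500
    n_go_groups: int = 25
    go_base_prob: float = 0.08       # marginal membership probability per group
    planted_enriched_groups: dict[str, float] = field(
        default_factory=lambda: {"GO:0022857": 10.0}  # transmembrane transporter activity
    )
    n_snp_sites: int = 500
    coverage_mean: float = 20.0
    sequencing_error: float = 0.01
    n_populations: int = 2
    fst_like_divergence: float = 0.2
    cold_cutoff_C: float = 10.0
    n_transcripts: int = 30
    transcript_length: int = 2000
    frac_with_ssr: float = 0.5
    frac_with_cds: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_responsive", "frac_down", "frac_t2_only",
                     "sequencing_error", "fst_like_divergence", "go_base_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        for name in ("n_genes", "n_samples_per_group", "library_size_mean",
                     "mean_gene_length", "n_go_groups", "n_snp_sites", "n_populations"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be positive")
        if not self.groups:
            raise ConfigurationError("groups must be non-empty")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Ground truth recorded by the generator for recovery tests."""

    responsive_gene_ids: set[str] = field(default_factory=set)
    #: gene -> {group_label: true log2 fold-change vs warm baseline}
    true_lfc: dict[str, dict[str, float]] = field(default_factory=dict)
    enriched_group_ids: set[str] = field(default_factory=set)
    #: sample -> {site_id: (allele1, allele2)}
    true_genotypes: dict[str, dict[str, tuple[str, str]]] = field(default_factory=dict)
    #: sample -> population index
    populations: dict[str, int] = field(default_factory=dict)
    #: seq_id -> list of planted SSR records (dicts)
    planted_ssrs: dict[str, list[dict]] = field(default_factory=dict)
    #: seq_id -> planted CDS record {"start", "end", "strand", "frame"}
    planted_cds: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        import json

        payload = {
            "responsive_gene_ids": sorted(self.responsive_gene_ids),
            "true_lfc": self.true_lfc,
            "enriched_group_ids": sorted(self.enriched_group_ids),
            "true_genotypes": {
                s: {k: list(v) for k, v in d.items()} for s, d in self.true_genotypes.items()
            },
            "populations": self.populations,
            "planted_ssrs": self.planted_ssrs,
            "planted_cds": self.planted_cds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(
            responsive_gene_ids=set(d["responsive_gene_ids"]),
            true_lfc=d["true_lfc"],
            enriched_group_ids=set(d["enriched_group_ids"]),
            true_genotypes={
                s: {k: tuple(v) for k, v in g.items()} for s, g in d["true_genotypes"].items()
            },
            populations={k: int(v) for k, v in d["populations"].items()},
            planted_ssrs=d["planted_ssrs"],
            planted_cds=d["planted_cds"],
        )
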