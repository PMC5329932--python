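"""End-to-end orchestration over plain-text interchange files.

Each stage reads and writes TSV/JSON in the run directory, so stages
are independently testable and replaceable; a manifest records the
configuration hash, the per-stage seeds fanned out from the top-level
seed, and a checksum for every output file.  Rerunning with the same
configuration reproduces all deterministic outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coldacc import diffexp, enrichment, expression, simulate, ssr as ssr_mod, variants
from coldacc.containers import CountMatrix, SampleDesign, SimulationConfig

log = logging.getLogger(__name__)

STAGES = ("simulate", "fpkm", "de", "enrich", "genotype", "ssr")


@dataclass
class PipelineConfig:
    out_dir: str = "coldacc_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    n_iter: int = 10000
    saturation_percentages: tuple[float, ...] = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    saturation_reps: int = 20
    fpkm_min: float = 0.0
    het_min_fraction: float = 0.2
    min_reads_per_sample: int = 6
    max_alleles: int = 2
    n_subsample_sites: int | None = None
    min_repeats: dict[int, int] = field(default_factory=lambda: dict(ssr_mod.DEFAULT_MIN_REPEATS))
    compound_max_gap: int = 100
    dry_run: bool = False

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # the run is defined by parameters, not location
        payload = json.dumps(_as_jsonable(d), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    A stage failure halts the run with the stage name in the error.
    Inputs referenced by non-simulate runs must exist before any stage
    executes.
    """
    out = Path(config.out_dir)
    config.simulation.seed = config.stage_seed("simulate")

    if config.dry_run:
        return {
            "dry_run": True,
            "stages": list(config.stages),
            "config_hash": config.config_hash(),
            "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
        }

    required: list[Path] = []
    if "simulate" not in config.stages:
        required += [out / "counts.tsv", out / "design.tsv"]
        if "enrich" in config.stages:
            required.append(out / "annotation.tsv")
        if "genotype" in config.stages:
            required.append(out / "variants.tsv")
        if "ssr" in config.stages:
            required.append(out / "transcripts.fasta")
    missing = [str(p) for p in required if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs before any stage ran: {missing}")

    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
        "stages_run": [],
        "outputs": {},
        "notes": [],
    }

    current = "?"
    try:
        for stage in config.stages:
            current = stage
            _STAGE_FN[stage](config, out, manifest)
            manifest["stages_run"].append(stage)
    except Exception as err:  # noqa: BLE001 - annotate stage then re-raise
        raise RuntimeError(f"stage {current!r} failed: {err}") from err

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(_as_jsonable(manifest), indent=1, sort_keys=True))
    return manifest


def _stage_simulate(config: PipelineConfig, out: Path, manifest: dict) -> None:
    counts, design, annotation, sites, sequences, truth = simulate.generate_all(config.simulation)
    counts.to_tsv(out / "counts.tsv")
    design.to_tsv(out / "design.tsv")
    annotation.to_tsv(out / "annotation.tsv")
    sites.to_tsv(out / "variants.tsv")
    simulate.write_fasta(sequences, out / "transcripts.fasta")
    simulate.cds_truth_to_frame(truth).to_csv(out / "cds.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")


def _load_counts_design(out: Path) -> tuple[CountMatrix, SampleDesign]:
    return CountMatrix.from_tsv(out / "counts.tsv"), SampleDesign.from_tsv(out / "design.tsv")


def _stage_fpkm(config: PipelineConfig, out: Path, manifest: dict) -> None:
    counts, design = _load_counts_design(out)
    fpkm = expression.compute_fpkm(counts)
    fpkm.to_csv(out / "fpkm.tsv", sep="\t", index_label="gene_id", float_format="%.6g")
    curves = []
    for sample in counts.sample_ids:
        c = expression.saturation_curve(
            counts,
            sample,
            percentages=config.saturation_percentages,
            fpkm_threshold=config.fpkm_min,
            n_reps=config.saturation_reps,
            seed=config.stage_seed("fpkm"),
        )
        df = c.as_frame()
        df.insert(0, "sample", sample)
        curves.append(df)
    pd.concat(curves).to_csv(out / "saturation.tsv", sep="\t", index=False, float_format="%.6g")
    expression.density_summary(fpkm, design).to_csv(
        out / "density.tsv", sep="\t", float_format="%.6g"
    )


def _cold_high_groups(design: SampleDesign, cutoff: float = 10.0) -> tuple[list[str], list[str]]:
    lows = [g for g in design.groups if design.group_temperature(g) < cutoff]
    highs = [g for g in design.groups if design.group_temperature(g) >= cutoff]
    return lows, highs


def _stage_de(config: PipelineConfig, out: Path, manifest: dict) -> None:
    counts, design = _load_counts_design(out)
    lows, highs = _cold_high_groups(design)
    if not lows or not highs:
        manifest["notes"].append("de: need at least one low and one high temperature group")
        return
    consistent: dict[str, diffexp.ConsistentDEGSet] = {}
    results_by_low: dict[str, dict[str, diffexp.DEResult]] = {}
    for low in lows:
        results = {
            high: diffexp.test_pairwise(counts, design, low, high, alpha=config.alpha)
            for high in highs
        }
        results_by_low[low] = results
        for high, res in results.items():
            res.table.to_csv(out / f"de_{low}_vs_{high}.tsv", sep="\t",
                             index_label="gene_id", float_format="%.6g")
        cset = diffexp.consistent_degs(results, low)
        consistent[low] = cset
        (out / f"consistent_{low}.json").write_text(
            json.dumps(
                {
                    "low_group": low,
                    "high_groups": cset.high_groups,
                    "genes": {
                        g: {"directions": cset.directions[g],
                            "consistent_direction": cset.consistent_direction[g]}
                        for g in sorted(cset.gene_ids)
                    },
                },
                indent=1,
                sort_keys=True,
            )
        )
    if len(lows) >= 2:
        direct = diffexp.test_pairwise(counts, design, lows[0], lows[1], alpha=config.alpha)
        report = diffexp.overlap_analysis(consistent[lows[0]], consistent[lows[1]], direct)
        (out / "overlap.json").write_text(json.dumps(_as_jsonable(report), indent=1, sort_keys=True))
    degs_all = set().union(*(c.gene_ids for c in consistent.values()))
    if degs_all:
        fpkm = expression.compute_fpkm(counts)
        diffexp.deg_fpkm_export(fpkm, degs_all).to_csv(
            out / "deg_log10_fpkm.tsv", sep="\t", index_label="gene_id", float_format="%.6g"
        )


def _stage_enrich(config: PipelineConfig, out: Path, manifest: dict) -> None:
    counts, design = _load_counts_design(out)
    annotation = enrichment.GOAnnotationMap.from_tsv(out / "annotation.tsv")
    fpkm = expression.compute_fpkm(counts)
    background = set(fpkm.index[(fpkm > 0).any(axis=1)])
    lows, _ = _cold_high_groups(design)
    sets: dict[str, set[str]] = {"background": background}
    stars: dict[str, list] = {}
    for low in lows:
        path = out / f"consistent_{low}.json"
        if not path.exists():
            continue
        degs = set(json.loads(path.read_text())["genes"]) & background
        if not degs:
            manifest["notes"].append(f"enrich: no consistent DEGs for {low}")
            continue
        results = enrichment.enrichment_test(
            degs, background, annotation,
            n_iter=config.n_iter, alpha=config.alpha, seed=config.stage_seed("enrich"),
        )
        enrichment.results_to_frame(results).to_csv(
            out / f"enrichment_{low}.tsv", sep="\t", float_format="%.6g"
        )
        sets[f"deg_{low}"] = degs
        stars[f"deg_{low}"] = results
    enrichment.go_barchart_table(annotation, sets, stars or None).to_csv(
        out / "go_barchart.tsv", sep="\t", float_format="%.6g"
    )


def _stage_genotype(config: PipelineConfig, out: Path, manifest: dict) -> None:
    sites = variants.SiteTable.from_tsv(out / "variants.tsv")
    sites = variants.quality_filter(sites)
    sites = variants.select_sites(
        sites,
        max_alleles=config.max_alleles,
        min_reads_per_sample=config.min_reads_per_sample,
    )
    if len(sites) == 0:
        manifest["notes"].append("genotype: no sites pass the filters")
        return
    n_sub = config.n_subsample_sites
    if n_sub is not None:
        n_sub = min(n_sub, len(sites))
    gm = variants.build_matrix(
        sites, n_subsample=n_sub, seed=config.stage_seed("genotype"),
        het_min_fraction=config.het_min_fraction,
    )
    gm.to_fasta(out / "genotypes.fasta")
    gm.to_nexus(out / "genotypes.nex")
    gm.to_phylip(out / "genotypes.phy")
    dist = variants.distance_matrix(gm)
    dist.to_csv(out / "distances.tsv", sep="\t", float_format="%.6g")
    if len(gm.sample_ids) >= 3:
        (out / "nj_tree.nwk").write_text(variants.nj_tree(dist) + "\n")


def _stage_ssr(config: PipelineConfig, out: Path, manifest: dict) -> None:
    sequences = simulate.read_fasta(out / "transcripts.fasta")
    records = []
    for sid, seq in sequences.items():
        records.extend(
            ssr_mod.find_ssrs(seq, seq_id=sid, min_repeats=config.min_repeats,
                              compound_max_gap=config.compound_max_gap)
        )
    ssr_mod.records_to_frame(records).to_csv(out / "ssr.tsv", sep="\t", index=False)
    markers = ssr_mod.ssr_marker_filter(records)
    pd.DataFrame([m.__dict__ for m in markers]).to_csv(out / "ssr_markers.tsv", sep="\t", index=False)
    summary = ssr_mod.ssr_summary(records)
    if not summary["by_motif"].empty:
        summary["by_class"].to_csv(out / "ssr_summary_class.tsv", sep="\t",
                                   index=False, float_format="%.6g")
        summary["by_motif"].to_csv(out / "ssr_summary_motif.tsv", sep="\t",
                                   index=False, float_format="%.6g")


_STAGE_FN = {
    "simulate": _stage_simulate,
    "fpkm": _stage_fpkm,
    "de": _stage_de,
    "enrich": _stage_enrich,
    "genotype": _stage_genotype,
    "ssr": _stage_ssr,
}
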