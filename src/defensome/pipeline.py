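"""End-to-end orchestration: one reproducible run over a cohort directory.

``run_all`` executes metrics -> islands -> coloc -> tradeoff -> spacers
(+ anti-defense tally when phage annotations are present) on a cohort
directory, writing per-stage TSV/JSON outputs, a manifest (resolved
parameters, seeds, input checksums, package version) and a machine-readable
``summary.json`` with the headline statistics of the run.
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
import yaml

from . import __version__ as _version
from . import coloc, islands, metrics, spacers, tradeoff
from .errors import ConfigError, PipelineError
from .io import (read_cohort, read_fasta, read_gene_table, validate_cohort)

log = logging.getLogger("defensome")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Unknown keys are rejected; every field is echoed into the manifest.
    """

    cohort_dir: str
    out_dir: str
    seed: int = 0
    # metrics
    first_line_threshold: float = 0.10
    named_first_line: list[str] | None = None
    # islands
    max_gap: int = 10
    min_def_genes: int = 5
    min_families: int = 3
    gap_semantics: str = "intervening"
    # coloc
    containment: str = "all"
    island_containment: str = "any"
    priority: list[str] = field(default_factory=lambda: list(
        coloc.DEFAULT_PRIORITY))
    correction: bool = True
    # tradeoff
    trait: str = "ARG"
    min_bin: int = 1
    weight_by_n: bool = False
    # spacers (optional stage)
    spacers_fasta: str | None = None
    phages_fasta: str | None = None
    spacer_origin_tsv: str | None = None
    max_mismatch: int = 1
    min_coverage: float = 0.95
    # anti-defense (optional stage)
    phage_genes_tsv: str | None = None
    phage_universe_size: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        missing = {"cohort_dir", "out_dir"} - set(d)
        if missing:
            raise ConfigError(f"missing config key(s): {sorted(missing)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate_inputs(cfg: RunConfig) -> None:
    """Validation-first contract: fail before any stage runs."""
    d = Path(cfg.cohort_dir)
    for required in ("genes.tsv", "systems.tsv", "qc.tsv"):
        if not (d / required).exists():
            raise ConfigError(f"cohort dir {d} missing {required}")
    wants_spacers = cfg.spacers_fasta or cfg.phages_fasta
    if wants_spacers:
        for p in (cfg.spacers_fasta, cfg.phages_fasta):
            if p is None or not Path(p).exists():
                raise ConfigError(
                    "spacers stage requested but spacers/phages FASTA missing")
    if cfg.phage_genes_tsv and not Path(cfg.phage_genes_tsv).exists():
        raise ConfigError(f"phage gene table {cfg.phage_genes_tsv} not found")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return None if np.isnan(v) else v
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written to disk).

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages are retained and listed in ``manifest.json`` under
    ``partial``.
    """
    logging.basicConfig(level=cfg.log_level)
    _validate_inputs(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {}
    for p in sorted(Path(cfg.cohort_dir).glob("*")):
        if p.is_file():
            inputs[p.name] = _sha256(p)
    manifest = {
        "version": _version,
        "config": dataclasses.asdict(cfg),
        "input_checksums": inputs,
        "stages_completed": [],
    }
    summary: dict = {"seed": cfg.seed}
    completed = manifest["stages_completed"]

    def _finish_stage(name: str):
        completed.append(name)
        _dump_json(manifest, out / "manifest.json")

    stage = "load"
    try:
        cohort = read_cohort(cfg.cohort_dir)
        diag = validate_cohort(cohort)
        if diag.violations:
            log.warning("%d cohort violations", len(diag.violations))
        summary["n_genomes"] = diag.n_genomes
        summary["n_genes"] = diag.n_genes
        summary["n_systems"] = diag.n_systems
        summary["n_mges"] = diag.n_mges
        _finish_stage(stage)

        stage = "metrics"
        has_systems = diag.n_systems > 0
        if has_systems:
            prev = metrics.prevalence(cohort)
            if cfg.named_first_line:
                fl = set(cfg.named_first_line)
                acc = set(prev["family"]) - fl
            else:
                fl, acc = metrics.partition_first_line(
                    prev, cfg.first_line_threshold)
            prev.to_csv(out / "prevalence.tsv", sep="\t", index=False)
            _dump_json({"first_line": sorted(fl), "accessory": sorted(acc)},
                       out / "partition.json")
            summary["first_line_families"] = sorted(fl)
            summary["first_line_share"] = metrics.family_share(cohort, fl)
        else:
            fl = set()
            summary["first_line_families"] = []
        profiles = metrics.profiles_table(cohort, fl)
        profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)
        summary["totals"] = metrics.cohort_totals(cohort)
        if has_systems and profiles["n_systems"].nunique() >= 2:
            rho, p = metrics.spearman(profiles["n_systems"],
                                      profiles["size_bp"])
            summary["spearman_systems_vs_size"] = {"rho": rho, "pvalue": p}
        _finish_stage(stage)

        stage = "islands"
        isl = islands.detect_islands_cohort(
            cohort, max_gap=cfg.max_gap, min_def_genes=cfg.min_def_genes,
            min_families=cfg.min_families, gap_semantics=cfg.gap_semantics)
        census = islands.island_census(isl)
        rows = [{
            "genome_id": i.genome_id, "contig_id": i.contig_id,
            "first_index": i.first_index, "last_index": i.last_index,
            "span_genes": i.span_genes, "n_defense": i.n_defense,
            "n_families": len(i.families),
            "families": ",".join(sorted(i.families)),
            "systems": ",".join(sorted(i.systems)),
        } for i in isl]
        pd.DataFrame(rows, columns=[
            "genome_id", "contig_id", "first_index", "last_index",
            "span_genes", "n_defense", "n_families", "families", "systems",
        ]).to_csv(out / "islands.tsv", sep="\t", index=False)
        _dump_json(dataclasses.asdict(census), out / "census.json")
        summary["n_islands"] = census.n_islands
        summary["island_defense_gene_pct"] = census.proportion_pct
        _finish_stage(stage)

        stage = "coloc"
        if has_systems:
            oet = coloc.mge_oe_table(cohort, tuple(cfg.priority),
                                     cfg.containment, cfg.correction)
            oet.to_long().to_csv(out / "oe_mge.tsv", sep="\t", index=False)
            oei = coloc.island_oe_table(cohort, isl, cfg.island_containment,
                                        cfg.correction)
            oei.to_long().to_csv(out / "oe_islands.tsv", sep="\t",
                                 index=False)
            dens = coloc.compartment_density(cohort, tuple(cfg.priority),
                                             cfg.containment)
            dens.rename_axis("compartment").reset_index().to_csv(
                out / "densities.tsv", sep="\t", index=False)
            summary["density_per_kb"] = dens.to_dict()
        _finish_stage(stage)

        stage = "tradeoff"
        if has_systems and all(cfg.trait in ga.traits for ga in cohort):
            env = tradeoff.build_envelope(cohort, cfg.trait, "all",
                                          first_line=fl, min_bin=cfg.min_bin)
            pd.DataFrame({"x": env.x, "y_max": env.y_max,
                          "n_at_x": env.n_at_x}).to_csv(
                out / "envelope.tsv", sep="\t", index=False)
            fit = tradeoff.fit_sigmoid(env, seed=cfg.seed,
                                       weight_by_n=cfg.weight_by_n)
            _dump_json(dataclasses.asdict(fit), out / "fit.json")
            corr = tradeoff.category_correlations(cohort, cfg.trait, fl)
            corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
            summary["tradeoff_fit"] = {
                "a": fit.a, "b": fit.b, "c": fit.c,
                "r_squared": fit.r_squared, "converged": fit.converged}
        _finish_stage(stage)

        stage = "spacers"
        if cfg.spacers_fasta:
            sp = read_fasta(cfg.spacers_fasta)
            ph = read_fasta(cfg.phages_fasta)
            hits = spacers.find_protospacers(sp, ph, cfg.max_mismatch,
                                             cfg.min_coverage)
            spacers.hits_table(hits).to_csv(out / "hits.tsv", sep="\t",
                                            index=False)
            summary["n_spacer_hits"] = len(hits)
            if cfg.spacer_origin_tsv:
                origin_df = pd.read_csv(cfg.spacer_origin_tsv, sep="\t")
                origin = dict(zip(origin_df["spacer_id"],
                                  origin_df["genome_id"]))
                links = spacers.link_hosts(hits, origin)
                links.to_csv(out / "links.tsv", sep="\t", index=False)
                summary["n_targeted_phages"] = spacers.n_targeted_phages(links)
        _finish_stage(stage)

        stage = "antidef"
        if cfg.phage_genes_tsv:
            genes = read_gene_table(cfg.phage_genes_tsv)
            universe = cfg.phage_universe_size or len(
                {g.genome_id for g in genes})
            tally = spacers.tally_anti_defense(genes, universe)
            _dump_json(dataclasses.asdict(tally), out / "tally.json")
            summary["anti_defense"] = {
                "n_genes": tally.n_genes, "n_phages": tally.n_phages,
                "prevalence_pct": tally.prevalence_pct}
        _finish_stage(stage)
    except ConfigError:
        raise
    except Exception as exc:
        manifest["partial"] = True
        _dump_json(manifest, out / "manifest.json")
        raise PipelineError(stage, str(exc)) from exc

    _dump_json(summary, out / "summary.json")
    _dump_json(manifest, out / "manifest.json")
    return summary
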