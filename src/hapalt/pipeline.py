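"""End-to-end pipeline orchestration.

Stages run in a fixed order — synthesize/ingest, QC, phasing, core-haplotype
frequencies, altitude correlation, association, selection inference, network,
forward simulation — each reading its inputs from the previous stage's output
files, so any stage whose outputs are intact is skipped on re-run and a
deleted output re-computes only its own stage.  A manifest records per-stage
output checksums, seeds and wall times; with a fixed config and seed the
checksums are reproducible run-to-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import GenotypePanel
from .haplotypes import (
    CoreMotif,
    altitude_correlation,
    pop_core_frequencies,
)
from .io import (
    default_panel_loci,
    load_panel_config,
    read_genotypes,
    read_population_table,
    write_genotypes,
    write_population_table,
)
from .network import cluster_partition, frequency_filter, median_joining
from .phasing import HaplotypeSet, em_phase, switch_error
from .qc import run_qc
from .selection import (
    McmcSettings,
    allele_counts_by_population,
    altitude_association,
    fit_selection,
    region_summary,
)
from .synthetic import (
    SimPanelSpec,
    read_truth_haplotypes,
    simulate_panel,
    write_truth_haplotypes,
)
from .forward_sim import scenario_grid

log = logging.getLogger("hapalt.pipeline")

STAGES = [
    "synth",
    "qc",
    "phase",
    "core_freq",
    "correlate",
    "assoc",
    "selestim",
    "network",
    "simulate",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    output_dir: Path
    seed: int = 0
    synthetic: dict | None = None
    input: dict | None = None
    qc: dict = field(default_factory=dict)
    phasing: dict = field(default_factory=dict)
    association: dict = field(default_factory=lambda: {"modes": ["additive"]})
    mcmc: dict = field(default_factory=dict)
    network: dict = field(default_factory=lambda: {"epsilon": 0, "min_frequency": 2})
    simulation: dict = field(default_factory=dict)
    panel_config: str | None = None
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        base = Path(base_dir) if base_dir else Path.cwd()
        if "output_dir" not in raw:
            raise PipelineError("config must set output_dir")
        cfg = cls(
            output_dir=(base / raw["output_dir"]).resolve(),
            seed=int(raw.get("seed", 0)),
            synthetic=raw.get("synthetic"),
            input=raw.get("input"),
            qc=raw.get("qc", {}),
            phasing=raw.get("phasing", {}),
            association=raw.get("association", {"modes": ["additive"]}),
            mcmc=raw.get("mcmc", {}),
            network=raw.get("network", {"epsilon": 0, "min_frequency": 2}),
            simulation=raw.get("simulation", {}),
            panel_config=raw.get("panel_config"),
            stages=raw.get("stages", list(STAGES)),
        )
        if cfg.synthetic is None and cfg.input is None:
            raise PipelineError(
                "config must provide either a 'synthetic' spec or an 'input' block"
            )
        if cfg.input is not None:
            for key in ("genotypes", "populations"):
                if key not in cfg.input:
                    raise PipelineError(f"input block missing {key!r}")
                p = base / cfg.input[key]
                if not p.exists():
                    raise PipelineError(f"input file does not exist: {p}")
        unknown = [s for s in cfg.stages if s not in STAGES]
        if unknown:
            raise PipelineError(f"unknown stages: {unknown}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        return cls.from_dict(raw, base_dir=path.parent)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stage implementations; each returns the list of files it wrote


def _loci(config: PipelineConfig):
    if config.panel_config:
        return load_panel_config(config.panel_config)[0]
    return default_panel_loci()


def _stage_synth(config: PipelineConfig, out: Path) -> list[Path]:
    geno = out / "genotypes.tsv"
    pops = out / "populations.tsv"
    truth = out / "truth_haplotypes.tsv"
    if config.synthetic is not None:
        spec_kwargs = dict(config.synthetic)
        spec_kwargs.setdefault("seed", config.seed)
        spec = SimPanelSpec(loci=_loci(config), **spec_kwargs)
        panel, truth_df = simulate_panel(spec)
        write_genotypes(panel, geno)
        write_population_table(panel.populations, pops)
        write_truth_haplotypes(truth_df, truth)
        return [geno, pops, truth]
    populations = read_population_table(config.input["populations"])
    panel = read_genotypes(
        config.input["genotypes"],
        populations,
        loci=_loci(config),
        fmt=config.input.get("format", "tabular"),
    )
    write_genotypes(panel, geno)
    write_population_table(panel.populations, pops)
    return [geno, pops]


def _load_panel(config: PipelineConfig, out: Path, stage_file: str) -> GenotypePanel:
    populations = read_population_table(out / "populations.tsv")
    return read_genotypes(out / stage_file, populations, loci=_loci(config))


def _stage_qc(config: PipelineConfig, out: Path) -> list[Path]:
    panel = _load_panel(config, out, "genotypes.tsv")
    filtered, report = run_qc(
        panel,
        max_sample_missing=config.qc.get("max_sample_missing", 0.20),
        max_snp_missing=config.qc.get("max_snp_missing", 0.30),
    )
    geno = out / "qc_genotypes.tsv"
    write_genotypes(filtered, geno)
    rep_json = out / "qc_report.json"
    _write_json(report.to_dict(), rep_json)
    rep_txt = out / "qc_report.txt"
    rep_txt.write_text(report.to_text())
    return [geno, rep_json, rep_txt]


def _qc_panel(config: PipelineConfig, out: Path) -> GenotypePanel:
    populations = read_population_table(out / "populations.tsv")
    report = json.loads((out / "qc_report.json").read_text())
    loci = [l for l in _loci(config) if l.id not in report["removed_locus_ids"]]
    return read_genotypes(out / "qc_genotypes.tsv", populations, loci=loci)


def _stage_phase(config: PipelineConfig, out: Path) -> list[Path]:
    panel = _qc_panel(config, out)
    hapset = em_phase(
        panel,
        max_iter=int(config.phasing.get("max_iter", 1000)),
        tol=float(config.phasing.get("tol", 1e-8)),
        n_restarts=int(config.phasing.get("n_restarts", 0)),
        seed=config.seed,
    )
    haps = out / "haplotypes.tsv"
    assigns = out / "assignments.tsv"
    hapset.write(haps, assigns)
    extra: list[Path] = []
    truth_path = out / "truth_haplotypes.tsv"
    if truth_path.exists():
        truth = read_truth_haplotypes(truth_path)
        err = switch_error(hapset, truth)
        sw = out / "switch_error.json"
        _write_json({"switch_error": err}, sw)
        extra.append(sw)
    return [haps, assigns] + extra


def _load_hapset(config: PipelineConfig, out: Path) -> HaplotypeSet:
    panel = _qc_panel(config, out)
    hap_frame = pd.read_csv(out / "haplotypes.tsv", sep="\t", dtype={"haplotype": str})
    assigns = pd.read_csv(out / "assignments.tsv", sep="\t",
                          dtype={"hap1": str, "hap2": str})
    return HaplotypeSet(
        haplotypes=hap_frame["haplotype"].tolist(),
        frequencies=hap_frame["frequency"].to_numpy(),
        assignments=assigns,
        log_likelihood=float("nan"),
        n_iter=0,
        converged=True,
        locus_ids=panel.locus_ids,
    )


def _stage_core_freq(config: PipelineConfig, out: Path) -> list[Path]:
    panel = _qc_panel(config, out)
    hapset = _load_hapset(config, out)
    motif = CoreMotif.from_panel(panel.loci)
    freqs = pop_core_frequencies(hapset, panel, motif)
    path = out / "core_frequencies.tsv"
    freqs.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return [path]


def _stage_correlate(config: PipelineConfig, out: Path) -> list[Path]:
    freqs = pd.read_csv(out / "core_frequencies.tsv", sep="\t")
    rho, p = altitude_correlation(freqs)
    path = out / "correlation.json"
    _write_json({"spearman_rho": rho, "p_value": p, "n_populations": len(freqs)},
                path)
    return [path]


def _stage_assoc(config: PipelineConfig, out: Path) -> list[Path]:
    panel = _qc_panel(config, out)
    paths = []
    for mode in config.association.get("modes", ["additive"]):
        table = altitude_association(panel, mode=mode)
        path = out / f"association_{mode}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths.append(path)
    return paths


def _stage_selestim(config: PipelineConfig, out: Path) -> list[Path]:
    panel = _qc_panel(config, out)
    derived, totals, codes = allele_counts_by_population(panel)
    settings = McmcSettings(seed=config.seed, **config.mcmc)
    fit = fit_selection(derived, totals, demes=codes,
                        locus_ids=panel.locus_ids, mcmc=settings)
    summary = out / "selection_summary.tsv"
    trace = out / "selection_trace.tsv"
    fit.write(summary, trace)
    paths = [summary, trace]
    _, cfg_raw = load_panel_config(config.panel_config)
    regions_cfg = cfg_raw.get("regions")
    if regions_cfg:
        lids = panel.locus_ids
        loci_all = [l.id for l in _loci(config)]
        regions = {}
        for name, (start, end) in regions_cfg.items():
            if start in loci_all and end in loci_all:
                i0, i1 = loci_all.index(start), loci_all.index(end)
                members = [l for l in loci_all[i0:i1 + 1] if l in lids]
                if members:
                    regions[name] = members
        if regions:
            reg = region_summary(fit, regions)
            rpath = out / "region_summary.tsv"
            reg.to_csv(rpath, sep="\t", index=False, float_format="%.6g")
            paths.append(rpath)
    return paths


def _stage_network(config: PipelineConfig, out: Path) -> list[Path]:
    panel = _qc_panel(config, out)
    hapset = _load_hapset(config, out)
    counts = hapset.counts()
    min_freq = int(config.network.get("min_frequency", 2))
    counts = frequency_filter(counts, min_freq)
    if not counts:
        raise PipelineError("no haplotypes pass the network frequency filter")
    net = median_joining(counts, epsilon=int(config.network.get("epsilon", 0)))
    edges = out / "network_edges.tsv"
    gml = out / "network.gml"
    net.write_edges(edges)
    net.write_gml(gml)
    motif = CoreMotif.from_panel(panel.loci)
    part = cluster_partition(net, motif, panel.locus_ids)
    clusters = out / "clusters.json"
    _write_json(
        {
            "core": part["core"],
            "non_core": part["non_core"],
            "separation": None if np.isnan(part["separation"])
            else int(part["separation"]),
            "total_cost": net.total_cost,
        },
        clusters,
    )
    return [edges, gml, clusters]


def _stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    sim = dict(config.simulation)
    grid = scenario_grid(
        p0_values=sim.get("p0", [0.01, 0.05, 0.1]),
        split_years_values=sim.get("split_years", [2800, 10000, 30000]),
        sigma=float(sim.get("sigma", 118.0)),
        fitness_mode=sim.get("fitness_mode", "additive"),
        replicates=int(sim.get("replicates", 100)),
        seed=config.seed,
        ancestral_ne=int(sim.get("ancestral_ne", 10000)),
        pop_ne=tuple(sim.get("pop_ne", (5000, 5000))),
    )
    path = out / "simulation_grid.tsv"
    grid.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return [path]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "qc": _stage_qc,
    "phase": _stage_phase,
    "core_freq": _stage_core_freq,
    "correlate": _stage_correlate,
    "assoc": _stage_assoc,
    "selestim": _stage_selestim,
    "network": _stage_network,
    "simulate": _stage_simulate,
}

_STAGE_OUTPUTS = {
    "synth": ["genotypes.tsv", "populations.tsv"],
    "qc": ["qc_genotypes.tsv", "qc_report.json", "qc_report.txt"],
    "phase": ["haplotypes.tsv", "assignments.tsv"],
    "core_freq": ["core_frequencies.tsv"],
    "correlate": ["correlation.json"],
    "assoc": [],  # mode-dependent, checked dynamically
    "selestim": ["selection_summary.tsv", "selection_trace.tsv"],
    "network": ["network_edges.tsv", "network.gml", "clusters.json"],
    "simulate": ["simulation_grid.tsv"],
}


def _expected_outputs(stage: str, config: PipelineConfig) -> list[str]:
    if stage == "assoc":
        return [f"association_{m}.tsv"
                for m in config.association.get("modes", ["additive"])]
    return _STAGE_OUTPUTS[stage]


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute the configured stages; returns the run manifest.

    A stage is skipped when all of its expected outputs already exist
    (resume semantics); ``force=True`` recomputes everything.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        expected = [out / f for f in _expected_outputs(stage, config)]
        if not force and expected and all(f.exists() for f in expected):
            log.info("stage %s: outputs present, skipping", stage)
            manifest["stages"][stage] = {"status": "cached"}
            for f in expected:
                manifest["checksums"][f.name] = _sha256(f)
            continue
        log.info("stage %s: running (seed=%d)", stage, config.seed)
        t0 = time.monotonic()
        try:
            written = _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_json(manifest, manifest_path)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        elapsed = time.monotonic() - t0
        manifest["stages"][stage] = {
            "status": "ok",
            "wall_time_s": round(elapsed, 3),
            "outputs": [f.name for f in written],
        }
        for f in written:
            manifest["checksums"][f.name] = _sha256(f)
        log.info("stage %s: done in %.2fs", stage, elapsed)
    _write_json(manifest, manifest_path)
    return manifest


def demo_config(output_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """A small bundled synthetic configuration for the one-command demo."""
    return PipelineConfig.from_dict(
        {
            "output_dir": str(output_dir),
            "seed": seed,
            "synthetic": {
                "n_populations": 12,
                "samples_per_pop": 30,
                "duplicate_pairs": 10,
                "sex_discordant": 6,
            },
            "mcmc": {
                "pilot_runs": 4,
                "pilot_len": 100,
                "burn_in": 800,
                "thin": 2,
                "n_samples": 300,
            },
            "simulation": {"replicates": 30},
        }
    )
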