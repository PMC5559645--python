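"""End-to-end pipeline tying the analysis stages together.

Stages: (simulate) -> QC -> Dirichlet-process clustering -> clone tree ->
WGD timing (tetraploid genomes) -> per-branch signature refit ->
(drivers).  Every tunable defaults to the values the analysis is defined
with: presence-test error rate 1/200, at most 7 signatures per solution,
2% / 50-mutation exposure floors, +0.02 Pearson improvement rule,
branches need more than 20 mutations for signature analysis, 100
bootstrap resamples for WGD timing, targeted logR threshold 1, q < 0.1
for enrichment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ccf import DirichletProcessCCF, qc_filter
from .exceptions import ConfigurationError
from .io import read_mutation_table, read_segments, read_signature_catalog
from .phylogeny import build_tree
from .signatures import branch_signatures
from .simulate import synthetic_signature_catalog
from .wgd import WGDTimingModel

log = logging.getLogger("clonetrack")


@dataclass
class PipelineConfig:
    """Paths, stage toggles and tunables for one pipeline run."""

    mutations: str | None = None
    segments: str | None = None
    purity: str | None = None
    signature_catalog: str | None = None  # None: synthetic stand-in catalogue
    outdir: str = "clonetrack_out"
    seed: int = 0

    # stage toggles
    run_cluster: bool = True
    run_tree: bool = True
    run_wgd: bool = True
    run_signatures: bool = True

    # tunables (defaults are the analysis' defining values)
    error_rate: float = 1.0 / 200.0
    tau: float = 0.05
    dp_sweeps: int = 1000
    dp_burn_in: int = 500
    min_cluster_size: int | None = None
    max_signatures: int = 7
    sig_min_fraction: float = 0.02
    sig_min_count: float = 50.0
    sig_min_improvement: float = 0.02
    min_branch_mutations: int = 20
    wgd_bootstrap: int = 100
    logr_threshold: float = 1.0
    q_threshold: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; writes per-stage outputs and a run
    log into ``config.outdir`` and returns the in-memory results bundle.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {"version": __version__, "seed": config.seed}
    try:
        log.info("clonetrack %s starting (seed=%d)", __version__, config.seed)

        stage = "load-inputs"
        if config.mutations is None or config.segments is None or config.purity is None:
            raise ConfigurationError("mutations, segments and purity paths are required")
        mutations = read_mutation_table(config.mutations)
        segments = read_segments(config.segments)
        missing = [s for s in mutations.samples if s not in segments.samples]
        if missing:
            raise ConfigurationError(f"no segments for sample(s) {missing}")
        pur = pd.read_csv(config.purity, sep="\t")
        purity = dict(zip(pur["sample"], pur["purity"]))
        catalog = (read_signature_catalog(config.signature_catalog)
                   if config.signature_catalog else synthetic_signature_catalog())

        stage = "qc"
        retained, excluded, stats = qc_filter(mutations, segments, purity)
        results["qc"] = stats
        excluded.to_csv(outdir / "excluded.tsv", sep="\t", index=False)
        log.info("QC retained %d/%d mutations", stats["n_retained"], stats["n_total"])

        if config.run_cluster:
            stage = "cluster"
            subs = retained[retained["var_class"] == "substitution"].reset_index(drop=True)
            model = DirichletProcessCCF.from_dataframe(subs, purity,
                                                       samples=mutations.samples)
            clustering = model.fit(sweeps=config.dp_sweeps, burn_in=config.dp_burn_in,
                                   seed=config.seed,
                                   min_cluster_size=config.min_cluster_size)
            results["clustering"] = clustering
            clustering.clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            clustering.assignments().to_csv(outdir / "assignments.tsv",
                                            sep="\t", index=False)
            log.info("clustering found %d clusters", clustering.n_clusters)

        if config.run_tree and config.run_cluster:
            stage = "tree"
            tree = build_tree(clustering.clusters, mutations.samples, tau=config.tau)
            assignments = clustering.assignments()
            assignments["cluster"] = assignments["cluster"].map(
                lambda k: tree.merge_map.get(int(k), int(k)))
            tree.attach_mutations(assignments, retained)
            results["tree"] = tree
            (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
            tree.branch_stats_table().to_csv(outdir / "branch_stats.tsv",
                                             sep="\t", index=False)
            log.info("tree built: root=%s, %d branches", tree.root, len(tree.clusters))

        if config.run_wgd and config.run_tree and config.run_cluster:
            stage = "wgd-timing"
            trunk = tree.root
            trunk_ids = set(tree.branch_mutations.get(trunk, []))
            sample0 = mutations.samples[0]
            sel = retained["mutation_id"].isin(trunk_ids) & \
                (retained[f"c:{sample0}"] == 4)
            if sel.sum() >= 20:
                sub_ccfs = [float(tree.ccf[k][0]) for k in tree.clusters
                            if k != trunk and tree.ccf[k][0] > tree.tau]
                wgd_model = WGDTimingModel(retained.loc[sel, f"X:{sample0}"],
                                           retained.loc[sel, f"n:{sample0}"],
                                           purity[sample0], subclonal_ccfs=sub_ccfs)
                timing = wgd_model.fit(bootstrap=config.wgd_bootstrap, seed=config.seed)
                results["wgd"] = timing
                (outdir / "wgd_timing.json").write_text(json.dumps({
                    "t": timing.t_, "ci": list(timing.ci_),
                    "pi": {nm: float(p) for nm, p in
                           zip(timing.state_names, timing.pi_)},
                    "n_mutations": timing.n_mutations}, indent=2))
                log.info("WGD time t=%.3f (CI %.3f-%.3f)", timing.t_, *timing.ci_)
            else:
                log.info("WGD timing skipped: no tetraploid trunk mutations")

        if config.run_signatures and config.run_tree and config.run_cluster:
            stage = "signatures"
            sigs = branch_signatures(tree, retained, assignments, catalog,
                                     min_mutations=config.min_branch_mutations,
                                     max_size=config.max_signatures,
                                     min_fraction=config.sig_min_fraction,
                                     min_count=config.sig_min_count,
                                     min_improvement=config.sig_min_improvement)
            results["signatures"] = sigs
            rows = []
            for k, sol in sigs.items():
                if isinstance(sol, dict):
                    rows.append({"cluster": k, "signature": "", "exposure": np.nan,
                                 "r": np.nan, "note": sol["skipped"]})
                else:
                    for s, e in zip(sol.signatures, sol.exposures):
                        rows.append({"cluster": k, "signature": s,
                                     "exposure": float(e), "r": sol.r_, "note": ""})
            pd.DataFrame(rows).to_csv(outdir / "signatures.tsv", sep="\t", index=False)
            log.info("signatures refitted for %d branches", len(sigs))

        config.to_yaml(outdir / "config_used.yaml")
        return results
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise ConfigurationError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
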