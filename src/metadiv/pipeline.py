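"""End-to-end orchestration: simulate/load -> preprocess -> DC test ->
pathways -> network statistics -> enzyme integration, with a
deterministic human-readable summary.

A single top-level seed deterministically derives per-stage seeds via
``numpy.random.SeedSequence.spawn``, so one number reproduces the whole
run. Every stage writes its table(s) under the output directory and the
summary reports the headline quantities with the parameters and seeds
used.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import dc as dcmod
from . import enzyme as enzmod
from . import io as mio
from . import netstats, pathway, preprocess
import importlib
simmod = importlib.import_module(__package__ + ".simulate")
from .exceptions import MetadivError
from .io import SPECIES, SPECIES_PAIRS  # noqa: F401

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "report"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults match the module-level choices."""

    mode: str = "synthetic"              # synthetic | user_data
    out_dir: str = "metadiv_out"
    seed: int = 0
    # user_data inputs
    abundance_path: str | None = None
    samples_path: str | None = None
    network_dir: str | None = None
    expression_path: str | None = None
    expression_individuals_path: str | None = None
    # synthetic config overrides
    sim: dict = field(default_factory=dict)
    # preprocessing
    log2_input: bool = False
    corr_threshold: float = 0.8
    pc_mad_k: float = 6.0
    alpha: float = 0.05
    # testing thresholds
    sig: float = 0.05
    ns: float = 0.1
    min_members: int = 2
    connectivity_cutoff: int = 20
    concordance_mode: str = "both_dc"
    pair: str = "HC"
    cutoffs: tuple = (25, 50, 100, 200)
    n_permutations: int = 1000
    n_bootstrap: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise MetadivError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.cutoffs = tuple(cfg.cutoffs)
        return cfg

    def to_yaml(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh,
                           sort_keys=True)


def _stage_seed(seed, k):
    return int(np.random.SeedSequence(seed).spawn(k + 1)[k]
               .generate_state(1)[0] % (2 ** 31))


def _load_inputs(cfg: PipelineConfig):
    if cfg.mode == "synthetic":
        sim_cfg = simmod.SimConfig(**cfg.sim)
        sim_cfg.seed = _stage_seed(cfg.seed, 0)
        data = simmod.simulate(sim_cfg)
        data.write(os.path.join(cfg.out_dir, "inputs"))
        enzyme_de = dcmod.enzyme_de_from_matrix(data.expression,
                                                data.expression_species)
        return (data.abundance, data.samples, data.network, enzyme_de,
                data.truth)
    matrix, samples = mio.read_abundance(cfg.abundance_path,
                                         cfg.samples_path)
    net = mio.read_network(f"{cfg.network_dir}/compound_reaction.tsv",
                           f"{cfg.network_dir}/reaction_enzyme.tsv",
                           f"{cfg.network_dir}/compound_pathway.tsv")
    if cfg.expression_individuals_path:
        expr, expr_sp = mio.read_expression_matrix(
            cfg.expression_path, cfg.expression_individuals_path)
        enzyme_de = dcmod.enzyme_de_from_matrix(expr, expr_sp)
    else:
        enzyme_de = mio.read_expression_lr(cfg.expression_path)
    return matrix, samples, net, enzyme_de, None


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of stage outputs.

    Any stage failure aborts with the stage name attached.
    """
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    cfg.to_yaml(os.path.join(cfg.out_dir, "config_used.yaml"))
    outputs = {"config": cfg}
    timings = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise MetadivError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", name, timings[name])
        return out

    matrix, samples, net, enzyme_de, truth = stage(
        "load", lambda: _load_inputs(cfg))
    outputs["truth"] = truth

    clean, kept_samples, qc = stage("preprocess", lambda:
        preprocess.preprocess_pipeline(
            matrix, samples, log2_input=cfg.log2_input,
            corr_threshold=cfg.corr_threshold, pc_mad_k=cfg.pc_mad_k,
            alpha=cfg.alpha))
    outputs["qc"] = qc
    mio.write_abundance(clean, os.path.join(cfg.out_dir, "normalized.tsv"))

    dc_res = stage("dc_test", lambda:
        dcmod.run_dc(clean, kept_samples, sig=cfg.sig, ns=cfg.ns))
    outputs["dc"] = dc_res
    for pair in SPECIES_PAIRS:
        mio.write_results_table(dc_res.pair_frame(pair),
                                os.path.join(cfg.out_dir,
                                             f"dc_{pair}.tsv"))
    mio.write_results_table(dc_res.patterns.reset_index(),
                            os.path.join(cfg.out_dir, "patterns.tsv"))

    pw = stage("pathways", lambda:
        pathway.score_pathways(dc_res, net, min_members=cfg.min_members))
    outputs["pathways"] = pw
    mio.write_results_table(pw.frame,
                            os.path.join(cfg.out_dir,
                                         "pathway_scores.tsv"))

    def _network_stage():
        rng = np.random.default_rng(_stage_seed(cfg.seed, 2))
        degrees = netstats.connectivity(net, clean.metabolite_ids)
        out = {"degrees": degrees}
        lr = dc_res.pair_frame(cfg.pair).set_index("metabolite_id")["LR"]
        try:
            out["connectivity"] = netstats.split_and_compare(
                degrees, lr, cutoff=cfg.connectivity_cutoff,
                B=cfg.n_permutations, rng=rng)
        except MetadivError as exc:
            logger.warning("connectivity comparison skipped: %s", exc)
            out["connectivity"] = None
        pt = netstats.pair_correlations(clean, kept_samples, net)
        out["pair_table"] = pt
        out["coupling"] = {
            sp: netstats.coupling_test(pt, sp, B=cfg.n_permutations,
                                       rng=rng)
            for sp in SPECIES}
        out["concordance"] = netstats.direction_concordance(
            pt, dc_res, pair=cfg.pair, mode=cfg.concordance_mode,
            q_cutoff=cfg.sig, B=cfg.n_bootstrap, rng=rng)
        return out

    net_out = stage("network", _network_stage)
    outputs["network"] = net_out

    def _enzyme_stage():
        rng = np.random.default_rng(_stage_seed(cfg.seed, 3))
        assoc = enzmod.build_associations(net, dc_res, enzyme_de,
                                          pair=cfg.pair)
        out = {"associations": assoc}
        n_met = assoc["metabolite"].nunique()
        n_enz = assoc["enzyme"].nunique()
        try:
            out["by_metabolite"] = enzmod.stratify_by_metabolite(
                assoc, ("q", cfg.sig), pair=cfg.pair,
                B=cfg.n_permutations, rng=rng)
        except MetadivError as exc:
            logger.warning("by_metabolite not computable: %s", exc)
            out["by_metabolite"] = None
        try:
            out["by_enzyme"] = enzmod.stratify_by_enzyme(
                assoc, ("q", cfg.sig), pair=cfg.pair,
                B=cfg.n_permutations, rng=rng)
        except MetadivError as exc:
            logger.warning("by_enzyme not computable: %s", exc)
            out["by_enzyme"] = None
        sweep_cuts = ([c for c in cfg.cutoffs if c < n_enz]
                      if len([c for c in cfg.cutoffs if c < n_enz]) >= 3
                      else sorted(
            {max(2, n_enz // 8), max(3, n_enz // 4), max(4, n_enz // 2)}))
        try:
            out["sweep"] = enzmod.cutoff_sweep(
                assoc, sweep_cuts, direction="by_enzyme", pair=cfg.pair,
                B=max(100, cfg.n_permutations // 5), rng=rng)
        except MetadivError as exc:
            logger.warning("cutoff sweep not computable: %s", exc)
            out["sweep"] = None
        return out

    enz_out = stage("enzyme_link", _enzyme_stage)
    outputs["enzyme"] = enz_out
    outputs["timings"] = timings

    text = report(outputs)
    with open(os.path.join(cfg.out_dir, "summary.txt"), "w",
              encoding="utf-8") as fh:
        fh.write(text)
    return outputs


def report(outputs: dict) -> str:
    """Deterministic text summary of whatever stages are present."""
    cfg = outputs.get("config")
    lines = ["metadiv pipeline summary",
             "=" * 40]
    if cfg is not None:
        lines.append(f"mode={cfg.mode} seed={cfg.seed} pair={cfg.pair} "
                     f"B_perm={cfg.n_permutations} "
                     f"B_boot={cfg.n_bootstrap}")

    qc = outputs.get("qc")
    if qc is None:
        lines.append("[preprocess] not run")
    else:
        lines.append(f"[preprocess] excluded replicates: "
                     f"{qc.excluded_measurement_ids or 'none'}; "
                     f"regressed components: "
                     f"{[k + 1 for k in qc.removed_components] or 'none'}")

    dc_res = outputs.get("dc")
    if dc_res is None:
        lines.append("[dc_test] not run")
    else:
        lines.append("[dc_test] " + dc_res.summary().replace("\n", "\n  "))

    pw = outputs.get("pathways")
    if pw is None:
        lines.append("[pathways] not run")
    else:
        lines.append("[pathways] " + pw.summary().replace("\n", "\n  "))

    net_out = outputs.get("network")
    if net_out is None:
        lines.append("[network] not run")
    else:
        conn = net_out.get("connectivity")
        if conn is not None:
            lines.append(
                f"[network] connectivity: median LR low-high = "
                f"{conn.statistic:+.3f} (low n={conn.n_low}, high "
                f"n={conn.n_high}), permutation p={conn.permutation_p:.4g}")
        for sp, res in net_out["coupling"].items():
            lines.append("[network] coupling " + res.summary())
        lines.append("[network] " + net_out["concordance"].summary())

    enz_out = outputs.get("enzyme")
    if enz_out is None:
        lines.append("[enzyme_link] not run")
    else:
        assoc = enz_out["associations"]
        lines.append(f"[enzyme_link] {assoc['enzyme'].nunique()} enzymes, "
                     f"{len(assoc)} associations")
        for key in ("by_metabolite", "by_enzyme", "sweep"):
            item = enz_out.get(key)
            lines.append("[enzyme_link] "
                         + (item.summary() if item is not None
                            else f"{key}: not computable"))
    return "\n".join(lines) + "\n"
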