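"""Configured pipeline: rank genes, date, reconstruct traits, cross-validate,
screen identities, and report.

The configuration is a flat YAML document (no code execution): a ``stages``
list, a global ``seed`` and ``workdir``, and one block per stage.  Unknown
keys are rejected at validation time.  Every stage logs its parameters and
RNG seed, and all stochastic stages are deterministic under a fixed seed,
so identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixture as fixture_mod
from .dating import DatingModel, fossil_cross_validate, mcmc_date
from .gene_ranking import gene_stats, rank_and_select
from .identity import identity_report
from .io import read_calibrations, read_fasta, read_newick, read_traits
from .mk import akaike_weights, fit_mk
from .parsimony import count_origins, fitch_count
from .posterior import summarize_chronogram
from .rate_models import RateProcessParams
from .simmap import simmap_modal_origins, stochastic_map
from .synthetic import BranchData, sim_bd_tree, sim_branch_data, sim_calibrations, sim_rates
from .io import write_calibrations, write_newick

log = logging.getLogger("volvoclock")

STAGES = ("fixture", "simulate", "rankgenes", "date", "asr", "xval", "identity", "report")
_TOP_KEYS = {"stages", "seed", "workdir"} | set(STAGES)

__all__ = ["load_config", "run_pipeline", "cross_model_report"]


def load_config(source) -> dict:
    """Load and validate a pipeline configuration (YAML path or dict)."""
    if isinstance(source, (str, Path)):
        config = yaml.safe_load(Path(source).read_text())
    else:
        config = dict(source)
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for stage in config.get("stages", []):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    config.setdefault("seed", 0)
    config.setdefault("workdir", "volvoclock_out")
    return config


def run_pipeline(source) -> dict:
    """Execute the configured stages in their declared order.

    Returns {stage name: artifact dict}; every table is also written as TSV
    under the workdir.  A stage failure raises, aborting the run.
    """
    config = load_config(source)
    workdir = Path(config["workdir"])
    workdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    artifacts: dict[str, dict] = {}
    for stage in config.get("stages", []):
        log.info("stage %s starting (seed=%d)", stage, seed)
        fn = globals()[f"_stage_{stage}"]
        artifacts[stage] = fn(config.get(stage, {}) or {}, workdir, seed, artifacts)
        log.info("stage %s done", stage)
    return artifacts


# ----------------------------------------------------------------------
def _stage_fixture(cfg: dict, workdir: Path, seed: int, artifacts) -> dict:
    outdir = Path(cfg.get("outdir", workdir / "fixture"))
    fx = fixture_mod.build_volvocine_fixture(outdir)
    return {"fixture": fx, "outdir": outdir}


def _stage_simulate(cfg: dict, workdir: Path, seed: int, artifacts) -> dict:
    n_tips = int(cfg.get("n_tips", 20))
    birth = float(cfg.get("birth", 0.02))
    death = float(cfg.get("death", 0.01))
    sites = int(cfg.get("sites", 1000))
    clock_cfg = cfg.get("clock", {})
    params = RateProcessParams(
        model=clock_cfg.get("model", "UGAM"),
        base_rate=float(clock_cfg.get("base_rate", 1e-3)),
        variance=float(clock_cfg.get("variance", 2.5e-7)),
        reversion=float(clock_cfg.get("reversion", 0.05)),
    )
    tree = sim_bd_tree(n_tips, birth, death, seed=seed)
    rates = sim_rates(tree, params, seed=seed + 1)
    data = sim_branch_data(tree, rates, sites, seed=seed + 2)
    internal = [v for v in range(tree.n_nodes)
                if not tree.is_tip(v) and v != tree.root]
    n_cal = min(int(cfg.get("n_calibrations", 3)), len(internal))
    rng = np.random.default_rng(seed + 3)
    nodes = [tree.root] + list(
        rng.choice(internal, size=max(n_cal - 1, 0), replace=False)
    )
    cals = sim_calibrations(
        tree, nodes, width=float(cfg.get("calibration_width", 0.1))
        * float(tree.ages[tree.root]), seed=seed + 4,
    )
    outdir = workdir / "simulated"
    outdir.mkdir(exist_ok=True)
    obs = tree.copy()
    obs.lengths = data.lengths.copy()
    obs.length_kind = "subst"
    obs.ages = None
    write_newick(obs, outdir / "branch_lengths.nwk")
    write_calibrations(cals, outdir / "calibrations.tsv")
    truth = pd.DataFrame({
        "node": range(tree.n_nodes),
        "true_age": tree.ages,
        "true_rate": rates,
    })
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return {"tree": tree, "rates": rates, "data": data, "calibrations": cals,
            "params": params, "outdir": outdir}


def _stage_rankgenes(cfg: dict, workdir: Path, seed: int, artifacts) -> dict:
    species = read_newick(Path(cfg["species_tree"]).read_text())
    gene_dir = Path(cfg["gene_trees"])
    genes = {
        p.stem: read_newick(p.read_text(), allow_polytomy=True)
        for p in sorted(gene_dir.glob("*.nwk"))
    }
    stats = gene_stats(genes, species)
    selected, table = rank_and_select(stats, int(cfg.get("k", 8)))
    table.to_csv(workdir / "gene_ranking.tsv", sep="\t", index=False)
    (workdir / "selected_genes.txt").write_text("\n".join(selected) + "\n")
    return {"selected": selected, "table": table}


def _dating_inputs(cfg: dict, seed: int, artifacts):
    if "simulate" in artifacts:
        sim = artifacts["simulate"]
        return sim["tree"], sim["data"], sim["calibrations"]
    tree = read_newick(Path(cfg["tree"]).read_text())
    sites = int(cfg.get("sites", 10000))
    data = BranchData.from_lengths(tree.lengths, sites)
    cals = read_calibrations(cfg["calibrations"])
    # topology only: the sampler proposes node ages afresh
    return tree, data, cals


def _stage_date(cfg: dict, workdir: Path, seed: int, artifacts) -> dict:
    tree, data, cals = _dating_inputs(cfg, seed, artifacts)
    models = cfg.get("models", [cfg.get("model", "CIR")])
    n_gen = int(cfg.get("n_gen", 10000))
    sample_every = int(cfg.get("sample_every", 10))
    n_chains = int(cfg.get("chains", 2))
    chronograms = {}
    for model_name in models:
        params = RateProcessParams(
            model=model_name,
            base_rate=float(cfg.get("base_rate", 1e-3)),
            variance=float(cfg.get("variance", 2.5e-7)),
            reversion=float(cfg.get("reversion", 0.05)),
        )
        model = DatingModel(
            tree=tree, calibrations=cals, clock=params,
            root_max=float(cfg.get("root_max", 2000.0)),
        )
        samples = mcmc_date(
            model, data, n_gen=n_gen, sample_every=sample_every,
            seed=seed, n_chains=n_chains,
        )
        chron, text = summarize_chronogram(samples)
        chron.table().to_csv(
            workdir / f"chronogram_{model_name}.tsv", sep="\t", index=False
        )
        (workdir / f"chronogram_{model_name}.nex").write_text(text)
        sample_log = pd.DataFrame(samples.node_ages)
        sample_log.insert(0, "chain", samples.chain_id)
        sample_log.insert(1, "generation", samples.generation)
        sample_log.to_csv(
            workdir / f"samples_{model_name}.tsv", sep="\t", index=False
        )
        chronograms[model_name] = chron
    return {"chronograms": chronograms, "tree": tree}


# default ancestral conditions for the fixture characters, established by
# the unicellular, isogamous outgroups of the wider phylogeny
_ANCESTRAL = {
    "cellularity": ("multi", "uni"),
    "gametes2": ("aniso", "iso"),
    "gametes3": (["aniso", "oog"], "iso"),
    "somatic_cells": ("1", "0"),
    "germ_cells": ("1", "0"),
    "spheroid": ("1", "0"),
    "meiotic_hatching": ("reduced", "full"),
    "internal_fert": ("1", "0"),
    "extrafertile_females": ("1", "0"),
    "dwarf_males": ("1", "0"),
    "mating_system": ("monoecy", "dioecy"),
    **{f"kirk_step_{i}": ("1", "0") for i in range(1, 13)},
}


def _stage_asr(cfg: dict, workdir: Path, seed: int, artifacts) -> dict:
    if cfg.get("tree", "fixture") == "fixture":
        fx = artifacts.get("fixture", {}).get("fixture")
        if fx is None:
            fx = fixture_mod.build_volvocine_fixture()
        tree, traits = fx.tree, fx.traits
    else:
        tree = read_newick(Path(cfg["tree"]).read_text(), length_kind="my")
        traits = read_traits(cfg["traits"], cfg.get("trait_states"))
    characters = cfg.get("characters", ["cellularity", "gametes2", "somatic_cells"])
    n_maps = int(cfg.get("n_maps", 200))
    rows = []
    for char in characters:
        col = traits.column(char)
        states = traits.states(char)
        derived, ancestral = _ANCESTRAL.get(char, (states[-1], states[0]))
        changes, _sets = fitch_count(tree, col, states=states)
        origins = count_origins(tree, col, derived, states=states,
                                root_state=ancestral)
        fit_er = fit_mk(tree, col, "ER", states=states, seed=seed)
        row = {
            "character": char,
            "fitch_min_changes": changes,
            "parsimony_min_origins": origins,
            "er_rate": float(fit_er.model.rates[0]),
            "er_loglik": fit_er.loglik,
        }
        if not fit_er.degenerate:
            if cfg.get("compare_ard", True) and len(states) >= 2:
                fit_ard = fit_mk(tree, col, "ARD", states=states, seed=seed)
                w = akaike_weights([
                    (fit_er.loglik, fit_er.n_params),
                    (fit_ard.loglik, fit_ard.n_params),
                ])
                row["akaike_weight_er"] = float(w[0])
                row["akaike_weight_ard"] = float(w[1])
            # root pinned to the ancestral condition for mapping (the
            # fixture tree lacks the outgroups that would anchor it)
            import dataclasses

            pi = [1.0 if s == ancestral else 0.0 for s in states]
            map_model = dataclasses.replace(fit_er.model, root_prior=pi)
            maps = stochastic_map(tree, col, map_model, n_maps, seed=seed)
            row["simmap_modal_origins"] = simmap_modal_origins(maps, derived)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(workdir / "asr_origins.tsv", sep="\t", index=False)
    return {"table": table}


def _stage_xval(cfg: dict, workdir: Path, seed: int, artifacts) -> dict:
    tree, data, cals = _dating_inputs(cfg, seed, artifacts)
    params = RateProcessParams(
        model=cfg.get("model", "CIR"),
        base_rate=float(cfg.get("base_rate", 1e-3)),
        variance=float(cfg.get("variance", 2.5e-7)),
        reversion=float(cfg.get("reversion", 0.05)),
    )
    model = DatingModel(
        tree=tree, calibrations=cals, clock=params,
        root_max=float(cfg.get("root_max", 2000.0)),
    )
    table, ss = fossil_cross_validate(
        model, data, n_gen=int(cfg.get("n_gen", 2000)),
        sample_every=int(cfg.get("sample_every", 5)), seed=seed,
    )
    table.to_csv(workdir / "fossil_xval.tsv", sep="\t", index=False)
    return {"table": table, "total_ss": ss}


def _stage_identity(cfg: dict, workdir: Path, seed: int, artifacts) -> dict:
    seqs = read_fasta(cfg["fasta"])
    pairs = [tuple(p) for p in cfg.get("pairs", [])] or None
    table = identity_report(
        seqs, pairs=pairs, convention=cfg.get("convention", "all-columns"),
        protein=bool(cfg.get("protein", False)),
    )
    table.to_csv(workdir / "identity.tsv", sep="\t", index=False)
    return {"table": table}


def cross_model_report(chronograms: dict) -> pd.DataFrame:
    """Per-node, per-model age comparison with a symmetric non-overlap flag.

    A model is flagged at a node when its 95% HPD interval overlaps none of
    the other models' intervals there (the outlier criterion applied to the
    UGAM volvocine dates).
    """
    models = list(chronograms)
    any_tree = chronograms[models[0]].tree
    rows = []
    for v in range(any_tree.n_nodes):
        if any_tree.is_tip(v):
            continue
        row = {"node": v}
        for m in models:
            c = chronograms[m]
            row[f"{m}_mean"] = c.mean[v]
            row[f"{m}_hpd_low"] = c.hpd_low[v]
            row[f"{m}_hpd_high"] = c.hpd_high[v]
        for m in models:
            c = chronograms[m]
            overlaps = [
                not (c.hpd_high[v] < chronograms[o].hpd_low[v]
                     or chronograms[o].hpd_high[v] < c.hpd_low[v])
                for o in models if o != m
            ]
            row[f"{m}_nonoverlap"] = bool(overlaps) and not any(overlaps)
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_report(cfg: dict, workdir: Path, seed: int, artifacts) -> dict:
    out: dict = {}
    if "date" in artifacts and len(artifacts["date"]["chronograms"]) > 1:
        table = cross_model_report(artifacts["date"]["chronograms"])
        table.to_csv(workdir / "cross_model.tsv", sep="\t", index=False)
        out["cross_model"] = table
    if "asr" in artifacts:
        out["asr"] = artifacts["asr"]["table"]
    return out
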