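"""End-to-end orchestration with resumable, hash-stamped stage outputs.

``run_all`` executes the full analysis on one model: wildtype reference,
per-gene allele sweeps, essentiality, single-reaction decomposition,
currency analysis, gene--trait modularity, and the step randomization test.
Every stage writes a TSV whose first line embeds a hash of the run
configuration; a stage is skipped when its output already exists with a
matching hash, so reruns are idempotent and byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from pleioflux import currency as currency_mod
from pleioflux.currency import CurrencyMetabolite, load_currency_list
from pleioflux.model_io import (
    MetabolicModel,
    ModelConfig,
    extract_biomass_components,
    load_model,
)
from pleioflux.modularity import GeneTraitNetwork, scaled_modularity
from pleioflux.pleiotropy import (
    REDUCTION_THRESHOLD,
    allele_pleiotropy,
    build_reference,
    classify_genes,
    default_fraction_grid,
    essentiality_count,
    reaction_pleiotropy,
    sweep_gene,
)
from pleioflux.model_io import reactions_constrained_by_gene
from pleioflux.step_statistics import step_randomization_test

__all__ = ["RunConfig", "run_all", "summarize"]

log = logging.getLogger("pleioflux")


@dataclass
class RunConfig:
    """Everything a full run needs; all stochastic stages derive their seeds
    from ``seed`` so a run is reproducible end to end."""

    model_path: str
    output_dir: str
    biomass_reaction_id: Optional[str] = None
    exclusion_list: tuple[str, ...] = ()
    currency_list_path: Optional[str] = None
    grid_step: float = 0.005
    threshold: float = REDUCTION_THRESHOLD
    n_null: int = 10_000
    n_rand: int = 1_000_000
    seed: int = 0
    solver: str = "glpk"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        n = round(1.0 / self.grid_step)
        if abs(n * self.grid_step - 1.0) > 1e-9:
            raise ValueError(f"grid step {self.grid_step} does not divide 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "exclusion_list" in raw:
            raw["exclusion_list"] = tuple(raw["exclusion_list"])
        return cls(**raw)

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write_stage(df: pd.DataFrame, path: Path, digest: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={digest}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _stage_done(path: Path, digest: str) -> bool:
    if not path.exists():
        return False
    with open(path) as fh:
        first = fh.readline().strip()
    return first == f"# config_hash={digest}"


def read_stage(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _timed(name: str, digest: str, path: Path):
    """Stage guard: returns None when the stage output is already current."""
    if _stage_done(path, digest):
        log.info("stage %s: up to date (%s), skipping", name, path.name)
        return False
    return True


def run_all(config: RunConfig, mm: Optional[MetabolicModel] = None) -> Path:
    """Run every stage; returns the output directory.

    ``mm`` may be supplied directly (e.g. a synthetic fixture) to bypass
    file loading; otherwise the model is read from ``config.model_path``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31))
             for name in ("modularity", "steptest")}

    if mm is None:
        mm = load_model(
            config.model_path,
            ModelConfig(biomass_reaction_id=config.biomass_reaction_id),
            solver=config.solver,
        )
    mm.cobra_model.solver = config.solver
    components = extract_biomass_components(mm, config.exclusion_list)
    grid = default_fraction_grid(config.grid_step)
    genes = sorted(g.id for g in mm.genes)

    t0 = time.time()
    ref = build_reference(mm, components, threshold=config.threshold)
    ref_path = out / "reference.tsv"
    if _timed("reference", digest, ref_path):
        df = pd.DataFrame(
            {
                "component": list(ref.component_max),
                "wildtype_max": list(ref.component_max.values()),
            }
        )
        df.loc[len(df)] = [mm.biomass_reaction_id, ref.biomass_max]
        _write_stage(df, ref_path, digest)
        log.info("stage reference: %.1fs", time.time() - t0)

    # ---- per-gene sweeps ------------------------------------------------------
    sweeps_path = out / "sweeps.tsv"
    summary_path = out / "summary.tsv"
    if _timed("sweep", digest, sweeps_path) or _timed("sweep", digest, summary_path):
        t0 = time.time()
        frames = []
        summary_rows = []
        classes = classify_genes(ref, genes)
        for g in genes:
            profile = sweep_gene(ref, g, grid)
            frames.append(profile.as_frame())
            summary_rows.append(
                (
                    g,
                    profile.knockout_pleiotropy,
                    essentiality_count(ref, g, 0.0),
                    profile.steps,
                    classes.loc[g, "class"],
                    bool(classes.loc[g, "fitness_contributing"]),
                )
            )
        _write_stage(pd.concat(frames, ignore_index=True), sweeps_path, digest)
        summary = pd.DataFrame(
            summary_rows,
            columns=["gene", "ko_pleiotropy", "essentiality", "steps",
                     "class", "fitness_contributing"],
        )
        _write_stage(summary, summary_path, digest)
        log.info("stage sweep: %d genes, %.1fs", len(genes), time.time() - t0)
    summary = read_stage(summary_path)

    # ---- single-reaction decomposition (type I vs type II) --------------------
    decompose_path = out / "decompose.tsv"
    if _timed("decompose", digest, decompose_path):
        t0 = time.time()
        rows = []
        for g in genes:
            constrained = sorted(reactions_constrained_by_gene(mm, g))
            if len(constrained) < 2:
                continue
            gene_p, _ = allele_pleiotropy(ref, g, 0.0)
            if gene_p == 0:
                continue
            best = max(reaction_pleiotropy(ref, r) for r in constrained)
            rows.append((g, len(constrained), gene_p, best, best / gene_p))
        _write_stage(
            pd.DataFrame(
                rows,
                columns=["gene", "n_reactions", "ko_pleiotropy",
                         "max_single_reaction", "type2_share"],
            ),
            decompose_path,
            digest,
        )
        log.info("stage decompose: %.1fs", time.time() - t0)

    # ---- currency analysis ----------------------------------------------------
    currency_path = out / "currency.tsv"
    if config.currency_list_path and _timed("currency", digest, currency_path):
        t0 = time.time()
        cms = load_currency_list(config.currency_list_path)
        rows = []
        for mode in ("pleiotropy", "essentiality"):
            result = currency_mod.reduction_analysis(
                mm, components, cms, mode=mode, genes=genes,
                threshold=config.threshold,
            )
            for name, frac in result.per_metabolite.items():
                rows.append((mode, name, frac, len(result.pleiotropic_genes)))
            rows.append((mode, "any", result.any_fraction,
                         len(result.pleiotropic_genes)))
            rows.append((mode, "all-free", result.all_free_fraction,
                         len(result.pleiotropic_genes)))
        _write_stage(
            pd.DataFrame(
                rows, columns=["mode", "metabolite", "fraction_reduced",
                               "n_pleiotropic"]
            ),
            currency_path,
            digest,
        )
        log.info("stage currency: %.1fs", time.time() - t0)

    # ---- modularity -----------------------------------------------------------
    modularity_path = out / "modularity.tsv"
    edges_path = out / "edges.tsv"
    partition_path = out / "partition.tsv"
    affected = {
        g: allele_pleiotropy(ref, g, 0.0)[1] for g in genes
    }
    has_edges = any(affected.values())
    if has_edges and _timed("modularity", digest, modularity_path):
        t0 = time.time()
        net = GeneTraitNetwork.from_affected_sets(affected)
        result = scaled_modularity(net, n_null=config.n_null,
                                   seed=seeds["modularity"])
        _write_stage(
            pd.DataFrame(
                [
                    {
                        "q": result.q,
                        "z": result.z if result.z is not None else float("nan"),
                        "p": result.p,
                        "n_null": result.n_null,
                        "n_genes": len(net.genes),
                        "n_traits": len(net.traits),
                        "m": net.m,
                    }
                ]
            ),
            modularity_path,
            digest,
        )
        _write_stage(
            pd.DataFrame(sorted(net.edges), columns=["gene", "trait"]),
            edges_path, digest,
        )
        _write_stage(
            pd.DataFrame(
                sorted(result.partition.items()), columns=["node", "module"]
            ),
            partition_path, digest,
        )
        log.info("stage modularity: %.1fs", time.time() - t0)

    # ---- step randomization test ----------------------------------------------
    steptest_path = out / "steptest.tsv"
    eligible = summary[summary.ko_pleiotropy > 0]
    if len(eligible) >= 3 and _timed("steptest", digest, steptest_path):
        t0 = time.time()
        result = step_randomization_test(
            eligible.ko_pleiotropy.to_numpy(),
            eligible.steps.to_numpy(),
            n_rand=config.n_rand,
            seed=seeds["steptest"],
        )
        _write_stage(
            pd.DataFrame(
                [
                    {
                        "rho": result.rho,
                        "n_genes": result.n_genes,
                        "n_rand": result.n_rand,
                        "p": result.p,
                        "null_mean": result.null_mean,
                        "null_sd": result.null_sd,
                        "seed": result.seed,
                    }
                ]
            ),
            steptest_path,
            digest,
        )
        log.info("stage steptest: %.1fs", time.time() - t0)

    return out


def summarize(output_dir: str | Path) -> pd.DataFrame:
    """Headline statistics from a completed run bundle.

    Means and medians of knockout pleiotropy and essentiality over
    fitness-contributing genes, histogram-style counts, and the step-test
    and modularity results where present. Empty denominators yield NaN
    rather than zero.
    """
    out = Path(output_dir)
    summary = read_stage(out / "summary.tsv")
    fit = summary[summary.fitness_contributing]
    rows = [
        ("n_genes", len(summary)),
        ("n_fitness_contributing", len(fit)),
        ("mean_ko_pleiotropy", fit.ko_pleiotropy.mean() if len(fit) else float("nan")),
        ("median_ko_pleiotropy", fit.ko_pleiotropy.median() if len(fit) else float("nan")),
        ("mean_essentiality", fit.essentiality.mean() if len(fit) else float("nan")),
        ("median_essentiality", fit.essentiality.median() if len(fit) else float("nan")),
        ("mean_steps", fit.steps.mean() if len(fit) else float("nan")),
    ]
    modularity_path = out / "modularity.tsv"
    if modularity_path.exists():
        mod = read_stage(modularity_path).iloc[0]
        rows += [("modularity_q", mod.q), ("scaled_modularity", mod.z),
                 ("modularity_p", mod.p)]
    steptest_path = out / "steptest.tsv"
    if steptest_path.exists():
        st = read_stage(steptest_path).iloc[0]
        rows += [("step_rho", st.rho), ("step_p", st.p)]
    return pd.DataFrame(rows, columns=["statistic", "value"])
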