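"""End-to-end pipeline: expression table -> tissue models -> statistics.

Stage order: discretize expression, map gene states through GPRs, solve
the iMAT MILP per sample, run FVA, then the comparative statistics (total
variation ranking, flux-change calls, rate-limiting detection, active-set
overlap, hierarchical clustering) and hypergeometric enrichment for the
configured sample pairs.  Every intermediate is written as a flat text
file stamped with the configuration hash, and identical configurations
reproduce byte-identical outputs (the iMAT optimum is canonicalized).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import Annotation, enrich, enrichment_frame
from .expression import ExpressionTable, discretize, gene_fold_changes
from .fba import fva, rate_limiting
from .fluxstats import cluster_patterns, compare_fluxes, rank_fluctuating_reactions
from .imat import active_set_overlap, extract_tissue_model, reaction_states, solve_imat
from .network import MetabolicNetwork, read_network

__all__ = ["PipelineError", "RunConfig", "run_pipeline", "read_flux_matrix"]

logger = logging.getLogger("fluxshift")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All pipeline paths and parameters.

    Parameter defaults are the workflow's standard values: 15%/15%
    expression quantiles, fold-change thresholds 2 and 0.5, flux-change
    ratio thresholds +-0.5, activation threshold epsilon = 1.0.
    """

    model_path: str = ""
    expression_path: str = ""
    manifest_path: str = ""
    annotation_path: str = ""  # optional; default: network subsystems
    outdir: str = "fluxshift_out"
    dialect: str = "tabular"  # model dialect: tabular | sbml
    low_q: float = 0.15
    high_q: float = 0.15
    epsilon: float = 1.0
    activity_tol: float = 1e-6
    fva_scope: str = "generic"  # generic | union | per-tissue
    ratio_up: float = 0.5
    ratio_down: float = -0.5
    fc_up: float = 2.0
    fc_down: float = 0.5
    pseudocount: float = 1.0
    alpha: float = 0.05
    adjust: str = "BH"
    metric: str = "euclidean"
    linkage: str = "average"
    time_limit: float = 60.0
    seed: int = 0
    pairs: str = ""  # "s1:s2,s3:s4"; empty -> consecutive manifest pairs
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        """Flat ``key = value`` config file; CLI overrides take precedence."""
        values: dict[str, object] = {}
        valid = {f.name: f.type for f in fields(cls)}
        with open(path, encoding="utf-8") as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise PipelineError(f"{path}:{lineno}: expected key = value")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in valid:
                    raise PipelineError(f"{path}:{lineno}: unknown option {key!r}")
                values[key] = value
        config = cls()
        for key, value in values.items():
            current = getattr(config, key)
            if isinstance(current, bool):
                value = value in ("1", "true", "True", "yes")
            elif isinstance(current, int):
                value = int(value)
            elif isinstance(current, float):
                value = float(value)
            setattr(config, key, value)
        return replace(config, **overrides) if overrides else config

    def canonical_text(self) -> str:
        payload = asdict(self)
        return "\n".join(f"{key} = {payload[key]}" for key in sorted(payload))

    @property
    def config_hash(self) -> str:
        # hash the analysis configuration only: where the outputs land and
        # how verbosely we log do not change any result
        payload = asdict(self)
        payload.pop("outdir")
        payload.pop("log_level")
        text = "\n".join(f"{key} = {payload[key]}" for key in sorted(payload))
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def parsed_pairs(self, samples: list[str]) -> list[tuple[str, str]]:
        if self.pairs.strip():
            out = []
            for chunk in self.pairs.split(","):
                parts = chunk.split(":")
                if len(parts) != 2:
                    raise PipelineError(f"bad pair spec {chunk!r}; use s1:s2")
                a, b = (p.strip() for p in parts)
                for s in (a, b):
                    if s not in samples:
                        raise PipelineError(f"pair references unknown sample {s!r}")
                out.append((a, b))
            return out
        return list(zip(samples, samples[1:]))


def read_manifest(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "stage", "order"}
    missing = required - set(frame.columns)
    if missing:
        raise PipelineError(f"manifest {path} lacks columns {sorted(missing)}")
    return frame.sort_values("order", kind="mergesort").reset_index(drop=True)


def read_flux_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="reaction_id")


def _write_tsv(frame: pd.DataFrame, path: str, config_hash: str, index: bool) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"# config_hash={config_hash}\n")
        frame.to_csv(
            handle, sep="\t", index=index, float_format="%.9g", lineterminator="\n"
        )


def _write_json(payload: dict, path: str, config_hash: str) -> None:
    payload = {"config_hash": config_hash, **payload}
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def _scope_constraints(
    scope: str,
    network: MetabolicNetwork,
    active_sets: list[set[str]],
) -> dict[str, tuple[float, float]] | None:
    """FVA bound overrides for the configured variability scope.

    ``generic`` uses the full network; ``union`` restricts flux to the
    union of all tissues' active reactions (inactive-everywhere reactions
    are pinned to zero).  A per-tissue scope is deliberately not offered:
    the flux-change ratio divides both tissues' fluxes by the same
    variability range, which requires a scope shared by the compared pair.
    """
    if scope == "generic":
        return None
    if scope != "union":
        raise PipelineError(f"fva: unknown fva_scope {scope!r} (use generic|union)")
    union: set[str] = set().union(*active_sets) if active_sets else set()
    return {
        r.id: (0.0, 0.0) for r in network.reactions if r.id not in union
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the artifact manifest (also written).

    Raises :class:`PipelineError` naming the failing stage; validates all
    input paths before any solve (fail fast).
    """
    logging.basicConfig(level=config.log_level)
    for label, path in (
        ("model", config.model_path),
        ("expression", config.expression_path),
        ("manifest", config.manifest_path),
    ):
        if not path or not os.path.exists(path):
            raise PipelineError(f"config: {label} file {path!r} not found")
    if config.annotation_path and not os.path.exists(config.annotation_path):
        raise PipelineError(
            f"config: annotation file {config.annotation_path!r} not found"
        )
    os.makedirs(config.outdir, exist_ok=True)
    chash = config.config_hash
    outputs: list[str] = []

    def out(name: str) -> str:
        outputs.append(name)
        return os.path.join(config.outdir, name)

    # -- load inputs -------------------------------------------------------
    try:
        network = read_network(config.model_path, dialect=config.dialect)
        table = ExpressionTable.from_tsv(config.expression_path)
        manifest = read_manifest(config.manifest_path)
    except Exception as exc:
        raise PipelineError(f"load: {exc}") from exc
    samples = list(manifest["sample_id"])
    missing = set(samples) - set(table.samples)
    if missing:
        raise PipelineError(f"load: manifest samples missing from table: {sorted(missing)}")
    pairs = config.parsed_pairs(samples)

    # -- discretize --------------------------------------------------------
    logger.info("discretizing %d genes x %d samples", len(table.genes), len(samples))
    state_map = discretize(table, low_q=config.low_q, high_q=config.high_q)
    state_map.to_tsv(out("states.tsv"), header_comment=f"config_hash={chash}")

    # -- iMAT per sample ---------------------------------------------------
    models = []
    flux_cols = {}
    for sample in samples:
        rstates = reaction_states(network, state_map, sample)
        solution = solve_imat(
            network, rstates, epsilon=config.epsilon, time_limit=config.time_limit
        )
        if solution.status == "infeasible":
            raise PipelineError(f"imat: sample {sample}: base network infeasible")
        model = extract_tissue_model(
            network,
            solution,
            sample,
            activity_tol=config.activity_tol,
            source_states=rstates,
        )
        models.append(model)
        flux_cols[sample] = solution.fluxes
        logger.info(
            "imat %s: objective=%d active=%d status=%s",
            sample, solution.objective, len(model.active_reactions), solution.status,
        )
        _write_json(
            {
                "tissue": sample,
                "objective": solution.objective,
                "epsilon": config.epsilon,
                "status": solution.status,
                "active_reactions": sorted(model.active_reactions),
                "satisfied_high": sorted(solution.satisfied_high),
                "satisfied_low": sorted(solution.satisfied_low),
                "fluxes": solution.fluxes,
            },
            out(f"tissue_{sample}.json"),
            chash,
        )
    flux_matrix = pd.DataFrame(flux_cols, index=network.reaction_ids)[samples]
    flux_matrix.index.name = "reaction_id"
    _write_tsv(flux_matrix, out("flux_matrix.tsv"), chash, index=True)

    # -- FVA ---------------------------------------------------------------
    try:
        scope_overrides = _scope_constraints(
            config.fva_scope, network, [m.active_reactions for m in models]
        )
        fva_ranges = fva(network, scope_overrides)
    except Exception as exc:
        raise PipelineError(f"fva: {exc}") from exc
    fva_frame = pd.DataFrame(
        {
            "reaction_id": network.reaction_ids,
            "minflux": [fva_ranges[r][0] for r in network.reaction_ids],
            "maxflux": [fva_ranges[r][1] for r in network.reaction_ids],
        }
    )
    _write_tsv(fva_frame, out("fva.tsv"), chash, index=False)

    # -- statistics --------------------------------------------------------
    tv_frame = rank_fluctuating_reactions(flux_matrix, samples)
    _write_tsv(tv_frame, out("total_variation.tsv"), chash, index=False)

    if config.annotation_path:
        rxn_annotation = Annotation.from_tsv(
            config.annotation_path, universe=network.reaction_ids
        )
    else:
        rxn_annotation = Annotation.reactions_from_network(network)

    rl_rows = []
    rl_enrichment = []
    for model in models:
        limited = rate_limiting(model, network)
        for rid in sorted(limited):
            rl_rows.append(
                (model.tissue, rid, model.fluxes[rid], network.reaction(rid).upper_bound)
            )
        if limited:
            rl_enrichment += enrich(
                limited, rxn_annotation, f"rate_limiting_{model.tissue}",
                adjust=config.adjust,
            )
    _write_tsv(
        pd.DataFrame(rl_rows, columns=["tissue", "reaction_id", "flux", "bound"]),
        out("rate_limiting.tsv"),
        chash,
        index=False,
    )
    _write_tsv(
        enrichment_frame(rl_enrichment),
        out("rate_limiting_enrichment.tsv"),
        chash,
        index=False,
    )

    clustering = cluster_patterns(
        flux_matrix, axis="columns", metric=config.metric, method=config.linkage
    )
    with open(out("clustering.newick"), "w", encoding="utf-8") as handle:
        handle.write(f"# config_hash={chash} metric={config.metric} linkage={config.linkage}\n")
        handle.write(clustering.to_newick() + "\n")
    _write_tsv(clustering.heights_frame(), out("clustering_heights.tsv"), chash, index=False)

    _write_json(active_set_overlap(models), out("overlap.json"), chash)

    # -- comparisons + enrichment -----------------------------------------
    gene_annotation = Annotation.genes_from_network(network, table.genes)

    for tissue1, tissue2 in pairs:
        tag = f"{tissue1}_vs_{tissue2}"
        comparison = compare_fluxes(
            flux_matrix,
            tissue1,
            tissue2,
            fva_ranges,
            up_threshold=config.ratio_up,
            down_threshold=config.ratio_down,
        )
        _write_tsv(comparison, out(f"compare_{tag}.tsv"), chash, index=False)

        changes = gene_fold_changes(
            table,
            tissue1,
            tissue2,
            pseudocount=config.pseudocount,
            up_threshold=config.fc_up,
            down_threshold=config.fc_down,
        )
        gene_universe = gene_annotation.universe
        results = []
        for direction in ("up", "down"):
            flux_sel = set(comparison.loc[comparison["call"] == direction, "reaction_id"])
            results += enrich(flux_sel, rxn_annotation, f"flux_{direction}", adjust=config.adjust)
            gene_sel = {c.gene for c in changes if c.call == direction} & gene_universe
            results += enrich(gene_sel, gene_annotation, f"gene_{direction}", adjust=config.adjust)
        _write_tsv(
            enrichment_frame(results), out(f"enrichment_{tag}.tsv"), chash, index=False
        )

    manifest_path = out("run_manifest.json")
    manifest_payload = {
        "version": __version__,
        "config": config.canonical_text(),
        "seed": config.seed,
        "samples": samples,
        "pairs": [list(p) for p in pairs],
        "outputs": sorted(outputs),
    }
    _write_json(manifest_payload, manifest_path, chash)
    return manifest_payload
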