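"""Hypergeometric pathway enrichment for gene and reaction sets.

Tests whether a selection (up-/down-regulated genes, up-/down-regulated or
rate-limiting reactions, an active set) over-represents any pathway
relative to a universe of annotated items.  The p-value is the upper tail
P(X >= k) of the hypergeometric distribution with population N (universe),
K successes (pathway members) and n draws (selection size).  Raw p-values
drive the significance call by default; Benjamini-Hochberg adjusted values
are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import MetabolicNetwork

__all__ = [
    "Annotation",
    "EnrichmentResult",
    "hypergeometric_tail",
    "enrich",
    "significant",
    "enrichment_frame",
]


@dataclass
class Annotation:
    """Flat item -> pathway-labels map over an explicit universe."""

    mapping: dict[str, frozenset[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set(self.mapping)
        stray = set(self.mapping) - self.universe
        if stray:
            raise ValueError(
                f"annotated items outside the universe: {sorted(stray)[:5]}"
            )
        for item, labels in self.mapping.items():
            if any(not lab for lab in labels):
                raise ValueError(f"empty pathway label on item {item!r}")

    @property
    def pathways(self) -> dict[str, set[str]]:
        """Pathway label -> member items."""
        out: dict[str, set[str]] = {}
        for item, labels in self.mapping.items():
            for label in labels:
                out.setdefault(label, set()).add(item)
        return out

    @classmethod
    def from_tsv(cls, path: str, universe: Iterable[str] | None = None) -> "Annotation":
        frame = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, names=["item_id", "pathway"],
            header=0,
        )
        mapping: dict[str, frozenset[str]] = {}
        grouped: dict[str, set[str]] = {}
        for item, pathway in zip(frame["item_id"], frame["pathway"]):
            grouped.setdefault(item, set()).add(pathway)
        mapping = {item: frozenset(labels) for item, labels in grouped.items()}
        return cls(mapping, set(universe) if universe is not None else set())

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("item_id\tpathway\n")
            for item in sorted(self.mapping):
                for label in sorted(self.mapping[item]):
                    handle.write(f"{item}\t{label}\n")

    @classmethod
    def reactions_from_network(cls, network: MetabolicNetwork) -> "Annotation":
        """Reaction -> subsystem annotation; universe = all network reactions."""
        mapping = {
            r.id: frozenset((r.subsystem,))
            for r in network.reactions
            if r.subsystem
        }
        return cls(mapping, {r.id for r in network.reactions})

    @classmethod
    def genes_from_network(
        cls, network: MetabolicNetwork, expressed_genes: Iterable[str] | None = None
    ) -> "Annotation":
        """Gene -> subsystems of the reactions it participates in.

        The universe defaults to all model genes; passing the expression
        table's genes restricts it to model genes actually measured.
        """
        mapping: dict[str, set[str]] = {}
        for rxn in network.reactions:
            if not rxn.subsystem:
                continue
            for gene in rxn.genes:
                mapping.setdefault(gene, set()).add(rxn.subsystem)
        universe = set(network.genes)
        if expressed_genes is not None:
            universe &= set(expressed_genes)
            mapping = {g: labels for g, labels in mapping.items() if g in universe}
        return cls(
            {g: frozenset(labels) for g, labels in mapping.items()}, universe
        )


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    k: int  # selection members in the pathway
    n: int  # selection size
    K: int  # pathway size in the universe
    N: int  # universe size
    p_value: float
    adjusted_p: float
    direction: str


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) of Hypergeometric(N, K, n), via the survival function."""
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(
            f"invalid hypergeometric arguments k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    selection: Iterable[str],
    annotation: Annotation,
    direction_label: str = "",
    adjust: str = "BH",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a selection over every annotated pathway.

    Results are sorted ascending by raw p-value, ties by pathway label.
    ``adjust`` is ``"BH"`` (Benjamini-Hochberg) or ``"none"`` (adjusted_p
    then equals the raw p-value).
    """
    selected = set(selection)
    universe = annotation.universe
    if not universe:
        raise ValueError("empty annotation universe")
    stray = selected - universe
    if stray:
        raise ValueError(f"selection items outside the universe: {sorted(stray)[:5]}")
    if not selected:
        warnings.warn("empty selection: all p-values are 1.0", stacklevel=2)
    n = len(selected)
    N = len(universe)
    results = []
    pathways = annotation.pathways
    for label in sorted(pathways):
        members = pathways[label] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(selected & members)
        p = hypergeometric_tail(k, n, K, N)
        results.append((label, k, K, p))
    if not results:
        return []
    if adjust == "BH":
        adjusted = multipletests([r[3] for r in results], method="fdr_bh")[1]
    elif adjust == "none":
        adjusted = [r[3] for r in results]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out = [
        EnrichmentResult(
            pathway=label,
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=float(p),
            adjusted_p=float(adj),
            direction=direction_label,
        )
        for (label, k, K, p), adj in zip(results, adjusted)
    ]
    out.sort(key=lambda r: (r.p_value, r.pathway))
    return out


def significant(
    results: list[EnrichmentResult], alpha: float = 0.05, use_adjusted: bool = False
) -> list[EnrichmentResult]:
    """Filter results at level ``alpha`` on raw (default) or adjusted p."""
    key = (lambda r: r.adjusted_p) if use_adjusted else (lambda r: r.p_value)
    return [r for r in results if key(r) < alpha]


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "direction": [r.direction for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
        }
    )
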