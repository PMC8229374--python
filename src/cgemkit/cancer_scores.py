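"""Warburg-effect flux ratios and hallmark gene-set activation for CGEMs.

Two flux-ratio indices quantify the Warburg phenotype of a context-specific
model from its FBA flux state:

* AFR (glycolytic to oxidative ATP flux ratio) = flux(GAPD) / flux(ATPS4mi)
* EOR (extracellular acidification vs oxygen consumption) =
  flux(D_LACt2) / flux(O2t)

Sign convention: transport fluxes are positive for uptake into the cell, so a
lactate-secreting, oxygen-consuming model has EOR < 0 and (with glycolysis and
oxidative phosphorylation both running) AFR > 0.  The reaction ids are the
Recon3D names by default and configurable for toy models that alias them.

The gene-set index is the percentage of a hallmark-of-cancer gene list that
remains linked (through GPR rules) to reactions of the extracted model, out of
the hallmark genes present in the parent model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .extraction import ExtractionResult
from .flux_core import FluxState

__all__ = [
    "ReactionAliases",
    "ScoreReport",
    "afr_score",
    "eor_score",
    "hallmark_activation",
    "score_cgem",
    "read_gene_list",
]


@dataclass(frozen=True)
class ReactionAliases:
    """Ids of the six reserved reactions in the model at hand."""

    biomass: str = "biomass_reaction"
    atp_demand: str = "DM_atp_c_"
    gapd: str = "GAPD"
    atps: str = "ATPS4mi"
    lactate_transport: str = "D_LACt2"
    oxygen_transport: str = "O2t"

    def protected_set(self) -> frozenset[str]:
        return frozenset(
            (
                self.biomass,
                self.atp_demand,
                self.gapd,
                self.atps,
                self.lactate_transport,
                self.oxygen_transport,
            )
        )


DEFAULT_ALIASES = ReactionAliases()


@dataclass(frozen=True)
class ScoreReport:
    """Per-CGEM validation indices (NaN marks an undefined ratio)."""

    sample_id: str
    algorithm: str
    afr: float
    eor: float
    hallmark_percent: float
    flags: tuple[str, ...] = ()


def _ratio(flux: FluxState, numerator: str, denominator: str) -> float:
    num = flux[numerator]
    den = flux[denominator]
    if den == 0.0:
        return math.nan
    return num / den


def afr_score(flux: FluxState, aliases: ReactionAliases = DEFAULT_ALIASES) -> float:
    """Glycolytic-to-oxidative ATP flux ratio; NaN if the oxidative flux is 0."""
    return _ratio(flux, aliases.gapd, aliases.atps)


def eor_score(flux: FluxState, aliases: ReactionAliases = DEFAULT_ALIASES) -> float:
    """Lactate-transport to oxygen-transport flux ratio; negative for a
    lactate-secreting, oxygen-consuming state. NaN if oxygen flux is 0."""
    return _ratio(flux, aliases.lactate_transport, aliases.oxygen_transport)


def hallmark_activation(
    result: ExtractionResult, hallmark_genes: Iterable[str]
) -> float:
    """Percentage of (model-resident) hallmark genes retained by the CGEM.

    The denominator counts hallmark genes present in the parent model; the
    numerator counts those referenced by a GPR of any kept reaction.
    """
    hallmark = set(hallmark_genes)
    if not hallmark:
        raise ValueError("hallmark gene set is empty")
    in_model = hallmark & set(result.parent_genes)
    if not in_model:
        raise ValueError(
            "no hallmark gene occurs in the parent model "
            f"{result.parent_model_id!r}"
        )
    retained = in_model & set(result.kept_genes)
    return 100.0 * len(retained) / len(in_model)


def score_cgem(
    result: ExtractionResult,
    flux: FluxState,
    hallmark_genes: Iterable[str],
    aliases: ReactionAliases = DEFAULT_ALIASES,
) -> ScoreReport:
    """Assemble the three validation indices for one CGEM."""
    afr = afr_score(flux, aliases)
    eor = eor_score(flux, aliases)
    flags = []
    if math.isnan(afr):
        flags.append("afr_zero_denominator")
    if math.isnan(eor):
        flags.append("eor_zero_denominator")
    if not flux.optimal:
        flags.append(f"fba_{flux.status}")
    return ScoreReport(
        sample_id=result.sample_id,
        algorithm=result.algorithm,
        afr=afr,
        eor=eor,
        hallmark_percent=hallmark_activation(result, hallmark_genes),
        flags=tuple(flags),
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one id per line; blank lines ignored."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
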