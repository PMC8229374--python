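"""Synthetic inputs with known ground truth: a desk-scale Warburg-capable
metabolic network and simulated expression datasets.

The toy model stands in for a curated human reconstruction.  Its core couples
lumped glycolysis to a biomass reaction, with two routes of NADH reoxidation:
oxidative phosphorylation (oxygen-limited) and lactate dehydrogenase plus
lactate export.  Because oxygen uptake is capped while glucose is ample, the
biomass optimum secretes lactate while consuming oxygen — the Warburg
phenotype — so the glycolytic/oxidative flux ratio is positive and the
lactate/oxygen transport ratio negative by construction.  The six reserved
reaction ids (``biomass_reaction``, ``DM_atp_c_``, ``GAPD``, ``ATPS4mi``,
``D_LACt2``, ``O2t``) name their analogues directly, so downstream defaults
apply unchanged.

Around the core, ``n_pathways`` optional nutrient modules (uptake + transport
+ catabolism, each in its own subsystem with its own genes) provide small,
stoichiometrically identical ATP bonuses.  Whether a sample's context model
retains a module is decided purely by its expression through GPR mapping, so
planting per-group expression shifts in module subsystems yields groups with
known discriminative reactions — the ground truth for clustering and feature
selection — while leaving the core flux state essentially unchanged.

Expression is simulated per gene as a log-normal baseline shared by the
dataset, multiplied by the group's planted fold change where applicable, with
per-sample biological jitter, additive replicate noise, and per-sample gene
missingness whose default rate depends on the platform (proteome profiles
cover far fewer genes than transcriptome profiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model_io import MetabolicModel, Reaction, parse_gpr

__all__ = [
    "ToyModelSpec",
    "SimulationDesign",
    "make_toy_model",
    "simulate_expression",
    "hallmark_gene_list",
    "random_network",
    "MODULE_SUBSYSTEMS",
    "PLATFORM_MISSINGNESS",
]

SUB_EXCHANGE = "Exchange/demand reaction"
SUB_TRANSPORT = "Transport, extracellular"
SUB_GLYCOLYSIS = "Glycolysis"
SUB_PPP = "Pentose phosphate pathway"
SUB_TCA = "Citric acid cycle"
SUB_OXPHOS = "Oxidative phosphorylation"
SUB_BIOMASS = "Biomass"

#: optional nutrient modules: (tag, subsystem, transporter GPR, catabolic GPR)
_MODULES = (
    ("gln", "Glutaminolysis", "gSLC1A5", "gGLS and gGLUD1"),
    ("ala", "Alanine and aspartate metabolism", "gSLC7A5", "gGPT or gGPT2"),
    ("fru", "Fructose and mannose metabolism", "gSLC2A5", "gKHK and gALDOB"),
    ("rib", "Nucleotide interconversion", "gSLC29A1", "gRBKS"),
    ("fao", "Fatty acid oxidation", "gCD36", "gCPT1A and gACADVL"),
    ("ser", "Glycine, serine and threonine metabolism", "gSLC1A4", "gSHMT1 or gSHMT2"),
)

MODULE_SUBSYSTEMS = tuple(m[1] for m in _MODULES)

PLATFORM_MISSINGNESS = {"rnaseq": 0.02, "microarray": 0.08, "proteome": 0.35}

#: default uptake capacity of each optional nutrient (keeps every module's
#: biomass bonus small relative to the glucose/oxygen core)
_MODULE_UPTAKE = 0.5


@dataclass(frozen=True)
class ToyModelSpec:
    """Construction parameters of the synthetic network."""

    n_pathways: int = 6
    include_warburg_core: bool = True
    glucose_uptake: float = 10.0
    oxygen_uptake: float = 5.0
    module_uptake: float = _MODULE_UPTAKE
    model_id: str = "toy_warburg"

    def __post_init__(self) -> None:
        if not 0 <= self.n_pathways <= len(_MODULES):
            raise ValueError(f"n_pathways must lie in 0..{len(_MODULES)}")
        if not self.include_warburg_core:
            raise ValueError("the Warburg core is the backbone; it cannot be dropped")


def _rxn(rid, stoich, lb, ub, subsystem, gpr=None) -> Reaction:
    return Reaction(
        reaction_id=rid,
        lower_bound=lb,
        upper_bound=ub,
        stoichiometry=stoich,
        gpr=parse_gpr(gpr) if gpr else None,
        subsystem=subsystem,
    )


def make_toy_model(spec: ToyModelSpec | None = None) -> MetabolicModel:
    """Deterministically build the synthetic Warburg-capable network."""
    spec = spec or ToyModelSpec()
    M = 1000.0
    rxns: list[Reaction] = [
        # exchanges (cobra convention: negative flux = uptake)
        _rxn("EX_glc_e", {"glc_e": -1}, -spec.glucose_uptake, 0.0, SUB_EXCHANGE),
        _rxn("EX_o2_e", {"o2_e": -1}, -spec.oxygen_uptake, 0.0, SUB_EXCHANGE),
        _rxn("EX_lac_e", {"lac_e": -1}, 0.0, M, SUB_EXCHANGE),
        _rxn("EX_co2_e", {"co2_e": -1}, 0.0, M, SUB_EXCHANGE),
        _rxn("EX_h2o_e", {"h2o_e": -1}, -M, M, SUB_EXCHANGE),
        _rxn("DM_atp_c_", {"atp_c": -1, "adp_c": 1}, 1.0, M, SUB_EXCHANGE),
        # transport (positive = uptake into the cell)
        _rxn("GLCt1", {"glc_e": -1, "glc_c": 1}, 0.0, M, SUB_TRANSPORT,
             "gSLC2A1 or gSLC2A3"),
        _rxn("O2t", {"o2_e": -1, "o2_c": 1}, 0.0, M, SUB_TRANSPORT),
        _rxn("D_LACt2", {"lac_e": -1, "lac_c": 1}, -M, M, SUB_TRANSPORT,
             "gSLC16A1 or gSLC16A3"),
        _rxn("CO2t", {"co2_c": -1, "co2_e": 1}, 0.0, M, SUB_TRANSPORT),
        _rxn("H2Ot", {"h2o_c": -1, "h2o_e": 1}, -M, M, SUB_TRANSPORT),
        # glycolysis (GAPD lumps lower glycolysis: net 2 ATP / 2 NADH / 2 pyr
        # per fructose-1,6-bisphosphate)
        _rxn("HEX1", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1},
             0.0, M, SUB_GLYCOLYSIS, "gHK1 or gHK2"),
        _rxn("PGI", {"g6p_c": -1, "f6p_c": 1}, -M, M, SUB_GLYCOLYSIS, "gGPI"),
        _rxn("PFK", {"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1},
             0.0, M, SUB_GLYCOLYSIS, "gPFKL and gPFKM"),
        _rxn("GAPD",
             {"fdp_c": -1, "adp_c": -4, "nad_c": -2,
              "pyr_c": 2, "atp_c": 4, "nadh_c": 2},
             0.0, M, SUB_GLYCOLYSIS, "gGAPDH"),
        _rxn("LDH_L", {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1},
             -M, M, SUB_GLYCOLYSIS, "gLDHA or gLDHB"),
        # pentose phosphate (oxidative branch + lumped non-oxidative return)
        _rxn("G6PDH2r", {"g6p_c": -1, "nad_c": -2, "ru5p_c": 1, "nadh_c": 2,
                         "co2_c": 1},
             0.0, M, SUB_PPP, "gG6PD"),
        _rxn("TKT1", {"ru5p_c": -1.2, "f6p_c": 1}, 0.0, M, SUB_PPP,
             "gTKT and gTALDO1"),
        # TCA (lumped)
        _rxn("PDHm", {"pyr_c": -1, "nad_c": -1, "accoa_c": 1, "nadh_c": 1,
                      "co2_c": 1},
             0.0, M, SUB_TCA, "gPDHA1 and gDLAT"),
        _rxn("CSm", {"accoa_c": -1, "nad_c": -3, "nadh_c": 3, "co2_c": 2},
             0.0, M, SUB_TCA, "gCS"),
        # oxidative phosphorylation (P/O = 2.5)
        _rxn("ATPS4mi",
             {"nadh_c": -2, "o2_c": -1, "adp_c": -5,
              "nad_c": 2, "atp_c": 5, "h2o_c": 1},
             0.0, M, SUB_OXPHOS, "gATP5F1A and gATP5F1B"),
        # biomass: carbon skeletons + energy + reducing power
        _rxn("biomass_reaction",
             {"g6p_c": -0.2, "pyr_c": -1, "atp_c": -10, "nadh_c": -1,
              "adp_c": 10, "nad_c": 1},
             0.0, M, SUB_BIOMASS),
    ]
    for i, (tag, subsystem, t_gpr, c_gpr) in enumerate(_MODULES[: spec.n_pathways]):
        # nutrients differ in uptake capacity and (compensatingly) in molar
        # ATP/pyruvate yield, so every module contributes the same small bonus
        # to the core while its own flux magnitudes remain module-specific —
        # the groups' flux fingerprints stay in general position for PCA
        # without leaking group information into the shared core fluxes
        uptake = spec.module_uptake * (1.0 + 0.2 * i)
        yield_coef = spec.module_uptake / uptake
        rxns.extend(
            [
                _rxn(f"EX_{tag}_e", {f"{tag}_e": -1}, -uptake, 0.0,
                     subsystem),
                _rxn(f"{tag.upper()}t", {f"{tag}_e": -1, f"{tag}_c": 1},
                     0.0, M, subsystem, t_gpr),
                _rxn(f"{tag.upper()}cat",
                     {f"{tag}_c": -1, "adp_c": -yield_coef,
                      "pyr_c": yield_coef, "atp_c": yield_coef},
                     0.0, M, subsystem, c_gpr),
            ]
        )
    metabolites: list[str] = []
    for rxn in rxns:
        for met in rxn.stoichiometry:
            if met not in metabolites:
                metabolites.append(met)
    return MetabolicModel(
        model_id=spec.model_id,
        metabolites=metabolites,
        reactions=rxns,
        objective_reaction="biomass_reaction",
    )


def hallmark_gene_list(model: MetabolicModel, n_absent: int = 5) -> list[str]:
    """A synthetic hallmark-of-cancer gene list for the toy model.

    Uses every gene of the central-carbon subsystems plus the module catabolic
    genes, and appends ``n_absent`` ids that do not occur in the model — real
    hallmark lists likewise contain genes missing from the reconstruction.
    """
    wanted = {SUB_GLYCOLYSIS, SUB_TCA, SUB_OXPHOS, SUB_PPP} | set(MODULE_SUBSYSTEMS)
    genes: set[str] = set()
    for rxn in model.reactions:
        if rxn.subsystem in wanted:
            genes |= rxn.genes()
    out = sorted(genes)
    out.extend(f"gHALLMARK_ONLY{i}" for i in range(1, n_absent + 1))
    return out


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationDesign:
    """Design of one simulated expression dataset.

    ``planted_subsystems`` maps group label -> {subsystem: fold change}
    (fold > 1 up-regulates the subsystem's genes, < 1 down-regulates).  When
    omitted, a default design is built: ``n_groups`` groups, group i
    up-regulating module subsystem i (fold ``effect_size``) and down-regulating
    the *other groups'* marker modules (fold ``1/effect_size``); modules beyond
    the first ``n_groups`` stay at baseline in every group.  The marker modules
    (those whose fold differs between groups) are the planted discriminative
    ground truth.
    """

    n_groups: int = 4
    n_samples_per_group: int = 5
    n_replicates: int = 2
    platform: str = "rnaseq"
    effect_size: float = 4.0
    noise_sd: float = 0.1
    missing_fraction: float | None = None
    planted_subsystems: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.platform not in PLATFORM_MISSINGNESS:
            raise ValueError(f"unknown platform {self.platform!r}")
        mf = self.resolved_missing_fraction
        if not 0 <= mf < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.planted_subsystems is not None:
            object.__setattr__(
                self,
                "planted_subsystems",
                {g: dict(m) for g, m in self.planted_subsystems.items()},
            )

    @property
    def resolved_missing_fraction(self) -> float:
        if self.missing_fraction is not None:
            return float(self.missing_fraction)
        return PLATFORM_MISSINGNESS[self.platform]

    def resolved_planting(self) -> dict[str, dict[str, float]]:
        if self.planted_subsystems is not None:
            return {g: dict(m) for g, m in self.planted_subsystems.items()}
        if self.n_groups > len(MODULE_SUBSYSTEMS):
            raise ValueError(
                f"default design supports at most {len(MODULE_SUBSYSTEMS)} groups"
            )
        planted: dict[str, dict[str, float]] = {}
        markers = MODULE_SUBSYSTEMS[: self.n_groups]
        for i in range(self.n_groups):
            label = f"group{i + 1}"
            folds = {}
            for j, subsystem in enumerate(markers):
                if self.effect_size == 1.0:
                    continue
                folds[subsystem] = (
                    self.effect_size if j == i else 1.0 / self.effect_size
                )
            planted[label] = folds
        return planted


def _genes_of_subsystem(model: MetabolicModel, subsystem: str) -> frozenset[str]:
    genes: set[str] = set()
    for rxn in model.reactions:
        if rxn.subsystem == subsystem:
            genes |= rxn.genes()
    return frozenset(genes)


def simulate_expression(
    model: MetabolicModel, design: SimulationDesign | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a replicated gene x sample expression matrix.

    Returns ``(matrix, metadata, ground_truth)``: the matrix has one column
    per replicate measurement, the metadata table maps each column to its
    sample, replicate group, platform and group label, and the ground-truth
    record stores the planted design (group labels, planted genes, and the
    reactions of the subsystems that discriminate between groups).
    """
    design = design or SimulationDesign()
    rng = np.random.default_rng(design.seed)
    genes = sorted(model.gene_ids)
    planted = design.resolved_planting()
    missing = design.resolved_missing_fraction

    baseline = pd.Series(rng.lognormal(mean=1.0, sigma=0.6, size=len(genes)), index=genes)
    # module (marker-pathway) genes share a fixed, solidly-expressed baseline,
    # so a planted fold change — not a lucky baseline draw — decides their
    # rank relative to expression thresholds: at baseline they sit above the
    # lower quartile of the core distribution, down-regulated (fold <~ 1/3)
    # they fall below the core floor.  The rest of the gene universe keeps
    # log-normal between-gene heterogeneity above a moderate floor (metabolic
    # housekeeping genes are not silent).
    module_genes: set[str] = set()
    for subsystem in MODULE_SUBSYSTEMS:
        module_genes |= _genes_of_subsystem(model, subsystem)
    is_module = baseline.index.isin(module_genes)
    baseline.loc[is_module] = 4.5
    floor = 1.5
    baseline.loc[~is_module] = baseline.loc[~is_module].clip(lower=floor)
    fold = {
        group: pd.Series(
            {
                gene: float(np.prod([
                    f for subsystem, f in folds.items()
                    if gene in _genes_of_subsystem(model, subsystem)
                ]) or 1.0)
                for gene in genes
            }
        )
        for group, folds in planted.items()
    }

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for group in sorted(planted):
        factor = fold[group].to_numpy()
        for s in range(design.n_samples_per_group):
            sample_id = f"{group}_s{s + 1}"
            jitter = (
                np.exp(rng.normal(0.0, design.noise_sd, size=len(genes)))
                if design.noise_sd > 0
                else 1.0
            )
            sample_mean = baseline.to_numpy() * factor * jitter
            detected = (
                rng.random(len(genes)) >= missing if missing > 0 else
                np.ones(len(genes), dtype=bool)
            )
            for r in range(design.n_replicates):
                col = f"{sample_id}_r{r + 1}"
                noise = (
                    rng.normal(0.0, design.noise_sd, size=len(genes))
                    if design.noise_sd > 0
                    else 0.0
                )
                values = np.clip(sample_mean + noise, 0.0, None)
                values = np.where(detected, values, np.nan)
                columns[col] = values
                meta_rows.append(
                    {
                        "column": col,
                        "sample": sample_id,
                        "platform": design.platform,
                        "group": group,
                    }
                )
    matrix = pd.DataFrame(columns, index=genes)
    metadata = pd.DataFrame(meta_rows)

    # discriminative ground truth: subsystems whose planted fold differs
    # between at least two groups
    all_subsystems = sorted({s for folds in planted.values() for s in folds})
    discriminative = [
        s
        for s in all_subsystems
        if len({folds.get(s, 1.0) for folds in planted.values()}) > 1
    ]
    discriminative_reactions = sorted(
        rxn.reaction_id
        for rxn in model.reactions
        if rxn.subsystem in set(discriminative)
    )
    ground_truth = {
        "model_id": model.model_id,
        "groups": {
            row["sample"]: row["group"] for row in meta_rows
        },
        "planted_subsystems": {g: dict(m) for g, m in planted.items()},
        "planted_genes": {
            g: sorted(
                gene for gene in genes if fold[g].loc[gene] != 1.0
            )
            for g in planted
        },
        "discriminative_subsystems": discriminative,
        "discriminative_reactions": discriminative_reactions,
        "design": {
            "n_groups": design.n_groups,
            "n_samples_per_group": design.n_samples_per_group,
            "n_replicates": design.n_replicates,
            "platform": design.platform,
            "effect_size": design.effect_size,
            "noise_sd": design.noise_sd,
            "missing_fraction": missing,
            "seed": design.seed,
        },
    }
    return matrix, metadata, ground_truth


# ---------------------------------------------------------------------------
# random networks (test oracles)
# ---------------------------------------------------------------------------


def random_network(
    rng: np.random.Generator,
    n_reactions: int = 20,
    n_metabolites: int | None = None,
    reversible_fraction: float = 0.3,
    n_exchanges: int | None = None,
    bound: float = 10.0,
    model_id: str = "random_net",
) -> MetabolicModel:
    """A random stoichiometric network for property and oracle tests.

    Internal reactions connect 1-2 substrates to 1-2 products with unit
    coefficients; a subset of metabolites gets exchange reactions so the
    network can carry steady-state flux.  No GPRs are attached — extraction
    tests supply reaction activities directly.
    """
    if n_metabolites is None:
        n_metabolites = max(3, n_reactions // 2)
    if n_exchanges is None:
        n_exchanges = max(2, n_reactions // 4)
    mets = [f"m{i}" for i in range(n_metabolites)]
    rxns: list[Reaction] = []
    n_internal = n_reactions - n_exchanges
    for j in range(n_internal):
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        chosen = rng.choice(n_metabolites, size=min(n_sub + n_prod, n_metabolites),
                            replace=False)
        subs = chosen[:n_sub]
        prods = chosen[n_sub:]
        stoich = {mets[i]: -1.0 for i in subs}
        stoich.update({mets[i]: 1.0 for i in prods})
        if not stoich:
            continue
        reversible = rng.random() < reversible_fraction
        rxns.append(
            Reaction(
                reaction_id=f"r{j}",
                lower_bound=-bound if reversible else 0.0,
                upper_bound=bound,
                stoichiometry=stoich,
            )
        )
    ex_mets = rng.choice(n_metabolites, size=min(n_exchanges, n_metabolites),
                         replace=False)
    for i, m in enumerate(ex_mets):
        rxns.append(
            Reaction(
                reaction_id=f"EX_{mets[m]}",
                lower_bound=-bound,
                upper_bound=bound,
                stoichiometry={mets[m]: -1.0},
            )
        )
    used = [m for m in mets if any(m in r.stoichiometry for r in rxns)]
    return MetabolicModel(
        model_id=model_id, metabolites=used, reactions=rxns, objective_reaction=None
    )
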