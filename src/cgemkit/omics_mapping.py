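"""Expression preprocessing and GPR-based mapping of genes onto reactions.

Preprocessing follows the usual two steps for heterogeneous expression
compendia: technical replicates are averaged (missing entries ignored), and
each profile is min-max scaled to [0, 1] independently, i.e.
``(value - min) / (max - min)`` within the sample.  Per-sample scaling is used
because every downstream expression threshold in this package is
quantile-based within a profile.

Mapping evaluates the boolean GPR tree of each reaction against the profile:
AND nodes (enzyme complexes) take the minimum and OR nodes (isozymes) the
maximum of their children.  A gene without data is MISSING; MISSING children
are dropped at each node, and a node whose children are all MISSING is itself
MISSING.  A reaction with no GPR, or whose genes are all without data, gets no
value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .model_io import GPRRule, MetabolicModel

__all__ = [
    "ExpressionProfile",
    "ReactionActivity",
    "preprocess",
    "map_expression",
    "evaluate_gpr",
]

PLATFORMS = ("microarray", "rnaseq", "proteome")


@dataclass(frozen=True)
class ExpressionProfile:
    """A normalized expression profile for one sample.

    ``values`` maps gene id -> scalar in [0, 1]; genes without data are simply
    absent from the mapping.
    """

    sample_id: str
    values: Mapping[str, float]
    platform: str = "rnaseq"
    group_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        bad = {g: v for g, v in self.values.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise ValueError(
                f"profile {self.sample_id!r}: values outside [0, 1] for "
                f"{sorted(bad)[:5]}"
            )


@dataclass(frozen=True)
class ReactionActivity:
    """Reaction-level activity for one sample; missing reactions map to None."""

    sample_id: str
    values: Mapping[str, float | None]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    def get(self, reaction_id: str) -> float | None:
        return self.values.get(reaction_id)

    @property
    def missing(self) -> frozenset[str]:
        return frozenset(r for r, v in self.values.items() if v is None)


def preprocess(
    raw: pd.DataFrame,
    replicate_groups: Mapping[str, str] | None = None,
    platforms: Mapping[str, str] | None = None,
    group_labels: Mapping[str, str] | None = None,
) -> list[ExpressionProfile]:
    """Average replicates and min-max normalize each resulting profile.

    Parameters
    ----------
    raw : gene x sample matrix (NaN marks missing measurements).
    replicate_groups : map raw column -> sample id; columns sharing a sample id
        are averaged (NaN ignored).  Defaults to the identity (no replicates).
    platforms, group_labels : optional per-sample metadata, keyed by sample id.

    Samples whose genes are all missing are dropped with a warning; constant
    profiles (max == min) are set to all zeros with a warning.
    """
    if replicate_groups is None:
        replicate_groups = {c: c for c in raw.columns}
    unknown = set(replicate_groups) - set(raw.columns)
    if unknown:
        raise KeyError(f"replicate_groups references unknown columns {sorted(unknown)}")
    averaged = raw.T.groupby(
        raw.columns.map(replicate_groups).astype(str)
    ).mean().T  # NaN-ignoring mean per replicate group

    profiles: list[ExpressionProfile] = []
    for sample_id in averaged.columns:
        col = averaged[sample_id]
        values = col.dropna()
        if values.empty:
            warnings.warn(f"sample {sample_id!r} has no measured genes; dropped")
            continue
        lo, hi = float(values.min()), float(values.max())
        if hi > lo:
            scaled = (values - lo) / (hi - lo)
        else:
            warnings.warn(f"sample {sample_id!r} is constant; normalized to zeros")
            scaled = values * 0.0
        profiles.append(
            ExpressionProfile(
                sample_id=str(sample_id),
                values=scaled.to_dict(),
                platform=(platforms or {}).get(sample_id, "rnaseq"),
                group_label=(group_labels or {}).get(sample_id),
            )
        )
    return profiles


def evaluate_gpr(rule: GPRRule, values: Mapping[str, float]) -> float | None:
    """Recursive GPR evaluation: AND -> min, OR -> max, MISSING propagated.

    Children without data are ignored at each node; a node with no informative
    child is MISSING (None).
    """
    if rule.op == "gene":
        return values.get(rule.gene)
    child_values = [
        v for v in (evaluate_gpr(c, values) for c in rule.children) if v is not None
    ]
    if not child_values:
        return None
    return min(child_values) if rule.op == "and" else max(child_values)


def map_expression(model: MetabolicModel, profile: ExpressionProfile) -> ReactionActivity:
    """Map a normalized expression profile onto the model's reactions."""
    out: dict[str, float | None] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            out[rxn.reaction_id] = None
        else:
            out[rxn.reaction_id] = evaluate_gpr(rxn.gpr, profile.values)
    return ReactionActivity(sample_id=profile.sample_id, values=out)


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a gene x sample TSV (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns
    ``column, sample, platform, group`` (one row per raw expression column)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"column", "sample", "platform", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file missing columns {sorted(missing)}")
    return meta
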