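"""Pairwise metabolic-pattern similarity: subsystem Jaccard and Bland-Altman.

Two context-specific models are compared on two levels:

* *which* reactions remain — the Jaccard index of the kept sets, computed per
  subsystem and averaged over the subsystems present in either model, so that
  large subsystems do not dominate;
* *how much* flux the shared network carries — a Bland-Altman analysis of the
  two FBA flux vectors, with limits of agreement mean(d) +/- 1.96 sd(d) and a
  two-sided one-sample location test of the differences against zero.

Flux vectors are aligned over the union of reactions, imputing zero flux for
reactions absent from a model (they carry no flux by construction); an
intersection-only alignment is available via ``alignment="intersection"``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import ExtractionResult
from .flux_core import FluxState
from .model_io import MetabolicModel

__all__ = [
    "JaccardReport",
    "BlandAltmanResult",
    "jaccard_subsystem",
    "bland_altman",
    "disagreement_matrix",
]

LOA_FACTOR = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class JaccardReport:
    pair: tuple[str, str]
    per_subsystem: Mapping[str, float]
    mean_index: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_subsystem", dict(self.per_subsystem))


@dataclass(frozen=True)
class BlandAltmanResult:
    pair: tuple[str, str]
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    p_value: float
    mode: str
    n_pairs: int
    n_dropped: int = 0


def jaccard_subsystem(
    a: ExtractionResult, b: ExtractionResult, model: MetabolicModel
) -> JaccardReport:
    """Subsystem-averaged Jaccard index of two kept-reaction sets.

    For each subsystem s, J_s = |A∩s ∩ B∩s| / |A∩s ∪ B∩s|; subsystems with no
    kept reaction in either model are skipped; the report's mean is the
    arithmetic mean of the remaining J_s.
    """
    if a.parent_model_id != model.model_id or b.parent_model_id != model.model_id:
        raise ValueError(
            "both extraction results must derive from the given parent model "
            f"({a.parent_model_id!r}, {b.parent_model_id!r} vs {model.model_id!r})"
        )
    kept_a, kept_b = set(a.kept_reactions), set(b.kept_reactions)
    per: dict[str, float] = {}
    for subsystem, rxns in sorted(model.subsystems().items()):
        members = set(rxns)
        sa, sb = kept_a & members, kept_b & members
        union = sa | sb
        if not union:
            continue
        per[subsystem] = len(sa & sb) / len(union)
    mean = float(np.mean(list(per.values()))) if per else math.nan
    return JaccardReport(pair=(a.sample_id, b.sample_id), per_subsystem=per, mean_index=mean)


def _aligned_fluxes(
    flux_a: FluxState, flux_b: FluxState, alignment: str
) -> tuple[np.ndarray, np.ndarray]:
    da, db = flux_a.as_dict(), flux_b.as_dict()
    if alignment == "union":
        keys = sorted(set(da) | set(db))
        a = np.array([da.get(k, 0.0) for k in keys])
        b = np.array([db.get(k, 0.0) for k in keys])
    elif alignment == "intersection":
        keys = sorted(set(da) & set(db))
        a = np.array([da[k] for k in keys])
        b = np.array([db[k] for k in keys])
    else:
        raise ValueError("alignment must be 'union' or 'intersection'")
    return a, b


def bland_altman(
    flux_a: FluxState,
    flux_b: FluxState,
    mode: str = "raw",
    alignment: str = "union",
    test: str = "ttest",
) -> BlandAltmanResult:
    """Bland-Altman agreement of two flux states.

    ``mode="raw"`` uses differences a - b; ``mode="percent"`` uses
    100 * (a - b) / mean(a, b) with zero-mean pairs dropped.  The p-value is a
    two-sided one-sample test (t-test by default, ``test="wilcoxon"`` for a
    signed-rank alternative) of the differences against zero.
    """
    a, b = _aligned_fluxes(flux_a, flux_b, alignment)
    d = a - b
    dropped = 0
    if mode == "percent":
        m = (a + b) / 2.0
        keep = m != 0.0
        dropped = int((~keep).sum())
        d = 100.0 * d[keep] / m[keep]
    elif mode != "raw":
        raise ValueError("mode must be 'raw' or 'percent'")
    n = d.size
    if n < 3:
        raise ValueError(f"need at least 3 usable flux pairs, got {n}")
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    if sd_d == 0.0:
        p = 1.0 if mean_d == 0.0 else 0.0
    elif test == "ttest":
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    elif test == "wilcoxon":
        p = float(stats.wilcoxon(d, zero_method="wilcox").pvalue) if np.any(d != 0) else 1.0
    else:
        raise ValueError("test must be 'ttest' or 'wilcoxon'")
    return BlandAltmanResult(
        pair=(flux_a.model_id, flux_b.model_id),
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_low=mean_d - LOA_FACTOR * sd_d,
        loa_high=mean_d + LOA_FACTOR * sd_d,
        p_value=p,
        mode=mode,
        n_pairs=int(n),
        n_dropped=dropped,
    )


def disagreement_matrix(
    flux_states: Sequence[FluxState],
    alpha: float = 0.05,
    mode: str = "raw",
    alignment: str = "union",
    test: str = "ttest",
) -> tuple[float, pd.DataFrame]:
    """Fraction of CGEM pairs whose flux states disagree (p < alpha).

    Returns the percentage of significantly disagreeing unordered pairs and
    the full pairwise table; pairs whose comparison fails (too few usable
    fluxes) are skipped and marked in the table.
    """
    if len(flux_states) < 2:
        raise ValueError("need at least two flux states")
    records = []
    significant = 0
    tested = 0
    for fa, fb in itertools.combinations(flux_states, 2):
        row = {"a": fa.model_id, "b": fb.model_id}
        try:
            res = bland_altman(fa, fb, mode=mode, alignment=alignment, test=test)
        except ValueError as exc:
            row.update({"p_value": math.nan, "error": str(exc)})
            records.append(row)
            continue
        tested += 1
        significant += int(res.p_value < alpha)
        row.update(
            {
                "p_value": res.p_value,
                "mean_difference": res.mean_difference,
                "sd_difference": res.sd_difference,
                "loa_low": res.loa_low,
                "loa_high": res.loa_high,
                "error": "",
            }
        )
        records.append(row)
    table = pd.DataFrame.from_records(records)
    if tested == 0:
        raise ValueError("no testable pair of flux states")
    return 100.0 * significant / tested, table
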