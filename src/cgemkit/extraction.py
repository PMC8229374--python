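"""Context-specific model extraction: GIMME, iMAT, INIT and FASTCORE.

Each algorithm consumes a flux-consistent parent model and a per-sample
:class:`~cgemkit.omics_mapping.ReactionActivity`, and produces an
:class:`ExtractionResult` — the set of reactions kept in the context-specific
submodel ("active reactions") plus the induced submodel itself.

Common post-processing (:func:`_finalize`): protected reactions, together
with a minimal flux support that keeps them operational, are always added to
the kept set, and the induced submodel is re-checked with FASTCC so that FBA
on every context model is well-posed.

Expression thresholds are quantiles of the non-missing mapped activities of
the profile at hand; reactions without a mapped value are never penalized and
never rewarded (they are kept or dropped according to flux support alone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .flux_core import (
    DEFAULT_SOLVER,
    InfeasibleModelError,
    SolverConfig,
    fastcc,
    fba,
    fva,
    solve_lp,
)
from .model_io import MetabolicModel

__all__ = [
    "ExtractionConfig",
    "ExtractionResult",
    "ExtractionError",
    "CoreInconsistentError",
    "gimme",
    "imat",
    "init_extract",
    "fastcore",
    "core_from_activity",
    "extract",
    "ALGORITHMS",
]

ALGORITHMS = ("gimme", "imat", "init", "fastcore")


class ExtractionError(RuntimeError):
    pass


class CoreInconsistentError(ExtractionError):
    """A core reaction cannot carry flux in the (supposedly consistent) model."""


@dataclass(frozen=True)
class ExtractionConfig:
    """Parameters shared by the extraction algorithms.

    ``expression_threshold`` (GIMME/INIT/FASTCORE) and the iMAT
    ``high_quantile``/``low_quantile`` are quantiles in (0, 1) of the
    non-missing mapped activity values of the sample being integrated.
    ``epsilon_active`` is the flux threshold that defines an active reaction;
    ``biomass_fraction`` is the GIMME lower bound on the objective as a
    fraction of its unconstrained optimum.
    """

    algorithm: str = "gimme"
    expression_threshold: float = 0.25
    high_quantile: float = 0.75
    low_quantile: float = 0.25
    core_quantile: float = 0.75
    epsilon_active: float = 1e-4
    biomass_fraction: float = 0.9
    protected: frozenset[str] = frozenset()
    accumulating_metabolites: frozenset[str] = frozenset()
    accumulation_max: float = 1.0
    milp_time_limit: float = 60.0
    solver: SolverConfig = DEFAULT_SOLVER

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.low_quantile < self.high_quantile:
            raise ValueError("low_quantile must be below high_quantile")
        if not 0 < self.biomass_fraction <= 1:
            raise ValueError("biomass_fraction must lie in (0, 1]")
        object.__setattr__(
            self,
            "epsilon_active",
            max(float(self.epsilon_active), self.solver.epsilon_floor),
        )

    def summary(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "expression_threshold": self.expression_threshold,
            "high_quantile": self.high_quantile,
            "low_quantile": self.low_quantile,
            "core_quantile": self.core_quantile,
            "epsilon_active": self.epsilon_active,
            "biomass_fraction": self.biomass_fraction,
            "protected": sorted(self.protected),
        }


@dataclass(frozen=True)
class ExtractionResult:
    """A context-specific submodel for one sample and one algorithm."""

    sample_id: str
    algorithm: str
    kept_reactions: frozenset[str]
    context_model: MetabolicModel
    parent_model_id: str
    parent_genes: frozenset[str]
    diagnostics: dict = field(default_factory=dict)

    @property
    def kept_genes(self) -> frozenset[str]:
        genes: set[str] = set()
        for rxn in self.context_model.reactions:
            genes |= rxn.genes()
        return frozenset(genes)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _activity_array(model: MetabolicModel, activity) -> np.ndarray:
    vals = np.full(len(model.reactions), np.nan)
    amap = activity.values
    for j, rxn in enumerate(model.reactions):
        v = amap.get(rxn.reaction_id)
        if v is not None:
            vals[j] = float(v)
    return vals


def _quantile_threshold(a: np.ndarray, q: float) -> float | None:
    finite = a[np.isfinite(a)]
    if finite.size == 0:
        return None
    return float(np.quantile(finite, q))


def _above(a: np.ndarray, threshold: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.greater_equal(np.nan_to_num(a, nan=-np.inf), threshold)


def _protected_support(
    model: MetabolicModel, protected: frozenset[str], cfg: ExtractionConfig
) -> set[str]:
    """Reactions carrying flux in an L1-minimal distribution that activates
    every protected reaction (in its attainable direction) simultaneously."""
    if not protected:
        return set()
    eps = cfg.epsilon_active
    delta_target = max(eps * 10, 1e-2)
    ranges = fva(model, reactions=sorted(protected), cfg=cfg.solver)
    S = model.stoichiometry
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    lo = lb.copy()
    hi = ub.copy()
    for rid, (vmin, vmax) in ranges.items():
        j = model.reaction_index(rid)
        if vmax >= eps:
            lo[j] = max(lo[j], min(delta_target, 0.5 * vmax))
        elif vmin <= -eps:
            hi[j] = min(hi[j], max(-delta_target, 0.5 * vmin))
        else:
            raise ExtractionError(
                f"protected reaction {rid!r} cannot carry flux >= "
                f"{eps:g} in model {model.model_id!r}"
            )
    # min sum |v| with the tightened bounds
    S2 = sparse.hstack([S, -S], format="csr")
    eye = sparse.identity(n, format="csr")
    split = sparse.hstack([eye, -eye], format="csr")
    A_ub = sparse.vstack([split, -split], format="csr")
    b_ub = np.concatenate([hi, -lo])
    res = solve_lp(
        np.ones(2 * n),
        S2,
        np.zeros(S.shape[0]),
        [(0.0, None)] * (2 * n),
        A_ub=A_ub,
        b_ub=b_ub,
        cfg=cfg.solver,
    )
    if res.status != 0:
        raise ExtractionError(
            f"no flux distribution activates all protected reactions of "
            f"{model.model_id!r} simultaneously"
        )
    v = res.x[:n] - res.x[n:]
    ids = model.reaction_ids
    return {ids[j] for j in np.flatnonzero(np.abs(v) > 1e-9)}


def _finalize(
    model: MetabolicModel,
    kept_raw: set[str],
    cfg: ExtractionConfig,
    sample_id: str,
    algorithm: str,
    diagnostics: dict,
    add_protected_support: bool = True,
) -> ExtractionResult:
    kept = set(kept_raw) | set(cfg.protected)
    if add_protected_support and cfg.protected:
        kept |= _protected_support(model, cfg.protected, cfg)
    sub = model.submodel(kept, model_id=f"{model.model_id}:{sample_id}:{algorithm}")
    consistency = fastcc(sub, epsilon=cfg.epsilon_active, cfg=cfg.solver)
    context = sub.submodel(
        consistency.consistent_reactions, model_id=sub.model_id
    )
    lost = set(cfg.protected) - consistency.consistent_reactions
    if lost:
        raise ExtractionError(
            f"{algorithm} on {sample_id!r}: protected reactions lost during "
            f"consistency pruning: {sorted(lost)}"
        )
    if model.objective_reaction in consistency.consistent_reactions:
        context.objective_reaction = model.objective_reaction
    diagnostics = dict(diagnostics)
    diagnostics["config"] = cfg.summary()
    diagnostics["n_kept_raw"] = len(kept)
    diagnostics["n_pruned_inconsistent"] = len(kept) - len(
        consistency.consistent_reactions
    )
    return ExtractionResult(
        sample_id=sample_id,
        algorithm=algorithm,
        kept_reactions=frozenset(context.reaction_ids),
        context_model=context,
        parent_model_id=model.model_id,
        parent_genes=model.gene_ids,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# GIMME
# ---------------------------------------------------------------------------


def gimme(
    model: MetabolicModel, activity, cfg: ExtractionConfig | None = None
) -> ExtractionResult:
    """GIMME: minimize flux through below-threshold reactions while holding the
    objective at a fraction of its optimum.

    Stage 1 finds the biomass optimum z*; stage 2 minimizes
    ``sum_r w_r |v_r|`` over penalized reactions (``w_r = threshold -
    activity_r`` for mapped activities below the threshold, 0 otherwise)
    subject to ``objective >= biomass_fraction * z*``.  Kept reactions are the
    expressed ones, the flux carriers of the stage-2 solution, and the
    protected set.
    """
    cfg = cfg or ExtractionConfig(algorithm="gimme")
    a = _activity_array(model, activity)
    t = _quantile_threshold(a, cfg.expression_threshold)
    diagnostics: dict = {"threshold": t}

    state1 = fba(model, cfg=cfg.solver, parsimonious=False)
    if not state1.optimal:
        raise InfeasibleModelError(
            f"GIMME stage 1 on {model.model_id!r}: FBA status {state1.status}"
        )
    z_star = state1.objective_value
    diagnostics["z_star"] = z_star

    if t is None:  # no expression data at all: nothing can be penalized
        return _finalize(
            model, set(model.reaction_ids), cfg, activity.sample_id, "gimme",
            diagnostics,
        )

    with np.errstate(invalid="ignore"):
        w = np.where(np.isfinite(a) & (a < t), t - a, 0.0)
    S = model.stoichiometry
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    c_obj = np.zeros(n)
    c_obj[model.reaction_index(state1.objective_reaction)] = 1.0
    S2 = sparse.hstack([S, -S], format="csr")
    eye = sparse.identity(n, format="csr")
    split = sparse.hstack([eye, -eye], format="csr")
    cv = np.concatenate([c_obj, -c_obj])
    A_ub = sparse.vstack([split, -split, -sparse.csr_matrix(cv)], format="csr")
    b_ub = np.concatenate([ub, -lb, [-cfg.biomass_fraction * z_star]])
    res = solve_lp(
        np.concatenate([w, w]),
        S2,
        np.zeros(S.shape[0]),
        [(0.0, None)] * (2 * n),
        A_ub=A_ub,
        b_ub=b_ub,
        cfg=cfg.solver,
    )
    if res.status != 0:
        raise InfeasibleModelError(
            f"GIMME stage 2 on {model.model_id!r} failed (status {res.status})"
        )
    v = res.x[:n] - res.x[n:]
    diagnostics["inconsistency"] = float(res.fun)
    expressed = _above(a, t)
    active = np.abs(v) >= cfg.epsilon_active * (1 - 1e-9)
    unmapped = ~np.isfinite(a)
    # only reactions classified inactive by the data and idle in the stage-2
    # solution are removed; unmapped reactions are never removal candidates
    # (which stage-2 optimum the solver returns is degenerate in their fluxes)
    kept_mask = expressed | active | unmapped
    ids = model.reaction_ids
    kept = {ids[j] for j in np.flatnonzero(kept_mask)}
    return _finalize(model, kept, cfg, activity.sample_id, "gimme", diagnostics)


# ---------------------------------------------------------------------------
# iMAT
# ---------------------------------------------------------------------------


def imat(
    model: MetabolicModel, activity, cfg: ExtractionConfig | None = None
) -> ExtractionResult:
    """iMAT: split reactions into highly and poorly expressed sets and find the
    flux distribution maximizing agreement with the classification.

    Each high reaction contributes a binary rewarding ``|v_r| >= epsilon``
    (one indicator per direction, at most one active); each low reaction a
    binary rewarding ``v_r = 0``.  Unclassified reactions are retained.
    """
    cfg = cfg or ExtractionConfig(algorithm="imat")
    a = _activity_array(model, activity)
    th_high = _quantile_threshold(a, cfg.high_quantile)
    th_low = _quantile_threshold(a, cfg.low_quantile)
    eps = cfg.epsilon_active
    n = len(model.reactions)
    ids = model.reaction_ids
    if th_high is None:
        high_idx = np.array([], dtype=int)
        low_idx = np.array([], dtype=int)
    else:
        high_mask = _above(a, th_high)
        with np.errstate(invalid="ignore"):
            low_mask = np.isfinite(a) & (a <= th_low) & ~high_mask
        high_idx = np.flatnonzero(high_mask)
        low_idx = np.flatnonzero(low_mask)
    diagnostics: dict = {
        "n_high": int(len(high_idx)),
        "n_low": int(len(low_idx)),
        "threshold_high": th_high,
        "threshold_low": th_low,
    }

    S = model.stoichiometry
    lb, ub = model.bounds_arrays()
    h, l = len(high_idx), len(low_idx)
    nvar = n + 2 * h + l
    if h + l == 0:
        kept = set(ids)
        diagnostics["agreement"] = 0
        diagnostics["optimal"] = True
        return _finalize(model, kept, cfg, activity.sample_id, "imat", diagnostics)

    rows, cols, data, con_lb, con_ub = [], [], [], [], []
    row = 0

    def add_row(entries: list[tuple[int, float]], lo: float, hi: float) -> None:
        nonlocal row
        for col, val in entries:
            rows.append(row)
            cols.append(col)
            data.append(val)
        con_lb.append(lo)
        con_ub.append(hi)
        row += 1

    Scoo = S.tocoo()
    steady_rows = S.shape[0]
    for i, j, val in zip(Scoo.row, Scoo.col, Scoo.data):
        rows.append(i)
        cols.append(j)
        data.append(val)
    con_lb.extend([0.0] * steady_rows)
    con_ub.extend([0.0] * steady_rows)
    row = steady_rows

    for i, j in enumerate(high_idx):
        yf = n + i
        yb = n + h + i
        # yf = 1  =>  v_j >= eps
        add_row([(j, 1.0), (yf, lb[j] - eps)], lb[j], np.inf)
        # yb = 1  =>  v_j <= -eps
        add_row([(j, 1.0), (yb, ub[j] + eps)], -np.inf, ub[j])
        add_row([(yf, 1.0), (yb, 1.0)], 0.0, 1.0)
    for i, j in enumerate(low_idx):
        y0 = n + 2 * h + i
        # y0 = 1  =>  v_j = 0
        add_row([(j, 1.0), (y0, ub[j])], -np.inf, ub[j])
        add_row([(j, 1.0), (y0, lb[j])], lb[j], np.inf)

    A = sparse.csc_matrix((data, (rows, cols)), shape=(row, nvar))
    c = np.zeros(nvar)
    c[n:] = -1.0
    var_lb = np.concatenate([lb, np.zeros(2 * h + l)])
    var_ub = np.concatenate([ub, np.ones(2 * h + l)])
    integrality = np.concatenate([np.zeros(n), np.ones(2 * h + l)])
    res = milp(
        c,
        constraints=LinearConstraint(A, np.array(con_lb), np.array(con_ub)),
        bounds=Bounds(var_lb, var_ub),
        integrality=integrality,
        options={"time_limit": cfg.milp_time_limit},
    )
    if res.x is None:
        raise InfeasibleModelError(
            f"iMAT MILP on {model.model_id!r} returned no solution "
            f"(status {res.status})"
        )
    v = res.x[:n]
    diagnostics["agreement"] = int(round(-res.fun))
    diagnostics["optimal"] = bool(res.status == 0)
    classified = set(high_idx) | set(low_idx)
    active = np.abs(v) >= eps * (1 - 1e-6)
    kept = {ids[j] for j in range(n) if j not in classified or active[j]}
    return _finalize(model, kept, cfg, activity.sample_id, "imat", diagnostics)


# ---------------------------------------------------------------------------
# INIT
# ---------------------------------------------------------------------------


def init_extract(
    model: MetabolicModel, activity, cfg: ExtractionConfig | None = None
) -> ExtractionResult:
    """INIT: maximize the total evidence weight of active reactions.

    Weight ``w_r = activity_r - threshold`` (positive evidence for expressed
    reactions, negative for unexpressed, zero/absent for unmapped); binary
    ``y_r`` indicates that reaction r carries ``|v_r| >= epsilon``.  The
    steady-state condition can be relaxed to a small net accumulation
    ``0 <= b_m <= accumulation_max`` for metabolites listed in
    ``cfg.accumulating_metabolites``.
    """
    cfg = cfg or ExtractionConfig(algorithm="init")
    a = _activity_array(model, activity)
    t = _quantile_threshold(a, cfg.expression_threshold)
    eps = cfg.epsilon_active
    n = len(model.reactions)
    ids = model.reaction_ids
    with np.errstate(invalid="ignore"):
        w = np.where(np.isfinite(a), a - (t if t is not None else 0.0), 0.0)
    weighted = np.flatnonzero(w != 0.0)
    diagnostics: dict = {"threshold": t, "n_weighted": int(len(weighted))}
    if len(weighted) == 0:
        diagnostics["total_weight"] = 0.0
        return _finalize(model, set(), cfg, activity.sample_id, "init", diagnostics)

    S = model.stoichiometry
    lb, ub = model.bounds_arrays()
    acc_idx = [
        i for i, m in enumerate(model.metabolites)
        if m in cfg.accumulating_metabolites
    ]
    nw = len(weighted)
    rev = [j for j in weighted if lb[j] < 0 < ub[j]]
    rev_pos = {j: k for k, j in enumerate(rev)}
    nvar = n + len(acc_idx) + nw + len(rev)
    y_of = {j: n + len(acc_idx) + i for i, j in enumerate(weighted)}
    s_of = {j: n + len(acc_idx) + nw + rev_pos[j] for j in rev}

    rows, cols, data, con_lb, con_ub = [], [], [], [], []
    row = 0

    def add_row(entries: list[tuple[int, float]], lo: float, hi: float) -> None:
        nonlocal row
        for col, val in entries:
            rows.append(row)
            cols.append(col)
            data.append(val)
        con_lb.append(lo)
        con_ub.append(hi)
        row += 1

    Scoo = S.tocoo()
    for i, j, val in zip(Scoo.row, Scoo.col, Scoo.data):
        rows.append(i)
        cols.append(j)
        data.append(val)
    for k, i in enumerate(acc_idx):  # S_m v - b_m = 0 for accumulating m
        rows.append(i)
        cols.append(n + k)
        data.append(-1.0)
    con_lb.extend([0.0] * S.shape[0])
    con_ub.extend([0.0] * S.shape[0])
    row = S.shape[0]

    for j in weighted:
        y = y_of[j]
        # y = 0  =>  v = 0
        add_row([(j, 1.0), (y, -ub[j])], -np.inf, 0.0)
        add_row([(j, 1.0), (y, -lb[j])], 0.0, np.inf)
        if lb[j] >= 0:
            add_row([(j, 1.0), (y, -eps)], 0.0, np.inf)  # y=1 => v >= eps
        elif ub[j] <= 0:
            add_row([(j, 1.0), (y, eps)], -np.inf, 0.0)  # y=1 => v <= -eps
        else:
            s = s_of[j]
            # y=1, s=0 => v >= eps ; y=1, s=1 => v <= -eps
            add_row([(j, 1.0), (y, -eps), (s, -(lb[j] - eps))], 0.0, np.inf)
            add_row([(j, 1.0), (s, eps + ub[j]), (y, ub[j])], -np.inf, 2 * ub[j])

    A = sparse.csc_matrix((data, (rows, cols)), shape=(row, nvar))
    c = np.zeros(nvar)
    for j in weighted:
        c[y_of[j]] = -w[j]
    var_lb = np.concatenate(
        [lb, np.zeros(len(acc_idx)), np.zeros(nw + len(rev))]
    )
    var_ub = np.concatenate(
        [ub, np.full(len(acc_idx), cfg.accumulation_max), np.ones(nw + len(rev))]
    )
    integrality = np.concatenate(
        [np.zeros(n + len(acc_idx)), np.ones(nw + len(rev))]
    )
    res = milp(
        c,
        constraints=LinearConstraint(A, np.array(con_lb), np.array(con_ub)),
        bounds=Bounds(var_lb, var_ub),
        integrality=integrality,
        options={"time_limit": cfg.milp_time_limit},
    )
    if res.x is None:
        raise InfeasibleModelError(
            f"INIT MILP on {model.model_id!r} returned no solution "
            f"(status {res.status})"
        )
    v = res.x[:n]
    diagnostics["total_weight"] = float(-res.fun)
    diagnostics["optimal"] = bool(res.status == 0)
    active = np.abs(v) >= eps * (1 - 1e-6)
    kept: set[str] = set()
    weighted_set = set(weighted)
    for j in range(n):
        if j in weighted_set:
            if res.x[y_of[j]] >= 0.5:
                kept.add(ids[j])
        elif active[j]:
            kept.add(ids[j])
    return _finalize(model, kept, cfg, activity.sample_id, "init", diagnostics)


# ---------------------------------------------------------------------------
# FASTCORE
# ---------------------------------------------------------------------------


def _lp7_current(S, lb, ub, targets: np.ndarray, eps: float, cfg: SolverConfig):
    n = S.shape[1]
    k = len(targets)
    A_eq = sparse.hstack([S, sparse.csr_matrix((S.shape[0], k))], format="csr")
    sel = sparse.csr_matrix((np.ones(k), (np.arange(k), targets)), shape=(k, n))
    A_ub = sparse.hstack([-sel, sparse.identity(k, format="csr")], format="csr")
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    bounds = list(zip(lb, ub)) + [(0.0, eps)] * k
    res = solve_lp(
        c, A_eq, np.zeros(S.shape[0]), bounds, A_ub=A_ub, b_ub=np.zeros(k), cfg=cfg
    )
    return res.x[:n] if res.status == 0 else None


def _lp10_current(
    S, lb, ub, K: np.ndarray, P: np.ndarray, eps: float, cfg: SolverConfig
) -> np.ndarray | None:
    """min sum_{r in P} |v_r| subject to v_K forced well above epsilon.

    The forcing level is scaled up (bounded by the reactions' own upper
    bounds) so that the sparse mode's support reactions themselves carry flux
    comfortably above epsilon; if the scaled LP is infeasible the plain
    epsilon forcing is used.
    """
    n = S.shape[1]
    for scale in (1e3, 1.0):
        lo = lb.copy()
        for j in K:
            lo[j] = max(lo[j], min(eps * scale, 0.99 * ub[j], 1.0) if scale > 1 else eps)
            lo[j] = min(lo[j], ub[j])
        S2 = sparse.hstack([S, -S], format="csr")
        eye = sparse.identity(n, format="csr")
        split = sparse.hstack([eye, -eye], format="csr")
        A_ub = sparse.vstack([split, -split], format="csr")
        b_ub = np.concatenate([ub, -lo])
        c = np.zeros(2 * n)
        for j in P:
            c[j] = 1.0
            c[n + j] = 1.0
        res = solve_lp(
            c,
            S2,
            np.zeros(S.shape[0]),
            [(0.0, None)] * (2 * n),
            A_ub=A_ub,
            b_ub=b_ub,
            cfg=cfg,
        )
        if res.status == 0:
            return res.x[:n] - res.x[n:]
    return None


def fastcore(
    model: MetabolicModel,
    core: Iterable[str],
    cfg: ExtractionConfig | None = None,
    sample_id: str = "core",
) -> ExtractionResult:
    """FASTCORE: a compact flux-consistent submodel containing the core set.

    Iterates sparse-mode searches (LP-7 support maximization followed by an
    L1-sparsity LP over non-core reactions), flipping the orientation of
    reversible core reactions that could not be activated forward.  The
    result contains ``core`` and the protected set and is flux-consistent;
    its size is small but not guaranteed minimal.
    """
    cfg = cfg or ExtractionConfig(algorithm="fastcore")
    eps = cfg.epsilon_active
    core_ids = set(core) | set(cfg.protected)
    unknown = core_ids - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"core reactions not in model: {sorted(unknown)}")
    n = len(model.reactions)
    ids = model.reaction_ids
    index = {rid: j for j, rid in enumerate(ids)}
    C = {index[rid] for rid in core_ids}
    if not C:
        return _finalize(
            model, set(), cfg, sample_id, "fastcore", {"core_size": 0},
            add_protected_support=False,
        )

    S = sparse.lil_matrix(model.stoichiometry)
    lb, ub = model.bounds_arrays()
    lb0 = lb.copy()
    irreversible = {j for j in range(n) if lb0[j] >= 0 or ub[j] <= 0}

    def flip(j: int) -> None:
        S[:, j] = -S[:, j]
        lb[j], ub[j] = -ub[j], -lb[j]

    # orient backward-only reactions forward once so LP-7 can see them
    for j in range(n):
        if ub[j] <= 0 and lb[j] < 0:
            flip(j)

    def find_sparse_mode(Ji: set[int], P: set[int], singleton: bool) -> set[int]:
        if not Ji:
            return set()
        targets = np.array([min(Ji)] if singleton else sorted(Ji))
        Scsr = S.tocsr()
        v = _lp7_current(Scsr, lb, ub, targets, eps, cfg.solver)
        if v is None:
            return set()
        K = targets[v[targets] >= 0.99 * eps]
        if len(K) == 0:
            return set()
        v = _lp10_current(Scsr, lb, ub, K, np.array(sorted(P)), eps, cfg.solver)
        if v is None:
            return set()
        return set(np.flatnonzero(np.abs(v) >= 0.99 * eps))

    J = C & irreversible
    P = set(range(n)) - C
    A = find_sparse_mode(J, P, singleton=False)
    if J - A:
        bad = sorted(ids[j] for j in (J - A))
        raise CoreInconsistentError(
            f"irreversible core reactions cannot carry flux: {bad}"
        )
    J = C - A
    flipped = False
    singleton = False
    while J:
        P = P - A
        Ji = {min(J)} if singleton else set(J)
        A |= find_sparse_mode(Ji, P, singleton)
        if J & A:
            J -= A
            flipped = False
        else:
            Ji_rev = Ji - irreversible
            if flipped or not Ji_rev:
                if singleton:
                    raise CoreInconsistentError(
                        f"core reaction {ids[min(J)]!r} cannot carry flux"
                    )
                flipped = False
                singleton = True
            else:
                for j in Ji_rev:
                    flip(j)
                flipped = True

    kept = {ids[j] for j in A}
    core_id_set = {ids[j] for j in C}
    kept = _compact_support(model, kept, core_id_set, eps, cfg.solver)
    diagnostics = {"core_size": len(C), "support_size": len(A),
                   "compacted_size": len(kept)}
    return _finalize(
        model, kept, cfg, sample_id, "fastcore", diagnostics,
        add_protected_support=False,
    )


def _compact_support(
    model: MetabolicModel,
    kept: set[str],
    core: set[str],
    eps: float,
    solver: SolverConfig,
) -> set[str]:
    """Greedy compaction of a FASTCORE support set.

    The union of sparse modes accumulated by the main loop can carry a few
    redundant support reactions; each non-core reaction is tentatively
    removed (deterministic order) and the removal is committed whenever the
    remaining submodel stays flux-consistent on the whole core.
    """
    for rid in sorted(kept - core, reverse=True):
        if rid not in kept:
            continue  # already dropped by a cascading consistency check
        candidate = kept - {rid}
        consistent = fastcc(
            model.submodel(candidate, model_id="compact"), epsilon=eps, cfg=solver
        ).consistent_reactions
        if core <= consistent:
            kept = set(consistent)
    return kept


def core_from_activity(
    model: MetabolicModel, activity, cfg: ExtractionConfig
) -> set[str]:
    """Core set for FASTCORE: reactions whose mapped activity reaches the core
    quantile.

    FASTCORE expects its core to contain only confidently active reactions;
    the default core quantile therefore coincides with iMAT's highly-expressed
    set rather than with the (much looser) GIMME/INIT expression threshold.
    """
    a = _activity_array(model, activity)
    t = _quantile_threshold(a, cfg.core_quantile)
    if t is None:
        return set()
    ids = model.reaction_ids
    return {ids[j] for j in np.flatnonzero(_above(a, t))}


def extract(
    model: MetabolicModel, activity, cfg: ExtractionConfig
) -> ExtractionResult:
    """Dispatch to the configured algorithm."""
    if cfg.algorithm == "gimme":
        return gimme(model, activity, cfg)
    if cfg.algorithm == "imat":
        return imat(model, activity, cfg)
    if cfg.algorithm == "init":
        return init_extract(model, activity, cfg)
    if cfg.algorithm == "fastcore":
        core = core_from_activity(model, activity, cfg)
        return fastcore(model, core, cfg, sample_id=activity.sample_id)
    raise ValueError(f"unknown algorithm {cfg.algorithm!r}")
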