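"""Linear-programming core: FBA, FVA, and FASTCC flux-consistency reduction.

All LPs are solved through one backend wrapper (:func:`solve_lp`) built on
scipy's HiGHS interface, so tolerances and solver options live in a single
:class:`SolverConfig`.

FBA here is deterministic by construction: after the objective optimum is
found, the flux vector is refined by a secondary minimization of the total
absolute flux at the (numerically) fixed optimum — a pFBA-style tie-break.
Plain FBA returns an arbitrary optimal vertex that depends on solver
internals; downstream statistics consume whole flux vectors, so the
degeneracy has to be resolved explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_io import MetabolicModel

__all__ = [
    "SolverConfig",
    "FluxState",
    "ConsistencyResult",
    "InfeasibleModelError",
    "fba",
    "fva",
    "fastcc",
    "consistent_submodel",
]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration shared by every LP/MILP in the package.

    ``feasibility_tol`` is requested from the solver; ``assert_tol`` is what
    returned solutions are *checked* against (steady state and bounds).
    ``epsilon`` is the flux-activity threshold used by FASTCC and the
    extraction algorithms; requests below ``epsilon_floor`` are clamped with a
    warning because they are meaningless at LP feasibility tolerance.
    """

    feasibility_tol: float = 1e-9
    assert_tol: float = 1e-6
    epsilon: float = 1e-4
    epsilon_floor: float = 1e-6
    time_limit: float = 120.0

    def clamp_epsilon(self, epsilon: float | None) -> float:
        eps = self.epsilon if epsilon is None else float(epsilon)
        if eps <= 0:
            raise ValueError("epsilon must be positive")
        if eps < self.epsilon_floor:
            warnings.warn(
                f"epsilon {eps:g} is below the solver feasibility floor; "
                f"clamping to {self.epsilon_floor:g}",
                stacklevel=3,
            )
            eps = self.epsilon_floor
        return eps


DEFAULT_SOLVER = SolverConfig()


class InfeasibleModelError(RuntimeError):
    """Raised when an operation requires a feasible/optimal LP but got none."""


@dataclass(frozen=True)
class FluxState:
    """A steady-state flux distribution with its objective value.

    ``status`` is ``"optimal"``, ``"infeasible"`` or ``"unbounded"``; the flux
    vector is only meaningful for optimal states.
    """

    model_id: str
    reactions: tuple[str, ...]
    flux: np.ndarray
    objective_value: float
    objective_reaction: str | None
    status: str = "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        try:
            return float(self.flux[self.reactions.index(reaction_id)])
        except ValueError:
            raise KeyError(
                f"reaction {reaction_id!r} absent from flux state of {self.model_id!r}"
            )

    def as_dict(self) -> dict[str, float]:
        return {rid: float(v) for rid, v in zip(self.reactions, self.flux)}

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class ConsistencyResult:
    """FASTCC output: partition of the reactions into consistent/removed."""

    model_id: str
    consistent_reactions: frozenset[str]
    removed_reactions: frozenset[str]
    epsilon: float


# ---------------------------------------------------------------------------
# LP backend
# ---------------------------------------------------------------------------


def solve_lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix | None,
    b_eq: np.ndarray | None,
    bounds: Sequence[tuple[float, float]],
    A_ub: sparse.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
    cfg: SolverConfig = DEFAULT_SOLVER,
):
    """Minimize ``c @ x`` subject to equalities, inequalities and bounds."""
    return linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": cfg.feasibility_tol,
            "dual_feasibility_tolerance": cfg.feasibility_tol,
        },
    )


def _status_name(status_code: int) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(status_code, "failed")


def _objective_vector(model: MetabolicModel, objective: str | None) -> tuple[np.ndarray, str]:
    rid = objective or model.objective_reaction
    if rid is None:
        raise ValueError(f"model {model.model_id!r} has no objective reaction")
    c = np.zeros(len(model.reactions))
    c[model.reaction_index(rid)] = 1.0
    return c, rid


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------


def fba(
    model: MetabolicModel,
    objective: str | None = None,
    sense: str = "max",
    cfg: SolverConfig = DEFAULT_SOLVER,
    parsimonious: bool = True,
) -> FluxState:
    """Flux balance analysis with a pFBA-style tie-break.

    Maximizes (or minimizes) the objective reaction subject to ``S v = 0`` and
    the flux bounds, then minimizes the total absolute flux at the fixed
    optimal objective so the returned vector is reproducible.

    Infeasible or unbounded problems are reported through ``FluxState.status``
    rather than an exception.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    c, objective_id = _objective_vector(model, objective)
    sign = -1.0 if sense == "max" else 1.0
    S = model.stoichiometry
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    res = solve_lp(sign * c, S, np.zeros(S.shape[0]), list(zip(lb, ub)), cfg=cfg)
    status = _status_name(res.status)
    reactions = tuple(model.reaction_ids)
    if status != "optimal":
        return FluxState(
            model_id=model.model_id,
            reactions=reactions,
            flux=np.full(n, np.nan),
            objective_value=np.nan,
            objective_reaction=objective_id,
            status=status,
        )
    z_star = float(c @ res.x)
    v = res.x
    if parsimonious:
        refined = _minimize_l1_at_objective(S, lb, ub, c, z_star, sense, cfg)
        if refined is not None:
            v = refined
    _check_flux(model, S, lb, ub, v, cfg)
    return FluxState(
        model_id=model.model_id,
        reactions=reactions,
        flux=np.asarray(v, dtype=float),
        objective_value=z_star,
        objective_reaction=objective_id,
        status="optimal",
    )


def _minimize_l1_at_objective(
    S: sparse.spmatrix,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    z_star: float,
    sense: str,
    cfg: SolverConfig,
) -> np.ndarray | None:
    """min sum|v| with v = p - n (p, n >= 0) at objective within a small slack."""
    n = S.shape[1]
    S2 = sparse.hstack([S, -S], format="csr")
    eye = sparse.identity(n, format="csr")
    split = sparse.hstack([eye, -eye], format="csr")  # v = p - n
    slack = 1e-8 * max(1.0, abs(z_star))
    # bounds on v expressed as inequalities; objective pinned from the losing side
    rows = [split, -split]
    rhs = [ub, -lb]
    cv = np.concatenate([c, -c])
    if sense == "max":
        rows.append(-sparse.csr_matrix(cv))
        rhs.append(np.array([-(z_star - slack)]))
    else:
        rows.append(sparse.csr_matrix(cv))
        rhs.append(np.array([z_star + slack]))
    A_ub = sparse.vstack(rows, format="csr")
    b_ub = np.concatenate(rhs)
    res = solve_lp(
        np.ones(2 * n),
        S2,
        np.zeros(S.shape[0]),
        [(0.0, None)] * (2 * n),
        A_ub=A_ub,
        b_ub=b_ub,
        cfg=cfg,
    )
    if res.status != 0:
        return None
    return res.x[:n] - res.x[n:]


def _check_flux(model, S, lb, ub, v, cfg: SolverConfig) -> None:
    resid = np.abs(S @ v)
    if resid.size and resid.max() > cfg.assert_tol:
        raise InfeasibleModelError(
            f"model {model.model_id!r}: steady-state residual {resid.max():.3g} "
            f"exceeds tolerance {cfg.assert_tol:g}"
        )
    if np.any(v < lb - cfg.assert_tol) or np.any(v > ub + cfg.assert_tol):
        raise InfeasibleModelError(
            f"model {model.model_id!r}: flux bound violation beyond tolerance"
        )


def fva(
    model: MetabolicModel,
    reactions: Iterable[str] | None = None,
    fraction_of_optimum: float = 0.0,
    cfg: SolverConfig = DEFAULT_SOLVER,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis: per-reaction attainable (min, max) flux.

    With ``fraction_of_optimum > 0`` the objective is additionally constrained
    to at least that fraction of its FBA optimum.
    """
    S = model.stoichiometry
    lb, ub = model.bounds_arrays()
    bounds = list(zip(lb, ub))
    A_ub = b_ub = None
    if fraction_of_optimum > 0:
        if not 0 < fraction_of_optimum <= 1:
            raise ValueError("fraction_of_optimum must lie in [0, 1]")
        c, _ = _objective_vector(model, None)
        base = fba(model, cfg=cfg, parsimonious=False)
        if not base.optimal:
            raise InfeasibleModelError(
                f"FVA on {model.model_id!r}: base FBA is {base.status}"
            )
        A_ub = sparse.csr_matrix(-c)
        b_ub = np.array([-fraction_of_optimum * base.objective_value])
    targets = list(reactions) if reactions is not None else model.reaction_ids
    out: dict[str, tuple[float, float]] = {}
    zeros = np.zeros(S.shape[0])
    for rid in targets:
        j = model.reaction_index(rid)
        c = np.zeros(len(model.reactions))
        c[j] = 1.0
        lo = solve_lp(c, S, zeros, bounds, A_ub=A_ub, b_ub=b_ub, cfg=cfg)
        hi = solve_lp(-c, S, zeros, bounds, A_ub=A_ub, b_ub=b_ub, cfg=cfg)
        if lo.status != 0 or hi.status != 0:
            raise InfeasibleModelError(
                f"FVA on {model.model_id!r}: LP for {rid!r} returned status "
                f"{_status_name(lo.status)}/{_status_name(hi.status)}"
            )
        out[rid] = (float(lo.x[j]), float(hi.x[j]))
    return out


# ---------------------------------------------------------------------------
# FASTCC
# ---------------------------------------------------------------------------


def _lp7(
    S: sparse.spmatrix,
    lb: np.ndarray,
    ub: np.ndarray,
    target_idx: np.ndarray,
    epsilon: float,
    cfg: SolverConfig,
) -> np.ndarray | None:
    """LP-7: maximize the number of target reactions carrying flux >= epsilon.

    Auxiliary variables z_j in [0, epsilon] with v_j >= z_j; maximizing
    sum(z) pushes as many targets as possible up to epsilon simultaneously.
    Returns the flux vector v, or None if the LP fails.
    """
    n = S.shape[1]
    k = len(target_idx)
    if k == 0:
        return np.zeros(n)
    A_eq = sparse.hstack([S, sparse.csr_matrix((S.shape[0], k))], format="csr")
    rows = np.arange(k)
    sel = sparse.csr_matrix((np.ones(k), (rows, target_idx)), shape=(k, n))
    A_ub = sparse.hstack([-sel, sparse.identity(k, format="csr")], format="csr")
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    bounds = list(zip(lb, ub)) + [(0.0, epsilon)] * k
    res = solve_lp(
        c, A_eq, np.zeros(S.shape[0]), bounds, A_ub=A_ub, b_ub=np.zeros(k), cfg=cfg
    )
    if res.status != 0:
        return None
    return res.x[:n]


def fastcc(
    model: MetabolicModel,
    epsilon: float | None = None,
    cfg: SolverConfig = DEFAULT_SOLVER,
) -> ConsistencyResult:
    """FASTCC flux-consistency check.

    A reaction is consistent iff some feasible steady-state flux distribution
    carries at least ``epsilon`` absolute flux through it.  The implementation
    certifies blocks of reactions with LP-7-style support maximization, then
    settles stragglers (including the reverse direction of reversible
    reactions) one at a time; the resulting partition does not depend on the
    order in which reactions were examined.
    """
    cfg = cfg or DEFAULT_SOLVER
    eps = cfg.clamp_epsilon(epsilon)
    S = model.stoichiometry
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    certify_at = eps * (1.0 - 1e-6)

    consistent = np.zeros(n, dtype=bool)
    undecided = np.ones(n, dtype=bool)

    def certify(v: np.ndarray | None) -> None:
        if v is None:
            return
        hit = np.abs(v) >= certify_at
        consistent[hit] = True
        undecided[hit] = False

    # block pass: forward support for everything at once
    certify(_lp7(S, lb, ub, np.flatnonzero(undecided), eps, cfg))
    # reverse block pass for still-undecided reversible reactions
    rev = np.flatnonzero(undecided & (lb < 0))
    if len(rev):
        S_f = sparse.lil_matrix(S.copy())
        lb_f, ub_f = lb.copy(), ub.copy()
        for j in rev:
            S_f[:, j] = -S_f[:, j]
            lb_f[j], ub_f[j] = -ub[j], -lb[j]
        certify(_lp7(S_f.tocsr(), lb_f, ub_f, rev, eps, cfg))
    # singleton LP-7 probes for the remainder (forward, then flipped)
    for j in np.flatnonzero(undecided):
        if not undecided[j]:
            continue
        certify(_lp7(S, lb, ub, np.array([j]), eps, cfg))
        if not undecided[j]:
            continue
        if lb[j] < 0:
            S_j = sparse.lil_matrix(S.copy())
            S_j[:, j] = -S_j[:, j]
            lb_j, ub_j = lb.copy(), ub.copy()
            lb_j[j], ub_j[j] = -ub[j], -lb[j]
            v = _lp7(S_j.tocsr(), lb_j, ub_j, np.array([j]), eps, cfg)
            if v is not None and abs(v[j]) >= certify_at:
                consistent[j] = True
        undecided[j] = False  # decided either way

    ids = model.reaction_ids
    kept = frozenset(ids[i] for i in np.flatnonzero(consistent))
    removed = frozenset(ids) - kept
    return ConsistencyResult(
        model_id=model.model_id,
        consistent_reactions=kept,
        removed_reactions=removed,
        epsilon=eps,
    )


def consistent_submodel(
    model: MetabolicModel,
    result: ConsistencyResult | None = None,
    epsilon: float | None = None,
    cfg: SolverConfig = DEFAULT_SOLVER,
) -> MetabolicModel:
    """Induced submodel on the FASTCC-consistent reaction set."""
    if result is None:
        result = fastcc(model, epsilon=epsilon, cfg=cfg)
    return model.submodel(result.consistent_reactions, model_id=model.model_id)
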