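"""Independent brute-force oracles for the LP/MILP operations.

Everything here builds its own dense matrices straight from the reaction
dictionaries and calls scipy.optimize.linprog directly — deliberately not
reusing any solver plumbing from the package, so that agreement between the
two routes is evidence and not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def dense_problem(model):
    """Dense S, lb, ub built directly from the reaction stoichiometries."""
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    n = len(model.reactions)
    S = np.zeros((len(model.metabolites), n))
    lb = np.zeros(n)
    ub = np.zeros(n)
    for j, rxn in enumerate(model.reactions):
        lb[j] = rxn.lower_bound
        ub[j] = rxn.upper_bound
        for met, coef in rxn.stoichiometry.items():
            S[met_index[met], j] = coef
    return S, lb, ub


def _solve(c, S, lb, ub, extra_lb=None, extra_ub=None):
    lo = lb if extra_lb is None else np.maximum(lb, extra_lb)
    hi = ub if extra_ub is None else np.minimum(ub, extra_ub)
    if np.any(lo > hi):
        return None
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lo, hi)), method="highs")
    return res if res.status == 0 else None


def oracle_fva(model):
    """Per-reaction (min, max) attainable flux by two LPs per reaction."""
    S, lb, ub = dense_problem(model)
    n = S.shape[1]
    out = {}
    for j, rxn in enumerate(model.reactions):
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve(c, S, lb, ub)
        hi = _solve(-c, S, lb, ub)
        if lo is None or hi is None:
            raise RuntimeError(f"oracle FVA failed for {rxn.reaction_id}")
        out[rxn.reaction_id] = (float(lo.x[j]), float(hi.x[j]))
    return out


def oracle_fba_objective(model, objective=None):
    """LP optimum of the (maximized) objective reaction."""
    S, lb, ub = dense_problem(model)
    rid = objective or model.objective_reaction
    j = [r.reaction_id for r in model.reactions].index(rid)
    c = np.zeros(S.shape[1])
    c[j] = -1.0
    res = _solve(c, S, lb, ub)
    if res is None:
        return None
    return float(res.x[j])


def oracle_consistent_set(model, epsilon):
    """Reactions able to carry |v| >= epsilon, straight from brute-force FVA."""
    ranges = oracle_fva(model)
    return {
        rid
        for rid, (vmin, vmax) in ranges.items()
        if max(abs(vmin), abs(vmax)) >= epsilon
    }


def _feasible_with_directions(S, lb, ub, forced):
    """Feasibility with per-reaction forced status.

    ``forced`` maps column -> ("on+", eps) / ("on-", eps) / ("off", None).
    """
    extra_lb = np.full(S.shape[1], -np.inf)
    extra_ub = np.full(S.shape[1], np.inf)
    for j, (status, eps) in forced.items():
        if status == "on+":
            extra_lb[j] = eps
        elif status == "on-":
            extra_ub[j] = -eps
        elif status == "off":
            extra_lb[j] = 0.0
            extra_ub[j] = 0.0
    return _solve(np.zeros(S.shape[1]), S, lb, ub, extra_lb, extra_ub) is not None


def oracle_imat_agreement(model, high, low, epsilon):
    """Maximum achievable iMAT agreement by exhaustive enumeration.

    Every high reaction is tried active-forward, active-backward or
    unsatisfied; every low reaction tried off or unsatisfied; the best total
    number of satisfied constraints over all feasible combinations is
    returned.
    """
    S, lb, ub = dense_problem(model)
    ids = [r.reaction_id for r in model.reactions]
    high_idx = [ids.index(r) for r in sorted(high)]
    low_idx = [ids.index(r) for r in sorted(low)]
    best = 0
    high_options = [("on+",), ("on-",), ("skip",)]
    for high_choice in itertools.product(*([range(3)] * len(high_idx))):
        for low_choice in itertools.product(*([range(2)] * len(low_idx))):
            agreement = sum(1 for c in high_choice if c < 2) + sum(low_choice)
            if agreement <= best:
                continue
            forced = {}
            ok = True
            for j, c in zip(high_idx, high_choice):
                if c == 0:
                    forced[j] = ("on+", epsilon)
                elif c == 1:
                    if lb[j] >= 0:
                        ok = False
                        break
                    forced[j] = ("on-", epsilon)
            if not ok:
                continue
            for j, c in zip(low_idx, low_choice):
                if c == 1:
                    forced[j] = ("off", None)
            if _feasible_with_directions(S, lb, ub, forced):
                best = agreement
    return best


def oracle_init_best_weight(model, weights, epsilon):
    """Maximum total INIT evidence weight by exhaustive enumeration.

    ``weights`` maps reaction id -> weight; reactions absent from the map are
    unconstrained.  Enumerates on/off status for every weighted reaction (and
    the direction of active reversible ones).
    """
    S, lb, ub = dense_problem(model)
    ids = [r.reaction_id for r in model.reactions]
    widx = [(ids.index(r), w) for r, w in sorted(weights.items())]
    best = -np.inf
    for active in itertools.product([0, 1], repeat=len(widx)):
        total = sum(w for (j, w), a in zip(widx, active) if a)
        if total <= best:
            continue
        direction_slots = [
            j for (j, _), a in zip(widx, active) if a and lb[j] < 0 < ub[j]
        ]
        base = {}
        ok = True
        for (j, _), a in zip(widx, active):
            if not a:
                base[j] = ("off", None)
            elif lb[j] >= 0:
                base[j] = ("on+", epsilon)
            elif ub[j] <= 0:
                base[j] = ("on-", epsilon)
        for dirs in itertools.product([0, 1], repeat=len(direction_slots)):
            forced = dict(base)
            for j, d in zip(direction_slots, dirs):
                forced[j] = ("on+", epsilon) if d == 0 else ("on-", epsilon)
            if _feasible_with_directions(S, lb, ub, forced):
                best = max(best, total)
                break
    return best


def oracle_gimme_inconsistency(model, weights, objective, fraction, epsilon=None):
    """Independent formulation of the GIMME stage-2 LP.

    min sum w_r * t_r with t_r >= v_r, t_r >= -v_r, S v = 0, bounds,
    and objective >= fraction * optimum.
    """
    S, lb, ub = dense_problem(model)
    ids = [r.reaction_id for r in model.reactions]
    n = len(ids)
    z = oracle_fba_objective(model, objective)
    if z is None:
        return None
    w = np.array([weights.get(r, 0.0) for r in ids])
    jobj = ids.index(objective)
    # variables [v, t]
    c = np.concatenate([np.zeros(n), w])
    A_eq = np.hstack([S, np.zeros_like(S)])
    eye = np.eye(n)
    A_ub = np.vstack(
        [
            np.hstack([eye, -eye]),     # v - t <= 0
            np.hstack([-eye, -eye]),    # -v - t <= 0
        ]
    )
    b_ub = np.zeros(2 * n)
    row = np.zeros(2 * n)
    row[jobj] = -1.0
    A_ub = np.vstack([A_ub, row])
    b_ub = np.concatenate([b_ub, [-fraction * z]])
    bounds = list(zip(lb, ub)) + [(0, None)] * n
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]), A_ub=A_ub, b_ub=b_ub,
                  bounds=bounds, method="highs")
    return float(res.fun) if res.status == 0 else None


def oracle_min_consistent_superset(model, core, epsilon):
    """Size of the smallest flux-consistent reaction subset containing core.

    Searches subsets of the non-core consistent reactions in increasing size;
    a candidate passes when each of its reactions can carry |v| >= epsilon
    within the candidate submodel.  Exponential — only for tiny networks.
    """
    consistent = oracle_consistent_set(model, epsilon)
    if not set(core) <= consistent:
        raise ValueError("core contains inconsistent reactions")
    others = sorted(consistent - set(core))
    core = sorted(core)
    for size in range(0, len(others) + 1):
        for extra in itertools.combinations(others, size):
            candidate = list(core) + list(extra)
            sub = model.submodel(candidate)
            if oracle_consistent_set(sub, epsilon) == set(candidate):
                return len(candidate)
    raise RuntimeError("no consistent superset found")
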