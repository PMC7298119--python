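"""Systematic exploration of the whole-body model.

Three layers:

* carrying-capacity scaling experiments — multiply the deconjugator and/or
  converter capacities, re-solve the steady state and report percent
  changes of every named flux and pool against the basal run;
* local sensitivity — the same percent changes along a log-spaced grid of
  multiplicative factors on each capacity;
* global sensitivity — first-order Sobol indices by the extended-FAST
  (fast99) frequency method and partial correlation coefficients (PCC) of
  eleven flux-parameter groups against the steady-state pool levels.

Steady states are solved by a damped Newton continuation from the basal
fixed point, with a long stiff integration as fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import root
from scipy.integrate import solve_ivp

from .wholebody import (WholeBodyParams, rhs, compute_flux_table,
                        steady_state_vector, FluxTable, STATE_NAMES)

POOL_NAMES = ["lpbs", "lc", "ipbs", "ic", "hbs", "hc", "hce", "hdl",
              "ldl", "pc"]
POOL_IDX = [STATE_NAMES.index(n) for n in POOL_NAMES]

#: the eleven parameter groups of the global design; members are shifted
#: conjointly by one multiplier. "k_LCa" scales the cholesterol occurrences
#: of the shared emulsion-uptake constant, "k_LPBSa" its BS occurrences.
PARAMETER_GROUPS: dict[str, list[str]] = {
    "k_in": ["f_meal"],
    "BCR_MAX": ["BCR_max"],
    "k_LCa": ["k_lca"],
    "k_HCo": ["k_hco"],
    "B_to_H": ["k_ldlha", "k_hdlha"],
    "synthesis": ["ICS_max", "HCS_max", "PCS_max"],
    "k_LPBSa": ["k_lpbsa"],
    "k_HBSo": ["k_hbso"],
    "k_HBSs": ["k_hbss"],
    "PBSD_MAX": ["pbsd_max"],
    "CCC_MAX": ["ccc_max"],
}
CAPACITY_GROUPS = ("PBSD_MAX", "CCC_MAX")


class SteadyStateFailure(RuntimeError):
    pass


# --------------------------------------------------------------------------
# steady-state solver (Newton continuation)
# --------------------------------------------------------------------------

def _live_f(x_live, params):
    x = np.concatenate([np.maximum(x_live, 0.0), np.zeros(4)])
    return rhs(0.0, x, params)[:12]


def _initial_guess(params: WholeBodyParams, basal: np.ndarray) -> np.ndarray:
    g = basal[:12].copy()
    g[0] = params.ccc_max
    sat = g[2] / (params.K_pbsd + g[2]) if g[2] > 0 else 0.0
    g[1] = max(params.pbsd_max - params.d_pbsd * sat / params.mu_pbsd,
               1e-6 * params.pbsd_max)
    return g


def solve_steady_state(params: WholeBodyParams, basal: np.ndarray,
                       tol: float = 1e-9, fallback_days: float = 400.0):
    """Steady state of the live subsystem, continued from ``basal``.

    Newton (hybr) first; on failure or a negative/unstable root, integrate
    the stiff system for ``fallback_days`` and retry. Raises
    :class:`SteadyStateFailure` if both fail.
    """
    guess = _initial_guess(params, basal)
    r = root(_live_f, guess, args=(params,), method="hybr", tol=1e-12)
    x = np.maximum(r.x, 0.0) if r.success else None
    if x is not None and np.max(np.abs(_live_f(x, params))) < tol * 1e3:
        # reject roots on the extinct-guild branch when capacity is positive
        if (params.ccc_max <= 0 or x[0] > 1e-6 * params.ccc_max):
            return x
    x0 = np.concatenate([guess, np.zeros(4)])
    sol = solve_ivp(rhs, (0.0, fallback_days), x0, args=(params,),
                    method="LSODA", rtol=1e-10, atol=1e-10)
    if not sol.success:
        raise SteadyStateFailure("integration fallback failed")
    r = root(_live_f, sol.y[:12, -1], args=(params,), method="hybr", tol=1e-12)
    if not r.success:
        raise SteadyStateFailure("Newton polish failed after integration")
    return np.maximum(r.x, 0.0)


def _full_state(x_live: np.ndarray) -> np.ndarray:
    return np.concatenate([x_live, np.zeros(4)])


# --------------------------------------------------------------------------
# capacity scaling experiments
# --------------------------------------------------------------------------

@dataclass
class ScalingExperiment:
    factor_pbsd: float
    factor_ccc: float
    flux_change: dict        # percent change per named flux vs basal
    pool_change: dict        # percent change per pool concentration
    fluxes: FluxTable
    state: np.ndarray
    converged: bool


def _percent(new: float, old: float) -> float:
    if abs(old) < 1e-300:
        return 0.0 if abs(new) < 1e-300 else np.inf
    return 100.0 * (new - old) / old


def run_scaling_experiment(params: WholeBodyParams, factor_pbsd: float = 1.0,
                           factor_ccc: float = 1.0) -> ScalingExperiment:
    """Re-solve the steady state with the guild carrying capacities
    multiplied by the given factors and report percent changes of every
    named flux and pool against the basal steady state."""
    if factor_pbsd <= 0 or factor_ccc <= 0:
        raise ValueError("capacity factors must be positive")
    basal = steady_state_vector(params)
    basal_flux = compute_flux_table(basal, params)
    scaled = replace(params, pbsd_max=params.pbsd_max * factor_pbsd,
                     ccc_max=params.ccc_max * factor_ccc, steady_state=None)
    converged = True
    if factor_pbsd == 1.0 and factor_ccc == 1.0:
        x_live = basal[:12]          # identity experiment: changes are 0
    else:
        try:
            x_live = solve_steady_state(scaled, basal)
        except SteadyStateFailure:
            converged = False
            x_live = basal[:12]
    x = _full_state(x_live)
    flux = compute_flux_table(x, scaled)
    flux_change, seen = {}, set()
    for e in flux.edges:
        if e.name in seen:
            continue
        seen.add(e.name)
        flux_change[e.name] = _percent(flux[e.name], basal_flux[e.name])
    pool_change = {n: _percent(x[i], basal[i])
                   for n, i in zip(POOL_NAMES, POOL_IDX)}
    return ScalingExperiment(factor_pbsd=factor_pbsd, factor_ccc=factor_ccc,
                             flux_change=flux_change, pool_change=pool_change,
                             fluxes=flux, state=x, converged=converged)


DEFAULT_Q_GRID = [1 / 100, 1 / 50, 1 / 20, 1 / 10, 1 / 5, 1 / 2,
                  1, 2, 5, 10, 20, 50, 100]


def local_sensitivity_scan(params: WholeBodyParams,
                           q_grid=None) -> dict[str, list[ScalingExperiment]]:
    """Percent-change curves along a multiplicative grid applied to each
    capacity in turn (the other held basal)."""
    q_grid = list(q_grid) if q_grid is not None else list(DEFAULT_Q_GRID)
    if any(q <= 0 for q in q_grid):
        raise ValueError("grid factors must be positive")
    return {
        "pbsd": [run_scaling_experiment(params, factor_pbsd=q) for q in q_grid],
        "ccc": [run_scaling_experiment(params, factor_ccc=q) for q in q_grid],
    }


# --------------------------------------------------------------------------
# extended FAST (fast99) first-order Sobol indices
# --------------------------------------------------------------------------

def _complementary_frequencies(k: int, w_comp_max: int) -> np.ndarray:
    """Complementary frequencies spread evenly over [1, w_comp_max] so the
    complementary space is well traversed within one sweep; cycles when
    there are more parameters than admissible frequencies."""
    w_comp_max = max(w_comp_max, 1)
    if k <= w_comp_max:
        return np.floor(np.linspace(1, w_comp_max, k))
    return 1.0 + np.arange(k) % w_comp_max


def efast_first_order(func, d: int, n_per_param: int, seed: int = 0,
                      M: int = 4) -> np.ndarray:
    """First-order Sobol indices of ``func`` on the unit hypercube.

    One frequency sweep per parameter: the parameter of interest rides the
    highest admissible frequency ``w_max = (n - 1) / (2 M)`` and the
    complementary set cycles through frequencies at most ``w_max / (2 M)``;
    the index is the spectral mass at the first ``M`` harmonics of
    ``w_max`` over the total spectral mass. ``func`` maps an (n, d) array
    of unit-cube points to n outputs.
    """
    n = int(n_per_param)
    if n % 2 == 0:
        n += 1
    w_max = (n - 1) // (2 * M)
    if w_max < 1:
        raise ValueError("n too small for the requested harmonics")
    w_comp_max = max(w_max // (2 * M), 1)
    rng = np.random.default_rng(seed)
    s = 2.0 * np.pi * np.arange(n) / n
    indices = np.empty(d)
    for i in range(d):
        w = np.empty(d)
        w[i] = w_max
        others = [j for j in range(d) if j != i]
        w[others] = _complementary_frequencies(len(others), w_comp_max)
        phi = rng.uniform(0, 2 * np.pi, size=d)
        x = 0.5 + np.arcsin(np.sin(np.outer(s, w) + phi)) / np.pi
        y = np.asarray(func(x), dtype=float)
        y = y - y.mean()
        spec = np.abs(np.fft.rfft(y)) ** 2 / n ** 2
        total = 2.0 * np.sum(spec[1:])
        first = 2.0 * np.sum(spec[[p * w_max for p in range(1, M + 1)]])
        indices[i] = first / total if total > 0 else 0.0
    return indices


def partial_correlation(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """PCC of each column of ``X`` with ``y``, controlling for the other
    columns: the correlation of the two residuals after regressing both on
    the remaining columns (with intercept). Zero-variance residuals give a
    PCC of 0."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    out = np.empty(d)
    scale = max(float(np.std(y)), 1e-300)
    for j in range(d):
        A = np.column_stack([X[:, [k for k in range(d) if k != j]],
                             np.ones(n)])
        ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        rx = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
        denom = np.linalg.norm(ry) * np.linalg.norm(rx)
        if denom < 1e-12 * scale * np.sqrt(n):
            out[j] = 0.0
        else:
            out[j] = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    return out


# --------------------------------------------------------------------------
# global sensitivity of the whole-body model
# --------------------------------------------------------------------------

@dataclass
class SensitivityDesign:
    """Design of the global analysis: parameter groups, ranges and sizes.

    Flux-parameter groups range over +/- ``span`` of the basal value;
    capacities over ``cap_lo``..``cap_hi`` times basal, sampled
    log-uniformly by default (linear via ``capacity_log=False``).
    ``n_samples`` is the total model-evaluation budget of the eFAST sweep
    (split across groups); ``n_pcc`` the Monte-Carlo sample of the PCC.
    """

    groups: dict = field(default_factory=lambda: dict(PARAMETER_GROUPS))
    span: float = 0.5
    cap_lo: float = 0.01
    cap_hi: float = 100.0
    capacity_log: bool = True
    n_samples: int = 10_000
    n_pcc: int = 2_000
    seed: int = 0


@dataclass
class SensitivityResult:
    groups: list[str]
    outputs: list[str]
    sobol: dict          # output -> {group: S1}
    pcc: dict            # output -> {group: pcc}
    residual: dict       # output -> 1 - sum(S1)
    n_failures: int


def _apply_multipliers(params: WholeBodyParams, groups: dict,
                       mult: np.ndarray) -> WholeBodyParams:
    changes = {}
    for (gname, members), m in zip(groups.items(), mult):
        for attr in members:
            if attr == "k_lpbsa":
                base = params.k_lpbsa if params.k_lpbsa is not None else params.k_lca
                changes["k_lpbsa"] = base * m
            else:
                changes[attr] = getattr(params, attr) * m
    if "k_lpbsa" not in changes and params.k_lpbsa is None:
        changes["k_lpbsa"] = params.k_lca  # freeze BS uptake at basal
    return replace(params, steady_state=None, **changes)


def _unit_to_multipliers(u: np.ndarray, design: SensitivityDesign,
                         names: list[str]) -> np.ndarray:
    m = 1.0 - design.span + 2.0 * design.span * u
    for j, name in enumerate(names):
        if name in CAPACITY_GROUPS:
            if design.capacity_log:
                m[..., j] = design.cap_lo * (design.cap_hi / design.cap_lo) ** u[..., j]
            else:
                m[..., j] = design.cap_lo + (design.cap_hi - design.cap_lo) * u[..., j]
    return m


def global_sensitivity(params: WholeBodyParams,
                       design: SensitivityDesign | None = None) -> SensitivityResult:
    """eFAST first-order Sobol indices and PCCs of the steady-state pool
    levels with respect to the eleven flux-parameter groups.

    Steady-state failures at sample points are excluded from the PCC sample
    and imputed with the basal output in the frequency sweep (they are
    counted in ``n_failures``)."""
    design = design or SensitivityDesign()
    names = list(design.groups)
    d = len(names)
    basal = steady_state_vector(params)
    basal_out = basal[POOL_IDX]
    failures = [0]

    def outputs_for(u_block: np.ndarray) -> np.ndarray:
        mult = _unit_to_multipliers(np.array(u_block, copy=True), design, names)
        out = np.empty((len(mult), len(POOL_IDX)))
        ok = np.ones(len(mult), dtype=bool)
        for k, m in enumerate(mult):
            try:
                x = solve_steady_state(_apply_multipliers(params, design.groups, m),
                                       basal)
                out[k] = x[POOL_IDX]
            except SteadyStateFailure:
                failures[0] += 1
                ok[k] = False
        if not ok.any():
            out[:] = basal_out
        elif not ok.all():
            # impute failed points along the sweep so the excluded samples
            # do not inject spurious spectral mass
            idx = np.arange(len(mult))
            for o in range(out.shape[1]):
                out[~ok, o] = np.interp(idx[~ok], idx[ok], out[ok, o])
        return out

    n_per = max(design.n_samples // d, 65)
    sobol_mat = np.empty((d, len(POOL_NAMES)))

    # one frequency sweep per group, capturing all outputs at once
    n = n_per if n_per % 2 == 1 else n_per + 1
    M = 4
    w_max = (n - 1) // (2 * M)
    w_comp_max = max(w_max // (2 * M), 1)
    rng = np.random.default_rng(design.seed)
    s = 2.0 * np.pi * np.arange(n) / n
    for i in range(d):
        w = np.empty(d)
        w[i] = w_max
        others = [j for j in range(d) if j != i]
        w[others] = _complementary_frequencies(len(others), w_comp_max)
        phi = rng.uniform(0, 2 * np.pi, size=d)
        u = 0.5 + np.arcsin(np.sin(np.outer(s, w) + phi)) / np.pi
        Y = outputs_for(u)
        Yc = Y - Y.mean(axis=0)
        spec = np.abs(np.fft.rfft(Yc, axis=0)) ** 2 / n ** 2
        total = 2.0 * spec[1:].sum(axis=0)
        harm = [p * w_max for p in range(1, M + 1)]
        first = 2.0 * spec[harm].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sobol_mat[i] = np.where(total > 0, first / total, 0.0)

    # PCC on an independent uniform sample
    rng_pcc = np.random.default_rng(design.seed + 1)
    U = rng_pcc.uniform(size=(design.n_pcc, d))
    mult = _unit_to_multipliers(U.copy(), design, names)
    rows, Yp = [], []
    for k, m in enumerate(mult):
        try:
            x = solve_steady_state(_apply_multipliers(params, design.groups, m),
                                   basal)
            rows.append(k)
            Yp.append(x[POOL_IDX])
        except SteadyStateFailure:
            failures[0] += 1
    Yp = np.array(Yp)
    Xp = U[rows]

    sobol = {out: {g: float(sobol_mat[i, o]) for i, g in enumerate(names)}
             for o, out in enumerate(POOL_NAMES)}
    pcc = {out: {g: float(v) for g, v in
                 zip(names, partial_correlation(Xp, Yp[:, o]))}
           for o, out in enumerate(POOL_NAMES)}
    residual = {out: float(1.0 - sum(sobol[out].values()))
                for out in POOL_NAMES}
    return SensitivityResult(groups=names, outputs=list(POOL_NAMES),
                             sobol=sobol, pcc=pcc, residual=residual,
                             n_failures=failures[0])
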