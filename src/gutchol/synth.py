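"""Synthetic inputs with the statistical structure the analysis assumes.

Generates every input the pipeline consumes without any download: growth
assays (logistic / delayed-logistic trajectories with Monod or quadratic
conversion plus truncated-Gaussian observation noise), BSH enzyme assays
(linear activity vs density), the whole-body calibration ledger, and a
tracer "experimental" distribution. Defaults are the study conditions: the
posterior-mean kinetic parameters, the published calibration fluxes and
the reported 3-day labeled-cholesterol distribution.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from .kinetics import (D8Params, XylParams, GrowthAssay, simulate_d8,
                       simulate_xyl, deconjugation_constant)
from .wholebody import CalibrationLedger

#: posterior-mean in vitro kinetic parameters (generating truths)
D8_TRUE = D8Params(mu=0.44772, k_cc=0.27441, K=1.6681)
XYL_TRUE = XylParams(mu=1.9375, beta=1.1186, delta=24.495, K=0.10439,
                     k_bxyl=0.0838)

#: BSH activity regression truth (nmol min^-1 mg_prot^-1 per unit density)
BSH_SLOPE_TRUE = 19.2466

#: reported 3-day labeled-cholesterol distribution (% of recovered label)
TRACER_DATA = {"feces": 48.1, "host_tissues": 26.4, "intestinal": 25.5}


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model of the synthetic assays: i.i.d. Gaussian,
    truncated at zero, on the density and metabolite channels."""

    density_sd: float = 0.02
    metabolite_sd: float = 0.02
    n_replicates: int = 3
    n_timepoints: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_sd < 0 or self.metabolite_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def _truncate(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, None)


def gen_growth_assay(model: str, true_params=None,
                     noise: NoiseSpec | None = None,
                     bs0_levels=None, t_end: float | None = None,
                     density0: float = 0.05) -> list[GrowthAssay]:
    """Simulate noisy growth assays of the chosen strain model.

    One assay per replicate per initial-BS level. For the D8 model the
    metabolite channels are the cholesterol/coprostanol fractions started
    at (1, 0); for the Xyl model they are the PBS/SBS concentrations
    started at (bs0-dependent level, 0) with a constant PBS history.
    The default inoculum is 5% of the maximal density — large enough that
    the zero-truncation of the observation noise never distorts the early
    samples the Gaussian likelihood assumes.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    assays = []
    if model == "d8":
        p = true_params or D8_TRUE
        bs0_levels = bs0_levels if bs0_levels is not None else [0.0, 1.0, 30.0]
        t_end = t_end or 24.0
        times = np.linspace(0.0, t_end, noise.n_timepoints)
        for bs0 in bs0_levels:
            for r in range(noise.n_replicates):
                dens, cl, cp = simulate_d8(p, (density0, 1.0, 0.0), times)
                assays.append(GrowthAssay(
                    times=times,
                    density=_truncate(dens + rng.normal(0, noise.density_sd,
                                                        len(times))),
                    metabolite_a=_truncate(cl + rng.normal(
                        0, noise.metabolite_sd, len(times))),
                    metabolite_b=_truncate(cp + rng.normal(
                        0, noise.metabolite_sd, len(times))),
                    initial_bs=bs0, replicate_id=f"bs{bs0:g}_r{r}",
                    density_eps=max(0.25, 6 * noise.density_sd),
                    density0=density0, metab_a0=1.0, metab_b0=0.0))
    elif model == "xyl":
        p = true_params or XYL_TRUE
        bs0_levels = bs0_levels if bs0_levels is not None else [1.0, 2.0]
        t_end = t_end or 48.0
        times = np.linspace(0.0, t_end, noise.n_timepoints)
        for pbs0 in bs0_levels:
            # the composite deconjugation constant carries 1/[BS]0 of the
            # growth medium, so each level has its own value
            kb = deconjugation_constant(BSH_SLOPE_TRUE, pbs0 * 1000.0)
            p_level = replace(p, k_bxyl=kb)
            for r in range(noise.n_replicates):
                dens, pbs, sbs = simulate_xyl(p_level,
                                              (density0, float(pbs0), 0.0),
                                              times)
                assays.append(GrowthAssay(
                    times=times,
                    density=_truncate(dens + rng.normal(0, noise.density_sd,
                                                        len(times))),
                    metabolite_a=_truncate(pbs + rng.normal(
                        0, noise.metabolite_sd, len(times))),
                    metabolite_b=_truncate(sbs + rng.normal(
                        0, noise.metabolite_sd, len(times))),
                    initial_bs=pbs0 * 1000.0,  # mmol/L -> nmol/mL
                    replicate_id=f"pbs{pbs0:g}_r{r}",
                    density_eps=max(0.25, 6 * noise.density_sd),
                    density0=density0, metab_a0=float(pbs0), metab_b0=0.0))
    else:
        raise ValueError(f"unknown model {model!r}")
    return assays


def gen_bsh_assay(slope: float = BSH_SLOPE_TRUE, intercept: float = 0.0,
                  noise_sd: float = 1.0, n: int = 12, seed: int = 0):
    """Densities uniform on [0, 1]; activity = slope*density + intercept
    + Gaussian noise (activity may be slightly negative, as measured)."""
    if n < 3:
        raise ValueError("n must be at least 3")
    rng = np.random.default_rng(seed)
    density = rng.uniform(0.0, 1.0, size=n)
    activity = slope * density + intercept + rng.normal(0, noise_sd, size=n)
    return density, activity


def gen_ledger_and_tracer_data(perturbation_sd: float = 0.0, seed: int = 0,
                               tracer_sem: float = 0.0):
    """Default calibration ledger (published fluxes verbatim, optionally
    jittered by a relative Gaussian perturbation on the literature entries)
    plus the reported 3-day tracer fraction vector (optionally with
    per-compartment SEM noise, renormalized to 100%)."""
    if perturbation_sd < 0:
        raise ValueError("perturbation_sd must be non-negative")
    rng = np.random.default_rng(seed)
    ledger = CalibrationLedger()
    if perturbation_sd > 0:
        fluxes = copy.deepcopy(ledger.fluxes)
        for k in fluxes:
            if k == "ss_chol_copro_ref":
                continue
            fluxes[k] *= float(np.exp(rng.normal(0, perturbation_sd)))
        ledger.fluxes = fluxes
    data = dict(TRACER_DATA)
    if tracer_sem > 0:
        vals = np.array(list(data.values()))
        vals = np.clip(vals + rng.normal(0, tracer_sem, len(vals)), 0.1, None)
        vals *= 100.0 / vals.sum()
        data = {k: float(v) for k, v in zip(data, vals)}
    return ledger, data
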