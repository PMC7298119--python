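"""Rescaling of in vitro strain kinetics to gut-scale functional guilds.

The in vitro models run in hours on normalized single-strain densities; the
whole-body model runs in days on the normalized densities of two functional
guilds — coprostanol-converting cholesterol degraders (CCC) and primary
bile-salt deconjugators (PBSD) — at the bacterial level of the small
intestine ``b_gut_max``. Rates are converted hour -> day by the factor 24,
densities by the ratio of the maximal observed in vitro concentration to
``b_gut_max``, PBS concentrations mmol/L -> mg/L by the mean conjugated
bile-salt molecular weight ``w_pbs``, and the in vitro deconjugation
constant by the ratio of the fecal (in vivo) BSH activity to the in vitro
activity at maximal density.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .kinetics import D8Params, XylParams


class UpscalingError(ValueError):
    """Missing or invalid upscaling constant."""


@dataclass(frozen=True)
class UpscaleConstants:
    """Constants linking in vitro cultures to the small-intestine community.

    b_gut_max : bacterial level of the small intestine (CFU/mL);
    w_pbs : mean conjugated bile-salt molecular weight (mg/mmol);
    a_bsh_mic : fecal BSH activity measured in vivo (nmol min^-1 mg_prot^-1);
    a_bsh_invitro : in vitro BSH activity at maximal Xyl density (same unit,
    the regression slope since density is normalized to 1);
    d8_max, bxyl_max : maximal observed in vitro concentrations (CFU/mL);
    q_col_cop : excreted coprostanol-to-cholesterol ratio (intermediate
    converter phenotype; human range roughly 0.01 - 4).
    """

    b_gut_max: float = 5.0e9
    w_pbs: float = 467.847
    a_bsh_mic: float | None = 0.0033
    a_bsh_invitro: float = 19.2466
    d8_max: float = 2.0e9
    bxyl_max: float = 4.0e9
    q_col_cop: float = 0.1

    def __post_init__(self) -> None:
        for name in ("b_gut_max", "w_pbs", "a_bsh_invitro", "d8_max",
                     "bxyl_max", "q_col_cop"):
            if getattr(self, name) <= 0:
                raise UpscalingError(f"{name} must be positive")
        if not (0.01 <= self.q_col_cop <= 4.0):
            raise UpscalingError(
                "q_col_cop outside the reported human range [0.01, 4]")


@dataclass(frozen=True)
class MicrobialParams:
    """Gut-scale guild parameters, all in day-based units."""

    mu_ccc: float        # day^-1
    mu_pbsd: float       # day^-1
    d_pbsd: float        # day^-1
    K_pbsd: float        # mg / L
    k_pbsd: float        # day^-1 (per squared normalized PBSD density)
    K_ccc: float         # dimensionless (normalized density)
    k_cc: float          # day^-1

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def upscale_microbial_params(d8: D8Params, xyl: XylParams,
                             c: UpscaleConstants, k_lce: float,
                             invert_density_ratio: bool = False) -> MicrobialParams:
    """Derive the in vivo guild parameters from the in vitro posteriors.

    Frozen conventions (each formula is emitted by :func:`audit_table`):

    * ``mu_ccc  = 24 * d8.mu  * (d8_max / b_gut_max)``
    * ``mu_pbsd = 24 * xyl.mu * (bxyl_max / b_gut_max)``
    * ``d_pbsd  = 24 * xyl.beta``
    * ``K_pbsd  = w_pbs * xyl.K``
    * ``k_pbsd  = 24 * xyl.k_bxyl * a_bsh_mic / a_bsh_invitro``
    * ``K_ccc   = d8.K * d8_max / b_gut_max``
    * ``k_cc    = q_col_cop * k_lce``

    ``invert_density_ratio`` switches the growth-rate density ratio to
    ``b_gut_max / max`` (the printed fraction is typographically ambiguous).
    """
    if k_lce <= 0:
        raise UpscalingError("k_lce must be positive")
    if c.a_bsh_mic is None:
        raise UpscalingError("a_bsh_mic (fecal BSH activity) is not configured")
    r_d8 = c.d8_max / c.b_gut_max
    r_xyl = c.bxyl_max / c.b_gut_max
    if invert_density_ratio:
        r_d8, r_xyl = 1.0 / r_d8, 1.0 / r_xyl
    return MicrobialParams(
        mu_ccc=24.0 * d8.mu * r_d8,
        mu_pbsd=24.0 * xyl.mu * r_xyl,
        d_pbsd=24.0 * xyl.beta,
        K_pbsd=c.w_pbs * xyl.K,
        k_pbsd=24.0 * xyl.k_bxyl * c.a_bsh_mic / c.a_bsh_invitro,
        K_ccc=d8.K * c.d8_max / c.b_gut_max,
        k_cc=c.q_col_cop * k_lce,
    )


def audit_table(d8: D8Params, xyl: XylParams, c: UpscaleConstants,
                k_lce: float, **kwargs) -> list[dict]:
    """Audit rows (parameter, formula, value, unit) for the derived set."""
    p = upscale_microbial_params(d8, xyl, c, k_lce, **kwargs)
    formulas = {
        "mu_ccc": ("24 * mu_BspD8 * d8_max / b_gut_max", "day^-1"),
        "mu_pbsd": ("24 * mu_Bxyl * bxyl_max / b_gut_max", "day^-1"),
        "d_pbsd": ("24 * beta_Bxyl", "day^-1"),
        "K_pbsd": ("w_pbs * K_Bxyl", "mg L^-1"),
        "k_pbsd": ("24 * k_bxyl * a_bsh_mic / a_bsh_invitro", "day^-1"),
        "K_ccc": ("K_D8 * d8_max / b_gut_max", "-"),
        "k_cc": ("q_col_cop * k_lce", "day^-1"),
    }
    return [{"parameter": name, "formula": f, "value": getattr(p, name),
             "unit": u} for name, (f, u) in formulas.items()]


def delay_negligibility_check(params, horizon: float = 50.0,
                              delta_days: float | None = None,
                              n_eval: int = 2001, step: float = 0.005,
                              perturb_lpbs: float = 0.0):
    """Relative L2 distance between the delayed and non-delayed PBSD dynamics.

    Runs the calibrated whole-body model twice over ``[0, horizon]`` days —
    once with the instantaneous PBSD repression term and once with the
    luminal-PBS concentration sensed with delay ``delta_days`` (the in vitro
    delay rescaled to days by default) — and returns
    ``||x_dde - x_ode||_2 / ||x_ode||_2`` over the non-cumulative states.

    Both runs use the same fixed-step integrator (so the distance is not
    contaminated by solver differences) and start from the calibrated
    steady state, which is the regime in which the whole-body model is
    operated; ``perturb_lpbs`` applies a relative offset to the initial
    luminal PBS concentration to probe the transient regime.
    """
    import warnings
    from . import wholebody

    if delta_days is None:
        delta_days = 24.495 / 24.0
    if delta_days < 0:
        raise UpscalingError("delay must be non-negative")
    if horizon < delta_days:
        warnings.warn("horizon shorter than the rescaled delay; the delayed "
                      "term never leaves its history segment", stacklevel=2)
    times = np.linspace(0.0, horizon, n_eval)
    x0 = wholebody.steady_state_vector(params)
    x0[2] *= 1.0 + perturb_lpbs
    sol_ode = wholebody.integrate_fixed(params, x0, times, step=step,
                                        pbsd_delay=0.0)
    sol_dde = wholebody.integrate_fixed(params, x0, times, step=step,
                                        pbsd_delay=delta_days)
    live = wholebody.NON_CUMULATIVE_IDX
    diff = sol_dde[:, live] - sol_ode[:, live]
    denom = np.linalg.norm(sol_ode[:, live])
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(diff) / denom)
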