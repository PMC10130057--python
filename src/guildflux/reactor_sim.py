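"""Kinetic simulation of the coupled three-guild nitrogen-removal system.

Batch (closed-bottle) cycling studies and steady-state continuous operation
are both modelled as well-mixed reactors in which each guild turns over its
reaction at a multiplicative Monod rate::

    v_g = vmax_g * prod_s  C_s / (K_{g,s} + C_s)

Nitrogenous concentrations are carried in mg N/L, dissolved methane in
mmol/L.  Extents (and vmax) are mmol reaction-units/L/d.

Only the bacterial methane half-saturation constant (2.6 uM) is an
experimentally anchored value; the archaeal methane constant defaults to
ten times that, and the nitrogen-species constants are placeholders
(1 mg N/L) exposed through configuration — results depending on them are
simulation-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .stoichiometry import (
    DEFAULT_N_ATOMS,
    GUILD_ORDER,
    N_MOLAR_MASS,
    PARTITION_SPECIES,
    FluxPartition,
    RateVector,
    Reaction,
    ReactorConfig,
    guild_reactions,
    partition_fluxes,
    removal_efficiency,
)

__all__ = [
    "GuildKinetics",
    "KineticParams",
    "SimState",
    "SteadyState",
    "default_kinetics",
    "simulate_batch",
    "solve_steady_state",
    "BACTERIAL_CH4_KS_MMOL",
    "ARCHAEAL_CH4_KS_MMOL",
]

#: Methane half-saturation constant of n-DAMO bacteria, 2.6 uM in mmol/L.
BACTERIAL_CH4_KS_MMOL = 2.6e-3
#: Archaeal methane constant: 10x bacterial (the minimum consistent with
#: "at least one order of magnitude higher").
ARCHAEAL_CH4_KS_MMOL = 2.6e-2

#: Placeholder half-saturation for nitrogenous substrates (mg N/L).
DEFAULT_N_KS_MG = 1.0

_STATE_SPECIES = ("NH4", "NO2", "NO3", "CH4")


@dataclass(frozen=True)
class GuildKinetics:
    """Monod parameters for one guild.

    ``ks`` maps substrate symbol -> half-saturation constant in the
    substrate's native concentration unit (mg N/L for N species, mmol/L
    for CH4).  Substrates absent from ``ks`` do not limit the rate.
    """

    vmax: float
    ks: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValueError("vmax must be >= 0")
        ks = {sp: float(k) for sp, k in self.ks.items()}
        for sp, k in ks.items():
            if not k > 0:
                raise ValueError(f"ks[{sp!r}] must be > 0")
        object.__setattr__(self, "ks", ks)

    def rate(self, conc: Mapping[str, float], skip: Tuple[str, ...] = ()) -> float:
        v = self.vmax
        for sp, k in self.ks.items():
            if sp in skip:
                continue
            c = max(float(conc.get(sp, 0.0)), 0.0)
            v *= c / (k + c)
        return v


@dataclass(frozen=True)
class KineticParams:
    """Per-guild kinetics in guild order (anammox, bacteria, archaea)."""

    anammox: GuildKinetics
    ndamo_bacteria: GuildKinetics
    ndamo_archaea: GuildKinetics

    def guild(self, guild_id: str) -> GuildKinetics:
        return getattr(self, guild_id)


def default_kinetics(
    vmax: Mapping[str, float] | float = 1.0,
    n_ks_mg: float = DEFAULT_N_KS_MG,
) -> KineticParams:
    """Default parameter set; ``vmax`` may be one value or per-guild map."""
    if isinstance(vmax, (int, float)):
        vmax = {g: float(vmax) for g in GUILD_ORDER}
    return KineticParams(
        anammox=GuildKinetics(vmax["anammox"], {"NH4": n_ks_mg, "NO2": n_ks_mg}),
        ndamo_bacteria=GuildKinetics(
            vmax["ndamo_bacteria"], {"NO2": n_ks_mg, "CH4": BACTERIAL_CH4_KS_MMOL}
        ),
        ndamo_archaea=GuildKinetics(
            vmax["ndamo_archaea"], {"NO3": n_ks_mg, "CH4": ARCHAEAL_CH4_KS_MMOL}
        ),
    )


@dataclass
class SimState:
    """Batch trajectory: concentrations, cumulative N2-N, and bookkeeping.

    ``concentrations`` holds mg N/L for NH4/NO2/NO3 and mmol/L for CH4.
    ``n2_n`` is cumulative dinitrogen-N produced (mg N/L-equivalent) and
    ``assimilated_n`` the cumulative nitrogen unaccounted for by the
    registry's written equations (the anammox biomass shortfall), so that
    dissolved N + n2_n + assimilated_n is conserved.
    """

    times: np.ndarray
    concentrations: Dict[str, np.ndarray]
    n2_n: np.ndarray
    assimilated_n: np.ndarray
    clamp_count: int = 0

    def total_n(self) -> np.ndarray:
        """Total tracked nitrogen (mg N/L) at every time point."""
        dissolved = sum(
            self.concentrations[sp] * DEFAULT_N_ATOMS[sp] * 1.0
            for sp in ("NH4", "NO2", "NO3")
        )
        return dissolved + self.n2_n + self.assimilated_n

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time_d, species, value, unit) table of the trajectory."""
        rows = []
        for sp in _STATE_SPECIES:
            unit = "mmol/L" if sp == "CH4" else "mg_N/L"
            for t, v in zip(self.times, self.concentrations[sp]):
                rows.append((t, sp, v, unit))
        for t, v in zip(self.times, self.n2_n):
            rows.append((t, "N2_N_cum", v, "mg_N/L"))
        return pd.DataFrame(rows, columns=["time_d", "species", "value", "unit"])


def _guild_extents(
    conc: Mapping[str, float],
    params: KineticParams,
    methane_nonlimiting: bool,
) -> np.ndarray:
    skip = ("CH4",) if methane_nonlimiting else ()
    return np.array([params.guild(g).rate(conc, skip=skip) for g in GUILD_ORDER])


def _derivative(
    y: np.ndarray,
    params: KineticParams,
    S: np.ndarray,
    imbalance: np.ndarray,
    n2_coeffs: np.ndarray,
    methane_nonlimiting: bool,
    methane_closed: bool,
) -> np.ndarray:
    # y = [NH4, NO2, NO3, CH4, N2N_cum, assimN_cum]
    conc = {sp: y[i] for i, sp in enumerate(_STATE_SPECIES)}
    v = _guild_extents(conc, params, methane_nonlimiting)
    dy = np.empty_like(y)
    dy[:3] = N_MOLAR_MASS * (S[:3] @ v)  # N species, 1 N atom each
    dy[3] = (S[3] @ v) if methane_closed else 0.0
    dy[4] = N_MOLAR_MASS * 2.0 * float(n2_coeffs @ v)
    dy[5] = -N_MOLAR_MASS * float(imbalance @ v)
    return dy


def _rk4_step(y, dt, deriv):
    k1 = deriv(y)
    k2 = deriv(y + 0.5 * dt * k1)
    k3 = deriv(y + 0.5 * dt * k2)
    k4 = deriv(y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_batch(
    initial: Mapping[str, float],
    params: KineticParams,
    duration_d: float,
    dt_d: float,
    methane_mode: str = "closed_bottle",
    registry: Optional[Mapping[str, Reaction]] = None,
) -> SimState:
    """Integrate the closed three-guild batch system with fixed-step RK4.

    ``initial`` gives starting concentrations (mg N/L; CH4 mmol/L); absent
    species start at 0.  ``methane_mode`` is ``closed_bottle`` (methane is
    a depleting state variable) or ``non_limiting`` (methane factor held at
    saturation).  Steps that would drive a concentration negative are
    recursively halved before a final clamp at zero.
    """
    if not duration_d > 0:
        raise ValueError("duration_d must be > 0")
    if not dt_d > 0:
        raise ValueError("dt_d must be > 0")
    if dt_d >= duration_d:
        raise ValueError("dt_d must be smaller than duration_d")
    if methane_mode not in ("closed_bottle", "non_limiting"):
        raise ValueError(f"unknown methane_mode {methane_mode!r}")
    if registry is None:
        registry = guild_reactions()
    rxns = [registry[g] for g in GUILD_ORDER]
    S = np.array(
        [[r.coefficient(sp) for r in rxns] for sp in _STATE_SPECIES]
    )
    imbalance = np.array([r.nitrogen_imbalance() for r in rxns])
    n2_coeffs = np.array([r.coefficient("N2") for r in rxns])
    nonlimiting = methane_mode == "non_limiting"

    def deriv(y: np.ndarray) -> np.ndarray:
        d = _derivative(y, params, S, imbalance, n2_coeffs, nonlimiting, not nonlimiting)
        if not np.all(np.isfinite(d)):
            raise RuntimeError(f"NaN in derivative; state = {y.tolist()}")
        return d

    y = np.array(
        [float(initial.get(sp, 0.0)) for sp in _STATE_SPECIES] + [0.0, 0.0]
    )
    if np.any(y < 0):
        raise ValueError("initial concentrations must be >= 0")

    n_steps = int(round(duration_d / dt_d))
    times = np.linspace(0.0, n_steps * dt_d, n_steps + 1)
    traj = np.empty((n_steps + 1, y.size))
    traj[0] = y
    clamp_count = 0

    def advance(y0: np.ndarray, dt: float, depth: int) -> np.ndarray:
        y1 = _rk4_step(y0, dt, deriv)
        if np.min(y1[:4]) < -1e-9 and depth < 22:
            half = advance(y0, dt / 2.0, depth + 1)
            return advance(half, dt / 2.0, depth + 1)
        return y1

    for i in range(n_steps):
        y = advance(y, dt_d, 0)
        neg = y[:4] < 0
        if np.any(neg):
            clamp_count += int(np.sum(neg))
            y[:4] = np.maximum(y[:4], 0.0)
        traj[i + 1] = y

    return SimState(
        times=times,
        concentrations={sp: traj[:, i] for i, sp in enumerate(_STATE_SPECIES)},
        n2_n=traj[:, 4],
        assimilated_n=traj[:, 5],
        clamp_count=clamp_count,
    )


@dataclass
class SteadyState:
    """Converged continuous-operation solution."""

    effluent: Dict[str, float]
    extents: Dict[str, float]
    partition: FluxPartition
    efficiency_percent: float
    residual: np.ndarray
    config: ReactorConfig = field(repr=False, default=None)


def solve_steady_state(
    config: ReactorConfig,
    params: KineticParams,
    methane: str | float = "non_limiting",
    registry: Optional[Mapping[str, Reaction]] = None,
    tol: float = 1e-9,
    max_nfev: int = 2000,
) -> SteadyState:
    """Solve (influent - effluent)/HRT + S v(effluent) = 0 for the effluent.

    ``methane`` is ``"non_limiting"`` (methane factor at saturation) or a
    fixed dissolved concentration in mmol/L (membrane-fed).  The converged
    effluent is reported with its total-nitrogen removal efficiency and the
    flux partition implied by the effluent balance.
    """
    if registry is None:
        registry = guild_reactions()
    rxns = [registry[g] for g in GUILD_ORDER]
    S_n = np.array(
        [[r.coefficient(sp) for r in rxns] for sp in PARTITION_SPECIES]
    )
    nonlimiting = methane == "non_limiting"
    ch4_conc = None if nonlimiting else float(methane)
    if ch4_conc is not None and ch4_conc < 0:
        raise ValueError("fixed methane concentration must be >= 0")

    influent = np.array([config.influent.get(sp, 0.0) for sp in PARTITION_SPECIES])

    def extents_at(c: np.ndarray) -> np.ndarray:
        conc = {sp: c[i] for i, sp in enumerate(PARTITION_SPECIES)}
        if ch4_conc is not None:
            conc["CH4"] = ch4_conc
        return _guild_extents(conc, params, nonlimiting)

    def balance(c: np.ndarray) -> np.ndarray:
        return (influent - c) / config.hrt_days + N_MOLAR_MASS * (S_n @ extents_at(c))

    best = None
    for x0 in (np.maximum(influent, 1e-3) * 0.01, influent.copy() + 1e-6):
        sol = least_squares(
            balance,
            x0,
            bounds=(np.zeros(3), np.full(3, np.inf)),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=max_nfev,
        )
        res_norm = float(np.linalg.norm(balance(sol.x)))
        if best is None or res_norm < best[1]:
            best = (sol.x, res_norm)
        if res_norm <= tol:
            break
    effluent_vec, res_norm = best
    residual = balance(effluent_vec)
    if res_norm > 1e-8 * max(1.0, float(np.linalg.norm(influent / config.hrt_days))):
        raise RuntimeError(
            f"steady-state solver did not converge; last residual {residual}"
        )

    effluent = {sp: float(v) for sp, v in zip(PARTITION_SPECIES, effluent_vec)}
    extents = {g: float(v) for g, v in zip(GUILD_ORDER, extents_at(effluent_vec))}
    rates = RateVector(
        {
            sp: (effluent[sp] - config.influent.get(sp, 0.0)) / config.hrt_days
            for sp in PARTITION_SPECIES
        },
        "mg_N/L/d",
    )
    partition = partition_fluxes(rates, reactions=registry, solver="nnls")
    eff = removal_efficiency(float(influent.sum()), float(effluent_vec.sum()))
    return SteadyState(
        effluent=effluent,
        extents=extents,
        partition=partition,
        efficiency_percent=eff,
        residual=residual,
        config=config,
    )
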