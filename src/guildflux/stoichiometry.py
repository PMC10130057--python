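"""Reaction registry, stoichiometric matrices and guild flux partitioning.

The three microbial guilds driving nitrogen turnover in coupled
anammox / n-DAMO reactors are represented as molar reactions:

* anammox        — NH4+ + 1.32 NO2-      -> 1.02 N2 + 0.26 NO3- + 2.03 H2O
* n-DAMO bacteria — 3 CH4 + 8 NO2- + 8 H+ -> 3 CO2 + 4 N2 + 10 H2O
* n-DAMO archaea  — CH4 + 4 NO3-          -> CO2 + 4 NO2- + 2 H2O

Measured net conversion rates of NH4+, NO2- and NO3- are partitioned into
per-guild reaction extents by solving the stoichiometric linear system; the
methane- and dinitrogen-producing columns are deliberately left out of the
solve so that methane consumption is an out-of-sample prediction.

Sign convention: coefficients and rates are negative for consumption and
positive for production.  Reporting rates (``r_AN``, ``r_DB``, ``r_DA``) are
positive removal rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

__all__ = [
    "N_MOLAR_MASS",
    "CH4_MOLAR_MASS",
    "DEFAULT_N_ATOMS",
    "DEFAULT_N_SLACK",
    "Reaction",
    "RateVector",
    "ReactorConfig",
    "MeasurementSeries",
    "FluxPartition",
    "NegativeExtentWarning",
    "guild_reactions",
    "build_stoich_matrix",
    "net_rates_from_series",
    "partition_fluxes",
    "predict_methane",
    "predict_n2",
    "removal_efficiency",
    "anammox_max_efficiency",
]

#: Molar mass of nitrogen used for mg N <-> mmol conversions (g/mol).
N_MOLAR_MASS = 14.0067
#: Molar mass of methane (g/mol).
CH4_MOLAR_MASS = 16.043

#: Nitrogen atoms per formula unit for the species handled here.
DEFAULT_N_ATOMS: Dict[str, int] = {
    "NH4": 1,
    "NO2": 1,
    "NO3": 1,
    "N2": 2,
    "CH4": 0,
    "CO2": 0,
    "H2O": 0,
    "H": 0,
}

#: Default tolerated nitrogen-atom imbalance (mol N per unit extent).  The
#: published anammox equation is ~0.02 mol N short because the biomass term
#: is omitted; the registry must accept it as printed.
DEFAULT_N_SLACK = 0.05

ANAMMOX_ID = "anammox"
NDAMO_BACTERIA_ID = "ndamo_bacteria"
NDAMO_ARCHAEA_ID = "ndamo_archaea"
GUILD_ORDER: Tuple[str, str, str] = (ANAMMOX_ID, NDAMO_BACTERIA_ID, NDAMO_ARCHAEA_ID)

#: Species over which the guild partition is solved.
PARTITION_SPECIES: Tuple[str, str, str] = ("NH4", "NO2", "NO3")

MG_N_UNITS = "mg_N/L/d"
MMOL_UNITS = "mmol/L/d"


class NegativeExtentWarning(UserWarning):
    """Exact solve produced a negative reaction extent."""


@dataclass(frozen=True)
class Reaction:
    """A named chemical transformation with signed molar coefficients.

    Parameters
    ----------
    id : str
        Short machine name, e.g. ``"anammox"``.
    label : str
        Human-readable name.
    coefficients : mapping
        Chemical species symbol -> signed molar coefficient (negative means
        consumed, positive produced).
    n_atoms : mapping
        Species -> nitrogen atoms per formula unit.  Defaults cover the
        species used by the built-in registry.
    """

    id: str
    label: str
    coefficients: Mapping[str, float]
    n_atoms: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_ATOMS))

    def __post_init__(self) -> None:
        coeffs = dict(self.coefficients)
        if not coeffs:
            raise ValueError(f"reaction {self.id!r}: empty coefficient map")
        if not any(c < 0 for c in coeffs.values()):
            raise ValueError(f"reaction {self.id!r}: no consumed species")
        if not any(c > 0 for c in coeffs.values()):
            raise ValueError(f"reaction {self.id!r}: no produced species")
        for sp in coeffs:
            if sp not in self.n_atoms:
                raise ValueError(
                    f"reaction {self.id!r}: species {sp!r} missing from n_atoms"
                )
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "n_atoms", dict(self.n_atoms))

    def coefficient(self, species: str) -> float:
        """Signed coefficient of ``species`` (0 if absent)."""
        return float(self.coefficients.get(species, 0.0))

    def nitrogen_imbalance(self) -> float:
        """Net nitrogen atoms created per unit extent (signed)."""
        return float(
            sum(c * self.n_atoms[sp] for sp, c in self.coefficients.items())
        )

    def check_nitrogen_balance(self, slack: float = DEFAULT_N_SLACK) -> None:
        """Raise ``ValueError`` if |N imbalance| exceeds ``slack``."""
        imb = self.nitrogen_imbalance()
        if abs(imb) > slack:
            raise ValueError(
                f"reaction {self.id!r}: nitrogen imbalance {imb:+.4f} mol N "
                f"per unit extent exceeds slack {slack}"
            )


def guild_reactions(n_slack: float = DEFAULT_N_SLACK) -> Dict[str, Reaction]:
    """Return the built-in three-guild reaction registry.

    ``n_slack`` is the tolerated nitrogen-atom imbalance; the default accepts
    the anammox equation as printed (0.02 mol N short), while ``n_slack=0``
    rejects it.
    """
    registry = {
        ANAMMOX_ID: Reaction(
            ANAMMOX_ID,
            "anaerobic ammonium oxidation",
            {"NH4": -1.0, "NO2": -1.32, "N2": 1.02, "NO3": 0.26, "H2O": 2.03},
        ),
        NDAMO_BACTERIA_ID: Reaction(
            NDAMO_BACTERIA_ID,
            "nitrite-dependent anaerobic methane oxidation (bacteria)",
            {"CH4": -3.0, "NO2": -8.0, "H": -8.0, "CO2": 3.0, "N2": 4.0, "H2O": 10.0},
        ),
        NDAMO_ARCHAEA_ID: Reaction(
            NDAMO_ARCHAEA_ID,
            "nitrate-dependent anaerobic methane oxidation (archaea)",
            {"CH4": -1.0, "NO3": -4.0, "CO2": 1.0, "NO2": 4.0, "H2O": 2.0},
        ),
    }
    for rxn in registry.values():
        rxn.check_nitrogen_balance(n_slack)
    return registry


def build_stoich_matrix(
    reactions: Sequence[Reaction], species_order: Sequence[str]
) -> np.ndarray:
    """Assemble the (species x reactions) signed coefficient matrix.

    Entry ``(i, j)`` is the coefficient of ``species_order[i]`` in
    ``reactions[j]``; species absent from a reaction contribute 0.
    Raises ``ValueError`` on duplicate species symbols.
    """
    seen = set()
    for sp in species_order:
        if sp in seen:
            raise ValueError(f"duplicate species symbol {sp!r} in species_order")
        seen.add(sp)
    mat = np.zeros((len(species_order), len(reactions)))
    for j, rxn in enumerate(reactions):
        for i, sp in enumerate(species_order):
            mat[i, j] = rxn.coefficient(sp)
    return mat


@dataclass(frozen=True)
class RateVector:
    """Net volumetric conversion rates, consumption negative.

    ``basis_units`` is either ``"mg_N/L/d"`` (per-N-atom mass basis, only
    meaningful for nitrogenous species) or ``"mmol/L/d"`` (molar basis).
    """

    rates: Mapping[str, float]
    basis_units: str = MMOL_UNITS

    def __post_init__(self) -> None:
        rates = {sp: float(v) for sp, v in self.rates.items()}
        for sp, v in rates.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite rate for species {sp!r}")
        missing = set(PARTITION_SPECIES) - set(rates)
        if missing:
            raise ValueError(f"rate vector missing species: {sorted(missing)}")
        if self.basis_units not in (MG_N_UNITS, MMOL_UNITS):
            raise ValueError(f"unknown basis_units {self.basis_units!r}")
        object.__setattr__(self, "rates", rates)

    def to_mmol(self, n_atoms: Mapping[str, int] = DEFAULT_N_ATOMS) -> "RateVector":
        """Convert to mmol/L/d.  mg-N rates divide by 14.0067 x N-atoms."""
        if self.basis_units == MMOL_UNITS:
            return self
        out = {}
        for sp, v in self.rates.items():
            n = n_atoms.get(sp, 0)
            if n == 0:
                raise ValueError(
                    f"cannot convert {sp!r} from mg N basis: species carries no N"
                )
            out[sp] = v / (N_MOLAR_MASS * n)
        return RateVector(out, MMOL_UNITS)

    def to_mg_n(self, n_atoms: Mapping[str, int] = DEFAULT_N_ATOMS) -> "RateVector":
        """Convert nitrogenous-species rates to mg N/L/d."""
        if self.basis_units == MG_N_UNITS:
            return self
        out = {}
        for sp, v in self.rates.items():
            n = n_atoms.get(sp, 0)
            if n == 0:
                raise ValueError(f"cannot express {sp!r} in mg N: no nitrogen atoms")
            out[sp] = v * N_MOLAR_MASS * n
        return RateVector(out, MG_N_UNITS)


@dataclass(frozen=True)
class ReactorConfig:
    """Continuous-reactor operating parameters.

    Influent concentrations are mg N/L for nitrogenous species and mmol/L
    for methane.
    """

    hrt_days: float
    influent: Mapping[str, float]
    volume_l: float = 1.0

    def __post_init__(self) -> None:
        if not self.hrt_days > 0:
            raise ValueError("hrt_days must be > 0")
        if not self.volume_l > 0:
            raise ValueError("volume_l must be > 0")
        influent = {sp: float(v) for sp, v in self.influent.items()}
        for sp, v in influent.items():
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"influent concentration for {sp!r} must be >= 0")
        object.__setattr__(self, "influent", influent)


@dataclass
class MeasurementSeries:
    """Tidy time-stamped concentration profiles.

    ``data`` columns: ``time_d``, ``species``, ``value``, ``unit``.
    """

    data: pd.DataFrame

    REQUIRED_COLUMNS = ("time_d", "species", "value", "unit")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"measurement series missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    def species(self) -> List[str]:
        return sorted(self.data["species"].unique())

    def series_for(self, species: str) -> Tuple[np.ndarray, np.ndarray]:
        """(times, values) for one species, in stored row order."""
        sub = self.data[self.data["species"] == species]
        if sub.empty:
            raise ValueError(f"series has no rows for species {species!r}")
        return sub["time_d"].to_numpy(float), sub["value"].to_numpy(float)


@dataclass
class FluxPartition:
    """Guild extents plus derived reporting rates and predictions.

    Extents are mmol reaction-units/L/d in guild order (anammox, n-DAMO
    bacteria, n-DAMO archaea).  ``predicted_n2`` is mmol N2/L/d (molecular
    dinitrogen, not N atoms).
    """

    extents: Dict[str, float]
    r_AN: float
    r_DB: float
    r_DA: float
    predicted_ch4: float
    predicted_n2: float
    residual: Dict[str, float]
    solver: str
    warnings: List[str] = field(default_factory=list)
    basis_units: str = MMOL_UNITS

    @property
    def extent_vector(self) -> np.ndarray:
        return np.array([self.extents[g] for g in GUILD_ORDER])


def net_rates_from_series(
    series: MeasurementSeries,
    config: ReactorConfig,
    mode: str = "steady_state",
    species: Optional[Sequence[str]] = None,
) -> RateVector:
    """Net volumetric conversion rates (mg N/L/d) from a concentration series.

    ``steady_state`` treats the series as effluent samples of a continuous
    reactor: rate = (mean effluent - influent) / HRT, so full removal of a
    100 mg N/L feed at HRT 1 d gives -100 mg N/L/d.  ``dynamic`` fits a
    least-squares slope to a batch trajectory per species.
    """
    if mode not in ("steady_state", "dynamic"):
        raise ValueError(f"unknown mode {mode!r}")
    if species is None:
        species = PARTITION_SPECIES
    rates: Dict[str, float] = {}
    for sp in species:
        times, values = series.series_for(sp)  # raises on missing column
        if mode == "steady_state":
            influent = config.influent.get(sp, 0.0)
            rates[sp] = (float(np.mean(values)) - influent) / config.hrt_days
        else:
            if len(times) < 2:
                raise ValueError(f"dynamic mode needs >=2 time points for {sp!r}")
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"non-monotone timestamps for species {sp!r}")
            slope = np.polyfit(times, values, 1)[0]
            rates[sp] = float(slope)
    return RateVector(rates, MG_N_UNITS)


def partition_fluxes(
    rates: RateVector,
    reactions: Optional[Mapping[str, Reaction]] = None,
    solver: str = "exact",
) -> FluxPartition:
    """Partition measured net N rates into per-guild reaction extents.

    Solves ``S e = r`` restricted to NH4/NO2/NO3 over the three guild
    reactions.  ``solver="exact"`` uses LU on the 3x3 system (a negative
    extent is recorded as a warning, not raised); ``solver="nnls"``
    minimises ||S e - r||_2 subject to e >= 0.  CH4 and N2 columns are not
    part of the solve — they are returned as out-of-sample predictions.
    """
    if solver not in ("exact", "nnls"):
        raise ValueError(f"unknown solver {solver!r}")
    if reactions is None:
        reactions = guild_reactions()
    missing = [g for g in GUILD_ORDER if g not in reactions]
    if missing:
        raise ValueError(f"reaction registry missing guilds: {missing}")
    rxns = [reactions[g] for g in GUILD_ORDER]

    r_mmol = rates.to_mmol()
    r = np.array([r_mmol.rates[sp] for sp in PARTITION_SPECIES])
    S = build_stoich_matrix(rxns, PARTITION_SPECIES)

    notes: List[str] = []
    if solver == "exact":
        if np.linalg.cond(S) > 1e12:
            raise ValueError(
                "stoichiometric system is singular under the exact solver; "
                "use solver='nnls'"
            )
        e = np.linalg.solve(S, r)
        if np.any(e < -1e-12):
            msg = (
                "exact solve produced negative extent(s): "
                + ", ".join(
                    f"{g}={v:.4g}" for g, v in zip(GUILD_ORDER, e) if v < -1e-12
                )
            )
            notes.append(msg)
            warnings.warn(msg, NegativeExtentWarning, stacklevel=2)
    else:
        e, _ = _scipy_nnls(S, r)

    residual_vec = S @ e - r
    residual = {sp: float(v) for sp, v in zip(PARTITION_SPECIES, residual_vec)}
    extents = {g: float(v) for g, v in zip(GUILD_ORDER, e)}

    an, db, da = rxns
    r_an = abs(an.coefficient("NO2")) * extents[ANAMMOX_ID]
    r_db = abs(db.coefficient("NO2")) * extents[NDAMO_BACTERIA_ID]
    r_da = abs(da.coefficient("NO3")) * extents[NDAMO_ARCHAEA_ID]
    ch4 = (
        abs(db.coefficient("CH4")) * extents[NDAMO_BACTERIA_ID]
        + abs(da.coefficient("CH4")) * extents[NDAMO_ARCHAEA_ID]
    )
    n2 = (
        an.coefficient("N2") * extents[ANAMMOX_ID]
        + db.coefficient("N2") * extents[NDAMO_BACTERIA_ID]
    )
    return FluxPartition(
        extents=extents,
        r_AN=r_an,
        r_DB=r_db,
        r_DA=r_da,
        predicted_ch4=ch4,
        predicted_n2=n2,
        residual=residual,
        solver=solver,
        warnings=notes,
    )


def predict_methane(partition: FluxPartition) -> float:
    """Total predicted methane consumption rate (mmol CH4/L/d)."""
    return partition.predicted_ch4


def predict_n2(partition: FluxPartition) -> float:
    """Total predicted dinitrogen production as N atoms (mmol N/L/d)."""
    return 2.0 * partition.predicted_n2


def removal_efficiency(influent_tn: float, effluent_tn: float) -> float:
    """Total-nitrogen removal efficiency in percent."""
    if influent_tn <= 0:
        raise ValueError("influent total nitrogen must be > 0")
    if effluent_tn < 0:
        raise ValueError("effluent total nitrogen must be >= 0")
    return 100.0 * (influent_tn - effluent_tn) / influent_tn


def anammox_max_efficiency(reaction: Reaction) -> float:
    """Maximum TN removal (%) achievable by an anammox-type reaction alone.

    N-atom-weighted: 100 x (N consumed - N released as nitrate) / N consumed.
    Invariant under uniform scaling of the coefficients.
    """
    if not (
        reaction.coefficient("NH4") < 0
        and reaction.coefficient("NO2") < 0
        and reaction.coefficient("NO3") >= 0
    ):
        raise ValueError(
            "reaction must consume NH4 and NO2 and produce (or omit) NO3"
        )
    consumed = sum(
        -c * reaction.n_atoms[sp]
        for sp, c in reaction.coefficients.items()
        if c < 0
    )
    nitrate_out = reaction.coefficient("NO3") * reaction.n_atoms["NO3"]
    return 100.0 * (consumed - nitrate_out) / consumed
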