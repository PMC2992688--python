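"""Reaction rate laws and ODE integration for the LOX/HPL network.

The state vector tracks 11 species (nmol/mL): free linoleic acid (LA),
the eight hydroperoxide isomers, n-hexanal and its cleavage co-product
12-oxo-(Z)-9-dodecenoic acid.  Every reaction is irreversible
Michaelis-Menten:

* each LOX isozyme present in the genotype consumes LA at
  v_i = Vmax_i * LA / (Km_i + LA) and distributes the product over the
  eight isomers with its fixed branching fractions (additive
  competition for the shared LA pool);
* HPL cleaves 13HOD-S(Z,E) and 13HOD-R(Z,E) through independent
  Michaelis-Menten channels, producing n-hexanal and the oxo-acid 1:1.

The six HPL-inactive isomers are terminal pools.  Oxygen and enzyme
levels are not state variables (assumed non-limiting), and there is no
feedback or product inhibition, so LA is strictly non-increasing and
n-hexanal strictly non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import (
    HPL_SUBSTRATES,
    ISOMERS,
    LOX_ISOZYMES,
    ModelConfig,
)

__all__ = [
    "SPECIES",
    "SolverError",
    "mm_rate",
    "rhs",
    "initial_state",
    "TimeCourse",
    "simulate",
]

#: Ordered state-vector layout (and CSV column order after ``time_min``).
SPECIES: tuple[str, ...] = ("LA", *ISOMERS, "hexanal", "oxoacid")

_I_LA = 0
_I_HEX = SPECIES.index("hexanal")
_I_OXO = SPECIES.index("oxoacid")
_I_HPL = tuple(SPECIES.index(s) for s in HPL_SUBSTRATES)


class SolverError(RuntimeError):
    """ODE integration failed; carries the solver's diagnostic message."""


def mm_rate(vmax: float, km: float, s: float) -> float:
    """Irreversible Michaelis-Menten rate ``vmax * s / (km + s)``.

    Parameters are the maximal rate, the Michaelis constant (km > 0)
    and the substrate concentration (s >= 0), all in consistent units.
    """
    if km <= 0:
        raise ValueError(f"km must be > 0, got {km}")
    if s < 0:
        raise ValueError(f"substrate concentration must be >= 0, got {s}")
    return vmax * s / (km + s)


@dataclass(frozen=True)
class _CompiledRates:
    """Config flattened into arrays for fast RHS evaluation.

    An isozyme absent from the genotype enters with Vmax = 0, which is
    exactly equivalent to removing its reactions.
    """

    lox_vmax: np.ndarray        # (3,)
    lox_km: np.ndarray          # (3,)
    frac: np.ndarray            # (3, 8) rows renormalized to sum to 1
    hpl_vmax: np.ndarray        # (2,) zeroed when HPL is disabled
    hpl_km: np.ndarray          # (2,)

    @classmethod
    def from_config(cls, config: ModelConfig) -> "_CompiledRates":
        lox_vmax = np.array(
            [
                config.kinetics[iso].vmax_scaled if config.genotype.has(iso) else 0.0
                for iso in LOX_ISOZYMES
            ]
        )
        lox_km = np.array([config.kinetics[iso].km for iso in LOX_ISOZYMES])
        frac = np.array(
            [[config.ratios.normalized(iso)[isomer] for isomer in ISOMERS]
             for iso in LOX_ISOZYMES]
        )
        if config.hpl_enabled:
            hpl_vmax = np.array(
                [config.kinetics["HPL_SZE"].vmax_scaled,
                 config.kinetics["HPL_RZE"].vmax_scaled]
            )
        else:
            hpl_vmax = np.zeros(2)
        hpl_km = np.array(
            [config.kinetics["HPL_SZE"].km, config.kinetics["HPL_RZE"].km]
        )
        return cls(lox_vmax, lox_km, frac, hpl_vmax, hpl_km)


def _rhs_arrays(y: np.ndarray, c: _CompiledRates) -> np.ndarray:
    la = max(y[_I_LA], 0.0)  # guard against solver under-shoot
    v_lox = c.lox_vmax * la / (c.lox_km + la)
    dy = np.zeros_like(y)
    dy[_I_LA] = -v_lox.sum()
    dy[1 : 1 + len(ISOMERS)] = v_lox @ c.frac
    h = np.maximum(y[list(_I_HPL)], 0.0)
    v_hpl = c.hpl_vmax * h / (c.hpl_km + h)
    for idx, v in zip(_I_HPL, v_hpl):
        dy[idx] -= v
    dy[_I_HEX] = v_hpl.sum()
    dy[_I_OXO] = v_hpl.sum()
    return dy


def rhs(state, config: ModelConfig) -> np.ndarray:
    """Time derivative of the 11-species state vector.

    ``state`` is an array-like in :data:`SPECIES` order.  Absent
    isozymes and a disabled HPL contribute zero flux.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (len(SPECIES),):
        raise ValueError(f"state must have shape ({len(SPECIES)},)")
    return _rhs_arrays(y, _CompiledRates.from_config(config))


def initial_state(config: ModelConfig) -> np.ndarray:
    """All-zero state except the initial LA pool."""
    y0 = np.zeros(len(SPECIES))
    y0[_I_LA] = config.initial_la
    return y0


@dataclass(frozen=True)
class TimeCourse:
    """Concentration trajectories of all species on an output grid.

    ``time`` is in minutes, strictly increasing from 0; ``states`` has
    one row per grid point in :data:`SPECIES` order, nmol/mL.
    """

    time: np.ndarray
    states: np.ndarray
    config: ModelConfig

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, SPECIES.index(species)]

    @property
    def la(self) -> np.ndarray:
        return self["LA"]

    @property
    def hexanal(self) -> np.ndarray:
        return self["hexanal"]

    @property
    def oxoacid(self) -> np.ndarray:
        return self["oxoacid"]

    def hod_total(self) -> np.ndarray:
        return self.states[:, 1 : 1 + len(ISOMERS)].sum(axis=1)

    def mass_balance(self) -> np.ndarray:
        """LA + sum(HOD) + hexanal minus LA0 at each grid point.

        n-hexanal counts each cleavage event once; the oxo-acid is the
        co-product of the same event, not an extra sink.
        """
        return self.la + self.hod_total() + self.hexanal - self.config.initial_la

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time_min", self.time)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def simulate(config: ModelConfig) -> TimeCourse:
    """Integrate the network from t = 0 to ``config.duration``.

    Uses LSODA (adaptive, stiffness-switching) at the configured
    tolerances and reports the solution on an even grid of
    ``config.n_points`` points.  Raises :class:`SolverError` on solver
    failure, and if the solution leaves the physical region by more
    than tolerance.
    """
    compiled = _CompiledRates.from_config(config)
    t_eval = np.linspace(0.0, config.duration, config.n_points)
    sol = solve_ivp(
        lambda t, y: _rhs_arrays(y, compiled),
        (0.0, config.duration),
        initial_state(config),
        method="LSODA",
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise SolverError(sol.message)
    states = sol.y.T
    # non-negativity asserted post hoc (not enforced by projection)
    floor = -(config.atol * 1e3 + config.rtol * config.initial_la)
    if states.min() < floor:
        raise SolverError(
            f"negative concentration {states.min():.3e} beyond tolerance"
        )
    return TimeCourse(time=t_eval, states=states, config=config)
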