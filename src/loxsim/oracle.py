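"""Closed-form solution of the pathway in the sub-saturated limit.

At the published parameters the free-LA pool (67 nmol/mL) is ~4 orders
of magnitude below every Michaelis constant, so each Michaelis-Menten
rate is effectively first order: v = (Vmax/Km) * s.  The network then
becomes a linear cascade with an exact algebraic solution, which serves
as an independent oracle for the ODE integrator (it shares no code with
it) and as the source of hand-checkable reference values.

With K = sum_i k_i (k_i = Vmax_i/Km_i over the active isozymes),
F_j = sum_i k_i f_ij / K the lumped branching fraction into isomer j,
and kappa_j = Vmax_HPL,j / Km_HPL:

* LA(t)     = LA0 * exp(-K t)
* terminal isomer:  hod_j(t) = LA0 * F_j * (1 - exp(-K t))
* HPL-active isomer (two-exponential cascade):
    hod_j(t)     = LA0 * F_j * K * (exp(-K t) - exp(-kappa_j t)) / (kappa_j - K)
    hexanal_j(t) = LA0 * F_j * [1 - (kappa_j e^{-K t} - K e^{-kappa_j t})
                                    / (kappa_j - K)]
* hexanal = oxoacid = sum_j hexanal_j over the two active isomers.

The degenerate case kappa_j ~= K switches to the analytic limit
hod_j = LA0 F_j K t e^{-Kt}, hexanal_j = LA0 F_j [1 - (1 + Kt) e^{-Kt}].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    HPL_SUBSTRATES,
    ISOMERS,
    LOX_ISOZYMES,
    Genotype,
    ModelConfig,
)
from .pathway import SPECIES

__all__ = ["LinearizedModel", "closed_form", "relative_table"]

#: Validity bound: LA0 / min(active Km) must stay below this.
_SUBSAT_BOUND = 1e-2

#: Relative threshold below which kappa_j and K are treated as equal.
_DEGENERATE_TOL = 1e-8


@dataclass(frozen=True)
class LinearizedModel:
    """First-order rate constants of the linearized cascade."""

    k: dict[str, float]          # per active LOX isozyme, 1/min
    kappa: dict[str, float]      # per HPL-active isomer, 1/min
    frac: dict[str, dict[str, float]]  # normalized branching rows
    initial_la: float
    saturation_bound: float      # LA0 / min(Km) actually realised

    @classmethod
    def from_config(cls, config: ModelConfig) -> "LinearizedModel":
        active = [iso for iso in LOX_ISOZYMES if config.genotype.has(iso)]
        kms = [config.kinetics[iso].km for iso in active]
        if config.hpl_enabled:
            kms += [config.kinetics["HPL_SZE"].km, config.kinetics["HPL_RZE"].km]
        bound = config.initial_la / min(kms) if kms else 0.0
        if bound >= _SUBSAT_BOUND:
            raise ValueError(
                f"sub-saturated closed form invalid: LA0/min(Km) = {bound:.3g} "
                f">= {_SUBSAT_BOUND:g}"
            )
        k = {
            iso: config.kinetics[iso].vmax_scaled / config.kinetics[iso].km
            for iso in active
        }
        kappa = {}
        if config.hpl_enabled:
            kappa = {
                "13HOD_SZE": config.kinetics["HPL_SZE"].vmax_scaled
                / config.kinetics["HPL_SZE"].km,
                "13HOD_RZE": config.kinetics["HPL_RZE"].vmax_scaled
                / config.kinetics["HPL_RZE"].km,
            }
        frac = {iso: config.ratios.normalized(iso) for iso in active}
        return cls(k, kappa, frac, config.initial_la, bound)

    @property
    def total_rate(self) -> float:
        """K = sum of active first-order LOX rate constants, 1/min."""
        return sum(self.k.values())

    def lumped_fraction(self, isomer: str) -> float:
        """F_j: branching into ``isomer`` lumped over active isozymes."""
        K = self.total_rate
        if K == 0.0:
            return 0.0
        return sum(self.k[iso] * self.frac[iso][isomer] for iso in self.k) / K


def _cascade_product(K: float, kappa: float, t: np.ndarray) -> np.ndarray:
    """Fraction of an A->B->C cascade arrived in C at time t (A0 = 1)."""
    if abs(kappa - K) <= _DEGENERATE_TOL * max(K, kappa):
        return 1.0 - (1.0 + K * t) * np.exp(-K * t)
    return 1.0 - (kappa * np.exp(-K * t) - K * np.exp(-kappa * t)) / (kappa - K)


def _cascade_intermediate(K: float, kappa: float, t: np.ndarray) -> np.ndarray:
    """Fraction of the cascade sitting in B at time t (A0 = 1)."""
    if abs(kappa - K) <= _DEGENERATE_TOL * max(K, kappa):
        return K * t * np.exp(-K * t)
    return K * (np.exp(-K * t) - np.exp(-kappa * t)) / (kappa - K)


def closed_form(config: ModelConfig, t) -> dict[str, np.ndarray]:
    """Exact sub-saturated solution at time(s) ``t`` (minutes).

    Returns a mapping from species name to concentration (nmol/mL);
    values are scalars or arrays matching ``t``.  Raises ``ValueError``
    when the sub-saturation precondition LA0/min(Km) < 1e-2 fails.
    """
    lin = LinearizedModel.from_config(config)
    t = np.asarray(t, dtype=float)
    K = lin.total_rate
    la0 = lin.initial_la

    out: dict[str, np.ndarray] = {}
    if K == 0.0:
        out["LA"] = np.full_like(t, la0)
        for isomer in ISOMERS:
            out[isomer] = np.zeros_like(t)
        out["hexanal"] = np.zeros_like(t)
        out["oxoacid"] = np.zeros_like(t)
        return out

    decay = np.exp(-K * t)
    out["LA"] = la0 * decay
    hexanal = np.zeros_like(t)
    for isomer in ISOMERS:
        F = lin.lumped_fraction(isomer)
        if isomer in lin.kappa:  # HPL-active: two-step cascade
            kappa = lin.kappa[isomer]
            out[isomer] = la0 * F * _cascade_intermediate(K, kappa, t)
            hexanal = hexanal + la0 * F * _cascade_product(K, kappa, t)
        else:  # terminal pool
            out[isomer] = la0 * F * (1.0 - decay)
    out["hexanal"] = hexanal
    out["oxoacid"] = hexanal.copy()
    return out


def closed_form_vector(config: ModelConfig, t) -> np.ndarray:
    """:func:`closed_form` packed in :data:`~loxsim.pathway.SPECIES` order."""
    sol = closed_form(config, t)
    return np.stack([np.asarray(sol[s]) for s in SPECIES], axis=-1)


def relative_table(config: ModelConfig) -> dict[str, float]:
    """Genotype scan computed entirely from closed forms.

    Returns final-time n-hexanal per genotype relative to the wild
    type, independent of any ODE solver.  Layout mirrors
    :func:`loxsim.scenarios.genotype_scan`.
    """
    from .scenarios import GENOTYPE_NAMES  # local import avoids a cycle

    t = float(config.duration)
    peaks = {}
    for name in GENOTYPE_NAMES:
        sub = config.with_genotype(Genotype.from_name(name))
        peaks[name] = float(np.asarray(closed_form(sub, t)["hexanal"]))
    wt = peaks["L123"]
    return {name: peaks[name] / wt for name in GENOTYPE_NAMES}
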