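"""Canonical kinetic parameters for the soybean LOX/HPL pathway model.

The model describes what happens when soybean seeds are homogenized:
three lipoxygenase (LOX) isozymes (L-1, L-2, L-3) compete for the free
linoleic acid (LA) pool, oxygenating it into eight positional/stereo
hydroperoxide isomers in isozyme-specific fixed proportions.  Two of
those isomers, 13HOD-S(Z,E) and 13HOD-R(Z,E), are substrates of
hydroperoxide lyase (HPL), which cleaves them 1:1 into n-hexanal (the
"green/beany" off-flavor readout) and 12-oxo-(Z)-9-dodecenoic acid.

All quantities live in one consistent unit system:

* concentration: nmol/mL
* rate: nmol mL^-1 min^-1
* time: min

so the LOX Michaelis constant is 490 000 nmol/mL, the HPL constant
50 000 nmol/mL, and the initial free-LA pool 67 nmol/mL.  Maximal rates
are scaled to a reference homogenate protein content of 15 mg/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "LOX_ISOZYMES",
    "ISOMERS",
    "HPL_SUBSTRATES",
    "PROTEIN_REFERENCE",
    "ConfigError",
    "EnzymeKinetics",
    "ProductRatioTable",
    "Genotype",
    "WILD_TYPE",
    "ModelConfig",
    "default_parameters",
    "load_config",
    "loads_config",
    "dump_config",
    "kinetics_frame",
]

#: The three seed LOX isozymes, in conventional order.
LOX_ISOZYMES: tuple[str, ...] = ("L1", "L2", "L3")

#: The eight hydroperoxy-octadecadienoic acid (HOD) product isomers.
#: Position (13/9) x chirality (S/R) x double-bond geometry (Z,E / E,E).
ISOMERS: tuple[str, ...] = (
    "13HOD_SZE",
    "13HOD_RZE",
    "13HOD_SEE",
    "13HOD_REE",
    "9HOD_SZE",
    "9HOD_RZE",
    "9HOD_SEE",
    "9HOD_REE",
)

#: The only two isomers HPL accepts as substrate.
HPL_SUBSTRATES: tuple[str, ...] = ("13HOD_SZE", "13HOD_RZE")

#: Reference homogenate protein content, mg protein / mL.
PROTEIN_REFERENCE: float = 15.0

#: Enzyme identifiers recognised in kinetics records.
ENZYME_IDS: tuple[str, ...] = ("L1", "L2", "L3", "HPL_SZE", "HPL_RZE")


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass(frozen=True)
class EnzymeKinetics:
    """Michaelis-Menten constants for one enzyme-substrate pair.

    Parameters
    ----------
    enzyme_id
        One of ``L1``, ``L2``, ``L3`` (LOX isozymes acting on LA) or
        ``HPL_SZE`` / ``HPL_RZE`` (HPL acting on 13HOD-S(Z,E) or
        13HOD-R(Z,E)).
    km
        Michaelis constant, nmol/mL.
    vmax_specific
        Maximal rate per mg of homogenate protein,
        nmol mL^-1 min^-1 (mg protein)^-1.
    vmax_scaled
        Maximal rate at the reference protein content of 15 mg/mL,
        nmol mL^-1 min^-1.  Stored, not recomputed, because the source
        table prints independently rounded values (e.g. 38 500 for HPL
        on the R isomer where 2 600 x 15 = 39 000).
    """

    enzyme_id: str
    km: float
    vmax_specific: float
    vmax_scaled: float

    def __post_init__(self) -> None:
        if self.enzyme_id not in ENZYME_IDS:
            raise ConfigError(f"unknown enzyme_id {self.enzyme_id!r}")
        if not self.km > 0:
            raise ConfigError(f"kinetics.{self.enzyme_id}.km must be > 0")
        if self.vmax_specific < 0 or self.vmax_scaled < 0:
            raise ConfigError(f"kinetics.{self.enzyme_id}: Vmax must be >= 0")


@dataclass(frozen=True)
class ProductRatioTable:
    """Branching fractions of LOX product isomers per isozyme.

    ``fraction[isozyme][isomer]`` is the dimensionless share of the
    isozyme's total product going into that isomer, as printed
    (rows sum to 1.000-1.001 because the source percentages are rounded).
    Rate laws use :meth:`normalized`, which rescales each row to sum to
    exactly 1 so that mass is conserved to solver precision.
    """

    fraction: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for iso in LOX_ISOZYMES:
            row = self.fraction[iso]
            for isomer in ISOMERS:
                f = row[isomer]
                if not 0.0 <= f <= 1.0:
                    raise ConfigError(
                        f"ratios.{iso}.{isomer} must be in [0, 1], got {f}"
                    )
            total = sum(row[isomer] for isomer in ISOMERS)
            if abs(total - 1.0) > 0.005:
                raise ConfigError(
                    f"ratios.{iso} row sums to {total:.4f}, expected 1 +/- 0.005"
                )

    def row_sum(self, isozyme: str) -> float:
        return sum(self.fraction[isozyme][isomer] for isomer in ISOMERS)

    def normalized(self, isozyme: str) -> dict[str, float]:
        """Row rescaled to sum to exactly 1 (used by the rate equations)."""
        total = self.row_sum(isozyme)
        return {isomer: self.fraction[isozyme][isomer] / total for isomer in ISOMERS}


@dataclass(frozen=True)
class Genotype:
    """The set of LOX isozymes present in a simulated bean line.

    Named by the conventional subscript nomenclature: ``L123`` is the
    wild type, ``L13`` carries L-1 and L-3 only, ``L0`` carries none.
    """

    present: frozenset[str]

    def __post_init__(self) -> None:
        extra = self.present - set(LOX_ISOZYMES)
        if extra:
            raise ConfigError(f"unknown isozymes in genotype: {sorted(extra)}")

    @classmethod
    def from_name(cls, name: str) -> "Genotype":
        """Parse names like ``L123``, ``L2``, ``L0``."""
        if not name.startswith("L"):
            raise ConfigError(f"invalid genotype name {name!r}")
        digits = name[1:]
        if digits == "0":
            return cls(frozenset())
        if not digits or not all(d in "123" for d in digits) or len(set(digits)) != len(digits):
            raise ConfigError(f"invalid genotype name {name!r}")
        return cls(frozenset(f"L{d}" for d in sorted(digits)))

    @property
    def name(self) -> str:
        if not self.present:
            return "L0"
        return "L" + "".join(sorted(iso[1] for iso in self.present))

    def has(self, isozyme: str) -> bool:
        return isozyme in self.present

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


WILD_TYPE = Genotype(frozenset(LOX_ISOZYMES))


@dataclass(frozen=True)
class ModelConfig:
    """Complete, validated parameterization of one simulation.

    Defaults are the published estimates; every field can be overridden
    through :func:`load_config`.
    """

    initial_la: float = 67.0
    protein_reference: float = PROTEIN_REFERENCE
    duration: float = 100.0
    genotype: Genotype = WILD_TYPE
    kinetics: Mapping[str, EnzymeKinetics] = field(default_factory=dict)
    ratios: ProductRatioTable | None = None
    hpl_enabled: bool = True
    rtol: float = 1e-8
    atol: float = 1e-12
    n_points: int = 1001

    def __post_init__(self) -> None:
        if not self.initial_la > 0:
            raise ConfigError("initial_la must be > 0")
        if not self.duration > 0:
            raise ConfigError("duration must be > 0")
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")
        missing = set(ENZYME_IDS) - set(self.kinetics)
        if missing:
            raise ConfigError(f"kinetics missing records for {sorted(missing)}")
        if self.ratios is None:
            raise ConfigError("ratios table is required")

    # -- convenience constructors -------------------------------------

    def with_genotype(self, genotype: Genotype | str) -> "ModelConfig":
        if isinstance(genotype, str):
            genotype = Genotype.from_name(genotype)
        return replace(self, genotype=genotype)

    def with_km_scaled(self, isozyme: str, factor: float) -> "ModelConfig":
        """Return a copy with ``km`` of one LOX isozyme multiplied by ``factor``."""
        if isozyme not in LOX_ISOZYMES:
            raise ConfigError(f"unknown LOX isozyme {isozyme!r}")
        if not factor > 0:
            raise ConfigError("Km scale factor must be > 0")
        kin = dict(self.kinetics)
        kin[isozyme] = replace(kin[isozyme], km=kin[isozyme].km * factor)
        return replace(self, kinetics=kin)

    def with_vmax_scaled(self, isozyme: str, factor: float) -> "ModelConfig":
        if isozyme not in LOX_ISOZYMES:
            raise ConfigError(f"unknown LOX isozyme {isozyme!r}")
        if factor < 0:
            raise ConfigError("Vmax scale factor must be >= 0")
        kin = dict(self.kinetics)
        kin[isozyme] = replace(
            kin[isozyme],
            vmax_specific=kin[isozyme].vmax_specific * factor,
            vmax_scaled=kin[isozyme].vmax_scaled * factor,
        )
        return replace(self, kinetics=kin)


# ---------------------------------------------------------------------------
# Published defaults
# ---------------------------------------------------------------------------

# Michaelis-Menten estimates, nmol/mL and nmol mL^-1 min^-1.
# vmax_specific is per mg protein; vmax_scaled is at 15 mg protein/mL
# and kept as printed (HPL_RZE: 38 500, not 2 600 x 15).
_DEFAULT_KINETICS: tuple[EnzymeKinetics, ...] = (
    EnzymeKinetics("L1", km=490_000.0, vmax_specific=550.0, vmax_scaled=8_250.0),
    EnzymeKinetics("L2", km=490_000.0, vmax_specific=2_600.0, vmax_scaled=39_000.0),
    EnzymeKinetics("L3", km=490_000.0, vmax_specific=170.0, vmax_scaled=2_550.0),
    EnzymeKinetics("HPL_SZE", km=50_000.0, vmax_specific=19_000.0, vmax_scaled=285_000.0),
    EnzymeKinetics("HPL_RZE", km=50_000.0, vmax_specific=2_600.0, vmax_scaled=38_500.0),
)

# Product-isomer branching, percent of total product at pH 6.8,
# stored as fractions.  Columns: L-1, L-2, L-3.
_DEFAULT_RATIOS_PERCENT: dict[str, tuple[float, float, float]] = {
    "13HOD_SZE": (57.4, 75.1, 6.8),
    "13HOD_RZE": (14.4, 2.3, 5.9),
    "13HOD_SEE": (5.0, 2.5, 13.6),
    "13HOD_REE": (1.2, 1.5, 10.7),
    "9HOD_SZE": (16.2, 12.7, 21.8),
    "9HOD_RZE": (4.0, 2.6, 21.8),
    "9HOD_SEE": (1.4, 1.8, 9.8),
    "9HOD_REE": (0.4, 1.6, 9.7),
}


def _default_ratio_table() -> ProductRatioTable:
    fraction = {
        iso: {isomer: _DEFAULT_RATIOS_PERCENT[isomer][i] / 100.0 for isomer in ISOMERS}
        for i, iso in enumerate(LOX_ISOZYMES)
    }
    return ProductRatioTable(fraction)


def default_parameters() -> ModelConfig:
    """The published parameterization: wild type, LA0 = 67 nmol/mL, 100 min."""
    return ModelConfig(
        kinetics={k.enzyme_id: k for k in _DEFAULT_KINETICS},
        ratios=_default_ratio_table(),
    )


# ---------------------------------------------------------------------------
# Config file dialect: flat YAML mapping with dotted keys
# ---------------------------------------------------------------------------

_SCALAR_KEYS: dict[str, type] = {
    "initial_la": float,
    "protein_reference": float,
    "duration": float,
    "genotype": str,
    "hpl_enabled": bool,
    "rtol": float,
    "atol": float,
    "n_points": int,
}

_KINETIC_FIELDS = ("km", "vmax_specific", "vmax_scaled")


def dump_config(config: ModelConfig) -> str:
    """Serialize a config to the flat dotted-key dialect (YAML scalars)."""
    flat: dict[str, object] = {
        "initial_la": config.initial_la,
        "protein_reference": config.protein_reference,
        "duration": config.duration,
        "genotype": config.genotype.name,
        "hpl_enabled": config.hpl_enabled,
        "rtol": config.rtol,
        "atol": config.atol,
        "n_points": config.n_points,
    }
    for eid in ENZYME_IDS:
        k = config.kinetics[eid]
        for fname in _KINETIC_FIELDS:
            flat[f"kinetics.{eid}.{fname}"] = getattr(k, fname)
    for iso in LOX_ISOZYMES:
        for isomer in ISOMERS:
            flat[f"ratios.{iso}.{isomer}"] = config.ratios.fraction[iso][isomer]
    return yaml.safe_dump(flat, sort_keys=True, default_flow_style=False)


def loads_config(text: str) -> ModelConfig:
    """Parse the dotted-key dialect; keys absent fall back to defaults."""
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key/value mapping")

    base = default_parameters()
    scalars: dict[str, object] = {}
    kinetics = {eid: base.kinetics[eid] for eid in ENZYME_IDS}
    ratios_pct = {
        iso: dict(base.ratios.fraction[iso]) for iso in LOX_ISOZYMES
    }

    for key, value in raw.items():
        key = str(key)
        if key in _SCALAR_KEYS:
            scalars[key] = value
            continue
        parts = key.split(".")
        if len(parts) == 3 and parts[0] == "kinetics":
            _, eid, fname = parts
            if eid not in ENZYME_IDS or fname not in _KINETIC_FIELDS:
                raise ConfigError(f"unknown config key {key!r}")
            try:
                kinetics[eid] = replace(kinetics[eid], **{fname: float(value)})
            except ConfigError:
                raise
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad value for {key!r}: {value!r}") from exc
            continue
        if len(parts) == 3 and parts[0] == "ratios":
            _, iso, isomer = parts
            if iso not in LOX_ISOZYMES or isomer not in ISOMERS:
                raise ConfigError(f"unknown config key {key!r}")
            ratios_pct[iso][isomer] = float(value)
            continue
        raise ConfigError(f"unknown config key {key!r}")

    genotype = base.genotype
    if "genotype" in scalars:
        genotype = Genotype.from_name(str(scalars.pop("genotype")))

    kwargs: dict[str, object] = {}
    for key, caster in _SCALAR_KEYS.items():
        if key == "genotype":
            continue
        if key in scalars:
            try:
                kwargs[key] = caster(scalars[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad value for {key!r}: {scalars[key]!r}") from exc

    return ModelConfig(
        genotype=genotype,
        kinetics=kinetics,
        ratios=ProductRatioTable(ratios_pct),
        **kwargs,
    )


def load_config(path: str | Path) -> ModelConfig:
    """Load a config file, overriding defaults key by key."""
    path = Path(path)
    text = path.read_text()
    return loads_config(text)


def kinetics_frame(config: ModelConfig | None = None) -> pd.DataFrame:
    """Kinetic constants as a tidy table (nmol/mL, nmol mL^-1 min^-1)."""
    if config is None:
        config = default_parameters()
    rows = [
        {
            "enzyme_id": eid,
            "km": config.kinetics[eid].km,
            "vmax_specific": config.kinetics[eid].vmax_specific,
            "vmax_scaled": config.kinetics[eid].vmax_scaled,
        }
        for eid in ENZYME_IDS
    ]
    return pd.DataFrame(rows)
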