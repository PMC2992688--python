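"""Km sensitivity sweeps.

The LOX Michaelis constants are the weakest estimates in the model (the
L-2/L-3 values are borrowed from L-1), so the scans here multiply one
isozyme's Km by log-spaced factors while holding Vmax fixed and measure
the effect on peak n-hexanal — either for the wild type relative to the
default-parameter peak, or as a full per-genotype table relative to the
same-factor wild type.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .parameters import LOX_ISOZYMES, ConfigError, ModelConfig
from .scenarios import GENOTYPE_NAMES, genotype_scan, peak_hexanal
from .pathway import simulate

__all__ = ["DEFAULT_FACTORS", "km_sweep", "km_sweep_genotypes"]

#: Default multiplier grid: the reported scans are 10- and 1000-fold.
DEFAULT_FACTORS: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)


def _check_sweep_args(isozyme: str, factors: Sequence[float]) -> list[float]:
    if isozyme not in LOX_ISOZYMES:
        raise ConfigError(f"unknown LOX isozyme {isozyme!r}")
    factors = [float(f) for f in factors]
    if not factors:
        raise ConfigError("factor list is empty")
    for f in factors:
        if not f > 0:
            raise ConfigError(f"Km scale factor must be > 0, got {f}")
    return factors


def km_sweep(
    isozyme: str,
    factors: Iterable[float] = DEFAULT_FACTORS,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Wild-type peak n-hexanal versus Km scaling of one isozyme.

    For each factor, Km(isozyme) is multiplied (Vmax unchanged), the
    wild type is simulated over the default duration, and the peak is
    reported relative to the unscaled (factor = 1) peak.  Columns:
    ``isozyme, factor, peak_hexanal, relative_peak``.
    """
    from .parameters import default_parameters

    if config is None:
        config = default_parameters()
    factors = _check_sweep_args(isozyme, list(factors))
    base_peak = peak_hexanal(simulate(config.with_genotype("L123")))
    rows = []
    for f in factors:
        peak = peak_hexanal(
            simulate(config.with_km_scaled(isozyme, f).with_genotype("L123"))
        )
        rows.append(
            {
                "isozyme": isozyme,
                "factor": f,
                "peak_hexanal": peak,
                "relative_peak": peak / base_peak,
            }
        )
    return pd.DataFrame(rows)


def km_sweep_genotypes(
    isozyme: str,
    factors: Iterable[float] = DEFAULT_FACTORS,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Per-genotype scan at each Km scaling (long format).

    Each genotype's peak is normalized by the wild-type peak *at the
    same factor*, so the factor = 1 column reproduces the default scan.
    Columns: ``isozyme, factor, genotype, relative_peak``.
    """
    from .parameters import default_parameters

    if config is None:
        config = default_parameters()
    factors = _check_sweep_args(isozyme, list(factors))
    rows = []
    for f in factors:
        scan = genotype_scan(config.with_km_scaled(isozyme, f))
        for g in GENOTYPE_NAMES:
            rows.append(
                {
                    "isozyme": isozyme,
                    "factor": f,
                    "genotype": g,
                    "relative_peak": scan.relative[g],
                }
            )
    return pd.DataFrame(rows)
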