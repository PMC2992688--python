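"""Comparison of model output against published null-bean experiments.

Six independent studies measured n-hexanal generation in LOX-null
soybean lines relative to the wild type.  Their values are embedded
here (relative units, wild type = 1.00; missing measurements are NaN)
and summarized per genotype so model predictions can be flagged as
inside or outside the experimentally observed range.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .parameters import ConfigError
from .scenarios import GENOTYPE_NAMES, GenotypeScanResult

__all__ = ["literature_table", "experimental_range", "compare"]

_SOURCES = tuple(f"source_{i}" for i in range(1, 7))

# Relative n-hexanal per genotype from six published null-bean studies.
# NaN marks genotypes a study did not measure (distinct from zero).
_LITERATURE: dict[str, tuple[float, ...]] = {
    "L123": (1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
    "L1": (0.50, math.nan, 0.18, 0.49, 0.11, 0.06),
    "L2": (0.60, 1.73, 0.94, 2.51, 1.39, 2.00),
    "L3": (math.nan, math.nan, math.nan, 0.40, 0.10, 0.29),
    "L12": (0.89, 1.17, 0.59, math.nan, math.nan, math.nan),
    "L13": (0.63, 0.33, 0.38, math.nan, math.nan, math.nan),
    "L23": (0.73, 0.90, 0.97, math.nan, math.nan, math.nan),
    "L0": (math.nan, math.nan, math.nan, 0.22, 0.10, 0.06),
}


def literature_table() -> pd.DataFrame:
    """The embedded study values, one row per genotype, one column per study."""
    return pd.DataFrame.from_dict(
        _LITERATURE, orient="index", columns=list(_SOURCES)
    ).loc[list(GENOTYPE_NAMES)]


def experimental_range(genotype: str) -> tuple[float, float, float]:
    """(min, max, mean) over the non-missing study values for a genotype."""
    if genotype not in _LITERATURE:
        raise ConfigError(f"unknown genotype {genotype!r}")
    vals = [v for v in _LITERATURE[genotype] if not math.isnan(v)]
    if not vals:
        return (math.nan, math.nan, math.nan)
    return (min(vals), max(vals), sum(vals) / len(vals))


def compare(model: GenotypeScanResult) -> pd.DataFrame:
    """Model relative values side by side with the experimental ranges.

    The model column is rounded to the 2-decimal reporting precision
    before the inclusive interval check ``lit_min <= model <= lit_max``.
    Columns: ``genotype, model, lit_min, lit_max, lit_mean, in_range``.
    """
    rows = []
    for g in GENOTYPE_NAMES:
        lo, hi, mean = experimental_range(g)
        value = round(model.relative[g], 2)
        in_range = bool(lo <= value <= hi) if not math.isnan(lo) else False
        rows.append(
            {
                "genotype": g,
                "model": value,
                "lit_min": lo,
                "lit_max": hi,
                "lit_mean": mean,
                "in_range": in_range,
            }
        )
    return pd.DataFrame(rows)
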