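"""Genotype knockout scans and product-distribution analyses.

Soybean breeding lines exist that lack one or more of the three seed
LOX isozymes.  The model mimics them by zeroing the flux of the absent
isozymes (equivalently Vmax = 0), keeping everything else identical,
and asking how much n-hexanal each line generates relative to the wild
type over the standard 100-minute homogenate time course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ISOMERS, Genotype, ModelConfig
from .pathway import TimeCourse, simulate

__all__ = [
    "GENOTYPE_NAMES",
    "peak_hexanal",
    "GenotypeScanResult",
    "genotype_scan",
    "product_distribution",
]

#: All eight LOX genotypes, wild type first (reporting order).
GENOTYPE_NAMES: tuple[str, ...] = (
    "L123",
    "L1",
    "L2",
    "L3",
    "L12",
    "L13",
    "L23",
    "L0",
)


def peak_hexanal(tc: TimeCourse) -> float:
    """Maximum n-hexanal over the grid, nmol/mL.

    The model has no hexanal sink, so this equals the final value; it
    is kept as an explicit maximum so the operation stays correct if a
    downstream consumption step (e.g. ADH) is ever added.
    """
    return float(np.max(tc.hexanal))


@dataclass(frozen=True)
class GenotypeScanResult:
    """Peak n-hexanal per genotype, absolute and relative to wild type.

    ``peak`` and ``relative`` hold unrounded values; reporting rounds
    the relative column to 2 decimals (see :meth:`to_frame`).
    """

    peak: dict[str, float]
    relative: dict[str, float]
    config: ModelConfig

    def to_frame(self, round_relative: bool = True) -> pd.DataFrame:
        rel = {
            g: round(self.relative[g], 2) if round_relative else self.relative[g]
            for g in GENOTYPE_NAMES
        }
        return pd.DataFrame(
            {
                "genotype": list(GENOTYPE_NAMES),
                "peak_hexanal_nmol_per_mL": [self.peak[g] for g in GENOTYPE_NAMES],
                "relative_to_wildtype": [rel[g] for g in GENOTYPE_NAMES],
            }
        )


def genotype_scan(config: ModelConfig) -> GenotypeScanResult:
    """Simulate all 8 genotypes and report peak n-hexanal vs wild type.

    The ``genotype`` field of ``config`` is ignored; every genotype is
    run with otherwise identical parameters.  Relative values are
    computed from unrounded peaks.
    """
    peaks: dict[str, float] = {}
    for name in GENOTYPE_NAMES:
        tc = simulate(config.with_genotype(Genotype.from_name(name)))
        peaks[name] = peak_hexanal(tc)
    wt = peaks["L123"]
    relative = {name: peaks[name] / wt for name in GENOTYPE_NAMES}
    return GenotypeScanResult(peak=peaks, relative=relative, config=config)


def product_distribution(config: ModelConfig) -> pd.DataFrame:
    """Hydroperoxide spectrum at the end of the run, HPL switched off.

    With the cleavage step disabled the eight isomer pools record the
    raw positional/stereo specificity of each isozyme mixture.  Returns
    one row per genotype, one column per isomer, nmol/mL at
    ``config.duration``.
    """
    from dataclasses import replace

    base = replace(config, hpl_enabled=False)
    rows = []
    for name in GENOTYPE_NAMES:
        tc = simulate(base.with_genotype(Genotype.from_name(name)))
        rows.append({"genotype": name, **{iso: tc[iso][-1] for iso in ISOMERS}})
    return pd.DataFrame(rows).set_index("genotype")
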