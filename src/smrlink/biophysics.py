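"""Buoyant-mass / volume / density relationships and distribution summaries.

A suspended microchannel resonator (SMR) measures the *buoyant* mass of a
cell: the mass in excess of the fluid it displaces,

    m_b = V (rho - rho_fluid) = m (1 - rho_fluid / rho),

with m_b in picograms, the cell volume V in cubic micrometres, and the cell
density rho and fluid density rho_fluid in g/cm^3.  The identity
1 pg/um^3 == 1 g/cm^3 makes the units close under these formulas, so no
conversion factors appear anywhere.

The measurement buffer (PBS + 2% FBS + FITC-dextran) has density
1.005 g/cm^3; a cell with zero buoyant mass is neutrally buoyant at exactly
that density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Density of the measurement buffer in g/cm^3.
DEFAULT_FLUID_DENSITY = 1.005


@dataclass(frozen=True)
class DensityRecord:
    """One cell's mass/volume/density bookkeeping, mutually consistent."""

    buoyant_mass: float  # pg
    volume: float  # um^3
    fluid_density: float  # g/cm^3
    cell_density: float  # g/cm^3
    total_mass: float  # pg


@dataclass(frozen=True)
class DistributionSummary:
    """Median/IQR box-plot summary of a measurement vector."""

    n: int
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    #: quantile convention recorded with every summary
    quantile_method: str = "linear"


def cell_density(m_b, volume, fluid_density: float = DEFAULT_FLUID_DENSITY):
    """Cell density from buoyant mass and volume: rho = rho_fluid + m_b / V.

    Parameters are in pg, um^3 and g/cm^3; broadcasting over arrays is
    supported.  Raises ``ValueError`` for non-positive volume or fluid
    density.
    """
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ValueError("volume must be positive")
    if fluid_density <= 0:
        raise ValueError("fluid_density must be positive")
    rho = fluid_density + np.asarray(m_b, dtype=float) / volume
    return rho if rho.ndim else float(rho)


def total_mass(rho, volume):
    """Total (not buoyant) cell mass m = rho * V, in pg."""
    rho = np.asarray(rho, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if np.any(rho <= 0) or np.any(volume <= 0):
        raise ValueError("density and volume must be positive")
    m = rho * volume
    return m if m.ndim else float(m)


def buoyant_mass(m, rho, fluid_density: float = DEFAULT_FLUID_DENSITY):
    """Buoyant mass from total mass and density: m_b = m (1 - rho_fluid/rho)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    m_b = np.asarray(m, dtype=float) * (1.0 - fluid_density / rho)
    return m_b if m_b.ndim else float(m_b)


def density_record(
    m_b: float, volume: float, fluid_density: float = DEFAULT_FLUID_DENSITY
) -> DensityRecord:
    """Full, internally consistent record for one cell."""
    rho = cell_density(m_b, volume, fluid_density)
    m = total_mass(rho, volume)
    return DensityRecord(
        buoyant_mass=float(m_b),
        volume=float(volume),
        fluid_density=float(fluid_density),
        cell_density=rho,
        total_mass=m,
    )


def summarize(values) -> DistributionSummary:
    """Median and interquartile range of a measurement vector.

    Quartiles use linear interpolation between order statistics (numpy's
    default, the "type 7" convention); the convention is recorded in the
    result.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return DistributionSummary(n=values.size, median=float(med), q1=float(q1), q3=float(q3))


def density_table(
    events, fluid_density: float = DEFAULT_FLUID_DENSITY
) -> pd.DataFrame:
    """Per-cell density table for an event table that carries volumes.

    Returns columns cell_id, buoyant_mass_pg, volume_um3, fluid_density,
    cell_density, total_mass_pg; rows without a volume are dropped.
    """
    df = events.df
    if "volume" not in df.columns:
        raise ValueError("event table has no volume column; density needs volume")
    sub = df.dropna(subset=["volume"])
    rho = cell_density(sub["buoyant_mass"].to_numpy(), sub["volume"].to_numpy(), fluid_density)
    m = total_mass(rho, sub["volume"].to_numpy())
    return pd.DataFrame(
        {
            "cell_id": sub["cell_id"].to_numpy(),
            "buoyant_mass_pg": sub["buoyant_mass"].to_numpy(),
            "volume_um3": sub["volume"].to_numpy(),
            "fluid_density": fluid_density,
            "cell_density": rho,
            "total_mass_pg": m,
        }
    )
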