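"""Indirect standardisation: census interpolation, national rates, expected counts.

Expected counts per spatial unit are obtained by applying nationwide
age-and-year-specific incidence rates to local person-time:

    E_k = sum_i sum_j q_ij * P_ijk        (diagnosis analysis)
    E_k = sum_j   q_0j * P_0jk            (birth analysis, age < 1 year)

so that E_k is the count the unit would see if its population
experienced the national rates — the offset of both the point-process
and the areal model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import CaseSet, ExpectedSurface, PopulationPanel

__all__ = [
    "RateTable",
    "interpolate_population",
    "national_rates",
    "expected_cases",
]


@dataclass
class RateTable:
    """Nationwide incidence rates q_ij per person-year, by age group and year."""

    rates: np.ndarray  # (I, J)
    age_groups: tuple
    years: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if self.rates.shape != (len(self.age_groups), len(self.years)):
            raise ValueError("rate table shape inconsistent with labels")

    def to_csv(self, path: str | Path) -> None:
        i, j = np.meshgrid(np.arange(len(self.age_groups)),
                           np.arange(len(self.years)), indexing="ij")
        pd.DataFrame({
            "age_group": np.asarray(self.age_groups)[i.ravel()],
            "year": self.years[j.ravel()],
            "rate": self.rates.ravel(),
        }).to_csv(path, index=False)


def interpolate_population(census_panel: PopulationPanel, years) -> PopulationPanel:
    """Fill a full yearly panel from census-year layers.

    Per (age group, cell), values at non-census years are linear
    interpolations between the bracketing censuses; years before the
    first and after the last census are held constant at the nearest
    census value (constant extrapolation avoids negative populations).
    """
    census_years = np.asarray(census_panel.years, dtype=float)
    if census_years.size == 0:
        raise ValueError("no census years available")
    order = np.argsort(census_years)
    census_years = census_years[order]
    counts = census_panel.counts[:, order, :]
    years = np.asarray(years)
    I, _, K = counts.shape
    out = np.empty((I, years.size, K))
    for i in range(I):
        # np.interp holds endpoints constant outside the census span
        out[i] = np.array([
            np.interp(years.astype(float), census_years, counts[i, :, k])
            for k in range(K)
        ]).T
    return PopulationPanel(out, census_panel.age_groups, years)


def national_rates(cases: CaseSet, panel: PopulationPanel) -> RateTable:
    """q_ij = (cases in age group i, year j) / national person-time in (i, j)."""
    I, J = len(panel.age_groups), len(panel.years)
    n_ij = np.zeros((I, J))
    ai = {a: i for i, a in enumerate(panel.age_groups)}
    yi = {int(y): j for j, y in enumerate(panel.years)}
    for age, year, cnt in cases.records.groupby(
            ["age_group", "year"], observed=True).size().reset_index(
            name="n").itertuples(index=False):
        if age not in ai or int(year) not in yi:
            raise ValueError(f"case stratum ({age}, {year}) not in the panel")
        n_ij[ai[age], yi[int(year)]] = cnt
    pop_ij = panel.counts.sum(axis=2)
    if np.any((n_ij > 0) & (pop_ij <= 0)):
        raise ValueError("cases observed in a stratum with zero national population")
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(pop_ij > 0, n_ij / np.maximum(pop_ij, 1e-300), 0.0)
    return RateTable(q, panel.age_groups, np.asarray(panel.years))


def expected_cases(rates: RateTable, panel: PopulationPanel,
                   analysis: str = "diagnosis") -> ExpectedSurface:
    """Indirectly standardised expected counts per spatial unit.

    The diagnosis analysis sums q_ij * P_ijk over all age groups and
    years; the birth analysis uses only the under-1 stratum (the panel's
    first — and for a birth panel, only — age group).
    """
    if tuple(rates.age_groups) != tuple(panel.age_groups) or not np.array_equal(
            np.asarray(rates.years), np.asarray(panel.years)):
        raise ValueError("rate table and panel index sets differ")
    if analysis == "diagnosis":
        E = np.einsum("ij,ijk->k", rates.rates, panel.counts)
    elif analysis == "birth":
        E = np.einsum("j,jk->k", rates.rates[0], panel.counts[0])
    else:
        raise ValueError(f"unknown analysis kind {analysis!r}")
    return ExpectedSurface(E, unit_kind="grid", analysis=analysis)
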