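"""Scenario grids, relative increments and photosynthetic light-use efficiency.

Derived quantities over the fitted curve parameters: A_n predicted for a
set of CO2 scenarios over every spectrum x intensity cell; the percent
increment of each cell relative to a reference condition,

    An_relative = 100 * (An_i - An_ref) / An_ref

and photosynthetic light-use efficiency, PLUE = 1000 * A_n / PPFD
(mmol CO2 fixed per mol incident photons). All chained computation uses
unrounded values; rounding (half away from zero) is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from co2resp.curve_model import EffectsTable, an_predict, assemble_params
from co2resp.util import round_half_up

DEFAULT_CO2_SCENARIOS: Tuple[float, ...] = (200.0, 400.0, 850.0)


@dataclass
class ScenarioGrid:
    """A_n over (spectrum, intensity, CO2 scenario) cells.

    ``values`` holds unrounded predictions in long form (columns spectrum,
    intensity, co2, an); ``rounding`` is the decimal precision used for
    display exports only.
    """

    co2_scenarios: Tuple[float, ...]
    values: pd.DataFrame
    rounding: int = 2

    def cell(self, spectrum: str, intensity: float, co2: float) -> float:
        """Unrounded A_n at one cell."""
        m = self.values[
            (self.values.spectrum == spectrum)
            & (self.values.intensity == intensity)
            & (self.values.co2 == co2)
        ]
        if len(m) != 1:
            raise KeyError(f"no unique cell ({spectrum}, {intensity}, {co2})")
        return float(m.an.iloc[0])

    def rounded(self) -> pd.DataFrame:
        out = self.values.copy()
        out["an"] = round_half_up(out["an"].to_numpy(), self.rounding)
        return out


@dataclass(frozen=True)
class PlueValue:
    """PLUE together with the unrounded A_n and PPFD it was formed from."""

    plue: float
    an_unrounded: float
    ppfd: float

    def __post_init__(self) -> None:
        if abs(self.plue * self.ppfd / 1000.0 - self.an_unrounded) > 1e-9:
            raise ValueError("inconsistent PLUE triple")


def scenario_table(
    effects: EffectsTable,
    co2_list: Sequence[float] = DEFAULT_CO2_SCENARIOS,
    rounding: int = 2,
) -> ScenarioGrid:
    """Predicted A_n for every design cell at each CO2 scenario."""
    co2s = tuple(float(x) for x in co2_list)
    if not co2s:
        raise ValueError("co2_list must be non-empty")
    if any(x < 0 for x in co2s):
        raise ValueError(f"CO2 scenarios must be >= 0: {co2s}")
    rows = []
    for s in effects.levels.spectrum_labels:
        for i in effects.levels.intensities:
            p = assemble_params(effects, s, i)
            for co2 in co2s:
                rows.append((s, i, co2, float(an_predict(p, co2))))
    df = pd.DataFrame(rows, columns=["spectrum", "intensity", "co2", "an"])
    return ScenarioGrid(co2_scenarios=co2s, values=df, rounding=rounding)


def relative_increment(an_i: float, an_reference: float) -> float:
    """Percent increment of ``an_i`` over ``an_reference`` (unrounded inputs)."""
    if an_reference == 0:
        raise ZeroDivisionError(
            f"reference A_n is zero; relative increment undefined (an_i={an_i})"
        )
    return 100.0 * (an_i - an_reference) / an_reference


def relative_increment_table(
    effects: EffectsTable,
    co2_list: Sequence[float] = DEFAULT_CO2_SCENARIOS,
    reference: Tuple[str, float, float] | None = None,
) -> pd.DataFrame:
    """Percent increments of every scenario cell against one reference cell.

    The default reference is the design's reference spectrum and intensity
    at 400 ppm. Returns long form with unrounded ``relative`` values;
    display convention is integer precision.
    """
    grid = scenario_table(effects, co2_list)
    if reference is None:
        reference = (
            effects.levels.reference_spectrum,
            effects.levels.reference_intensity,
            400.0,
        )
    ref_spectrum, ref_intensity, ref_co2 = reference
    p_ref = assemble_params(effects, ref_spectrum, ref_intensity)
    an_ref = float(an_predict(p_ref, ref_co2))
    if an_ref == 0:
        raise ZeroDivisionError(
            f"reference cell ({ref_spectrum}, {ref_intensity}, {ref_co2}) has A_n = 0"
        )
    out = grid.values.copy()
    out["relative"] = 100.0 * (out["an"] - an_ref) / an_ref
    return out.drop(columns="an")


def plue(an_unrounded: float, ppfd: float) -> PlueValue:
    """Light-use efficiency 1000 * A_n / PPFD, in mmol CO2 per mol photons."""
    if ppfd <= 0:
        raise ValueError(f"ppfd must be > 0, got {ppfd}")
    return PlueValue(
        plue=1000.0 * an_unrounded / ppfd,
        an_unrounded=an_unrounded,
        ppfd=float(ppfd),
    )


def plue_table(
    effects: EffectsTable,
    co2_list: Sequence[float] = DEFAULT_CO2_SCENARIOS,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """PLUE for every cell plus its mean over spectra.

    Returns ``(cells, means)``: long-form PLUE per (spectrum, intensity,
    co2), and the arithmetic mean over spectra per (intensity, co2).
    Negative values are legal; at very low light, respiration dominates.
    """
    grid = scenario_table(effects, co2_list)
    cells = grid.values.copy()
    cells["plue"] = 1000.0 * cells["an"] / cells["intensity"]
    cells = cells.drop(columns="an")
    means = (
        cells.groupby(["intensity", "co2"], sort=False)["plue"]
        .mean()
        .reset_index()
    )
    return cells, means
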