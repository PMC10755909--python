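"""Synthetic gas-exchange experiment generator.

Emulates the study's measurement protocol: each leaf sweeps 8 CO2 levels
(200-900 ppm in 100-ppm steps) at each of 7 light intensities, with the
sweep direction alternating between consecutive intensity blocks (up at
30, down at 90, up at 200, ...), 56 conditions in total, three readings
per condition. Readings are generated from the asymptotic-regression mean
with a plant-level Gaussian shift u on the asymptote d (entering through
the same saturation weight g = 1 - exp(-CO2/b) the model assumes, so
simulation and fit are exactly conjugate) and heteroscedastic Gaussian
noise with one SD per intensity level. Readings are treated as
equilibrated: no instrument lag or drift is simulated.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from co2resp.curve_model import (
    EffectsTable,
    FactorLevels,
    assemble_params,
    load_reference_effects,
)

CO2_LEVELS: Tuple[float, ...] = (200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0, 900.0)

#: Default residual SDs (umol m-2 s-1), one per intensity, increasing with
#: intensity: gas-exchange noise scales with flux magnitude.
DEFAULT_RESIDUAL_SDS: Dict[float, float] = {
    30.0: 0.30, 90.0: 0.35, 200.0: 0.45, 350.0: 0.55,
    500.0: 0.65, 700.0: 0.75, 1000.0: 0.80,
}
DEFAULT_SIGMA_U = 0.7


@dataclass(frozen=True)
class MeasurementProtocol:
    """Ordered (co2, intensity) conditions with a reading count per condition."""

    sequence: Tuple[Tuple[float, float], ...]
    readings_per_condition: int = 3

    def __post_init__(self) -> None:
        if self.readings_per_condition < 1:
            raise ValueError("readings_per_condition must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


def protocol_sequence(
    intensities: Sequence[float] = (30.0, 90.0, 200.0, 350.0, 500.0, 700.0, 1000.0),
    co2_levels: Sequence[float] = CO2_LEVELS,
    readings_per_condition: int = 3,
) -> MeasurementProtocol:
    """The canonical 56-step sweep: intensities ascending, CO2 snaking.

    The CO2 sweep starts ascending in the first (lowest) intensity block
    and reverses direction in each subsequent block, mirroring how the
    cuvette conditions were stepped in the underlying experiment.
    """
    seq = []
    for k, intensity in enumerate(intensities):
        block = list(co2_levels) if k % 2 == 0 else list(co2_levels)[::-1]
        seq.extend((float(co2), float(intensity)) for co2 in block)
    return MeasurementProtocol(tuple(seq), readings_per_condition)


@dataclass
class SimulationTruth:
    """Generating parameters for a synthetic experiment.

    Defaults reproduce the study's design: effects from the bundled
    published-table reconstruction, sigma_u = 0.7 umol m-2 s-1,
    per-intensity residual SDs from 0.3 (at 30) to 0.8 (at 1000), three
    plants per spectrum.
    """

    effects: EffectsTable = field(default_factory=load_reference_effects)
    sigma_u: float = DEFAULT_SIGMA_U
    residual_sds: Dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUAL_SDS)
    )
    plants_per_spectrum: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if any(v < 0 for v in self.residual_sds.values()):
            raise ValueError("residual SDs must be >= 0")
        if self.plants_per_spectrum < 1:
            raise ValueError("plants_per_spectrum must be >= 1")
        missing = set(self.effects.levels.intensities) - set(self.residual_sds)
        if missing:
            raise ValueError(f"residual_sds missing intensity levels {sorted(missing)}")


def perturb_truth(truth: SimulationTruth, scale: float) -> SimulationTruth:
    """Scale all intensity and spectrum offsets by ``scale``.

    ``scale = 0`` collapses every design cell onto the intercept triple: a
    null-model generator for type-I-error studies of the pairwise
    comparison stage. ``scale = 1`` returns an equivalent truth.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    eff = truth.effects
    new_effects = EffectsTable(
        levels=eff.levels,
        intercepts=dict(eff.intercepts),
        intensity_offsets={
            p: {lv: scale * v for lv, v in offs.items()}
            for p, offs in eff.intensity_offsets.items()
        },
        spectrum_offsets={
            p: {lab: scale * v for lab, v in offs.items()}
            for p, offs in eff.spectrum_offsets.items()
        },
        sigma_u=eff.sigma_u,
        residual_sds=dict(eff.residual_sds) if eff.residual_sds else None,
    )
    return replace(truth, effects=new_effects)


def simulate_experiment(
    truth: SimulationTruth,
    protocol: Optional[MeasurementProtocol] = None,
    spectra: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Simulate the full experiment as a long-format reading table.

    For each spectrum and plant, one asymptote shift u ~ N(0, sigma_u^2) is
    drawn; each reading then is

        an = c + (d + u - c) * g + e,   g = 1 - exp(-co2 / b)

    with e ~ N(0, sd_intensity^2). One RNG seeded from ``truth.seed``
    drives everything; all plant-level u draws are consumed before any
    observation noise, in deterministic (spectrum, plant) order, so the
    same truth yields a byte-identical table.
    """
    if protocol is None:
        protocol = protocol_sequence()
    levels = truth.effects.levels
    if spectra is None:
        spectra = levels.spectrum_labels
    unknown = set(spectra) - set(levels.spectrum_labels)
    if unknown:
        raise ValueError(f"spectra not in the effects table: {sorted(unknown)}")

    rng = np.random.default_rng(truth.seed)
    n_plants = len(spectra) * truth.plants_per_spectrum
    u_draws = rng.normal(0.0, truth.sigma_u, size=n_plants)

    co2 = np.array([step[0] for step in protocol.sequence])
    intensity = np.array([step[1] for step in protocol.sequence])
    reps = protocol.readings_per_condition
    sd_step = np.array([truth.residual_sds[i] for i in intensity])

    records = []
    plant_no = 0
    for spectrum in spectra:
        cell = {
            i: assemble_params(truth.effects, spectrum, i)
            for i in sorted(set(intensity))
        }
        c = np.array([cell[i].c for i in intensity])
        d = np.array([cell[i].d for i in intensity])
        b = np.array([cell[i].b for i in intensity])
        g = 1.0 - np.exp(-co2 / b)
        mean = c + (d - c) * g
        for k in range(truth.plants_per_spectrum):
            u = u_draws[plant_no]
            plant_id = f"{spectrum}-P{k + 1}"
            eps = rng.normal(0.0, 1.0, size=(len(protocol), reps)) * sd_step[:, None]
            an = mean[:, None] + u * g[:, None] + eps
            for step in range(len(protocol)):
                for r in range(reps):
                    records.append(
                        (plant_id, spectrum, intensity[step], co2[step], r + 1,
                         an[step, r])
                    )
            plant_no += 1
    return pd.DataFrame(
        records,
        columns=["plant_id", "spectrum", "intensity", "co2", "replicate", "an"],
    )
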