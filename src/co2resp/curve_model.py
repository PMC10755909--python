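"""Asymptotic CO2-response curve and additive parameter tables.

The mean model for leaf net CO2 assimilation is the three-parameter
asymptotic regression

    A_n(CO2) = c + (d - c) * (1 - exp(-CO2 / b))

where ``c`` is A_n at zero CO2 (dark/low-CO2 respiration makes it
negative), ``d`` the horizontal asymptote (maximum attainable A_n), and
``b`` a CO2 scale in ppm: ``1/b`` is proportional to the relative rate at
which A_n approaches its asymptote. Each of (c, d, b) is decomposed
additively, on the natural scale, into an intercept at the reference
spectrum x intensity cell plus one offset per non-reference intensity and
one per non-reference spectrum. A validated reconstruction of the study's
published 10-spectra x 7-intensity parameter table ships with the package
(:func:`load_reference_effects`).

Units throughout: A_n, c, d in umol CO2 m-2 s-1; CO2 and b in ppm; light
intensity (PPFD) in umol photons m-2 s-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from co2resp.util import check_finite

PARAMETERS = ("c", "d", "b")

#: Photon-flux composition of the ten LED spectra (percent blue/green/red).
#: Mix labels read as percent-waveband pairs, e.g. 80R20B = 80 % red + 20 %
#: blue; the trichromatic mix approximates the solar spectrum.
SPECTRUM_MIXES: Dict[str, Tuple[float, float, float]] = {
    "100B": (100.0, 0.0, 0.0),
    "80B20G": (80.0, 20.0, 0.0),
    "20B80G": (20.0, 80.0, 0.0),
    "100G": (0.0, 100.0, 0.0),
    "80G20R": (0.0, 80.0, 20.0),
    "20G80R": (0.0, 20.0, 80.0),
    "100R": (0.0, 0.0, 100.0),
    "80R20B": (20.0, 0.0, 80.0),
    "20R80B": (80.0, 0.0, 20.0),
    "37R36G27B": (27.0, 36.0, 37.0),
}

#: Spectrum ordering used by the published parameter and scenario tables.
DEFAULT_SPECTRA: Tuple[str, ...] = (
    "37R36G27B", "100B", "100G", "100R", "20B80G",
    "20G80R", "20R80B", "80B20G", "80G20R", "80R20B",
)
DEFAULT_INTENSITIES: Tuple[float, ...] = (30.0, 90.0, 200.0, 350.0, 500.0, 700.0, 1000.0)
REFERENCE_SPECTRUM = "37R36G27B"
REFERENCE_INTENSITY = 350.0


@dataclass(frozen=True)
class SpectrumMix:
    """A named blue/green/red photon-flux composition (percent of total)."""

    label: str
    blue_pct: float
    green_pct: float
    red_pct: float

    def __post_init__(self) -> None:
        for name, v in (("blue_pct", self.blue_pct),
                        ("green_pct", self.green_pct),
                        ("red_pct", self.red_pct)):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.label}: {name}={v} outside [0, 100]")
        total = self.blue_pct + self.green_pct + self.red_pct
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"{self.label}: photon fractions sum to {total}, not 100")


@dataclass(frozen=True)
class CurveParams:
    """The (c, d, b) triple of one spectrum x intensity cell.

    ``b`` must be strictly positive. ``d <= c`` makes the curve
    non-increasing in CO2; it is physically odd but occurs in shade-level
    fits, so it raises a warning rather than an error.
    """

    c: float
    d: float
    b: float

    def __post_init__(self) -> None:
        check_finite("CurveParams", self.c, self.d, self.b)
        if self.b <= 0:
            raise ValueError(f"b must be > 0, got {self.b}")
        if self.d <= self.c:
            warnings.warn(
                f"d={self.d} <= c={self.c}: A_n curve is non-increasing in CO2",
                stacklevel=2,
            )


@dataclass(frozen=True)
class FactorLevels:
    """Ordered design levels and the reference cell of the additive coding."""

    intensities: Tuple[float, ...]
    spectra: Tuple[SpectrumMix, ...]
    reference_intensity: float
    reference_spectrum: str

    def __post_init__(self) -> None:
        labels = [s.label for s in self.spectra]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate spectrum labels")
        if len(set(self.intensities)) != len(self.intensities):
            raise ValueError("duplicate intensity levels")
        if self.reference_intensity not in self.intensities:
            raise ValueError(f"reference intensity {self.reference_intensity} not a design level")
        if self.reference_spectrum not in labels:
            raise ValueError(f"reference spectrum {self.reference_spectrum!r} not a design level")

    @property
    def spectrum_labels(self) -> Tuple[str, ...]:
        return tuple(s.label for s in self.spectra)

    @property
    def nonref_intensities(self) -> Tuple[float, ...]:
        return tuple(i for i in self.intensities if i != self.reference_intensity)

    @property
    def nonref_spectra(self) -> Tuple[str, ...]:
        return tuple(s for s in self.spectrum_labels if s != self.reference_spectrum)


def default_factor_levels() -> FactorLevels:
    """The study design: 10 spectra x 7 intensities, reference 37R36G27B at 350."""
    spectra = tuple(
        SpectrumMix(lab, *SPECTRUM_MIXES[lab]) for lab in DEFAULT_SPECTRA
    )
    return FactorLevels(
        intensities=DEFAULT_INTENSITIES,
        spectra=spectra,
        reference_intensity=REFERENCE_INTENSITY,
        reference_spectrum=REFERENCE_SPECTRUM,
    )


@dataclass
class EffectsTable:
    """Additive decomposition of (c, d, b) plus optional variance components.

    For each parameter p the cell value at (spectrum s, intensity i) is

        p(s, i) = intercept_p + intensity_offset_p[i] + spectrum_offset_p[s]

    with both offsets zero at the reference levels. ``sigma_u`` is the SD of
    the plant-level random shift on the asymptote d; ``residual_sds`` is one
    residual SD per intensity level (the heteroscedastic error model).
    """

    levels: FactorLevels
    intercepts: Dict[str, float]
    intensity_offsets: Dict[str, Dict[float, float]]
    spectrum_offsets: Dict[str, Dict[str, float]]
    sigma_u: Optional[float] = None
    residual_sds: Optional[Dict[float, float]] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for p in PARAMETERS:
            if p not in self.intercepts:
                raise ValueError(f"missing intercept for parameter {p!r}")
            io = self.intensity_offsets.get(p, {})
            so = self.spectrum_offsets.get(p, {})
            if set(io) != set(self.levels.nonref_intensities):
                raise ValueError(
                    f"intensity offsets for {p!r} must cover exactly the "
                    f"non-reference intensities {self.levels.nonref_intensities}"
                )
            if set(so) != set(self.levels.nonref_spectra):
                raise ValueError(
                    f"spectrum offsets for {p!r} must cover exactly the "
                    f"non-reference spectra"
                )
        if self.sigma_u is not None and self.sigma_u < 0:
            raise ValueError(f"sigma_u must be >= 0, got {self.sigma_u}")
        if self.residual_sds is not None:
            if set(self.residual_sds) != set(self.levels.intensities):
                raise ValueError("residual_sds must have one entry per intensity level")
            bad = {k: v for k, v in self.residual_sds.items() if v <= 0}
            if bad:
                raise ValueError(f"residual SDs must be > 0: {bad}")
        # every assembled b must be positive
        for s in self.levels.spectrum_labels:
            for i in self.levels.intensities:
                b = self.value("b", s, i)
                if b <= 0:
                    raise ValueError(f"assembled b <= 0 at ({s}, {i}): {b}")

    def value(self, parameter: str, spectrum: str, intensity: float) -> float:
        """Assembled value of one parameter at one design cell."""
        if parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {parameter!r}")
        if spectrum not in self.levels.spectrum_labels:
            raise ValueError(f"unknown spectrum label {spectrum!r}")
        if intensity not in self.levels.intensities:
            raise ValueError(f"unknown intensity level {intensity!r}")
        return (
            self.intercepts[parameter]
            + self.intensity_offsets[parameter].get(intensity, 0.0)
            + self.spectrum_offsets[parameter].get(spectrum, 0.0)
        )


def an_predict(params: CurveParams, co2) -> np.ndarray | float:
    """Deterministic mean A_n at CO2 concentration(s) ``co2`` (ppm).

    Returns ``c + (d - c) * (1 - exp(-co2 / b))``; strictly increasing in
    CO2 iff d > c, bounded between c (at CO2 = 0) and the asymptote d.
    """
    co2_arr = np.asarray(co2, dtype=float)
    check_finite("an_predict co2", co2_arr)
    if np.any(co2_arr < 0):
        raise ValueError(f"co2 must be >= 0, got {co2!r}")
    g = 1.0 - np.exp(-co2_arr / params.b)
    out = params.c + (params.d - params.c) * g
    return out if out.ndim else float(out)


def assemble_params(effects: EffectsTable, spectrum_label: str, intensity: float) -> CurveParams:
    """Assemble the (c, d, b) triple for one design cell from additive effects."""
    return CurveParams(
        c=effects.value("c", spectrum_label, intensity),
        d=effects.value("d", spectrum_label, intensity),
        b=effects.value("b", spectrum_label, intensity),
    )


def params_table(effects: EffectsTable) -> Dict[Tuple[str, float], CurveParams]:
    """All spectrum x intensity cells as a mapping (label, intensity) -> CurveParams."""
    return {
        (s, i): assemble_params(effects, s, i)
        for s in effects.levels.spectrum_labels
        for i in effects.levels.intensities
    }


def params_frame(effects: EffectsTable) -> pd.DataFrame:
    """The cell table as a tidy DataFrame (spectrum, intensity, c, d, b)."""
    rows = [
        (s, i, p.c, p.d, p.b)
        for (s, i), p in params_table(effects).items()
    ]
    return pd.DataFrame(rows, columns=["spectrum", "intensity", "c", "d", "b"])


def decompose_cells(
    cells: pd.DataFrame, levels: FactorLevels, b_floor: Optional[float] = None
) -> EffectsTable:
    """Least-squares re-decomposition of a full cell table into additive effects.

    ``cells`` needs columns spectrum, intensity, c, d, b covering every
    design cell. For an exactly additive table the decomposition is exact;
    otherwise it is the least-squares projection onto the main-effects
    space. Offsets come out relative to the reference levels in ``levels``,
    which makes this the tool for re-expressing a table under a different
    reference coding.
    """
    required = {"spectrum", "intensity", "c", "d", "b"}
    if not required.issubset(cells.columns):
        raise ValueError(f"cell table must have columns {sorted(required)}")
    cells = cells.copy()
    cells["intensity"] = cells["intensity"].astype(float)
    idx = {(r.spectrum, r.intensity) for r in cells.itertuples()}
    expected = {(s, i) for s in levels.spectrum_labels for i in levels.intensities}
    if idx != expected:
        missing = sorted(expected - idx)
        raise ValueError(f"cell table does not cover the full design; missing {missing[:5]}")

    nonref_i = levels.nonref_intensities
    nonref_s = levels.nonref_spectra
    ncoef = 1 + len(nonref_i) + len(nonref_s)
    X = np.zeros((len(cells), ncoef))
    X[:, 0] = 1.0
    for r, row in enumerate(cells.itertuples()):
        if row.intensity != levels.reference_intensity:
            X[r, 1 + nonref_i.index(row.intensity)] = 1.0
        if row.spectrum != levels.reference_spectrum:
            X[r, 1 + len(nonref_i) + nonref_s.index(row.spectrum)] = 1.0

    intercepts: Dict[str, float] = {}
    int_off: Dict[str, Dict[float, float]] = {}
    spec_off: Dict[str, Dict[str, float]] = {}
    for p in PARAMETERS:
        beta, *_ = np.linalg.lstsq(X, cells[p].to_numpy(float), rcond=None)
        intercepts[p] = float(beta[0])
        int_off[p] = {lv: float(beta[1 + k]) for k, lv in enumerate(nonref_i)}
        spec_off[p] = {
            lab: float(beta[1 + len(nonref_i) + k]) for k, lab in enumerate(nonref_s)
        }
    if b_floor is not None:
        # an inexactly additive table can project to a non-positive b in some
        # cell; a uniform upward shift of the intercept preserves additivity
        # and every contrast while restoring positivity
        min_b = min(
            intercepts["b"] + int_off["b"].get(i, 0.0) + spec_off["b"].get(s, 0.0)
            for s in levels.spectrum_labels for i in levels.intensities
        )
        if min_b < b_floor:
            intercepts["b"] += b_floor - min_b
    return EffectsTable(levels, intercepts, int_off, spec_off)


def load_reference_effects() -> EffectsTable:
    """The bundled reconstruction of the study's published parameter table.

    Offsets were reconstructed from the published per-intensity baseline row
    and the per-spectrum additive shift column; two spectrum rows of the
    printed c values are typographically corrupted in the source and are
    represented here by their additive reconstruction, which is the version
    consistent with the published scenario grids.
    """
    ref = resources.files("co2resp").joinpath("data/reference_effects.csv")
    with resources.as_file(ref) as path:
        return read_effects_csv(path)


def read_effects_csv(path) -> EffectsTable:
    """Read an effects-format CSV (parameter, term, level, value rows)."""
    df = pd.read_csv(path, dtype={"level": str}, keep_default_na=False)
    required = {"parameter", "term", "level", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"effects CSV must have columns {sorted(required)}")

    meta = df[df.parameter == "meta"].set_index("term")["level"].to_dict()
    ref_intensity = float(meta["reference_intensity"])
    ref_spectrum = meta["reference_spectrum"]

    body = df[df.parameter != "meta"]
    intensities = [ref_intensity]
    spectra = [ref_spectrum]
    for row in body.itertuples():
        if row.term == "intensity" and float(row.level) not in intensities:
            intensities.append(float(row.level))
        if row.term == "spectrum" and row.level not in spectra:
            spectra.append(row.level)
    intensities.sort()
    # keep reference spectrum first, others in file order
    mixes = tuple(
        SpectrumMix(lab, *SPECTRUM_MIXES[lab]) if lab in SPECTRUM_MIXES
        else SpectrumMix(lab, 100.0, 0.0, 0.0)
        for lab in spectra
    )
    levels = FactorLevels(tuple(intensities), mixes, ref_intensity, ref_spectrum)

    intercepts: Dict[str, float] = {}
    int_off: Dict[str, Dict[float, float]] = {p: {} for p in PARAMETERS}
    spec_off: Dict[str, Dict[str, float]] = {p: {} for p in PARAMETERS}
    sigma_u = None
    residual_sds: Dict[float, float] = {}
    for row in body.itertuples():
        v = float(row.value)
        if row.parameter in PARAMETERS:
            if row.term == "intercept":
                intercepts[row.parameter] = v
            elif row.term == "intensity":
                int_off[row.parameter][float(row.level)] = v
            elif row.term == "spectrum":
                spec_off[row.parameter][row.level] = v
            else:
                raise ValueError(f"unknown term {row.term!r}")
        elif row.parameter == "sigma_u":
            sigma_u = v
        elif row.parameter == "residual_sd":
            residual_sds[float(row.level)] = v
        else:
            raise ValueError(f"unknown parameter {row.parameter!r}")
    return EffectsTable(
        levels, intercepts, int_off, spec_off,
        sigma_u=sigma_u, residual_sds=residual_sds or None,
    )


def write_effects_csv(effects: EffectsTable, path) -> None:
    rows: List[Tuple[str, str, str, str]] = [
        ("meta", "reference_intensity", _fmt_level(effects.levels.reference_intensity), ""),
        ("meta", "reference_spectrum", effects.levels.reference_spectrum, ""),
    ]
    for p in PARAMETERS:
        rows.append((p, "intercept", "", repr(effects.intercepts[p])))
        for lv in effects.levels.nonref_intensities:
            rows.append((p, "intensity", _fmt_level(lv), repr(effects.intensity_offsets[p][lv])))
        for lab in effects.levels.nonref_spectra:
            rows.append((p, "spectrum", lab, repr(effects.spectrum_offsets[p][lab])))
    if effects.sigma_u is not None:
        rows.append(("sigma_u", "sd", "", repr(effects.sigma_u)))
    if effects.residual_sds is not None:
        for lv in effects.levels.intensities:
            rows.append(("residual_sd", "intensity", _fmt_level(lv), repr(effects.residual_sds[lv])))
    pd.DataFrame(rows, columns=["parameter", "term", "level", "value"]).to_csv(path, index=False)


def _fmt_level(intensity: float) -> str:
    return str(int(intensity)) if float(intensity).is_integer() else repr(float(intensity))
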