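"""Temperature dependence of the reaction rates.

Two levels of description coexist here.  The physical relations —
Arrhenius rate law and the Stokes–Einstein diffusion coefficient — are
expository: activation energies and collision prefactors are not
tabulated for composite processes like transcription or translation, so
the cold-shift scenarios are instead driven by per-reaction
multiplicative factors (``ShiftFactors``).  The reasoning connecting the
two is the encounter count: making an mRNA or a protein requires on the
order of a thousand successful diffusive encounters, degradation only a
few, so a temperature drop slows production far more than degradation.

The named scenarios reproduce the four canonical factor combinations:
uniform slowdown, production hit harder than degradation, and the two
mixed cases where only one degradation reaction is spared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .kinetics import RateConstants

__all__ = [
    "GAS_CONSTANT_R",
    "BOLTZMANN_KB",
    "ArrheniusParams",
    "DiffusionParams",
    "ShiftFactors",
    "EncounterEstimate",
    "celsius_to_kelvin",
    "arrhenius_rate",
    "stokes_einstein_D",
    "q10_factor",
    "encounter_estimate",
    "apply_shift",
    "scenario_factors",
    "SCENARIOS",
    "RATES_24C",
    "RATES_14C",
]

#: universal gas constant (J mol^-1 K^-1, CODATA)
GAS_CONSTANT_R = 8.314462618
#: Boltzmann constant (J K^-1, CODATA)
BOLTZMANN_KB = 1.380649e-23

#: baseline rate set at 24 degC (a.u.): k1, k2, k3, k4
RATES_24C = RateConstants(k1=2.5, k2=1.0, k3=2.5, k4=1.0)
#: rate set at 14 degC: production 10-fold slower, degradation 2-fold slower
RATES_14C = RateConstants(k1=0.25, k2=0.5, k3=0.25, k4=0.5)


def celsius_to_kelvin(temp_c: float) -> float:
    return temp_c + 273.15


@dataclass(frozen=True)
class ArrheniusParams:
    """Prefactor and activation energy of an Arrhenius rate law."""

    prefactor_A: float
    delta_G: float  # J mol^-1
    gas_constant_R: float = GAS_CONSTANT_R

    def __post_init__(self) -> None:
        if self.prefactor_A <= 0:
            raise ValueError("prefactor_A must be positive")
        if self.delta_G < 0:
            raise ValueError("delta_G must be non-negative")


@dataclass(frozen=True)
class DiffusionParams:
    """Inputs of the Stokes–Einstein diffusion coefficient."""

    temperature_T: float  # K
    viscosity_eta: float  # Pa s
    hydro_radius_R0: float  # m
    boltzmann_kb: float = BOLTZMANN_KB

    def __post_init__(self) -> None:
        for name in ("temperature_T", "viscosity_eta", "hydro_radius_R0",
                     "boltzmann_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ShiftFactors:
    """Dimensionless multiplicative factors on k1..k4 at the shift."""

    f1: float
    f2: float
    f3: float
    f4: float

    def __post_init__(self) -> None:
        for name in ("f1", "f2", "f3", "f4"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite")

    def compose(self, other: "ShiftFactors") -> "ShiftFactors":
        """Element-wise product: applying self then other."""
        return ShiftFactors(
            self.f1 * other.f1, self.f2 * other.f2,
            self.f3 * other.f3, self.f4 * other.f4,
        )


@dataclass(frozen=True)
class EncounterEstimate:
    """Successful-encounter counts for synthesizing one macromolecule."""

    mrna_encounters: int
    translation_encounters: int
    mrna_order_of_magnitude: float
    translation_order_of_magnitude: float


def arrhenius_rate(params: ArrheniusParams, temperature_k: float) -> float:
    """Arrhenius rate ``k = A * exp(-dG / (R T))`` at absolute temperature T."""
    if temperature_k <= 0:
        raise ValueError("absolute temperature must be positive")
    return params.prefactor_A * math.exp(
        -params.delta_G / (params.gas_constant_R * temperature_k)
    )


def stokes_einstein_D(params: DiffusionParams) -> float:
    """Diffusion coefficient ``D = kb T / (6 pi eta R0)`` (m^2 s^-1).

    Linear in T at fixed viscosity; the ratio of D between two
    temperatures therefore equals the temperature ratio, which is why
    slower diffusion alone explains only a few percent of rate change
    over a 10 K drop.
    """
    return (params.boltzmann_kb * params.temperature_T) / (
        6.0 * math.pi * params.viscosity_eta * params.hydro_radius_R0
    )


def q10_factor(q10: float, delta_T: float) -> float:
    """Van't Hoff factor ``q10 ** (delta_T / 10)``.

    ``delta_T`` is the signed temperature change in Kelvin: negative for
    cooling, giving a factor < 1 (slowdown).
    """
    if q10 <= 1:
        raise ValueError("q10 must exceed 1")
    return q10 ** (delta_T / 10.0)


def _order_of_magnitude(n: float) -> float:
    return 10.0 ** round(math.log10(n))


def encounter_estimate(protein_length_aa: int) -> EncounterEstimate:
    """Successful diffusive encounters needed per macromolecule.

    The mRNA needs at least three nucleotides per codon, so ~3L
    encounters for a protein of L amino acids; translation needs roughly
    one loaded tRNA per residue, ~L encounters.  For a typical 350-aa
    protein both land around the thousand mark — orders of magnitude
    above the single encounter a protease or RNase needs, which is the
    asymmetry behind production being hit harder by cold.
    """
    if protein_length_aa < 1:
        raise ValueError("protein_length_aa must be >= 1")
    mrna_n = 3 * protein_length_aa
    trans_n = protein_length_aa
    return EncounterEstimate(
        mrna_encounters=mrna_n,
        translation_encounters=trans_n,
        mrna_order_of_magnitude=_order_of_magnitude(mrna_n),
        translation_order_of_magnitude=_order_of_magnitude(trans_n),
    )


def apply_shift(rates: RateConstants, factors: ShiftFactors) -> RateConstants:
    """Element-wise product of rates and shift factors."""
    return RateConstants(
        rates.k1 * factors.f1,
        rates.k2 * factors.f2,
        rates.k3 * factors.f3,
        rates.k4 * factors.f4,
    )


#: named cold-shift scenarios (24 degC -> 14 degC factor sets)
SCENARIOS: dict[str, ShiftFactors] = {
    # all four reactions slowed by the same factor: concentrations invariant
    "fig3a": ShiftFactors(0.1, 0.1, 0.1, 0.1),
    # production 10-fold slower, both degradations 2-fold slower
    "fig3b": ShiftFactors(0.1, 0.5, 0.1, 0.5),
    # only protein degradation spared (2-fold), mRNA degradation 10-fold
    "fig3c": ShiftFactors(0.1, 0.1, 0.1, 0.5),
    # only mRNA degradation spared (2-fold), protein degradation 10-fold
    "fig3d": ShiftFactors(0.1, 0.5, 0.1, 0.1),
}


def scenario_factors(name: str) -> ShiftFactors:
    """Factor set of a named cold-shift scenario (fig3a..fig3d)."""
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {sorted(SCENARIOS)}"
        ) from None
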