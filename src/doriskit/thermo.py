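"""Equilibrium model of oligo--overhang capture.

A biotinylated access oligo binding a file's exposed overhang is treated as
a two-state hybridization at equilibrium:

    K = exp(-dG0 / (R T))                       (equilibrium constant)
    [oligo.strand] / [strand] = K [oligo]       (bound:free ratio)

With the oligo in large excess, the ratio ``K*[oligo]`` is read as the
separation efficiency.  Taken literally it is unbounded, so two forms are
exposed: the literal product clipped to 1, and the standard saturating
isotherm ``K c / (1 + K c)``; they agree to first order when ``K c << 1``.

dG0 can be supplied directly or estimated for a perfectly matched duplex
from unified nearest-neighbor parameters (dG = dH - T*dS over dinucleotide
stacks plus terminal initiation terms; dH in kcal/mol, dS in cal/mol/K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .sequences import validate_sequence

#: Gas constant in kcal/(mol K).
GAS_CONSTANT = 1.987e-3

# Unified DNA/DNA nearest-neighbor parameters: stack -> (dH kcal/mol,
# dS cal/(mol K)).  Keys are the 5'->3' dinucleotide on one strand.
NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    "CC": (-8.0, -19.9),
}

#: Duplex-initiation terms per terminal base pair: (dH, dS).
NN_INITIATION: dict[str, tuple[float, float]] = {
    "G": (0.1, -2.8),
    "C": (0.1, -2.8),
    "A": (2.3, 4.1),
    "T": (2.3, 4.1),
}


@dataclass(frozen=True)
class BindingModel:
    """Thermodynamic state of one oligo--overhang binding reaction."""

    delta_g0: float  # kcal/mol; negative = favorable
    temperature: float  # Kelvin
    oligo_concentration: float  # mol/L
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        if self.oligo_concentration < 0:
            raise ValueError("concentration must be non-negative")


def equilibrium_constant(model: BindingModel) -> float:
    """K = exp(-dG0 / (R T)), dimensionless on the molar scale."""
    return math.exp(-model.delta_g0 / (model.gas_constant * model.temperature))


def bound_ratio(K: float, oligo_concentration: float) -> float:
    """Bound:free strand ratio K*[oligo] (the literal model form)."""
    if K < 0 or oligo_concentration < 0:
        raise ValueError("K and concentration must be non-negative")
    return K * oligo_concentration


def bound_fraction(
    K: float,
    oligo_concentration: float,
    form: str = "clipped_linear",
) -> float:
    """Fraction of strands captured, in [0, 1].

    ``clipped_linear``: min(K c, 1).  ``saturating``: K c / (1 + K c).
    """
    r = bound_ratio(K, oligo_concentration)
    if form == "clipped_linear":
        return min(r, 1.0)
    if form == "saturating":
        return r / (1.0 + r)
    raise ValueError(f"unknown form {form!r}")


def nn_delta_g(duplex: str, temperature: float) -> float:
    """dG0 (kcal/mol) of a perfectly matched duplex at ``temperature`` (K),
    summed over nearest-neighbor stacks plus initiation terms."""
    validate_sequence(duplex)
    if len(duplex) < 2:
        raise ValueError("duplex must be at least 2 nt")
    if temperature <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    dh, ds = 0.0, 0.0
    for i in range(len(duplex) - 1):
        h, s = NN_UNIFIED[duplex[i : i + 2]]
        dh += h
        ds += s
    for terminal in (duplex[0], duplex[-1]):
        h, s = NN_INITIATION[terminal]
        dh += h
        ds += s
    return dh - temperature * ds / 1000.0


def separation_efficiency(
    oligo: str,
    temperature_celsius: float,
    oligo_concentration: float,
    form: str = "clipped_linear",
) -> dict:
    """Convenience pipeline: NN dG0 -> K -> bound fraction.

    Returns a dict with dG0, K, and both fraction forms (the requested
    ``form`` under ``"separation_efficiency"``).
    """
    T = temperature_celsius + 273.15
    dg = nn_delta_g(oligo, T)
    model = BindingModel(dg, T, oligo_concentration)
    K = equilibrium_constant(model)
    return {
        "delta_g0_kcal_mol": dg,
        "temperature_K": T,
        "K": K,
        "bound_ratio": bound_ratio(K, oligo_concentration),
        "clipped_linear": bound_fraction(K, oligo_concentration, "clipped_linear"),
        "saturating": bound_fraction(K, oligo_concentration, "saturating"),
        "separation_efficiency": bound_fraction(K, oligo_concentration, form),
    }
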