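"""Closed-form titration curve models and the coupled two-site ionization model.

In fast exchange, an NMR resonance's chemical shift at a given pH is the
population-weighted average of the shifts of the protonation states.  For a
single ionizable group with acid dissociation midpoint ``pKa`` this gives the
familiar sigmoid

    delta(pH) = (delta_HA + delta_A * 10**(pH - pKa)) / (1 + 10**(pH - pKa))

and for two sequential macroscopic transitions a double sigmoid

    delta(pH) = (delta_H2A + delta_HA * 10**(pH - pKa1)
                 + delta_A * 10**(2*pH - pKa1 - pKa2))
                / (1 + 10**(pH - pKa1) + 10**(2*pH - pKa1 - pKa2)).

When two titratable groups interact (e.g. a buried aspartate and the attacking
cysteine of a -CXXC- motif), the observed macroscopic constants are composites
of four *microscopic* constants describing each site's deprotonation
conditioned on the state of the other.  :class:`CoupledSiteModel` enumerates
the four microstates explicitly and provides exact conversions between the
microscopic and macroscopic descriptions.

pH values are treated as an opaque axis (direct meter readings; no solvent
isotope correction is ever applied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "OnePkaParams",
    "TwoPkaParams",
    "CoupledSiteModel",
    "MicrostateFractions",
    "shift_one_pka",
    "shift_two_pka",
    "microstate_fractions",
    "site_deprotonation_fraction",
    "macroscopic_from_microscopic",
    "microscopic_from_macroscopic",
]

_LN10 = math.log(10.0)

#: Tolerance on thermodynamic cycle closure of a CoupledSiteModel.
CYCLE_TOL = 1e-9


def _check_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class OnePkaParams:
    """Parameters of a single-pKa chemical-shift titration curve.

    ``delta_protonated`` and ``delta_deprotonated`` are the limiting shifts
    (ppm) of the fully protonated and fully deprotonated species; they need
    not be ordered, since titrations may move a resonance upfield or
    downfield.  ``pka`` is the midpoint on the pH axis.
    """

    delta_protonated: float
    delta_deprotonated: float
    pka: float

    def __post_init__(self) -> None:
        _check_finite("delta_protonated", self.delta_protonated)
        _check_finite("delta_deprotonated", self.delta_deprotonated)
        _check_finite("pka", self.pka)

    @property
    def amplitude(self) -> float:
        """Total shift change across the titration (signed, ppm)."""
        return self.delta_deprotonated - self.delta_protonated


@dataclass(frozen=True)
class TwoPkaParams:
    """Parameters of a two-pKa (double sigmoid) titration curve.

    ``delta_state0``/``delta_state1``/``delta_state2`` are the shifts of the
    doubly protonated, intermediate, and doubly deprotonated species.
    ``pka1 <= pka2`` is required; use :meth:`canonical` to relabel an
    unordered parameter set.
    """

    delta_state0: float
    delta_state1: float
    delta_state2: float
    pka1: float
    pka2: float

    def __post_init__(self) -> None:
        for name in ("delta_state0", "delta_state1", "delta_state2", "pka1", "pka2"):
            _check_finite(name, getattr(self, name))
        if self.pka1 > self.pka2:
            raise ValueError(
                f"pka1 ({self.pka1}) must be <= pka2 ({self.pka2}); "
                "use TwoPkaParams.canonical to relabel"
            )

    @classmethod
    def canonical(
        cls,
        delta_state0: float,
        delta_state1: float,
        delta_state2: float,
        pka1: float,
        pka2: float,
    ) -> "TwoPkaParams":
        """Construct with pKas sorted into ascending order.

        The limiting shifts are fixed endpoints of the curve; only the pKa
        labels are swapped, so the represented curve is unchanged up to the
        (symmetric) functional form.
        """
        if pka1 > pka2:
            pka1, pka2 = pka2, pka1
        return cls(delta_state0, delta_state1, delta_state2, pka1, pka2)


@dataclass(frozen=True)
class CoupledSiteModel:
    """Four-microstate ionization scheme for two interacting titratable groups.

    Microscopic constants (all on the pKa scale):

    - ``pk_a_first``: site A deprotonates while B is still protonated
    - ``pk_b_first``: site B deprotonates while A is still protonated
    - ``pk_a_given_b``: site A deprotonates after B has deprotonated
    - ``pk_b_given_a``: site B deprotonates after A has deprotonated

    The thermodynamic cycle must close:
    ``pk_a_first + pk_b_given_a == pk_b_first + pk_a_given_b``.
    """

    pk_a_first: float
    pk_b_first: float
    pk_a_given_b: float
    pk_b_given_a: float

    def __post_init__(self) -> None:
        for name in ("pk_a_first", "pk_b_first", "pk_a_given_b", "pk_b_given_a"):
            _check_finite(name, getattr(self, name))
        gap = (self.pk_a_first + self.pk_b_given_a) - (self.pk_b_first + self.pk_a_given_b)
        if abs(gap) > CYCLE_TOL:
            raise ValueError(
                f"thermodynamic cycle does not close: "
                f"pk_a_first + pk_b_given_a - pk_b_first - pk_a_given_b = {gap:g}"
            )

    @classmethod
    def from_three(
        cls,
        pk_a_first: float,
        pk_b_first: float,
        pk_b_given_a: float,
    ) -> "CoupledSiteModel":
        """Build a model from three constants, deriving the fourth by closure."""
        pk_a_given_b = pk_a_first + pk_b_given_a - pk_b_first
        return cls(pk_a_first, pk_b_first, pk_a_given_b, pk_b_given_a)

    @classmethod
    def symmetric(cls, pk_low: float, pk_high: float) -> "CoupledSiteModel":
        """Symmetric coupled model: either site may titrate first at ``pk_low``,
        and the remaining site then titrates at ``pk_high``.

        This is the scheme behind a double sigmoid with two almost equal
        steps, as seen for the Asp/Cys pair of a Q488A-like active site.
        """
        return cls(pk_low, pk_low, pk_high, pk_high)

    @property
    def first_step_fraction_b(self) -> float:
        """Fraction of the first macroscopic transition carried by site B.

        Equals ``K_B / (K_A + K_B)``; 0.5 for a symmetric model ("two almost
        equal steps" in the site-B observable).
        """
        # stable ratio: 1 / (1 + K_A/K_B)
        return 1.0 / (1.0 + 10.0 ** (self.pk_b_first - self.pk_a_first))


@dataclass(frozen=True)
class MicrostateFractions:
    """Populations of the four protonation microstates at one pH.

    ``f_hh``: both sites protonated; ``f_ah``: A deprotonated only;
    ``f_hb``: B deprotonated only; ``f_ab``: both deprotonated.
    """

    f_hh: float
    f_ah: float
    f_hb: float
    f_ab: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_hh, self.f_ah, self.f_hb, self.f_ab])


def shift_one_pka(ph, params: OnePkaParams):
    """Chemical shift (ppm) of a single-pKa titration at ``ph``.

    Accepts a scalar or array pH.  Evaluated in a logistic form that stays
    finite for |pH - pKa| up to hundreds of units.
    """
    ph = np.asarray(ph, dtype=float)
    _check_finite("ph", ph)
    # fraction deprotonated = 1 / (1 + 10**(pKa - pH))
    x = _LN10 * (ph - params.pka)
    with np.errstate(over="ignore"):
        f = 1.0 / (1.0 + np.exp(-x))
    out = params.delta_protonated + (params.delta_deprotonated - params.delta_protonated) * f
    return out if out.ndim else float(out)


def shift_two_pka(ph, params: TwoPkaParams):
    """Chemical shift (ppm) of a two-pKa titration at ``ph`` (scalar or array).

    Uses an exponent-shifted (softmax) evaluation of the three Boltzmann-like
    terms so the curve is finite far outside the titration window.
    """
    ph = np.asarray(ph, dtype=float)
    _check_finite("ph", ph)
    e0 = np.zeros_like(ph)
    e1 = _LN10 * (ph - params.pka1)
    e2 = _LN10 * (2.0 * ph - params.pka1 - params.pka2)
    m = np.maximum(e0, np.maximum(e1, e2))
    w0 = np.exp(e0 - m)
    w1 = np.exp(e1 - m)
    w2 = np.exp(e2 - m)
    out = (
        params.delta_state0 * w0 + params.delta_state1 * w1 + params.delta_state2 * w2
    ) / (w0 + w1 + w2)
    return out if out.ndim else float(out)


def _microstate_weight_exponents(ph, model: CoupledSiteModel):
    """Log-scale (natural log) statistical weights of the four microstates.

    Relative to the fully protonated state HH, the weights are
    1 : K_A/[H] : K_B/[H] : K_A*K_B|A/[H]^2 with [H] = 10**-pH.
    """
    ph = np.asarray(ph, dtype=float)
    e_hh = np.zeros_like(ph)
    e_ah = _LN10 * (ph - model.pk_a_first)
    e_hb = _LN10 * (ph - model.pk_b_first)
    e_ab = _LN10 * (2.0 * ph - model.pk_a_first - model.pk_b_given_a)
    return e_hh, e_ah, e_hb, e_ab


def microstate_fractions(ph: float, model: CoupledSiteModel) -> MicrostateFractions:
    """Population fractions of the four microstates at ``ph``.

    Computed from the partition function
    ``Z = 1 + (K_A + K_B)/[H] + K_A*K_B|A/[H]**2`` via a numerically stable
    softmax; the fractions sum to 1 to ~1e-15.
    """
    _check_finite("ph", ph)
    exps = _microstate_weight_exponents(float(ph), model)
    m = max(float(e) for e in exps)
    ws = [math.exp(float(e) - m) for e in exps]
    z = sum(ws)
    return MicrostateFractions(*(w / z for w in ws))


def site_deprotonation_fraction(
    ph, model: CoupledSiteModel, site: Literal["A", "B"]
):
    """Fraction of molecules in which ``site`` is deprotonated at ``ph``.

    For site B this is ``f_hb + f_ab`` (and analogously for A); it is a
    monotone nondecreasing double sigmoid identical to the two-pKa closed
    form evaluated with the macroscopic constants and an intermediate plateau
    of ``K_B/(K_A+K_B)`` (site B) or ``K_A/(K_A+K_B)`` (site A).
    Accepts scalar or array pH.
    """
    if site not in ("A", "B"):
        raise ValueError(f"site must be 'A' or 'B', got {site!r}")
    ph_arr = np.asarray(ph, dtype=float)
    _check_finite("ph", ph_arr)
    e_hh, e_ah, e_hb, e_ab = _microstate_weight_exponents(ph_arr, model)
    m = np.maximum(np.maximum(e_hh, e_ah), np.maximum(e_hb, e_ab))
    w_hh = np.exp(e_hh - m)
    w_ah = np.exp(e_ah - m)
    w_hb = np.exp(e_hb - m)
    w_ab = np.exp(e_ab - m)
    z = w_hh + w_ah + w_hb + w_ab
    num = (w_ah + w_ab) if site == "A" else (w_hb + w_ab)
    out = num / z
    return out if out.ndim else float(out)


def macroscopic_from_microscopic(model: CoupledSiteModel) -> tuple[float, float]:
    """Macroscopic (total-proton-count) pKas of a coupled two-site model.

    ``Ka1 = K_A + K_B`` and ``Ka2 = K_A * K_B|A / (K_A + K_B)``; returned as
    ``(-log10 Ka1, -log10 Ka2)`` with ``pka1_macro <= pka2_macro``.  For a
    symmetric model the statistical factor log10(2) splits the macroscopic
    values outward from the shared microscopic pair.
    """
    # pKa1 = -log10(K_A + K_B), stable via logaddexp in base e
    la = -_LN10 * model.pk_a_first
    lb = -_LN10 * model.pk_b_first
    pka1 = -float(np.logaddexp(la, lb)) / _LN10
    # Ka1*Ka2 = K_A * K_B|A  =>  pKa1 + pKa2 = pk_a_first + pk_b_given_a
    pka2 = model.pk_a_first + model.pk_b_given_a - pka1
    return (pka1, pka2) if pka1 <= pka2 else (pka2, pka1)


def microscopic_from_macroscopic(
    pka1_macro: float,
    pka2_macro: float,
    first_step_fraction_b: float,
) -> CoupledSiteModel:
    """Invert the macroscopic description back to microscopic constants.

    The two macroscopic pKas alone under-determine the four microscopic
    constants; the additional observable is the fraction of the first
    macroscopic transition carried by site B, ``r = K_B/(K_A+K_B)`` — in an
    NMR titration of a site-B reporter this is the relative height of the
    first step of the double sigmoid.  ``r = 0.5`` ("two almost equal
    steps") recovers the symmetric model.

    Raises ``ValueError`` unless ``0 < r < 1``.
    """
    r = float(first_step_fraction_b)
    if not (0.0 < r < 1.0):
        raise ValueError(f"first_step_fraction_b must be in (0, 1), got {r}")
    _check_finite("pka1_macro", pka1_macro)
    _check_finite("pka2_macro", pka2_macro)
    # K_B = r*Ka1, K_A = (1-r)*Ka1, K_B|A = Ka1*Ka2/K_A, K_A|B by closure.
    pk_b_first = pka1_macro - math.log10(r)
    pk_a_first = pka1_macro - math.log10(1.0 - r)
    pk_b_given_a = pka1_macro + pka2_macro - pk_a_first
    return CoupledSiteModel.from_three(pk_a_first, pk_b_first, pk_b_given_a)
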