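"""Isotopocule algebra and mixing/fractionation primitives.

The asymmetric N2O molecule carries three independent natural-abundance
tracers: the site preference ``SP = d15N_alpha - d15N_beta`` (alpha is the
central N atom, beta the terminal one), the bulk ``d15N`` (their average) and
``d18O``. Each microbial production pathway emits N2O within a characteristic
(SP, d18O) window, and partial reduction of N2O to N2 shifts the residual gas
along a Rayleigh (closed-system) line ``delta_r = delta_0 + eps * ln(r)``
where ``r`` is the unreduced fraction.

This module implements the delta-scale arithmetic shared by the linear-system
and Bayesian partitioners: delta definitions, alpha/beta <-> bulk/SP
conversions, the Rayleigh reduction shift, microscopic product ratios,
background subtraction of ambient N2O, and the soil-water reference shift for
d18O.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import (
    DomainError,
    InvalidInputError,
    NoEmissionError,
    UndefinedRatioError,
)

__all__ = [
    "Process",
    "PROCESS_ORDER",
    "DeltaValue",
    "IsotopoculeDelta",
    "ProcessSignature",
    "SourceLibrary",
    "delta_from_ratio",
    "ratio_from_delta",
    "bulk_sp_from_alpha_beta",
    "alpha_beta_from_bulk_sp",
    "reduction_shift",
    "micro_ratio_rm",
    "micro_ratio_mr",
    "emitted_signature",
    "water_correct",
    "sd_from_range",
]

_CONSISTENCY_TOL = 1e-9  # permil, pure-arithmetic identities


class Process(str, Enum):
    """The four modeled microbial N2O sources."""

    BD = "bD"  # bacterial denitrification
    FD = "fD"  # fungal denitrification
    NI = "Ni"  # nitrification
    ND = "nD"  # nitrifier denitrification


#: Canonical ordering of sources in every vector/matrix of this package.
PROCESS_ORDER: tuple[Process, ...] = (Process.BD, Process.FD, Process.NI, Process.ND)


@dataclass(frozen=True)
class DeltaValue:
    """A per-mil isotopic delta relative to a named reference.

    Parameters
    ----------
    value : float
        Delta in permil. Must exceed -1000 permil (the underlying isotope
        ratio must stay positive).
    reference : str
        ``"air-N2"`` for 15N, ``"VSMOW"`` for 18O, or ``"soil-water"`` for
        water-corrected d18O.
    """

    value: float
    reference: str = "air-N2"

    _REFERENCES = ("air-N2", "VSMOW", "soil-water")

    def __post_init__(self):
        if self.reference not in self._REFERENCES:
            raise InvalidInputError(
                f"unknown reference {self.reference!r}; expected one of {self._REFERENCES}"
            )
        if not self.value > -1000.0:
            raise InvalidInputError(
                f"delta = {self.value} permil implies a non-positive isotope ratio"
            )


@dataclass(frozen=True)
class IsotopoculeDelta:
    """Complete position-resolved N2O isotopic composition (permil).

    ``d15N_bulk`` and ``d15N_SP`` must be consistent with the site-specific
    values: bulk is the mean of alpha and beta, SP their difference.
    """

    d15N_alpha: float
    d15N_beta: float
    d15N_bulk: float
    d15N_SP: float
    d18O: float

    def __post_init__(self):
        bulk, sp = bulk_sp_from_alpha_beta(self.d15N_alpha, self.d15N_beta)
        if abs(bulk - self.d15N_bulk) > _CONSISTENCY_TOL:
            raise InvalidInputError(
                f"d15N_bulk={self.d15N_bulk} inconsistent with (alpha+beta)/2={bulk}"
            )
        if abs(sp - self.d15N_SP) > _CONSISTENCY_TOL:
            raise InvalidInputError(
                f"d15N_SP={self.d15N_SP} inconsistent with alpha-beta={sp}"
            )

    @classmethod
    def from_alpha_beta(cls, alpha: float, beta: float, d18O: float) -> "IsotopoculeDelta":
        bulk, sp = bulk_sp_from_alpha_beta(alpha, beta)
        return cls(alpha, beta, bulk, sp, d18O)

    @classmethod
    def from_bulk_sp(cls, bulk: float, sp: float, d18O: float) -> "IsotopoculeDelta":
        alpha, beta = alpha_beta_from_bulk_sp(bulk, sp)
        return cls(alpha, beta, bulk, sp, d18O)


@dataclass(frozen=True)
class ProcessSignature:
    """Isotopic end member of one production pathway.

    SP and d18O are permil; d18O is referenced to soil water (the literature
    values are tabulated for d18O_H2O = 0).
    """

    process: Process
    sp_mean: float
    sp_sd: float
    o18_mean: float
    o18_sd: float

    def __post_init__(self):
        if self.sp_sd < 0 or self.o18_sd < 0:
            raise InvalidInputError(f"negative SD in signature for {self.process}")


# Literature source signatures (permil, mean/SD) and net reduction isotope
# effects. SDs follow the half-range/2 convention of sd_from_range.
_DEFAULT_SIGNATURES = (
    ProcessSignature(Process.BD, -1.90, 2.8, 19.20, 1.65),
    ProcessSignature(Process.FD, 33.50, 3.18, 47.20, 3.28),
    ProcessSignature(Process.NI, 35.00, 1.68, 23.50, 3.0),
    ProcessSignature(Process.ND, -5.9, 3.88, 16.8, 1.25),
)


@dataclass(frozen=True)
class SourceLibrary:
    """The four source signatures plus the N2O-reduction isotope effects.

    ``eps_sp`` and ``eps_o`` are the net closed-system enrichment factors for
    SP and d18O during N2O -> N2 reduction (both negative: the residual N2O
    gets isotopically heavier as reduction proceeds).
    """

    signatures: tuple[ProcessSignature, ...] = _DEFAULT_SIGNATURES
    eps_sp_mean: float = -5.0
    eps_sp_sd: float = 1.35
    eps_o_mean: float = -15.0
    eps_o_sd: float = 5.0

    def __post_init__(self):
        procs = [s.process for s in self.signatures]
        if sorted(p.value for p in procs) != sorted(p.value for p in PROCESS_ORDER):
            raise InvalidInputError(
                f"library must contain exactly one signature per process, got {procs}"
            )
        if self.eps_sp_sd < 0 or self.eps_o_sd < 0:
            raise InvalidInputError("negative SD for a reduction isotope effect")
        # normalize ordering to PROCESS_ORDER
        ordered = tuple(sorted(self.signatures, key=lambda s: PROCESS_ORDER.index(s.process)))
        object.__setattr__(self, "signatures", ordered)

    @classmethod
    def default(cls) -> "SourceLibrary":
        """Library with the shipped literature values."""
        return cls()

    # -- array views in PROCESS_ORDER ------------------------------------
    @property
    def sp_means(self) -> np.ndarray:
        return np.array([s.sp_mean for s in self.signatures])

    @property
    def sp_sds(self) -> np.ndarray:
        return np.array([s.sp_sd for s in self.signatures])

    @property
    def o18_means(self) -> np.ndarray:
        return np.array([s.o18_mean for s in self.signatures])

    @property
    def o18_sds(self) -> np.ndarray:
        return np.array([s.o18_sd for s in self.signatures])

    def draw(self, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
        """Draw ``n`` independent normal realizations of all library parameters.

        Column order within each array is PROCESS_ORDER. Returns a dict with
        keys ``sp`` (n, 4), ``o18`` (n, 4), ``eps_sp`` (n,), ``eps_o`` (n,).
        The draw order (sp block, o18 block, eps_sp, eps_o) is part of the
        reproducibility contract.
        """
        sp = rng.normal(self.sp_means, self.sp_sds, size=(n, 4))
        o18 = rng.normal(self.o18_means, self.o18_sds, size=(n, 4))
        eps_sp = rng.normal(self.eps_sp_mean, self.eps_sp_sd, size=n)
        eps_o = rng.normal(self.eps_o_mean, self.eps_o_sd, size=n)
        return {"sp": sp, "o18": o18, "eps_sp": eps_sp, "eps_o": eps_o}


# ---------------------------------------------------------------------------
# scalar/array operations
# ---------------------------------------------------------------------------

def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Delta (permil) of a sample isotope ratio against a standard ratio.

    ``delta = (R_sample / R_standard - 1) * 1000``.
    """
    if np.any(np.asarray(r_sample) <= 0) or np.any(np.asarray(r_standard) <= 0):
        raise InvalidInputError("isotope ratios must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def ratio_from_delta(delta_permil: float, r_standard: float) -> float:
    """Inverse of :func:`delta_from_ratio`."""
    if np.any(np.asarray(r_standard) <= 0):
        raise InvalidInputError("standard ratio must be positive")
    return r_standard * (1.0 + delta_permil / 1000.0)


def bulk_sp_from_alpha_beta(alpha: float, beta: float) -> tuple[float, float]:
    """(bulk, SP) from the site-specific deltas: mean and difference."""
    return (alpha + beta) / 2.0, alpha - beta


def alpha_beta_from_bulk_sp(bulk: float, sp: float) -> tuple[float, float]:
    """(alpha, beta) from bulk and site preference; exact inverse of
    :func:`bulk_sp_from_alpha_beta`."""
    return bulk + sp / 2.0, bulk - sp / 2.0


def reduction_shift(delta0, epsilon, r_n2o):
    """Closed-system (Rayleigh) isotopic shift of residual N2O.

    ``delta_r = delta_0 + eps * ln(r)`` with ``r`` the unreduced N2O fraction
    in (0, 1]. With the (negative) literature eps values the residual gas is
    enriched relative to the produced gas. Accepts scalars or arrays.
    """
    r = np.asarray(r_n2o, dtype=float)
    if np.any(r <= 0) or np.any(r > 1):
        raise DomainError(f"r_n2o must lie in (0, 1], got {r_n2o}")
    out = np.asarray(delta0, dtype=float) + np.asarray(epsilon, dtype=float) * np.log(r)
    return float(out) if out.ndim == 0 else out


def _product_ratio(num, den, what: str) -> float:
    if num < 0 or den < 0:
        raise InvalidInputError(f"{what}: fluxes must be non-negative")
    if num == 0 and den == 0:
        raise UndefinedRatioError(f"{what}: both fluxes are zero")
    return num / (num + den)


def micro_ratio_rm(n2o_bD: float, n2_bD: float) -> float:
    """Microscopic product ratio of the reduction-then-mixing scenario:
    bacterial N2O over bacterial (N2O + N2)."""
    return _product_ratio(n2o_bD, n2_bD, "micro_ratio_rm")


def micro_ratio_mr(n2o_emitted: float, n2_emitted: float) -> float:
    """Microscopic product ratio of the mixing-then-reduction scenario:
    total emitted N2O over emitted (N2O + N2)."""
    return _product_ratio(n2o_emitted, n2_emitted, "micro_ratio_mr")


def emitted_signature(c_mix: float, d_mix: float, c_air: float, d_air: float) -> float:
    """Isotopic signature of the emitted N2O by background subtraction.

    Two-member mixing of ambient air N2O and soil-emitted N2O:
    ``c_mix * d_mix = c_air * d_air + (c_mix - c_air) * d_emitted``.
    Concentrations in ppm, deltas in permil.
    """
    if c_air < 0:
        raise InvalidInputError("air concentration must be non-negative")
    if c_mix <= c_air:
        raise NoEmissionError(
            f"mixture N2O ({c_mix} ppm) does not exceed background ({c_air} ppm)"
        )
    return (c_mix * d_mix - c_air * d_air) / (c_mix - c_air)


def water_correct(d18O_n2o: float, d18O_h2o: float) -> float:
    """Re-reference d18O of N2O from VSMOW to soil water by subtracting the
    soil-water d18O (both permil vs VSMOW)."""
    return d18O_n2o - d18O_h2o


def sd_from_range(range_halfwidth: float) -> float:
    """Standard deviation from a tabulated half-range, under the convention
    that a published range spans mean +/- 2 SD."""
    if range_halfwidth < 0:
        raise InvalidInputError("range half-width must be non-negative")
    return range_halfwidth / 2.0
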