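"""15N gas-flux (15NGF) calculations.

A soil amended with highly enriched 15NO3- emits N2 and N2O whose heavy
isotopologue abundances (29/30 for N2, 45/46 for N2O) carry two pieces of
information: the 15N atom fraction ``a_p`` of the emitting (denitrifying)
pool and the fraction ``d`` of the sampled gas derived from that pool.
Under random (binomial) isotope pairing within each pool, the excess mole
fractions of the heavy isotopologues over a natural-abundance background
``a_b`` are

    x_single_xs = d * [2 a_p (1 - a_p) - 2 a_b (1 - a_b)]
    x_double_xs = d * [a_p^2 - a_b^2]

which invert in closed form through a quadratic in ``a_p``. From the
pool-derived fractions and the headspace concentration changes this module
derives the denitrified N2O and N2 fluxes, the source partitioning
coefficient ``SPC = N2O_denitrified / N2O_emitted`` and the macroscopic
product ratio ``R_N2O = N2O_denitrified / (N2O_denitrified + N2_denitrified)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as k
from .exceptions import (
    BelowDetectionError,
    InconsistentExcessError,
    InvalidInputError,
    UndefinedRatioError,
)

__all__ = [
    "HeadspaceSample",
    "IncubationSetup",
    "PoolEnrichment",
    "FluxSummary",
    "ExcessFractions",
    "binomial_isotopologue_fractions",
    "excess_isotopologue_fractions",
    "pool_enrichment_from_excess",
    "headspace_flux",
    "ppm_from_flux",
    "spc",
    "macro_ratio",
    "gasflux_pipeline",
]

logger = logging.getLogger(__name__)

_D_TOL = 1e-6  # tolerance on the pool-derived fraction upper bound


@dataclass(frozen=True)
class HeadspaceSample:
    """One headspace gas sample from a jar incubation.

    ``r29``/``r30`` are N2 isotopologue ratios to mass 28; ``r45``/``r46``
    are N2O isotopologue ratios to mass 44 (assumed already corrected for
    17O unless the pipeline's correction toggle is used).
    ``cumulative_dilution`` is the product of the dilution factors of all
    sampling events that occurred after jar closure and before this sample
    (1.0 for the sample taken at closure).
    """

    replicate: str
    time: float          # hours since closure
    n2o_conc: float      # ppm
    r29: float
    r30: float
    r45: float
    r46: float
    cumulative_dilution: float = 1.0

    def __post_init__(self):
        if self.time < 0:
            raise InvalidInputError("sample time must be non-negative")
        if self.n2o_conc < 0:
            raise InvalidInputError("N2O concentration must be non-negative")
        for name in ("r29", "r30", "r45", "r46"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if not 0 < self.cumulative_dilution <= 1:
            raise InvalidInputError("cumulative_dilution must be in (0, 1]")


@dataclass(frozen=True)
class IncubationSetup:
    """Geometry and conditions of a sealed-jar soil incubation.

    Defaults reproduce a 450 mL jar with 150 g fresh soil flooded with 60 mL
    of nitrate solution, sampled by replacing 30 mL of headspace with lab
    air. If ``headspace_volume`` is not given it is estimated as the jar
    volume minus added water and soil solids (particle density 2.65 kg/L);
    an explicit value should be preferred for flooded soils.
    """

    jar_volume: float = 0.450          # L
    soil_mass: float = 0.150           # kg fresh soil
    water_added: float = 0.060         # L
    sample_volume: float = 0.030       # L replaced per sampling event
    temperature: float = 20.0          # degrees C
    background_atom_fraction: float = k.R15_AIR_N2  # natural 15N abundance
    headspace_volume: float | None = None

    def __post_init__(self):
        if self.headspace_volume is None:
            v = self.jar_volume - self.water_added - self.soil_mass / k.SOIL_PARTICLE_DENSITY
            object.__setattr__(self, "headspace_volume", v)
        if self.headspace_volume <= 0:
            raise InvalidInputError("headspace volume must be positive")
        if self.sample_volume >= self.headspace_volume:
            raise InvalidInputError("sample volume must be smaller than the headspace")
        if not 0 < self.background_atom_fraction < 1:
            raise InvalidInputError("background atom fraction must be in (0, 1)")

    @property
    def dilution_factor(self) -> float:
        """Fraction of headspace gas remaining after one sampling event."""
        return (self.headspace_volume - self.sample_volume) / self.headspace_volume

    @property
    def temperature_K(self) -> float:
        return self.temperature + k.ZERO_CELSIUS_K


@dataclass(frozen=True)
class PoolEnrichment:
    """15N atom fraction of the emitting pool and pool-derived gas fraction."""

    a_p: float
    d: float

    def __post_init__(self):
        if not 0 < self.a_p < 1:
            raise InvalidInputError("a_p must be an atom fraction in (0, 1)")
        if not -_D_TOL <= self.d <= 1 + _D_TOL:
            raise InvalidInputError("d must be a fraction in [0, 1]")


@dataclass(frozen=True)
class FluxSummary:
    """Across-replicate summary of the 15NGF stage (fluxes in ugN kg-1 h-1)."""

    n2o_total: float
    n2o_total_sd: float
    n2o_denitrified: float
    n2o_denitrified_sd: float
    n2_denitrified: float
    n2_denitrified_sd: float
    spc: float
    spc_sd: float
    r_macro: float
    r_macro_sd: float
    a_p_n2o: float = float("nan")
    a_p_n2o_sd: float = float("nan")
    a_p_n2: float = float("nan")
    a_p_n2_sd: float = float("nan")
    n_replicates: int = 0

    def __post_init__(self):
        if not 0 <= self.spc <= 1 or not 0 <= self.r_macro <= 1:
            raise InvalidInputError("SPC and R_N2O must be fractions in [0, 1]")
        if self.n2o_denitrified > self.n2o_total * (1 + 1e-9):
            raise InvalidInputError("denitrified N2O cannot exceed total N2O")


@dataclass(frozen=True)
class ExcessFractions:
    """Dilution-corrected heavy-isotopologue excess mole fractions.

    N2 excesses are relative to the whole headspace N2; N2O excesses are
    relative to the *emitted* N2O (background air N2O subtracted first), so
    the pool-derived fraction recovered from them is directly the SPC.
    Excesses may be negative within instrument noise; they are flagged via
    the ``*_below_detection`` fields, never clipped.
    """

    x29_xs: float
    x30_xs: float
    x45_xs: float
    x46_xs: float
    n2o_emitted_ppm: float
    n2_below_detection: bool
    n2o_below_detection: bool


def binomial_isotopologue_fractions(a: float) -> tuple[float, float, float]:
    """(light, single-heavy, double-heavy) mole fractions of a diatomic-N
    species whose N atoms are drawn independently at atom fraction ``a``."""
    return (1 - a) ** 2, 2 * a * (1 - a), a * a


def _mole_fractions(r_single: float, r_double: float) -> tuple[float, float]:
    """Heavy-isotopologue mole fractions from ratios to the light mass."""
    norm = 1.0 + r_single + r_double
    return r_single / norm, r_double / norm


def seventeen_o_correct(r45_raw: float, r17_standard: float = 0.000373) -> float:
    """Remove the 17O contribution from a raw N2O mass-45 ratio.

    Mass 45 collects both 14N15N16O/15N14N16O and 14N14N17O; with 17O at its
    standard abundance the correction is a constant subtraction of the 17O/16O
    ratio. Used only when the pipeline's ``correct_17o`` toggle is on.
    """
    return r45_raw - r17_standard


def excess_isotopologue_fractions(
    sample: HeadspaceSample, background: HeadspaceSample
) -> ExcessFractions:
    """Heavy-isotopologue excesses of a sample over its pre-closure background.

    The background sample (time 0, same replicate) defines both the ambient
    isotopologue composition and the ambient N2O concentration. Dilution from
    headspace sampling is undone by dividing accumulated excesses by the
    sample's cumulative dilution factor.
    """
    if sample.replicate != background.replicate:
        raise InvalidInputError(
            f"sample replicate {sample.replicate!r} != background {background.replicate!r}"
        )
    phi = sample.cumulative_dilution / background.cumulative_dilution

    # N2: ambient N2 dominates, so total N2 is treated as constant and the
    # within-N2 mole-fraction excess scales with the dilution factor.
    x29_s, x30_s = _mole_fractions(sample.r29, sample.r30)
    x29_b, x30_b = _mole_fractions(background.r29, background.r30)
    x29_xs = (x29_s - x29_b) / phi
    x30_xs = (x30_s - x30_b) / phi
    n2_below = (
        abs(sample.r29 - background.r29) < k.DETECTION_SIGMA_FACTOR * k.IRMS_SIGMA_R29
        and abs(sample.r30 - background.r30) < k.DETECTION_SIGMA_FACTOR * k.IRMS_SIGMA_R30
    )

    # N2O: subtract the background air N2O at the isotopologue level, then
    # express the heavy excesses per mole of emitted N2O.
    x45_s, x46_s = _mole_fractions(sample.r45, sample.r46)
    x45_b, x46_b = _mole_fractions(background.r45, background.r46)
    c_em = (sample.n2o_conc - background.n2o_conc) / phi
    if c_em > 0:
        h45_em = (x45_s * sample.n2o_conc - x45_b * background.n2o_conc) / phi
        h46_em = (x46_s * sample.n2o_conc - x46_b * background.n2o_conc) / phi
        x45_xs = h45_em / c_em - x45_b
        x46_xs = h46_em / c_em - x46_b
    else:
        x45_xs = x46_xs = 0.0
    n2o_below = c_em <= 0 or (
        abs(sample.r45 - background.r45) < k.DETECTION_SIGMA_FACTOR * k.IRMS_SIGMA_R45
        and abs(sample.r46 - background.r46) < k.DETECTION_SIGMA_FACTOR * k.IRMS_SIGMA_R46
    )

    return ExcessFractions(
        x29_xs=x29_xs,
        x30_xs=x30_xs,
        x45_xs=x45_xs,
        x46_xs=x46_xs,
        n2o_emitted_ppm=c_em,
        n2_below_detection=n2_below,
        n2o_below_detection=n2o_below,
    )


def pool_enrichment_from_excess(
    x_single_xs: float, x_double_xs: float, a_bgd: float
) -> PoolEnrichment:
    """Invert the two-pool binomial model for (a_p, d).

    Solves ``x_single_xs = d [2 a_p(1-a_p) - 2 a_b(1-a_b)]`` and
    ``x_double_xs = d [a_p^2 - a_b^2]`` in closed form: their ratio yields
    a quadratic ``(2 + q) a_p^2 - 2 a_p + [2 a_b(1-a_b) - q a_b^2] = 0``
    with ``q = x_single_xs / x_double_xs``, whose root in ``(a_b, 1)`` is the
    pool enrichment; ``d`` follows from the double-heavy equation.

    Raises
    ------
    BelowDetectionError
        If no root exists in ``(a_bgd, 1)`` (excesses at or below background).
    InconsistentExcessError
        If the implied pool-derived fraction falls outside ``[0, 1]``.
    """
    if not 0 <= a_bgd < 1:
        raise InvalidInputError("background atom fraction must be in [0, 1)")
    if x_double_xs <= 0:
        raise BelowDetectionError(
            f"double-heavy excess {x_double_xs:.3g} <= 0: no labeled pool detectable"
        )
    q = x_single_xs / x_double_xs
    a_coef = 2.0 + q
    c_coef = 2 * a_bgd * (1 - a_bgd) - q * a_bgd * a_bgd
    disc = 1.0 - a_coef * c_coef
    if disc < 0 or a_coef <= 0:
        raise BelowDetectionError("no real pool enrichment solves the excess pair")
    root = math.sqrt(disc)
    candidates = [(1.0 + root) / a_coef, (1.0 - root) / a_coef]
    a_p = next((a for a in candidates if a_bgd < a < 1), None)
    if a_p is None:
        raise BelowDetectionError(
            f"no pool enrichment in ({a_bgd}, 1); candidates {candidates}"
        )
    d = x_double_xs / (a_p * a_p - a_bgd * a_bgd)
    if not -_D_TOL <= d <= 1 + _D_TOL:
        raise InconsistentExcessError(
            f"pool-derived fraction d = {d:.4g} outside [0, 1]"
        )
    return PoolEnrichment(a_p=a_p, d=min(max(d, 0.0), 1.0))


def headspace_flux(
    c_t0: float,
    c_t1: float,
    interval: float,
    setup: IncubationSetup,
    n_atoms: int = 2,
) -> float:
    """Convert a headspace concentration change (ppm, dilution-corrected)
    into a nitrogen flux in ugN per kg soil per hour, via the ideal gas law
    at the incubation temperature and 1 atm."""
    if interval <= 0:
        raise InvalidInputError("interval must be positive")
    mol = (c_t1 - c_t0) * 1e-6 * setup.headspace_volume / (
        k.R_GAS_L_ATM * setup.temperature_K
    )
    micrograms_n = mol * n_atoms * k.N_MOLAR_MASS * 1e6
    return micrograms_n / setup.soil_mass / interval


def ppm_from_flux(
    flux: float, duration: float, setup: IncubationSetup, n_atoms: int = 2
) -> float:
    """Headspace concentration increase (ppm) accumulated by a constant
    nitrogen flux over ``duration`` hours; inverse of :func:`headspace_flux`."""
    micrograms_n = flux * setup.soil_mass * duration
    mol = micrograms_n / (n_atoms * k.N_MOLAR_MASS * 1e6)
    return mol * k.R_GAS_L_ATM * setup.temperature_K / setup.headspace_volume * 1e6


def spc(n2o_denitrified: float, n2o_total: float) -> float:
    """Source partitioning coefficient: fraction of emitted N2O derived from
    the (denitrifying) nitrate pool."""
    if n2o_total <= 0:
        raise UndefinedRatioError("total N2O flux must be positive")
    if not -1e-9 <= n2o_denitrified <= n2o_total * (1 + 1e-9):
        raise InvalidInputError(
            f"denitrified N2O ({n2o_denitrified}) must lie in [0, total={n2o_total}]"
        )
    return min(max(n2o_denitrified / n2o_total, 0.0), 1.0)


def macro_ratio(n2o_denitrified: float, n2_denitrified: float) -> float:
    """Macroscopic product ratio R_N2O = N2O_den / (N2O_den + N2_den)."""
    if n2o_denitrified < 0 or n2_denitrified < 0:
        raise InvalidInputError("fluxes must be non-negative")
    if n2o_denitrified == 0 and n2_denitrified == 0:
        raise UndefinedRatioError("both denitrified fluxes are zero")
    return n2o_denitrified / (n2o_denitrified + n2_denitrified)


def _with_dilution(samples: list[HeadspaceSample], setup: IncubationSetup):
    """Fill in cumulative dilution factors from the sampling order if the
    caller left them at the default."""
    ordered = sorted(samples, key=lambda s: s.time)
    if any(s.cumulative_dilution != 1.0 for s in ordered):
        return ordered  # caller did their own bookkeeping
    phi = setup.dilution_factor
    return [replace(s, cumulative_dilution=phi**i) for i, s in enumerate(ordered)]


def gasflux_pipeline(
    samples: list[HeadspaceSample],
    setup: IncubationSetup | None = None,
    correct_17o: bool = False,
) -> FluxSummary:
    """Full 15NGF reduction: per-replicate pool enrichments, denitrified
    fluxes, SPC and R_N2O, averaged across replicates.

    Ratios (SPC, R_N2O) are computed per replicate and then averaged — not
    taken as ratios of mean fluxes — and SDs are across-replicate (ddof=1).
    Within each replicate the latest sample whose N2O isotopologue excess is
    above detection is used against the time-0 background; below-detection
    samples are excluded with a log record.
    """
    setup = setup or IncubationSetup()
    if correct_17o:
        samples = [
            replace(s, r45=seventeen_o_correct(s.r45)) for s in samples
        ]
    by_rep: dict[str, list[HeadspaceSample]] = {}
    for s in samples:
        by_rep.setdefault(s.replicate, []).append(s)

    rows = []
    diagnostics: dict[str, str] = {}
    a_b = setup.background_atom_fraction
    for rep, rep_samples in sorted(by_rep.items()):
        ordered = _with_dilution(rep_samples, setup)
        if len(ordered) < 2:
            diagnostics[rep] = "fewer than two time points"
            continue
        background = ordered[0]
        chosen = None
        for s in reversed(ordered[1:]):
            xs = excess_isotopologue_fractions(s, background)
            if xs.n2o_below_detection:
                logger.info(
                    "replicate %s t=%gh: N2O isotopologue excess below detection, excluded",
                    rep, s.time,
                )
                continue
            chosen = (s, xs)
            break
        if chosen is None:
            diagnostics[rep] = "all time points below N2O detection limit"
            continue
        s, xs = chosen
        interval = s.time - background.time
        n2o_total_flux = headspace_flux(
            0.0, xs.n2o_emitted_ppm, interval, setup, n_atoms=2
        )
        try:
            pe_n2o = pool_enrichment_from_excess(xs.x45_xs, xs.x46_xs, a_b)
        except (BelowDetectionError, InconsistentExcessError) as err:
            diagnostics[rep] = f"N2O pool inversion failed: {err}"
            continue
        spc_rep = pe_n2o.d  # excesses are per mole of *emitted* N2O
        n2o_den_flux = spc_rep * n2o_total_flux

        if xs.n2_below_detection:
            diagnostics[rep] = "N2 excess below detection"
            logger.info("replicate %s: N2 excess below detection, excluded", rep)
            continue
        try:
            pe_n2 = pool_enrichment_from_excess(xs.x29_xs, xs.x30_xs, a_b)
        except (BelowDetectionError, InconsistentExcessError) as err:
            diagnostics[rep] = f"N2 pool inversion failed: {err}"
            continue
        n2_den_ppm = pe_n2.d * k.N2_AIR_PPM
        n2_den_flux = headspace_flux(0.0, n2_den_ppm, interval, setup, n_atoms=2)

        rows.append(
            dict(
                replicate=rep,
                n2o_total=n2o_total_flux,
                n2o_den=n2o_den_flux,
                n2_den=n2_den_flux,
                spc=spc_rep,
                r_macro=macro_ratio(n2o_den_flux, n2_den_flux),
                a_p_n2o=pe_n2o.a_p,
                a_p_n2=pe_n2.a_p,
            )
        )

    if not rows:
        raise BelowDetectionError(
            f"no replicate yielded usable 15NGF data: {diagnostics}"
        )

    def agg(key):
        vals = np.array([r[key] for r in rows])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return float(np.mean(vals)), sd

    n2o_total = agg("n2o_total")
    n2o_den = agg("n2o_den")
    n2_den = agg("n2_den")
    spc_ms = agg("spc")
    r_ms = agg("r_macro")
    ap45 = agg("a_p_n2o")
    ap29 = agg("a_p_n2")
    return FluxSummary(
        n2o_total=n2o_total[0],
        n2o_total_sd=n2o_total[1],
        n2o_denitrified=min(n2o_den[0], n2o_total[0]),
        n2o_denitrified_sd=n2o_den[1],
        n2_denitrified=n2_den[0],
        n2_denitrified_sd=n2_den[1],
        spc=spc_ms[0],
        spc_sd=spc_ms[1],
        r_macro=r_ms[0],
        r_macro_sd=r_ms[1],
        a_p_n2o=ap45[0],
        a_p_n2o_sd=ap45[1],
        a_p_n2=ap29[0],
        a_p_n2_sd=ap29[1],
        n_replicates=len(rows),
    )
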