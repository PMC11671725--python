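"""Constrained Monte Carlo solution of the four-source mixing systems.

The emitted N2O is modeled as a mixture of four sources — bacterial
denitrification (bD), fungal denitrification (fD), nitrification (Ni) and
nitrifier denitrification (nD) — constrained by four equations:

    row 1:  d18O mixing of the four sources          = d18O_sample
    row 2:  d15N-SP mixing of the four sources       = d15N-SP_sample
    row 3:  f_bD + f_fD                              = SPC  (15N gas flux)
    row 4:  f_bD + f_fD + f_Ni + f_nD                = 1

Partial reduction of N2O to N2 shifts isotopic signatures by eps*ln(r).
In the reduction-then-mixing (RM) scenario only the bacterial source is
reduced before mixing, so the shift is applied to the bD column; in the
mixing-then-reduction (MR) scenario the mixture is reduced after mixing, so
the shift moves to the right-hand side of the two delta rows. The
microscopic product ratio r in the logarithm is approximated by the
macroscopic R_N2O measured by the 15N gas-flux method (valid when bacterial
denitrification dominates); an optional fixed-point mode re-solves the RM
system with r updated from the solved f_bD until convergence.

A direct solve of either system with mean parameters can return negative
fractions, so uncertainty is propagated by a constrained Monte Carlo: all
14 parameters (8 source signatures, 2 reduction effects, 2 sample deltas,
SPC, R_N2O) are drawn independently from normal distributions (SPC and
R_N2O truncated to (0, 1]), each draw's 4x4 system is solved exactly, and
the draw is accepted iff all four fractions lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateSystemError,
    DomainError,
    InvalidInputError,
    NoAcceptedDrawsError,
)
from .gas_flux import FluxSummary
from .iso_core import PROCESS_ORDER, SourceLibrary, reduction_shift

__all__ = [
    "Scenario",
    "EmittedMeasurement",
    "PartitionSolution",
    "MonteCarloRun",
    "effective_sources",
    "build_system",
    "solve_partition",
    "MonteCarloPartitioner",
    "monte_carlo_partition",
    "r_consistency_check",
]

_F_TOL = 1e-9          # acceptance tolerance on fraction bounds
_COND_LIMIT = 1e12     # condition-number threshold for a degenerate system

#: Fixed Monte Carlo draw order (reproducibility contract): the source
#: library block (sp[4], o18[4], eps_sp, eps_o) is drawn first from a single
#: generator, then sample SP, sample d18O, then truncated SPC and R_N2O.
MC_DRAW_ORDER = (
    "sp_bD", "sp_fD", "sp_Ni", "sp_nD",
    "o18_bD", "o18_fD", "o18_Ni", "o18_nD",
    "eps_sp", "eps_o", "sp_sample", "o18_sample", "spc", "r_n2o",
)


class Scenario(str, Enum):
    """Ordering of N2O reduction relative to mixing."""

    RM = "RM"  # reduction then mixing: only bacterial N2O is reduced
    MR = "MR"  # mixing then reduction: the mixed pool is reduced


def _as_scenario(scenario) -> Scenario:
    return Scenario(scenario)


@dataclass(frozen=True)
class EmittedMeasurement:
    """Summary measurement of the emitted N2O (deltas in permil vs soil
    water for d18O; SPC and R_N2O as fractions)."""

    sp_mean: float
    sp_sd: float
    o18_mean: float
    o18_sd: float
    spc_mean: float
    spc_sd: float
    r_mean: float
    r_sd: float

    def __post_init__(self):
        for name in ("sp_sd", "o18_sd", "spc_sd", "r_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if not 0 <= self.spc_mean <= 1:
            raise InvalidInputError("spc_mean must be a fraction in [0, 1]")
        if not 0 <= self.r_mean <= 1:
            raise InvalidInputError("r_mean must be a fraction in [0, 1]")


@dataclass(frozen=True)
class PartitionSolution:
    """A point on the source simplex (f_bD, f_fD, f_Ni, f_nD)."""

    f_bD: float
    f_fD: float
    f_Ni: float
    f_nD: float

    def __post_init__(self):
        f = self.as_array()
        if np.any(f < -_F_TOL) or np.any(f > 1 + _F_TOL):
            raise InvalidInputError(f"fractions outside [0, 1]: {f}")
        if abs(f.sum() - 1.0) > 1e-9:
            raise InvalidInputError(f"fractions must sum to 1, got {f.sum()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_bD, self.f_fD, self.f_Ni, self.f_nD])

    @classmethod
    def from_array(cls, f: Sequence[float]) -> "PartitionSolution":
        return cls(*(float(x) for x in f))


@dataclass
class MonteCarloRun:
    """Result of a constrained Monte Carlo partitioning run."""

    n_draws: int
    seed: int | None
    scenario: Scenario
    accepted: np.ndarray           # (m, 4) accepted fraction vectors
    accepted_spc: np.ndarray       # (m,) SPC draws of the accepted systems
    accepted_r: np.ndarray         # (m,) R_N2O draws of the accepted systems
    acceptance_count: int
    summary: pd.DataFrame          # index mean/sd, columns f_bD..f_nD
    rejection_diagnostics: dict = field(default_factory=dict)
    r_check: float | None = None

    @property
    def acceptance_rate(self) -> float:
        return self.acceptance_count / self.n_draws

    @property
    def mean(self) -> np.ndarray:
        return self.summary.loc["mean"].to_numpy()

    @property
    def sd(self) -> np.ndarray:
        return self.summary.loc["sd"].to_numpy()


# ---------------------------------------------------------------------------
# deterministic core
# ---------------------------------------------------------------------------

def effective_sources(library_draw: dict, scenario, r_draw: float):
    """Scenario-dependent effective source signatures.

    ``library_draw`` holds ``sp`` and ``o18`` arrays in source order plus
    ``eps_sp``/``eps_o`` scalars (or matching arrays). In the RM scenario the
    bacterial source is pre-shifted by eps*ln(r) in both isotopic dimensions;
    in the MR scenario the sources are returned unchanged (the shift is
    applied to the measurement side when the system is built).
    """
    scenario = _as_scenario(scenario)
    r = np.asarray(r_draw, dtype=float)
    if np.any(r <= 0) or np.any(r > 1):
        raise DomainError(f"r_draw must be in (0, 1], got {r_draw}")
    sp = np.array(library_draw["sp"], dtype=float, copy=True)
    o18 = np.array(library_draw["o18"], dtype=float, copy=True)
    if scenario is Scenario.RM:
        sp[..., 0] = reduction_shift(sp[..., 0], library_draw["eps_sp"], r)
        o18[..., 0] = reduction_shift(o18[..., 0], library_draw["eps_o"], r)
    return sp, o18


def build_system(
    library_draw: dict, measurement_draw: dict, scenario, r_draw: float
) -> np.ndarray:
    """Assemble the 4x5 augmented mixing matrix for one parameter draw.

    ``measurement_draw`` holds scalars ``sp``, ``o18`` and ``spc``.
    """
    scenario = _as_scenario(scenario)
    sp, o18 = effective_sources(library_draw, scenario, r_draw)
    rhs_sp = float(measurement_draw["sp"])
    rhs_o18 = float(measurement_draw["o18"])
    if scenario is Scenario.MR:
        lnr = np.log(r_draw)
        rhs_sp = rhs_sp - float(library_draw["eps_sp"]) * lnr
        rhs_o18 = rhs_o18 - float(library_draw["eps_o"]) * lnr
    system = np.zeros((4, 5))
    system[0, :4] = o18
    system[0, 4] = rhs_o18
    system[1, :4] = sp
    system[1, 4] = rhs_sp
    system[2, :4] = (1.0, 1.0, 0.0, 0.0)
    system[2, 4] = float(measurement_draw["spc"])
    system[3, :4] = 1.0
    system[3, 4] = 1.0
    return system


def solve_partition(system: np.ndarray) -> PartitionSolution:
    """Exact solve of one augmented 4x5 system.

    Raises :class:`DegenerateSystemError` when the source matrix is singular
    or its condition number exceeds 1e12 (e.g. two identical sources).
    """
    system = np.asarray(system, dtype=float)
    if system.shape != (4, 5):
        raise InvalidInputError(f"expected a 4x5 augmented matrix, got {system.shape}")
    a, b = system[:, :4], system[:, 4]
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise DegenerateSystemError(f"system condition number {cond:.3g} exceeds 1e12")
    f = np.linalg.solve(a, b)
    residual = np.abs(a @ f - b).max()
    if residual > 1e-9:
        raise DegenerateSystemError(f"solve residual {residual:.3g} exceeds 1e-9")
    # constraint rows guarantee sum == 1; renormalize away float dust only
    return PartitionSolution(*(float(x) for x in f))


def _truncnorm_01(rng, mean, sd, size):
    """Normal draws truncated to (0, 1]; degenerate SD returns the mean."""
    if sd == 0:
        if not 0 < mean <= 1:
            raise DomainError(f"degenerate ratio draw {mean} outside (0, 1]")
        return np.full(size, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


class MonteCarloPartitioner(BaseEstimator):
    """Constrained Monte Carlo estimator of the four-source partition.

    Parameters
    ----------
    scenario : {"RM", "MR"}
        Reduction/mixing ordering (see module docstring).
    n_draws : int
        Number of solved systems (rejected-and-redrawn ratio draws do not
        count, so exactly ``n_draws`` systems are solved).
    random_state : int or None
        Seed for the single numpy Generator driving every draw.
    source_library : SourceLibrary or None
        Source signatures and reduction effects; the shipped literature
        library when None.
    fixed_point : bool
        RM only: iterate r = f_bD*N2O/(f_bD*N2O + N2) (requires ``fluxes``)
        instead of using the drawn R_N2O in the logarithm.
    fluxes : FluxSummary or None
        Mean N2O/N2 fluxes used by the fixed-point mode and the
        r-consistency check.

    Attributes
    ----------
    accepted_ : ndarray of shape (m, 4)
        Accepted fraction vectors in source order (bD, fD, Ni, nD).
    acceptance_count_ : int
    summary_ : DataFrame with rows ``mean``/``sd`` over accepted draws.
    fractions_ : ndarray of shape (4,), the posterior-ensemble means.
    run_ : MonteCarloRun with the full ensemble and diagnostics.
    """

    def __init__(
        self,
        scenario: str = "RM",
        n_draws: int = 100_000,
        random_state: int | None = None,
        source_library: SourceLibrary | None = None,
        fixed_point: bool = False,
        fluxes: FluxSummary | None = None,
        max_fixed_point_iter: int = 100,
    ):
        self.scenario = scenario
        self.n_draws = n_draws
        self.random_state = random_state
        self.source_library = source_library
        self.fixed_point = fixed_point
        self.fluxes = fluxes
        self.max_fixed_point_iter = max_fixed_point_iter

    # -- internals -------------------------------------------------------
    def _draw_parameters(self, measurement: EmittedMeasurement, rng):
        lib = self.source_library or SourceLibrary.default()
        n = self.n_draws
        draws = lib.draw(rng, n)
        draws["sp_sample"] = rng.normal(measurement.sp_mean, measurement.sp_sd, size=n)
        draws["o18_sample"] = rng.normal(measurement.o18_mean, measurement.o18_sd, size=n)
        draws["spc"] = _truncnorm_01(rng, measurement.spc_mean, measurement.spc_sd, n)
        draws["r"] = _truncnorm_01(rng, measurement.r_mean, measurement.r_sd, n)
        return draws

    @staticmethod
    def _solve_batch(draws, scenario: Scenario, r: np.ndarray):
        """Vectorized solve of all drawn 4x4 systems; returns (n, 4) f."""
        n = r.shape[0]
        lnr = np.log(r)
        sp = draws["sp"].copy()
        o18 = draws["o18"].copy()
        rhs_sp = draws["sp_sample"].copy()
        rhs_o18 = draws["o18_sample"].copy()
        if scenario is Scenario.RM:
            sp[:, 0] = sp[:, 0] + draws["eps_sp"] * lnr
            o18[:, 0] = o18[:, 0] + draws["eps_o"] * lnr
        else:
            rhs_sp = rhs_sp - draws["eps_sp"] * lnr
            rhs_o18 = rhs_o18 - draws["eps_o"] * lnr
        a = np.zeros((n, 4, 4))
        a[:, 0, :] = o18
        a[:, 1, :] = sp
        a[:, 2, 0] = a[:, 2, 1] = 1.0
        a[:, 3, :] = 1.0
        b = np.column_stack([rhs_o18, rhs_sp, draws["spc"], np.ones(n)])
        with np.errstate(all="ignore"):
            try:
                f = np.linalg.solve(a, b[..., None])[..., 0]
            except np.linalg.LinAlgError:
                # fall back to per-draw solves, marking exact singularities
                f = np.full((n, 4), np.nan)
                for i in range(n):
                    try:
                        f[i] = np.linalg.solve(a[i], b[i])
                    except np.linalg.LinAlgError:
                        pass
        return f

    # -- estimator API ---------------------------------------------------
    def fit(self, measurement: EmittedMeasurement, y=None):
        """Run the constrained Monte Carlo against one measurement."""
        if not isinstance(measurement, EmittedMeasurement):
            raise InvalidInputError("fit expects an EmittedMeasurement")
        scenario = _as_scenario(self.scenario)
        if self.n_draws < 1:
            raise InvalidInputError("n_draws must be >= 1")
        rng = np.random.default_rng(self.random_state)
        draws = self._draw_parameters(measurement, rng)
        r = draws["r"]
        f = self._solve_batch(draws, scenario, r)

        not_converged = np.zeros(r.shape[0], dtype=bool)
        if self.fixed_point:
            if scenario is not Scenario.RM:
                raise InvalidInputError("fixed_point mode applies to the RM scenario")
            if self.fluxes is None:
                raise InvalidInputError("fixed_point mode requires fluxes")
            n2o, n2 = self.fluxes.n2o_total, self.fluxes.n2_denitrified

            def r_implied(frac):
                with np.errstate(invalid="ignore"):
                    fbd = np.clip(frac[:, 0], 1e-12, 1.0)
                    return fbd * n2o / (fbd * n2o + n2)

            # damped iteration: plain substitution can enter 2-cycles when
            # the solved f_bD responds strongly to r
            for _ in range(self.max_fixed_point_iter):
                f = self._solve_batch(draws, scenario, r)
                r_new = r_implied(f)
                delta = np.abs(r_new - r)
                r = 0.5 * (r + r_new)
                if np.nanmax(delta) < 1e-6:
                    break
            f = self._solve_batch(draws, scenario, r)
            with np.errstate(invalid="ignore"):
                not_converged = ~(np.abs(r_implied(f) - r) < 1e-5)

        finite = np.all(np.isfinite(f), axis=1)
        inside = (
            finite
            & ~not_converged
            & np.all((f >= -_F_TOL) & (f <= 1 + _F_TOL), axis=1)
        )
        accepted = f[inside]
        diagnostics = {
            "non_finite": int(np.sum(~finite)),
            "fixed_point_not_converged": int(np.sum(not_converged)),
            **{
                f"f_{p.value}_out_of_bounds": int(
                    np.sum(finite & ((f[:, i] < -_F_TOL) | (f[:, i] > 1 + _F_TOL)))
                )
                for i, p in enumerate(PROCESS_ORDER)
            },
        }
        if accepted.shape[0] == 0:
            raise NoAcceptedDrawsError(
                "no Monte Carlo draw satisfied the [0, 1] fraction constraints",
                diagnostics=diagnostics,
            )
        cols = [f"f_{p.value}" for p in PROCESS_ORDER]
        sd = accepted.std(axis=0, ddof=1) if accepted.shape[0] > 1 else np.zeros(4)
        summary = pd.DataFrame(
            [accepted.mean(axis=0), sd], index=["mean", "sd"], columns=cols
        )
        self.run_ = MonteCarloRun(
            n_draws=self.n_draws,
            seed=self.random_state,
            scenario=scenario,
            accepted=accepted,
            accepted_spc=draws["spc"][inside],
            accepted_r=r[inside],
            acceptance_count=int(accepted.shape[0]),
            summary=summary,
            rejection_diagnostics=diagnostics,
        )
        if self.fluxes is not None:
            self.run_.r_check = r_consistency_check(self.run_, self.fluxes, scenario)
        self.accepted_ = accepted
        self.acceptance_count_ = self.run_.acceptance_count
        self.summary_ = summary
        self.fractions_ = summary.loc["mean"].to_numpy()
        return self


def monte_carlo_partition(
    library: SourceLibrary | None,
    measurement: EmittedMeasurement,
    scenario: str = "RM",
    n_draws: int = 100_000,
    seed: int | None = None,
    **kwargs,
) -> MonteCarloRun:
    """Functional wrapper over :class:`MonteCarloPartitioner`."""
    est = MonteCarloPartitioner(
        scenario=scenario,
        n_draws=n_draws,
        random_state=seed,
        source_library=library,
        **kwargs,
    )
    return est.fit(measurement).run_


def r_consistency_check(run: MonteCarloRun | float, fluxes: FluxSummary, scenario) -> float:
    """Recompute the microscopic product ratio implied by a run's mean f_bD.

    RM: ``r = fbar_bD*N2O_total / (fbar_bD*N2O_total + N2)`` (only bacterial
    N2O is subject to reduction); MR: ``r = N2O_total / (N2O_total + N2)``.
    Comparing the result against the R_N2O used in the solve tests the
    linearization R_N2O ~= r_N2O.
    """
    scenario = _as_scenario(scenario)
    if isinstance(run, MonteCarloRun):
        if run.acceptance_count == 0:
            raise NoAcceptedDrawsError("r-consistency check needs accepted draws")
        f_bd = float(run.mean[0])
    else:
        f_bd = float(run)
    n2o, n2 = fluxes.n2o_total, fluxes.n2_denitrified
    if scenario is Scenario.RM:
        return f_bd * n2o / (f_bd * n2o + n2)
    return n2o / (n2o + n2)
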