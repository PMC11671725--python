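"""Bayesian mixing/fractionation partitioning by Markov-chain Monte Carlo.

This is a three-dimensional isotope mixing-and-fractionation model in the
style of FRAME-type Bayesian mixing tools: the observed dimensions are
d15N-SP, d18O and the source partitioning coefficient SPC from the parallel
15N gas-flux experiment, and the five unknowns are the four source
fractions (on the simplex) plus the residual N2O fraction r_N2O in (0, 1].
Because r is a free parameter here, no denitrified-N2 measurement is needed.

The SPC dimension mixes "source values" (1, 1, 0, 0) — only the two
denitrifying pathways draw on the nitrate pool — and undergoes no
fractionation. The two isotopic dimensions follow the same RM/MR scenario
algebra as the linear-system solver, with r now sampled rather than fixed.

Sampling is Metropolis-Hastings with a logistic-normal random walk on the
simplex (additive Gaussian steps in log-ratio coordinates, with the softmax
Jacobian folded into the uniform-simplex prior) and a reflected Gaussian
step for r. Source-signature and reduction-effect uncertainty is not fixed:
the ten library parameters (four SP and four d18O signatures, two reduction
effects) are part of the chain state with their literature normals as
priors. Each iteration proposes fresh values for them from those
distributions, blockwise per source (independence proposals, so the prior
cancels and the move is accepted on the likelihood ratio alone), which
integrates the source uncertainty into the posterior exactly.

Priors: symmetric Dirichlet(1) (uniform) on the simplex, uniform on r,
literature normals on the source signatures and reduction effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import InvalidInputError
from .iso_core import PROCESS_ORDER, SourceLibrary
from .partition_ls import EmittedMeasurement, Scenario, _as_scenario

__all__ = [
    "BayesConfig",
    "PosteriorRun",
    "log_likelihood",
    "correlation_matrix",
    "BayesianPartitioner",
    "sample_posterior",
    "posterior_report",
]

_VARS = [f"f_{p.value}" for p in PROCESS_ORDER] + ["r_n2o"]


@dataclass(frozen=True)
class BayesConfig:
    """Sampler configuration.

    ``proposal_scale`` is the SD of the Gaussian steps in the simplex
    log-ratio coordinates; ``proposal_scale_r`` the SD of the reflected step
    on r. Defaults give 20-40% acceptance on study-like inputs.
    """

    n_iter: int = 200_000
    burn_in: float = 0.5
    seed: int | None = None
    proposal_scale: float = 0.05
    proposal_scale_r: float = 0.015
    scenario: str = "RM"

    def __post_init__(self):
        if not 0 < self.burn_in < 1:
            raise InvalidInputError("burn_in must be a fraction in (0, 1)")
        if self.n_iter < 1000:
            raise InvalidInputError("n_iter must be at least 1000")


@dataclass
class PosteriorRun:
    """Post-burn-in MCMC output."""

    chain: np.ndarray               # (m, 5): f_bD, f_fD, f_Ni, f_nD, r
    acceptance_rate: float
    summary: pd.DataFrame           # rows mean/sd, columns _VARS
    correlations: pd.DataFrame      # 5x5 Pearson matrix (NaN where undefined)
    config: BayesConfig | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def mean(self) -> np.ndarray:
        return self.summary.loc["mean"].to_numpy()

    @property
    def sd(self) -> np.ndarray:
        return self.summary.loc["sd"].to_numpy()


def log_likelihood(state, measurement: EmittedMeasurement, library_draw: dict,
                   scenario) -> float:
    """Gaussian log-likelihood of the three observed dimensions.

    ``state`` is ``(f, r)`` with ``f`` a length-4 simplex vector. Returns
    ``-inf`` for states off the simplex or with r outside (0, 1]. Source
    signatures enter through ``library_draw`` (keys ``sp``, ``o18`` length-4
    arrays, scalars ``eps_sp``/``eps_o``); the normalization constant of the
    Gaussians is omitted (it is state-independent).
    """
    f, r = state
    f = np.asarray(f, dtype=float)
    if (
        f.shape != (4,)
        or np.any(f < 0)
        or abs(f.sum() - 1.0) > 1e-9
        or not 0 < r <= 1
    ):
        return -math.inf
    scenario = _as_scenario(scenario)
    lnr = math.log(r)
    sp = np.asarray(library_draw["sp"], dtype=float)
    o18 = np.asarray(library_draw["o18"], dtype=float)
    eps_sp = float(library_draw["eps_sp"])
    eps_o = float(library_draw["eps_o"])
    if scenario is Scenario.RM:
        sp_pred = f @ sp + f[0] * eps_sp * lnr
        o18_pred = f @ o18 + f[0] * eps_o * lnr
    else:
        sp_pred = f @ sp + eps_sp * lnr
        o18_pred = f @ o18 + eps_o * lnr
    spc_pred = f[0] + f[1]
    return -0.5 * (
        ((sp_pred - measurement.sp_mean) / measurement.sp_sd) ** 2
        + ((o18_pred - measurement.o18_mean) / measurement.o18_sd) ** 2
        + ((spc_pred - measurement.spc_mean) / measurement.spc_sd) ** 2
    )


def _reflect_01(x: float) -> float:
    """Reflect a real number into [0, 1] (period-2 triangle map)."""
    x = math.fmod(x, 2.0)
    if x < 0:
        x += 2.0
    return 2.0 - x if x > 1.0 else x


def correlation_matrix(chain: np.ndarray) -> np.ndarray:
    """Pearson correlations with NaN for zero-variance columns (numpy's
    corrcoef is undefined there)."""
    sd = chain.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(chain, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    # numerically-constant columns (float dust from the mean subtraction)
    zero = sd <= 1e-12 * np.maximum(1.0, np.abs(chain).max(axis=0))
    corr[zero, :] = np.nan
    corr[:, zero] = np.nan
    return corr


def _initial_state(measurement, lib, scenario) -> tuple[np.ndarray, float]:
    """Feasible starting point: the deterministic mean-parameter solve when
    it lands inside the simplex, else the barycenter."""
    from .partition_ls import build_system, solve_partition

    r0 = min(max(measurement.r_mean, 1e-3), 1.0)
    try:
        draw = {"sp": lib.sp_means, "o18": lib.o18_means,
                "eps_sp": lib.eps_sp_mean, "eps_o": lib.eps_o_mean}
        m = {"sp": measurement.sp_mean, "o18": measurement.o18_mean,
             "spc": measurement.spc_mean}
        f = solve_partition(build_system(draw, m, scenario, r0)).as_array()
        f = np.clip(f, 1e-4, None)
        f = f / f.sum()
    except Exception:
        f = np.full(4, 0.25)
    return f, r0


class BayesianPartitioner(BaseEstimator):
    """MCMC estimator of the four source fractions and r_N2O.

    Parameters mirror :class:`BayesConfig`; ``sample_source_uncertainty``
    can be switched off to hold the library at its means (useful for
    validation against the deterministic solve).

    Attributes
    ----------
    chain_ : ndarray (m, 5)
        Post-burn-in states (f_bD, f_fD, f_Ni, f_nD, r_n2o).
    summary_ : DataFrame with rows mean/sd.
    correlations_ : DataFrame, 5x5 Pearson correlation matrix.
    acceptance_rate_ : float
    run_ : PosteriorRun
    """

    def __init__(
        self,
        scenario: str = "RM",
        n_iter: int = 200_000,
        burn_in: float = 0.5,
        random_state: int | None = None,
        proposal_scale: float = 0.05,
        proposal_scale_r: float = 0.015,
        source_library: SourceLibrary | None = None,
        sample_source_uncertainty: bool = True,
    ):
        self.scenario = scenario
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.random_state = random_state
        self.proposal_scale = proposal_scale
        self.proposal_scale_r = proposal_scale_r
        self.source_library = source_library
        self.sample_source_uncertainty = sample_source_uncertainty

    def fit(self, measurement: EmittedMeasurement, y=None):
        """Sample the posterior for one measurement."""
        if not isinstance(measurement, EmittedMeasurement):
            raise InvalidInputError("fit expects an EmittedMeasurement")
        for name in ("sp_sd", "o18_sd", "spc_sd"):
            if getattr(measurement, name) <= 0:
                raise InvalidInputError(
                    f"{name} must be positive: a zero-SD dimension degenerates "
                    "the Gaussian likelihood"
                )
        config = BayesConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            seed=self.random_state,
            proposal_scale=self.proposal_scale,
            proposal_scale_r=self.proposal_scale_r,
            scenario=self.scenario,
        )
        scenario = _as_scenario(self.scenario)
        lib = self.source_library or SourceLibrary.default()
        rng = np.random.default_rng(self.random_state)
        n = config.n_iter

        # Pre-drawn randomness, in a fixed order (reproducibility contract):
        # per-iteration library proposals, then the mixing-state proposal
        # steps, then the acceptance uniforms (library blocks first).
        lib_draws = lib.draw(rng, n)
        # scale-mixture random walk: mostly local steps, occasional larger
        # kicks to cross the ridge of the tightly-constrained posterior
        kick = rng.choice([1.0, 4.0, 16.0], size=n, p=[0.6, 0.3, 0.1])
        z_steps = rng.normal(0.0, config.proposal_scale, size=(n, 3)) * kick[:, None]
        r_steps = rng.normal(0.0, config.proposal_scale_r, size=n) * kick
        log_u_lib = np.log(rng.random((n, 5)))
        log_u = np.log(rng.random(n))

        sp_arr, o18_arr = lib_draws["sp"], lib_draws["o18"]
        eps_sp_arr, eps_o_arr = lib_draws["eps_sp"], lib_draws["eps_o"]
        sp_obs, sp_sd = measurement.sp_mean, measurement.sp_sd
        o18_obs, o18_sd = measurement.o18_mean, measurement.o18_sd
        spc_obs, spc_sd = measurement.spc_mean, measurement.spc_sd
        rm = scenario is Scenario.RM

        def loglik(f, lnr, th):
            """Gaussian log-likelihood under library state ``th``
            (sp0..sp3, o0..o3, eps_sp, eps_o)."""
            f0, f1, f2, f3 = f
            if rm:
                sp_pred = (f0 * th[0] + f1 * th[1] + f2 * th[2] + f3 * th[3]
                           + f0 * th[8] * lnr)
                o18_pred = (f0 * th[4] + f1 * th[5] + f2 * th[6] + f3 * th[7]
                            + f0 * th[9] * lnr)
            else:
                sp_pred = (f0 * th[0] + f1 * th[1] + f2 * th[2] + f3 * th[3]
                           + th[8] * lnr)
                o18_pred = (f0 * th[4] + f1 * th[5] + f2 * th[6] + f3 * th[7]
                            + th[9] * lnr)
            spc_pred = f0 + f1
            return -0.5 * (
                ((sp_pred - sp_obs) / sp_sd) ** 2
                + ((o18_pred - o18_obs) / o18_sd) ** 2
                + ((spc_pred - spc_obs) / spc_sd) ** 2
            )

        def f_from_z(z):
            e0, e1, e2 = math.exp(z[0]), math.exp(z[1]), math.exp(z[2])
            norm = 1.0 + e0 + e1 + e2
            return (e0 / norm, e1 / norm, e2 / norm, 1.0 / norm)

        # library proposal blocks: one per source (SP + d18O), one for eps
        blocks = ((0, 4), (1, 5), (2, 6), (3, 7), (8, 9))

        f_init, r = _initial_state(measurement, lib, scenario)
        z = np.log(f_init[:3] / f_init[3])
        f_curr = f_from_z(z)
        th = list(lib.sp_means) + list(lib.o18_means) + [lib.eps_sp_mean,
                                                         lib.eps_o_mean]
        lnr = math.log(r)
        ll_curr = loglik(f_curr, lnr, th)
        chain = np.empty((n, 5))
        accepted = 0
        sample_lib = self.sample_source_uncertainty
        for i in range(n):
            if sample_lib:
                # blockwise independence proposals from the literature
                # normals: the prior cancels, leaving the likelihood ratio
                prop = (
                    sp_arr[i, 0], sp_arr[i, 1], sp_arr[i, 2], sp_arr[i, 3],
                    o18_arr[i, 0], o18_arr[i, 1], o18_arr[i, 2], o18_arr[i, 3],
                    eps_sp_arr[i], eps_o_arr[i],
                )
                for b, (j1, j2) in enumerate(blocks):
                    old1, old2 = th[j1], th[j2]
                    th[j1], th[j2] = prop[j1], prop[j2]
                    ll_prop = loglik(f_curr, lnr, th)
                    if log_u_lib[i, b] < ll_prop - ll_curr:
                        ll_curr = ll_prop
                    else:
                        th[j1], th[j2] = old1, old2

            # mixing-state move: logistic-normal walk + reflected r step
            z_prop = z + z_steps[i]
            r_prop = _reflect_01(r + r_steps[i])
            if r_prop > 0.0:
                f_prop = f_from_z(z_prop)
                lnr_prop = math.log(r_prop)
                ll_prop = loglik(f_prop, lnr_prop, th)
                # uniform-simplex prior in log-ratio coords (softmax Jacobian)
                dprior = (
                    math.log(f_prop[0]) + math.log(f_prop[1])
                    + math.log(f_prop[2]) + math.log(f_prop[3])
                    - math.log(f_curr[0]) - math.log(f_curr[1])
                    - math.log(f_curr[2]) - math.log(f_curr[3])
                )
                if log_u[i] < ll_prop - ll_curr + dprior:
                    z, r, lnr, f_curr, ll_curr = z_prop, r_prop, lnr_prop, f_prop, ll_prop
                    accepted += 1
            chain[i, :4] = f_curr
            chain[i, 4] = r

        keep = chain[int(n * config.burn_in):]
        acceptance_rate = accepted / n
        if acceptance_rate < 1e-3:
            warnings.warn(
                f"MCMC acceptance rate {acceptance_rate:.2e} < 0.1%: the chain "
                "has not mixed; inspect proposal scales and measurement SDs",
                RuntimeWarning,
            )
        sd = keep.std(axis=0, ddof=1)
        summary = pd.DataFrame(
            [keep.mean(axis=0), sd], index=["mean", "sd"], columns=_VARS
        )
        correlations = pd.DataFrame(
            correlation_matrix(keep), index=_VARS, columns=_VARS
        )
        self.run_ = PosteriorRun(
            chain=keep,
            acceptance_rate=acceptance_rate,
            summary=summary,
            correlations=correlations,
            config=config,
            diagnostics={"n_iter": n, "n_kept": keep.shape[0], "accepted": accepted},
        )
        self.chain_ = keep
        self.summary_ = summary
        self.correlations_ = correlations
        self.acceptance_rate_ = acceptance_rate
        return self


def sample_posterior(
    measurement: EmittedMeasurement,
    library: SourceLibrary | None = None,
    config: BayesConfig | None = None,
) -> PosteriorRun:
    """Functional wrapper over :class:`BayesianPartitioner`."""
    config = config or BayesConfig()
    est = BayesianPartitioner(
        scenario=config.scenario,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        random_state=config.seed,
        proposal_scale=config.proposal_scale,
        proposal_scale_r=config.proposal_scale_r,
        source_library=library,
    )
    return est.fit(measurement).run_


def posterior_report(run: PosteriorRun, bins: int = 40) -> dict:
    """Summaries, Pearson correlations and histogram data for a run.

    Correlations of constant chains are reported as NaN. Histograms are
    returned as ``{variable: (counts, bin_edges)}``.
    """
    if run.chain.shape[0] == 0:
        raise InvalidInputError("empty chain")
    histograms = {
        var: np.histogram(run.chain[:, j], bins=bins) for j, var in enumerate(_VARS)
    }
    return {
        "summary": run.summary,
        "correlations": run.correlations,
        "histograms": histograms,
        "acceptance_rate": run.acceptance_rate,
    }
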