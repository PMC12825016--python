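"""Global sensitivity analysis: LHS sampling, MLRA indices, rank tests.

The eight nanoparticle-specific parameters are perturbed ±50% around a
baseline set by Latin hypercube sampling (unbound fractions are clipped at
their physical upper bound of 1 after perturbation).  For each sampled
parameter vector the model is simulated and summarised by seven outputs:
the trapezoidal AUC from 0 to 500 h of each concentration compartment
(kidneys, plasma, lungs, MPS, others) and the final cumulative urine and
feces masses.  Multivariate linear regression of each z-scored output on
the jointly z-scored parameters yields standardized coefficients used as
sensitivity indices (SIs).  The default design draws 10 independent
replicates of 100 samples (1,000 model evaluations in total); parameters
are then ranked by |SI| within each replicate and the rankings compared by
one-way ANOVA with Tukey's HSD across replicates.

Volumes and the fixed lung/kidney flows are physiological constants and
are not perturbed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from . import model as _model
from .params import KINETIC_PARAM_NAMES, DoseSpec, KineticParams, PhysiologyParams

__all__ = [
    "GsaConfig",
    "SensitivityResult",
    "lhs_sample",
    "evaluate_outputs",
    "mlra_indices",
    "rank_parameters",
    "run_gsa",
    "OUTPUT_NAMES",
]

logger = logging.getLogger(__name__)

#: Model outputs summarised per sample, in reporting order.
OUTPUT_NAMES = (
    "kidneys_auc",
    "plasma_auc",
    "lungs_auc",
    "mps_auc",
    "others_auc",
    "urine_final",
    "feces_final",
)

_F_PARAMS = ("f_lu", "f_mps", "f_k", "f_o")


@dataclass(frozen=True)
class GsaConfig:
    """Sampling design for the global sensitivity analysis."""

    baseline: KineticParams
    n_samples: int = 100
    n_replicates: int = 10
    perturbation: float = 0.5
    t_end: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10 * len(KINETIC_PARAM_NAMES):
            raise ValueError(
                f"n_samples must be at least 10 per parameter "
                f"({10 * len(KINETIC_PARAM_NAMES)}), got {self.n_samples}"
            )
        if not 0.0 <= self.perturbation < 1.0:
            raise ValueError("perturbation fraction must lie in [0, 1)")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")


def lhs_sample(config: GsaConfig, replicate: int = 0) -> np.ndarray:
    """Draw one LHS replicate: an ``n_samples × 8`` parameter matrix.

    Each column is stratified over ``[P(1−δ), P(1+δ)]`` with exactly one
    sample per equal-probability stratum; the draw is reproducible from
    ``(config.seed, replicate)``.  Unbound-fraction columns are clipped to
    1 after perturbation, so their upper strata may collapse onto the
    bound when the baseline fraction exceeds ``1/(1+δ)``.
    """
    baseline = config.baseline.to_array()
    if np.any(baseline == 0):
        zero = [n for n, b in zip(KINETIC_PARAM_NAMES, baseline) if b == 0]
        raise ValueError(f"baseline parameter(s) {zero} are zero: perturbation range collapses")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, replicate]))
    sampler = qmc.LatinHypercube(d=len(baseline), seed=rng)
    unit = sampler.random(config.n_samples)
    lower = baseline * (1.0 - config.perturbation)
    upper = baseline * (1.0 + config.perturbation)
    samples = lower + unit * (upper - lower)
    for j, name in enumerate(KINETIC_PARAM_NAMES):
        if name in _F_PARAMS:
            samples[:, j] = np.minimum(samples[:, j], 1.0)
    return samples


def _auc_grid(t_end: float, n: int = 400) -> np.ndarray:
    """Log-dense time grid from 0 to ``t_end`` for trapezoidal AUCs."""
    return np.concatenate(([0.0], np.geomspace(1e-4, t_end, n)))


def evaluate_outputs(
    samples: np.ndarray,
    phys: PhysiologyParams,
    dose_amount: float = 100.0,
    t_end: float = 500.0,
    grid_points: int = 400,
) -> np.ndarray:
    """Evaluate the seven model outputs for every sampled parameter row.

    Rows whose simulation fails are flagged with NaN and logged; callers
    drop them.  A zero dose short-circuits to all-zero outputs (the model
    is linear in the dose).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    out = np.full((len(samples), len(OUTPUT_NAMES)), np.nan)
    if dose_amount == 0.0:
        out[:] = 0.0
        return out
    grid = _auc_grid(t_end, grid_points)
    dose = DoseSpec(amount_ug=dose_amount)
    for i, row in enumerate(samples):
        try:
            kin = KineticParams.from_array(row)
            sim = _model.simulate(phys, kin, dose, grid, units=_model.MICROGRAM, method="expm")
            aucs = {
                c: np.trapezoid(sim.concentrations[c].to_numpy(), grid)
                for c in _model.CONCENTRATION_COMPARTMENTS
            }
            out[i] = [
                aucs["kidneys"],
                aucs["plasma"],
                aucs["lungs"],
                aucs["mps"],
                aucs["others"],
                sim.excreta["urine"].iloc[-1],
                sim.excreta["feces"].iloc[-1],
            ]
        except Exception as exc:
            logger.warning("GSA sample %d excluded: %r", i, exc)
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    centred = x - x.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centred / sd, 0.0)
    return z


def mlra_indices(samples: np.ndarray, outputs: np.ndarray) -> np.ndarray:
    """Standardized regression coefficients (SIs) for one replicate.

    Jointly regresses each z-scored output on the z-scored parameter
    matrix; returns an ``8 × n_outputs`` SI matrix.
    """
    samples = np.asarray(samples, dtype=float)
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    ok = np.all(np.isfinite(outputs), axis=1)
    samples, outputs = samples[ok], outputs[ok]
    if len(samples) < 10 * samples.shape[1]:
        raise ValueError("need at least 10 valid samples per parameter for MLRA")
    zx = _zscore(samples)
    rank = np.linalg.matrix_rank(zx)
    if rank < zx.shape[1]:
        raise ValueError("collinear sample matrix: regression is not identifiable")
    zy = _zscore(outputs)
    beta, *_ = np.linalg.lstsq(zx, zy, rcond=None)
    return beta


@dataclass
class SensitivityResult:
    """SI matrices per replicate plus the derived parameter rankings."""

    si: np.ndarray  # (n_replicates, 8, n_outputs)
    config: GsaConfig
    param_names: tuple = KINETIC_PARAM_NAMES
    output_names: tuple = OUTPUT_NAMES
    n_excluded: int = 0

    def si_frame(self) -> pd.DataFrame:
        """Long-format SI table (replicate, parameter, output, si)."""
        reps, params, outs = self.si.shape
        rows = []
        for r in range(reps):
            for p in range(params):
                for o in range(outs):
                    rows.append((r, self.param_names[p], self.output_names[o], self.si[r, p, o]))
        return pd.DataFrame(rows, columns=["replicate", "parameter", "output", "si"])

    def ranks(self) -> np.ndarray:
        """Per-replicate ranks of |SI| (1 = most influential), ties averaged."""
        abs_si = np.abs(self.si)
        ranked = np.empty_like(abs_si)
        for r in range(abs_si.shape[0]):
            for o in range(abs_si.shape[2]):
                ranked[r, :, o] = stats.rankdata(-abs_si[r, :, o], method="average")
        return ranked

    def mean_ranks(self) -> pd.DataFrame:
        """Mean rank of each parameter per output (Figure-style rank table)."""
        return pd.DataFrame(
            self.ranks().mean(axis=0), index=list(self.param_names), columns=list(self.output_names)
        )


def rank_parameters(result: SensitivityResult, alpha: float = 0.05):
    """Rank parameters by |SI| and test the separation across replicates.

    For each output: parameters are ranked by |SI| within each replicate
    and averaged; a one-way ANOVA compares the |SI| distributions of the
    eight parameters across replicates, and Tukey's HSD gives the pairwise
    grouping.  Returns ``(mean_rank_table, test_summary)`` where the test
    summary is a frame with one row per output (ANOVA F and p) and a
    ``tukey`` attribute dict keyed by output.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if result.si.shape[0] < 2:
        raise ValueError("ranking tests require at least 2 replicates")
    mean_rank = result.mean_ranks()
    abs_si = np.abs(result.si)
    rows = []
    tukey = {}
    for o, out_name in enumerate(result.output_names):
        groups = [abs_si[:, p, o] for p in range(abs_si.shape[1])]
        if np.allclose(np.ptp(np.concatenate(groups)), 0.0):
            f_stat, p_val = np.nan, 1.0
        else:
            f_stat, p_val = stats.f_oneway(*groups)
        rows.append((out_name, f_stat, p_val))
        values = abs_si[:, :, o].T.ravel()
        labels = np.repeat(result.param_names, abs_si.shape[0])
        try:
            tukey[out_name] = pairwise_tukeyhsd(values, labels, alpha=alpha)
        except Exception as exc:  # degenerate (all-equal) groups
            tukey[out_name] = None
            logger.info("Tukey HSD unavailable for %s: %r", out_name, exc)
    summary = pd.DataFrame(rows, columns=["output", "anova_F", "anova_p"]).set_index("output")
    summary.attrs["alpha"] = alpha
    return mean_rank, summary, tukey


def run_gsa(
    phys: PhysiologyParams,
    config: GsaConfig,
    dose_amount: float = 100.0,
) -> SensitivityResult:
    """Full pipeline: LHS replicates → model outputs → MLRA SIs."""
    si = np.empty((config.n_replicates, len(KINETIC_PARAM_NAMES), len(OUTPUT_NAMES)))
    n_excluded = 0
    for r in range(config.n_replicates):
        samples = lhs_sample(config, replicate=r)
        outputs = evaluate_outputs(
            samples, phys, dose_amount=dose_amount, t_end=config.t_end
        )
        n_excluded += int(np.sum(~np.all(np.isfinite(outputs), axis=1)))
        si[r] = mlra_indices(samples, outputs)
    return SensitivityResult(si=si, config=config, n_excluded=n_excluded)
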