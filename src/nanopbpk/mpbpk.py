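"""Model / Results classes for calibrating the minimal PBPK model.

`MinimalPBPKModel` wraps a :class:`~nanopbpk.datasets.BiodistributionDataset`
plus the species physiology; :meth:`MinimalPBPKModel.fit` estimates the
eight nanoparticle-specific parameters (four unbound fractions, two
excretion rate constants, two empirical blood flows) by bounded nonlinear
least squares on the replicate means, with the compartment volumes and the
lung/kidney blood flows fixed at their physiological values.  The returned
:class:`PBPKResults` carries the estimates, Jacobian-based (linearised)
95% confidence intervals, per-compartment Pearson correlations, residuals
and a text ``summary()``.

Residuals are unweighted and expressed in the data's own units (%ID/g for
tissues, %ID for excreta); an optional log-residual objective is available
for heavily skewed data but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import model as _model
from .datasets import BiodistributionDataset
from .params import (
    KINETIC_PARAM_NAMES,
    DoseSpec,
    KineticParams,
    PhysiologyParams,
    load_kinetics,
)

# %ID mode normalises the dose away; any positive placeholder works.
_DUMMY_DOSE = DoseSpec(amount_ug=100.0)

__all__ = [
    "MinimalPBPKModel",
    "PBPKResults",
    "residuals",
    "pearson_r",
    "default_bounds",
]


def default_bounds(phys: PhysiologyParams) -> tuple[np.ndarray, np.ndarray]:
    """Default box bounds for the eight fitted parameters.

    Unbound fractions live in [0, 1]; excretion rate constants are capped
    at 100 h^-1; the empirical flows are kept below the species' lung blood
    flow, a cardiac-output proxy, so that fitted flows stay physiologic.
    """
    lower = np.zeros(8)
    upper = np.array([1.0, 1.0, 1.0, 1.0, 100.0, 100.0, phys.q_lu, phys.q_lu])
    return lower, upper


def _predict_at(
    kin: KineticParams, phys: PhysiologyParams, obs: pd.DataFrame
) -> np.ndarray:
    """Model predictions (in %ID units) matched to observation rows."""
    times = np.unique(np.concatenate(([0.0], obs["time_h"].to_numpy(dtype=float))))
    sim = _model.simulate(phys, kin, _DUMMY_DOSE, times, units=_model.PERCENT_ID, method="expm")
    lookup = {}
    for comp in _model.CONCENTRATION_COMPARTMENTS:
        lookup[comp] = dict(zip(times, sim.concentrations[comp].to_numpy()))
    for comp in _model.EXCRETA_COMPARTMENTS:
        lookup[comp] = dict(zip(times, sim.excreta[comp].to_numpy()))
    try:
        return np.array(
            [lookup[c][t] for c, t in zip(obs["compartment"], obs["time_h"].astype(float))]
        )
    except KeyError as exc:  # unknown compartment label
        raise ValueError(f"observation for unknown compartment {exc.args[0]!r}") from exc


def residuals(
    kin: KineticParams,
    phys: PhysiologyParams,
    data: BiodistributionDataset,
    log_scale: bool = False,
) -> np.ndarray:
    """Unweighted residual vector (model − observed) across all observations.

    The model is simulated in %ID mode so tissue predictions are %ID/g and
    excreta predictions %ID, directly comparable with the data.
    """
    obs = data.observations
    if obs.empty:
        raise ValueError("dataset has no observations")
    if not obs["compartment"].isin(_model.CONCENTRATION_COMPARTMENTS).any():
        raise ValueError("at least one tissue compartment must be observed")
    predicted = _predict_at(kin, phys, obs)
    observed = obs["value"].to_numpy(dtype=float)
    if log_scale:
        floor = 1e-12
        return np.log(np.maximum(predicted, floor)) - np.log(np.maximum(observed, floor))
    return predicted - observed


def pearson_r(predicted, observed) -> float:
    """Sample Pearson correlation of pooled predictions vs observations."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1 or len(predicted) < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(predicted, observed).statistic)


class MinimalPBPKModel:
    """Minimal PBPK model bound to a biodistribution dataset.

    Parameters
    ----------
    data
        Observed or synthetic biodistribution time series.
    phys
        Species physiology (volumes, fixed flows).
    log_residuals
        Fit on log-transformed values instead of the default plain scale.
    """

    def __init__(
        self,
        data: BiodistributionDataset,
        phys: PhysiologyParams,
        log_residuals: bool = False,
    ):
        self.data = data
        self.phys = phys
        self.log_residuals = log_residuals

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, phys: PhysiologyParams, dose, **kwargs):
        """Build a model from a tidy observation frame (see datasets.SCHEMA)."""
        data = BiodistributionDataset(
            np_label=str(frame["np_type"].iloc[0]),
            species=str(frame["species"].iloc[0]),
            observations=frame,
            dose=dose,
        )
        return cls(data, phys, **kwargs)

    # -- objective ---------------------------------------------------------
    def _residual_array(self, x: np.ndarray) -> np.ndarray:
        kin = KineticParams.from_array(np.clip(x, 0.0, None))
        return residuals(kin, self.phys, self.data, log_scale=self.log_residuals)

    def _default_start(self) -> np.ndarray:
        try:
            return load_kinetics(self.data.np_label).to_array()
        except KeyError:
            lower, upper = default_bounds(self.phys)
            return (lower + upper) / 2.0

    def fit(
        self,
        start: KineticParams | np.ndarray | None = None,
        bounds: tuple[np.ndarray, np.ndarray] | None = None,
        n_starts: int = 8,
        seed: int = 0,
        **ls_kwargs,
    ) -> "PBPKResults":
        """Bounded least squares with a Latin-hypercube multistart.

        The supplied (or default) start is always attempted; ``n_starts``
        additional starting points are drawn by Latin hypercube sampling
        within the bounds to guard against local minima.  The best
        converged solution by objective value wins.
        """
        lower, upper = bounds if bounds is not None else default_bounds(self.phys)
        if start is None:
            x0 = self._default_start()
        elif isinstance(start, KineticParams):
            x0 = start.to_array()
        else:
            x0 = np.asarray(start, dtype=float)
        if np.any(x0 < lower) or np.any(x0 > upper):
            raise ValueError("starting point lies outside the bounds")

        starts = [x0]
        if n_starts > 0:
            sampler = qmc.LatinHypercube(d=len(x0), seed=seed)
            unit = sampler.random(n_starts)
            starts.extend(lower + unit * (upper - lower))

        ls_defaults = dict(method="trf", x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-10)
        ls_defaults.update(ls_kwargs)
        best = None
        attempts = []
        for x_init in starts:
            try:
                sol = least_squares(
                    self._residual_array, x_init, bounds=(lower, upper), **ls_defaults
                )
            except Exception as exc:  # pragma: no cover - defensive
                attempts.append(repr(exc))
                continue
            attempts.append(f"cost={sol.cost:.6g} success={sol.success}")
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError(
                "least-squares fit failed to converge from any start: " + "; ".join(attempts)
            )
        return PBPKResults(self, best, (lower, upper), seed=seed, attempts=attempts)


@dataclass
class PBPKResults:
    """Estimates, uncertainties and diagnostics from a PBPK fit."""

    model: MinimalPBPKModel
    optimizer_result: object = field(repr=False)
    bounds: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    seed: int = 0
    attempts: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        sol = self.optimizer_result
        self.x = np.asarray(sol.x, dtype=float)
        self.params = KineticParams.from_array(
            np.clip(self.x, 0.0, None),
            np_label=self.model.data.np_label,
            species=self.model.data.species,
        )
        self.resid = np.asarray(sol.fun, dtype=float)
        self.cost = float(sol.cost)
        self.success = bool(sol.success)
        m, p = len(self.resid), len(self.x)
        self.df_resid = max(m - p, 1)
        self.scale = 2.0 * self.cost / self.df_resid  # residual variance estimate
        jac = np.asarray(sol.jac, dtype=float)
        jtj = jac.T @ jac
        try:
            cov_unscaled = np.linalg.inv(jtj)
            self._singular = False
        except np.linalg.LinAlgError:
            cov_unscaled = np.linalg.pinv(jtj)
            self._singular = True
        self.cov_params = self.scale * cov_unscaled
        self.bse = np.sqrt(np.maximum(np.diag(self.cov_params), 0.0))

    # -- uncertainty -------------------------------------------------------
    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Linearised (delta-method) confidence intervals per parameter."""
        tval = stats.t.ppf(1 - alpha / 2, self.df_resid)
        lo = self.x - tval * self.bse
        hi = self.x + tval * self.bse
        return pd.DataFrame(
            {"estimate": self.x, "lower": lo, "upper": hi},
            index=list(KINETIC_PARAM_NAMES),
        )

    # -- goodness of fit ---------------------------------------------------
    def _pred_obs(self) -> tuple[np.ndarray, np.ndarray, pd.Series]:
        obs = self.model.data.observations
        predicted = _predict_at(self.params, self.model.phys, obs)
        return predicted, obs["value"].to_numpy(dtype=float), obs["compartment"]

    @property
    def pearson_overall(self) -> float:
        predicted, observed, _ = self._pred_obs()
        return pearson_r(predicted, observed)

    @property
    def pearson_by_compartment(self) -> pd.Series:
        predicted, observed, comp = self._pred_obs()
        out = {}
        for c in comp.unique():
            mask = (comp == c).to_numpy()
            if mask.sum() >= 3 and np.ptp(predicted[mask]) > 0 and np.ptp(observed[mask]) > 0:
                out[c] = pearson_r(predicted[mask], observed[mask])
            else:
                out[c] = np.nan
        return pd.Series(out, name="pearson_r")

    def predict(self, times, compartments=None) -> pd.DataFrame:
        """Fitted trajectories (%ID units) at the requested times."""
        times = np.asarray(times, dtype=float)
        grid = times if times[0] == 0 else np.concatenate(([0.0], times))
        sim = _model.simulate(
            self.model.phys, self.params, _DUMMY_DOSE, grid,
            units=_model.PERCENT_ID, method="expm",
        )
        frame = pd.concat([sim.concentrations, sim.excreta], axis=1)
        frame.index = grid
        frame = frame.loc[times]
        if compartments is not None:
            frame = frame[list(compartments)]
        return frame

    def confidence_band(self, times, compartments=None, alpha: float = 0.05) -> pd.DataFrame:
        """Pointwise linearised 95% band around the fitted trajectory.

        Uses the delta method: the band half-width at time t is
        ``t_crit * sqrt(g(t)^T Cov g(t))`` with ``g`` the parameter
        gradient of the prediction, by forward finite differences.
        """
        if self._singular:
            raise np.linalg.LinAlgError(
                "Jacobian cross-product is singular; confidence band unavailable"
            )
        compartments = (
            list(compartments)
            if compartments is not None
            else list(_model.COMPARTMENTS)
        )
        times = np.asarray(times, dtype=float)
        base = self.predict(times, compartments)
        grads = np.empty((len(times), len(compartments), len(self.x)))
        for j in range(len(self.x)):
            step = 1e-6 * max(abs(self.x[j]), 1e-6)
            x_pert = self.x.copy()
            x_pert[j] += step
            pert_params = KineticParams.from_array(np.clip(x_pert, 0.0, None))
            sim = _model.simulate(
                self.model.phys, pert_params, _DUMMY_DOSE,
                times if times[0] == 0 else np.concatenate(([0.0], times)),
                units=_model.PERCENT_ID, method="expm",
            )
            frame = pd.concat([sim.concentrations, sim.excreta], axis=1)
            frame.index = sim.time
            pert = frame.loc[times, compartments].to_numpy()
            grads[:, :, j] = (pert - base.to_numpy()) / step
        var = np.einsum("tcj,jk,tck->tc", grads, self.cov_params, grads)
        half = stats.t.ppf(1 - alpha / 2, self.df_resid) * np.sqrt(np.maximum(var, 0.0))
        rows = []
        for i, c in enumerate(compartments):
            rows.append(
                pd.DataFrame(
                    {
                        "compartment": c,
                        "time_h": times,
                        "fit": base[c].to_numpy(),
                        "lower": base[c].to_numpy() - half[:, i],
                        "upper": base[c].to_numpy() + half[:, i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit report."""
        from statsmodels.iolib.table import SimpleTable

        ci = self.conf_int()
        rows = [
            [name, f"{ci['estimate'][name]:.4g}", f"{self.bse[i]:.3g}",
             f"{ci['lower'][name]:.4g}", f"{ci['upper'][name]:.4g}"]
            for i, name in enumerate(KINETIC_PARAM_NAMES)
        ]
        table = SimpleTable(
            rows,
            headers=["parameter", "estimate", "std err", "ci 2.5%", "ci 97.5%"],
            title=(
                f"Minimal PBPK fit: {self.model.data.np_label} "
                f"({self.model.data.species})"
            ),
        )
        lines = [str(table), ""]
        lines.append(f"objective (0.5*SSR): {self.cost:.6g}   n_obs: {len(self.resid)}")
        lines.append(f"overall Pearson R: {self.pearson_overall:.4f}")
        by_c = self.pearson_by_compartment
        lines.append(
            "per-compartment R: "
            + ", ".join(f"{c}={v:.3f}" for c, v in by_c.items() if np.isfinite(v))
        )
        lines.append(f"multistart seed: {self.seed}; attempts: {len(self.attempts)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Machine-readable twin of :meth:`summary`."""
        ci = self.conf_int()
        return {
            "np_label": self.model.data.np_label,
            "species": self.model.data.species,
            "estimates": dict(zip(KINETIC_PARAM_NAMES, map(float, self.x))),
            "std_errors": dict(zip(KINETIC_PARAM_NAMES, map(float, self.bse))),
            "ci_lower": dict(zip(KINETIC_PARAM_NAMES, map(float, ci["lower"]))),
            "ci_upper": dict(zip(KINETIC_PARAM_NAMES, map(float, ci["upper"]))),
            "objective": self.cost,
            "pearson_overall": float(self.pearson_overall),
            "pearson_by_compartment": {
                k: (float(v) if np.isfinite(v) else None)
                for k, v in self.pearson_by_compartment.items()
            },
            "success": self.success,
            "seed": self.seed,
        }

    def plot_fit(self, ax=None):
        """Observed points over the fitted trajectories (log-time axis)."""
        import matplotlib.pyplot as plt

        obs = self.model.data.observations
        t_max = float(obs["time_h"].max())
        grid = np.concatenate(([0.0], np.geomspace(1e-3, t_max, 200)))
        fitted = self.predict(grid)
        if ax is None:
            _, ax = plt.subplots()
        for comp in obs["compartment"].unique():
            line, = ax.plot(grid, fitted[comp], label=comp)
            sub = obs[obs["compartment"] == comp]
            ax.errorbar(
                sub["time_h"], sub["value"], yerr=sub["sd"],
                fmt="x", color=line.get_color(),
            )
        ax.set_xlabel("time (h)")
        ax.set_ylabel("%ID/g or %ID")
        ax.set_yscale("log")
        ax.legend()
        return ax
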