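"""Synthetic biodistribution data with the in vivo study's sampling design.

Ground truth is a noise-free model simulation in %ID mode; observations
are the truth corrupted by multiplicative, mean-preserving log-normal
noise — radioactivity measurements are positive with roughly proportional
error.  With coefficient of variation ``CV``, each replicate draw is

    obs = truth * exp(N(-sigma^2 / 2, sigma)),   sigma^2 = ln(1 + CV^2)

so that E[obs] = truth.  The default design mirrors the animal study:
five tissue harvest times (5 min encoded as 1/12 h, 30 min, 2 h, 24 h,
72 h) with n = 5 replicates, cumulative urine and feces at 2/24/48/72 h.
The generator does not emulate gamma-counter counting statistics, decay
correction or organ-harvest mass variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model as _model
from .datasets import SCHEMA, BiodistributionDataset
from .params import DoseSpec, KineticParams, PhysiologyParams, load_kinetics, load_physiology

__all__ = ["StudyDesign", "generate_dataset", "make_recovery_suite"]

#: Tissue compartments reported by the generator: all five concentration
#: states, including the lumped "others" pool.
TISSUE_COMPARTMENTS = _model.CONCENTRATION_COMPARTMENTS


@dataclass(frozen=True)
class StudyDesign:
    """Sampling times, replication and noise level of a synthetic study."""

    tissue_times: tuple = (1.0 / 12.0, 0.5, 2.0, 24.0, 72.0)
    excreta_times: tuple = (2.0, 24.0, 48.0, 72.0)
    n_replicates: int = 5
    cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for times in (self.tissue_times, self.excreta_times):
            arr = np.asarray(times, dtype=float)
            if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
                raise ValueError("timepoints must be positive and strictly increasing")
        if self.cv < 0:
            raise ValueError("CV must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def generate_dataset(
    phys: PhysiologyParams,
    kin: KineticParams,
    dose: DoseSpec,
    design: StudyDesign = StudyDesign(),
    np_label: str | None = None,
) -> BiodistributionDataset:
    """Simulate ground truth and draw a noisy replicated dataset.

    The returned dataset carries the replicate-mean observation table (the
    calibration input), the individual replicate draws and the noise-free
    truth for recovery scoring.  Identical seeds give bit-identical data.
    """
    label = np_label or kin.np_label or "synthetic"
    grid = np.unique(np.concatenate(([0.0], design.tissue_times, design.excreta_times)))
    sim = _model.simulate(phys, kin, dose, grid, units=_model.PERCENT_ID, method="expm")

    truth_rows = []
    for comp in TISSUE_COMPARTMENTS:
        series = dict(zip(sim.time, sim.concentrations[comp]))
        for t in design.tissue_times:
            truth_rows.append((comp, float(t), series[t], "%ID/g"))
    for comp in _model.EXCRETA_COMPARTMENTS:
        series = dict(zip(sim.time, sim.excreta[comp]))
        for t in design.excreta_times:
            truth_rows.append((comp, float(t), series[t], "%ID"))
    truth = pd.DataFrame(truth_rows, columns=["compartment", "time_h", "value", "unit"])

    rng = np.random.default_rng(design.seed)
    factors = _lognormal_factors(rng, design.cv, (len(truth), design.n_replicates))
    draws = truth["value"].to_numpy()[:, None] * factors

    replicates = truth.loc[truth.index.repeat(design.n_replicates)].reset_index(drop=True)
    replicates["replicate"] = np.tile(np.arange(design.n_replicates), len(truth))
    replicates["value"] = draws.ravel()

    observations = truth.copy()
    if design.cv == 0:  # noise-free data must reproduce the truth exactly
        observations["sd"] = 0.0
    else:
        observations["value"] = draws.mean(axis=1)
        observations["sd"] = draws.std(axis=1, ddof=1) if design.n_replicates > 1 else 0.0
    observations["n"] = design.n_replicates
    observations["np_type"] = label
    observations["species"] = phys.species
    observations = observations[list(SCHEMA)]

    return BiodistributionDataset(
        np_label=label,
        species=phys.species,
        observations=observations,
        dose=dose,
        replicates=replicates,
        truth=truth,
    )


def make_recovery_suite(
    np_labels,
    noise_levels,
    n_seeds: int,
    species: str = "mouse",
    design: StudyDesign = StudyDesign(),
):
    """Deterministic dataset collection for parameter-recovery studies.

    Returns ``(datasets, registry)``: datasets keyed by
    ``(np_label, cv, seed)`` and a truth registry frame with one row per
    dataset recording the generating parameters.
    """
    phys = load_physiology(species)
    datasets = {}
    registry_rows = []
    for label in np_labels:
        kin = load_kinetics(label)  # raises KeyError for unknown labels
        dose = DoseSpec.from_per_bw(20.0, phys.bw)
        for cv in noise_levels:
            for seed in range(1, n_seeds + 1):
                d = StudyDesign(
                    tissue_times=design.tissue_times,
                    excreta_times=design.excreta_times,
                    n_replicates=design.n_replicates,
                    cv=cv,
                    seed=seed,
                )
                datasets[(kin.np_label, cv, seed)] = generate_dataset(
                    phys, kin, dose, d, np_label=kin.np_label
                )
                row = {"np_label": kin.np_label, "cv": cv, "seed": seed}
                row.update(
                    {name: getattr(kin, name) for name in
                     ("f_lu", "f_mps", "f_k", "f_o", "k_e_mps", "k_e_k", "q_mps", "q_o")}
                )
                registry_rows.append(row)
    return datasets, pd.DataFrame(registry_rows)
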