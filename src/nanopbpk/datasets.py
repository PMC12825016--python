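"""Biodistribution dataset container and tidy-CSV I/O.

Observations follow the in vivo study layout: tissue concentrations in
%ID/g at a handful of harvest times and cumulative urine/feces masses in
%ID, each summarised as a replicate mean with its SD and replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .params import DoseSpec

__all__ = ["BiodistributionDataset", "read_dataset", "write_dataset"]

TISSUE_COMPARTMENTS = ("plasma", "lungs", "mps", "kidneys", "others")
EXCRETA_COMPARTMENTS = ("urine", "feces")
VALID_COMPARTMENTS = TISSUE_COMPARTMENTS + EXCRETA_COMPARTMENTS

#: Columns of the observation table (one row per compartment/time mean).
SCHEMA = ("np_type", "species", "compartment", "time_h", "value", "sd", "n", "unit")


@dataclass
class BiodistributionDataset:
    """Observed (or synthetic) biodistribution time series.

    ``observations`` is a frame with columns :data:`SCHEMA` holding
    replicate means; an optional ``replicates`` frame keeps the individual
    draws when the dataset is synthetic.
    """

    np_label: str
    species: str
    observations: pd.DataFrame
    dose: DoseSpec
    replicates: pd.DataFrame | None = field(default=None, repr=False)
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        obs = self.observations
        missing = set(SCHEMA) - set(obs.columns)
        if missing:
            raise ValueError(f"observation table is missing columns {sorted(missing)}")
        unknown = set(obs["compartment"]) - set(VALID_COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown compartments {sorted(unknown)}")
        if (obs["time_h"] < 0).any():
            raise ValueError("observation times must be non-negative")
        if (obs["value"] < 0).any():
            raise ValueError("observed values must be non-negative")
        tissues = obs["compartment"].isin(TISSUE_COMPARTMENTS)
        if not (obs.loc[tissues, "unit"] == "%ID/g").all():
            raise ValueError("tissue observations must be in %ID/g")
        if not (obs.loc[~tissues, "unit"] == "%ID").all():
            raise ValueError("excreta observations must be in %ID")

    @property
    def tissue_observations(self) -> pd.DataFrame:
        return self.observations[
            self.observations["compartment"].isin(TISSUE_COMPARTMENTS)
        ].reset_index(drop=True)

    @property
    def excreta_observations(self) -> pd.DataFrame:
        return self.observations[
            self.observations["compartment"].isin(EXCRETA_COMPARTMENTS)
        ].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.observations)


def read_dataset(path, dose: DoseSpec | None = None) -> BiodistributionDataset:
    """Read a tidy dataset CSV (columns :data:`SCHEMA`), validating headers.

    The murine study dose (20 mg/kg × 0.02 kg = 400 µg) is assumed when no
    dose is given and the species column says mouse.
    """
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(SCHEMA) - set(frame.columns)
    if missing:
        raise ValueError(f"dataset file {path} is missing columns {sorted(missing)}")
    np_label = str(frame["np_type"].iloc[0])
    species = str(frame["species"].iloc[0])
    if dose is None:
        if species.casefold() != "mouse":
            raise ValueError("dose must be supplied explicitly for non-mouse datasets")
        dose = DoseSpec.from_per_bw(20.0, 0.02)
    return BiodistributionDataset(
        np_label=np_label, species=species, observations=frame[list(SCHEMA)], dose=dose
    )


def write_dataset(dataset: BiodistributionDataset, path, header_comment: str | None = None) -> None:
    """Write the replicate-mean observation table as tidy CSV."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        # %.17g guarantees binary round-trip of the float columns
        dataset.observations.to_csv(fh, index=False, float_format="%.17g")
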