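"""Parameter containers and packaged parameter tables.

The model carries two kinds of parameters:

* **Physiological** quantities (compartment volumes, regional blood flows,
  body weight) that are properties of the species, taken from the
  literature.  Organ volumes equal organ weights under the assumption of a
  tissue density of 1 g/mL.  The mononuclear-phagocyte-system (MPS)
  compartment lumps liver and spleen; the "others" compartment lumps every
  remaining perfused tissue.
* **Nanoparticle-specific kinetic** quantities estimated from
  biodistribution data: the unbound fractions ``f_i`` (the fraction of
  particles in organ *i* free to re-enter circulation), the first-order
  excretion rate constants ``k_e_mps`` (into feces) and ``k_e_k`` (into
  urine), and the empirical blood-flow rates ``q_mps`` and ``q_o``.

Packaged tables cover mouse physiology, human physiology and seven fitted
nanoparticle parameter sets (six silica-nanoparticle variants in mice and
ultrasmall "C dots" in humans).  Every packaged value carries a provenance
flag: ``printed`` (taken verbatim from the source table), ``derived-sum``
(a lumped volume recomputed from organ weights) or
``text-vs-table-conflict`` (the narrative text quotes a slightly different
number than the table prints).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from math import isfinite

import pandas as pd

__all__ = [
    "PhysiologyParams",
    "KineticParams",
    "DoseSpec",
    "available_np_labels",
    "load_physiology",
    "load_kinetics",
    "load_parameter_tables",
    "load_organ_weights",
    "derive_lumped_volumes",
    "load_nca_reference",
]

#: Names of the eight nanoparticle-specific quantities, in fitting order.
KINETIC_PARAM_NAMES = (
    "f_lu",
    "f_mps",
    "f_k",
    "f_o",
    "k_e_mps",
    "k_e_k",
    "q_mps",
    "q_o",
)


def _data_path(name: str):
    return resources.files("nanopbpk.data").joinpath(name)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, comment="#")


@dataclass(frozen=True)
class PhysiologyParams:
    """Species-level volumes (mL), blood flows (mL/h) and body weight (kg).

    ``q_mps`` and ``q_o`` here are the literature blood flows; they serve as
    defaults / initial guesses, whereas the calibrated nanoparticle-specific
    flows live in :class:`KineticParams`.
    """

    species: str
    v_p: float
    v_lu: float
    v_mps: float
    v_k: float
    v_o: float
    q_lu: float
    q_k: float
    q_mps: float
    q_o: float
    bw: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "species":
                continue
            value = getattr(self, f.name)
            if not isfinite(value) or value <= 0:
                raise ValueError(
                    f"physiological parameter {f.name!r} must be finite and "
                    f"strictly positive, got {value!r}"
                )

    @property
    def volumes(self) -> dict[str, float]:
        return {
            "plasma": self.v_p,
            "lungs": self.v_lu,
            "mps": self.v_mps,
            "kidneys": self.v_k,
            "others": self.v_o,
        }


@dataclass(frozen=True)
class KineticParams:
    """The eight nanoparticle-specific quantities of the model.

    Unbound fractions are dimensionless and confined to [0, 1]; excretion
    rate constants are in h^-1 and blood flows in mL/h, all non-negative.
    """

    f_lu: float
    f_mps: float
    f_k: float
    f_o: float
    k_e_mps: float
    k_e_k: float
    q_mps: float
    q_o: float
    np_label: str | None = field(default=None, compare=False)
    species: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("f_lu", "f_mps", "f_k", "f_o"):
            value = getattr(self, name)
            if not isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValueError(f"unbound fraction {name!r} must lie in [0, 1], got {value!r}")
        for name in ("k_e_mps", "k_e_k", "q_mps", "q_o"):
            value = getattr(self, name)
            if not isfinite(value) or value < 0:
                raise ValueError(f"{name!r} must be finite and non-negative, got {value!r}")

    def to_array(self):
        import numpy as np

        return np.array([getattr(self, n) for n in KINETIC_PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values, **meta) -> "KineticParams":
        if len(values) != len(KINETIC_PARAM_NAMES):
            raise ValueError(f"expected {len(KINETIC_PARAM_NAMES)} values, got {len(values)}")
        return cls(**dict(zip(KINETIC_PARAM_NAMES, map(float, values))), **meta)

    def replace(self, **changes) -> "KineticParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class DoseSpec:
    """Intravenous dose specification.

    Either an absolute dose in µg or a per-body-weight dose (mg/kg) plus the
    body weight (kg).  The derived absolute mass ``amount_ug`` is what the
    simulation uses; the standard murine regimen (20 mg/kg into a 0.02 kg
    mouse) corresponds to 400 µg.
    """

    amount_ug: float
    dose_per_bw: float | None = None
    bw: float | None = None

    def __post_init__(self) -> None:
        if not isfinite(self.amount_ug) or self.amount_ug <= 0:
            raise ValueError(f"dose must be strictly positive, got {self.amount_ug!r}")

    @classmethod
    def from_per_bw(cls, dose_mg_per_kg: float, bw_kg: float) -> "DoseSpec":
        if bw_kg <= 0:
            raise ValueError("body weight must be strictly positive")
        return cls(
            amount_ug=dose_mg_per_kg * bw_kg * 1000.0,
            dose_per_bw=dose_mg_per_kg,
            bw=bw_kg,
        )


def _normalise_label(label: str) -> str:
    folded = unicodedata.normalize("NFKD", label).encode("ascii", "ignore").decode()
    return folded.replace("-", " ").replace("_", " ").strip().casefold()


def available_np_labels() -> list[str]:
    """Labels of the packaged nanoparticle kinetic parameter sets."""
    return list(_read_packaged("kinetics.csv")["np_label"].unique())


def load_physiology(species: str) -> PhysiologyParams:
    """Load the packaged physiology table for ``species`` (mouse or human)."""
    table = _read_packaged("physiology.csv")
    sub = table[table["species"] == species.strip().casefold()]
    if sub.empty:
        known = sorted(table["species"].unique())
        raise KeyError(f"unknown species {species!r}; packaged species: {known}")
    values = dict(zip(sub["parameter"], sub["value"]))
    return PhysiologyParams(species=species.strip().casefold(), **values)


def load_kinetics(np_label: str) -> KineticParams:
    """Load a packaged nanoparticle kinetic parameter set by label.

    Labels are matched case-insensitively and ignoring accents, so
    ``"Stöber"`` and ``"stober"`` both resolve to the packaged ``Stober``
    set.
    """
    table = _read_packaged("kinetics.csv")
    wanted = _normalise_label(np_label)
    match = table[table["np_label"].map(_normalise_label) == wanted]
    if match.empty:
        raise KeyError(
            f"unknown nanoparticle label {np_label!r}; packaged labels: "
            f"{available_np_labels()}"
        )
    values = dict(zip(match["parameter"], match["value"]))
    return KineticParams(
        **values,
        np_label=match["np_label"].iloc[0],
        species=match["species"].iloc[0],
    )


def load_parameter_tables(species: str, np_label: str) -> tuple[PhysiologyParams, KineticParams]:
    """Return the packaged (physiology, kinetics) pair for a run."""
    kin = load_kinetics(np_label)
    if kin.species is not None and kin.species.casefold() != species.strip().casefold():
        raise ValueError(
            f"packaged parameter set {kin.np_label!r} was fitted in "
            f"{kin.species!r}, not {species!r}"
        )
    return load_physiology(species), kin


def load_organ_weights(species: str | None = None) -> pd.DataFrame:
    """Organ-weight table (g) underlying the lumped compartment volumes."""
    table = _read_packaged("organ_weights.csv")
    if species is not None:
        table = table[table["species"] == species.strip().casefold()].reset_index(drop=True)
        if table.empty:
            raise KeyError(f"unknown species {species!r}")
    return table


def derive_lumped_volumes(species: str) -> dict[str, float]:
    """Recompute lumped compartment volumes (mL) from organ weights.

    Under the 1 g/mL density assumption the MPS volume is liver + spleen
    weight and the "others" volume is the sum of every organ weight not
    assigned to a named compartment.
    """
    weights = load_organ_weights(species)
    grouped = weights.groupby("lumped_compartment")["weight_g"].sum()
    return {
        "v_mps": float(grouped.get("mps", float("nan"))),
        "v_lu": float(grouped.get("lungs", float("nan"))),
        "v_k": float(grouped.get("kidneys", float("nan"))),
        "v_o": float(grouped.get("others", float("nan"))),
    }


def load_nca_reference() -> pd.DataFrame:
    """Packaged non-compartmental reference metrics for the six mouse NPs.

    Long-format table (np_label, compartment, metric, value, provenance);
    cells whose typeset source was ambiguous carry the provenance flag
    ``parsed-with-caution`` and missing (accumulating-compartment) entries
    are simply absent.
    """
    return _read_packaged("nca_reference_mouse.csv")
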