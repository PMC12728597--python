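"""Data model and CSV I/O for fractionation experiments.

A gravity-driven size-exclusion run loads a small sample volume onto a
column and collects the eluate in ``n_fractions`` fixed-volume aliquots.
Each fraction's DNA concentration (ng/μL) is then read on a micro-volume
UV spectrophotometer.  This module holds the column geometry
(:class:`ColumnSpec`), one replicate's fraction-wise measurements
(:class:`ElutionProfile`) and gel band-intensity tables
(:class:`GelBandTable`), plus readers/writers for the plain-CSV dialect
used throughout the package.

Units are fixed internally: volumes in μL (column volume in mL on input,
converted nowhere else), concentrations in ng/μL, masses in ng.
Concentrations are accepted as already-converted mass concentrations;
conversion from raw A260 readings is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ColumnSpec",
    "ElutionProfile",
    "GelBandTable",
    "fraction_to_volume",
    "fraction_interval",
    "fraction_mass",
    "read_profile_csv",
    "write_profile_csv",
    "read_gel_csv",
    "write_gel_csv",
]

VolumeConvention = Literal["end", "midpoint"]

#: Required columns of the profile CSV dialect.
REQUIRED_COLUMNS = ("replicate_id", "fraction", "concentration_ng_per_uL")


@dataclass(frozen=True)
class ColumnSpec:
    """Fractionation geometry of a gravity-flow size-exclusion column.

    Parameters
    ----------
    column_volume_mL : float
        Total packed resin volume (CV), in mL.
    loading_volume_uL : float
        Sample volume applied before elution (LV), in μL.
    fraction_volume_uL : float
        Volume of each collected fraction, in μL.
    n_fractions : int
        Number of fractions collected; the total elution volume is
        ``n_fractions * fraction_volume_uL``.

    Defaults follow the optimized small-scale setup: a 0.8 mL CV column
    loaded with 50 μL of sample and eluted in nine 100 μL fractions.
    """

    column_volume_mL: float = 0.8
    loading_volume_uL: float = 50.0
    fraction_volume_uL: float = 100.0
    n_fractions: int = 9

    def __post_init__(self) -> None:
        for name in ("column_volume_mL", "loading_volume_uL", "fraction_volume_uL"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not (isinstance(self.n_fractions, (int, np.integer)) and self.n_fractions >= 1):
            raise ValidationError("n_fractions must be an integer >= 1")

    @property
    def total_elution_volume_uL(self) -> float:
        return self.n_fractions * self.fraction_volume_uL


def fraction_to_volume(
    fraction_index: int,
    column_spec: ColumnSpec,
    convention: VolumeConvention = "end",
) -> float:
    """Map a 1-based fraction index to an elution volume in μL.

    The ``end`` convention (default) places fraction *n* at the cumulative
    eluted volume at the end of that fraction, ``n * fraction_volume``;
    this reproduces the usual x-axis where fraction 3 of 100 μL fractions
    sits at 300 μL.  ``midpoint`` places it at ``(n - 0.5) * fraction_volume``.

    The loading volume is not added: elution volume counts eluent only.
    """
    if fraction_index < 1:
        raise ValidationError(f"fraction_index must be >= 1, got {fraction_index}")
    if convention == "end":
        return fraction_index * column_spec.fraction_volume_uL
    if convention == "midpoint":
        return (fraction_index - 0.5) * column_spec.fraction_volume_uL
    raise ValidationError(f"unknown volume convention {convention!r}")


def fraction_interval(fraction_index: int, column_spec: ColumnSpec) -> tuple[float, float]:
    """Elution-volume interval ``((n-1)*Vf, n*Vf]`` spanned by fraction *n*, in μL."""
    if fraction_index < 1:
        raise ValidationError(f"fraction_index must be >= 1, got {fraction_index}")
    vf = column_spec.fraction_volume_uL
    return ((fraction_index - 1) * vf, fraction_index * vf)


def fraction_mass(concentration_ng_per_uL: float, column_spec: ColumnSpec) -> float:
    """Mass (ng) in one fraction: concentration × fraction volume.

    Linear in concentration; zero concentration gives zero mass.
    """
    if concentration_ng_per_uL < 0:
        raise ValidationError("concentration must be >= 0")
    return concentration_ng_per_uL * column_spec.fraction_volume_uL


@dataclass(frozen=True)
class ElutionProfile:
    """One replicate's fraction-wise elution measurements.

    ``fractions`` are strictly increasing 1-based indices; ``volumes_uL``
    are the corresponding (strictly increasing, positive) elution volumes;
    ``concentrations`` are the spectrophotometer readings in ng/μL.
    ``input_mass_ng``, when known, is the mass of target species loaded
    and enables measured-yield computation.
    """

    replicate_id: str
    fractions: np.ndarray  # int, 1-based
    volumes_uL: np.ndarray
    concentrations: np.ndarray  # ng/μL
    input_mass_ng: float | None = None

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=int)
        vol = np.asarray(self.volumes_uL, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if not (fr.shape == vol.shape == conc.shape) or fr.ndim != 1:
            raise ValidationError("fractions, volumes and concentrations must be 1-D and equal length")
        if fr.size == 0:
            raise ValidationError("profile must contain at least one fraction")
        if fr[0] < 1 or np.any(np.diff(fr) <= 0):
            raise ValidationError("fraction indices must be strictly increasing and start at >= 1")
        if vol[0] <= 0 or np.any(np.diff(vol) <= 0):
            raise ValidationError("elution volumes must be positive and strictly increasing")
        if np.any(conc < 0):
            raise ValidationError("concentrations must be >= 0")
        if self.input_mass_ng is not None and not self.input_mass_ng > 0:
            raise ValidationError("input_mass_ng must be > 0 when given")
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "volumes_uL", vol)
        object.__setattr__(self, "concentrations", conc)

    @property
    def n_points(self) -> int:
        return int(self.fractions.size)

    def masses_ng(self, column_spec: ColumnSpec) -> np.ndarray:
        """Per-fraction masses (ng): concentration × fraction volume."""
        return self.concentrations * column_spec.fraction_volume_uL

    def total_mass_ng(self, column_spec: ColumnSpec) -> float:
        return float(np.sum(self.masses_ng(column_spec)))

    def with_concentrations(self, concentrations: np.ndarray) -> "ElutionProfile":
        return replace(self, concentrations=np.asarray(concentrations, dtype=float))


@dataclass(frozen=True)
class GelBandTable:
    """Per-species band intensities across fractions from gel densitometry.

    Rows are species (e.g. ``"nanostructure"``, ``"staples"``); columns are
    fraction indices.  Intensities are arbitrary units, non-negative, and
    each species row must carry at least one nonzero value.
    """

    species: tuple[str, ...]
    fractions: np.ndarray
    intensities: np.ndarray  # shape (n_species, n_fractions)

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensities, dtype=float)
        fr = np.asarray(self.fractions, dtype=int)
        if inten.ndim != 2 or inten.shape != (len(self.species), fr.size):
            raise ValidationError("intensities must have shape (n_species, n_fractions)")
        if np.any(inten < 0):
            raise ValidationError("band intensities must be >= 0")
        for i, sp in enumerate(self.species):
            if not np.any(inten[i] > 0):
                raise ValidationError(f"species {sp!r} has all-zero intensities")
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "intensities", inten)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities,
            index=list(self.species),
            columns=[str(f) for f in self.fractions],
        )


def read_profile_csv(
    path: str | Path,
    column_spec: ColumnSpec | None = None,
    convention: VolumeConvention = "end",
) -> list[ElutionProfile]:
    """Read elution profiles from CSV, one :class:`ElutionProfile` per replicate.

    The CSV must have a header with columns ``replicate_id``, ``fraction``
    and ``concentration_ng_per_uL``; optional columns are
    ``elution_volume_uL`` (otherwise derived from ``column_spec`` via
    :func:`fraction_to_volume`) and ``input_mass_ng`` (constant per
    replicate).  Rows may appear in any order; they are sorted by fraction
    within each replicate.  An empty table (header only) yields an empty
    list.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        return []

    has_volume = "elution_volume_uL" in df.columns
    if not has_volume and column_spec is None:
        raise FormatError(
            f"{path}: no elution_volume_uL column and no column_spec to derive volumes from"
        )

    neg = df.index[df["concentration_ng_per_uL"] < 0]
    if len(neg):
        # +2: header row plus 1-based numbering of data rows
        raise ValidationError(
            f"{path}: negative concentration at data row {int(neg[0]) + 2}"
        )

    profiles: list[ElutionProfile] = []
    for rep_id, group in df.groupby("replicate_id", sort=True):
        group = group.sort_values("fraction")
        dup = group["fraction"].duplicated()
        if dup.any():
            f = int(group.loc[dup.idxmax(), "fraction"])
            raise ValidationError(
                f"{path}: duplicate (replicate={rep_id!r}, fraction={f}) entry"
            )
        fractions = group["fraction"].to_numpy(dtype=int)
        if has_volume:
            volumes = group["elution_volume_uL"].to_numpy(dtype=float)
        else:
            volumes = np.array(
                [fraction_to_volume(int(f), column_spec, convention) for f in fractions]
            )
        input_mass: float | None = None
        if "input_mass_ng" in group.columns:
            vals = group["input_mass_ng"].dropna().unique()
            if len(vals) > 1:
                raise ValidationError(
                    f"{path}: input_mass_ng not constant within replicate {rep_id!r}"
                )
            if len(vals) == 1:
                input_mass = float(vals[0])
        profiles.append(
            ElutionProfile(
                replicate_id=str(rep_id),
                fractions=fractions,
                volumes_uL=volumes,
                concentrations=group["concentration_ng_per_uL"].to_numpy(dtype=float),
                input_mass_ng=input_mass,
            )
        )
    return profiles


def write_profile_csv(profiles: Iterable[ElutionProfile], path: str | Path) -> None:
    """Write profiles to the CSV dialect read by :func:`read_profile_csv`."""
    rows = []
    for p in profiles:
        for f, v, c in zip(p.fractions, p.volumes_uL, p.concentrations):
            row = {
                "replicate_id": p.replicate_id,
                "fraction": int(f),
                "elution_volume_uL": float(v),
                "concentration_ng_per_uL": float(c),
            }
            if p.input_mass_ng is not None:
                row["input_mass_ng"] = float(p.input_mass_ng)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gel_csv(path: str | Path) -> GelBandTable:
    """Read a gel band-intensity table: a ``species`` column then one column per fraction."""
    path = Path(path)
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise FormatError(f"{path}: missing required column 'species'")
    frac_cols = [c for c in df.columns if c != "species"]
    if not frac_cols:
        raise FormatError(f"{path}: no fraction columns")
    try:
        fractions = np.array([int(c) for c in frac_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: fraction column names must be integers") from exc
    return GelBandTable(
        species=tuple(df["species"].astype(str)),
        fractions=fractions,
        intensities=df[frac_cols].to_numpy(dtype=float),
    )


def write_gel_csv(table: GelBandTable, path: str | Path) -> None:
    df = table.to_frame().reset_index(names="species")
    df.to_csv(path, index=False)
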