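"""Core data structures for NIR leaf spectra and wet-chemistry reference values.

The study design behind this package: leaves of 27 *Vaccinium* cultivars
(V. corymbosum and V. ashei) sampled in three Portuguese regions (RA — Northern
Coast, RB — Northern Inland, RC — South Inland) and three seasons (spring/May,
fall/September, winter/December), with diffuse-reflectance NIR spectra recorded
on a 10000–4000 cm⁻¹ grid and five replicate spectra per sample.  Six canonical
season/region subsets ("data-set designs") drive the calibration and
transferability analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

PARAMETERS = ("TPC", "TFC", "TAC")

UNITS = {
    "TPC": "mg gallic acid/g dry leaf",
    "TFC": "mg catechin/g dry leaf",
    "TAC": "mM Trolox/g dry leaf",
}

REGIONS = ("RA", "RB", "RC")
SEASONS = ("spring", "fall", "winter")

GRID_TOLERANCE = 1e-6  # cm⁻¹, max deviation between grids treated as "equal"

META_COLUMNS = ("sample_id", "cultivar", "species", "region", "season", "plant_id")


@dataclass
class Spectrum:
    """A single NIR spectrum on a strictly descending wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str
    replicate_index: int = 1

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValueError("wavenumbers and absorbance must have equal length")
        if self.wavenumbers.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(
            np.isfinite(self.absorbance)
        ):
            raise ValueError(f"non-finite values in spectrum {self.sample_id!r}")
        if not np.all(np.diff(self.wavenumbers) < 0):
            raise ValueError("wavenumber grid must be strictly descending")


class SpectraSet:
    """Replicate spectra on one shared grid plus per-sample metadata.

    Parameters
    ----------
    wavenumbers
        Shared grid, strictly descending, in cm⁻¹.
    intensities
        2-D array, one row per spectrum (replicate), aligned with ``meta``.
    meta
        One row per spectrum with columns ``sample_id``, ``replicate``,
        ``cultivar``, ``species``, ``region``, ``season``, ``plant_id``.
    """

    def __init__(
        self, wavenumbers: np.ndarray, intensities: np.ndarray, meta: pd.DataFrame
    ) -> None:
        wavenumbers = np.asarray(wavenumbers, dtype=float)
        intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
        if not np.all(np.diff(wavenumbers) < 0):
            raise ValueError("wavenumber grid must be strictly descending")
        if wavenumbers.size < 2:
            raise ValueError("grid needs at least 2 points")
        if intensities.shape[1] != wavenumbers.size:
            raise ValueError(
                f"intensity matrix has {intensities.shape[1]} columns, "
                f"grid has {wavenumbers.size} points"
            )
        if not np.all(np.isfinite(intensities)):
            raise ValueError("non-finite absorbance values")
        meta = meta.reset_index(drop=True)
        if len(meta) != intensities.shape[0]:
            raise ValueError("metadata rows must match number of spectra")
        if "replicate" not in meta.columns:
            meta = meta.copy()
            meta["replicate"] = (
                meta.groupby("sample_id", sort=False).cumcount() + 1
            )
        dup = meta.duplicated(subset=["sample_id", "replicate"])
        if dup.any():
            raise ValueError(
                "replicate indices must be unique within a sample; duplicated: "
                f"{meta.loc[dup, 'sample_id'].unique().tolist()}"
            )
        self.wavenumbers = wavenumbers
        self.intensities = intensities
        self.meta = meta

    # -- basic views -------------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.meta["sample_id"]))

    def spectra(self) -> Iterator[Spectrum]:
        for i, row in self.meta.iterrows():
            yield Spectrum(
                self.wavenumbers,
                self.intensities[i],
                sample_id=row["sample_id"],
                replicate_index=int(row["replicate"]),
            )

    def select_rows(self, mask: np.ndarray) -> "SpectraSet":
        mask = np.asarray(mask)
        return SpectraSet(
            self.wavenumbers, self.intensities[mask], self.meta.loc[mask]
        )

    def __len__(self) -> int:
        return self.n_spectra

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SpectraSet({self.n_spectra} spectra × {self.n_points} points, "
            f"{len(self.sample_ids)} samples)"
        )


class ReferenceTable:
    """Long-format table of assay reference values (mean ± SD per cell).

    Required columns: cultivar, region, season, parameter, mean, sd, units.
    Optional: sample_id, species, plant_id.  Missing table cells are simply
    absent rows — never imputed.
    """

    REQUIRED = ("cultivar", "region", "season", "parameter", "mean", "sd", "units")

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"reference table missing columns: {missing}")
        if (df["mean"] <= 0).any():
            raise ValueError("reference means must be positive")
        if (df["sd"] < 0).any():
            raise ValueError("reference SDs must be non-negative")
        for param, sub in df.groupby("parameter"):
            if sub["units"].nunique() > 1:
                raise ValueError(f"inconsistent units for parameter {param!r}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_fixture_csv(cls, path, parameter: str) -> "ReferenceTable":
        df = pd.read_csv(path)
        df["parameter"] = parameter
        df["units"] = UNITS[parameter]
        return cls(df)

    @property
    def parameters(self) -> list[str]:
        return sorted(self.df["parameter"].unique())

    def lookup(
        self,
        parameter: str,
        cultivar: str | None = None,
        region: str | None = None,
        season: str | None = None,
    ) -> pd.DataFrame:
        sub = self.df[self.df["parameter"] == parameter]
        if cultivar is not None:
            sub = sub[sub["cultivar"] == cultivar]
        if region is not None:
            sub = sub[sub["region"] == region]
        if season is not None:
            sub = sub[sub["season"] == season]
        return sub

    def cell(self, parameter: str, cultivar: str, region: str, season: str):
        """Return (mean, sd) of one table cell, or None if the cell is absent."""
        sub = self.lookup(parameter, cultivar, region, season)
        if sub.empty:
            return None
        row = sub.iloc[0]
        return float(row["mean"]), float(row["sd"])

    def filter(self, design: "DataSetDesign") -> "ReferenceTable":
        sub = self.df[
            self.df["season"].isin(design.seasons)
            & self.df["region"].isin(design.regions)
        ]
        if sub.empty:
            raise ValueError(f"design {design.id} retains no reference rows")
        return ReferenceTable(sub)

    def concat(self, other: "ReferenceTable") -> "ReferenceTable":
        return ReferenceTable(pd.concat([self.df, other.df], ignore_index=True))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ReferenceTable({len(self.df)} rows, parameters={self.parameters})"


@dataclass(frozen=True)
class DataSetDesign:
    """A season/region filter defining one of the study's data sets."""

    id: int | None
    seasons: frozenset
    regions: frozenset
    label: str = ""

    def matches(self, season: str, region: str) -> bool:
        return season in self.seasons and region in self.regions


DESIGNS: dict[int, DataSetDesign] = {
    1: DataSetDesign(1, frozenset(SEASONS), frozenset(REGIONS), "all leaves"),
    2: DataSetDesign(2, frozenset(SEASONS), frozenset({"RA"}), "single region RA"),
    3: DataSetDesign(3, frozenset({"spring"}), frozenset(REGIONS), "spring, 3 regions"),
    4: DataSetDesign(4, frozenset({"spring"}), frozenset({"RA"}), "spring RA"),
    5: DataSetDesign(5, frozenset({"fall"}), frozenset({"RA"}), "fall RA"),
    6: DataSetDesign(6, frozenset({"winter"}), frozenset({"RA"}), "winter RA"),
}


def get_design(design: int | DataSetDesign) -> DataSetDesign:
    if isinstance(design, DataSetDesign):
        return design
    if design not in DESIGNS:
        raise ValueError(f"design id must be 1..6, got {design!r}")
    return DESIGNS[design]


def build_dataset(
    spectra: SpectraSet | None,
    reference: ReferenceTable,
    design: int | DataSetDesign,
) -> tuple[SpectraSet | None, ReferenceTable]:
    """Restrict a spectra/reference pair to one season/region design.

    ``spectra`` may be None when only the reference table is being filtered
    (e.g. summaries over the printed fixture tables).
    """
    design = get_design(design)
    ref = reference.filter(design)
    if spectra is None:
        return None, ref
    mask = (
        spectra.meta["season"].isin(design.seasons)
        & spectra.meta["region"].isin(design.regions)
    ).to_numpy()
    if not mask.any():
        raise ValueError(f"design {design.id} retains no spectra")
    return spectra.select_rows(mask), ref


def align_reference(
    spectra: SpectraSet,
    reference: ReferenceTable,
    parameter: str,
    average_replicates: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the (X, y, groups) triple for regression.

    Each spectrum becomes one row of X; y repeats the sample's reference mean
    across its replicates; ``groups`` carries the sample id of every row so
    cross-validation can hold out whole samples.  With
    ``average_replicates=True`` replicates are averaged to one row per sample.
    """
    if parameter not in reference.parameters:
        raise ValueError(
            f"parameter {parameter!r} not in reference table "
            f"(has {reference.parameters})"
        )
    ref = reference.df[reference.df["parameter"] == parameter]
    if "sample_id" in ref.columns and spectra.meta["sample_id"].isin(
        ref["sample_id"]
    ).all():
        value_by_sample = ref.set_index("sample_id")["mean"]
        keys = spectra.meta["sample_id"]
    else:
        value_by_sample = ref.set_index(["cultivar", "region", "season"])["mean"]
        keys = pd.MultiIndex.from_frame(
            spectra.meta[["cultivar", "region", "season"]]
        )
    missing = [
        sid
        for sid, key in zip(spectra.meta["sample_id"], keys)
        if key not in value_by_sample.index
    ]
    if missing:
        raise ValueError(
            f"no {parameter} reference value for samples: "
            f"{sorted(set(missing))}"
        )
    y = value_by_sample.loc[keys].to_numpy(dtype=float)
    X = spectra.intensities
    groups = spectra.meta["sample_id"].to_numpy()
    if average_replicates:
        uniq = list(dict.fromkeys(groups))
        X = np.vstack([X[groups == g].mean(axis=0) for g in uniq])
        y = np.array([y[groups == g][0] for g in uniq])
        groups = np.array(uniq)
    return X, y, groups


def summarize_counts(plants: pd.DataFrame) -> dict:
    """Design summary computed from the plants fixture (never hard-coded)."""
    per_species = plants.groupby("species")["cultivar"].nunique().to_dict()
    return {
        "n_cultivars": int(plants["cultivar"].nunique()),
        "n_plants": int(plants["n_plants"].sum()),
        "cultivars_per_species": per_species,
        "plants_per_species": plants.groupby("species")["n_plants"].sum().to_dict(),
    }


# ---------------------------------------------------------------------------
# File I/O — wide CSV (column 1 wavenumber, one column per replicate spectrum)
# with a sidecar metadata CSV; minimal JCAMP-DX for single spectra.
# ---------------------------------------------------------------------------

WAVENUMBER_COLUMN = "wavenumber_cm-1"


def save_spectra(spectra: SpectraSet, spectra_path, meta_path) -> None:
    cols = {WAVENUMBER_COLUMN: spectra.wavenumbers}
    for i, row in spectra.meta.iterrows():
        cols[f"{row['sample_id']}__r{int(row['replicate'])}"] = spectra.intensities[i]
    pd.DataFrame(cols).to_csv(spectra_path, index=False)
    spectra.meta.drop(columns=["replicate"]).drop_duplicates().to_csv(
        meta_path, index=False
    )


_COLUMN_RE = re.compile(r"^(?P<sample>.+)__r(?P<rep>\d+)$")


def load_spectra(
    path, format: str = "csv", meta_path=None
) -> SpectraSet:
    """Load spectra from a wide CSV (or a single-block JCAMP-DX file).

    The grid is reordered to descending wavenumbers if needed.  For CSV input
    with no sidecar metadata, cultivar/region/season fields are left empty.
    """
    if format == "jcamp":
        wn, ab, title = read_jcamp(path)
        meta = pd.DataFrame(
            [
                {
                    "sample_id": title or Path(str(path)).stem,
                    "replicate": 1,
                    "cultivar": "",
                    "species": "",
                    "region": "",
                    "season": "",
                    "plant_id": "",
                }
            ]
        )
        order = np.argsort(wn)[::-1]
        return SpectraSet(wn[order], ab[order][None, :], meta)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    df = pd.read_csv(path)
    if WAVENUMBER_COLUMN not in df.columns:
        raise ValueError(f"first column must be {WAVENUMBER_COLUMN!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {bad.index[0] + 2} "
                f"(1-based, incl. header)"
            )
    wn = df[WAVENUMBER_COLUMN].to_numpy(dtype=float)
    order = np.argsort(wn)[::-1]
    wn = wn[order]
    rows = []
    meta_rows = []
    for col in df.columns:
        if col == WAVENUMBER_COLUMN:
            continue
        m = _COLUMN_RE.match(col)
        sample_id, rep = (m["sample"], int(m["rep"])) if m else (col, 1)
        rows.append(df[col].to_numpy(dtype=float)[order])
        meta_rows.append({"sample_id": sample_id, "replicate": rep})
    meta = pd.DataFrame(meta_rows)
    if meta_path is not None:
        side = pd.read_csv(meta_path)
        meta = meta.merge(side, on="sample_id", how="left", validate="many_to_one")
    for c in META_COLUMNS:
        if c not in meta.columns:
            meta[c] = ""
    return SpectraSet(wn, np.vstack(rows), meta)


def grids_equal(a: np.ndarray, b: np.ndarray, tol: float = GRID_TOLERANCE) -> bool:
    return a.shape == b.shape and bool(np.all(np.abs(a - b) <= tol))


def merge_spectra(sets: Sequence[SpectraSet]) -> SpectraSet:
    """Concatenate SpectraSets sharing one grid; name the offender otherwise."""
    if not sets:
        raise ValueError("nothing to merge")
    base = sets[0]
    for s in sets[1:]:
        if not grids_equal(base.wavenumbers, s.wavenumbers):
            offender = s.meta["sample_id"].iloc[0] if len(s.meta) else "?"
            raise ValueError(
                f"grid mismatch: spectrum {offender!r} is not on the shared grid"
            )
    return SpectraSet(
        base.wavenumbers,
        np.vstack([s.intensities for s in sets]),
        pd.concat([s.meta for s in sets], ignore_index=True),
    )


# -- JCAMP-DX (single-block XYDATA, linear abscissa, AFFN numbers only) -----


def read_jcamp(path) -> tuple[np.ndarray, np.ndarray, str]:
    title = ""
    xfactor = yfactor = 1.0
    firstx = lastx = None
    npoints = None
    ys: list[float] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "TITLE":
                title = val
            elif key == "XFACTOR":
                xfactor = float(val)
            elif key == "YFACTOR":
                yfactor = float(val)
            elif key == "FIRSTX":
                firstx = float(val)
            elif key == "LASTX":
                lastx = float(val)
            elif key == "NPOINTS":
                npoints = int(val)
            elif key == "XYDATA":
                in_data = True
            elif key == "END":
                in_data = False
            continue
        if in_data:
            vals = [float(v) for v in re.split(r"[,\s]+", line) if v]
            ys.extend(vals[1:])  # first number on each line is the X check value
    if firstx is None or lastx is None or npoints is None:
        raise ValueError("JCAMP file missing FIRSTX/LASTX/NPOINTS")
    if len(ys) != npoints:
        raise ValueError(f"expected {npoints} points, parsed {len(ys)}")
    x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    y = np.asarray(ys, dtype=float) * yfactor
    return x, y, title


def write_jcamp(path, wavenumbers: np.ndarray, absorbance: np.ndarray,
                title: str = "spectrum") -> None:
    wn = np.asarray(wavenumbers, dtype=float)
    ab = np.asarray(absorbance, dtype=float)
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={wn[0]:.6f}",
        f"##LASTX={wn[-1]:.6f}",
        f"##NPOINTS={wn.size}",
        "##XYDATA=(X++(Y..Y))",
    ]
    for i in range(0, wn.size, 6):
        chunk = ab[i : i + 6]
        lines.append(
            f"{wn[i]:.4f} " + " ".join(f"{v:.8e}" for v in chunk)
        )
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")
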