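"""Tabular I/O for two-color array pipelines.

Reads and writes GenePix-results-style (GPR) tab-separated probe tables with
two dye channels (foreground/background median per spot), probe→gene /
probe→taxon mapping tables, normalized-probe tables, and provides small
metadata utilities such as mass-concentration → molar conversion for
hydrochemistry tables.

The GPR dialect handled here is deliberately narrow: tab-separated, a single
header row naming at least ``ID`` plus ``F<wl> Median`` / ``B<wl> Median``
for both wavelengths, and an optional ATF-style preamble of lines beginning
with a double quote, which is skipped.  Binary scanner formats and image
quantification are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Dye wavelength carrying each sample.  The convention follows common
#: two-color practice for these experiments: Cy5 (635 nm) = biofilm,
#: Cy3 (532 nm) = plankton.
DEFAULT_CHANNEL_MAP: dict[str, str] = {"biofilm": "635", "plankton": "532"}

#: Column order of an emitted GPR-like file.
GPR_COLUMNS = [
    "Block", "Row", "Column", "ID", "Name",
    "F635 Median", "B635 Median", "F532 Median", "B532 Median", "Flags",
]

#: Canonical in-memory spot columns.
SPOT_COLUMNS = ["probe_id", "f_biofilm", "b_biofilm", "f_plankton", "b_plankton", "flag"]

SATURATION_CEILING = 2 ** 16 - 1  # 16-bit scanner ceiling


class GprFormatError(ValueError):
    """A GPR-like file violates the expected dialect."""


class ProbeMapError(ValueError):
    """A probe mapping table is empty or ambiguous."""


@dataclass
class ArrayExperiment:
    """One two-channel hybridization.

    Parameters
    ----------
    campaign, replicate
        Labels identifying the sampling campaign (e.g. ``"2004"``) and the
        technical replicate within it.
    spots
        One row per spot with columns ``probe_id, f_biofilm, b_biofilm,
        f_plankton, b_plankton, flag``.  Spots with a nonzero quality flag
        are excluded from every statistic but never silently dropped.
    channel_map
        Which dye wavelength carries which sample; always explicit, never
        inferred from the data.
    kind
        ``"expression"`` for the genomic array, ``"pam"`` for the
        phylochip (prokaryotic acidophile microarray) layout.
    """

    campaign: str
    replicate: str
    spots: pd.DataFrame
    channel_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    kind: str = "expression"

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise GprFormatError(f"spot table missing columns: {missing}")
        ids = self.spots["probe_id"]
        dup = ids[ids.duplicated()].unique().tolist()
        if dup and self.kind == "expression":
            raise GprFormatError(f"duplicate probe ids on array: {dup[:10]}")
        neg = self.spots[["f_biofilm", "b_biofilm", "f_plankton", "b_plankton"]].to_numpy()
        if np.any(neg < 0):
            raise GprFormatError("negative intensities in spot table")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def n_flagged(self) -> int:
        """Number of spots excluded from statistics by their quality flag."""
        return int((self.spots["flag"] != 0).sum())

    def swap_channels(self) -> "ArrayExperiment":
        """Return a copy with biofilm and plankton channels exchanged."""
        spots = self.spots.rename(
            columns={
                "f_biofilm": "f_plankton", "f_plankton": "f_biofilm",
                "b_biofilm": "b_plankton", "b_plankton": "b_biofilm",
            }
        )[SPOT_COLUMNS].copy()
        cmap = {"biofilm": self.channel_map["plankton"], "plankton": self.channel_map["biofilm"]}
        return ArrayExperiment(self.campaign, self.replicate, spots, cmap, self.kind)


def _required_columns(channel_map: dict[str, str]) -> list[str]:
    cols = ["ID"]
    for wl in channel_map.values():
        cols += [f"F{wl} Median", f"B{wl} Median"]
    return cols


def read_gpr(
    path: str | Path,
    campaign: str = "NA",
    replicate: str = "1",
    channel_map: dict[str, str] | None = None,
    kind: str = "expression",
) -> ArrayExperiment:
    """Read a GPR-like tab-separated file into an :class:`ArrayExperiment`.

    ATF-style preamble lines beginning with ``"`` are skipped.  A missing
    required column raises :class:`GprFormatError` naming it; duplicate
    probe ids raise an error listing the duplicates.  Flagged spots are
    retained (and counted in ``n_flagged``), never dropped.
    """
    path = Path(path)
    channel_map = dict(channel_map or DEFAULT_CHANNEL_MAP)
    with path.open() as fh:
        lines = fh.readlines()
    skip = 0
    while skip < len(lines) and lines[skip].lstrip().startswith('"'):
        skip += 1
    if skip == len(lines):
        raise GprFormatError(f"{path}: no header row found")
    table = pd.read_csv(path, sep="\t", skiprows=skip)
    for col in _required_columns(channel_map):
        if col not in table.columns:
            raise GprFormatError(f"{path}: missing required column {col!r}")
    wl_b, wl_p = channel_map["biofilm"], channel_map["plankton"]
    spots = pd.DataFrame(
        {
            "probe_id": table["ID"].astype(str),
            "f_biofilm": table[f"F{wl_b} Median"].astype(float),
            "b_biofilm": table[f"B{wl_b} Median"].astype(float),
            "f_plankton": table[f"F{wl_p} Median"].astype(float),
            "b_plankton": table[f"B{wl_p} Median"].astype(float),
            "flag": (table["Flags"] if "Flags" in table.columns else 0),
        }
    )
    spots["flag"] = spots["flag"].astype(int)
    array = ArrayExperiment(campaign, replicate, spots, channel_map, kind=kind)
    if array.n_flagged:
        log.info("%s: %d/%d spots excluded by quality flag", path.name, array.n_flagged, array.n_spots)
    return array


def write_gpr(array: ArrayExperiment, path: str | Path, quantize: bool = True) -> Path:
    """Write an :class:`ArrayExperiment` as a GPR-like TSV.

    With ``quantize`` (the default, matching scanner output) intensities are
    rounded to integers and clipped to the 16-bit saturation ceiling;
    disable it to preserve float values exactly.
    """
    path = Path(path)
    spots = array.spots
    n = len(spots)
    ncol = max(1, int(np.ceil(np.sqrt(n))))
    wl_b, wl_p = array.channel_map["biofilm"], array.channel_map["plankton"]

    def _chan(values: pd.Series) -> pd.Series:
        if quantize:
            return np.clip(np.rint(values), 0, SATURATION_CEILING).astype(int)
        return values

    out = pd.DataFrame(
        {
            "Block": 1,
            "Row": np.arange(n) // ncol + 1,
            "Column": np.arange(n) % ncol + 1,
            "ID": spots["probe_id"],
            "Name": spots["probe_id"],
            f"F{wl_b} Median": _chan(spots["f_biofilm"]),
            f"B{wl_b} Median": _chan(spots["b_biofilm"]),
            f"F{wl_p} Median": _chan(spots["f_plankton"]),
            f"B{wl_p} Median": _chan(spots["b_plankton"]),
            "Flags": spots["flag"],
        }
    )[GPR_COLUMNS]
    out.to_csv(path, sep="\t", index=False)
    return path


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a two-column TSV mapping probe → gene (or probe → taxon).

    Returns a :class:`pandas.Series` indexed by probe id.  Probes listed
    twice with conflicting targets raise :class:`ProbeMapError`; an empty
    table raises as well.  Probes absent from the map are *not* an error —
    downstream code treats them as ``"unassigned"``.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ProbeMapError(f"{path}: expected two columns, got {list(table.columns)}")
    if len(table) == 0:
        raise ProbeMapError(f"{path}: empty probe map")
    probe_col, target_col = table.columns[:2]
    dedup = table.drop_duplicates()
    conflicts = dedup[probe_col][dedup[probe_col].duplicated()].unique().tolist()
    if conflicts:
        raise ProbeMapError(f"{path}: probes mapped to multiple targets: {conflicts[:10]}")
    return pd.Series(dedup[target_col].values, index=dedup[probe_col].values, name=target_col)


def write_probe_map(mapping: pd.Series | pd.DataFrame, path: str | Path,
                    columns: tuple[str, str] = ("probe_id", "gene_id")) -> Path:
    path = Path(path)
    if isinstance(mapping, pd.Series):
        out = pd.DataFrame({columns[0]: mapping.index, columns[1]: mapping.values})
    else:
        out = mapping
    out.to_csv(path, sep="\t", index=False)
    return path


NORMALIZED_COLUMNS = ["probe_id", "A", "M_raw", "M_lowess", "M_corrected", "detected_flag"]


def write_normalized(probes: pd.DataFrame, path: str | Path) -> Path:
    """Write a normalized-probe table (see :mod:`envarray.normalize`)."""
    out = probes.copy()
    if "detected_flag" not in out.columns and "detected" in out.columns:
        out["detected_flag"] = out["detected"].astype(int)
    if "M_corrected" not in out.columns:
        out["M_corrected"] = np.nan
    out[NORMALIZED_COLUMNS].to_csv(path, sep="\t", index=False)
    return Path(path)


def read_normalized(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in NORMALIZED_COLUMNS if c not in table.columns]
    if missing:
        raise GprFormatError(f"{path}: missing normalized columns {missing}")
    table["detected"] = table["detected_flag"].astype(bool)
    return table


def mass_conc_to_molar(conc_mg_per_l: float, molar_mass_g_per_mol: float) -> float:
    """Convert a mass concentration (mg/L) to millimolar.

    mM = (mg/L) / (g/mol), since 1 mg/L = 1 g/m³ and 1 mol/m³ = 1 mM.
    The molar mass is an explicit argument because published hydrochemistry
    tables are not always consistent about ion vs. free-acid masses: e.g.
    82.68 mg/L acetate is 1.377 mM with the acetate-ion mass (60.05) and
    1.400 mM with the free-acid convention minus a proton (59.04), while
    field reports sometimes print 1.36 mM.  Rounding is left to the caller.
    """
    if molar_mass_g_per_mol <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass_g_per_mol}")
    if conc_mg_per_l < 0:
        raise ValueError(f"concentration must be non-negative, got {conc_mg_per_l}")
    return conc_mg_per_l / molar_mass_g_per_mol
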