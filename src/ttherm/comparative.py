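"""Testudinidae literature meta-analysis of thermal lability versus mass.

Each record is one published measurement (species may repeat): daily core
range, daily air range, body mass, and its source.  Three rank
correlations characterise thermal inertia in the family: core range vs
mass, core range vs air range, and the air-range-corrected quotient
(core range / air range) vs mass.  The quotient removes the dominant
environmental-forcing signal, so a surviving negative correlation with
mass is the thermal-inertia effect proper.

CSV schema
----------
``species,genus,mass_kg,delta_tbc,delta_tair,source,mass_estimated``
with mass in kg, ranges in degC and ``mass_estimated`` a true/false flag
marking masses inferred rather than weighed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, RowError, SchemaError
from .response import KendallResult, kendall_tau

SCHEMA = ("species", "genus", "mass_kg", "delta_tbc", "delta_tair", "source", "mass_estimated")

#: Example cohort shipped with the package — synthetic, generated by
#: :func:`ttherm.synthetic.synthetic_comparative_cohort`; replace with a
#: literature-collated table for real analyses.
EXAMPLE_TABLE = Path(__file__).parent / "data" / "testudinidae_synthetic.csv"


def read_comparative_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a comparative table; row-level errors name the row."""
    raw = pd.read_csv(path)
    missing = [c for c in SCHEMA if c not in raw.columns]
    if missing:
        raise SchemaError(f"comparative table: missing columns {missing}")
    df = raw.copy()
    for i, row in df.iterrows():
        line = int(i) + 2  # header + 1-based
        if not row["mass_kg"] > 0:
            raise RowError(f"non-positive mass {row['mass_kg']}", row=line)
        if row["delta_tbc"] < 0 or row["delta_tair"] < 0:
            raise RowError("negative temperature range", row=line)
    df["mass_estimated"] = df["mass_estimated"].astype(bool)
    return df


def comparative_summary(records: pd.DataFrame) -> dict:
    """Bookkeeping: measurements, species, genera, sources, estimated masses."""
    return {
        "n_measurements": int(len(records)),
        "n_species": int(records["species"].nunique()),
        "n_genera": int(records["genus"].nunique()),
        "n_sources": int(records["source"].nunique()),
        "n_mass_estimated": int(records["mass_estimated"].sum()),
    }


@dataclass
class ComparativeCorrelations:
    tbc_vs_mass: KendallResult
    tbc_vs_tair: KendallResult
    quotient_vs_mass: KendallResult
    records: pd.DataFrame  # with the quotient column appended

    def summary(self) -> str:
        def fmt(name: str, r: KendallResult) -> str:
            if not r.defined:
                return f"  {name:<24} undefined (all tied)"
            return f"  {name:<24} tau={r.tau:+.2f}  z={r.z:+.2f}  p={r.p:.3g}  n={r.n}"

        return "\n".join(
            [
                "Testudinidae comparative correlations",
                fmt("core range vs mass", self.tbc_vs_mass),
                fmt("core range vs air range", self.tbc_vs_tair),
                fmt("quotient vs mass", self.quotient_vs_mass),
            ]
        )


def comparative_correlations(
    records: pd.DataFrame, min_records: int = 5
) -> ComparativeCorrelations:
    """The three Kendall correlations of the meta-analysis.

    Records with an undefined quotient (zero air range) are excluded from
    the quotient-vs-mass test only.
    """
    out = records.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["quotient"] = np.where(
            out["delta_tair"] > 0, out["delta_tbc"] / out["delta_tair"], np.nan
        )
    out["quotient_exceeds_one"] = out["quotient"] > 1
    defined = out.dropna(subset=["quotient"])
    if len(defined) < min_records:
        raise InsufficientDataError(
            f"only {len(defined)} records with a defined quotient (< {min_records})"
        )
    return ComparativeCorrelations(
        tbc_vs_mass=kendall_tau(out["delta_tbc"], out["mass_kg"]),
        tbc_vs_tair=kendall_tau(out["delta_tbc"], out["delta_tair"]),
        quotient_vs_mass=kendall_tau(defined["quotient"], defined["mass_kg"]),
        records=out,
    )
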