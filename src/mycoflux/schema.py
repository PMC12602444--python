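"""Tidy measurement-table schema: reading, validation, and unit normalisation.

One row per (microcosm, plant, tissue).  Isotope composition may arrive as
atom percent (``atom_pct_13C`` / ``atom_pct_15N``) or as delta ‰ against the
international standards (``delta13C_permil`` / ``delta15N_permil``); the
reader detects which by column name and converts to atom fractions at ingest.
Element contents are ingested as percent (as labs report them) and stored as
mass fractions.

CSV dialect: UTF-8, comma-separated, ``.`` decimal, mandatory header row.
"""

from __future__ import annotations

import io
import os
from typing import Union

import numpy as np
import pandas as pd

from .units import AIR, VPDB, delta_to_atom_fraction

#: columns that must be present in every measurements CSV
REQUIRED_COLUMNS = [
    "microcosm_id",
    "treatment",
    "species",
    "plant_role",
    "tissue",
    "biomass_g",
    "c_content_pct",
    "n_content_pct",
    "labelled_13C",
    "labelled_15N",
]

ISOTOPE_COLUMN_SETS = {
    "atom_percent": ["atom_pct_13C", "atom_pct_15N"],
    "delta_permil": ["delta13C_permil", "delta15N_permil"],
}

VALID_TREATMENTS = {"labelled", "control"}
VALID_ROLES = {"orchid", "pine"}
VALID_TISSUES = {"aboveground", "belowground"}


class SchemaError(ValueError):
    """The measurements table violates the documented schema."""


def _rows(mask: pd.Series) -> str:
    # header is line 1, first data row line 2
    lines = (np.flatnonzero(np.asarray(mask)) + 2).tolist()
    shown = ", ".join(str(x) for x in lines[:8])
    return f"line(s) {shown}" + (" ..." if len(lines) > 8 else "")


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw measurements table and return the canonical frame.

    The canonical frame keeps the descriptive columns, stores element contents
    as fractions (``c_content``, ``n_content``) and isotope composition as
    atom fractions (``af_13C``, ``af_15N``), and casts label flags to bool.
    Raises :class:`SchemaError` naming the offending CSV line numbers.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    notation = None
    for kind, cols in ISOTOPE_COLUMN_SETS.items():
        if all(c in df.columns for c in cols):
            notation = kind
            break
    if notation is None:
        raise SchemaError(
            "isotope columns not found: provide either "
            "atom_pct_13C/atom_pct_15N or delta13C_permil/delta15N_permil"
        )

    if len(df) == 0:
        raise SchemaError("measurements table is empty")

    out = df.copy()
    for col in ("microcosm_id", "treatment", "species", "plant_role", "tissue"):
        out[col] = out[col].astype(str).str.strip()

    bad = ~out["treatment"].isin(VALID_TREATMENTS)
    if bad.any():
        raise SchemaError(f"treatment must be labelled/control at {_rows(bad)}")
    bad = ~out["plant_role"].isin(VALID_ROLES)
    if bad.any():
        raise SchemaError(f"plant_role must be orchid/pine at {_rows(bad)}")
    bad = ~out["tissue"].isin(VALID_TISSUES)
    if bad.any():
        raise SchemaError(f"tissue must be aboveground/belowground at {_rows(bad)}")

    for col in ["biomass_g", "c_content_pct", "n_content_pct"] + ISOTOPE_COLUMN_SETS[notation]:
        out[col] = pd.to_numeric(out[col], errors="coerce")
        bad = out[col].isna()
        if bad.any():
            raise SchemaError(f"non-numeric or missing {col} at {_rows(bad)}")

    bad = out["biomass_g"] <= 0
    if bad.any():
        raise SchemaError(f"biomass_g must be positive at {_rows(bad)}")
    bad = (out["c_content_pct"] <= 0) | (out["c_content_pct"] >= 100)
    if bad.any():
        raise SchemaError(f"c_content_pct must lie in (0, 100) at {_rows(bad)}")
    bad = (out["n_content_pct"] <= 0) | (out["n_content_pct"] >= 100)
    if bad.any():
        raise SchemaError(f"n_content_pct must lie in (0, 100) at {_rows(bad)}")
    bad = out["c_content_pct"] + out["n_content_pct"] >= 100
    if bad.any():
        raise SchemaError(f"C% + N% must stay below 100 at {_rows(bad)}")

    for col in ("labelled_13C", "labelled_15N"):
        vals = out[col]
        if vals.dtype != bool:
            mapped = (
                vals.astype(str).str.strip().str.lower().map(
                    {"true": True, "false": False, "1": True, "0": False}
                )
            )
            bad = mapped.isna()
            if bad.any():
                raise SchemaError(f"{col} must be boolean at {_rows(bad)}")
            out[col] = mapped.astype(bool)

    out["c_content"] = out["c_content_pct"] / 100.0
    out["n_content"] = out["n_content_pct"] / 100.0

    if notation == "atom_percent":
        for col, af in (("atom_pct_13C", "af_13C"), ("atom_pct_15N", "af_15N")):
            bad = (out[col] < 0) | (out[col] > 100)
            if bad.any():
                raise SchemaError(f"{col} must lie in [0, 100] at {_rows(bad)}")
            out[af] = out[col] / 100.0
    else:
        for col, af, std in (
            ("delta13C_permil", "af_13C", VPDB),
            ("delta15N_permil", "af_15N", AIR),
        ):
            bad = out[col] < -1000
            if bad.any():
                raise SchemaError(f"{col} below -1000 permil at {_rows(bad)}")
            out[af] = [delta_to_atom_fraction(d, std) for d in out[col]]

    dup = out.duplicated(subset=["microcosm_id", "plant_role", "tissue"], keep=False)
    if dup.any():
        raise SchemaError(
            f"duplicate (microcosm, plant, tissue) entries at {_rows(dup)}"
        )

    # controls carry no label; labelled microcosms label exactly one plant per
    # element, and the reciprocal design puts the two labels on different plants
    ctrl = out["treatment"] == "control"
    bad = ctrl & (out["labelled_13C"] | out["labelled_15N"])
    if bad.any():
        raise SchemaError(f"control rows must not carry label flags at {_rows(bad)}")

    lab = out[~ctrl]
    for mid, grp in lab.groupby("microcosm_id", sort=False):
        for col, tag in (("labelled_13C", "13C"), ("labelled_15N", "15N")):
            donors = grp.loc[grp[col], "plant_role"].unique()
            if len(donors) != 1:
                raise SchemaError(
                    f"labelled microcosm {mid!r} must label exactly one plant "
                    f"with {tag} (found {len(donors)})"
                )
        roles = set(grp["plant_role"])
        if roles != VALID_ROLES:
            raise SchemaError(
                f"labelled microcosm {mid!r} must contain one orchid and one pine"
            )
        c_donor = grp.loc[grp["labelled_13C"], "plant_role"].iloc[0]
        n_donor = grp.loc[grp["labelled_15N"], "plant_role"].iloc[0]
        if c_donor == n_donor:
            raise SchemaError(
                f"labelled microcosm {mid!r}: 13C and 15N labels must sit on "
                "different plants (reciprocal dual-labelling design)"
            )
    return out


def read_measurements(path_or_buf: Union[str, os.PathLike, io.IOBase]) -> pd.DataFrame:
    """Read and validate a measurements CSV, returning the canonical frame."""
    # round_trip float parsing keeps write->read bit-identical
    df = pd.read_csv(path_or_buf, float_precision="round_trip")
    return validate_measurements(df)
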