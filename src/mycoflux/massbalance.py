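"""Tracer mass balance: enrichment x element content x biomass -> tracer µg.

The chain per tissue is

    APE        = labelled atom fraction - control atom fraction
    tracer µg  = APE x element mass fraction x dry biomass (g) x 1e6

with the 1e6 factor converting grams of element to micrograms of tracer.  The
factor is applied exactly once, here; enrichment and content must already be
plain fractions.  Whole-plant pools are obtained by summing tissue masses
(mass-weighted aggregation), never by averaging atom percents.

Two pool kinds exist per labelled microcosm and element: the donor plant's
``assimilated_by_label`` pool (tracer it took up and retained) and the
neighbouring plant's ``received_via_network`` pool (tracer that crossed the
fungal connection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .units import Element, EnrichmentFlag

ArrayLike = Union[float, np.ndarray]


class PoolKind(str, Enum):
    ASSIMILATED = "assimilated_by_label"
    RECEIVED = "received_via_network"


class MassBalanceError(ValueError):
    """Invalid inputs to the tracer mass balance."""


class MissingControlError(MassBalanceError):
    """A labelled group has no matching control baseline."""


@dataclass(frozen=True)
class TissueMeasurement:
    """One plant tissue's biomass, contents, and isotope composition."""

    microcosm_id: str
    treatment: str
    species: str
    plant_role: str
    tissue: str
    biomass_g: float
    c_content: float
    n_content: float
    af_13C: float
    af_15N: float

    def __post_init__(self) -> None:
        if self.biomass_g <= 0:
            raise MassBalanceError(f"biomass must be positive, got {self.biomass_g}")
        for name, v in (("c_content", self.c_content), ("n_content", self.n_content)):
            if not 0.0 < v < 1.0:
                raise MassBalanceError(f"{name} must lie in (0, 1), got {v}")
        if self.c_content + self.n_content >= 1.0:
            raise MassBalanceError("c_content + n_content must stay below 1")


@dataclass(frozen=True)
class PoolMass:
    """Tracer mass (µg) in one plant pool, with its per-tissue breakdown."""

    element: Element
    pool_kind: PoolKind
    microcosm_id: str
    species: str
    plant_role: str
    mass_ug: float
    tissue_breakdown: Dict[str, float] = field(default_factory=dict)
    flag: EnrichmentFlag = EnrichmentFlag.OK


def tissue_tracer_mass(
    ape: ArrayLike, element_content: ArrayLike, biomass_g: ArrayLike
) -> ArrayLike:
    """Tracer mass (µg) in one tissue: APE x content x biomass x 1e6.

    ``ape`` is an atom-fraction excess (may be negative under noise);
    ``element_content`` a mass fraction in (0, 1); ``biomass_g`` dry mass in
    grams.  Linear in every argument.
    """
    ape = np.asarray(ape, dtype=float)
    element_content = np.asarray(element_content, dtype=float)
    biomass_g = np.asarray(biomass_g, dtype=float)
    if np.any(biomass_g <= 0):
        raise MassBalanceError("biomass must be positive")
    if np.any((element_content <= 0) | (element_content >= 1)):
        raise MassBalanceError("element content must lie in (0, 1)")
    out = ape * element_content * biomass_g * 1e6
    return float(out) if out.ndim == 0 else out


def plant_pool(
    element: Element,
    pool_kind: PoolKind,
    microcosm_id: str,
    species: str,
    plant_role: str,
    tissues: Iterable[Tuple[str, float, EnrichmentFlag]],
) -> PoolMass:
    """Aggregate per-tissue tracer masses into a whole-plant pool.

    ``tissues`` yields (tissue name, mass µg, flag) triples.  Masses are
    summed; a ``below_zero`` flag on any tissue propagates to the pool.
    Duplicate tissue entries are a schema error.
    """
    breakdown: Dict[str, float] = {}
    flag = EnrichmentFlag.OK
    for name, mass, tissue_flag in tissues:
        if name in breakdown:
            raise MassBalanceError(
                f"duplicate tissue {name!r} for {plant_role} in microcosm {microcosm_id!r}"
            )
        breakdown[name] = float(mass)
        if tissue_flag is EnrichmentFlag.BELOW_ZERO:
            flag = EnrichmentFlag.BELOW_ZERO
    if not breakdown:
        raise MassBalanceError("plant pool needs at least one tissue")
    return PoolMass(
        element=element,
        pool_kind=pool_kind,
        microcosm_id=microcosm_id,
        species=species,
        plant_role=plant_role,
        mass_ug=float(sum(breakdown.values())),
        tissue_breakdown=breakdown,
        flag=flag,
    )


def control_baselines(df: pd.DataFrame) -> pd.DataFrame:
    """Pooled control baselines per (species, tissue, element).

    Controls are pooled across all control microcosms of a species; the pooled
    mean atom fraction defines the enrichment baseline, and the pooled sd feeds the
    detection threshold.  Returns a frame with columns species, tissue,
    element, af_mean, af_sd, n_control.
    """
    ctrl = df[df["treatment"] == "control"]
    if len(ctrl) == 0:
        raise MissingControlError("dataset contains no control microcosms")
    rows = []
    for (species, tissue), grp in ctrl.groupby(["species", "tissue"], sort=True):
        for element, col in ((Element.C13, "af_13C"), (Element.N15, "af_15N")):
            vals = grp[col].to_numpy(dtype=float)
            rows.append(
                {
                    "species": species,
                    "tissue": tissue,
                    "element": element.value,
                    "af_mean": float(vals.mean()),
                    "af_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n_control": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


_AF_COL = {Element.C13: "af_13C", Element.N15: "af_15N"}
_CONTENT_COL = {Element.C13: "c_content", Element.N15: "n_content"}
_LABEL_COL = {Element.C13: "labelled_13C", Element.N15: "labelled_15N"}


def enrichment_table(
    df: pd.DataFrame, baselines: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-tissue enrichment of every labelled row, for both elements.

    Long format: one row per (labelled tissue row, element) carrying the APE
    (atom-fraction excess over the pooled control baseline), the tissue tracer
    mass (the per-tissue mass balance), the control dispersion, and flags.
    """
    if baselines is None:
        baselines = control_baselines(df)
    lab = df[df["treatment"] == "labelled"]
    if len(lab) == 0:
        raise MassBalanceError("no labelled microcosms found")

    parts = []
    for element in (Element.C13, Element.N15):
        part = lab[
            [
                "microcosm_id",
                "species",
                "plant_role",
                "tissue",
                "biomass_g",
                _CONTENT_COL[element],
                _AF_COL[element],
                _LABEL_COL[element],
            ]
        ].rename(
            columns={
                _CONTENT_COL[element]: "content",
                _AF_COL[element]: "af",
                _LABEL_COL[element]: "is_donor",
            }
        )
        part["element"] = element.value
        parts.append(part)
    enr = pd.concat(parts, ignore_index=True)

    enr = enr.merge(baselines, on=["species", "tissue", "element"], how="left")
    missing = enr["af_mean"].isna()
    if missing.any():
        first = enr[missing].iloc[0]
        raise MissingControlError(
            f"no control baseline for species={first['species']!r}, "
            f"tissue={first['tissue']!r}, element={first['element']}"
        )
    enr["ape"] = enr["af"] - enr["af_mean"]
    enr["tracer_ug"] = tissue_tracer_mass(
        enr["ape"].to_numpy(), enr["content"].to_numpy(), enr["biomass_g"].to_numpy()
    )
    enr["flag"] = np.where(
        enr["ape"] < 0, EnrichmentFlag.BELOW_ZERO.value, EnrichmentFlag.OK.value
    )
    return enr.rename(
        columns={"af_mean": "control_af_mean", "af_sd": "control_af_sd"}
    ).drop(columns=["af"])


def build_pools(
    df: pd.DataFrame, baselines: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-plant tracer pools for every labelled microcosm and element.

    For each labelled microcosm and element the plant carrying that element's
    label yields the ``assimilated_by_label`` pool and its neighbour the
    ``received_via_network`` pool.  Control microcosms emit no pools (they
    only parameterise baselines).  Returns a tidy frame, one row per
    (microcosm, plant, element, pool_kind).
    """
    enr = enrichment_table(df, baselines)
    if enr.duplicated(["microcosm_id", "plant_role", "element", "tissue"]).any():
        raise MassBalanceError("duplicate tissue entries for one plant")
    keys = ["microcosm_id", "species", "plant_role", "element"]
    wide = enr.pivot_table(
        index=keys, columns="tissue", values="tracer_ug", aggfunc="sum"
    )
    for tissue in ("aboveground", "belowground"):
        if tissue not in wide.columns:
            wide[tissue] = np.nan
    agg = enr.groupby(keys, sort=True).agg(
        is_donor=("is_donor", "first"),
        any_below_zero=("flag", lambda f: (f == EnrichmentFlag.BELOW_ZERO.value).any()),
    )
    pools = agg.join(wide[["aboveground", "belowground"]]).reset_index()
    pools["mass_ug"] = pools[["aboveground", "belowground"]].sum(axis=1)
    pools["pool_kind"] = np.where(
        pools["is_donor"], PoolKind.ASSIMILATED.value, PoolKind.RECEIVED.value
    )
    pools["flag"] = np.where(
        pools["any_below_zero"],
        EnrichmentFlag.BELOW_ZERO.value,
        EnrichmentFlag.OK.value,
    )
    pools = pools.rename(
        columns={"aboveground": "aboveground_ug", "belowground": "belowground_ug"}
    )
    return pools[
        [
            "microcosm_id",
            "species",
            "plant_role",
            "element",
            "pool_kind",
            "mass_ug",
            "aboveground_ug",
            "belowground_ug",
            "flag",
        ]
    ]
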