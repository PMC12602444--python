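"""Synthetic dual-labelling microcosm experiments with known ground truth.

The generator emulates the compartmented-microcosm design: an orchid and a
pine seedling share a pot split by a hyphae-permeable mesh, connected by a
common mycorrhizal fungus.  In each labelled microcosm one plant's shoot is
exposed to ¹³CO₂ while the *other* plant's leaves take up ¹⁵N from labelled
ammonium nitrate; the two reciprocal orientations are generated in equal
numbers.  Unlabelled reference microcosms at natural abundance serve as
controls.

Per labelled microcosm and element the donor draws a tracer uptake ``T``
(lognormal — uptake is positive and multiplicative); a fraction ``φ`` of it
crosses the network to the neighbour and ``(1 − φ) T`` stays in the donor.
Plant-level tracer is split across aboveground/belowground tissues by fixed
allocation fractions, converted to an atom-fraction excess through the
tissue's element pool (biomass x content), stacked on the natural-abundance
baseline, and finally blurred with Gaussian IRMS noise applied in delta space
(where instrument precision is stated) before converting back.

Ground truth records ``T``, ``φT`` and ``100 φ`` per microcosm and element,
so the analysis pipeline's percent-transferred estimates can be checked
against construction.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .units import (
    AIR,
    VPDB,
    Element,
    atom_fraction_to_delta,
    delta_to_atom_fraction,
)


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species generative parameters.

    Biomass (g dry mass per tissue) and tracer uptakes (µg per labelling
    event) are lognormal with the given coefficients of variation; element
    contents are mass fractions with a small lognormal spread.  Allocation
    fractions give the aboveground share of a plant's tracer, separately for
    tracer the plant assimilated itself and for tracer received through the
    network (received tracer arrives through the roots and is root-biased).
    """

    name: str
    biomass_above_g: float
    biomass_below_g: float
    biomass_cv: float = 0.2
    c_content: float = 0.45
    n_content: float = 0.015
    content_cv: float = 0.05
    uptake_13c_ug: float = 1000.0
    uptake_15n_ug: float = 600.0
    uptake_cv: float = 0.3
    donor_alloc_above: float = 0.6
    received_alloc_above: float = 0.4

    def __post_init__(self) -> None:
        for nm in ("biomass_above_g", "biomass_below_g", "uptake_13c_ug", "uptake_15n_ug"):
            if getattr(self, nm) <= 0:
                raise SimulationConfigError(f"{self.name}: {nm} must be positive")
        for nm in ("biomass_cv", "content_cv", "uptake_cv"):
            if getattr(self, nm) < 0:
                raise SimulationConfigError(f"{self.name}: {nm} must be >= 0")
        for nm in ("c_content", "n_content"):
            if not 0 < getattr(self, nm) < 1:
                raise SimulationConfigError(f"{self.name}: {nm} must lie in (0, 1)")
        for nm in ("donor_alloc_above", "received_alloc_above"):
            if not 0 <= getattr(self, nm) <= 1:
                raise SimulationConfigError(f"{self.name}: {nm} must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one simulated microcosm experiment.

    ``phi_*`` are the transfer fractions per element and direction (share of
    the donor's assimilated tracer that reaches the neighbour, in [0, 1)).
    ``n_labelled`` is the number of replicate microcosms *per labelling
    orientation* (each orientation is one treatment); ``n_control`` the number
    of unlabelled reference microcosms.
    """

    orchid: SpeciesParams
    pine: SpeciesParams
    phi_c_orchid_to_pine: float = 0.0
    phi_c_pine_to_orchid: float = 0.0
    phi_n_orchid_to_pine: float = 0.0
    phi_n_pine_to_orchid: float = 0.0
    baseline_d13c_permil: float = -27.0
    baseline_d15n_permil: float = 0.0
    analytical_sd_permil: float = 0.15
    n_labelled: int = 4
    n_control: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in (
            "phi_c_orchid_to_pine",
            "phi_c_pine_to_orchid",
            "phi_n_orchid_to_pine",
            "phi_n_pine_to_orchid",
        ):
            if not 0 <= getattr(self, nm) < 1:
                raise SimulationConfigError(f"{nm} must lie in [0, 1)")
        if self.analytical_sd_permil < 0:
            raise SimulationConfigError("analytical_sd_permil must be >= 0")
        if self.n_labelled < 1 or self.n_control < 1:
            raise SimulationConfigError("n_labelled and n_control must be >= 1")

    def phi(self, element: Element, donor_role: str) -> float:
        key = {
            (Element.C13, "orchid"): "phi_c_orchid_to_pine",
            (Element.C13, "pine"): "phi_c_pine_to_orchid",
            (Element.N15, "orchid"): "phi_n_orchid_to_pine",
            (Element.N15, "pine"): "phi_n_pine_to_orchid",
        }[(element, donor_role)]
        return getattr(self, key)


# Default magnitudes: a pine seedling is a fast-growing autotroph that fixes
# roughly an order of magnitude more carbon during a 20-h ¹³CO₂ pulse than a
# small mixotrophic Cymbidium; foliar ¹⁵N uptakes are of comparable size.
def default_orchid(name: str = "Cymbidium sp.", **over) -> SpeciesParams:
    base = dict(
        name=name,
        biomass_above_g=1.2,
        biomass_below_g=0.8,
        c_content=0.45,
        n_content=0.015,
        uptake_13c_ug=700.0,
        uptake_15n_ug=600.0,
    )
    base.update(over)
    return SpeciesParams(**base)


def default_pine(name: str = "Pinus yunnanensis", **over) -> SpeciesParams:
    base = dict(
        name=name,
        biomass_above_g=2.0,
        biomass_below_g=1.0,
        c_content=0.48,
        n_content=0.012,
        uptake_13c_ug=8000.0,
        uptake_15n_ug=800.0,
    )
    base.update(over)
    return SpeciesParams(**base)


def default_config(**over) -> SimulationConfig:
    kwargs = dict(orchid=default_orchid(), pine=default_pine())
    kwargs.update(over)
    return SimulationConfig(**kwargs)


def study_like_scenarios() -> Dict[str, SimulationConfig]:
    """Three named scenarios mirroring the observed species-specific patterns.

    * ``goeringii-like`` — strictly unidirectional: carbon pine→orchid,
      nitrogen orchid→pine.
    * ``faberi-like`` — carbon and nitrogen both bidirectional; the nitrogen
      uptakes are balanced against the transfer fractions so the expected
      nitrogen flows cancel (no net N), while net carbon runs pine→orchid.
    * ``serratum-like`` — both elements bidirectional with a clear net:
      carbon pine→orchid, nitrogen orchid→pine.
    """
    return {
        "goeringii-like": default_config(
            orchid=default_orchid("Cymbidium goeringii"),
            phi_c_pine_to_orchid=0.014,
            phi_n_orchid_to_pine=0.0030,
        ),
        "faberi-like": default_config(
            # nitrogen no-net: equal transfer fractions on equal uptakes, so
            # the expected flows cancel exactly
            orchid=default_orchid("Cymbidium faberi", uptake_15n_ug=700.0),
            pine=default_pine(uptake_15n_ug=700.0),
            phi_c_orchid_to_pine=0.016,
            phi_c_pine_to_orchid=0.030,
            phi_n_orchid_to_pine=0.006,
            phi_n_pine_to_orchid=0.006,
        ),
        "serratum-like": default_config(
            orchid=default_orchid("Cymbidium goeringii var. serratum"),
            phi_c_orchid_to_pine=0.027,
            phi_c_pine_to_orchid=0.014,
            phi_n_orchid_to_pine=0.090,
            phi_n_pine_to_orchid=0.0025,
        ),
    }


_BASELINE = {
    Element.C13: ("baseline_d13c_permil", VPDB),
    Element.N15: ("baseline_d15n_permil", AIR),
}
_CONTENT_ATTR = {Element.C13: "c_content", Element.N15: "n_content"}
_UPTAKE_ATTR = {Element.C13: "uptake_13c_ug", Element.N15: "uptake_15n_ug"}
_AF_COL = {Element.C13: "af_13C", Element.N15: "af_15N"}


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    if cv == 0:
        return mean if size is None else np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2), size)


@dataclass
class _Plant:
    species: SpeciesParams
    role: str
    biomass: Dict[str, float]
    contents: Dict[Element, float]
    # tracer µg per (element, tissue)
    tracer: Dict[Tuple[Element, str], float] = field(default_factory=dict)


def _draw_plant(rng: np.random.Generator, sp: SpeciesParams, role: str) -> _Plant:
    biomass = {
        "aboveground": float(_lognormal(rng, sp.biomass_above_g, sp.biomass_cv)),
        "belowground": float(_lognormal(rng, sp.biomass_below_g, sp.biomass_cv)),
    }
    contents = {
        Element.C13: float(
            np.clip(_lognormal(rng, sp.c_content, sp.content_cv), 1e-6, 0.95)
        ),
        Element.N15: float(
            np.clip(_lognormal(rng, sp.n_content, sp.content_cv), 1e-6, 0.5)
        ),
    }
    return _Plant(sp, role, biomass, contents)


def _allocate(plant: _Plant, element: Element, mass_ug: float, above_frac: float) -> None:
    for tissue, frac in (("aboveground", above_frac), ("belowground", 1.0 - above_frac)):
        plant.tracer[(element, tissue)] = plant.tracer.get((element, tissue), 0.0) + mass_ug * frac


def _measure(
    plant: _Plant,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Dict[str, Dict[Element, float]]:
    """Tissue atom fractions: baseline + tracer excess (+ delta-space noise)."""
    out: Dict[str, Dict[Element, float]] = {}
    for tissue in ("aboveground", "belowground"):
        out[tissue] = {}
        for element in (Element.C13, Element.N15):
            attr, std = _BASELINE[element]
            base_af = delta_to_atom_fraction(getattr(config, attr), std)
            pool_ug = plant.biomass[tissue] * plant.contents[element] * 1e6
            ape = plant.tracer.get((element, tissue), 0.0) / pool_ug
            af = base_af + ape
            if af >= 1.0:
                raise SimulationConfigError(
                    f"configured transfer drives atom fraction to {af:.3f} >= 1 "
                    f"({plant.species.name}, {tissue}, {element.value})"
                )
            if config.analytical_sd_permil > 0:
                delta = atom_fraction_to_delta(af, std)
                delta += rng.normal(0.0, config.analytical_sd_permil)
                af = delta_to_atom_fraction(max(delta, -1000.0), std)
            out[tissue][element] = af
    return out


def simulate_experiment(
    config: SimulationConfig, seed: Optional[int] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one complete microcosm experiment.

    Returns ``(measurements, ground_truth)``.  ``measurements`` is the
    canonical tidy frame (one row per microcosm x plant x tissue, atom
    fractions in ``af_13C``/``af_15N`` plus atom-percent I/O columns).
    ``ground_truth`` has one row per labelled microcosm x element with the
    true uptake ``T``, the transferred tracer ``φT``, and the true percent
    transferred ``100 φ``.

    Microcosms ``L1..Ln`` carry orientation A (orchid ¹³C donor, pine ¹⁵N
    donor), ``L(n+1)..L(2n)`` the reciprocal orientation B; ``K1..Km`` are
    controls.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    meas_rows = []
    truth_rows = []

    def emit(mid: str, treatment: str, plant: _Plant, afs, c_donor: str, n_donor: str):
        for tissue in ("aboveground", "belowground"):
            meas_rows.append(
                {
                    "microcosm_id": mid,
                    "treatment": treatment,
                    "species": plant.species.name,
                    "plant_role": plant.role,
                    "tissue": tissue,
                    "biomass_g": plant.biomass[tissue],
                    "c_content_pct": plant.contents[Element.C13] * 100.0,
                    "n_content_pct": plant.contents[Element.N15] * 100.0,
                    "labelled_13C": treatment == "labelled" and plant.role == c_donor,
                    "labelled_15N": treatment == "labelled" and plant.role == n_donor,
                    "atom_pct_13C": afs[tissue][Element.C13] * 100.0,
                    "atom_pct_15N": afs[tissue][Element.N15] * 100.0,
                    "af_13C": afs[tissue][Element.C13],
                    "af_15N": afs[tissue][Element.N15],
                    "c_content": plant.contents[Element.C13],
                    "n_content": plant.contents[Element.N15],
                }
            )

    n = config.n_labelled
    for i in range(2 * n):
        mid = f"L{i + 1}"
        orientation = "A" if i < n else "B"
        c_donor = "orchid" if orientation == "A" else "pine"
        n_donor = "pine" if orientation == "A" else "orchid"
        plants = {
            "orchid": _draw_plant(rng, config.orchid, "orchid"),
            "pine": _draw_plant(rng, config.pine, "pine"),
        }
        for element, donor_role in ((Element.C13, c_donor), (Element.N15, n_donor)):
            donor = plants[donor_role]
            recipient = plants["pine" if donor_role == "orchid" else "orchid"]
            uptake_mean = getattr(donor.species, _UPTAKE_ATTR[element])
            T = float(_lognormal(rng, uptake_mean, donor.species.uptake_cv))
            phi = config.phi(element, donor_role)
            _allocate(donor, element, (1.0 - phi) * T, donor.species.donor_alloc_above)
            _allocate(
                recipient, element, phi * T, recipient.species.received_alloc_above
            )
            truth_rows.append(
                {
                    "microcosm_id": mid,
                    "orientation": orientation,
                    "element": element.value,
                    "donor_role": donor_role,
                    "recipient_role": recipient.role,
                    "uptake_ug": T,
                    "transferred_ug": phi * T,
                    "retained_ug": (1.0 - phi) * T,
                    "true_percent_transferred": 100.0 * phi,
                }
            )
        for role in ("orchid", "pine"):
            plant = plants[role]
            afs = _measure(plant, config, rng)
            emit(mid, "labelled", plant, afs, c_donor, n_donor)

    for j in range(config.n_control):
        mid = f"K{j + 1}"
        for role, sp in (("orchid", config.orchid), ("pine", config.pine)):
            plant = _draw_plant(rng, sp, role)
            afs = _measure(plant, config, rng)
            emit(mid, "control", plant, afs, "", "")

    return pd.DataFrame(meas_rows), pd.DataFrame(truth_rows)


def true_patterns(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth pattern and net direction per element, from the config.

    A direction truly transfers iff its φ > 0; the true net is the difference
    of expected flows ``φ_ab E[T_a] − φ_ba E[T_b]`` (zero means no net).
    """
    rows = []
    for element in (Element.C13, Element.N15):
        phi_op = config.phi(element, "orchid")
        phi_po = config.phi(element, "pine")
        flow_op = phi_op * getattr(config.orchid, _UPTAKE_ATTR[element])
        flow_po = phi_po * getattr(config.pine, _UPTAKE_ATTR[element])
        if phi_op == 0 and phi_po == 0:
            pattern, net = "none", "none"
        elif (phi_op == 0) != (phi_po == 0):
            pattern = "unidirectional"
            net = "orchid_to_pine" if phi_op > 0 else "pine_to_orchid"
        elif np.isclose(flow_op, flow_po, rtol=1e-9):
            pattern, net = "bidirectional_no_net", "none"
        else:
            pattern = "bidirectional_net"
            net = "orchid_to_pine" if flow_op > flow_po else "pine_to_orchid"
        rows.append(
            {
                "element": element.value,
                "pattern": pattern,
                "net_direction": net,
                "expected_net_ug": flow_op - flow_po,
            }
        )
    return pd.DataFrame(rows)


#: columns written to measurements.csv (I/O representation; atom percent)
CSV_COLUMNS = [
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
    "atom_pct_13C",
    "atom_pct_15N",
]


def write_fixtures(
    measurements: pd.DataFrame,
    ground_truth: pd.DataFrame,
    directory,
    config: Optional[SimulationConfig] = None,
) -> Dict[str, Path]:
    """Write measurements.csv, ground_truth.csv and a config snapshot.

    Floats are written at full round-trip precision so re-reading reproduces
    the tables bit-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": directory / "measurements.csv",
        "ground_truth": directory / "ground_truth.csv",
    }
    measurements[CSV_COLUMNS].to_csv(paths["measurements"], index=False)
    ground_truth.to_csv(paths["ground_truth"], index=False)
    if config is not None:
        paths["config"] = directory / "config.yaml"
        snapshot = dataclasses.asdict(config)
        with open(paths["config"], "w", encoding="utf-8") as fh:
            yaml.safe_dump(snapshot, fh, sort_keys=False)
    return paths


def config_from_yaml(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML snapshot (inverse of write_fixtures)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    try:
        orchid = SpeciesParams(**data.pop("orchid"))
        pine = SpeciesParams(**data.pop("pine"))
        return SimulationConfig(orchid=orchid, pine=pine, **data)
    except TypeError as exc:
        raise SimulationConfigError(f"bad config file {path}: {exc}") from None
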