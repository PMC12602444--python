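"""Directional transfer inference over plant tracer pools.

Per labelled microcosm and element the mass balance yields a donor pool
(tracer assimilated and retained by the labelled plant) and a recipient pool
(tracer found in the neighbour, i.e. moved through the fungal network).  This
module turns those pools into:

* percent transferred, ``100 x transferred / (transferred + assimilated)`` —
  the share of a donor's tracer budget that ended up in the neighbour;
* a detection verdict per recipient, against a threshold built from the
  analytical precision and the control dispersion (two-sd rule, strict
  inequality);
* a net-transfer estimate per plant pair and element with a seeded,
  small-sample-expanded percentile bootstrap confidence interval;
* the transfer-pattern taxonomy per pair and element: none, unidirectional,
  bidirectional without net transfer, bidirectional with net transfer;
* the classical group-comparison contract (Shapiro-Wilk and Levene
  pre-checks, one-way ANOVA, Tukey HSD, compact letter display).

Percent values are summarised across replicate microcosms as mean ± SE.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import massbalance
from .massbalance import PoolKind
from .units import (
    Element,
    EnrichmentFlag,
    STANDARDS,
    delta_sd_to_atom_fraction_sd,
)


class InferenceError(ValueError):
    pass


class UndefinedRatioError(InferenceError):
    """Percent transferred is undefined when both pools are zero."""


class ConfigurationError(InferenceError):
    pass


def percent_transferred(transferred_ug: float, assimilated_ug: float) -> float:
    """Share (%) of the donor's tracer budget found in the recipient.

    ``100 x transferred / (transferred + assimilated)``.  Flagged-negative
    masses are floored to zero for this ratio only; the ratio is bounded in
    [0, 100].  Both arguments zero is undefined.
    """
    t = max(float(transferred_ug), 0.0)
    a = max(float(assimilated_ug), 0.0)
    if t == 0.0 and a == 0.0:
        raise UndefinedRatioError(
            "percent transferred undefined: transferred and assimilated both zero"
        )
    return 100.0 * t / (t + a)


@dataclass(frozen=True)
class DetectionResult:
    detected: bool
    threshold: float
    weighted_mean_ape: float


def detect_transfer(
    tissue_apes: Sequence[float],
    biomass_weights: Optional[Sequence[float]] = None,
    control_af_sds: Optional[Sequence[float]] = None,
    analytical_sd_permil: Optional[float] = None,
    element: Optional[Element] = None,
    control_atom_fraction: float = 0.0,
) -> DetectionResult:
    """Decide whether a recipient's enrichment rises above noise.

    The verdict compares the biomass-weighted mean APE of the recipient's
    tissues against ``T = max(2 x analytical sd in atom-fraction units,
    2 x control sd)``, with a strict inequality (a value exactly at the
    threshold is *not* detected).  The analytical sd, stated in ‰, is
    converted at the control composition; the control sd is the pooled
    dispersion of unlabelled microcosms, taken at its largest across the
    recipient's tissues.
    """
    apes = np.asarray(tissue_apes, dtype=float)
    if apes.size == 0:
        raise ConfigurationError("no tissue APEs supplied")
    if biomass_weights is None:
        weights = np.ones_like(apes)
    else:
        weights = np.asarray(biomass_weights, dtype=float)
        if weights.shape != apes.shape or np.any(weights <= 0):
            raise ConfigurationError("biomass weights must be positive, one per tissue")
    mean_ape = float(np.average(apes, weights=weights))

    candidates = []
    if control_af_sds is not None:
        ctrl = np.asarray(control_af_sds, dtype=float)
        if ctrl.size:
            candidates.append(2.0 * float(np.max(ctrl)))
    if analytical_sd_permil is not None:
        if element is None:
            raise ConfigurationError(
                "element required to convert the analytical sd from permil"
            )
        candidates.append(
            2.0
            * delta_sd_to_atom_fraction_sd(
                analytical_sd_permil, STANDARDS[element], control_atom_fraction
            )
        )
    if not candidates:
        raise ConfigurationError(
            "detection needs control dispersion or an analytical sd"
        )
    threshold = max(candidates)
    return DetectionResult(mean_ape > threshold, threshold, mean_ape)


@dataclass(frozen=True)
class NetTransferResult:
    """Signed net transfer (first direction minus second), µg."""

    estimate_ug: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_boot: int
    alpha: float
    ci_available: bool = True

    @property
    def excludes_zero(self) -> bool:
        if not self.ci_available:
            return False
        return not (self.ci_low <= 0.0 <= self.ci_high)


def _expanded_levels(alpha: float, n_a: int, n_b: int) -> Tuple[float, float]:
    # Small-sample expansion of the percentile interval: widen the nominal
    # quantile levels by the plug-in-variance bias factor sqrt(n/(n-1)) and
    # the t/z ratio at the smaller arm's df.  At n = 4 per arm the plain
    # percentile interval covers ~86%; expanded it holds ~95%.
    df = max(min(n_a, n_b) - 1, 1)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    c = np.sqrt(min(n_a, n_b) / df) * stats.t.ppf(1.0 - alpha / 2.0, df) / z
    lo = float(stats.norm.cdf(-z * c))
    return lo, 1.0 - lo


def _bootstrap_diff_ci(
    a: np.ndarray, b: np.ndarray, n_boot: int, rng: np.random.Generator, alpha: float
) -> Tuple[float, float]:
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    lo_lv, hi_lv = _expanded_levels(alpha, a.size, b.size)
    lo, hi = np.quantile(diffs, [lo_lv, hi_lv])
    return float(lo), float(hi)


def net_transfer(
    a_to_b: Sequence[float],
    b_to_a: Sequence[float],
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> NetTransferResult:
    """Net transfer between two directions with a bootstrap CI.

    Point estimate ``mean(a_to_b) - mean(b_to_a)``; the CI is a seeded
    percentile bootstrap over replicate microcosms with a small-sample
    expansion of the quantile levels.  Net transfer is declared present when
    the CI excludes zero.  Exactly antisymmetric in its arguments for the same
    seed (the resampling is tied to a canonical ordering of the two samples).
    """
    a = np.asarray(a_to_b, dtype=float)
    b = np.asarray(b_to_a, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InferenceError("each direction needs at least one replicate value")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is too small for stable percentile quantiles",
            UserWarning,
            stacklevel=2,
        )
    estimate = float(a.mean() - b.mean())
    if a.size < 2 or b.size < 2:
        return NetTransferResult(estimate, None, None, n_boot, alpha, ci_available=False)

    # canonical orientation makes f(a, b) == -f(b, a) exact under one seed
    flip = tuple(a.tolist()) > tuple(b.tolist())
    first, second = (b, a) if flip else (a, b)
    rng = np.random.default_rng(seed)
    lo, hi = _bootstrap_diff_ci(first, second, n_boot, rng, alpha)
    if flip:
        lo, hi = -hi, -lo
    return NetTransferResult(estimate, lo, hi, n_boot, alpha)


class TransferPattern(str, Enum):
    NONE = "none"
    UNIDIRECTIONAL = "unidirectional"
    BIDIRECTIONAL_NO_NET = "bidirectional_no_net"
    BIDIRECTIONAL_NET = "bidirectional_net"


class NetDirection(str, Enum):
    ORCHID_TO_PINE = "orchid_to_pine"
    PINE_TO_ORCHID = "pine_to_orchid"
    NONE = "none"


@dataclass(frozen=True)
class PairPattern:
    """Classified transfer pattern for one plant pair and element."""

    element: Element
    pattern: TransferPattern
    net_direction: NetDirection
    net: Optional[NetTransferResult] = None


def classify_pattern(
    detected_orchid_to_pine: bool,
    detected_pine_to_orchid: bool,
    net: Optional[NetTransferResult],
    element: Element,
) -> PairPattern:
    """Map detection verdicts and the net estimate onto the pattern taxonomy.

    ``net`` must be the orchid→pine minus pine→orchid contrast and is required
    only when both directions are detected.  Exhaustive and deterministic over
    the verdict space.
    """
    if not detected_orchid_to_pine and not detected_pine_to_orchid:
        return PairPattern(element, TransferPattern.NONE, NetDirection.NONE, net)
    if detected_orchid_to_pine != detected_pine_to_orchid:
        direction = (
            NetDirection.ORCHID_TO_PINE
            if detected_orchid_to_pine
            else NetDirection.PINE_TO_ORCHID
        )
        return PairPattern(element, TransferPattern.UNIDIRECTIONAL, direction, net)
    if net is None:
        raise ConfigurationError(
            "both directions detected: a net-transfer result is required"
        )
    if not net.excludes_zero:
        return PairPattern(
            element, TransferPattern.BIDIRECTIONAL_NO_NET, NetDirection.NONE, net
        )
    direction = (
        NetDirection.ORCHID_TO_PINE
        if net.estimate_ug > 0
        else NetDirection.PINE_TO_ORCHID
    )
    return PairPattern(element, TransferPattern.BIDIRECTIONAL_NET, direction, net)


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with Tukey HSD letters and distributional pre-checks."""

    factor: str
    f_statistic: float
    p_value: float
    shapiro_p: float
    levene_p: float
    letters: Dict[str, str]
    warnings: Tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _compact_letter_display(
    names: Sequence[str], significant: Mapping[Tuple[str, str], bool]
) -> Dict[str, str]:
    # insert-absorb: start from one letter covering everything, split on each
    # significant pair, drop letter-sets contained in another
    sets = [set(names)]
    for i, j in itertools.combinations(range(len(names)), 2):
        if not significant.get((names[i], names[j]), False):
            continue
        for s in [s for s in sets if names[i] in s and names[j] in s]:
            sets.remove(s)
            s1, s2 = s - {names[i]}, s - {names[j]}
            for cand in (s1, s2):
                if cand and not any(cand <= other for other in sets):
                    sets.append(cand)
            sets = [s for s in sets if not any(s < other for other in sets)]
    # stable letter order: by best (largest) group mean first is the caller's
    # concern; here, order sets by first member appearance
    sets.sort(key=lambda s: min(names.index(n) for n in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: Dict[str, str] = {n: "" for n in names}
    for letter, s in zip(alphabet, sets):
        for n in names:
            if n in s:
                out[n] += letter
    return out


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    factor: str = "group",
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA with Tukey HSD across named groups.

    Runs Shapiro-Wilk on the pooled group-mean residuals and Levene across
    groups first; failures are reported as warnings, not hard stops.  Tukey
    HSD pairwise rejections at ``alpha`` feed a compact letter display —
    groups sharing a letter are not significantly different.
    """
    if len(groups) < 2:
        raise InferenceError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise InferenceError(f"group {name!r} has n < 2")

    warn: list[str] = []
    residuals = np.concatenate([a - a.mean() for a in arrays.values()])
    if np.ptp(residuals) == 0:
        shapiro_p = 1.0  # constant residuals: normality test undefined
    else:
        shapiro_p = float(stats.shapiro(residuals).pvalue)
    if shapiro_p < alpha:
        warn.append(f"Shapiro-Wilk rejects normality of residuals (p={shapiro_p:.3g})")
    try:
        levene_p = float(stats.levene(*arrays.values()).pvalue)
    except ValueError:
        levene_p = 1.0
    if levene_p < alpha:
        warn.append(f"Levene rejects homogeneity of variance (p={levene_p:.3g})")

    f_res = stats.f_oneway(*arrays.values())
    f_stat, p_value = float(f_res.statistic), float(f_res.pvalue)
    if not np.isfinite(f_stat):  # all values identical across groups
        f_stat, p_value = 0.0, 1.0

    names = list(arrays)
    significant: Dict[Tuple[str, str], bool] = {}
    if p_value < alpha:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate([[n] * arrays[n].size for n in names])
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        res = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        for _, row in res.iterrows():
            key = (str(row["group1"]), str(row["group2"]))
            rej = bool(row["reject"])
            significant[key] = rej
            significant[(key[1], key[0])] = rej
    letters = _compact_letter_display(names, significant)
    return GroupComparison(
        factor, f_stat, p_value, shapiro_p, levene_p, letters, tuple(warn)
    )


# ---------------------------------------------------------------------------
# whole-dataset orchestration


@dataclass(frozen=True)
class TransferEstimate:
    """Directional transfer for one plant pair and element, over replicates."""

    element: Element
    donor_role: str
    recipient_role: str
    amount_ug: float
    amount_se: float
    percent_transferred: float
    percent_se: float
    n: int
    detected: bool


@dataclass
class TransferReport:
    """Full quantification result for one measurements table."""

    pools: pd.DataFrame
    detections: pd.DataFrame
    transfers: pd.DataFrame
    patterns: pd.DataFrame
    manifest: dict = field(default_factory=dict)


_ROLE_OTHER = {"orchid": "pine", "pine": "orchid"}

_DIRECTION_OF_DONOR = {
    "orchid": NetDirection.ORCHID_TO_PINE.value,
    "pine": NetDirection.PINE_TO_ORCHID.value,
}


def _se(values: np.ndarray) -> float:
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def quantify(
    df: pd.DataFrame,
    analytical_sd_permil: float = 0.15,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TransferReport:
    """Run the full tracer pipeline on a canonical measurements frame.

    Stages: pooled control baselines → per-tissue enrichment → per-plant pools
    → per-microcosm recipient detection → per-direction transfer summaries
    (mean ± SE over replicate microcosms, group detection by strict majority
    of replicates) → net transfer per pair and element (seeded bootstrap) →
    pattern classification.

    A recipient pool below detection is censored to 0 µg (flag
    ``below_detection``) before percent and net computations; its raw mass is
    kept in the pools table.
    """
    baselines = massbalance.control_baselines(df)
    enr = massbalance.enrichment_table(df, baselines)
    pools = massbalance.build_pools(df, baselines)

    warn: list[str] = []

    # per-microcosm recipient detection
    det_rows = []
    recip = enr[~enr["is_donor"]]
    for (mid, role, element), grp in recip.groupby(
        ["microcosm_id", "plant_role", "element"], sort=True
    ):
        el = Element(element)
        res = detect_transfer(
            grp["ape"].to_numpy(),
            grp["biomass_g"].to_numpy(),
            grp["control_af_sd"].to_numpy(),
            analytical_sd_permil,
            el,
            float(np.average(grp["control_af_mean"], weights=grp["biomass_g"])),
        )
        det_rows.append(
            {
                "microcosm_id": mid,
                "plant_role": role,
                "species": grp["species"].iloc[0],
                "element": element,
                "detected": res.detected,
                "threshold": res.threshold,
                "weighted_mean_ape": res.weighted_mean_ape,
            }
        )
    detections = pd.DataFrame(det_rows)

    pools = pools.merge(
        detections[["microcosm_id", "plant_role", "element", "detected"]],
        on=["microcosm_id", "plant_role", "element"],
        how="left",
    )
    received = pools["pool_kind"] == PoolKind.RECEIVED.value
    censored = received & pools["detected"].eq(False)
    pools["censored_mass_ug"] = np.where(censored, 0.0, pools["mass_ug"])
    pools.loc[censored, "flag"] = EnrichmentFlag.BELOW_DETECTION.value
    if (pools["flag"] == EnrichmentFlag.BELOW_ZERO.value).any():
        warn.append("negative APE retained in one or more pools (flag below_zero)")
    if censored.any():
        warn.append(
            f"{int(censored.sum())} recipient pool(s) below detection censored to 0 µg"
        )

    # pair key: one orchid taxon vs pine; a dataset may hold several pairs
    orchid_species = (
        df.loc[df["plant_role"] == "orchid", ["microcosm_id", "species"]]
        .drop_duplicates()
        .rename(columns={"species": "pair"})
    )
    pools = pools.merge(orchid_species, on="microcosm_id", how="left")
    detections = detections.merge(orchid_species, on="microcosm_id", how="left")

    donors = pools[pools["pool_kind"] == PoolKind.ASSIMILATED.value]
    recips = pools[pools["pool_kind"] == PoolKind.RECEIVED.value]

    transfer_rows = []
    pattern_rows = []
    for (pair, element), dgrp in donors.groupby(["pair", "element"], sort=True):
        el = Element(element)
        per_direction: Dict[str, dict] = {}
        for donor_role, sub in dgrp.groupby("plant_role", sort=True):
            recipient_role = _ROLE_OTHER[donor_role]
            mids = sub["microcosm_id"].tolist()
            r = recips[
                (recips["pair"] == pair)
                & (recips["element"] == element)
                & (recips["microcosm_id"].isin(mids))
            ].set_index("microcosm_id")
            d = sub.set_index("microcosm_id")
            amounts = r.loc[mids, "censored_mass_ug"].to_numpy(dtype=float)
            assim = d.loc[mids, "mass_ug"].to_numpy(dtype=float)
            percents = np.array(
                [percent_transferred(t, a) for t, a in zip(amounts, assim)]
            )
            det = detections[
                (detections["pair"] == pair)
                & (detections["element"] == element)
                & (detections["microcosm_id"].isin(mids))
            ]["detected"].to_numpy(dtype=bool)
            # a direction counts as detected when at least half of its
            # replicate microcosms individually clear the threshold; with a
            # <=5% per-microcosm false-fire rate, two independent confirmations
            # keep the group-level false rate well under 1%
            group_detected = bool(det.sum() * 2 >= det.size)
            direction = _DIRECTION_OF_DONOR[donor_role]
            per_direction[direction] = {
                "amounts": amounts,
                "detected": group_detected,
            }
            transfer_rows.append(
                {
                    "pair": pair,
                    "element": element,
                    "direction": direction,
                    "donor_role": donor_role,
                    "recipient_role": recipient_role,
                    "n": len(mids),
                    "amount_ug": float(amounts.mean()),
                    "amount_se": _se(amounts),
                    "percent_transferred": float(percents.mean()),
                    "percent_se": _se(percents),
                    "detected": group_detected,
                    "n_detected_microcosms": int(det.sum()),
                }
            )

        fwd = per_direction.get(NetDirection.ORCHID_TO_PINE.value)
        bwd = per_direction.get(NetDirection.PINE_TO_ORCHID.value)
        if fwd is None or bwd is None:
            warn.append(
                f"pair {pair!r} element {element}: only one labelling orientation "
                "present, net transfer not estimable"
            )
            continue
        net = net_transfer(
            fwd["amounts"], bwd["amounts"], n_boot=n_boot, seed=seed, alpha=alpha
        )
        pat = classify_pattern(fwd["detected"], bwd["detected"], net, el)
        pattern_rows.append(
            {
                "pair": pair,
                "element": element,
                "pattern": pat.pattern.value,
                "net_direction": pat.net_direction.value,
                "net_ug": net.estimate_ug,
                "net_ci_low": net.ci_low,
                "net_ci_high": net.ci_high,
                "net_excludes_zero": net.excludes_zero,
            }
        )

    transfers = pd.DataFrame(transfer_rows)
    patterns = pd.DataFrame(pattern_rows)
    manifest = {
        "analytical_sd_permil": analytical_sd_permil,
        "n_boot": n_boot,
        "seed": seed,
        "alpha": alpha,
        "n_labelled_microcosms": int(df.loc[df["treatment"] == "labelled", "microcosm_id"].nunique()),
        "n_control_microcosms": int(df.loc[df["treatment"] == "control", "microcosm_id"].nunique()),
        "warnings": warn,
    }
    return TransferReport(pools, detections, transfers, patterns, manifest)
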