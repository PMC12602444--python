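"""Transfer-pattern taxonomy and between-scenario comparison.

Collects the per-scenario pattern calls into one table and compares the
percent of nitrogen transferred orchid→pine across the three orchid taxa
with the one-way ANOVA / Tukey HSD contract (compact letter display).
"""

from pathlib import Path

import pandas as pd

import mycoflux as mf
from mycoflux.inference import percent_transferred
from mycoflux.massbalance import PoolKind

SEED = 42
ROOT = Path(__file__).resolve().parent.parent / "results"


def per_microcosm_percents(pools: pd.DataFrame, element: str, donor_role: str):
    donors = pools[
        (pools["pool_kind"] == PoolKind.ASSIMILATED.value)
        & (pools["element"] == element)
        & (pools["plant_role"] == donor_role)
    ]
    recips = pools[pools["pool_kind"] == PoolKind.RECEIVED.value].set_index(
        ["microcosm_id", "element"]
    )
    return [
        percent_transferred(
            recips.loc[(d["microcosm_id"], element)]["censored_mass_ug"], d["mass_ug"]
        )
        for _, d in donors.iterrows()
    ]


def main() -> None:
    rows = []
    groups = {}
    for scenario_dir in sorted((ROOT / "fixtures").iterdir()):
        name = scenario_dir.name
        patterns = pd.read_csv(ROOT / name / "patterns.csv")
        patterns.insert(0, "scenario", name)
        rows.append(patterns)
        pools = pd.read_csv(ROOT / name / "pools.csv")
        groups[name] = per_microcosm_percents(pools, "15N", "orchid")

    summary = pd.concat(rows, ignore_index=True)
    summary.to_csv(ROOT / "patterns_summary.csv", index=False)
    print(summary[["scenario", "element", "pattern", "net_direction"]].to_string(index=False))

    cmp = mf.compare_groups(groups, factor="orchid taxon")
    lines = [
        f"percent 15N transferred orchid->pine, one-way ANOVA across orchid taxa",
        f"F = {cmp.f_statistic:.2f}, p = {cmp.p_value:.3g} "
        f"(Shapiro p = {cmp.shapiro_p:.3g}, Levene p = {cmp.levene_p:.3g})",
        "Tukey HSD letters (shared letter = not significantly different):",
    ]
    for name, letter in cmp.letters.items():
        mean = sum(groups[name]) / len(groups[name])
        lines.append(f"  {name}: {mean:.2f} %  [{letter}]")
    lines += [f"  warning: {w}" for w in cmp.warnings]
    text = "\n".join(lines)
    (ROOT / "group_comparison.txt").write_text(text + "\n")
    print()
    print(text)


if __name__ == "__main__":
    main()
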