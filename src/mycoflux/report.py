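"""Deterministic text reporting of transfer results.

Renders the per-pair, per-element transfer summary as a Markdown-ish text
block with ASCII arrow diagrams (orchid =C=> pine style), mirroring the way
transfer-pattern figures are usually drawn: one panel per element with both
directional flows and a net marker.
"""

from __future__ import annotations

import json
from typing import Optional

import pandas as pd

_ARROWS = {
    "orchid_to_pine": "orchid ==({elem})==> pine",
    "pine_to_orchid": "orchid <==({elem})== pine",
}


class EmptyReportError(ValueError):
    pass


def _fmt(x: Optional[float], digits: int = 3) -> str:
    if x is None or pd.isna(x):
        return "n/a"
    return f"{x:.{digits}g}"


def render_report(
    transfers: pd.DataFrame,
    patterns: pd.DataFrame,
    manifest: Optional[dict] = None,
) -> str:
    """Render the transfer table and pattern calls as deterministic text."""
    if len(transfers) == 0:
        raise EmptyReportError("no transfer rows to report")
    lines = ["# Interplant tracer transfer report", ""]
    for pair in sorted(transfers["pair"].unique()):
        lines.append(f"## Pair: {pair} / pine")
        sub = transfers[transfers["pair"] == pair]
        for element in sorted(sub["element"].unique()):
            esub = sub[sub["element"] == element].set_index("direction")
            lines.append(f"### Element {element}")
            pat_rows = patterns[
                (patterns["pair"] == pair) & (patterns["element"] == element)
            ]
            pattern = pat_rows["pattern"].iloc[0] if len(pat_rows) else "n/a"
            net_dir = pat_rows["net_direction"].iloc[0] if len(pat_rows) else "n/a"
            for direction in ("orchid_to_pine", "pine_to_orchid"):
                if direction not in esub.index:
                    continue
                row = esub.loc[direction]
                arrow = _ARROWS[direction].format(elem=element)
                if not row["detected"]:
                    lines.append(f"    {arrow}   below detection")
                    continue
                lines.append(
                    f"    {arrow}   {_fmt(row['amount_ug'])} ± "
                    f"{_fmt(row['amount_se'])} µg "
                    f"({_fmt(row['percent_transferred'])} ± "
                    f"{_fmt(row['percent_se'])} % of the donor's tracer, "
                    f"n={int(row['n'])})"
                )
            if pattern == "none":
                lines.append("    no detectable transfer in either direction")
            else:
                net_line = f"    pattern: {pattern}"
                if net_dir != "none":
                    net = pat_rows.iloc[0]
                    net_line += (
                        f"; NET {net_dir.replace('_', ' ')} "
                        f"({_fmt(abs(net['net_ug']))} µg, 95% CI "
                        f"[{_fmt(net['net_ci_low'])}, {_fmt(net['net_ci_high'])}])"
                    )
                lines.append(net_line)
            lines.append("")
    if manifest:
        lines.append("## Run manifest")
        lines.append("```json")
        lines.append(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    return "\n".join(lines)
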