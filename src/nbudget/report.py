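"""Budget-table reporting and QA/QC screening.

The report mirrors the national summary-table layout: items grouped by
receiving land-use class in a fixed order, magnitudes in Tg N/yr rounded to
one decimal (half-up), per-class subtotals, the grand total, and each
class's share of it.

QA/QC follows the screening idea of checking every record and excluding
extreme values: records of an item falling strictly outside a percentile
band (default [p0.5, p99.5]) are flagged, and can optionally be excluded
with the remaining records of that item rescaled so the item total is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .budget import NATIONAL, FluxTable
from .errors import ValidationError
from .vocab import BUDGET_ITEMS, KG_PER_TG, LANDUSE_ORDER


def round_tg(kg: float, decimals: int = 1) -> float:
    """kg N/yr -> Tg N/yr with half-up rounding at the report precision."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(kg / KG_PER_TG)).quantize(q, rounding=ROUND_HALF_UP))


def budget_report(table: FluxTable) -> tuple[pd.DataFrame, str]:
    """Format a national flux table as the summary budget report.

    Returns (frame, text).  The frame has one row per (landuse, item) in the
    canonical order plus subtotal / total rows, with exact kg values and the
    rounded Tg column; the text is a printable rendition.
    """
    national = table.national()
    rows = []
    grand_total = 0.0
    subtotals: dict[str, float] = {}
    for landuse in LANDUSE_ORDER:
        subtotal = 0.0
        for item in BUDGET_ITEMS[landuse]:
            try:
                kg = national.get(landuse, item)
            except KeyError:
                kg = 0.0
            subtotal += kg
            rows.append({"landuse": landuse, "item": item, "kgN_per_yr": kg,
                         "Tg": round_tg(kg)})
        rows.append({"landuse": landuse, "item": "(subtotal)",
                     "kgN_per_yr": subtotal, "Tg": round_tg(subtotal)})
        subtotals[landuse] = subtotal
        grand_total += subtotal
    for landuse in LANDUSE_ORDER:
        share = 100.0 * subtotals[landuse] / grand_total if grand_total > 0 else 0.0
        rows.append({"landuse": landuse, "item": "(share %)",
                     "kgN_per_yr": share, "Tg": round(share, 1)})
    rows.append({"landuse": "all", "item": "(grand total)",
                 "kgN_per_yr": grand_total, "Tg": round_tg(grand_total)})
    frame = pd.DataFrame(rows, columns=["landuse", "item", "kgN_per_yr", "Tg"])

    lines = [f"{'Land-use type':<12} {'Item':<36} {'N input (Tg)':>12}"]
    for landuse in LANDUSE_ORDER:
        for item in BUDGET_ITEMS[landuse]:
            row = frame[(frame.landuse == landuse) & (frame.item == item)].iloc[0]
            lines.append(f"{landuse:<12} {item:<36} {row.Tg:>12.1f}")
        sub = frame[(frame.landuse == landuse) & (frame.item == "(subtotal)")].iloc[0]
        lines.append(f"{landuse:<12} {'subtotal':<36} {sub.Tg:>12.1f}")
    total = frame[frame.item == "(grand total)"].iloc[0]
    lines.append(f"{'all':<12} {'grand total':<36} {total.Tg:>12.1f}")
    return frame, "\n".join(lines)


# ---------------------------------------------------------------------------
# QA/QC
# ---------------------------------------------------------------------------


@dataclass
class QaqcResult:
    table: pd.DataFrame       # input rows + 'flagged' column
    report: pd.DataFrame      # one row per flag: region_id, item, value, bounds
    cleaned: FluxTable | None  # exclusion output (None when exclude=False)


def qaqc_screen(
    table: FluxTable,
    p_low: float = 0.5,
    p_high: float = 99.5,
    exclude: bool = False,
) -> QaqcResult:
    """Flag per-item extreme records by a percentile band.

    A regional record is flagged when its magnitude lies strictly outside
    [P(p_low), P(p_high)] of all regional records of the same (landuse,
    item).  With ``exclude=True`` flagged records are removed and the
    remaining records of the item rescaled so the national item total is
    preserved; if every record of an item is flagged that is a hard error.
    """
    df = table.frame
    regional = df[df.region_id != NATIONAL].copy()
    if regional.empty:
        regional = df.copy()
    regional["flagged"] = False
    flags = []
    for (landuse, item), grp in regional.groupby(["landuse", "item"]):
        lo, hi = np.percentile(grp.kgN_per_yr.to_numpy(), [p_low, p_high])
        bad = (grp.kgN_per_yr < lo) | (grp.kgN_per_yr > hi)
        if bad.all() and len(grp) > 0:
            raise ValidationError(
                f"QA/QC excluded every record of ({landuse}, {item})")
        regional.loc[grp.index[bad], "flagged"] = True
        for idx in grp.index[bad]:
            flags.append({
                "region_id": regional.loc[idx, "region_id"],
                "landuse": landuse, "item": item,
                "kgN_per_yr": regional.loc[idx, "kgN_per_yr"],
                "p_low": lo, "p_high": hi,
            })
    report = pd.DataFrame(
        flags, columns=["region_id", "landuse", "item", "kgN_per_yr",
                        "p_low", "p_high"])

    cleaned: FluxTable | None = None
    if exclude:
        kept = regional[~regional.flagged].copy()
        for (landuse, item), grp in regional.groupby(["landuse", "item"]):
            total = grp.kgN_per_yr.sum()
            kept_mask = (kept.landuse == landuse) & (kept.item == item)
            kept_total = kept.loc[kept_mask, "kgN_per_yr"].sum()
            if kept_total > 0:
                kept.loc[kept_mask, "kgN_per_yr"] *= total / kept_total
        cleaned = FluxTable.from_frame(kept.drop(columns=["flagged"]))
    return QaqcResult(table=regional, report=report, cleaned=cleaned)
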