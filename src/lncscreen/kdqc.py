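"""Knockdown quality control.

Each ASO's knockdown efficiency is measured by RT-qPCR with several primer
pairs (typically three). An ASO counts as a successful knockdown when more
than 40% knockdown is seen in at least two primer pairs, or more than 60%
in a single primer pair — strict inequalities in both cases. Targets enter
downstream per-lncRNA analyses only when enough of their ASOs succeeded.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "KnockdownRecord",
    "classify_knockdown",
    "successful_targets",
    "records_from_table",
]

#: Efficiency that at least two primer pairs must exceed (strictly).
TWO_PRIMER_THRESHOLD = 0.40
#: Efficiency that a single primer pair must exceed (strictly).
ONE_PRIMER_THRESHOLD = 0.60


@dataclass(frozen=True)
class KnockdownRecord:
    """Per-ASO knockdown efficiencies, one value per primer pair."""

    aso_id: str
    target_id: str
    efficiencies: tuple = field(default=())

    def __post_init__(self):
        if len(self.efficiencies) == 0:
            raise ValueError(f"{self.aso_id}: no knockdown efficiencies given")
        for e in self.efficiencies:
            if not (0.0 <= e <= 1.0):
                raise ValueError(
                    f"{self.aso_id}: efficiency {e} outside [0, 1] "
                    "(expected a knocked-down fraction)"
                )


def classify_knockdown(record: KnockdownRecord) -> bool:
    """True iff the ASO passes the knockdown-success rule.

    Success requires >40% efficiency in at least two primer pairs, or >60%
    in at least one. Both thresholds are strict, so exactly 0.40 / 0.60 do
    not count; the decision is invariant to primer-pair order and monotone
    in every efficiency.
    """
    effs = record.efficiencies
    n_over_40 = sum(1 for e in effs if e > TWO_PRIMER_THRESHOLD)
    return n_over_40 >= 2 or max(effs) > ONE_PRIMER_THRESHOLD


def successful_targets(records: Iterable[KnockdownRecord],
                       min_asos: int = 2) -> set[str]:
    """Target ids with at least ``min_asos`` successfully-knocked-down ASOs.

    An empty record list yields an empty set.
    """
    counts: dict[str, int] = defaultdict(int)
    for rec in records:
        if classify_knockdown(rec):
            counts[rec.target_id] += 1
    return {t for t, k in counts.items() if k >= min_asos}


def records_from_table(table: pd.DataFrame) -> list[KnockdownRecord]:
    """Build records from a long table (aso_id, target_id, primer_id, efficiency).

    Efficiencies are averaged per (aso, primer) if the table contains
    transfection duplicates, then the success rule is applied per primer mean.
    """
    required = {"aso_id", "target_id", "efficiency"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"knockdown table missing columns: {sorted(missing)}")
    records = []
    group_cols = ["aso_id", "target_id"]
    primer_col = "primer_id" if "primer_id" in table.columns else None
    for (aso, target), sub in table.groupby(group_cols, sort=True):
        if primer_col is not None:
            effs = sub.groupby(primer_col)["efficiency"].mean()
        else:
            effs = sub["efficiency"]
        records.append(
            KnockdownRecord(aso_id=aso, target_id=target,
                            efficiencies=tuple(effs.tolist()))
        )
    return records


def qc_table(records: Sequence[KnockdownRecord]) -> pd.DataFrame:
    """Summary table: one row per ASO with success call and best efficiency."""
    rows = [
        {
            "aso_id": r.aso_id,
            "target_id": r.target_id,
            "n_primers": len(r.efficiencies),
            "max_efficiency": max(r.efficiencies),
            "mean_efficiency": sum(r.efficiencies) / len(r.efficiencies),
            "success": classify_knockdown(r),
        }
        for r in records
    ]
    return pd.DataFrame(rows)
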