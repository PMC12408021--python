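"""MAG quality tiers from completeness/contamination estimates.

High quality: completeness >= 85 and contamination < 5.
Medium quality: 50 <= completeness < 85 and contamination < 5.
Everything else is low quality. Boundaries follow these inequalities
literally (>= 85 inclusive, < 5 strict).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

TIERS = ("high", "medium", "low")


@dataclass
class MagRecord:
    mag_id: str
    sample_id: str
    species: str
    completeness: float
    contamination: float
    tier: str = ""

    def __post_init__(self):
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"completeness out of range: {self.completeness}")
        if self.contamination < 0:
            raise ValueError(f"negative contamination: {self.contamination}")
        expected = assign_tier(self.completeness, self.contamination)
        if not self.tier:
            self.tier = expected
        elif self.tier != expected:
            raise ValueError(f"tier {self.tier!r} inconsistent with thresholds "
                             f"({self.completeness}, {self.contamination})")


def assign_tier(completeness: float, contamination: float) -> str:
    if not 0 <= completeness <= 100:
        raise ValueError(f"completeness out of range: {completeness}")
    if contamination < 0:
        raise ValueError(f"negative contamination: {contamination}")
    if completeness >= 85 and contamination < 5:
        return "high"
    if 50 <= completeness < 85 and contamination < 5:
        return "medium"
    return "low"


def tier_summary(records, total_samples: int | None = None) -> pd.DataFrame:
    """Counts and percentages per tier (one decimal), plus the fraction of
    samples yielding at least one MAG when ``total_samples`` is given."""
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    tiers = pd.Series([r.tier for r in records])
    counts = tiers.value_counts().reindex(TIERS, fill_value=0)
    total = len(records)
    out = pd.DataFrame({"count": counts,
                        "percent": (counts / total * 100).round(1)})
    out.index.name = "tier"
    if total_samples is not None:
        n_with = len({r.sample_id for r in records})
        out.attrs["samples_with_mag"] = n_with
        out.attrs["total_samples"] = total_samples
        out.attrs["samples_with_mag_percent"] = round(n_with / total_samples * 100, 1)
    return out


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def frame_to_records(df: pd.DataFrame) -> list[MagRecord]:
    return [MagRecord(row["mag_id"], row["sample_id"], row["species"],
                      float(row["completeness"]), float(row["contamination"]),
                      str(row.get("tier", "") or ""))
            for _, row in df.iterrows()]
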