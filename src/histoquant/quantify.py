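"""Per-channel counts, marker ratios, replicate aggregation, and the
manual-vs-automatic validation metric.

Count tables are tidy pandas DataFrames with one row per (section, channel).
Technical replicates (multiple sections from one animal) are summarized per
animal by the arithmetic mean before any group statistics; marker ratios
(Iba1/DAPI, ED1/DAPI, Iba1/ED1) are computed per animal after aggregation.
Validation compares automated counts against blinded manual counts as
absolute percent error relative to the manual count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COUNT_COLUMNS",
    "RATIOS",
    "ValidationReport",
    "aggregate_replicates",
    "compute_ratios",
    "validate_counts",
]

COUNT_COLUMNS = ["animal_id", "group", "section_id", "replicate", "channel", "count"]

#: The three reported marker ratios as (name, numerator, denominator).
RATIOS = (
    ("Iba1/DAPI", "Iba1", "DAPI"),
    ("ED1/DAPI", "ED1", "DAPI"),
    ("Iba1/ED1", "Iba1", "ED1"),
)


def _check_counts(table: pd.DataFrame, need: tuple) -> None:
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise ValueError(f"count table is missing columns: {missing}")
    if len(table) and (table["count"] < 0).any():
        raise ValueError("counts must be non-negative")


def aggregate_replicates(table: pd.DataFrame, channels: tuple | None = None) -> pd.DataFrame:
    """Mean over technical replicates: one row per (animal, channel).

    The per-animal value is the arithmetic mean of that animal's replicate
    counts, kept real-valued (no rounding).  If ``channels`` is given,
    animals with no rows for a requested channel are flagged in a ``missing``
    boolean column (with NaN count) rather than silently scored zero.
    """
    _check_counts(table, ("animal_id", "channel", "count"))
    if table.empty:
        raise ValueError("empty count table: nothing to aggregate")
    group_cols = ["animal_id", "channel"]
    if "group" in table.columns:
        group_cols.insert(1, "group")
    agg = (
        table.groupby(group_cols, sort=True)["count"]
        .mean()
        .reset_index()
    )
    agg["missing"] = False
    if channels:
        frames = [agg]
        for animal, sub in agg.groupby("animal_id"):
            have = set(sub["channel"])
            for ch in channels:
                if ch not in have:
                    row = {"animal_id": animal, "channel": ch, "count": np.nan, "missing": True}
                    if "group" in agg.columns:
                        row["group"] = sub["group"].iloc[0]
                    frames.append(pd.DataFrame([row]))
        agg = pd.concat(frames, ignore_index=True).sort_values(
            ["animal_id", "channel"], ignore_index=True
        )
    return agg


def compute_ratios(per_animal: pd.DataFrame) -> pd.DataFrame:
    """The three named marker ratios per animal.

    A zero (or absent) denominator flags the ratio as undefined — it is kept
    in the table with ``defined=False`` and NaN value, never silently dropped.
    """
    _check_counts(per_animal, ("animal_id", "channel", "count"))
    wide = per_animal.pivot_table(
        index="animal_id", columns="channel", values="count", aggfunc="first"
    )
    groups = (
        per_animal.drop_duplicates("animal_id").set_index("animal_id")["group"]
        if "group" in per_animal.columns
        else None
    )
    rows = []
    for animal, counts in wide.iterrows():
        for name, num, den in RATIOS:
            num_v = counts.get(num, np.nan)
            den_v = counts.get(den, np.nan)
            defined = np.isfinite(num_v) and np.isfinite(den_v) and den_v > 0
            row = {
                "animal_id": animal,
                "ratio": name,
                "value": float(num_v) / float(den_v) if defined else np.nan,
                "defined": bool(defined),
            }
            if groups is not None:
                row["group"] = groups.get(animal)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Per-staining absolute percent errors of automated vs manual counts."""

    per_image_errors: dict = field(default_factory=dict)  # channel -> {image_id: pct}
    mean_abs_error_pct: dict = field(default_factory=dict)
    sd_abs_error_pct: dict = field(default_factory=dict)

    def n_images(self, channel: str) -> int:
        return len(self.per_image_errors.get(channel, {}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "channel": ch,
                "n_images": self.n_images(ch),
                "mean_abs_error_pct": self.mean_abs_error_pct[ch],
                "sd_abs_error_pct": self.sd_abs_error_pct[ch],
            }
            for ch in sorted(self.per_image_errors)
        ]
        return pd.DataFrame(rows)


def validate_counts(auto: pd.DataFrame, manual: pd.DataFrame) -> ValidationReport:
    """Absolute percent error of automated counts against manual truth.

    Per matched (image, channel) pair the error is
    ``|auto - manual| / manual * 100``; per staining the mean and the
    sample SD (n-1 denominator) over its images are reported.  Unmatched
    images on either side raise with the orphan list; pairs with manual
    count 0 are excluded with a warning (percent error undefined).
    """
    for name, df in (("auto", auto), ("manual", manual)):
        for col in ("image_id", "channel", "count"):
            if col not in df.columns:
                raise ValueError(f"{name} table needs column {col!r}")
    a = auto.set_index(["image_id", "channel"])["count"]
    m = manual.set_index(["image_id", "channel"])["count"]
    orphans = sorted(set(a.index.tolist()) ^ set(m.index.tolist()))
    if orphans:
        raise ValueError(f"unmatched (image, channel) pairs: {orphans}")

    report = ValidationReport()
    for (image_id, channel), manual_count in m.items():
        auto_count = a.loc[(image_id, channel)]
        if manual_count == 0:
            warnings.warn(
                f"manual count 0 for {image_id}/{channel}: percent error undefined, excluded",
                stacklevel=2,
            )
            continue
        err = abs(float(auto_count) - float(manual_count)) / float(manual_count) * 100.0
        report.per_image_errors.setdefault(channel, {})[image_id] = err
    for channel, errs in report.per_image_errors.items():
        vals = np.asarray(list(errs.values()), dtype=float)
        report.mean_abs_error_pct[channel] = float(vals.mean())
        report.sd_abs_error_pct[channel] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return report
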