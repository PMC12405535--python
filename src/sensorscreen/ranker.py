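"""Ranking of condition-responsive sensors from sensor-level FOR tables.

Sensors are first required to be OFF in the gavage (input inoculum) sample
(FOR < 0.25). ``in_vivo`` mode scores each sensor by mean faecal FOR minus
gavage FOR; ``condition`` mode scores by mean FOR in the treatment group
minus mean FOR in the control group. Scores sort descending, ties broken by
sensor id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RankedSensor", "rank_sensors"]

GAVAGE = "gavage"


@dataclass(frozen=True)
class RankedSensor:
    sensor_id: str
    gavage_for: float
    group_means: dict[str, float]
    score: float
    rank: int
    n_samples: int


def rank_sensors(
    for_table: pd.DataFrame,
    design: Mapping[str, str],
    mode: str = "in_vivo",
    treatment: str | None = None,
    control: str | None = None,
    max_gavage_for: float = 0.25,
    gavage_label: str = GAVAGE,
) -> list[RankedSensor]:
    """Rank sensors for responsiveness.

    Parameters
    ----------
    for_table:
        Long-format sensor-level FOR table with columns ``sensor_id``,
        ``sample_id``, ``fractional_odds_ratio`` and optionally ``qc_pass``
        and ``sample_qc_pass`` (rows failing either are dropped).
    design:
        sample_id -> condition label; exactly one gavage sample expected
        (label equal to ``gavage_label``).
    mode:
        ``in_vivo`` (mean over all non-gavage samples minus gavage) or
        ``condition`` (mean(treatment) - mean(control); both labels required).
    """
    if mode not in ("in_vivo", "condition"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    if mode == "condition" and (treatment is None or control is None):
        raise ValueError("condition mode requires treatment and control labels")

    df = for_table.copy()
    required = {"sensor_id", "sample_id", "fractional_odds_ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"for_table must have columns {sorted(required)}")
    for flag in ("qc_pass", "sample_qc_pass"):
        if flag in df.columns:
            df = df[df[flag].astype(bool)]
    df = df.dropna(subset=["fractional_odds_ratio"])
    df["condition"] = df["sample_id"].map(dict(design))
    if df["condition"].isna().any():
        missing = sorted(df.loc[df["condition"].isna(), "sample_id"].unique())
        raise ValueError(f"samples missing from design: {missing}")

    gavage = df[df["condition"] == gavage_label]
    if gavage.empty:
        raise ValueError("no gavage sample present (or it failed QC)")
    gavage_for = gavage.groupby("sensor_id")["fractional_odds_ratio"].mean()

    rest = df[df["condition"] != gavage_label]
    group_means = (
        rest.groupby(["sensor_id", "condition"])["fractional_odds_ratio"]
        .mean()
        .unstack()
    )
    n_samples = rest.groupby("sensor_id")["sample_id"].nunique()

    excluded: list[str] = []
    scored: list[tuple[str, float, float, dict[str, float], int]] = []
    for sensor_id in sorted(set(df["sensor_id"])):
        if sensor_id not in gavage_for.index:
            excluded.append(sensor_id)
            continue
        g = float(gavage_for[sensor_id])
        if not g < max_gavage_for:
            continue
        means = (
            {
                str(c): float(v)
                for c, v in group_means.loc[sensor_id].dropna().items()
            }
            if sensor_id in group_means.index
            else {}
        )
        if mode == "in_vivo":
            sensor_rows = rest[rest["sensor_id"] == sensor_id]
            if sensor_rows.empty:
                excluded.append(sensor_id)
                continue
            score = float(sensor_rows["fractional_odds_ratio"].mean()) - g
        else:
            if treatment not in means or control not in means:
                excluded.append(sensor_id)
                continue
            score = means[treatment] - means[control]
        scored.append(
            (sensor_id, g, score, means, int(n_samples.get(sensor_id, 0)))
        )
    if excluded:
        logger.info("sensors excluded for missing data: %s", ", ".join(excluded))

    scored.sort(key=lambda item: (-item[2], item[0]))
    return [
        RankedSensor(
            sensor_id=sensor_id,
            gavage_for=g,
            group_means=means,
            score=score,
            rank=i + 1,
            n_samples=n,
        )
        for i, (sensor_id, g, score, means, n) in enumerate(scored)
    ]
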