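"""CSV dialects and readers/writers for tracks, phenotypes and timelines.

All formats are plain CSV so exports from common spot-tracking tools can
be adapted with a header rename:

* tracks: ``track_id,group,t_min,x_um,y_um`` — one row per cell per time
  point; unknown extra columns are preserved as opaque per-point metadata
  and written back on round trip.
* phenotypes: ``embryo_id,genotype,side,p1..p5,cb1..cb5,fusions`` — one
  row per embryo side; ``fusions`` holds ``;``-separated adjacent pairs
  like ``1-2;4-5`` (empty when none).
* timelines: ``pouch_index,formation_time_hpf``.

Readers validate records and either collect malformed rows (with their
1-based file line numbers) into an error report, or abort on the first
problem in strict mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputValidationError
from .scoring import POUCH_KEYS, PhenotypeRecord
from .simulate import TimelineEvent
from .tracks import Track

logger = logging.getLogger(__name__)

__all__ = [
    "TRACK_COLUMNS",
    "PHENOTYPE_COLUMNS",
    "ReadReport",
    "write_tracks",
    "read_tracks",
    "write_phenotypes",
    "read_phenotypes",
    "write_timeline",
    "read_timeline",
    "write_metrics",
    "read_metrics",
]

TRACK_COLUMNS = ("track_id", "group", "t_min", "x_um", "y_um")
CB_KEYS = ("cb1", "cb2", "cb3", "cb4", "cb5")
PHENOTYPE_COLUMNS = ("embryo_id", "genotype", "side") + POUCH_KEYS + CB_KEYS + ("fusions",)
METRIC_COLUMNS = (
    "track_id",
    "group",
    "velocity_um_per_min",
    "persistence",
    "n_valid_steps",
    "n_skipped_triples",
    "deviation_angles_deg",
)


@dataclass
class ReadReport:
    """Per-file account of rejected records."""

    path: str
    n_read: int = 0
    n_rejected: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)
    # (1-based file line number of the offending row, message)

    def add(self, line: int, message: str) -> None:
        self.n_rejected += 1
        self.errors.append((line, message))


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# tracks


def write_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        df = pd.DataFrame(
            {
                "track_id": tr.track_id,
                "group": tr.group,
                "t_min": tr.t_min,
                "x_um": tr.x_um,
                "y_um": tr.y_um,
            }
        )
        for key, val in tr.meta.items():
            df[key] = val
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(TRACK_COLUMNS)
    )
    out.to_csv(path, index=False)


def read_tracks(
    path: str | Path, strict: bool = False
) -> tuple[list[Track], ReadReport]:
    """Read a track table; malformed tracks are rejected, not repaired.

    A track whose timestamps are not strictly increasing (or that has
    fewer than 2 points, or non-finite values) is dropped and recorded in
    the report with the file line number of the offending row.  Extra
    columns are preserved in ``Track.meta``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACK_COLUMNS, path)
    report = ReadReport(path=str(path))
    extra_cols = [c for c in df.columns if c not in TRACK_COLUMNS]
    tracks: list[Track] = []
    # +2: 1-based lines plus the header row
    df = df.assign(_line=np.arange(len(df)) + 2)
    for track_id, sub in df.groupby("track_id", sort=False):
        report.n_read += 1
        line0 = int(sub["_line"].iloc[0])
        t = sub["t_min"].to_numpy(dtype=float)
        bad_step = np.nonzero(np.diff(t) <= 0)[0]
        if bad_step.size:
            line = int(sub["_line"].iloc[bad_step[0] + 1])
            msg = f"track {track_id!r}: non-monotone timestamp at line {line}"
            if strict:
                raise InputValidationError(f"{path}: {msg}")
            report.add(line, msg)
            continue
        try:
            tracks.append(
                Track(
                    track_id=str(track_id),
                    group=str(sub["group"].iloc[0]),
                    t_min=t,
                    x_um=sub["x_um"].to_numpy(dtype=float),
                    y_um=sub["y_um"].to_numpy(dtype=float),
                    meta={c: sub[c].to_numpy() for c in extra_cols},
                )
            )
        except InputValidationError as exc:
            if strict:
                raise InputValidationError(f"{path}: {exc}") from exc
            report.add(line0, str(exc))
    if report.n_rejected:
        logger.warning(
            "%s: rejected %d of %d tracks", path, report.n_rejected, report.n_read
        )
    return tracks, report


# ---------------------------------------------------------------------------
# phenotypes


def _format_fusions(pairs: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{i}-{j}" for i, j in pairs)


def _parse_fusions(text: str) -> tuple[tuple[int, int], ...]:
    text = text.strip()
    if not text:
        return ()
    pairs = []
    for part in text.split(";"):
        i, j = part.split("-")
        pairs.append((int(i), int(j)))
    return tuple(pairs)


def write_phenotypes(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {"embryo_id": rec.embryo_id, "genotype": rec.genotype, "side": rec.side}
        row.update({k: rec.pouch_states[k] for k in POUCH_KEYS})
        row.update(dict(zip(CB_KEYS, rec.cb_elements)))
        row["fusions"] = _format_fusions(rec.fused_pairs)
        rows.append(row)
    pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS)).to_csv(path, index=False)


def read_phenotypes(
    path: str | Path, strict: bool = False
) -> tuple[list[PhenotypeRecord], ReadReport]:
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(df, PHENOTYPE_COLUMNS, path)
    report = ReadReport(path=str(path))
    records: list[PhenotypeRecord] = []
    for idx, row in df.iterrows():
        report.n_read += 1
        line = int(idx) + 2
        try:
            records.append(
                PhenotypeRecord(
                    embryo_id=str(row["embryo_id"]),
                    genotype=str(row["genotype"]),
                    side=str(row["side"]),
                    pouch_states={k: str(row[k]) for k in POUCH_KEYS},
                    cb_elements=tuple(str(row[k]) for k in CB_KEYS),
                    fused_pairs=_parse_fusions(str(row["fusions"])),
                )
            )
        except (InputValidationError, ValueError) as exc:
            if strict:
                raise InputValidationError(f"{path}: line {line}: {exc}") from exc
            report.add(line, str(exc))
    if report.n_rejected:
        logger.warning(
            "%s: rejected %d of %d phenotype rows",
            path, report.n_rejected, report.n_read,
        )
    return records, report


# ---------------------------------------------------------------------------
# timelines


def write_timeline(events: Iterable[TimelineEvent], path: str | Path) -> None:
    pd.DataFrame(
        [(e.pouch_index, e.formation_time_hpf) for e in events],
        columns=["pouch_index", "formation_time_hpf"],
    ).to_csv(path, index=False)


def read_timeline(path: str | Path) -> list[TimelineEvent]:
    df = pd.read_csv(path)
    _require_columns(df, ("pouch_index", "formation_time_hpf"), path)
    return [
        TimelineEvent(int(r["pouch_index"]), float(r["formation_time_hpf"]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# per-track metrics


def write_metrics(metrics, path: str | Path) -> None:
    """Write TrackMetrics rows; angles are ';'-joined in one column."""
    rows = []
    for m in metrics:
        rows.append(
            {
                "track_id": m.track_id,
                "group": m.group,
                "velocity_um_per_min": m.velocity_um_per_min,
                "persistence": m.persistence,
                "n_valid_steps": m.n_valid_steps,
                "n_skipped_triples": m.n_skipped_triples,
                "deviation_angles_deg": ";".join(
                    repr(float(a)) for a in m.deviation_angles_deg
                ),
            }
        )
    pd.DataFrame(rows, columns=list(METRIC_COLUMNS)).to_csv(path, index=False)


def read_metrics(path: str | Path):
    from .tracks import TrackMetrics

    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    _require_columns(df, METRIC_COLUMNS, path)
    out = []
    for _, row in df.iterrows():
        raw = str(row["deviation_angles_deg"]).strip()
        angles = (
            np.array([float(a) for a in raw.split(";")]) if raw else np.empty(0)
        )
        out.append(
            TrackMetrics(
                track_id=str(row["track_id"]),
                group=str(row["group"]),
                velocity_um_per_min=float(row["velocity_um_per_min"]),
                persistence=float(row["persistence"]) if row["persistence"] != "" else float("nan"),
                deviation_angles_deg=angles,
                n_valid_steps=int(row["n_valid_steps"]),
                n_skipped_triples=int(row["n_skipped_triples"]),
            )
        )
    return out
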