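"""HRV panel data model: readers/writers, validation, and 4-week averaging.

A *panel* is the subject x week x phase table of frequency-domain HRV
indices: the physiological stress index (PSI, dimensionless), the band
powers TP, VLF, LF, HF (ms^2), and the LF/HF ratio.  Each subject is
measured before ("pre") and after ("post") the weekly intervention session
over a four-week course.

The averaging stage collapses the panel per phase to one row per subject —
the arithmetic mean over the subject's available weeks of each index — and
drops LF/HF, which is functionally dependent on LF and HF and is therefore
omitted from the grey-model sequences.  The averaged table maps directly to
the raw sequences consumed by :mod:`greyhrv.grey`: PSI is the major
sequence, (TP, VLF, LF, HF) the influence sequences, subjects in row order.

The study's printed per-week and averaged tables are bundled as CSV fixtures
(``load_table1``/``load_table2``/``load_table3``).
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grey import GreyHrvError, InvalidInputError, RawSequence

__all__ = [
    "Phase",
    "HrvMeasurement",
    "HrvPanel",
    "AveragedTable",
    "SchemaError",
    "ParseError",
    "DuplicateRecordError",
    "MissingDataError",
    "load_panel",
    "write_panel",
    "average_over_weeks",
    "to_sequences",
    "averaged_table_to_csv",
    "averaged_table_to_json",
    "load_table1",
    "load_table2",
    "load_table3",
]

logger = logging.getLogger("greyhrv")

CANONICAL_COLUMNS = ("subject_id", "week", "phase", "psi", "tp", "vlf", "lf", "hf", "lfhf")
INDEX_COLUMNS = ("psi", "tp", "vlf", "lf", "hf", "lfhf")
#: indices carried into the averaged per-phase table (LF/HF excluded as dependent)
AVERAGED_INDICES = ("psi", "tp", "vlf", "lf", "hf")

_PHASE_TOKENS = {"pre": "pre", "before": "pre", "post": "post", "after": "post"}

#: relative tolerance of the soft band-additivity check |tp - (vlf+lf+hf)| <= 0.05*tp
TP_ADDITIVITY_RTOL = 0.05


class SchemaError(GreyHrvError, ValueError):
    """Input table is missing a required column."""


class ParseError(GreyHrvError, ValueError):
    """A cell could not be parsed as the required type."""


class DuplicateRecordError(GreyHrvError, ValueError):
    """The same (subject, week, phase) triple appears more than once."""


class MissingDataError(GreyHrvError, ValueError):
    """A subject has no records in the requested phase."""


class Phase(str, Enum):
    PRE = "pre"
    POST = "post"

    @classmethod
    def parse(cls, token: str | "Phase") -> "Phase":
        if isinstance(token, Phase):
            return token
        key = str(token).strip().lower()
        if key not in _PHASE_TOKENS:
            raise ParseError(f"unrecognized phase token {token!r} (expected pre/before or post/after)")
        return cls(_PHASE_TOKENS[key])


@dataclass(frozen=True)
class HrvMeasurement:
    """One subject x week x phase HRV measurement."""

    subject_id: str
    week: int
    phase: Phase
    psi: float
    tp: float
    vlf: float
    lf: float
    hf: float
    lfhf: float

    def __post_init__(self):
        if self.week not in (1, 2, 3, 4):
            raise InvalidInputError(
                f"subject {self.subject_id}: week must be 1-4, got {self.week}"
            )
        for name in ("psi", "tp", "vlf", "lf", "hf", "lfhf"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidInputError(
                    f"subject {self.subject_id} week {self.week} {self.phase.value}: "
                    f"{name} must be a nonnegative finite number, got {v}"
                )

    def tp_additivity_ok(self) -> bool:
        """Soft check that TP approximately equals VLF + LF + HF."""
        if self.tp == 0:
            return (self.vlf + self.lf + self.hf) == 0
        return abs(self.tp - (self.vlf + self.lf + self.hf)) <= TP_ADDITIVITY_RTOL * self.tp


class HrvPanel:
    """An ordered collection of HRV measurements keyed by (subject, week, phase)."""

    def __init__(self, records: Iterable[HrvMeasurement]):
        self.records: list[HrvMeasurement] = []
        self._index: dict[tuple[str, int, str], HrvMeasurement] = {}
        subjects: list[str] = []
        for rec in records:
            key = (rec.subject_id, rec.week, rec.phase.value)
            if key in self._index:
                raise DuplicateRecordError(
                    f"duplicate record for subject {rec.subject_id}, "
                    f"week {rec.week}, phase {rec.phase.value}"
                )
            self._index[key] = rec
            self.records.append(rec)
            if rec.subject_id not in subjects:
                subjects.append(rec.subject_id)
        self.subjects: tuple[str, ...] = tuple(subjects)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def is_complete(self) -> bool:
        """True when every subject has all 4 weeks x 2 phases."""
        return all(
            (s, w, p) in self._index
            for s in self.subjects
            for w in (1, 2, 3, 4)
            for p in ("pre", "post")
        )

    def phase_records(self, phase: Phase | str) -> dict[str, list[HrvMeasurement]]:
        phase = Phase.parse(phase)
        out: dict[str, list[HrvMeasurement]] = {s: [] for s in self.subjects}
        for rec in self.records:
            if rec.phase is phase:
                out[rec.subject_id].append(rec)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": r.subject_id,
                "week": r.week,
                "phase": r.phase.value,
                **{k: getattr(r, k) for k in INDEX_COLUMNS},
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))

    def scaled(self, power_factor: float) -> "HrvPanel":
        """Return a copy with every band power (TP, VLF, LF, HF) multiplied by a constant."""
        return HrvPanel(
            HrvMeasurement(
                r.subject_id, r.week, r.phase, r.psi,
                r.tp * power_factor, r.vlf * power_factor,
                r.lf * power_factor, r.hf * power_factor, r.lfhf,
            )
            for r in self.records
        )


@dataclass(frozen=True)
class AveragedTable:
    """Per-subject means over weeks of one phase (LF/HF dropped)."""

    phase: Phase
    subjects: tuple[str, ...]
    rows: tuple[Mapping[str, float], ...]  # one dict per subject, keys AVERAGED_INDICES

    def __len__(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(list(self.rows), columns=list(AVERAGED_INDICES))
        df.insert(0, "subject_id", list(self.subjects))
        return df


def _resolve_columns(header: Sequence[str], dialect: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical column names to actual header names (case-insensitive)."""
    dialect = dict(dialect or {})
    lower = {str(c).strip().lower(): c for c in header}
    mapping = {}
    missing = []
    for canon in CANONICAL_COLUMNS:
        actual = dialect.get(canon, canon)
        if actual.strip().lower() in lower:
            mapping[canon] = lower[actual.strip().lower()]
        else:
            missing.append(actual)
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in header if c not in mapping.values()]
    if extra:
        logger.warning("ignoring unrecognized column(s): %s", ", ".join(map(str, extra)))
    return mapping


def load_panel(source: str | IO[str], dialect: Mapping[str, str] | None = None) -> HrvPanel:
    """Read a panel from a delimited-text file path or stream.

    The header must name the canonical columns (order-free, case-insensitive);
    ``dialect`` may remap canonical names to custom header names.  Phase
    tokens pre/before and post/after are accepted case-insensitively.
    """
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if df.columns.size == 0:
        raise SchemaError("input has no header row")
    mapping = _resolve_columns(df.columns, dialect)
    records = []
    n_additivity = 0
    for i in range(len(df)):
        pos = i + 2  # header is line 1
        raw = {canon: df.iloc[i][mapping[canon]] for canon in CANONICAL_COLUMNS}
        try:
            week = int(float(raw["week"]))
            numeric = {k: float(raw[k]) for k in INDEX_COLUMNS}
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric cell at data row {pos}: {exc}") from None
        rec = HrvMeasurement(
            subject_id=str(raw["subject_id"]).strip(),
            week=week,
            phase=Phase.parse(raw["phase"]),
            **numeric,
        )
        if not rec.tp_additivity_ok():
            n_additivity += 1
        records.append(rec)
    if n_additivity:
        logger.warning(
            "%d of %d records have |TP - (VLF+LF+HF)| > %g*TP (soft band-additivity check)",
            n_additivity, len(records), TP_ADDITIVITY_RTOL,
        )
    panel = HrvPanel(records)
    if panel.records and not panel.is_complete():
        logger.warning("panel is incomplete (not all 4 weeks x 2 phases present for every subject)")
    return panel


def write_panel(panel: HrvPanel, target: str | IO[str]) -> None:
    """Write a panel as canonical CSV at full stored precision (repr round-trip)."""
    df = panel.to_frame()
    for col in INDEX_COLUMNS:
        df[col] = df[col].map(repr)
    df.to_csv(target, index=False)


def average_over_weeks(panel: HrvPanel, phase: Phase | str) -> AveragedTable:
    """Per-subject arithmetic mean over available weeks of one phase.

    Full precision is kept; rounding (2 decimals in the printed tables)
    happens only at report time.
    """
    phase = Phase.parse(phase)
    by_subject = panel.phase_records(phase)
    rows = []
    for subject in panel.subjects:
        recs = by_subject[subject]
        if not recs:
            raise MissingDataError(
                f"subject {subject} has no records in phase {phase.value!r}"
            )
        rows.append(
            {k: float(np.mean([getattr(r, k) for r in recs])) for k in AVERAGED_INDICES}
        )
    return AveragedTable(phase=phase, subjects=panel.subjects, rows=tuple(rows))


def to_sequences(table: AveragedTable) -> tuple[RawSequence, list[RawSequence]]:
    """Turn an averaged table into grey-model sequences.

    PSI across subjects (row order) is the major sequence; TP, VLF, LF, HF in
    that fixed order are the influence sequences.  Length checks are left to
    the grey fit (a single-subject table fails there, not here).
    """
    if len(table) == 0:
        raise InvalidInputError("averaged table is empty")
    cols = {k: [row[k] for row in table.rows] for k in AVERAGED_INDICES}
    major = RawSequence("PSI", cols["psi"])
    influences = [RawSequence(lbl, cols[lbl.lower()]) for lbl in ("TP", "VLF", "LF", "HF")]
    return major, influences


def averaged_table_to_csv(table: AveragedTable, target: str | IO[str], decimals: int = 2) -> None:
    df = table.to_frame()
    for col in AVERAGED_INDICES:
        df[col] = df[col].round(decimals)
    df.to_csv(target, index=False, float_format=f"%.{decimals}f")


def averaged_table_to_json(table: AveragedTable) -> str:
    doc = {
        "phase": table.phase.value,
        "indices": list(AVERAGED_INDICES),
        "rows": [
            {"subject_id": s, **{k: row[k] for k in AVERAGED_INDICES}}
            for s, row in zip(table.subjects, table.rows)
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def _fixture_text(name: str) -> io.StringIO:
    return io.StringIO(resources.files("greyhrv.fixtures").joinpath(name).read_text())


def load_table1() -> HrvPanel:
    """Bundled per-week study panel: 45 subjects x 4 weeks x 2 phases."""
    return load_panel(_fixture_text("table1.csv"))


def _load_printed_average(name: str, phase: Phase) -> AveragedTable:
    df = pd.read_csv(_fixture_text(name), dtype={"subject_id": str})
    rows = tuple(
        {k: float(r[k]) for k in AVERAGED_INDICES} for _, r in df.iterrows()
    )
    return AveragedTable(phase=phase, subjects=tuple(df["subject_id"]), rows=rows)


def load_table2() -> AveragedTable:
    """Bundled printed 4-week pre-phase averages (one row per subject)."""
    return _load_printed_average("table2.csv", Phase.PRE)


def load_table3() -> AveragedTable:
    """Bundled printed 4-week post-phase averages (one row per subject)."""
    return _load_printed_average("table3.csv", Phase.POST)
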