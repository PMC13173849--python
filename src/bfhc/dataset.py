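"""Model, read, validate and summarize the PAH metadata table.

The canonical interchange format is UTF-8 CSV with the header::

    id,iupac_name,xyz_file,n_carbon,n_hydrogen,bay,fjord,harbor,canyon,
    topology,carcinogenicity,log_p,log_iball

Spreadsheet (``.xlsx``) ingest is supported as a convenience.  Column names
are matched case/spacing-insensitively and a mapping config can translate
arbitrary deposited headers onto the canonical ones.

Carcinogenic activity uses a seven-label ordered vocabulary
``-, ±, L, LM, M, HM, H`` (lowest to highest).  The alias ``+`` resolves to
``LM`` on ingest and the substitution is logged.  log P and log Iball are
curated inputs: they are stored and validated, never computed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import DatasetError
from .pipeline import AnalysisConfig, analyze
from .structure_io import read_structure

__all__ = [
    "CARCINOGENICITY_LABELS",
    "PAHRecord",
    "ValidationReport",
    "read_table",
    "write_table",
    "encode_carcinogenicity",
    "decode_carcinogenicity",
    "cross_validate",
    "summarize",
]

logger = logging.getLogger(__name__)

#: Ordered vocabulary, lowest to highest activity.
CARCINOGENICITY_LABELS = ("-", "±", "L", "LM", "M", "HM", "H")

_LABEL_TO_ORDINAL = {label: i for i, label in enumerate(CARCINOGENICITY_LABELS)}

# unicode dashes and plus/minus variants seen in hand-curated tables
_LABEL_NORMALIZATION = {
    "–": "-", "—": "-", "−": "-",
    "+-": "±", "+/-": "±",
}
_ALIASES = {"+": "LM"}

CSV_COLUMNS = (
    "id", "iupac_name", "xyz_file", "n_carbon", "n_hydrogen",
    "bay", "fjord", "harbor", "canyon", "topology",
    "carcinogenicity", "log_p", "log_iball",
)

_COLUMN_SYNONYMS: Dict[str, str] = {
    "name": "iupac_name",
    "iupac": "iupac_name",
    "compound": "iupac_name",
    "xyz": "xyz_file",
    "xyz_input_file": "xyz_file",
    "file": "xyz_file",
    "c": "n_carbon",
    "carbon": "n_carbon",
    "carbons": "n_carbon",
    "number_of_carbons": "n_carbon",
    "h": "n_hydrogen",
    "hydrogen": "n_hydrogen",
    "hydrogens": "n_hydrogen",
    "number_of_hydrogens": "n_hydrogen",
    "b": "bay",
    "f": "fjord",
    "harbour": "harbor",
    "logp": "log_p",
    "log_p_value": "log_p",
    "logiball": "log_iball",
    "log_iball_index": "log_iball",
    "carcinogenicity_label": "carcinogenicity",
    "activity": "carcinogenicity",
    "topology_class": "topology",
    "fused_ring_topology": "topology",
}


def normalize_label(raw: str) -> str:
    """Resolve unicode variants and the ``+`` alias; raise on unknown labels."""
    label = str(raw).strip()
    label = _LABEL_NORMALIZATION.get(label, label)
    if label in _ALIASES:
        resolved = _ALIASES[label]
        logger.info("carcinogenicity alias %r resolved to %r", label, resolved)
        return resolved
    if label.upper() in {"L", "LM", "M", "HM", "H"}:
        label = label.upper()
    if label not in _LABEL_TO_ORDINAL:
        raise DatasetError(f"unknown carcinogenicity label: {raw!r}")
    return label


def encode_carcinogenicity(label: str, collapse_L_to_negative: bool = False) -> int:
    """Ordinal position of *label* in the seven-level scheme (0..6).

    ``collapse_L_to_negative`` applies the alternative reading in which
    ``L`` is grouped with non-carcinogenic (encoded 0).
    """
    resolved = normalize_label(label)
    if collapse_L_to_negative and resolved == "L":
        return 0
    return _LABEL_TO_ORDINAL[resolved]


def decode_carcinogenicity(ordinal: int) -> str:
    try:
        return CARCINOGENICITY_LABELS[ordinal]
    except (IndexError, TypeError) as exc:
        raise DatasetError(f"ordinal out of range: {ordinal!r}") from exc


@dataclass
class PAHRecord:
    """One row of the metadata table."""

    id: str
    iupac_name: str = ""
    xyz_file: str = ""
    n_carbon: Optional[int] = None
    n_hydrogen: Optional[int] = None
    bay: Optional[int] = None
    fjord: Optional[int] = None
    harbor: Optional[int] = None
    canyon: Optional[int] = None
    topology: Optional[str] = None
    carcinogenicity: Optional[str] = None
    log_p: Optional[float] = None
    log_iball: Optional[float] = None

    def __post_init__(self) -> None:
        if self.carcinogenicity is not None:
            self.carcinogenicity = normalize_label(self.carcinogenicity)

    def to_row(self) -> dict:
        def cell(value):
            return "" if value is None else value
        return {name: cell(getattr(self, name)) for name in CSV_COLUMNS}


@dataclass
class ValidationReport:
    n_records: int = 0
    n_valid: int = 0
    vocabulary_violations: List[str] = field(default_factory=list)
    count_mismatches: List[tuple] = field(default_factory=list)
    unreadable: List[str] = field(default_factory=list)
    missing_logp: int = 0
    missing_logiball: int = 0
    distinct_carcinogenicity_labels: int = 0

    def ok(self) -> bool:
        return not self.vocabulary_violations and not self.count_mismatches


def _canonical_column(name: str) -> str:
    key = re.sub(r"[^a-z0-9]+", "_", str(name).strip().lower()).strip("_")
    if key in CSV_COLUMNS:
        return key
    return _COLUMN_SYNONYMS.get(key, key)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and not value.strip()


def _parse_int(value, row: int, column: str) -> Optional[int]:
    if _is_missing(value):
        return None
    try:
        as_float = float(value)
    except (TypeError, ValueError) as exc:
        raise DatasetError(f"row {row}: non-integer {column} cell {value!r}") from exc
    if as_float != int(as_float):
        raise DatasetError(f"row {row}: non-integer {column} cell {value!r}")
    return int(as_float)


def _parse_float(value, row: int, column: str) -> Optional[float]:
    if _is_missing(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise DatasetError(f"row {row}: unparseable {column} cell {value!r}") from exc


def read_table(
    source: Union[str, Path],
    column_map: Optional[Mapping[str, str]] = None,
) -> List[PAHRecord]:
    """Read a delimited or spreadsheet metadata table into records.

    *column_map* translates raw header names (matched case/spacing-
    insensitively) onto canonical field names, overriding the built-in
    synonym table.
    """
    path = Path(source)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path, dtype=object)

    overrides = {
        re.sub(r"[^a-z0-9]+", "_", k.strip().lower()).strip("_"): v
        for k, v in (column_map or {}).items()
    }
    renamed = {}
    for raw in frame.columns:
        key = re.sub(r"[^a-z0-9]+", "_", str(raw).strip().lower()).strip("_")
        renamed[raw] = overrides.get(key, _canonical_column(raw))
    frame = frame.rename(columns=renamed)

    required = {"id", "carcinogenicity"}
    missing = required - set(frame.columns)
    if missing:
        raise DatasetError(
            f"missing required columns: {', '.join(sorted(missing))} "
            f"(found: {', '.join(map(str, frame.columns))})"
        )

    records = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=2):  # 1-based + header
        get = lambda col: row[col] if col in frame.columns else None
        label_raw = get("carcinogenicity")
        if _is_missing(label_raw):
            label = None
        else:
            try:
                label = normalize_label(label_raw)
            except DatasetError as exc:
                raise DatasetError(f"row {pos}: {exc}") from exc
        topology = get("topology")
        topology = None if _is_missing(topology) else str(topology).strip().lower()
        records.append(
            PAHRecord(
                id=str(get("id")).strip(),
                iupac_name="" if _is_missing(get("iupac_name")) else str(get("iupac_name")).strip(),
                xyz_file="" if _is_missing(get("xyz_file")) else str(get("xyz_file")).strip(),
                n_carbon=_parse_int(get("n_carbon"), pos, "n_carbon"),
                n_hydrogen=_parse_int(get("n_hydrogen"), pos, "n_hydrogen"),
                bay=_parse_int(get("bay"), pos, "bay"),
                fjord=_parse_int(get("fjord"), pos, "fjord"),
                harbor=_parse_int(get("harbor"), pos, "harbor"),
                canyon=_parse_int(get("canyon"), pos, "canyon"),
                topology=topology,
                carcinogenicity=label,
                log_p=_parse_float(get("log_p"), pos, "log_p"),
                log_iball=_parse_float(get("log_iball"), pos, "log_iball"),
            )
        )
    return records


def write_table(records: Sequence[PAHRecord], destination: Union[str, Path]) -> None:
    """Write records as canonical CSV (missing values become empty cells)."""
    frame = pd.DataFrame([r.to_row() for r in records], columns=list(CSV_COLUMNS))
    frame.to_csv(destination, index=False)


def cross_validate(
    records: Sequence[PAHRecord],
    structure_dir: Union[str, Path],
    config: AnalysisConfig = AnalysisConfig(),
) -> ValidationReport:
    """Recompute structural fields from the XYZ files and diff against records.

    Recorded values are never overwritten; discrepancies are findings.
    Unreadable structures are reported per record, not fatal.
    """
    structure_dir = Path(structure_dir)
    report = ValidationReport(n_records=len(records))
    labels = set()
    checked_fields = (
        "n_carbon", "n_hydrogen", "bay", "fjord", "harbor", "canyon", "topology"
    )
    for record in records:
        if record.carcinogenicity is not None:
            labels.add(record.carcinogenicity)
        if record.log_p is None:
            report.missing_logp += 1
        if record.log_iball is None:
            report.missing_logiball += 1

        candidates = [structure_dir / record.xyz_file] if record.xyz_file else []
        if record.xyz_file and not record.xyz_file.endswith(".xyz"):
            candidates.append(structure_dir / (record.xyz_file + ".xyz"))
        path = next((p for p in candidates if p.is_file()), None)
        if path is None:
            report.unreadable.append(record.id)
            continue
        try:
            result = analyze(read_structure(path), config)
        except Exception as exc:  # noqa: BLE001 - report, do not abort the batch
            logger.warning("record %s: %s", record.id, exc)
            report.unreadable.append(record.id)
            continue

        bay, fjord, harbor, canyon = result.bfhc()
        recomputed = {
            "n_carbon": result.n_carbon,
            "n_hydrogen": result.n_hydrogen,
            "bay": bay,
            "fjord": fjord,
            "harbor": harbor,
            "canyon": canyon,
            "topology": result.topology,
        }
        mismatched = False
        for name in checked_fields:
            recorded = getattr(record, name)
            if recorded is None:
                continue
            if recorded != recomputed[name]:
                report.count_mismatches.append(
                    (record.id, name, recorded, recomputed[name])
                )
                mismatched = True
        if not mismatched:
            report.n_valid += 1
    report.distinct_carcinogenicity_labels = len(labels)
    return report


def summarize(records: Sequence[PAHRecord]) -> dict:
    """Deterministic dataset summary counts."""
    if not records:
        raise DatasetError("cannot summarize an empty record list")
    topology_tally: Dict[str, int] = {}
    labels = set()
    n_logp = n_logiball = 0
    for record in records:
        if record.log_p is not None:
            n_logp += 1
        if record.log_iball is not None:
            n_logiball += 1
        if record.carcinogenicity is not None:
            labels.add(record.carcinogenicity)
        if record.topology is not None:
            topology_tally[record.topology] = topology_tally.get(record.topology, 0) + 1
    return {
        "n_records": len(records),
        "n_log_p": n_logp,
        "n_log_iball": n_logiball,
        "distinct_carcinogenicity_labels": len(labels),
        "topology_tally": dict(sorted(topology_tally.items())),
    }
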