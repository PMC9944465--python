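"""Readers and writers for every on-disk artifact of the kinome pipeline.

Formats
-------
* intensity tables: wide CSV, one row per peptide, one column per
  ``sample:replicate:exposure_ms`` reading,
* kinase annotation sources: two-column TSV (peptide id, comma-separated
  kinase names),
* pathway collections: GMT (tab-separated, ``id  description  member...``),
* PPI edge lists: TSV with a header (``node_a  node_b  confidence
  [action_type]``) or 3-column SIF (``A  pp  B``, confidence defaults to 1),
* clinical tables: CSV with one row per case.

All readers validate their input and raise :class:`FormatError` with file
coordinates on malformed content; all reader/writer pairs round-trip.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")

__all__ = [
    "FormatError",
    "IntensityTable",
    "KinaseAnnotationSource",
    "PathwayCollection",
    "EdgeList",
    "ClinicalTable",
    "read_intensity_table",
    "write_intensity_table",
    "read_kinase_db",
    "write_kinase_db",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_clinical_table",
    "write_clinical_table",
]


class FormatError(ValueError):
    """Malformed on-disk input; message carries file coordinates."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class IntensityTable:
    """Raw spot intensities over the exposure-time series.

    ``data`` is long-form with columns ``peptide_id, sample, replicate,
    exposure_ms, intensity``.  Every (sample, replicate) array must have been
    read on the same exposure grid.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"peptide_id", "sample", "replicate", "exposure_ms", "intensity"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"intensity table missing columns: {sorted(missing)}")
        if not self.data["intensity"].map(math.isfinite).all():
            raise FormatError("intensity table contains non-finite values")
        self.validate_exposure_grid()

    def validate_exposure_grid(self) -> None:
        grids = {
            key: tuple(sorted(sub["exposure_ms"].unique()))
            for key, sub in self.data.groupby(["sample", "replicate"], sort=False)
        }
        distinct = set(grids.values())
        if len(distinct) > 1:
            raise FormatError(
                f"ragged exposure grid across arrays: {sorted(distinct)}"
            )

    @property
    def peptide_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["peptide_id"]))

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    @property
    def exposure_times(self) -> list[float]:
        return sorted(self.data["exposure_ms"].unique())

    def canonical(self) -> pd.DataFrame:
        """Order-independent long form used for equality checks."""
        return (
            self.data.sort_values(
                ["peptide_id", "sample", "replicate", "exposure_ms"]
            ).reset_index(drop=True)
        )

    def __eq__(self, other: object) -> bool:  # round-trip identity support
        if not isinstance(other, IntensityTable):
            return NotImplemented
        a, b = self.canonical(), other.canonical()
        if a.shape != b.shape:
            return False
        return bool(
            (a[["peptide_id", "sample"]].values == b[["peptide_id", "sample"]].values).all()
            and (a["replicate"].values == b["replicate"].values).all()
            and (abs(a["exposure_ms"].values - b["exposure_ms"].values) < 1e-9).all()
            and (abs(a["intensity"].values - b["intensity"].values) < 1e-9).all()
        )


@dataclass(frozen=True)
class KinaseAnnotationSource:
    """One kinase-substrate annotation database: peptide -> candidate kinases."""

    source_name: str
    annotations: Mapping[str, frozenset[str]]

    def get(self, peptide_id: str) -> frozenset[str] | None:
        return self.annotations.get(peptide_id)


@dataclass
class PathwayCollection:
    """Gene sets with a background universe for over-representation tests."""

    pathways: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        members: set[str] = set()
        for pid, (_, mem) in self.pathways.items():
            if not mem:
                raise FormatError(f"pathway {pid!r} is empty")
            members |= mem
        if not self.universe:
            self.universe = frozenset(members)
        elif not members <= self.universe:
            raise FormatError("pathway members outside the declared universe")

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class EdgeList:
    """Undirected weighted protein-protein interaction edges."""

    records: list[tuple[str, str, float, str | None]]

    def __post_init__(self) -> None:
        for a, b, c, _ in self.records:
            if a == b:
                raise FormatError(f"self-loop on node {a!r}")
            if not 0.0 <= c <= 1.0:
                raise FormatError(f"edge {a}-{b} confidence {c} outside [0, 1]")

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b, _, _ in self.records:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ClinicalTable:
    """Per-case best response, survival times and event flags."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"case_id", "response", "pfs_months", "pfs_event", "os_months", "os_event"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"clinical table missing columns: {sorted(missing)}")
        bad = set(self.data["response"]) - set(RESPONSE_CATEGORIES)
        if bad:
            raise FormatError(
                f"unknown response codes {sorted(bad)}; allowed: {RESPONSE_CATEGORIES}"
            )
        for col in ("pfs_months", "os_months"):
            if (self.data[col] < 0).any():
                raise FormatError(f"negative times in column {col!r}")

    @property
    def case_ids(self) -> list[str]:
        return list(self.data["case_id"])


# ---------------------------------------------------------------------------
# intensity tables
# ---------------------------------------------------------------------------


def _reading_column(sample: str, replicate: str, exposure: float) -> str:
    exp = int(exposure) if float(exposure).is_integer() else exposure
    return f"{sample}:{replicate}:{exp}"


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    wide = table.data.pivot_table(
        index="peptide_id",
        columns=["sample", "replicate", "exposure_ms"],
        values="intensity",
        sort=False,
    )
    wide = wide.loc[table.peptide_ids]
    wide.columns = [_reading_column(s, r, e) for s, r, e in wide.columns]
    wide.index.name = "peptide_id"
    wide.to_csv(path)  # default float repr: lossless round-trip


def read_intensity_table(path: str | Path) -> IntensityTable:
    """Read a wide intensity CSV whose header encodes sample:replicate:exposure."""
    wide = pd.read_csv(path, index_col=0)
    rows: list[tuple[str, str, str, float, float]] = []
    for col in wide.columns:
        parts = col.split(":")
        if len(parts) != 3:
            raise FormatError(
                f"{path}: column {col!r} does not encode sample:replicate:exposure_ms"
            )
        sample, replicate, exposure = parts
        try:
            exposure_ms = float(exposure)
        except ValueError as err:
            raise FormatError(f"{path}: non-numeric exposure in column {col!r}") from err
        for pep, value in wide[col].items():
            fval = float(value)
            if not math.isfinite(fval):
                raise FormatError(f"{path}: non-numeric cell at row {pep!r}, column {col!r}")
            rows.append((str(pep), sample, replicate, exposure_ms, fval))
    data = pd.DataFrame(
        rows, columns=["peptide_id", "sample", "replicate", "exposure_ms", "intensity"]
    )
    return IntensityTable(data)


# ---------------------------------------------------------------------------
# kinase annotation sources
# ---------------------------------------------------------------------------


def normalize_kinase_name(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Uppercase a kinase symbol and fold known aliases onto one spelling."""
    canon = name.strip().upper()
    if aliases:
        canon = aliases.get(canon, canon)
    return canon


def read_kinase_db(
    path: str | Path,
    source_name: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> KinaseAnnotationSource:
    """Read a two-column TSV of ``peptide_id<TAB>kinase1,kinase2,...``.

    Kinase names are uppercased and alias-normalized on load; an empty kinase
    field yields a peptide with an empty annotation set.
    """
    path = Path(path)
    annotations: dict[str, frozenset[str]] = {}
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("peptide_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 1:
                raise FormatError(f"{path}:{lineno}: empty row")
            peptide = parts[0].strip()
            raw = parts[1] if len(parts) > 1 else ""
            names = frozenset(
                normalize_kinase_name(tok, aliases)
                for tok in raw.split(",")
                if tok.strip()
            )
            annotations[peptide] = names
    return KinaseAnnotationSource(source_name or path.stem, annotations)


def write_kinase_db(source: KinaseAnnotationSource, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("peptide_id\tkinases\n")
        for pep in sorted(source.annotations):
            fh.write(f"{pep}\t{','.join(sorted(source.annotations[pep]))}\n")


# ---------------------------------------------------------------------------
# GMT pathway sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> PathwayCollection:
    path = Path(path)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            pid, desc = parts[0], parts[1]
            members = frozenset(tok for tok in parts[2:] if tok)
            pathways[pid] = (desc, members)
    return PathwayCollection(pathways, frozenset(universe) if universe else frozenset())


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for pid, (desc, members) in collection.pathways.items():
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, min_confidence: float = 0.4) -> EdgeList:
    """Read TSV or SIF edges, drop low-confidence and self-loop rows, and
    collapse symmetric duplicates keeping the maximum confidence."""
    path = Path(path)
    raw: list[tuple[str, str, float, str | None]] = []
    with open(path, newline="") as fh:
        first = True
        sif = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if first:
                first = False
                if parts[0].lower() in {"node_a", "source", "protein1"}:
                    continue
                # SIF dialect: middle token is a relation, not a number
                if len(parts) == 3 and not _is_number(parts[2]):
                    sif = True
            if sif or (len(parts) == 3 and not _is_number(parts[2])):
                if len(parts) != 3:
                    raise FormatError(f"{path}:{lineno}: malformed SIF row")
                a, rel, b = parts
                raw.append((a, b, 1.0, rel))
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected node_a, node_b, confidence")
            a, b = parts[0], parts[1]
            try:
                conf = float(parts[2])
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: non-numeric confidence") from err
            action = parts[3] if len(parts) > 3 and parts[3] else None
            raw.append((a, b, conf, action))
    best: dict[tuple[str, str], tuple[float, str | None]] = {}
    for a, b, conf, action in raw:
        if a == b or conf < min_confidence:
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in best or conf > best[key][0]:
            best[key] = (conf, action)
    records = [(a, b, conf, action) for (a, b), (conf, action) in sorted(best.items())]
    return EdgeList(records)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("node_a\tnode_b\tconfidence\taction_type\n")
        for a, b, conf, action in edges.records:
            fh.write(f"{a}\t{b}\t{conf:.6g}\t{action or ''}\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = ["case_id", "response", "pfs_months", "pfs_event", "os_months", "os_event"]


def read_clinical_table(path: str | Path) -> ClinicalTable:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    if not rows:
        raise FormatError(f"{path}: empty clinical table")
    records = []
    for i, row in enumerate(rows, start=2):
        missing = [c for c in _CLINICAL_COLUMNS if c not in row or row[c] is None]
        if missing:
            raise FormatError(f"{path}:{i}: missing columns {missing}")
        rec = {
            "case_id": row["case_id"],
            "response": row["response"].strip().upper(),
            "pfs_months": float(row["pfs_months"]),
            "pfs_event": _parse_bool(row["pfs_event"], path, i),
            "os_months": float(row["os_months"]),
            "os_event": _parse_bool(row["os_event"], path, i),
        }
        for key, value in row.items():
            if key not in _CLINICAL_COLUMNS:
                rec[key] = value
        records.append(rec)
    return ClinicalTable(pd.DataFrame(records))


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    out = table.data.copy()
    out["pfs_event"] = out["pfs_event"].astype(int)
    out["os_event"] = out["os_event"].astype(int)
    out.to_csv(path, index=False, float_format="%.10g")


def _parse_bool(token: str, path: Path, lineno: int) -> bool:
    tok = str(token).strip().lower()
    if tok in {"1", "true", "yes"}:
        return True
    if tok in {"0", "false", "no"}:
        return False
    raise FormatError(f"{path}:{lineno}: cannot parse event flag {token!r}")
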