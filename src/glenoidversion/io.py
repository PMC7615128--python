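"""Landmark and results I/O.

Reads 3DSlicer fiducial files (legacy ``.fcsv`` and Markups ``.mrk.json``)
plus a plain internal CSV format, maps free-text landmark labels to the
anatomical roles each method needs, and writes per-case results tables.

Every position is converted on ingest into the internal LPS-like frame
(x medial/left+, y posterior+, z superior+).  Readers reject rather than
guess: a file without a declared coordinate system is an error, and role
resolution fails loudly on missing or ambiguous labels.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import as_point3
from .methods import (
    METHOD_NAMES,
    AxialLandmarks,
    CorrectedLandmarks,
    TwoPlaneLandmarks,
)

__all__ = [
    "LandmarkSet",
    "RoleMap",
    "ResultsTable",
    "LandmarkFormatError",
    "RoleResolutionError",
    "read_fcsv",
    "read_markups_json",
    "read_internal_csv",
    "write_internal_csv",
    "write_fcsv",
    "read_landmarks",
    "resolve_roles",
    "METHOD_ROLES",
]

#: canonical anatomical role names (also the default expected labels)
ALL_ROLES = (
    "glenoid_superior",
    "glenoid_anterior",
    "glenoid_posterior",
    "glenoid_center",
    "medial_border",
    "inferior_angle",
    "vault_tip",
)

#: roles required by each method
METHOD_ROLES: Dict[str, Tuple[str, ...]] = {
    "two_plane": (
        "glenoid_superior", "glenoid_anterior", "glenoid_posterior",
        "glenoid_center", "medial_border", "inferior_angle",
    ),
    "friedman": ("glenoid_anterior", "glenoid_posterior", "medial_border"),
    "vault": ("glenoid_anterior", "glenoid_posterior", "vault_tip"),
    "corrected_friedman": (
        "glenoid_center", "medial_border", "inferior_angle",
        "glenoid_anterior", "glenoid_posterior",
    ),
}


class LandmarkFormatError(ValueError):
    """Malformed or ambiguous landmark file."""


class RoleResolutionError(ValueError):
    """A required anatomical role could not be resolved to exactly one landmark."""


@dataclass
class LandmarkSet:
    """Named 3-D points for one case, stored internally in the LPS-like frame."""

    case_id: str
    points: List[Tuple[str, np.ndarray]]
    source_frame: str = "LPS"

    def __post_init__(self):
        self.points = [(str(lbl), as_point3(pos, str(lbl))) for lbl, pos in self.points]

    @property
    def labels(self) -> List[str]:
        return [lbl for lbl, _ in self.points]

    def get(self, label: str) -> np.ndarray:
        for lbl, pos in self.points:
            if lbl == label:
                return pos
        raise KeyError(label)


_FRAME_ALIASES = {"LPS": "LPS", "RAS": "RAS", "0": "RAS", "1": "LPS"}


def _to_internal(xyz: np.ndarray, source_frame: str) -> np.ndarray:
    """RAS -> LPS flips x and y; LPS passes through.  Involutive."""
    if source_frame == "RAS":
        return xyz * np.array([-1.0, -1.0, 1.0])
    return xyz


def read_fcsv(path, case_id: Optional[str] = None) -> LandmarkSet:
    """Read a 3DSlicer fiducial CSV (.fcsv).

    The header must declare ``# CoordinateSystem = LPS|RAS|0|1`` (0 = RAS,
    1 = LPS); there is no silent default.  Column layout is taken from the
    ``# columns = ...`` header when present, else the standard Slicer layout
    (id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID).
    """
    path = Path(path)
    text = path.read_text().splitlines()
    frame = None
    columns = ["id", "x", "y", "z", "ow", "ox", "oy", "oz",
               "vis", "sel", "lock", "label", "desc", "associatedNodeID"]
    points: List[Tuple[str, np.ndarray]] = []
    for lineno, line in enumerate(text, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*CoordinateSystem\s*=\s*(\S+)", line, flags=re.IGNORECASE)
            if m:
                raw = m.group(1)
                if raw not in _FRAME_ALIASES:
                    raise LandmarkFormatError(
                        f"{path}:{lineno}: unknown CoordinateSystem {raw!r}"
                    )
                frame = _FRAME_ALIASES[raw]
            m = re.match(r"#\s*columns\s*=\s*(.+)", line, flags=re.IGNORECASE)
            if m:
                columns = [c.strip() for c in m.group(1).split(",")]
            continue
        if frame is None:
            raise LandmarkFormatError(
                f"{path}: data row before any CoordinateSystem header; "
                "refusing to guess RAS vs LPS"
            )
        fields = line.split(",")
        try:
            xyz = np.array([float(fields[columns.index(c)]) for c in ("x", "y", "z")])
        except (ValueError, IndexError) as exc:
            raise LandmarkFormatError(
                f"{path}:{lineno}: cannot parse coordinates: {exc}"
            ) from exc
        label_idx = columns.index("label") if "label" in columns else 11
        label = fields[label_idx].strip() if label_idx < len(fields) else ""
        points.append((label, _to_internal(xyz, frame)))
    if frame is None:
        raise LandmarkFormatError(f"{path}: missing CoordinateSystem header")
    return LandmarkSet(case_id=case_id or path.stem, points=points, source_frame=frame)


def read_markups_json(path, case_id: Optional[str] = None) -> LandmarkSet:
    """Read a 3DSlicer Markups file (.mrk.json)."""
    path = Path(path)
    doc = json.loads(path.read_text())
    markups = doc.get("markups")
    if not markups:
        raise LandmarkFormatError(f"{path}: no markups in file")
    points: List[Tuple[str, np.ndarray]] = []
    frame_seen = None
    for markup in markups:
        raw = str(markup.get("coordinateSystem", ""))
        if raw not in _FRAME_ALIASES:
            raise LandmarkFormatError(
                f"{path}: unknown or missing coordinateSystem {raw!r}"
            )
        frame = _FRAME_ALIASES[raw]
        frame_seen = frame
        cps = markup.get("controlPoints")
        if not cps:
            raise LandmarkFormatError(f"{path}: markup has no controlPoints")
        for cp in cps:
            pos = np.asarray(cp["position"], dtype=float)
            points.append((str(cp.get("label", "")), _to_internal(pos, frame)))
    if not points:
        raise LandmarkFormatError(f"{path}: empty markups")
    return LandmarkSet(case_id=case_id or path.name.replace(".mrk.json", ""),
                       points=points, source_frame=frame_seen)


def write_internal_csv(ls: LandmarkSet, csv_path) -> Path:
    """Write the internal format: ``label,x,y,z`` CSV (LPS, mm) plus a JSON
    sidecar ``<stem>.meta.json`` carrying case_id and frame."""
    csv_path = Path(csv_path)
    lines = ["label,x,y,z"]
    for lbl, pos in ls.points:
        lines.append(f"{lbl},{float(pos[0])!r},{float(pos[1])!r},{float(pos[2])!r}")
    csv_path.write_text("\n".join(lines) + "\n")
    sidecar = csv_path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(
        {"case_id": ls.case_id, "coordinate_system": "LPS"}, indent=2) + "\n")
    return csv_path


def read_internal_csv(csv_path, case_id: Optional[str] = None) -> LandmarkSet:
    """Read the internal ``label,x,y,z`` CSV (always LPS, mm)."""
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".meta.json")
    if case_id is None and sidecar.exists():
        case_id = json.loads(sidecar.read_text()).get("case_id")
    points: List[Tuple[str, np.ndarray]] = []
    for lineno, line in enumerate(csv_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or (lineno == 1 and line.lower().startswith("label,")):
            continue
        fields = line.split(",")
        if len(fields) != 4:
            raise LandmarkFormatError(f"{csv_path}:{lineno}: expected label,x,y,z")
        try:
            xyz = np.array([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise LandmarkFormatError(
                f"{csv_path}:{lineno}: cannot parse coordinates: {exc}") from exc
        points.append((fields[0], xyz))
    return LandmarkSet(case_id=case_id or csv_path.stem, points=points, source_frame="LPS")


def write_fcsv(ls: LandmarkSet, path) -> Path:
    """Write a Slicer-compatible .fcsv (declared LPS)."""
    path = Path(path)
    lines = [
        "# Markups fiducial file version = 4.11",
        "# CoordinateSystem = LPS",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for k, (lbl, pos) in enumerate(ls.points, start=1):
        lines.append(
            f"{k},{float(pos[0])!r},{float(pos[1])!r},{float(pos[2])!r},"
            f"0,0,0,1,1,1,0,{lbl},,"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_landmarks(path, case_id: Optional[str] = None) -> LandmarkSet:
    """Dispatch on file extension: .fcsv, .mrk.json / .json, or internal .csv."""
    p = Path(path)
    name = p.name.lower()
    if name.endswith(".fcsv"):
        return read_fcsv(p, case_id)
    if name.endswith(".json"):
        return read_markups_json(p, case_id)
    if name.endswith(".csv"):
        return read_internal_csv(p, case_id)
    raise LandmarkFormatError(f"{p}: unrecognised landmark file extension")


@dataclass
class RoleMap:
    """Mapping from anatomical role to a label pattern.

    Default: exact, case-insensitive match on the role name itself.  Patterns
    are regular expressions matched against the full label (``fullmatch``),
    case-insensitively, so legacy annotations like ``Glenoid Centre.*`` can be
    accommodated from a small JSON config file.
    """

    patterns: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RoleMap":
        return cls(patterns=dict(json.loads(Path(path).read_text())))

    def pattern_for(self, role: str) -> str:
        return self.patterns.get(role, re.escape(role))

    def resolve(self, ls: LandmarkSet, role: str) -> np.ndarray:
        pat = re.compile(self.pattern_for(role), flags=re.IGNORECASE)
        hits = [(lbl, pos) for lbl, pos in ls.points if pat.fullmatch(lbl)]
        if not hits:
            raise RoleResolutionError(
                f"case {ls.case_id!r}: no landmark matches role {role!r} "
                f"(pattern {self.pattern_for(role)!r}); labels present: {ls.labels}"
            )
        if len(hits) > 1:
            raise RoleResolutionError(
                f"case {ls.case_id!r}: role {role!r} is ambiguous: "
                f"{[lbl for lbl, _ in hits]}"
            )
        return hits[0][1]


def resolve_roles(ls: LandmarkSet, method: str, role_map: Optional[RoleMap] = None):
    """Resolve a landmark set into the typed record a method needs.

    Returns ``(record, unused_labels)`` where the record is a
    TwoPlaneLandmarks / AxialLandmarks / CorrectedLandmarks instance.  For the
    2-D methods the annotated axial-slice points are used as-is with their
    superior coordinate dropped.  Missing and ambiguous roles raise.
    """
    if method not in METHOD_NAMES:
        raise ValueError(f"unknown method {method!r}; choose from {METHOD_NAMES}")
    rm = role_map or RoleMap()
    roles = METHOD_ROLES[method]
    missing = []
    resolved: Dict[str, np.ndarray] = {}
    for role in roles:
        try:
            resolved[role] = rm.resolve(ls, role)
        except RoleResolutionError as exc:
            if "no landmark matches" in str(exc):
                missing.append(role)
            else:
                raise
    if missing:
        raise RoleResolutionError(
            f"case {ls.case_id!r}: method {method!r} is missing roles {missing}; "
            f"labels present: {ls.labels}"
        )
    used_patterns = [re.compile(rm.pattern_for(r), flags=re.IGNORECASE) for r in roles]
    unused = [lbl for lbl in ls.labels if not any(p.fullmatch(lbl) for p in used_patterns)]

    if method == "two_plane":
        record = TwoPlaneLandmarks(**{r: resolved[r] for r in roles})
    elif method == "friedman":
        record = AxialLandmarks(
            glenoid_anterior=resolved["glenoid_anterior"][:2],
            glenoid_posterior=resolved["glenoid_posterior"][:2],
            medial_reference=resolved["medial_border"][:2],
            method_tag="friedman",
        )
    elif method == "vault":
        record = AxialLandmarks(
            glenoid_anterior=resolved["glenoid_anterior"][:2],
            glenoid_posterior=resolved["glenoid_posterior"][:2],
            medial_reference=resolved["vault_tip"][:2],
            method_tag="vault",
        )
    else:  # corrected_friedman
        record = CorrectedLandmarks(**{r: resolved[r] for r in roles})
    return record, unused


@dataclass
class ResultsTable:
    """Rows of (case_id, method, version_deg), one per case x method."""

    rows: List[Tuple[str, str, float]] = field(default_factory=list)

    def add(self, case_id: str, method: str, version_deg: float) -> None:
        v = float(version_deg)
        if not (-90.0 <= v <= 90.0):
            raise ValueError(f"version {v} outside [-90, 90]")
        self.rows.append((str(case_id), str(method), v))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["case_id", "method", "version_deg"])

    def versions_for(self, method: str) -> List[float]:
        return [v for _, m, v in self.rows if m == method]

    def to_csv(self, path_or_buf) -> None:
        """CSV with degrees at 3 decimal places (0.001° ≪ landmark precision)."""
        df = self.to_dataframe()
        df["version_deg"] = df["version_deg"].map(lambda v: f"{v:.3f}")
        df.to_csv(path_or_buf, index=False)

    def to_json(self, path) -> None:
        """Lossless JSON mirror of the table."""
        Path(path).write_text(json.dumps(
            [{"case_id": c, "method": m, "version_deg": v} for c, m, v in self.rows],
            indent=2) + "\n")

    @classmethod
    def from_csv(cls, path_or_buf) -> "ResultsTable":
        df = pd.read_csv(path_or_buf)
        t = cls()
        for _, row in df.iterrows():
            t.add(row["case_id"], row["method"], float(row["version_deg"]))
        return t

    @classmethod
    def from_json(cls, path) -> "ResultsTable":
        t = cls()
        for row in json.loads(Path(path).read_text()):
            t.add(row["case_id"], row["method"], float(row["version_deg"]))
        return t
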