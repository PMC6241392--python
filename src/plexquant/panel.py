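"""Structured assay Panel Information.

A panel file is a small YAML document describing a multiplex kit:

.. code-block:: yaml

    panel_name: Human Growth Factor Panel (13-plex)
    std_dilution: 4.0          # fold dilution D between standard levels
    units: pg/ml
    analytes:
      A:                       # bead group
        A4: {name: Angiopoietin-2, concentration: 50000.0}
        ...

Group order and within-group analyte order are significant: analytes are
listed from low to high reporter-discrimination intensity, which is the
contract the positional cluster-to-ID assignment relies on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class AnalyteEntry:
    """One analyte: display name and standard start concentration C0."""

    name: str
    start_concentration: float


@dataclass(frozen=True)
class PanelInfo:
    panel_name: str
    std_dilution: float
    units: str
    #: ordered mapping group_id -> (ordered mapping analyte_id -> AnalyteEntry)
    groups: dict[str, dict[str, AnalyteEntry]] = field(default_factory=dict)

    @property
    def group_ids(self) -> list[str]:
        return list(self.groups)

    @property
    def analyte_ids(self) -> list[str]:
        return [a for g in self.groups.values() for a in g]

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_ids)

    def analytes_in(self, group_id: str) -> dict[str, AnalyteEntry]:
        if group_id not in self.groups:
            raise ConfigError(
                f"unknown bead group {group_id!r}; panel has {self.group_ids}"
            )
        return self.groups[group_id]

    def entry(self, analyte_id: str) -> AnalyteEntry:
        for group in self.groups.values():
            if analyte_id in group:
                return group[analyte_id]
        raise ConfigError(f"unknown analyte ID {analyte_id!r}")


def _validate_panel(doc: dict, source: str) -> PanelInfo:
    if not isinstance(doc, dict):
        raise ConfigError(f"{source}: panel file must be a YAML mapping")
    for key in ("panel_name", "std_dilution", "units", "analytes"):
        if key not in doc:
            raise ConfigError(f"{source}: missing required field {key!r}")
    try:
        dilution = float(doc["std_dilution"])
    except (TypeError, ValueError):
        raise ConfigError(
            f"{source}: field 'std_dilution' must be numeric, "
            f"got {doc['std_dilution']!r}"
        ) from None
    if not dilution > 1:
        raise ConfigError(f"{source}: field 'std_dilution' must be > 1, got {dilution}")
    analytes = doc["analytes"]
    if not isinstance(analytes, dict) or not analytes:
        raise ConfigError(f"{source}: field 'analytes' must be a non-empty mapping")
    groups: dict[str, dict[str, AnalyteEntry]] = {}
    seen: set[str] = set()
    for group_id, members in analytes.items():
        if not isinstance(members, dict) or not members:
            raise ConfigError(
                f"{source}: group {group_id!r} in 'analytes' must be a "
                "non-empty mapping of analyte IDs"
            )
        entries: dict[str, AnalyteEntry] = {}
        for analyte_id, info in members.items():
            aid = str(analyte_id)
            if aid in seen:
                raise ConfigError(f"{source}: duplicate analyte ID {aid!r}")
            seen.add(aid)
            if not isinstance(info, dict) or "name" not in info:
                raise ConfigError(
                    f"{source}: analyte {aid!r} must define field 'name'"
                )
            if "concentration" not in info:
                raise ConfigError(
                    f"{source}: analyte {aid!r} must define field 'concentration'"
                )
            conc = float(info["concentration"])
            if not conc > 0:
                raise ConfigError(
                    f"{source}: analyte {aid!r} field 'concentration' must be > 0"
                )
            entries[aid] = AnalyteEntry(name=str(info["name"]), start_concentration=conc)
        groups[str(group_id)] = entries
    return PanelInfo(
        panel_name=str(doc["panel_name"]),
        std_dilution=dilution,
        units=str(doc["units"]),
        groups=groups,
    )


def _packaged_panel_files() -> list:
    root = resources.files(__package__) / "panels"
    return sorted(
        (p for p in root.iterdir() if p.name.endswith((".yaml", ".yml"))),
        key=lambda p: p.name,
    )


def list_panels() -> pd.DataFrame:
    """Table of panels shipped with the package (file, panel_name)."""
    rows = []
    for p in _packaged_panel_files():
        doc = yaml.safe_load(p.read_text())
        rows.append({"file": p.name, "panel_name": doc.get("panel_name", "?")})
    return pd.DataFrame(rows, columns=["file", "panel_name"])


def load_panel(source: str | Path) -> PanelInfo:
    """Load Panel Information from a packaged panel or an external file.

    ``source`` is either a path to a YAML file, or a name pattern
    (case-insensitive substring/regex) matched against the names of the
    packaged panels; exactly one packaged panel must match.
    """
    path = Path(source)
    if path.suffix in (".yaml", ".yml") or path.exists():
        if not path.exists():
            raise ConfigError(f"panel file not found: {path}")
        doc = yaml.safe_load(path.read_text())
        return _validate_panel(doc, str(path))

    pattern = re.compile(str(source), re.IGNORECASE)
    matches = []
    for p in _packaged_panel_files():
        doc = yaml.safe_load(p.read_text())
        name = str(doc.get("panel_name", ""))
        if pattern.search(name):
            matches.append((name, doc, p))
    if len(matches) == 1:
        name, doc, p = matches[0]
        return _validate_panel(doc, p.name)
    candidates = [str(d.get("panel_name", f.name)) for _, d, f in matches] or [
        str(yaml.safe_load(p.read_text()).get("panel_name", p.name))
        for p in _packaged_panel_files()
    ]
    raise ConfigError(
        f"panel pattern {source!r} matched {len(matches)} packaged panels; "
        f"candidates: {candidates}"
    )


def as_analyte_table(panel: PanelInfo) -> pd.DataFrame:
    """Flatten a panel to one row per analyte, preserving order.

    Columns: ``analyte_id, group_id, name, start_concentration``; the
    join key for event/MFI tables is ``analyte_id``.
    """
    rows = [
        {
            "analyte_id": aid,
            "group_id": gid,
            "name": entry.name,
            "start_concentration": entry.start_concentration,
        }
        for gid, members in panel.groups.items()
        for aid, entry in members.items()
    ]
    return pd.DataFrame(
        rows, columns=["analyte_id", "group_id", "name", "start_concentration"]
    )
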