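"""Mapping cluster structure to bead and analyte identities.

Identification is positional: clusters are ranked by their centers along
the clustering channel(s) and assigned the caller's IDs in order, so the
ID list must be sorted the way the beads are -- for LEGENDplex-style
kits the lowest analyte ID has the lowest discrimination (APC)
intensity. The two-stage convenience wrapper first splits events into
bead groups on forward/side scatter, then resolves analytes within each
group on the discrimination channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import NOISE, ClusterParams, cluster_events, trim_cluster
from .errors import DataError
from .fcs_io import _require_channels
from .panel import PanelInfo

#: default annotation column names
BEAD_GROUP_COL = "bead_group"
ANALYTE_ID_COL = "analyte_id"


@dataclass(frozen=True)
class IdentStageArgs:
    """Arguments for one identification stage.

    ``parameters`` are the 1 or 2 channels to cluster on,
    ``column_name`` the annotation column written, and ``params`` the
    clustering settings (including the trim fraction).
    """

    parameters: tuple[str, ...]
    column_name: str
    params: ClusterParams

    def __post_init__(self):
        if not 1 <= len(self.parameters) <= 2:
            raise DataError(
                f"identification uses 1 or 2 channels, got {self.parameters!r}"
            )


def _rank_clusters(centers: np.ndarray) -> np.ndarray:
    """Cluster indices ordered ascending by first-axis center, ties by
    the following axes."""
    keys = tuple(centers[:, j] for j in reversed(range(centers.shape[1])))
    return np.lexsort(keys)


def _assign_ids(
    events: pd.DataFrame,
    labels: np.ndarray,
    order: np.ndarray,
    ids: Sequence[str],
    column_name: str,
) -> pd.DataFrame:
    id_of_cluster = {int(c): ids[pos] for pos, c in enumerate(order)}
    values = np.array(
        [id_of_cluster[l] if l != NOISE else None for l in labels], dtype=object
    )
    out = events.copy()
    out[column_name] = values
    assigned = int((labels != NOISE).sum())
    assert assigned + int((labels == NOISE).sum()) == len(events)
    return out


def identify_analyte(
    events: pd.DataFrame,
    parameters: Sequence[str] | str,
    analyte_ids: Sequence[str],
    params: ClusterParams,
    column_name: str = ANALYTE_ID_COL,
) -> pd.DataFrame:
    """Cluster events on the given channel(s) and assign IDs positionally.

    Clusters are trimmed by ``params.trim``, ranked ascending by center
    (first listed channel, ties broken by the second) and given
    ``analyte_ids`` in order -- the lowest-ranked cluster receives the
    first ID. Trimmed or noise events get a missing ID.
    """
    if isinstance(parameters, str):
        parameters = (parameters,)
    parameters = tuple(parameters)
    _require_channels(events, parameters)
    ids = list(analyte_ids)
    k = len(ids)
    # partitioning engines cluster into k groups; for dbscan, k is the
    # expected count checked against what the density scan finds
    params = replace(params, k=k)
    points = events[list(parameters)].to_numpy(dtype=float)
    result = cluster_events(points, params)
    if result.n_clusters != k:
        raise DataError(
            f"found {result.n_clusters} clusters but {k} analyte IDs were given"
        )
    labels = trim_cluster(points, result.labels, params.trim)
    order = _rank_clusters(result.centers)
    return _assign_ids(events, labels, order, ids, column_name)


def identify_legendplex_analyte(
    events: pd.DataFrame,
    panel: PanelInfo,
    scatter_args: IdentStageArgs | None = None,
    reporter_args: IdentStageArgs | None = None,
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-stage identification for size/granularity-grouped kits.

    Stage 1 clusters on forward/side scatter into the panel's bead
    groups; the group listed first in ``group_order`` (default: panel
    order) is assigned to the lowest-FSC cluster. Stage 2 reruns
    identification independently within each bead group on the
    discrimination channel, using that group's ordered analyte IDs.
    Events unassigned at either stage carry a missing ID downstream.
    """
    if not panel.groups:
        raise DataError("panel defines no bead groups")
    if scatter_args is None:
        scatter_args = IdentStageArgs(
            parameters=("FSC-A", "SSC-A"),
            column_name=BEAD_GROUP_COL,
            params=ClusterParams(method="clara", trim=0.01),
        )
    if reporter_args is None:
        reporter_args = IdentStageArgs(
            parameters=("FL6-H",),
            column_name=ANALYTE_ID_COL,
            params=ClusterParams(method="clara", trim=0.03),
        )
    if len(scatter_args.parameters) != 2:
        raise DataError("scatter stage needs exactly 2 channels (FSC, SSC)")
    if len(reporter_args.parameters) != 1:
        raise DataError("reporter stage needs exactly 1 discrimination channel")
    groups = list(group_order) if group_order is not None else panel.group_ids
    if sorted(groups) != sorted(panel.group_ids):
        raise DataError(
            f"group_order {groups} does not match panel groups {panel.group_ids}"
        )

    try:
        out = identify_analyte(
            events,
            scatter_args.parameters,
            groups,
            scatter_args.params,
            column_name=scatter_args.column_name,
        )
    except DataError as exc:
        raise DataError(f"scatter stage: {exc}") from exc

    out[reporter_args.column_name] = np.array([None] * len(out), dtype=object)
    for gid in groups:
        member_ids = list(panel.analytes_in(gid))
        mask = out[scatter_args.column_name].to_numpy() == gid
        sub = out.loc[mask]
        if len(sub) == 0:
            continue
        try:
            sub_assigned = identify_analyte(
                sub,
                reporter_args.parameters,
                member_ids,
                reporter_args.params,
                column_name=reporter_args.column_name,
            )
        except DataError as exc:
            raise DataError(f"reporter stage, bead group {gid!r}: {exc}") from exc
        out.loc[mask, reporter_args.column_name] = sub_assigned[
            reporter_args.column_name
        ].to_numpy()
    return out


def identify_grid_analyte(
    events: pd.DataFrame,
    parameters: Sequence[str],
    id_grid: Sequence[Sequence[str]],
    params: ClusterParams,
    column_name: str = ANALYTE_ID_COL,
) -> pd.DataFrame:
    """Positional identification on a 2-D intensity grid.

    For kits that discriminate beads by two fluorochromes the IDs come
    as rows of a grid: clusters are sorted by the first channel's center
    and chunked into rows of the given row lengths, then each row is
    sorted by the second channel's center, yielding a row-major
    assignment. A single-row grid therefore reduces to ranking on the
    second channel alone.
    """
    parameters = tuple(parameters)
    if len(parameters) != 2:
        raise DataError(f"grid identification needs exactly 2 channels, "
                        f"got {parameters!r}")
    _require_channels(events, parameters)
    rows = [list(r) for r in id_grid]
    ids_flat = [i for r in rows for i in r]
    k = len(ids_flat)
    if k == 0:
        raise DataError("id_grid is empty")
    params = replace(params, k=k)
    points = events[list(parameters)].to_numpy(dtype=float)
    result = cluster_events(points, params)
    if result.n_clusters != k:
        raise DataError(
            f"found {result.n_clusters} clusters but the ID grid has {k} cells"
        )
    labels = trim_cluster(points, result.labels, params.trim)

    by_first = np.argsort(result.centers[:, 0], kind="stable")
    order = []
    start = 0
    for row in rows:
        chunk = by_first[start : start + len(row)]
        chunk = chunk[np.argsort(result.centers[chunk, 1], kind="stable")]
        order.extend(int(c) for c in chunk)
        start += len(row)
    return _assign_ids(events, labels, np.asarray(order), ids_flat, column_name)
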