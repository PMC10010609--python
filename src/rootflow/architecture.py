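"""Branched root system architectures and their discretization.

Coordinate convention: every axial position is an arc-length distance to
a root tip, in meters. A lateral's ``insertion_position`` is the
distance from its *parent's* tip to the branching point; REV
``distance_to_tip`` is measured along the REV's own axis to that axis's
apex; razor-blade positions in :meth:`REVGraph.cut_at_distance` are
distances to the primary tip of the *intact* root (anatomical
coordinates, preserved through cuts).

Only a single primary axis (order 0) carrying first-order laterals
(order 1) is supported, matching young seminal root systems.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Axis",
    "RootSystem",
    "REVGraph",
    "CutSegmentSet",
    "DIAMETER_DEFAULTS",
    "ARCHITECTURE_COLUMNS",
    "read_architecture",
    "write_architecture",
    "reconstruct_from_cuts",
    "discretize",
    "cut_at_distance",
    "generate_synthetic_rsa",
]

#: Mean root diameters (m) by growth condition and root order, used when
#: a digitized architecture carries no diameter column.
DIAMETER_DEFAULTS = {
    "CTR": {0: 1.05e-3, 1: 0.36e-3},
    "PEG": {0: 1.03e-3, 1: 0.39e-3},
}

ARCHITECTURE_COLUMNS = [
    "axis_id",
    "parent_axis",
    "insertion_position_m",
    "length_m",
    "order",
    "diameter_m",
]


class ArchitectureError(ValueError):
    """Structural problem in a root system description."""


@dataclass
class Axis:
    """One root axis (primary or first-order lateral)."""

    axis_id: str
    parent_axis: Optional[str]  # None for the primary
    insertion_position: float  # m from the parent's tip (0 for primary)
    length: float  # m
    diameter: float  # m
    order: int  # 0 = primary, 1 = first-order lateral

    def __post_init__(self):
        if self.length <= 0:
            raise ArchitectureError(f"axis {self.axis_id}: length must be > 0")
        if self.diameter <= 0:
            raise ArchitectureError(f"axis {self.axis_id}: diameter must be > 0")
        if self.order not in (0, 1):
            raise ArchitectureError(
                f"axis {self.axis_id}: only orders 0 and 1 are supported"
            )
        if (self.parent_axis is None) != (self.order == 0):
            raise ArchitectureError(
                f"axis {self.axis_id}: order-0 axes must be parentless and laterals parented"
            )


class RootSystem:
    """A rooted tree of axes with exactly one primary."""

    def __init__(self, axes: Iterable[Axis], provenance: str = ""):
        self.axes: dict[str, Axis] = {}
        for ax in axes:
            if ax.axis_id in self.axes:
                raise ArchitectureError(f"duplicate axis_id {ax.axis_id!r}")
            self.axes[ax.axis_id] = ax
        self.provenance = provenance
        self._validate()

    def _validate(self):
        primaries = [a for a in self.axes.values() if a.order == 0]
        if len(primaries) != 1:
            raise ArchitectureError(
                f"expected exactly one primary axis, found {len(primaries)}"
            )
        for ax in self.axes.values():
            if ax.order == 0:
                continue
            parent = self.axes.get(ax.parent_axis)
            if parent is None:
                raise ArchitectureError(
                    f"lateral {ax.axis_id} references missing parent {ax.parent_axis!r}"
                )
            if ax.order != parent.order + 1:
                raise ArchitectureError(
                    f"lateral {ax.axis_id}: order must be parent order + 1"
                )
            if not 0.0 <= ax.insertion_position <= parent.length + 1e-12:
                raise ArchitectureError(
                    f"lateral {ax.axis_id}: insertion position "
                    f"{ax.insertion_position} outside parent length {parent.length}"
                )

    @property
    def primary(self) -> Axis:
        return next(a for a in self.axes.values() if a.order == 0)

    @property
    def laterals(self) -> list[Axis]:
        return [a for a in self.axes.values() if a.order == 1]

    @property
    def total_length(self) -> float:
        return sum(a.length for a in self.axes.values())

    def __len__(self) -> int:
        return len(self.axes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "axis_id": a.axis_id,
                "parent_axis": "" if a.parent_axis is None else a.parent_axis,
                "insertion_position_m": a.insertion_position,
                "length_m": a.length,
                "order": a.order,
                "diameter_m": a.diameter,
            }
            for a in self.axes.values()
        ]
        return pd.DataFrame(rows, columns=ARCHITECTURE_COLUMNS)


def read_architecture(source, condition: str = "CTR", provenance: str = "") -> RootSystem:
    """Read a per-axis table (SmartRoot-style CSV export) into a RootSystem.

    ``source`` is a path or a DataFrame with columns ``axis_id,
    parent_axis, insertion_position_m, length_m, order`` and optionally
    ``diameter_m``; missing diameters are filled from
    :data:`DIAMETER_DEFAULTS` for the given growth ``condition``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, float_precision="round_trip")
    required = ["axis_id", "parent_axis", "insertion_position_m", "length_m", "order"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ArchitectureError(f"missing architecture columns: {missing}")
    if condition not in DIAMETER_DEFAULTS:
        raise ValueError(f"unknown condition {condition!r}")
    defaults = DIAMETER_DEFAULTS[condition]
    axes = []
    for _, row in df.iterrows():
        order = int(row["order"])
        diam = row.get("diameter_m", np.nan)
        if diam is None or (isinstance(diam, float) and math.isnan(diam)):
            diam = defaults.get(order)
            if diam is None:
                raise ArchitectureError(f"no default diameter for order {order}")
        parent = row["parent_axis"]
        if parent is None or (isinstance(parent, float) and math.isnan(parent)) or parent == "":
            parent = None
        axes.append(
            Axis(
                axis_id=str(row["axis_id"]),
                parent_axis=None if parent is None else str(parent),
                insertion_position=float(row["insertion_position_m"]),
                length=float(row["length_m"]),
                diameter=float(diam),
                order=order,
            )
        )
    return RootSystem(axes, provenance=provenance)


def write_architecture(rs: RootSystem, path) -> None:
    rs.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class CutSegmentSet:
    """Digitized segments released by one blade stroke.

    ``primary_length`` is the length of the primary piece; ``laterals``
    is a sequence of ``(position_from_piece_tip, length)`` or
    ``(position_from_piece_tip, length, diameter)`` tuples, positions
    measured from the tip of this primary piece.
    """

    primary_length: float
    laterals: Sequence[tuple] = field(default_factory=list)

    def __post_init__(self):
        if self.primary_length is None or self.primary_length <= 0:
            raise ArchitectureError("cut set must contain a primary piece of positive length")


def reconstruct_from_cuts(
    cut_sets: Sequence[CutSegmentSet],
    basal_remainder: RootSystem,
    condition: str = "CTR",
) -> RootSystem:
    """Paste cut segment sets back onto the basal remainder.

    ``cut_sets`` are ordered from the first (most distal) to the last
    cut. Lateral insertion positions recorded relative to each piece's
    tip are re-offset by the cumulative primary length distal to that
    piece; the first piece's tip is the tip of the reconstructed root.
    The intact root is never scanned experimentally, so this pasting is
    the canonical way to obtain the pre-cut architecture.
    """
    defaults = DIAMETER_DEFAULTS[condition]
    old_primary = basal_remainder.primary
    distal_total = float(sum(cs.primary_length for cs in cut_sets))
    new_primary_length = old_primary.length + distal_total

    axes: list[Axis] = [
        Axis(
            axis_id=old_primary.axis_id,
            parent_axis=None,
            insertion_position=0.0,
            length=new_primary_length,
            diameter=old_primary.diameter,
            order=0,
        )
    ]
    # laterals already on the basal remainder: positions were recorded
    # relative to the remainder's (cut) tip -> offset by all pasted pieces
    for lat in basal_remainder.laterals:
        axes.append(
            Axis(
                axis_id=lat.axis_id,
                parent_axis=old_primary.axis_id,
                insertion_position=lat.insertion_position + distal_total,
                length=lat.length,
                diameter=lat.diameter,
                order=1,
            )
        )
    offset = 0.0
    for i, cs in enumerate(cut_sets):
        for j, rec in enumerate(cs.laterals):
            pos, length = rec[0], rec[1]
            diam = rec[2] if len(rec) > 2 else defaults[1]
            axes.append(
                Axis(
                    axis_id=f"cut{i}_lat{j}",
                    parent_axis=old_primary.axis_id,
                    insertion_position=pos + offset,
                    length=length,
                    diameter=diam,
                    order=1,
                )
            )
        offset += cs.primary_length
    return RootSystem(axes, provenance=f"reconstructed from {len(cut_sets)} cuts")


class REVGraph:
    """Discretized root: a tree of cylindrical representative elementary
    volumes (REVs) stored as flat arrays.

    Array attributes (length ``n_revs``): ``parent`` (index of the REV
    toward the base, −1 for the basal REV), ``length``, ``diameter``,
    ``dist_to_tip`` (REV center to its own axis's apex, anatomical,
    preserved through cuts), ``order``, ``axis_index``, ``is_cut_face``.
    Child REV indices are always greater than their parent's, so
    leaf-to-root orderings are simply descending index order.
    """

    def __init__(
        self,
        parent: np.ndarray,
        length: np.ndarray,
        diameter: np.ndarray,
        dist_to_tip: np.ndarray,
        order: np.ndarray,
        axis_index: np.ndarray,
        is_cut_face: np.ndarray,
        axis_meta: pd.DataFrame,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.diameter = np.asarray(diameter, dtype=float)
        self.dist_to_tip = np.asarray(dist_to_tip, dtype=float)
        self.order = np.asarray(order, dtype=np.int64)
        self.axis_index = np.asarray(axis_index, dtype=np.int64)
        self.is_cut_face = np.asarray(is_cut_face, dtype=bool)
        #: per-axis table: axis_id, parent (-1 for primary), order,
        #: original_length, attach_primary_dtt (insertion position of the
        #: lateral on the primary, anatomical; nan for the primary)
        self.axis_meta = axis_meta
        self._validate()

    def _validate(self):
        n = len(self.parent)
        basal = np.flatnonzero(self.parent < 0)
        if len(basal) != 1:
            raise ArchitectureError("REVGraph must have exactly one basal REV")
        if n and not np.all(self.parent[1:] < np.arange(1, n)):
            raise ArchitectureError("REV parents must precede children")

    @property
    def n_revs(self) -> int:
        return len(self.parent)

    @property
    def basal_rev(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def surface(self) -> np.ndarray:
        """Lateral (cylindrical) surface π·d·l of each REV, m²."""
        return np.pi * self.diameter * self.length

    @property
    def total_length(self) -> float:
        return float(self.length.sum())

    @property
    def total_surface(self) -> float:
        return float(self.surface.sum())

    @property
    def primary_axis_length(self) -> float:
        """Original (pre-cut) primary axis length."""
        return float(self.axis_meta.loc[self.axis_meta["order"] == 0, "original_length"].iloc[0])

    def children_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR adjacency (ptr, idx) of child REVs per REV."""
        n = self.n_revs
        counts = np.bincount(self.parent[self.parent >= 0], minlength=n)
        ptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=ptr[1:])
        idx = np.empty(max(int(ptr[-1]), 1), dtype=np.int64)
        fill = ptr[:-1].copy()
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                idx[fill[p]] = i
                fill[p] += 1
        return ptr, idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rev_id": np.arange(self.n_revs),
                "parent_rev": self.parent,
                "axis_index": self.axis_index,
                "order": self.order,
                "length_m": self.length,
                "diameter_m": self.diameter,
                "distance_to_tip_m": self.dist_to_tip,
                "is_cut_face": self.is_cut_face,
            }
        )

    # -- cutting ------------------------------------------------------

    def cut_at_distance(self, x_blade: float, lateral_mode: str = "stretched") -> "REVGraph":
        """Excise the root distal to a razor blade at ``x_blade`` meters
        from the intact primary tip.

        With ``lateral_mode="stretched"`` (the experimental convention:
        laterals are stretched and aligned tipward along the primary
        before cutting) a lateral attached at primary coordinate ``p``
        with original length ``L`` spans primary coordinates
        ``[p − L, p]`` and the blade keeps its basal ``p − x_blade``.
        ``lateral_mode="own_distance"`` instead removes lateral REVs by
        their own distance to their own tip — the main geometric
        alternative when laterals cannot be assumed aligned. Newly
        opened distal xylem surfaces are flagged ``is_cut_face``.
        Anatomical ``dist_to_tip`` values are preserved, so the
        operation is idempotent for equal blade positions.
        """
        if lateral_mode not in ("stretched", "own_distance"):
            raise ValueError(f"unknown lateral_mode {lateral_mode!r}")
        meta = self.axis_meta
        primary_len = self.primary_axis_length
        if x_blade <= 0:
            raise ValueError("blade position must be > 0")
        if x_blade >= primary_len:
            raise ValueError(
                f"blade at {x_blade} m would leave no primary root "
                f"(remaining primary length {primary_len} m)"
            )
        keep = np.ones(self.n_revs, dtype=bool)
        cut_now = np.zeros(len(meta), dtype=bool)
        for ai in range(len(meta)):
            on_axis = self.axis_index == ai
            if not on_axis.any():
                continue
            if meta.at[ai, "order"] == 0:
                rm = on_axis & (self.dist_to_tip < x_blade)
            elif lateral_mode == "own_distance":
                p = float(meta.at[ai, "attach_primary_dtt"])
                if p <= x_blade:
                    rm = on_axis  # attachment point itself is excised
                else:
                    rm = on_axis & (self.dist_to_tip < x_blade)
            else:
                p = float(meta.at[ai, "attach_primary_dtt"])
                L = float(meta.at[ai, "original_length"])
                kept_len = p - x_blade
                if kept_len <= 0:
                    rm = on_axis
                elif kept_len >= L:
                    rm = np.zeros(self.n_revs, dtype=bool)
                else:
                    # remove REVs whose center lies beyond the kept basal part
                    rm = on_axis & (self.dist_to_tip < L - kept_len)
            if rm.any():
                keep &= ~rm
                cut_now[ai] = True
        if not keep[self.basal_rev]:
            raise ValueError("blade position removes the basal REV")

        old_idx = np.flatnonzero(keep)
        remap = -np.ones(self.n_revs, dtype=np.int64)
        remap[old_idx] = np.arange(len(old_idx))
        new_parent = self.parent[old_idx].copy()
        pos = new_parent >= 0
        new_parent[pos] = remap[new_parent[pos]]
        if np.any(new_parent[pos] < 0):
            raise ArchitectureError("cut disconnected the graph")  # pragma: no cover
        flags = self.is_cut_face[old_idx].copy()
        axis_idx = self.axis_index[old_idx]
        dtt = self.dist_to_tip[old_idx]
        for ai in np.flatnonzero(cut_now):
            on_axis = np.flatnonzero(axis_idx == ai)
            if len(on_axis):
                distal = on_axis[np.argmin(dtt[on_axis])]
                flags[distal] = True
        return REVGraph(
            parent=new_parent,
            length=self.length[old_idx],
            diameter=self.diameter[old_idx],
            dist_to_tip=dtt,
            order=self.order[old_idx],
            axis_index=axis_idx,
            is_cut_face=flags,
            axis_meta=meta,
        )


def cut_at_distance(g: REVGraph, x_blade: float, lateral_mode: str = "stretched") -> REVGraph:
    """Functional alias for :meth:`REVGraph.cut_at_distance`."""
    return g.cut_at_distance(x_blade, lateral_mode=lateral_mode)


def discretize(rs: RootSystem, l_target: float = 1e-3) -> REVGraph:
    """Split each axis into ``ceil(length / l_target)`` equal-length REVs.

    Lateral base REVs become children of the primary REV whose span
    contains the insertion position; junctions carry no extra
    resistance. The default 1 mm REV length is of the order of the
    primary root diameter, small enough for numerical convergence of
    basal flow.
    """
    if l_target <= 0:
        raise ValueError("l_target must be > 0")
    prim = rs.primary
    axes_sorted = [prim] + sorted(rs.laterals, key=lambda a: a.axis_id)

    parent_l, length_l, diam_l, dtt_l, order_l, axisidx_l = [], [], [], [], [], []
    meta_rows = []
    # primary chain, base -> apex
    n0 = max(1, math.ceil(prim.length / l_target - 1e-12))
    l0 = prim.length / n0
    axis_start = {}
    for i in range(n0):
        parent_l.append(i - 1)
        length_l.append(l0)
        diam_l.append(prim.diameter)
        dtt_l.append(prim.length - (i + 0.5) * l0)
        order_l.append(0)
        axisidx_l.append(0)
    axis_start[prim.axis_id] = 0
    meta_rows.append(
        {
            "axis_id": prim.axis_id,
            "parent": -1,
            "order": 0,
            "original_length": prim.length,
            "attach_primary_dtt": np.nan,
        }
    )
    for ai, lat in enumerate(axes_sorted[1:], start=1):
        p = lat.insertion_position  # distance from the primary tip
        # primary REV index (base->apex) whose span contains p
        j = int(min(max(math.floor((prim.length - p) / l0), 0), n0 - 1))
        nl = max(1, math.ceil(lat.length / l_target - 1e-12))
        ll = lat.length / nl
        start = len(parent_l)
        for i in range(nl):
            parent_l.append(j if i == 0 else start + i - 1)
            length_l.append(ll)
            diam_l.append(lat.diameter)
            dtt_l.append(lat.length - (i + 0.5) * ll)
            order_l.append(1)
            axisidx_l.append(ai)
        meta_rows.append(
            {
                "axis_id": lat.axis_id,
                "parent": 0,
                "order": 1,
                "original_length": lat.length,
                "attach_primary_dtt": p,
            }
        )
    return REVGraph(
        parent=np.array(parent_l, dtype=np.int64),
        length=np.array(length_l),
        diameter=np.array(diam_l),
        dist_to_tip=np.array(dtt_l),
        order=np.array(order_l, dtype=np.int64),
        axis_index=np.array(axisidx_l, dtype=np.int64),
        is_cut_face=np.zeros(len(parent_l), dtype=bool),
        axis_meta=pd.DataFrame(meta_rows),
    )


def generate_synthetic_rsa(
    primary_length: float = 0.30,
    lateral_density: float = 70.0,
    lateral_length_law: tuple[float, float] = (0.04, 0.015),
    seed: Optional[int] = None,
    apical_zone: float = 0.02,
    condition: str = "CTR",
    placement: str = "poisson",
    min_lateral_length: float = 0.005,
) -> RootSystem:
    """Generate a reproducible synthetic root system.

    Laterals are placed along the primary by a Poisson process of
    intensity ``lateral_density`` (m⁻¹) on the branched zone — the
    primary minus an apical unbranched zone — with lengths drawn from a
    normal law ``(mean, sd)`` truncated at ``min_lateral_length``.
    Defaults emulate an 11-day-old hydroponic maize seminal root:
    ~0.3 m primary bearing ~20 first-order laterals.
    """
    if primary_length <= 0 or lateral_density < 0 or apical_zone < 0:
        raise ValueError("generator arguments must be positive")
    rng = np.random.default_rng(seed)
    defaults = DIAMETER_DEFAULTS[condition]
    axes = [
        Axis("primary", None, 0.0, primary_length, defaults[0], 0),
    ]
    branchable = max(primary_length - apical_zone, 0.0)
    if lateral_density > 0 and branchable > 0:
        if placement == "poisson":
            n_lat = rng.poisson(lateral_density * branchable)
        elif placement == "uniform":
            n_lat = int(round(lateral_density * branchable))
        else:
            raise ValueError(f"unknown placement {placement!r}")
        positions = np.sort(rng.uniform(apical_zone, primary_length, size=n_lat))
        mean, sd = lateral_length_law
        lengths = np.clip(rng.normal(mean, sd, size=n_lat), min_lateral_length, None)
        for i, (pos, ln) in enumerate(zip(positions, lengths)):
            axes.append(Axis(f"lat{i:03d}", "primary", float(pos), float(ln), defaults[1], 1))
    return RootSystem(axes, provenance=f"synthetic(seed={seed})")
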