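"""Combined RGC + myelinated optic-nerve-fibre morphologies.

A fibre is a single unbranched compartment chain

    dendrites -- soma -- AH -- AIS -- DA -- [node, 2xPN, 2xJN, 6xIN]* -- node

running parallel to the nerve's longitudinal (z) axis.  The dendritic tree is
a surrogate: a symmetric branched arbour represented as an equivalent chain
whose compartments carry a branch-multiplicity factor (membrane area and
axial conductance are multiplied by the number of identical branches at that
depth).  This is exact for a symmetric tree in a locally uniform field, which
holds here because the dendrites sit ~5 mm from the nerve electrodes.

ON and OFF cells differ only in the axon-hillock height H (OFF = ON + 40 um);
everything else, including the myelinated axon fibre (MAF), is shared.

MAF geometry follows the MRG double-cable segmentation: each node-to-node
unit is node, PN (paranode), JN (juxtaparanode), 6x IN (internode), JN, PN.
Per-diameter dimensions come from a small table linearly interpolated in
fibre diameter; the three tabulated diameters 1.4 / 2.8 / 4.3 um are the
modal diameters of the rat optic nerve fibre-size groups, carrying natural
abundance weights 0.903 / 0.094 / 0.003.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Compartment",
    "FibreSpec",
    "FibreModel",
    "DIAMETER_WEIGHTS",
    "FIBRE_DIAMETERS_UM",
    "MAF_GEOMETRY_TABLE",
    "maf_geometry",
    "internodal_distance_um",
    "build_rgc_front_end",
    "build_maf",
    "build_fibre",
    "place_fibre",
    "grid_positions",
    "fibre_to_text",
    "fibre_from_text",
    "NODE_A_Z_UM",
]

FRONT_END_REGIONS = ("dendrite", "soma", "AH", "AIS", "DA")
MAF_REGIONS = ("node", "PN", "JN", "IN")
REGION_ORDER = FRONT_END_REGIONS + MAF_REGIONS

#: Rat optic-nerve fibre-diameter classes (um) and abundance weights.
FIBRE_DIAMETERS_UM = (1.4, 2.8, 4.3)
DIAMETER_WEIGHTS = {1.4: 0.903, 2.8: 0.094, 4.3: 0.003}

#: First node of Ranvier (node A): 0.8 mm from the soma, i.e. 4.2 mm proximal
#: to the interference electrode at 5 mm.
NODE_A_Z_UM = 800.0

Z_SHIFTS = (0.0, 0.25, 0.5)


@dataclass(frozen=True)
class Compartment:
    """One cable compartment.

    ``n_branches`` > 1 marks equivalent-tree dendrite compartments; membrane
    area and axial conductance scale by it.  ``lamellae`` is the myelin wrap
    count (0 for unmyelinated regions).
    """

    region: str
    length_um: float
    diameter_um: float
    path_pos_um: float  # midpoint position along the chain, soma centre = 0
    midpoint_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    myelinated: bool = False
    n_branches: int = 1
    lamellae: int = 0

    def __post_init__(self) -> None:
        if self.region not in REGION_ORDER:
            raise ValueError(f"unknown region tag {self.region!r}")
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError("compartment length and diameter must be > 0")
        if self.myelinated and self.region not in ("PN", "JN", "IN"):
            raise ValueError(f"region {self.region!r} may not be myelinated")
        if self.region == "node" and self.myelinated:
            raise ValueError("nodes of Ranvier are never myelinated")

    @property
    def area_um2(self) -> float:
        """Membrane (axolemma) area including branch multiplicity."""
        return float(np.pi * self.diameter_um * self.length_um * self.n_branches)


@dataclass(frozen=True)
class FibreSpec:
    """Where a fibre sits and which class it belongs to."""

    cell_type: str  # "ON" | "OFF"
    d_f_um: float
    x_um: float = 0.0
    y_um: float = 0.0
    z_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_type not in ("ON", "OFF"):
            raise ValueError("cell_type must be 'ON' or 'OFF'")
        if self.d_f_um not in FIBRE_DIAMETERS_UM:
            raise ValueError(f"d_f must be one of {FIBRE_DIAMETERS_UM}")
        if self.z_shift not in Z_SHIFTS:
            raise ValueError(f"z_shift must be one of {Z_SHIFTS}")

    @property
    def weight(self) -> float:
        return DIAMETER_WEIGHTS[self.d_f_um]


# ---------------------------------------------------------------------------
# MAF geometry table
# ---------------------------------------------------------------------------

#: Per-diameter MRG-style dimensions, linearly interpolated in d_f.
#: Columns: fibre diameter D2f (um) -> dict of
#:   inl: node-to-node (internodal) distance, um
#:   d_node: nodal diameter D1, um
#:   d_axon: axon diameter under the myelin, um (g-ratio ~ 0.7)
#:   l_node, l_pn, l_jn: segment lengths, um (6 IN segments fill the rest)
#:   lamellae: myelin wrap count
#: Built from standard small-fibre scalings (internodal distance ~ 100 x d_f)
#: and constrained so each unit is node + 2 PN + 2 JN + 6 IN. Synthetic table
#: standing in for a digitised literature interpolation.
MAF_GEOMETRY_TABLE = {
    1.4: {"inl": 140.0, "d_node": 0.50, "d_axon": 0.98, "l_node": 1.0,
          "l_pn": 3.0, "l_jn": 7.0, "lamellae": 12},
    2.8: {"inl": 280.0, "d_node": 1.00, "d_axon": 1.96, "l_node": 1.0,
          "l_pn": 3.0, "l_jn": 14.0, "lamellae": 24},
    4.3: {"inl": 430.0, "d_node": 1.50, "d_axon": 3.01, "l_node": 1.0,
          "l_pn": 3.0, "l_jn": 21.5, "lamellae": 37},
}


def maf_geometry(d_f_um: float) -> dict:
    """Interpolated MAF dimensions for a fibre diameter inside the table range."""
    keys = sorted(MAF_GEOMETRY_TABLE)
    if not keys[0] <= d_f_um <= keys[-1]:
        raise ValueError(
            f"fibre diameter {d_f_um} um outside table range "
            f"[{keys[0]}, {keys[-1]}]; extrapolation is not supported"
        )
    out = {}
    for name in ("inl", "d_node", "d_axon", "l_node", "l_pn", "l_jn", "lamellae"):
        ys = [MAF_GEOMETRY_TABLE[k][name] for k in keys]
        v = float(np.interp(d_f_um, keys, ys))
        out[name] = int(round(v)) if name == "lamellae" else v
    out["l_in"] = (out["inl"] - out["l_node"] - 2 * out["l_pn"] - 2 * out["l_jn"]) / 6.0
    if out["l_in"] <= 0:
        raise ValueError(f"degenerate geometry at d_f={d_f_um}")
    return out


def internodal_distance_um(d_f_um: float) -> float:
    return maf_geometry(d_f_um)["inl"]


# ---------------------------------------------------------------------------
# Fibre model
# ---------------------------------------------------------------------------


@dataclass
class FibreModel:
    """Ordered compartment chain with landmark indices."""

    compartments: list[Compartment]
    cell_type: str
    d_f_um: float
    index_ais_centre: int
    index_node_a: int
    index_node_b: int
    table_version: str = "finblock-maf-1"
    placed: bool = False
    spec: FibreSpec | None = None

    def __len__(self) -> int:
        return len(self.compartments)

    @property
    def regions(self) -> list[str]:
        return [c.region for c in self.compartments]

    @property
    def midpoints_um(self) -> np.ndarray:
        return np.array([c.midpoint_um for c in self.compartments])

    @property
    def node_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.compartments)
                         if c.region == "node"])

    def path_positions(self) -> np.ndarray:
        return np.array([c.path_pos_um for c in self.compartments])


def _chain(segments: Iterable[tuple[str, float, float, int, int]],
           start_um: float) -> list[Compartment]:
    """Lay segments end-to-end; returns compartments with path midpoints."""
    out = []
    z = start_um
    for region, length, diam, nbranch, lam in segments:
        out.append(Compartment(
            region=region, length_um=length, diameter_um=diam,
            path_pos_um=z + length / 2.0,
            myelinated=region in ("PN", "JN", "IN"),
            n_branches=nbranch, lamellae=lam,
        ))
        z += length
    return out


# Front-end default dimensions (um).  The dendritic arbour has a 400 um field
# diameter (200 um path length per branch) with 4 primary branches splitting
# to 8 and 16 with tapering calibre; soma 20 um; AIS 40 um; the DA runs to
# the first node at NODE_A_Z_UM.
DENDRITE_FIELD_DIAMETER_UM = 400.0
DENDRITE_BRANCH_COUNTS = (4, 2, 1)  # terminal, intermediate, primary
AH_HEIGHT_ON_UM = 40.0
AH_HEIGHT_OFF_UM = 80.0
SOMA_DIAMETER_UM = 20.0
AIS_LENGTH_UM = 40.0
AXON_FRONT_DIAMETER_UM = 1.2


def build_rgc_front_end(cell_type: str) -> list[Compartment]:
    """Dendrites, soma, AH, AIS and DA for an ON or OFF cell.

    The chain is returned in proximal-to-distal order starting at the distal
    dendrite tip; the soma centre defines path position 0.  Only the AH
    height differs between cell types (OFF is 40 um taller).
    """
    if cell_type not in ("ON", "OFF"):
        raise ValueError("cell_type must be 'ON' or 'OFF'")
    h_ah = AH_HEIGHT_ON_UM if cell_type == "ON" else AH_HEIGHT_OFF_UM

    radius = DENDRITE_FIELD_DIAMETER_UM / 2.0
    seg = radius / 10.0  # 10 dendritic compartments per branch path
    distal, mid, prox = DENDRITE_BRANCH_COUNTS
    dend = []
    # distal -> proximal: thin terminal branches down to thick primaries
    for _ in range(4):
        dend.append(("dendrite", seg, 0.8, distal, 0))
    for _ in range(3):
        dend.append(("dendrite", seg, 1.2, mid, 0))
    for _ in range(3):
        dend.append(("dendrite", seg, 2.0, prox, 0))

    segs = list(dend)
    segs.append(("soma", SOMA_DIAMETER_UM, SOMA_DIAMETER_UM, 1, 0))
    n_ah = max(int(round(h_ah / 10.0)), 1)
    for _ in range(n_ah):
        segs.append(("AH", h_ah / n_ah, 3.0, 1, 0))
    for _ in range(4):
        segs.append(("AIS", AIS_LENGTH_UM / 4.0, AXON_FRONT_DIAMETER_UM, 1, 0))
    # DA runs from the AIS end to the leading face of node A (length 1 um),
    # so its extent absorbs the ON/OFF hillock-height difference
    axon_start = SOMA_DIAMETER_UM / 2.0 + h_ah + AIS_LENGTH_UM
    da_length = (NODE_A_Z_UM - 0.5) - axon_start
    if da_length <= 0:
        raise ValueError("front end longer than the node-A distance")
    n_da = max(int(round(da_length / 25.0)), 1)
    for _ in range(n_da):
        segs.append(("DA", da_length / n_da, AXON_FRONT_DIAMETER_UM, 1, 0))

    start = -(radius + SOMA_DIAMETER_UM / 2.0)  # soma centre lands at 0
    return _chain(segs, start)


def build_maf(d_f_um: float, nerve_length_mm: float = 10.0) -> list[Compartment]:
    """Myelinated axon fibre: repeating node + 2 PN + 2 JN + 6 IN units.

    The chain starts at node A (path position ``NODE_A_Z_UM``) and contains
    ``floor(nerve_length / internodal_distance) + 1`` nodes, so each
    node-to-node unit has exactly 10 non-nodal compartments.
    """
    g = maf_geometry(d_f_um)
    nerve_um = nerve_length_mm * 1000.0
    n_nodes = int(np.floor(nerve_um / g["inl"])) + 1
    lam = g["lamellae"]
    unit = (
        [("PN", g["l_pn"], d_f_um, 1, lam)]
        + [("JN", g["l_jn"], d_f_um, 1, lam)]
        + [("IN", g["l_in"], d_f_um, 1, lam)] * 6
        + [("JN", g["l_jn"], d_f_um, 1, lam)]
        + [("PN", g["l_pn"], d_f_um, 1, lam)]
    )
    node = ("node", g["l_node"], g["d_node"], 1, 0)
    segs = [node]
    for _ in range(n_nodes - 1):
        segs.extend(unit)
        segs.append(node)
    return _chain(segs, NODE_A_Z_UM - g["l_node"] / 2.0)


def build_fibre(cell_type: str, d_f_um: float,
                nerve_length_mm: float = 10.0) -> FibreModel:
    """Full RGC + optic-nerve fibre chain (unplaced: midpoints not yet set)."""
    front = build_rgc_front_end(cell_type)
    maf = build_maf(d_f_um, nerve_length_mm)
    comps = front + maf
    ais = [i for i, c in enumerate(comps) if c.region == "AIS"]
    nodes = [i for i, c in enumerate(comps) if c.region == "node"]
    return FibreModel(
        compartments=comps,
        cell_type=cell_type,
        d_f_um=d_f_um,
        index_ais_centre=ais[len(ais) // 2],
        index_node_a=nodes[0],
        index_node_b=nodes[-1],
    )


def place_fibre(model: FibreModel, spec: FibreSpec,
                electrode_z_mm: float = 5.0,
                grid=None) -> FibreModel:
    """Assign 3D midpoints for a fibre at a grid position with a z-shift.

    The fibre runs parallel to the z axis through ``(x, y)``.  The whole
    chain is translated rigidly so that at ``z_shift = 0`` the node nearest
    the interference electrode is centred on it, and a shift ``s`` moves the
    fibre by ``s x internodal distance`` (so the same shift value maps to
    different absolute offsets for different diameters).
    """
    if model.d_f_um != spec.d_f_um:
        raise ValueError("spec diameter does not match the built model")
    elec_z = electrode_z_mm * 1000.0
    inl = internodal_distance_um(spec.d_f_um)
    node_z = np.array([model.compartments[i].path_pos_um
                       for i in model.node_indices])
    nearest = node_z[np.argmin(np.abs(node_z - elec_z))]
    shift = (elec_z - nearest) + spec.z_shift * inl

    placed = [replace(c, midpoint_um=(spec.x_um, spec.y_um, c.path_pos_um + shift))
              for c in model.compartments]
    out = replace(model, compartments=placed, placed=True, spec=spec)
    if grid is not None:
        lo = np.asarray(grid.origin_um)
        hi = np.asarray(grid.upper_um)
        nb = np.asarray(placed[model.index_node_b].midpoint_um)
        if np.any(nb < lo) or np.any(nb > hi):
            raise ValueError(
                f"placement puts node B at {tuple(nb)}, outside the solved "
                f"field grid [{tuple(lo)} .. {tuple(hi)}]"
            )
    return out


def grid_positions(cell_um: float = 40.0, n_cells: int = 6) -> list[tuple[float, float]]:
    """Cell centres of the simulated cross-section quadrant.

    Default: a 6 x 6 grid of 40 x 40 um cells with centres at
    20, 60, ..., 220 um; only the x >= 0, y >= 0 quadrant is needed because
    the field geometry is symmetric about the nerve axis.
    """
    centres = [cell_um / 2.0 + i * cell_um for i in range(n_cells)]
    return [(x, y) for x in centres for y in centres]


# ---------------------------------------------------------------------------
# Plain-text serialization (one compartment per record)
# ---------------------------------------------------------------------------


def fibre_to_text(model: FibreModel, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# finblock fibre {model.cell_type} d_f={model.d_f_um} "
                 f"table={model.table_version}\n")
        fh.write(f"# ais_centre={model.index_ais_centre} "
                 f"node_a={model.index_node_a} node_b={model.index_node_b}\n")
        fh.write("# region length_um diam_um path_um x y z myelinated "
                 "n_branches lamellae\n")
        for c in model.compartments:
            x, y, z = c.midpoint_um
            fh.write(
                f"{c.region} {c.length_um:.17g} {c.diameter_um:.17g} "
                f"{c.path_pos_um:.17g} {x:.17g} {y:.17g} {z:.17g} "
                f"{int(c.myelinated)} {c.n_branches} {c.lamellae}\n"
            )
    return path


def fibre_from_text(path: str | Path) -> FibreModel:
    path = Path(path)
    comps = []
    header = {}
    cell_type, d_f = "ON", 1.4
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            toks = line[1:].split()
            if toks and toks[0] == "finblock":
                cell_type = toks[2]
                d_f = float(toks[3].split("=")[1])
            for t in toks:
                if "=" in t:
                    k, _, v = t.partition("=")
                    header[k] = v
            continue
        p = line.split()
        if len(p) != 10:
            raise ValueError(f"{path}:{lineno}: expected 10 fields, got {len(p)}")
        comps.append(Compartment(
            region=p[0], length_um=float(p[1]), diameter_um=float(p[2]),
            path_pos_um=float(p[3]),
            midpoint_um=(float(p[4]), float(p[5]), float(p[6])),
            myelinated=bool(int(p[7])), n_branches=int(p[8]),
            lamellae=int(p[9]),
        ))
    return FibreModel(
        compartments=comps, cell_type=cell_type, d_f_um=d_f,
        index_ais_centre=int(header.get("ais_centre", 0)),
        index_node_a=int(header.get("node_a", 0)),
        index_node_b=int(header.get("node_b", len(comps) - 1)),
        placed=True,
    )
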