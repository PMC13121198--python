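"""Quasi-static extracellular potential maps for bipolar nerve-cuff style electrodes.

The optic nerve is modelled as a stack of concentric resistive layers
(nerve-fibre space, pia, CSF, dura, fat, optional surround) inside a box that
is solved with a structured-grid finite-difference discretisation of the
current-conservation equation ``div(sigma grad V) = 0``.  The interference
electrode is a 200 um disc treated as an ideal current source (Neumann
condition, 1 uA total) and the reference disc is held at ground (Dirichlet).
Solutions are stored per unit current (mV per uA) and scaled linearly at run
time -- tissue is treated as purely resistive, so the field follows the
electrode current instantaneously.

An analytic point source/sink pair in an infinite homogeneous medium is
provided as an independent oracle for the finite-difference solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import cg, spsolve

__all__ = [
    "Layer",
    "ConductivityProfile",
    "ElectrodeSpec",
    "GridSpec",
    "PotentialMap",
    "default_profile",
    "default_electrodes",
    "solve_bipolar_field",
    "analytic_bipolar_field",
    "interpolate_potentials",
    "export_map",
    "import_map",
    "PENETRATION_DEPTH_UM",
]

#: Distance from the outer fat surface to the nerve midline: the electrode
#: penetration depth, i.e. nerve-fibre-space radius + pia + CSF + dura + fat.
PENETRATION_DEPTH_UM = 283.47


class FieldError(RuntimeError):
    """Raised when the finite-difference system cannot be solved."""


@dataclass(frozen=True)
class Layer:
    """One resistive tissue layer.

    ``thickness_um`` is the radial extent of the layer; for the innermost
    entry (the nerve-fibre space) it is the cylinder radius.
    """

    name: str
    thickness_um: float
    sigma: float  # S/m

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if self.sigma <= 0:
            raise ValueError(f"layer {self.name!r}: conductivity must be > 0")


@dataclass(frozen=True)
class ConductivityProfile:
    """Layered cylindrical nerve, ordered outward from the fibre space."""

    layers: tuple[Layer, ...]
    nerve_length_mm: float = 10.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("profile needs at least one layer")

    @property
    def penetration_depth_um(self) -> float:
        """Radius of the outer fat surface (surround excluded)."""
        core = [l for l in self.layers if l.name != "surround"]
        return float(sum(l.thickness_um for l in core))

    @property
    def outer_radius_um(self) -> float:
        return float(sum(l.thickness_um for l in self.layers))

    def radial_boundaries(self) -> np.ndarray:
        return np.cumsum([l.thickness_um for l in self.layers])

    def sigma_at_radius(self, r_um: np.ndarray) -> np.ndarray:
        """Conductivity as a function of distance from the nerve axis.

        Radii beyond the outermost layer keep that layer's conductivity,
        matching the insulating outer box boundary of the solver.
        """
        bounds = self.radial_boundaries()
        idx = np.searchsorted(bounds, np.asarray(r_um, dtype=float), side="left")
        idx = np.clip(idx, 0, len(self.layers) - 1)
        sigmas = np.array([l.sigma for l in self.layers])
        return sigmas[idx]

    def homogenised(self, sigma: float) -> "ConductivityProfile":
        """Every layer set to one conductivity (analytic-limit checks)."""
        return replace(
            self,
            layers=tuple(replace(l, sigma=sigma) for l in self.layers),
        )


def default_profile(surround: Layer | None = None) -> ConductivityProfile:
    """Murine optic-nerve layer stack.

    Thicknesses sum to the 283.47 um electrode penetration depth.
    Conductivities are standard tissue values: nerve fibre space treated as
    isotropic white matter, highly conductive CSF, resistive dura/fat.
    """
    layers = [
        Layer("nerve_fibre_space", 230.0, 0.57),
        Layer("pia", 10.0, 0.17),
        Layer("csf", 20.0, 1.70),
        Layer("dura", 15.0, 0.06),
        Layer("fat", 8.47, 0.04),
    ]
    if surround is not None:
        layers.append(replace(surround, name="surround"))
    return ConductivityProfile(tuple(layers))


@dataclass(frozen=True)
class ElectrodeSpec:
    """Planar disc electrode, centre on the nerve axis.

    The disc normal is perpendicular to the nerve (z) axis by convention, so
    the conductive face lies in a plane that contains the longitudinal axis.
    """

    centre_um: tuple[float, float, float]
    diameter_um: float = 200.0
    role: str = "current_source"  # or "ground"
    normal: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        if self.role not in ("current_source", "ground"):
            raise ValueError(f"unknown electrode role {self.role!r}")
        n = np.asarray(self.normal, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0):
            raise ValueError("electrode normal must be a unit vector")


def default_electrodes(
    interference_z_mm: float = 5.0, reference_z_mm: float = 6.0
) -> tuple[ElectrodeSpec, ElectrodeSpec]:
    """Bipolar pair: interference disc 5 mm from the soma, reference 6 mm."""
    src = ElectrodeSpec((0.0, 0.0, interference_z_mm * 1000.0), role="current_source")
    gnd = ElectrodeSpec((0.0, 0.0, reference_z_mm * 1000.0), role="ground")
    return src, gnd


@dataclass(frozen=True)
class GridSpec:
    """Regular axis-aligned grid: origin + spacing + point counts."""

    origin_um: tuple[float, float, float]
    spacing_um: tuple[float, float, float]
    shape: tuple[int, int, int]

    @classmethod
    def from_bounds(
        cls,
        lo: Sequence[float],
        hi: Sequence[float],
        spacing: float | Sequence[float],
    ) -> "GridSpec":
        sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        n = np.maximum(np.round((hi - lo) / sp).astype(int) + 1, 2)
        return cls(tuple(lo), tuple(sp), tuple(int(v) for v in n))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin_um[i] + self.spacing_um[i] * np.arange(self.shape[i])
            for i in range(3)
        )

    @property
    def upper_um(self) -> tuple[float, float, float]:
        return tuple(
            self.origin_um[i] + self.spacing_um[i] * (self.shape[i] - 1)
            for i in range(3)
        )

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class PotentialMap:
    """3D regular-grid potential in mV per uA of electrode current."""

    grid: GridSpec
    values: np.ndarray  # shape == grid.shape, mV/uA
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential map contains non-finite values")

    def interpolate(self, points_um: np.ndarray) -> np.ndarray:
        return interpolate_potentials(self, points_um)

    def scaled(self, current_ua: float) -> "PotentialMap":
        return PotentialMap(
            self.grid,
            self.values * current_ua,
            {**self.metadata, "current_ua": current_ua},
        )


# ---------------------------------------------------------------------------
# Electrode discretisation helpers
# ---------------------------------------------------------------------------


def _disc_node_mask(grid: GridSpec, elec: ElectrodeSpec) -> np.ndarray:
    """Boolean mask of grid nodes lying on the electrode's conductive face."""
    ax = np.asarray(elec.normal, dtype=float)
    axis = int(np.argmax(np.abs(ax)))
    xs, ys, zs = grid.axes()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = (X, Y, Z)
    c = np.asarray(elec.centre_um, dtype=float)
    half = grid.spacing_um[axis] / 2.0
    on_plane = np.abs(coords[axis] - c[axis]) <= half + 1e-9
    in_plane = [i for i in range(3) if i != axis]
    r2 = sum((coords[i] - c[i]) ** 2 for i in in_plane)
    mask = on_plane & (r2 <= (elec.diameter_um / 2.0) ** 2 + 1e-9)
    return mask


def _require_enclosed(grid: GridSpec, elec: ElectrodeSpec) -> None:
    lo = np.asarray(grid.origin_um)
    hi = np.asarray(grid.upper_um)
    c = np.asarray(elec.centre_um)
    if np.any(c < lo) or np.any(c > hi):
        raise ValueError(
            f"grid [{lo}..{hi}] does not enclose electrode at {tuple(c)}"
        )


# ---------------------------------------------------------------------------
# Finite-difference solver
# ---------------------------------------------------------------------------


def _face_conductances(profile: ConductivityProfile, grid: GridSpec):
    """Per-node conductivity and harmonic-mean face conductances.

    Units: sigma in S/m, lengths in um, currents in uA -> potentials in volts.
    (sigma * area/spacing has units S/m*um = 1e-6 S; times V gives uA.)
    """
    xs, ys, zs = grid.axes()
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    r = np.sqrt(X**2 + Y**2)
    sig2d = profile.sigma_at_radius(r)  # (nx, ny): cylinder is z-invariant
    sig = np.repeat(sig2d[:, :, None], grid.shape[2], axis=2)

    dx, dy, dz = grid.spacing_um
    areas = (dy * dz, dx * dz, dx * dy)
    spacings = (dx, dy, dz)
    faces = []
    for axis in range(3):
        s0 = np.moveaxis(sig, axis, 0)[:-1]
        s1 = np.moveaxis(sig, axis, 0)[1:]
        harm = 2.0 * s0 * s1 / (s0 + s1)
        g = np.moveaxis(harm, 0, axis) * (areas[axis] / spacings[axis])
        faces.append(g)
    return sig, faces


def solve_bipolar_field(
    profile: ConductivityProfile,
    source: ElectrodeSpec,
    ground: ElectrodeSpec,
    grid: GridSpec,
    current_ua: float = 1.0,
    rtol: float = 1e-9,
    end_faces: str = "ground",
) -> PotentialMap:
    """Finite-difference solution of the bipolar quasi-static field.

    Uniform current density (``current_ua`` total, default 1 uA) over the
    source disc, V = 0 on the ground disc, zero normal current on the outer
    lateral box faces.  The two longitudinal end faces are grounded by
    default (``end_faces='ground'``): the nerve section is an open conductor
    that continues rostrally into the eye globe (the current-return context)
    and caudally towards the chiasm, so sealing it would trap the injected
    current and inflate the potentials; ``end_faces='insulate'`` gives the
    fully sealed variant.  The returned map is normalised to 1 uA regardless
    of ``current_ua``.
    """
    if end_faces not in ("ground", "insulate"):
        raise ValueError("end_faces must be 'ground' or 'insulate'")
    if source.role != "current_source" or ground.role != "ground":
        raise ValueError("expected (current_source, ground) electrode roles")
    _require_enclosed(grid, source)
    _require_enclosed(grid, ground)

    src_mask = _disc_node_mask(grid, source)
    gnd_mask = _disc_node_mask(grid, ground)
    if not src_mask.any() or not gnd_mask.any():
        raise ValueError("electrode disc does not intersect any grid node; refine grid")

    _, faces = _face_conductances(profile, grid)
    n = grid.n_points
    shape = grid.shape
    idx = np.arange(n).reshape(shape)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        a = np.moveaxis(idx, axis, 0)
        i0 = a[:-1].ravel()
        i1 = a[1:].ravel()
        g = np.moveaxis(faces[axis], axis, 0).ravel()
        rows += [i0, i1]
        cols += [i1, i0]
        vals += [-g, -g]
        np.add.at(diag, i0, g)
        np.add.at(diag, i1, g)

    rows = np.concatenate(rows + [np.arange(n)])
    cols = np.concatenate(cols + [np.arange(n)])
    vals = np.concatenate(vals + [diag])
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    b = np.zeros(n)
    src_idx = idx[src_mask]
    b[src_idx] = current_ua / src_idx.size  # uniform uA per disc node

    # Dirichlet elimination for ground nodes (V = 0): drop their rows/cols.
    free = np.ones(n, dtype=bool)
    free[idx[gnd_mask]] = False
    if end_faces == "ground":
        free[idx[:, :, 0]] = False
        free[idx[:, :, -1]] = False
    if diag.max() <= 0 or not np.all(np.isfinite(diag)):
        raise FieldError("degenerate conductivities: singular system")
    Af = A[free][:, free]
    bf = b[free]

    if Af.shape[0] <= 50_000:
        vf = spsolve(Af.tocsc(), bf)
    else:
        M = sparse.diags(1.0 / Af.diagonal())
        vf, info = cg(Af, bf, rtol=rtol, atol=0.0, maxiter=20_000, M=M)
        if info != 0:
            raise FieldError(f"conjugate-gradient solve failed (info={info})")
    if not np.all(np.isfinite(vf)):
        raise FieldError("non-finite potentials: ill-conditioned system")

    v = np.zeros(n)
    v[free] = vf
    values_mv = (v / current_ua).reshape(shape) * 1e3  # V -> mV, per uA
    meta = {
        "solver": "fd",
        "profile": [
            {"name": l.name, "thickness_um": l.thickness_um, "sigma": l.sigma}
            for l in profile.layers
        ],
        "source_um": list(source.centre_um),
        "ground_um": list(ground.centre_um),
        "disc_diameter_um": source.diameter_um,
    }
    return PotentialMap(grid, values_mv, meta)


def analytic_bipolar_field(
    sigma: float,
    source_pos_um: Sequence[float],
    sink_pos_um: Sequence[float] | None,
    grid: GridSpec,
    current_ua: float = 1.0,
    clamp_radius_um: float = 1.0,
) -> PotentialMap:
    """Ideal point source + sink in an infinite homogeneous medium.

    ``V(r) = I/(4 pi sigma) * (1/|r-r_src| - 1/|r-r_snk|)`` in mV per uA.
    ``sink_pos_um=None`` gives the isolated-source (sink at infinity) limit.
    Points closer than ``clamp_radius_um`` to either pole are evaluated at the
    clamp radius, so the map stays finite; evaluating exactly at a pole with
    ``clamp_radius_um=0`` raises.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    src = np.asarray(source_pos_um, dtype=float)
    poles = [(src, +1.0)]
    if sink_pos_um is not None:
        snk = np.asarray(sink_pos_um, dtype=float)
        if np.allclose(src, snk):
            raise ValueError("source and sink coincide")
        poles.append((snk, -1.0))

    xs, ys, zs = grid.axes()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    v = np.zeros(grid.shape)
    for pos, sign in poles:
        r = np.sqrt((X - pos[0]) ** 2 + (Y - pos[1]) ** 2 + (Z - pos[2]) ** 2)
        if clamp_radius_um <= 0 and np.any(r == 0):
            raise FieldError("grid node coincides with a point source")
        r = np.maximum(r, clamp_radius_um)
        # I[uA]=1e-6 A, r[um]=1e-6 m -> V[volt] = 1/(4 pi sigma r_um); -> mV
        v += sign / (4.0 * np.pi * sigma * r) * 1e3
    meta = {
        "solver": "analytic",
        "sigma": sigma,
        "source_um": list(src),
        "sink_um": None if sink_pos_um is None else list(np.asarray(sink_pos_um)),
    }
    return PotentialMap(grid, v * current_ua, meta)


def point_potential_mv_per_ua(sigma: float, r_um: float) -> float:
    """Closed-form isolated point source: mV at distance r per uA."""
    if r_um <= 0:
        raise ValueError("r must be > 0")
    return 1e3 / (4.0 * np.pi * sigma * r_um)


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------


def interpolate_potentials(pmap: PotentialMap, points_um: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the map at arbitrary 3D points (um).

    Exact at grid nodes.  A point outside the grid bounding box raises with
    the offending coordinates; there is no silent extrapolation.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    lo = np.asarray(pmap.grid.origin_um)
    hi = np.asarray(pmap.grid.upper_um)
    bad = np.any((pts < lo - 1e-9) | (pts > hi + 1e-9), axis=1)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"point {tuple(pts[i])} outside potential-map grid "
            f"[{tuple(lo)} .. {tuple(hi)}]"
        )
    interp = RegularGridInterpolator(
        pmap.grid.axes(), pmap.values, method="linear", bounds_error=False,
        fill_value=None,
    )
    return interp(np.clip(pts, lo, hi))


# ---------------------------------------------------------------------------
# Text export / import (spreadsheet-style x y z V table)
# ---------------------------------------------------------------------------


def export_map(pmap: PotentialMap, path: str | Path) -> Path:
    """Write a map as a whitespace-delimited ``x y z V`` table.

    A ``%``-prefixed header carries the grid definition and metadata (also
    written to a ``.json`` sidecar).  Values use 17 significant digits so the
    round trip is bitwise lossless.
    """
    path = Path(path)
    xs, ys, zs = pmap.grid.axes()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    with path.open("w") as fh:
        fh.write("% finblock potential map\n")
        fh.write(f"% origin_um: {pmap.grid.origin_um[0]:.17g} "
                 f"{pmap.grid.origin_um[1]:.17g} {pmap.grid.origin_um[2]:.17g}\n")
        fh.write(f"% spacing_um: {pmap.grid.spacing_um[0]:.17g} "
                 f"{pmap.grid.spacing_um[1]:.17g} {pmap.grid.spacing_um[2]:.17g}\n")
        fh.write(f"% shape: {pmap.grid.shape[0]} {pmap.grid.shape[1]} "
                 f"{pmap.grid.shape[2]}\n")
        fh.write("% columns: x[um] y[um] z[um] V[mV/uA]\n")
        for x, y, z, v in zip(X.ravel(), Y.ravel(), Z.ravel(), pmap.values.ravel()):
            fh.write(f"{x:.17g} {y:.17g} {z:.17g} {v:.17g}\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(pmap.metadata, indent=1, sort_keys=True))
    return path


def import_map(path: str | Path) -> PotentialMap:
    """Read a map written by :func:`export_map`.

    Raises a parse error naming the first malformed or missing line if the
    record count does not match the declared grid shape.
    """
    path = Path(path)
    header: dict[str, list[float]] = {}
    values = []
    expected = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("%"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, rest = body.partition(":")
                    key = key.strip()
                    if key in ("origin_um", "spacing_um", "shape"):
                        header[key] = [float(t) for t in rest.split()]
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                values.append(float(parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad record: {line!r}") from exc
    for key in ("origin_um", "spacing_um", "shape"):
        if key not in header:
            raise ValueError(f"{path}: missing '% {key}:' header")
    shape = tuple(int(v) for v in header["shape"])
    n_expected = int(np.prod(shape))
    if len(values) != n_expected:
        raise ValueError(
            f"{path}:{len(values) + 5}: expected {n_expected} records for shape "
            f"{shape}, found {len(values)}"
        )
    grid = GridSpec(tuple(header["origin_um"]), tuple(header["spacing_um"]), shape)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return PotentialMap(grid, np.asarray(values).reshape(shape), meta)
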