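"""Synthetic limb-socket generator with known ground truth.

Residual limbs are surfaces of revolution with elliptical cross-sections
and a smooth (cosine-blended) proximal-to-distal radius profile chosen by
shape class: conical limbs taper strongly, cylindrical limbs hardly at
all, and bulbous limbs carry a raised-cosine distal bulge.  Landmarks sit
on the proximal rim: epicondyles on the +/-x axis, olecranon posterior.

Sockets are derived from the limb surface itself: the limb's angular
radius profile (recovered by slicing the mesh, so any star-shaped limb
works) is offset outward by a radial clearance, extended distally by a
rounded end relief, cut proximally at a trimline with epicondylar indents,
and optionally pierced by a posterior olecranon cutout.  Planted deviation
patches (raised-cosine bumps along a unit direction from the anatomical
origin) give the local-deviation analysis a known recovery target.

Cohorts emulate the reference population: lengths from a truncated normal
matched to the demographic table's moments, a pediatric/adult age mixture,
balanced sexes, and mostly conical/cylindrical shapes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import trimesh

from .anatomy import LandmarkSet
from .demographics import REFERENCE_DEMOGRAPHICS
from .errors import InputError
from .library import Library, LibraryEntry, ParticipantMeta, build_library
from .mesh_core import slice_area

__all__ = [
    "LimbParams",
    "PlantedPatch",
    "SocketDesignParams",
    "PopulationSpec",
    "generate_limb",
    "derive_socket",
    "generate_cohort",
]

_N_THETA = 64
_N_Z = 48
_N_SHAFT = 36
_N_CAP = 8


@dataclass
class LimbParams:
    """Parameters of one synthetic residual limb."""

    length: float = 76.3            # proximal-distal extent, mm
    a0: float = 28.0                # proximal medio-lateral semi-axis, mm
    b0: float = 24.0                # proximal anterior-posterior semi-axis, mm
    taper: float = 0.6              # distal/proximal radius ratio
    shape: str = "conical"
    bulge_amp: float = 0.0          # bulbous only: extra radius fraction
    bulge_center: float = 0.8       # bulbous only: profile position in [0, 1]
    bulge_width: float = 0.2
    noise_sd: float = 0.0           # radial surface noise SD, mm
    side: str = "right"

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise InputError("limb length must be positive")
        if not (0 < self.taper <= 1.2):
            raise InputError("taper must lie in (0, 1.2]")
        if self.shape not in ("conical", "cylindrical", "bulbous"):
            raise InputError("shape must be conical, cylindrical or bulbous")
        if self.shape == "cylindrical" and abs(self.taper - 1.0) > 0.05:
            raise InputError("cylindrical limbs require taper within 0.05 of 1")
        if self.shape == "conical" and self.taper > 0.8:
            raise InputError("conical limbs require taper <= 0.8")
        if min(self.a0, self.b0) <= 5.0:
            raise InputError("proximal semi-axes must exceed 5 mm")
        if self.noise_sd < 0:
            raise InputError("noise SD cannot be negative")
        if self.side not in ("left", "right"):
            raise InputError("side must be 'left' or 'right'")

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Radius multiplier rho(t), t = 0 proximal .. 1 distal."""
        t = np.asarray(t, dtype=float)
        rho = 1.0 + (self.taper - 1.0) * 0.5 * (1.0 - np.cos(np.pi * t))
        if self.shape == "bulbous" and self.bulge_amp > 0:
            u = (t - self.bulge_center) / self.bulge_width
            bump = np.where(np.abs(u) < 1.0,
                            0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
            rho = rho + self.bulge_amp * bump
        return rho


@dataclass
class PlantedPatch:
    """Raised-cosine surface bump for local-deviation recovery tests."""

    direction: np.ndarray           # unit vector from the anatomical origin
    amplitude: float                # mm; negative = deflation
    extent_deg: float = 40.0        # full angular extent of the bump

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise InputError("patch direction must be non-zero")
        self.direction = d / n
        if not (0 < self.extent_deg <= 180):
            raise InputError("patch extent must lie in (0, 180] degrees")


@dataclass
class SocketDesignParams:
    """Parameters of a derived socket."""

    clearance: float = 2.0          # radial clearance over the limb, mm
    distal_relief: float = 3.0      # extra depth below the limb tip, mm
    trim_fraction: float = 0.97     # covered fraction of limb length
    indent_depth: float = 6.0       # supracondylar trimline rise, mm
    indent_width_deg: float = 50.0
    indent_medial_scale: float = 0.75  # medial indent depth relative to lateral
    cutout: bool = True             # posterior olecranon cutout
    cutout_width_deg: float = 70.0
    cutout_depth_frac: float = 0.18  # of limb length
    cutout_bar: float = 5.0         # solid bar between trimline and cutout, mm
    patches: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.clearance < 0:
            raise InputError("clearance must be non-negative")
        if not self.distal_relief > 0:
            raise InputError("distal relief must be positive")
        if not (0.5 < self.trim_fraction <= 1.0):
            raise InputError("trim fraction must lie in (0.5, 1]")


def _revolution_mesh(rows_xyz: np.ndarray, apex: np.ndarray | None,
                     close_top: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vertices/faces of a tube from stacked rings (row 0 = top).

    Rings are counter-clockwise seen from +z, so the lateral winding is
    outward; the bottom is closed by ``apex`` (fan) and the top by a
    centroid fan when ``close_top``.
    """
    n_rows, n_theta, _ = rows_xyz.shape
    vertices = [rows_xyz.reshape(-1, 3)]
    faces = []
    for j in range(n_rows - 1):
        base = j * n_theta
        nxt = base + n_theta
        i = np.arange(n_theta)
        ip = (i + 1) % n_theta
        faces.append(np.column_stack([base + i, nxt + i, nxt + ip]))
        faces.append(np.column_stack([base + i, nxt + ip, base + ip]))
    index = n_rows * n_theta
    if apex is not None:
        vertices.append(np.asarray(apex, dtype=float)[None, :])
        base = (n_rows - 1) * n_theta
        i = np.arange(n_theta)
        ip = (i + 1) % n_theta
        faces.append(np.column_stack([base + ip, base + i,
                                      np.full(n_theta, index)]))
        index += 1
    if close_top:
        top = rows_xyz[0].mean(axis=0)
        vertices.append(top[None, :])
        i = np.arange(n_theta)
        ip = (i + 1) % n_theta
        faces.append(np.column_stack([i, ip, np.full(n_theta, index)]))
        index += 1
    return np.vstack(vertices), np.vstack(faces)


def generate_limb(params: LimbParams, seed: int = 0) -> tuple[trimesh.Trimesh, LandmarkSet]:
    """Deterministic limb mesh + landmarks for one parameter set.

    The limb occupies z in [-length, 0] with the proximal rim (and the
    landmarks) at z = 0; end rings are noise-free so the z-extent equals
    the nominal length exactly.
    """
    rng = np.random.default_rng(seed)
    theta = np.arange(_N_THETA) * (2.0 * np.pi / _N_THETA)
    t = np.linspace(0.0, 1.0, _N_Z)
    rho = params.profile(t)
    a = params.a0 * rho
    b = params.b0 * rho
    noise = rng.normal(0.0, params.noise_sd, size=(_N_Z, _N_THETA))
    noise[0] = 0.0
    noise[-1] = 0.0
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    x = (a[:, None] + noise) * cos_t[None, :]
    y = (b[:, None] + noise) * sin_t[None, :]
    z = np.broadcast_to((-params.length * t)[:, None], x.shape)
    rows = np.stack([x, y, z], axis=-1)
    apex = np.array([0.0, 0.0, -params.length])
    vertices, faces = _revolution_mesh(rows, apex=apex, close_top=True)
    landmarks = LandmarkSet(
        medial_epicondyle=np.array([-params.a0, 0.0, 0.0]),
        lateral_epicondyle=np.array([params.a0, 0.0, 0.0]),
        olecranon=np.array([0.0, -params.b0, 0.0]),
        side=params.side,
    )
    if params.side == "left":
        vertices = vertices.copy()
        vertices[:, 0] *= -1.0
        faces = faces[:, ::-1]
        landmarks = LandmarkSet(
            medial_epicondyle=np.array([params.a0, 0.0, 0.0]),
            lateral_epicondyle=np.array([-params.a0, 0.0, 0.0]),
            olecranon=np.array([0.0, -params.b0, 0.0]),
            side="left",
        )
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    return mesh, landmarks


def _angular_radius_table(limb: trimesh.Trimesh, n_stations: int = 36,
                          n_theta: int = _N_THETA) -> tuple[np.ndarray, np.ndarray]:
    """(station z values, radius[station, theta]) recovered by slicing.

    Works for any star-shaped limb whose axis is the frame z-axis.
    """
    zmin, zmax = limb.bounds[:, 2]
    span = zmax - zmin
    stations = np.linspace(zmin + 0.02 * span, zmax - 0.02 * span, n_stations)
    theta_grid = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    radii = np.empty((n_stations, n_theta))
    for k, z in enumerate(stations):
        loops = slice_area(limb, z).loops
        if not loops:
            raise InputError("limb slice produced no contour; axis misaligned?")
        pts = np.vstack(loops)
        ang = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * np.pi)
        rad = np.hypot(pts[:, 0], pts[:, 1])
        order = np.argsort(ang)
        ang, rad = ang[order], rad[order]
        ang_ext = np.concatenate([ang - 2 * np.pi, ang, ang + 2 * np.pi])
        rad_ext = np.concatenate([rad, rad, rad])
        radii[k] = np.interp(theta_grid, ang_ext, rad_ext)
    return stations, radii


def derive_socket(
    limb: trimesh.Trimesh,
    design: SocketDesignParams,
    seed: int = 0,
) -> tuple[trimesh.Trimesh, np.ndarray, np.ndarray]:
    """Socket mesh derived from an aligned limb, plus registration points.

    Returns ``(socket, trimline_indent_point, obturator_point)``.  The
    trimline indent point is the deepest dip of the proximal trimline (the
    lateral epicondyle seat); the obturator point is the centre of the
    olecranon cutout (or the posterior trimline point when the cutout is
    off).  Unreferenced vertices inside the cutout are kept so the
    obturator centre remains anchored to mesh coordinates.
    """
    zmin, zmax = limb.bounds[:, 2]
    length = zmax - zmin
    stations, radius_table = _angular_radius_table(limb)
    theta = np.arange(_N_THETA) * (2.0 * np.pi / _N_THETA)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    def radius_at(z: float) -> np.ndarray:
        z = np.clip(z, stations[0], stations[-1])
        k = np.searchsorted(stations, z)
        if k == 0:
            return radius_table[0]
        if k >= len(stations):
            return radius_table[-1]
        w = (z - stations[k - 1]) / (stations[k] - stations[k - 1])
        return (1 - w) * radius_table[k - 1] + w * radius_table[k]

    # the supracondylar collar rises z_trim above the epicondylar plane and
    # the lateral trimline indent dips back down to exactly z = 0, where
    # the epicondyles rest -- the registration convention's origin height
    z_trim = design.indent_depth - (1.0 - design.trim_fraction) * length
    if z_trim <= 0.5:
        raise InputError(
            "trimline configuration leaves no supracondylar collar: "
            "indent_depth must exceed (1 - trim_fraction) * limb length")
    half_w = np.radians(design.indent_width_deg) / 2.0
    def indent_profile(center, depth_scale):
        d = np.angle(np.exp(1j * (theta - center)))
        return np.where(np.abs(d) < half_w,
                        depth_scale * np.cos(np.pi * d / (2 * half_w)) ** 2, 0.0)
    dips = z_trim * (indent_profile(0.0, 1.0)
                     + indent_profile(np.pi, design.indent_medial_scale))
    z_top = z_trim - dips  # per-column trimline height

    rows = []
    for j in range(_N_SHAFT):
        frac = j / (_N_SHAFT - 1.0)          # 0 at trimline, 1 at limb tip
        z_cols = z_top + frac * (zmin - z_top)
        ring = np.empty((_N_THETA, 3))
        for i in range(_N_THETA):
            r = radius_at(z_cols[i])[i] + design.clearance
            ring[i] = (r * cos_t[i], r * sin_t[i], z_cols[i])
        rows.append(ring)
    tip_radius = radius_at(zmin) + design.clearance
    for k in range(1, _N_CAP):
        u = np.sin(0.5 * np.pi * k / _N_CAP)
        shrink = np.sqrt(max(1.0 - u * u, 0.0))
        r = tip_radius * shrink
        zc = zmin - design.distal_relief * u
        rows.append(np.column_stack([r * cos_t, r * sin_t,
                                     np.full(_N_THETA, zc)]))
    rows = np.stack(rows)
    apex = np.array([0.0, 0.0, zmin - design.distal_relief])
    vertices, faces = _revolution_mesh(rows, apex=apex, close_top=False)

    # planted deviation patches: push vertices along their direction from
    # the anatomical origin with a raised-cosine angular falloff
    for patch in design.patches:
        norms = np.linalg.norm(vertices, axis=1)
        units = vertices / np.maximum(norms, 1e-12)[:, None]
        ang = np.arccos(np.clip(units @ patch.direction, -1.0, 1.0))
        half = np.radians(patch.extent_deg) / 2.0
        w = np.where(ang < half, np.cos(0.5 * np.pi * ang / half) ** 2, 0.0)
        vertices = vertices + patch.amplitude * w[:, None] * units

    obturator_theta = 1.5 * np.pi  # posterior
    if design.cutout:
        z_cut_top = z_trim - design.cutout_bar
        z_cut_bottom = z_cut_top - design.cutout_depth_frac * length
        half_cut = np.radians(design.cutout_width_deg) / 2.0
        tri_centers = vertices[faces].mean(axis=1)
        ang = np.abs(np.angle(np.exp(1j * (np.arctan2(tri_centers[:, 1],
                                                      tri_centers[:, 0])
                                           - obturator_theta))))
        inside = ((ang < half_cut)
                  & (tri_centers[:, 2] > z_cut_bottom)
                  & (tri_centers[:, 2] < z_cut_top))
        faces = faces[~inside]
        z_obt = 0.5 * (z_cut_top + z_cut_bottom)
        r_obt = radius_at(z_obt)[_N_THETA * 3 // 4] + design.clearance
        obturator = np.array([r_obt * np.cos(obturator_theta),
                              r_obt * np.sin(obturator_theta), z_obt])
    else:
        r_obt = radius_at(z_trim)[_N_THETA * 3 // 4] + design.clearance
        obturator = np.array([r_obt * np.cos(obturator_theta),
                              r_obt * np.sin(obturator_theta), z_trim])

    socket = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    indent_point = vertices[0].copy()  # column theta=0, trimline row
    return socket, indent_point, obturator


@dataclass
class PopulationSpec:
    """Cohort-level sampling distributions (moment-matched to the
    reference demographic table)."""

    length_mean: float = float(REFERENCE_DEMOGRAPHICS["limb_length"].mean())
    length_sd: float = float(REFERENCE_DEMOGRAPHICS["limb_length"].std(ddof=1))
    length_bounds: tuple = (35.0, 125.0)
    pediatric_frac: float = 9.0 / 19.0
    pediatric_age: tuple = (8.0, 17.0)
    adult_age: tuple = (18.0, 70.0)
    male_frac: float = 10.0 / 19.0
    shape_probs: dict = field(default_factory=lambda: {
        "conical": 10.0 / 19.0, "cylindrical": 9.0 / 19.0, "bulbous": 0.0})
    noise_sd: float = 0.1
    #: stand-in length-class cutoffs, mm: below the first is very short,
    #: above the second is long
    length_class_cutoffs: tuple = (60.0, 130.0)

    def length_class(self, length: float) -> str:
        lo, hi = self.length_class_cutoffs
        if length < lo:
            return "very_short"
        if length >= hi:
            return "long"
        return "short"


def _draw_limb_params(rng: np.random.Generator, spec: PopulationSpec) -> LimbParams:
    lo, hi = spec.length_bounds
    while True:
        length = rng.normal(spec.length_mean, spec.length_sd)
        if lo <= length <= hi:
            break
    shapes = list(spec.shape_probs)
    probs = np.array([spec.shape_probs[s] for s in shapes], dtype=float)
    shape = rng.choice(shapes, p=probs / probs.sum())
    if shape == "conical":
        taper = rng.uniform(0.45, 0.70)
        bulge = 0.0
    elif shape == "cylindrical":
        taper = rng.uniform(0.96, 1.04)
        bulge = 0.0
    else:
        taper = rng.uniform(0.96, 1.04)
        bulge = rng.uniform(0.15, 0.30)
    a0 = rng.uniform(23.0, 33.0)
    aspect = rng.uniform(0.75, 0.95)
    return LimbParams(
        length=float(length),
        a0=float(a0),
        b0=float(a0 * aspect),
        taper=float(taper),
        shape=str(shape),
        bulge_amp=float(bulge),
        noise_sd=spec.noise_sd,
        side="right",
    )


def _draw_design(rng: np.random.Generator) -> SocketDesignParams:
    return SocketDesignParams(
        clearance=2.0,
        distal_relief=float(rng.uniform(2.0, 6.0)),
        trim_fraction=0.97,
        indent_depth=float(rng.uniform(4.0, 8.0)),
        cutout=True,
    )


def generate_cohort(
    n: int,
    seed: int = 0,
    population: PopulationSpec | None = None,
) -> tuple[Library, dict]:
    """A seeded cohort of ``n`` limb-socket library entries + ground truth.

    The ground-truth record stores every generator parameter per
    participant so recovery tests can compare against planted values.
    """
    if n < 2:
        raise InputError("a cohort needs at least 2 participants")
    spec = population or PopulationSpec()
    rng = np.random.default_rng(seed)
    entries = []
    truth: dict[str, dict] = {}
    for i in range(n):
        pid = f"S{i + 1:02d}"
        limb_params = _draw_limb_params(rng, spec)
        design = _draw_design(rng)
        age = (rng.uniform(*spec.pediatric_age)
               if rng.random() < spec.pediatric_frac
               else rng.uniform(*spec.adult_age))
        sex = "M" if rng.random() < spec.male_frac else "F"
        limb_seed = int(rng.integers(0, 2**31 - 1))
        limb, landmarks = generate_limb(limb_params, seed=limb_seed)
        socket, indent, obturator = derive_socket(limb, design)
        meta = ParticipantMeta(
            id=pid, sex=sex, age=float(round(age, 1)),
            limb_length=limb_params.length,
            length_class=spec.length_class(limb_params.length),
            shape_class=limb_params.shape,
        )
        entries.append(LibraryEntry(meta=meta, limb=limb,
                                    landmarks=landmarks, socket=socket))
        record = {
            "limb_params": asdict(limb_params),
            "design": {k: v for k, v in asdict(design).items() if k != "patches"},
            "limb_seed": limb_seed,
            "indent_point": indent.tolist(),
            "obturator_point": obturator.tolist(),
        }
        truth[pid] = record
    library = build_library(entries)
    truth["_manifest_hash"] = hashlib.sha256(
        json.dumps(truth, sort_keys=True).encode()).hexdigest()
    return library, truth
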