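"""Spherical head model: sensors, source grid, and the analytic lead field.

The forward problem is solved on a concentric three-shell conductor
(brain / skull / scalp) with piecewise-constant conductivity.  The scalp
potential of a dipole inside the innermost shell is expanded in Legendre
harmonics; for each harmonic order the radial transfer coefficient is
obtained by solving the interface conditions (continuity of potential and
of radial current density, zero current through the scalp surface).  For
radially oriented dipoles — the only orientation used on the source grid —
the potential at a scalp point at angular distance ``theta`` from the
dipole axis is

    V(theta) = 1/(4 pi sigma_1 R^2) * sum_n  n t_n (b/R)^(n-1) P_n(cos theta)

where ``b`` is the dipole eccentricity, ``R`` the scalp radius, ``t_n`` the
per-order transfer coefficient of the shell stack and ``P_n`` the Legendre
polynomial.  With equal shell conductivities the stack degenerates to the
homogeneous sphere, for which ``t_n = (2n+1)/n`` in these units; that
closed form serves as the independent oracle in the test suite.

Units: positions in mm, dipole moments in nA*m, potentials in microvolt.
All lead-field columns are average-referenced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    GeometryError,
    MontageFormatError,
    NumericalError,
    ShapeError,
)

__all__ = [
    "HeadModelSpec",
    "SensorArray",
    "SourceGrid",
    "LeadField",
    "build_sensor_array",
    "build_source_grid",
    "compute_leadfield",
    "forward_project",
    "save_leadfield",
    "load_leadfield",
]

#: fraction of the brain-shell radius to which the source grid is clipped
GRID_CLIP_FRACTION = 0.9


@dataclass(frozen=True)
class HeadModelSpec:
    """Concentric three-shell sphere: radii (mm) and conductivities (S/m).

    Defaults approximate an adult head: brain 80 mm / skull 85 mm / scalp
    92 mm with conductivities 0.33 / 0.0042 / 0.33 S/m (the ~1:80 skull
    ratio classically used for EEG forward models).
    """

    shell_radii: tuple[float, float, float] = (80.0, 85.0, 92.0)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        r = np.asarray(self.shell_radii, dtype=float)
        c = np.asarray(self.conductivities, dtype=float)
        if r.shape != (3,) or c.shape != (3,):
            raise ConfigurationError("need exactly 3 shell radii and 3 conductivities")
        if not np.all(np.diff(r) > 0):
            raise ConfigurationError(f"shell radii must be strictly increasing, got {r}")
        if not np.all(c > 0):
            raise ConfigurationError(f"conductivities must be positive, got {c}")

    @property
    def brain_radius(self) -> float:
        return float(self.shell_radii[0])

    @property
    def scalp_radius(self) -> float:
        return float(self.shell_radii[2])

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class SensorArray:
    """Scalp electrode set under an average reference.

    positions are head-centered Cartesian mm and lie on the scalp sphere.
    """

    labels: list[str]
    positions: np.ndarray  # (n_sensors, 3) mm
    reference: str = "average"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ShapeError("sensor positions must be (n, 3)")
        if len(self.labels) != self.positions.shape[0]:
            raise ShapeError("labels and positions disagree in length")
        if len(set(self.labels)) != len(self.labels):
            raise MontageFormatError("duplicate channel labels in montage")

    @property
    def n_sensors(self) -> int:
        return len(self.labels)


@dataclass
class SourceGrid:
    """Regular lattice of candidate dipole locations inside the brain shell."""

    voxel_positions: np.ndarray  # (n_voxels, 3) mm
    spacing: float  # mm
    hemisphere_labels: np.ndarray  # (n_voxels,) of {"left", "right"}
    orientations: np.ndarray  # (n_voxels, 3) unit radial

    @property
    def n_voxels(self) -> int:
        return self.voxel_positions.shape[0]

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        return self.hemisphere_labels == hemisphere

    def nearest_voxel(self, position: np.ndarray) -> int:
        """Index of the grid voxel closest to ``position`` (mm)."""
        d = np.linalg.norm(self.voxel_positions - np.asarray(position, float), axis=1)
        return int(np.argmin(d))


@dataclass
class LeadField:
    """Sensor x voxel gain matrix in microvolt per nA*m, average-referenced."""

    gain: np.ndarray  # (n_sensors, n_voxels)
    grid: SourceGrid
    sensors: SensorArray
    head: HeadModelSpec
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.gain.shape[1]


# ---------------------------------------------------------------------------
# sensors


def _fibonacci_cap(n: int, max_polar_deg: float = 115.0) -> np.ndarray:
    """Quasi-uniform unit vectors over a spherical cap (synthetic montage)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    zmin = np.cos(np.deg2rad(max_polar_deg))
    z = 1 - (1 - zmin) * (i + 0.5) / n
    phi = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z**2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def build_sensor_array(
    montage_spec: str | Path = "biosemi64",
    head: HeadModelSpec | None = None,
) -> SensorArray:
    """Build a :class:`SensorArray` from a named layout or a montage TSV.

    ``montage_spec`` may be a standard-montage name (resolved through the
    layouts bundled with :mod:`mne`, e.g. ``"biosemi64"``), the name
    ``"synthetic<N>"`` for a quasi-uniform N-electrode cap, or a path to a
    tab-separated file with header columns ``label``, ``x``, ``y``, ``z``
    (mm).  Positions are radially projected onto the scalp sphere of
    ``head`` so every electrode sits exactly on the outer surface.
    """
    head = head or HeadModelSpec()
    spec = str(montage_spec)

    if spec.endswith(".tsv") or Path(spec).is_file():
        df = pd.read_csv(spec, sep="\t")
        required = {"label", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise MontageFormatError(
                f"montage TSV must have columns {sorted(required)}, got {list(df.columns)}"
            )
        labels = [str(v) for v in df["label"]]
        pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    elif spec.startswith("synthetic"):
        n = int(spec.removeprefix("synthetic") or "64")
        labels = [f"S{i:03d}" for i in range(n)]
        pos = _fibonacci_cap(n)
    else:
        import mne  # deferred: only needed for named standard layouts

        montage = mne.channels.make_standard_montage(spec)
        ch_pos = montage.get_positions()["ch_pos"]
        labels = list(ch_pos)
        pos = np.asarray([ch_pos[k] for k in labels], dtype=float)

    if len(labels) != len(set(labels)):
        raise MontageFormatError("duplicate channel labels in montage")
    if len(labels) < 16:
        raise ConfigurationError(
            f"at least 16 channels required for source localization, got {len(labels)}"
        )

    center = head.center_array
    if spec.endswith(".tsv") or Path(spec).is_file():
        rel = pos - center  # TSV positions are head-centered mm
    else:
        rel = pos  # template layouts are centered in their own frame
    # project every electrode radially onto the scalp sphere
    norms = np.linalg.norm(rel, axis=1)
    if np.any(norms == 0):
        raise MontageFormatError("montage contains an electrode at the head center")
    projected = center + head.scalp_radius * rel / norms[:, None]
    return SensorArray(labels=labels, positions=projected)


# ---------------------------------------------------------------------------
# source grid


def build_source_grid(head: HeadModelSpec | None = None, spacing: float = 5.0) -> SourceGrid:
    """Cartesian lattice clipped to a ball at 90% of the brain-shell radius.

    Hemisphere label is the sign of x (x <= 0 -> "left"); orientations are
    radial unit vectors (the voxel at the exact center, if present, is
    oriented along +z).
    """
    head = head or HeadModelSpec()
    if spacing <= 0:
        raise ConfigurationError("grid spacing must be positive")
    if spacing > head.brain_radius:
        raise ConfigurationError(
            f"spacing {spacing} mm exceeds brain radius {head.brain_radius} mm"
        )
    r_max = GRID_CLIP_FRACTION * head.brain_radius
    n_steps = int(np.floor(r_max / spacing))
    axis = np.arange(-n_steps, n_steps + 1) * spacing
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= r_max]
    pts = pts + head.center_array

    rel = pts - head.center_array
    norms = np.linalg.norm(rel, axis=1)
    orientations = np.zeros_like(rel)
    nonzero = norms > 0
    orientations[nonzero] = rel[nonzero] / norms[nonzero, None]
    orientations[~nonzero] = (0.0, 0.0, 1.0)

    hemispheres = np.where(rel[:, 0] <= 0, "left", "right").astype(object)
    return SourceGrid(
        voxel_positions=pts,
        spacing=float(spacing),
        hemisphere_labels=np.asarray(hemispheres),
        orientations=orientations,
    )


# ---------------------------------------------------------------------------
# lead field


def _shell_transfer_coefficients(
    head: HeadModelSpec, n_max: int
) -> np.ndarray:
    """Per-order transfer coefficients t_n of the three-shell stack.

    Radii are normalized by the scalp radius so high orders stay within
    floating-point range.  For order n the radial potential in each region
    is a combination of r^n and r^-(n+1); the dipole's own term in region 1
    enters with unit coefficient and the five remaining coefficients follow
    from the interface conditions.  t_n is the surface combination
    B3 + C3 evaluated at r = 1.
    """
    r1, r2, r3 = (np.asarray(head.shell_radii, float) / head.shell_radii[2])
    s1, s2, s3 = head.conductivities
    t = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        # unknowns: [A1, B2, C2, B3, C3]
        a = np.zeros((5, 5))
        b = np.zeros(5)
        rn1, rm1 = r1**n, r1 ** -(n + 1)
        rn2, rm2 = r2**n, r2 ** -(n + 1)
        # potential continuity at r1:  A1 r1^n + r1^-(n+1) = B2 r1^n + C2 r1^-(n+1)
        a[0] = [rn1, -rn1, -rm1, 0, 0]
        b[0] = -rm1
        # radial current continuity at r1
        dp1, dm1 = n * r1 ** (n - 1), -(n + 1) * r1 ** -(n + 2)
        a[1] = [s1 * dp1, -s2 * dp1, -s2 * dm1, 0, 0]
        b[1] = -s1 * dm1
        # potential continuity at r2
        a[2] = [0, rn2, rm2, -rn2, -rm2]
        # radial current continuity at r2
        dp2, dm2 = n * r2 ** (n - 1), -(n + 1) * r2 ** -(n + 2)
        a[3] = [0, s2 * dp2, s2 * dm2, -s3 * dp2, -s3 * dm2]
        # zero radial current at the scalp surface r = 1
        a[4] = [0, 0, 0, n, -(n + 1)]
        sol = np.linalg.solve(a, b)
        t[n] = sol[3] + sol[4]  # B3 * 1^n + C3 * 1^-(n+1)
    return t


def homogeneous_sphere_potential(
    sensor_unit: np.ndarray,
    dipole_pos: np.ndarray,
    head: HeadModelSpec,
    n_terms: int = 200,
) -> float:
    """Brute-force series for a radial unit dipole in a homogeneous sphere.

    Independent closed form (t_n = (2n+1)/n) used as the oracle for the
    degenerate equal-conductivity shell stack.  ``sensor_unit`` is the unit
    vector toward the sensor; returns microvolt per nA*m.
    """
    center = head.center_array
    rel = np.asarray(dipole_pos, float) - center
    b = np.linalg.norm(rel) / head.scalp_radius
    axis = rel / np.linalg.norm(rel) if b > 0 else np.array([0.0, 0.0, 1.0])
    x = float(np.dot(sensor_unit, axis))
    sigma = head.conductivities[0]
    r3_m = head.scalp_radius * 1e-3
    total = 0.0
    p_prev, p_curr = 1.0, x  # P0, P1
    for n in range(1, n_terms + 1):
        total += (2 * n + 1) * b ** (n - 1) * p_curr
        p_prev, p_curr = p_curr, ((2 * n + 1) * x * p_curr - n * p_prev) / (n + 1)
    return total * 1e-3 / (4 * np.pi * sigma * r3_m**2)


def compute_leadfield(
    sensors: SensorArray,
    grid: SourceGrid,
    head: HeadModelSpec,
    max_terms: int = 200,
    tol: float = 1e-10,
) -> LeadField:
    """Analytic three-shell lead field for radially oriented unit dipoles.

    Column j holds the average-referenced scalp potentials (microvolt) of a
    1 nA*m dipole at grid voxel j oriented along the grid's radial
    orientation.  The Legendre series is truncated when the largest term
    falls below ``tol`` of the accumulated potential scale; failure to
    reach that by ``max_terms`` raises :class:`NumericalError`.
    """
    center = head.center_array
    rel_vox = grid.voxel_positions - center
    ecc = np.linalg.norm(rel_vox, axis=1)
    if np.any(ecc >= head.brain_radius):
        bad = int(np.argmax(ecc))
        raise GeometryError(
            f"voxel {bad} at eccentricity {ecc[bad]:.1f} mm is not inside the "
            f"brain shell ({head.brain_radius} mm)"
        )
    rel_sens = sensors.positions - center
    sens_unit = rel_sens / np.linalg.norm(rel_sens, axis=1)[:, None]

    # cos(angle) between each sensor direction and each dipole axis;
    # the dipole axis is the radial orientation, so this also covers the
    # central voxel (axis +z).
    cos_theta = sens_unit @ grid.orientations.T  # (n_sens, n_vox)
    b_hat = ecc / head.scalp_radius  # (n_vox,)

    t = _shell_transfer_coefficients(head, max_terms)
    sigma1 = head.conductivities[0]
    r3_m = head.scalp_radius * 1e-3
    prefactor = 1e-3 / (4 * np.pi * sigma1 * r3_m**2)  # nA*m -> microvolt

    v = np.zeros_like(cos_theta)
    p_prev = np.ones_like(cos_theta)  # P0
    p_curr = cos_theta.copy()  # P1
    converged = False
    quiet = 0
    for n in range(1, max_terms + 1):
        radial = b_hat ** (n - 1)  # 0**0 == 1 handles the central voxel
        coef = n * t[n]
        v += coef * radial[None, :] * p_curr
        term_scale = abs(coef) * radial.max()
        ref_scale = max(np.abs(v).max(), np.finfo(float).tiny)
        quiet = quiet + 1 if term_scale < tol * ref_scale else 0
        if quiet >= 2:
            converged = True
            break
        p_prev, p_curr = p_curr, (
            (2 * n + 1) * cos_theta * p_curr - n * p_prev
        ) / (n + 1)
    if not converged:
        raise NumericalError(
            f"lead-field series not converged to {tol:g} within {max_terms} terms "
            f"(max eccentricity ratio {b_hat.max():.3f})"
        )

    gain = prefactor * v
    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    return LeadField(gain=gain, grid=grid, sensors=sensors, head=head)


def forward_project(leadfield: LeadField, moments: np.ndarray) -> np.ndarray:
    """Project dipole moments (voxels x time, nA*m) to scalp (sensors x time, microvolt)."""
    moments = np.asarray(moments, dtype=float)
    if moments.ndim != 2 or moments.shape[0] != leadfield.n_voxels:
        raise ShapeError(
            f"moments must be ({leadfield.n_voxels}, n_times), got {moments.shape}"
        )
    return leadfield.gain @ moments


def project_sparse(leadfield: LeadField, voxel_indices: np.ndarray, moments: np.ndarray) -> np.ndarray:
    """Like :func:`forward_project` but for moments given only at ``voxel_indices``."""
    moments = np.asarray(moments, dtype=float)
    if moments.shape[0] != len(voxel_indices):
        raise ShapeError("one moment row per active voxel required")
    return leadfield.gain[:, voxel_indices] @ moments


# ---------------------------------------------------------------------------
# persistence


def save_leadfield(leadfield: LeadField, path: str | Path) -> None:
    """Persist gain + geometry to an HDF5 container with a JSON spec attr."""
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=leadfield.gain)
        f.create_dataset("voxel_positions", data=leadfield.grid.voxel_positions)
        f.create_dataset("orientations", data=leadfield.grid.orientations)
        f.create_dataset(
            "hemisphere_labels",
            data=np.asarray([s.encode() for s in leadfield.grid.hemisphere_labels]),
        )
        f.create_dataset("sensor_positions", data=leadfield.sensors.positions)
        f.create_dataset(
            "sensor_labels", data=np.asarray([s.encode() for s in leadfield.sensors.labels])
        )
        f.attrs["spacing"] = leadfield.grid.spacing
        f.attrs["head_spec"] = json.dumps(
            {
                "shell_radii": list(leadfield.head.shell_radii),
                "conductivities": list(leadfield.head.conductivities),
                "center": list(leadfield.head.center),
            }
        )


def load_leadfield(path: str | Path) -> LeadField:
    with h5py.File(path, "r") as f:
        spec = json.loads(f.attrs["head_spec"])
        head = HeadModelSpec(
            shell_radii=tuple(spec["shell_radii"]),
            conductivities=tuple(spec["conductivities"]),
            center=tuple(spec["center"]),
        )
        grid = SourceGrid(
            voxel_positions=f["voxel_positions"][()],
            spacing=float(f.attrs["spacing"]),
            hemisphere_labels=np.asarray([s.decode() for s in f["hemisphere_labels"][()]], dtype=object),
            orientations=f["orientations"][()],
        )
        sensors = SensorArray(
            labels=[s.decode() for s in f["sensor_labels"][()]],
            positions=f["sensor_positions"][()],
        )
        return LeadField(gain=f["gain"][()], grid=grid, sensors=sensors, head=head)
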