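"""Deterministic generator of vertebra-like and disc-like closed meshes.

Every pipeline stage keys on a handful of structural features of real
segmented lumbar anatomy: an ellipsoidal vertebral body with posterior
processes (spinous, two transverse, two articular), flat-ish superior and
inferior body surfaces, and lens/cylinder-shaped discs whose smallest PCA
axis is the stacking axis.  The generator reproduces exactly those features
with seeded smooth noise, so the whole pipeline is testable without any
patient data.

Anatomical frame (declared, fixed): superior = +z, anterior = +y, left = +x.
Level numbering follows clinical convention: L1 superior-most, so
``centroid_z(L5) < centroid_z(L1)``.

The vertebra is a star-shaped radial displacement field applied to a unit
icosphere: positive smooth radius fields are closed, manifold and
self-intersection-free by construction, which a CSG union of primitives would
not guarantee without a boolean engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _tm

from .mesh_core import TriMesh

__all__ = ["SpineFixtureParams", "make_vertebra", "make_disc", "make_lumbar_stack"]


@dataclass
class SpineFixtureParams:
    """Geometry and noise parameters of the synthetic lumbar stack (mm)."""

    n_levels: int = 5
    body_radii: tuple[float, float, float] = (20.0, 15.0, 12.0)  # left, anterior, superior semi-axes
    process_length: float = 25.0
    disc_height: float = 10.0
    disc_radii: tuple[float, float] = (18.0, 13.0)
    gap: float = 0.5
    seed: int = 0
    noise_amplitude: float = 0.2
    subdivisions: int = 4  # vertebra refinement; edges ~1 mm on the body, as
    # dense as the distance-based clustering steps assume
    disc_resolution: tuple[int, int] = (48, 12)  # azimuthal x axial samples

    def __post_init__(self) -> None:
        lengths = (*self.body_radii, self.process_length, self.disc_height, *self.disc_radii)
        if any(l <= 0 for l in lengths):
            raise ValueError("all lengths must be positive")
        if not (0 <= self.gap < self.disc_height):
            raise ValueError("gap must be in [0, disc_height)")
        if self.noise_amplitude >= 0.1 * min(self.body_radii + self.disc_radii):
            raise ValueError("noise_amplitude must stay below 10% of the smallest semi-axis")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")

    @property
    def level_spacing(self) -> float:
        """Vertical distance between adjacent vertebra centroids."""
        return 2.0 * self.body_radii[2] + self.disc_height + 2.0 * self.gap

    def level_z(self, level: int) -> float:
        """Centroid height of vertebra `level` (L1 superior-most)."""
        return (self.n_levels - level) * self.level_spacing


def _bump(u: np.ndarray, center: np.ndarray, width: float) -> np.ndarray:
    """Smooth directional bump: exp(-(angle to center)^2 / width^2) on the sphere."""
    c = np.asarray(center, dtype=float)
    c = c / np.linalg.norm(c)
    ang = np.arccos(np.clip(u @ c, -1.0, 1.0))
    return np.exp(-((ang / width) ** 2))


def _smooth_noise(u: np.ndarray, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Low-order seeded spherical-harmonic-style perturbation (degree <= 4)."""
    if amplitude == 0.0:
        return np.zeros(len(u))
    x, y, z = u.T
    basis = [
        x, y, z,
        x * y, y * z, x * z, x * x - y * y, 3 * z * z - 1,
        x * (5 * z * z - 1), y * (5 * z * z - 1), z * (5 * z * z - 3),
        x * y * z,
    ]
    coeff = rng.normal(size=len(basis))
    raw = sum(c * b for c, b in zip(coeff, basis))
    scale = np.max(np.abs(raw))
    return amplitude * raw / (scale if scale > 0 else 1.0)


def vertebra_radius_field(params: SpineFixtureParams):
    """Radius field r(u) of the noise-free vertebra, for mesh and oracle use.

    Base: ellipsoid with the configured semi-axes.  Added: smooth posterior
    bumps — one spinous process (posterior, -y), two transverse processes
    (lateral, +/-x slightly posterior) and two articular bumps
    (posterior-superior/-inferior) — each scaled from ``process_length``.
    """
    a, b, c = params.body_radii
    L = params.process_length

    def radius(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float).reshape(-1, 3)
        # superellipsoidal body (exponent 4): vertebral endplates are nearly
        # flat, unlike a plain ellipsoid whose poles curve away from the disc
        f = ((u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2) ** 2 + (u[:, 2] / c) ** 4
        base = f ** (-0.25)
        r = base.copy()
        # spinous process: straight posterior
        r += 0.55 * L * _bump(u, np.array([0.0, -1.0, 0.0]), 0.28)
        # transverse processes: lateral, slightly posterior
        for sx in (+1.0, -1.0):
            r += 0.45 * L * _bump(u, np.array([sx, -0.35, 0.0]), 0.25)
        # articular bumps: posterior, superior and inferior (kept clear of the discs)
        for sz in (+1.0, -1.0):
            r += 0.14 * L * _bump(u, np.array([0.0, -0.85, sz * 0.45]), 0.26)
        return r

    return radius


def analytic_vertebra_volume(params: SpineFixtureParams, n_theta: int = 200, n_phi: int = 400) -> float:
    """Volume of the noise-free vertebra by spherical quadrature of r(u)^3 / 3.

    Independent oracle for the generated mesh: V = (1/3) * integral of r^3 dOmega.
    """
    radius = vertebra_radius_field(params)
    mu, wmu = np.polynomial.legendre.leggauss(n_theta)  # mu = cos(polar angle)
    phi = (np.arange(n_phi) + 0.5) * 2.0 * np.pi / n_phi
    MU, PHI = np.meshgrid(mu, phi, indexing="ij")
    s = np.sqrt(1.0 - MU**2)
    u = np.stack([s * np.cos(PHI), s * np.sin(PHI), MU], axis=-1).reshape(-1, 3)
    r = radius(u).reshape(n_theta, n_phi)
    dphi = 2.0 * np.pi / n_phi
    return float((wmu[:, None] * r**3 / 3.0).sum() * dphi)


def make_vertebra(params: SpineFixtureParams, level: int) -> TriMesh:
    """Closed vertebra-like mesh for level `level` (1 = L1, superior-most)."""
    if not (1 <= level <= params.n_levels):
        raise ValueError(f"level must be in [1, {params.n_levels}], got {level}")
    ico = _tm.creation.icosphere(subdivisions=params.subdivisions, radius=1.0)
    u = np.asarray(ico.vertices, dtype=float)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    radius = vertebra_radius_field(params)(u)
    rng = np.random.default_rng((params.seed * 1000003 + level * 101) % (2**31))
    # noise damped toward the poles: endplate surfaces stay smooth and the
    # vertebra-disc clearance is governed by the configured gap, not the noise
    radius = radius + _smooth_noise(u, rng, params.noise_amplitude) * (1.0 - u[:, 2] ** 2)
    v = u * radius[:, None]
    v = v - v.mean(axis=0)  # centroid at origin before stacking
    v[:, 2] += params.level_z(level)
    return TriMesh(v, np.asarray(ico.faces, dtype=np.int64))


def make_disc(params: SpineFixtureParams, level: int) -> TriMesh:
    """Closed elliptical-cylinder disc between vertebra `level` and `level`+1.

    Rounded rim (superellipse profile); the two largest-variance PCA axes span
    the transverse plane and the smallest aligns with the stacking axis.
    """
    if not (1 <= level <= params.n_levels - 1):
        raise ValueError(f"disc level must be in [1, {params.n_levels - 1}], got {level}")
    ra, rb = params.disc_radii
    h = params.disc_height
    n_az, n_ax = params.disc_resolution
    rng = np.random.default_rng((params.seed * 1000003 + 7919 * level) % (2**31))

    # rounded-cylinder profile: superellipse (|rho|^4 + |zeta|^4 = 1) sampled
    # uniformly in its angular parameter, so the caps and the wall both get
    # evenly sized rows (a plain axial parametrization starves the caps)
    phi = np.linspace(-np.pi / 2, np.pi / 2, n_ax + 2)[1:-1]
    rscale = np.abs(np.cos(phi)) ** 0.5
    z = 0.5 * h * np.sign(np.sin(phi)) * np.abs(np.sin(phi)) ** 0.5
    theta = np.arange(n_az) * 2.0 * np.pi / n_az
    rows = []
    for zi, si in zip(z, rscale):
        ring = np.stack(
            [ra * si * np.cos(theta), rb * si * np.sin(theta), np.full(n_az, zi)], axis=1
        )
        rows.append(ring)
    V = np.concatenate(rows)
    bot = len(V)
    top = len(V) + 1
    V = np.concatenate([V, [[0.0, 0.0, -0.5 * h]], [[0.0, 0.0, 0.5 * h]]])
    n_ax = len(phi)
    F = []
    for i in range(n_ax - 1):
        for j in range(n_az):
            a = i * n_az + j
            b = i * n_az + (j + 1) % n_az
            c = (i + 1) * n_az + j
            d = (i + 1) * n_az + (j + 1) % n_az
            F.append((a, b, d))
            F.append((a, d, c))
    for j in range(n_az):  # caps
        a, b = j, (j + 1) % n_az
        F.append((b, a, bot))
        a2, b2 = (n_ax - 1) * n_az + j, (n_ax - 1) * n_az + (j + 1) % n_az
        F.append((a2, b2, top))
    F = np.asarray(F, dtype=np.int64)
    if params.noise_amplitude > 0:
        u = V / np.maximum(np.linalg.norm(V, axis=1, keepdims=True), 1e-9)
        noise = _smooth_noise(u, rng, params.noise_amplitude)
        # displace along the local outward direction, damped on the caps so the
        # disc-vertebra clearance stays at the configured gap
        V = V + (noise * (1.0 - u[:, 2] ** 2))[:, None] * u
    # place between the two vertebra centroids
    zc = 0.5 * (params.level_z(level) + params.level_z(level + 1))
    V = V + np.array([0.0, 0.0, zc])
    return TriMesh(V, F)


def make_lumbar_stack(params: SpineFixtureParams | None = None) -> dict[str, TriMesh]:
    """Labeled map L1..Ln -> vertebra mesh, D1..D(n-1) -> disc mesh."""
    params = params or SpineFixtureParams()
    out: dict[str, TriMesh] = {}
    for level in range(1, params.n_levels + 1):
        out[f"L{level}"] = make_vertebra(params, level)
    for level in range(1, params.n_levels):
        out[f"D{level}"] = make_disc(params, level)
    return out


def write_stack(params: SpineFixtureParams, out_dir) -> dict[str, str]:
    """Write L*.stl / D*.stl plus a JSON parameter manifest; returns the file map."""
    from .mesh_io import save_stl

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack = make_lumbar_stack(params)
    files = {}
    for name, mesh in stack.items():
        path = out_dir / f"{name}.stl"
        save_stl(mesh, path)
        files[name] = str(path)
    manifest = {
        "n_levels": params.n_levels,
        "body_radii": list(params.body_radii),
        "process_length": params.process_length,
        "disc_height": params.disc_height,
        "disc_radii": list(params.disc_radii),
        "gap": params.gap,
        "seed": params.seed,
        "noise_amplitude": params.noise_amplitude,
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return files
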