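"""Digital cylindrical phantoms with spherical luminescent targets.

A phantom is an analytic description — cylinder geometry, homogeneous
background optical properties, and a list of spherical nanophosphor targets
carrying a relative concentration ρ. Rasterization onto the scan-slice voxel
grid produces the ground-truth :class:`ConcentrationMap` that reconstruction
is scored against.

Units: lengths in mm, optical coefficients in 1/cm (the convention of the
tissue-optics literature); conversions to 1/mm happen inside the forward
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import yaml

__all__ = [
    "OpticalProperties", "SphericalTarget", "Phantom", "ConcentrationMap",
    "PhantomConfig", "make_phantom", "random_phantom",
    "rasterize_concentration", "save_phantom", "load_phantom",
]

# §4.4-style soft-tissue-like defaults for the diffusion regime
DEFAULT_MU_A = 0.5        # 1/cm
DEFAULT_MU_S_PRIME = 15.0  # 1/cm


class ContainmentError(ValueError):
    """A target sphere does not lie entirely inside the phantom cylinder."""


class OverlapError(ValueError):
    """Two target spheres intersect."""


class PlacementError(RuntimeError):
    """Random placement failed to satisfy containment/non-overlap."""


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous background optics of the turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (1/cm).
    mu_s_prime : float
        Reduced scattering coefficient (1/cm). The diffusion approximation
        behind the light-propagation kernel needs ``mu_s_prime >> mu_a``;
        a warning is emitted when ``mu_s_prime < 10 * mu_a``.
    refractive_index : float
        Refractive index of the medium (>= 1).
    """

    mu_a: float = DEFAULT_MU_A
    mu_s_prime: float = DEFAULT_MU_S_PRIME
    refractive_index: float = 1.37

    def __post_init__(self) -> None:
        if not (self.mu_a > 0 and self.mu_s_prime > 0):
            raise ValueError("mu_a and mu_s_prime must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.mu_s_prime < 10 * self.mu_a:
            warnings.warn(
                "mu_s_prime < 10*mu_a: outside the diffusion regime, "
                "the propagation kernel is inaccurate",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SphericalTarget:
    """Spherical nanophosphor inclusion.

    center is a 3-vector (mm) in the phantom frame, whose origin sits on the
    cylinder axis at half height; radius in mm; concentration in relative
    units (> 0).
    """

    center: tuple[float, float, float]
    radius: float
    concentration: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("target radius must be positive")
        if self.concentration <= 0:
            raise ValueError("target concentration must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class Phantom:
    """Cylindrical phantom: geometry + optics + targets.

    The cylinder axis is z; the scan plane is z = 0 (half height). The voxel
    grid of the rasterized slice spans [-radius, radius]² with isotropic
    ``voxel_size``.
    """

    radius: float = 12.5
    height: float = 20.0
    voxel_size: float = 0.25
    background: OpticalProperties = field(default_factory=OpticalProperties)
    targets: tuple[SphericalTarget, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.height > 0 and self.voxel_size > 0):
            raise ValueError("radius, height and voxel_size must be positive")
        object.__setattr__(self, "targets", tuple(self.targets))
        for i, t in enumerate(self.targets):
            _check_containment(t, self.radius, self.height, index=i)
        for i, a in enumerate(self.targets):
            for j, b in enumerate(self.targets[i + 1:], start=i + 1):
                d = np.linalg.norm(np.subtract(a.center, b.center))
                if d <= a.radius + b.radius:
                    raise OverlapError(
                        f"targets {i} and {j} overlap "
                        f"(center distance {d:.3f} <= {a.radius + b.radius:.3f} mm)"
                    )

    @property
    def n_grid(self) -> int:
        """Voxels per side of the slice grid (grid fully covers the cross-section)."""
        return int(np.ceil(2 * self.radius / self.voxel_size))

    def scaled(self, factor: float) -> "Phantom":
        """Same phantom with every target concentration multiplied by ``factor``."""
        targets = tuple(replace(t, concentration=t.concentration * factor)
                        for t in self.targets)
        return replace(self, targets=targets)


def _check_containment(t: SphericalTarget, radius: float, height: float,
                       index: int | None = None) -> None:
    cx, cy, cz = t.center
    name = f"target {index}" if index is not None else "target"
    if np.hypot(cx, cy) + t.radius > radius + 1e-12:
        raise ContainmentError(
            f"{name} at ({cx:.2f}, {cy:.2f}, {cz:.2f}) mm with radius "
            f"{t.radius:.2f} mm extends beyond the cylinder radius {radius} mm"
        )
    if abs(cz) + t.radius > height / 2 + 1e-12:
        raise ContainmentError(
            f"{name} extends beyond the cylinder height (|z|+r = "
            f"{abs(cz) + t.radius:.2f} > {height / 2:.2f} mm)"
        )


@dataclass(frozen=True)
class ConcentrationMap:
    """Voxelized nanophosphor concentration ρ on the scan slice.

    ``values`` is (n, n) with values >= 0, exactly 0 outside the cylinder
    cross-section; ``origin`` is the (x, y) of the corner of voxel (0, 0);
    indexing is values[ix, iy] with x = origin[0] + (ix + ½)·voxel_size.
    """

    values: np.ndarray
    origin: tuple[float, float]
    voxel_size: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("ConcentrationMap values must be 2D (one scan slice)")
        if np.any(v < 0):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every voxel center, each of shape ``self.shape``."""
        n0, n1 = self.values.shape
        x = self.origin[0] + (np.arange(n0) + 0.5) * self.voxel_size
        y = self.origin[1] + (np.arange(n1) + 0.5) * self.voxel_size
        return np.meshgrid(x, y, indexing="ij")


def grid_coords(phantom: Phantom) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-center coordinates of the phantom's slice grid."""
    n = phantom.n_grid
    half = n * phantom.voxel_size / 2
    c = -half + (np.arange(n) + 0.5) * phantom.voxel_size
    return np.meshgrid(c, c, indexing="ij")


def make_phantom(radius: float = 12.5, height: float = 20.0,
                 targets: list[SphericalTarget] | tuple[SphericalTarget, ...] = (),
                 background: OpticalProperties | None = None,
                 voxel_size: float = 0.25,
                 seed: int | None = None) -> Phantom:
    """Build a validated cylindrical phantom.

    Raises :class:`ContainmentError` if any target pokes out of the cylinder
    and :class:`OverlapError` if two target spheres intersect.
    """
    return Phantom(
        radius=radius, height=height, voxel_size=voxel_size,
        background=background or OpticalProperties(),
        targets=tuple(targets), seed=seed,
    )


def rasterize_concentration(phantom: Phantom) -> ConcentrationMap:
    """Rasterize ρ on the scan slice (z = 0): each voxel takes the
    concentration of the target sphere containing its center, else 0.

    Linear in the concentrations: scaling every target by c scales the map
    by exactly c.
    """
    x, y = grid_coords(phantom)
    values = np.zeros_like(x)
    for t in phantom.targets:
        cx, cy, cz = t.center
        r_slice_sq = t.radius ** 2 - cz ** 2  # sphere ∩ slice plane
        if r_slice_sq <= 0:
            continue
        inside = (x - cx) ** 2 + (y - cy) ** 2 <= r_slice_sq
        values[inside] = t.concentration
    values[x ** 2 + y ** 2 > phantom.radius ** 2] = 0.0
    half = phantom.n_grid * phantom.voxel_size / 2
    return ConcentrationMap(values=values, origin=(-half, -half),
                            voxel_size=phantom.voxel_size)


@dataclass(frozen=True)
class PhantomConfig:
    """Sampling ranges for :func:`random_phantom`.

    Every range is (low, high); target count is drawn uniformly from
    ``n_targets``; optical parameters are drawn uniformly within
    ``optical_perturbation`` (relative, e.g. 0.2 = ±20%) around the nominal
    (μa = 0.5, μs′ = 15) cm⁻¹; targets are placed on the scan plane (z = 0)
    when ``in_plane`` so the 2D slice carries the full signal.
    """

    radius: float = 12.5
    height: float = 20.0
    voxel_size: float = 0.25
    n_targets: tuple[int, int] = (1, 4)
    target_radius: tuple[float, float] = (0.5, 2.5)
    concentration: tuple[float, float] = (0.5, 2.0)
    optical_perturbation: float = 0.2
    mu_a: float = DEFAULT_MU_A
    mu_s_prime: float = DEFAULT_MU_S_PRIME
    refractive_index: float = 1.37
    in_plane: bool = True
    max_attempts: int = 2000

    def __post_init__(self) -> None:
        for name in ("n_targets", "target_radius", "concentration"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range must be positive and ordered")
        if not 0 <= self.optical_perturbation < 1:
            raise ValueError("optical_perturbation must be in [0, 1)")


def random_phantom(seed: int, config: PhantomConfig | None = None) -> Phantom:
    """Draw a reproducible random phantom.

    Targets are rejected-and-resampled until containment and non-overlap
    hold; after ``config.max_attempts`` failures a :class:`PlacementError`
    is raised. Identical (seed, config) give a field-by-field identical
    phantom.
    """
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    p = cfg.optical_perturbation
    background = OpticalProperties(
        mu_a=cfg.mu_a * rng.uniform(1 - p, 1 + p),
        mu_s_prime=cfg.mu_s_prime * rng.uniform(1 - p, 1 + p),
        refractive_index=cfg.refractive_index,
    )
    n_targets = int(rng.integers(cfg.n_targets[0], cfg.n_targets[1] + 1))
    targets: list[SphericalTarget] = []
    attempts = 0
    while len(targets) < n_targets:
        if attempts >= cfg.max_attempts:
            raise PlacementError(
                f"could not place {n_targets} non-overlapping targets inside "
                f"the cylinder after {cfg.max_attempts} attempts (seed {seed})"
            )
        attempts += 1
        r = rng.uniform(*cfg.target_radius)
        conc = rng.uniform(*cfg.concentration)
        # uniform position in the admissible disc of radius (R - r)
        rho_max = cfg.radius - r
        if rho_max <= 0:
            continue
        u = rng.uniform()
        phi = rng.uniform(0, 2 * np.pi)
        rad = rho_max * np.sqrt(u)
        cz = 0.0 if cfg.in_plane else rng.uniform(-(cfg.height / 2 - r),
                                                  cfg.height / 2 - r)
        cand = SphericalTarget(center=(rad * np.cos(phi), rad * np.sin(phi), cz),
                               radius=r, concentration=conc)
        if all(np.linalg.norm(np.subtract(cand.center, t.center))
               > cand.radius + t.radius for t in targets):
            targets.append(cand)
    return Phantom(radius=cfg.radius, height=cfg.height,
                   voxel_size=cfg.voxel_size, background=background,
                   targets=tuple(targets), seed=seed)


# ---------------------------------------------------------------------------
# serialization: HDF5 container + YAML sidecar summary

def save_phantom(phantom: Phantom, path) -> None:
    """Write the phantom (scalars, target table, rasterized map) to HDF5,
    plus a human-readable ``<path>.yaml`` summary for provenance."""
    cmap = rasterize_concentration(phantom)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "xlct-phantom-v1"
        f.attrs["radius_mm"] = phantom.radius
        f.attrs["height_mm"] = phantom.height
        f.attrs["voxel_size_mm"] = phantom.voxel_size
        f.attrs["seed"] = -1 if phantom.seed is None else phantom.seed
        g = f.create_group("background")
        g.attrs["mu_a_per_cm"] = phantom.background.mu_a
        g.attrs["mu_s_prime_per_cm"] = phantom.background.mu_s_prime
        g.attrs["refractive_index"] = phantom.background.refractive_index
        tbl = np.array([(t.center[0], t.center[1], t.center[2],
                         t.radius, t.concentration) for t in phantom.targets],
                       dtype=float).reshape(-1, 5)
        f.create_dataset("targets", data=tbl)
        f.create_dataset("concentration_map", data=cmap.values)
        f["concentration_map"].attrs["origin_mm"] = cmap.origin
    summary = {
        "radius_mm": phantom.radius, "height_mm": phantom.height,
        "voxel_size_mm": phantom.voxel_size, "seed": phantom.seed,
        "background": {"mu_a_per_cm": phantom.background.mu_a,
                       "mu_s_prime_per_cm": phantom.background.mu_s_prime,
                       "refractive_index": phantom.background.refractive_index},
        "targets": [{"center_mm": list(t.center), "radius_mm": t.radius,
                     "concentration": t.concentration}
                    for t in phantom.targets],
    }
    with open(f"{path}.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)


def load_phantom(path) -> Phantom:
    """Read a phantom written by :func:`save_phantom`."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "xlct-phantom-v1":
            raise ValueError(f"{path}: not an xlct phantom container")
        bg = f["background"].attrs
        targets = tuple(
            SphericalTarget(center=(row[0], row[1], row[2]),
                            radius=row[3], concentration=row[4])
            for row in f["targets"][()]
        )
        seed = int(f.attrs["seed"])
        return Phantom(
            radius=float(f.attrs["radius_mm"]),
            height=float(f.attrs["height_mm"]),
            voxel_size=float(f.attrs["voxel_size_mm"]),
            background=OpticalProperties(
                mu_a=float(bg["mu_a_per_cm"]),
                mu_s_prime=float(bg["mu_s_prime_per_cm"]),
                refractive_index=float(bg["refractive_index"]),
            ),
            targets=targets,
            seed=None if seed == -1 else seed,
        )
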