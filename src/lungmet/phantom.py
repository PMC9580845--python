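"""Synthetic mouse-thorax phantoms with exact ground-truth masks.

The phantom emulates the contrast of self-gated bSSFP thorax stacks: a
bright body ellipsoid on a dark background, two dark lung ellipsoids inside
it, hyperintense vessel-like tubes inside the lungs (intensity only — they
stay labelled as lung, to exercise false-positive behaviour downstream),
hyperintense spherical metastases (labelled 2), and pure-noise slices at
both ends of the stack. Geometry is rasterized by voxel centre: a voxel
belongs to a primitive iff its centre satisfies the implicit equation, which
makes every ground-truth count brute-force checkable.

All intensities live on a [0, 1] scale; additive Gaussian noise (clipped to
[0, 1]) models magnitude-image noise. A Rician option is provided for
realism but the Gaussian default keeps analytic expectations simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .core_io import DEFAULT_SPACING_MM, LabelStack, VolumeStack

__all__ = [
    "Ellipsoid",
    "Sphere",
    "Tube",
    "PhantomSpec",
    "PhantomSpecError",
    "generate_phantom",
    "GrowthTimepoint",
    "generate_growth_series",
    "GROWTH_RATES",
]


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is geometrically invalid."""


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]  # (z, y, x) voxels
    semi_axes: tuple[float, float, float]

    def contains(self, zz, yy, xx):
        cz, cy, cx = self.center
        az, ay, ax = self.semi_axes
        return (
            ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def contains(self, zz, yy, xx):
        cz, cy, cx = self.center
        return ((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) <= self.radius**2


@dataclass(frozen=True)
class Tube:
    """A cylinder of given radius around the segment start-end (voxels)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float

    def contains(self, zz, yy, xx):
        p0 = np.asarray(self.start, dtype=float)
        d = np.asarray(self.end, dtype=float) - p0
        L2 = float(d @ d)
        vz, vy, vx = zz - p0[0], yy - p0[1], xx - p0[2]
        if L2 == 0.0:
            dist2 = vz**2 + vy**2 + vx**2
        else:
            t = np.clip((vz * d[0] + vy * d[1] + vx * d[2]) / L2, 0.0, 1.0)
            dist2 = (vz - t * d[0]) ** 2 + (vy - t * d[1]) ** 2 + (vx - t * d[2]) ** 2
        return dist2 <= self.radius**2


def _default_lungs(dims) -> tuple[Ellipsoid, Ellipsoid]:
    Z, Y, X = dims
    semi = (0.30 * Z, 0.28 * Y, 0.16 * X)
    return (
        Ellipsoid((0.5 * Z, 0.52 * Y, 0.32 * X), semi),
        Ellipsoid((0.5 * Z, 0.52 * Y, 0.68 * X), semi),
    )


def _default_vessels(lungs: Sequence[Ellipsoid]) -> tuple[Tube, ...]:
    out = []
    for lung in lungs:
        cz, cy, cx = lung.center
        az = lung.semi_axes[0]
        r = max(1.0, 0.012 * 2 * lung.semi_axes[2] / 0.32)
        out.append(Tube((cz - 0.6 * az, cy, cx), (cz + 0.6 * az, cy, cx), r))
    return tuple(out)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic thorax stack.

    Intensities are relative scalars on [0, 1] ordered
    ``lung_intensity < body_intensity < met_intensity`` (vessels share the
    metastasis-like hyperintensity). ``n_noise_slices_each_end`` slices at
    both stack ends carry pure noise and background-only labels, mimicking
    slices outside the animal.
    """

    dims: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    background_intensity: float = 0.03
    body_intensity: float = 0.55
    lung_intensity: float = 0.12
    vessel_intensity: float = 0.85
    met_intensity: float = 0.85
    body: Ellipsoid | None = None
    lung_ellipsoids: tuple[Ellipsoid, Ellipsoid] | None = None
    vessels: tuple[Tube, ...] | None = None
    metastases: tuple[Sphere, ...] = ()
    n_noise_slices_each_end: int | None = None
    noise_sigma: float = 0.02
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    seed: int = 0

    def resolved(self) -> "PhantomSpec":
        """Fill geometry defaults derived from ``dims``."""
        Z, Y, X = self.dims
        body = self.body or Ellipsoid(
            (0.5 * Z, 0.5 * Y, 0.5 * X), (0.40 * Z, 0.42 * Y, 0.45 * X)
        )
        lungs = (
            self.lung_ellipsoids
            if self.lung_ellipsoids is not None
            else _default_lungs(self.dims)
        )
        vessels = self.vessels if self.vessels is not None else _default_vessels(lungs)
        n_noise = self.n_noise_slices_each_end
        if n_noise is None:
            n_noise = max(0, Z // 16)
        return replace(
            self, body=body, lung_ellipsoids=tuple(lungs), vessels=tuple(vessels),
            n_noise_slices_each_end=int(n_noise),
        )

    def validate(self) -> "PhantomSpec":
        spec = self.resolved()
        Z = spec.dims[0]
        if not spec.lung_intensity < spec.body_intensity < spec.met_intensity:
            raise PhantomSpecError(
                "intensities must satisfy lung < body < metastasis, got "
                f"{spec.lung_intensity}, {spec.body_intensity}, {spec.met_intensity}"
            )
        if not 0 <= spec.n_noise_slices_each_end <= Z // 4:
            raise PhantomSpecError(
                f"n_noise_slices_each_end must be in [0, {Z // 4}], "
                f"got {spec.n_noise_slices_each_end}"
            )
        return spec

    @staticmethod
    def random(
        dims: tuple[int, int, int] = (128, 128, 128),
        n_metastases: int = 3,
        seed: int = 0,
        radius_range: tuple[float, float] = (1.6, 3.5),
        **kwargs,
    ) -> "PhantomSpec":
        """A spec with randomly placed, well-separated intra-lung metastases."""
        base = PhantomSpec(dims=dims, seed=seed, **kwargs).resolved()
        rng = np.random.default_rng(seed)
        placed: list[Sphere] = []
        attempts = 0
        while len(placed) < n_metastases:
            attempts += 1
            if attempts > 20000:
                raise PhantomSpecError(
                    f"could not place {n_metastases} metastases in the lungs"
                )
            if attempts % 2000 == 0:
                placed.clear()  # restart: earlier spheres can block the rest
            lung = base.lung_ellipsoids[rng.integers(len(base.lung_ellipsoids))]
            r = float(rng.uniform(*radius_range))
            if r + 1.0 > min(lung.semi_axes):
                continue  # sphere cannot fit in this lung along its short axis
            # sample a centre such that the full sphere fits in the ellipsoid
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = rng.uniform() ** (1 / 3)
            margin = np.maximum(np.asarray(lung.semi_axes) - (r + 1.5), 0.5)
            c = np.asarray(lung.center) + u * rad * margin
            cand = Sphere(tuple(c), r)
            if any(
                np.linalg.norm(np.subtract(cand.center, p.center)) < cand.radius + p.radius + 3.0
                for p in placed
            ):
                continue
            placed.append(cand)
        return replace(base, metastases=tuple(placed))


def _grids(dims):
    Z, Y, X = dims
    return np.meshgrid(
        np.arange(Z, dtype=float),
        np.arange(Y, dtype=float),
        np.arange(X, dtype=float),
        indexing="ij",
        sparse=True,
    )


def rasterize(primitive, dims) -> np.ndarray:
    """Boolean voxel-centre rasterization of a geometric primitive."""
    zz, yy, xx = _grids(dims)
    return primitive.contains(zz, yy, xx)


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeStack, LabelStack]:
    """Render one phantom: noise-free geometry, then noise, then end slices.

    Returns the intensity stack (float32 in [0, 1]) and its exact label
    stack. Same seed, same spec -> bit-identical output.
    """
    spec = spec.validate()
    Z, Y, X = spec.dims
    zz, yy, xx = _grids(spec.dims)

    body = spec.body.contains(zz, yy, xx)
    lung = np.zeros(spec.dims, dtype=bool)
    for ell in spec.lung_ellipsoids:
        lung |= ell.contains(zz, yy, xx)
    lung &= body
    met = np.zeros(spec.dims, dtype=bool)
    for s in spec.metastases:
        vox = s.contains(zz, yy, xx)
        if not (vox <= lung).all():
            raise PhantomSpecError(f"metastasis {s} extends outside the lungs")
        met |= vox
    vessel = np.zeros(spec.dims, dtype=bool)
    for t in spec.vessels:
        vessel |= t.contains(zz, yy, xx)
    vessel &= lung & ~met

    intensity = np.full(spec.dims, spec.background_intensity, dtype=np.float32)
    intensity[body] = spec.body_intensity
    intensity[lung] = spec.lung_intensity
    intensity[vessel] = spec.vessel_intensity
    intensity[met] = spec.met_intensity

    labels = np.zeros(spec.dims, dtype=np.int64)
    labels[lung] = 1
    labels[met] = 2

    n = spec.n_noise_slices_each_end
    if n > 0:
        intensity[:n] = 0.0
        intensity[Z - n :] = 0.0
        labels[:n] = 0
        labels[Z - n :] = 0

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        if spec.noise_model == "rician":
            re = intensity + rng.normal(0.0, spec.noise_sigma, spec.dims)
            im = rng.normal(0.0, spec.noise_sigma, spec.dims)
            intensity = np.sqrt(re**2 + im**2).astype(np.float32)
        else:
            intensity = intensity + rng.normal(
                0.0, spec.noise_sigma, spec.dims
            ).astype(np.float32)
        intensity = np.clip(intensity, 0.0, 1.0)

    return (
        VolumeStack(intensity.astype(np.float32), spacing_mm=spec.spacing_mm),
        LabelStack(labels, spacing_mm=spec.spacing_mm),
    )


#: Exponential volume growth rates per timepoint interval (fast vs slow
#: metastatic growth between successive imaging sessions).
GROWTH_RATES = {"fast": 0.9, "slow": 0.3}


@dataclass(frozen=True)
class GrowthTimepoint:
    stack: VolumeStack
    labels: LabelStack
    met_voxel_count: int
    met_volume_mm3: float


def generate_growth_series(
    spec: PhantomSpec,
    n_timepoints: int,
    growth: Literal["slow", "fast"] = "slow",
    seed: int | None = None,
) -> list[GrowthTimepoint]:
    """Render a longitudinal series with exponentially growing metastases.

    The spheres in ``spec.metastases`` are the radii at the first timepoint;
    total metastasis volume then grows as ``V_t = V_0 * exp(rate * t)`` with
    the per-interval rate taken from :data:`GROWTH_RATES`, so a *fast* series
    crosses any absolute volume threshold at an earlier timepoint than a
    *slow* one started from the same seed.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    if growth not in GROWTH_RATES:
        raise ValueError(f"growth must be one of {sorted(GROWTH_RATES)}")
    rate = GROWTH_RATES[growth]
    base = spec.validate()
    voxel_mm3 = float(np.prod(base.spacing_mm))
    out = []
    for t in range(n_timepoints):
        scale = float(np.exp(rate * t / 3.0))  # radius scale: volume scale^(1/3)
        mets = tuple(
            Sphere(s.center, s.radius * scale) for s in base.metastases
        )
        tp_seed = base.seed if seed is None else seed
        tp_spec = replace(base, metastases=mets, seed=tp_seed + t)
        stack, labels = generate_phantom(tp_spec)
        count = int((labels.data == 2).sum())
        out.append(GrowthTimepoint(stack, labels, count, count * voxel_mm3))
    return out
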