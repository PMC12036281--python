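"""Synthetic coronal CT phantoms with known per-region opacification.

A phantom is a stack of coronal slices: a bone-intensity background
(~+700 HU) carved with twelve ellipsoidal air cavities (~-1000 HU), one
per Lund-Mackay region.  Each cavity is partially refilled with
soft-tissue intensity (~+40 HU) from its inferior (large-row) end
upward — a gravity-like air-fluid-level analogue — so that a designed
fraction of its voxels is opacified.  Gaussian intensity noise is added
last, after the ground-truth table has been extracted from the exact
construction masks.

Because region masks and filled-voxel counts are known exactly, every
downstream stage (preprocessing, segmentation, threshold scoring,
metrics) can be exercised end-to-end with no clinical data.  The default
canvas is 448x512 to match the segmentation patch size; a small-canvas
mode (e.g. 112x128) keeps CPU training runs fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError
from .imaging import ImageVolume, LabelVolume
from .regions import Region, SinusType
from .scoring import map_score

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "PhantomVolume",
    "default_geometry",
    "generate_phantom",
    "default_fixture_suite",
    "training_suite",
]

HU_AIR = -1000.0
HU_BONE = 700.0
HU_SOFT = 40.0
DEFAULT_NOISE_SD = 20.0

# Fractional layout of the twelve cavities on a unit (slice, row, col) cube.
# Slices run anterior -> posterior, rows superior -> inferior, and the
# right-side regions sit at low column indices.  The ostiomeatal complex is
# deliberately tiny — small regions are the hard case for segmentation and
# scoring alike.  Values are (center_s, center_r, center_c, semi_s, semi_r,
# semi_c) for the RIGHT member; the left member mirrors the column center.
_LAYOUT: dict[SinusType, tuple[float, float, float, float, float, float]] = {
    SinusType.FRONTAL: (0.15, 0.15, 0.35, 0.09, 0.08, 0.08),
    SinusType.ANTERIOR_ETHMOID: (0.35, 0.30, 0.42, 0.09, 0.07, 0.045),
    SinusType.OMC: (0.42, 0.52, 0.40, 0.045, 0.033, 0.024),
    SinusType.MAXILLARY: (0.45, 0.70, 0.22, 0.21, 0.17, 0.12),
    SinusType.POSTERIOR_ETHMOID: (0.62, 0.30, 0.42, 0.09, 0.07, 0.045),
    SinusType.SPHENOID: (0.85, 0.45, 0.38, 0.09, 0.11, 0.08),
}


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates (slice, row, col)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean voxel mask of the ellipsoid interior on a grid."""
        cs, cr, cc = self.center
        a, b, c = self.semi_axes
        s = (np.arange(shape[0]) - cs) / a
        r = (np.arange(shape[1]) - cr) / b
        k = (np.arange(shape[2]) - cc) / c
        return (
            s[:, None, None] ** 2 + r[None, :, None] ** 2 + k[None, None, :] ** 2
        ) <= 1.0

    def in_bounds(self, shape: tuple[int, int, int]) -> bool:
        return all(
            c - a >= 0 and c + a <= dim - 1
            for c, a, dim in zip(self.center, self.semi_axes, shape)
        )


def default_geometry(
    n_slices: int,
    height: int = 448,
    width: int = 512,
    min_semi_axis: float = 1.2,
    omit: set[Region] | frozenset[Region] = frozenset(),
) -> dict[Region, Ellipsoid]:
    """Scale the fractional layout onto a voxel grid.

    Semi-axes are floored at ``min_semi_axis`` voxels so every region
    stays non-empty even on very small canvases.  ``omit`` drops regions
    entirely, modelling aplastic (congenitally absent) sinuses.
    """
    dims = (n_slices, height, width)
    geom: dict[Region, Ellipsoid] = {}
    for region in Region:
        if region in omit:
            continue
        fs, fr, fc, as_, ar, ac = _LAYOUT[region.sinus]
        if region.side.value == "left":
            fc = 1.0 - fc
        center = (fs * (n_slices - 1), fr * (height - 1), fc * (width - 1))
        semi = tuple(
            max(f * d, min_semi_axis) for f, d in zip((as_, ar, ac), dims)
        )
        # short stacks: pull centers inward so the floored semi-axes fit
        center = tuple(
            min(max(c, a), d - 1 - a) for c, a, d in zip(center, semi, dims)
        )
        geom[region] = Ellipsoid(center, semi)  # type: ignore[arg-type]
    return geom


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic volume.

    ``target_fractions`` maps each present region to its designed
    opacification fraction in [0, 1].  Intensities default to air -1000,
    bone +700 and soft tissue +40 HU; ``noise_sd`` is additive Gaussian
    noise in HU applied after truth extraction.
    """

    n_slices: int
    height: int = 448
    width: int = 512
    region_geometries: dict[Region, Ellipsoid] | None = None
    target_fractions: dict[Region, float] = field(default_factory=dict)
    hu_air: float = HU_AIR
    hu_bone: float = HU_BONE
    hu_soft: float = HU_SOFT
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    name: str = "phantom"

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_slices, self.height, self.width)

    def geometry(self) -> dict[Region, Ellipsoid]:
        if self.region_geometries is not None:
            return self.region_geometries
        return default_geometry(self.n_slices, self.height, self.width)

    def fraction_for(self, region: Region) -> float:
        return float(self.target_fractions.get(region, 0.0))

    def validate(self) -> None:
        for region, frac in self.target_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"target fraction for {region.name} must lie in [0,1], got {frac}"
                )
        for region, ell in self.geometry().items():
            if not ell.in_bounds(self.shape):
                raise GeometryError(
                    f"{region.name} ellipsoid extends outside volume bounds {self.shape}"
                )


@dataclass
class PhantomVolume:
    """A generated phantom: image, labels and its exact ground truth."""

    image: ImageVolume
    labels: LabelVolume
    truth: pd.DataFrame
    spec: PhantomSpec

    @property
    def name(self) -> str:
        return self.spec.name

    def truth_sub_score(self, region: Region) -> int:
        row = self.truth[self.truth["region"] == region.name.lower()]
        return int(row["sub_score"].iloc[0])

    @property
    def truth_total(self) -> int:
        return int(self.truth["sub_score"].sum())


def _fill_order(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cavity voxels ordered inferior-first (descending row), then by
    slice and column — a flat, deterministic fluid level."""
    s, r, c = np.nonzero(mask)
    order = np.lexsort((c, s, -r))
    return s[order], r[order], c[order]


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Render a spec into an image volume, label volume and truth table.

    Identical ``(spec, seed)`` produce bit-identical output.  Overlapping
    region ellipsoids are rejected with :class:`GeometryError`.
    """
    spec.validate()
    shape = spec.shape
    image = np.full(shape, spec.hu_bone, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int16)

    geometry = spec.geometry()
    rows = []
    for region in Region:  # fixed order for determinism
        if region not in geometry:
            rows.append(
                {
                    "region": region.name.lower(),
                    "side": region.side.value,
                    "sinus": region.sinus.value,
                    "designed_fraction": np.nan,
                    "realized_fraction": np.nan,
                    "sub_score": 0,
                    "absent": True,
                    "total_pixels": 0,
                    "opacified_pixels": 0,
                }
            )
            continue
        mask = geometry[region].mask(shape)
        if np.any(labels[mask] != 0):
            clash = Region(int(labels[mask].max()))
            raise GeometryError(
                f"{region.name} ellipsoid overlaps {clash.name}"
            )
        labels[mask] = int(region)
        image[mask] = spec.hu_air

        n_total = int(mask.sum())
        frac = spec.fraction_for(region)
        n_fill = int(round(frac * n_total))
        fs, fr, fc = _fill_order(mask)
        image[fs[:n_fill], fr[:n_fill], fc[:n_fill]] = spec.hu_soft

        realized = n_fill / n_total
        rows.append(
            {
                "region": region.name.lower(),
                "side": region.side.value,
                "sinus": region.sinus.value,
                "designed_fraction": frac,
                "realized_fraction": realized,
                "sub_score": map_score(realized),
                "absent": False,
                "total_pixels": n_total,
                "opacified_pixels": n_fill,
            }
        )

    truth = pd.DataFrame(rows)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    return PhantomVolume(
        image=ImageVolume(image),
        labels=LabelVolume(labels),
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# fixture suites


def _uniform(frac: float) -> dict[Region, float]:
    return {r: frac for r in Region}

# Mixed designed fractions exercising all three score bands and both band
# boundaries across the twelve regions.
_MIXED_CYCLE = (0.005, 0.50, 0.96, 1.0, 0.0, 0.30)


def default_fixture_suite(
    seed: int,
    noise_sd: float = 0.0,
    n_slices: int = 24,
    height: int = 448,
    width: int = 512,
) -> list[PhantomVolume]:
    """The documented deterministic fixture suite.

    Five volumes: all-clear (every fraction 0), all-opacified (every
    fraction 1, designed total 24), all-partial (0.30), a mixed volume
    cycling fractions through all three score bands, and an aplastic
    volume with the right frontal sinus absent.  Together every region
    visits each score band at least once.  Noise defaults to 0 so the
    suite doubles as the exact-recovery fixture; pass ``noise_sd`` to
    emulate acquisition noise.
    """
    mixed = {r: _MIXED_CYCLE[(int(r) - 1) % len(_MIXED_CYCLE)] for r in Region}
    base = dict(n_slices=n_slices, height=height, width=width, noise_sd=noise_sd)
    specs = [
        PhantomSpec(**base, target_fractions=_uniform(0.0), seed=seed, name="all_clear"),
        PhantomSpec(**base, target_fractions=_uniform(1.0), seed=seed + 1, name="all_opacified"),
        PhantomSpec(**base, target_fractions=_uniform(0.30), seed=seed + 2, name="all_partial"),
        PhantomSpec(**base, target_fractions=mixed, seed=seed + 3, name="mixed_bands"),
        PhantomSpec(
            **base,
            target_fractions=_uniform(0.30),
            region_geometries=default_geometry(
                n_slices, height, width, omit={Region.RIGHT_FRONTAL}
            ),
            seed=seed + 4,
            name="aplastic_right_frontal",
        ),
    ]
    return [generate_phantom(s) for s in specs]


def training_suite(
    seed: int,
    n_subjects: int = 6,
    slices_per_subject: int = 10,
    height: int = 112,
    width: int = 128,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[PhantomVolume]:
    """Small-canvas phantoms with randomized fractions for training runs.

    Each subject gets independent per-region opacification fractions drawn
    uniformly on [0, 1]; geometry is fixed, so the network learns intensity
    and position cues rather than memorizing one fill level.
    """
    rng = np.random.default_rng(seed)
    volumes = []
    for i in range(n_subjects):
        fracs = {r: float(rng.uniform()) for r in Region}
        spec = PhantomSpec(
            n_slices=slices_per_subject,
            height=height,
            width=width,
            target_fractions=fracs,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            name=f"subject_{i:03d}",
        )
        volumes.append(generate_phantom(spec))
    return volumes
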