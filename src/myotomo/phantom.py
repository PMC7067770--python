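"""Synthetic muscle-bundle phantoms with voxel-level ground truth.

The generator emulates reconstructed tomography stacks of a stained muscle
bundle: bright polygonal fibre cross-sections packed inside a roughly circular
bundle, separated by dark interstitial "muscle fibre space" whose intensity sits
at the background level.  Fibre cross-sections are Voronoi cells of
quasi-uniform seed points; denervation atrophy is modelled by shrinking each
cell toward its centroid (which widens the interstitial space) and by blending
the polygonal outline toward its inscribed circle (fibres become round as they
atrophy).  Cells are extruded along z with a gentle per-fibre sinusoidal
centroid jitter so that fibres are tubes rather than prisms.

Cell boundaries that coincide with the bundle boundary are *not* shrunk: the
outer envelope of the fibre bundle (the fascia line) stays in place while the
space between fibres widens, which is what the downstream contour measurement
(morphological closing + hole filling of the fibre mask) can actually observe.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Volume, check_congruent

__all__ = [
    "PhantomSpec",
    "PhantomVolume",
    "InjuryModel",
    "Side",
    "InjuryTrajectory",
    "StudyDesign",
    "generate_fiber_map",
    "render_intensity",
    "generate_phantom",
    "atrophy_for",
    "default_trajectory",
    "generate_study",
    "synthetic_weight",
    "histology_slice",
]

# Geometry constants of the atrophy model.  The baseline gap keeps adjacent
# healthy fibres separated by a visible interstitial line; the atrophy
# coefficient sets how far a maximally atrophied fibre retreats from its cell
# boundary (linear in the atrophy level).
BASE_GAP_FRAC = 0.02
ATROPHY_SHRINK_FRAC = 0.45
#: minimum sensible Voronoi cell area (px^2) used by the feasibility check
MIN_CELL_AREA_PX2 = 16.0


class InjuryModel(str, enum.Enum):
    SECTION = "SECTION"
    CRUSH = "CRUSH"


class Side(str, enum.Enum):
    INJURY = "INJURY"
    NON_INJURY = "NON_INJURY"


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic muscle volume.

    ``atrophy`` in [0, 1] widens the interstitial space (0 = healthy packing,
    1 = maximal widening); ``rounding`` in [0, 1] morphs cross-sections from
    polygonal Voronoi cells (0) to inscribed circles (1).
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    voxel_size_um: float = 1.625
    n_fibers: int = 24
    bundle_radius_frac: float = 0.84
    atrophy: float = 0.35
    rounding: float = 0.0
    fiber_intensity: float = 200.0
    background_intensity: float = 50.0
    noise_sigma: float = 10.0
    jitter_px: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.atrophy <= 1.0):
            raise ValueError(f"atrophy must be in [0,1]; got {self.atrophy}")
        if not (0.0 <= self.rounding <= 1.0):
            raise ValueError(f"rounding must be in [0,1]; got {self.rounding}")
        if self.fiber_intensity <= self.background_intensity:
            raise ValueError("fiber_intensity must exceed background_intensity")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints; got {self.shape}")
        if not (0.0 < self.bundle_radius_frac <= 1.0):
            raise ValueError("bundle_radius_frac must be in (0,1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        bundle_area = np.pi * self.bundle_radius_px**2
        if bundle_area < self.n_fibers * MIN_CELL_AREA_PX2:
            raise ValueError(
                f"{self.n_fibers} fibres cannot fit: bundle area "
                f"{bundle_area:.0f} px^2 < n_fibers * {MIN_CELL_AREA_PX2} px^2"
            )

    @property
    def bundle_radius_px(self) -> float:
        return self.bundle_radius_frac * min(self.shape[1], self.shape[2]) / 2.0


@dataclass
class PhantomVolume:
    """A generated phantom: intensity stack plus voxel-exact truth masks."""

    spec: PhantomSpec
    truth_fiber: np.ndarray
    truth_contour: np.ndarray
    truth_space: np.ndarray
    intensity: Volume | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        check_congruent(self.truth_fiber, self.truth_contour, self.truth_space)
        if self.intensity is not None:
            check_congruent(self.truth_fiber, self.intensity.data)

    @property
    def truth_space_fraction(self) -> float:
        """Truth space voxels as a fraction of the bundle-contour voxels."""
        return float(self.truth_space.sum()) / float(self.truth_contour.sum())


def _sample_seed_points(
    rng: np.random.Generator, n: int, radius: float, n_candidates: int = 24
) -> np.ndarray:
    """Quasi-uniform (Mitchell best-candidate) points in a disc around (0,0)."""
    pts: list[np.ndarray] = []
    for i in range(n):
        # rejection-sample candidates uniformly in the disc
        cand = np.empty((0, 2))
        while len(cand) < n_candidates:
            c = rng.uniform(-radius, radius, size=(4 * n_candidates, 2))
            c = c[np.hypot(c[:, 0], c[:, 1]) <= radius]
            cand = np.vstack([cand, c])
        cand = cand[:n_candidates]
        if not pts:
            pts.append(cand[0])
            continue
        d = np.min(
            np.linalg.norm(cand[:, None, :] - np.asarray(pts)[None, :, :], axis=2),
            axis=1,
        )
        pts.append(cand[int(np.argmax(d))])
    return np.asarray(pts)


def _fiber_template_masks(spec: PhantomSpec, rng: np.random.Generator):
    """Per-fibre 2D cross-section masks on the (y, x) grid, plus the disc."""
    _, ny, nx = spec.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    rb = spec.bundle_radius_px

    yy, xx = np.mgrid[0:ny, 0:nx]
    rel_y, rel_x = yy - cy, xx - cx
    disc = rel_y**2 + rel_x**2 <= rb**2

    seeds = _sample_seed_points(rng, spec.n_fibers, 0.92 * rb)

    # nearest-seed (Voronoi) label for every disc pixel
    pix = np.column_stack([rel_y[disc], rel_x[disc]])
    d2 = ((pix[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)

    shrink = 1.0 - BASE_GAP_FRAC - ATROPHY_SHRINK_FRAC * spec.atrophy
    masks = []
    for i in range(spec.n_fibers):
        cell_pix = pix[labels == i]
        if len(cell_pix) == 0:  # degenerate cell swallowed by neighbours
            masks.append(np.zeros((ny, nx), dtype=bool))
            continue
        c = cell_pix.mean(axis=0)
        rel = cell_pix - c
        r = np.linalg.norm(rel, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(r[:, None] > 0, rel / np.maximum(r, 1e-12)[:, None], 0.0)

        # distance from the centroid to each Voronoi bisector along u, and the
        # perpendicular bisector distances for the inscribed radius
        others = np.delete(np.arange(spec.n_fibers), i)
        r_bis = np.full(len(cell_pix), np.inf)
        r_insc = np.inf
        for j in others:
            n_ij = seeds[j] - seeds[i]
            m_ij = (seeds[j] + seeds[i]) / 2.0
            denom = u @ n_ij
            t = np.where(denom > 1e-12, (m_ij - c) @ n_ij / np.maximum(denom, 1e-12), np.inf)
            r_bis = np.minimum(r_bis, t)
            r_insc = min(r_insc, float((m_ij - c) @ n_ij / np.linalg.norm(n_ij)))

        # distance from the centroid to the bundle circle along u
        b = u @ c
        disc_t = -b + np.sqrt(np.maximum(b**2 + rb**2 - c @ c, 0.0))
        r_insc = max(0.5, min(r_insc, rb - float(np.linalg.norm(c))))

        r_cell = np.minimum(r_bis, disc_t)
        # fascia-anchored directions (bundle boundary binds) are not shrunk
        s_dir = np.where(disc_t < r_bis, 1.0, shrink)
        r_fib = s_dir * ((1.0 - spec.rounding) * r_cell + spec.rounding * r_insc)

        m = np.zeros((ny, nx), dtype=bool)
        keep = r <= r_fib
        m[yy[disc][labels == i][keep], xx[disc][labels == i][keep]] = True
        masks.append(m)
    return masks, disc


def generate_fiber_map(spec: PhantomSpec) -> PhantomVolume:
    """Generate the ground-truth label masks (no intensity rendering).

    Returns a :class:`PhantomVolume` whose ``truth_fiber``, ``truth_contour``
    and ``truth_space`` masks satisfy the partition
    ``truth_space = truth_contour & ~truth_fiber`` voxelwise.
    """
    spec.validate()
    nz, ny, nx = spec.shape
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x67656F]))

    masks, disc = _fiber_template_masks(spec, rng)

    # per-fibre sinusoidal centroid jitter along z (integer pixel offsets)
    phases = rng.uniform(0, 2 * np.pi, size=(spec.n_fibers, 2))
    periods = rng.uniform(24, 48, size=spec.n_fibers)
    z = np.arange(nz)

    fiber = np.zeros((nz, ny, nx), dtype=bool)
    amp = float(spec.jitter_px)
    offsets_y = np.rint(amp * np.sin(2 * np.pi * z[None, :] / periods[:, None] + phases[:, 0:1])).astype(int)
    offsets_x = np.rint(amp * np.sin(2 * np.pi * z[None, :] / periods[:, None] + phases[:, 1:2])).astype(int)
    for i, m in enumerate(masks):
        if not m.any():
            continue
        for k in range(nz):
            dy, dx = offsets_y[i, k], offsets_x[i, k]
            if dy == 0 and dx == 0:
                fiber[k] |= m
            else:
                fiber[k] |= np.roll(np.roll(m, dy, axis=0), dx, axis=1)
    contour = np.broadcast_to(disc, (nz, ny, nx)).copy()
    fiber &= contour
    space = contour & ~fiber
    return PhantomVolume(spec=spec, truth_fiber=fiber, truth_contour=contour, truth_space=space)


def render_intensity(phantom: PhantomVolume, spec: PhantomSpec | None = None) -> Volume:
    """Render the intensity stack for a phantom: bright fibres on a dark
    background (interstitial space sits at the background level), plus
    additive zero-mean Gaussian noise. Deterministic given the spec seed."""
    spec = spec or phantom.spec
    img = np.where(
        phantom.truth_fiber, float(spec.fiber_intensity), float(spec.background_intensity)
    ).astype(np.float32)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x6E6F69]))
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape).astype(np.float32)
    vol = Volume(img, spec.voxel_size_um)
    phantom.intensity = vol
    return vol


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Generate truth masks and render the intensity stack in one call."""
    phantom = generate_fiber_map(spec)
    render_intensity(phantom, spec)
    return phantom


# ---------------------------------------------------------------------------
# injury trajectories and whole-study generation
# ---------------------------------------------------------------------------

_SECTION_INJURY = {1: 0.2, 7: 0.4, 14: 0.6, 21: 0.8}
_CRUSH_INJURY = {1: 0.2, 7: 0.5, 14: 0.7, 21: 0.4}
#: contralateral (uninjured side) atrophy as a fraction of the injured side
NON_INJURY_SCALE = 0.6


@dataclass(frozen=True)
class InjuryTrajectory:
    """Atrophy level per day for one (injury model, side) series."""

    model: InjuryModel
    side: Side
    atrophy_by_day: dict[int, float]

    def __post_init__(self) -> None:
        days = sorted(self.atrophy_by_day)
        vals = [self.atrophy_by_day[d] for d in days]
        if self.model is InjuryModel.SECTION and self.side is Side.INJURY:
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError("SECTION injury trajectory must be non-decreasing")
        if self.model is InjuryModel.CRUSH and self.side is Side.INJURY and 14 in days:
            peak = self.atrophy_by_day[14]
            before = [self.atrophy_by_day[d] for d in days if d < 14]
            after = [self.atrophy_by_day[d] for d in days if d > 14]
            if any(v > peak for v in before) or any(v >= peak for v in after):
                raise ValueError("CRUSH injury trajectory must peak at day 14")

    @property
    def days(self) -> list[int]:
        return sorted(self.atrophy_by_day)

    def atrophy(self, day: int) -> float:
        try:
            return self.atrophy_by_day[int(day)]
        except KeyError:
            raise KeyError(f"day {day} not in trajectory days {self.days}") from None


def default_trajectory(model: InjuryModel | str, side: Side | str) -> InjuryTrajectory:
    model, side = InjuryModel(model), Side(side)
    base = _SECTION_INJURY if model is InjuryModel.SECTION else _CRUSH_INJURY
    scale = 1.0 if side is Side.INJURY else NON_INJURY_SCALE
    return InjuryTrajectory(
        model=model, side=side, atrophy_by_day={d: scale * a for d, a in base.items()}
    )


def atrophy_for(model: InjuryModel | str, side: Side | str, day: int) -> float:
    """Atrophy level of the default trajectories for one (model, side, day)."""
    return default_trajectory(model, side).atrophy(day)


@dataclass(frozen=True)
class StudyDesign:
    """Group x side x day x replicate layout of a synthetic study."""

    models: tuple = (InjuryModel.SECTION, InjuryModel.CRUSH)
    sides: tuple = (Side.INJURY, Side.NON_INJURY)
    days: tuple = (1, 7, 14, 21)
    replicates: int = 6

    def cells(self):
        for m in self.models:
            for s in self.sides:
                for d in self.days:
                    for r in range(self.replicates):
                        yield InjuryModel(m), Side(s), int(d), r


def _sub_seed(master_seed: int, *parts) -> int:
    """Stable per-volume sub-seed below 2**31 from a master seed and keys."""
    key = "|".join(str(p) for p in parts).encode()
    return (zlib.crc32(key) ^ (int(master_seed) * 2654435761)) % (2**31)


# weight model: healthy soleus wet weight ~0.010 g for a 30 g mouse, mild
# growth over the 3-week survival window, atrophy removes up to ~35 % of mass
WEIGHT_BASE_G = 0.0100
WEIGHT_GROWTH_PER_DAY = 0.004
WEIGHT_ATROPHY_COEF = 0.35
WEIGHT_NOISE_SD_G = 0.0003


def synthetic_weight(atrophy: float, day: int, rng: np.random.Generator) -> float:
    """Sample a synthetic wet muscle weight (g) for one specimen."""
    w0 = WEIGHT_BASE_G * (1.0 + WEIGHT_GROWTH_PER_DAY * (int(day) - 1))
    return float(w0 * (1.0 - WEIGHT_ATROPHY_COEF * atrophy) + rng.normal(0.0, WEIGHT_NOISE_SD_G))


def generate_study(
    design: StudyDesign | None = None,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    couple_rounding: bool = True,
    render: bool = True,
):
    """Generate one phantom per study cell plus a synthetic weight table.

    Yields nothing lazily: returns ``(volumes, weights)`` where ``volumes`` is
    a list of :class:`PhantomVolume` (with ``sample_id`` set) and ``weights`` a
    tidy :class:`pandas.DataFrame` with columns
    ``sample_id, group, side, day, weight_g``.  With ``couple_rounding`` the
    fibre rounding follows the atrophy level, mirroring the polygonal-to-round
    shape change of atrophying fibres.
    """
    design = design or StudyDesign()
    base_spec = base_spec or PhantomSpec()
    volumes: list[PhantomVolume] = []
    rows = []
    for model, side, day, rep in design.cells():
        a = atrophy_for(model, side, day)
        sub = _sub_seed(seed, model.value, side.value, day, rep)
        spec = replace(
            base_spec,
            atrophy=a,
            rounding=(a if couple_rounding else base_spec.rounding),
            seed=sub,
        )
        phantom = generate_fiber_map(spec)
        if render:
            render_intensity(phantom, spec)
        sid = f"{model.value[0]}{'' if side is Side.INJURY else 'N'}_d{day:02d}_r{rep}"
        phantom.sample_id = sid
        volumes.append(phantom)
        wrng = np.random.default_rng(_sub_seed(seed, "weight", model.value, side.value, day, rep))
        rows.append(
            {
                "sample_id": sid,
                "group": model.value,
                "side": side.value,
                "day": day,
                "weight_g": round(synthetic_weight(a, day, wrng), 6),
            }
        )
    weights = pd.DataFrame(rows, columns=["sample_id", "group", "side", "day", "weight_g"])
    return volumes, weights


def histology_slice(phantom: PhantomVolume, z: int):
    """Extract one slice as a 2D histology-style image with its 2D truth.

    Returns ``(image2d, fiber2d, contour2d, space2d)``; ``image2d`` is ``None``
    when the phantom has not been intensity-rendered.
    """
    nz = phantom.truth_fiber.shape[0]
    z = int(z)
    if not (0 <= z < nz):
        raise IndexError(f"slice {z} out of range for stack of {nz} slices")
    img = None if phantom.intensity is None else phantom.intensity.data[z]
    return img, phantom.truth_fiber[z], phantom.truth_contour[z], phantom.truth_space[z]
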