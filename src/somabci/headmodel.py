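"""Spherical three-shell head model, somatomotor ROI atlas, and lead field.

The head is modeled as three concentric spheres (scalp, skull, brain) with
piecewise-constant conductivity.  Cortical sources are radially oriented
current dipoles on a sphere just inside the brain shell; scalp potentials
follow the classical Legendre-series solution of Laplace's equation in the
layered conductor, so the forward map ``W = L @ S`` is available in closed
form without meshes.  Electrodes live on the scalp sphere and everything is
average-referenced, matching the reference-free nature of EEG.

Coordinate conventions: +z through the vertex, +y anterior, +x toward the
subject's right; the mid-sagittal (interhemispheric) plane is x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

from ._rng import substream

__all__ = [
    "HeadModel", "ElectrodeArray", "ROIRegion", "ROIAtlas", "SourceSpace",
    "LeadField", "ROI_BASE_IDS", "build_head_model", "build_electrode_array",
    "build_roi_atlas", "build_source_space", "compute_lead_field",
    "project_sources",
]

# Somatomotor regions used per hemisphere: primary foot/hand somatosensory
# (S1F, S1H), cingulate motor (CMA), primary foot/hand motor (M1F, M1H),
# supplementary and pre-supplementary motor (SMA, pSMA), dorsal and ventral
# premotor (PMd, PMv).
ROI_BASE_IDS = ("S1F", "S1H", "CMA", "M1F", "M1H", "SMA", "pSMA", "PMd", "PMv")

# Default cap centers as (lateral, anterior) angles in degrees for the LEFT
# hemisphere; the right hemisphere is the mirror image through x = 0.
# Foot representations sit medially (< 15 deg of midline), hand
# representations laterally (30-45 deg), somatosensory caps posterior to and
# premotor caps anterior to the motor strip, following the homuncular layout
# along the central sulcus.  CMA (a medial-wall area) is placed on the
# posterior midline strip of this synthetic geometry.
_DEFAULT_CENTERS_DEG: dict[str, tuple[float, float]] = {
    "S1F": (9.0, -18.0),
    "M1F": (9.0, 0.0),
    "SMA": (9.0, 18.0),
    "pSMA": (9.0, 36.0),
    "CMA": (9.0, -36.0),
    "S1H": (36.0, -18.0),
    "M1H": (36.0, 0.0),
    "PMd": (36.0, 18.0),
    "PMv": (58.0, 14.0),
}

_DEFAULT_RADIUS_DEG = 8.0


@dataclass(frozen=True)
class HeadModel:
    """Concentric three-sphere volume conductor.

    radii are (scalp, skull, brain) outer-shell radii in meters, strictly
    decreasing; conductivities are (scalp, skull, brain) in S/m.
    """

    radii: tuple[float, float, float] = (0.090, 0.085, 0.080)
    conductivities: tuple[float, float, float] = (1.0, 0.0125, 1.0)

    def __post_init__(self) -> None:
        r = self.radii
        if not (r[0] > r[1] > r[2] > 0):
            raise ValueError(f"radii must be strictly decreasing scalp > skull > brain, got {r}")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError(f"conductivities must be strictly positive, got {self.conductivities}")

    @property
    def scalp_radius(self) -> float:
        return self.radii[0]

    @property
    def skull_radius(self) -> float:
        return self.radii[1]

    @property
    def brain_radius(self) -> float:
        return self.radii[2]


def build_head_model(radii: tuple[float, float, float] = (0.090, 0.085, 0.080),
                     conductivities: tuple[float, float, float] = (1.0, 0.0125, 1.0)) -> HeadModel:
    """Validate and return a :class:`HeadModel` (defaults: scalp/brain 1 S/m, skull 0.0125 S/m)."""
    return HeadModel(tuple(radii), tuple(conductivities))


@dataclass
class ElectrodeArray:
    """Electrodes on the scalp sphere, average-referenced."""

    labels: list[str]
    positions: np.ndarray  # (n, 3), meters, norm == scalp radius
    reference: str = "average"
    mirror_index: np.ndarray | None = None  # permutation mapping each electrode to its x -> -x twin

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("electrode labels must be unique")
        if len(self.labels) < 4:
            raise ValueError("need at least 4 electrodes")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_electrodes, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.ptp(norms) > 1e-9:
            raise ValueError("all electrodes must sit on the scalp sphere")
        if self.reference != "average":
            raise ValueError("only the average reference is supported")

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)


def _ring_layout(ring_polar_deg: list[float], ring_counts: list[int]) -> np.ndarray:
    """Unit vectors on rings of constant polar angle, mirror-symmetric in x."""
    pts = []
    for polar, count in zip(ring_polar_deg, ring_counts):
        th = np.deg2rad(polar)
        if count == 1:
            pts.append([0.0, 0.0, 1.0] if polar == 0 else
                       [0.0, np.sin(th), np.cos(th)])
            continue
        # azimuths symmetric about phi = pi/2 so the set is closed under x -> -x
        phi = np.pi / 2 + 2 * np.pi * np.arange(count) / count
        pts.extend(np.column_stack([np.cos(phi) * np.sin(th),
                                    np.sin(phi) * np.sin(th),
                                    np.full(count, np.cos(th))]))
    return np.asarray(pts)


def build_electrode_array(n_electrodes: int = 32, head_model: HeadModel | None = None) -> ElectrodeArray:
    """Quasi-uniform upper-hemisphere montage of 32 (default) or 118 electrodes.

    Both layouts are built from rings of constant polar angle with azimuths
    chosen so the montage is exactly mirror-symmetric about the mid-sagittal
    plane; 118 channels approximates the density of a high-resolution 10-5
    montage.
    """
    head_model = head_model or HeadModel()
    if n_electrodes == 32:
        unit = _ring_layout([0, 22, 44, 66], [1, 6, 10, 15])
    elif n_electrodes == 118:
        unit = _ring_layout([0, 15, 30, 45, 60, 75, 85], [1, 6, 12, 18, 24, 28, 29])
    else:
        raise ValueError("supported montages: 32 or 118 electrodes")
    assert len(unit) == n_electrodes
    positions = unit * head_model.scalp_radius
    labels = [f"E{i + 1:03d}" for i in range(n_electrodes)]
    mirrored = positions * np.array([-1.0, 1.0, 1.0])
    # match each electrode to its mirror twin (exact by construction)
    d = np.linalg.norm(positions[:, None, :] - mirrored[None, :, :], axis=2)
    mirror_index = np.argmin(d, axis=0)
    if np.max(np.min(d, axis=0)) > 1e-9 * head_model.scalp_radius:
        raise RuntimeError("electrode layout is not mirror-symmetric")
    return ElectrodeArray(labels, positions, "average", mirror_index)


@dataclass(frozen=True)
class ROIRegion:
    id: str          # e.g. "S1H_L"
    name: str
    lobe: str        # "L" or "R"
    center: tuple[float, float, float]  # unit vector
    radius_deg: float


@dataclass
class ROIAtlas:
    regions: list[ROIRegion]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.regions]
        if len(ids) != len(set(ids)):
            raise ValueError("ROI ids must be unique")
        for lobe in ("L", "R"):
            if sum(r.lobe == lobe for r in self.regions) != len(self.regions) // 2:
                raise ValueError("atlas must have equally many regions per lobe")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.regions]

    def lobe_ids(self, lobe: str) -> list[str]:
        return [r.id for r in self.regions if r.lobe == lobe]

    def region(self, roi_id: str) -> ROIRegion:
        for r in self.regions:
            if r.id == roi_id:
                return r
        raise KeyError(f"unknown ROI id: {roi_id}")


def _cap_center(lateral_deg: float, anterior_deg: float, lobe: str) -> np.ndarray:
    """Unit vector for a cap center given lateral/anterior angles from vertex."""
    v = np.array([0.0, 0.0, 1.0])
    a = np.deg2rad(anterior_deg)
    # tilt toward +y (anterior)
    v = np.array([v[0], v[1] * np.cos(a) + v[2] * np.sin(a), -v[1] * np.sin(a) + v[2] * np.cos(a)])
    sign = -1.0 if lobe == "L" else 1.0  # left hemisphere is x < 0
    lat = np.deg2rad(lateral_deg)
    # tilt toward +/-x (lateral)
    v = np.array([v[0] * np.cos(lat) + sign * v[2] * np.sin(lat), v[1],
                  -sign * v[0] * np.sin(lat) + v[2] * np.cos(lat)])
    return v / np.linalg.norm(v)


_FULL_NAMES = {
    "S1F": "primary foot somatosensory area",
    "S1H": "primary hand somatosensory area",
    "CMA": "cingulate motor area",
    "M1F": "primary foot motor area",
    "M1H": "primary hand motor area",
    "SMA": "supplementary motor area",
    "pSMA": "presupplementary motor area",
    "PMd": "dorsal premotor cortex",
    "PMv": "ventral premotor cortex",
}


def build_roi_atlas(radius_deg: float = _DEFAULT_RADIUS_DEG,
                    centers_deg: dict[str, tuple[float, float]] | None = None) -> ROIAtlas:
    """18-region somatomotor atlas: 9 spherical caps per hemisphere.

    ``centers_deg`` maps base ids to (lateral, anterior) angles for the left
    hemisphere; the right hemisphere is generated by mirror symmetry.  Raises
    if any two same-hemisphere caps overlap.
    """
    centers = dict(_DEFAULT_CENTERS_DEG)
    if centers_deg:
        unknown = set(centers_deg) - set(ROI_BASE_IDS)
        if unknown:
            raise ValueError(f"unknown ROI base ids in overrides: {sorted(unknown)}")
        centers.update(centers_deg)
    regions: list[ROIRegion] = []
    for lobe in ("L", "R"):
        for base in ROI_BASE_IDS:
            lat, ant = centers[base]
            c = _cap_center(lat, ant, lobe)
            regions.append(ROIRegion(f"{base}_{lobe}", _FULL_NAMES[base], lobe,
                                     tuple(c), radius_deg))
    # same-lobe caps must not overlap
    for lobe in ("L", "R"):
        caps = [r for r in regions if r.lobe == lobe]
        for i in range(len(caps)):
            for j in range(i + 1, len(caps)):
                ang = np.rad2deg(np.arccos(np.clip(
                    np.dot(caps[i].center, caps[j].center), -1.0, 1.0)))
                if ang < caps[i].radius_deg + caps[j].radius_deg:
                    raise ValueError(
                        f"ROI caps overlap: {caps[i].id} and {caps[j].id} "
                        f"are {ang:.1f} deg apart with radii {caps[i].radius_deg} + {caps[j].radius_deg}")
    return ROIAtlas(regions)


@dataclass
class SourceSpace:
    """Radially oriented dipoles on a cortical sphere, labeled by ROI cap."""

    positions: np.ndarray    # (n, 3) meters, strictly inside the skull
    orientations: np.ndarray  # (n, 3) unit vectors (radial)
    roi_labels: np.ndarray    # (n,) ROI id or "background"
    atlas: ROIAtlas = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.roi_labels = np.asarray(self.roi_labels, dtype=object)
        if not np.allclose(np.linalg.norm(self.orientations, axis=1), 1.0, atol=1e-9):
            raise ValueError("orientations must be unit vectors")

    @property
    def n_sources(self) -> int:
        return len(self.positions)

    def roi_members(self, roi_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.roi_labels == roi_id)
        if idx.size == 0:
            raise ValueError(f"ROI {roi_id} has no member sources")
        return idx


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the full sphere (golden-angle lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_source_space(n_sources: int = 600, head_model: HeadModel | None = None,
                       atlas: ROIAtlas | str | None = "default", seed: int = 0,
                       depth_fraction: float = 0.95) -> SourceSpace:
    """Fibonacci-lattice source sphere at ``depth_fraction`` of the brain radius.

    Each source is labeled with the ROI cap containing it, or "background".
    The ``seed`` rotates the lattice azimuthally so different seeds yield
    different (but reproducible) samplings.  Raises if any atlas ROI ends up
    without member sources; pass ``atlas=None`` for an unlabeled space (e.g.
    pure localization studies).
    """
    head_model = head_model or HeadModel()
    if atlas == "default":
        atlas = build_roi_atlas()
    if atlas is not None and n_sources < 2 * len(atlas.regions):
        raise ValueError(f"n_sources must be at least {2 * len(atlas.regions)}")
    if not (0 < depth_fraction < 1):
        raise ValueError("depth_fraction must lie in (0, 1)")
    unit = _fibonacci_sphere(n_sources)
    rot = substream(seed, "source_space").uniform(0, 2 * np.pi)
    c, s = np.cos(rot), np.sin(rot)
    unit = unit @ np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]).T
    radius = depth_fraction * head_model.brain_radius
    positions = unit * radius
    labels = np.full(n_sources, "background", dtype=object)
    if atlas is not None:
        for region in atlas.regions:
            cos_r = np.cos(np.deg2rad(region.radius_deg))
            inside = unit @ np.asarray(region.center) >= cos_r
            labels[inside] = region.id
        empty = [r.id for r in atlas.regions if not np.any(labels == r.id)]
        if empty:
            raise ValueError(f"ROIs with no member sources (increase n_sources or cap radius): {empty}")
    return SourceSpace(positions, unit.copy(), labels, atlas)


@dataclass
class LeadField:
    """Gain matrix of the forward map W = L @ S (average-referenced)."""

    matrix: np.ndarray  # (n_electrodes, n_sources)
    electrode_ref: ElectrodeArray
    source_ref: SourceSpace

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(self.matrix).all():
            raise ValueError("lead field contains non-finite entries")


def _shell_series_coefficients(n_terms: int, b_norm: float, head_model: HeadModel) -> np.ndarray:
    """Legendre coefficients of the scalp potential of a radial unit dipole.

    Works in scalp-radius units; returns ``coef[n]`` for n = 0..n_terms such
    that V(theta) = (1/r_scalp^2) * sum_n coef[n] * P_n(cos theta).
    """
    r_scalp, r_skull, r_brain = head_model.radii
    sig_scalp, sig_skull, sig_brain = head_model.conductivities
    rho1 = r_brain / r_scalp   # brain/skull boundary
    rho2 = r_skull / r_scalp   # skull/scalp boundary
    coef = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        src = n * b_norm ** (n - 1) / (4 * np.pi * sig_brain)
        # unknowns [A1, A2, B2, A3, B3]; layer 1 = brain (contains the source),
        # layer 2 = skull, layer 3 = scalp
        a = np.zeros((5, 5))
        rhs = np.zeros(5)
        p1n, p1m = rho1 ** n, rho1 ** (-(n + 1))
        p2n, p2m = rho2 ** n, rho2 ** (-(n + 1))
        d1n, d1m = n * rho1 ** (n - 1), -(n + 1) * rho1 ** (-(n + 2))
        d2n, d2m = n * rho2 ** (n - 1), -(n + 1) * rho2 ** (-(n + 2))
        # potential continuity at brain/skull
        a[0] = [p1n, -p1n, -p1m, 0, 0]
        rhs[0] = -src * p1m
        # radial current continuity at brain/skull
        a[1] = [sig_brain * d1n, -sig_skull * d1n, -sig_skull * d1m, 0, 0]
        rhs[1] = -sig_brain * src * d1m
        # potential continuity at skull/scalp
        a[2] = [0, p2n, p2m, -p2n, -p2m]
        # radial current continuity at skull/scalp
        a[3] = [0, sig_skull * d2n, sig_skull * d2m, -sig_scalp * d2n, -sig_scalp * d2m]
        # zero radial current at the outer scalp surface (rho = 1)
        a[4] = [0, 0, 0, n, -(n + 1)]
        sol = np.linalg.solve(a, rhs)
        coef[n] = sol[3] + sol[4]  # A3 + B3 evaluated at rho = 1
    return coef


def compute_lead_field(electrodes: ElectrodeArray, sources: SourceSpace,
                       head_model: HeadModel | None = None, n_terms: int = 200,
                       convergence_tol: float = 1e-8) -> LeadField:
    """Analytic three-sphere lead field for radial dipoles, average-referenced.

    The truncated Legendre series is checked for self-consistency: the
    magnitude of the last retained term relative to the cumulative series
    must fall below ``convergence_tol`` or a diagnostic error is raised.
    """
    head_model = head_model or HeadModel()
    r_scalp = head_model.scalp_radius
    src_radii = np.linalg.norm(sources.positions, axis=1)
    if np.any(src_radii >= head_model.brain_radius):
        raise ValueError("all sources must lie strictly inside the brain radius")
    elec_norms = np.linalg.norm(electrodes.positions, axis=1)
    if not np.allclose(elec_norms, r_scalp, atol=1e-9):
        raise ValueError("electrodes must sit on the scalp radius of the head model")

    elec_unit = electrodes.positions / r_scalp
    gain = np.empty((electrodes.n_electrodes, sources.n_sources))
    # group sources by (identical) depth so shell coefficients are shared
    for b in np.unique(np.round(src_radii, 12)):
        idx = np.flatnonzero(np.abs(src_radii - b) < 1e-9)
        coef = _shell_series_coefficients(n_terms, b / r_scalp, head_model)
        cos_theta = elec_unit @ (sources.positions[idx] / src_radii[idx, None]).T
        vals = npleg.legval(cos_theta, coef)
        # convergence diagnostic: contribution of the final term
        tail = np.abs(coef[n_terms]) * 1.0  # |P_n| <= 1 on [-1, 1]
        scale = np.max(np.abs(vals)) + 1e-300
        if tail / scale > convergence_tol:
            raise RuntimeError(
                f"Legendre series not converged at n_terms={n_terms}: relative "
                f"last-term bound {tail / scale:.2e} > {convergence_tol:.0e}; increase n_terms")
        gain[:, idx] = vals / r_scalp ** 2
    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    return LeadField(gain, electrodes, sources)


def project_sources(leadfield: LeadField, source_activity: np.ndarray) -> np.ndarray:
    """Apply the forward map: W = L @ S, shape (n_electrodes, n_samples)."""
    source_activity = np.asarray(source_activity, dtype=float)
    if source_activity.ndim != 2 or source_activity.shape[0] != leadfield.matrix.shape[1]:
        raise ValueError(
            f"source_activity must be (n_sources={leadfield.matrix.shape[1]}, n_samples), "
            f"got {source_activity.shape}")
    return leadfield.matrix @ source_activity
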