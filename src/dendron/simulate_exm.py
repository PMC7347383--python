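"""Synthetic expansion-microscopy volumes with known synapse placements.

Generates two-channel 3D image volumes that emulate ~4.2x-expanded brain
tissue containing a single GnRH-neuron dendrite segment: channel 0 is the
cytoplasmic fill (a tube around the centerline), channel 1 holds presynaptic
marker puncta.  Puncta are placed either with their centroid on the tube
membrane ("synapses") or offset outward by a fixed gap ("decoys"), and the
ground truth of every placement is returned so that the quantification
pipeline can be validated by parameter recovery.

All lengths are micrometres.  Pre-expansion lengths refer to the original
tissue; post-expansion lengths are pre-expansion times the expansion factor
and are the frame in which voxels, centerlines and centroids live.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ExmGeneratorParams",
    "GeneratorTruth",
    "ImageVolume",
    "generate_exm_volume",
    "generate_truth",
    "make_centerline",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ExmGeneratorParams:
    """Parameters of the synthetic expanded-tissue imaging model.

    Attributes
    ----------
    expansion_factor : float
        Isotropic tissue expansion factor E (default 4.2, the value implied
        by a 60 um dendrite segment imaging at 252 um).
    voxel_xy, voxel_z : float
        Voxel size, um post-expansion.  The default 0.6 um z step matches
        confocal stacks collected at 600 nm focus intervals.
    psf_sigma_xy, psf_sigma_z : float
        Gaussian PSF sigmas, um post-expansion.  The lateral default treats
        the ~70 nm effective resolution of expanded tissue as the order of
        magnitude of the lateral FWHM.
    dendrite_radius : float
        Tube radius, um pre-expansion.
    segment_length : float
        Centerline arc length, um pre-expansion (60 for the proximal
        dendrite, 15 for the distal dendron).
    synapse_rate, decoy_rate : float
        Expected puncta per 10 um of pre-expansion centerline; counts are
        Poisson unless ``cluster_mean > 1``.
    decoy_gap : float
        Outward offset of decoy punctum centroids from the membrane, um
        pre-expansion.
    punctum_diameter_mean, punctum_diameter_sd : float
        Lognormal punctum diameter (pre-expansion FWHM of the rendered
        Gaussian blob before PSF convolution).
    noise_sd : float
        Additive Gaussian noise, relative to the unit tube intensity.
    curvature_amplitude : float
        Amplitude (um pre-expansion) of an optional smooth sinusoidal bend
        of the centerline; 0 gives a straight dendrite.
    cluster_mean : float
        Mean puncta per innervation cluster.  1 (default) gives homogeneous
        Poisson placement; values > 1 give a Neyman-Scott clustered pattern
        with the same overall rate.
    cluster_sd : float
        Within-cluster spread along the centerline, um pre-expansion.
    """

    expansion_factor: float = 4.2
    voxel_xy: float = 0.1
    voxel_z: float = 0.6
    psf_sigma_xy: float = 0.07
    psf_sigma_z: float = 0.3
    dendrite_radius: float = 0.4
    segment_length: float = 15.0
    synapse_rate: float = 2.0
    decoy_rate: float = 2.0
    decoy_gap: float = 1.0
    punctum_diameter_mean: float = 0.8
    punctum_diameter_sd: float = 0.16
    noise_sd: float = 0.02
    curvature_amplitude: float = 0.0
    cluster_mean: float = 1.0
    cluster_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.expansion_factor > 1:
            raise ValueError("expansion_factor must exceed 1")
        for name in ("voxel_xy", "voxel_z", "psf_sigma_xy", "psf_sigma_z",
                     "dendrite_radius", "segment_length", "decoy_gap",
                     "punctum_diameter_mean"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("synapse_rate", "decoy_rate", "noise_sd",
                     "punctum_diameter_sd", "curvature_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cluster_mean < 1:
            raise ValueError("cluster_mean must be >= 1")
        if self.segment_length * self.expansion_factor < self.voxel_xy:
            raise ValueError("segment shorter than one voxel")


@dataclass
class GeneratorTruth:
    """Ground-truth puncta placements emitted alongside a synthetic volume.

    ``synapse_positions`` / ``decoy_positions`` are arc-length coordinates
    along the centerline in um pre-expansion; ``punctum_records`` carry the
    post-expansion centroid (x, y, z um), pre-expansion diameter and label.
    """

    synapse_positions: np.ndarray
    decoy_positions: np.ndarray
    punctum_records: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "synapse_positions_um_pre": [float(v) for v in self.synapse_positions],
            "decoy_positions_um_pre": [float(v) for v in self.decoy_positions],
            "punctum_records": [
                {**r, "centroid_um_post": [float(v) for v in r["centroid_um_post"]]}
                for r in self.punctum_records
            ],
        }


@dataclass
class ImageVolume:
    """Two-channel 3D voxel grid with physical calibration.

    ``voxels`` has shape (2, nz, ny, nx); axis order within a channel is
    (z, y, x).  Physical coordinates are um post-expansion with the origin
    at the centre of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    voxel_xy: float
    voxel_z: float
    expansion_factor: float
    channel_names: tuple[str, str] = ("cytoplasm", "presynaptic")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 4 or self.voxels.shape[0] != 2:
            raise ValueError("voxels must have shape (2, nz, ny, nx)")
        if self.voxels.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) in um post-expansion."""
        nz, ny, nx = self.shape
        return (nx * self.voxel_xy, ny * self.voxel_xy, nz * self.voxel_z)


def make_centerline(params: ExmGeneratorParams, n_nodes: int = 201,
                    y_center: float = 0.0, z_center: float = 0.0,
                    x_start: float = 0.0) -> np.ndarray:
    """Centerline polyline, (n, 3) array of (x, y, z) um post-expansion.

    Straight along x by default; ``curvature_amplitude`` adds one period of
    a smooth sine bend in y.
    """
    E = params.expansion_factor
    length_post = params.segment_length * E
    x = np.linspace(x_start, x_start + length_post, n_nodes)
    y = np.full_like(x, y_center)
    if params.curvature_amplitude > 0:
        y = y + params.curvature_amplitude * E * np.sin(
            2 * np.pi * (x - x_start) / length_post)
    z = np.full_like(x, z_center)
    return np.column_stack([x, y, z])


def _polyline_arcs(centerline: np.ndarray) -> np.ndarray:
    seg = np.diff(centerline, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])


def _point_and_frame_at_arc(centerline: np.ndarray, arcs: np.ndarray,
                            s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolated point plus two unit normals spanning the plane
    perpendicular to the local tangent."""
    s = float(np.clip(s, 0.0, arcs[-1]))
    i = int(np.clip(np.searchsorted(arcs, s) - 1, 0, len(arcs) - 2))
    f = (s - arcs[i]) / max(arcs[i + 1] - arcs[i], 1e-12)
    pt = centerline[i] + f * (centerline[i + 1] - centerline[i])
    t = centerline[i + 1] - centerline[i]
    t = t / np.linalg.norm(t)
    # normal basis: n1 in the plane closest to y, n2 completes the frame
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref, t)) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    n1 = ref - np.dot(ref, t) * t
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(t, n1)
    return pt, n1, n2


def _draw_positions(rng: np.random.Generator, rate_per_10um: float,
                    length: float, cluster_mean: float,
                    cluster_sd: float) -> np.ndarray:
    """Arc-length positions (um pre-expansion) of puncta along the segment."""
    expected = rate_per_10um * length / 10.0
    if expected <= 0:
        return np.empty(0)
    if cluster_mean <= 1.0:
        n = rng.poisson(expected)
        return np.sort(rng.uniform(0.0, length, size=n))
    n_clusters = rng.poisson(expected / cluster_mean)
    pos = []
    for _ in range(n_clusters):
        c = rng.uniform(0.0, length)
        k = max(1, rng.poisson(cluster_mean))
        pos.extend(np.clip(rng.normal(c, cluster_sd, size=k), 0.0, length))
    return np.sort(np.asarray(pos))


def generate_truth(params: ExmGeneratorParams,
                   centerline: np.ndarray | None = None) -> GeneratorTruth:
    """Draw puncta placements (without rendering a volume).

    Uses the same random sub-streams as :func:`generate_exm_volume`, so the
    truth for a given seed is identical whether or not a volume is rendered
    and is unaffected by ``noise_sd``.
    """
    E = params.expansion_factor
    if centerline is None:
        centerline = make_centerline(params)
    arcs = _polyline_arcs(centerline)
    ss = np.random.SeedSequence(params.seed)
    place_rng, size_rng, _noise = [np.random.default_rng(c) for c in ss.spawn(3)]

    L = params.segment_length
    syn = _draw_positions(place_rng, params.synapse_rate, L,
                          params.cluster_mean, params.cluster_sd)
    dec = _draw_positions(place_rng, params.decoy_rate, L,
                          params.cluster_mean, params.cluster_sd)
    phis = place_rng.uniform(0, 2 * np.pi, size=len(syn) + len(dec))

    mean, sd = params.punctum_diameter_mean, params.punctum_diameter_sd
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    diams = np.exp(size_rng.normal(mu, np.sqrt(sigma2), size=len(phis)))

    r_post = params.dendrite_radius * E
    records = []
    for k, (s_pre, label) in enumerate(
            [(s, "synapse") for s in syn] + [(s, "decoy") for s in dec]):
        pt, n1, n2 = _point_and_frame_at_arc(centerline, arcs, s_pre * E)
        rho = r_post if label == "synapse" else r_post + params.decoy_gap * E
        phi = phis[k]
        centroid = pt + rho * (np.cos(phi) * n1 + np.sin(phi) * n2)
        records.append({
            "centroid_um_post": centroid,
            "diameter_um_pre": float(diams[k]),
            "label": label,
            "arc_um_pre": float(s_pre),
        })
    return GeneratorTruth(synapse_positions=syn, decoy_positions=dec,
                          punctum_records=records)


def _render_tube(shape: tuple[int, int, int], centerline: np.ndarray,
                 radius_post: float, voxel_xy: float, voxel_z: float) -> np.ndarray:
    nz, ny, nx = shape
    xs = np.arange(nx) * voxel_xy
    ys = np.arange(ny) * voxel_xy
    zs = np.arange(nz) * voxel_z
    straight = np.allclose(centerline[:, 1], centerline[0, 1]) and \
        np.allclose(centerline[:, 2], centerline[0, 2])
    vol = np.zeros(shape, dtype=np.float32)
    if straight:
        d2 = (ys[None, :] - centerline[0, 1]) ** 2 + \
            (zs[:, None] - centerline[0, 2]) ** 2
        disk = (d2 <= radius_post ** 2).astype(np.float32)  # (nz, ny)
        xmask = (xs >= centerline[0, 0]) & (xs <= centerline[-1, 0])
        vol[:, :, xmask] = disk[:, :, None]
        return vol
    # curved: distance to a finely resampled centerline, evaluated only in a
    # bounding slab around the tube to keep memory in check
    arcs = _polyline_arcs(centerline)
    fine_s = np.arange(0, arcs[-1], voxel_xy / 2)
    fine = np.array([_point_and_frame_at_arc(centerline, arcs, s)[0] for s in fine_s])
    from scipy.spatial import cKDTree
    tree = cKDTree(fine)
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    d, _ = tree.query(pts, workers=-1)
    vol = (d.reshape(shape) <= radius_post).astype(np.float32)
    return vol


def _add_gaussian_blob(channel: np.ndarray, centroid: np.ndarray,
                       sigma_post: float, voxel_xy: float, voxel_z: float) -> None:
    """Add an isotropic (in physical units) Gaussian blob of peak 1 in place."""
    nz, ny, nx = channel.shape
    cx, cy, cz = centroid
    half = 4.0 * sigma_post
    ix0 = max(0, int(np.floor((cx - half) / voxel_xy)))
    ix1 = min(nx, int(np.ceil((cx + half) / voxel_xy)) + 1)
    iy0 = max(0, int(np.floor((cy - half) / voxel_xy)))
    iy1 = min(ny, int(np.ceil((cy + half) / voxel_xy)) + 1)
    iz0 = max(0, int(np.floor((cz - half) / voxel_z)))
    iz1 = min(nz, int(np.ceil((cz + half) / voxel_z)) + 1)
    if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
        return
    gx = np.exp(-((np.arange(ix0, ix1) * voxel_xy - cx) ** 2) / (2 * sigma_post ** 2))
    gy = np.exp(-((np.arange(iy0, iy1) * voxel_xy - cy) ** 2) / (2 * sigma_post ** 2))
    gz = np.exp(-((np.arange(iz0, iz1) * voxel_z - cz) ** 2) / (2 * sigma_post ** 2))
    blob = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    np.maximum(channel[iz0:iz1, iy0:iy1, ix0:ix1],
               blob.astype(np.float32),
               out=channel[iz0:iz1, iy0:iy1, ix0:ix1])


def generate_exm_volume(
        params: ExmGeneratorParams,
) -> tuple[ImageVolume, np.ndarray, GeneratorTruth]:
    """Render a two-channel synthetic ExM volume.

    Returns the volume, the centerline polyline ((n, 3) um post-expansion)
    and the ground-truth placements.  Identical parameters (including seed)
    give bit-identical output; the truth is unaffected by ``noise_sd``
    because placement, size and noise use separate random sub-streams.
    """
    E = params.expansion_factor
    r_post = params.dendrite_radius * E
    d_post = params.punctum_diameter_mean * E

    if params.decoy_rate > 0 and params.decoy_gap * E < 2 * params.psf_sigma_xy:
        warnings.warn("decoy_gap is below the PSF scale; decoys will be "
                      "unresolvable from membrane-contacting puncta",
                      stacklevel=2)

    pad = d_post / 2 + 4 * params.psf_sigma_z + 1.0
    half_r = r_post + (params.decoy_gap * E if params.decoy_rate > 0 else 0.0) \
        + d_post + 2.0
    bend = params.curvature_amplitude * E
    length_post = params.segment_length * E
    nx = int(np.ceil((length_post + 2 * pad) / params.voxel_xy))
    ny = int(np.ceil(2 * (half_r + bend) / params.voxel_xy))
    nz = int(np.ceil(2 * half_r / params.voxel_z))

    y_c = ny * params.voxel_xy / 2
    z_c = nz * params.voxel_z / 2
    centerline = make_centerline(params, y_center=y_c, z_center=z_c, x_start=pad)
    truth = generate_truth(params, centerline)

    cyto = _render_tube((nz, ny, nx), centerline, r_post,
                        params.voxel_xy, params.voxel_z)
    presyn = np.zeros_like(cyto)
    for rec in truth.punctum_records:
        sigma = rec["diameter_um_pre"] * E / _FWHM_PER_SIGMA
        _add_gaussian_blob(presyn, rec["centroid_um_post"], sigma,
                           params.voxel_xy, params.voxel_z)

    sig_vox = (params.psf_sigma_z / params.voxel_z,
               params.psf_sigma_xy / params.voxel_xy,
               params.psf_sigma_xy / params.voxel_xy)
    cyto = gaussian_filter(cyto, sig_vox)
    presyn = gaussian_filter(presyn, sig_vox)

    ss = np.random.SeedSequence(params.seed)
    noise_rng = np.random.default_rng(ss.spawn(3)[2])
    if params.noise_sd > 0:
        noise = noise_rng.normal(0.0, params.noise_sd, size=(2, nz, ny, nx))
    else:
        noise = np.zeros((2, nz, ny, nx))
    voxels = np.clip(np.stack([cyto, presyn]) + noise, 0.0, None)

    volume = ImageVolume(voxels=voxels, voxel_xy=params.voxel_xy,
                         voxel_z=params.voxel_z, expansion_factor=E)
    return volume, centerline, truth
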