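"""Synthetic two-channel 3D stacks with Gaussian puncta and geometric occluders.

Puncta are rendered as isotropic 3D Gaussians whose full width at half
maximum matches the marker diameter (0.5 µm presynaptic, 0.3 µm
postsynaptic); anisotropic voxels are handled by working in physical µm
coordinates throughout. Paired pre/post puncta sit within the juxtaposition
distance (0.5 µm); occluders (nucleus spheres, vessel tubes) are rendered
into a third channel and no punctum is placed inside them. Photon noise is
Poisson, scaled so the peak signal-to-noise ratio equals ``snr``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from synaptomics.puncta import (
    FWHM_FACTOR,
    POST_DIAMETER_UM,
    PRE_DIAMETER_UM,
    ImageStack,
)
from synaptomics.synthetic.design import ParameterError


@dataclass
class ImageGroundTruth:
    """Planted puncta geometry and occluders for one synthetic stack."""

    pre_centroids: np.ndarray  # (n, 3) µm, (z, y, x)
    post_centroids: np.ndarray
    paired_indices: list[tuple[int, int]]
    nucleus_blobs: list[tuple[tuple[float, float, float], float]] = field(default_factory=list)
    vessel_tubes: list[tuple[tuple, tuple, float]] = field(default_factory=list)
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)
    stack_shape: tuple[int, int, int] = (20, 256, 256)
    pairing_distance: float = 0.5

    def __post_init__(self) -> None:
        self.pre_centroids = np.asarray(self.pre_centroids, float).reshape(-1, 3)
        self.post_centroids = np.asarray(self.post_centroids, float).reshape(-1, 3)
        extent = np.asarray(self.stack_shape) * np.asarray(self.voxel_size)
        for name, pts in (("pre", self.pre_centroids), ("post", self.post_centroids)):
            if len(pts) and ((pts < 0).any() or (pts >= extent).any()):
                raise ParameterError(f"{name} centroids fall outside the stack bounds")
        for i, j in self.paired_indices:
            d = np.linalg.norm(self.pre_centroids[i] - self.post_centroids[j])
            if d > self.pairing_distance + 1e-9:
                raise ParameterError(
                    f"paired separation {d:.3f} µm exceeds {self.pairing_distance} µm")
        for pts in (self.pre_centroids, self.post_centroids):
            for p in pts:
                if self._inside_occluder(p):
                    raise ParameterError("a centroid lies inside an occluder")

    def _inside_occluder(self, p: np.ndarray) -> bool:
        for center, r in self.nucleus_blobs:
            if np.linalg.norm(p - np.asarray(center)) <= r:
                return True
        for p0, p1, r in self.vessel_tubes:
            if _point_segment_distance(p, np.asarray(p0), np.asarray(p1)) <= r:
                return True
        return False

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.stack_shape) * np.asarray(self.voxel_size)

    def occluded_volume_um3(self, oversample: int = 2) -> float:
        """Monte-Carlo-free voxel estimate of the occluder volume in µm³."""
        if not self.nucleus_blobs and not self.vessel_tubes:
            return 0.0
        mask = render_occluder_mask(self, oversample=1)
        return float(mask.sum()) * float(np.prod(self.voxel_size))


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = float(np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-12), 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def _voxel_grids_um(shape, voxel_size):
    zs = (np.arange(shape[0]) + 0.5) * voxel_size[0]
    ys = (np.arange(shape[1]) + 0.5) * voxel_size[1]
    xs = (np.arange(shape[2]) + 0.5) * voxel_size[2]
    return zs, ys, xs


def render_occluder_mask(truth: ImageGroundTruth, oversample: int = 1) -> np.ndarray:
    """Boolean voxel mask of all occluders (voxel centers inside any object)."""
    zs, ys, xs = _voxel_grids_um(truth.stack_shape, truth.voxel_size)
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    mask = np.zeros(truth.stack_shape, dtype=bool)
    for center, r in truth.nucleus_blobs:
        cz, cy, cx = center
        mask |= (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    for p0, p1, r in truth.vessel_tubes:
        a, b = np.asarray(p0, float), np.asarray(p1, float)
        ab = b - a
        denom = max(float(ab @ ab), 1e-12)
        pz, py, px = zz - a[0], yy - a[1], xx - a[2]
        t = np.clip((pz * ab[0] + py * ab[1] + px * ab[2]) / denom, 0.0, 1.0)
        d2 = ((pz - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (px - t * ab[2]) ** 2)
        mask |= d2 <= r ** 2
    return mask


def simulate_image_truth(
    n_pairs: int = 200,
    n_unpaired_pre: int = 20,
    n_unpaired_post: int = 20,
    stack_shape: tuple[int, int, int] = (20, 256, 256),
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1),
    pairing_distance: float = 0.5,
    pair_sep_range: tuple[float, float] = (0.1, 0.4),
    min_spot_separation: float = 1.0,
    n_nuclei: int = 0,
    nucleus_radius_um: float = 1.5,
    n_vessels: int = 0,
    vessel_radius_um: float = 1.0,
    seed: int = 0,
) -> ImageGroundTruth:
    """Sample a ground-truth puncta geometry by rejection.

    Paired presynaptic puncta are offset from their postsynaptic partner by a
    uniformly oriented displacement with norm in ``pair_sep_range`` (inside
    the 0.5-µm juxtaposition distance). Same-channel puncta keep at least
    ``min_spot_separation`` µm apart so detection resolves them, and unpaired
    puncta stay > ``pairing_distance`` + margin from every opposite-channel
    punctum so they never form spurious pairs.
    """
    rng = np.random.default_rng(seed)
    extent = np.asarray(stack_shape) * np.asarray(voxel_size)
    margin = 0.6
    if (extent <= 2 * margin).any():
        raise ParameterError("stack too small for the placement margin")

    nuclei = []
    for _ in range(n_nuclei):
        c = rng.uniform(margin, extent - margin)
        nuclei.append((tuple(float(v) for v in c), nucleus_radius_um))
    vessels = []
    for _ in range(n_vessels):
        y = float(rng.uniform(margin, extent[1] - margin))
        z = float(rng.uniform(margin, extent[0] - margin))
        vessels.append(((z, y, 0.0), (z, y, float(extent[2])), vessel_radius_um))

    def inside_occluder(p, pad=0.3):
        for center, r in nuclei:
            if np.linalg.norm(p - np.asarray(center)) <= r + pad:
                return True
        for p0, p1, r in vessels:
            if _point_segment_distance(p, np.asarray(p0), np.asarray(p1)) <= r + pad:
                return True
        return False

    def far_enough(p, others, d):
        return all(np.linalg.norm(p - o) > d for o in others)

    post_pts: list[np.ndarray] = []
    pre_pts: list[np.ndarray] = []
    pairs: list[tuple[int, int]] = []

    def draw_point(avoid_same, avoid_other, other_gap):
        for _ in range(20000):
            p = rng.uniform(margin, extent - margin)
            if inside_occluder(p):
                continue
            if not far_enough(p, avoid_same, min_spot_separation):
                continue
            if other_gap and not far_enough(p, avoid_other, other_gap):
                continue
            return p
        raise ParameterError("could not place puncta; reduce counts or enlarge stack")

    for _ in range(n_pairs):
        # if no valid partner exists around a drawn post site, redraw the post
        for _ in range(200):
            post = draw_point(post_pts, pre_pts, pairing_distance + 0.2)
            pre = None
            for _ in range(200):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                sep = rng.uniform(*pair_sep_range)
                cand = post + sep * v
                if ((cand < margin).any() or (cand >= extent - margin).any()
                        or inside_occluder(cand)
                        or not far_enough(cand, pre_pts, min_spot_separation)):
                    continue
                pre = cand
                break
            if pre is not None:
                break
        else:
            raise ParameterError("could not place a paired pre/post punctum")
        pairs.append((len(pre_pts), len(post_pts)))
        post_pts.append(post)
        pre_pts.append(pre)

    gap = pairing_distance + 0.2
    for _ in range(n_unpaired_pre):
        pre_pts.append(draw_point(pre_pts, post_pts, gap))
    for _ in range(n_unpaired_post):
        post_pts.append(draw_point(post_pts, pre_pts, gap))

    return ImageGroundTruth(
        pre_centroids=np.asarray(pre_pts).reshape(-1, 3),
        post_centroids=np.asarray(post_pts).reshape(-1, 3),
        paired_indices=pairs,
        nucleus_blobs=nuclei,
        vessel_tubes=vessels,
        voxel_size=voxel_size,
        stack_shape=stack_shape,
        pairing_distance=pairing_distance,
    )


def _render_gaussians(shape, voxel_size, centroids, sigma_um, amplitude) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    if len(centroids) == 0:
        return img
    voxel = np.asarray(voxel_size)
    half = np.ceil(4 * sigma_um / voxel).astype(int)
    for c in centroids:
        c_vox = c / voxel - 0.5  # voxel-center convention
        lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
        hi = np.minimum(np.floor(c_vox).astype(int) + half + 2, shape)
        if (lo >= hi).any():
            continue
        zs = ((np.arange(lo[0], hi[0]) + 0.5) * voxel[0] - c[0]) ** 2
        ys = ((np.arange(lo[1], hi[1]) + 0.5) * voxel[1] - c[1]) ** 2
        xs = ((np.arange(lo[2], hi[2]) + 0.5) * voxel[2] - c[2]) ** 2
        d2 = zs[:, None, None] + ys[None, :, None] + xs[None, None, :]
        img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(
            -d2 / (2 * sigma_um ** 2))
    return img


def generate_image_stack(
    truth: ImageGroundTruth,
    snr: float = 20.0,
    amplitude: float = 1000.0,
    background_counts: float = 1.0,
    seed: int = 0,
) -> tuple[ImageStack, ImageGroundTruth]:
    """Render the ground truth into a noisy two-channel stack (+ occluders).

    Poisson noise is applied in scaled photon counts so the expected peak SNR
    (peak counts / sqrt(peak counts)) equals ``snr``.
    """
    if snr <= 0:
        raise ParameterError("snr must be positive")
    rng = np.random.default_rng(seed)
    pre_sigma = PRE_DIAMETER_UM / FWHM_FACTOR
    post_sigma = POST_DIAMETER_UM / FWHM_FACTOR
    pre = _render_gaussians(truth.stack_shape, truth.voxel_size,
                            truth.pre_centroids, pre_sigma, amplitude)
    post = _render_gaussians(truth.stack_shape, truth.voxel_size,
                             truth.post_centroids, post_sigma, amplitude)
    channels = {}
    scale = snr ** 2 / amplitude
    for name, img in (("pre", pre), ("post", post)):
        lam = img * scale + background_counts
        channels[name] = rng.poisson(lam).astype(float) / scale
    if truth.nucleus_blobs or truth.vessel_tubes:
        occ = render_occluder_mask(truth).astype(float) * amplitude
        lam = occ * scale + background_counts
        channels["occluder"] = rng.poisson(lam).astype(float) / scale
    stack = ImageStack(channels=channels, voxel_size=truth.voxel_size)
    return stack, truth


# ----------------------------------------------------------------- TIFF I/O

def write_image_stack(stack: ImageStack, truth: ImageGroundTruth | None, path_base: str) -> None:
    """Write a multi-page TIFF (channels stacked along axis 0) + JSON sidecar."""
    order = sorted(stack.channels)
    arr = np.stack([stack.channels[c] for c in order]).astype(np.float32)
    tifffile.imwrite(f"{path_base}.tif", arr)
    side = {
        "channels": order,
        "voxel_size_um": list(stack.voxel_size),
        "animal_id": stack.animal_id,
        "layer": stack.layer,
        "marker_pair": stack.marker_pair,
        "group": stack.group,
        "sex": stack.sex,
    }
    if truth is not None:
        side["ground_truth"] = {
            "pre_centroids_um": truth.pre_centroids.tolist(),
            "post_centroids_um": truth.post_centroids.tolist(),
            "paired_indices": [list(p) for p in truth.paired_indices],
            "nucleus_blobs": [[list(c), r] for c, r in truth.nucleus_blobs],
            "pairing_distance_um": truth.pairing_distance,
        }
    with open(f"{path_base}.json", "w") as fh:
        json.dump(side, fh, indent=2)


def read_image_stack(path_base: str) -> ImageStack:
    """Read a stack written by :func:`write_image_stack`."""
    arr = tifffile.imread(f"{path_base}.tif")
    with open(f"{path_base}.json") as fh:
        side = json.load(fh)
    channels = {name: arr[i].astype(float) for i, name in enumerate(side["channels"])}
    return ImageStack(
        channels=channels,
        voxel_size=tuple(side["voxel_size_um"]),
        animal_id=side.get("animal_id", ""),
        layer=side.get("layer", ""),
        marker_pair=side.get("marker_pair", ""),
        group=side.get("group", ""),
        sex=side.get("sex", ""),
    )
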