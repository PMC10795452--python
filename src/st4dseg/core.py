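"""Data model and I/O for respiratory 4D-CT.

A 4D-CT is an ordered set of P phase volumes reconstructed over one
respiratory cycle (phase tags "00%".."90%" for P=10; 0% is end-inspiration,
50% end-expiration). Arrays are indexed ``(h, w, k, p)`` with 0-based
indices: ``h`` rows run anterior-posterior, ``w`` columns left-right, and
``k`` slices superior to inferior. Intensities are Hounsfield units and are
passed through I/O unmodified.

Triplet sampling defines the network inputs: the *spatial* triplet is three
anatomically adjacent slices within one phase (slice edges clamp — anatomy
is not periodic along the scan axis), and the *temporal* triplet is the same
slice index in the previous/current/next phase (phase edges wrap — the
respiratory cycle is periodic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FourDCT",
    "TripletPair",
    "PhaseMaskSet",
    "default_phase_labels",
    "load_phase_volumes",
    "load_manifest",
    "extract_triplet",
    "normalize_hu",
    "merge_igtv",
    "save_mask",
    "load_mask",
    "save_volume",
    "crop_volume",
]

#: HU display window used for network input normalization; brackets both the
#: tumor (about -171..497 HU, mean 25) and liver (about 10..228 HU, mean 106.5)
#: intensity ranges seen in free-breathing liver 4D-CT.
DEFAULT_HU_WINDOW = (-200.0, 300.0)

SPACING_ATOL_MM = 1e-3


def default_phase_labels(p: int) -> list[str]:
    """Phase tags "00%", "10%", ... for an even split of the cycle."""
    return [f"{round(100 * i / p):02d}%" for i in range(p)]


@dataclass
class FourDCT:
    """A 4D-CT tensor ``data[h, w, k, p]`` in HU with voxel geometry.

    ``spacing`` is (row mm, col mm, slice mm); ``phase_labels`` is the
    acquisition-ordered list of P unique phase tags.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    phase_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D array (h, w, k, p), got ndim={self.data.ndim}")
        if self.P < 3:
            raise ValueError(f"P >= 3 required for temporal triplets, got P={self.P}")
        if self.L < 1:
            raise ValueError("L >= 1 required")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if not self.phase_labels:
            self.phase_labels = default_phase_labels(self.P)
        if len(self.phase_labels) != self.P:
            raise ValueError(
                f"{len(self.phase_labels)} phase labels for P={self.P} phases"
            )
        if len(set(self.phase_labels)) != self.P:
            raise ValueError("phase labels must be unique")

    @property
    def H(self) -> int:
        return self.data.shape[0]

    @property
    def W(self) -> int:
        return self.data.shape[1]

    @property
    def L(self) -> int:
        return self.data.shape[2]

    @property
    def P(self) -> int:
        return self.data.shape[3]

    def phase(self, p: int) -> np.ndarray:
        """The 3D volume of phase ``p``, shape (H, W, L)."""
        return self.data[..., p]

    def slice(self, p: int, k: int) -> np.ndarray:
        return self.data[:, :, k, p]


@dataclass
class TripletPair:
    """One network sample: spatial and temporal triplets centered on slice (p, k).

    ``spatial`` stacks (I_p^{k-1}, I_p^k, I_p^{k+1}) and ``temporal`` stacks
    (I_{p-1}^k, I_p^k, I_{p+1}^k), each as a (3, H, W) array whose middle
    entry is the shared center slice.
    """

    spatial: np.ndarray
    temporal: np.ndarray
    center: tuple[int, int]
    label: np.ndarray | None = None

    def __post_init__(self):
        if self.spatial.shape != self.temporal.shape or self.spatial.shape[0] != 3:
            raise ValueError("spatial and temporal triplets must both be (3, H, W)")
        if not np.array_equal(self.spatial[1], self.temporal[1]):
            raise ValueError("triplet centers disagree: both must be I_p^k")
        if self.label is not None and self.label.shape != self.spatial.shape[1:]:
            raise ValueError("label extents must match the slice extents")


@dataclass
class PhaseMaskSet:
    """Per-phase binary masks (H, W, L, P) with optional merged IGTV volume."""

    masks: np.ndarray
    spacing: tuple[float, float, float]
    igtv: np.ndarray | None = None

    def __post_init__(self):
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 4:
            raise ValueError("masks must be a 4D (h, w, k, p) array")
        _check_binary(self.masks)
        if self.igtv is not None:
            _check_binary(self.igtv)

    @property
    def P(self) -> int:
        return self.masks.shape[3]

    def phase(self, p: int) -> np.ndarray:
        return self.masks[..., p]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _check_binary(arr):
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask must be strictly 0/1-valued, found values {vals[:5]}")


# ---------------------------------------------------------------------------
# I/O (NIfTI-1; spacing from the affine/zooms, one file per phase)
# ---------------------------------------------------------------------------

def _read_nifti(path):
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of types
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def load_phase_volumes(paths, spacing_override=None) -> FourDCT:
    """Assemble one 4D-CT from ordered per-phase NIfTI files.

    All files must share extents exactly and spacing to within 1e-3 mm;
    ``spacing_override`` replaces the header spacing when given.
    """
    paths = [Path(p) for p in paths]
    if len(paths) < 3:
        raise ValueError(f"P >= 3 required, got {len(paths)} phase files")
    volumes, spacings = [], []
    for path in paths:
        data, spacing = _read_nifti(path)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D phase volume, got ndim={data.ndim}")
        if volumes and data.shape != volumes[0].shape:
            raise ValueError(
                f"{path}: extents {data.shape} differ from first phase {volumes[0].shape}"
            )
        if spacings and not np.allclose(spacing, spacings[0], atol=SPACING_ATOL_MM):
            raise ValueError(
                f"{path}: spacing {spacing} differs from first phase {spacings[0]}"
            )
        volumes.append(data)
        spacings.append(spacing)
    spacing = spacing_override if spacing_override is not None else spacings[0]
    return FourDCT(np.stack(volumes, axis=-1), spacing)


def load_manifest(manifest_path) -> FourDCT:
    """Load a 4D set from a plain-text manifest (one NIfTI path per line, phase order)."""
    manifest_path = Path(manifest_path)
    lines = [ln.strip() for ln in manifest_path.read_text().splitlines()]
    paths = [manifest_path.parent / ln for ln in lines if ln and not ln.startswith("#")]
    return load_phase_volumes(paths)


def _affine(spacing):
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_volume(volume, spacing, path):
    """Write a 3D array as NIfTI-1 with a diagonal affine from the spacing."""
    img = nib.Nifti1Image(np.asarray(volume), _affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def save_mask(mask, spacing, path):
    """Write a binary mask volume; round-trips bit-exactly through :func:`load_mask`."""
    mask = np.asarray(mask)
    _check_binary(mask)
    save_volume(mask.astype(np.uint8), spacing, path)


def load_mask(path):
    data, spacing = _read_nifti(path)
    _check_binary(data)
    return data.astype(np.uint8), spacing


# ---------------------------------------------------------------------------
# sampling and preprocessing
# ---------------------------------------------------------------------------

def extract_triplet(ct: FourDCT, p: int, k: int, with_label=None) -> TripletPair:
    """Build the spatial/temporal triplet pair centered on slice (p, k).

    Phase neighbors wrap cyclically; slice neighbors clamp at the volume
    edges. ``with_label`` is an optional (H, W, L, P) mask array from which
    the center label slice is taken.
    """
    if not (0 <= p < ct.P):
        raise IndexError(f"phase index {p} out of range [0, {ct.P})")
    if not (0 <= k < ct.L):
        raise IndexError(f"slice index {k} out of range [0, {ct.L})")
    k_lo, k_hi = max(k - 1, 0), min(k + 1, ct.L - 1)
    p_prev, p_next = (p - 1) % ct.P, (p + 1) % ct.P
    spatial = np.stack([ct.slice(p, k_lo), ct.slice(p, k), ct.slice(p, k_hi)])
    temporal = np.stack([ct.slice(p_prev, k), ct.slice(p, k), ct.slice(p_next, k)])
    label = None if with_label is None else np.asarray(with_label)[:, :, k, p]
    return TripletPair(spatial, temporal, (p, k), label)


def temporal_neighbors(p: int, P: int) -> tuple[int, int, int]:
    """Cyclic (previous, center, next) phase indices."""
    return ((p - 1) % P, p, (p + 1) % P)


def spatial_neighbors(k: int, L: int) -> tuple[int, int, int]:
    """Clamped (above, center, below) slice indices."""
    return (max(k - 1, 0), k, min(k + 1, L - 1))


def normalize_hu(x, window=DEFAULT_HU_WINDOW):
    """Affine map of HU into [0, 1] over ``window``, clipped outside it."""
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise ValueError(f"window low {lo} must be below high {hi}")
    return np.clip((np.asarray(x, dtype=np.float32) - lo) / (hi - lo), 0.0, 1.0)


def merge_igtv(masks: PhaseMaskSet) -> PhaseMaskSet:
    """Merge per-phase tumor masks into the internal GTV: the exact voxelwise union."""
    if masks.masks.shape[3] == 0:
        raise ValueError("cannot merge an empty mask set")
    igtv = (masks.masks.any(axis=3)).astype(np.uint8)
    return PhaseMaskSet(masks.masks, masks.spacing, igtv=igtv)


def crop_volume(volume, box):
    """Crop with half-open voxel intervals ``(h0, h1, w0, w1, k0, k1)``."""
    h0, h1, w0, w1, k0, k1 = box
    return volume[h0:h1, w0:w1, k0:k1]
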