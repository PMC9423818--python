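"""Color Doppler pre-processing: quadrature data -> standardized flow images.

The scanner stores, per pixel, the normalized lag-1 autocorrelation of the
Doppler ensemble as quadrature components (rxx, rxy) together with the signal
power in dB.  The phase of the lag-1 autocorrelation encodes the mean Doppler
shift (the Kasai autocorrelation velocity estimator), so

    R(0,0) = 10^(P_dB / 10)                      (linear power)
    R(0,1) = (rxx + i * rxy) * R(0,0)            (lag-1 autocorrelation)
    v      = arg(R(0,1)) / pi * f_nyquist        (color-flow velocity)

Flow is separated from background tissue by Otsu-thresholding the dB power
map; the velocity raster is masked, cropped to the largest connected flow
component, zero-padded to a square, resized to 64x64 and normalized to
[-1, 1] by the fixed physical scale v / f_nyquist.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from hemoflow.types import (
    ContractError,
    DataIntegrityError,
    DegenerateInputError,
    FlowImage,
    Label,
    NoFlowError,
    QuadratureFrame,
    VelocityMap,
)

#: 8-connectivity structuring element for "largest component" labelling
_CONN8 = np.ones((3, 3), dtype=bool)


def compute_autocorrelation(frame: QuadratureFrame) -> tuple[np.ndarray, np.ndarray]:
    """Recover autocorrelation estimates R(0,0) and R(0,1) from a raw frame.

    Inverts the dB power encoding, ``R(0,0) = 10^(P/10)``, and rescales the
    normalized quadrature components, ``R(0,1) = (rxx + i rxy) * R(0,0)``.

    Returns
    -------
    r00 : 2-D float array, linear power, >= 0
    r01 : 2-D complex array, lag-1 autocorrelation
    """
    r00 = np.power(10.0, frame.power_db / 10.0)
    r01 = (frame.rxx + 1j * frame.rxy) * r00
    return r00, r01


def compute_velocity(r01: np.ndarray, f_nyquist: float) -> np.ndarray:
    """Kasai phase-to-velocity map: ``v = arg(R(0,1)) / pi * f_nyquist``.

    The phase is taken in (-pi, pi], so a phase of exactly pi maps to
    +f_nyquist.  Pixels with ``R(0,1) == 0`` carry no signal and are assigned
    velocity 0.
    """
    if not f_nyquist > 0:
        raise ContractError(f"f_nyquist must be > 0, got {f_nyquist}")
    r01 = np.asarray(r01)
    if not np.all(np.isfinite(r01)):
        bad = np.argwhere(~np.isfinite(r01))[0]
        raise DataIntegrityError(f"non-finite r01 at pixel {tuple(bad)}")
    vel = np.angle(r01) / np.pi * f_nyquist
    vel = np.where(r01 == 0, 0.0, vel)
    return vel


def compute_power(r00: np.ndarray) -> np.ndarray:
    """Color-flow power is the zero-lag autocorrelation: ``CF_power = R(0,0)``.

    An identity pass-through kept as a named pipeline stage; rejects negative
    input, which cannot be a power.
    """
    r00 = np.asarray(r00, dtype=float)
    if np.any(r00 < 0):
        bad = np.argwhere(r00 < 0)[0]
        raise DataIntegrityError(f"negative power at pixel {tuple(bad)}")
    return r00.copy()


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold over an ``n_bins`` histogram, tie-broken exactly.

    The between-class variance of a split, w0*w1*(mu0 - mu1)^2, is an exact
    rational in the histogram counts when bin centers are indexed 0..n-1
    (the affine map from indices to physical centers rescales the variance
    monotonically, so the argmax is unchanged).  Splits are compared with
    exact integer arithmetic, which makes the maximizer — and therefore the
    mask — fully reproducible even when empty bins between modes produce
    mathematically tied splits that float arithmetic would order
    arbitrarily.  Ties take the first (lowest) maximizing split.  Returns
    the center of the last below-class bin; flow/foreground is strictly
    above it.
    """
    values = np.asarray(values, dtype=float)
    if values.min() == values.max():
        raise DegenerateInputError("constant raster: Otsu threshold undefined")
    hist, edges = np.histogram(values.ravel(), bins=n_bins)
    counts = [int(c) for c in hist]
    w_total = sum(counts)
    s_total = sum(i * c for i, c in enumerate(counts))
    best_num = best_den = 0  # running maximum as an exact fraction num/den
    best_split = 1
    w0 = s0 = 0
    for split in range(1, n_bins):
        w0 += counts[split - 1]
        s0 += (split - 1) * counts[split - 1]
        w1 = w_total - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (s0 * w1 - (s_total - s0) * w0) ** 2
        den = w0 * w1
        # exact comparison of fractions; best_den == 0 means no candidate yet
        if best_den == 0 or num * best_den > best_num * den:
            best_num, best_den, best_split = num, den, split
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(centers[best_split - 1])


def otsu_mask(power_db: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Binary flow mask from the dB power raster by Otsu's method.

    The threshold maximizes the between-class variance over an ``n_bins``
    histogram of the raster; pixels strictly above the threshold are flow.

    Raises
    ------
    DegenerateInputError
        If the raster is constant (no threshold separates anything).
    """
    power_db = np.asarray(power_db, dtype=float)
    return power_db > otsu_threshold(power_db, n_bins=n_bins)


def apply_mask(
    velocity: np.ndarray,
    mask: np.ndarray,
    cf_power: np.ndarray | None = None,
    f_nyquist: float = 1.0,
    frame_id: str = "",
    timepoint: str = "",
) -> VelocityMap:
    """Zero velocities outside the flow mask and bundle into a VelocityMap."""
    velocity = np.asarray(velocity, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if velocity.shape != mask.shape:
        raise ContractError(
            f"velocity {velocity.shape} and mask {mask.shape} shapes differ"
        )
    if cf_power is None:
        cf_power = np.zeros_like(velocity)
    masked = np.where(mask, velocity, 0.0)
    return VelocityMap(
        cf_vel=masked,
        cf_power=cf_power,
        mask=mask,
        f_nyquist=f_nyquist,
        frame_id=frame_id,
        timepoint=timepoint,
    )


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Boolean raster of the largest 8-connected component of ``mask``."""
    labels, n = ndimage.label(mask, structure=_CONN8)
    if n == 0:
        raise NoFlowError("mask contains no flow pixels")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def extract_roi(
    vmap: VelocityMap,
    out_size: int = 64,
    label: Label | str = Label.UNKNOWN,
    aux: np.ndarray | None = None,
) -> FlowImage | tuple[FlowImage, np.ndarray]:
    """Standardize a masked velocity map into an ``out_size`` flow image.

    Steps: (1) find the largest 8-connected component of the flow mask;
    (2) crop to its bounding box; (3) zero-pad the shorter axis symmetrically
    to a square (odd remainder goes to the trailing side); (4) bilinear-resize
    to ``out_size`` x ``out_size``; (5) normalize by the fixed physical scale
    ``v / f_nyquist`` and clip to [-1, 1].

    ``aux``, if given, is an auxiliary raster (e.g. a ground-truth mask as
    floats) carried through the identical crop/pad/resize geometry and
    returned alongside the image.
    """
    comp = _largest_component(vmap.mask)
    rows = np.any(comp, axis=1)
    cols = np.any(comp, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]

    def _crop_pad(raster: np.ndarray) -> np.ndarray:
        crop = raster[r0 : r1 + 1, c0 : c1 + 1]
        h, w = crop.shape
        side = max(h, w)
        top = (side - h) // 2
        left = (side - w) // 2
        return np.pad(
            crop, ((top, side - h - top), (left, side - w - left)), mode="constant"
        )

    vel = np.where(comp, vmap.cf_vel, 0.0)
    square = _crop_pad(vel)
    small = resize(
        square, (out_size, out_size), order=1, anti_aliasing=False, preserve_range=True
    )
    pixels = np.clip(small / vmap.f_nyquist, -1.0, 1.0)
    img = FlowImage(
        pixels=pixels, label=label, provenance=vmap.frame_id, timepoint=vmap.timepoint
    )
    if aux is None:
        return img
    aux_small = resize(
        _crop_pad(np.asarray(aux, dtype=float)),
        (out_size, out_size),
        order=1,
        anti_aliasing=False,
        preserve_range=True,
    )
    return img, aux_small


def preprocess_frame(
    frame: QuadratureFrame,
    out_size: int = 64,
    n_bins: int = 256,
    label: Label | str = Label.UNKNOWN,
    aux: np.ndarray | None = None,
) -> FlowImage | tuple[FlowImage, np.ndarray]:
    """Full pipeline: raw quadrature frame -> standardized flow image."""
    r00, r01 = compute_autocorrelation(frame)
    vel = compute_velocity(r01, frame.f_nyquist)
    power = compute_power(r00)
    mask = otsu_mask(frame.power_db, n_bins=n_bins)
    # no-signal pixels carry no phase: drop them from the flow mask
    mask = mask & (r01 != 0)
    vmap = apply_mask(
        vel,
        mask,
        cf_power=power,
        f_nyquist=frame.f_nyquist,
        frame_id=frame.frame_id,
        timepoint=frame.timepoint,
    )
    return extract_roi(vmap, out_size=out_size, label=label, aux=aux)
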