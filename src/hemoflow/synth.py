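"""Synthetic Doppler flow phantom: normal arterial flow and hemorrhagic jets.

Emulates the two flow classes the detector must separate, at the level the
detector consumes (post-Kasai velocity fields encoded back into quadrature
frames), not at the acoustic level:

* **normal** — a gently curved vessel lumen carrying laminar, pulsatile,
  one-directional flow with a parabolic (Poiseuille) cross-lumen profile and
  additive Gaussian velocity noise;
* **hemorrhage** — the same vessel plus a localized turbulent jet straddling
  the vessel wall, in which per-pixel velocities take random magnitudes and
  randomly flipped signs, reproducing the alternating-sign "red-blue check"
  aliasing pattern of turbulent extravasation at an arterial injury site.

Power levels inside/outside the lumen are chosen so Otsu thresholding of the
dB power raster recovers the vessel.  Every generator output is a pure
function of (config, arguments), so fixtures are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from hemoflow.preprocess import preprocess_frame
from hemoflow.types import ContractError, FlowImage, Label, NoFlowError, QuadratureFrame

logger = logging.getLogger(__name__)

#: lag-1 correlation magnitude inside the lumen (high ensemble coherence)
_RHO_LUMEN = 0.95
#: lag-1 correlation magnitude in background tissue (incoherent clutter)
_RHO_BACKGROUND = 0.2


@dataclass
class SynthConfig:
    """Parameters of the synthetic flow phantom.

    Velocities are expressed as fractions of the Nyquist velocity; power
    levels in dB control the Otsu separability of lumen vs. background.
    """

    frame_height: int = 96
    frame_width: int = 96
    vessel_width_px: int = 20
    vessel_curvature: float = 4.0
    peak_velocity_frac: float = 0.6
    pulsatility: float = 0.3
    noise_sd: float = 0.03
    jet_size_px: int = 16
    jet_alias_prob: float = 0.5
    background_power_db: float = 5.0
    lumen_power_db: float = 25.0
    power_noise_db: float = 1.0
    f_nyquist: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.peak_velocity_frac < 1.0):
            raise ContractError("peak_velocity_frac must lie in (0, 1)")
        if not (0.0 <= self.jet_alias_prob <= 1.0):
            raise ContractError("jet_alias_prob must lie in [0, 1]")
        if not (0.0 <= self.pulsatility < 1.0):
            raise ContractError("pulsatility must lie in [0, 1)")
        if self.lumen_power_db <= self.background_power_db:
            raise ContractError("lumen_power_db must exceed background_power_db")
        # peak velocity at systole must stay below Nyquist to avoid wrap
        if self.peak_velocity_frac * (1 + self.pulsatility) >= 1.0:
            raise ContractError(
                "peak_velocity_frac * (1 + pulsatility) must stay below 1"
            )


def _frame_rng(cfg: SynthConfig, frame_seed: int | None) -> np.random.Generator:
    if frame_seed is None:
        frame_seed = cfg.seed
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, frame_seed]))


def _vessel_geometry(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centerline row per column, signed distance to centerline, lumen mask."""
    rows = np.arange(cfg.frame_height)[:, None]
    cols = np.arange(cfg.frame_width)[None, :]
    centerline = cfg.frame_height / 2.0 + cfg.vessel_curvature * np.sin(
        2 * np.pi * cols / cfg.frame_width
    )
    dist = rows - centerline
    lumen = np.abs(dist) <= cfg.vessel_width_px / 2.0
    return centerline, dist, lumen


def _laminar_velocity(
    cfg: SynthConfig, cardiac_phase: float, dist: np.ndarray, lumen: np.ndarray
) -> np.ndarray:
    """Pulsatile Poiseuille profile: v = vmax * (1 - (2d/w)^2) inside the lumen."""
    vmax = (
        cfg.peak_velocity_frac
        * cfg.f_nyquist
        * (1.0 + cfg.pulsatility * np.sin(2 * np.pi * cardiac_phase))
    )
    profile = 1.0 - (2.0 * dist / cfg.vessel_width_px) ** 2
    return np.where(lumen, vmax * np.clip(profile, 0.0, None), 0.0)


def _encode(
    cfg: SynthConfig, velocity: np.ndarray, lumen_like: np.ndarray,
    rng: np.random.Generator, frame_id: str, timepoint: str,
) -> QuadratureFrame:
    """Encode a velocity field into quadrature components and a dB power map."""
    phase = np.clip(velocity / cfg.f_nyquist, -1.0, 1.0) * np.pi
    rho = np.where(lumen_like, _RHO_LUMEN, _RHO_BACKGROUND)
    power_db = np.where(lumen_like, cfg.lumen_power_db, cfg.background_power_db)
    power_db = power_db + rng.normal(0.0, cfg.power_noise_db, size=power_db.shape)
    return QuadratureFrame(
        rxx=rho * np.cos(phase),
        rxy=rho * np.sin(phase),
        power_db=power_db,
        f_nyquist=cfg.f_nyquist,
        frame_id=frame_id,
        timepoint=timepoint,
    )


def make_normal_frame(
    cfg: SynthConfig,
    cardiac_phase: float,
    frame_seed: int | None = None,
    return_truth: bool = False,
):
    """Raw quadrature frame of normal laminar vessel flow.

    ``cardiac_phase`` in [0, 1) scales the velocity by
    ``1 + pulsatility * sin(2 pi phase)``.  ``frame_seed`` individualizes the
    noise draw; outputs are pure functions of (cfg, arguments).  With
    ``return_truth`` the programmed noise-free velocity field and the lumen
    mask are returned as well.
    """
    rng = _frame_rng(cfg, frame_seed)
    _, dist, lumen = _vessel_geometry(cfg)
    v_true = _laminar_velocity(cfg, cardiac_phase, dist, lumen)
    noise = rng.normal(0.0, cfg.noise_sd * cfg.f_nyquist, size=v_true.shape)
    v = np.clip(v_true + np.where(lumen, noise, 0.0), -cfg.f_nyquist, cfg.f_nyquist)
    frame = _encode(
        cfg, v, lumen, rng, frame_id=f"normal-{frame_seed}", timepoint="T0"
    )
    if return_truth:
        return frame, v_true, lumen
    return frame


def make_hemorrhage_frame(
    cfg: SynthConfig,
    cardiac_phase: float,
    frame_seed: int | None = None,
    return_truth_field: bool = False,
):
    """Raw frame with a turbulent jet at the vessel wall, plus its truth mask.

    The jet is a disk of diameter ``jet_size_px`` centered on the vessel wall
    (half inside the lumen, half outside — extravasated blood is still flow,
    so the jet carries lumen-level power).  Each jet pixel draws a velocity
    magnitude in [0.5, 1] x f_nyquist with sign flipped against the vessel
    flow direction with probability ``jet_alias_prob``, producing the
    high-spatial-frequency alternating-sign pattern of post-Kasai aliasing.
    """
    rng = _frame_rng(cfg, frame_seed if frame_seed is not None else -1)
    centerline, dist, lumen = _vessel_geometry(cfg)
    v_true = _laminar_velocity(cfg, cardiac_phase, dist, lumen)
    noise = rng.normal(0.0, cfg.noise_sd * cfg.f_nyquist, size=v_true.shape)
    v = v_true + np.where(lumen, noise, 0.0)

    # jet center sits on the lower vessel wall at a column in the middle half
    jx = int(rng.integers(cfg.frame_width // 4, 3 * cfg.frame_width // 4))
    jy = centerline[0, jx] + cfg.vessel_width_px / 2.0
    rows = np.arange(cfg.frame_height)[:, None]
    cols = np.arange(cfg.frame_width)[None, :]
    truth_mask = (rows - jy) ** 2 + (cols - jx) ** 2 <= (cfg.jet_size_px / 2.0) ** 2

    mag = rng.uniform(0.5, 1.0, size=v.shape) * cfg.f_nyquist
    flip = rng.uniform(size=v.shape) < cfg.jet_alias_prob
    sign = np.where(flip, -1.0, 1.0)
    v = np.where(truth_mask, sign * mag, v)
    v = np.clip(v, -cfg.f_nyquist, cfg.f_nyquist)

    frame = _encode(
        cfg,
        v,
        lumen | truth_mask,
        rng,
        frame_id=f"hemorrhage-{frame_seed}",
        timepoint="T1",
    )
    if return_truth_field:
        return frame, truth_mask, v_true, lumen
    return frame, truth_mask


def make_dataset(
    cfg: SynthConfig,
    n_normal: int,
    n_anomalous: int,
    out_size: int = 64,
) -> tuple[list[FlowImage], pd.DataFrame, list[np.ndarray | None]]:
    """Generate preprocessed flow images for both classes with a manifest.

    Frames are generated across uniformly sampled cardiac phases, run through
    the full Doppler preprocessing pipeline, and collected with a manifest
    table (id, label, timepoint, source, excluded).  Frames that fail
    preprocessing (no flow after masking) are logged and excluded.  The third
    return value carries, per kept image, the ground-truth jet mask mapped
    through the same ROI geometry (None for normal images).

    Reproducible: two calls with the same cfg produce identical outputs.
    """
    if n_normal < 0 or n_anomalous < 0:
        raise ContractError("counts must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 982451653]))
    images: list[FlowImage] = []
    truths: list[np.ndarray | None] = []
    records = []
    plan = [(Label.NORMAL, i) for i in range(n_normal)] + [
        (Label.HEMORRHAGE, i) for i in range(n_anomalous)
    ]
    for label, i in plan:
        phase = float(rng.uniform())
        fid = f"{label.value}-{i:05d}"
        try:
            if label is Label.NORMAL:
                frame = make_normal_frame(cfg, phase, frame_seed=i)
                img = preprocess_frame(frame, out_size=out_size, label=label)
                truth = None
            else:
                frame, tmask = make_hemorrhage_frame(cfg, phase, frame_seed=i)
                img, truth = preprocess_frame(
                    frame, out_size=out_size, label=label, aux=tmask.astype(float)
                )
                truth = truth > 0.5
        except NoFlowError as exc:
            logger.warning("frame %s excluded: %s", fid, exc)
            records.append(
                dict(id=fid, label=label.value, timepoint="", source="synth",
                     excluded=True)
            )
            continue
        img.provenance = fid
        images.append(img)
        truths.append(truth)
        records.append(
            dict(id=fid, label=label.value, timepoint=img.timepoint,
                 source="synth", excluded=False)
        )
    manifest = pd.DataFrame.from_records(
        records, columns=["id", "label", "timepoint", "source", "excluded"]
    )
    return images, manifest, truths


def config_to_dict(cfg: SynthConfig) -> dict:
    """Plain-dict view of a config, for run-directory freezing."""
    return asdict(cfg)
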