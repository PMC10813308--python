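"""Multimode-interference specklegram simulator.

The forward model mimics a tapered multimode fiber read out by a camera:
a set of guided modes with amplitudes ``a_m`` and phases ``phi_m`` is
superposed on surrogate transverse profiles, the output intensity is
``|A(x, y)|**2``, and analyte concentration enters through a saturating
dose-response that shifts mode phases and exchanges mode powers.  All
randomness is seeded so a (config, seed) pair regenerates the same
dataset bit for bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SimulationGrid",
    "ModeState",
    "ModeBasis",
    "CameraModel",
    "DoseResponseModel",
    "build_mode_basis",
    "build_coupling_matrix",
    "init_mode_state",
    "synthesize_field",
    "field_to_intensity",
    "couple_powers",
    "apply_concentration",
    "add_camera_noise",
    "render_specklegram",
    "generate_dataset",
    "DEFAULT_PANEL",
]

#: Concentration panel of the assay, in ng/mL.
DEFAULT_PANEL = (1.0, 5.0, 10.0, 20.0, 30.0, 50.0, 100.0, 500.0, 1000.0)


@dataclass(frozen=True)
class SimulationGrid:
    """Camera/raster geometry.  ``tip_to_camera`` and ``exposure`` are
    acquisition metadata carried for provenance; the renderer forms the
    speckle directly at the output plane."""

    width: int = 1280
    height: int = 1024
    pixel_pitch_um: float = 5.3
    tip_to_camera_mm: float = 5.0
    exposure_ms: float = 6.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def npixels(self) -> int:
        return self.height * self.width


@dataclass
class ModeState:
    """Amplitudes/phases of the guided-mode ensemble; powers are a_m**2
    and are kept normalized to sum to 1."""

    amplitudes: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if self.amplitudes.shape != self.phases.shape:
            raise ValueError("amplitudes and phases must have equal length")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def M(self) -> int:
        return self.amplitudes.size

    @property
    def powers(self) -> np.ndarray:
        return self.amplitudes**2

    def normalized(self) -> "ModeState":
        total = float(np.sum(self.powers))
        if total <= 0:
            raise ValueError("total mode power must be positive")
        return ModeState(self.amplitudes / np.sqrt(total), self.phases.copy())


@dataclass(frozen=True)
class ModeBasis:
    """Orthonormal surrogate transverse profiles on the grid, stacked as
    (M, height, width)."""

    profiles: np.ndarray
    grid: SimulationGrid

    @property
    def M(self) -> int:
        return self.profiles.shape[0]

    def gram(self) -> np.ndarray:
        flat = self.profiles.reshape(self.M, -1)
        return flat @ flat.T


@dataclass(frozen=True)
class CameraModel:
    """Digitisation model: optional scaled-Poisson shot noise, additive
    Gaussian read noise, clipping and quantisation to ``bit_depth``."""

    bit_depth: int = 16
    shot_noise: bool = True
    photons_per_count: float = 4.0
    read_noise_sd: float = 30.0
    gain_counts: float = 8000.0

    def __post_init__(self) -> None:
        if not (1 <= self.bit_depth <= 16):
            raise ValueError("bit_depth must be in [1, 16]")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        if self.photons_per_count <= 0:
            raise ValueError("photons_per_count must be positive")

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class DoseResponseModel:
    """Hill-form map from concentration (ng/mL) to a dimensionless
    perturbation ``r(c) = response_max * c**h / (K**h + c**h)`` that
    drives per-mode phase shifts ``beta_m * r(c)`` and one mode-coupling
    power-exchange step scaled by ``coupling_scale * r(c)``."""

    response_max: float
    half_sat_K: float = 100.0
    hill_h: float = 1.0
    mode_sensitivities: np.ndarray = field(default_factory=lambda: np.ones(1))
    coupling_scale: float = 0.2

    def __post_init__(self) -> None:
        if self.response_max < 0 or self.half_sat_K <= 0 or self.hill_h <= 0:
            raise ValueError("invalid dose-response parameters")
        self.mode_sensitivities = np.asarray(self.mode_sensitivities, dtype=float)

    def response(self, c: float | np.ndarray) -> float | np.ndarray:
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be non-negative")
        ch = np.power(c, self.hill_h)
        out = self.response_max * ch / (self.half_sat_K**self.hill_h + ch)
        return float(out) if out.ndim == 0 else out


def _rng(seed: int | np.random.SeedSequence) -> np.random.Generator:
    return np.random.default_rng(seed)


def spawn_seed(base_seed: int, *tags) -> int:
    """Derive a stable 31-bit child seed from a base seed and hashable tags.

    Stages of the pipeline draw from independent streams so they can be
    rerun in isolation.
    """
    h = hashlib.sha256(repr((int(base_seed),) + tuple(tags)).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def build_mode_basis(
    M: int,
    grid: SimulationGrid,
    seed: int,
    kind: str = "smooth",
    smooth_sigma: float | None = None,
) -> ModeBasis:
    """Build M orthonormal surrogate mode profiles on the grid.

    ``smooth``: low-pass-filtered Gaussian random fields; ``cosine``:
    2D cosine products.  Either way the stack is passed through a QR
    orthonormalisation sweep so the discrete Gram matrix is the identity.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if M > grid.npixels:
        raise ValueError(
            f"infeasible basis: M={M} exceeds pixel count {grid.npixels}"
        )
    h, w = grid.shape
    if kind == "smooth":
        sigma = smooth_sigma if smooth_sigma is not None else max(2.0, min(h, w) / 40.0)
        rng = _rng(seed)
        raw = rng.standard_normal((M, h, w))
        raw = ndimage.gaussian_filter(raw, sigma=(0, sigma, sigma), mode="wrap")
    elif kind == "cosine":
        ky, kx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        raw = np.empty((M, h, w))
        # enumerate (p, q) frequency pairs in increasing order
        idx = 0
        order = 0
        while idx < M:
            for p in range(order + 1):
                q = order - p
                if idx >= M:
                    break
                raw[idx] = np.cos(np.pi * (p + 0.31) * ky / h) * np.cos(
                    np.pi * (q + 0.47) * kx / w
                )
                idx += 1
            order += 1
    else:
        raise ValueError(f"unknown basis kind {kind!r}")

    flat = raw.reshape(M, -1).T  # (npix, M)
    q, r = np.linalg.qr(flat)
    # fix the sign so the basis is deterministic regardless of LAPACK
    q = q * np.sign(np.diag(r))
    return ModeBasis(profiles=np.ascontiguousarray(q.T.reshape(M, h, w)), grid=grid)


def init_mode_state(M: int, seed: int) -> ModeState:
    """Baseline mode ensemble: powers drawn uniform then normalized,
    phases uniform on [0, 2*pi)."""
    rng = _rng(seed)
    p = rng.uniform(0.5, 1.5, size=M)
    p /= p.sum()
    phases = rng.uniform(0.0, 2.0 * np.pi, size=M)
    return ModeState(np.sqrt(p), phases)


def build_coupling_matrix(M: int, h_scale: float, seed: int) -> np.ndarray:
    """Symmetric non-negative coupling coefficients h_mn with zero diagonal,
    entries i.i.d. uniform on [0, h_scale]."""
    if h_scale < 0:
        raise ValueError("h_scale must be non-negative")
    rng = _rng(seed)
    upper = rng.uniform(0.0, h_scale, size=(M, M))
    h = np.triu(upper, k=1)
    h = h + h.T
    return h


def _check_coupling(h: np.ndarray) -> None:
    h = np.asarray(h)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError("coupling matrix must be square")
    if not np.allclose(h, h.T, atol=1e-12):
        raise ValueError("coupling matrix must be symmetric")
    if np.any(h < 0):
        raise ValueError("coupling coefficients must be non-negative")
    if np.any(np.diag(h) != 0):
        raise ValueError("coupling matrix diagonal must be zero")


def couple_powers(
    modes: ModeState,
    h: np.ndarray,
    gain: float = 1.0,
    convention: str = "relax",
) -> np.ndarray:
    """One step of mode power exchange, ``dP_m = gain * sum_n h_mn (p_n - p_m)``.

    The default "relax" convention flows power toward equipartition; the
    printed sign (p_m - p_n), which amplifies imbalance, is available as
    ``convention="printed"``.  Either way ``sum_m dP_m == 0`` because h is
    symmetric and (p_m - p_n) antisymmetric.
    """
    _check_coupling(h)
    if gain < 0:
        raise ValueError("gain must be non-negative")
    p = modes.powers
    if h.shape[0] != p.size:
        raise ValueError("coupling matrix size must match mode count")
    flow = h @ p - p * h.sum(axis=1)  # sum_n h_mn (p_n - p_m)
    if convention == "relax":
        dP = gain * flow
    elif convention == "printed":
        dP = -gain * flow
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return dP


def apply_concentration(
    modes: ModeState,
    dose: DoseResponseModel,
    c: float,
    h: np.ndarray | None = None,
    convention: str = "relax",
) -> ModeState:
    """Perturb the baseline mode state by analyte concentration ``c``.

    Phases shift by ``beta_m * r(c)``; powers take one coupling step of
    size ``coupling_scale * r(c)`` and are clipped at zero and
    re-normalized.  ``c == 0`` returns the input state unchanged.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    r = dose.response(c)
    if r == 0.0:
        return ModeState(modes.amplitudes.copy(), modes.phases.copy())
    beta = dose.mode_sensitivities
    if beta.size != modes.M:
        raise ValueError("mode_sensitivities length must match mode count")
    phases = modes.phases + beta * r
    p = modes.powers
    if h is not None and dose.coupling_scale > 0:
        dP = couple_powers(modes, h, gain=dose.coupling_scale * r, convention=convention)
        p = np.clip(p + dP, 0.0, None)
    p = p / p.sum()
    return ModeState(np.sqrt(p), phases)


def synthesize_field(modes: ModeState, basis: ModeBasis) -> np.ndarray:
    """Superpose the mode ensemble on the basis profiles:
    ``A(x,y) = sum_m a_m psi_m(x,y) exp(j phi_m)``."""
    if modes.M != basis.M:
        raise ValueError(
            f"mode count {modes.M} does not match basis size {basis.M}"
        )
    coeff = modes.amplitudes * np.exp(1j * modes.phases)
    flat = basis.profiles.reshape(basis.M, -1)
    return (coeff @ flat).reshape(basis.grid.shape)


def field_to_intensity(fieldarr: np.ndarray) -> np.ndarray:
    """Intensity of the superposed field, ``I = |A|**2``."""
    if not np.all(np.isfinite(fieldarr)):
        raise ValueError("field contains non-finite values")
    return np.abs(fieldarr) ** 2


def add_camera_noise(
    img: np.ndarray, cam: CameraModel, seed: int
) -> np.ndarray:
    """Digitise an intensity image: scaled-Poisson shot noise, Gaussian
    read noise, clip at 0 and full scale, round to integer counts.

    With both noise sources off the operation is pure clip+round, so an
    already-quantised in-range image passes through unchanged.
    """
    img = np.asarray(img, dtype=float)
    if np.any(img < 0) or not np.all(np.isfinite(img)):
        raise ValueError("intensity image must be finite and non-negative")
    rng = _rng(seed)
    counts = img
    if cam.shot_noise:
        ppc = cam.photons_per_count
        counts = rng.poisson(counts * ppc).astype(float) / ppc
    if cam.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, cam.read_noise_sd, size=counts.shape)
    counts = np.clip(np.rint(counts), 0, cam.full_scale)
    return counts.astype(np.uint16)


@dataclass(frozen=True)
class RenderConfig:
    """Everything needed to render one fiber's specklegrams."""

    grid: SimulationGrid
    basis: ModeBasis
    baseline: ModeState
    coupling: np.ndarray
    dose: DoseResponseModel
    camera: CameraModel
    convention: str = "relax"
    phase_jitter_sd: float = 0.01  # radians, per-frame drift


def render_specklegram(
    c: float,
    cfg: RenderConfig,
    seed: int,
    noise: bool = True,
) -> np.ndarray:
    """Render one specklegram at concentration ``c`` (ng/mL).

    ``seed`` controls the per-frame degrees of freedom (phase jitter and
    camera noise); the fiber itself (basis, baseline state, coupling) is
    fixed by the config, so frames at the same concentration are
    replicates of one fiber.  Bit-identical for identical (c, cfg, seed).
    """
    state = apply_concentration(
        cfg.baseline, cfg.dose, c, h=cfg.coupling, convention=cfg.convention
    )
    if noise and cfg.phase_jitter_sd > 0:
        jrng = _rng(spawn_seed(seed, "jitter"))
        state = ModeState(
            state.amplitudes,
            state.phases + jrng.normal(0.0, cfg.phase_jitter_sd, size=state.M),
        )
    intensity = field_to_intensity(synthesize_field(state, cfg.basis))
    # orthonormal profiles give mean intensity ~ 1/npixels; rescale so the
    # baseline fills a fixed fraction of the camera's dynamic range
    intensity = intensity * (cfg.grid.npixels * cfg.camera.gain_counts)
    if not noise:
        return intensity
    return add_camera_noise(intensity, cfg.camera, spawn_seed(seed, "camera"))


SPLIT_NAMES = ("train", "validation", "test")


def generate_dataset(
    cfg: RenderConfig,
    seed: int,
    panel: tuple[float, ...] = DEFAULT_PANEL,
    per_class: int = 100,
    split: tuple[float, float, float] = (0.5, 0.25, 0.25),
    out_dir=None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate the labelled specklegram dataset.

    Returns a manifest DataFrame with columns
    ``id,path,concentration_ng_per_ml,split,seed`` and the image stack
    (N, height, width) uint16 in manifest order.  Replicates within a
    class share the fiber and differ in frame seed (phase jitter + camera
    noise).  The split is stratified exactly per class.  When ``out_dir``
    is given, 16-bit grayscale PNGs and ``manifest.csv`` are written
    there as well.
    """
    if len(panel) == 0:
        raise ValueError("concentration panel must be non-empty")
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split ratio must sum to 1")
    counts = [int(round(per_class * s)) for s in split]
    if sum(counts) != per_class:
        raise ValueError("split ratio does not divide per_class evenly")

    records = []
    images = np.empty(
        (len(panel) * per_class,) + cfg.grid.shape, dtype=np.uint16
    )
    i = 0
    for k, c in enumerate(panel):
        for rep in range(per_class):
            frame_seed = spawn_seed(seed, "frame", k, rep)
            images[i] = render_specklegram(c, cfg, frame_seed)
            if rep < counts[0]:
                tag = "train"
            elif rep < counts[0] + counts[1]:
                tag = "validation"
            else:
                tag = "test"
            ident = f"c{k:02d}_r{rep:03d}"
            records.append(
                {
                    "id": ident,
                    "path": f"{ident}.png",
                    "concentration_ng_per_ml": c,
                    "split": tag,
                    "seed": frame_seed,
                }
            )
            i += 1
    manifest = pd.DataFrame.from_records(records)
    if manifest["id"].duplicated().any():
        raise ValueError("duplicate identifiers in manifest")
    if out_dir is not None:
        import imageio.v3 as iio
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for row, img in zip(records, images):
            iio.imwrite(out / row["path"], img)
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest, images
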