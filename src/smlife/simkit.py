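"""Synthetic single-molecule TIRF data with exact ground truth.

This module generates every input the analysis pipeline consumes — dwell-time
samples, background-subtracted intensity traces, multi-frame movies with
labeled cell masks, Z-ring snapshot images with midlines, and Hill-shaped
titration tables — together with a :class:`GroundTruthManifest` recording the
true parameters of everything rendered.

The generative model mirrors membrane-bound FtsZ subunits imaged by TIRF:
a molecule binds at a fixed intracellular position, fluoresces for a dwell
time drawn from either a single-exponential distribution (mean lifetime
``tau_s``) or a deterministic treadmilling model (``dwell = L / v``,
filament length over treadmilling speed), and may photobleach irreversibly
with a fixed probability per exposure.  Cameras add Poisson shot noise on
signal plus background and Gaussian read noise.

All operations are pure functions of their parameters and ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AcquisitionParams",
    "DwellModel",
    "PhotophysicsParams",
    "GroundTruthManifest",
    "simulate_dwell_times",
    "apply_photobleaching",
    "render_trace",
    "render_movie",
    "render_ring_cells",
    "simulate_titration",
    "save_movie",
    "save_mask",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera/acquisition settings.

    Parameters
    ----------
    frame_interval_s : float
        Seconds between frame starts.
    exposure_s : float
        Seconds of light integration per frame; must not exceed the
        frame interval.
    n_frames : int
        Number of frames in a time lapse.
    pixel_size_um : float
        Micrometers per pixel (default 0.1 µm/px, typical of a 100x
        sCMOS/EMCCD system; every physical-unit output scales through it).
    psf_sigma_px : float
        Gaussian PSF standard deviation in pixels.
    """

    frame_interval_s: float = 0.5
    exposure_s: float = 0.5
    n_frames: int = 480
    pixel_size_um: float = 0.1
    psf_sigma_px: float = 1.3

    def __post_init__(self) -> None:
        if self.exposure_s > self.frame_interval_s + 1e-12:
            raise ValueError("exposure_s must be <= frame_interval_s")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_size_um <= 0 or self.psf_sigma_px <= 0:
            raise ValueError("pixel_size_um and psf_sigma_px must be > 0")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass(frozen=True)
class DwellModel:
    """Residence-time model for a membrane-bound subunit.

    ``mode='exponential'`` draws i.i.d. exponential dwells with mean
    ``tau_s``.  ``mode='treadmill'`` returns the deterministic dwell
    ``filament_length_um / treadmill_speed_um_s``: a subunit added at the
    growing end of a treadmilling filament of length L moving at speed v
    leaves the filament after exactly L/v seconds.
    """

    mode: str = "exponential"
    tau_s: float | None = 5.0
    filament_length_um: float | None = None
    treadmill_speed_um_s: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "exponential":
            if self.tau_s is None or self.tau_s <= 0:
                raise ValueError("exponential mode requires tau_s > 0")
        elif self.mode == "treadmill":
            if (
                self.filament_length_um is None
                or self.treadmill_speed_um_s is None
                or self.filament_length_um <= 0
                or self.treadmill_speed_um_s <= 0
            ):
                raise ValueError("treadmill mode requires L > 0 and v > 0")
        else:
            raise ValueError(f"unknown dwell mode {self.mode!r}")

    @property
    def mean_dwell_s(self) -> float:
        if self.mode == "exponential":
            return float(self.tau_s)
        return float(self.filament_length_um / self.treadmill_speed_um_s)


@dataclass(frozen=True)
class PhotophysicsParams:
    """Spot brightness, camera noise and photobleaching.

    Amplitude/background/read-noise defaults (2500 / 100 / 20 counts) are
    synthetic conventions, chosen so the pipeline's 500-count trace filter
    and 60-count state-separation rule operate in a realistic regime; they
    are not measured values.  ``spot_amplitude_counts`` is the PSF *peak*:
    averaging over the 5x5 analysis window dilutes it by ~2.4x at the
    default PSF width, so a 2500-count peak yields a ~1000-count trace
    amplitude, comfortably above the 500-count filter.
    """

    spot_amplitude_counts: float = 2500.0
    background_counts: float = 100.0
    read_noise_sd_counts: float = 20.0
    shot_noise: bool = True
    bleach_rate_per_exposure: float = 0.0
    amplitude_cv: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "spot_amplitude_counts",
            "background_counts",
            "read_noise_sd_counts",
            "amplitude_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.bleach_rate_per_exposure <= 1.0:
            raise ValueError("bleach_rate_per_exposure must be in [0, 1]")

    @property
    def noiseless(self) -> bool:
        return (
            not self.shot_noise
            and self.read_noise_sd_counts == 0.0
            and self.amplitude_cv == 0.0
        )


@dataclass
class GroundTruthManifest:
    """True parameters of everything rendered by a generator call.

    ``molecules`` holds one record per rendered molecule (cell id, position,
    bind/unbind/bleach times); ``cells`` one per cell (label, length,
    true ring positions); serializes losslessly to/from JSON.
    """

    seed: int
    params: dict = field(default_factory=dict)
    molecules: list[dict] = field(default_factory=list)
    cells: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruthManifest":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Dwell times


def simulate_dwell_times(model: DwellModel, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` dwell times (seconds) from the dwell model.

    Exponential mode gives i.i.d. samples with mean ``tau_s``; treadmill
    mode gives the constant L/v.  Same (model, n, seed) always returns the
    same array.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model.mode == "treadmill":
        return np.full(n, model.mean_dwell_s)
    return _rng(seed).exponential(model.tau_s, size=n)


def apply_photobleaching(
    dwells_s: np.ndarray,
    bleach_rate_per_exposure: float,
    frame_interval_s: float,
    seed: int,
) -> np.ndarray:
    """Truncate dwell times at the molecule's photobleaching time.

    Bleaching is a Bernoulli event at the end of each exposure, so the
    fluorescent lifetime of a bleach-limited molecule is ``k * frame_interval``
    with ``k`` geometric.  With constant exposure, halving the frame interval
    doubles the exposures per second and halves the bleach-limited lifetime —
    the basis of the frame-interval photobleaching control.
    """
    dwells_s = np.asarray(dwells_s, dtype=float)
    if bleach_rate_per_exposure <= 0:
        return dwells_s.copy()
    k = _rng(seed).geometric(bleach_rate_per_exposure, size=dwells_s.shape)
    return np.minimum(dwells_s, k * frame_interval_s)


# ---------------------------------------------------------------------------
# Traces


def render_trace(
    bind_s: float,
    dwell_s: float,
    acq: AcquisitionParams,
    phot: PhotophysicsParams,
    seed: int,
) -> tuple[np.ndarray, dict]:
    """Render one background-subtracted intensity trace.

    Frames whose exposure window lies fully inside ``[bind, bind + dwell)``
    carry the full spot amplitude; edge frames are scaled by the fractional
    temporal overlap (integrating-camera physics).  Photobleaching may end
    the signal after any illuminated exposure.  Shot noise is Poisson on
    signal + background with the mean background subtracted back out, so a
    noiseless render is an exact step function.

    Returns ``(values, truth)`` where truth records the effective unbind
    time (after bleaching) and the bleach frame if any.
    """
    if bind_s < 0:
        raise ValueError("bind_s must be >= 0")
    rng = _rng(seed)
    n = acq.n_frames
    signal = np.zeros(n)
    unbind_s = bind_s + dwell_s
    bleach_frame: int | None = None
    p_bleach = phot.bleach_rate_per_exposure
    for i in range(n):
        t0 = i * acq.frame_interval_s
        overlap = min(unbind_s, t0 + acq.exposure_s) - max(bind_s, t0)
        if overlap <= 0:
            continue
        frac = overlap / acq.exposure_s
        signal[i] = phot.spot_amplitude_counts * frac * _amplitude_factor(phot, rng)
        if p_bleach > 0 and rng.random() < p_bleach:
            bleach_frame = i
            unbind_s = min(unbind_s, t0 + acq.exposure_s)
            break
    values = signal.copy()
    if phot.shot_noise:
        values = rng.poisson(signal + phot.background_counts).astype(float)
        values -= phot.background_counts
    if phot.read_noise_sd_counts > 0:
        values = values + rng.normal(0.0, phot.read_noise_sd_counts, size=n)
    truth = {
        "bind_s": float(bind_s),
        "dwell_s": float(dwell_s),
        "unbind_s": float(unbind_s),
        "bleach_frame": bleach_frame,
    }
    return values, truth


# ---------------------------------------------------------------------------
# Cell geometry shared by movie and ring renderers


def _pack_cells(
    n_cells: int,
    lengths_px: np.ndarray,
    width_px: int,
    image_shape: tuple[int, int],
    rng: np.random.Generator,
    margin_px: int = 6,
):
    """Place axis-aligned rod (spherocylinder footprint) cells on a grid.

    Raises ValueError when the requested cells cannot fit.
    """
    h, w = image_shape
    pitch_r = width_px + 2 * margin_px
    max_len = int(lengths_px.max())
    pitch_c = max_len + 2 * margin_px
    n_rows = max((h - margin_px) // pitch_r, 0)
    n_cols = max((w - margin_px) // pitch_c, 0)
    if n_rows * n_cols < n_cells:
        raise ValueError(
            f"cannot place {n_cells} cells of length {max_len}px in image {image_shape}"
        )
    slots = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    order = rng.permutation(len(slots))[:n_cells]
    cells = []
    for label, idx in enumerate(order, start=1):
        r_slot, c_slot = slots[idx]
        length = int(lengths_px[label - 1])
        row = margin_px + r_slot * pitch_r + width_px // 2
        col0 = margin_px + c_slot * pitch_c + rng.integers(0, max_len - length + 1)
        cells.append({"label": label, "row": row, "col_start": col0, "length_px": length})
    return cells


def _rod_mask(mask: np.ndarray, cell: dict, width_px: int) -> None:
    """Paint a horizontal spherocylinder footprint into the labeled mask."""
    radius = width_px / 2.0
    row, c0, length = cell["row"], cell["col_start"], cell["length_px"]
    # axis segment chosen so the footprint spans exactly `length` columns
    # (inclusive pixel extent c0 .. c0 + length - 1)
    a, b = c0 + radius, c0 + length - 1 - radius
    rr = np.arange(max(0, int(row - radius - 1)), min(mask.shape[0], int(row + radius + 2)))
    cc = np.arange(max(0, int(c0 - 1)), min(mask.shape[1], int(c0 + length + 2)))
    R, C = np.meshgrid(rr, cc, indexing="ij")
    cx = np.clip(C, a, b)
    inside = (R - row) ** 2 + (C - cx) ** 2 <= radius**2
    sub = mask[rr[0] : rr[-1] + 1, cc[0] : cc[-1] + 1]
    sub[inside] = cell["label"]


def _add_gaussian_spot(frame: np.ndarray, row: float, col: float, amp: float, sigma: float) -> None:
    r = int(np.ceil(4 * sigma))
    r0, r1 = int(np.floor(row)) - r, int(np.floor(row)) + r + 1
    c0, c1 = int(np.floor(col)) - r, int(np.floor(col)) + r + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, frame.shape[0]), min(c1, frame.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c)
    cc = np.arange(c0c, c1c)
    g = np.exp(-((rr[:, None] - row) ** 2 + (cc[None, :] - col) ** 2) / (2 * sigma**2))
    frame[r0c:r1c, c0c:c1c] += amp * g


def _amplitude_factor(phot: PhotophysicsParams, rng: np.random.Generator, size=None):
    """Mean-one multiplicative brightness fluctuation of a bound fluorophore.

    Real single fluorophores flicker frame to frame (dipole wobble, defocus,
    partial triplet shelving); a mean-corrected lognormal with coefficient
    of variation ``amplitude_cv`` emulates that apparent-brightness noise.
    """
    if phot.amplitude_cv <= 0:
        return 1.0 if size is None else np.ones(size)
    s = np.sqrt(np.log1p(phot.amplitude_cv**2))
    return rng.lognormal(-0.5 * s**2, s, size=size)


def _camera_noise(frames: np.ndarray, phot: PhotophysicsParams, rng: np.random.Generator) -> np.ndarray:
    out = frames
    if phot.shot_noise:
        out = rng.poisson(np.maximum(out, 0.0)).astype(float)
    if phot.read_noise_sd_counts > 0:
        out = out + rng.normal(0.0, phot.read_noise_sd_counts, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# Movies


def render_movie(
    n_cells: int,
    molecules_per_cell: int,
    model: DwellModel,
    acq: AcquisitionParams,
    phot: PhotophysicsParams,
    image_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    cell_length_um: float = 4.0,
    cell_width_um: float = 0.9,
    min_separation_px: float = 12.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruthManifest]:
    """Render a single-molecule TIRF time lapse with ground truth.

    Each molecule binds at a fixed position inside a cell at a time uniform
    over the movie, stays for a dwell drawn from ``model`` (truncated by
    photobleaching), and is rendered as a 2-D Gaussian of width
    ``acq.psf_sigma_px`` with amplitude scaled by fractional temporal
    overlap on edge frames.  Binding sites keep a minimum in-plane
    separation (default 12 px — beyond the reach of the 9x9 background
    annulus plus PSF tails): the sparse-labeling regime single-molecule
    imaging requires, so that distinct sites neither merge under the 3-px
    rule nor contaminate each other's local-background estimate.

    Returns ``(movie, mask, manifest)``; movie is float, shape
    ``(n_frames, H, W)``; mask is uint16 labeled.
    """
    rng = _rng(seed)
    width_px = max(3, int(round(cell_width_um / acq.pixel_size_um)))
    length_px = int(round(cell_length_um / acq.pixel_size_um))
    lengths = np.full(n_cells, length_px)
    cells = _pack_cells(n_cells, lengths, width_px, image_shape, rng)
    mask = np.zeros(image_shape, dtype=np.uint16)
    for cell in cells:
        _rod_mask(mask, cell, width_px)

    T = acq.duration_s
    molecules: list[dict] = []
    for cell in cells:
        radius = width_px / 2.0
        # keep sites a rounding-safe margin inside the spherocylinder footprint
        a = cell["col_start"] + radius
        b = cell["col_start"] + cell["length_px"] - 1 - radius
        r_inner = radius - 1.6
        placed: list[tuple[float, float]] = []
        # rejection sampling can wedge itself (two early sites blocking the
        # rest), so restart the whole cell on failure
        for _restart in range(200):
            placed = []
            for _ in range(60 * max(molecules_per_cell, 1)):
                if len(placed) == molecules_per_cell:
                    break
                row = cell["row"] + rng.uniform(-r_inner, r_inner)
                col = cell["col_start"] + rng.uniform(1.0, cell["length_px"] - 1.0)
                cx = min(max(col, a), b)
                if (row - cell["row"]) ** 2 + (col - cx) ** 2 > r_inner**2:
                    continue
                if all(
                    (row - r) ** 2 + (col - c) ** 2 >= min_separation_px**2 for r, c in placed
                ):
                    placed.append((row, col))
            if len(placed) == molecules_per_cell:
                break
        if len(placed) < molecules_per_cell:
            raise ValueError(
                f"cannot place {molecules_per_cell} molecules at >= {min_separation_px} px "
                f"separation in a {cell['length_px']}-px cell"
            )
        for row, col in placed:
            bind = rng.uniform(0.0, T)
            dwell = simulate_dwell_times(model, 1, rng.integers(2**31))[0]
            molecules.append(
                {
                    "cell_id": int(cell["label"]),
                    "row": float(row),
                    "col": float(col),
                    "bind_s": float(bind),
                    "unbind_s": float(bind + dwell),
                    "dwell_s": float(dwell),
                    "bleach_frame": None,
                }
            )

    # photobleaching: geometric number of illuminated exposures survived
    if phot.bleach_rate_per_exposure > 0:
        for m in molecules:
            k = int(rng.geometric(phot.bleach_rate_per_exposure))
            first = int(np.floor(m["bind_s"] / acq.frame_interval_s))
            bleach_t = (first + k) * acq.frame_interval_s
            if bleach_t < m["unbind_s"]:
                m["unbind_s"] = float(bleach_t)
                m["bleach_frame"] = first + k - 1

    movie = np.empty((acq.n_frames,) + tuple(image_shape), dtype=np.float32)
    base = np.full(image_shape, phot.background_counts, dtype=float)
    for i in range(acq.n_frames):
        frame = base.copy()
        t0 = i * acq.frame_interval_s
        for m in molecules:
            overlap = min(m["unbind_s"], t0 + acq.exposure_s) - max(m["bind_s"], t0)
            if overlap <= 0:
                continue
            frac = overlap / acq.exposure_s
            amp = phot.spot_amplitude_counts * frac * _amplitude_factor(phot, rng)
            _add_gaussian_spot(frame, m["row"], m["col"], amp, acq.psf_sigma_px)
        # per-frame camera noise keeps peak memory at one float64 frame
        movie[i] = _camera_noise(frame, phot, rng)

    manifest = GroundTruthManifest(
        seed=int(seed),
        params={
            "acq": dataclasses.asdict(acq),
            "phot": dataclasses.asdict(phot),
            "model": dataclasses.asdict(model),
            "image_shape": list(image_shape),
            "cell_length_um": cell_length_um,
            "cell_width_um": cell_width_um,
        },
        molecules=molecules,
        cells=[
            {
                "label": int(c["label"]),
                "length_um": c["length_px"] * acq.pixel_size_um,
                "row": int(c["row"]),
                "col_start": int(c["col_start"]),
                "ring_positions_um": [],
                "ring_sigma_um": None,
            }
            for c in cells
        ],
    )
    return movie, mask, manifest


# ---------------------------------------------------------------------------
# Z-ring snapshots


def render_ring_cells(
    n_cells: int,
    cell_length_um,
    rings_per_cell: int,
    ring_sigma_um: float,
    acq: AcquisitionParams,
    phot: PhotophysicsParams,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    cell_width_um: float = 0.9,
    cell_intensity_counts: float = 150.0,
    ring_amplitude_counts: float = 600.0,
    ring_position_frac=None,
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray], GroundTruthManifest]:
    """Render an epifluorescence-style snapshot of rod cells with Z-rings.

    Each ring is a Gaussian ridge transverse to the cell axis (SD
    ``ring_sigma_um`` along the axis, uniform across the cell width) on top
    of a uniform cytoplasmic signal.  ``cell_length_um`` may be a scalar, a
    ``(mean, sd)`` tuple for a clipped-normal length distribution, or a
    sequence of per-cell lengths.  ``ring_position_frac`` pins ring
    positions at fixed fractions of cell length (scalar or sequence);
    by default positions are uniform in the central 70% of the cell.

    Returns ``(image, mask, midlines, manifest)`` where midlines maps cell
    label to an ``(N, 2)`` polyline of (row, col) points spanning the cell,
    and the manifest stores true ring arclength positions and the Gaussian
    FWHM ``2*sqrt(2 ln 2)*sigma``.
    """
    if rings_per_cell > 0 and ring_sigma_um <= 0:
        raise ValueError("ring_sigma_um must be > 0")
    rng = _rng(seed)
    px = acq.pixel_size_um
    if np.isscalar(cell_length_um):
        lengths_um = np.full(n_cells, float(cell_length_um))
    elif isinstance(cell_length_um, tuple) and len(cell_length_um) == 2:
        mean, sd = cell_length_um
        lengths_um = np.clip(rng.normal(mean, sd, n_cells), 0.5 * mean, 2.0 * mean)
    else:
        lengths_um = np.asarray(cell_length_um, dtype=float)
        if len(lengths_um) != n_cells:
            raise ValueError("cell_length_um sequence must have n_cells entries")
    width_px = max(3, int(round(cell_width_um / px)))
    lengths_px = np.round(lengths_um / px).astype(int)
    cells = _pack_cells(n_cells, lengths_px, width_px, image_shape, rng)
    mask = np.zeros(image_shape, dtype=np.uint16)
    for cell in cells:
        _rod_mask(mask, cell, width_px)

    fwhm_factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    image = np.full(image_shape, phot.background_counts, dtype=float)
    image[mask > 0] += cell_intensity_counts
    midlines: dict[int, np.ndarray] = {}
    cell_records = []
    for cell in cells:
        label = cell["label"]
        c0, length = cell["col_start"], cell["length_px"]
        row = cell["row"]
        cols = np.arange(c0, c0 + length)
        midlines[label] = np.column_stack([np.full(cols.size, float(row)), cols.astype(float)])
        if ring_position_frac is None:
            fracs = rng.uniform(0.15, 0.85, size=rings_per_cell)
        else:
            fracs = np.atleast_1d(np.asarray(ring_position_frac, dtype=float))
            if fracs.size == 1:
                fracs = np.repeat(fracs, rings_per_cell)
        ring_pos_um = []
        in_cell = mask == label
        for frac in fracs[:rings_per_cell]:
            x0 = c0 + frac * length
            ring_pos_um.append(float(frac * length * px))
            sigma_px = ring_sigma_um / px
            cc = np.arange(image_shape[1], dtype=float)
            ridge = ring_amplitude_counts * np.exp(-((cc - x0) ** 2) / (2 * sigma_px**2))
            image[in_cell] += ridge[np.nonzero(in_cell)[1]]
        cell_records.append(
            {
                "label": int(label),
                "length_um": float(length * px),
                "row": int(row),
                "col_start": int(c0),
                "ring_positions_um": sorted(ring_pos_um),
                "ring_sigma_um": float(ring_sigma_um) if rings_per_cell else None,
                "ring_fwhm_um": float(fwhm_factor * ring_sigma_um) if rings_per_cell else None,
            }
        )
    image = _camera_noise(image, phot, rng)
    manifest = GroundTruthManifest(
        seed=int(seed),
        params={
            "acq": dataclasses.asdict(acq),
            "phot": dataclasses.asdict(phot),
            "rings_per_cell": rings_per_cell,
            "ring_sigma_um": ring_sigma_um,
            "image_shape": list(image_shape),
        },
        cells=cell_records,
    )
    return image, mask, midlines, manifest


# ---------------------------------------------------------------------------
# Titration tables


def simulate_titration(
    leak: float,
    max_response: float,
    k_half: float,
    n_hill: float,
    doses,
    replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a dose-response titration from a 4-parameter Hill model.

    Response at dose d is ``leak + (max - leak) * d^n / (K^n + d^n)`` with
    mean-corrected multiplicative lognormal noise of coefficient of
    variation ``noise_cv`` (so the expected response equals the model value,
    and dose 0 has mean exactly ``leak``).

    Returns a tidy ``(dose, replicate, response)`` table plus the true
    parameters.
    """
    if k_half <= 0 or n_hill <= 0:
        raise ValueError("k_half and n_hill must be > 0")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0) or noise_cv < 0:
        raise ValueError("doses and noise_cv must be non-negative")
    rng = _rng(seed)
    rows = []
    with np.errstate(divide="ignore"):
        dn = np.where(doses > 0, doses**n_hill, 0.0)
    mean_resp = leak + (max_response - leak) * dn / (k_half**n_hill + dn)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
    for rep in range(replicates):
        for d, mu in zip(doses, mean_resp):
            val = mu
            if noise_cv > 0:
                val = mu * rng.lognormal(-0.5 * sigma**2, sigma)
            rows.append({"dose": float(d), "replicate": rep, "response": float(val)})
    truth = {
        "leak": leak,
        "max": max_response,
        "k_half": k_half,
        "n_hill": n_hill,
        "noise_cv": noise_cv,
        "seed": int(seed),
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# File output (multi-frame grayscale TIFF, 16-bit labeled masks)


def save_movie(path: str | Path, movie: np.ndarray) -> None:
    """Write a movie or snapshot as uint16 grayscale TIFF (counts clipped)."""
    data = np.clip(np.round(movie), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), mask.astype(np.uint16))
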