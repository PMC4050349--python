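"""Synthetic 4D time-lapse and MeDIP-seq generators with known ground truth.

Every downstream stage (focus detection, linking, distance-change mobility,
nuclear texture metrics, windowed channel correlation, island enrichment)
is validated against data planted here, so each generator exposes its
latent state as an explicit :class:`GroundTruth`.

Imaging model
-------------
Foci diffuse inside a spherical nucleus (Brownian steps of per-axis
variance ``2*D*dt``, reflective boundary at the nuclear radius) while the
nucleus as a whole undergoes a rigid per-frame motion (translation of the
centre plus rotation about it).  The rigid transform is applied after the
Brownian step, about the nuclear centroid.  Each focus is rendered as a 3D
Gaussian of physical width ``focus_sigma``; a uniform nucleoplasmic
background fills the nucleus and Gaussian sensor noise sets the SNR
(peak focus amplitude over noise standard deviation).  The default
acquisition preset is 20 frames at 5-min intervals, i.e. a 0–95 min
series.  No photobleaching, aberration or division is modelled; the
microscope noise level is a free parameter (the source experiments do not
report one).

Sequencing model
----------------
One latent methylation landscape per genome, shared by both enrichment
channels: a smooth long-range background (logistic-squashed random walk,
so that averaging over larger windows raises channel correlation) with
CpG islands overlaid at planted levels — heavy islands at level >= 0.8,
light below.  Per fine window, each channel draws a count whose mean is
proportional to background + latent level; counts are negative binomial
with dispersion ``channel_noise`` (variance mu + noise*mu^2; Poisson at
0... except that a dispersion of exactly 0 is rendered deterministically,
count = round(mu), so two channels with equal means are bit-identical).
The input channel is level-independent (uniform mean).  Reads are emitted
as fixed-length fragments whose midpoints fall uniformly inside their
window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import medip
from .foci import FocusTrack

__all__ = [
    "TimelapseParams",
    "MedipSimParams",
    "GroundTruth",
    "ImageStack4D",
    "simulate_tracks",
    "simulate_timelapse",
    "simulate_medip",
    "MedipSim",
    "write_tiff",
    "read_tiff",
]

FRAGMENT_LENGTH_BP = 200  # emitted read/fragment length


# ---------------------------------------------------------------------------
# parameter blocks

@dataclass
class TimelapseParams:
    """World description for one simulated nucleus time-lapse.

    Units: µm, minutes.  ``diffusion_coeff`` is per focus population
    (µm²/min); ``rigid_translation`` is the per-frame drift of the nuclear
    centre and ``rigid_rotation`` the per-frame rotation (degrees) about
    it; ``snr`` is peak focus amplitude over noise SD.
    """

    n_frames: int = 20
    frame_interval: float = 5.0
    voxel_size: tuple[float, float, float] = (0.5, 0.25, 0.25)  # z, y, x µm
    nucleus_radius: float = 5.0
    n_foci: int = 6
    focus_sigma: float = 0.4
    diffusion_coeff: float = 0.01
    rigid_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # x, y, z µm/frame
    rigid_rotation: float = 0.0  # degrees/frame about z through the centre
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if min(self.voxel_size) <= 0 or self.nucleus_radius <= 0:
            raise ValueError("voxel_size and nucleus_radius must be positive")
        if self.n_foci < 1 or self.focus_sigma <= 0:
            raise ValueError("need n_foci >= 1 and focus_sigma > 0")
        # packing limit: foci kept 4 sigma apart inside the placement sphere
        r_place = self.nucleus_radius - 2.0 * self.focus_sigma
        if r_place <= 0:
            raise ValueError("focus_sigma too large for nucleus_radius")
        min_sep = 4.0 * self.focus_sigma
        capacity = 0.3 * (r_place / min_sep) ** 3 / 0.125  # ~30% sphere packing
        if self.n_foci > max(1, int(capacity)):
            raise ValueError(
                f"cannot place {self.n_foci} foci {min_sep:.2f} µm apart inside "
                f"a {self.nucleus_radius:.2f} µm nucleus (packing limit)"
            )

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class MedipSimParams:
    """World description for the two-channel enrichment simulation."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    window: int = 1000
    n_islands: int = 100
    island_len: int = 1000
    frac_heavy: float = 0.5
    methylation_background: float = 0.05
    reads_per_channel: int = 200_000
    channel_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_heavy <= 1.0:
            raise ValueError("frac_heavy must lie in [0, 1]")
        if self.window > self.chrom_length:
            raise ValueError("window larger than chromosome")
        if self.chrom_length % self.window != 0:
            raise ValueError("window must divide chrom_length")
        if self.island_len > self.chrom_length:
            raise ValueError("island_len larger than chromosome")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class GroundTruth:
    """Latent state behind a simulation: tracks, methylation, island labels."""

    true_tracks: list[FocusTrack] = field(default_factory=list)
    true_methylation: pd.DataFrame | None = None  # per-window latent level
    island_labels: pd.DataFrame | None = None  # chrom,start,end,level,group


@dataclass
class ImageStack4D:
    """Time-ordered 3D volumes with physical calibration.

    ``data`` has axes (t, z, y, x); ``voxel_size`` is (z, y, x) in µm and
    ``frame_interval`` in minutes.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4D (t, z, y, x)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def um_to_voxel(self, xyz_um: np.ndarray) -> np.ndarray:
        """µm coordinates (x, y, z) to fractional voxel indices (z, y, x)."""
        xyz_um = np.asarray(xyz_um, dtype=float)
        dz, dy, dx = self.voxel_size
        return xyz_um[..., ::-1] / np.array([dz, dy, dx])

    def voxel_to_um(self, zyx_vox: np.ndarray) -> np.ndarray:
        zyx_vox = np.asarray(zyx_vox, dtype=float)
        dz, dy, dx = self.voxel_size
        return (zyx_vox * np.array([dz, dy, dx]))[..., ::-1]


# ---------------------------------------------------------------------------
# time-lapse simulation

def _rotation_z(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _place_foci(rng: np.random.Generator, params: TimelapseParams) -> np.ndarray:
    """Initial focus positions, rejection-sampled with minimum separation."""
    r_place = params.nucleus_radius - 2.0 * params.focus_sigma
    min_sep = 4.0 * params.focus_sigma
    placed: list[np.ndarray] = []
    for _ in range(20_000):
        p = rng.uniform(-r_place, r_place, size=3)
        if np.linalg.norm(p) > r_place:
            continue
        if all(np.linalg.norm(p - q) >= min_sep for q in placed):
            placed.append(p)
            if len(placed) == params.n_foci:
                return np.array(placed)
    raise ValueError("could not place foci without overlap (packing limit)")


def _reflect_into_sphere(p: np.ndarray, radius: float) -> np.ndarray:
    r = np.linalg.norm(p)
    if r <= radius or r == 0.0:
        return p
    # radial reflection at the boundary; repeat in the rare multi-crossing case
    while r > radius:
        p = p * ((2.0 * radius - r) / r)
        r = abs(np.linalg.norm(p))
    return p


def simulate_tracks(params: TimelapseParams) -> list[FocusTrack]:
    """Ground-truth focus trajectories in the lab frame (µm).

    Brownian steps (variance ``2*D*dt`` per axis, reflective at the
    nuclear boundary) in the nucleus frame, composed with the cumulative
    rigid transform of frame t: rotation by ``t * rigid_rotation`` degrees
    about the nuclear centre plus centre drift ``t * rigid_translation``.
    """
    rng = np.random.default_rng(params.seed)
    intra = _place_foci(rng, params)  # positions relative to nuclear centre
    step_sd = np.sqrt(2.0 * params.diffusion_coeff * params.frame_interval)
    trans = np.asarray(params.rigid_translation, dtype=float)
    boundary = params.nucleus_radius - 2.0 * params.focus_sigma

    lab = np.empty((params.n_frames, params.n_foci, 3))
    for t in range(params.n_frames):
        if t > 0 and step_sd > 0:
            steps = rng.normal(0.0, step_sd, size=(params.n_foci, 3))
            for i in range(params.n_foci):
                intra[i] = _reflect_into_sphere(intra[i] + steps[i], boundary)
        rot = _rotation_z(t * params.rigid_rotation)
        lab[t] = intra @ rot.T + t * trans

    return [
        FocusTrack(
            i,
            np.arange(params.n_frames),
            lab[:, i, :],
            times_min=params.times_min,
        )
        for i in range(params.n_foci)
    ]


def _render_frame(
    positions_um: np.ndarray,
    centre_um: np.ndarray,
    grids_um: tuple[np.ndarray, np.ndarray, np.ndarray],
    params: TimelapseParams,
) -> np.ndarray:
    """Noiseless frame: nuclear background plus Gaussian foci (x,y,z µm)."""
    zg, yg, xg = grids_um
    amp = 1.0
    background = 0.15 * amp
    r2 = (
        (xg - centre_um[0]) ** 2
        + (yg - centre_um[1]) ** 2
        + (zg - centre_um[2]) ** 2
    )
    frame = np.where(r2 <= params.nucleus_radius**2, background, 0.0)
    s2 = 2.0 * params.focus_sigma**2
    for x0, y0, z0 in positions_um:
        frame += amp * np.exp(
            -((xg - x0) ** 2 + (yg - y0) ** 2 + (zg - z0) ** 2) / s2
        )
    return frame


def simulate_timelapse(
    params: TimelapseParams,
) -> tuple[ImageStack4D, GroundTruth]:
    """Render a calibrated 4D stack around simulated focus trajectories.

    The field of view covers the nucleus plus its total rigid drift with a
    2 µm margin; ground-truth tracks are returned in the same µm frame as
    the stack (origin at the voxel-(0,0,0) centre).
    """
    tracks = simulate_tracks(params)
    rng = np.random.default_rng(params.seed + 1_000_003)

    trans = np.asarray(params.rigid_translation, dtype=float)
    total_drift = np.abs(trans) * (params.n_frames - 1)
    margin = 2.0
    half = params.nucleus_radius + margin + total_drift / 2.0
    centre0 = half  # nuclear centre at frame 0, in µm from the origin
    dz, dy, dx = params.voxel_size
    shape = (
        int(np.ceil(2 * half[2] / dz)),
        int(np.ceil(2 * half[1] / dy)),
        int(np.ceil(2 * half[0] / dx)),
    )
    zg, yg, xg = np.meshgrid(
        np.arange(shape[0]) * dz,
        np.arange(shape[1]) * dy,
        np.arange(shape[2]) * dx,
        indexing="ij",
    )

    noise_sd = 1.0 / params.snr
    data = np.empty((params.n_frames,) + shape, dtype=np.float32)
    for t in range(params.n_frames):
        centre_t = centre0 + t * trans
        pos = np.array([tr.positions[t] for tr in tracks]) + centre0
        frame = _render_frame(pos, centre_t, (zg, yg, xg), params)
        frame += rng.normal(0.0, noise_sd, size=shape)
        data[t] = frame.astype(np.float32)

    # shift ground truth into the image frame
    shifted = [
        FocusTrack(tr.track_id, tr.frames, tr.positions + centre0,
                   times_min=tr.times_min)
        for tr in tracks
    ]
    stack = ImageStack4D(data, params.voxel_size, params.frame_interval)
    return stack, GroundTruth(true_tracks=shifted)


# ---------------------------------------------------------------------------
# MeDIP simulation

def _latent_landscape(
    rng: np.random.Generator, n_windows: int
) -> np.ndarray:
    """Smooth latent methylation level in [0, 1] with long-range structure."""
    walk = np.cumsum(rng.normal(0.0, 0.15, size=n_windows))
    walk -= walk.mean()
    return 1.0 / (1.0 + np.exp(-walk))


def _draw_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion == 0.0:
        return np.round(mu).astype(np.int64)
    # NB with var = mu + dispersion * mu^2
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


@dataclass
class MedipSim:
    """Bundle returned by :func:`simulate_medip`."""

    tracks: dict[str, medip.GenomicTrack]  # chanA, chanB, input (binned)
    reads: dict[str, pd.DataFrame]  # raw fragments per channel
    islands: pd.DataFrame  # chrom,start,end,name,score,strand,level
    ground_truth: GroundTruth


def simulate_medip(
    params: MedipSimParams,
    channel_seeds: tuple[int, int, int] | None = None,
    latent: dict[str, np.ndarray] | None = None,
) -> MedipSim:
    """Simulate two enrichment channels plus input over one shared landscape.

    Channel seeds default to ``seed*3 + (1, 2, 3)``; passing identical
    seeds for chanA and chanB (with ``channel_noise=0``) yields
    bit-identical tracks, the degenerate case used by correlation tests.
    ``latent`` overrides the generated per-window methylation landscape
    (chrom -> levels in [0, 1]); islands are skipped when it is given.
    """
    rng = np.random.default_rng(params.seed)
    chrom_sizes = params.chrom_sizes
    n_win = params.chrom_length // params.window

    # latent landscape + islands
    latent_rows = []
    island_rows = []
    per_chrom_latent: dict[str, np.ndarray] = {}
    islands_per_chrom = params.n_islands // params.n_chroms
    extra = params.n_islands % params.n_chroms
    for ci, chrom in enumerate(chrom_sizes):
        if latent is not None:
            lv = np.asarray(latent[chrom], dtype=float)
            if lv.shape != (n_win,) or lv.min() < 0 or lv.max() > 1:
                raise ValueError("latent override must be per-window levels in [0, 1]")
            per_chrom_latent[chrom] = lv
            latent_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": np.arange(n_win) * params.window,
                        "end": (np.arange(n_win) + 1) * params.window,
                        "level": lv,
                    }
                )
            )
            continue
        lv = _latent_landscape(rng, n_win)
        k = islands_per_chrom + (1 if ci < extra else 0)
        if k > 0:
            isl_w = params.island_len // params.window or 1
            max_start = n_win - isl_w
            # non-overlapping island starts on the window grid
            slots = rng.choice(max_start // (2 * isl_w), size=k, replace=False)
            starts_w = np.sort(slots) * 2 * isl_w
            heavy = rng.random(k) < params.frac_heavy
            levels = np.where(
                heavy,
                rng.uniform(0.85, 1.0, size=k),
                rng.uniform(0.10, 0.55, size=k),
            )
            for s_w, lev in zip(starts_w, levels):
                lv[s_w:s_w + isl_w] = lev
                island_rows.append(
                    {
                        "chrom": chrom,
                        "start": int(s_w * params.window),
                        "end": int(s_w * params.window + params.island_len),
                        "name": f"CpG_{chrom}_{s_w}",
                        "score": 0,
                        "strand": ".",
                        "level": float(lev),
                    }
                )
        per_chrom_latent[chrom] = lv
        latent_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(n_win) * params.window,
                    "end": (np.arange(n_win) + 1) * params.window,
                    "level": lv,
                }
            )
        )
    latent_df = pd.concat(latent_rows, ignore_index=True)
    islands = pd.DataFrame(island_rows)
    if not islands.empty:
        islands["group"] = np.where(islands["level"] >= 0.8, "heavy", "light")

    # channel means over the concatenated genome
    all_latent = np.concatenate([per_chrom_latent[c] for c in chrom_sizes])
    weight = params.methylation_background + all_latent
    mu_signal = params.reads_per_channel * weight / weight.sum()
    mu_input = np.full(
        all_latent.size, params.reads_per_channel / all_latent.size
    )

    if channel_seeds is None:
        channel_seeds = (params.seed * 3 + 1, params.seed * 3 + 2, params.seed * 3 + 3)
    reads: dict[str, pd.DataFrame] = {}
    tracks: dict[str, medip.GenomicTrack] = {}
    for name, mu, ch_seed in zip(
        ("chanA", "chanB", "input"), (mu_signal, mu_signal, mu_input), channel_seeds
    ):
        ch_rng = np.random.default_rng(ch_seed)
        counts = _draw_counts(ch_rng, mu, params.channel_noise)
        reads[name] = _emit_reads(ch_rng, counts, chrom_sizes, params)
        tracks[name] = medip.rpkm(
            medip.bin_counts(reads[name], chrom_sizes, params.window)
        )

    gt = GroundTruth(
        true_methylation=latent_df,
        island_labels=islands[["chrom", "start", "end", "level", "group"]]
        if not islands.empty
        else islands,
    )
    return MedipSim(tracks, reads, islands, gt)


def _emit_reads(
    rng: np.random.Generator,
    counts: np.ndarray,
    chrom_sizes: dict[str, int],
    params: MedipSimParams,
) -> pd.DataFrame:
    """Fragments with midpoints uniform inside their source window."""
    frames = []
    offset = 0
    n_win = params.chrom_length // params.window
    half = FRAGMENT_LENGTH_BP // 2
    for chrom, size in chrom_sizes.items():
        c = counts[offset:offset + n_win]
        offset += n_win
        win_idx = np.repeat(np.arange(n_win), c)
        mids = win_idx * params.window + rng.integers(
            0, params.window, size=win_idx.size
        )
        start = np.clip(mids - half, 0, size - FRAGMENT_LENGTH_BP)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": start, "end": start + FRAGMENT_LENGTH_BP}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# on-disk fixture formats

def write_tiff(stack: ImageStack4D, path: str | Path) -> None:
    """Multi-page TIFF with axes TZYX and calibration in the description."""
    meta = {
        "axes": "TZYX",
        "voxel_size_um": list(stack.voxel_size),
        "frame_interval_min": stack.frame_interval,
    }
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        metadata=meta,
    )


def read_tiff(path: str | Path) -> ImageStack4D:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if isinstance(meta, str):
        meta = json.loads(meta)
    voxel = tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0)))
    interval = float(meta.get("frame_interval_min", 1.0))
    if data.ndim == 3:
        data = data[:, None]
    return ImageStack4D(data, voxel, interval)


def write_medip_fixtures(sim: MedipSim, out_dir: str | Path) -> dict[str, Path]:
    """Write bedGraph tracks, island BED and chrom.sizes under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    any_track = next(iter(sim.tracks.values()))
    sizes = (
        any_track.windows.groupby("chrom", sort=False)["end"].max().reset_index()
    )
    p = out / "genome.chrom.sizes"
    sizes.to_csv(p, sep="\t", header=False, index=False)
    paths["chrom_sizes"] = p
    for name, track in sim.tracks.items():
        p = out / f"{name}.rpkm.bedGraph"
        medip.write_bedgraph(track.windows, p, value_col="rpkm")
        paths[name] = p
    for name, rd in sim.reads.items():
        p = out / f"{name}.reads.bed"
        rd.to_csv(p, sep="\t", header=False, index=False)
        paths[f"{name}_reads"] = p
    if not sim.islands.empty:
        p = out / "islands.bed"
        sim.islands[
            ["chrom", "start", "end", "name", "score", "strand", "level"]
        ].to_csv(p, sep="\t", header=False, index=False)
        paths["islands"] = p
    return paths
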