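"""Forward models for the imaging experiments the quantifiers consume.

The simulator emulates straightened axon segments as 3D cylinders observed
in 2D projection: a tubular ER channel meanders along the axon axis, and
punctate ribosome-like emitters are either tethered near the tubule surface
(``bound``) or scattered through the axoplasm (``unbound``).  Rendering
convolves the projected emitters with an isotropic Gaussian PSF and applies
Poisson shot noise plus Gaussian read noise.  All generators are
bit-reproducible given their parameters and a seed; sub-streams for batches
are derived by hashing ``(master_seed, group, index)`` through numpy's
``SeedSequence`` spawn keys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import AxonTrace, BinaryMask, PixelImage, Rect
from .errors import ConfigError, ParameterError
from .frap import FrapSeries
from .presets import SimulationPreset

__all__ = [
    "GroundTruthScene", "make_axon_trace", "make_scene", "render_channel",
    "emit_localizations", "SimulatedSegment", "ConditionPair",
    "simulate_condition_pair", "ContactSegment", "simulate_contact_segments",
    "simulate_branch_segments", "simulate_frap", "MorphologySim",
    "simulate_morphology", "analytic_sholl", "ambiguous_radii",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
# wobble of the tubule centerline: number of sinusoids, wavelength range (um)
_N_WAVES = 3
_WAVELENGTH_RANGE_UM = (6.0, 20.0)
_WOBBLE_FRACTION = 0.9


def _substream(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for (master_seed, *key)."""
    return np.random.default_rng(
        np.random.SeedSequence(int(master_seed), spawn_key=tuple(key))
    )


@dataclass(frozen=True)
class GroundTruthScene:
    """Simulated axon content: geometry, ER tubule(s) and puncta.

    ``positions_nm`` is ``(n, 3)``: x along the axon, y lateral (0 = axon
    axis), z depth; imaging projects along z.  ``tubule_coeffs`` holds, per
    tubule, rows of ``(amplitude_nm, wavelength_nm, phase_rad)`` describing
    the sinusoidal lateral meander of its centerline.
    """

    trace: AxonTrace
    er_tubule_radius_nm: float
    positions_nm: np.ndarray
    amplitudes: np.ndarray
    bound: np.ndarray
    bound_fraction: float
    bind_distance_nm: float
    seed: int
    tubule_coeffs: np.ndarray  # (n_tubules, _N_WAVES, 3)

    @property
    def n_puncta(self) -> int:
        return len(self.amplitudes)

    @property
    def length_nm(self) -> float:
        return self.trace.length_nm

    @property
    def axon_radius_nm(self) -> float:
        return self.trace.width_nm / 2.0

    def tubule_y(self, x_nm: np.ndarray, tubule: int = 0) -> np.ndarray:
        """Lateral centerline position of one tubule at axial positions x."""
        x = np.asarray(x_nm, dtype=float)
        y = np.zeros_like(x)
        for amp, wavelength, phase in self.tubule_coeffs[tubule]:
            y += amp * np.sin(2.0 * np.pi * x / wavelength + phase)
        return y

    def distance_to_tubule_axis(self, positions_nm: np.ndarray) -> np.ndarray:
        """3D distance from each point to the nearest tubule centerline,
        using the vertical (small-slope) approximation."""
        p = np.atleast_2d(positions_nm)
        d = np.full(len(p), np.inf)
        for t in range(len(self.tubule_coeffs)):
            yt = self.tubule_y(p[:, 0], t)
            d = np.minimum(d, np.hypot(p[:, 1] - yt, p[:, 2]))
        return d


def make_axon_trace(
    length_um: float, width_nm: float, n_branches: int, seed: int
) -> AxonTrace:
    """Straightened (horizontal) axon segment of the stated arc length.

    Branch points, when requested, are sampled uniformly along the arc.
    """
    if length_um < 1:
        raise ParameterError("length_um must be >= 1")
    if width_nm <= 0:
        raise ParameterError("width_nm must be positive")
    if n_branches < 0:
        raise ParameterError("n_branches must be >= 0")
    length_nm = float(length_um) * 1000.0
    rng = np.random.default_rng(seed)
    branches = tuple(np.sort(rng.uniform(0.0, length_nm, int(n_branches))))
    vertices = np.array([[0.0, 0.0], [length_nm, 0.0]])
    return AxonTrace(vertices=vertices, width_nm=float(width_nm),
                     branch_points_nm=branches)


def _make_tubules(
    rng: np.random.Generator,
    n_tubules: int,
    axon_radius_nm: float,
    er_tubule_radius_nm: float,
    bind_distance_nm: float,
) -> np.ndarray:
    """Random smooth meanders, bounded so tubule + binding shell stay
    inside the axon cylinder."""
    headroom = axon_radius_nm - er_tubule_radius_nm - bind_distance_nm
    total_amp = _WOBBLE_FRACTION * max(headroom, 0.0)
    coeffs = np.zeros((n_tubules, _N_WAVES, 3))
    lo, hi = _WAVELENGTH_RANGE_UM
    for t in range(n_tubules):
        weights = rng.dirichlet(np.ones(_N_WAVES))
        coeffs[t, :, 0] = total_amp * weights
        coeffs[t, :, 1] = 1000.0 * np.exp(
            rng.uniform(np.log(lo), np.log(hi), _N_WAVES)
        )
        coeffs[t, :, 2] = rng.uniform(0.0, 2.0 * np.pi, _N_WAVES)
    return coeffs


def make_scene(
    trace: AxonTrace,
    n_puncta: int,
    bound_fraction: float,
    bind_distance_nm: float,
    er_tubule_radius_nm: float,
    seed: int,
    n_tubules: int = 1,
    amplitude_cv: float = 0.25,
) -> GroundTruthScene:
    """Place ER tubule(s) and puncta inside the axon cylinder.

    Exactly ``round(bound_fraction * n_puncta)`` puncta are flagged bound and
    placed within ``bind_distance_nm`` of a tubule surface; the rest are
    placed uniformly in the axon cylinder and — when ``bind_distance_nm > 0``
    — rejected out of the binding shell, so the two classes are geometrically
    distinct.  Amplitudes are lognormal with coefficient of variation
    ``amplitude_cv`` (0 for identical puncta).
    """
    if n_puncta < 0:
        raise ParameterError("n_puncta must be >= 0")
    if not 0.0 <= bound_fraction <= 1.0:
        raise ParameterError("bound_fraction must be in [0, 1]")
    if bind_distance_nm < 0:
        raise ParameterError("bind_distance_nm must be >= 0")
    if er_tubule_radius_nm <= 0:
        raise ParameterError("er_tubule_radius_nm must be positive")
    if n_tubules < 1:
        raise ParameterError("n_tubules must be >= 1")

    rng = np.random.default_rng(seed)
    r_ax = trace.width_nm / 2.0
    r_tub = float(er_tubule_radius_nm)
    if r_tub + bind_distance_nm >= r_ax:
        raise ParameterError(
            "tubule radius + bind distance must be smaller than the axon radius"
        )
    length = trace.length_nm
    coeffs = _make_tubules(rng, n_tubules, r_ax, r_tub, bind_distance_nm)

    scene = GroundTruthScene(
        trace=trace, er_tubule_radius_nm=r_tub,
        positions_nm=np.empty((0, 3)), amplitudes=np.empty(0),
        bound=np.empty(0, dtype=bool), bound_fraction=float(bound_fraction),
        bind_distance_nm=float(bind_distance_nm), seed=int(seed),
        tubule_coeffs=coeffs,
    )

    n_bound = int(round(bound_fraction * n_puncta))
    n_free = n_puncta - n_bound

    # bound: radial shell [r_tub, r_tub + bind] around a random tubule
    xb = rng.uniform(0.0, length, n_bound)
    tub_idx = rng.integers(0, n_tubules, n_bound)
    rho = r_tub + rng.uniform(0.0, 1.0, n_bound) * bind_distance_nm
    phi = rng.uniform(0.0, 2.0 * np.pi, n_bound)
    yb = np.empty(n_bound)
    for t in range(n_tubules):
        sel = tub_idx == t
        yb[sel] = scene.tubule_y(xb[sel], t) + rho[sel] * np.cos(phi[sel])
    zb = rho * np.sin(phi)
    bound_pos = np.column_stack([xb, yb, zb])

    # unbound: uniform in the cylinder, rejected out of the binding shell
    free_pos = np.empty((0, 3))
    shell = r_tub + bind_distance_nm
    need = n_free
    while need > 0:
        m = max(4 * need, 64)
        x = rng.uniform(0.0, length, m)
        y = rng.uniform(-r_ax, r_ax, m)
        z = rng.uniform(-r_ax, r_ax, m)
        keep = y * y + z * z <= r_ax * r_ax
        cand = np.column_stack([x, y, z])[keep]
        if bind_distance_nm > 0:
            cand = cand[scene.distance_to_tubule_axis(cand) > shell]
        free_pos = np.vstack([free_pos, cand[:need]])
        need = n_free - len(free_pos)

    positions = np.vstack([bound_pos, free_pos])
    bound_flags = np.concatenate(
        [np.ones(n_bound, dtype=bool), np.zeros(n_free, dtype=bool)]
    )
    if amplitude_cv > 0:
        sigma = math.sqrt(math.log(1.0 + amplitude_cv**2))
        amps = rng.lognormal(-0.5 * sigma**2, sigma, n_puncta)
    else:
        amps = np.ones(n_puncta)

    return GroundTruthScene(
        trace=trace, er_tubule_radius_nm=r_tub, positions_nm=positions,
        amplitudes=amps, bound=bound_flags, bound_fraction=float(bound_fraction),
        bind_distance_nm=float(bind_distance_nm), seed=int(seed),
        tubule_coeffs=coeffs,
    )


def _render_grid(
    scene: GroundTruthScene, pixel_size_nm: float, psf_fwhm_nm: float
) -> tuple[int, int, float]:
    """Common image geometry: (ny, nx, margin_nm).

    The grid covers the axon strip plus a blur margin on all sides; scene
    point ``(x, y)`` maps to image position ``(x + margin, y + H/2)`` with
    ``H = width + 2 * margin``.
    """
    margin_px = int(math.ceil(2.5 * psf_fwhm_nm / pixel_size_nm))
    margin_nm = margin_px * pixel_size_nm
    ny = int(math.ceil(scene.trace.width_nm / pixel_size_nm)) + 2 * margin_px
    nx = int(math.ceil(scene.length_nm / pixel_size_nm)) + 2 * margin_px
    return ny, nx, margin_nm


def _deposit_bilinear(
    grid: np.ndarray, rows: np.ndarray, cols: np.ndarray, amps: np.ndarray
) -> None:
    """Mass-conserving bilinear deposit of point emitters at fractional
    array coordinates."""
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    ny, nx = grid.shape
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
        np.add.at(grid, (rr[ok], cc[ok]), amps[ok] * w[ok])


def render_channel(
    scene: GroundTruthScene,
    source: str,
    pixel_size_nm: float,
    psf_fwhm_nm: float,
    photon_scale: float,
    read_noise_sd: float,
    seed: int,
    background_level: float = 0.0,
    noise: bool = True,
) -> PixelImage:
    """Render one channel of a scene as a noisy 2D projection.

    The ideal emitter map (tubule as a projected-cylinder ridge, puncta as
    points deposited bilinearly) is convolved with an isotropic Gaussian PSF
    of the stated FWHM (kernel truncated at 4 sigma), scaled by
    ``photon_scale``, offset by ``background_level`` photons/pixel, then
    corrupted by Poisson shot noise and additive Gaussian read noise and
    clipped at zero.  ``noise=False`` returns the noiseless expectation.
    """
    if source not in ("er", "puncta"):
        raise ParameterError("source must be 'er' or 'puncta'")
    if pixel_size_nm <= 0 or psf_fwhm_nm <= 0:
        raise ParameterError("pixel size and PSF FWHM must be positive")
    if pixel_size_nm > psf_fwhm_nm:
        raise ParameterError(
            "pixel_size_nm must not exceed psf_fwhm_nm (Nyquist-ish sampling)"
        )
    if photon_scale < 0 or read_noise_sd < 0 or background_level < 0:
        raise ParameterError("photon_scale / noise levels must be >= 0")

    ny, nx, margin_nm = _render_grid(scene, pixel_size_nm, psf_fwhm_nm)
    h_nm = ny * pixel_size_nm
    ideal = np.zeros((ny, nx))

    if source == "er":
        # projected cylinder: chord length 2*sqrt(r^2 - d^2) at lateral
        # distance d from the centerline
        x_c = (np.arange(nx) + 0.5) * pixel_size_nm - margin_nm
        y_c = (np.arange(ny) + 0.5) * pixel_size_nm - h_nm / 2.0
        r = scene.er_tubule_radius_nm
        inside = (x_c >= 0) & (x_c <= scene.length_nm)
        for t in range(len(scene.tubule_coeffs)):
            yt = scene.tubule_y(x_c, t)
            d = y_c[:, None] - yt[None, :]
            chord = 2.0 * np.sqrt(np.clip(r * r - d * d, 0.0, None))
            ideal += chord * inside[None, :]
    else:
        if scene.n_puncta > 0:
            cols = (scene.positions_nm[:, 0] + margin_nm) / pixel_size_nm - 0.5
            rows = (scene.positions_nm[:, 1] + h_nm / 2.0) / pixel_size_nm - 0.5
            _deposit_bilinear(ideal, rows, cols, scene.amplitudes)

    sigma_px = psf_fwhm_nm * _FWHM_TO_SIGMA / pixel_size_nm
    blurred = gaussian_filter(ideal, sigma_px, mode="constant", truncate=4.0)
    signal = photon_scale * blurred + background_level
    if not noise:
        img = signal
    else:
        rng = np.random.default_rng(seed)
        img = rng.poisson(np.clip(signal, 0.0, None)).astype(float)
        if read_noise_sd > 0:
            img += rng.normal(0.0, read_noise_sd, img.shape)
        img = np.clip(img, 0.0, None)
    return PixelImage(img, pixel_size_nm, channel_label=source)


def emit_localizations(
    scene: GroundTruthScene,
    precision_nm: float,
    mean_blinks: float,
    seed: int,
    er_density_per_um: float = 50.0,
    n_frames: int = 1000,
):
    """Simulate SMLM localization tables for both channels.

    Each punctum blinks ``Poisson(mean_blinks)`` times; every localization is
    its projected position jittered by isotropic Gaussian noise of sd
    ``precision_nm``.  ER localizations sample the projected tubule rim at a
    linear density of ``er_density_per_um`` per micron.  Returns a pandas
    DataFrame with columns ``x_nm, y_nm, precision_nm, frame, channel``; the
    y origin is the bottom edge of the axon strip.
    """
    import pandas as pd

    if precision_nm <= 0:
        raise ParameterError("precision_nm must be positive")
    if mean_blinks < 0:
        raise ParameterError("mean_blinks must be >= 0")
    rng = np.random.default_rng(seed)
    r_ax = scene.axon_radius_nm
    frames_x, frames_y, channels = [], [], []

    counts = rng.poisson(mean_blinks, scene.n_puncta)
    reps = np.repeat(np.arange(scene.n_puncta), counts)
    frames_x.append(scene.positions_nm[reps, 0])
    frames_y.append(scene.positions_nm[reps, 1])
    channels.append(np.full(len(reps), "ribo"))

    n_er = rng.poisson(er_density_per_um * scene.length_nm / 1000.0
                       * len(scene.tubule_coeffs))
    xe = rng.uniform(0.0, scene.length_nm, n_er)
    tub = rng.integers(0, len(scene.tubule_coeffs), n_er)
    ye = np.empty(n_er)
    for t in range(len(scene.tubule_coeffs)):
        sel = tub == t
        # rim of the tubule seen in projection: arcsine-distributed offset
        ye[sel] = scene.tubule_y(xe[sel], t) + scene.er_tubule_radius_nm \
            * np.cos(rng.uniform(0.0, 2.0 * np.pi, sel.sum()))
    frames_x.append(xe)
    frames_y.append(ye)
    channels.append(np.full(n_er, "er"))

    x = np.concatenate(frames_x)
    y = np.concatenate(frames_y) + r_ax
    n = len(x)
    x = x + rng.normal(0.0, precision_nm, n)
    y = y + rng.normal(0.0, precision_nm, n)
    return pd.DataFrame({
        "x_nm": x,
        "y_nm": y,
        "precision_nm": np.full(n, float(precision_nm)),
        "frame": rng.integers(0, n_frames, n),
        "channel": np.concatenate(channels),
    })


@dataclass(frozen=True)
class SimulatedSegment:
    """One rendered axon segment plus the geometry needed to quantify it."""

    image: PixelImage
    trace: AxonTrace          # in image coordinates
    background_roi: Rect
    scene: GroundTruthScene


@dataclass(frozen=True)
class ConditionPair:
    """Two labeled groups of rendered segments differing only by the
    preset's programmed scale factor."""

    control: tuple[SimulatedSegment, ...]
    test: tuple[SimulatedSegment, ...]
    preset: SimulationPreset
    master_seed: int

    @property
    def groups(self) -> dict[str, tuple[SimulatedSegment, ...]]:
        return {"control": self.control, "test": self.test}


def _segment_from_scene(
    scene: GroundTruthScene, preset: SimulationPreset, photon_scale: float,
    noise_rng_seedkey: tuple[int, ...], master_seed: int, noise: bool,
) -> SimulatedSegment:
    px = preset.pixel_size_nm
    fwhm = preset.psf_fwhm_nm
    noise_seed = int(
        np.random.SeedSequence(master_seed, spawn_key=noise_rng_seedkey)
        .generate_state(1)[0]
    )
    image = render_channel(
        scene, "puncta", px, fwhm, photon_scale,
        preset.read_noise_sd, noise_seed,
        background_level=preset.background_level, noise=noise,
    )
    ny, nx, margin_nm = _render_grid(scene, px, fwhm)
    h_nm = ny * px
    y_mid = h_nm / 2.0
    verts = scene.trace.vertices + np.array([margin_nm, y_mid])
    trace_img = AxonTrace(
        vertices=verts, width_nm=scene.trace.width_nm,
        branch_points_nm=scene.trace.branch_points_nm,
    )
    roi = Rect(x=0, y=0, w=nx, h=2)
    return SimulatedSegment(image=image, trace=trace_img,
                            background_roi=roi, scene=scene)


def simulate_condition_pair(
    preset: SimulationPreset,
    n_per_group: int,
    seed: int,
    paired_geometry: bool = False,
    noise: bool = True,
) -> ConditionPair:
    """Render a control group and a test group of axon segments.

    The only systematic difference between groups is the preset's
    ``scale_factor``, applied to the test group's photon scale or punctum
    density according to ``scale_target``.  With ``paired_geometry=True``
    both groups share scene geometry index-by-index (with photon-scale
    targets and ``noise=False`` the group ratio is then exactly the factor).
    """
    if preset.kind != "condition_pair":
        raise ConfigError(
            f"preset {preset.name!r} is not a condition-pair preset"
        )
    if n_per_group < 0:
        raise ParameterError("n_per_group must be >= 0")
    factor = float(preset.scale_factor)
    target = preset.scale_target
    if target not in ("photon_scale", "density"):
        raise ConfigError(f"unknown scale_target {preset.scale_target!r}")
    amplitude_cv = preset.get("amplitude_cv", 0.25)
    groups: dict[str, list[SimulatedSegment]] = {"control": [], "test": []}
    for gi, gname in enumerate(("control", "test")):
        is_test = gname == "test"
        photon = preset.photon_scale * (factor if is_test and target == "photon_scale" else 1.0)
        for i in range(n_per_group):
            scene_key = (0, i) if paired_geometry else (10 + gi, i)
            scene_seed = int(
                np.random.SeedSequence(seed, spawn_key=scene_key)
                .generate_state(1)[0]
            )
            rng_n = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(20 + gi, i))
            )
            n_puncta = int(preset.n_puncta)
            if target == "density":
                lam = preset.n_puncta * (factor if is_test else 1.0)
                n_puncta = int(rng_n.poisson(lam))
            trace = make_axon_trace(
                preset.length_um, preset.width_nm, 0, seed=scene_seed
            )
            scene = make_scene(
                trace, n_puncta, preset.get("bound_fraction", 0.0),
                preset.get("bind_distance_nm", 0.0),
                preset.get("er_tubule_radius_nm", 50.0),
                seed=scene_seed, amplitude_cv=amplitude_cv,
            )
            groups[gname].append(_segment_from_scene(
                scene, preset, photon, (30 + gi, i), seed, noise
            ))
    return ConditionPair(
        control=tuple(groups["control"]), test=tuple(groups["test"]),
        preset=preset, master_seed=int(seed),
    )


@dataclass(frozen=True)
class ContactSegment:
    """Two-channel rendering of one contact-experiment segment."""

    er_image: PixelImage
    ribo_image: PixelImage
    scene: GroundTruthScene


def simulate_contact_segments(
    preset: SimulationPreset,
    n_segments: int,
    seed: int,
    bound_fraction: float | None = None,
    noise: bool = True,
) -> list[ContactSegment]:
    """Render two-channel STED-like segments for the contact estimator.

    ``bound_fraction`` overrides the preset value (used by parameter-recovery
    sweeps); everything else comes from the preset.
    """
    if preset.kind != "contact":
        raise ConfigError(f"preset {preset.name!r} is not a contact preset")
    bf = preset.bound_fraction if bound_fraction is None else float(bound_fraction)
    out = []
    for i in range(n_segments):
        scene_seed = int(
            np.random.SeedSequence(seed, spawn_key=(0, i)).generate_state(1)[0]
        )
        trace = make_axon_trace(preset.length_um, preset.width_nm, 0, scene_seed)
        scene = make_scene(
            trace, int(preset.n_puncta), bf, preset.bind_distance_nm,
            preset.er_tubule_radius_nm, seed=scene_seed,
            amplitude_cv=preset.get("amplitude_cv", 0.25),
        )
        er_seed = int(
            np.random.SeedSequence(seed, spawn_key=(1, i)).generate_state(1)[0]
        )
        ribo_seed = int(
            np.random.SeedSequence(seed, spawn_key=(2, i)).generate_state(1)[0]
        )
        er = render_channel(
            scene, "er", preset.pixel_size_nm, preset.psf_fwhm_nm,
            preset.photon_scale_er, preset.read_noise_sd, er_seed,
            background_level=preset.background_level, noise=noise,
        )
        ribo = render_channel(
            scene, "puncta", preset.pixel_size_nm, preset.psf_fwhm_nm,
            preset.photon_scale, preset.read_noise_sd, ribo_seed,
            background_level=preset.background_level, noise=noise,
        )
        out.append(ContactSegment(er_image=er, ribo_image=ribo, scene=scene))
    return out


def simulate_branch_segments(
    preset: SimulationPreset, n_segments: int, seed: int, noise: bool = True
) -> list[SimulatedSegment]:
    """Render branched axon segments with punctum density enriched at
    branch-point windows by the preset's programmed fold.

    Branch positions are uniform along the shaft subject to a minimum
    separation (two window widths plus 2 um) from each other and the ends,
    so measurement windows never overlap.
    """
    if preset.kind != "branch":
        raise ConfigError(f"preset {preset.name!r} is not a branch preset")
    length_nm = preset.length_um * 1000.0
    w_nm = preset.branch_window_um * 1000.0
    min_sep = 2.0 * w_nm + 2000.0
    fold = float(preset.branch_enrichment)
    lam_shaft = preset.shaft_density_per_um / 1000.0  # per nm
    out = []
    for i in range(n_segments):
        rng = _substream(seed, 0, i)
        # branch positions with separation constraint
        for _ in range(1000):
            bp = np.sort(rng.uniform(min_sep, length_nm - min_sep,
                                     int(preset.n_branches)))
            if len(bp) < 2 or np.min(np.diff(bp)) >= min_sep:
                break
        windows = [(b - w_nm / 2.0, b + w_nm / 2.0) for b in bp]

        # inhomogeneous Poisson along x by thinning
        lam_max = lam_shaft * fold
        n_cand = rng.poisson(lam_max * length_nm)
        xc = rng.uniform(0.0, length_nm, n_cand)
        in_window = np.zeros(n_cand, dtype=bool)
        for lo, hi in windows:
            in_window |= (xc >= lo) & (xc < hi)
        rate = np.where(in_window, lam_max, lam_shaft)
        keep = rng.uniform(0.0, lam_max, n_cand) < rate
        x = xc[keep]
        n = len(x)
        r_ax = preset.width_nm / 2.0
        # uniform in the cylinder cross-section
        rho = r_ax * np.sqrt(rng.uniform(0.0, 1.0, n))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        positions = np.column_stack([x, rho * np.cos(phi), rho * np.sin(phi)])
        cv = preset.get("amplitude_cv", 0.25)
        if cv > 0:
            s = math.sqrt(math.log(1.0 + cv * cv))
            amps = rng.lognormal(-0.5 * s * s, s, n)
        else:
            amps = np.ones(n)
        trace = AxonTrace(
            vertices=np.array([[0.0, 0.0], [length_nm, 0.0]]),
            width_nm=preset.width_nm, branch_points_nm=tuple(bp),
        )
        scene = GroundTruthScene(
            trace=trace, er_tubule_radius_nm=50.0, positions_nm=positions,
            amplitudes=amps, bound=np.zeros(n, dtype=bool),
            bound_fraction=0.0, bind_distance_nm=0.0, seed=int(seed),
            tubule_coeffs=np.zeros((1, _N_WAVES, 3)),
        )
        out.append(_segment_from_scene(
            scene, preset, preset.photon_scale, (1, i), seed, noise
        ))
    return out


def simulate_frap(
    prebleach_level: float,
    bleach_depth: float,
    recovery_fraction: float,
    recovery_tau_s: float,
    acq_bleach_rate: float,
    n_prebleach: int,
    n_frames: int,
    frame_interval_s: float,
    noise_sd: float,
    seed: int,
    background: float = 0.0,
) -> FrapSeries:
    """Simulate a photobleaching-recovery trace plus an unbleached reference.

    The bleached region drops to ``prebleach_level * (1 - bleach_depth)`` at
    the bleach frame and recovers mono-exponentially (time constant
    ``recovery_tau_s``) toward the level set by ``recovery_fraction``; both
    the trace and the co-emitted reference decay by
    ``exp(-acq_bleach_rate * frame)`` to model acquisition bleaching.
    Gaussian noise is added last.
    """
    if prebleach_level <= 0:
        raise ParameterError("prebleach_level must be positive")
    if not 0.0 <= bleach_depth <= 1.0:
        raise ParameterError("bleach_depth must be in [0, 1]")
    if not 0.0 <= recovery_fraction <= 1.0:
        raise ParameterError("recovery_fraction must be in [0, 1]")
    if recovery_tau_s <= 0 or frame_interval_s <= 0:
        raise ParameterError("time constants must be positive")
    if acq_bleach_rate < 0 or noise_sd < 0:
        raise ParameterError("rates and noise must be >= 0")
    if n_prebleach < 3:
        raise ParameterError("need at least 3 prebleach frames")
    if n_frames <= n_prebleach:
        raise ParameterError("n_frames must exceed n_prebleach")

    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames)
    times = frames * frame_interval_s
    t_post = (frames - n_prebleach) * frame_interval_s
    plateau = prebleach_level * (
        1.0 - bleach_depth
        + bleach_depth * recovery_fraction
    )
    post = plateau - (plateau - prebleach_level * (1.0 - bleach_depth)) \
        * np.exp(-np.clip(t_post, 0.0, None) / recovery_tau_s)
    ideal = np.where(frames < n_prebleach, prebleach_level, post)
    decay = np.exp(-acq_bleach_rate * frames)
    raw = ideal * decay + background
    reference = prebleach_level * decay + background
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, n_frames)
        reference = reference + rng.normal(0.0, noise_sd, n_frames)
    return FrapSeries(
        times_s=times.astype(float), raw=raw.astype(float),
        background=float(background), reference=reference.astype(float),
        bleach_index=int(n_prebleach),
    )


@dataclass(frozen=True)
class MorphologySim:
    """Rasterized neuron tree plus its exact segment list.

    ``segments_um`` are ``(p0, p1)`` pairs in microns relative to the soma
    center, from which analytic Sholl ground truth is computable.
    """

    mask: BinaryMask
    center_rc: tuple[int, int]
    segments_um: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    seed: int

    def ground_truth_sholl(self, radii_um: np.ndarray) -> np.ndarray:
        return analytic_sholl(self.segments_um, radii_um)


def _grow_tree(
    rng: np.random.Generator,
    n_primary: int,
    mean_length_um: float,
    branch_prob: float,
    max_depth: int = 3,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    segments = []
    stack = []
    for k in range(n_primary):
        angle = 2.0 * np.pi * k / n_primary + rng.uniform(-0.2, 0.2)
        length = mean_length_um * rng.uniform(0.85, 1.15)
        stack.append(((0.0, 0.0), angle, length, 0))
    while stack:
        origin, angle, length, depth = stack.pop()
        end = (origin[0] + length * math.cos(angle),
               origin[1] + length * math.sin(angle))
        segments.append((origin, end))
        if depth < max_depth and rng.uniform() < branch_prob:
            for sign in (-1.0, 1.0):
                child_angle = angle + sign * math.radians(rng.uniform(25.0, 40.0))
                child_len = length * rng.uniform(0.55, 0.75)
                if child_len > 2.0:
                    stack.append((end, child_angle, child_len, depth + 1))
    return segments


def simulate_morphology(
    n_primary: int,
    mean_length_um: float,
    branch_prob: float,
    seed: int,
    pixel_size_um: float = 1.0,
) -> MorphologySim:
    """Raster a simple neuron tree (line segments rooted at a soma center)
    into a binary fill mask, keeping the exact segment list as ground truth.
    """
    if n_primary < 1:
        raise ParameterError("n_primary must be >= 1")
    if mean_length_um <= 0 or pixel_size_um <= 0:
        raise ParameterError("lengths must be positive")
    if not 0.0 <= branch_prob <= 1.0:
        raise ParameterError("branch_prob must be in [0, 1]")
    from scipy.ndimage import binary_dilation
    from skimage.draw import line as draw_line

    rng = np.random.default_rng(seed)
    segments = _grow_tree(rng, n_primary, mean_length_um, branch_prob)
    reach = max(max(abs(p[0]), abs(p[1])) for seg in segments for p in seg)
    half = int(math.ceil(reach / pixel_size_um)) + 3
    size = 2 * half + 1
    mask = np.zeros((size, size), dtype=bool)
    for p0, p1 in segments:
        r0 = half + int(round(p0[1] / pixel_size_um))
        c0 = half + int(round(p0[0] / pixel_size_um))
        r1 = half + int(round(p1[1] / pixel_size_um))
        c1 = half + int(round(p1[0] / pixel_size_um))
        rr, cc = draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    # neurites are ~3 px thick, like a thresholded fill; a 1-px skeleton can
    # slip diagonally through a discretized circle without sharing a pixel
    mask = binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))
    return MorphologySim(
        mask=BinaryMask(mask, pixel_size_nm=pixel_size_um * 1000.0),
        center_rc=(half, half),
        segments_um=tuple((tuple(p0), tuple(p1)) for p0, p1 in segments),
        seed=int(seed),
    )


def analytic_sholl(segments_um, radii_um) -> np.ndarray:
    """Exact circle-segment crossing counts for a list of line segments
    around the origin (the geometric Sholl oracle).

    For each radius, counts parameter values ``t in [0, 1)`` where
    ``|p0 + t (p1 - p0)| = r``; half-open so a crossing at a shared tree
    vertex is counted once.
    """
    radii = np.atleast_1d(np.asarray(radii_um, dtype=float))
    counts = np.zeros(len(radii), dtype=int)
    for p0, p1 in segments_um:
        p0 = np.asarray(p0, float)
        d = np.asarray(p1, float) - p0
        a = float(d @ d)
        b = 2.0 * float(p0 @ d)
        for j, r in enumerate(radii):
            c = float(p0 @ p0) - r * r
            disc = b * b - 4.0 * a * c
            if disc <= 0:
                continue  # no crossing, or a tangency (excluded)
            sq = math.sqrt(disc)
            for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                if 0.0 <= t < 1.0:
                    counts[j] += 1
    return counts


def ambiguous_radii(segments_um, radii_um, tol_um: float = 3.0) -> np.ndarray:
    """Boolean flags for radii whose circle passes within ``tol_um`` of a
    tree vertex or of a segment's closest approach — the cases where
    rasterized intersection counting legitimately disagrees with the
    analytic oracle (tangencies, branch points still merged at pixel scale).
    """
    radii = np.atleast_1d(np.asarray(radii_um, dtype=float))
    flags = np.zeros(len(radii), dtype=bool)
    for p0, p1 in segments_um:
        p0 = np.asarray(p0, float)
        p1 = np.asarray(p1, float)
        d = p1 - p0
        for dist in (np.linalg.norm(p0), np.linalg.norm(p1)):
            flags |= np.abs(radii - dist) < tol_um
        # closest approach of the infinite line, if the foot is interior
        t = -float(p0 @ d) / float(d @ d)
        if 0.0 < t < 1.0:
            foot = p0 + t * d
            flags |= np.abs(radii - np.linalg.norm(foot)) < tol_um / 2.0
    return flags
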