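"""Synthetic nerve phantom, activity events, raw recordings and reference images.

The phantom emulates a rat sciatic nerve at the level of a 1.4 mm I.D.
recording cuff: three elliptical fascicles (tibial, peroneal, sural) packed
inside the nerve disk.  An activity event raises the conductivity of one
fascicle by a small fraction (~0.04–0.1%) with a smooth stimulus-locked time
course.  The recording generator runs the forward model for the baseline and
perturbed conductivities and emits per-channel waveforms: a 6 kHz carrier
whose amplitude switches between the two forward solutions along the
activity profile, a biphasic compound-action-potential contaminant locked to
the stimulus triggers, and white Gaussian channel noise.

Reference cross-section images ("microCT-like", "histology-like") are
rendered from the same geometry after a per-axis shrinkage/rescaling and a
rotation relative to the fiducial, emulating fixed-tissue references that
must be co-registered back to the circular cuff frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely import affinity
from shapely.geometry import Point

from .conventions import NERVE_RADIUS_UM, xy_from_polar
from .forward import (
    CEMSystem,
    ConductivityField,
    ElectrodeLayout,
    InjectionProtocol,
    SIGMA_NERVE_DEFAULT,
)
from .mesh import REGION_NERVE, TriMesh

FASCICLE_LABELS = ("tibial", "peroneal", "sural")

# base fascicle layout (polar center, semi-axes) in µm; jittered per seed
_DEFAULT_LAYOUT = {
    "tibial": dict(r=280.0, theta=135.0, a=260.0, b=210.0),
    "peroneal": dict(r=330.0, theta=255.0, a=170.0, b=140.0),
    "sural": dict(r=390.0, theta=10.0, a=110.0, b=90.0),
}


class PackingError(RuntimeError):
    """Fascicle rejection sampling failed to produce a feasible packing."""


STIM_RATE_HZ_DEFAULT = 5.0
INJECTION_DURATION_S_DEFAULT = 60.0


def protocol_timing(
    stim_rate_hz: float = STIM_RATE_HZ_DEFAULT,
    injection_duration_s: float = INJECTION_DURATION_S_DEFAULT,
    n_injections: int = 14,
) -> dict:
    """Trial/timing arithmetic of the recording protocol: trials averaged
    per injection and the total acquisition time per stimulated branch."""
    return dict(
        trials_per_injection=int(round(stim_rate_hz * injection_duration_s)),
        total_minutes=n_injections * injection_duration_s / 60.0,
    )


@dataclass
class FascicleSpec:
    label: str
    center_r_um: float
    center_theta_deg: float
    a_um: float  # semi-major
    b_um: float  # semi-minor
    orientation_deg: float = 0.0  # major-axis direction, deg CW from +y

    def center_xy_um(self) -> tuple[float, float]:
        x, y = xy_from_polar(self.center_r_um, self.center_theta_deg)
        return float(x), float(y)

    def polygon(self):
        """Shapely polygon of the ellipse (µm frame)."""
        circ = Point(0.0, 0.0).buffer(1.0, quad_segs=64)
        ell = affinity.scale(circ, self.a_um, self.b_um)
        # orientation measured CW from +y == CCW angle of major axis from +x
        # is (90 − orientation); shapely rotates CCW
        ell = affinity.rotate(ell, 90.0 - self.orientation_deg, origin=(0, 0))
        x0, y0 = self.center_xy_um()
        return affinity.translate(ell, x0, y0)

    def contains_points(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Vectorized point-in-ellipse test via the quadratic form."""
        x0, y0 = self.center_xy_um()
        phi = np.radians(90.0 - self.orientation_deg)  # CCW from +x
        dx, dy = x_um - x0, y_um - y0
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        return (u / self.a_um) ** 2 + (v / self.b_um) ** 2 <= 1.0

    def area_um2(self) -> float:
        return float(np.pi * self.a_um * self.b_um)


@dataclass
class FasciclePhantom:
    nerve_radius_um: float = NERVE_RADIUS_UM
    fascicles: list[FascicleSpec] = field(default_factory=list)
    side: str = "right"
    fiducial_deg: float = 0.0
    seed: int | None = None

    def fascicle(self, label: str) -> FascicleSpec:
        for f in self.fascicles:
            if f.label == label:
                return f
        raise KeyError(f"no fascicle labelled {label!r}")

    def com_table_um(self) -> dict[str, tuple[float, float]]:
        return {f.label: f.center_xy_um() for f in self.fascicles}


@dataclass
class ActivityEvent:
    """Stimulus-locked conductivity increase in one fascicle.

    The temporal profile is a raised-cosine pulse normalized to peak 1;
    ``duration30_ms`` is its width at 30% of peak, matching the reported
    response-duration metric.
    """

    fascicle: str = "tibial"
    fractional_change: float = 5e-4
    onset_ms: float = 0.7
    duration30_ms: float = 0.7
    cap_amplitude_uv: float = 200.0

    # fraction of the raised-cosine period spent above 30% of peak
    _D30_FRACTION = 1.0 - np.arccos(0.4) / np.pi  # ≈ 0.631

    def __post_init__(self):
        if self.fractional_change < 0:
            raise ValueError("fractional change must be >= 0")
        if self.onset_ms < 0:
            raise ValueError("onset latency must be >= 0")

    @property
    def period_ms(self) -> float:
        return self.duration30_ms / self._D30_FRACTION

    def profile(self, t_ms: np.ndarray) -> np.ndarray:
        """Raised-cosine activity profile, peak 1, zero outside the pulse."""
        t = np.asarray(t_ms, dtype=float) - self.onset_ms
        T = self.period_ms
        out = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / T))
        out[(t < 0) | (t > T)] = 0.0
        return out

    def cap_template_uv(self, t_ms: np.ndarray) -> np.ndarray:
        """Biphasic CAP contaminant: Gaussian first derivative, sub-ms width,
        peak `cap_amplitude_uv`, spectral content well below 4 kHz."""
        sigma = 0.25  # ms
        t = np.asarray(t_ms, dtype=float) - self.onset_ms - 2.0 * sigma
        g = -t / sigma * np.exp(0.5 - 0.5 * (t / sigma) ** 2)
        return self.cap_amplitude_uv * g


def make_phantom(
    seed: int,
    nerve_radius_um: float = NERVE_RADIUS_UM,
    side: str = "right",
    jitter_theta_deg: float = 24.0,
    jitter_r_um: float = 70.0,
    jitter_size: float = 0.1,
    wall_margin_um: float = 25.0,
    gap_margin_um: float = 30.0,
    max_attempts: int = 200,
) -> FasciclePhantom:
    """Draw a deterministic three-fascicle phantom.

    Fascicle centers, sizes and orientations are jittered around a default
    layout; candidate packings are rejected until all ellipses lie inside the
    nerve disk (with margin) and are pairwise disjoint.
    """
    if nerve_radius_um <= 0:
        raise ValueError("nerve radius must be positive")
    rng = np.random.default_rng(seed)
    scale = nerve_radius_um / NERVE_RADIUS_UM
    disk = Point(0, 0).buffer(nerve_radius_um - wall_margin_um, quad_segs=128)
    for _ in range(max_attempts):
        fascicles = []
        for label in FASCICLE_LABELS:
            base = _DEFAULT_LAYOUT[label]
            theta = (base["theta"] + rng.uniform(-jitter_theta_deg, jitter_theta_deg)) % 360.0
            orient = rng.uniform(0.0, 180.0)
            if side == "left":
                # left-side anatomy is the mirror image of the right side
                theta = (360.0 - theta) % 360.0
                orient = (180.0 - orient) % 180.0
            fascicles.append(
                FascicleSpec(
                    label=label,
                    center_r_um=scale * base["r"] + rng.uniform(-jitter_r_um, jitter_r_um),
                    center_theta_deg=theta,
                    a_um=scale * base["a"] * (1.0 + rng.uniform(-jitter_size, jitter_size)),
                    b_um=scale * base["b"] * (1.0 + rng.uniform(-jitter_size, jitter_size)),
                    orientation_deg=orient,
                )
            )
        polys = [f.polygon() for f in fascicles]
        if not all(disk.contains(p) for p in polys):
            continue
        ok = True
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                if polys[i].distance(polys[j]) < gap_margin_um:
                    ok = False
        if ok:
            return FasciclePhantom(
                nerve_radius_um=nerve_radius_um,
                fascicles=fascicles,
                side=side,
                seed=seed,
            )
    raise PackingError(f"no feasible packing after {max_attempts} attempts")


def perturbation_field(
    phantom: FasciclePhantom,
    event: ActivityEvent,
    mesh: TriMesh,
    baseline_sigma: float = SIGMA_NERVE_DEFAULT,
) -> np.ndarray:
    """Per-element conductivity increase (S/m) at the event's peak:
    baseline σ × fractional change on elements whose centroid lies inside
    the active fascicle ellipse, zero elsewhere."""
    fas = phantom.fascicle(event.fascicle)
    cent = mesh.element_centroids() * 1e6  # m -> µm
    inside = fas.contains_points(cent[:, 0], cent[:, 1])
    inside &= mesh.region == REGION_NERVE
    delta = np.zeros(mesh.n_elements)
    delta[inside] = baseline_sigma * event.fractional_change
    return delta


@dataclass
class RawRecording:
    """Per-injection multichannel waveforms with triggers and ground truth."""

    waveforms: list[np.ndarray]  # n_injections arrays of (n_channels, n_samples)
    triggers_s: np.ndarray  # trigger times within each injection run
    sample_rate: float
    protocol: InjectionProtocol
    phantom: FasciclePhantom
    event: ActivityEvent
    baseline_voltages: np.ndarray  # (n_injections, n_electrodes)
    perturbed_voltages: np.ndarray
    noise_sd_v: float
    seed: int
    stim_rate_hz: float = 5.0
    channel_map: np.ndarray | None = None

    @property
    def n_injections(self) -> int:
        return len(self.waveforms)

    @property
    def n_channels(self) -> int:
        return self.waveforms[0].shape[0]


def noise_sd_for_snr(
    target_snr: float,
    peak_dv_v: float,
    n_trials: int,
    sample_rate: float,
    bandwidth: float = 2e3,
) -> float:
    """Channel white-noise SD giving the requested averaged-trace SNR.

    After the ±bandwidth band-pass the envelope noise SD is
    σ·sqrt(4·bandwidth/fs) (in-phase narrowband component), and trial
    averaging divides it by √N, so

        σ = (peak δV / SNR) · √N · sqrt(fs / (4·bandwidth)).
    """
    if target_snr <= 0:
        raise ValueError("target SNR must be positive")
    return (
        abs(peak_dv_v)
        / target_snr
        * np.sqrt(n_trials)
        * np.sqrt(sample_rate / (4.0 * bandwidth))
    )


def synthesize_recording(
    phantom: FasciclePhantom,
    layout: ElectrodeLayout,
    protocol: InjectionProtocol,
    event: ActivityEvent,
    noise_sd: float,
    sample_rate: float = 100e3,
    seed: int = 0,
    mesh: TriMesh | None = None,
    n_trials: int = 300,
    stim_rate_hz: float = 5.0,
    baseline_system: CEMSystem | None = None,
    sigma: ConductivityField | None = None,
    faulty_electrodes: set[int] | None = None,
    cap_gain_jitter: float = 0.3,
    dtype=np.float64,
) -> RawRecording:
    """Generate raw carrier-modulated cuff recordings for every injection.

    Each channel is ``A_m(t)·cos(2πf_c t) + CAP(t) + noise`` where the
    carrier amplitude A_m steps from the baseline forward voltage to the
    perturbed-field forward voltage along the activity profile after each
    stimulus trigger.  Deterministic for a fixed seed.
    """
    if sample_rate < 4.0 * protocol.carrier_hz:
        raise ValueError(
            f"sample rate {sample_rate} Hz below 4× carrier; aliasing risk"
        )
    if mesh is None:
        raise ValueError("a mesh is required to run the forward model")
    rng = np.random.default_rng(seed)

    if sigma is None:
        sigma = ConductivityField.baseline(mesh)
    if baseline_system is None:
        baseline_system = CEMSystem(mesh, sigma, layout)
    delta = perturbation_field(phantom, event, mesh)
    pert_system = CEMSystem(mesh, sigma.perturbed(delta), layout)

    L = layout.n_electrodes
    currents = np.zeros((protocol.n_injections, L))
    for k, (src, snk) in enumerate(protocol.pairs):
        currents[k, src] = protocol.current_a
        currents[k, snk] = -protocol.current_a
    _, U0 = baseline_system.solve_currents(currents)
    _, U1 = pert_system.solve_currents(currents)

    period_s = 1.0 / stim_rate_hz
    n_samples = int(round(n_trials * period_s * sample_rate))
    t = np.arange(n_samples) / sample_rate
    triggers = np.arange(n_trials) * period_s
    carrier_wave = np.cos(2.0 * np.pi * protocol.carrier_hz * t)

    # stimulus-locked modulation profile and CAP template over one period
    t_in_period_ms = (t % period_s) * 1e3
    prof = event.profile(t_in_period_ms)
    cap_v = event.cap_template_uv(t_in_period_ms) * 1e-6

    cap_gain = 1.0 + rng.uniform(-cap_gain_jitter, cap_gain_jitter, size=L)
    faulty = faulty_electrodes or set()

    waveforms = []
    for k in range(protocol.n_injections):
        x = np.empty((L, n_samples), dtype=dtype)
        for ch in range(L):  # channel-wise keeps peak memory ~1 channel
            xc = (U0[k, ch] + (U1[k, ch] - U0[k, ch]) * prof) * carrier_wave
            xc += cap_gain[ch] * cap_v
            if noise_sd > 0:
                xc += rng.normal(0.0, noise_sd, size=n_samples)
            if ch in faulty:
                xc += rng.normal(0.0, 50.0 * max(noise_sd, 1e-6), size=n_samples)
            x[ch] = xc
        waveforms.append(x)

    return RawRecording(
        waveforms=waveforms,
        triggers_s=triggers,
        sample_rate=sample_rate,
        protocol=protocol,
        phantom=phantom,
        event=event,
        baseline_voltages=U0,
        perturbed_voltages=U1,
        noise_sd_v=noise_sd,
        seed=seed,
        stim_rate_hz=stim_rate_hz,
    )


# ---------------------------------------------------------------------------
# reference images (microCT-like / histology-like)
# ---------------------------------------------------------------------------

@dataclass
class DistortionSpec:
    """Rigid deformation applied to a reference modality: per-axis scaling
    (tissue shrinkage), then rotation; both invertible."""

    scale_x: float = 1.0
    scale_y: float = 1.0
    rotation_deg: float = 0.0

    def __post_init__(self):
        if not (0.5 < self.scale_x < 1.5 and 0.5 < self.scale_y < 1.5):
            raise ValueError("distortion scales must lie in (0.5, 1.5)")
        if not (-180.0 <= self.rotation_deg <= 180.0):
            raise ValueError("rotation must be within ±180°")

    def matrix(self) -> np.ndarray:
        """2×2 linear map (µm frame): rotate(R) · diag(sx, sy)."""
        th = np.radians(-self.rotation_deg)  # CW-positive rotation in xy
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return R @ np.diag([self.scale_x, self.scale_y])

    def apply(self, xy_um: np.ndarray) -> np.ndarray:
        return np.asarray(xy_um) @ self.matrix().T

    def inverse(self, xy_um: np.ndarray) -> np.ndarray:
        return np.asarray(xy_um) @ np.linalg.inv(self.matrix()).T


_MODALITY_STYLE = {
    "microct": dict(pixel_size_um=4.0, bg=0.15, nerve=0.45, fascicle=0.75, noise=0.04),
    "histology": dict(pixel_size_um=2.0, bg=0.05, nerve=0.30, fascicle=0.85, noise=0.03),
}


@dataclass
class ReferenceImages:
    image: np.ndarray
    pixel_size_um: float
    masks: dict[str, np.ndarray]  # per-fascicle + "nerve" boolean masks
    mask_labels: dict[str, str]  # mask key -> anatomical label ("?" if untraced)
    distortion: DistortionSpec
    fiducial_px: tuple[float, float]
    com_true_um: dict[str, tuple[float, float]]  # pre-distortion ground truth
    com_distorted_um: dict[str, tuple[float, float]]
    modality: str
    side: str
    nerve_radius_um: float
    seed: int

    def center_px(self) -> tuple[float, float]:
        return ((self.image.shape[1] - 1) / 2.0, (self.image.shape[0] - 1) / 2.0)


def _px_grid_um(shape: tuple[int, int], pixel_size_um: float):
    """Pixel-center coordinates (µm), origin at image center, +y up."""
    h, w = shape
    x = (np.arange(w) - (w - 1) / 2.0) * pixel_size_um
    y = ((h - 1) / 2.0 - np.arange(h)) * pixel_size_um
    return np.meshgrid(x, y)


def render_reference_images(
    phantom: FasciclePhantom,
    modality: str = "microct",
    distortion: DistortionSpec | None = None,
    seed: int = 0,
) -> ReferenceImages:
    """Render a distorted cross-section image + fascicle masks for one
    reference modality, with ground-truth centers recorded before and after
    distortion."""
    if modality not in _MODALITY_STYLE:
        raise ValueError(f"unknown modality {modality!r}")
    style = _MODALITY_STYLE[modality]
    rng = np.random.default_rng(seed)
    if distortion is None:
        # fixed-tissue shrinkage ~10% with mild anisotropy + arbitrary rotation
        distortion = DistortionSpec(
            scale_x=0.92 + rng.uniform(-0.04, 0.04),
            scale_y=0.88 + rng.uniform(-0.04, 0.04),
            rotation_deg=rng.uniform(-60.0, 60.0),
        )

    ps = style["pixel_size_um"]
    Rn = phantom.nerve_radius_um
    half = 1.35 * Rn
    n_px = int(np.ceil(2 * half / ps))
    X, Y = _px_grid_um((n_px, n_px), ps)
    # work in the *distorted* frame: a pixel at (X, Y) corresponds to the
    # undistorted tissue point M⁻¹ (X, Y)
    Minv = np.linalg.inv(distortion.matrix())
    Xu = Minv[0, 0] * X + Minv[0, 1] * Y
    Yu = Minv[1, 0] * X + Minv[1, 1] * Y

    nerve_mask = Xu**2 + Yu**2 <= Rn**2
    image = np.full((n_px, n_px), style["bg"])
    image[nerve_mask] = style["nerve"]

    masks: dict[str, np.ndarray] = {"nerve": nerve_mask}
    mask_labels: dict[str, str] = {}
    com_true, com_dist = {}, {}
    for i, f in enumerate(phantom.fascicles):
        m = f.contains_points(Xu, Yu)
        level = style["fascicle"] * (1.0 - 0.08 * i)
        image[m] = level
        if modality == "histology" and f.label == "sural":
            key = "unlabeled-0"  # no tracer in the sural fascicle
            mask_labels[key] = "?"
            image[m] = style["nerve"] + 0.08  # faint, untraced
        else:
            key = f.label
            mask_labels[key] = f.label
        masks[key] = m
        com_true[f.label] = f.center_xy_um()
        com_dist[f.label] = tuple(distortion.apply(np.array(f.center_xy_um())))

    # fiducial: bright dot on the distorted nerve boundary at the cuff opening
    fx, fy = xy_from_polar(Rn, phantom.fiducial_deg)
    fdx, fdy = distortion.apply(np.array([fx, fy]))
    fid_mask = (X - fdx) ** 2 + (Y - fdy) ** 2 <= (4.0 * ps) ** 2
    image[fid_mask] = 1.0

    image += rng.normal(0.0, style["noise"], size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    cx, cy = (n_px - 1) / 2.0, (n_px - 1) / 2.0
    fid_px = (cx + fdx / ps, cy - fdy / ps)

    return ReferenceImages(
        image=image,
        pixel_size_um=ps,
        masks=masks,
        mask_labels=mask_labels,
        distortion=distortion,
        fiducial_px=fid_px,
        com_true_um=com_true,
        com_distorted_um=com_dist,
        modality=modality,
        side=phantom.side,
        nerve_radius_um=Rn,
        seed=seed,
    )
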