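"""Synthetic dynamic perfusion phantom with known ground truth.

Each phantom patient has three short-axis slices (basal, mid, apical) with
annular myocardium, a gamma-variate arterial input, and a planted MBF
field: a remote level everywhere except configurable defect regions
defined as polar intervals (angular range in the bullseye convention,
transmural range as wall-depth fractions).  The dynamic signal is the
forward model of the quantification pipeline — the tissue concentration is
the discrete convolution of the AIF with the Fermi impulse response of the
pixel's true MBF — converted to signal with ``S = S0 * (1 + c)`` plus
seeded Gaussian noise of SD ``noise_sd * S0``.

Default flow levels (remote 2.35, defect 1.1 mL/min/g) sit at typical
stress values for normally perfused and ischaemic myocardium, so synthetic
statistics are commensurate with clinical ranges.  The default forward
response shape is ``width_w = 10 s``, ``decay_k = 0.3 /s``,
``delay_td = 2 s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import SliceGeometry
from .kinetics import (
    ArterialInput,
    ConcentrationCurve,
    DynamicSeries,
    FermiParameters,
    convolve_aif,
    fermi_response,
)

__all__ = [
    "GammaVariate",
    "Defect",
    "PhantomSpec",
    "SliceTruth",
    "make_aif",
    "make_truth",
    "render_series",
    "make_patient",
]

SLICE_ORDER = ("basal", "mid", "apical")


@dataclass(frozen=True)
class GammaVariate:
    """Gamma-variate bolus model ``A * ((t-t0)/beta)^alpha * exp(-(t-t0)/beta)``."""

    t0: float = 5.0         # bolus arrival, s
    alpha: float = 2.5      # shape
    beta: float = 3.5       # time scale, s
    amplitude: float = 5.0  # peak-scaling factor (dimensionless concentration)

    def __call__(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        x = np.clip(t - self.t0, 0.0, None) / self.beta
        c = self.amplitude * x**self.alpha * np.exp(-x)
        c[t <= self.t0] = 0.0
        return c

    @property
    def peak_time(self) -> float:
        return self.t0 + self.alpha * self.beta


@dataclass(frozen=True)
class Defect:
    """A perfusion defect as a polar region of the myocardium.

    Angles are degrees in the bullseye convention (0 at the anterior RV
    insertion point, increasing toward the inferior insertion point);
    transmural fractions run 0 (subendocardium) to 1 (subepicardium).
    """

    slices: tuple = ("basal", "mid")
    theta_start: float = 60.0
    theta_extent: float = 90.0
    f_start: float = 0.0
    f_extent: float = 1.0
    mbf: float = 1.1

    def __post_init__(self):
        if not 0 < self.theta_extent <= 360:
            raise ValueError("theta_extent must be in (0, 360]")
        if not (0 <= self.f_start < 1 and 0 < self.f_extent <= 1 - self.f_start):
            raise ValueError("transmural interval must lie within [0, 1]")
        for s in self.slices:
            if s not in SLICE_ORDER:
                raise ValueError(f"unknown slice {s!r}")

    def contains(self, theta_deg: np.ndarray, f: np.ndarray) -> np.ndarray:
        dtheta = np.mod(theta_deg - self.theta_start, 360.0)
        return (
            (dtheta < self.theta_extent)
            & (f >= self.f_start)
            & (f < self.f_start + self.f_extent)
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic patient."""

    image_size: int = 96
    #: (endo_radius, epi_radius) pixels per slice
    radii: dict = field(
        default_factory=lambda: {
            "basal": (11.0, 19.0),
            "mid": (10.0, 18.0),
            "apical": (8.0, 15.0),
        }
    )
    #: image-frame angle (degrees) of the anterior RV insertion point
    rv_angle: float = 200.0
    #: angular distance (degrees) from the anterior to the inferior
    #: insertion point, in the direction of increasing bullseye angle
    septal_span: float = 120.0
    defects: tuple = ()
    remote_mbf: float = 2.35
    aif_params: GammaVariate = field(default_factory=GammaVariate)
    frame_interval_s: float = 1.0
    n_frames: int = 50
    s0: float = 100.0
    noise_sd: float = 0.02
    seed: int = 0
    #: forward Fermi response shape (width_w s, decay_k 1/s, delay_td s)
    response_shape: tuple = (10.0, 0.3, 2.0)

    def __post_init__(self):
        for label, (endo, epi) in self.radii.items():
            if not endo < epi:
                raise ValueError(f"endo radius must be below epi radius ({label})")
        if not 0.0 < self.septal_span < 180.0:
            raise ValueError("septal_span must lie strictly between 0 and 180 degrees")
        for d in self.defects:
            if d.mbf >= self.remote_mbf:
                raise ValueError("defect MBF must be below the remote MBF")

    @property
    def frame_times(self) -> np.ndarray:
        return self.frame_interval_s * np.arange(self.n_frames)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["aif_params"] = asdict(self.aif_params)
        d["defects"] = [asdict(x) for x in self.defects]
        return d


@dataclass
class SliceTruth:
    """Ground truth for one slice: geometry, MBF field and masks."""

    geometry: SliceGeometry
    mbf_field: np.ndarray     # true MBF per pixel, NaN off-myocardium
    myo_mask: np.ndarray
    defect_mask: np.ndarray   # reference defect mask (subset of myo_mask)


def make_aif(aif_params: GammaVariate, times: np.ndarray) -> ArterialInput:
    """Evaluate the gamma-variate bolus on a time grid."""
    values = aif_params(times)
    return ArterialInput(ConcentrationCurve(values=values, times=np.asarray(times, float)))


def _circle(center: float, radius: float, n: int = 120) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center + radius * np.cos(ang), center + radius * np.sin(ang)])


def make_truth(spec: PhantomSpec) -> dict[str, SliceTruth]:
    """Geometry, true MBF fields and reference defect masks per slice."""
    size = spec.image_size
    c = (size - 1) / 2.0
    phi_a = np.deg2rad(spec.rv_angle)
    phi_i = np.deg2rad(spec.rv_angle + spec.septal_span)
    out = {}
    for label in SLICE_ORDER:
        r_endo, r_epi = spec.radii[label]
        if r_epi + 3 > c:
            raise ValueError("epicardium does not fit inside the image")
        geom = SliceGeometry(
            endo_contour=_circle(c, r_endo),
            epi_contour=_circle(c, r_epi),
            rv_anterior=np.array(
                [c + (r_epi + 2) * np.cos(phi_a), c + (r_epi + 2) * np.sin(phi_a)]
            ),
            rv_inferior=np.array(
                [c + (r_epi + 2) * np.cos(phi_i), c + (r_epi + 2) * np.sin(phi_i)]
            ),
            slice_label=label,
        )
        yy, xx = np.mgrid[0:size, 0:size]
        r = np.hypot(xx - c, yy - c)
        myo = (r >= r_endo) & (r < r_epi)
        # bullseye angle of each pixel (direction: +phi, by construction)
        phi = np.arctan2(yy - c, xx - c)
        theta = np.rad2deg(np.mod(phi - phi_a, 2.0 * np.pi))
        f = np.clip((r - r_endo) / (r_epi - r_endo), 0.0, 1.0)
        field_arr = np.full((size, size), np.nan)
        field_arr[myo] = spec.remote_mbf
        defect = np.zeros((size, size), dtype=bool)
        for d in spec.defects:
            if label not in d.slices:
                continue
            region = myo & d.contains(theta, f)
            field_arr[region] = d.mbf
            defect |= region
        out[label] = SliceTruth(
            geometry=geom, mbf_field=field_arr, myo_mask=myo, defect_mask=defect
        )
    return out


def render_series(
    spec: PhantomSpec,
    truth: dict[str, SliceTruth],
    aif: ArterialInput,
) -> dict[str, DynamicSeries]:
    """Forward-simulate the dynamic signal for every slice.

    Myocardial pixels follow the convolution of the AIF with the Fermi
    response of their true MBF; cavity pixels follow the AIF itself;
    background stays at baseline.  One seeded noise draw covers all slices
    so identical specs give bit-identical series.
    """
    times = spec.frame_times
    dt = spec.frame_interval_s
    w, k, td = spec.response_shape
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    c = (size - 1) / 2.0
    out = {}
    for label in SLICE_ORDER:
        st = truth[label]
        field_arr = st.mbf_field
        curves = np.zeros((spec.n_frames, size, size))
        for mbf in np.unique(field_arr[st.myo_mask]):
            resp = fermi_response(FermiParameters(mbf, w, k, td), times)
            tissue = convolve_aif(aif, resp, dt)
            sel = st.myo_mask & (field_arr == mbf)
            curves[:, sel] = tissue[:, None]
        r_endo = spec.radii[label][0]
        yy, xx = np.mgrid[0:size, 0:size]
        cavity = np.hypot(xx - c, yy - c) < r_endo
        curves[:, cavity] = aif.values[:, None]
        signal = spec.s0 * (1.0 + curves)
        if spec.noise_sd > 0:
            signal = signal + rng.normal(
                0.0, spec.noise_sd * spec.s0, size=signal.shape
            )
        signal = np.clip(signal, 0.0, None)
        out[label] = DynamicSeries(
            frames=signal, frame_times=times.copy(), slice_label=label
        )
    return out


def truth_bullseye_mask(spec: PhantomSpec, n_layers: int = 10, n_angles: int = 60) -> np.ndarray:
    """Ground-truth defect mask on the bullseye grid (3, layers, angles).

    A grid cell is positive when its centre (angle-bin centre, transmural
    layer centre) lies inside a planted defect of its slice.
    """
    mask = np.zeros((3, n_layers, n_angles), dtype=bool)
    theta = (np.arange(n_angles) + 0.5) * (360.0 / n_angles)
    f = (np.arange(n_layers) + 0.5) / n_layers
    ff, tt = np.meshgrid(f, theta, indexing="ij")
    for si, label in enumerate(SLICE_ORDER):
        for d in spec.defects:
            if label in d.slices:
                mask[si] |= d.contains(tt, ff)
    return mask


def make_patient(spec: PhantomSpec):
    """Convenience: ``(truth, aif, series)`` for one phantom patient."""
    truth = make_truth(spec)
    aif = make_aif(spec.aif_params, spec.frame_times)
    series = render_series(spec, truth, aif)
    return truth, aif, series
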