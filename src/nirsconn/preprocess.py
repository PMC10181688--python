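"""Intensity -> hemoglobin conversion and band-pass filtering.

Continuous-wave fNIRS measures light attenuation at two wavelengths (here
760 and 850 nm).  The change in optical density of channel *k*,

    dOD_k(t) = -ln( I_k(t) / mean_t I_k(t) ),

relates linearly to the changes in oxy- and deoxy-hemoglobin concentration
through the modified Beer-Lambert law (MBLL):

    dOD_lambda = (eps_HbO,lambda * dHbO + eps_HbR,lambda * dHbR) * d * DPF_lambda

with *d* the source-detector separation and DPF the differential pathlength
factor correcting for photon scattering.  With two wavelengths per optode
pair this is a 2x2 linear system solved per time point.

Hemodynamic task responses live well below 1 Hz, so the signals are
band-passed 0.01-0.40 Hz with a linear-phase FIR filter of order 71 applied
forward-backward (zero phase).  Zero-phase application matters here: a
one-directional FIR pass delays every channel by (order/2) samples, which
would contaminate the lagged regressions used for connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DataError, NumericalError, PairingError, ValidationError
from .io import EventMarker, IntensityRecording, ProbeGeometry

__all__ = [
    "DEFAULT_EXTINCTION",
    "DEFAULT_DPF",
    "FilterSpec",
    "HbSeries",
    "optical_density",
    "mbll",
    "design_fir_bandpass",
    "apply_filter",
]

#: Molar extinction coefficients in 1/(mM*cm), {wavelength: (HbO, HbR)}.
#: Standard continuous-wave fNIRS values for the 760/850 nm pair.
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    760.0: (1.4866, 3.8437),
    850.0: (2.5264, 1.7986),
}

#: Differential pathlength factor applied to both wavelengths by default.
DEFAULT_DPF = 6.0


@dataclass
class HbSeries:
    """Per-channel hemoglobin concentration changes in micromolar.

    One row per source-detector pair (the two wavelengths of a pair collapse
    into one HbO/HbR pair), with the pair's midpoint coordinate attached.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_coords: np.ndarray
    run_condition: str | None = None
    event_markers: list[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        self.channel_coords = np.asarray(self.channel_coords, dtype=float)
        self.event_markers = [EventMarker(*m) for m in self.event_markers]
        if self.hbo.shape != self.hbr.shape:
            raise ValidationError("hbo and hbr must share shape and channel order")
        if self.hbo.ndim != 2:
            raise ValidationError("hbo/hbr must be channels x time matrices")
        if self.channel_coords.shape != (self.hbo.shape[0], 3):
            raise ValidationError("channel_coords must be (L, 3)")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise DataError("non-finite values in hemoglobin series")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass FIR specification: ``order`` is the filter order (taps - 1)."""

    order: int = 71
    band: tuple[float, float] = (0.010, 0.400)
    fs: float = 10.2

    def __post_init__(self) -> None:
        low, high = self.band
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        if not (0 < low < high):
            raise ValidationError(f"need 0 < low < high, got band {self.band}")
        if high >= self.fs / 2:
            raise ValidationError(
                f"upper band edge {high} Hz must be below Nyquist {self.fs / 2} Hz"
            )


def optical_density(recording: IntensityRecording) -> np.ndarray:
    """Change in optical density per channel, referenced to the channel's
    temporal mean intensity: dOD(t) = -ln(I(t) / mean(I)).

    Invariant to global intensity rescaling; a constant trace maps to zero.
    """
    I = recording.intensities
    if not np.all(I > 0):
        bad = int(np.argwhere(~(I > 0))[0][0])
        raise DataError(f"channel {bad} has non-positive intensity")
    return -np.log(I / I.mean(axis=1, keepdims=True))


def _dpf_for(dpf, wavelength: float) -> float:
    if np.isscalar(dpf):
        return float(dpf)
    return float(dpf[wavelength])


def mbll(
    od: np.ndarray,
    geometry: ProbeGeometry,
    *,
    fs: float,
    dpf=DEFAULT_DPF,
    extinction: dict[float, tuple[float, float]] | None = None,
    run_condition: str | None = None,
    event_markers=(),
) -> HbSeries:
    """Invert the modified Beer-Lambert law.

    Parameters
    ----------
    od
        Optical-density matrix, channels x time, rows ordered as
        ``geometry.channels`` (two wavelength rows per source-detector pair).
    geometry
        Montage; source-detector distances are taken from its coordinates
        (assumed centimetres so the output lands in micromolar).
    dpf
        Differential pathlength factor: scalar, or mapping wavelength -> DPF.
    extinction
        Mapping wavelength -> (eps_HbO, eps_HbR) in 1/(mM*cm).

    Returns
    -------
    HbSeries with one row per source-detector pair, in micromolar.
    """
    if extinction is None:
        extinction = DEFAULT_EXTINCTION
    od = np.asarray(od, dtype=float)
    if od.shape[0] != geometry.n_channels:
        raise ValidationError("OD row count must match geometry channel count")

    distances = geometry.sd_distances()
    pairs = geometry.pairs()

    hbo_rows, hbr_rows, coords = [], [], []
    for (s, d), idx in pairs.items():
        if len(idx) != 2:
            raise PairingError(
                f"source {s} / detector {d}: expected 2 wavelength channels, "
                f"found {len(idx)}"
            )
        k1, k2 = idx
        wl1 = geometry.channels[k1].wavelength
        wl2 = geometry.channels[k2].wavelength
        if wl1 == wl2:
            raise PairingError(
                f"source {s} / detector {d}: duplicate wavelength {wl1} nm"
            )
        dist = distances[k1]
        if dist <= 0:
            raise ValidationError(
                f"source {s} / detector {d}: non-positive separation"
            )
        try:
            e1 = extinction[wl1]
            e2 = extinction[wl2]
        except KeyError as exc:
            raise ValidationError(
                f"no extinction coefficients for wavelength {exc.args[0]} nm"
            ) from exc
        # Rows scaled by pathlength: dOD = E @ [dHbO_mM, dHbR_mM]
        E = np.array(
            [
                [e1[0] * dist * _dpf_for(dpf, wl1), e1[1] * dist * _dpf_for(dpf, wl1)],
                [e2[0] * dist * _dpf_for(dpf, wl2), e2[1] * dist * _dpf_for(dpf, wl2)],
            ]
        )
        if abs(np.linalg.det(E)) < 1e-12 * np.abs(E).max() ** 2:
            raise NumericalError(
                f"extinction system for pair ({s},{d}) is singular"
            )
        conc_mM = np.linalg.solve(E, od[[k1, k2], :])
        hbo_rows.append(conc_mM[0] * 1e3)  # mM -> uM
        hbr_rows.append(conc_mM[1] * 1e3)
        coords.append(geometry.channel_coords[k1])

    return HbSeries(
        hbo=np.vstack(hbo_rows),
        hbr=np.vstack(hbr_rows),
        fs=fs,
        channel_coords=np.vstack(coords),
        run_condition=run_condition,
        event_markers=list(event_markers),
    )


def mbll_forward(
    hbo_uM: np.ndarray,
    hbr_uM: np.ndarray,
    distance: float,
    wavelengths=(760.0, 850.0),
    dpf=DEFAULT_DPF,
    extinction: dict[float, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Forward Beer-Lambert model: hemoglobin (uM) -> dOD at each wavelength.

    The exact inverse of :func:`mbll` for a single pair; used by the
    simulator and by round-trip checks.
    """
    if extinction is None:
        extinction = DEFAULT_EXTINCTION
    out = []
    for wl in wavelengths:
        eps_o, eps_r = extinction[wl]
        out.append(
            (eps_o * hbo_uM * 1e-3 + eps_r * hbr_uM * 1e-3)
            * distance
            * _dpf_for(dpf, wl)
        )
    return np.asarray(out)


def design_fir_bandpass(spec: FilterSpec) -> np.ndarray:
    """Linear-phase band-pass FIR taps (windowed-sinc, Hamming window).

    Order 71 yields 72 symmetric taps.  At fs = 10.2 Hz with the default
    0.01-0.40 Hz band this gives > 90 dB attenuation at 2 Hz and unity gain
    mid-passband; the lower edge is gentler than the upper because 0.01 Hz
    is far narrower than the achievable transition width at this length.
    """
    taps = signal.firwin(
        spec.order + 1,
        list(spec.band),
        pass_zero=False,
        window="hamming",
        fs=spec.fs,
    )
    return taps


def _filter_matrix(x: np.ndarray, taps: np.ndarray, zero_phase: bool = True) -> np.ndarray:
    if x.shape[-1] <= 3 * len(taps):
        raise DataError(
            f"series of {x.shape[-1]} samples is too short for zero-phase "
            f"filtering with {len(taps)} taps (need > {3 * len(taps)})"
        )
    if not zero_phase:
        return signal.lfilter(taps, [1.0], x, axis=-1)
    # 'even' padtype = mirror reflection at the edges
    return signal.filtfilt(taps, [1.0], x, axis=-1, padtype="even")


def apply_filter(hb: HbSeries, taps: np.ndarray, zero_phase: bool = True) -> HbSeries:
    """Zero-phase (forward-backward) filtering of both chromophores.

    Length-preserving; edges handled by reflection padding.  The effective
    magnitude response is the square of the single-pass response and the
    phase response is identically zero, so in-band components keep their
    timing -- essential before fitting lagged models.  ``zero_phase=False``
    falls back to a single causal pass (which delays everything by half the
    filter length; use only for diagnostics).
    """
    return HbSeries(
        hbo=_filter_matrix(hb.hbo, taps, zero_phase),
        hbr=_filter_matrix(hb.hbr, taps, zero_phase),
        fs=hb.fs,
        channel_coords=hb.channel_coords,
        run_condition=hb.run_condition,
        event_markers=list(hb.event_markers),
    )
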