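"""Forward simulation of task BOLD series on a digital phantom.

The generative model per voxel is

    y(t) = b * (1 + sum_c e_c * g(v) * 1[v in ROI_c] * x_c(t))
           + drift(t) + sum_k l_k(v) * s_k(t) + thermal(t)

where ``b`` is the baseline intensity, ``e_c`` the effect size of
contrast *c* (fraction of baseline), ``x_c`` the canonical-HRF response
to that contrast's driving conditions, ``g(v)`` an optional grey-matter
partial-volume scaling, ``drift`` a slow polynomial, ``s_k`` shared
low-rank "physiological" time courses whose spatial loadings ``l_k``
concentrate in white matter and CSF, and ``thermal`` AR(1)-correlated
Gaussian noise.  Two stock noise profiles caricature the acquisition
schemes being compared: a thermal-noise-dominated multiband-like profile
and a physiological-noise-dominated 3D-readout-like profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventTable
from .glm import CONTRAST_DEFINITIONS, HRFSpec, condition_regressors
from .phantom import Phantom
from .volume import Volume4D

__all__ = ["NoiseProfile", "SMS_LIKE", "EPI3D_LIKE", "simulate_bold", "get_profile"]


@dataclass(frozen=True)
class NoiseProfile:
    """Noise composition of a simulated acquisition, as baseline fractions.

    ``thermal_sd`` is the marginal standard deviation of the AR(1)
    thermal component; ``rho`` its lag-1 autocorrelation.  Physiological
    components are shared time courses with per-tissue loading
    amplitudes ``physio_amp_gm/wm/csf`` (standard deviation contributed
    per unit tissue probability).  ``drift_amp`` scales a random
    polynomial drift of order ``drift_order``.
    """

    name: str
    thermal_sd: float
    rho: float
    n_physio: int = 3
    physio_amp_gm: float = 0.0
    physio_amp_wm: float = 0.0
    physio_amp_csf: float = 0.0
    physio_amp_global: float = 0.0
    drift_amp: float = 0.0
    drift_order: int = 2

    def __post_init__(self) -> None:
        if self.thermal_sd < 0:
            raise ValueError("thermal_sd must be >= 0")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        for a in (self.physio_amp_gm, self.physio_amp_wm,
                  self.physio_amp_csf, self.physio_amp_global,
                  self.drift_amp):
            if a < 0:
                raise ValueError("negative variance parameters")

    def physio_thermal_ratio(self) -> float:
        """Physiological-to-thermal variance ratio for a grey-matter voxel
        of unit tissue probability (the regime detection happens in)."""
        if self.thermal_sd == 0:
            return np.inf if self.n_physio and self.physio_amp_gm else 0.0
        loading = self.physio_amp_gm + self.physio_amp_global
        return self.n_physio * loading**2 / self.thermal_sd**2


#: thermal-noise-dominated profile (multiband-like acquisition); total
#: grey-matter noise ~2.3% of baseline, i.e. raw voxel tSNR ~40
SMS_LIKE = NoiseProfile(
    name="sms_like",
    thermal_sd=0.022,
    rho=0.30,
    n_physio=3,
    physio_amp_gm=0.0035,
    physio_amp_wm=0.008,
    physio_amp_csf=0.010,
    physio_amp_global=0.001,
    drift_amp=0.01,
)

#: physiological-noise-dominated profile (3D-readout-like acquisition),
#: matched in total grey-matter variance to the profile above
EPI3D_LIKE = NoiseProfile(
    name="epi3d_like",
    thermal_sd=0.013,
    rho=0.30,
    n_physio=3,
    physio_amp_gm=0.010,
    physio_amp_wm=0.019,
    physio_amp_csf=0.024,
    physio_amp_global=0.002,
    drift_amp=0.01,
)

_PROFILES = {p.name: p for p in (SMS_LIKE, EPI3D_LIKE)}


def get_profile(name: str) -> NoiseProfile:
    try:
        return _PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown noise profile {name!r}; available: {sorted(_PROFILES)}"
        ) from None


def _physio_timecourses(
    n_physio: int, n_volumes: int, tr: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance shared noise time courses.

    Component 1 is a respiratory-like sinusoid (~0.3 Hz), component 2 a
    cardiac sinusoid (~1 Hz) aliased by the volume TR, component 3 a
    smoothed random walk; further components repeat the cycle with phase
    jitter.  These frequencies are modelling assumptions, not measured
    spectra.
    """
    t = np.arange(n_volumes) * tr
    fs = 1.0 / tr
    comps = []
    for k in range(n_physio):
        kind = k % 3
        if kind == 0:
            f = 0.3 + rng.normal(0, 0.01)
            c = np.sqrt(2.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        elif kind == 1:
            f_cardiac = 1.0 + rng.normal(0, 0.02)
            # fold the cardiac frequency into the sampled band
            f_alias = abs(f_cardiac - round(f_cardiac / fs) * fs)
            c = np.sqrt(2.0) * np.sin(
                2 * np.pi * f_alias * t + rng.uniform(0, 2 * np.pi)
            )
        else:
            walk = np.cumsum(rng.standard_normal(n_volumes))
            kernel = np.exp(-0.5 * (np.arange(-10, 11) / 3.0) ** 2)
            c = np.convolve(walk, kernel / kernel.sum(), mode="same")
            c = (c - c.mean()) / max(c.std(), 1e-12)
        comps.append(c)
    return np.array(comps)  # (n_physio, t)


def _ar1_noise(
    shape: tuple[int, ...], n_volumes: int, rho: float, sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation *sd*."""
    eps = rng.standard_normal(shape + (n_volumes,))
    if rho == 0:
        return sd * eps
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0]  # stationary start: marginal distribution
    scale = np.sqrt(1.0 - rho**2)
    for i in range(1, n_volumes):
        out[..., i] = rho * out[..., i - 1] + scale * eps[..., i]
    return sd * out


def contrast_response(
    events: EventTable,
    contrast: str,
    n_volumes: int,
    tr: float,
    hrf: HRFSpec = HRFSpec(),
) -> np.ndarray:
    """Canonical-HRF response of a contrast's ROI: the summed convolved
    boxcars of the conditions that drive it (its positive set)."""
    pos, _ = CONTRAST_DEFINITIONS[contrast]
    x = np.zeros(n_volumes)
    for cond in pos:
        if cond in events.conditions:
            xi, _ = condition_regressors(events, cond, n_volumes, tr, hrf)
            x += xi
    return x


def simulate_bold(
    phantom: Phantom,
    events: EventTable,
    effect_sizes: dict[str, float],
    profile: NoiseProfile,
    n_volumes: int,
    tr: float,
    seed: int = 0,
    *,
    hrf: HRFSpec = HRFSpec(),
    gm_scaling: bool = True,
) -> Volume4D:
    """Simulate a 4D BOLD run on *phantom* under *profile*.

    ``effect_sizes`` maps contrast names (which must have ROIs in the
    phantom) to activation amplitudes as fractions of baseline at unit
    regressor value.  With ``gm_scaling`` the amplitude is additionally
    scaled by the voxel's grey-matter probability, mimicking partial
    volume of the signal-generating tissue.  Identical arguments and seed
    give identical output.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if len(events) and events.end_time > n_volumes * tr + 1e-9:
        raise ValueError("events extend past the simulated run")
    for c, e in effect_sizes.items():
        if e < 0:
            raise ValueError(f"negative effect size for {c!r}")
        if c not in phantom.rois:
            raise ValueError(f"no ROI in phantom for contrast {c!r}")

    rng = np.random.default_rng(seed)
    shape = phantom.shape
    brain = phantom.brain_mask
    base = phantom.baseline

    data = np.repeat(base[..., None], n_volumes, axis=-1).astype(np.float64)

    # task activation confined to each contrast's ROI
    gain = phantom.gm if gm_scaling else np.ones(shape)
    for c, e in effect_sizes.items():
        if e == 0:
            continue
        x = contrast_response(events, c, n_volumes, tr, hrf)
        roi = phantom.rois[c]
        amp = (base * e * gain)[roi]  # (n_roi,)
        data[roi] += amp[:, None] * x[None, :]

    # slow polynomial drift, random per voxel
    if profile.drift_amp > 0 and profile.drift_order > 0:
        tt = np.linspace(-1.0, 1.0, n_volumes)
        basis = np.array(
            [np.polynomial.legendre.Legendre.basis(k + 1)(tt)
             for k in range(profile.drift_order)]
        )  # (order, t)
        coef = rng.standard_normal((int(brain.sum()), profile.drift_order))
        drift = (coef @ basis) * profile.drift_amp * base[brain][:, None]
        data[brain] += drift

    # shared physiological components, loadings largest in WM/CSF
    if profile.n_physio > 0:
        s = _physio_timecourses(profile.n_physio, n_volumes, tr, rng)
        tissue_amp = np.stack(
            [
                profile.physio_amp_gm * phantom.gm,
                profile.physio_amp_wm * phantom.wm,
                profile.physio_amp_csf * phantom.csf,
            ]
        )
        for k in range(profile.n_physio):
            # per-component tissue-weight jitter so components differ
            # spatially as well as temporally
            w = 1.0 + 0.2 * rng.standard_normal(3)
            sign = rng.choice([-1.0, 1.0])
            loading = (
                np.tensordot(w, tissue_amp, axes=1) + profile.physio_amp_global
            ) * base
            data[brain] += sign * loading[brain][:, None] * s[k][None, :]

    # AR(1)-correlated thermal noise
    if profile.thermal_sd > 0:
        noise = _ar1_noise(
            (int(brain.sum()),), n_volumes, profile.rho,
            profile.thermal_sd * 1.0, rng,
        )
        data[brain] += noise * base[brain][:, None]

    return Volume4D(
        data=data, tr=tr, voxel_size_mm=phantom.voxel_size_mm, mask=brain
    )
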