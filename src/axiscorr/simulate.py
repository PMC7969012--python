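"""Synthetic axis fragments with platform / focus / depletion structure.

The generator emulates the signal structure the correlation analysis is
designed to detect.  Each fragment carries two channels on a 1-D pixel
grid along a chromosome axis:

* a patchy *platform* channel (the axial IHO1-like signal): a positive
  baseline plus Gaussian texture noise, clipped at zero and smoothed;
* a *focus* channel (the DMC1/RAD51-like DSB marker): Gaussian bumps of
  amplitude ``focus_amp`` and width ``focus_sigma_px`` centered at
  points drawn from a Poisson process of intensity ``focus_rate_per_px``.

Each focus multiplies the platform by a local valley
``1 - d * exp(-(i - p)^2 / (2 * depletion_sigma_px^2))`` — the local
depletion hypothesis, with depth ``d in [0, 1]``.  ``coupling`` biases
focus placement toward platform peaks (positive) or troughs (negative)
via exponential tilting of the pre-depletion platform; at 0 the
placement is uniform.  I.i.d. Gaussian measurement noise is added to
both channels.  Intensities are in arbitrary units throughout.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .profiles import AxisProfile, AxisTrace, ImageChannel

__all__ = [
    "SyntheticParams",
    "SyntheticFragment",
    "LayoutError",
    "generate_fragment",
    "generate_cohort",
    "genotype_presets",
    "render_image",
]

_MAX_REJECTION_TRIES = 1000


class LayoutError(ValueError):
    """The requested image is too small for the fragment layout."""


@dataclass(frozen=True)
class SyntheticParams:
    """Full parameterization of the generative model.

    Lengths and sigmas are in pixels (1 px = 65 nm of axis by default),
    intensities in arbitrary units.  Defaults give a platform texture
    with a few-pixel grain, foci whose visible extent spans roughly
    8-12 px, and depletion valleys about twice as wide as the foci.
    """

    n_fragments: int = 500
    length_range_px: tuple[int, int] = (30, 120)
    platform_base: float = 100.0
    platform_noise_sd: float = 40.0
    platform_smooth_sigma_px: float = 3.0
    focus_rate_per_px: float = 0.03
    focus_amp: float = 150.0
    focus_sigma_px: float = 3.0
    depletion_depth: float = 0.7
    depletion_sigma_px: float = 6.0
    coupling: float = 0.0
    noise_sd: float = 2.0
    pixel_size_nm: float = 65.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range_px
        if lo < 3 or hi < lo:
            raise ValueError("length_range_px must satisfy 3 <= lo <= hi")
        if not 0.0 <= self.depletion_depth <= 1.0:
            raise ValueError("depletion_depth must lie in [0, 1]")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [-1, 1]")
        for name in (
            "platform_noise_sd",
            "platform_smooth_sigma_px",
            "focus_rate_per_px",
            "focus_amp",
            "focus_sigma_px",
            "depletion_sigma_px",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")

    def replace(self, **kwargs) -> "SyntheticParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_range_px"] = list(d["length_range_px"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticParams":
        d = dict(d)
        d["length_range_px"] = tuple(d["length_range_px"])
        return cls(**d)


@dataclass
class SyntheticFragment:
    """One generated fragment: ground truth, observations, focus centers."""

    platform_true: np.ndarray
    focus_true: np.ndarray
    platform_obs: np.ndarray
    focus_obs: np.ndarray
    focus_positions: np.ndarray
    params: SyntheticParams
    fragment_id: str = ""

    @property
    def length(self) -> int:
        return self.platform_true.size

    def to_profile(self, cell_id: str = "", condition: str = "") -> AxisProfile:
        return AxisProfile(
            intensities={"platform": self.platform_obs, "focus": self.focus_obs},
            cell_id=cell_id,
            fragment_id=self.fragment_id,
            condition=condition,
            pixel_size_nm=self.params.pixel_size_nm,
        )


def _place_foci(
    n_foci: int, length: int, pre_platform: np.ndarray, coupling: float, rng
) -> np.ndarray:
    """Draw focus centers, optionally tilted toward platform peaks.

    Placement weight is proportional to ``exp(coupling * z)`` with ``z``
    the standardized pre-depletion platform — a monotone function of the
    platform for positive coupling, of its complement for negative.
    Rejection sampling is capped; on exhaustion the focus falls back to
    a uniform draw with a warning.
    """
    if n_foci == 0:
        return np.empty(0)
    if coupling == 0.0 or pre_platform.std() == 0.0:
        return rng.uniform(0.0, length - 1.0, size=n_foci)
    z = (pre_platform - pre_platform.mean()) / pre_platform.std()
    grid = np.arange(length, dtype=float)
    positions = np.empty(n_foci)
    for k in range(n_foci):
        for _ in range(_MAX_REJECTION_TRIES):
            p = rng.uniform(0.0, length - 1.0)
            accept = np.exp(coupling * (np.interp(p, grid, z) - z.max()))
            if coupling < 0:
                accept = np.exp(coupling * (np.interp(p, grid, z) - z.min()))
            if rng.uniform() < accept:
                positions[k] = p
                break
        else:
            warnings.warn(
                "rejection sampling exhausted; placing focus uniformly",
                stacklevel=2,
            )
            positions[k] = rng.uniform(0.0, length - 1.0)
    return positions


def generate_fragment(
    params: SyntheticParams, rng: np.random.Generator, fragment_id: str = ""
) -> SyntheticFragment:
    """Generate one fragment from the model; deterministic given ``rng`` state."""
    lo, hi = params.length_range_px
    length = int(rng.integers(lo, hi + 1))
    grid = np.arange(length, dtype=float)

    raw = params.platform_base + rng.normal(0.0, params.platform_noise_sd, size=length)
    pre_platform = np.clip(raw, 0.0, None)
    if params.platform_smooth_sigma_px > 0:
        pre_platform = ndimage.gaussian_filter1d(
            pre_platform, params.platform_smooth_sigma_px, mode="reflect"
        )

    n_foci = int(rng.poisson(params.focus_rate_per_px * length))
    positions = _place_foci(n_foci, length, pre_platform, params.coupling, rng)

    platform = pre_platform.copy()
    focus = np.zeros(length)
    for p in positions:
        gauss = np.exp(-((grid - p) ** 2) / (2.0 * params.focus_sigma_px**2))
        focus += params.focus_amp * gauss
        if params.depletion_sigma_px > 0:
            valley = np.exp(-((grid - p) ** 2) / (2.0 * params.depletion_sigma_px**2))
        else:
            valley = (grid == np.round(p)).astype(float)
        platform *= 1.0 - params.depletion_depth * valley

    platform_obs = platform + rng.normal(0.0, params.noise_sd, size=length)
    focus_obs = focus + rng.normal(0.0, params.noise_sd, size=length)
    return SyntheticFragment(
        platform_true=platform,
        focus_true=focus,
        platform_obs=platform_obs,
        focus_obs=focus_obs,
        focus_positions=positions,
        params=params,
        fragment_id=fragment_id,
    )


def generate_cohort(
    params: SyntheticParams,
    n_fragments: int | None = None,
    condition: str = "synthetic",
    cells_of: int = 10,
):
    """Generate a cohort of fragments as pipeline-ready profiles.

    Fragments are grouped into pseudo-cells of ``cells_of`` fragments
    (mimicking the 5-12 axes selected per spread image).  Returns
    ``(profiles, ground_truth)`` where ``ground_truth`` is a JSON-ready
    dict with per-fragment focus positions and the full parameter set.
    """
    n = params.n_fragments if n_fragments is None else int(n_fragments)
    if n < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(params.seed)
    profiles, truth = [], []
    fragments = []
    for k in range(n):
        frag = generate_fragment(params, rng, fragment_id=f"frag{k:04d}")
        cell = f"cell{k // cells_of:03d}"
        profiles.append(frag.to_profile(cell_id=cell, condition=condition))
        fragments.append(frag)
        truth.append(
            {
                "fragment_id": frag.fragment_id,
                "cell_id": cell,
                "length_px": frag.length,
                "focus_positions_px": [float(p) for p in frag.focus_positions],
            }
        )
    sidecar = {
        "condition": condition,
        "params": params.to_dict(),
        "n_fragments": n,
        "fragments": truth,
    }
    return profiles, sidecar


def genotype_presets() -> dict[str, SyntheticParams]:
    """Named parameter sets for the qualitative regimes of interest.

    * ``wt_like`` — deep local depletion around foci, uniform placement:
      strong negative cross-correlation at lag 0.
    * ``atr_null_like`` — no depletion, uniform placement: null
      cross-correlation (depletion machinery disabled).
    * ``atr_atm_null_like`` — no depletion, foci biased toward platform
      peaks: weak positive cross-correlation at lag 0.
    * ``irradiation_1h_like`` — exogenous breaks placed uniformly before
      any depletion has acted: null cross-correlation.

    These are qualitative regime fixtures, not fits to any measured
    biology.
    """
    return {
        "wt_like": SyntheticParams(depletion_depth=0.7, coupling=0.0),
        "atr_null_like": SyntheticParams(depletion_depth=0.0, coupling=0.0),
        "atr_atm_null_like": SyntheticParams(depletion_depth=0.0, coupling=0.5),
        "irradiation_1h_like": SyntheticParams(depletion_depth=0.0, coupling=0.0),
    }


def get_preset(name: str) -> SyntheticParams:
    presets = genotype_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None


def render_image(
    fragments,
    psf_sigma_px: float = 1.0,
    background: float = 50.0,
    margin: int = 12,
    shape: tuple[int, int] | None = None,
    pixel_size_nm: float = 65.0,
):
    """Paint fragments as horizontal lines into a 2-channel image.

    Each fragment's observed channels are painted one pixel wide along a
    straight horizontal trace, blurred with an isotropic Gaussian PSF of
    ``psf_sigma_px``, and offset by a constant ``background``.  Because a
    traced fragment is a window on a continuous axis, the painted signal
    is extended past both trace ends by edge replication over the PSF
    support, so blurring does not taper the profile at the ends.  Returns
    ``(channels, traces)`` where ``channels`` maps ``"platform"`` /
    ``"focus"`` to :class:`ImageChannel` and ``traces`` are the ground
    truth :class:`AxisTrace` objects.  Raises :class:`LayoutError` if a
    caller-supplied ``shape`` cannot hold the layout.
    """
    fragments = list(fragments)
    pad = int(np.ceil(4.0 * psf_sigma_px))
    if margin < pad + 1:
        raise LayoutError(f"margin {margin} too small for PSF pad {pad}")
    pitch = 2 * margin
    n_rows_needed = margin + pitch * max(len(fragments), 1)
    width_needed = (
        2 * margin + max((f.length for f in fragments), default=1)
    )
    if shape is None:
        shape = (n_rows_needed, width_needed)
    if shape[0] < n_rows_needed or shape[1] < width_needed:
        raise LayoutError(
            f"image {shape} too small; need at least ({n_rows_needed}, {width_needed})"
        )
    planes = {name: np.zeros(shape) for name in ("platform", "focus")}
    traces = []
    for k, frag in enumerate(fragments):
        row = margin + pitch * k
        col0 = margin
        sl = slice(col0 - pad, col0 + frag.length + pad)
        for name, obs in (("platform", frag.platform_obs), ("focus", frag.focus_obs)):
            vals = np.clip(obs, 0.0, None)
            if pad:
                vals = np.concatenate([np.full(pad, vals[0]), vals, np.full(pad, vals[-1])])
            planes[name][row, sl] = vals
        traces.append(
            AxisTrace(
                vertices=np.array([[row, col0], [row, col0 + frag.length - 1]]),
                width_px=1,
                fragment_id=frag.fragment_id or f"frag{k:04d}",
            )
        )
    channels = {}
    for name, plane in planes.items():
        if psf_sigma_px > 0:
            plane = ndimage.gaussian_filter(plane, psf_sigma_px)
        channels[name] = ImageChannel(
            pixels=plane + background,
            channel_name=name,
            pixel_size_nm=pixel_size_nm,
        )
    return channels, traces
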