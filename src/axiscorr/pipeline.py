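"""End-to-end orchestration: inputs -> scaling -> curves -> outputs.

A run is described by a :class:`RunConfig` (loadable from YAML).  Three
input modes are supported: ``synthetic`` (built-in generator, by preset
name or explicit parameters), ``profile-table`` (the canonical TSV
dialect) and ``images`` (TIFF channels plus axis traces and background
regions).  Every run emits, per condition: auto-correlation curves for
both channels, the cross-correlation curve with per-lag p-values, plot
panels, and a manifest recording parameters, seed and content digests
of every output file, so identical config + seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as axio
from .correlation import (
    DegenerateFragmentError,
    correlation_curve,
    scale_fragment,
)
from .simulate import SyntheticParams, generate_cohort, get_preset

__all__ = ["RunConfig", "run_pipeline", "load_config", "scale_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``primary_channel`` is the platform signal (auto-correlated and the
    ``s`` series of the cross-correlation); ``partner_channel`` the
    focus signal.  ``x_max`` defaults to the 0..20 px window; an
    optional disjoint ``extra_window`` (e.g. ``(40, 43)``) adds a
    second lag range to the outputs.
    """

    mode: str = "synthetic"  # synthetic | profile-table | images
    primary_channel: str = "platform"
    partner_channel: str = "focus"
    x_max: int = 20
    extra_window: tuple[int, int] | None = None
    estimator: str = "fragment_mean"
    sample_unit: str = "product"
    seed: int = 0
    out_dir: str = "axiscorr_run"
    # synthetic mode
    preset: str | None = "wt_like"
    synthetic_params: dict | None = None
    n_fragments: int | None = None
    # profile-table mode
    profile_table: str | None = None
    # images mode
    image_paths: dict = field(default_factory=dict)  # channel name -> TIFF path
    trace_path: str | None = None
    trace_width_px: int = 5
    background_regions: list = field(default_factory=list)
    condition: str = "run"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.x_max < 1:
            raise ValueError("x_max must be >= 1")
        if self.primary_channel == self.partner_channel:
            raise ValueError("primary and partner channels must differ")
        if self.mode not in ("synthetic", "profile-table", "images"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.extra_window is not None:
            lo, hi = self.extra_window
            if not (0 <= lo <= hi):
                raise ValueError("extra_window must be (lo, hi) with 0 <= lo <= hi")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.extra_window is not None:
            d["extra_window"] = list(self.extra_window)
        return d


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "extra_window" in raw and raw["extra_window"] is not None:
        raw["extra_window"] = tuple(raw["extra_window"])
    return RunConfig(**raw)


def scale_cohort(profiles, primary: str, partner: str):
    """Scale a cohort, excluding degenerate fragments with a logged count."""
    scaled, n_degenerate = [], 0
    for p in profiles:
        try:
            scaled.append(scale_fragment(p, primary, partner))
        except DegenerateFragmentError:
            n_degenerate += 1
    if n_degenerate:
        logger.warning("excluded %d zero-variance fragment(s)", n_degenerate)
    if not scaled:
        raise ValueError("no usable fragments after excluding degenerate ones")
    return scaled


def _load_profiles(config: RunConfig):
    if config.mode == "synthetic":
        if config.synthetic_params:
            params = SyntheticParams.from_dict(config.synthetic_params)
        else:
            params = get_preset(config.preset)
        params = params.replace(seed=config.seed)
        condition = config.preset or "synthetic"
        profiles, sidecar = generate_cohort(
            params, config.n_fragments, condition=condition
        )
        return profiles, {"synthetic_ground_truth": sidecar}
    if config.mode == "profile-table":
        if not config.profile_table:
            raise ValueError("profile-table mode requires profile_table path")
        return axio.read_profiles(config.profile_table), {}
    # images mode
    import tifffile

    from .profiles import BackgroundSet, ImageChannel, extract_profiles
    from .roi import read_roi_zip, read_text_traces

    if not config.image_paths or not config.trace_path:
        raise ValueError("images mode requires image_paths and trace_path")
    channels = []
    for name, path in config.image_paths.items():
        pixels = np.asarray(tifffile.imread(path), dtype=float)
        if pixels.ndim != 2:
            raise ValueError(f"{path}: expected a single 2-D grayscale page")
        channels.append(ImageChannel(pixels=pixels, channel_name=name))
    tp = str(config.trace_path)
    if tp.endswith(".zip"):
        traces = read_roi_zip(tp, width_px=config.trace_width_px)
    else:
        traces = read_text_traces(tp, width_px=config.trace_width_px)
    backgrounds = (
        BackgroundSet(regions=[np.asarray(r, float) for r in config.background_regions])
        if config.background_regions
        else None
    )
    profiles = extract_profiles(
        channels, traces, backgrounds, condition=config.condition
    )
    return profiles, {}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _windows(config: RunConfig):
    yield config.x_max
    # the extra window is computed on the wider range and trimmed on output


def run_pipeline(config: RunConfig) -> dict:
    """Execute one run; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles, extras = _load_profiles(config)

    by_condition: dict[str, list] = {}
    for p in profiles:
        by_condition.setdefault(p.condition or "run", []).append(p)

    x_top = config.x_max
    if config.extra_window is not None:
        x_top = max(x_top, config.extra_window[1])

    outputs: list[Path] = []
    curve_summaries = {}
    for condition, cond_profiles in by_condition.items():
        scaled = scale_cohort(
            cond_profiles, config.primary_channel, config.partner_channel
        )
        swapped = [
            dataclasses.replace(f, s=f.r, r=f.s) for f in scaled
        ]
        curves = {
            f"auto_{config.primary_channel}": correlation_curve(
                scaled, "auto", x_top, config.estimator, config.sample_unit,
                condition=condition,
            ),
            f"auto_{config.partner_channel}": correlation_curve(
                swapped, "auto", x_top, config.estimator, config.sample_unit,
                condition=condition,
            ),
            "cross": correlation_curve(
                scaled, "cross", x_top, config.estimator, config.sample_unit,
                condition=condition,
            ),
        }
        keep = np.zeros(x_top + 1, dtype=bool)
        keep[: config.x_max + 1] = True
        if config.extra_window is not None:
            lo, hi = config.extra_window
            keep[lo : hi + 1] = True
        for name, curve in curves.items():
            trimmed = dataclasses.replace(
                curve,
                lags_px=curve.lags_px[keep],
                values=curve.values[keep],
                sem=curve.sem[keep],
                n_products=curve.n_products[keep],
                p_values=curve.p_values[keep],
            )
            path = out / f"{condition}_{name}.tsv"
            axio.write_curve(trimmed, path, sidecar={"seed": config.seed})
            outputs += [path, Path(str(path) + ".json")]
            curves[name] = trimmed
        cross = curves["cross"]
        curve_summaries[condition] = {
            "g0": float(cross.value_at(0)),
            "g0_p": float(cross.p_at(0)),
            "n_fragments": cross.n_fragments,
            "n_cells": cross.n_cells,
        }
        if config.make_plots:
            from .plotting import plot_condition_panel

            plot_path = out / f"{condition}_curves.png"
            plot_condition_panel(curves, plot_path, condition=condition)
            outputs.append(plot_path)
        logger.info(
            "condition %s: %d fragments, %d cells, g(0)=%.4f (p=%.3g)",
            condition, cross.n_fragments, cross.n_cells,
            cross.value_at(0), cross.p_at(0),
        )

    for name, payload in extras.items():
        path = out / f"{name}.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs.append(path)

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "conditions": curve_summaries,
        "outputs": {str(p.relative_to(out)): _digest(p) for p in outputs},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
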