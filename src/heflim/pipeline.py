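"""End-to-end pipeline: simulate (or ingest) -> fit -> phasor -> statistics.

A "study" mirrors the structure of the tissue experiment: for each sample
there is one peritumoral and one cancerous image.  Each image is fitted
per pixel, split into four clockwise quadrants, and summarised by quadrant
mean lifetimes; the pooled quadrant means feed the two-group Student t-test,
per-sample normalization yields cancerous/peritumoral lifetime ratios, and
the ratios are correlated against a clinical-indicator table.

Every run writes a JSON manifest (config snapshot, seeds, input checksums,
package version, per-stage timings, output paths) sufficient to re-execute
identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ConfigurationError
from .fitting import FitSettings, fit_cube
from .io import write_cube, write_lifetime_image
from .phasor import cluster_phasor, phasor_transform, segment_image
from .regionstats import (
    correlate_table,
    lifetime_ratio,
    normalize_to_peritumoral,
    quadrant_means,
    two_sample_ttest,
)
from .render import DEFAULT_RANGE_PS, render_lifetime_image, save_rgb
from .synth import (
    AcquisitionConfig,
    default_region_specs,
    simulate_clinical_table,
    simulate_cube,
    uniform_layout,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger("heflim")


@dataclass
class PipelineConfig:
    """All settings for one pipeline run."""

    out_dir: Path
    seed: int = 7
    image_size: tuple[int, int] = (64, 64)
    n_samples: int = 3
    photons_per_pixel: float = 5000.0
    n_bins: int = 256
    repetition_frequency: float = 76e6
    fit_min_photons: int = 100
    phasor_harmonic: int = 1
    phasor_k: int = 3
    render_range_ps: tuple[float, float] = DEFAULT_RANGE_PS
    clinical_csv: Path | None = None  # optional measured indicator table
    clinical_target_r: float = 0.8  # used when simulating the indicator column
    clinical_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        lo, hi = self.render_range_ps
        if not lo < hi:
            raise ConfigurationError("render range low must be < high")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        raw["out_dir"] = Path(raw["out_dir"])
        if raw.get("clinical_csv"):
            raw["clinical_csv"] = Path(raw["clinical_csv"])
        if "image_size" in raw:
            raw["image_size"] = tuple(raw["image_size"])
        if "render_range_ps" in raw:
            raw["render_range_ps"] = tuple(raw["render_range_ps"])
        return cls(**raw)

    def acquisition(self) -> AcquisitionConfig:
        return AcquisitionConfig(
            n_bins=self.n_bins,
            repetition_frequency=self.repetition_frequency,
            image_size=self.image_size,
        )


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def save(self, path: Path) -> Path:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full synthetic study and write all stage outputs.

    Identical seeds produce identical outputs.  Returns the manifest, also
    written to ``<out_dir>/manifest.json``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    manifest = RunManifest(config=cfg_dict, version=__version__, seed=config.seed)
    acq = config.acquisition()
    specs = default_region_specs(config.photons_per_pixel)
    fit_settings = FitSettings(min_photons=config.fit_min_photons)

    if config.clinical_csv is not None and not Path(config.clinical_csv).exists():
        raise ConfigurationError(
            f"stats stage: clinical CSV not found: {config.clinical_csv}"
        )

    measurements = []
    ratios = []
    sample_ids = []
    rng = np.random.default_rng(config.seed)
    for i in range(config.n_samples):
        sample_id = f"S{i+1}"
        sample_ids.append(sample_id)
        sample_meas = []
        for region in ("peritumoral", "cancerous"):
            stage = f"{sample_id}_{region}"
            t0 = time.perf_counter()
            seed = int(rng.integers(0, 2**31 - 1))
            layout = uniform_layout(config.image_size, region)
            cube = simulate_cube(layout, specs, acq, seed)
            cube_path = out / f"{stage}_cube.h5"
            write_cube(cube, cube_path)
            manifest.outputs[f"cube_{stage}"] = str(cube_path)
            manifest.checksums[str(cube_path)] = _sha256(cube_path)
            manifest.timings_s[f"simulate_{stage}"] = time.perf_counter() - t0

            t0 = time.perf_counter()
            image, fit_table = fit_cube(cube, settings=fit_settings)
            fit_csv = out / f"{stage}_fits.csv"
            fit_table.to_csv(fit_csv, index=False)
            manifest.outputs[f"fits_{stage}"] = str(fit_csv)
            for key, p in write_lifetime_image(image, out / stage).items():
                manifest.outputs[f"{key}_{stage}"] = str(p)
            png = save_rgb(
                render_lifetime_image(image, config.render_range_ps),
                out / f"{stage}_tau_m.png",
            )
            manifest.outputs[f"render_{stage}"] = str(png)
            manifest.timings_s[f"fit_{stage}"] = time.perf_counter() - t0
            logger.info("fitted %s in %.1fs", stage, manifest.timings_s[f"fit_{stage}"])

            t0 = time.perf_counter()
            pmap = phasor_transform(cube, n=config.phasor_harmonic)
            phasor_csv = out / f"{stage}_phasor.csv"
            rows, cols = np.nonzero(pmap.mask)
            pd.DataFrame(
                {"row": rows, "col": cols, "G": pmap.G[pmap.mask], "S": pmap.S[pmap.mask]}
            ).to_csv(phasor_csv, index=False)
            manifest.outputs[f"phasor_{stage}"] = str(phasor_csv)
            assignment = cluster_phasor(
                pmap, k=config.phasor_k, seed=config.seed, lifetime_image=image
            )
            seg_png = save_rgb(segment_image(assignment), out / f"{stage}_segments.png")
            manifest.outputs[f"segments_{stage}"] = str(seg_png)
            manifest.timings_s[f"phasor_{stage}"] = time.perf_counter() - t0

            sample_meas.extend(quadrant_means(image, sample_id, region))
        measurements.extend(sample_meas)
        ratios.append(lifetime_ratio(sample_meas))

    # stats stage
    t0 = time.perf_counter()
    meas_df = pd.concat(
        [normalize_to_peritumoral([m for m in measurements if m.sample_id == s])
         for s in sample_ids],
        ignore_index=True,
    )
    meas_csv = out / "measurements.csv"
    meas_df.to_csv(meas_csv, index=False)
    manifest.outputs["measurements"] = str(meas_csv)

    peri = meas_df.loc[meas_df.region == "peritumoral", "mean_tau_m_ps"]
    canc = meas_df.loc[meas_df.region == "cancerous", "mean_tau_m_ps"]
    t_stat, p_val = two_sample_ttest(canc, peri)
    stats_json = out / "stats.json"
    stats_json.write_text(
        json.dumps(
            {
                "t": t_stat,
                "p": p_val,
                "n_per_group": int(len(peri)),
                "peritumoral_mean_ps": float(peri.mean()),
                "cancerous_mean_ps": float(canc.mean()),
                "ratios": ratios,
            },
            indent=2,
        )
    )
    manifest.outputs["stats"] = str(stats_json)
    manifest.timings_s["stats"] = time.perf_counter() - t0

    # correlation stage
    t0 = time.perf_counter()
    if config.clinical_csv is not None:
        clin = pd.read_csv(config.clinical_csv)
    else:
        clin = simulate_clinical_table(
            ratios if len(ratios) >= 3 else ratios * 3,
            target_r=config.clinical_target_r,
            noise_sd=config.clinical_noise_sd,
            seed=config.seed + 1,
        )
    results = correlate_table(clin)
    corr_csv = out / "correlation.csv"
    pd.DataFrame(
        [{"indicator": r.indicator, "r": r.r, "n": r.n} for r in results]
    ).to_csv(corr_csv, index=False)
    manifest.outputs["correlation"] = str(corr_csv)
    manifest.timings_s["correlate"] = time.perf_counter() - t0

    manifest_path = out / "manifest.json"
    manifest.save(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest
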