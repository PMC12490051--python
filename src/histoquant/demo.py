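"""End-to-end demonstration pipeline on synthetic data.

Generates a full synthetic study — 3 treatment groups x 8 animals, six
coronal levels per animal — then runs every stage of the package on it:
fluorescence phantoms are segmented and counted per channel, HES phantoms
are color-classified and fed through the Cavalieri volume estimator, counts
are aggregated per animal, ratios formed, and each endpoint is routed
through the group-comparison statistics.  Deterministic per seed; all
tabular outputs are CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import fixtures, quantify, segmentation, volumetry
from .image_io import convert_bit_depth, gamma_correct
from .stats import GroupSample, route_and_compare

__all__ = ["DemoConfig", "run_demo"]

log = logging.getLogger("histoquant")

#: Per-level mean tissue / cavity cross-section areas (mm^2) of the synthetic
#: lesioned brain, anterior (+1 mm) to posterior (-4 mm).  Chosen so the
#: Cavalieri sums land in the hundreds of mm^3 (tissue) and tens (cavity),
#: the scale typical of a rat hemisphere-level lesion study.
_TISSUE_PROFILE_MM2 = (70.0, 85.0, 90.0, 85.0, 75.0, 60.0)
_CAVITY_PROFILE_MM2 = (2.0, 6.0, 9.0, 9.0, 6.0, 3.0)

#: Mean true per-image cell counts by channel for the fluorescence phantoms:
#: dense nuclear stain, sparser microglial and phagocyte markers.
_CHANNEL_MEANS = {"DAPI": 50, "Iba1": 20, "ED1": 12}


class DemoConfig(dict):
    """Flat run configuration; serialized next to the outputs."""

    @property
    def sha256(self) -> str:
        payload = json.dumps(self, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _default_config(seed: int) -> DemoConfig:
    return DemoConfig(
        seed=seed,
        n_operated=25,
        n_deaths=1,
        n_groups=3,
        fluor_shape=[192, 192],
        fluor_blob_radius_px=4.0,
        fluor_min_separation_px=14.0,
        fluor_noise_sd=15.0,
        fluor_bit_depth=12,
        hes_raster=[256, 256],
        hes_pixel_size_um=50.0,
        gamma=1.0,
        blur_sigma_px=2.0,
        marker_distance_fraction=0.8,
        data_driven_fraction=0.25,
        alpha=0.05,
        channel_means=dict(_CHANNEL_MEANS),
        count_effect={},     # e.g. {"RvD1": {"DAPI": 0.5}} multiplies the mean
        cavity_effect={},    # e.g. {"RvD1": 2.0} multiplies cavity areas
        tissue_cv=0.08,
        cavity_cv=0.15,
    )


def _segment_count(phantom, cfg: segmentation.SegmentationConfig, gamma: float) -> int:
    img = gamma_correct(phantom.image, gamma)
    if img.bit_depth != 8:
        img = convert_bit_depth(img)
    return segmentation.segment_and_count(img, cfg)["count"]


def _triptych(phantom, cfg: segmentation.SegmentationConfig, path: Path) -> None:
    """Original / watershed / size-filtered panels for one phantom."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img8 = convert_bit_depth(phantom.image)
    labels = segmentation.watershed_segment(img8, cfg)
    regions = segmentation.region_table(labels, img8)
    filtered, _ = segmentation.size_filter(labels, regions, cfg)
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.6))
    axes[0].imshow(img8.pixels, cmap="gray")
    axes[0].set_title("original")
    axes[1].imshow(labels, cmap="nipy_spectral", interpolation="nearest")
    axes[1].set_title("watershed")
    axes[2].imshow(filtered, cmap="nipy_spectral", interpolation="nearest")
    axes[2].set_title("size-filtered")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_demo(seed: int, out_dir, config: DemoConfig | None = None,
             write_images: bool = True) -> dict:
    """Run the whole synthetic study; returns the result tables.

    Writes cohort, per-section counts, per-animal counts, ratios, areas,
    volumes and a statistics report (CSV/JSON) plus a segmentation triptych
    into ``out_dir``; the effective configuration is saved alongside.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    cfg = config or _default_config(seed)
    log.info("demo seed=%s out=%s config_sha256=%s", seed, out_dir, cfg.sha256)
    rng = np.random.default_rng(cfg["seed"])
    seg_cfg = segmentation.SegmentationConfig(
        blur_sigma_px=cfg["blur_sigma_px"],
        marker_distance_fraction=cfg["marker_distance_fraction"],
        data_driven_fraction=cfg["data_driven_fraction"],
    )

    cohort = fixtures.make_cohort(
        n_operated=cfg["n_operated"], n_deaths=cfg["n_deaths"], n_groups=cfg["n_groups"],
        seed=int(rng.integers(2**31)),
    )
    fixtures.write_cohort(cohort, out_dir / "cohort.csv")

    # --- fluorescence counting -------------------------------------------
    count_rows = []
    triptych_done = not write_images
    for animal, group in cohort.animals:
        n_reps = int(rng.integers(1, 3))  # one or two technical replicates
        for rep in range(1, n_reps + 1):
            for channel, mean_count in cfg["channel_means"].items():
                eff = cfg["count_effect"].get(group, {}).get(channel, 1.0)
                true_n = int(rng.poisson(mean_count * eff))
                phantom = fixtures.make_fluor_phantom(
                    n_cells=true_n,
                    min_separation_px=cfg["fluor_min_separation_px"],
                    blob_radius_px=cfg["fluor_blob_radius_px"],
                    noise_sd=cfg["fluor_noise_sd"],
                    bit_depth=cfg["fluor_bit_depth"],
                    shape=tuple(cfg["fluor_shape"]),
                    seed=int(rng.integers(2**31)),
                    channel=channel,
                )
                auto = _segment_count(phantom, seg_cfg, cfg["gamma"])
                count_rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "section_id": f"{animal}_r{rep}",
                        "replicate": rep,
                        "channel": channel,
                        "count": auto,
                        "truth_count": phantom.truth_count,
                    }
                )
                if not triptych_done and channel == "DAPI":
                    _triptych(phantom, seg_cfg, out_dir / "segmentation_triptych.png")
                    triptych_done = True
    counts = pd.DataFrame(count_rows)
    counts.to_csv(out_dir / "counts_per_section.csv", index=False)

    per_animal = quantify.aggregate_replicates(
        counts[quantify.COUNT_COLUMNS], channels=tuple(cfg["channel_means"])
    )
    per_animal.to_csv(out_dir / "counts_per_animal.csv", index=False)
    ratios = quantify.compute_ratios(per_animal)
    ratios.to_csv(out_dir / "ratios_per_animal.csv", index=False)

    # --- HES volumetry ----------------------------------------------------
    scheme = volumetry.SectioningScheme(levels_mm=cohort.levels, sections_per_level=1)
    area_rows, volume_rows = [], []
    for animal, group in cohort.animals:
        tissue_scale = rng.normal(1.0, cfg["tissue_cv"])
        cavity_scale = rng.normal(1.0, cfg["cavity_cv"]) * cfg["cavity_effect"].get(group, 1.0)
        measurements = []
        for lv, t_mm2, c_mm2 in zip(cohort.levels, _TISSUE_PROFILE_MM2, _CAVITY_PROFILE_MM2):
            phantom = fixtures.make_hes_phantom(
                shape="annulus",
                tissue_area_mm2=max(t_mm2 * tissue_scale, 1.0),
                cavity_area_mm2=max(c_mm2 * cavity_scale, 0.05),
                pixel_size_um=cfg["hes_pixel_size_um"],
                raster_shape=tuple(cfg["hes_raster"]),
            )
            tissue, _bg = volumetry.classify_tissue(phantom.image)
            cavity = volumetry.find_cavity(tissue)
            m = volumetry.measure_areas(
                tissue & ~cavity, cavity, phantom.pixel_size_um, level_mm=lv
            )
            measurements.append(m)
            area_rows.append(
                {
                    "animal_id": animal,
                    "group": group,
                    "level_mm": lv,
                    "replicate": 1,
                    "tissue_area_mm2": m.tissue_area_mm2,
                    "cavity_area_mm2": m.cavity_area_mm2,
                }
            )
        est = volumetry.cavalieri_volume(measurements, scheme)
        volume_rows.append(
            {
                "animal_id": animal,
                "group": group,
                "tissue_volume_mm3": est.tissue_volume_mm3,
                "cavity_volume_mm3": est.cavity_volume_mm3,
                "n_levels_used": est.n_levels_used,
            }
        )
    areas = pd.DataFrame(area_rows)
    areas.to_csv(out_dir / "areas_per_section.csv", index=False)
    volumes = pd.DataFrame(volume_rows)
    volumes.to_csv(out_dir / "volumes_per_animal.csv", index=False)

    # --- group statistics -------------------------------------------------
    stats_report = {}
    endpoints = {
        "tissue_volume_mm3": volumes.set_index("animal_id"),
        "cavity_volume_mm3": volumes.set_index("animal_id"),
    }
    for metric, df in endpoints.items():
        samples = [
            GroupSample(g, sub[metric].to_numpy()) for g, sub in df.groupby("group")
        ]
        stats_report[metric] = _result_dict(route_and_compare(samples, alpha=cfg["alpha"]))
    for channel in cfg["channel_means"]:
        sub = per_animal[(per_animal["channel"] == channel) & (~per_animal["missing"])]
        samples = [GroupSample(g, s["count"].to_numpy()) for g, s in sub.groupby("group")]
        stats_report[f"count_{channel}"] = _result_dict(
            route_and_compare(samples, alpha=cfg["alpha"])
        )
    for ratio_name in [r[0] for r in quantify.RATIOS]:
        sub = ratios[(ratios["ratio"] == ratio_name) & ratios["defined"]]
        samples = [GroupSample(g, s["value"].to_numpy()) for g, s in sub.groupby("group")]
        stats_report[f"ratio_{ratio_name}"] = _result_dict(
            route_and_compare(samples, alpha=cfg["alpha"])
        )

    (out_dir / "stats_report.json").write_text(json.dumps(stats_report, indent=2))
    pd.DataFrame(
        [
            {"metric": k, "route": v["route"], "omnibus_p": v["omnibus_p"],
             "significant": v["significant"]}
            for k, v in stats_report.items()
        ]
    ).to_csv(out_dir / "stats_report.csv", index=False)
    (out_dir / "config.json").write_text(json.dumps(dict(cfg), indent=2, sort_keys=True))

    return {
        "cohort": cohort,
        "counts": counts,
        "per_animal": per_animal,
        "ratios": ratios,
        "areas": areas,
        "volumes": volumes,
        "stats": stats_report,
        "config": cfg,
    }


def _result_dict(res) -> dict:
    return {
        "route": res.route,
        "shapiro_p": res.shapiro_p,
        "levene_p": res.levene_p,
        "omnibus_statistic": res.omnibus_statistic,
        "omnibus_p": res.omnibus_p,
        "significant": bool(res.significant),
        "posthoc": res.posthoc.to_dict(orient="records") if res.posthoc is not None else None,
    }
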