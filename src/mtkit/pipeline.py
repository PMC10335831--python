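"""End-to-end report generation and packaged demo fixtures.

Every stage is a thin driver over the library modules; all randomness
flows from the single configured seed, and every parameter actually used
is recorded in the run log JSON next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import PipelineConfig
from .errors import ConfigurationError, NeverMotileError
from .imaging import (
    ap_profile,
    call_posterior_enrichment,
    detect_inner_peaks,
    measure_crescent_length,
    summarize_fractions,
)
from .ptm import summarize as ptm_summarize
from .simulate import (
    OocyteSimConfig,
    PSMSimConfig,
    StreamingSimConfig,
    TrajectorySimConfig,
    simulate_oocyte_image,
    simulate_psm_table,
    simulate_streaming_movie,
    simulate_trajectories,
)
from .streaming import classify_movie, summarize_patterns
from .transport import assign_direction, compute_metrics, is_motile, metrics_table

log = logging.getLogger("mtkit")

__all__ = ["run_transport", "run_streaming", "run_ptm", "run_oocyte", "run_demo", "generate_fixtures"]


def _require(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"required input not found: {p}")
    return p


def _ensure_out(out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _log_params(out: Path, stage: str, cfg: PipelineConfig, extra: dict | None = None) -> None:
    payload = {
        "stage": stage,
        "seed": cfg.seed,
        "transport": dataclasses.asdict(cfg.transport),
        "flow": dataclasses.asdict(cfg.flow),
        "classifier": dataclasses.asdict(cfg.classifier),
        "ptm": dataclasses.asdict(cfg.ptm),
        "imaging": dataclasses.asdict(cfg.imaging),
    }
    if extra:
        payload.update(extra)
    mio.write_json(out / f"{stage}_params.json", payload)


def run_transport(cfg: PipelineConfig, tracks_csv, axis=(1.0, 0.0)) -> pd.DataFrame:
    """Segment tracks, keep motile ones, write per-track metrics CSV."""
    out = _ensure_out(cfg.out_dir)
    tracks = mio.read_tracks_csv(_require(tracks_csv), axis=np.asarray(axis, dtype=float))
    metrics = []
    for tr in tracks:
        try:
            if not is_motile(tr, cfg.transport):
                continue
            direction = assign_direction(tr)
            metrics.append(compute_metrics(tr, cfg.transport, direction=direction))
        except NeverMotileError:
            continue
    table = metrics_table(metrics) if metrics else pd.DataFrame()
    table.to_csv(out / "transport_metrics.csv", index=False)
    _log_params(out, "transport", cfg, {"n_tracks_in": len(tracks), "n_motile": len(metrics)})
    return table


def _save_posterior_kymograph(path, stack, pixel_size, frame_interval) -> None:
    """Figure output: kymograph along a line near the posterior cortex."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .streaming import build_kymograph

    _, h, w = stack.shape
    y = 0.75 * (h - 1)
    line = np.array([[0.1 * (w - 1), y], [0.9 * (w - 1), y]])
    kymo = build_kymograph(stack, line, width=3, pixel_size=pixel_size,
                           frame_interval=frame_interval)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.imshow(kymo.matrix, aspect="auto", cmap="gray",
              extent=[0, kymo.matrix.shape[1] * frame_interval,
                      kymo.matrix.shape[0] * pixel_size, 0])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("distance along line (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_streaming(cfg: PipelineConfig, movies: dict[str, list], pixel_size=0.65, frame_interval=2.0) -> pd.DataFrame:
    """Classify movies per genotype and write the percentage summary CSV.

    ``movies`` maps genotype -> list of TIFF paths.
    """
    out = _ensure_out(cfg.out_dir)
    calls = {}
    for genotype, paths in movies.items():
        calls[genotype] = []
        for i, p in enumerate(paths):
            stack = mio.read_movie_tiff(_require(p))
            calls[genotype].append(
                classify_movie(
                    stack,
                    flow_params=cfg.flow,
                    classifier=cfg.classifier,
                    pixel_size=pixel_size,
                    frame_interval=frame_interval,
                )
            )
            if i == 0:
                _save_posterior_kymograph(
                    out / f"kymograph_{genotype}.png",
                    stack,
                    pixel_size,
                    frame_interval,
                )
    summary = summarize_patterns(calls)
    summary.to_csv(out / "streaming_summary.csv", index=False)
    mio.write_json(
        out / "streaming_calls.json",
        {g: [c.pattern for c in cs] for g, cs in calls.items()},
    )
    _log_params(out, "streaming", cfg)
    return summary


def run_ptm(cfg: PipelineConfig, psm_tsv, column_map=None) -> pd.DataFrame:
    """Tabulate glutamylation frequencies and write count + percent CSVs."""
    out = _ensure_out(cfg.out_dir)
    table = mio.read_psm_tsv(_require(psm_tsv), column_map=column_map)
    summary = ptm_summarize(table, tolerance_da=cfg.ptm.tolerance_da)
    summary.counts.to_csv(out / "ptm_counts.csv", index=False)
    pct = summary.table()
    pct.to_csv(out / "ptm_frequencies.csv", index=False)
    _log_params(out, "ptm", cfg)
    return pct


def run_oocyte(cfg: PipelineConfig, images: dict[str, list]) -> pd.DataFrame:
    """Measure each oocyte image (crescent, enrichment, peaks); write CSVs.

    ``images`` maps genotype -> list of (image_tiff, geometry_json) pairs.
    """
    out = _ensure_out(cfg.out_dir)
    rows, enrich = [], {}
    for genotype, pairs in images.items():
        enrich[genotype] = []
        for img_path, geom_path in pairs:
            img = mio.read_image_tiff(_require(img_path))
            geom = mio.read_geometry_json(_require(geom_path))
            crescent = measure_crescent_length(
                img, geom, threshold_frac=cfg.imaging.crescent_threshold_frac
            )
            enriched = call_posterior_enrichment(
                img,
                geom,
                band_frac=cfg.imaging.enrichment_band_frac,
                ratio_min=cfg.imaging.enrichment_ratio_min,
            )
            prof = detect_inner_peaks(
                ap_profile(img, geom),
                margin_frac=cfg.imaging.peak_margin_frac,
                prominence_frac=cfg.imaging.peak_prominence_frac,
            )
            rows.append(
                {
                    "genotype": genotype,
                    "image": str(img_path),
                    "crescent_um": crescent,
                    "posterior_enriched": enriched,
                    "peak_class": prof.classification,
                }
            )
            enrich[genotype].append(enriched)
    per_oocyte = pd.DataFrame(rows)
    per_oocyte.to_csv(out / "oocyte_metrics.csv", index=False)
    summarize_fractions(enrich).to_csv(out / "oocyte_enrichment_summary.csv", index=False)
    _log_params(out, "oocyte", cfg)
    return per_oocyte


# ---------------------------------------------------------------- fixtures

# Exact-counts PSM populations per genotype: alphaTub84B/D total with
# (0E, 1E, 2E, 3E) category counts, and the alphaTub67C total.
_FIXTURE_PSM = {
    "w": ((58, (17, 29, 8, 4)), 12),
    "TTLL5-pBac": ((24, (23, 1, 0, 0)), 12),
    "TTLL5-MiEx": ((6, (6, 0, 0, 0)), 4),
}


def fixture_psm_table(seed: int = 0) -> pd.DataFrame:
    """The packaged exact-counts PSM fixture (three genotypes)."""
    parts = []
    for i, (genotype, ((n84, counts), n67)) in enumerate(_FIXTURE_PSM.items()):
        probs = tuple(c / n84 for c in counts)
        cfg = PSMSimConfig(
            n_psm_84bd=n84,
            n_psm_67c=n67,
            sidechain_probs=probs,
            genotype=genotype,
            seed=seed + i,
        )
        parts.append(simulate_psm_table(cfg, exact_counts=True))
    df = pd.concat(parts, ignore_index=True)
    df["psm_id"] = [f"psm{i:05d}" for i in range(len(df))]
    return df


def generate_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the packaged demo dataset: the exact-counts PSM fixture, 20
    trajectories, one streaming movie per pattern, six oocyte images, a
    ground-truth sidecar JSON and a sha256 manifest."""
    out = _ensure_out(out_dir)
    truth: dict = {"seed": seed}

    psm = fixture_psm_table(seed)
    mio.write_psm_tsv(out / "psms.tsv", psm)

    traj_cfg = TrajectorySimConfig(n_tracks=20, seed=seed)
    sims = simulate_trajectories(traj_cfg)
    mio.write_tracks_csv(out / "tracks.csv", [s.trajectory for s in sims])
    truth["tracks"] = {
        "n_tracks": traj_cfg.n_tracks,
        "transport_speed_mean": traj_cfg.transport_speed_mean,
        "stationary_pause_prob": traj_cfg.stationary_pause_prob,
    }

    truth["movies"] = {}
    from .simulate import PATTERNS

    for i, pattern in enumerate(PATTERNS):
        movie = simulate_streaming_movie(
            StreamingSimConfig(pattern=pattern, seed=seed + 100 + i)
        )
        name = f"movie_{pattern}.tif"
        mio.write_movie_tiff(out / name, movie.stack)
        truth["movies"][name] = {"pattern": pattern}

    truth["oocytes"] = {}
    arcs = [20.0, 30.0, 40.0, 50.0, 60.0, 70.0]
    for i, arc in enumerate(arcs):
        sim = simulate_oocyte_image(
            OocyteSimConfig(
                crescent_arc_um=arc,
                inner_peaks=((0.55, 150.0, 6.0),) if i % 2 == 0 else (),
                seed=seed + 200 + i,
            )
        )
        img_name, geom_name = f"oocyte_{i}.tif", f"oocyte_{i}_geom.json"
        mio.write_image_tiff(out / img_name, sim.image)
        mio.write_geometry_json(out / geom_name, sim.geometry)
        truth["oocytes"][img_name] = sim.truth

    mio.write_json(out / "ground_truth.json", truth)
    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.name != "manifest.json"
    }
    mio.write_json(out / "manifest.json", manifest)
    return truth


def run_demo(cfg: PipelineConfig) -> dict:
    """Generate fixtures under out_dir/fixtures and run every stage on them."""
    out = _ensure_out(cfg.out_dir)
    fx = out / "fixtures"
    truth = generate_fixtures(fx, seed=cfg.seed)
    results = {
        "transport": run_transport(cfg, fx / "tracks.csv"),
        "ptm": run_ptm(cfg, fx / "psms.tsv"),
        "streaming": run_streaming(
            cfg,
            {
                "demo": sorted(fx.glob("movie_*.tif")),
            },
        ),
        "oocyte": run_oocyte(
            cfg,
            {
                "demo": [
                    (fx / f"oocyte_{i}.tif", fx / f"oocyte_{i}_geom.json")
                    for i in range(6)
                ]
            },
        ),
    }
    log.info("demo complete: %s", {k: len(v) for k, v in results.items()})
    return {"truth": truth, "results": results}
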