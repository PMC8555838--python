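"""Reports, point-light exports, and the end-to-end pipeline.

The pipeline chains ingest -> normalize -> decompose (common and per
signer) -> compare -> report, logging each stage with its parameters, and
writes an HDF5 bundle plus flat CSV/JSON reports with a checksum manifest.
Reports are pure functions of stored results, so they can be regenerated
from the bundle without recomputation, and a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import mocap_io, normalization, pm_extraction, similarity, synthetic_data
from .mocap_io import MarkerSet, PostureMatrix, StaticColumns
from .pm_extraction import PMDecomposition

logger = logging.getLogger("signsynergy")

#: Axis-pair per anatomical plane under the package's coordinate convention
#: (x mediolateral, y vertical, z anteroposterior).
PLANE_AXES = {"frontal": ("x", "y"), "sagittal": ("z", "y"), "transverse": ("x", "z")}


class ReportingError(ValueError):
    """Invalid reporting request."""


@dataclasses.dataclass
class PipelineConfig:
    """All tunable pipeline parameters, YAML round-trippable.

    Defaults encode the study conditions: 6 signers x 24 five-second trials
    at 250 fps, 6 Hz 4th-order zero-phase weight filtering, 15-degree
    leave-one-out robustness threshold, 0.7/0.5 similarity thresholds, and
    component retention by the 94.6% cumulative-variance rule.
    """

    n_signers: int = 6
    n_trials: int = 24
    trial_s: float = 5.0
    fps: float = 250.0
    n_markers: int = 21
    n_synergies: int = 8
    variance_decay: float = 0.65
    snr_db: float | None = 20.0
    share_mode: str = "identical"
    cutoff_hz: float = 6.0
    filter_order: int = 4
    welch_segment_s: float = 4.0
    welch_overlap: float = 0.5
    welch_window: str = "hann"
    n_pms: int | str = "auto"
    ev_target: float = 0.946
    similarity_mode: str = "abs"
    high_threshold: float = 0.7
    moderate_threshold: float = 0.5
    combination_threshold: float = 0.4
    loo_threshold_deg: float = 15.0
    drop_static_columns: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def cohort_config(self) -> synthetic_data.CohortConfig:
        return synthetic_data.CohortConfig(
            n_signers=self.n_signers,
            n_trials=self.n_trials,
            trial_s=self.trial_s,
            fps=self.fps,
            n_markers=self.n_markers,
            n_synergies=self.n_synergies,
            variance_decay=self.variance_decay,
            snr_db=self.snr_db,
            share_mode=self.share_mode,  # type: ignore[arg-type]
            seed=self.seed,
        )


def variance_report(
    decomposition: PMDecomposition,
    n_show: int = 15,
    filtered_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-PM explained variance table (percent), with cumulative column.

    If filtered weight signals are provided, a second EV column computed
    from their variances is included, since filtering slightly reallocates
    power.  A free-text description column is left for the analyst.
    """
    n = min(n_show, decomposition.n_components)
    ev_pct = decomposition.ev_fraction[:n] * 100.0
    table = pd.DataFrame(
        {
            "pm": np.arange(1, n + 1),
            "ev_pct": ev_pct,
            "cumulative_ev_pct": np.cumsum(decomposition.ev_fraction)[:n] * 100.0,
        }
    )
    if filtered_weights is not None:
        var_f = filtered_weights.var(axis=0, ddof=0)
        total = decomposition.eigenvalues.sum()
        table["ev_pct_filtered"] = var_f[:n] / total * 100.0
    table["description"] = ""
    return table


def export_pld(
    trajectory_full: np.ndarray,
    markerset: MarkerSet,
    plane: str,
    path: str | Path,
    frame_rate: float,
    key_frames: tuple[int, int] | None = None,
    frames: np.ndarray | slice | None = None,
) -> Path:
    """Write a 2-D point-light animation of a full-marker trajectory.

    ``trajectory_full`` is ``T x 3M`` in the full marker layout.  The plane
    selects an axis pair; CSV gets one row per (frame, marker), JSON the
    whole animation plus flagged minimum/maximum-weighting key frames.
    """
    if plane not in PLANE_AXES:
        raise ReportingError(f"unknown plane {plane!r}; expected {sorted(PLANE_AXES)}")
    ax_u, ax_v = PLANE_AXES[plane]
    axis_index = {"x": 0, "y": 1, "z": 2}
    traj = np.asarray(trajectory_full, dtype=float)
    if frames is not None:
        traj = traj[frames]
    coords = traj.reshape(traj.shape[0], markerset.count, 3)
    uv = coords[:, :, [axis_index[ax_u], axis_index[ax_v]]]
    path = Path(path)
    payload = {
        "plane": plane,
        "axes": [ax_u, ax_v],
        "frame_rate": frame_rate,
        "markers": list(markerset.names),
        "key_frames": (
            {"min": int(key_frames[0]), "max": int(key_frames[1])}
            if key_frames is not None
            else None
        ),
        "frames": np.round(uv, 9).tolist(),
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(payload))
    elif path.suffix == ".csv":
        t_idx = np.repeat(np.arange(uv.shape[0]), markerset.count)
        rows = pd.DataFrame(
            {
                "frame": t_idx,
                "marker": list(markerset.names) * uv.shape[0],
                ax_u: uv.reshape(-1, 2)[:, 0],
                ax_v: uv.reshape(-1, 2)[:, 1],
            }
        )
        rows.to_csv(path, index=False, float_format="%.9f")
    else:
        raise ReportingError("point-light export must be .json or .csv")
    return path


def load_pld(path: str | Path) -> dict:
    """Read a JSON point-light animation back (frames as an array)."""
    data = json.loads(Path(path).read_text())
    data["frames"] = np.asarray(data["frames"], dtype=float)
    return data


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def ingest_cohort(
    trials: dict[str, list[mocap_io.Trial]],
    markerset: MarkerSet,
    config: PipelineConfig,
) -> tuple[PostureMatrix, StaticColumns | None]:
    """Reference trials to the pelvis, cut the analysis window, and stack."""
    processed = []
    for signer in trials:
        for tr in trials[signer]:
            tr = mocap_io.reference_to_pelvis(tr, markerset)
            tr = mocap_io.extract_segment(tr, 0.0, config.trial_s)
            processed.append(tr)
    pm = mocap_io.build_posture_matrix(processed, markerset)
    static = None
    if config.drop_static_columns:
        pm, static = mocap_io.drop_static_columns(pm)
        logger.info(
            "ingest: dropped %d static columns (%s)",
            static.dropped.size,
            ", ".join(static.dropped_labels),
        )
    logger.info("ingest: posture matrix %d x %d", pm.n_rows, pm.n_columns)
    return pm, static


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    trials: dict[str, list[mocap_io.Trial]] | None = None,
    export_plds: bool = True,
) -> dict:
    """Execute the full analysis and write the output bundle.

    With ``trials=None`` a synthetic cohort is generated from the config.
    Returns the manifest (relative path -> sha256) that is also written as
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    markerset = MarkerSet.default_upper_body()
    if trials is None:
        logger.info("simulate: generating cohort (seed=%d)", config.seed)
        trials, _truth = synthetic_data.generate_cohort(config.cohort_config())

    pm, static = ingest_cohort(trials, markerset, config)
    cohort = normalization.normalize_cohort(pm)
    logger.info("normalize: %d signers", len(cohort.params))

    common = pm_extraction.fit_pca(cohort)
    w_filt = pm_extraction.filter_weights(
        common.weights, pm.frame_rate, config.cutoff_hz, config.filter_order
    )
    spectrum = pm_extraction.welch_psd(
        common.weights,
        pm.frame_rate,
        config.welch_segment_s,
        config.welch_overlap,
        config.welch_window,
    )
    if config.n_pms == "auto":
        n_pms = pm_extraction.n_components_for_variance(common, config.ev_target)
    else:
        n_pms = int(config.n_pms)
    logger.info(
        "decompose: %d components retained (cutoff=%g Hz, order=%d)",
        n_pms,
        config.cutoff_hz,
        config.filter_order,
    )

    signers = cohort.matrix.signer_ids()
    individual = {
        s: pm_extraction.fit_pca(
            cohort.signer_block(s), fitted_on=s, frame_rate=pm.frame_rate
        )
        for s in signers
    }

    sim_results = {
        s: similarity.individual_vs_common(
            cohort.signer_block(s),
            common,
            n_pms,
            pm.frame_rate,
            individual=individual[s],
            cutoff_hz=config.cutoff_hz,
            order=config.filter_order,
            mode=config.similarity_mode,
            high_threshold=config.high_threshold,
            moderate_threshold=config.moderate_threshold,
            combination_threshold=config.combination_threshold,
        )
        for s in signers
    }
    loo = similarity.loo_robustness(
        cohort, n_pms, config.loo_threshold_deg, config.similarity_mode
    )
    max_n = min(15, min(d.n_components for d in individual.values()))
    xproj_curve = []
    for n in range(1, max_n + 1):
        vals = [
            similarity.cross_projection(
                cohort.signer_block(a), individual[a],
                cohort.signer_block(b), individual[b], n,
            ).symmetric
            for i, a in enumerate(signers)
            for b in signers[i + 1 :]
        ]
        vals = np.array(vals)
        xproj_curve.append(
            (n, vals.mean(), vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0)
        )
    logger.info("compare: %d signer pairs, N up to %d", len(signers) * (len(signers) - 1) // 2, max_n)

    # ---- outputs -----------------------------------------------------
    files: list[Path] = []

    bundle = out / "cohort.h5"
    with h5py.File(bundle, "w") as f:
        mocap_io.save_posture_matrix(f.create_group("posture_matrix"), pm)
        mocap_io.save_posture_matrix(f.create_group("normalized"), cohort.matrix)
        normalization.save_params(f.create_group("params"), cohort.params)
        pm_extraction.save_decomposition(f.create_group("pca/common"), common)
        for s in signers:
            pm_extraction.save_decomposition(f.create_group(f"pca/{s}"), individual[s])
        f.create_dataset("pca/common_weights_filtered", data=w_filt, track_times=False)
        g = f.create_group("spectrum")
        g.create_dataset("frequencies", data=spectrum.frequencies, track_times=False)
        g.create_dataset("psd", data=spectrum.psd, track_times=False)
        if static is not None:
            sg = f.create_group("static_columns")
            sg.create_dataset("kept", data=static.kept, track_times=False)
            sg.create_dataset("dropped", data=static.dropped, track_times=False)
            vg = sg.create_group("dropped_values")
            for signer, vals in static.dropped_values.items():
                vg.create_dataset(signer, data=vals, track_times=False)
    files.append(bundle)

    var_table = variance_report(common, filtered_weights=w_filt)
    var_path = out / "variance_common.csv"
    var_table.to_csv(var_path, index=False, float_format="%.9f")
    files.append(var_path)

    ind_rows = []
    for s in signers:
        cum = individual[s].cumulative_ev()
        ind_rows.append(
            {
                "signer": s,
                "n_pms_for_target": pm_extraction.n_components_for_variance(
                    individual[s], config.ev_target
                ),
                "first8_cumulative_ev_pct": cum[min(7, cum.size - 1)] * 100.0,
            }
        )
    ind_path = out / "variance_individual.csv"
    pd.DataFrame(ind_rows).to_csv(ind_path, index=False, float_format="%.9f")
    files.append(ind_path)

    for s in signers:
        r = sim_results[s]
        df = pd.DataFrame(r.sim_matrix, index=r.row_labels, columns=r.col_labels)
        p = out / f"similarity_{s}.csv"
        df.to_csv(p, float_format="%.9f")
        files.append(p)

    loo_path = out / "loo_angles.csv"
    pd.DataFrame(
        [
            {"left_out": r.left_out}
            | {f"pm{i + 1}_deg": a for i, a in enumerate(r.angles_deg)}
            for r in loo
        ]
    ).to_csv(loo_path, index=False, float_format="%.9f")
    files.append(loo_path)

    xp_path = out / "cross_projection.csv"
    pd.DataFrame(
        xproj_curve, columns=["n_components", "mean_symmetric_similarity", "sem"]
    ).to_csv(xp_path, index=False, float_format="%.9f")
    files.append(xp_path)

    if export_plds:
        first_signer = signers[0]
        params = cohort.params[first_signer]
        rows_idx = cohort.matrix.signer_row_indices(first_signer)
        for i in range(n_pms):
            t_min, t_max = pm_extraction.extreme_posture_frames(w_filt, i)
            pmov = pm_extraction.resynthesize_pm(
                common, params, i, weights=w_filt[rows_idx]
            )
            traj = pmov.trajectory
            if static is not None:
                traj = mocap_io.restore_static_columns(traj, static, first_signer)
            for plane in ("frontal", "sagittal"):
                p = out / f"pm{i + 1}_{plane}.json"
                # key frames are cohort-global; exported frames are this signer's
                export_pld(
                    traj[:: max(1, traj.shape[0] // 500)],
                    markerset,
                    plane,
                    p,
                    pm.frame_rate,
                    key_frames=(t_min, t_max),
                )
                files.append(p)

    manifest = {p.name: _sha256(p) for p in sorted(files)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("report: wrote %d files to %s", len(files) + 1, out)
    return manifest
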