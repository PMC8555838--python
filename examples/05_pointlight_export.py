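"""Resynthesize a principal movement and export a point-light animation.

Projects PM1 back into millimetre coordinates for one signer (mean posture
plus the weight-modulated eigenposture), finds the frames of extreme
weighting (the two postures a stick-figure plot would highlight), and
writes frontal- and sagittal-plane point-light JSON animations.
"""

from pathlib import Path

import signsynergy as ss
from signsynergy import mocap_io

config = ss.CohortConfig(n_signers=2, n_trials=4, trial_s=5.0, seed=11)
trials, _ = ss.generate_cohort(config)
ms = config.markerset()
flat = [mocap_io.reference_to_pelvis(t, ms) for s in trials for t in trials[s]]
pm = mocap_io.build_posture_matrix(flat, ms)
pm, static = mocap_io.drop_static_columns(pm)
cohort = ss.normalize_cohort(pm)
decomp = ss.fit_pca(cohort)

w_filt = ss.filter_weights(decomp.weights, config.fps)
t_min, t_max = ss.extreme_posture_frames(w_filt, 0)
print(f"PM1 weighting is most negative at frame {t_min}, most positive at {t_max}")

rows = cohort.matrix.signer_row_indices("signer1")
movement = ss.resynthesize_pm(
    decomp, cohort.params["signer1"], 0, weights=w_filt[rows]
)
traj = mocap_io.restore_static_columns(movement.trajectory, static, "signer1")

out = Path("scratch") / "pld"
out.mkdir(parents=True, exist_ok=True)
for plane in ("frontal", "sagittal"):
    path = ss.export_pld(
        traj[::25], ms, plane, out / f"pm1_{plane}.json", config.fps / 25,
        key_frames=(t_min, t_max),
    )
    data = ss.load_pld(path)
    print(f"{plane}: {data['frames'].shape[0]} frames x {len(data['markers'])} "
          f"markers on axes {data['axes']} -> {path}")
print("(each JSON frame holds 2-D dot positions; the flagged key frames are "
      "the extreme postures of this movement)")
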