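"""Videokymography and fold-trajectory analysis of the simulated videos.

Extracts kymograms at the posterior/middle/anterior scanlines (axis
fractions 0.25/0.5/0.75), traces the left/right edges, computes deflection
trajectories with symmetry and left-right phase metrics, and estimates the
anterior-posterior phase lag.  Kymogram images land in ``scratch/``; the
metric table in ``results/``.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from phonovision import estimate_ap_phase_lag, fold_trajectories, multi_position_kymograms
from phonovision.io import load_frame_stack, save_edge_track
from phonovision.segmentation import area_waveform

ROOT = Path(__file__).resolve().parents[1]
FRACTIONS = (0.25, 0.5, 0.75)


def main() -> None:
    stacks_dir = ROOT / "scratch" / "stacks"
    results_dir = ROOT / "results"
    kymo_dir = ROOT / "scratch" / "kymograms"
    kymo_dir.mkdir(parents=True, exist_ok=True)
    conditions = pd.read_csv(results_dir / "01_conditions.csv")

    rows = []
    for _, cond in conditions.iterrows():
        name = cond["condition"]
        stack = load_frame_stack(stacks_dir / f"{name}.tif")
        masks, _ = area_waveform(stack)
        pairs = multi_position_kymograms(stack, FRACTIONS, masks=masks)
        for frac, (kymo, track) in zip(FRACTIONS, pairs):
            tifffile.imwrite(kymo_dir / f"{name}_{frac:.2f}.tif",
                             np.round(kymo.matrix * 65535).astype(np.uint16))
            save_edge_track(track, stack.time,
                            ROOT / "scratch" / "tables" / f"edges_{name}_{frac:.2f}.csv")

        tracks = [t for _, t in pairs]
        traj = fold_trajectories(tracks[1])  # mid-glottal plane
        ap_lag = estimate_ap_phase_lag(tracks, FRACTIONS, stack.calib.fps)
        rows.append({
            "condition": name,
            "symmetry_index": traj.symmetry_index,
            "lr_phase_lag_rad": traj.phase_lag,
            "mean_delta_left_mm": float(traj.delta_left.mean()),
            "mean_delta_right_mm": float(traj.delta_right.mean()),
            "delta_ratio": float(traj.delta_left.mean() / traj.delta_right.mean())
            if traj.delta_right.mean() > 0 else None,
            "ap_phase_lag_rad": ap_lag,
            "true_ap_phase_lag_rad": cond["ap_phase_lag_rad"],
        })
        print(f"{name}: symmetry {traj.symmetry_index:.3f}  "
              f"delta ratio {rows[-1]['delta_ratio']:.3f}  "
              f"AP lag {ap_lag if ap_lag is None else round(ap_lag, 3)} rad")

    pd.DataFrame(rows).to_csv(results_dir / "03_trajectories.csv", index=False,
                              float_format="%.6g")
    print(f"\ntable at {results_dir / '03_trajectories.csv'}")


if __name__ == "__main__":
    main()
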