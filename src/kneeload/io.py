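"""File formats: per-trial IMU CSVs, per-frame pose-keypoint JSONs
(OpenPose body-25 dialect), ground-truth JSON, and cohort tables.

Trial directory layout (as written by ``write_trial`` / the simulate CLI):

    trial_dir/
      imu_<site>.csv          # t, qw, qx, qy, qz, ax, ay, az
      keypoints/frame_%06d.json
      truth.json              # speed, KFA predictor, nine peaks, curves
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .timeseries import (
    BODY25_INDEX,
    BODY25_NAMES,
    IMU_SITES,
    ImuStream,
    KeypointSeries,
)

IMU_COLUMNS = ("t", "qw", "qx", "qy", "qz", "ax", "ay", "az")
#: Landmarks the synthetic camera produces (others stay zero triplets).
MODELED_LANDMARKS = ("Nose", "MidHip", "RHip", "RKnee", "RAnkle",
                     "LHip", "LKnee", "LAnkle")


def write_imu_csv(stream: ImuStream, path: Path) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.time, stream.quat, stream.accel]),
        columns=list(IMU_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_imu_csv(path: Path, site: str | None = None) -> ImuStream:
    df = pd.read_csv(path)
    if list(df.columns) != list(IMU_COLUMNS):
        raise InvalidArgumentError(
            f"{path}: expected columns {IMU_COLUMNS}, got {tuple(df.columns)}"
        )
    if site is None:
        site = Path(path).stem.removeprefix("imu_")
    quat = df[["qw", "qx", "qy", "qz"]].to_numpy()
    quat = quat / np.linalg.norm(quat, axis=1, keepdims=True)
    return ImuStream(
        site=site,
        time=df["t"].to_numpy(),
        quat=quat,
        accel=df[["ax", "ay", "az"]].to_numpy(),
    )


def read_imu_dir(trial_dir: Path) -> dict[str, ImuStream]:
    trial_dir = Path(trial_dir)
    streams = {}
    for site in IMU_SITES:
        path = trial_dir / f"imu_{site}.csv"
        if path.exists():
            streams[site] = read_imu_csv(path, site)
    if not streams:
        raise InvalidArgumentError(f"no imu_<site>.csv files in {trial_dir}")
    return streams


def write_keypoint_frames(series: KeypointSeries, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = series.n_frames
    for i in range(n):
        flat = np.zeros(3 * len(BODY25_NAMES))
        for name in series.points:
            j = BODY25_INDEX[name]
            flat[3 * j : 3 * j + 3] = series.points[name][i]
        payload = {
            "version": 1.3,
            "people": [{"person_id": [-1],
                        "pose_keypoints_2d": [round(float(v), 3) for v in flat]}],
        }
        with open(directory / f"frame_{i:06d}.json", "w") as fh:
            json.dump(payload, fh)


def read_keypoint_frames(
    directory: Path,
    fs: float = 100.0,
    image_size: tuple[int, int] = (480, 272),
    landmarks: tuple[str, ...] = MODELED_LANDMARKS,
) -> KeypointSeries:
    """Read a directory of per-frame pose JSONs (sorted by filename).

    Frames with an empty ``people`` list are tolerated and read as missing
    (zero-confidence) detections.
    """
    files = sorted(Path(directory).glob("frame_*.json"))
    if not files:
        raise InvalidArgumentError(f"no frame_*.json files in {directory}")
    points = {name: np.zeros((len(files), 3)) for name in landmarks}
    for i, path in enumerate(files):
        with open(path) as fh:
            payload = json.load(fh)
        people = payload.get("people", [])
        if not people:
            continue
        flat = np.asarray(people[0]["pose_keypoints_2d"], dtype=float)
        for name in landmarks:
            j = BODY25_INDEX[name]
            points[name][i] = flat[3 * j : 3 * j + 3]
    return KeypointSeries(points=points, fs=fs, image_size=image_size)


def write_trial(trial, directory: Path) -> None:
    """Write one synthetic trial (IMU CSVs, keypoint JSONs, truth.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if trial.imu:
        for site, stream in trial.imu.items():
            write_imu_csv(stream, directory / f"imu_{site}.csv")
    if trial.keypoints is not None:
        write_keypoint_frames(trial.keypoints, directory / "keypoints")
    truth = {
        "subject_id": trial.subject_id,
        "velocity_class": trial.velocity_class,
        "direction": trial.direction,
        "trial_index": trial.trial_index,
        "valid": trial.valid,
        "height_cm": trial.subject.height,
        "mass_kg": trial.subject.mass,
        "age_years": trial.subject.age,
        "sex": trial.subject.sex,
        "true_speed_cms": trial.true_speed,
        "kfa_predictor_deg": trial.kfa_predictor_truth,
        "stance_window": [trial.stance_truth.start, trial.stance_truth.end],
        "peaks_realized": trial.load.peaks_realized,
        "peaks_noiseless": trial.load.peaks_noiseless,
        "kjcf_medial": np.round(trial.load.curves.medial, 3).tolist(),
        "kjcf_lateral": np.round(trial.load.curves.lateral, 3).tolist(),
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


def read_truth(trial_dir: Path) -> dict:
    with open(Path(trial_dir) / "truth.json") as fh:
        return json.load(fh)


def write_cohort_csv(cohort, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "mass": p.mass,
                "height": p.height,
                "age": p.age,
                "sex": p.sex,
                "comfortable_speed": p.comfortable_speed,
            }
            for p in cohort
        ]
    ).to_csv(path, index=False, float_format="%.9g")


def read_cohort_csv(path: Path):
    from .synthetic.cohort import SubjectProfile

    df = pd.read_csv(path)
    return [
        SubjectProfile(
            subject_id=str(r.subject_id),
            mass=float(r.mass),
            height=float(r.height),
            age=float(r.age),
            sex=int(r.sex),
            comfortable_speed=float(r.comfortable_speed),
        )
        for r in df.itertuples()
    ]
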