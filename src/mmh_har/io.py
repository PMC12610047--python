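"""On-disk layouts for sessions and segment sets.

Sessions are HDF5 files with groups ``/kin`` (8 x T at 240 Hz), ``/semg``
(2 x T' with a rate attribute) and ``/labels`` (int8, kinematic clock),
plus ``subject_id``, ``channel_names`` and ``mvc`` attributes. A CSV
fallback writes one file per channel group with identical column order.

Segment sets are HDF5 with ``/x`` (n x 10 x 240 float32), ``/y`` (n int8)
and ``/subject`` (n strings).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .activities import ActivityClass, CHANNEL_NAMES
from .preprocess import Segment, SegmentSet
from .synth import RawSession


def save_session_hdf5(session: RawSession, path) -> None:
    with h5py.File(path, "w") as f:
        kin = f.create_dataset("kin", data=session.kin)
        kin.attrs["rate_hz"] = session.kin_rate_hz
        semg = f.create_dataset("semg", data=session.semg)
        semg.attrs["rate_hz"] = session.semg_rate_hz
        f.create_dataset("labels", data=session.labels.astype(np.int8))
        f.attrs["subject_id"] = session.subject_id
        f.attrs["channel_names"] = list(session.channel_names)
        f.attrs["mvc"] = session.mvc


def load_session_hdf5(path) -> RawSession:
    with h5py.File(path, "r") as f:
        return RawSession(
            subject_id=str(f.attrs["subject_id"]),
            kin=f["kin"][...],
            semg=f["semg"][...],
            labels=f["labels"][...],
            kin_rate_hz=float(f["kin"].attrs["rate_hz"]),
            semg_rate_hz=float(f["semg"].attrs["rate_hz"]),
            channel_names=tuple(
                n.decode() if isinstance(n, bytes) else str(n)
                for n in f.attrs["channel_names"]
            ),
            mvc=float(f.attrs["mvc"]),
        )


def save_session_csv(session: RawSession, directory) -> None:
    """CSV fallback: <subject>_kin.csv (8 kinematic columns + label) and
    <subject>_semg.csv (2 raw sEMG columns); rates in a sidecar meta CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = session.subject_id
    kin_cols = list(session.channel_names[:8])
    pd.DataFrame(
        dict(zip(kin_cols, session.kin), label=session.labels)
    ).to_csv(directory / f"{sid}_kin.csv", index=False)
    pd.DataFrame(
        dict(zip(session.channel_names[8:], session.semg))
    ).to_csv(directory / f"{sid}_semg.csv", index=False)
    pd.DataFrame(
        {
            "subject_id": [sid],
            "kin_rate_hz": [session.kin_rate_hz],
            "semg_rate_hz": [session.semg_rate_hz],
            "mvc": [session.mvc],
        }
    ).to_csv(directory / f"{sid}_meta.csv", index=False)


def load_session_csv(directory, subject_id: str) -> RawSession:
    directory = Path(directory)
    kin_df = pd.read_csv(directory / f"{subject_id}_kin.csv")
    semg_df = pd.read_csv(directory / f"{subject_id}_semg.csv")
    meta = pd.read_csv(directory / f"{subject_id}_meta.csv").iloc[0]
    return RawSession(
        subject_id=subject_id,
        kin=kin_df[list(CHANNEL_NAMES[:8])].to_numpy().T,
        semg=semg_df[list(CHANNEL_NAMES[8:])].to_numpy().T,
        labels=kin_df["label"].to_numpy().astype(np.int8),
        kin_rate_hz=float(meta["kin_rate_hz"]),
        semg_rate_hz=float(meta["semg_rate_hz"]),
        mvc=float(meta["mvc"]),
    )


def save_segments_hdf5(ss: SegmentSet, path) -> None:
    x, y = ss.xy_arrays()
    subjects = np.array([s.subject_id for s in ss.segments], dtype="S32")
    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=x.astype(np.float32))
        f.create_dataset("y", data=y.astype(np.int8))
        f.create_dataset("subject", data=subjects)


def load_segments_hdf5(path) -> SegmentSet:
    with h5py.File(path, "r") as f:
        x = f["x"][...].astype(np.float64)
        y = f["y"][...]
        subjects = [s.decode() for s in f["subject"][...]]
    return SegmentSet(
        [
            Segment(x=x[i], y=ActivityClass(int(y[i])), subject_id=subjects[i])
            for i in range(x.shape[0])
        ]
    )
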