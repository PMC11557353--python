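"""Minimal SNIRF (HDF5) reader and writer for continuous-wave intensity data.

Implements the subset of the Shared Near Infrared Format needed to move
recordings between pipeline stages and to ingest real data: one /nirs
group with an intensity ``dataTimeSeries`` (time x measurements), a
``measurementList`` mapping each column to a source, detector and
wavelength, a ``probe`` block, and one stim block encoding the walking
interval.  ROI labels are not part of the SNIRF standard; they travel in
the montage (JSON) or are supplied by the caller on read.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .montage import Channel, Montage
from .synthetic import RawRecording, TaskTimeline


def write_snirf(recording: RawRecording, path: str | Path) -> None:
    """Write one trial to a SNIRF file (intensity data type)."""
    m = recording.montage
    n_ch = m.n_channels
    fs = m.sampling_rate_hz
    n = recording.intensity.shape[-1]
    # columns: channel-major, wavelength-minor
    data = np.empty((n, 2 * n_ch))
    for ci in range(n_ch):
        for wi in range(2):
            data[:, 2 * ci + wi] = recording.intensity[wi, ci, :]

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("/nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=recording.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("Group", data=recording.group)
        meta.create_dataset("TrialIndex", data=recording.trial_index)
        for key, val in (
            ("PreStand", recording.timeline.pre_stand_s),
            ("Walk", recording.timeline.walk_s),
            ("PostStand", recording.timeline.post_stand_s),
        ):
            meta.create_dataset(key, data=float(val))

        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.arange(n) / fs)
        for col in range(2 * n_ch):
            ci, wi = divmod(col, 2)
            ml = d1.create_group(f"measurementList{col + 1}")
            ml.create_dataset("sourceIndex", data=m.channels[ci].source_id)
            ml.create_dataset("detectorIndex", data=m.channels[ci].detector_id)
            ml.create_dataset("wavelengthIndex", data=wi + 1)
            ml.create_dataset("dataType", data=1)          # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(m.wavelengths_nm))
        n_src = max(c.source_id for c in m.channels)
        n_det = max(c.detector_id for c in m.channels)
        probe.create_dataset("sourcePos2D", data=np.zeros((n_src, 2)))
        probe.create_dataset("detectorPos2D", data=np.zeros((n_det, 2)))

        stim = nirs.create_group("stim1")
        stim.create_dataset("name", data="walk")
        stim.create_dataset(
            "data",
            data=np.array([[recording.timeline.pre_stand_s,
                            recording.timeline.walk_s, 1.0]]),
        )


def read_snirf(path: str | Path, montage: Montage | None = None) -> RawRecording:
    """Read a SNIRF file written by :func:`write_snirf` (or a compatible
    intensity recording).  If no montage is given, channels are
    reconstructed from the measurement list but need ROI labels from the
    caller; files written by this package pair with the default montage."""
    with h5py.File(path, "r") as f:
        nirs = f["/nirs"] if "nirs" in f else f["/nirs1"]
        d1 = nirs["data1"]
        data = np.asarray(d1["dataTimeSeries"])
        time = np.asarray(d1["time"])
        fs = 1.0 / float(np.median(np.diff(time)))
        meta = nirs["metaDataTags"]

        def _scalar(key, default=None):
            if key in meta:
                v = meta[key][()]
                return v.decode() if isinstance(v, bytes) else v
            return default

        timeline = TaskTimeline(
            pre_stand_s=float(_scalar("PreStand", 30.0)),
            walk_s=float(_scalar("Walk", 35.0)),
            post_stand_s=float(_scalar("PostStand", 10.0)),
        )
        cols = sorted(
            (k for k in d1 if k.startswith("measurementList")),
            key=lambda k: int(k.removeprefix("measurementList")),
        )
        n_ch = len(cols) // 2
        if montage is None:
            wavelengths = tuple(np.asarray(nirs["probe"]["wavelengths"])[:2])
            channels = []
            for ci in range(n_ch):
                ml = d1[cols[2 * ci]]
                channels.append(Channel(
                    channel_id=ci + 1,
                    source_id=int(ml["sourceIndex"][()]),
                    detector_id=int(ml["detectorIndex"][()]),
                    roi="LPFC",   # placeholder: SNIRF carries no ROI labels
                ))
            montage = Montage(channels=tuple(channels),
                              wavelengths_nm=wavelengths,
                              sampling_rate_hz=round(fs, 6))

        intensity = np.empty((2, n_ch, data.shape[0]))
        for col, name in enumerate(cols):
            ml = d1[name]
            wi = int(ml["wavelengthIndex"][()]) - 1
            ci = col // 2
            intensity[wi, ci, :] = data[:, col]

        return RawRecording(
            subject_id=str(_scalar("SubjectID", "unknown")),
            group=str(_scalar("Group", "unknown")),
            trial_index=int(_scalar("TrialIndex", 0)),
            timeline=timeline,
            montage=montage,
            intensity=intensity,
        )
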