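"""Probe layout and channel-to-region assignment.

A wearable fNIRS montage of 14 sources and 12 detectors yielding 30
measurement channels (3 cm source-detector separation, 730/850 nm, 11 Hz)
over six cortical regions of interest: left and right prefrontal (LPFC,
RPFC), premotor (LPMC, RPMC), and primary somatosensory (LPSC, RPSC)
cortex.  All downstream computation depends only on the channel->ROI
partition, never on scalp coordinates, which are optional metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

ROIS: tuple[str, ...] = ("LPFC", "RPFC", "LPMC", "RPMC", "LPSC", "RPSC")
"""Canonical ROI order; all fixed orderings in the package derive from it."""

DEFAULT_WAVELENGTHS_NM: tuple[float, float] = (730.0, 850.0)
DEFAULT_SAMPLING_RATE_HZ: float = 11.0
DEFAULT_SEPARATION_MM: float = 30.0


@dataclass(frozen=True)
class Channel:
    """One source-detector pair measured at both wavelengths."""

    channel_id: int
    source_id: int
    detector_id: int
    roi: str
    separation_mm: float = DEFAULT_SEPARATION_MM

    def __post_init__(self) -> None:
        if self.roi not in ROIS:
            raise ValueError(f"unknown ROI {self.roi!r}; expected one of {ROIS}")
        if self.separation_mm <= 0:
            raise ValueError("separation_mm must be > 0")


@dataclass(frozen=True)
class Montage:
    """An ordered set of channels plus the acquisition constants.

    Invariants (checked on construction): unique channel ids, every ROI
    represented by at least two channels (within-ROI connectivity is
    undefined otherwise), and positive sampling rate.
    """

    channels: tuple[Channel, ...]
    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS_NM
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    coordinates: dict[int, tuple[float, float]] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("channel_id values must be unique")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        for roi in self.rois:
            if sum(c.roi == roi for c in self.channels) < 2:
                raise ValueError(
                    f"ROI {roi} has fewer than 2 channels; "
                    "within-ROI connectivity would be undefined"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def rois(self) -> tuple[str, ...]:
        """ROIs present, in canonical order."""
        present = {c.roi for c in self.channels}
        return tuple(r for r in ROIS if r in present)

    def channel_indices(self, roi: str) -> list[int]:
        """Positions (0-based, in channel order) of the channels in *roi*."""
        return [i for i, c in enumerate(self.channels) if c.roi == roi]

    def roi_of(self) -> list[str]:
        """ROI label per channel, in channel order."""
        return [c.roi for c in self.channels]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "wavelengths_nm": list(self.wavelengths_nm),
            "sampling_rate_hz": self.sampling_rate_hz,
            "channels": [
                {
                    "channel": c.channel_id,
                    "source": c.source_id,
                    "detector": c.detector_id,
                    "roi": c.roi,
                    "separation_mm": c.separation_mm,
                }
                for c in self.channels
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        payload = json.loads(Path(path).read_text())
        channels = tuple(
            Channel(
                channel_id=d["channel"],
                source_id=d["source"],
                detector_id=d["detector"],
                roi=d["roi"],
                separation_mm=d.get("separation_mm", DEFAULT_SEPARATION_MM),
            )
            for d in payload["channels"]
        )
        return cls(
            channels=channels,
            wavelengths_nm=tuple(payload["wavelengths_nm"]),
            sampling_rate_hz=payload["sampling_rate_hz"],
        )


# Per-hemisphere wiring: (source, detector) pairs for the three ROIs.  Each
# hemisphere uses 7 sources and 6 detectors; the fifth channel of the PMC and
# PSC groups reuses a neighbouring optode, as dense grids do in practice.
_HEMI_PAIRS: dict[str, list[tuple[int, int]]] = {
    "PFC": [(1, 1), (1, 2), (2, 1), (2, 2), (3, 1)],
    "PMC": [(4, 3), (4, 4), (5, 3), (5, 4), (3, 3)],
    "PSC": [(6, 5), (6, 6), (7, 5), (7, 6), (5, 5)],
}


def build_default_montage() -> Montage:
    """The canonical 30-channel montage: 5 channels per ROI, 14 sources,
    12 detectors, left/right symmetric numbering (channels 1-15 left,
    16-30 right).  Deterministic.
    """
    channels: list[Channel] = []
    cid = 1
    for hemi, s_off, d_off in (("L", 0, 0), ("R", 7, 6)):
        for region in ("PFC", "PMC", "PSC"):
            for s, d in _HEMI_PAIRS[region]:
                channels.append(
                    Channel(
                        channel_id=cid,
                        source_id=s + s_off,
                        detector_id=d + d_off,
                        roi=f"{hemi}{region}",
                    )
                )
                cid += 1
    return Montage(channels=tuple(channels))


class ROIPair(NamedTuple):
    """A within- or between-region contrast descriptor."""

    kind: str  # "within" | "between"
    roi_a: str
    roi_b: str

    @property
    def name(self) -> str:
        return self.roi_a if self.kind == "within" else f"{self.roi_a}-{self.roi_b}"


def roi_pairs(montage: Montage) -> list[ROIPair]:
    """The within-ROI descriptors followed by the unordered between-ROI
    descriptors, both in the canonical ROI order (between pairs ordered
    lexicographically by ROI index).  For the default montage this is
    6 + C(6,2) = 21 descriptors.
    """
    rois = montage.rois
    pairs = [ROIPair("within", r, r) for r in rois]
    pairs += [
        ROIPair("between", rois[i], rois[j])
        for i in range(len(rois))
        for j in range(i + 1, len(rois))
    ]
    return pairs


def fc_column_order(montage: Montage | None = None) -> list[str]:
    """Fixed column order for connectivity tables: 6 within names then the
    15 between names."""
    m = montage if montage is not None else build_default_montage()
    return [p.name for p in roi_pairs(m)]
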