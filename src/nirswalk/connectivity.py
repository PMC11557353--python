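"""Channel-pair Pearson functional connectivity and ROI aggregation.

Connectivity is the Pearson correlation between the walking-block dHbO
series of every channel pair.  Per subject, the 30x30 matrix is reduced
to 6 within-ROI values (mean over the unique channel pairs inside each
region) and 15 between-ROI values (mean over all cross-region pairs),
then averaged over the three trials.  Raw correlation coefficients are
averaged by default (no Fisher z, no rectification of negative values);
a z-transform mode exists for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .montage import Montage, fc_column_order, roi_pairs
from .preprocessing import PreprocessConfig, WalkBlock, preprocess
from .synthetic import Cohort

logger = logging.getLogger(__name__)


@dataclass
class FCMatrix:
    """Symmetric channel-pair correlation matrix with a validity mask.

    Entries involving zero-variance channels are NaN and excluded from
    aggregation; ``valid`` marks usable channels.
    """

    values: np.ndarray           # (n_channels, n_channels)
    valid: np.ndarray            # (n_channels,) bool
    subject_id: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")


@dataclass
class ROIConnectivity:
    """6 within-ROI and 15 between-ROI mean connectivity values."""

    within: dict[str, float]
    between: dict[tuple[str, str], float]
    subject_id: str = ""
    n_trials_averaged: int = 1

    def as_row(self, montage: Montage) -> dict[str, float]:
        row: dict[str, float] = {}
        for p in roi_pairs(montage):
            row[p.name] = (
                self.within[p.roi_a] if p.kind == "within"
                else self.between[(p.roi_a, p.roi_b)]
            )
        return row


def channel_fc(block: WalkBlock) -> FCMatrix:
    """Pearson correlation for every channel pair of a walking block.

    Channels with zero variance yield NaN rows/columns (masked); fewer
    than 3 samples is an error.
    """
    x = block.hbo
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    sd = x.std(axis=1)
    valid = sd > 0
    values = np.full((x.shape[0], x.shape[0]), np.nan)
    if valid.sum() >= 1:
        sub = np.corrcoef(x[valid])
        sub = np.clip((sub + sub.T) / 2.0, -1.0, 1.0)
        values[np.ix_(valid, valid)] = sub
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("masked %d zero-variance channel(s)", n_bad)
    return FCMatrix(values=values, valid=valid,
                    subject_id=block.subject_id, trial_index=block.trial_index)


def aggregate_roi(fc: FCMatrix, montage: Montage) -> ROIConnectivity:
    """Arithmetic mean of raw r over each ROI pair set.

    Within-ROI: the C(n_R, 2) unique off-diagonal pairs inside the region;
    between: all n_R x n_S cross pairs.  Masked (NaN) pairs are excluded;
    a region with fewer than two valid channels yields NaN.
    """
    if fc.values.shape[0] != montage.n_channels:
        raise ValueError("montage does not match FC matrix dimension")
    within: dict[str, float] = {}
    between: dict[tuple[str, str], float] = {}
    idx = {r: np.array(montage.channel_indices(r)) for r in montage.rois}
    for p in roi_pairs(montage):
        if p.kind == "within":
            ii = idx[p.roi_a]
            sub = fc.values[np.ix_(ii, ii)]
            vals = sub[np.triu_indices(len(ii), 1)]
        else:
            vals = fc.values[np.ix_(idx[p.roi_a], idx[p.roi_b])].ravel()
        ok = np.isfinite(vals)
        if not ok.any():
            out = float("nan")
        else:
            if not ok.all():
                logger.info("%s: excluded %d masked pair(s)", p.name, (~ok).sum())
            out = float(vals[ok].mean())
        if p.kind == "within":
            within[p.roi_a] = out
        else:
            between[(p.roi_a, p.roi_b)] = out
    return ROIConnectivity(within=within, between=between,
                           subject_id=fc.subject_id)


def average_trials(per_trial: Sequence[ROIConnectivity]) -> ROIConnectivity:
    """Element-wise mean of per-trial ROI connectivity for one subject."""
    if not per_trial:
        raise ValueError("no trials to average")
    sids = {rc.subject_id for rc in per_trial}
    if len(sids) > 1:
        raise ValueError(f"trials belong to different subjects: {sorted(sids)}")
    within = {
        r: float(np.mean([rc.within[r] for rc in per_trial]))
        for r in per_trial[0].within
    }
    between = {
        k: float(np.mean([rc.between[k] for rc in per_trial]))
        for k in per_trial[0].between
    }
    return ROIConnectivity(
        within=within, between=between,
        subject_id=per_trial[0].subject_id,
        n_trials_averaged=len(per_trial),
    )


def fisher_z_average_trials(per_trial: Sequence[ROIConnectivity]) -> ROIConnectivity:
    """Alternative averaging through Fisher's z (sensitivity analysis)."""
    if not per_trial:
        raise ValueError("no trials to average")

    def zmean(vals: list[float]) -> float:
        z = np.arctanh(np.clip(vals, -0.999999, 0.999999))
        return float(np.tanh(np.mean(z)))

    within = {r: zmean([rc.within[r] for rc in per_trial]) for r in per_trial[0].within}
    between = {k: zmean([rc.between[k] for rc in per_trial])
               for k in per_trial[0].between}
    return ROIConnectivity(within=within, between=between,
                           subject_id=per_trial[0].subject_id,
                           n_trials_averaged=len(per_trial))


def cohort_connectivity(
    cohort: Cohort,
    cfg: PreprocessConfig | None = None,
    *,
    concatenate_trials: bool = False,
) -> pd.DataFrame:
    """Preprocess every recording and build the subject-level table:
    one row per subject with group, the 21 connectivity columns in fixed
    order (6 within then 15 between), joined with the gait table.

    ``concatenate_trials`` switches from correlate-per-trial-then-average
    (default) to correlating the concatenated trial blocks.
    """
    cfg = cfg or PreprocessConfig()
    montage = cohort.montage
    by_subject: dict[str, list[WalkBlock]] = {}
    groups: dict[str, str] = {}
    for rec in cohort.recordings:
        try:
            block = preprocess(rec, cfg)
        except ValueError as exc:
            logger.warning("dropping %s trial %d: %s",
                           rec.subject_id, rec.trial_index, exc)
            continue
        by_subject.setdefault(rec.subject_id, []).append(block)
        groups[rec.subject_id] = rec.group

    rows = []
    for sid, blocks in by_subject.items():
        if concatenate_trials:
            merged = WalkBlock(
                hbo=np.concatenate([b.hbo for b in blocks], axis=1),
                fs=blocks[0].fs, subject_id=sid, group=groups[sid],
            )
            rc = aggregate_roi(channel_fc(merged), montage)
            rc.n_trials_averaged = len(blocks)
        else:
            rc = average_trials(
                [aggregate_roi(channel_fc(b), montage) for b in blocks]
            )
        row = {"subject_id": sid, "group": groups[sid]}
        row.update(rc.as_row(montage))
        rows.append(row)

    cols = ["subject_id", "group"] + fc_column_order(montage)
    fc_df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    gait = cohort.gait_table.drop(columns=["group"], errors="ignore")
    return fc_df.merge(gait, on="subject_id", how="left")
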