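"""Closed-set 1-to-N identification on normalized GM maps.

An identification system holds a *gallery* of one enrolled volume per
subject.  Given a probe volume it computes the voxel-level distance to every
gallery entry, min-max normalizes those distances to scores on [0, 100] over
that probe's comparison pool, and returns the subject with the highest
score.  The *identification ratio* is the percentage of probes whose true
subject is returned at rank 1.  Every probe's subject is assumed enrolled
(closed set); there is no reject threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matching import Metric, gm_distance
from .verification import DEFAULT_SELECTOR
from .volumes import DatasetIndex, GMVolume


@dataclass
class Gallery:
    """One enrolled volume per subject, keyed and ordered by subject id."""

    entries: dict[str, GMVolume]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("a gallery needs at least 2 enrolled subjects")
        for sid, vol in self.entries.items():
            if vol.subject_id != sid:
                raise ValueError(
                    f"gallery key {sid!r} does not match volume subject "
                    f"{vol.subject_id!r}"
                )
        self.entries = dict(sorted(self.entries.items()))

    @property
    def N(self) -> int:
        return len(self.entries)


def build_gallery(
    index: DatasetIndex, selector: tuple[int, int] = DEFAULT_SELECTOR
) -> Gallery:
    """Enroll one volume per subject, picked by (visit_id, scan_id).

    The default selector (1, 2) enrolls the second scan of the first visit.
    Raises KeyError if any subject lacks the selected scan.
    """
    visit_id, scan_id = selector
    return Gallery(
        entries={s: index.get(s, visit_id, scan_id) for s in index.subjects}
    )


def identify(
    probe: GMVolume, gallery: Gallery, metric: Metric = "l1"
) -> tuple[str, float, bool]:
    """Return the best-matching enrolled subject for a probe.

    Distances probe-vs-every-gallery-entry are min-max normalized over that
    pool, and the arg-max-score subject returned (the minimum-distance entry
    always scores 100).  Exact distance ties are broken by the smallest
    subject id and flagged; in the all-equal degenerate pool every entry
    scores 100 and the tie flag is set.
    """
    subjects = list(gallery.entries)
    dists = np.array(
        [gm_distance(probe, gallery.entries[s], metric) for s in subjects]
    )
    d_min, d_max = float(dists.min()), float(dists.max())
    winners = np.flatnonzero(dists == d_min)
    best = subjects[int(winners[0])]  # subjects sorted -> smallest id wins ties
    tie = len(winners) > 1
    score = 100.0  # min-max normalization always awards the best match 100
    if d_max == d_min:
        tie = gallery.N > 1
    return best, score, tie


def identification_report(
    probes: Sequence[GMVolume], gallery: Gallery, metric: Metric = "l1"
) -> pd.DataFrame:
    """Rank-1 identification of every probe against the gallery.

    Columns: probe_id, returned_subject, true_subject, score, correct, tie.
    """
    if not probes:
        raise ValueError("empty probe list")
    rows = []
    for probe in probes:
        returned, score, tie = identify(probe, gallery, metric)
        rows.append(
            {
                "probe_id": "/".join(map(str, probe.key)),
                "returned_subject": returned,
                "true_subject": probe.subject_id,
                "score": score,
                "correct": returned == probe.subject_id,
                "tie": tie,
            }
        )
    return pd.DataFrame(rows)


def identification_ratio(
    probes: Sequence[GMVolume], gallery: Gallery, metric: Metric = "l1"
) -> float:
    """Percentage of probes whose true subject is returned at rank 1."""
    report = identification_report(probes, gallery, metric)
    return 100.0 * report["correct"].sum() / len(report)
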