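"""Verification protocol: pair enumeration, FAR/FRR, ROC, EER, separation.

A verification (1-to-1) experiment compares *genuine* pairs (two scans of
the same subject) against *imposter* pairs (scans of different subjects).
Two genuine protocols are supported:

* ``same_visit`` — both scans from the same imaging session; measures the
  floor of the matcher's discriminability (only acquisition noise differs).
* ``different_visit`` — scans from sessions separated in time; additionally
  exposed to intra-class variability (session drift).

Imposter pairs follow the one-volume-per-subject convention: a selector
picks a single scan per subject (default: second scan of the first visit)
and all C(N, 2) cross-subject pairs are formed, so 150 subjects give 11,175
imposter pairs.

Decision rule at threshold t on normalized scores: FRR is the percentage of
genuine pairs scoring strictly below t, FAR the percentage of imposter pairs
scoring strictly above t (a score equal to t counts as accepted-genuine and
correctly-rejected-imposter).  The ROC sweeps t over all observed scores;
the EER is the operating point where FAR equals FRR, linearly interpolated
between swept thresholds when no sweep point crosses exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .volumes import DatasetIndex, ScanKey

GenuineMode = Literal["same_visit", "different_visit"]

#: Default one-volume-per-subject selector: (visit_id, scan_id).
DEFAULT_SELECTOR: tuple[int, int] = (1, 2)


@dataclass
class PairProtocol:
    """The enumerated genuine and imposter pairs of one experiment."""

    mode: GenuineMode
    genuine_pairs: list[tuple[ScanKey, ScanKey]]
    imposter_pairs: list[tuple[ScanKey, ScanKey]]


@dataclass
class RocCurve:
    """Thresholded operating points; FAR/FRR in %, thresholds in score units."""

    points: list[tuple[float, float, float]]  # (threshold, FAR, FRR)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["threshold", "far", "frr"])


@dataclass
class EERResult:
    eer: float
    threshold_at_eer: float
    exact_crossing: bool


def enumerate_genuine_pairs(
    index: DatasetIndex, mode: GenuineMode
) -> list[tuple[ScanKey, ScanKey]]:
    """All unordered genuine pairs under a protocol, deterministic order.

    ``same_visit``: every within-visit scan pair of every subject/visit.
    ``different_visit``: every cross-visit scan pair within each subject.
    """
    pairs: list[tuple[ScanKey, ScanKey]] = []
    for subject in index.subjects:
        visits = index.visits(subject)
        if mode == "same_visit":
            for v in visits:
                for s1, s2 in itertools.combinations(index.scans(subject, v), 2):
                    pairs.append(((subject, v, s1), (subject, v, s2)))
        elif mode == "different_visit":
            for v1, v2 in itertools.combinations(visits, 2):
                for s1 in index.scans(subject, v1):
                    for s2 in index.scans(subject, v2):
                        pairs.append(((subject, v1, s1), (subject, v2, s2)))
        else:
            raise ValueError(f"unknown genuine mode {mode!r}")
    return pairs


def count_genuine_pairs(scans_per_visit: Sequence[int], mode: GenuineMode) -> int:
    """Closed-form genuine-pair count for one subject's visit structure.

    With m_j scans at visit j: ``different_visit`` gives sum over visit
    pairs j<k of m_j*m_k — equal to C(V,2)*m^2 when every visit has m scans;
    ``same_visit`` gives sum_j C(m_j, 2).  Always equals the length of the
    corresponding :func:`enumerate_genuine_pairs` output.
    """
    m = list(scans_per_visit)
    if not m:
        raise ValueError("scans_per_visit must be nonempty")
    if any(x < 1 for x in m):
        raise ValueError("every visit has at least one scan")
    if mode == "same_visit":
        return sum(comb(x, 2) for x in m)
    if mode == "different_visit":
        return sum(a * b for a, b in itertools.combinations(m, 2))
    raise ValueError(f"unknown genuine mode {mode!r}")


def count_genuine_pairs_dataset(index: DatasetIndex, mode: GenuineMode) -> int:
    """Dataset-total genuine-pair count (sum of per-subject counts)."""
    return sum(
        count_genuine_pairs(index.visit_structure(s), mode) for s in index.subjects
    )


def enumerate_imposter_pairs(
    index: DatasetIndex, selector: tuple[int, int] = DEFAULT_SELECTOR
) -> list[tuple[ScanKey, ScanKey]]:
    """All C(N, 2) cross-subject pairs, one selected volume per subject.

    ``selector`` is the (visit_id, scan_id) picked for every subject; the
    default (1, 2) is the second scan of the first visit.  Raises KeyError
    if any subject lacks the selected scan.
    """
    subjects = index.subjects
    if len(subjects) < 2:
        raise ValueError("imposter pairs require at least 2 subjects")
    visit_id, scan_id = selector
    keys: list[ScanKey] = []
    for s in subjects:
        index.get(s, visit_id, scan_id)  # raises if missing
        keys.append((s, visit_id, scan_id))
    return list(itertools.combinations(keys, 2))


def far_frr_at_threshold(
    genuine_scores: Sequence[float],
    imposter_scores: Sequence[float],
    threshold: float,
) -> tuple[float, float]:
    """(FAR %, FRR %) at one decision threshold, strict inequalities."""
    g = np.asarray(genuine_scores, dtype=float)
    i = np.asarray(imposter_scores, dtype=float)
    if g.size == 0 or i.size == 0:
        raise ValueError("genuine and imposter score lists must be nonempty")
    frr = 100.0 * int(np.count_nonzero(g < threshold)) / g.size
    far = 100.0 * int(np.count_nonzero(i > threshold)) / i.size
    return float(far), float(frr)


def roc_curve(
    genuine_scores: Sequence[float], imposter_scores: Sequence[float]
) -> RocCurve:
    """Sweep thresholds over all observed scores plus one point beyond each
    extreme (so the (FAR 100, FRR 0) and (FAR 0, FRR 100) endpoints appear).

    Midpoints between consecutive observed scores are swept as well: with
    strict decision inequalities both rates are constant on the open
    intervals between observed scores but change *at* them, so plateaus
    where FAR equals FRR can lie strictly between two observed values.
    """
    g = np.asarray(genuine_scores, dtype=float)
    i = np.asarray(imposter_scores, dtype=float)
    if g.size == 0 or i.size == 0:
        raise ValueError("genuine and imposter score lists must be nonempty")
    observed = np.unique(np.concatenate([g, i]))
    mids = (observed[:-1] + observed[1:]) / 2.0
    thresholds = np.unique(
        np.concatenate([[observed[0] - 1.0], observed, mids, [observed[-1] + 1.0]])
    )
    points = []
    for t in thresholds:
        far, frr = far_frr_at_threshold(g, i, float(t))
        points.append((float(t), far, frr))
    return RocCurve(points=points)


def eer(curve: RocCurve) -> EERResult:
    """Equal-error operating point of a swept ROC.

    If some swept threshold has FAR == FRR, that point is returned directly
    (smallest such threshold on ties, ``exact_crossing=True``).  Otherwise
    FAR(t) and FRR(t) are linearly interpolated between the two adjacent
    thresholds where FAR - FRR changes sign and the crossing value returned.
    """
    if not curve.points:
        raise ValueError("empty ROC curve")
    for t, far, frr in curve.points:
        if far == frr:
            return EERResult(eer=float(far), threshold_at_eer=float(t),
                             exact_crossing=True)
    pts = curve.points
    for (t1, far1, frr1), (t2, far2, frr2) in zip(pts, pts[1:]):
        d1 = far1 - frr1
        d2 = far2 - frr2
        if d1 > 0 > d2 or d1 < 0 < d2:
            # linear interpolation of both rates in t; crossing where equal
            alpha = d1 / (d1 - d2)
            t_star = t1 + alpha * (t2 - t1)
            rate = far1 + alpha * (far2 - far1)
            return EERResult(eer=rate, threshold_at_eer=t_star, exact_crossing=False)
    # Monotone curves always cross between the extreme endpoints; reaching
    # here means numerically identical adjacent points — fall back to the
    # point minimizing |FAR - FRR|.
    t, far, frr = min(curve.points, key=lambda p: abs(p[1] - p[2]))
    return EERResult(eer=(far + frr) / 2.0, threshold_at_eer=t, exact_crossing=False)


def separation_gap(
    genuine_scores: Sequence[float], imposter_scores: Sequence[float]
) -> tuple[float, float, bool]:
    """(max imposter score, min genuine score, separable).

    ``separable`` is True iff the highest imposter score lies strictly below
    the lowest genuine score — then any threshold strictly between the two
    yields FAR = FRR = 0 and the EER is exactly zero.
    """
    g = np.asarray(genuine_scores, dtype=float)
    i = np.asarray(imposter_scores, dtype=float)
    if g.size == 0 or i.size == 0:
        raise ValueError("genuine and imposter score lists must be nonempty")
    max_imp = float(i.max())
    min_gen = float(g.min())
    return max_imp, min_gen, max_imp < min_gen


def score_histogram(
    scores: Sequence[float], bin_width: float
) -> list[tuple[float, float]]:
    """Score distribution as (bin center, percentage of scores) over [0, 100].

    Bins are [k*w, (k+1)*w) with the final bin closed at the top so a score
    of exactly 100 is counted.  Percentages sum to 100.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score list")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(np.ceil(100.0 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(s, bins=edges)
    pct = 100.0 * counts / s.size
    centers = (edges[:-1] + edges[1:]) / 2.0
    return [(float(c), float(p)) for c, p in zip(centers, pct)]
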