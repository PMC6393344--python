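"""Damage-kinetics characterization and elastic-constant identification.

Damage-ratio curves exhibit a three-stage evolution — onset, growth and
saturation. This module locates the stage boundaries, classifies the
growth as monomodal or bimodal from the smoothed damage rate (a bimodal
rate marks the transition from localized to diffuse damage growth),
groups the eight stress criteria into aggressive / intermediate /
inefficient clusters, and identifies the solid-phase Young's modulus E0
and Poisson ratio nu0 by the linear-correction rule: reaction force is
strictly proportional to E0 in the linear model, so one trial solve and
a slope ratio recover the true modulus; the same (approximate) linearity
in nu links the mean lateral contraction to nu0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .damage import DamageCriterion, DamageHistory

__all__ = [
    "StageBoundaries",
    "Modality",
    "Category",
    "CriterionReport",
    "detect_stages",
    "detect_modality",
    "categorize_criteria",
    "identify_E0",
    "identify_v0",
]

Modality = str  # "monomodal" | "bimodal" | "inconclusive"
Category = str  # "aggressive" | "intermediate" | "inefficient"


@dataclass(frozen=True)
class StageBoundaries:
    """Onset / growth / saturation boundaries of a damage-ratio curve.

    ``onset`` is the first increment where the ratio exceeds
    ``onset_threshold`` of the final ratio, ``saturation`` the first
    exceeding ``saturation_threshold`` of it; growth spans the interval
    between. All three are None for an identically zero curve.
    """

    onset: int | None
    growth: tuple[int, int] | None
    saturation: int | None
    onset_threshold: float = 0.01
    saturation_threshold: float = 0.99

    @property
    def detected(self) -> bool:
        return self.onset is not None


def detect_stages(
    ratios: np.ndarray,
    onset_threshold: float = 0.01,
    saturation_threshold: float = 0.99,
) -> StageBoundaries:
    """Locate the three damage stages on a non-decreasing ratio curve."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0 or r[-1] <= 0:
        return StageBoundaries(None, None, None, onset_threshold, saturation_threshold)
    if np.any(np.diff(r) < -1e-12) or r.min() < 0 or r.max() > 1 + 1e-12:
        raise ValueError("damage-ratio curve must be non-decreasing in [0, 1]")
    final = r[-1]
    onset = int(np.argmax(r > onset_threshold * final))
    saturation = int(np.argmax(r >= saturation_threshold * final))
    return StageBoundaries(
        onset=onset,
        growth=(onset, saturation),
        saturation=saturation,
        onset_threshold=onset_threshold,
        saturation_threshold=saturation_threshold,
    )


def detect_modality(
    ratios: np.ndarray,
    smoothing_window: int = 5,
    prominence_fraction: float = 0.25,
    stages: StageBoundaries | None = None,
) -> Modality:
    """Classify the growth stage as monomodal or bimodal.

    The ratio curve is smoothed with a moving average of
    ``smoothing_window`` increments and differenced; the growth is
    bimodal iff the rate has at least two separated local maxima whose
    prominence exceeds ``prominence_fraction`` of the global rate
    maximum. A growth stage shorter than the window is inconclusive.
    """
    r = np.asarray(ratios, dtype=float)
    if stages is None:
        stages = detect_stages(r)
    if not stages.detected:
        return "inconclusive"
    a, b = stages.growth  # type: ignore[misc]
    if b - a + 1 < smoothing_window or r.size < smoothing_window + 1:
        return "inconclusive"
    kernel = np.ones(smoothing_window) / smoothing_window
    smooth = np.convolve(r, kernel, mode="same")
    rate = np.gradient(smooth)
    seg = rate[a : b + 1]
    if seg.max() <= 0:
        return "inconclusive"
    peaks, _ = find_peaks(seg, prominence=prominence_fraction * seg.max())
    return "bimodal" if len(peaks) >= 2 else "monomodal"


@dataclass(frozen=True)
class CriterionReport:
    criterion: DamageCriterion
    stages: StageBoundaries
    modality: Modality
    final_ratio: float
    category: Category


def categorize_criteria(
    histories: dict[DamageCriterion, DamageHistory] | dict[str, DamageHistory],
    seed: int = 0,
    smoothing_window: int = 5,
) -> tuple[dict[DamageCriterion, CriterionReport], bool]:
    """Group criteria into aggressive / intermediate / inefficient.

    All histories must come from the same fixture and schedule. Criteria
    are clustered by k-means (k = 3, fixed seed) on standardized
    (onset increment, final damage ratio); the earliest-onset cluster is
    aggressive, the latest-onset (and lowest-saturation) cluster is
    inefficient, the remainder intermediate. Returns the per-criterion
    reports and a flag marking a degenerate clustering (fewer than three
    distinct behaviors), in which case every criterion is labeled
    intermediate.
    """
    crits = [DamageCriterion(c) for c in histories]
    hists = list(histories.values())
    stages_list = [detect_stages(h.ratios) for h in hists]
    n_inc = max(len(h.ratios) for h in hists)
    # an undetected onset behaves as "beyond the last increment"
    onsets = np.array(
        [s.onset if s.detected else n_inc for s in stages_list], dtype=float
    )
    finals = np.array([h.final_ratio for h in hists])
    features = np.column_stack([onsets, finals])

    degenerate = len(np.unique(features, axis=0)) < 3 or len(crits) < 3
    if degenerate:
        categories = ["intermediate"] * len(crits)
    else:
        std = features.std(axis=0)
        std[std == 0] = 1.0
        Z = (features - features.mean(axis=0)) / std
        km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(Z)
        labels = km.labels_
        # rank clusters: earliest mean onset -> aggressive, latest -> inefficient
        mean_onset = np.array([onsets[labels == k].mean() for k in range(3)])
        mean_final = np.array([finals[labels == k].mean() for k in range(3)])
        order = np.lexsort((-mean_final, mean_onset))
        name_of = {order[0]: "aggressive", order[1]: "intermediate", order[2]: "inefficient"}
        categories = [name_of[l] for l in labels]

    reports = {}
    for crit, hist, stages, cat in zip(crits, hists, stages_list, categories):
        reports[crit] = CriterionReport(
            criterion=crit,
            stages=stages,
            modality=detect_modality(hist.ratios, smoothing_window, stages=stages),
            final_ratio=hist.final_ratio,
            category=cat,
        )
    return reports, degenerate


def identify_E0(experimental_slope: float, model_slope: float, trial_E: float) -> float:
    """True solid modulus from a trial solve and the experimental slope.

    The reaction force of the linear model is strictly proportional to
    E0, so E0 = trial_E * (experimental slope / model slope); one
    correction based on a linear function suffices.
    """
    if experimental_slope <= 0 or model_slope <= 0 or trial_E <= 0:
        raise ValueError("slopes and trial modulus must be positive")
    return trial_E * experimental_slope / model_slope


def identify_v0(observed_contraction: float, model_contraction: float, trial_nu: float) -> float:
    """Poisson ratio from observed vs modelled mean lateral contraction.

    Assumes the same linearity as the modulus identification (it is only
    approximate in nu); the result is clamped to (0, 0.5) with a warning
    when the linear extrapolation leaves the physical range.
    """
    if model_contraction == 0:
        raise ValueError("model contraction is zero: cannot identify nu0")
    nu = trial_nu * observed_contraction / model_contraction
    if not 0.0 < nu < 0.5:
        clamped = min(max(nu, 1e-3), 0.499)
        warnings.warn(
            f"identified nu0 = {nu:.3f} outside (0, 0.5); clamped to {clamped:.3f}",
            stacklevel=2,
        )
        return clamped
    return nu
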