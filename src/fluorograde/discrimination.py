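"""3D Gaussian-ellipsoid discrimination on the collagen feature triple.

Each tissue type's scatter of feature points (SHG-Int, Coll-Peak,
Coll-Int) is summarised by the ellipsoid of its fitted Gaussian that
encloses 60% of the probability mass: mean = sample mean, covariance =
sample covariance, and the Mahalanobis-squared boundary at the chi-squared
(3 dof) quantile of the requested mass.  Two threshold-gated membership
tests reproduce the clinical decision rules:

* control vs tumor — a point inside a grade I or grade II ellipsoid with
  SHG-Int > 2.5 is tumor; inside the control ellipsoid with
  SHG-Int <= 2.5 it is control;
* grade I vs grade II — inside the grade I ellipsoid with SHG-Int <= 22
  is grade I; inside the grade II ellipsoid with SHG-Int > 22 is grade II.

Points satisfying neither rule are *indeterminate*.  Sensitivity and
specificity are Se = TP/(TP+FN), Sp = TN/(TN+FP); by default
indeterminate points are excluded from the confusion counts (they are
abstentions, not decisions), with an option to count them as errors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .presets import TissueType

__all__ = [
    "FeaturePoint3D",
    "Ellipsoid3D",
    "ConfusionCounts",
    "Verdict",
    "fit_ellipsoid",
    "ellipsoid_contains",
    "ellipsoid_overlap_volume",
    "classify_control_tumor",
    "classify_grade",
    "sensitivity_specificity",
    "threshold_rules",
    "evaluate_cohort",
]

SHG_CONTROL_TUMOR_THRESHOLD = 2.5
SHG_GRADE_THRESHOLD = 22.0
COLL_INT_TUMOR_THRESHOLD = 28.0
DEFAULT_MASS = 0.60


@dataclass(frozen=True)
class FeaturePoint3D:
    """One sample in (SHG-Int, Coll-Peak, Coll-Int) space, in percent."""

    shg_int: float
    coll_peak: float
    coll_int: float
    label: TissueType | None = None

    def as_array(self) -> np.ndarray:
        return np.asarray([self.shg_int, self.coll_peak, self.coll_int])


class Verdict(str, enum.Enum):
    CONTROL = "control"
    TUMOR = "tumor"
    GRADE1 = "grade1"
    GRADE2 = "grade2"
    INDETERMINATE = "indeterminate"


@dataclass
class Ellipsoid3D:
    """Gaussian ellipsoid: mean, covariance and Mahalanobis^2 boundary."""

    mean: np.ndarray
    covariance: np.ndarray
    scale: float  # Mahalanobis^2 at the boundary
    mass: float = DEFAULT_MASS

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (3,) or self.covariance.shape != (3, 3):
            raise ValueError("ellipsoid lives in 3 dimensions")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        # symmetric positive definite check via Cholesky
        try:
            np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc

    def mahalanobis_sq(self, x: np.ndarray) -> np.ndarray:
        diff = np.atleast_2d(x) - self.mean
        sol = np.linalg.solve(self.covariance, diff.T)
        return np.einsum("ij,ji->i", diff, sol)

    def volume(self) -> float:
        """Euclidean volume of the ellipsoid."""
        r3 = self.scale ** 1.5
        return float(4.0 / 3.0 * np.pi * r3 * np.sqrt(np.linalg.det(self.covariance)))


def fit_ellipsoid(points, mass: float = DEFAULT_MASS,
                  diagonal_only: bool = False) -> Ellipsoid3D:
    """Fit the Gaussian ellipsoid enclosing ``mass`` probability.

    Mean and covariance are the sample statistics; the boundary is the
    chi-squared (3 dof) quantile of ``mass`` — the unique scaling for
    which a trivariate Gaussian puts exactly that mass inside its
    Mahalanobis ellipsoid.  ``diagonal_only`` drops covariances,
    axis-aligning the ellipsoid.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    arr = np.asarray([p.as_array() if isinstance(p, FeaturePoint3D) else p
                      for p in points], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("points must be 3-dimensional")
    if arr.shape[0] < 4:
        raise ValueError("need at least 4 points to fit a 3D ellipsoid")
    mean = arr.mean(axis=0)
    cov = np.cov(arr, rowvar=False)
    if diagonal_only:
        cov = np.diag(np.diag(cov))
    if np.linalg.matrix_rank(cov) < 3:
        raise ValueError("singular covariance: points are coplanar")
    return Ellipsoid3D(mean=mean, covariance=cov,
                       scale=float(chi2.ppf(mass, df=3)), mass=mass)


def ellipsoid_contains(e: Ellipsoid3D, p: FeaturePoint3D | np.ndarray) -> bool:
    """Boundary-inclusive membership test."""
    x = p.as_array() if isinstance(p, FeaturePoint3D) else np.asarray(p, float)
    return bool(e.mahalanobis_sq(x)[0] <= e.scale)


def ellipsoid_overlap_volume(e1: Ellipsoid3D, e2: Ellipsoid3D,
                             n_mc: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo Jaccard overlap |e1 n e2| / |e1 u e2|.

    Uniform sampling in the joint axis-aligned bounding box of the two
    ellipsoids; seeded and reproducible.
    """
    if n_mc < 10_000:
        raise ValueError("use at least 10^4 Monte-Carlo points")
    boxes = []
    for e in (e1, e2):
        half = np.sqrt(e.scale * np.diag(e.covariance))
        boxes.append((e.mean - half, e.mean + half))
    lo = np.minimum(boxes[0][0], boxes[1][0])
    hi = np.maximum(boxes[0][1], boxes[1][1])
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_mc, 3))
    in1 = e1.mahalanobis_sq(pts) <= e1.scale
    in2 = e2.mahalanobis_sq(pts) <= e2.scale
    union = np.count_nonzero(in1 | in2)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(in1 & in2) / union)


def classify_control_tumor(
    p: FeaturePoint3D,
    ellipsoids: dict,
    shg_threshold: float = SHG_CONTROL_TUMOR_THRESHOLD,
) -> Verdict:
    """Control-vs-tumor rule gated on ellipsoid membership and SHG-Int."""
    in_tumor = any(
        ellipsoid_contains(ellipsoids[tt], p)
        for tt in (TissueType.GRADE1, TissueType.GRADE2) if tt in ellipsoids
    )
    if in_tumor and p.shg_int > shg_threshold:
        return Verdict.TUMOR
    ctrl = ellipsoids.get(TissueType.CONTROL)
    if ctrl is not None and ellipsoid_contains(ctrl, p) and p.shg_int <= shg_threshold:
        return Verdict.CONTROL
    return Verdict.INDETERMINATE


def classify_grade(
    p: FeaturePoint3D,
    ellipsoids: dict,
    shg_threshold: float = SHG_GRADE_THRESHOLD,
) -> Verdict:
    """Grade I vs grade II rule: membership plus the SHG-Int threshold."""
    g1 = ellipsoids.get(TissueType.GRADE1)
    g2 = ellipsoids.get(TissueType.GRADE2)
    if g1 is not None and ellipsoid_contains(g1, p) and p.shg_int <= shg_threshold:
        return Verdict.GRADE1
    if g2 is not None and ellipsoid_contains(g2, p) and p.shg_int > shg_threshold:
        return Verdict.GRADE2
    return Verdict.INDETERMINATE


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """Se = TP/(TP+FN), Sp = TN/(TN+FP); NaN flags an undefined quantity."""
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    return se, sp


def _tally(pairs, positive: Verdict, negative: Verdict,
           positive_labels: set, indeterminate: str) -> ConfusionCounts:
    c = ConfusionCounts()
    for truth_positive, verdict in pairs:
        if verdict == Verdict.INDETERMINATE:
            if indeterminate == "exclude":
                continue
            # count as an error against the true class
            verdict = negative if truth_positive else positive
        if truth_positive:
            if verdict == positive:
                c.tp += 1
            else:
                c.fn += 1
        else:
            if verdict == negative:
                c.tn += 1
            else:
                c.fp += 1
    return c


@dataclass
class CohortEvaluation:
    """Resubstitution evaluation of the two discrimination tests."""

    ellipsoids: dict
    control_tumor: ConfusionCounts
    grade: ConfusionCounts
    se_control_tumor: float
    sp_control_tumor: float
    se_grade: float
    sp_grade: float
    overlap_control_tumor: float
    verdicts: list


def evaluate_cohort(
    points: list[FeaturePoint3D],
    mass: float = DEFAULT_MASS,
    shg_thresholds: tuple[float, float] = (SHG_CONTROL_TUMOR_THRESHOLD,
                                           SHG_GRADE_THRESHOLD),
    indeterminate: str = "exclude",
    overlap_seed: int = 0,
) -> CohortEvaluation:
    """Fit per-type ellipsoids and run both discrimination tests.

    Ellipsoids are fitted on the same labelled points they classify
    (resubstitution).  ``indeterminate`` is either ``"exclude"`` (drop
    abstentions from the confusion counts, the default) or ``"error"``
    (count them against the true class).

    The control-tumor test is positive for tumor; the grade test, run on
    grade I / II points only, is positive for grade II.
    """
    if indeterminate not in ("exclude", "error"):
        raise ValueError("indeterminate must be 'exclude' or 'error'")
    labels = {p.label for p in points}
    if None in labels:
        raise ValueError("every point needs a label for evaluation")
    ellipsoids = {
        tt: fit_ellipsoid([p for p in points if p.label == tt], mass=mass)
        for tt in TissueType if any(p.label == tt for p in points)
    }
    ct_pairs, verdicts = [], []
    for p in points:
        v = classify_control_tumor(p, ellipsoids, shg_thresholds[0])
        verdicts.append((p, "control_tumor", v))
        ct_pairs.append((p.label != TissueType.CONTROL, v))
    ct = _tally(ct_pairs, Verdict.TUMOR, Verdict.CONTROL, set(), indeterminate)

    g_pairs = []
    for p in points:
        if p.label not in (TissueType.GRADE1, TissueType.GRADE2):
            continue
        v = classify_grade(p, ellipsoids, shg_thresholds[1])
        verdicts.append((p, "grade", v))
        g_pairs.append((p.label == TissueType.GRADE2, v))
    gr = _tally(g_pairs, Verdict.GRADE2, Verdict.GRADE1, set(), indeterminate)

    se_ct, sp_ct = sensitivity_specificity(ct)
    se_g, sp_g = sensitivity_specificity(gr)

    overlap = float("nan")
    if TissueType.CONTROL in ellipsoids and (
            TissueType.GRADE1 in ellipsoids or TissueType.GRADE2 in ellipsoids):
        tumor_pts = [p for p in points if p.label != TissueType.CONTROL]
        tumor_ell = fit_ellipsoid(tumor_pts, mass=mass)
        overlap = ellipsoid_overlap_volume(ellipsoids[TissueType.CONTROL],
                                           tumor_ell, seed=overlap_seed)
    return CohortEvaluation(
        ellipsoids=ellipsoids,
        control_tumor=ct,
        grade=gr,
        se_control_tumor=se_ct,
        sp_control_tumor=sp_ct,
        se_grade=se_g,
        sp_grade=sp_g,
        overlap_control_tumor=overlap,
        verdicts=verdicts,
    )


def threshold_rules(
    features: FeaturePoint3D,
    bound_nadh_tau: float,
    bound_fad_tau: float,
) -> dict:
    """The four stand-alone threshold verdicts plus a majority vote.

    Coll-Int > 28 -> tumor; SHG-Int < 2.5 control / 2.5-22 grade I /
    > 22 grade II; bound-NADH lifetime > 2.1 ns control / 1.9-2.1 grade I /
    < 1.9 grade II; bound-FAD lifetime < 0.7 ns control / 0.7-1 grade I /
    > 1 ns grade II.
    """
    verdicts: dict[str, Verdict] = {}
    verdicts["coll_int"] = (Verdict.TUMOR
                            if features.coll_int > COLL_INT_TUMOR_THRESHOLD
                            else Verdict.CONTROL)
    if features.shg_int < SHG_CONTROL_TUMOR_THRESHOLD:
        verdicts["shg_int"] = Verdict.CONTROL
    elif features.shg_int <= SHG_GRADE_THRESHOLD:
        verdicts["shg_int"] = Verdict.GRADE1
    else:
        verdicts["shg_int"] = Verdict.GRADE2
    if bound_nadh_tau > 2.1:
        verdicts["bound_nadh_tau"] = Verdict.CONTROL
    elif bound_nadh_tau >= 1.9:
        verdicts["bound_nadh_tau"] = Verdict.GRADE1
    else:
        verdicts["bound_nadh_tau"] = Verdict.GRADE2
    if bound_fad_tau < 0.7:
        verdicts["bound_fad_tau"] = Verdict.CONTROL
    elif bound_fad_tau <= 1.0:
        verdicts["bound_fad_tau"] = Verdict.GRADE1
    else:
        verdicts["bound_fad_tau"] = Verdict.GRADE2

    # majority vote over the per-rule verdicts, tumor grades pooled as tumor
    votes: dict[str, int] = {}
    for v in verdicts.values():
        key = ("control" if v == Verdict.CONTROL else "tumor")
        votes[key] = votes.get(key, 0) + 1
    majority = max(votes, key=votes.get)
    if votes.get("control", 0) == votes.get("tumor", 0):
        verdicts["majority"] = Verdict.INDETERMINATE
    else:
        verdicts["majority"] = (Verdict.CONTROL if majority == "control"
                                else Verdict.TUMOR)
    return verdicts
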