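"""Evaluation statistics for nodule malignancy risk prediction.

Covers the full evaluation chain used to judge whether predicted follow-up
nodule images ("GP-nodules") improve risk assessment at baseline screening:

* image similarity (MSE, SSIM) between predicted and real follow-up patches;
* ROC analysis — AUC as the Mann-Whitney concordance probability with
  standard errors and paired AUC comparison via DeLong's structural
  components, plus Hochberg step-up multiple-comparison adjustment;
* three-level risk stratification (low / medium / high) by score thresholds
  (Brock: <0.0117 / [0.0117, 0.10] / >0.10; LCRP-style: <0.45 / [0.45, 0.81]
  / >0.81; Lung-RADS consumed as categories <3 / =3 / >3), with an
  order-statistic routine for matching subgroup sizes between two scorers;
* 3x3 reclassification tables split by outcome, and the net reclassification
  index: event NRI = (events escalated - events de-escalated) / n_event,
  nonevent NRI = (nonevents de-escalated - nonevents escalated) /
  n_nonevent, overall NRI = their sum (kept as exact rationals internally;
  reported values use half-up rounding). Component significance uses the
  Pencina-style Z statistic with variance (p_up + p_down - (p_up -
  p_down)^2) / n.

A packaged fixture ships the 3x3 migration counts of a 450-subject NLST
screening test cohort (53 biopsy-proven cancers, 397 negatives) whose risk
groups were re-assigned by a risk model reading GP-nodules; see
:func:`builtin_reclassification_counts`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from importlib import resources

import numpy as np
from scipy.stats import norm
from skimage.metrics import structural_similarity
from statsmodels.stats.multitest import multipletests

from .simgrowth import ImagePatch, measure_diameter_mm

__all__ = [
    "GROUPS", "BROCK_THRESHOLDS", "LCRP_THRESHOLDS",
    "NriResult", "ReclassTable", "RiskScoreSet", "RiskStrata", "ToyScorer",
    "builtin_reclassification_counts", "delong_test", "escalation_summary",
    "hochberg_adjust", "image_mse", "image_ssim", "lungrads_strata",
    "match_subgroup_thresholds", "nri", "nri_z_test", "patch_features",
    "reclassification_table", "roc_auc", "score_patches", "stratify_risk",
    "train_toy_scorer",
]

GROUPS = ("low", "medium", "high")
BROCK_THRESHOLDS = (0.0117, 0.10)
LCRP_THRESHOLDS = (0.45, 0.81)

_GROUP_INDEX = {g: i for i, g in enumerate(GROUPS)}


# -------------------------------------------------------------------- types
@dataclass(frozen=True)
class RiskScoreSet:
    """Per-subject continuous malignancy scores with binary outcomes."""

    subject_ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray  # 1 = cancer event

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        if not (len(self.subject_ids) == len(scores) == len(labels)):
            raise ValueError("subject_ids, scores, labels lengths differ")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    def require_both_classes(self) -> None:
        if self.labels.sum() == 0 or self.labels.sum() == len(self.labels):
            raise ValueError("ROC operations need both classes present")


@dataclass(frozen=True)
class RiskStrata:
    """Low/medium/high group assignment with the rule that produced it."""

    groups: tuple[str, ...]
    thresholds: tuple[float, float] | None = None
    rule: str = "thresholds"

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        if any(g not in GROUPS for g in self.groups):
            raise ValueError("groups must be low/medium/high")
        if self.thresholds is not None and not (
                self.thresholds[0] <= self.thresholds[1]):
            raise ValueError("need t_low <= t_high")

    def indices(self) -> np.ndarray:
        return np.array([_GROUP_INDEX[g] for g in self.groups], dtype=int)

    def sizes(self) -> tuple[int, int, int]:
        idx = self.indices()
        return tuple(int((idx == k).sum()) for k in range(3))


@dataclass(frozen=True)
class ReclassTable:
    """3x3 migration counts (rows initial, columns new), split by outcome."""

    event_counts: np.ndarray
    nonevent_counts: np.ndarray
    n_event: int
    n_nonevent: int

    def __post_init__(self):
        for name in ("event_counts", "nonevent_counts"):
            m = np.asarray(getattr(self, name), dtype=int)
            object.__setattr__(self, name, m)
            if m.shape != (3, 3) or (m < 0).any():
                raise ValueError(f"{name} must be a non-negative 3x3 matrix")
        if self.event_counts.sum() != self.n_event:
            raise ValueError("event counts do not sum to n_event")
        if self.nonevent_counts.sum() != self.n_nonevent:
            raise ValueError("nonevent counts do not sum to n_nonevent")

    @classmethod
    def from_counts(cls, event_counts, nonevent_counts) -> "ReclassTable":
        e = np.asarray(event_counts, dtype=int)
        ne = np.asarray(nonevent_counts, dtype=int)
        return cls(e, ne, int(e.sum()), int(ne.sum()))


def _round_half_up(x: float, dp: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{dp}"),
                                           rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class NriResult:
    """Net reclassification index with component Z-tests.

    ``*_frac`` fields carry the exact rationals; ``overall = event +
    nonevent`` holds exactly. Components with zero migration have an
    undefined Z statistic, reported as NaN.
    """

    event_nri: float
    nonevent_nri: float
    overall_nri: float
    z_event: float
    z_nonevent: float
    z_overall: float
    p_event: float
    p_nonevent: float
    p_overall: float
    event_nri_frac: Fraction = field(repr=False, default=Fraction(0))
    nonevent_nri_frac: Fraction = field(repr=False, default=Fraction(0))

    def rounded(self, dp: int = 2) -> tuple[float, float, float]:
        return (_round_half_up(self.event_nri, dp),
                _round_half_up(self.nonevent_nri, dp),
                _round_half_up(self.overall_nri, dp))


# ------------------------------------------------------------- image metrics
def _values(p) -> np.ndarray:
    return p.values if isinstance(p, ImagePatch) else np.asarray(p, dtype=float)


def image_mse(a, b) -> float:
    """Mean squared pixel difference."""
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    return float(np.mean((va - vb) ** 2))


def image_ssim(a, b) -> float:
    """Structural similarity (11x11 Gaussian window, sigma 1.5, range 1)."""
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    return float(structural_similarity(
        va, vb, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=1.0))


# ---------------------------------------------------------------- ROC / AUC
def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per event) and V01 (per nonevent)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(score_set: RiskScoreSet) -> tuple[float, float]:
    """AUC (Mann-Whitney, ties counted 1/2) and its DeLong standard error."""
    score_set.require_both_classes()
    auc, v10, v01 = _delong_components(score_set.scores, score_set.labels)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    return auc, float(np.sqrt(var))


def delong_test(scores_a: RiskScoreSet,
                scores_b: RiskScoreSet) -> tuple[float, float]:
    """Paired DeLong comparison of two correlated AUCs; returns (z, p)."""
    if scores_a.subject_ids != scores_b.subject_ids or \
            not np.array_equal(scores_a.labels, scores_b.labels):
        raise ValueError("DeLong comparison requires paired subjects/labels")
    scores_a.require_both_classes()
    auc_a, v10a, v01a = _delong_components(scores_a.scores, scores_a.labels)
    auc_b, v10b, v01b = _delong_components(scores_b.scores, scores_b.labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        z = 0.0 if delta == 0 else math.copysign(math.inf, delta)
    else:
        z = delta / math.sqrt(var)
    p = 0.0 if math.isinf(z) else float(2 * norm.sf(abs(z)))
    return float(z), p


def hochberg_adjust(p_values) -> np.ndarray:
    """Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1D p-value array")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="simes-hochberg")[1]


# ----------------------------------------------------------- stratification
def stratify_risk(scores, thresholds: tuple[float, float]) -> RiskStrata:
    """Threshold stratification: < t_low | [t_low, t_high] | > t_high."""
    t_low, t_high = thresholds
    if t_low > t_high:
        raise ValueError("need t_low <= t_high")
    groups = []
    for s in np.asarray(scores, dtype=float):
        if s < t_low:
            groups.append("low")
        elif s <= t_high:
            groups.append("medium")
        else:
            groups.append("high")
    return RiskStrata(tuple(groups), (float(t_low), float(t_high)))


def lungrads_strata(categories) -> RiskStrata:
    """Lung-RADS categories consumed as given: <3 low, =3 medium, >3 high."""
    groups = []
    for c in categories:
        if c < 3:
            groups.append("low")
        elif c == 3:
            groups.append("medium")
        else:
            groups.append("high")
    return RiskStrata(tuple(groups), None, rule="lung-rads")


@dataclass(frozen=True)
class ThresholdMatch:
    thresholds: tuple[float, float]
    target_sizes: tuple[int, int, int]
    achieved_sizes: tuple[int, int, int]

    @property
    def feasible(self) -> bool:
        return self.achieved_sizes == self.target_sizes


def match_subgroup_thresholds(scores, target_sizes) -> ThresholdMatch:
    """Place thresholds at order statistics to hit target subgroup sizes.

    With distinct scores the achieved sizes match exactly. When tied scores
    straddle a boundary, the whole tied block is absorbed into the lower
    group and the achieved sizes report the deviation.
    """
    scores = np.asarray(scores, dtype=float)
    n_low, n_med, n_high = (int(t) for t in target_sizes)
    if min(n_low, n_med, n_high) < 0 or n_low + n_med + n_high != len(scores):
        raise ValueError("target sizes must be >= 0 and sum to the score count")
    s = np.sort(scores)

    if n_low == 0:
        t_low = -math.inf
    elif s[n_low - 1] < s[n_low]:
        t_low = 0.5 * (s[n_low - 1] + s[n_low])
    else:  # tie across the boundary -> absorb into low
        t_low = float(np.nextafter(s[n_low - 1], math.inf))

    if n_high == 0:
        t_high = math.inf
    else:
        k = n_low + n_med  # first high index
        t_high = float(s[k - 1]) if k > 0 else float(np.nextafter(
            s[0], -math.inf))
    t_high = max(t_high, t_low)

    strata = stratify_risk(scores, (t_low, t_high))
    return ThresholdMatch((t_low, t_high), (n_low, n_med, n_high),
                          strata.sizes())


# -------------------------------------------------------- reclassification
def reclassification_table(initial: RiskStrata, new: RiskStrata,
                           labels) -> ReclassTable:
    """3x3 migration counts from initial to new strata, split by outcome."""
    labels = np.asarray(labels, dtype=int)
    gi, gn = initial.indices(), new.indices()
    if not (len(gi) == len(gn) == len(labels)):
        raise ValueError("strata and labels lengths differ")
    event = np.zeros((3, 3), dtype=int)
    nonevent = np.zeros((3, 3), dtype=int)
    for a, b, y in zip(gi, gn, labels):
        (event if y == 1 else nonevent)[a, b] += 1
    return ReclassTable.from_counts(event, nonevent)


def _up_down(counts: np.ndarray) -> tuple[int, int]:
    up = int(np.triu(counts, 1).sum())
    down = int(np.tril(counts, -1).sum())
    return up, down


def _component_z(nri_value: float, up: int, down: int, n: int
                 ) -> tuple[float, float, float]:
    """(z, p, variance) for one NRI component; NaN when nothing moved."""
    if up + down == 0:
        return math.nan, math.nan, 0.0
    p_up, p_down = up / n, down / n
    var = (p_up + p_down - (p_up - p_down) ** 2) / n
    if var <= 0:
        return math.nan, math.nan, 0.0
    z = nri_value / math.sqrt(var)
    return z, float(2 * norm.sf(abs(z))), var


def nri(table: ReclassTable) -> NriResult:
    """Net reclassification index with exact rational components.

    Escalation is any move to a strictly higher of the three ordered groups
    (low -> high counts once, like any other upward move).
    """
    if table.n_event == 0 or table.n_nonevent == 0:
        raise ValueError("NRI components undefined without both outcomes")
    up_e, down_e = _up_down(table.event_counts)
    up_n, down_n = _up_down(table.nonevent_counts)
    event_frac = Fraction(up_e - down_e, table.n_event)
    nonevent_frac = Fraction(down_n - up_n, table.n_nonevent)
    overall_frac = event_frac + nonevent_frac

    z_e, p_e, var_e = _component_z(float(event_frac), up_e, down_e,
                                   table.n_event)
    z_n, p_n, var_n = _component_z(float(nonevent_frac), up_n, down_n,
                                   table.n_nonevent)
    var_o = var_e + var_n
    if var_o > 0:
        z_o = float(overall_frac) / math.sqrt(var_o)
        p_o = float(2 * norm.sf(abs(z_o)))
    else:
        z_o, p_o = math.nan, math.nan

    return NriResult(
        event_nri=float(event_frac), nonevent_nri=float(nonevent_frac),
        overall_nri=float(overall_frac),
        z_event=z_e, z_nonevent=z_n, z_overall=z_o,
        p_event=p_e, p_nonevent=p_n, p_overall=p_o,
        event_nri_frac=event_frac, nonevent_nri_frac=nonevent_frac)


def nri_z_test(table: ReclassTable) -> dict[str, tuple[float, float]]:
    """(z, p) per NRI component; NaN where no subject moved."""
    res = nri(table)
    return {"event": (res.z_event, res.p_event),
            "nonevent": (res.z_nonevent, res.p_nonevent),
            "overall": (res.z_overall, res.p_overall)}


def escalation_summary(table: ReclassTable) -> dict[str, float]:
    """Escalation/de-escalation tallies and percentages per outcome group."""
    up_e, down_e = _up_down(table.event_counts)
    up_n, down_n = _up_down(table.nonevent_counts)
    return {
        "events_escalated": up_e,
        "events_deescalated": down_e,
        "events_escalated_pct": 100.0 * up_e / table.n_event,
        "events_deescalated_pct": 100.0 * down_e / table.n_event,
        "nonevents_escalated": up_n,
        "nonevents_deescalated": down_n,
        "nonevents_escalated_pct": 100.0 * up_n / table.n_nonevent,
        "nonevents_deescalated_pct": 100.0 * down_n / table.n_nonevent,
    }


def builtin_reclassification_counts() -> dict[str, ReclassTable]:
    """Packaged 3x3 migration counts of the 450-subject screening test set.

    Four comparison blocks, keyed by the rule that produced the initial
    strata: ``lung_rads``, ``brock``, ``lcrp_baseline``, ``lcrp_followup``.
    In every block the new strata come from the risk model reading
    GP-nodules predicted from baseline scans.
    """
    ref = resources.files("nodulegp.data") / "reclassification_counts.json"
    payload = json.loads(ref.read_text())
    return {name: ReclassTable.from_counts(block["event"], block["nonevent"])
            for name, block in payload["blocks"].items()}


# ------------------------------------------------------------- toy scorer
def patch_features(patch: ImagePatch) -> np.ndarray:
    """Simple morphological features: size, density, margin roughness."""
    v = patch.values
    d = measure_diameter_mm(patch)
    border = np.concatenate([v[0], v[-1], v[:, 0], v[:, -1]])
    bg = float(np.median(border))
    peak = float(v.max())
    half = bg + 0.5 * (peak - bg)
    mask = v > half
    area_mm2 = float(mask.sum()) * patch.pixel_spacing_mm ** 2
    disk_area = math.pi * (d / 2.0) ** 2 if d > 0 else 1.0
    spikiness = area_mm2 / max(disk_area, 1e-6)
    return np.array([d, float(v.mean()), peak, area_mm2, spikiness])


@dataclass
class ToyScorer:
    """Seeded logistic model over patch features; scores in [0, 1].

    A deliberately small stand-in for a full lung-cancer risk prediction
    model, used to turn patches (baseline, predicted follow-up, or real
    follow-up) into continuous malignancy scores for the evaluation chain.
    """

    model: object
    seed: int

    def score(self, patches) -> np.ndarray:
        feats = np.stack([patch_features(p) for p in patches])
        return self.model.predict_proba(feats)[:, 1]


def train_toy_scorer(patches, labels, seed: int = 0) -> ToyScorer:
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("toy scorer needs both classes in training data")
    feats = np.stack([patch_features(p) for p in patches])
    model = make_pipeline(
        StandardScaler(),
        LogisticRegression(max_iter=2000, random_state=seed))
    model.fit(feats, labels)
    return ToyScorer(model=model, seed=seed)


def score_patches(scorer: ToyScorer, patches, subject_ids=None,
                  labels=None) -> RiskScoreSet:
    scores = scorer.score(patches)
    n = len(scores)
    ids = tuple(subject_ids) if subject_ids is not None \
        else tuple(f"S{i:05d}" for i in range(n))
    lab = np.asarray(labels, dtype=int) if labels is not None \
        else np.zeros(n, dtype=int)
    return RiskScoreSet(ids, scores, lab)
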