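"""Expert-vs-model feature-importance concordance.

Two expert instruments are tabulated:

* structured interviews — a binary feature x doctor selection matrix; the
  selection frequency maps to a 3-level rank (selected by everyone -> 1, by
  at least half -> 2, otherwise -> 3);
* a weighted survey — per-feature counts of High/Medium/Low responses scored
  ``3*high + 2*medium + 1*low``.

Model-side importances can come from any per-feature global score vector
(e.g. Shapley values computed elsewhere); the shipped native scorer is
permutation importance.  :func:`alignment_report` compares two rankings by
level agreement and Spearman correlation of their serial orders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .tabular import LabeledTable

LEVELS = ("High", "Medium", "Low")


class AlignmentError(ValueError):
    pass


def _serials(scores: np.ndarray) -> np.ndarray:
    """1-based serial order by descending score, ties broken by feature order."""
    order = np.lexsort((np.arange(scores.size), -scores))
    serial = np.empty(scores.size, int)
    serial[order] = np.arange(1, scores.size + 1)
    return serial


@dataclass(frozen=True)
class ImportanceRanking:
    features: tuple[str, ...]
    scores: np.ndarray
    serials: np.ndarray
    levels: tuple[str, ...] | None = None

    @classmethod
    def from_scores(
        cls, features, scores, levels=None
    ) -> "ImportanceRanking":
        scores = np.asarray(scores, float)
        return cls(tuple(features), scores, _serials(scores), levels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"feature": self.features, "score": self.scores, "serial": self.serials}
        )
        if self.levels is not None:
            df["level"] = self.levels
        return df


# ---------------------------------------------------------------------------
# Model-side: permutation importance
# ---------------------------------------------------------------------------

def permutation_importance(
    adapter,
    table: LabeledTable,
    metric: str = "accuracy",
    repeats: int = 5,
    seed: int = 0,
) -> ImportanceRanking:
    """Mean metric drop over seeded column shuffles, per feature.

    ``adapter`` must already be fitted (``predict`` raises otherwise).
    """
    y = table.y

    def score(y_pred: np.ndarray) -> float:
        if metric == "accuracy":
            return float(np.mean(y_pred == y))
        if metric == "f1":
            from .evaluation import summary_metrics

            return summary_metrics(y, y_pred, average="binary").f1
        raise AlignmentError(f"unknown metric {metric!r}")

    baseline = score(adapter.predict(table.X))
    rng = np.random.default_rng(seed)
    drops = np.zeros(table.d)
    for j in range(table.d):
        acc = 0.0
        for _ in range(repeats):
            Xp = table.X.copy()
            Xp[:, j] = Xp[rng.permutation(table.n), j]
            acc += baseline - score(adapter.predict(Xp))
        drops[j] = acc / repeats
    return ImportanceRanking.from_scores(table.schema.feature_names, drops)


# ---------------------------------------------------------------------------
# Expert-side tabulations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterviewMatrix:
    """Binary feature x doctor selection matrix."""

    features: tuple[str, ...]
    selections: np.ndarray  # (n_features, n_doctors) in {0,1}

    def __post_init__(self) -> None:
        sel = np.asarray(self.selections)
        if sel.ndim != 2 or sel.shape[0] != len(self.features):
            raise AlignmentError("selection matrix shape mismatch")
        if sel.shape[1] < 1:
            raise AlignmentError("need at least one doctor column")
        if not np.isin(sel, (0, 1)).all():
            raise AlignmentError("selection entries must be 0/1")
        object.__setattr__(self, "selections", sel.astype(int))

    @classmethod
    def from_csv(cls, path: str | Path) -> "InterviewMatrix":
        df = pd.read_csv(path)
        return cls(tuple(df.iloc[:, 0]), df.iloc[:, 1:].to_numpy())


def interview_rank(m: InterviewMatrix) -> pd.DataFrame:
    """Selection frequency and 3-level rank per feature.

    Rank 1: selected by every doctor; rank 2: by at least half (rounded up)
    but not all; rank 3: the rest.
    """
    n_doc = m.selections.shape[1]
    freq = m.selections.sum(axis=1)
    half = int(np.ceil(n_doc / 2))
    rank = np.where(freq == n_doc, 1, np.where(freq >= half, 2, 3))
    return pd.DataFrame({"feature": m.features, "frequency": freq, "rank": rank})


@dataclass(frozen=True)
class SurveyCounts:
    features: tuple[str, ...]
    high: np.ndarray
    medium: np.ndarray
    low: np.ndarray
    respondent_total: int

    def __post_init__(self) -> None:
        for arr in (self.high, self.medium, self.low):
            if np.asarray(arr).min(initial=0) < 0:
                raise AlignmentError("survey counts must be nonnegative")
        sums = np.asarray(self.high) + np.asarray(self.medium) + np.asarray(self.low)
        if not (sums == self.respondent_total).all():
            warnings.warn(
                "survey rows do not all sum to the respondent total", stacklevel=3
            )

    @classmethod
    def from_csv(cls, path: str | Path, respondent_total: int | None = None) -> "SurveyCounts":
        df = pd.read_csv(path)
        high = df["High"].to_numpy(int)
        med = df["Medium"].to_numpy(int)
        low = df["Low"].to_numpy(int)
        if respondent_total is None:
            respondent_total = int(np.max(high + med + low))
        return cls(tuple(df.iloc[:, 0]), high, med, low, respondent_total)


def survey_score(
    c: SurveyCounts, weights: tuple[int, int, int] = (3, 2, 1)
) -> ImportanceRanking:
    """Weighted score ``w_h*high + w_m*medium + w_l*low`` with descending serials."""
    w_h, w_m, w_l = weights
    scores = w_h * np.asarray(c.high) + w_m * np.asarray(c.medium) + w_l * np.asarray(c.low)
    return ImportanceRanking.from_scores(c.features, scores.astype(float))


# ---------------------------------------------------------------------------
# Levels and concordance
# ---------------------------------------------------------------------------

def assign_levels(
    ranking: ImportanceRanking,
    level_counts: tuple[int, int, int] = (2, 7, 11),
    method: str = "counts",
) -> ImportanceRanking:
    """Cut a ranking into High / Medium / Low bands.

    ``method="counts"`` takes the top ``level_counts[0]`` features by score as
    High, the next block as Medium, the rest as Low (counts must sum to d).
    ``method="gap"`` places the two cuts at the largest consecutive score
    drops instead.
    """
    d = len(ranking.features)
    order = np.argsort(ranking.serials)  # feature indices, best first
    if method == "counts":
        if sum(level_counts) != d:
            raise AlignmentError(
                f"level_counts {level_counts} must sum to feature count {d}"
            )
        c_high, c_med, _ = level_counts
    elif method == "gap":
        sorted_scores = ranking.scores[order]
        drops = sorted_scores[:-1] - sorted_scores[1:]
        cut1, cut2 = np.sort(np.argsort(-drops, kind="stable")[:2])
        c_high, c_med = cut1 + 1, cut2 - cut1
    else:
        raise AlignmentError(f"unknown method {method!r}")
    levels = [""] * d
    for pos, j in enumerate(order):
        levels[j] = LEVELS[0] if pos < c_high else LEVELS[1] if pos < c_high + c_med else LEVELS[2]
    return ImportanceRanking(ranking.features, ranking.scores, ranking.serials, tuple(levels))


@dataclass(frozen=True)
class AlignmentReport:
    features: tuple[str, ...]
    level_match: np.ndarray
    match_fraction: float
    spearman: float
    disagreements: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "match_fraction": self.match_fraction,
            "spearman": self.spearman,
            "disagreements": list(self.disagreements),
            "per_feature": {
                f: bool(m) for f, m in zip(self.features, self.level_match)
            },
        }


def alignment_report(
    xai: ImportanceRanking, expert: ImportanceRanking
) -> AlignmentReport:
    """Level agreement and rank correlation between two rankings."""
    if set(xai.features) != set(expert.features):
        raise AlignmentError("feature sets differ between the two rankings")
    if xai.levels is None or expert.levels is None:
        raise AlignmentError("both rankings need assigned levels")
    # align expert to xai feature order
    pos = {f: i for i, f in enumerate(expert.features)}
    idx = np.array([pos[f] for f in xai.features])
    exp_levels = np.array(expert.levels)[idx]
    exp_serials = expert.serials[idx]
    match = np.array(xai.levels) == exp_levels
    rho = float(spearmanr(xai.serials, exp_serials).statistic)
    disagreements = tuple(f for f, m in zip(xai.features, match) if not m)
    return AlignmentReport(
        xai.features, match, float(np.mean(match)), rho, disagreements
    )


# ---------------------------------------------------------------------------
# Packaged expert fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("clusterbalance") / "data" / name


def load_interview_fixture() -> InterviewMatrix:
    """The five-doctor interview selection table for the thyroid features."""
    with resources.as_file(_data_path("thyroid_interviews.csv")) as p:
        return InterviewMatrix.from_csv(p)


def load_survey_fixture() -> SurveyCounts:
    """Summarized High/Medium/Low survey counts (30 respondents)."""
    with resources.as_file(_data_path("thyroid_survey.csv")) as p:
        return SurveyCounts.from_csv(p)


def load_concordance_fixture() -> tuple[ImportanceRanking, ImportanceRanking]:
    """Reference model-vs-expert levels and serials for the 20 features."""
    with resources.as_file(_data_path("thyroid_concordance.csv")) as p:
        df = pd.read_csv(p)
    feats = tuple(df["Feature"])
    # serials are ranks: score = -serial keeps serial order under from_scores
    xai = ImportanceRanking(
        feats,
        -df["XAI_Serial"].to_numpy(float),
        df["XAI_Serial"].to_numpy(int),
        tuple(df["XAI_Level"]),
    )
    expert = ImportanceRanking(
        feats,
        -df["Expert_Serial"].to_numpy(float),
        df["Expert_Serial"].to_numpy(int),
        tuple(df["Expert_Level"]),
    )
    return xai, expert
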