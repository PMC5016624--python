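"""Cross-layer centrality profiling and abstinence-outcome comparison.

Each trial participant is summarized by an 8-vector of in- and out-degrees
over the four layers (zero where absent — participants who never touched the
community are legitimate all-zero profiles). Profiles are clustered with a
Gaussian mixture fit by expectation-maximization on the raw degree counts;
the number of groups K is chosen by a log-likelihood plateau rule. Group
abstinence rates are compared pairwise with one-way two-group ANOVA on the
0/1 abstinence indicator, which for two groups satisfies F = t² of the
pooled-variance t test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .netbuild import MultirelationalNetwork

PROFILE_COLUMNS = (
    "MB_in", "MB_out", "BL_in", "BL_out", "GD_in", "GD_out", "PM_in", "PM_out",
)
#: ridge added to covariance diagonals; zero-inflated integer features make
#: singular components likely otherwise
COVARIANCE_RIDGE = 1e-6
DEFAULT_RESTARTS = 10
DEFAULT_PLATEAU_THRESHOLD = 0.05


def extract_profiles(multinet: MultirelationalNetwork, cohort) -> pd.DataFrame:
    """Per-user 8-vector of layer in/out-degrees, one row per cohort member."""
    cohort = sorted(cohort)
    if not cohort:
        raise ValueError("cohort must be nonempty")
    data = {}
    for column in PROFILE_COLUMNS:
        channel, side = column.split("_")
        layer = multinet.layer(channel)
        deg = layer.in_degree if side == "in" else layer.out_degree
        data[column] = [deg(u) if u in layer else 0 for u in cohort]
    return pd.DataFrame(data, index=pd.Index(cohort, name="user_id"))


def fit_mixture(
    profiles: pd.DataFrame,
    k: int,
    restarts: int = DEFAULT_RESTARTS,
    seed: int | None = None,
) -> tuple[GaussianMixture, float]:
    """Best-of-restarts EM fit with full covariances; returns the model and
    the total data log-likelihood."""
    n = len(profiles)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of profiles ({n})")
    X = profiles.to_numpy(dtype=float)
    model = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=COVARIANCE_RIDGE,
        n_init=restarts,
        random_state=seed,
    )
    model.fit(X)
    if not np.all(np.isfinite(model.covariances_)):
        raise ValueError("singular covariance after regularization")
    return model, float(model.score(X) * n)


@dataclass
class GroupingResult:
    selected_k: int
    loglik: dict[int, float]
    plateau_threshold: float
    warning: bool
    assignments: pd.Series          # user_id -> group label 1..K
    group_sizes: dict[int, int]
    group_means: pd.DataFrame       # one row per group, PROFILE_COLUMNS
    scaled: bool = False

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "selected_k": self.selected_k,
            "loglik": {str(k): v for k, v in self.loglik.items()},
            "plateau_threshold": self.plateau_threshold,
            "warning": self.warning,
            "group_sizes": {str(k): v for k, v in self.group_sizes.items()},
            "group_means": {
                str(g): row.to_dict() for g, row in self.group_means.iterrows()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def select_k_from_loglik(
    loglik: dict[int, float],
    plateau_threshold: float = DEFAULT_PLATEAU_THRESHOLD,
) -> tuple[int, bool]:
    """Smallest K whose relative log-likelihood gain to K+1 falls below the
    plateau threshold; falls back to the largest K (with a warning flag) when
    gains stay large throughout."""
    ks = sorted(loglik)
    if len(ks) < 2:
        return ks[-1], False
    for k in ks[:-1]:
        gain = (loglik[k + 1] - loglik[k]) / abs(loglik[k])
        if gain < plateau_threshold:
            return k, False
    return ks[-1], True


def select_k(
    profiles: pd.DataFrame,
    k_range=range(2, 11),
    restarts: int = DEFAULT_RESTARTS,
    seed: int | None = None,
    plateau_threshold: float = DEFAULT_PLATEAU_THRESHOLD,
) -> GroupingResult:
    """Fit the mixture for each K in a contiguous range and keep the plateau
    K's grouping. Groups are relabeled 1..K by descending mean total degree
    so numbering is reproducible."""
    ks = sorted(k_range)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k_range must be contiguous")
    models: dict[int, GaussianMixture] = {}
    loglik: dict[int, float] = {}
    for k in ks:
        models[k], loglik[k] = fit_mixture(profiles, k, restarts=restarts, seed=seed)
    selected, warning = select_k_from_loglik(loglik, plateau_threshold)

    model = models[selected]
    raw_labels = model.predict(profiles.to_numpy(dtype=float))
    order = np.argsort(-model.means_.sum(axis=1), kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series(
        [relabel[int(l)] for l in raw_labels], index=profiles.index, name="group"
    )
    sizes = labels.value_counts().sort_index().to_dict()
    means = profiles.groupby(labels).mean()
    means.index.name = "group"
    return GroupingResult(
        selected_k=selected,
        loglik=loglik,
        plateau_threshold=plateau_threshold,
        warning=warning,
        assignments=labels,
        group_sizes={int(k): int(v) for k, v in sizes.items()},
        group_means=means,
    )


def group_abstinence(
    result: GroupingResult, outcomes: pd.DataFrame, mode: str = "ITT"
) -> pd.DataFrame:
    """Per-group abstinence rates.

    ``ITT`` counts nonresponders as smoking (abstinent / group size);
    ``responders`` restricts the denominator to survey responders.
    """
    if mode not in ("ITT", "responders"):
        raise ValueError(f"mode must be 'ITT' or 'responders', got {mode!r}")
    by_user = outcomes.set_index("user_id")
    missing = [u for u in result.assignments.index if u not in by_user.index]
    if missing:
        raise KeyError(f"no outcome row for user(s): {missing[:5]}")
    rows = []
    for group, members in result.assignments.groupby(result.assignments):
        sub = by_user.loc[members.index]
        size = len(sub)
        responders = int(sub["responded"].sum())
        abstinent = int(sub["abstinent"].sum())
        denom = size if mode == "ITT" else responders
        rate = abstinent / denom if denom else math.nan
        rows.append((group, size, responders, abstinent, rate))
    return pd.DataFrame(
        rows, columns=["group", "size", "responders", "abstinent", "rate"]
    ).set_index("group")


def abstinence_rate(abstinent: int, denominator: int) -> float:
    """Rate as a percentage, as the outcome tables print it."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * abstinent / denominator


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    infinite: bool = False


def pairwise_anova(group_a, group_b) -> AnovaResult:
    """One-way two-group ANOVA on 0/1 outcome indicators.

    Degenerate inputs: both groups constant with equal means gives F = 0;
    both constant with different means sets the infinite-F flag.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    n = len(a) + len(b)
    grand = (a.sum() + b.sum()) / n
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df = (1, n - 2)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df=df, p=1.0)
        return AnovaResult(F=math.inf, df=df, p=0.0, infinite=True)
    f_stat = (ss_between / df[0]) / (ss_within / df[1])
    p = float(stats.f.sf(f_stat, *df))
    return AnovaResult(F=float(f_stat), df=df, p=p)


def anova_table(
    result: GroupingResult, outcomes: pd.DataFrame
) -> pd.DataFrame:
    """All pairwise group comparisons on the ITT abstinence indicator."""
    by_user = outcomes.set_index("user_id")
    indicator = {}
    for group, members in result.assignments.groupby(result.assignments):
        indicator[group] = by_user.loc[members.index, "abstinent"].astype(float).to_numpy()
    groups = sorted(indicator)
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            if len(indicator[ga]) < 2 or len(indicator[gb]) < 2:
                continue
            res = pairwise_anova(indicator[ga], indicator[gb])
            rows.append((ga, gb, res.F, res.df[1], res.p))
    return pd.DataFrame(rows, columns=["groupA", "groupB", "F", "df2", "p"])
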