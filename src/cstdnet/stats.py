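"""Rank-based model comparison: Friedman test and Nemenyi post-hoc.

Models (treatments, k) are ranked per evaluation metric (blocks, n), best
rank 1, ties averaged.  The Friedman statistic

    chi2 = 12 / (n k (k+1)) * sum_j R_j^2  -  3 n (k+1)

(with ``R_j`` the rank sum of model j) is referred to a chi-square with
k - 1 degrees of freedom; with ties the Conover generalization

    chi2 = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / (A - C)

is used, where ``A`` is the sum of squared individual ranks and
``C = n k (k+1)^2 / 4`` (it reduces to the classical statistic when no
ties exist).  The Nemenyi critical distance is
``CD = q_alpha(k) * sqrt(k (k+1) / (6 n))`` with ``q`` the infinite-df
studentized range quantile divided by sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

#: q_alpha(k) = Q(1-alpha, k, df=inf) / sqrt(2), k = 2..10 (Demsar's table)
NEMENYI_Q = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589,
           7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


@dataclass
class RankTable:
    """k models x n blocks (metrics) of possibly tied, averaged ranks."""

    models: list[str]
    blocks: list[str]
    ranks: np.ndarray  # shape (k, n)

    def __post_init__(self):
        self.ranks = np.asarray(self.ranks, dtype=float)
        k, n = self.ranks.shape
        if k != len(self.models) or n != len(self.blocks):
            raise ValueError("rank matrix shape does not match labels")
        expected = k * (k + 1) / 2
        sums = self.ranks.sum(axis=0)
        if not np.allclose(sums, expected):
            raise ValueError(f"each block's ranks must sum to {expected}, got {sums}")
        if self.ranks.min() < 1 or self.ranks.max() > k:
            raise ValueError("ranks must lie in [1, k]")

    @property
    def k(self) -> int:
        return self.ranks.shape[0]

    @property
    def n(self) -> int:
        return self.ranks.shape[1]

    def average_ranks(self) -> pd.Series:
        return pd.Series(self.ranks.mean(axis=1), index=self.models, name="avg_rank")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranks, index=self.models, columns=self.blocks)


def rank_models(table: pd.DataFrame, higher_is_better: bool = True) -> RankTable:
    """Rank models per metric column (rank 1 = best, ties averaged)."""
    values = table.to_numpy(dtype=float)
    sign = -1.0 if higher_is_better else 1.0
    ranks = np.column_stack([
        sps.rankdata(sign * values[:, j], method="average")
        for j in range(values.shape[1])
    ])
    return RankTable(models=list(table.index), blocks=list(table.columns), ranks=ranks)


def friedman(rt: RankTable, tie_correction: bool = True) -> tuple[float, float]:
    """Friedman chi-square statistic and its upper-tail p-value (df = k-1)."""
    k, n = rt.k, rt.n
    rj = rt.ranks.sum(axis=1)
    has_ties = any(
        len(np.unique(rt.ranks[:, j])) < k for j in range(n)
    )
    if tie_correction and has_ties:
        a = float((rt.ranks**2).sum())
        c = n * k * (k + 1) ** 2 / 4.0
        num = (k - 1) * float(((rj - n * (k + 1) / 2.0) ** 2).sum())
        # fully tied table: no rank variation at all, statistic is zero
        chi2 = num / (a - c) if a > c else 0.0
    else:
        chi2 = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
    p = float(sps.chi2.sf(chi2, df=k - 1))
    return chi2, p


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical distance ``q_alpha(k) * sqrt(k(k+1)/(6n))``."""
    try:
        q = NEMENYI_Q[round(alpha, 2)][k]
    except KeyError as exc:
        raise ValueError(f"no critical value tabulated for k={k}, alpha={alpha}") from exc
    return q * np.sqrt(k * (k + 1) / (6.0 * n))


@dataclass
class ComparisonReport:
    average_ranks: pd.Series
    chi2: float
    p_value: float
    critical_distance: float
    alpha: float
    significant: pd.DataFrame  # boolean k x k matrix

    def significant_pairs(self) -> list[tuple[str, str]]:
        names = list(self.significant.index)
        return [(a, b) for i, a in enumerate(names) for b in names[i + 1:]
                if self.significant.loc[a, b]]


def compare_report(rt: RankTable, alpha: float = 0.05,
                   tie_correction: bool = True) -> ComparisonReport:
    """Average ranks, Friedman test, and Nemenyi pairwise significance."""
    chi2, p = friedman(rt, tie_correction=tie_correction)
    cd = nemenyi_cd(rt.k, rt.n, alpha)
    avg = rt.average_ranks()
    diff = np.abs(avg.to_numpy()[:, None] - avg.to_numpy()[None, :])
    sig = pd.DataFrame(diff > cd, index=rt.models, columns=rt.models)
    return ComparisonReport(average_ranks=avg, chi2=chi2, p_value=p,
                            critical_distance=cd, alpha=alpha, significant=sig)


# ---- packaged comparison tables -----------------------------------------

def load_table(name: str) -> pd.DataFrame:
    """Load one of the packaged comparison-table CSVs by short name.

    Available: ``small_target_metrics``, ``small_target_ranks``,
    ``normal_target_metrics``, ``normal_target_ranks``,
    ``ablation_metrics``, ``ablation_ranks``.
    """
    ref = resources.files("cstdnet") / "tables" / f"{name}.csv"
    if not ref.is_file():
        raise FileNotFoundError(f"no packaged table named {name!r}")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, index_col=0)


def rank_table_from_frame(frame: pd.DataFrame) -> RankTable:
    """Wrap a models x metrics frame of pre-computed ranks."""
    return RankTable(models=list(frame.index), blocks=list(frame.columns),
                     ranks=frame.to_numpy(dtype=float))
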