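"""Pareto-front extraction, distance-to-front ranking and threshold counting.

Candidates live in the two-objective plane (acquisition affinity, predicted
solubility), both maximized. The front is the maximal non-dominated subset;
the distance of any point to the front is the minimum variance-normalized
Euclidean distance to a front member,

    d_P(x) = min_{x' in front} sqrt( (aff - aff')^2 / var_aff
                                   + (sol - sol')^2 / var_sol ),

with the variances computed over the full generated pool before any
filtering, so d_P is invariant under separate affine rescaling of either
objective. Top-B selection keeps the B smallest d_P with lexicographic
sequence tie-breaking for determinism. The squared-distance convention (no
root) is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import EpistasisLandscape


@dataclass(frozen=True)
class ObjectivePoint:
    sequence: str
    aff: float
    sol: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.aff) and np.isfinite(self.sol)):
            raise ValueError("objective coordinates must be finite")


def pareto_front(aff: np.ndarray, sol: np.ndarray) -> np.ndarray:
    """Indices of the maximal non-dominated subset under joint maximization.

    A point is dominated iff another point is >= in both coordinates and
    strictly greater in at least one. Duplicate coordinate pairs are all kept
    (they dominate nothing and are dominated by nothing among themselves).
    """
    aff = np.asarray(aff, float)
    sol = np.asarray(sol, float)
    if aff.shape != sol.shape or aff.ndim != 1 or len(aff) == 0:
        raise ValueError("need equal-length non-empty 1-d objective arrays")
    order = np.lexsort((-sol, -aff))  # aff desc, sol desc within ties
    front = []
    best_sol = -np.inf
    prev_aff, prev_sol = None, None
    for idx in order:
        a, s = aff[idx], sol[idx]
        if s > best_sol or (a == prev_aff and s == prev_sol):
            front.append(idx)
            prev_aff, prev_sol = a, s
            best_sol = max(best_sol, s)
    return np.sort(np.array(front))


class CandidateSet:
    """Scored sequences with Pareto annotations and d_P ranking."""

    def __init__(self, points: list[ObjectivePoint], squared: bool = False):
        if not points:
            raise ValueError("candidate set must be non-empty")
        # de-duplicate by sequence, keeping first occurrence
        seen: dict[str, ObjectivePoint] = {}
        for p in points:
            seen.setdefault(p.sequence, p)
        self.points = list(seen.values())
        self.aff = np.array([p.aff for p in self.points])
        self.sol = np.array([p.sol for p in self.points])
        self.squared = squared
        self.front_idx = pareto_front(self.aff, self.sol)
        self.sigma_aff2 = float(np.var(self.aff))
        self.sigma_sol2 = float(np.var(self.sol))

    @classmethod
    def from_arrays(cls, seqs, aff, sol, squared: bool = False) -> "CandidateSet":
        return cls(
            [ObjectivePoint(s, float(a), float(o)) for s, a, o in zip(seqs, aff, sol)],
            squared=squared,
        )

    def pareto_distance(self, point: ObjectivePoint) -> float:
        """Min variance-normalized distance from ``point`` to the front."""
        if self.sigma_aff2 <= 0 or self.sigma_sol2 <= 0:
            degenerate = "affinity" if self.sigma_aff2 <= 0 else "solubility"
            raise ValueError(f"zero variance in the {degenerate} coordinate")
        fa = self.aff[self.front_idx]
        fs = self.sol[self.front_idx]
        d2 = (point.aff - fa) ** 2 / self.sigma_aff2 + (point.sol - fs) ** 2 / self.sigma_sol2
        d2min = float(np.min(d2))
        return d2min if self.squared else float(np.sqrt(d2min))

    def distances(self) -> np.ndarray:
        return np.array([self.pareto_distance(p) for p in self.points])

    def select_top(self, B: int) -> list[str]:
        """The B sequences with smallest d_P; ties broken by sequence string."""
        if B > len(self.points):
            raise ValueError(f"B={B} exceeds candidate count {len(self.points)}")
        d = self.distances()
        order = sorted(range(len(self.points)), key=lambda i: (d[i], self.points[i].sequence))
        return [self.points[i].sequence for i in order[:B]]

    def report(self) -> pd.DataFrame:
        d = self.distances()
        front = np.zeros(len(self.points), dtype=bool)
        front[self.front_idx] = True
        df = pd.DataFrame(
            {
                "sequence": [p.sequence for p in self.points],
                "aff": self.aff,
                "sol": self.sol,
                "d_P": d,
                "front": front,
            }
        )
        df = df.sort_values(["d_P", "sequence"], kind="mergesort").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df


def threshold_count_eval(
    candidates: pd.DataFrame,
    truth: EpistasisLandscape,
    f_sol_min: float,
    B: int,
    f_aff_grid,
) -> pd.DataFrame:
    """Budgeted selection protocol scored against the ground-truth landscape.

    Keep candidates with predicted solubility strictly above ``f_sol_min``,
    rank by the acquisition column, truncate to the top ``B``, evaluate the
    true landscape affinity of the survivors and count how many exceed each
    grid threshold. ``candidates`` needs columns sequence / acq / sol_pred.
    Fewer than B survivors is flagged, not an error.
    """
    surv = candidates[candidates["sol_pred"] > f_sol_min]
    shortfall = len(surv) < B
    top = surv.sort_values(["acq", "sequence"], ascending=[False, True], kind="mergesort").head(B)
    true_aff = truth.evaluate_many(list(top["sequence"])) if len(top) else np.array([])
    counts = [int(np.sum(true_aff > t)) for t in f_aff_grid]
    out = pd.DataFrame({"f_aff_min": list(f_aff_grid), "count": counts})
    out.attrs["n_selected"] = len(top)
    out.attrs["shortfall"] = bool(shortfall)
    return out
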