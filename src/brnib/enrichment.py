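"""Rankings and virtual-screening enrichment metrics.

A ScoreTable is turned into a ranking (best combined score descending, stable
on ties) and evaluated with the standard early-recognition metrics:

* ROC **AUC** with the Hanley–McNeil/Wilcoxon standard error;
* **EFd** — the percentage of actives retrieved by the time a given fraction
  of the decoys has been retrieved;
* **BEDROC(α)** — the Truchon–Bailey Boltzmann-enhanced discrimination of the
  ROC, emphasising early recognition (α = 20 by default).

Compounds skipped by docking carry no score; they are appended to the bottom
of the ranking in a seeded uniform random order, which is the expected
behaviour of random picking and keeps early-enrichment numbers comparable
across methods that skip different compounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError

DEFAULT_EFD_FRACTIONS = (0.001, 0.005, 0.01, 0.05)
DEFAULT_BEDROC_ALPHAS = (20.0,)


@dataclass(frozen=True)
class Ranking:
    """Ordered compound list, actives flagged; skipped block at the bottom."""

    compound_ids: tuple[str, ...]
    is_active: np.ndarray  # bool, aligned with compound_ids
    n_scored: int  # entries before the appended skipped block
    seed: int  # seed used to shuffle the skipped block

    def __len__(self) -> int:
        return len(self.compound_ids)

    @property
    def n_actives(self) -> int:
        return int(self.is_active.sum())

    @property
    def n_decoys(self) -> int:
        return len(self) - self.n_actives


def make_ranking(table: pd.DataFrame, seed: int = 0) -> Ranking:
    """Rank a ScoreTable: scored rows by descending combined score (stable),
    skipped rows appended in a seeded uniform random permutation."""
    if len(table) == 0:
        raise UndefinedMetricError("empty score table")
    scored = table[~table["skipped"].astype(bool)]
    skipped = table[table["skipped"].astype(bool)]
    # mergesort is stable: ties keep table (input) order
    order = np.argsort(-scored["combined"].to_numpy(), kind="stable")
    ids = list(scored["compound_id"].to_numpy()[order])
    labels = list(scored["label"].to_numpy()[order])
    if len(skipped):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(skipped))
        ids.extend(skipped["compound_id"].to_numpy()[perm])
        labels.extend(skipped["label"].to_numpy()[perm])
    return Ranking(
        compound_ids=tuple(ids),
        is_active=np.array([l == "active" for l in labels], dtype=bool),
        n_scored=len(scored),
        seed=seed,
    )


def _require_both_classes(ranking: Ranking) -> None:
    if ranking.n_actives == 0 or ranking.n_decoys == 0:
        raise UndefinedMetricError(
            f"metric undefined: {ranking.n_actives} actives, {ranking.n_decoys} decoys"
        )


def auc(ranking: Ranking) -> tuple[float, float]:
    """ROC AUC and its Wilcoxon (Hanley–McNeil) standard error.

    AUC is the fraction of (active, decoy) pairs with the active ranked
    higher.  Ranks in a Ranking are a total order, so no tie handling is
    needed beyond the stable sort that produced it.
    """
    _require_both_classes(ranking)
    active = ranking.is_active
    n_a, n_d = ranking.n_actives, ranking.n_decoys
    # decoys ranked strictly below each active
    decoys_below = np.cumsum(~active[::-1])[::-1] - (~active)
    a = float(decoys_below[active].sum() / (n_a * n_d))
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_a - 1) * (q1 - a * a) + (n_d - 1) * (q2 - a * a)) / (n_a * n_d)
    return a, math.sqrt(max(var, 0.0))


def efd(ranking: Ranking, fraction: float) -> float:
    """Percentage of actives found when ``fraction`` of decoys have been found.

    The cutoff is the ceil(fraction × n_decoys)-th decoy in the ranking;
    actives strictly above that decoy count as found.
    """
    _require_both_classes(ranking)
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    threshold = math.ceil(fraction * ranking.n_decoys)
    actives_seen = 0
    decoys_seen = 0
    for is_act in ranking.is_active:
        if is_act:
            actives_seen += 1
        else:
            decoys_seen += 1
            if decoys_seen == threshold:
                break
    return 100.0 * actives_seen / ranking.n_actives


def bedroc(ranking: Ranking, alpha: float = 20.0) -> float:
    """Truchon–Bailey BEDROC ∈ [0, 1]: early-recognition-weighted enrichment."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if ranking.n_actives == 0 or len(ranking) < 2:
        raise UndefinedMetricError("BEDROC needs >= 1 active and >= 2 compounds")
    big_n = len(ranking)
    n = ranking.n_actives
    r_a = n / big_n
    ranks = np.flatnonzero(ranking.is_active) + 1  # 1-based
    x = ranks / big_n
    rie_denom = n * (1.0 / big_n) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / big_n) - 1.0)
    rie = float(np.exp(-alpha * x).sum()) / rie_denom
    factor = r_a * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * r_a)
    )
    value = rie * factor + 1.0 / (1.0 - math.exp(alpha * (1.0 - r_a)))
    return min(1.0, max(0.0, value))  # guard round-off at the [0, 1] bounds


def roc_curve(ranking: Ranking) -> np.ndarray:
    """ROC staircase as an (N+1, 2) array of (FPR, TPR), (0,0) → (1,1)."""
    _require_both_classes(ranking)
    tp = np.concatenate([[0], np.cumsum(ranking.is_active)]) / ranking.n_actives
    fp = np.concatenate([[0], np.cumsum(~ranking.is_active)]) / ranking.n_decoys
    return np.column_stack([fp, tp])


def write_roc_curve(curve: np.ndarray, path) -> None:
    """Two-column TSV (FPR, TPR) — the plotting interface."""
    np.savetxt(path, curve, fmt="%.10g", delimiter="\t", header="fpr\ttpr", comments="")


@dataclass(frozen=True)
class MetricReport:
    """Bundle of enrichment metrics for one ranking."""

    auc: float
    auc_se: float
    efd: dict[float, float] = field(default_factory=dict)  # fraction -> percent
    bedroc: dict[float, float] = field(default_factory=dict)  # alpha -> value

    def to_json(self) -> str:
        return json.dumps(
            {
                "auc": self.auc,
                "auc_se": self.auc_se,
                "efd": {str(k): v for k, v in self.efd.items()},
                "bedroc": {str(k): v for k, v in self.bedroc.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        d = json.loads(text)
        return cls(
            auc=d["auc"],
            auc_se=d["auc_se"],
            efd={float(k): v for k, v in d["efd"].items()},
            bedroc={float(k): v for k, v in d["bedroc"].items()},
        )


def metric_report(
    table: pd.DataFrame,
    fractions: Sequence[float] = DEFAULT_EFD_FRACTIONS,
    alphas: Sequence[float] = DEFAULT_BEDROC_ALPHAS,
    seed: int = 0,
) -> MetricReport:
    """All metrics for one ScoreTable (single ranking, shared skipped shuffle)."""
    ranking = make_ranking(table, seed=seed)
    a, se = auc(ranking)
    return MetricReport(
        auc=a,
        auc_se=se,
        efd={f: efd(ranking, f) for f in fractions},
        bedroc={al: bedroc(ranking, al) for al in alphas},
    )
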