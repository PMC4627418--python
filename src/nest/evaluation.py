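"""Evaluation harness for gene rankings against gold-standard gene sets.

Covers the four procedures used to benchmark network neighbor scores:

* ROC/AUC of a ranking against positive/negative gene sets, with the AUC
  computed by the tie-aware Mann–Whitney pair identity (fraction of
  (positive, negative) pairs where the positive scores higher, ties 1/2);
* the Wilcoxon rank-sum Z (normal approximation with tie and continuity
  corrections) — positive Z means positives rank higher;
* a multivariate logistic regression testing whether a score predicts
  essentiality after controlling for confounders such as network degree
  and the gene's own expression, reporting the Logit Z = coef/stderr;
* a Gaussian-noise degradation experiment: inject white noise scaled to
  the standard deviation of the original values, recompute both the raw
  ranking and the network-smoothed (NEST) ranking, and compare AUC
  reduction ratios (AUC0 − AUC)/AUC0, each predictor relative to its own
  noise-free baseline.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from sklearn.metrics import roc_curve

from .errors import ValidationError
from .network import WeightedGeneNetwork
from .scoring import ValueVector, _as_series, nest_scores

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gold standards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldStandard:
    """Disjoint positive and negative gene sets."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self):
        if not self.positives or not self.negatives:
            raise ValidationError("gold standard needs non-empty positives and negatives")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValidationError(
                f"gold standard positives and negatives overlap: {sorted(overlap)[:5]}"
            )

    @classmethod
    def from_sets(cls, positives: Iterable[str], negatives: Iterable[str]) -> "GoldStandard":
        return cls(frozenset(positives), frozenset(negatives))


def read_gene_list(path) -> list[str]:
    """One gene per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def auto_negatives(scores: ValueVector, positives: Iterable[str], n: Optional[int] = None) -> set[str]:
    """Equal-sized bottom-ranked negative set, mirroring the screen-analysis
    convention of matching positives with the same number of bottom genes."""
    s = _as_series(scores).dropna()
    pos = set(positives)
    candidates = s[~s.index.isin(pos)].sort_values(ascending=True)
    n = n if n is not None else len(pos & set(s.index))
    if n < 1 or len(candidates) < n:
        raise ValidationError("not enough non-positive genes to draw negatives from")
    return set(candidates.index[:n])


# ---------------------------------------------------------------------------
# ROC / rank statistics
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """ROC curve coordinates plus the Mann–Whitney AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def _overlap_scores(scores: ValueVector, gold: GoldStandard) -> tuple[np.ndarray, np.ndarray]:
    s = _as_series(scores)
    missing = s.isna().sum()
    if missing:
        logger.info("evaluation: excluding %d gene(s) without scores", int(missing))
    s = s.dropna()
    pos = s[s.index.isin(gold.positives)].to_numpy()
    neg = s[s.index.isin(gold.negatives)].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("gold standard has no scored positives or no scored negatives")
    return pos, neg


def roc_auc(scores: ValueVector, gold: GoldStandard) -> RocResult:
    """AUC for ranking positives above negatives (higher score = more essential).

    AUC is the Mann–Whitney pair statistic, computed from rank sums so that
    ties count 1/2 exactly; curve coordinates come from the usual
    threshold sweep.
    """
    pos, neg = _overlap_scores(scores, gold)
    n1, n2 = len(pos), len(neg)
    ranks = rankdata(np.concatenate([pos, neg]), method="average")
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n2)
    y = np.concatenate([np.ones(n1), np.zeros(n2)])
    fpr, tpr, _ = roc_curve(y, np.concatenate([pos, neg]))
    return RocResult(fpr=fpr, tpr=tpr, auc=float(auc), n_positive=n1, n_negative=n2)


def rank_sum_z(scores: ValueVector, gold: GoldStandard) -> float:
    """Wilcoxon rank-sum Z, tie-corrected, with continuity correction.

    Positive Z means positives rank above negatives; swapping the labels
    flips the sign exactly.
    """
    pos, neg = _overlap_scores(scores, gold)
    n1, n2 = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    ranks = rankdata(combined, method="average")
    w = ranks[:n1].sum()
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        raise ValidationError("all scores tied; rank-sum Z undefined")
    diff = w - mean_w
    correction = 0.5 * np.sign(diff)
    return float((diff - correction) / math.sqrt(var_w))


# ---------------------------------------------------------------------------
# logistic confounder analysis
# ---------------------------------------------------------------------------

@dataclass
class LogitTable:
    """Per-covariate coefficient, standard error, Logit Z = coef/stderr, Wald p.

    ``fitted`` holds the per-gene fitted probabilities of the combined
    model, for combined-predictor comparisons.
    """

    table: pd.DataFrame
    fitted: pd.Series
    n_genes: int
    converged: bool


def logistic_confounder_test(
    outcome: Mapping[str, int],
    covariates: Mapping[str, ValueVector],
) -> LogitTable:
    """Multivariate logistic fit of a binary outcome on named covariates.

    Typical use: outcome = screen essentiality, covariates = {"nest": ...,
    "degree": ..., "expression": ...}; the Logit Z column answers whether
    the network score carries signal beyond the confounders. Complete
    cases only; an intercept is always included. Constant covariates and
    perfect separation are rejected as errors.
    """
    if len(covariates) == 0:
        raise ValidationError("need at least one covariate")
    y = pd.Series(dict(outcome), dtype=float)
    if not set(y.dropna().unique()) <= {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    x = pd.DataFrame({name: _as_series(vals) for name, vals in covariates.items()})
    data = pd.concat([y.rename("__outcome__"), x], axis=1).dropna()
    if len(data) < len(covariates) + 2:
        raise ValidationError("too few complete cases for the logistic fit")
    y_fit = data["__outcome__"]
    if y_fit.nunique() < 2:
        raise ValidationError("outcome is constant over complete cases")
    x_fit = data.drop(columns="__outcome__")
    constant = [c for c in x_fit.columns if x_fit[c].nunique() == 1]
    if constant:
        raise ValidationError(f"covariate(s) constant across genes: {constant}")
    design = sm.add_constant(x_fit, has_constant="add")
    try:
        fit = sm.Logit(y_fit, design).fit(disp=0)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise ValidationError(f"logistic fit failed (separation or singular design): {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ValidationError("logistic fit did not converge (possible perfect separation)")
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "stderr": fit.bse,
            "z": fit.params / fit.bse,
            "p": fit.pvalues,
        }
    )
    return LogitTable(
        table=table,
        fitted=pd.Series(fit.predict(design), index=data.index),
        n_genes=len(data),
        converged=bool(fit.mle_retvals.get("converged", False)),
    )


# ---------------------------------------------------------------------------
# noise degradation
# ---------------------------------------------------------------------------

def inject_noise(values: ValueVector, level: float, seed: int) -> pd.Series:
    """Add Gaussian white noise with sd = level × sd(values).

    The base level is the sample standard deviation of all supplied values,
    so ``level`` is relative to the data's own spread; level 0 returns the
    input unchanged.
    """
    if level < 0:
        raise ValidationError("noise level must be non-negative")
    v = _as_series(values)
    if len(v) < 2:
        raise ValidationError("need at least 2 values to define a noise base level")
    if level == 0:
        return v.copy()
    base = float(np.std(v.to_numpy(), ddof=1))
    rng = np.random.default_rng(seed)
    return v + rng.normal(0.0, level * base, size=len(v))


def degradation_experiment(
    net: WeightedGeneNetwork,
    values: ValueVector,
    gold: GoldStandard,
    levels: Sequence[float],
    n_reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare noise robustness of the raw ranking vs the NEST ranking.

    For each noise level and replicate, noise is injected into the values;
    the raw predictor is the noisy values themselves, the NEST predictor is
    the neighbor-sum score recomputed from the noisy values. Reduction
    ratio = (AUC0 − AUC)/AUC0 against each predictor's own noise-free AUC0.
    Returns a tidy frame: level, predictor, mean_auc, mean_reduction_ratio,
    sd (of the reduction ratio over replicates).
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    v = _as_series(values)
    auc0 = {
        "raw": roc_auc(v, gold).auc,
        "nest": roc_auc(nest_scores(net, v).scored(), gold).auc,
    }
    degenerate = [k for k, a in auc0.items() if a == 0.0]
    if degenerate:
        raise ValidationError(
            f"noise-free AUC is 0 for predictor(s) {degenerate}; "
            "reduction ratios are undefined"
        )
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(len(levels), n_reps))
    rows = []
    for li, level in enumerate(levels):
        ratios = {"raw": [], "nest": []}
        aucs = {"raw": [], "nest": []}
        for rep in range(n_reps):
            noisy = inject_noise(v, level, seed=int(rep_seeds[li, rep]))
            preds = {
                "raw": noisy,
                "nest": nest_scores(net, noisy).scored(),
            }
            for name, pred in preds.items():
                auc = roc_auc(pred, gold).auc
                aucs[name].append(auc)
                ratios[name].append((auc0[name] - auc) / auc0[name])
        for name in ("raw", "nest"):
            r = np.asarray(ratios[name])
            rows.append(
                {
                    "level": level,
                    "predictor": name,
                    "mean_auc": float(np.mean(aucs[name])),
                    "mean_reduction_ratio": float(r.mean()),
                    "sd": float(r.std(ddof=1)) if n_reps > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
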