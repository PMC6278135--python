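"""PFA/PFB prediction from the three-gene pyrosequencing panel.

The classifier assumes each gene's percent-methylation is beta-distributed
within a subgroup. Per-gene class densities are fitted on a training set by
maximum likelihood, the decision threshold of a gene is the point where the
two densities are equal (likelihood ratio = 1; values below it favor the
hypomethylated PFB class), and a case-level rule combines the three per-gene
votes as *all*, *majority* or *any*. Rule selection maximizes PFB
specificity across the training and validation partitions, breaking ties
toward the rule that calls PFB least often.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateFitError, NoCrossoverError, ValidationError

GENES = ("CRIP1", "DRD4", "LBX2")
CLASSES = ("PFA", "PFB")
#: rule modes ordered from most to least conservative in calling PFB
MODES = ("all", "majority", "any")
_MODE_MIN_VOTES = {"all": 3, "majority": 2, "any": 1}


@dataclass(frozen=True)
class BetaFit:
    """Fitted beta distribution of one gene's methylation in one subgroup."""

    gene: str
    class_label: str
    alpha: float
    beta: float
    n_observations: int
    fit_method: str = "mle(floc=0, fscale=1), method-of-moments init"

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)
                and self.alpha > 0 and self.beta > 0):
            raise ValidationError(
                f"BetaFit({self.gene}, {self.class_label}): non-finite or "
                f"non-positive shapes ({self.alpha}, {self.beta})")
        if self.n_observations < 2:
            raise ValidationError("BetaFit requires n_observations >= 2")

    @property
    def mean(self) -> float:
        """Mean on the [0, 1] scale."""
        return self.alpha / (self.alpha + self.beta)

    def logpdf(self, x):
        return stats.beta.logpdf(x, self.alpha, self.beta)


@dataclass(frozen=True)
class ThresholdRule:
    """Per-gene percent thresholds plus a vote-combination mode."""

    thresholds: Mapping[str, float]
    mode: str
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        for gene, t in self.thresholds.items():
            if not 0.0 < t < 100.0:
                raise ValidationError(f"threshold for {gene} must be in (0, 100), got {t}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with PFB as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return self.tn / denom if denom else None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def validate_gene_panel(records: pd.DataFrame, require_labels: bool = True) -> None:
    """Check a gene-panel frame: all three genes present, values in [0, 100]."""
    for gene in GENES:
        if gene not in records.columns:
            raise ValidationError(f"gene panel is missing column {gene}")
        col = records[gene]
        if col.isna().any():
            raise ValidationError(f"gene panel has missing values for {gene}")
        if ((col < 0) | (col > 100)).any():
            raise ValidationError(f"{gene} values must be in [0, 100]")
    if require_labels:
        if "subgroup" not in records.columns or records["subgroup"].isna().any():
            raise ValidationError("every record must carry a subgroup label")
        bad = set(records["subgroup"]) - set(CLASSES)
        if bad:
            raise ValidationError(f"unknown subgroup labels: {sorted(bad)}")


def stratified_split(
    records: pd.DataFrame,
    train_fraction: float = 1.0 / 3.0,
    seed: int | None = None,
    allow_empty_class: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split labeled records 1:2 (by default) within each subgroup.

    Per class, round(train_fraction * n) samples (half away from zero) go to
    training, drawn without replacement; membership depends only on the
    sorted sample ids and the seed, never on input row order.
    """
    validate_gene_panel(records, require_labels=True)
    if records["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in gene panel")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    for cls in CLASSES:
        ids = sorted(records.loc[records["subgroup"] == cls, "sample_id"])
        if not ids:
            raise ValidationError(f"class {cls} absent from input")
        n_train = math.floor(train_fraction * len(ids) + 0.5)
        chosen = rng.choice(ids, size=n_train, replace=False) if n_train else []
        train_ids.extend(chosen)
        if not allow_empty_class and (n_train == 0 or n_train == len(ids)):
            raise ValidationError(
                f"class {cls} absent from a partition (n={len(ids)}, "
                f"train={n_train}); pass allow_empty_class=True to permit")
    mask = records["sample_id"].isin(train_ids)
    return records[mask].copy(), records[~mask].copy()


def fit_beta(values: Iterable[float], gene: str, class_label: str,
             clip_eps: float = 1e-3) -> BetaFit:
    """Fit a beta distribution to percent values by maximum likelihood.

    Values are scaled to [0, 1] and clipped to [clip_eps, 1 - clip_eps] so
    boundary observations (0% or 100%) keep a finite log-likelihood.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValidationError(f"fit_beta({gene}, {class_label}): need >= 2 values")
    if ((x < 0) | (x > 100)).any():
        raise ValidationError(f"fit_beta({gene}, {class_label}): values outside [0, 100]")
    x = np.clip(x / 100.0, clip_eps, 1.0 - clip_eps)
    if np.allclose(x, x[0]):
        raise DegenerateFitError(
            f"fit_beta({gene}, {class_label}): all values identical after clipping")
    m, v = float(x.mean()), float(x.var(ddof=1))
    # method-of-moments start; guard against variance too large for a beta
    common = max(m * (1.0 - m) / v - 1.0, 1e-3)
    a0, b0 = max(m * common, 1e-3), max((1.0 - m) * common, 1e-3)
    a, b, _, _ = stats.beta.fit(x, a0, b0, floc=0.0, fscale=1.0)
    return BetaFit(gene=gene, class_label=class_label, alpha=float(a),
                   beta=float(b), n_observations=int(x.size))


def lr_threshold(fit_pfa: BetaFit, fit_pfb: BetaFit, grid_step: float = 1e-4) -> float:
    """Percent threshold where the two fitted class densities are equal.

    The log-density difference (PFA minus PFB) is scanned on a grid of
    ``grid_step`` on the [0, 1] scale (0.01 percentage points by default);
    the sign change is refined by bisection. Below the returned threshold the
    PFB density dominates. Requires mean(PFB) < mean(PFA).
    """
    if not fit_pfb.mean < fit_pfa.mean:
        raise ValidationError(
            f"expected mean(PFB) < mean(PFA); got {fit_pfb.mean:.4f} >= {fit_pfa.mean:.4f}")

    def diff(x):
        return fit_pfa.logpdf(x) - fit_pfb.logpdf(x)

    grid = np.arange(grid_step, 1.0, grid_step)
    d = diff(grid)
    roots: list[float] = []
    exact = np.flatnonzero(d == 0.0)
    roots.extend(grid[exact])
    sign = np.sign(d)
    flips = np.flatnonzero((sign[:-1] * sign[1:]) < 0)
    for i in flips:
        roots.append(float(optimize.brentq(diff, grid[i], grid[i + 1])))
    if not roots:
        raise NoCrossoverError(
            f"densities for {fit_pfa.gene} never cross in (0, 100)")
    lo, hi = fit_pfb.mean, fit_pfa.mean
    if len(roots) > 1:
        inside = [r for r in roots if lo <= r <= hi]
        if len(inside) != 1:
            raise NoCrossoverError(
                f"{len(roots)} density crossings for {fit_pfa.gene}, "
                f"{len(inside)} inside the inter-mean interval")
        roots = inside
    return 100.0 * roots[0]


def predict(rule: ThresholdRule, record: Mapping[str, float]) -> str:
    """Classify one record: a gene votes PFB iff its value is strictly below
    the gene's threshold; the mode sets how many votes call the case PFB."""
    votes = 0
    for gene in GENES:
        if gene not in rule.thresholds:
            raise ValidationError(f"rule has no threshold for {gene}")
        if gene not in record or record[gene] is None or (
                isinstance(record[gene], float) and np.isnan(record[gene])):
            raise ValidationError(f"record is missing a value for {gene}")
        if record[gene] < rule.thresholds[gene]:
            votes += 1
    return "PFB" if votes >= _MODE_MIN_VOTES[rule.mode] else "PFA"


def predict_all(rule: ThresholdRule, records: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`predict` over a gene-panel frame."""
    validate_gene_panel(records, require_labels=False)
    votes = sum((records[g] < rule.thresholds[g]).astype(int) for g in GENES)
    labels = np.where(votes >= _MODE_MIN_VOTES[rule.mode], "PFB", "PFA")
    return pd.Series(labels, index=records.index, name="prediction")


def evaluate(predictions: Sequence[str], truths: Sequence[str]) -> ConfusionMatrix:
    """Confusion counts with PFB as the positive class."""
    preds, trus = list(predictions), list(truths)
    if len(preds) != len(trus):
        raise ValidationError("predictions and truths differ in length")
    bad = (set(preds) | set(trus)) - set(CLASSES)
    if bad:
        raise ValidationError(f"labels outside {{PFA, PFB}}: {sorted(bad)}")
    tp = sum(p == "PFB" and t == "PFB" for p, t in zip(preds, trus))
    fp = sum(p == "PFB" and t == "PFA" for p, t in zip(preds, trus))
    tn = sum(p == "PFA" and t == "PFA" for p, t in zip(preds, trus))
    fn = sum(p == "PFA" and t == "PFB" for p, t in zip(preds, trus))
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _specificity_or(cm: ConfusionMatrix, default: float = -1.0) -> float:
    s = cm.specificity
    return default if s is None else s


def select_rule(candidates: Sequence[ThresholdRule], train: pd.DataFrame,
                validation: pd.DataFrame) -> ThresholdRule:
    """Pick the candidate with the highest PFB specificity on both partitions.

    Lexicographic objective: max of (min specificity over the two datasets,
    sum of specificities, conservativeness), where all > majority > any.
    """
    if not candidates:
        raise ValidationError("empty candidate list")
    for frame in (train, validation):
        validate_gene_panel(frame, require_labels=True)
    conservativeness = {m: i for i, m in enumerate(reversed(MODES))}

    def key(rule: ThresholdRule):
        spec_t = _specificity_or(evaluate(predict_all(rule, train), train["subgroup"]))
        spec_v = _specificity_or(evaluate(predict_all(rule, validation), validation["subgroup"]))
        return (min(spec_t, spec_v), spec_t + spec_v, conservativeness[rule.mode])

    return max(candidates, key=key)


def train_classifier(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    clip_eps: float = 1e-3,
) -> dict:
    """Full training pass: per-gene/class beta fits on the training set,
    likelihood-ratio thresholds, the three candidate rules, and the selected
    rule with confusion matrices on both partitions."""
    validate_gene_panel(train, require_labels=True)
    validate_gene_panel(validation, require_labels=True)
    fits: dict[str, dict[str, BetaFit]] = {}
    thresholds: dict[str, float] = {}
    for gene in GENES:
        fits[gene] = {
            cls: fit_beta(train.loc[train["subgroup"] == cls, gene], gene, cls,
                          clip_eps=clip_eps)
            for cls in CLASSES
        }
        thresholds[gene] = lr_threshold(fits[gene]["PFA"], fits[gene]["PFB"])
    provenance = {"n_train": int(len(train)), "clip_eps": clip_eps}
    candidates = [ThresholdRule(thresholds=thresholds, mode=m, provenance=provenance)
                  for m in MODES]
    rule = select_rule(candidates, train, validation)
    confusion = {
        name: evaluate(predict_all(rule, frame), frame["subgroup"])
        for name, frame in (("training", train), ("validation", validation))
    }
    return {"fits": fits, "thresholds": thresholds, "candidates": candidates,
            "rule": rule, "confusion": confusion}
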