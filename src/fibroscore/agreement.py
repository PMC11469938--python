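"""Manual-vs-automated agreement: confusion matrices and Cohen's kappa.

Cohen's kappa corrects observed agreement for the agreement expected by
chance from the marginals:

    kappa = (p_o - p_e) / (1 - p_e)

Unweighted kappa treats every disagreement equally; linear and quadratic
weightings penalize ordinal disagreement by its distance on the 0-8
scale, which is often preferred for graded outcomes.  All three are
reported side by side in agreement reports.  Agreement can be evaluated
at tile level (per-tile labels) or at section level (composite scores
rounded to the nearest grade, supplemented by Lin's concordance
correlation on the unrounded values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .labels import CLASS_ORDER, NON_ALVEOLAR, Label, to_code

logger = logging.getLogger(__name__)

WEIGHTINGS = ("none", "linear", "quadratic")


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows = reference (manual), columns = predicted."""

    counts: np.ndarray
    class_order: Tuple[Label, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if c.shape != (k, k):
            raise ValueError("confusion matrix must be K x K for K classes")
        if c.min() < 0:
            raise ValueError("confusion counts must be nonnegative")
        if c.sum() < 1:
            raise ValueError("confusion matrix must count at least one item")
        self.counts = c

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = [str(c) for c in self.class_order]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


@dataclass
class KappaResult:
    """Chance-corrected agreement with its components."""

    kappa: float
    p_o: float
    p_e: float
    weighting: str
    n: int
    degenerate: bool = False


def confusion_matrix(
    reference: Sequence[Label],
    predicted: Sequence[Label],
    class_order: Optional[Sequence[Label]] = None,
) -> ConfusionMatrix:
    """Tally (reference, predicted) label pairs into a fixed-order matrix."""
    if len(reference) != len(predicted):
        raise ValueError("reference and predicted label sequences differ in length")
    if len(reference) == 0:
        raise ValueError("label sequences are empty")
    order = tuple(class_order) if class_order is not None else CLASS_ORDER
    index = {lab: i for i, lab in enumerate(order)}
    k = len(order)
    counts = np.zeros((k, k), dtype=np.int64)
    for r, p in zip(reference, predicted):
        try:
            counts[index[r], index[p]] += 1
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in class order {order}") from None
    return ConfusionMatrix(counts=counts, class_order=order)


def _weight_matrix(k: int, weighting: str) -> np.ndarray:
    i = np.arange(k)
    if weighting == "none":
        return (i[:, None] != i[None, :]).astype(np.float64)
    d = np.abs(i[:, None] - i[None, :]) / max(k - 1, 1)
    if weighting == "linear":
        return d
    if weighting == "quadratic":
        return d**2
    raise ValueError(f"unknown weighting {weighting!r}; expected one of {WEIGHTINGS}")


def cohen_kappa(cm: ConfusionMatrix, weighting: str = "none") -> KappaResult:
    """Cohen's kappa from a confusion matrix, optionally distance-weighted.

    Observed and chance agreement are ``1 - sum(w * p)`` over the observed
    and marginal-product proportion matrices respectively.  For the
    unweighted case this reduces to the familiar diagonal formulas.  The
    degenerate case ``p_e == 1`` (all mass in one cell both observed and
    by chance) is defined as kappa 1 for perfect agreement and 0
    otherwise, flagged ``degenerate``.
    """
    n = cm.n
    p = cm.counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = np.outer(row, col)
    w = _weight_matrix(len(cm.class_order), weighting)
    p_o = float(1.0 - (w * p).sum())
    p_e = float(1.0 - (w * expected).sum())
    if abs(1.0 - p_e) < 1e-15:
        kappa = 1.0 if abs(1.0 - p_o) < 1e-15 else 0.0
        return KappaResult(kappa=kappa, p_o=p_o, p_e=p_e, weighting=weighting, n=n, degenerate=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), p_o=p_o, p_e=p_e, weighting=weighting, n=n)


def lins_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient between paired scores."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need at least two paired values")
    sx, sy = x.var(), y.var()
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    denom = sx + sy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return 1.0
    return float(2 * cov / denom)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)


def agreement_report(
    manual: pd.DataFrame,
    automated: pd.DataFrame,
    level: str = "tile",
    include_non_alveolar: bool = False,
) -> dict:
    """Agreement between a manual and an automated grading table.

    Tile level: tables carry columns ``ident, row, col, label``; rows are
    matched on (ident, row, col) and a confusion matrix plus kappa under
    all three weightings is computed over the matched tile labels.

    Section level: tables carry ``ident, score``; composite scores are
    rounded half-up to the nearest grade for kappa, and Lin's concordance
    correlation on the unrounded scores is reported as a supplement.

    Unmatched rows are dropped with a logged warning; their count is part
    of the report.
    """
    if level not in ("tile", "section"):
        raise ValueError("level must be 'tile' or 'section'")
    keys = ["ident", "row", "col"] if level == "tile" else ["ident"]
    value_col = "label" if level == "tile" else "score"
    for name, df in (("manual", manual), ("automated", automated)):
        missing = [c for c in keys + [value_col] if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table lacks columns {missing}")
    merged = manual.merge(automated, on=keys, suffixes=("_manual", "_auto"))
    n_unmatched = (len(manual) - len(merged)) + (len(automated) - len(merged))
    if len(merged) == 0:
        raise ValueError("no matched idents between manual and automated tables")
    if n_unmatched:
        logger.warning("dropped %d unmatched rows from agreement computation", n_unmatched)

    report: dict = {"level": level, "n_matched": int(len(merged)), "n_unmatched": int(n_unmatched)}
    if level == "tile":
        ref = [_parse_label(v) for v in merged["label_manual"]]
        pred = [_parse_label(v) for v in merged["label_auto"]]
        if not include_non_alveolar:
            keep = [
                i
                for i, (r, p) in enumerate(zip(ref, pred))
                if r != NON_ALVEOLAR and p != NON_ALVEOLAR
            ]
            ref = [ref[i] for i in keep]
            pred = [pred[i] for i in keep]
            order: Tuple[Label, ...] = tuple(range(9))
        else:
            order = CLASS_ORDER
        if len(ref) == 0:
            raise ValueError("no gradable tile pairs after non-alveolar exclusion")
        cm = confusion_matrix(ref, pred, order)
    else:
        man = merged["score_manual"].to_numpy(dtype=np.float64)
        aut = merged["score_auto"].to_numpy(dtype=np.float64)
        ref = list(np.clip(_round_half_up(man), 0, 8))
        pred = list(np.clip(_round_half_up(aut), 0, 8))
        order = tuple(range(9))
        cm = confusion_matrix(ref, pred, order)
        if len(man) >= 2:
            report["concordance_ccc"] = lins_ccc(man, aut)
    report["confusion_matrix"] = cm.counts.tolist()
    report["class_order"] = [str(c) for c in cm.class_order]
    for weighting in WEIGHTINGS:
        k = cohen_kappa(cm, weighting)
        report[f"kappa_{weighting}"] = {
            "kappa": k.kappa,
            "p_o": k.p_o,
            "p_e": k.p_e,
            "n": k.n,
            "degenerate": k.degenerate,
        }
    return report


def _parse_label(v) -> Label:
    if isinstance(v, str) and v.strip().upper() == "NA":
        return NON_ALVEOLAR
    return to_code(int(v)) if int(v) != 9 else NON_ALVEOLAR
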