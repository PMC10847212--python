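"""Agreement mathematics: confusion matrices, mismatch typing, paired tests.

All comparisons operate on the collapsed fuel-type vocabulary (O-1a/O-1b
reported as O-1).  The five named comparison axes bind the four label sources
pairwise: provincial and national maps against the field call (field observed
agreement), the field decision tree against the field call (decision-tree
agreement), the provincial map against the field decision tree (forest
inventory agreement, holding the process constant), and national against
provincial (scaling agreement, 250 m vs 50 m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, PairingError
from .plot_model import COLLAPSED_CODES, PlotLabels, SUITABILITY_CATEGORIES, TraitTable
from .plot_model import CONFIDENCE_LEVELS, collapse_code


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the reported tables)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


# --- confusion matrices -----------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    """Cross-tabulation of predicted vs reference fuel-type labels.

    ``counts[i, j]`` is the number of plots with predicted label i and
    reference label j; overall agreement is trace / n.
    """

    labels: tuple[str, ...]
    counts: np.ndarray
    n: int

    @property
    def agreement(self) -> float:
        return float(np.trace(self.counts)) / self.n if self.n else math.nan

    @property
    def agreement_pct(self) -> float:
        """Overall agreement as a whole percent (half away from zero)."""
        return round_half_away(100.0 * self.agreement)

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix(self.labels, self.counts.T.copy(), self.n)

    def kappa(self) -> float:
        """Cohen's kappa (chance-corrected agreement); an optional extra."""
        if self.n == 0:
            return math.nan
        p = self.counts / self.n
        po = np.trace(p)
        pe = float(p.sum(axis=1) @ p.sum(axis=0))
        if pe == 1.0:
            return math.nan
        return float((po - pe) / (1.0 - pe))

    def to_rows(self) -> list[list]:
        """Serializable rows (header + counts) for delimited-text output."""
        head = ["predicted\\reference", *self.labels]
        body = [[lab, *map(int, row)] for lab, row in zip(self.labels, self.counts)]
        return [head, *body]


def _canonical_order(observed: set[str]) -> tuple[str, ...]:
    return tuple(c for c in COLLAPSED_CODES if c in observed)


def confusion(
    predicted: Sequence[str],
    reference: Sequence[str],
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Build a confusion matrix over the collapsed label vocabulary."""
    if len(predicted) != len(reference):
        raise PairingError(
            f"predicted ({len(predicted)}) and reference ({len(reference)}) differ in length"
        )
    pred = [collapse_code(c) for c in predicted]
    ref = [collapse_code(c) for c in reference]
    if labels is None:
        labs = _canonical_order(set(pred) | set(ref))
    else:
        labs = tuple(collapse_code(c) for c in labels)
    index = {lab: i for i, lab in enumerate(labs)}
    counts = np.zeros((len(labs), len(labs)), dtype=np.int64)
    for p, r in zip(pred, ref):
        counts[index[p], index[r]] += 1
    return ConfusionMatrix(labels=labs, counts=counts, n=len(pred))


def per_type_mismatch(cm: ConfusionMatrix) -> dict[str, tuple[int, int]]:
    """Per predicted type: (mismatch count, percent of that type's plots).

    Percent is 100 * count / row total rounded to the nearest integer.
    Predicted types with no plots are absent from the result (the "-" of the
    reported tables).
    """
    out: dict[str, tuple[int, int]] = {}
    for i, lab in enumerate(cm.labels):
        row_total = int(cm.counts[i].sum())
        if row_total == 0:
            continue
        count = row_total - int(cm.counts[i, i])
        pct = int(round_half_away(100.0 * count / row_total))
        out[lab] = (count, pct)
    return out


def frequent_mismatches(
    cm: ConfusionMatrix, threshold: int = 3
) -> list[tuple[str, str, int]]:
    """Off-diagonal (predicted, reference, count) cells with count >= threshold.

    Sorted by count descending; ties broken lexicographically by the pair.
    """
    cells = [
        (cm.labels[i], cm.labels[j], int(cm.counts[i, j]))
        for i in range(len(cm.labels))
        for j in range(len(cm.labels))
        if i != j and cm.counts[i, j] >= threshold
    ]
    return sorted(cells, key=lambda t: (-t[2], t[0], t[1]))


def mismatch_type(a: str, b: str, traits: TraitTable) -> str:
    """Type a label disagreement: none, structure, composition, or both.

    Codes equal after collapsing the O-1a/O-1b split are "none".  Distinct
    codes whose trait classes tie on both axes (seasonal pairs of one fuel
    type) are reported as a composition mismatch, the finer of the two axes.
    """
    ca, cb = collapse_code(a), collapse_code(b)
    if ca == cb:
        return "none"
    sdiff = traits.structural(ca) != traits.structural(cb)
    cdiff = traits.compositional(ca) != traits.compositional(cb)
    if sdiff and cdiff:
        return "structure_and_composition"
    if sdiff:
        return "structure"
    return "composition"


def vectors_from_mismatch_counts(
    row_totals: Mapping[str, int],
    mismatch_counts: Mapping[str, int],
) -> tuple[list[str], list[str]]:
    """Construct (predicted, reference) vectors realizing summary counts.

    For each predicted type with ``row_totals[t]`` plots, of which
    ``mismatch_counts.get(t, 0)`` disagree with the reference, emits that many
    agreeing pairs (t, t) and mismatching pairs (t, u) with u cycling over the
    other labels.  Any such assignment of mismatch destinations leaves overall
    agreement, per-type mismatch counts, and per-type percentages invariant,
    so published marginal summaries can be re-expanded into vectors and pushed
    back through the confusion-matrix machinery.
    """
    labels = list(row_totals)
    predicted: list[str] = []
    reference: list[str] = []
    for t, total in row_totals.items():
        miss = mismatch_counts.get(t, 0)
        if miss > total:
            raise PairingError(f"type {t}: mismatch count {miss} exceeds row total {total}")
        predicted.extend([t] * total)
        reference.extend([t] * (total - miss))
        others = [u for u in labels if u != t]
        if miss and not others:
            raise PairingError("cannot realize mismatches with a single-label vocabulary")
        reference.extend(others[i % len(others)] for i in range(miss))
    return predicted, reference


# --- comparison axes --------------------------------------------------------


@dataclass(frozen=True)
class ComparisonAxis:
    """A named predicted-vs-reference binding of two label sources."""

    name: str
    predicted: str
    reference: str


#: The five axes of the study design, in reporting order.
DEFAULT_AXES: tuple[ComparisonAxis, ...] = (
    ComparisonAxis("field_observed_provincial", "provincial", "field_assigned"),
    ComparisonAxis("field_observed_national", "national", "field_assigned"),
    ComparisonAxis("field_decision_tree", "field_decision_tree", "field_assigned"),
    ComparisonAxis("forest_inventory", "provincial", "field_decision_tree"),
    ComparisonAxis("scaling", "national", "provincial"),
)


def compute_axes(
    labels: Sequence[PlotLabels],
    axes: Iterable[ComparisonAxis] = DEFAULT_AXES,
    label_set: Sequence[str] | None = None,
) -> dict[str, ConfusionMatrix]:
    """Confusion matrix per comparison axis over a shared label vocabulary."""
    if label_set is None:
        observed = {
            collapse_code(l.source(src))
            for l in labels
            for src in ("field_assigned", "field_decision_tree", "provincial", "national")
        }
        label_set = _canonical_order(observed)
    return {
        ax.name: confusion(
            [l.source(ax.predicted) for l in labels],
            [l.source(ax.reference) for l in labels],
            labels=label_set,
        )
        for ax in axes
    }


# --- suitability and confidence summaries -----------------------------------


def suitability_summary(labels: Iterable[PlotLabels]) -> dict[str, tuple[int, float]]:
    """Counts and one-decimal percents of the four applicability categories."""
    cats = [l.suitability_category for l in labels]
    n = len(cats)
    return {
        c: (cats.count(c), round_half_away(100.0 * cats.count(c) / n, 1) if n else 0.0)
        for c in SUITABILITY_CATEGORIES
    }


def confidence_summary(labels: Iterable[PlotLabels]) -> dict[str, tuple[int, float]]:
    """Counts and one-decimal percents of provincial fuel-typing confidence."""
    levels = [l.confidence for l in labels]
    n = len(levels)
    return {
        c: (levels.count(c), round_half_away(100.0 * levels.count(c) / n, 1) if n else 0.0)
        for c in CONFIDENCE_LEVELS
    }


# --- paired one-sided t-tests ----------------------------------------------


@dataclass(frozen=True)
class PairedTestResult:
    """Paired one-sided t-test of field minus inventory differences."""

    mean_diff: float
    sd_diff: float
    n: int
    t: float
    p_one_sided: float
    direction: str = "greater"

    @property
    def df(self) -> int:
        return self.n - 1


def paired_t_from_summary(
    mean_diff: float, sd_diff: float, n: int, direction: str = "greater"
) -> PairedTestResult:
    """Closed-form paired t from the mean and SD of paired differences.

    t = d-bar / (s / sqrt(n)) on n - 1 degrees of freedom; the one-sided p is
    the upper tail for direction "greater" (field exceeds inventory, i.e.
    inventory underprediction) and the lower tail for "less".
    """
    if n < 2:
        raise DegenerateInputError(f"paired t needs n >= 2, got {n}")
    if sd_diff <= 0:
        raise DegenerateInputError("paired t undefined for zero-variance differences")
    if direction not in ("greater", "less"):
        raise DegenerateInputError(f"unknown direction {direction!r}")
    t = mean_diff / (sd_diff / math.sqrt(n))
    p = stats.t.sf(t, n - 1) if direction == "greater" else stats.t.cdf(t, n - 1)
    return PairedTestResult(
        mean_diff=mean_diff, sd_diff=sd_diff, n=n, t=t, p_one_sided=float(p),
        direction=direction,
    )


def paired_t_one_sided(
    field: Sequence[float], inventory: Sequence[float], direction: str = "greater"
) -> PairedTestResult:
    """Paired one-sided t-test on raw vectors, differencing field - inventory."""
    if len(field) != len(inventory):
        raise PairingError(
            f"field ({len(field)}) and inventory ({len(inventory)}) differ in length"
        )
    d = np.asarray(field, dtype=float) - np.asarray(inventory, dtype=float)
    if len(d) < 2:
        raise DegenerateInputError(f"paired t needs n >= 2, got {len(d)}")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("paired t undefined for zero-variance differences")
    return paired_t_from_summary(float(d.mean()), sd, len(d), direction)


# --- categorical agreement --------------------------------------------------


@dataclass(frozen=True)
class AgreementResult:
    n_agree: int
    n: int
    proportion: float
    percent: int  # nearest whole percent


def categorical_agreement(a: Sequence[str], b: Sequence[str]) -> AgreementResult:
    """Exact-match agreement between two categorical label vectors."""
    if len(a) != len(b):
        raise PairingError(f"vectors differ in length ({len(a)} vs {len(b)})")
    n_agree = sum(x == y for x, y in zip(a, b))
    prop = n_agree / len(a) if a else math.nan
    pct = int(round_half_away(100.0 * prop)) if a else 0
    return AgreementResult(n_agree=n_agree, n=len(a), proportion=prop, percent=pct)
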