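"""Screening-evaluation statistics for biopsy-level classification.

The system under evaluation predicts one of four classes per tissue —
Positive (P), Adenoma (A), Negative (N), Unclassifiable (X) — against a
pathologist ground truth expressed in the Japanese Group Classification
(Group 1 non-neoplastic ... Group 5 carcinoma, Group X inadequate, plus the
non-epithelial lymphoma and carcinoid rows kept separate).

Instead of plain accuracy, performance is summarised by three screening
indices tailored to a double-check quality-control workflow:

* undetected rate of carcinoma = (n(A|G5) + n(N|G5)) / n(G5) x 100
* undetected rate of adenoma   = n(N|G3) / n(G3) x 100
* over-detected proportion     = (n(P|G3) + n(P|G1) + n(A|G1)
                                  + n(X|G3) + n(X|G1)) / n(ALL) x 100

where n(a|b) counts tissues with truth b and prediction a.  G5 is the
Group 5 row alone (lymphoma/carcinoid are separate rows and enter only
n(ALL)).  The over-detected proportion is the fraction of tissues a second
pathologist would have to re-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

TRUTH_ROWS = (
    "Group5",
    "lymphoma",
    "carcinoid",
    "Group4",
    "Group3",
    "Group2",
    "Group1",
    "GroupX",
)
PREDICTION_COLS = ("P", "A", "N", "X")


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero (round-half-up)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Counts n(prediction | truth) over the closed label vocabularies."""

    counts: pd.DataFrame  # index TRUTH_ROWS, columns PREDICTION_COLS

    def __post_init__(self) -> None:
        df = self.counts.reindex(index=list(TRUTH_ROWS), columns=list(PREDICTION_COLS))
        if df.isna().any().any():
            missing = set(self.counts.index) - set(TRUTH_ROWS)
            missing |= set(self.counts.columns) - set(PREDICTION_COLS)
            raise ValueError(f"confusion matrix has unknown or missing labels: {missing or 'NaN cells'}")
        if (df.to_numpy() < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        self.counts = df.astype(int)

    @property
    def n_all(self) -> int:
        return int(self.counts.to_numpy().sum())

    def n(self, prediction: str, truth: str) -> int:
        """n(a|b): tissues with pathologist truth ``truth`` predicted ``prediction``."""
        return int(self.counts.at[truth, prediction])

    def row_total(self, truth: str) -> int:
        return int(self.counts.loc[truth].sum())

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "group"
        out.to_csv(path)


def load_reference_matrix(name: str) -> ConfusionMatrix:
    """Load one of the packaged two-hospital evaluation matrices.

    ``name`` is ``"tokyo"`` or ``"east"`` — the published confusion matrices
    of the two-institution colorectal biopsy screening study this package
    re-implements the pipeline of.
    """
    key = name.lower()
    if key not in ("tokyo", "east"):
        raise ValueError("reference matrix name must be 'tokyo' or 'east'")
    ref = resources.files("coloscreen.data") / f"confusion_{key}.csv"
    with resources.as_file(ref) as p:
        return ConfusionMatrix.from_csv(p)


def build_matrix(truth: list[str], predictions: list[str]) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel truth / prediction lists."""
    if len(truth) != len(predictions):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(predictions)} predictions")
    counts = pd.DataFrame(0, index=list(TRUTH_ROWS), columns=list(PREDICTION_COLS))
    for t, p in zip(truth, predictions):
        if t not in TRUTH_ROWS:
            raise ValueError(f"unknown truth label {t!r}")
        if p not in PREDICTION_COLS:
            raise ValueError(f"unknown prediction label {p!r}")
        counts.at[t, p] += 1
    return ConfusionMatrix(counts)


def undetected_rate_carcinoma(cm: ConfusionMatrix) -> float:
    """Percent of Group 5 (carcinoma) tissues predicted Adenoma or Negative."""
    n_g5 = cm.row_total("Group5")
    if n_g5 == 0:
        raise ZeroDivisionError("no Group5 tissues: undetected carcinoma rate undefined")
    return _round1(100.0 * (cm.n("A", "Group5") + cm.n("N", "Group5")) / n_g5)


def undetected_rate_adenoma(cm: ConfusionMatrix) -> float:
    """Percent of Group 3 (adenoma) tissues predicted Negative."""
    n_g3 = cm.row_total("Group3")
    if n_g3 == 0:
        raise ZeroDivisionError("no Group3 tissues: undetected adenoma rate undefined")
    return _round1(100.0 * cm.n("N", "Group3") / n_g3)


def over_detected_proportion(cm: ConfusionMatrix) -> float:
    """Percent of all tissues flagged for second-pathologist re-check.

    Numerator: Group 3 predicted P or X, plus Group 1 predicted P, A or X.
    Denominator: every tissue, including the lymphoma / carcinoid /
    Group 2 / Group 4 / Group X rows.
    """
    if cm.n_all == 0:
        raise ZeroDivisionError("empty matrix: over-detected proportion undefined")
    num = (
        cm.n("P", "Group3")
        + cm.n("P", "Group1")
        + cm.n("A", "Group1")
        + cm.n("X", "Group3")
        + cm.n("X", "Group1")
    )
    return _round1(100.0 * num / cm.n_all)


@dataclass
class IndexReport:
    """The three screening indices, as percentages in [0, 100].

    An index whose denominator is zero is ``None`` (undefined), never 0.
    """

    undetected_carcinoma_pct: float | None
    undetected_adenoma_pct: float | None
    over_detected_pct: float | None
    n_all: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "undetected_carcinoma_pct": self.undetected_carcinoma_pct,
            "undetected_adenoma_pct": self.undetected_adenoma_pct,
            "over_detected_pct": self.over_detected_pct,
            "n_all": self.n_all,
            "notes": self.notes,
        }


def compute_indices(cm: ConfusionMatrix) -> IndexReport:
    """All three indices; zero-denominator indices reported as undefined."""
    report = IndexReport(None, None, None, n_all=cm.n_all)
    try:
        report.undetected_carcinoma_pct = undetected_rate_carcinoma(cm)
    except ZeroDivisionError:
        report.notes.append("undetected carcinoma rate undefined: no Group5 tissues")
    try:
        report.undetected_adenoma_pct = undetected_rate_adenoma(cm)
    except ZeroDivisionError:
        report.notes.append("undetected adenoma rate undefined: no Group3 tissues")
    try:
        report.over_detected_pct = over_detected_proportion(cm)
    except ZeroDivisionError:
        report.notes.append("over-detected proportion undefined: empty cohort")
    return report


def evaluate_run(
    truth_csv: str | Path,
    predictions_csv: str | Path,
    out_matrix_csv: str | Path | None = None,
    out_report_json: str | Path | None = None,
) -> tuple[ConfusionMatrix, IndexReport]:
    """Join truth and prediction tables on tissue_id, build the matrix, report.

    ``truth_csv`` columns: tissue_id, group; ``predictions_csv`` columns:
    tissue_id, final_class (Positive/Adenoma/Negative/Unclassifiable or the
    short P/A/N/X codes).
    """
    truth = pd.read_csv(truth_csv, dtype=str)
    pred = pd.read_csv(predictions_csv, dtype=str)
    if set(truth["tissue_id"]) != set(pred["tissue_id"]):
        raise ValueError("tissue_id sets of truth and prediction tables differ")
    merged = truth.merge(pred, on="tissue_id", validate="one_to_one")
    long_to_short = {"Positive": "P", "Adenoma": "A", "Negative": "N", "Unclassifiable": "X"}
    preds = [long_to_short.get(c, c) for c in merged["final_class"]]
    cm = build_matrix(list(merged["group"]), preds)
    report = compute_indices(cm)
    if out_matrix_csv is not None:
        cm.to_csv(out_matrix_csv)
    if out_report_json is not None:
        Path(out_report_json).write_text(json.dumps(report.to_dict(), indent=2))
    return cm, report
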