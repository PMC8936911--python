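"""Confusion-matrix containers, validation, and file I/O.

The canonical orientation throughout the package is rows = predicted class,
columns = true class.  Input files using the transposed dialect
(rows = true) are transposed on load.  Cell counts ``n_ij`` are held as
integers; :func:`normalize` produces the maximum-likelihood plug-in
probabilities ``p_ij = n_ij / n`` used by every downstream estimator.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Sequence
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

__all__ = [
    "ConfusionCounts",
    "ProbabilityTable",
    "from_labels",
    "read_matrix",
    "normalize",
    "write_report",
    "read_report",
]

#: probability tables must sum to one within this tolerance
_SUM_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """An r x r table of classification counts, rows = predicted, cols = true.

    Parameters
    ----------
    counts
        Square matrix of nonnegative integers; ``counts[i, j]`` is the number
        of samples predicted as class ``i`` whose true class is ``j``.
    class_labels
        Ordered class identifiers, one per row/column.
    """

    counts: np.ndarray
    class_labels: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise FormatError(
                f"confusion matrix must be square, got shape {counts.shape}"
            )
        if counts.shape[0] < 2:
            raise InputError(
                f"need at least 2 classes, got r={counts.shape[0]}; "
                "pass class_order to supply absent classes"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = np.asarray(counts, dtype=np.int64)
            if not np.array_equal(as_int, counts):
                bad = np.argwhere(np.asarray(counts) != as_int)[0]
                raise FormatError(
                    f"non-integer count at cell ({bad[0]}, {bad[1]})"
                )
            counts = as_int
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at cell ({bad[0]}, {bad[1]})"
            )
        labels = tuple(self.class_labels)
        if len(labels) != counts.shape[0]:
            raise InputError(
                f"{len(labels)} labels for {counts.shape[0]} classes"
            )
        if len(set(labels)) != len(labels):
            raise InputError(f"duplicate class labels in {labels!r}")
        if counts.sum() < 1:
            raise InputError("confusion matrix is empty (n = 0)")
        counts = np.asarray(counts, dtype=np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_labels", labels)

    @property
    def r(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        """Total sample size."""
        return int(self.counts.sum())


@dataclasses.dataclass(frozen=True)
class ProbabilityTable:
    """Cell probabilities p_ij of a multinomial confusion distribution.

    Rows are predicted classes, columns true classes; entries sum to 1.
    Margins ``p_i.`` (row) and ``p_.i`` (column) are recomputed on demand.
    """

    p: np.ndarray
    class_labels: tuple = None

    def __post_init__(self):
        p = np.asarray(self.p, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise FormatError(f"probability table must be square, got {p.shape}")
        if p.shape[0] < 2:
            raise InputError(f"need at least 2 classes, got r={p.shape[0]}")
        if (p < 0).any() or (p > 1).any():
            bad = np.argwhere((p < 0) | (p > 1))[0]
            raise InputError(f"probability outside [0,1] at cell ({bad[0]}, {bad[1]})")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise InputError(f"probabilities sum to {p.sum():.15g}, not 1")
        labels = self.class_labels
        labels = tuple(labels) if labels is not None else tuple(
            f"class_{i + 1}" for i in range(p.shape[0])
        )
        if len(labels) != p.shape[0] or len(set(labels)) != len(labels):
            raise InputError("class_labels must be distinct, one per class")
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "class_labels", labels)

    @classmethod
    def _unchecked(cls, p: np.ndarray, class_labels) -> "ProbabilityTable":
        """Bypass validation (internal; perturbed tables need not sum to 1)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "p", np.asarray(p, dtype=np.float64))
        object.__setattr__(obj, "class_labels", tuple(class_labels))
        return obj

    @property
    def r(self) -> int:
        return self.p.shape[0]

    @property
    def row_margins(self) -> np.ndarray:
        """p_i. — probability of *predicting* class i."""
        return self.p.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        """p_.i — probability that class i is the *true* class."""
        return self.p.sum(axis=0)


def from_labels(
    true_labels: Sequence,
    pred_labels: Sequence,
    class_order: Sequence | None = None,
) -> ConfusionCounts:
    """Tally a confusion matrix from aligned true/predicted label sequences.

    Rows of the result are predicted classes, columns true classes.  The
    class order is ``class_order`` when given, otherwise the sorted union of
    labels observed in either sequence.
    """
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise InputError(
            f"{len(true_labels)} true labels but {len(pred_labels)} predicted"
        )
    if len(true_labels) == 0:
        raise InputError("empty label sequences")
    observed = set(true_labels) | set(pred_labels)
    if class_order is not None:
        labels = list(class_order)
        missing = observed - set(labels)
        if missing:
            raise InputError(
                f"label {sorted(missing, key=repr)[0]!r} not in class_order"
            )
    else:
        labels = sorted(observed)
    index = {lab: k for k, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, q in zip(true_labels, pred_labels):
        counts[index[q], index[t]] += 1
    return ConfusionCounts(counts, tuple(labels))


def read_matrix(
    path: Union[str, Path],
    delimiter: str = "auto",
    has_header_row: bool = False,
    has_label_column: bool = False,
    orientation: str = "rows-predicted",
) -> ConfusionCounts:
    """Read a confusion matrix from a CSV/TSV file.

    Parameters
    ----------
    delimiter
        ``"comma"``, ``"tab"``, or ``"auto"`` (``.tsv`` suffix means tab).
    has_header_row, has_label_column
        Whether the first row / first column carries class labels.  No
        sniffing is done: numeric class labels make auto-detection ambiguous.
    orientation
        ``"rows-predicted"`` (canonical) or ``"rows-true"`` (transposed
        on load).
    """
    path = Path(path)
    if orientation not in ("rows-predicted", "rows-true"):
        raise InputError(f"unknown orientation {orientation!r}")
    if delimiter == "auto":
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    elif delimiter in ("comma", ","):
        sep = ","
    elif delimiter in ("tab", "\t"):
        sep = "\t"
    else:
        raise InputError(f"unknown delimiter {delimiter!r}")

    try:
        df = pd.read_csv(
            path,
            sep=sep,
            header=0 if has_header_row else None,
            index_col=0 if has_label_column else None,
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: not a rectangular table ({exc})") from exc
    if df.shape[0] != df.shape[1]:
        raise FormatError(
            f"{path}: confusion matrix must be square, got "
            f"{df.shape[0]} rows x {df.shape[1]} columns"
        )
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        bad = next(
            (i, j)
            for i in range(body.shape[0])
            for j in range(body.shape[1])
            if not isinstance(body[i, j], (int, float, np.number))
        )
        raise FormatError(f"{path}: non-numeric cell at {bad}")
    if has_header_row:
        labels = tuple(str(c) for c in df.columns)
    elif has_label_column:
        labels = tuple(str(i) for i in df.index)
    else:
        labels = tuple(f"class_{i + 1}" for i in range(df.shape[0]))
    try:
        cc = ConfusionCounts(body, labels)
    except (FormatError, InputError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc
    if orientation == "rows-true":
        cc = ConfusionCounts(cc.counts.T, cc.class_labels)
    return cc


def normalize(counts: ConfusionCounts) -> ProbabilityTable:
    """MLE plug-in probabilities: p_ij = n_ij / n."""
    n = counts.n
    if n < 1:
        raise InputError("cannot normalize an empty table (n = 0)")
    return ProbabilityTable(counts.counts / n, counts.class_labels)


# --- reports -----------------------------------------------------------

_REPORT_FIELDS = (
    "measure",
    "estimate",
    "variance",
    "se",
    "ci_lower",
    "ci_upper",
    "alpha",
    "n",
    "r",
)


def _estimate_record(est) -> dict:
    """Flatten an F1Estimate-like object into the stable report schema."""
    rec = {}
    for field in _REPORT_FIELDS:
        value = getattr(est, field)
        if isinstance(value, (np.floating, np.integer)):
            value = value.item()
        rec[field] = value
    return rec


def write_report(
    estimates: Iterable,
    format: str = "json",
    destination=None,
    extra: dict | None = None,
) -> str:
    """Serialize F1 estimates to JSON or TSV.

    JSON output is a dict with an ``"estimates"`` list (one object per
    measure, fields ``measure, estimate, variance, se, ci_lower, ci_upper,
    alpha, n, r``) plus any ``extra`` provenance keys.  Numbers are written
    at full double precision so a round-trip read reproduces them exactly.

    Returns the rendered text; also writes it to ``destination`` (a path or
    open file) when given.
    """
    records = [_estimate_record(e) for e in estimates]
    if not records:
        raise InputError("no estimates to report")
    if format == "json":
        payload = {"estimates": records}
        if extra:
            payload.update(extra)
        text = json.dumps(payload, indent=2) + "\n"
    elif format == "tsv":
        df = pd.DataFrame.from_records(records, columns=_REPORT_FIELDS)
        text = df.to_csv(sep="\t", index=False, float_format="%.17g")
    else:
        raise InputError(f"unknown report format {format!r}")
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            try:
                Path(destination).write_text(text)
            except OSError as exc:
                raise F1CIIOError(f"cannot write report to {destination}: {exc}") from exc
    return text


class F1CIIOError(OSError):
    """Report destination could not be written."""


def read_report(source) -> list[dict]:
    """Parse a JSON or TSV report back into a list of record dicts."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return json.loads(text)["estimates"]
    import io

    df = pd.read_csv(io.StringIO(text), sep="\t")
    return df.to_dict(orient="records")
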