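"""Core data container and CSV interchange for voice-feature tables.

The package's working currency is the :class:`FeatureMatrix`: an ``n x d``
numeric matrix of biomedical voice measurements with a binary status label
per row (``+1`` = Parkinson's disease, ``-1`` = healthy) and, optionally, a
subject identifier per row (recordings are repeated measurements of the
same speaker, so several rows usually share one subject).

CSV files follow the layout of the Oxford Parkinson's detection table: a
``name`` column carrying the subject/recording identifier, a ``status``
column in ``{0, 1}``, and 22 numeric MDVP/jitter/shimmer/nonlinear feature
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "PARKINSONS_FEATURES",
    "read_voice_csv",
    "write_voice_csv",
    "SvmSwarmError",
    "DimensionMismatch",
    "LengthMismatch",
    "InvalidLabel",
    "InvalidConfig",
    "InvalidMethod",
    "ZeroVarianceColumn",
    "DegenerateCovariance",
    "SingleClassInput",
    "NonPositivePhi",
    "NonFiniteFitness",
    "NoSolution",
    "ClassTooSmall",
    "NoConvergenceWarning",
]


class SvmSwarmError(ValueError):
    """Base class for all svmswarm errors."""


class DimensionMismatch(SvmSwarmError):
    """Feature dimensions of two objects do not agree."""


class LengthMismatch(SvmSwarmError):
    """Two paired vectors have different lengths."""


class InvalidLabel(SvmSwarmError):
    """A label outside {+1, -1} was supplied."""


class InvalidConfig(SvmSwarmError):
    """A configuration value violates its documented constraint."""


class InvalidMethod(SvmSwarmError):
    """Unknown optimizer method name."""


class ZeroVarianceColumn(SvmSwarmError):
    """A feature column is constant; its Z-score is undefined."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"zero-variance column(s): {', '.join(self.columns)}")


class DegenerateCovariance(SvmSwarmError):
    """The covariance matrix has no positive eigenvalue."""


class SingleClassInput(SvmSwarmError):
    """Training data contain only one class."""


class NonPositivePhi(SvmSwarmError):
    """Gaussian kernel width must be strictly positive."""


class NonFiniteFitness(SvmSwarmError):
    """A fitness evaluation returned NaN or infinity."""


class NoSolution(SvmSwarmError):
    """No confusion matrix is consistent with the printed metrics."""


class ClassTooSmall(SvmSwarmError):
    """A class has too few rows to honour the requested split."""


class NoConvergenceWarning(UserWarning):
    """The dual solver hit its update budget before reaching tolerance."""


#: The 22 voice-measurement attribute names of the Oxford Parkinson's table:
#: fundamental-frequency statistics, five jitter measures, six shimmer
#: measures, two noise-to-harmonics ratios, and five nonlinear measures.
PARKINSONS_FEATURES: tuple[str, ...] = (
    "MDVP:Fo(Hz)",
    "MDVP:Fhi(Hz)",
    "MDVP:Flo(Hz)",
    "MDVP:Jitter(%)",
    "MDVP:Jitter(Abs)",
    "MDVP:RAP",
    "MDVP:PPQ",
    "Jitter:DDP",
    "MDVP:Shimmer",
    "MDVP:Shimmer(dB)",
    "Shimmer:APQ3",
    "Shimmer:APQ5",
    "MDVP:APQ",
    "Shimmer:DDA",
    "NHR",
    "HNR",
    "RPDE",
    "D2",
    "DFA",
    "spread1",
    "spread2",
    "PPE",
)


@dataclass
class FeatureMatrix:
    """A labeled numeric feature table.

    Parameters
    ----------
    values : (n, d) ndarray of float
        One row per recording; all entries finite.
    labels : (n,) ndarray of int
        Class labels in ``{+1, -1}``; ``+1`` is the positive (disease) class.
    subject_ids : (n,) ndarray of str, optional
        Subject identifier per row; rows of one subject form a group.
    feature_names : sequence of str, optional
        Column names; defaults to ``f0 .. f{d-1}``.
    """

    values: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SvmSwarmError("values must be a 2-D array")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise SvmSwarmError("need at least one row and one feature")
        if not np.all(np.isfinite(self.values)):
            raise SvmSwarmError("values contain non-finite entries")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (n,):
            raise LengthMismatch(f"labels length {self.labels.shape} != {n}")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise InvalidLabel("labels must be +1 or -1")
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids)
            if self.subject_ids.shape != (n,):
                raise LengthMismatch("subject_ids length mismatch")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(d)]
        elif len(self.feature_names) != d:
            raise LengthMismatch("feature_names length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def take(self, idx: np.ndarray) -> "FeatureMatrix":
        """Row subset as a new FeatureMatrix."""
        return FeatureMatrix(
            values=self.values[idx],
            labels=self.labels[idx],
            subject_ids=None if self.subject_ids is None else self.subject_ids[idx],
            feature_names=list(self.feature_names),
        )

    def with_values(self, values: np.ndarray,
                    feature_names: list[str] | None = None) -> "FeatureMatrix":
        """Same rows (labels, subjects), new feature columns."""
        return FeatureMatrix(
            values=values,
            labels=self.labels,
            subject_ids=self.subject_ids,
            feature_names=feature_names
            if feature_names is not None
            else [f"c{j}" for j in range(values.shape[1])],
        )


def read_voice_csv(path) -> FeatureMatrix:
    """Read a Parkinson's-style CSV into a :class:`FeatureMatrix`.

    Expects a header with a ``name`` subject column, a ``status`` column in
    ``{0, 1}`` (mapped to ``{-1, +1}``) and numeric feature columns
    (comma-delimited, decimal point, UTF-8). The subject identifier is the
    ``name`` value up to its last ``_``-separated token when the name looks
    like ``phon_R01_S01_1`` (recording index suffix), else the full name.
    """
    df = pd.read_csv(path)
    if "status" not in df.columns:
        raise SvmSwarmError("CSV must contain a 'status' column")
    names = df["name"].astype(str) if "name" in df.columns else pd.Series(
        [f"row{i}" for i in range(len(df))]
    )
    subject = names.str.rsplit("_", n=1).str[0].to_numpy()
    feat_cols = [c for c in df.columns if c not in ("name", "status")]
    status = df["status"].to_numpy()
    if not np.all(np.isin(status, (0, 1))):
        raise InvalidLabel("status column must contain only 0 and 1")
    return FeatureMatrix(
        values=df[feat_cols].to_numpy(dtype=float),
        labels=np.where(status == 1, 1, -1),
        subject_ids=subject,
        feature_names=feat_cols,
    )


def write_voice_csv(fm: FeatureMatrix, path) -> None:
    """Write a :class:`FeatureMatrix` in the standard CSV dialect.

    Row names are ``<subject>_<k>`` with ``k`` numbering a subject's
    recordings, so that :func:`read_voice_csv` recovers the subject grouping.
    """
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    if fm.subject_ids is not None:
        counter: dict[str, int] = {}
        names = []
        for sid in fm.subject_ids:
            counter[sid] = counter.get(str(sid), 0) + 1
            names.append(f"{sid}_{counter[str(sid)]}")
        df.insert(0, "name", names)
    else:
        df.insert(0, "name", [f"row_{i}" for i in range(fm.n)])
    df["status"] = (fm.labels == 1).astype(int)
    df.to_csv(path, index=False)
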