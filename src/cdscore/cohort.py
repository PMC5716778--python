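"""Core in-memory containers: expression matrix, clinical table, cohort.

Expression is stored on the *linear* MAS5-style scale (non-negative
fluorescence intensities); any log transform in this package is
display-only, because the differential screen's fold-change filter and the
published per-gene ratios are linear-scale quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: recognized sample class labels
CLASS_LABELS = ("BMPC", "MMC", "HMCL", "unknown")

REQUIRED_CLINICAL = ("os_time", "os_event")
OPTIONAL_SURVIVAL = ("efs_time", "efs_event")


class ExpressionMatrix:
    """Probesets x samples matrix of linear-scale intensities.

    Parameters
    ----------
    values
        DataFrame indexed by probeset ID with sample IDs as columns, or
        anything :func:`pandas.DataFrame` accepts together with
        ``probeset_ids`` / ``sample_ids``.
    """

    def __init__(self, values, probeset_ids=None, sample_ids=None):
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(
                np.asarray(values, dtype=float),
                index=list(probeset_ids),
                columns=list(sample_ids),
            )
        values = values.astype(float)
        self._validate(values)
        self.values: pd.DataFrame = values

    @staticmethod
    def _validate(values: pd.DataFrame) -> None:
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probeset IDs: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        arr = values.to_numpy()
        bad = ~np.isfinite(arr)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite intensity at probeset {values.index[r]!r}, "
                f"sample {values.columns[c]!r}"
            )
        neg = arr < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative intensity {arr[r, c]} at probeset "
                f"{values.index[r]!r}, sample {values.columns[c]!r}"
            )

    @property
    def probeset_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        p, s = self.shape
        return f"<ExpressionMatrix {p} probesets x {s} samples>"

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.values.equals(other.values)


class ClinicalTable:
    """Per-sample clinical annotations: survival endpoints plus arbitrary
    named covariate columns (ISS stage, beta2-microglobulin, t(4;14),
    del17p, precomputed external risk scores...).

    The table is indexed by unique sample ID.  ``os_time``/``os_event``
    are required; ``efs_time``/``efs_event`` are optional; every other
    column is preserved as a covariate.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if table.index.name != "sample_id":
            if "sample_id" in table.columns:
                table = table.set_index("sample_id")
            else:
                raise SchemaError("clinical table requires a 'sample_id' column")
        table.index = table.index.astype(str)
        missing = [c for c in REQUIRED_CLINICAL if c not in table.columns]
        if missing:
            raise SchemaError(f"clinical table missing required columns: {missing}")
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs in clinical table: {dups[:5]}")
        self._validate_survival(table, "os_time", "os_event")
        if ("efs_time" in table.columns) != ("efs_event" in table.columns):
            raise SchemaError("efs_time and efs_event must be given together")
        if "efs_time" in table.columns:
            self._validate_survival(table, "efs_time", "efs_event")
        self.table: pd.DataFrame = table

    @staticmethod
    def _validate_survival(table: pd.DataFrame, tcol: str, ecol: str) -> None:
        t = pd.to_numeric(table[tcol], errors="coerce")
        if t.isna().any() or not np.isfinite(t).all() or (t < 0).any():
            row = table.index[~(np.isfinite(t) & (t >= 0))][0]
            raise ValidationError(f"{tcol} must be finite and >= 0 (sample {row!r})")
        e = pd.to_numeric(table[ecol], errors="coerce")
        ok = e.isin([0, 1])
        if not ok.all():
            row = table.index[~ok][0]
            raise ValidationError(
                f"{ecol} must be 0 or 1 (sample {row!r} has {table.loc[row, ecol]!r})"
            )
        table[tcol] = t.astype(float)
        table[ecol] = e.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def covariate_names(self) -> list[str]:
        skip = set(REQUIRED_CLINICAL) | set(OPTIONAL_SURVIVAL) | {"class_label"}
        return [c for c in self.table.columns if c not in skip]

    @property
    def has_efs(self) -> bool:
        return "efs_time" in self.table.columns

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)].reset_index())

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        return isinstance(other, ClinicalTable) and self.table.equals(other.table)


@dataclass
class AlignmentReport:
    """IDs dropped on either side when intersecting expression and
    clinical sample sets.  Nothing is dropped silently."""

    dropped_expression: list[str] = field(default_factory=list)
    dropped_clinical: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_expression) + len(self.dropped_clinical)


class Cohort:
    """An expression matrix aligned sample-for-sample with a clinical table.

    ``class_labels`` optionally assigns each sample one of
    ``{"BMPC", "MMC", "HMCL", "unknown"}`` (normal plasma cells, malignant
    plasma cells, myeloma cell line).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        clinical: ClinicalTable,
        class_labels: Mapping[str, str] | pd.Series | None = None,
        name: str = "cohort",
        alignment_report: AlignmentReport | None = None,
    ):
        if expression.sample_ids != clinical.sample_ids:
            raise AlignmentError(
                "expression and clinical sample IDs differ in content or order; "
                "use align_cohort() to harmonize them"
            )
        self.expression = expression
        self.clinical = clinical
        self.name = name
        self.alignment_report = alignment_report or AlignmentReport()
        if class_labels is None:
            self.class_labels = pd.Series(
                "unknown", index=expression.values.columns, name="class_label"
            )
        else:
            labels = pd.Series(class_labels).astype(str)
            labels = labels.reindex(expression.sample_ids)
            if labels.isna().any():
                missing = labels.index[labels.isna()].tolist()
                raise ValidationError(f"class label missing for samples {missing[:5]}")
            bad = ~labels.isin(CLASS_LABELS)
            if bad.any():
                raise ValidationError(
                    f"unknown class label {labels[bad].iloc[0]!r}; "
                    f"expected one of {CLASS_LABELS}"
                )
            labels.name = "class_label"
            self.class_labels = labels

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def survival(self, endpoint: str = "os") -> tuple[np.ndarray, np.ndarray]:
        """Return (times, events) for ``endpoint`` in {"os", "efs"}."""
        if endpoint not in ("os", "efs"):
            raise ValueError(f"endpoint must be 'os' or 'efs', got {endpoint!r}")
        if endpoint == "efs" and not self.clinical.has_efs:
            raise SchemaError(f"cohort {self.name!r} has no EFS annotation")
        t = self.clinical.table[f"{endpoint}_time"].to_numpy(dtype=float)
        e = self.clinical.table[f"{endpoint}_event"].to_numpy(dtype=int)
        return t, e

    def samples_with_label(self, label: str) -> list[str]:
        return self.class_labels.index[self.class_labels == label].tolist()

    def expression_vector(self, probeset_id: str) -> np.ndarray:
        if probeset_id not in self.expression.values.index:
            raise KeyError(f"probeset {probeset_id!r} not in cohort {self.name!r}")
        return self.expression.values.loc[probeset_id].to_numpy(dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        p, s = self.expression.shape
        return f"<Cohort {self.name!r}: {s} samples, {p} probesets>"


def align_cohort(
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    class_labels: Mapping[str, str] | pd.Series | None = None,
    name: str = "cohort",
) -> Cohort:
    """Intersect expression and clinical sample IDs into a :class:`Cohort`.

    Sample order follows the expression matrix.  IDs present on only one
    side are recorded in ``cohort.alignment_report`` and logged; an empty
    intersection raises :class:`AlignmentError`.  Aligning an
    already-aligned pair is the identity.
    """
    expr_ids = expression.sample_ids
    clin_ids = set(clinical.sample_ids)
    shared = [s for s in expr_ids if s in clin_ids]
    if not shared:
        raise AlignmentError(
            f"no shared sample IDs between expression ({len(expr_ids)} samples) "
            f"and clinical table ({len(clin_ids)} samples)"
        )
    report = AlignmentReport(
        dropped_expression=[s for s in expr_ids if s not in clin_ids],
        dropped_clinical=[s for s in clinical.sample_ids if s not in set(shared)],
    )
    if report.n_dropped:
        logger.warning(
            "align_cohort(%s): dropped %d expression-only samples %s and "
            "%d clinical-only samples %s",
            name,
            len(report.dropped_expression),
            report.dropped_expression[:5],
            len(report.dropped_clinical),
            report.dropped_clinical[:5],
        )
    expr = expression.subset_samples(shared) if report.dropped_expression else expression
    clin = clinical.subset(shared) if clinical.sample_ids != shared else clinical
    if class_labels is not None:
        class_labels = pd.Series(class_labels).reindex(shared)
    return Cohort(expr, clin, class_labels=class_labels, name=name, alignment_report=report)
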