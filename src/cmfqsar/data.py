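"""Core data containers and CSV IO for activity and descriptor tables.

The activity table holds a compound x cell-line matrix of nonnegative
PKi magnitudes with an observation mask (missing assays are allowed and
are exactly what the factorization model predicts).  The descriptor
table holds a complete compound x feature matrix, e.g. the 28 drug-like
index counts, with an optional quantitative/qualitative tag per feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ActivityTable",
    "DescriptorTable",
    "ValidationError",
    "load_activity_table",
    "load_descriptor_table",
    "align",
    "pki_magnitude",
]

#: tokens accepted as "missing" when reading activity CSVs
MISSING_TOKENS = ("", "NA")

QUANTITATIVE = "quantitative"
QUALITATIVE = "qualitative"


class ValidationError(ValueError):
    """Raised when a table violates its structural contract."""


def _check_unique(ids, what):
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ActivityTable:
    """m x n nonnegative activity matrix with an observation mask.

    Parameters
    ----------
    compound_ids : list of str
        Unique row identifiers.
    cellline_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (m, n)
        Activity magnitudes; entries where ``mask`` is 0 carry no meaning.
    mask : ndarray of shape (m, n)
        1 where the activity was observed, 0 where missing.
    """

    compound_ids: list
    cellline_ids: list
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.compound_ids = list(self.compound_ids)
        self.cellline_ids = list(self.cellline_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask)
        _check_unique(self.compound_ids, "compound")
        _check_unique(self.cellline_ids, "cell-line")
        m, n = len(self.compound_ids), len(self.cellline_ids)
        if self.values.shape != (m, n):
            raise ValidationError(
                f"values shape {self.values.shape} != ({m}, {n})"
            )
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask and values shapes differ")
        self.mask = (self.mask != 0).astype(float)
        obs = self.mask.astype(bool)
        bad = obs & (self.values < 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"negative observed activity at compound "
                f"{self.compound_ids[i]!r}, cell line {self.cellline_ids[j]!r}"
            )
        # unobserved cells carry no meaning; store them as 0 for determinism
        self.values = np.where(obs, self.values, 0.0)

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "ActivityTable":
        return ActivityTable(
            list(self.compound_ids),
            list(self.cellline_ids),
            self.values.copy(),
            self.mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.cellline_ids
        )
        return df.mask(self.mask == 0)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="compound")


@dataclass
class DescriptorTable:
    """Complete m x r descriptor matrix with per-feature kind tags."""

    compound_ids: list
    feature_names: list
    values: np.ndarray
    kinds: list = field(default=None)

    def __post_init__(self):
        self.compound_ids = list(self.compound_ids)
        self.feature_names = list(self.feature_names)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.compound_ids, "compound")
        _check_unique(self.feature_names, "feature")
        m, r = len(self.compound_ids), len(self.feature_names)
        if self.values.shape != (m, r):
            raise ValidationError(
                f"values shape {self.values.shape} != ({m}, {r})"
            )
        if not np.isfinite(self.values).all():
            i, j = map(int, np.argwhere(~np.isfinite(self.values))[0])
            raise ValidationError(
                f"missing/non-finite descriptor at compound "
                f"{self.compound_ids[i]!r}, feature {self.feature_names[j]!r}"
                " (descriptor matrix must be complete)"
            )
        if self.kinds is None:
            self.kinds = [QUANTITATIVE] * r
        self.kinds = list(self.kinds)
        if len(self.kinds) != r:
            raise ValidationError("kinds length != number of features")
        for k in self.kinds:
            if k not in (QUANTITATIVE, QUALITATIVE):
                raise ValidationError(f"unknown feature kind {k!r}")

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "DescriptorTable":
        return DescriptorTable(
            list(self.compound_ids),
            list(self.feature_names),
            self.values.copy(),
            list(self.kinds),
        )

    def to_csv(self, path, kinds_path=None) -> None:
        pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.feature_names
        ).to_csv(path, index_label="compound")
        if kinds_path is not None:
            pd.DataFrame(
                {"feature_name": self.feature_names, "kind": self.kinds}
            ).to_csv(kinds_path, index=False)


def load_activity_table(path, missing_token: str = "NA") -> ActivityTable:
    """Read a compound x cell-line activity CSV.

    Header row holds cell-line ids, first column compound ids.  Cells
    that are empty or equal to ``missing_token`` are treated as missing.
    """
    na = sorted({missing_token, *MISSING_TOKENS})
    df = pd.read_csv(
        path, index_col=0, na_values=na, keep_default_na=False, dtype=str
    )
    raw = df.to_numpy()
    mask = ~pd.isna(raw)
    values = np.zeros(raw.shape, dtype=float)
    for i, j in np.argwhere(mask):
        try:
            values[i, j] = float(raw[i, j])
        except ValueError as exc:
            raise ValidationError(
                f"non-numeric activity {raw[i, j]!r} at compound "
                f"{df.index[i]!r}, cell line {df.columns[j]!r}"
            ) from exc
    return ActivityTable(
        [str(c) for c in df.index],
        [str(c) for c in df.columns],
        values,
        mask.astype(float),
    )


def load_descriptor_table(path, kinds_path=None) -> DescriptorTable:
    """Read a complete compound x feature descriptor CSV.

    ``kinds_path`` is an optional two-column CSV (feature_name, kind)
    mapping features to ``quantitative`` or ``qualitative``; features
    not listed default to quantitative.
    """
    df = pd.read_csv(
        path, index_col=0, na_values=list(MISSING_TOKENS), keep_default_na=False
    )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()
                     & df[col].notna()]
            where = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric descriptor in feature {col!r} "
                f"(compound {where!r})"
            )
    kinds = None
    if kinds_path is not None:
        kdf = pd.read_csv(kinds_path)
        mapping = dict(zip(kdf.iloc[:, 0].astype(str), kdf.iloc[:, 1]))
        kinds = [mapping.get(str(f), QUANTITATIVE) for f in df.columns]
    return DescriptorTable(
        [str(c) for c in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
        kinds,
    )


def align(x: ActivityTable, y: DescriptorTable):
    """Reorder descriptor rows to match the activity table's compound order.

    The activity table's row order is authoritative.  Raises if the two
    compound id sets differ, naming the symmetric difference.
    """
    sx, sy = set(x.compound_ids), set(y.compound_ids)
    if sx != sy:
        diff = sorted(sx.symmetric_difference(sy))
        raise ValidationError(f"compound id sets differ: {diff}")
    pos = {c: i for i, c in enumerate(y.compound_ids)}
    order = [pos[c] for c in x.compound_ids]
    if order == list(range(len(order))):
        return x, y
    return x, DescriptorTable(
        list(x.compound_ids),
        list(y.feature_names),
        y.values[order],
        list(y.kinds),
    )


def pki_magnitude(ic50: float, ligand_conc: float = 0.0, kd: float = 1.0) -> float:
    """Cheng–Prusoff PKi magnitude |−log10(IC50 / (1 + [L]/K_D))|.

    IC50 is converted to an inhibition constant Ki by correcting for the
    competing radioligand concentration [L] relative to its dissociation
    constant K_D, then log-transformed.  The absolute value is taken so
    that the activity matrix is nonnegative, as the factorization requires.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if kd <= 0:
        raise ValueError("kd must be positive")
    if ligand_conc < 0:
        raise ValueError("ligand_conc must be nonnegative")
    return abs(-math.log10(ic50 / (1.0 + ligand_conc / kd)))
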