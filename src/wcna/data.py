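"""Core tabular and spectral data types, readers/writers and preprocessing.

The abundance table is the raw input to every downstream analysis: rows are
samples, columns are named metabolite features, values are concentrations in
arbitrary (non-negative) units.  Traits are categorical per-sample factors
(genotype, genetic background, ripeness class, ...).  A ``SpectrumSet``
holds 1D spectra on a shared ppm axis and can be reduced to an abundance
table by fixed-width binning.

All tables are plain delimited text; the delimiter is inferred from the file
extension (``.csv`` -> comma, anything else -> tab) and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "AbundanceMatrix",
    "TraitTable",
    "ScaledMatrix",
    "SpectrumSet",
    "read_abundance_table",
    "write_abundance_table",
    "read_trait_table",
    "write_trait_table",
    "autoscale",
    "bin_spectrum",
    "read_spectra",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise InputError(f"duplicate {what} id: {i!r}")
        seen.add(i)


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass
class AbundanceMatrix:
    """Samples x features concentration table.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``values``.
    feature_ids : list of str
        Unique feature (metabolite) identifiers, one per column.
    values : ndarray of shape (n_samples, n_features)
        Non-negative, finite concentrations in arbitrary units.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("abundance values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise InputError(
                f"{len(self.sample_ids)} sample ids but {n} rows of values"
            )
        if p != len(self.feature_ids):
            raise InputError(
                f"{len(self.feature_ids)} feature ids but {p} columns of values"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise InputError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise InputError(
                f"negative concentration at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceMatrix":
        return cls(
            sample_ids=[str(i) for i in frame.index],
            feature_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class TraitTable:
    """Per-sample categorical factors (genotype, background, ripeness, ...)."""

    sample_ids: list[str]
    factors: pd.DataFrame  # index = sample ids, columns = factor names, str cells

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        if list(self.factors.index) != list(self.sample_ids):
            self.factors = self.factors.loc[list(self.sample_ids)]
        for col in self.factors.columns:
            levels = self.factors[col]
            bad = levels.isna() | (levels.astype(str).str.strip() == "")
            if bad.any():
                sid = self.factors.index[bad.to_numpy().nonzero()[0][0]]
                raise InputError(
                    f"empty level for factor {col!r} at sample {sid!r}"
                )
        self.factors = self.factors.astype(str)
        self.factors.index.name = "sample_id"

    @property
    def factor_names(self) -> list[str]:
        return [str(c) for c in self.factors.columns]

    def levels(self, factor: str) -> pd.Series:
        if factor not in self.factors.columns:
            raise InputError(
                f"unknown factor {factor!r}; available: {self.factor_names}"
            )
        return self.factors[factor]

    def check_samples(self, sample_ids: Iterable[str]) -> None:
        """Verify every requested sample id is present; error listing any missing."""
        missing = [s for s in sample_ids if s not in set(self.sample_ids)]
        if missing:
            raise InputError(
                "trait table is missing samples: " + ", ".join(map(str, missing))
            )


@dataclass
class ScaledMatrix:
    """Per-feature standardized abundance data (mean 0, sd 1, ddof=1).

    Constant input features cannot be standardized; they are set to all-zero
    and listed in ``constant_features`` so network construction can exclude
    them.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    constant_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise InputError("scaled matrix shape does not match id lists")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(self.values)):
            raise InputError("scaled matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def drop_constant(self) -> "ScaledMatrix":
        """Return a copy without the flagged constant features."""
        if not self.constant_features:
            return self
        keep = [f for f in self.feature_ids if f not in set(self.constant_features)]
        idx = [self.feature_ids.index(f) for f in keep]
        return ScaledMatrix(
            sample_ids=list(self.sample_ids),
            feature_ids=keep,
            values=self.values[:, idx],
            constant_features=[],
        )


@dataclass
class SpectrumSet:
    """1D spectra on a shared, strictly monotone ppm axis."""

    ppm: np.ndarray
    intensities: np.ndarray  # (n_samples, n_points)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.ppm.ndim != 1:
            raise InputError("ppm axis must be 1-D")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InputError("ppm axis must be strictly monotone")
        if self.intensities.shape != (len(self.sample_ids), self.ppm.size):
            raise InputError(
                "intensities must be (n_samples, n_points) aligned to the ppm axis"
            )
        _check_unique(self.sample_ids, "sample")


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    sep = _infer_delimiter(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    cols = header.split(sep)[1:] if header else []
    seen: set[str] = set()
    for c in cols:  # pandas silently mangles duplicate column names
        if c in seen:
            raise InputError(f"duplicate column id: {c!r}")
        seen.add(c)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                            keep_default_na=False, na_values=[])
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty table: {path}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise InputError(f"empty table: {path}")
    return frame


def read_abundance_table(
    path: str | Path, delimiter: str | None = None
) -> AbundanceMatrix:
    """Read a samples x features concentration table.

    The first row holds feature names and the first column sample ids.  The
    numeric body must parse with a dot decimal separator regardless of
    locale; any cell that does not parse (including ``NA``/empty) is an
    error identifying its row and column.
    """
    frame = _read_table(path, delimiter)
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise InputError(f"duplicate sample id: {dup[0]!r}")
    dupc = frame.columns[frame.columns.duplicated()]
    if len(dupc):
        raise InputError(f"duplicate feature id: {dupc[0]!r}")
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = raw[i, j]
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise InputError(
                    f"non-numeric cell {cell!r} at sample "
                    f"{frame.index[i]!r}, feature {frame.columns[j]!r}"
                ) from exc
    return AbundanceMatrix(
        sample_ids=[str(i) for i in frame.index],
        feature_ids=[str(c) for c in frame.columns],
        values=values,
    )


def write_abundance_table(
    m: AbundanceMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write an abundance table at full float precision (round-trip safe)."""
    sep = _infer_delimiter(path, delimiter)
    m.to_frame().to_csv(path, sep=sep, float_format="%.17g",
                        index_label="sample_id")


def read_trait_table(path: str | Path, delimiter: str | None = None) -> TraitTable:
    """Read a sample-id keyed table of categorical factors."""
    frame = _read_table(path, delimiter)
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise InputError(f"duplicate sample id: {dup[0]!r}")
    frame.index = frame.index.map(str)
    return TraitTable(sample_ids=list(frame.index), factors=frame)


def write_trait_table(
    t: TraitTable, path: str | Path, delimiter: str | None = None
) -> None:
    sep = _infer_delimiter(path, delimiter)
    t.factors.to_csv(path, sep=sep, index_label="sample_id")


def read_spectra(
    paths: Sequence[str | Path],
    sample_ids: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> SpectrumSet:
    """Read per-sample two-column (ppm, intensity) files onto a shared axis."""
    if not paths:
        raise InputError("no spectrum files given")
    if sample_ids is None:
        sample_ids = [Path(p).stem for p in paths]
    axis = None
    rows = []
    for p in paths:
        sep = _infer_delimiter(p, delimiter)
        tab = pd.read_csv(p, sep=sep, header=None, comment="#")
        if tab.shape[1] < 2:
            raise InputError(f"spectrum file {p} must have two columns (ppm, intensity)")
        ppm = tab.iloc[:, 0].to_numpy(dtype=float)
        if axis is None:
            axis = ppm
        elif ppm.shape != axis.shape or not np.allclose(ppm, axis):
            raise InputError(f"ppm axis of {p} does not match the first spectrum")
        rows.append(tab.iloc[:, 1].to_numpy(dtype=float))
    return SpectrumSet(ppm=axis, intensities=np.vstack(rows),
                       sample_ids=[str(s) for s in sample_ids])


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def autoscale(m: AbundanceMatrix | ScaledMatrix) -> ScaledMatrix:
    """Standardize each feature to mean 0 and unit sample sd (ddof=1).

    Constant features (zero sample variance) are set to all-zero and flagged
    in ``constant_features`` — their correlation with anything is undefined
    and they must not enter network construction.
    """
    x = np.asarray(m.values, dtype=float)
    if x.shape[0] < 2:
        raise InputError("autoscaling needs at least 2 samples (sd undefined)")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    tol = 1e-12 * np.maximum(1.0, np.abs(mean))
    constant = sd <= tol
    safe_sd = np.where(constant, 1.0, sd)
    scaled = (x - mean) / safe_sd
    scaled[:, constant] = 0.0
    return ScaledMatrix(
        sample_ids=list(m.sample_ids),
        feature_ids=list(m.feature_ids),
        values=scaled,
        constant_features=[f for f, c in zip(m.feature_ids, constant) if c],
    )


def bin_spectrum(
    s: SpectrumSet,
    lo: float,
    hi: float,
    width: float,
    exclusions: Sequence[tuple[float, float]] = (),
    agg: str = "sum",
) -> AbundanceMatrix:
    """Reduce spectra to fixed-width bin features.

    Bins are half-open ``[b, b + width)`` intervals tiling ``[lo, hi)``.
    A bin whose interval intersects any exclusion interval ``[xl, xh)`` is
    dropped entirely.  Each surviving bin becomes one feature, named by its
    center ppm; the per-sample value is the sum (or mean) of the intensity
    points falling inside the bin.  Bins containing no data points get 0.
    """
    if not lo < hi:
        raise InputError(f"need lo < hi, got lo={lo}, hi={hi}")
    if width <= 0:
        raise InputError(f"bin width must be positive, got {width}")
    for xl, xh in exclusions:
        if not (lo <= xl < xh <= hi):
            raise InputError(
                f"exclusion [{xl}, {xh}) must lie within [{lo}, {hi}]"
            )
    if agg not in ("sum", "mean"):
        raise InputError(f"agg must be 'sum' or 'mean', got {agg!r}")

    eps = width * 1e-6
    n_bins = int(np.floor((hi - lo) / width + eps))
    starts = lo + width * np.arange(n_bins)
    ends = starts + width
    keep = np.ones(n_bins, dtype=bool)
    for xl, xh in exclusions:
        # half-open interval intersection test
        keep &= ~((starts < xh - eps) & (ends > xl + eps))
    if not keep.any():
        raise InputError("no bins survive the exclusion intervals")

    idx = np.floor((s.ppm - lo) / width + eps).astype(int)
    in_range = (s.ppm >= lo - eps) & (s.ppm < hi - eps) & (idx >= 0) & (idx < n_bins)

    sums = np.zeros((len(s.sample_ids), n_bins))
    counts = np.zeros(n_bins)
    np.add.at(counts, idx[in_range], 1.0)
    for r in range(len(s.sample_ids)):
        np.add.at(sums[r], idx[in_range], s.intensities[r, in_range])
    if agg == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            sums = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)

    centers = (starts + ends) / 2.0
    feature_ids = [f"ppm_{c:.6g}" for c in centers[keep]]
    return AbundanceMatrix(
        sample_ids=list(s.sample_ids),
        feature_ids=feature_ids,
        values=sums[:, keep],
    )
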