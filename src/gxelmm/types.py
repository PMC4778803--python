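"""Core in-memory containers for GxE mixed-model association studies.

All containers carry an explicit ordered list of sample IDs; every
multi-input operation in the package joins on those IDs rather than on row
position, so file row order never influences a statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "ExposureVector",
    "KinshipMatrix",
    "common_samples",
]

#: canonical missing-dosage marker
MISSING = np.nan

_VARIANT_COLUMNS = ["chrom", "pos", "a1", "a2"]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        dup = dup[dup > 1].index.tolist()
        raise ValueError(f"duplicate {what} IDs: {dup[:5]}")
    return ids


@dataclass
class GenotypeMatrix:
    """n samples x m variants of additively-coded dosages in {0, 1, 2, NaN}.

    ``variants`` is a DataFrame indexed by variant ID with columns
    ``chrom``, ``pos``, ``a1``, ``a2``; dosages count copies of ``a1``.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    validate: bool = True

    def __post_init__(self) -> None:
        self.samples = _check_unique(self.samples, "sample")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError(
                f"dosage rows ({n}) != number of samples ({len(self.samples)})"
            )
        if m != len(self.variants):
            raise ValueError(
                f"dosage columns ({m}) != number of variants ({len(self.variants)})"
            )
        _check_unique(self.variants.index, "variant")
        for col in _VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variant table missing column {col!r}")
        if self.validate:
            vals = self.dosages[~np.isnan(self.dosages)]
            bad = ~np.isin(vals, (0.0, 1.0, 2.0))
            if bad.any():
                raise ValueError(
                    f"dosages must be in {{0,1,2,NaN}}; found {vals[bad][:5]}"
                )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def reindex(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = _positions(self.samples, samples)
        return GenotypeMatrix(
            list(samples), self.variants, self.dosages[idx], validate=False
        )


@dataclass
class PhenotypeVector:
    """A real-valued phenotype per sample; NaN marks missing."""

    samples: list[str]
    values: np.ndarray
    name: str = "phenotype"

    def __post_init__(self) -> None:
        self.samples = _check_unique(self.samples, "sample")
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.samples):
            raise ValueError("phenotype length != number of samples")
        if np.isfinite(self.values).sum() < 2:
            raise ValueError("phenotype needs at least 2 non-missing values")

    def reindex(self, samples: Sequence[str]) -> "PhenotypeVector":
        idx = _positions(self.samples, samples)
        return PhenotypeVector(list(samples), self.values[idx], self.name)


@dataclass
class ExposureVector:
    """Per-sample environmental exposure D, binary {0,1} or continuous."""

    samples: list[str]
    values: np.ndarray
    mode: str = "binary"

    def __post_init__(self) -> None:
        self.samples = _check_unique(self.samples, "sample")
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.samples):
            raise ValueError("exposure length != number of samples")
        if self.mode not in ("binary", "continuous"):
            raise ValueError(f"exposure mode must be binary|continuous, got {self.mode}")
        if self.mode == "binary":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binary exposure must take values in {0, 1}")
        else:
            if not np.isfinite(self.values).all():
                raise ValueError("continuous exposure must be finite")

    @property
    def range(self) -> float:
        return float(np.ptp(self.values))

    def reindex(self, samples: Sequence[str]) -> "ExposureVector":
        idx = _positions(self.samples, samples)
        return ExposureVector(list(samples), self.values[idx], self.mode)


@dataclass
class KinshipMatrix:
    """n x n symmetric relatedness matrix with sample IDs.

    ``role`` distinguishes the genetic relationship matrix K ("genetic")
    from the GxE kinship K^D ("gxe"). Symmetry is always enforced;
    positive semidefiniteness of a genetic-role matrix is checked by
    :meth:`check_psd` (called by readers, not by the constructor, since
    the GRM built in :mod:`gxelmm.kinship` is PSD by construction).
    """

    samples: list[str]
    values: np.ndarray
    role: str = "genetic"

    _SYM_TOL = 1e-8

    def __post_init__(self) -> None:
        self.samples = _check_unique(self.samples, "sample")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kinship shape {self.values.shape} != ({n}, {n}) for {n} samples"
            )
        if self.role not in ("genetic", "gxe"):
            raise ValueError(f"kinship role must be genetic|gxe, got {self.role}")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        scale = max(1.0, np.abs(self.values).max(initial=0.0))
        if asym > self._SYM_TOL * scale:
            raise ValueError(f"kinship matrix asymmetric (max |K - K'| = {asym:g})")
        # enforce exact symmetry so downstream factorizations are stable
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def check_psd(self, rtol: float = 1e-8) -> None:
        """Raise if the smallest eigenvalue is below -rtol * largest."""
        w = np.linalg.eigvalsh(self.values)
        if w[0] < -rtol * max(w[-1], 1.0):
            raise ValueError(
                f"kinship not positive semidefinite (eigenvalues in [{w[0]:g}, {w[-1]:g}])"
            )

    def reindex(self, samples: Sequence[str]) -> "KinshipMatrix":
        idx = _positions(self.samples, samples)
        return KinshipMatrix(list(samples), self.values[np.ix_(idx, idx)], self.role)


def _positions(have: Sequence[str], want: Sequence[str]) -> np.ndarray:
    pos = {s: i for i, s in enumerate(have)}
    try:
        return np.array([pos[str(s)] for s in want], dtype=int)
    except KeyError as e:
        raise KeyError(f"sample {e.args[0]!r} not present") from None


def common_samples(*objects) -> list[str]:
    """Sample IDs shared by all inputs, ordered as in the first input.

    Raises if the intersection is empty. This is the join rule used by
    every multi-input operation in the package.
    """
    if not objects:
        raise ValueError("no objects given")
    ids = [s for s in objects[0].samples]
    for obj in objects[1:]:
        present = set(obj.samples)
        ids = [s for s in ids if s in present]
    if not ids:
        raise ValueError("no samples shared by all inputs")
    return ids


def aligned(*objects):
    """Reindex all inputs to their common samples; returns a tuple."""
    ids = common_samples(*objects)
    return tuple(obj.reindex(ids) for obj in objects)
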