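"""Physicochemical auto-covariance (AC) sequence features.

Each residue is encoded as its row in a 20-amino-acid scale table (14 scales
by default: hydrophilicity, flexibility, accessibility, turn propensity,
exposed surface, polarizability, antigenic propensity, hydrophobicity on two
scales, net charge index, polarity on two scales, solvent-accessible surface
area and side-chain volume). A protein of length L becomes an L x k signal
matrix; the lag-g auto-covariance of scale l,

    AC[l, g] = (1 / (L - g)) * sum_{m=1..L-g} (P[l, m] - mean_l) * (P[l, m+g] - mean_l)

with ``mean_l`` the full-length scale mean, compresses it to a fixed k*G
vector (gap g = 1..G, default G = 2, so 14 x 2 = 28 values per protein).
Training-set AC columns are z-scored (sample SD, n-1) and then min-max
scaled to [0, 1]; the fitted statistics are reused on held-out proteins with
clipping. A pair is the concatenation of its two scaled AC vectors in
canonical pair order (56 values with defaults).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_GAP_MAX = 2


class ScaleTable:
    """A residue-by-scale value table (rows: 20 amino acids, columns: named scales)."""

    def __init__(self, values: pd.DataFrame):
        if values.shape[0] != 20:
            raise ValueError(f"scale table must have exactly 20 rows, got {values.shape[0]}")
        if values.shape[1] < 1:
            raise ValueError("scale table needs at least one scale column")
        if values.isna().any().any():
            raise ValueError("scale table contains missing values")
        if len(set(values.columns)) != values.shape[1]:
            raise ValueError("scale table column names must be unique")
        self.values = values.astype(float)
        self._rows = {aa: values.loc[aa].to_numpy(dtype=float) for aa in values.index}

    @property
    def k(self) -> int:
        """Number of scales."""
        return self.values.shape[1]

    @property
    def scale_names(self) -> list[str]:
        return list(self.values.columns)

    def row(self, residue: str) -> np.ndarray:
        try:
            return self._rows[residue]
        except KeyError:
            raise KeyError(f"residue {residue!r} not in scale table") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScaleTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df)

    @classmethod
    def bundled(cls) -> "ScaleTable":
        """The packaged 20 x 14 table assembled from standard published indices."""
        with resources.files("ppifuse.data").joinpath("scale_table.csv").open() as fh:
            df = pd.read_csv(fh, index_col=0)
        return cls(df)


def residue_encode(protein, scales: ScaleTable) -> np.ndarray:
    """Encode a protein as an L x k matrix of per-residue scale values.

    ``protein`` may be a :class:`~ppifuse.io_formats.ProteinRecord` or a
    plain sequence string.
    """
    sequence = getattr(protein, "sequence", protein)
    name = getattr(protein, "id", "<sequence>")
    out = np.empty((len(sequence), scales.k))
    for i, residue in enumerate(sequence):
        try:
            out[i] = scales.row(residue)
        except KeyError:
            raise ValueError(
                f"protein {name}: residue {residue!r} at position {i + 1} not in scale table"
            ) from None
    return out


def auto_covariance(encoded: np.ndarray, gap_max: int = DEFAULT_GAP_MAX) -> np.ndarray:
    """Raw AC vector of length k * gap_max, ordered scale-major (l outer, g inner)."""
    if gap_max < 1:
        raise ValueError("gap_max must be >= 1")
    length, k = encoded.shape
    if length <= gap_max:
        raise ValueError(
            f"sequence length {length} must exceed the maximum gap {gap_max}"
        )
    centered = encoded - encoded.mean(axis=0, keepdims=True)
    out = np.empty((k, gap_max))
    for g in range(1, gap_max + 1):
        out[:, g - 1] = (centered[:-g] * centered[g:]).sum(axis=0) / (length - g)
    return out.ravel()


def ac_matrix(proteins: Sequence, scales: ScaleTable, gap_max: int = DEFAULT_GAP_MAX) -> np.ndarray:
    """Stack raw AC vectors for a collection of proteins (rows follow input order)."""
    return np.vstack([auto_covariance(residue_encode(p, scales), gap_max) for p in proteins])


class ACScaler:
    """Two-step per-column scaling fitted on a training AC matrix.

    Columns are z-scored with the training mean and sample (n-1) SD, then
    min-max scaled to [0, 1] using the training extrema of the z-scores.
    Held-out values are clipped to [0, 1]; zero-SD columns map to constant 0.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None
        self.zmin_: np.ndarray | None = None
        self.zmax_: np.ndarray | None = None

    def fit(self, raw: np.ndarray) -> "ACScaler":
        raw = np.asarray(raw, dtype=float)
        if raw.ndim != 2 or raw.shape[0] < 2:
            raise ValueError("fitting requires a 2-D matrix with at least 2 rows")
        self.mean_ = raw.mean(axis=0)
        self.sd_ = raw.std(axis=0, ddof=1)
        if np.any(self.sd_ == 0):
            log.warning(
                "%d zero-variance AC columns mapped to constant 0", int((self.sd_ == 0).sum())
            )
        z = self._zscore(raw)
        self.zmin_ = z.min(axis=0)
        self.zmax_ = z.max(axis=0)
        return self

    def _zscore(self, raw: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd_ == 0, 1.0, self.sd_)
        z = (raw - self.mean_) / sd
        z[:, self.sd_ == 0] = 0.0
        return z

    def transform(self, raw: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler is not fitted")
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        z = self._zscore(raw)
        span = self.zmax_ - self.zmin_
        safe_span = np.where(span == 0, 1.0, span)
        scaled = (z - self.zmin_) / safe_span
        scaled[:, span == 0] = 0.0
        return np.clip(scaled, 0.0, 1.0)

    def fit_transform(self, raw: np.ndarray) -> np.ndarray:
        return self.fit(raw).transform(raw)


def pair_feature(ac_u: np.ndarray, ac_v: np.ndarray) -> np.ndarray:
    """Concatenate two scaled per-protein AC vectors (canonical pair order)."""
    ac_u = np.asarray(ac_u, dtype=float).ravel()
    ac_v = np.asarray(ac_v, dtype=float).ravel()
    if ac_u.shape != ac_v.shape:
        raise ValueError(f"AC vector length mismatch: {ac_u.shape[0]} vs {ac_v.shape[0]}")
    return np.concatenate([ac_u, ac_v])
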