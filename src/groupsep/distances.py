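"""Pairwise distance matrices: genetic (p-distance, JC69, K2P) and geographic.

Genetic distances use pairwise deletion: an alignment column enters a
pair's comparison only if both strains carry an unambiguous base
(A/C/G/T) there.  Gaps and IUPAC ambiguity codes are excluded from the
comparable-site count, and a pair with zero comparable sites is an
error, never a silent zero.

Geographic distances are great-circle (haversine) kilometres on a
spherical Earth of radius 6371 km.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import ConcatenateAlignment, LocusAlignment, StrainMetadata

EARTH_RADIUS_KM = 6371.0

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINE = (0, 2)  # A, G

GENETIC_MODELS = ("p_distance", "jc69", "k2p")


class DistanceError(ValueError):
    """Raised when a distance is undefined (no comparable sites, saturation)."""


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    kind: str
    comparable_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, strain_id: str) -> int:
        return self.ids.index(strain_id)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) entries in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(s) for s in ids]
        comp = (
            self.comparable_sites[np.ix_(idx, idx)]
            if self.comparable_sites is not None
            else None
        )
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind, comp)


def encode_alignment(aln: LocusAlignment | ConcatenateAlignment) -> tuple[list[str], np.ndarray]:
    """Encode sequences as a (n_strains, n_columns) uint8 matrix.

    A/C/G/T -> 0..3; gaps, N and ambiguity codes -> 255 (not comparable).
    """
    ids = list(aln.sequences)
    lut = np.full(256, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        lut[ord(base)] = code
    rows = [
        lut[np.frombuffer(aln.sequences[sid].encode("ascii"), dtype=np.uint8)]
        for sid in ids
    ]
    return ids, np.vstack(rows)


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Proportion of differing sites among pairwise-comparable columns.

    Returns ``(distance, n_compared)``.  Raises :class:`DistanceError`
    when no column is comparable.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    xa = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        lut[ord(base)] = code
    ca, cb = lut[xa], lut[xb]
    comparable = (ca != 255) & (cb != 255)
    n = int(comparable.sum())
    if n == 0:
        raise DistanceError("no comparable sites")
    mismatches = int(((ca != cb) & comparable).sum())
    return mismatches / n, n


def jc69_correct(p: float) -> float:
    """Jukes–Cantor distance −(3/4)·ln(1 − 4p/3)."""
    if p >= 0.75:
        raise DistanceError(f"saturation: JC69 correction undefined at p={p}")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k2p_correct(p_transition: float, p_transversion: float) -> float:
    """Kimura two-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p_transition - p_transversion
    w2 = 1.0 - 2.0 * p_transversion
    if w1 <= 0 or w2 <= 0:
        raise DistanceError(
            f"saturation: K2P correction undefined at P={p_transition}, Q={p_transversion}"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _pairwise_counts(X: np.ndarray, i: int, j: int) -> tuple[int, int, int]:
    """(n_comparable, n_transitions, n_transversions) for rows i, j."""
    a, b = X[i], X[j]
    comparable = (a != 255) & (b != 255)
    diff = (a != b) & comparable
    both_purine = np.isin(a, _PURINE) & np.isin(b, _PURINE)
    both_pyrim = ~np.isin(a, _PURINE) & ~np.isin(b, _PURINE)
    ts = diff & (both_purine | both_pyrim)
    n = int(comparable.sum())
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return n, n_ts, n_tv


def distance_matrix(
    aln: LocusAlignment | ConcatenateAlignment, model: str = "p_distance"
) -> DistanceMatrix:
    """All-pairs genetic distances under ``p_distance``, ``jc69`` or ``k2p``."""
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {GENETIC_MODELS}")
    ids, X = encode_alignment(aln)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 strains")
    vals = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        comp[i, i] = X.shape[1]
        for j in range(i + 1, n):
            nc, n_ts, n_tv = _pairwise_counts(X, i, j)
            if nc == 0:
                raise DistanceError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            p = (n_ts + n_tv) / nc
            if model == "p_distance":
                d = p
            elif model == "jc69":
                try:
                    d = jc69_correct(p)
                except DistanceError as e:
                    raise DistanceError(f"{ids[i]!r} vs {ids[j]!r}: {e}") from e
            else:
                try:
                    d = k2p_correct(n_ts / nc, n_tv / nc)
                except DistanceError as e:
                    raise DistanceError(f"{ids[i]!r} vs {ids[j]!r}: {e}") from e
            vals[i, j] = vals[j, i] = d
            comp[i, j] = comp[j, i] = nc
    return DistanceMatrix(ids, vals, model, comp)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres, spherical Earth R=6371 km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geographic_matrix(meta: Sequence[StrainMetadata]) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between strain sampling sites."""
    missing = [m.strain_id for m in meta if m.latitude is None or m.longitude is None]
    if missing:
        raise ValueError(f"strains without coordinates: {missing}")
    ids = [m.strain_id for m in meta]
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(
                meta[i].latitude, meta[i].longitude, meta[j].latitude, meta[j].longitude
            )
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids, vals, "geographic_km")


def write_matrix_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path, kind: str = "p_distance") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(float), kind)


def write_matrix_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square format, for cross-validation with external NJ tools."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for sid, row in zip(dm.ids, dm.values):
            fh.write(sid[:10].ljust(10) + "  " + "  ".join(f"{v:.8f}" for v in row) + "\n")
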