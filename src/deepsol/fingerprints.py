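"""881-bit PubChem substructure fingerprints: data model and descriptor I/O.

Each compound is encoded as a fixed-length binary vector of 881 bits, one
per predefined chemical substructure key.  The bit definitions themselves
are an external standard computed by descriptor tools (e.g. PaDEL); this
module reads and writes the descriptor-CSV dialect those tools emit
(header ``Name,PubchemFP0,...,PubchemFP880``) and aligns fingerprints with
curated solubility records into a model-ready feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import CuratedDataset

__all__ = [
    "N_BITS",
    "FingerprintVector",
    "FeatureMatrix",
    "read_descriptor_csv",
    "write_descriptor_csv",
    "align_features",
]

N_BITS = 881
_HEADER = ["Name"] + [f"PubchemFP{i}" for i in range(N_BITS)]


@dataclass(frozen=True)
class FingerprintVector:
    """One compound's 881-bit substructure vector.

    The length-881 / binary invariants are enforced at construction; an
    object violating them cannot exist.
    """

    compound_id: str
    bits: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits)
        if arr.shape != (N_BITS,):
            raise ValueError(f"fingerprint must have exactly {N_BITS} bits, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("fingerprint bits must all be 0 or 1")
        object.__setattr__(self, "bits", arr.astype(np.uint8))

    def __len__(self) -> int:
        return N_BITS


@dataclass
class FeatureMatrix:
    """Aligned fingerprints (X) and logS targets (y), sorted by compound id.

    ``molecular_weight`` rides along when available so that category-level
    evaluation can convert predictions back to g/L.
    """

    compound_ids: np.ndarray
    X: np.ndarray           # (n, 881) uint8
    y: np.ndarray           # (n,) float
    molecular_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.compound_ids = np.asarray(self.compound_ids, dtype=object)
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.compound_ids)
        if self.X.shape[0] != n or self.y.shape[0] != n:
            raise ValueError("compound_ids, X and y must agree in length")
        if self.molecular_weight is not None:
            self.molecular_weight = np.asarray(self.molecular_weight, dtype=float)
            if self.molecular_weight.shape[0] != n:
                raise ValueError("molecular_weight length mismatch")

    @property
    def n(self) -> int:
        return int(self.X.shape[0])

    def subset(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        mw = None if self.molecular_weight is None else self.molecular_weight[idx]
        return FeatureMatrix(self.compound_ids[idx], self.X[idx], self.y[idx], mw)


class DescriptorDialectError(ValueError):
    """Raised when a descriptor CSV does not match the expected layout."""


def read_descriptor_csv(path: str | Path) -> list[FingerprintVector]:
    """Read fingerprints from a descriptor CSV (PaDEL dialect).

    The file must have a ``Name`` id column followed by exactly 881 binary
    feature columns in bit order 0..880.  A wrong column count raises a
    dialect error naming expected vs found; a non-binary cell raises a parse
    error with row/column coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] != N_BITS + 1:
        raise DescriptorDialectError(
            f"{path}: expected 1 id column + {N_BITS} feature columns, found {df.shape[1]} columns"
        )
    ids = df.iloc[:, 0].astype(str).to_numpy()
    try:
        mat = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise DescriptorDialectError(f"{path}: non-numeric fingerprint cell ({exc})") from None
    bad = ~np.isin(mat, (0.0, 1.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DescriptorDialectError(
            f"{path}: non-binary value {mat[r, c]!r} at data row {r}, column {df.columns[c + 1]}"
        )
    return [FingerprintVector(cid, row) for cid, row in zip(ids, mat.astype(np.uint8))]


def write_descriptor_csv(path: str | Path, fingerprints: list[FingerprintVector]) -> None:
    """Write fingerprints in the same descriptor-CSV dialect (round-trips bit-exactly)."""
    mat = np.stack([fp.bits for fp in fingerprints]) if fingerprints else np.empty((0, N_BITS), np.uint8)
    df = pd.DataFrame(mat, columns=_HEADER[1:])
    df.insert(0, "Name", [fp.compound_id for fp in fingerprints])
    df.to_csv(path, index=False)


class AlignmentError(ValueError):
    """Raised when curated records lack matching fingerprints (all listed)."""

    def __init__(self, missing_ids: list[str]):
        self.missing_ids = list(missing_ids)
        super().__init__(
            f"{len(missing_ids)} record(s) have no fingerprint: {', '.join(map(str, missing_ids))}"
        )


def align_features(
    fingerprints: list[FingerprintVector],
    dataset: CuratedDataset,
) -> FeatureMatrix:
    """Join fingerprints with curated logS targets by compound id.

    Only valid, non-censored records enter the matrix.  Rows are sorted by
    compound id so the output is invariant to the input ordering of either
    argument.  Missing fingerprints are reported exhaustively.
    """
    by_id = {fp.compound_id: fp for fp in fingerprints}
    records = sorted(dataset.modeling_records, key=lambda r: r.compound_id)
    missing = [r.compound_id for r in records if r.compound_id not in by_id]
    if missing:
        raise AlignmentError(missing)
    X = np.stack([by_id[r.compound_id].bits for r in records]) if records else np.empty((0, N_BITS), np.uint8)
    y = np.array([r.log_s for r in records], dtype=float)
    ids = np.array([r.compound_id for r in records], dtype=object)
    mw_vals = [r.molecular_weight for r in records]
    mw = np.array(mw_vals, dtype=float) if all(m is not None for m in mw_vals) and records else None
    return FeatureMatrix(ids, X, y, mw)
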