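"""Synthetic fingerprint datasets with a planted, recoverable mechanism.

Real solubility data pair 881-bit substructure fingerprints with logS
values; the statistical structure the regression models assume is that
substructures contribute additively (with possible pairwise combinations)
to logS.  The generator plants exactly that mechanism:

    logS_i = intercept + sum_j w_j b_ij + sum_(j,k) w_jk b_ij b_ik + eps_i,
    eps_i ~ Normal(0, noise_sd^2),

over Bernoulli fingerprint bits with optional block correlation (adjacent
bits co-occur, as real substructure keys do).  Because the ground truth is
known, recovery is checkable: with zero noise an OLS fit on the active bits
reproduces the planted weights, and a trained network's held-out R^2 has an
analytic ceiling Var(signal) / (Var(signal) + noise_sd^2).

Everything is seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import CompoundRecord, CuratedDataset, SolubilityUnit
from .fingerprints import N_BITS, FeatureMatrix, FingerprintVector, write_descriptor_csv

__all__ = ["SyntheticGroundTruth", "generate_dataset", "generate_fixture_tables"]


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Planted bit-weight function and noise level."""

    bit_weights: np.ndarray                 # (881,), sparse
    intercept: float = -3.0
    pairwise_terms: tuple[tuple[int, int, float], ...] = ()
    noise_sd: float = 0.3
    bit_density: float = 0.15
    seed: int = 0
    block_correlation: float = 0.5          # probability a bit copies its block's draw
    block_size: int = 4

    def __post_init__(self):
        w = np.asarray(self.bit_weights, dtype=float)
        if w.shape != (N_BITS,):
            raise ValueError(f"bit_weights must have shape ({N_BITS},)")
        object.__setattr__(self, "bit_weights", w)
        if not 0.0 < self.bit_density < 1.0:
            raise ValueError("bit_density must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.block_correlation <= 1.0:
            raise ValueError("block_correlation must be in [0, 1]")

    @property
    def active_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bit_weights)

    @classmethod
    def random(cls, k_active: int = 40, seed: int = 0, noise_sd: float = 0.3,
               bit_density: float = 0.15, weight_scale: float = 1.0,
               intercept: float = -3.0, n_pairwise: int = 0,
               pairwise_scale: float = 0.5,
               block_correlation: float = 0.5) -> "SyntheticGroundTruth":
        """Draw a random truth: k active bits with U(-scale, scale) weights,
        plus optional pairwise interaction terms between active bits."""
        if not 1 <= k_active <= N_BITS:
            raise ValueError("k_active must be in 1..881")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 881]))
        active = rng.choice(N_BITS, size=k_active, replace=False)
        w = np.zeros(N_BITS)
        w[active] = rng.uniform(-weight_scale, weight_scale, size=k_active)
        pairs: list[tuple[int, int, float]] = []
        for _ in range(n_pairwise):
            i, j = rng.choice(active, size=2, replace=False)
            pairs.append((int(i), int(j), float(rng.uniform(-pairwise_scale, pairwise_scale))))
        return cls(bit_weights=w, intercept=intercept, pairwise_terms=tuple(pairs),
                   noise_sd=noise_sd, bit_density=bit_density, seed=seed,
                   block_correlation=block_correlation)

    def signal(self, X: np.ndarray) -> np.ndarray:
        """Noise-free logS for a bit matrix (before clipping)."""
        s = self.intercept + X @ self.bit_weights
        for i, j, w in self.pairwise_terms:
            s = s + w * X[:, i] * X[:, j]
        return s

    def to_dict(self) -> dict:
        active = self.active_bits
        return {
            "intercept": self.intercept,
            "active_bits": active.tolist(),
            "active_weights": self.bit_weights[active].tolist(),
            "pairwise_terms": [list(t) for t in self.pairwise_terms],
            "noise_sd": self.noise_sd,
            "bit_density": self.bit_density,
            "seed": self.seed,
            "block_correlation": self.block_correlation,
            "block_size": self.block_size,
        }


def _draw_bits(rng: np.random.Generator, n: int, truth: SyntheticGroundTruth) -> np.ndarray:
    """Bernoulli(bit_density) bits; with block correlation a bit copies a
    per-block shared draw with probability ``block_correlation``, which keeps
    the marginal density exact while correlating adjacent bits."""
    p = truth.bit_density
    ind = rng.random((n, N_BITS)) < p
    if truth.block_correlation == 0.0:
        return ind.astype(np.uint8)
    n_blocks = math.ceil(N_BITS / truth.block_size)
    shared = rng.random((n, n_blocks)) < p
    shared_full = np.repeat(shared, truth.block_size, axis=1)[:, :N_BITS]
    copy_mask = rng.random((n, N_BITS)) < truth.block_correlation
    return np.where(copy_mask, shared_full, ind).astype(np.uint8)


def generate_dataset(
    n: int,
    truth: SyntheticGroundTruth,
    clip_range: tuple[float, float] | None = (-10.0, 1.0),
    mw_range: tuple[float, float] = (150.0, 600.0),
) -> tuple[FeatureMatrix, CuratedDataset]:
    """Sample n synthetic compounds from the planted mechanism.

    Emitted logS is clipped to a plausible range (pass ``clip_range=None``
    to disable); molecular weights are drawn uniformly so category-level
    metrics are exercised.  Fully deterministic for a fixed truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 17, n]))
    X = _draw_bits(rng, n, truth)
    y = truth.signal(X)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=n)
    if clip_range is not None:
        y = np.clip(y, *clip_range)
    mw = rng.uniform(*mw_range, size=n)

    width = max(5, len(str(n)))
    ids = np.array([f"SYN{i:0{width}d}" for i in range(n)], dtype=object)
    ds = CuratedDataset()
    ds.log("synthetic", "generate", n=n, seed=truth.seed, noise_sd=truth.noise_sd)
    for i in range(n):
        ds.records.append(
            CompoundRecord(
                compound_id=str(ids[i]),
                smiles="",
                solubility_value=float(10.0 ** y[i]),
                solubility_unit=SolubilityUnit.MOL_PER_L,
                molecular_weight=float(mw[i]),
                log_s=float(y[i]),
            )
        )
    fm = FeatureMatrix(ids, X, y.astype(float), mw)
    return fm, ds


# -- fixed end-to-end fixture -------------------------------------------------

# (id, smiles, solubility, unit); "<value" marks a censored entry.
_FIXTURE_ROWS = [
    ("CPD01", "CCO", "50", "mg/mL"),                                  # ethanol
    ("CPD02", "c1ccccc1", "1.79", "g/L"),                             # benzene
    ("CPD03", "CC(=O)Oc1ccccc1C(=O)O", "3", "mg/mL"),                 # aspirin
    ("CPD04", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "21.6", "g/L"),           # caffeine
    ("CPD05", "Oc1ccccc1", "83", "g/L"),                              # phenol
    ("CPD06", "Cc1ccccc1", "526", "mg/L"),                            # toluene
    ("CPD07", "CC(C)=O", "1000", "mg/mL"),                            # acetone
    ("CPD08", "CC(=O)O", "400", "g/L"),                               # acetic acid
    ("CPD09", "c1ccc2ccccc2c1", "31", "mg/L"),                        # naphthalene
    ("CPD10", "Nc1ccccc1", "36", "g/L"),                              # aniline
    ("CPD11", "c1ccncc1", "500", "g/L"),                              # pyridine
    ("CPD12", "C1CCCCC1", "55", "mg/L"),                              # cyclohexane
    ("CPD13", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O", "909", "g/L"),  # glucose
    ("CPD14", "NC(N)=O", "545", "g/L"),                               # urea
    ("CPD15", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "21", "ug/mL"),           # ibuprofen
    ("CPD16", "CC(=O)Nc1ccc(O)cc1", "14", "mg/mL"),                   # paracetamol
    ("CPD17", "NCC(=O)O", "249", "g/L"),                              # glycine
    ("CPD18", "CN1CCC[C@H]1c1cccnc1", "<0.01", "mg/mL"),              # censored entry
    ("CPD19", "OCC", "45", "mg/mL"),                                  # ethanol again (duplicate)
    ("CPD20", "C1CC", "10", "mg/L"),                                  # malformed SMILES (unclosed ring)
]


def generate_fixture_tables(directory: str | Path) -> tuple[Path, Path]:
    """Write the fixed 20-row smoke-test fixture.

    The raw compound table mixes units and contains one duplicate structure
    pair, one censored row and one malformed SMILES, so full curation yields
    exactly 18 valid records (17 with logS + 1 censored).  A matching
    descriptor CSV provides seeded 881-bit fingerprints for every id.
    Re-generation is byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    compounds_path = directory / "fixture_compounds.csv"
    fp_path = directory / "fixture_fingerprints.csv"

    df = pd.DataFrame(_FIXTURE_ROWS, columns=["id", "smiles", "solubility", "unit"])
    df.to_csv(compounds_path, index=False)

    rng = np.random.default_rng(20230881)
    fps = [
        FingerprintVector(cid, (rng.random(N_BITS) < 0.15).astype(np.uint8))
        for cid, *_ in _FIXTURE_ROWS
    ]
    write_descriptor_csv(fp_path, fps)
    return compounds_path, fp_path
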