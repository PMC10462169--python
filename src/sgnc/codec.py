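"""Molecule ↔ latent-vector codec contract and latent diagnostics.

A production deployment plugs a pretrained sequence-to-sequence autoencoder
in through the :class:`Codec` protocol (encode a molecule to a d-dimensional
real vector, decode a vector back to a SMILES string; d = 512 by default).
No network weights ship with this package. For desk-scale work and testing,
:class:`CodebookCodec` provides a fully deterministic stand-in: each known
molecule owns one latent "center", encoding is exact lookup, and decoding
maps an arbitrary vector to the SMILES of the nearest center (Euclidean,
ties to the lowest index) — i.e. latent space is partitioned into Voronoi
cells around the codebook.

Also here: reconstruction-rate validation of any codec, and the per-index
latent-profile diagnostic used to check that generated vectors stay inside
the distribution the encoder produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from sgnc.exceptions import ConfigError, DomainError

try:  # optional cheminformatics canonicalizer
    from rdkit import Chem as _Chem
    from rdkit import RDLogger as _RDLogger

    _RDLogger.DisableLog("rdApp.*")
except ImportError:  # pragma: no cover - exercised only without rdkit
    _Chem = None

DEFAULT_LATENT_DIM = 512


@dataclass
class MoleculeRecord:
    """One molecule: SMILES, identifier, optional per-target ΔG labels and descriptors.

    ``affinities`` maps a target name (e.g. "DAT") to a binding free energy in
    kcal/mol. ``descriptors`` holds the four Lipinski quantities when known:
    ``mw`` (daltons), ``logp``, ``nhd`` and ``nha`` (non-negative counts).
    """

    smiles: str
    id: str
    affinities: dict[str, float] = field(default_factory=dict)
    descriptors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.smiles:
            raise DomainError(f"molecule {self.id!r} has an empty SMILES string")
        for target, g in self.affinities.items():
            if not np.isfinite(g):
                raise DomainError(f"molecule {self.id!r}: non-finite affinity for {target!r}")
        for name in ("nhd", "nha"):
            if name in self.descriptors:
                v = self.descriptors[name]
                if v < 0 or v != int(v):
                    raise DomainError(f"molecule {self.id!r}: {name} must be a non-negative integer")


@runtime_checkable
class Codec(Protocol):
    """Encoder/decoder contract between molecules and latent vectors."""

    dimension: int

    def encode(self, molecule: MoleculeRecord) -> np.ndarray: ...

    def decode(self, vector: np.ndarray) -> str: ...


def canonical_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string with rdkit when available, else return it unchanged.

    Strings rdkit cannot parse are also returned unchanged, so purely
    synthetic token strings survive comparison by raw equality.
    """
    if _Chem is None:
        return smiles
    mol = _Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        return smiles
    return _Chem.MolToSmiles(mol)


class CodebookCodec:
    """Deterministic nearest-neighbor codec over a fixed molecule/center codebook.

    encode(molecule i) = center i exactly; decode(v) = SMILES of the center
    nearest to v in Euclidean distance, ties broken by lowest codebook index.
    """

    def __init__(self, molecules: Sequence[MoleculeRecord], centers: Sequence[np.ndarray]):
        if len(molecules) == 0 or len(centers) == 0:
            raise ConfigError("codebook must contain at least one molecule/center pair")
        if len(molecules) != len(centers):
            raise ConfigError(
                f"codebook lists differ in length: {len(molecules)} molecules, {len(centers)} centers"
            )
        centers = [np.asarray(c, dtype=float) for c in centers]
        d = centers[0].shape
        if len(d) != 1:
            raise ConfigError("centers must be one-dimensional vectors")
        if any(c.shape != d for c in centers):
            raise ConfigError("codebook centers have mismatched dimensions")
        stacked = np.vstack(centers)
        if not np.all(np.isfinite(stacked)):
            raise ConfigError("codebook centers must be finite")
        if len(np.unique(stacked, axis=0)) != len(centers):
            raise ConfigError("codebook centers must be pairwise distinct")
        self.molecules = list(molecules)
        self.centers = stacked
        self.dimension = int(d[0])
        self._index = {m.id: i for i, m in enumerate(self.molecules)}

    def encode(self, molecule: MoleculeRecord) -> np.ndarray:
        try:
            i = self._index[molecule.id]
        except KeyError:
            raise DomainError(f"molecule {molecule.id!r} is not in the codebook") from None
        return self.centers[i].copy()

    def decode(self, vector: np.ndarray) -> str:
        return self.molecules[self.nearest_index(vector)].smiles

    def nearest_index(self, vector: np.ndarray) -> int:
        """Index of the codebook center nearest to ``vector`` (ties → lowest index)."""
        v = np.asarray(vector, dtype=float)
        if v.shape != (self.dimension,):
            raise DomainError(f"vector has shape {v.shape}, codec dimension is {self.dimension}")
        dists = np.linalg.norm(self.centers - v, axis=1)
        return int(np.argmin(dists))  # argmin returns the first minimum


def make_codebook_codec(
    molecules: Sequence[MoleculeRecord], centers: Sequence[np.ndarray]
) -> CodebookCodec:
    """Build a :class:`CodebookCodec`; see the class docstring for semantics."""
    return CodebookCodec(molecules, centers)


def reconstruction_rate(codec: Codec, molecules: Sequence[MoleculeRecord]) -> float:
    """Fraction of molecules whose encode→decode round trip returns their own SMILES.

    Comparison is on canonicalized strings (rdkit when importable, raw
    equality otherwise). Returns a value in [0, 1].
    """
    if len(molecules) == 0:
        raise DomainError("reconstruction rate is undefined for an empty molecule list")
    hits = sum(
        canonical_smiles(codec.decode(codec.encode(m))) == canonical_smiles(m.smiles)
        for m in molecules
    )
    return hits / len(molecules)


def latent_profile(vectors: Sequence[np.ndarray], *, mean_of_abs: bool = False) -> np.ndarray:
    """Per-index absolute average of a set of latent vectors.

    The default reads "absolute average value" as |mean|: component j is the
    absolute value of the mean of component j over all vectors, which reveals
    sign cancellation across the set. ``mean_of_abs=True`` computes the mean
    of |component| instead.
    """
    if len(vectors) == 0:
        raise DomainError("latent profile of an empty vector list is undefined")
    try:
        arr = np.asarray(vectors, dtype=float)
    except ValueError as exc:
        raise DomainError(f"latent vectors have ragged shapes: {exc}") from None
    if arr.ndim != 2:
        raise DomainError("latent vectors have ragged or non-vector shapes")
    if mean_of_abs:
        return np.abs(arr).mean(axis=0)
    return np.abs(arr.mean(axis=0))


def profile_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Mean absolute per-index difference between two latent profiles.

    Non-negative, symmetric, and zero iff the profiles are identical.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise DomainError(f"profiles must be 1-D and of equal length, got {p.shape} vs {q.shape}")
    return float(np.abs(p - q).mean())
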