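"""Cosine-similarity computations and reference-compound selection.

Similarity between molecules is measured on their latent vectors with the
cosine similarity S_C(u, v) = u·v / (‖u‖‖v‖). Reference compounds for the
generator are picked per target by three joint criteria: very tight binding
to that target (ΔG < −9.54 kcal/mol, i.e. Ki below 0.1 μM), Lipinski's rule
of five, and an average cosine similarity to the target's dataset above
0.40 — a reference should be both potent and central to the chemical
neighborhood it represents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from sgnc.codec import MoleculeRecord
from sgnc.exceptions import DataError, DomainError
from sgnc.screening import lipinski_filter

#: Tight-binder cut-off: ΔG below this (kcal/mol) ~ Ki below 0.1 μM.
TIGHT_BINDING_DELTA_G = -9.54
#: Minimum average cosine similarity of a reference to its dataset.
MIN_AVG_SIMILARITY = 0.40


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity u·v / (‖u‖‖v‖) in [−1, 1]; zero vectors are a domain error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise DomainError(f"vectors must be 1-D of equal length, got {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DomainError("cosine similarity is undefined for a zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def similarity_matrix(
    queries: Sequence[np.ndarray], dataset: Sequence[np.ndarray]
) -> np.ndarray:
    """n×m matrix of cosine similarities between query and dataset vectors."""
    Q = np.asarray(queries, dtype=float)
    D = np.asarray(dataset, dtype=float)
    qn = np.linalg.norm(Q, axis=1)
    dn = np.linalg.norm(D, axis=1)
    if np.any(qn == 0) or np.any(dn == 0):
        raise DomainError("cosine similarity is undefined for a zero-norm vector")
    return np.clip((Q / qn[:, None]) @ (D / dn[:, None]).T, -1.0, 1.0)


def avg_similarity(
    candidate: np.ndarray,
    dataset: Sequence[np.ndarray],
    *,
    candidate_index: int | None = None,
) -> float:
    """Mean cosine similarity of a candidate to every dataset member.

    If the candidate itself is in the dataset, pass its position as
    ``candidate_index`` (or leave None to match by object identity); the
    self-comparison is excluded so it cannot inflate the average.
    """
    if candidate_index is None:
        others = [v for v in dataset if v is not candidate]
    else:
        others = [v for i, v in enumerate(dataset) if i != candidate_index]
    if len(others) == 0:
        raise DomainError("average similarity is undefined against an empty dataset")
    return float(np.mean([cosine_similarity(candidate, v) for v in others]))


def count_above(
    candidate: np.ndarray, dataset: Sequence[np.ndarray], threshold: float
) -> int:
    """Number of dataset members with cosine similarity to candidate strictly above threshold."""
    if not -1.0 <= threshold <= 1.0:
        raise DomainError(f"threshold must lie in [-1, 1], got {threshold}")
    return sum(cosine_similarity(candidate, v) > threshold for v in dataset)


@dataclass
class SelectionConfig:
    """Thresholds of the reference-selection criteria (strict inequalities)."""

    max_delta_g: float = TIGHT_BINDING_DELTA_G  # pass iff ΔG < this
    min_avg_sim: float = MIN_AVG_SIMILARITY  # pass iff Avg S_C > this
    require_lipinski: bool = True


def select_references(
    dataset: Sequence[tuple[MoleculeRecord, np.ndarray]],
    target: str,
    cfg: SelectionConfig | None = None,
) -> list[tuple[MoleculeRecord, np.ndarray, float]]:
    """Select and rank reference compounds for one target.

    Only records carrying a ΔG label for ``target`` participate; the average
    similarity of each is taken over that same per-target subset, excluding
    the record itself. Survivors satisfy all of: ΔG < −9.54 kcal/mol (strict),
    Lipinski's rule of five, and Avg S_C > 0.40 (strict). They are ranked by
    Avg S_C descending, ties by more-negative ΔG, then by id.

    Returns (record, latent vector, avg similarity) triples.
    """
    if cfg is None:
        cfg = SelectionConfig()
    subset = [(m, z) for m, z in dataset if target in m.affinities]
    if not subset:
        raise DataError(f"no records carry an affinity label for target {target!r}")
    vectors = [z for _, z in subset]
    survivors = []
    for i, (mol, z) in enumerate(subset):
        if len(subset) < 2:
            raise DataError(
                f"target {target!r} has a single record; average similarity is undefined"
            )
        g = mol.affinities[target]
        if not g < cfg.max_delta_g:
            continue
        if cfg.require_lipinski:
            missing = [k for k in ("mw", "logp", "nhd", "nha") if k not in mol.descriptors]
            if missing:
                raise DataError(f"molecule {mol.id!r} lacks Lipinski descriptors {missing}")
            if not lipinski_filter(mol)[0]:
                continue
        avg = avg_similarity(z, vectors, candidate_index=i)
        if avg > cfg.min_avg_sim:
            survivors.append((mol, z, avg))
    survivors.sort(key=lambda t: (-t[2], t[0].affinities[target], t[0].id))
    return survivors
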