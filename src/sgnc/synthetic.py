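"""Synthetic fixture datasets with the statistical structure the pipeline assumes.

Real deployments consume per-target inhibitor datasets (SMILES + binding
affinity), latent vectors from a pretrained autoencoder, and property
profiles from an external ADMET predictor. This module fabricates all three
at desk scale so every pipeline stage is testable without downloads:

* latent vectors cluster around one center per target (DAT, NET, SERT,
  hERG), emulating the observation that inhibitor families occupy compact
  latent neighborhoods;
* ΔG labels follow a planted linear map per target, ΔG = w·z + b + ε, with
  Gaussian noise of configurable SD — transporter families are centered in
  the tight-binding regime, the hERG family in the weak-binding regime, so
  reference selection and the affinity filter both have work to do;
* Lipinski descriptors are sampled inside declared ranges (not computed
  from structure), so most but not all molecules pass the rule of five;
* property profiles are drawn class-first: each property's screening class
  (excellent/medium/fail) is chosen with planted probabilities, then a value
  is sampled inside that class's interval.

Synthetic SMILES come from a tiny valid-by-construction fragment grammar
(a structural prefix plus an alkyl chain whose length encodes the molecule
index), so every string is unique, parseable, and stable under
canonicalization. All outputs are pure functions of (spec, seed); planted
ground truth is returned alongside the data so tests assert recovery
instead of re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from sgnc.codec import CodebookCodec, MoleculeRecord, make_codebook_codec
from sgnc.exceptions import ConfigError
from sgnc.generator import ReferenceSet
from sgnc.screening import PROPERTY_NAMES, PropertyProfile
from sgnc.similarity import SelectionConfig, select_references

TRANSPORTERS = ("DAT", "NET", "SERT")

# structural prefixes of the fragment grammar; all rdkit-parseable
_PREFIXES = ("c1ccccc1", "NC", "OC")


def _synthetic_smiles(index: int) -> str:
    """Unique, canonicalization-stable SMILES for a global molecule index."""
    prefix = _PREFIXES[index % len(_PREFIXES)]
    chain = "C" * (index // len(_PREFIXES) + 1)
    return prefix + chain


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults emulate a small per-target inhibitor collection: 50 molecules
    per target in a 16-dimensional latent space (full-scale runs use 512),
    cluster centers of norm 3 with spread 0.6 so within-family cosine
    similarity comfortably exceeds the 0.40 reference criterion, transporter
    affinities centered at −11 kcal/mol (tight) and hERG at −7 (weak), label
    noise 0.5 kcal/mol, and descriptor ranges that let most but not all
    molecules pass Lipinski.

    ``multi_target_fraction`` adds, per transporter, that fraction of extra
    molecules drawn around the mean of the three transporter centers and
    labelled on all four targets through the planted global linear maps — a
    cross-screened multi-target family (think triple-reuptake-inhibitor
    chemistry, counter-screened against hERG) occupying the bridge region
    the generator is meant to sample.
    """

    n_per_target: int = 50
    d: int = 16
    targets: tuple[str, ...] = ("DAT", "NET", "SERT", "hERG")
    cluster_spread: float = 0.6
    center_norm: float = 3.0
    affinity_means: dict[str, float] = field(
        default_factory=lambda: {"DAT": -11.0, "NET": -11.0, "SERT": -11.0, "hERG": -7.0}
    )
    weight_scale: float = 0.3
    noise_sd: float = 0.5
    multi_target_fraction: float = 0.2
    descriptor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mw": (250.0, 520.0),
            "logp": (0.5, 5.5),
            "nhd": (0, 6),
            "nha": (1, 11),
        }
    )
    property_class_fractions: dict[str, float] = field(
        default_factory=lambda: {"excellent": 0.6, "medium": 0.3, "fail": 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_target < 1 or self.d < 1:
            raise ConfigError("n_per_target and d must be positive")
        if self.cluster_spread < 0 or self.noise_sd < 0:
            raise ConfigError("cluster_spread and noise_sd must be non-negative")
        if not 0 <= self.multi_target_fraction <= 1:
            raise ConfigError("multi_target_fraction must lie in [0, 1]")
        fr = self.property_class_fractions
        if any(not 0 <= v <= 1 for v in fr.values()) or abs(sum(fr.values()) - 1) > 1e-9:
            raise ConfigError("property_class_fractions must be in [0,1] and sum to 1")
        missing = [t for t in self.targets if t not in self.affinity_means]
        if missing:
            raise ConfigError(f"affinity_means lacks target(s) {missing}")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a synthetic dataset."""

    centers: dict[str, np.ndarray]
    weights: dict[str, np.ndarray]
    intercepts: dict[str, float]
    noise_sd: float
    noiseless_labels: dict[str, float]  # "id:target" -> planted w·z + b before noise

    def to_jsonable(self) -> dict:
        return {
            "centers": {t: c.tolist() for t, c in self.centers.items()},
            "weights": {t: w.tolist() for t, w in self.weights.items()},
            "intercepts": self.intercepts,
            "noise_sd": self.noise_sd,
            "noiseless_labels": self.noiseless_labels,
        }


@dataclass
class SyntheticDataset:
    """(MoleculeRecord, latent vector) pairs plus planted truth; iterates over pairs."""

    pairs: list[tuple[MoleculeRecord, np.ndarray]]
    truth: SyntheticTruth

    def __iter__(self) -> Iterator[tuple[MoleculeRecord, np.ndarray]]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]


def make_latent_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw the synthetic per-target molecule collections.

    Per target: latent vectors z ~ N(center_t, spread²·I) around a
    target-specific center of norm ``center_norm``; labels
    ΔG = w_t·z + b_t + N(0, noise_sd²) with b_t set so the noiseless label at
    the cluster center equals the target's planted mean; descriptors sampled
    uniformly inside their declared ranges. Deterministic given spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    centers: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}
    intercepts: dict[str, float] = {}
    noiseless: dict[str, float] = {}
    pairs: list[tuple[MoleculeRecord, np.ndarray]] = []
    ranges = spec.descriptor_ranges
    index = 0
    for t in spec.targets:
        direction = rng.normal(size=spec.d)
        centers[t] = spec.center_norm * direction / np.linalg.norm(direction)
        weights[t] = spec.weight_scale * rng.normal(size=spec.d)
        intercepts[t] = spec.affinity_means[t] - float(weights[t] @ centers[t])
        for j in range(spec.n_per_target):
            z = centers[t] + spec.cluster_spread * rng.normal(size=spec.d)
            clean = float(weights[t] @ z) + intercepts[t]
            label = clean + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            mol_id = f"SYN-{t}-{j:04d}"
            noiseless[f"{mol_id}:{t}"] = clean
            record = MoleculeRecord(
                smiles=_synthetic_smiles(index),
                id=mol_id,
                affinities={t: label},
                descriptors={
                    "mw": float(rng.uniform(*ranges["mw"])),
                    "logp": float(rng.uniform(*ranges["logp"])),
                    "nhd": int(rng.integers(ranges["nhd"][0], ranges["nhd"][1] + 1)),
                    "nha": int(rng.integers(ranges["nha"][0], ranges["nha"][1] + 1)),
                },
            )
            pairs.append((record, z))
            index += 1

    # multi-target complement: molecules around the transporter-center mean,
    # labelled on every target via the same planted maps
    transporters = [t for t in spec.targets if t in TRANSPORTERS]
    n_bridge = round(spec.multi_target_fraction * spec.n_per_target) * len(transporters)
    if n_bridge and transporters:
        bridge_center = np.mean([centers[t] for t in transporters], axis=0)
        for j in range(n_bridge):
            z = bridge_center + spec.cluster_spread * rng.normal(size=spec.d)
            mol_id = f"SYN-MULTI-{j:04d}"
            affinities = {}
            for t in spec.targets:
                clean = float(weights[t] @ z) + intercepts[t]
                noiseless[f"{mol_id}:{t}"] = clean
                affinities[t] = clean + (
                    rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                )
            record = MoleculeRecord(
                smiles=_synthetic_smiles(index),
                id=mol_id,
                affinities=affinities,
                descriptors={
                    "mw": float(rng.uniform(*ranges["mw"])),
                    "logp": float(rng.uniform(*ranges["logp"])),
                    "nhd": int(rng.integers(ranges["nhd"][0], ranges["nhd"][1] + 1)),
                    "nha": int(rng.integers(ranges["nha"][0], ranges["nha"][1] + 1)),
                },
            )
            pairs.append((record, z))
            index += 1
    truth = SyntheticTruth(centers, weights, intercepts, spec.noise_sd, noiseless)
    return SyntheticDataset(pairs, truth)


# class-conditional value samplers: (lo, hi) uniform windows strictly inside
# each class region of the default range table
_CLASS_WINDOWS: dict[str, dict[str, tuple[float, float]]] = {
    "caco2": {"excellent": (-5.0, -4.0), "fail": (-7.0, -5.3)},
    "f20": {"excellent": (0.0, 0.3), "medium": (0.35, 0.7), "fail": (0.75, 1.0)},
    "pgp_sub": {"excellent": (0.0, 0.3), "medium": (0.35, 0.7), "fail": (0.75, 1.0)},
    "pgp_inh": {"excellent": (0.0, 0.3), "medium": (0.35, 0.7), "fail": (0.75, 1.0)},
    "vd": {"excellent": (0.1, 15.0), "fail": (25.0, 40.0)},
    "t_half": {"excellent": (0.0, 0.3), "medium": (0.35, 0.7), "fail": (0.75, 1.0)},
    "fdamdd": {"excellent": (0.0, 0.3), "medium": (0.35, 0.7), "fail": (0.75, 1.0)},
    "sas": {"excellent": (1.0, 5.5), "fail": (6.5, 9.0)},
    "logp": {"excellent": (0.2, 2.8), "fail": (3.5, 6.0)},
    "logs": {"excellent": (-3.5, 0.2), "fail": (-8.0, -4.5)},
}


@dataclass
class PropertyBatch:
    """Synthetic property profiles plus the planted class of every value."""

    profiles: list[PropertyProfile]
    planted_classes: list[dict[str, str]]

    def __iter__(self) -> Iterator[PropertyProfile]:
        return iter(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)


def make_property_profiles(ids: Sequence[str], spec: SyntheticSpec) -> PropertyBatch:
    """Draw one property profile per id, class-first with planted probabilities.

    For each property the screening class is drawn from
    ``spec.property_class_fractions``, then a value is sampled uniformly
    inside that class's interval of the default range table. Properties with
    no medium band fold the medium probability into excellent. The planted
    class of every value is returned as ground truth and is, by
    construction, exactly what range classification recovers.
    """
    rng = np.random.default_rng(spec.seed + 1)
    fr = spec.property_class_fractions
    profiles, planted = [], []
    for mol_id in ids:
        values: dict[str, float] = {}
        classes: dict[str, str] = {}
        for name in PROPERTY_NAMES:
            windows = _CLASS_WINDOWS[name]
            p_exc, p_med, p_fail = fr["excellent"], fr["medium"], fr["fail"]
            if "medium" not in windows:
                p_exc, p_med = p_exc + p_med, 0.0
            cls = rng.choice(["excellent", "medium", "fail"], p=[p_exc, p_med, p_fail])
            lo, hi = windows[cls]
            values[name] = float(rng.uniform(lo, hi))
            classes[name] = str(cls)
        profiles.append(PropertyProfile(id=mol_id, **values))
        planted.append(classes)
    return PropertyBatch(profiles, planted)


@dataclass
class CodebookFixture:
    """A complete desk-scale generation setup built from synthetic data."""

    codec: CodebookCodec
    references: ReferenceSet
    seed_vector: np.ndarray
    dataset: SyntheticDataset
    reference_records: list[MoleculeRecord]
    seed_record: MoleculeRecord

    def __iter__(self):  # (codec, references, seed_vector) per the module contract
        return iter((self.codec, self.references, self.seed_vector))


def make_codebook_fixture(
    spec: SyntheticSpec, selection: SelectionConfig | None = None
) -> CodebookFixture:
    """Build codec + references + seed vector from one synthetic dataset.

    The codebook codec is built over all synthetic molecules with their
    latent vectors as centers. One reference per transporter target is
    chosen by the standard selection criteria (top of the ranking); the seed
    vector is the latent vector of the transporter molecule closest to the
    references' weighted centroid — a stand-in for a compound potent on all
    three targets. Fully deterministic given spec.seed.
    """
    dataset = make_latent_dataset(spec)
    records = [m for m, _ in dataset.pairs]
    centers = [z for _, z in dataset.pairs]
    codec = make_codebook_codec(records, centers)
    ref_records: list[MoleculeRecord] = []
    ref_vectors: list[np.ndarray] = []
    for t in TRANSPORTERS:
        ranked = select_references(dataset.pairs, t, selection)
        if not ranked:
            raise ConfigError(
                f"synthetic spec produced no admissible reference for target {t!r}; "
                "loosen the spec (more molecules, tighter cluster, lower noise)"
            )
        mol, z, _ = ranked[0]
        ref_records.append(mol)
        ref_vectors.append(z)
    refs = ReferenceSet(references=ref_vectors)
    centroid = refs.centroid()
    candidates = [
        (m, z) for m, z in dataset.pairs
        if any(t in m.affinities for t in TRANSPORTERS) and m.id not in {r.id for r in ref_records}
    ]
    seed_record, seed_vector = min(
        candidates, key=lambda pair: (float(np.linalg.norm(pair[1] - centroid)), pair[0].id)
    )
    return CodebookFixture(codec, refs, seed_vector, dataset, ref_records, seed_record)
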