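"""End-to-end orchestration of the generation/screening cascade.

One run executes: select references → simulate Langevin dynamics from the
seed vector → decode snapshots → deduplicate → predict the four-target
affinity panel → affinity filter → novelty filter → Lipinski filter →
property-range screening → percent-excellent ranking. A single root seed
drives every stochastic stage through fixed per-stage offsets, so any stage
can be re-run in isolation reproducibly and two identical configs produce
byte-identical outputs.

The run also re-encodes the surviving candidates and reports the divergence
between their latent profile and the training set's — the feedback-loop
diagnostic that checks the generator stayed inside the encoder's
distribution.

Inputs come either from CSV files (dataset + latents + optional property
table; the codec is then the codebook over those molecules) or, by default,
from the synthetic fixture generator. Property values are always consumed,
never predicted, mirroring their origin in an external ADMET predictor.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from sgnc import io
from sgnc.affinity import PredictorConfig, predict_panel, train
from sgnc.codec import latent_profile, make_codebook_codec, profile_divergence
from sgnc.exceptions import ConfigError, DataError, SGNCError
from sgnc.generator import (
    GeneratorConfig,
    ReferenceSet,
    generate_candidates,
    simulate,
    snapshot_indices,
)
from sgnc.screening import (
    RangeTable,
    affinity_filter,
    classify_properties,
    lipinski_filter,
    novelty_filter,
    rank_leads,
)
from sgnc.similarity import SelectionConfig, select_references
from sgnc.synthetic import (
    TRANSPORTERS,
    SyntheticSpec,
    make_codebook_fixture,
    make_property_profiles,
)

log = logging.getLogger("sgnc")

# fixed per-stage seed offsets derived from the root seed
_SEED_GENERATOR = 1
_SEED_PREDICTOR = 2
_SEED_SYNTHETIC = 0
_SEED_MOD = 2**31


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    With no file paths set, inputs are synthesized from ``synthetic``.
    The default predictor settings are desk-scale (small hidden layers, few
    epochs, faster learning rate) so a fixture run completes in seconds; the
    full-scale architecture is available through the config.
    """

    seed: int = 0
    dataset_path: str | None = None
    latents_path: str | None = None
    properties_path: str | None = None
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    generator: GeneratorConfig = field(
        default_factory=lambda: GeneratorConfig(
            alpha=1.0, dt=0.005, n_steps=2000, noise_law="uniform", noise_amplitude=0.1,
            burn_in=0, snapshot_every=10,
        )
    )
    predictor: PredictorConfig = field(
        default_factory=lambda: PredictorConfig(
            hidden_sizes=(64, 128, 64), epochs=30, lr_schedule=[(20, 1e-3), (10, 1e-4)]
        )
    )
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    novelty_max_sim: float = 0.5
    ranges: RangeTable = field(default_factory=RangeTable)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        """Build a RunConfig from a YAML file with nested sub-config blocks."""
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        for key in ("seed", "dataset_path", "latents_path", "properties_path",
                    "novelty_max_sim", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticSpec(**raw["synthetic"])
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig(**raw["generator"])
        if "predictor" in raw:
            block = dict(raw["predictor"])
            if "hidden_sizes" in block:
                block["hidden_sizes"] = tuple(block["hidden_sizes"])
            if block.get("lr_schedule") is not None:
                block["lr_schedule"] = [tuple(p) for p in block["lr_schedule"]]
            kwargs["predictor"] = PredictorConfig(**block)
        if "selection" in raw:
            kwargs["selection"] = SelectionConfig(**raw["selection"])
        if seed is not None:
            kwargs["seed"] = seed
        return cls(**kwargs)

    def echo(self) -> dict:
        """JSON-serializable summary of the effective configuration."""
        return {
            "seed": self.seed,
            "dataset_path": self.dataset_path,
            "latents_path": self.latents_path,
            "properties_path": self.properties_path,
            "generator": {
                "alpha": self.generator.alpha, "dt": self.generator.dt,
                "n_steps": self.generator.n_steps, "noise_law": self.generator.noise_law,
                "noise_amplitude": self.generator.noise_amplitude,
                "step_cap": self.generator.step_cap, "burn_in": self.generator.burn_in,
                "snapshot_every": self.generator.snapshot_every,
            },
            "predictor": {
                "hidden_sizes": list(self.predictor.hidden_sizes),
                "epochs": self.predictor.epochs,
                "lr_schedule": [list(p) for p in self.predictor.lr_schedule],
                "batch_size": self.predictor.batch_size,
            },
            "selection": {
                "max_delta_g": self.selection.max_delta_g,
                "min_avg_sim": self.selection.min_avg_sim,
            },
            "novelty_max_sim": self.novelty_max_sim,
        }


@dataclass
class RunReport:
    """Stage counts, ranked leads and diagnostics of one pipeline run."""

    counts: dict[str, int]
    leads: list[dict]
    profile_divergence: float | None
    config: dict
    seed: int
    #: stage intermediates (panel, candidates, references, profiles, trajectory);
    #: populated only on request, never serialized
    artifacts: dict | None = None

    def to_jsonable(self) -> dict:
        return {
            "counts": self.counts,
            "leads": self.leads,
            "profile_divergence": self.profile_divergence,
            "config": self.config,
            "seed": self.seed,
        }


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                if isinstance(exc, SGNCError) and not str(exc).startswith(f"[{name}]"):
                    exc.args = (f"[{name}] {exc}",)
            else:
                log.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def _load_inputs(cfg: RunConfig):
    """Resolve (pairs, codec, refs, seed_vector, profiles) from files or fixtures."""
    if cfg.dataset_path is not None:
        if cfg.latents_path is None:
            raise ConfigError("a dataset path requires a latents path")
        records = io.read_dataset(cfg.dataset_path)
        latents = io.read_latents(cfg.latents_path)
        missing = [r.id for r in records if r.id not in latents]
        if missing:
            raise DataError(f"no latent vector for molecule(s) {missing[:5]}")
        pairs = [(r, latents[r.id]) for r in records]
        codec = make_codebook_codec([r for r, _ in pairs], [z for _, z in pairs])
        ref_vectors, ref_ids = [], []
        for t in TRANSPORTERS:
            ranked = select_references(pairs, t, cfg.selection)
            if not ranked:
                raise DataError(f"no admissible reference compound for target {t!r}")
            mol, z, _ = ranked[0]
            ref_vectors.append(z)
            ref_ids.append(mol.id)
        refs = ReferenceSet(references=ref_vectors)
        centroid = refs.centroid()
        pool = [
            (m, z) for m, z in pairs
            if any(t in m.affinities for t in TRANSPORTERS) and m.id not in set(ref_ids)
        ]
        if not pool:
            raise DataError("no transporter-labelled molecule available as a seed compound")
        _, seed_vector = min(
            pool, key=lambda p: (float(np.linalg.norm(p[1] - centroid)), p[0].id)
        )
    else:
        synth = SyntheticSpec(**{**cfg.synthetic.__dict__,
                                 "seed": (cfg.seed + _SEED_SYNTHETIC) % _SEED_MOD})
        fixture = make_codebook_fixture(synth, cfg.selection)
        pairs = fixture.dataset.pairs
        codec, refs, seed_vector = fixture.codec, fixture.references, fixture.seed_vector

    if cfg.properties_path is not None:
        profiles = {p.id: p for p in io.read_properties(cfg.properties_path)}
    else:
        synth_seed = SyntheticSpec(**{**cfg.synthetic.__dict__,
                                      "seed": (cfg.seed + _SEED_SYNTHETIC) % _SEED_MOD})
        batch = make_property_profiles([m.id for m, _ in pairs], synth_seed)
        profiles = {p.id: p for p in batch.profiles}
    return pairs, codec, refs, seed_vector, profiles


def run_pipeline(
    cfg: RunConfig, out_dir: str | Path | None = None, keep_artifacts: bool = False
) -> RunReport:
    """Execute the full cascade; optionally write leads.csv and report.json.

    Stage counts (decoded, deduplicated, affinity-pass, novelty-pass,
    Lipinski-pass, screening-pass) are non-increasing by construction.
    """
    logging.basicConfig(stream=sys.stderr, level=cfg.log_level,
                        format="%(levelname)s %(name)s: %(message)s")

    with _stage("inputs"):
        pairs, codec, refs, seed_vector, profiles = _load_inputs(cfg)
        by_smiles = {m.smiles: (m, z) for m, z in pairs}

    with _stage("train-predictors"):
        predictors = {}
        targets = sorted({t for m, _ in pairs for t in m.affinities})
        for j, t in enumerate(sorted(targets)):
            subset = [(z, m.affinities[t]) for m, z in pairs if t in m.affinities]
            X = np.vstack([z for z, _ in subset])
            y = np.array([g for _, g in subset])
            pcfg = PredictorConfig(
                hidden_sizes=cfg.predictor.hidden_sizes,
                epochs=cfg.predictor.epochs,
                lr_schedule=list(cfg.predictor.lr_schedule),
                batch_size=cfg.predictor.batch_size,
                activation=cfg.predictor.activation,
                seed=(cfg.seed + _SEED_PREDICTOR + j) % _SEED_MOD,
            )
            predictors[t] = train(X, y, pcfg)

    with _stage("generate"):
        gcfg = GeneratorConfig(**{**cfg.generator.__dict__,
                                  "seed": (cfg.seed + _SEED_GENERATOR) % _SEED_MOD})
        traj = simulate(seed_vector, refs, gcfg)
        raw_candidates = generate_candidates(traj, codec, gcfg)
        n_decoded = len(snapshot_indices(gcfg))
        # decoded SMILES map back to catalogued molecules: recover descriptors
        candidates = []
        for rec, z in raw_candidates:
            src, src_z = by_smiles[rec.smiles]
            candidates.append((src, src_z))

    with _stage("affinity-filter"):
        panel = predict_panel(candidates, predictors)
        aff_ok = affinity_filter(panel)
        aff_pass = [c for c, ok in zip(candidates, aff_ok) if ok]

    with _stage("novelty-filter"):
        nov_ok = novelty_filter(aff_pass, refs.references, cfg.novelty_max_sim)
        nov_pass = [c for c, ok in zip(aff_pass, nov_ok) if ok]

    with _stage("lipinski-filter"):
        lip_pass = [c for c in nov_pass if lipinski_filter(c[0])[0]]

    with _stage("screening"):
        verdicts = []
        for m, _ in lip_pass:
            if m.id not in profiles:
                raise DataError(f"no property profile for candidate {m.id!r}")
            verdicts.append(classify_properties(profiles[m.id], cfg.ranges))
        ranked = rank_leads(verdicts) if verdicts else []

    with _stage("diagnostics"):
        train_profile = latent_profile([z for _, z in pairs])
        divergence = None
        if lip_pass:
            reencoded = [codec.encode(m) for m, _ in lip_pass]
            divergence = profile_divergence(train_profile, latent_profile(reencoded))

    verdict_by_id = {v.id: v for v in verdicts}
    lead_rows = []
    for v in ranked:
        mol, _ = next(c for c in lip_pass if c[0].id == v.id)
        lead_rows.append({
            "id": v.id,
            "smiles": mol.smiles,
            "pct_excellent": v.pct_excellent,
            **{f"delta_g_{t}": float(panel.loc[v.id, t]) for t in panel.columns},
            **{f"class_{k}": c for k, c in v.classes.items()},
        })
    report = RunReport(
        counts={
            "decoded": n_decoded,
            "deduplicated": len(candidates),
            "affinity_pass": len(aff_pass),
            "novelty_pass": len(nov_pass),
            "lipinski_pass": len(lip_pass),
            "screening_pass": len(ranked),
        },
        leads=lead_rows,
        profile_divergence=divergence,
        config=cfg.echo(),
        seed=cfg.seed,
    )
    if keep_artifacts:
        report.artifacts = {
            "pairs": pairs,
            "candidates": candidates,
            "panel": panel,
            "references": refs,
            "profiles": profiles,
            "trajectory": traj,
            "verdicts": verdicts,
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_leads(out / "leads.csv", pd.DataFrame(
            lead_rows, columns=lead_rows[0].keys() if lead_rows else ["id", "smiles", "pct_excellent"]
        ))
        io.write_json(out / "report.json", report.to_jsonable())
    return report
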