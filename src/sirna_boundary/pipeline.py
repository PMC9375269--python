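"""One-shot orchestration: load/simulate -> iterate -> predict -> evaluate.

A run writes, under the output directory: the dataset actually analysed, the
removal log, the final P/I cluster assignment, per-record predictions, the
beta-parameter trace, a metrics JSON and a manifest (config, input checksum,
package version) sufficient to reproduce the outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data_io import Dataset, read_dataset, split_every_fifth, split_modulus, write_dataset
from .i_iteration import IterationEngine, IterationState
from .predict_evaluate import evaluate, predict_efficacy
from .synthetic_fixtures import FixtureConfig, generate_fixture

__all__ = ["RunConfig", "run_pipeline"]

_ALLOWED_ALPHA = tuple(range(5, 70, 5))


@dataclass
class RunConfig:
    input: str | None = None  # dataset path; None -> simulate a fixture
    format: str | None = None
    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    split: str = "every_fifth"  # every_fifth | none (use roles in the input)
    modulus: int = 5
    offset: int = 0
    alpha_start: int = 20
    max_alpha: int = 65
    potency_threshold: float = 70.0
    recompute_icc: str = "stage"
    icc_cluster_count: str = "initial"
    seed: int = 0
    outdir: str = "sirna_boundary_run"

    def validate(self) -> None:
        if self.alpha_start not in _ALLOWED_ALPHA:
            raise ValueError(
                f"alpha_start must be one of {_ALLOWED_ALPHA}, got {self.alpha_start}"
            )
        if self.max_alpha not in _ALLOWED_ALPHA or self.max_alpha < self.alpha_start:
            raise ValueError(f"bad max_alpha {self.max_alpha}")
        if self.split not in ("every_fifth", "modulus", "none"):
            raise ValueError(f"unknown split rule {self.split!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load(cfg: RunConfig) -> tuple[Dataset, dict]:
    if cfg.input is None:
        fixture = dataclasses.replace(
            cfg.fixture, seed=cfg.seed, potency_threshold=cfg.potency_threshold
        )
        ds = generate_fixture(fixture)
        meta = {"source": "simulated", "fixture": dataclasses.asdict(fixture)}
        return ds, meta
    path = Path(cfg.input)
    ds = read_dataset(path, cfg.format, potency_threshold=cfg.potency_threshold)
    if cfg.split == "every_fifth":
        ds = split_every_fifth(ds)
    elif cfg.split == "modulus":
        ds = split_modulus(ds, cfg.modulus, cfg.offset)
    elif any(r.role is None for r in ds.records):
        raise ValueError("split='none' requires a role column in the input")
    return ds, {"source": str(path), "sha256": _sha256(path)}


def _write_state(outdir: Path, state: IterationState) -> None:
    pd.DataFrame(
        [dataclasses.asdict(ev) for ev in state.removal_log],
        columns=["id", "alpha", "stage", "pass_no", "t", "condition"],
    ).to_csv(outdir / "removal_log.tsv", sep="\t", index=False)
    pd.DataFrame(state.beta_trace).to_csv(outdir / "beta_trace.tsv", sep="\t", index=False)
    clusters = pd.DataFrame(
        [{"id": i, "cluster": "P"} for i in state.p_cluster]
        + [{"id": i, "cluster": "I"} for i in state.i_cluster]
    )
    clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full boundary analysis; returns the metrics dictionary."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(cfg).items() if k != "fixture"},
            "fixture": dataclasses.asdict(cfg.fixture),
        },
        "version": __version__,
        "status": "failed",
    }
    try:
        ds, input_meta = _load(cfg)
        manifest["input"] = input_meta
        write_dataset(ds, outdir / "dataset.tsv")
        engine = IterationEngine(
            ds,
            recompute_icc=cfg.recompute_icc,
            icc_cluster_count=cfg.icc_cluster_count,
        )
        state = engine.run(alpha_start=cfg.alpha_start, alpha_stop=cfg.max_alpha)
        _write_state(outdir, state)
        predictions = predict_efficacy(engine, state)
        predictions.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        truth = {r.id: ds.is_potent(r) for r in ds.records}
        report = evaluate(state, predictions, truth)
        metrics = report.to_dict()
        metrics["n_removed"] = len(state.i_cluster)
        metrics["max_aggregate"] = state.max_aggregate
        (outdir / "metrics.json").write_text(
            json.dumps(metrics, indent=2, sort_keys=True) + "\n"
        )
        manifest["status"] = "ok"
        return metrics
    finally:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
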