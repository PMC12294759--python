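"""End-to-end orchestration: simulate → train → attribute → analyze.

A single :class:`RunConfig` (YAML-loadable, unknown keys rejected) drives
the whole workflow; every stage funnels randomness through seeds derived
from the one global seed, writes its artifacts under the output directory,
and the run closes with a manifest of artifact checksums plus a resolved
config echo, so reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .analysis import DEFAULT_KS, rank_genes, topk_overlap, total_score
from .attribution import AttributionConfig, attribute_dataset
from .hierarchy import build_masks
from .model import TrainConfig, save_model, train
from .synthetic import PLANTED_CLASSES, SyntheticSpec, simulate, strong_effect_preset

logger = logging.getLogger(__name__)


def derive_seed(seed: int, *tags: int) -> int:
    """A stable child seed below 2**31 for one named stage."""
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


def _build_section(cls, data: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """All stage configs under one roof; ``from_yaml`` validates strictly."""

    seed: int = 0
    outdir: Path = Path("frbinn-run")
    log_level: str = "INFO"
    simulation: SyntheticSpec = field(default_factory=strong_effect_preset)
    training: TrainConfig = field(default_factory=TrainConfig)
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    ks: tuple[int, ...] = DEFAULT_KS
    top_fraction: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        top_known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in data.items():
            if key == "simulation":
                kwargs[key] = _build_section(SyntheticSpec, value, key)
            elif key == "training":
                kwargs[key] = _build_section(TrainConfig, value, key)
            elif key == "attribution":
                kwargs[key] = _build_section(AttributionConfig, value, key)
            elif key == "ks":
                kwargs[key] = tuple(int(k) for k in value)
            elif key == "outdir":
                kwargs[key] = Path(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def echo(self) -> dict:
        data = dataclasses.asdict(self)
        data["outdir"] = str(self.outdir)
        for section in ("attribution",):
            for key in ("baseline", "background"):
                if data[section][key] is not None:
                    data[section][key] = list(map(float, data[section][key]))
        return data


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, train, attribute (IG + SV + conductance per non-normal
    class), analyze, and write a checksummed artifact manifest.

    Returns the manifest dict; raises on the first stage failure after
    writing whatever partial manifest exists.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    manifest_path = out / "manifest.json"

    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(config.echo(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["config"] = out / "config.json"

    try:
        t0 = time.perf_counter()
        dataset = simulate(config.simulation)
        io.write_expression(dataset.expression, out / "expression.tsv")
        io.write_labels(dataset.labels, out / "labels.tsv")
        gene_sets = {
            p: sorted(c for c, q in dataset.hierarchy.edges if q == p)
            for p in dataset.hierarchy.layers[1]
        }
        io.write_gmt(gene_sets, out / "gene_sets.gmt")
        io.write_edges(
            sorted(
                (c, p)
                for c, p in dataset.hierarchy.edges
                if c in set(dataset.hierarchy.layers[1])
            ),
            out / "edges.tsv",
        )
        with open(out / "planted.json", "w", encoding="utf-8") as fh:
            json.dump(dataset.planted, fh, indent=2, sort_keys=True)
        for name in ("expression", "labels", "gene_sets", "edges", "planted"):
            suffix = {"gene_sets": ".gmt", "planted": ".json"}.get(name, ".tsv")
            artifacts[name] = out / f"{name}{suffix}"
        timings["simulate"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        masks = build_masks(dataset.hierarchy)
        train_cfg = dataclasses.replace(
            config.training, seed=derive_seed(config.seed, 1)
        )
        model, report = train(dataset.expression, dataset.labels, masks, train_cfg)
        save_model(model, out / "model.npz")
        artifacts["model"] = out / "model.npz"
        timings["train"] = time.perf_counter() - t0
        logger.info("final training loss %.4f", report.epoch_losses[-1])

        t0 = time.perf_counter()
        attr_cfg = dataclasses.replace(
            config.attribution, seed=derive_seed(config.seed, 2)
        )
        rankings: dict[tuple[str, str], object] = {}
        for cls in PLANTED_CLASSES:
            for method in ("IG", "SV", "conductance"):
                result = attribute_dataset(
                    model, dataset.expression, dataset.labels, method,
                    attr_cfg, target_class=cls,
                )
                tag = f"{method}_{cls.replace('-', '')}"
                io.write_attribution_csv(result, out / f"attr_{tag}.csv")
                artifacts[f"attr_{tag}"] = out / f"attr_{tag}.csv"
                if method != "conductance":
                    rankings[(method, cls)] = rank_genes(result, class_tag=cls)
        timings["attribute"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        overlap_rows = []
        for cls in PLANTED_CLASSES:
            rep = topk_overlap(
                rankings[("IG", cls)], rankings[("SV", cls)], ks=config.ks
            )
            for k, frac in rep.fractions.items():
                overlap_rows.append(
                    {"comparison": f"IG-vs-SV/{cls}", "k": k, "fraction": frac}
                )
            combo = total_score(rankings[("IG", cls)], rankings[("SV", cls)])
            combo.as_frame().to_csv(out / f"total_{cls.replace('-', '')}.csv", index=False)
            artifacts[f"total_{cls.replace('-', '')}"] = out / f"total_{cls.replace('-', '')}.csv"
        cross = topk_overlap(
            rankings[("IG", "CP-CID")], rankings[("IG", "NCP-CID")],
            ks=tuple(k for k in config.ks if k <= config.simulation.n_genes),
        )
        for k, frac in cross.fractions.items():
            overlap_rows.append(
                {"comparison": "IG/CP-vs-NCP", "k": k, "fraction": frac}
            )
        import pandas as pd

        pd.DataFrame(overlap_rows).to_csv(out / "overlaps.csv", index=False)
        artifacts["overlaps"] = out / "overlaps.csv"
        timings["analyze"] = time.perf_counter() - t0
    finally:
        io.write_manifest(
            artifacts, manifest_path,
            extra={"seed": config.seed, "timings_s": {k: round(v, 3) for k, v in timings.items()}},
        )

    return json.loads(manifest_path.read_text())
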