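"""Synthetic four-class transcriptome cohorts over a known pathway hierarchy.

The generator emulates the statistical structure the classifier assumes: a
bulk-expression cohort with classes {cancer, CP-CID, NCP-CID, normal}, a
gene → pathway → superpathway hierarchy, and *disjoint planted gene sets*
that discriminate each non-normal class from the baseline.  Expression is
log-normal (TPM-like skew): each gene gets a baseline log2 level, samples add
a class effect on their class's planted genes plus Gaussian log-scale noise,
and values are exponentiated back to a non-negative TPM-like scale.  The
normal class is the unshifted baseline.  Everything is deterministic under
the spec's seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchy import PathwayHierarchy, build_hierarchy
from .model import CLASSES

PLANTED_CLASSES = ("cancer", "CP-CID", "NCP-CID")  # normal = baseline


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort blueprint; all sizes, effect scales and the seed in one place."""

    n_genes: int = 200
    n_pathways: int = 20
    n_superpathways: int = 4
    genes_per_pathway: int = 10
    samples_per_class: int = 100
    planted_per_class: int = 20
    effect_size: float = 2.0
    noise_sd: float = 0.5
    pathway_overlap: int = 0
    baseline_mean: float = 3.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_pathways, self.n_superpathways,
            self.genes_per_pathway, self.samples_per_class, self.planted_per_class,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.genes_per_pathway > self.n_genes:
            raise ValueError("genes_per_pathway exceeds n_genes")
        if self.planted_per_class * len(PLANTED_CLASSES) > self.n_genes:
            raise ValueError("planted sets would exceed the gene universe")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be >= 0")
        if not 0 <= self.pathway_overlap < self.genes_per_pathway:
            raise ValueError("pathway_overlap must be in [0, genes_per_pathway)")


@dataclass
class SyntheticDataset:
    hierarchy: PathwayHierarchy
    expression: pd.DataFrame  # samples × genes, TPM-like
    labels: pd.Series
    planted: dict[str, list[str]]
    spec: SyntheticSpec

    def checksum(self) -> str:
        """SHA-256 over the expression bytes, labels and planted manifest."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.expression.to_numpy()).tobytes())
        h.update(",".join(self.labels).encode())
        for cls in PLANTED_CLASSES:
            h.update(",".join(self.planted[cls]).encode())
        return h.hexdigest()


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_hierarchy(spec: SyntheticSpec) -> PathwayHierarchy:
    """Deterministic hierarchy: contiguous gene blocks per pathway (with the
    requested overlap), pathways dealt round-robin to superpathways."""
    genes = _gene_names(spec.n_genes)
    stride = spec.genes_per_pathway - spec.pathway_overlap
    gene_sets = {}
    pw_width = len(str(spec.n_pathways))
    for p in range(spec.n_pathways):
        start = (p * stride) % spec.n_genes
        members = [genes[(start + k) % spec.n_genes] for k in range(spec.genes_per_pathway)]
        gene_sets[f"P{p + 1:0{pw_width}d}"] = list(dict.fromkeys(members))
    sp_width = len(str(spec.n_superpathways))
    edges = [
        (name, f"SP{p % spec.n_superpathways + 1:0{sp_width}d}")
        for p, name in enumerate(gene_sets)
    ]
    return build_hierarchy(gene_sets, edges)


def _planted_sets(spec: SyntheticSpec) -> dict[str, list[str]]:
    """Disjoint planted genes, strided so each class's set spans pathways."""
    genes = _gene_names(spec.n_genes)
    k = len(PLANTED_CLASSES)
    return {
        cls: [genes[i * k + c] for i in range(spec.planted_per_class)]
        for c, cls in enumerate(PLANTED_CLASSES)
    }


def generate_expression(
    spec: SyntheticSpec, hierarchy: PathwayHierarchy | None = None
) -> SyntheticDataset:
    """Draw the cohort: balanced labels, planted log-scale class shifts.

    log2 expression of sample s, gene g =
    ``baseline_g + effect_size·[g planted for class(s)] + N(0, noise_sd)``,
    exponentiated to the TPM-like scale.
    """
    hierarchy = hierarchy or generate_hierarchy(spec)
    if len(hierarchy.genes) != spec.n_genes:
        raise ValueError(
            f"hierarchy has {len(hierarchy.genes)} genes, spec says {spec.n_genes}"
        )
    genes = _gene_names(spec.n_genes)
    planted = _planted_sets(spec)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(spec.seed)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)

    n_total = spec.samples_per_class * len(CLASSES)
    labels = [cls for cls in CLASSES for _ in range(spec.samples_per_class)]
    shift = np.zeros((n_total, spec.n_genes))
    for cls in PLANTED_CLASSES:
        cols = [gene_pos[g] for g in planted[cls]]
        rows = [i for i, lab in enumerate(labels) if lab == cls]
        shift[np.ix_(rows, cols)] = spec.effect_size

    log2_expr = baseline + shift + rng.normal(0.0, spec.noise_sd, size=shift.shape)
    tpm = np.exp2(log2_expr)

    width = len(str(n_total))
    sample_ids = [f"S{i:0{width}d}" for i in range(1, n_total + 1)]
    expression = pd.DataFrame(tpm, index=sample_ids, columns=genes)
    label_series = pd.Series(labels, index=sample_ids, name="label")

    # planted sets are pairwise disjoint by construction; assert on the manifest
    all_planted = [g for cls in PLANTED_CLASSES for g in planted[cls]]
    assert len(all_planted) == len(set(all_planted))

    return SyntheticDataset(
        hierarchy=hierarchy,
        expression=expression,
        labels=label_series,
        planted=planted,
        spec=spec,
    )


def strong_effect_preset() -> SyntheticSpec:
    """The frozen cohort used for end-to-end runs: 200 genes in 20 pathways
    of 10 under 4 superpathways, 100 samples per class, 20 planted genes per
    non-normal class, effect 2.0 and noise 0.5 on the log2 scale."""
    return SyntheticSpec(
        n_genes=200,
        n_pathways=20,
        n_superpathways=4,
        genes_per_pathway=10,
        samples_per_class=100,
        planted_per_class=20,
        effect_size=2.0,
        noise_sd=0.5,
        seed=20250711,
    )


def simulate(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Convenience: hierarchy + expression in one call."""
    spec = spec or strong_effect_preset()
    return generate_expression(spec, generate_hierarchy(spec))
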