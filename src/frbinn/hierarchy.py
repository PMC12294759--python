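"""Pathway hierarchies and the binary connectivity masks they induce.

A hierarchy is a layered DAG of biological entities: layer 0 holds genes,
layer 1 pathways, layer 2 superpathways (deeper stacks are allowed).  Every
edge connects adjacent layers.  The hierarchy is realised as a stack of
binary matrices ``S^l`` of shape ``(n_{l+1}, n_l)`` whose nonzeros are the
only connections the network is allowed to learn — the Hadamard product
``S ⊙ W`` in the forward pass zeroes every weight outside the prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROOT_NAME = "_ROOT"


class HierarchyError(ValueError):
    """Raised for structurally invalid gene-set / hierarchy input."""


@dataclass(frozen=True)
class PathwayHierarchy:
    """Layered entity names plus the membership edges between adjacent layers.

    Parameters
    ----------
    layers
        ``layers[0]`` are gene names, ``layers[1]`` pathway names, and so on
        upward.  Names are unique within a layer.
    edges
        Set of ``(child, parent)`` pairs; each pair connects some layer ``l``
        to layer ``l + 1``.
    """

    layers: tuple[tuple[str, ...], ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise HierarchyError("a hierarchy needs at least two layers")
        for i, layer in enumerate(self.layers):
            if len(set(layer)) != len(layer):
                raise HierarchyError(f"duplicate entity names in layer {i}")
        level = {}
        for i, layer in enumerate(self.layers):
            for name in layer:
                if name in level:
                    raise HierarchyError(f"entity {name!r} appears in two layers")
                level[name] = i
        parents: dict[str, int] = {}
        children: dict[str, int] = {}
        for child, parent in self.edges:
            if child not in level or parent not in level:
                raise HierarchyError(f"edge ({child!r}, {parent!r}) references unknown entity")
            if level[parent] != level[child] + 1:
                raise HierarchyError(
                    f"edge ({child!r}, {parent!r}) does not connect adjacent layers"
                )
            parents[child] = parents.get(child, 0) + 1
            children[parent] = children.get(parent, 0) + 1
        for gene in self.layers[0]:
            if parents.get(gene, 0) == 0:
                raise HierarchyError(f"gene {gene!r} has no parent pathway")
        for layer in self.layers[1:]:
            for name in layer:
                if children.get(name, 0) == 0:
                    raise HierarchyError(f"entity {name!r} has no children")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def genes(self) -> tuple[str, ...]:
        return self.layers[0]


@dataclass(frozen=True)
class MaskStack:
    """Binary connectivity matrices, one per pair of adjacent layers.

    ``masks[l]`` is a DataFrame with one row per layer-``l+1`` entity and one
    column per layer-``l`` entity (values 0/1); row and column labels carry
    the entity names, sorted lexicographically for run-to-run determinism.
    """

    masks: tuple[pd.DataFrame, ...] = field()

    def __post_init__(self) -> None:
        for l, m in enumerate(self.masks):
            values = m.to_numpy()
            if not np.isin(values, (0, 1)).all():
                raise HierarchyError(f"mask {l} has entries outside {{0, 1}}")
            if (values.sum(axis=1) == 0).any():
                raise HierarchyError(f"mask {l} has an all-zero row")
            if (values.sum(axis=0) == 0).any():
                raise HierarchyError(f"mask {l} has an all-zero column")
            if l > 0 and list(m.columns) != list(self.masks[l - 1].index):
                raise HierarchyError(
                    f"mask {l} columns do not match mask {l - 1} rows"
                )

    @property
    def gene_names(self) -> list[str]:
        return list(self.masks[0].columns)

    @property
    def layer_names(self) -> list[list[str]]:
        """Entity names per layer, genes first."""
        return [list(self.masks[0].columns)] + [list(m.index) for m in self.masks]

    def arrays(self) -> list[np.ndarray]:
        return [m.to_numpy(dtype=float) for m in self.masks]

    def nnz(self) -> list[int]:
        return [int(m.to_numpy().sum()) for m in self.masks]


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are collapsed, keeping first-appearance
    order.  Blank lines are ignored.

    Raises
    ------
    HierarchyError
        If a non-blank line has fewer than three tab-separated fields; the
        message names the offending line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise HierarchyError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if name in sets:
                raise HierarchyError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def build_hierarchy(
    gene_sets: dict[str, list[str]],
    pathway_edges: list[tuple[str, str]] | None = None,
) -> PathwayHierarchy:
    """Assemble a three-layer gene → pathway → superpathway hierarchy.

    ``pathway_edges`` are ``(pathway, superpathway)`` pairs; a pathway with no
    parent is attached to a synthetic root superpathway ``"_ROOT"`` so that
    incomplete hierarchy files still yield a valid network.  Deeper stacks can
    be built by chaining: the superpathway names of one call may serve as the
    set names of another (see :func:`stack_hierarchy`).

    Raises
    ------
    HierarchyError
        If the resulting gene layer is empty, an edge references an unknown
        pathway, or the pathway/superpathway edges contain a name on both
        sides (which would make the layer assignment cyclic).
    """
    pathway_edges = list(pathway_edges or [])
    pathways = list(gene_sets)
    if not pathways:
        raise HierarchyError("no gene sets given")
    known = set(pathways)
    for child, parent in pathway_edges:
        if child not in known:
            raise HierarchyError(f"edge child {child!r} is not a gene-set name")
        if parent in known:
            raise HierarchyError(
                f"edge parent {parent!r} is also a gene-set name; "
                "pathway/superpathway layers must be disjoint"
            )

    genes = list(dict.fromkeys(g for members in gene_sets.values() for g in members))
    if not genes:
        raise HierarchyError("gene layer is empty: every gene set is empty")

    parent_of: dict[str, list[str]] = {p: [] for p in pathways}
    for child, parent in pathway_edges:
        parent_of[child].append(parent)
    superpathways = list(dict.fromkeys(parent for _, parent in pathway_edges))
    orphans = [p for p in pathways if not parent_of[p]]
    if orphans:
        logger.warning(
            "%d pathway(s) without a parent attached to %s: %s",
            len(orphans), ROOT_NAME, ", ".join(orphans),
        )
        superpathways.append(ROOT_NAME)
        for p in orphans:
            parent_of[p].append(ROOT_NAME)

    edges: set[tuple[str, str]] = set()
    for name, members in gene_sets.items():
        for g in members:
            edges.add((g, name))
    for p, parents in parent_of.items():
        for sp in parents:
            edges.add((p, sp))

    return PathwayHierarchy(
        layers=(tuple(genes), tuple(pathways), tuple(superpathways)),
        edges=frozenset(edges),
    )


def build_masks(hierarchy: PathwayHierarchy) -> MaskStack:
    """Realise a hierarchy as its stack of binary mask matrices.

    Entity names are sorted lexicographically within each layer, so the
    matrices — and everything downstream of them — are bit-for-bit
    reproducible from identical input files.
    """
    ordered = [sorted(layer) for layer in hierarchy.layers]
    masks = []
    for l in range(hierarchy.n_layers - 1):
        cols = ordered[l]
        rows = ordered[l + 1]
        col_idx = {c: j for j, c in enumerate(cols)}
        row_idx = {r: i for i, r in enumerate(rows)}
        m = np.zeros((len(rows), len(cols)), dtype=np.int8)
        for child, parent in hierarchy.edges:
            if child in col_idx and parent in row_idx:
                m[row_idx[parent], col_idx[child]] = 1
        masks.append(pd.DataFrame(m, index=rows, columns=cols))
    return MaskStack(masks=tuple(masks))


def parameter_count(mask_stack: MaskStack, n_classes: int) -> int:
    """Number of trainable parameters of the masked network.

    Counts one weight per mask nonzero, one bias per hidden neuron, and the
    dense output head (``n_classes × last-layer width + n_classes``).
    """
    nnz = sum(mask_stack.nnz())
    biases = sum(m.shape[0] for m in mask_stack.masks)
    last_width = mask_stack.masks[-1].shape[0]
    return nnz + biases + n_classes * last_width + n_classes


def dense_parameter_count(mask_stack: MaskStack, n_classes: int) -> int:
    """Parameter count of a fully connected network of the same shape."""
    dense = sum(m.shape[0] * m.shape[1] for m in mask_stack.masks)
    biases = sum(m.shape[0] for m in mask_stack.masks)
    last_width = mask_stack.masks[-1].shape[0]
    return dense + biases + n_classes * last_width + n_classes
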