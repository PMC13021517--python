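"""Synthetic single-cell atlases with ontology structure and study shift.

This generator produces the three statistical features that motivate
hierarchy-aware training, without any external download:

* **hierarchically clustered counts** — each leaf cell type carries a
  marker-gene program; counts are negative-binomial (the standard
  scRNA-seq count family) around the program mean, scaled to a target
  library size;
* **mixed-granularity annotations** — with probability ``gamma`` a cell's
  leaf label is coarsened to a uniformly chosen strict ancestor,
  emulating studies that annotate "T cell" where others say
  "CD4-positive, alpha-beta T cell";
* **study-level distribution shift** — every study multiplies each gene's
  mean by a log-normal factor, so held-out studies form a genuine
  out-of-distribution test.

Donors are simulated as contiguous cell blocks within a study, so the
in-distribution split can be donor-partitioned (never split by cell).

Everything is bitwise reproducible given the config and seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from celldag.ontology import Ontology

__all__ = [
    "SimConfig",
    "SyntheticAtlas",
    "generate_ontology",
    "simulate_counts",
    "coarsen_labels",
    "split_id_ood",
    "normalize",
    "apply_inclusion_filters",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic atlas.

    Defaults give a small but non-trivial benchmark: an 8-leaf ontology of
    depth <= 3 with occasional multi-parent terms, 64 genes of which 5 per
    leaf are markers (8-fold elevated), overdispersed counts at ~2,000
    total counts per cell, 40% of labels coarsened to an ancestor, and 4
    studies of 400 cells / 4 donors with a gene-wise log-normal study
    effect of sd 0.6.
    """

    n_leaves: int = 8
    max_depth: int = 3
    extra_edge_prob: float = 0.1
    n_genes: int = 64
    markers_per_leaf: int = 5
    marker_fold: float = 8.0
    nb_mean: float = 1.0
    nb_dispersion: float = 2.0
    library_size_target: float = 2000.0
    granularity_gamma: float = 0.4
    n_studies: int = 4
    study_effect_sd: float = 0.6
    cells_per_study: int = 400
    donors_per_study: int = 4
    seed: int = 0

    def __post_init__(self):
        for name in ("extra_edge_prob", "granularity_gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "n_leaves",
            "n_genes",
            "markers_per_leaf",
            "marker_fold",
            "nb_mean",
            "nb_dispersion",
            "library_size_target",
            "n_studies",
            "cells_per_study",
            "donors_per_study",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.max_depth < 0:
            raise ValueError(f"max_depth must be >= 0, got {self.max_depth}")
        if self.study_effect_sd < 0:
            raise ValueError(
                f"study_effect_sd must be >= 0, got {self.study_effect_sd}"
            )
        if self.n_genes < self.n_leaves * self.markers_per_leaf:
            raise ValueError(
                "n_genes must be at least n_leaves * markers_per_leaf "
                f"({self.n_leaves * self.markers_per_leaf}), got {self.n_genes}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig field(s): {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class SyntheticAtlas:
    """A simulated cells x genes count matrix with ontology labels.

    ``observed_label`` equals ``true_label`` or one of its strict
    ancestors (mixed annotation granularity); ``study_id``/``donor_id``
    drive the out-of-distribution and donor-partitioned splits.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    true_label: np.ndarray
    observed_label: np.ndarray
    study_id: np.ndarray
    donor_id: np.ndarray
    ontology: Ontology

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def studies(self) -> list[str]:
        return sorted(set(self.study_id))

    def subset(self, mask: np.ndarray) -> "SyntheticAtlas":
        mask = np.asarray(mask)
        return replace(
            self,
            counts=self.counts[mask],
            cell_ids=self.cell_ids[mask],
            true_label=self.true_label[mask],
            observed_label=self.observed_label[mask],
            study_id=self.study_id[mask],
            donor_id=self.donor_id[mask],
        )

    # ------------------------------------------------------------------
    # disk round-trip: MatrixMarket counts + TSV metadata + edge list
    # ------------------------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "counts.mtx"), self.counts.astype(np.int64))
        pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "true_label": self.true_label,
                "observed_label": self.observed_label,
                "study_id": self.study_id,
                "donor_id": self.donor_id,
            }
        ).to_csv(outdir / "cells.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": self.gene_ids}).to_csv(
            outdir / "genes.tsv", sep="\t", index=False
        )
        self.ontology.to_edgelist(outdir / "ontology.tsv")

    @classmethod
    def read(cls, indir: str | Path) -> "SyntheticAtlas":
        indir = Path(indir)
        counts = sp.csr_matrix(scipy.io.mmread(str(indir / "counts.mtx")))
        cells = pd.read_csv(indir / "cells.tsv", sep="\t", dtype=str)
        genes = pd.read_csv(indir / "genes.tsv", sep="\t", dtype=str)
        return cls(
            counts=counts,
            cell_ids=cells["cell_id"].to_numpy(),
            gene_ids=genes["gene_id"].to_numpy(),
            true_label=cells["true_label"].to_numpy(),
            observed_label=cells["observed_label"].to_numpy(),
            study_id=cells["study_id"].to_numpy(),
            donor_id=cells["donor_id"].to_numpy(),
            ontology=Ontology.from_edgelist(indir / "ontology.tsv"),
        )


# ----------------------------------------------------------------------
# ontology generation
# ----------------------------------------------------------------------
def generate_ontology(cfg: SimConfig) -> Ontology:
    """A rooted random DAG with exactly ``n_leaves`` leaves, depth <= max_depth.

    A random tree is grown first (random branching, 2-3 children per
    internal node); then each non-root internal node independently gains an
    extra parent with probability ``extra_edge_prob``, chosen among
    internal nodes that are not its descendants — multi-parent terms
    without cycles, and without changing the leaf set.
    """
    if cfg.n_leaves > 1 and cfg.max_depth < 1:
        raise ValueError(
            f"cannot place {cfg.n_leaves} leaves under a root with max_depth=0"
        )
    rng = np.random.default_rng([cfg.seed, 0])
    counters = {"leaf": 0, "internal": 0}
    names: dict[str, str] = {}
    edges: list[tuple[str, str]] = []

    def new_node(kind: str) -> str:
        i = counters[kind]
        counters[kind] += 1
        node = f"CT:{'L' if kind == 'leaf' else 'N'}{i:04d}"
        names[node] = f"{'cell type' if kind == 'leaf' else 'cell group'} {i}"
        return node

    def build(n: int, depth: int) -> str:
        if n == 1:
            return new_node("leaf")
        node = new_node("internal")
        if depth == 1:
            parts = [1] * n
        else:
            k = int(rng.integers(2, min(n, 3) + 1))
            cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False))
            parts = np.diff(np.concatenate(([0], cuts, [n]))).tolist()
        for part in parts:
            child = build(int(part), depth - 1)
            edges.append((child, node))
        return node

    root = build(cfg.n_leaves, cfg.max_depth)

    if cfg.extra_edge_prob > 0 and counters["internal"] > 2:
        import networkx as nx

        g = nx.DiGraph(edges)  # child -> parent
        internals = sorted(n for n in g.nodes if n.startswith("CT:N"))
        for v in internals:
            if v == root or rng.random() >= cfg.extra_edge_prob:
                continue
            blocked = nx.ancestors(g, v) | {v} | set(g.successors(v))
            candidates = [u for u in internals if u not in blocked]
            if candidates:
                parent = candidates[int(rng.integers(len(candidates)))]
                edges.append((v, parent))
                g.add_edge(v, parent)

    return Ontology(names.keys(), edges, names=names)


# ----------------------------------------------------------------------
# count simulation
# ----------------------------------------------------------------------
def simulate_counts(dag: Ontology, cfg: SimConfig) -> SyntheticAtlas:
    """Draw cells from per-leaf expression programs with study effects.

    Each cell picks a leaf uniformly; the leaf's program elevates its
    marker block ``marker_fold``-fold over the flat baseline, rescaled so
    program means sum to ``library_size_target``.  Study effects multiply
    gene means by ``exp(N(0, study_effect_sd))`` (then rescale, so the
    shift is compositional).  Counts are negative binomial with dispersion
    ``nb_dispersion`` (``inf`` selects the Poisson limit).
    """
    taxonomy = dag.classify_nodes()
    leaves = [n for n, is_leaf in zip(dag.node_ids, taxonomy.is_leaf) if is_leaf]
    if not leaves:
        raise ValueError("ontology has no leaves")
    if cfg.n_genes < len(leaves) * cfg.markers_per_leaf:
        raise ValueError("n_genes too small for the requested marker blocks")

    rng = np.random.default_rng([cfg.seed, 1])
    g = cfg.n_genes
    programs = np.full((len(leaves), g), cfg.nb_mean, dtype=np.float64)
    for i in range(len(leaves)):
        block = slice(i * cfg.markers_per_leaf, (i + 1) * cfg.markers_per_leaf)
        programs[i, block] *= cfg.marker_fold
    programs *= cfg.library_size_target / programs.sum(axis=1, keepdims=True)

    study_factors = np.exp(
        rng.normal(0.0, cfg.study_effect_sd, size=(cfg.n_studies, g))
    )

    blocks, leaf_idx_all, study_all, donor_all, cell_ids = [], [], [], [], []
    for s in range(cfg.n_studies):
        n = cfg.cells_per_study
        leaf_idx = rng.integers(len(leaves), size=n)
        means = programs[leaf_idx] * study_factors[s]
        means *= cfg.library_size_target / means.sum(axis=1, keepdims=True)
        if np.isinf(cfg.nb_dispersion):
            counts = rng.poisson(means)
        else:
            theta = cfg.nb_dispersion
            counts = rng.negative_binomial(theta, theta / (theta + means))
        blocks.append(counts)
        leaf_idx_all.append(leaf_idx)
        study_all.extend([f"study{s}"] * n)
        donor_all.extend(
            f"study{s}_donor{d}" for d in np.arange(n) * cfg.donors_per_study // n
        )
        cell_ids.extend(f"study{s}_cell{i:05d}" for i in range(n))

    leaf_idx_all = np.concatenate(leaf_idx_all)
    labels = np.array(leaves, dtype=object)[leaf_idx_all].astype(str)
    return SyntheticAtlas(
        counts=sp.csr_matrix(np.vstack(blocks), dtype=np.int64),
        cell_ids=np.array(cell_ids),
        gene_ids=np.array([f"gene{j:04d}" for j in range(g)]),
        true_label=labels,
        observed_label=labels.copy(),
        study_id=np.array(study_all),
        donor_id=np.array(donor_all),
        ontology=dag,
    )


def coarsen_labels(atlas: SyntheticAtlas, gamma: float, seed: int) -> SyntheticAtlas:
    """Mixed-granularity annotation: coarsen each label with probability gamma.

    Independently per cell, with probability ``gamma`` the leaf label is
    replaced by a uniformly chosen strict ancestor (the root included);
    otherwise the leaf label is kept.  Labels whose term has no ancestors
    are never coarsened.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    rng = np.random.default_rng(seed)
    ancestors = {
        label: sorted(atlas.ontology.ancestors(label))
        for label in np.unique(atlas.true_label)
    }
    coarsen = rng.random(atlas.n_cells) < gamma
    observed = atlas.true_label.copy()
    for i in np.flatnonzero(coarsen):
        anc = ancestors[atlas.true_label[i]]
        if anc:
            observed[i] = anc[int(rng.integers(len(anc)))]
    return replace(atlas, observed_label=observed)


def split_id_ood(
    atlas: SyntheticAtlas,
    held_out_studies: Iterable[str],
    id_test_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[SyntheticAtlas, SyntheticAtlas, SyntheticAtlas]:
    """(train, id_test, ood_test) split by study and donor.

    The OOD test set contains every cell of the held-out studies.  The
    remaining cells are partitioned by donor, never by cell: within each
    retained study a fraction of donors (at least one) is assigned to the
    in-distribution test set, the rest to training.
    """
    held_out = set(held_out_studies)
    studies = set(atlas.studies)
    if not held_out:
        raise ValueError("held_out_studies must be nonempty")
    unknown = held_out - studies
    if unknown:
        raise ValueError(f"unknown study id(s): {sorted(unknown)}")
    if held_out == studies:
        raise ValueError("cannot hold out every study: nothing left to train on")

    rng = np.random.default_rng(seed)
    ood_mask = np.isin(atlas.study_id, sorted(held_out))
    id_test_mask = np.zeros(atlas.n_cells, dtype=bool)
    for study in sorted(studies - held_out):
        donors = sorted(set(atlas.donor_id[atlas.study_id == study]))
        n_test = max(1, int(round(id_test_fraction * len(donors))))
        if n_test >= len(donors):
            raise ValueError(
                f"id_test_fraction={id_test_fraction} leaves no training donors "
                f"in {study}"
            )
        chosen = rng.permutation(donors)[:n_test]
        id_test_mask |= np.isin(atlas.donor_id, chosen)
    train_mask = ~(ood_mask | id_test_mask)
    return atlas.subset(train_mask), atlas.subset(id_test_mask), atlas.subset(ood_mask)


def normalize(counts, target: float = 1e4, cell_ids: Sequence[str] | None = None):
    """Size-factor normalize to ``target`` counts per cell, then log(x + 1).

    Every cell's counts are scaled to a fixed total of 10,000 (by default)
    and natural-log transformed with a pseudocount of one.  Sparse input
    yields sparse output.  Cells with zero total counts are rejected with
    their identifiers listed.
    """
    sparse = sp.issparse(counts)
    if sparse:
        counts = counts.tocsr()
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        totals = np.asarray(counts.sum(axis=1)).ravel()
    else:
        counts = np.asarray(counts, dtype=np.float64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = (
            [str(cell_ids[i]) for i in zero]
            if cell_ids is not None
            else [str(i) for i in zero]
        )
        raise ValueError(
            f"{zero.size} cell(s) have zero total counts: {', '.join(ids[:10])}"
            + (" ..." if zero.size > 10 else "")
        )
    scale = target / totals
    if sparse:
        out = sp.diags(scale) @ counts.astype(np.float64)
        out = out.tocsr()
        out.data = np.log1p(out.data)
        return out
    return np.log1p(counts * scale[:, None])


def apply_inclusion_filters(
    atlas: SyntheticAtlas, min_cells: int = 5000, min_donors: int = 30
) -> tuple[SyntheticAtlas, dict[str, str]]:
    """Drop label classes below the cell- or donor-count thresholds.

    Mirrors atlas curation practice: a cell type must appear in at least
    ``min_cells`` cells drawn from at least ``min_donors`` donors, or the
    class and all its cells are removed.  Returns the filtered atlas and a
    report of the dropped classes with the reason.
    """
    if min_cells < 0 or min_donors < 0:
        raise ValueError("thresholds must be >= 0")
    dropped: dict[str, str] = {}
    keep_mask = np.ones(atlas.n_cells, dtype=bool)
    for label in np.unique(atlas.observed_label):
        mask = atlas.observed_label == label
        n_cells = int(mask.sum())
        n_donors = len(set(atlas.donor_id[mask]))
        reasons = []
        if n_cells < min_cells:
            reasons.append(f"{n_cells} cells < {min_cells}")
        if n_donors < min_donors:
            reasons.append(f"{n_donors} donors < {min_donors}")
        if reasons:
            dropped[str(label)] = "; ".join(reasons)
            keep_mask &= ~mask
    if not keep_mask.any():
        raise ValueError(
            "inclusion filters removed every class; thresholds too strict"
        )
    return atlas.subset(keep_mask), dropped
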