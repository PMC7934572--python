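"""Genetic distances, neighbour-joining trees and classical MDS ordination.

Distances between accessions are Jukes–Cantor corrections of a
genotype-mismatch proportion: at each site shared (non-missing) by a pair,
opposite homozygotes mismatch with weight 1, a heterozygote against a
homozygote with weight 0.5 (the expected allele-sharing under a random
allele draw) and identical genotypes with 0.  Trees are built with the
canonical Saitou–Nei agglomeration and optionally rooted on the pendant
edge of an outgroup accession.  Ordination is classical multidimensional
scaling (PCoA) of Euclidean dosage distances, whose leading axes double as
GWAS covariates.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .vcfio import GenotypePanel, impute_missing

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "jc69_distances",
    "neighbor_joining",
    "pcoa",
    "gwas_covariates",
]


@dataclass
class DistanceMatrix:
    """Symmetric JC69-corrected distances with the raw mismatch proportions."""

    sample_ids: list[str]
    d: np.ndarray  # corrected distances; inf where p >= 0.75
    p: np.ndarray  # observed mismatch proportions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    """Classical-MDS embedding with eigenvalues and percent variance."""

    coordinates: pd.DataFrame  # samples × axes, columns PC1..PCk
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # per returned axis, over positive eigenvalues


def jc69_distances(
    panel: GenotypePanel, monomorphic_inflation: float = 1.0
) -> DistanceMatrix:
    """Pairwise Jukes–Cantor distances from genotype mismatch proportions.

    p is computed over sites non-missing in both samples;
    d = −(3/4)·ln(1 − (4/3)p), flagged infinite where p ≥ 0.75.
    ``monomorphic_inflation`` ≥ 1 divides p to emulate dilution by invariant
    genome positions (1.0 = variant sites only).
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if monomorphic_inflation < 1.0:
        raise ValueError("monomorphic_inflation must be >= 1")

    x = panel.dosages / 2.0  # {0, 0.5, 1}
    valid = (~np.isnan(x)).astype(float)
    z = np.nan_to_num(x, nan=0.0)
    het = np.nan_to_num((panel.dosages == 1.0).astype(float), nan=0.0) * valid

    shared = valid @ valid.T
    sq = (z * z) @ valid.T
    cross = z @ z.T
    habs = het @ valid.T
    hcross = het @ het.T
    # |a-b| = (a-b)^2 + 0.25 * (het(a) xor het(b)) for dosage/2 values
    mismatch = sq + sq.T - 2.0 * cross + 0.25 * (habs + habs.T - 2.0 * hcross)

    if np.any(shared[~np.eye(panel.n_samples, dtype=bool)] == 0):
        ii, jj = np.where((shared == 0) & ~np.eye(panel.n_samples, dtype=bool))
        pairs = [
            (panel.samples[a], panel.samples[b]) for a, b in zip(ii, jj) if a < b
        ]
        raise ValueError(f"no shared non-missing sites for pairs: {pairs}")

    with np.errstate(invalid="ignore", divide="ignore"):
        p = mismatch / shared
    p /= monomorphic_inflation
    p = np.clip((p + p.T) / 2.0, 0.0, None)  # symmetrize numerical noise
    np.fill_diagonal(p, 0.0)

    d = np.full_like(p, np.inf)
    ok = p < 0.75
    d[ok] = -0.75 * np.log1p(-(4.0 / 3.0) * p[ok])
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(panel.samples), d, p)


def _nj_join_order(d: np.ndarray):
    """Run Saitou–Nei agglomeration; yield joins and final triplet.

    Works on a growing node index space: leaves 0..n-1, internals appended.
    Ties on the Q criterion break to the lexicographically smallest active
    index pair (deterministic).
    """
    n = d.shape[0]
    active = list(range(n))
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(n) if i < j
    }
    next_id = n
    joins = []  # (new_id, child_i, length_i, child_j, length_j)

    def get(i, j):
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # truncate a negative limb to 0, moving the deficit to its sibling
        if li < 0.0:
            lj = max(lj + li, 0.0)
            li = 0.0
        elif lj < 0.0:
            li = max(li + lj, 0.0)
            lj = 0.0
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(min(u, k), max(u, k))] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]
        joins.append((u, i, li, j, lj))

    return joins, active, get


def neighbor_joining(
    dm: DistanceMatrix | tuple[list[str], np.ndarray],
    outgroup: str | None = None,
) -> TreeNode:
    """Neighbour-joining tree (Saitou–Nei) with optional outgroup rooting.

    Negative limb lengths are truncated to 0 with the deficit moved to the
    sibling branch.  With an outgroup, the root is placed at the midpoint of
    the outgroup's pendant edge; otherwise the tree keeps the unrooted
    trifurcation at the last join.  Returns a scikit-bio TreeNode.
    """
    if isinstance(dm, DistanceMatrix):
        ids, d = dm.sample_ids, dm.d
    else:
        ids, d = dm
        d = np.asarray(d, dtype=float)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if np.isnan(d).any() or np.isinf(d).any():
        raise ValueError("distance matrix contains NaN/inf entries")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    if outgroup is not None and outgroup not in ids:
        raise ValueError(f"outgroup {outgroup!r} not among sample ids")

    joins, active, get = _nj_join_order(d)

    # adjacency of the unrooted tree
    adj: dict[int, list[tuple[int, float]]] = {}

    def link(a, b, ln):
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))

    for u, i, li, j, lj in joins:
        link(u, i, li)
        link(u, j, lj)

    if len(active) == 3:
        x, y, z = active
        hub = max(max(adj, default=n - 1), max(active)) + 1
        dxy, dxz, dyz = get(x, y), get(x, z), get(y, z)
        lx = max(0.5 * (dxy + dxz - dyz), 0.0)
        ly = max(0.5 * (dxy + dyz - dxz), 0.0)
        lz = max(0.5 * (dxz + dyz - dxy), 0.0)
        link(hub, x, lx)
        link(hub, y, ly)
        link(hub, z, lz)
        root_node = hub
    else:  # exactly 2 active nodes (n == 2 is excluded above)
        a, b = active
        link(a, b, get(a, b))
        root_node = a

    def name_of(i: int) -> str | None:
        return ids[i] if i < n else None

    def newick(node: int, parent: int | None) -> str:
        children = [(c, ln) for c, ln in adj[node] if c != parent]
        label = name_of(node) or ""
        if not children:
            return label
        inner = ",".join(f"{newick(c, node)}:{ln:.10g}" for c, ln in children)
        return f"({inner}){label}"

    if outgroup is None:
        tree_str = newick(root_node, None) + ";"
    else:
        og = ids.index(outgroup)
        (inner_node, pend_len), = adj[og]
        half = pend_len / 2.0
        rest = newick(inner_node, og)
        tree_str = f"({name_of(og)}:{half:.10g},{rest}:{half:.10g});"
    return TreeNode.read(io.StringIO(tree_str))


def pcoa(
    data: GenotypePanel | DistanceMatrix | tuple[list[str], np.ndarray],
    k: int = 2,
) -> OrdinationResult:
    """Classical multidimensional scaling (principal coordinates).

    Given a panel, distances are Euclidean on mean-imputed,
    variant-centered dosages.  Coordinates are eigenvector·√eigenvalue of
    the double-centered squared-distance matrix; negative eigenvalues are
    excluded from the percent-variance denominator.  Requested axes beyond
    the positive-eigenvalue count are truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(data, GenotypePanel):
        ids = list(data.samples)
        x = impute_missing(data, mode="mean").dosages
        x = x - x.mean(axis=0, keepdims=True)
        dmat = squareform(pdist(x))
    elif isinstance(data, DistanceMatrix):
        ids, dmat = data.sample_ids, data.d
    else:
        ids, dmat = data
        dmat = np.asarray(dmat, dtype=float)

    n = len(ids)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dmat ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    pos = evals > max(1e-10 * max(evals.max(), 1.0), 0.0)
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating"
        )
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    pct = 100.0 * evals[:k] / evals[pos].sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        eigenvalues=evals,
        percent_variance=pct,
    )


def gwas_covariates(panel: GenotypePanel, n_pcs: int = 2) -> np.ndarray:
    """Leading ordination axes of the marker panel, for use as fixed effects."""
    return pcoa(panel, k=n_pcs).coordinates.to_numpy()
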