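"""Tamura-3-parameter (T92) distances, NJ/BioNJ trees and ML topology selection.

The phylogeographic workflow mirrors standard forensic practice for placing
query mitotypes among population reference lineages:

1. pairwise distances under the Tamura 3-parameter model, which accounts for
   transition/transversion bias and G+C content θ:

       d = -h·ln(1 - P/h - Q) - (1/2)(1-h)·ln(1 - 2Q),   h = 2θ(1-θ)

   with P and Q the transition and transversion fractions over comparable
   sites (pairwise deletion of gaps and 'N');
2. starting topologies from Neighbour-Joining and BioNJ applied to that
   distance matrix;
3. Felsenstein-pruning log-likelihood under the T92 substitution model
   (stationary frequencies πG=πC=θ/2, πA=πT=(1-θ)/2, transition/transversion
   rate ratio κ, matrix normalised to one expected substitution per unit
   branch length), per-branch scalar optimisation, and selection of the
   topology with the superior log-likelihood;
4. a clade-label report summarising which population each query clusters with.

Trees are :class:`dendropy.Tree` objects (newick I/O via dendropy); rate
heterogeneity is deliberately not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

_STATES = "ACGT"
_CODE = {b: i for i, b in enumerate(_STATES)}
# transitions: A<->G (purines), C<->T (pyrimidines)
_IS_TRANSITION = np.zeros((4, 4), dtype=bool)
for _i, _j in ((0, 2), (2, 0), (1, 3), (3, 1)):
    _IS_TRANSITION[_i, _j] = True


class PhyloError(ValueError):
    """Invalid phylogenetic input."""


class SaturationError(PhyloError):
    """Distance undefined: sequences too diverged for the T92 correction."""


# ---------------------------------------------------------------------------
# Alignment


@dataclass
class Alignment:
    """Equal-length sequences over {A,C,G,T,-,N} with optional taxon labels."""

    ids: list[str]
    seqs: list[str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise PhyloError("ids and seqs must align")
        if len(set(self.ids)) != len(self.ids):
            raise PhyloError("duplicate taxon ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise PhyloError(f"rows have unequal lengths: {sorted(lengths)}")
        bad = set("".join(self.seqs).upper()) - set("ACGTN-")
        if bad:
            raise PhyloError(f"invalid characters in alignment: {sorted(bad)}")
        self.seqs = [s.upper() for s in self.seqs]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def encoded(self) -> np.ndarray:
        """(n_taxa, n_sites) int8 matrix; A..T → 0..3, gap/N → -1 (missing)."""
        arr = np.full((len(self.ids), self.n_sites), -1, dtype=np.int8)
        for i, s in enumerate(self.seqs):
            row = np.frombuffer(s.encode(), dtype=np.uint8)
            for base, code in _CODE.items():
                arr[i, row == ord(base)] = code
        return arr

    @classmethod
    def from_fasta(cls, path, labels: Mapping[str, str] | None = None) -> "Alignment":
        from Bio import SeqIO

        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        return cls(ids, seqs, dict(labels or {}))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.ids, self.seqs):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def estimate_theta(alignment: Alignment) -> float:
    """Alignment-wide G+C fraction over non-missing sites (θ of the T92 model)."""
    arr = alignment.encoded()
    valid = arr >= 0
    total = int(valid.sum())
    if total == 0:
        raise PhyloError("alignment has no non-missing sites")
    gc = int(((arr == 1) | (arr == 2)).sum())
    theta = gc / total
    # keep strictly inside (0, 1): a degenerate composition still defines a model
    return float(min(max(theta, 1e-6), 1 - 1e-6))


# ---------------------------------------------------------------------------
# T92 distance


def t92_distance(s1: str, s2: str, theta: float) -> float:
    """Pairwise T92 distance (substitutions/site), pairwise-deletion of gaps/N."""
    if len(s1) != len(s2):
        raise PhyloError("sequences must have equal length")
    if not 0 < theta < 1:
        raise PhyloError(f"theta must lie in (0, 1), got {theta}")
    a1 = np.array([_CODE.get(c, -1) for c in s1.upper()], dtype=np.int8)
    a2 = np.array([_CODE.get(c, -1) for c in s2.upper()], dtype=np.int8)
    ok = (a1 >= 0) & (a2 >= 0)
    m = int(ok.sum())
    if m == 0:
        raise PhyloError("zero comparable sites")
    x, y = a1[ok], a2[ok]
    diff = x != y
    ts = int((_IS_TRANSITION[x, y] & diff).sum())
    tv = int(diff.sum()) - ts
    P, Q = ts / m, tv / m
    h = 2.0 * theta * (1.0 - theta)
    arg1 = 1.0 - P / h - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(
            f"T92 distance undefined (P={P:.4f}, Q={Q:.4f}, theta={theta:.4f})"
        )
    return float(-h * np.log(arg1) - 0.5 * (1.0 - h) * np.log(arg2))


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with taxon order."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise PhyloError("matrix shape does not match taxa")
        if not np.all(np.isfinite(m)):
            raise PhyloError("distance matrix contains non-finite entries")
        if not np.allclose(m, m.T, atol=1e-12):
            raise PhyloError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise PhyloError("distance matrix diagonal is not zero")
        if np.any(m < -1e-12):
            raise PhyloError("distance matrix has negative entries")
        self.matrix = m

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.matrix[i, j])


def build_distance_matrix(
    alignment: Alignment,
    theta: float | None = None,
    per_pair_theta: bool = False,
) -> DistanceMatrix:
    """All pairwise T92 distances.

    θ defaults to a single alignment-wide estimate; ``per_pair_theta``
    re-estimates G+C content for each pair instead.  Saturation errors name
    the offending pair.
    """
    if len(alignment) < 2:
        raise PhyloError("need at least 2 taxa")
    n = len(alignment)
    shared_theta = theta if theta is not None else estimate_theta(alignment)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            th = shared_theta
            if per_pair_theta and theta is None:
                th = estimate_theta(
                    Alignment(
                        [alignment.ids[i], alignment.ids[j]],
                        [alignment.seqs[i], alignment.seqs[j]],
                    )
                )
            try:
                d = t92_distance(alignment.seqs[i], alignment.seqs[j], th)
            except PhyloError as err:
                raise type(err)(
                    f"pair ({alignment.ids[i]}, {alignment.ids[j]}): {err}"
                ) from err
            m[i, j] = m[j, i] = d
    return DistanceMatrix(list(alignment.ids), m)


# ---------------------------------------------------------------------------
# NJ / BioNJ


def _clamp_branch(length: float, context: str) -> float:
    if length < 0:
        logger.warning("negative branch length %.3g at %s clamped to 0", length, context)
        return 0.0
    return float(length)


def _agglomerate(dm: DistanceMatrix, bionj: bool) -> dendropy.Tree:
    """Shared NJ/BioNJ loop: Q-criterion joins; BioNJ adds variance weighting."""
    n = len(dm.taxa)
    if n < 3:
        raise PhyloError("tree building needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.taxa)
    nodes: list[dendropy.Node] = []
    for name in dm.taxa:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(node)
    D = dm.matrix.copy()
    V = D.copy()  # BioNJ variance estimates; unused for plain NJ

    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        Q = (r - 2) * D - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2 + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        li = _clamp_branch(li, f"join({i},{j})")
        lj = _clamp_branch(lj, f"join({i},{j})")
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        mask = np.ones(r, dtype=bool)
        mask[[i, j]] = False
        if bionj:
            vij = V[i, j]
            if vij > 1e-12:
                lam = 0.5 + (V[j, mask] - V[i, mask]).sum() / (2 * (r - 2) * vij)
                lam = float(min(max(lam, 0.0), 1.0))
            else:
                lam = 0.5
            new_d = lam * (D[i, mask] - li) + (1 - lam) * (D[j, mask] - lj)
            new_v = lam * V[i, mask] + (1 - lam) * V[j, mask] - lam * (1 - lam) * vij
        else:
            new_d = (D[i, mask] + D[j, mask] - D[i, j]) / 2
            new_v = new_d  # irrelevant for NJ

        keep = [k for k in range(r) if mask[k]]
        D_next = np.zeros((r - 1, r - 1))
        V_next = np.zeros((r - 1, r - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        V_next[:-1, :-1] = V[np.ix_(keep, keep)]
        D_next[-1, :-1] = D_next[:-1, -1] = new_d
        V_next[-1, :-1] = V_next[:-1, -1] = np.maximum(new_v, 0.0)
        D, V = D_next, V_next
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point resolution around an unrooted central node
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    root = dendropy.Node()
    for node, length in (
        (a, (dab + dac - dbc) / 2),
        (b, (dab + dbc - dac) / 2),
        (c, (dac + dbc - dab) / 2),
    ):
        root.add_child(node)
        node.edge.length = _clamp_branch(length, "final-three")
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic Neighbour-Joining (Saitou & Nei Q-criterion)."""
    return _agglomerate(dm, bionj=False)


def bionj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """BioNJ: NJ with variance-weighted distance reduction (Gascuel 1997)."""
    return _agglomerate(dm, bionj=True)


def build_tree(dm: DistanceMatrix, method: str = "nj") -> dendropy.Tree:
    method = method.lower()
    if method == "nj":
        return nj_tree(dm)
    if method == "bionj":
        return bionj_tree(dm)
    raise PhyloError(f"unknown tree method {method!r} (expected 'nj' or 'bionj')")


# ---------------------------------------------------------------------------
# T92 likelihood


@dataclass(frozen=True)
class T92Params:
    """T92 model parameters: G+C content θ and transition/transversion ratio κ."""

    theta: float = 0.5
    kappa: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise PhyloError(f"theta must lie in (0, 1), got {self.theta}")
        if self.kappa <= 0:
            raise PhyloError(f"kappa must be positive, got {self.kappa}")

    @property
    def pi(self) -> np.ndarray:
        t = self.theta
        return np.array([(1 - t) / 2, t / 2, t / 2, (1 - t) / 2])


class T92Model:
    """Eigendecomposed T92 rate matrix for fast transition probabilities."""

    def __init__(self, params: T92Params):
        self.params = params
        pi = params.pi
        q = np.where(_IS_TRANSITION, params.kappa, 1.0) * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        rate = -float(np.dot(pi, np.diag(q)))
        q /= rate  # one expected substitution per unit branch length
        self.Q = q
        sqrt_pi = np.sqrt(pi)
        sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        lam, u = eigh((sym + sym.T) / 2)
        self._lam = lam
        self._left = u / sqrt_pi[:, None]      # diag(pi^-1/2) @ U
        self._right = (u * sqrt_pi[:, None]).T  # U.T @ diag(pi^1/2)
        self.pi = pi

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one, all entries non-negative."""
        if t < 0:
            raise PhyloError(f"negative branch length {t}")
        p = (self._left * np.exp(self._lam * t)) @ self._right
        return np.clip(p, 0.0, None)


def _patterns(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    arr = alignment.encoded()
    patterns, counts = np.unique(arr, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _leaf_partials(patterns: np.ndarray) -> np.ndarray:
    """(n_taxa, 4, n_patterns) leaf conditionals; missing sites are all-ones."""
    n_taxa, n_pat = patterns.shape
    partials = np.zeros((n_taxa, 4, n_pat))
    for s in range(4):
        partials[:, s, :] = patterns == s
    partials[:, :, :] += (patterns == -1)[:, None, :]
    return partials


def _pruning_loglik(
    tree: dendropy.Tree,
    taxon_index: Mapping[str, int],
    leaf_partials: np.ndarray,
    counts: np.ndarray,
    model: T92Model,
) -> float:
    partial_of: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            if name not in taxon_index:
                raise PhyloError(f"tree leaf {name!r} not in alignment")
            partial_of[id(node)] = leaf_partials[taxon_index[name]]
        else:
            prod = None
            for child in node.child_nodes():
                t = child.edge.length if child.edge.length is not None else 0.0
                term = model.transition_matrix(t) @ partial_of.pop(id(child))
                prod = term if prod is None else prod * term
            partial_of[id(node)] = prod
    root_partial = partial_of[id(tree.seed_node)]
    site_lik = model.pi @ root_partial
    if np.any(site_lik <= 0):
        return -np.inf
    return float(np.dot(counts, np.log(site_lik)))


def t92_log_likelihood(
    tree: dendropy.Tree, alignment: Alignment, params: T92Params
) -> float:
    """Felsenstein-pruning log-likelihood of an alignment on a tree under T92.

    Gaps and 'N' are missing data (partial likelihood 1 in every state), so a
    column that is missing everywhere contributes exactly zero log-likelihood.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if leaves != set(alignment.ids):
        raise PhyloError(
            f"tree/alignment taxon mismatch: {sorted(leaves ^ set(alignment.ids))}"
        )
    patterns, counts = _patterns(alignment)
    taxon_index = {name: i for i, name in enumerate(alignment.ids)}
    return _pruning_loglik(
        tree, taxon_index, _leaf_partials(patterns), counts, T92Model(params)
    )


def _optimizable_edges(tree: dendropy.Tree) -> list[dendropy.Node]:
    return [n for n in tree.preorder_node_iter() if n.parent_node is not None]


def optimize_branch_lengths(
    tree: dendropy.Tree,
    alignment: Alignment,
    params: T92Params,
    max_branch: float = 10.0,
    tol: float = 1e-6,
    max_sweeps: int = 20,
) -> dendropy.Tree:
    """Coordinate-wise branch-length optimisation (in place; returns the tree).

    Each branch is optimised by bounded scalar search on [0, ``max_branch``]
    substitutions/site; sweeps repeat until the log-likelihood gain drops
    below ``tol`` or ``max_sweeps`` is reached.  The log-likelihood never
    decreases across sweeps (a proposed length is only accepted if it
    improves on the current one).
    """
    patterns, counts = _patterns(alignment)
    taxon_index = {name: i for i, name in enumerate(alignment.ids)}
    partials = _leaf_partials(patterns)
    model = T92Model(params)

    def loglik() -> float:
        return _pruning_loglik(tree, taxon_index, partials, counts, model)

    current = loglik()
    for _ in range(max_sweeps):
        before = current
        for node in _optimizable_edges(tree):
            old = node.edge.length if node.edge.length is not None else 0.0

            def neg(t: float, _node=node) -> float:
                _node.edge.length = float(t)
                return -loglik()

            res = minimize_scalar(neg, bounds=(0.0, max_branch), method="bounded")
            if res.success and -res.fun > current:
                node.edge.length = float(res.x)
                current = -res.fun
            else:
                node.edge.length = old
        if current - before < tol:
            break
    return tree


@dataclass
class TreeFit:
    """An optimised tree with its model parameters and log-likelihood."""

    tree: dendropy.Tree
    params: T92Params
    loglik: float


def fit_tree(
    tree: dendropy.Tree,
    alignment: Alignment,
    theta: float | None = None,
    kappa: float = 4.0,
    optimize_kappa: bool = True,
    kappa_bounds: tuple[float, float] = (0.1, 100.0),
    rounds: int = 2,
    **branch_kwargs,
) -> TreeFit:
    """Optimise branch lengths (and optionally κ) for one topology.

    θ is estimated from alignment base composition unless supplied; κ is
    refined by bounded scalar search alternating with branch sweeps.
    """
    params = T92Params(theta if theta is not None else estimate_theta(alignment), kappa)
    for _ in range(rounds):
        optimize_branch_lengths(tree, alignment, params, **branch_kwargs)
        if not optimize_kappa:
            break

        def neg_kappa(k: float) -> float:
            return -t92_log_likelihood(tree, alignment, replace(params, kappa=float(k)))

        res = minimize_scalar(neg_kappa, bounds=kappa_bounds, method="bounded")
        if res.success:
            params = replace(params, kappa=float(res.x))
    final = t92_log_likelihood(tree, alignment, params)
    return TreeFit(tree=tree, params=params, loglik=final)


def select_topology(
    candidates: Sequence[dendropy.Tree],
    alignment: Alignment,
    theta: float | None = None,
    kappa: float = 4.0,
    optimize_kappa: bool = True,
    **fit_kwargs,
) -> TreeFit:
    """Optimise every candidate topology and keep the superior log-likelihood.

    Ties go to the earlier candidate in input order (logged).
    """
    if not candidates:
        raise PhyloError("empty candidate list")
    fits = [
        fit_tree(t, alignment, theta=theta, kappa=kappa,
                 optimize_kappa=optimize_kappa, **fit_kwargs)
        for t in candidates
    ]
    best = max(range(len(fits)), key=lambda i: (fits[i].loglik, -i))
    if len(fits) > 1 and any(
        i != best and abs(fits[i].loglik - fits[best].loglik) < 1e-9 for i in range(len(fits))
    ):
        logger.info("log-likelihood tie between candidate topologies; keeping first")
    return fits[best]


# ---------------------------------------------------------------------------
# Clade labelling and simulation


def clade_label_report(
    tree: dendropy.Tree,
    labels: Mapping[str, str],
    queries: Sequence[str],
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """For each query leaf, the label composition of its smallest enclosing clade.

    Walking up from the query leaf, the first ancestor containing at least one
    informative co-member leaf defines the clade; co-member population labels
    are tallied and the majority label reported as the "clustered-with" call
    ("mixed" on a tie).  ``exclude`` names leaves that are uninformative as
    co-members (default: the other queries, so a population call is never made
    from sibling queries).  Clades are read on the tree's given (NJ-central)
    rooting.
    """
    leaf_by_name = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    excluded = set(queries) if exclude is None else set(exclude)
    rows = []
    for q in queries:
        if q not in leaf_by_name:
            raise PhyloError(f"query {q!r} is not a leaf of the tree")
        node = leaf_by_name[q].parent_node
        members: list[str] = []
        while node is not None:
            members = [
                leaf.taxon.label
                for leaf in node.leaf_iter()
                if leaf.taxon.label != q and leaf.taxon.label not in excluded
            ]
            if members:
                break
            node = node.parent_node
        tally: dict[str, int] = {}
        for m in members:
            lbl = labels.get(m, "unlabelled")
            tally[lbl] = tally.get(lbl, 0) + 1
        if not tally:
            call = "isolated"
        else:
            top = max(tally.values())
            winners = sorted(k for k, v in tally.items() if v == top)
            call = winners[0] if len(winners) == 1 else "mixed"
        rows.append(
            {
                "query": q,
                "clade_size": len(members),
                "label_counts": ";".join(f"{k}:{v}" for k, v in sorted(tally.items())),
                "call": call,
            }
        )
    return pd.DataFrame(rows)


def simulate_alignment(
    tree: dendropy.Tree,
    params: T92Params,
    n_sites: int,
    rng: np.random.Generator,
) -> Alignment:
    """Evolve sequences down a tree under T92 (for calibration and testing)."""
    model = T92Model(params)
    states: dict[int, np.ndarray] = {
        id(tree.seed_node): rng.choice(4, size=n_sites, p=model.pi)
    }
    ids, seqs = [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            t = node.edge.length if node.edge.length is not None else 0.0
            p = model.transition_matrix(t)
            # row-normalise against clip round-off before sampling
            p = p / p.sum(axis=1, keepdims=True)
            parent_states = states[id(node.parent_node)]
            cum = np.cumsum(p, axis=1)
            u = rng.random(n_sites)
            states[id(node)] = (u[:, None] > cum[parent_states]).sum(axis=1)
        if node.is_leaf():
            ids.append(node.taxon.label)
            seqs.append("".join(_STATES[s] for s in states[id(node)]))
    return Alignment(ids, seqs)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
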