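"""Tree inference and comparison: NJ, maximum parsimony, maximum likelihood,
nonparametric bootstrap, majority-rule consensus and topology comparison.

Trees are ``dendropy.Tree`` objects throughout; bootstrap / consensus
support values ride on internal-node labels in percent.  All searches are
deterministic given their seed; ties (in the NJ Q-criterion, in parsimony
attachment points, in NNI acceptance) break toward the lowest index so two
runs on the same input give bit-identical trees.

The likelihood engine is Felsenstein pruning over a reversible model
(JC69 / K2P / HKY85 / GTR) with optional discrete-gamma rate variation
(``ncat`` mean-of-quantile categories) and a proportion of invariant sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .distances import DistanceMatrix, distance_matrix
from .seqio import IUPAC, Alignment, Supermatrix, parse_newick

_BASES = "ACGT"
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
#: bitmask per character; gaps/'?'/ambiguity include every base they allow
#: (missing = all four bits, union-neutral in Fitch parsimony).
CHAR_BITS = {c: sum(_BITS[b] for b in bases) for c, bases in IUPAC.items()}
CHAR_BITS["-"] = 15
CHAR_BITS["?"] = 15


class TreeInputError(ValueError):
    pass


# --------------------------------------------------------------------------
# generic helpers

def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def support_of(node) -> float | None:
    """Support value carried on an internal node's label, if numeric."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def _unroot(tree: dendropy.Tree) -> dendropy.Tree:
    tree.is_rooted = False
    if len(tree.seed_node.child_nodes()) == 2:
        tree.collapse_basal_bifurcation()
    return tree


def bipartitions(tree: dendropy.Tree, with_support: bool = False):
    """Non-trivial splits as frozensets of leaf labels.

    Each split is canonicalised to the side *not* containing the
    alphabetically first leaf, so splits from different rootings compare
    equal.  With ``with_support`` returns ``{split: support}``.
    """
    labels = leaf_labels(tree)
    ref = min(labels)
    n = len(labels)
    out = {} if with_support else set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = labels - below if ref in below else below
        if len(side) < 2 or len(side) > n - 2:
            continue
        key = frozenset(side)
        if with_support:
            out[key] = support_of(node)
        else:
            out.add(key)
    return out


def compare_topologies(t1: dendropy.Tree, t2: dendropy.Tree) -> dict:
    """Shared / conflicting splits and the Robinson–Foulds distance."""
    if leaf_labels(t1) != leaf_labels(t2):
        raise TreeInputError("trees are on different leaf sets")
    s1, s2 = bipartitions(t1), bipartitions(t2)
    return {
        "shared": sorted(map(sorted, s1 & s2)),
        "only_t1": sorted(map(sorted, s1 - s2)),
        "only_t2": sorted(map(sorted, s2 - s1)),
        "rf": len(s1 ^ s2),
    }


def _tree_from_clades(labels, clade_support) -> dendropy.Tree:
    """Build a tree from nested clades (sides not containing min label)."""
    ref = min(labels)
    items = sorted(clade_support.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
    ns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    leaf_parent: dict[str, dendropy.Node] = {lb: root for lb in labels}
    for clade, supp in items:
        node = dendropy.Node()
        node.label = f"{supp:g}"
        # attach under the current common parent of the clade's leaves
        parent = leaf_parent[next(iter(clade))]
        parent.add_child(node)
        for lb in clade:
            leaf_parent[lb] = node
    for lb in sorted(labels):
        leaf = dendropy.Node()
        leaf.taxon = dendropy.Taxon(label=lb)
        ns.add_taxon(leaf.taxon)
        leaf_parent[lb].add_child(leaf)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    del ref
    return tree


def majority_consensus(trees, threshold: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus: keep splits with frequency > threshold
    (``threshold=1.0`` keeps unanimous splits only, i.e. strict consensus,
    implemented as frequency ≥ 1).  Retained nodes are labelled with their
    percent frequency."""
    trees = list(trees)
    if not trees:
        raise TreeInputError("no trees given")
    labels = leaf_labels(trees[0])
    for t in trees[1:]:
        if leaf_labels(t) != labels:
            raise TreeInputError("consensus input trees differ in leaf set")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for split in bipartitions(t):
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    keep = {}
    for split, c in counts.items():
        freq = c / n
        if (threshold >= 1.0 and c == n) or (threshold < 1.0 and freq > threshold):
            keep[split] = 100.0 * freq
    # clades relative to the reference leaf
    ref = min(labels)
    clades = {frozenset(labels - s if ref in s else s): v for s, v in keep.items()}
    return _tree_from_clades(labels, clades)


def map_supports(point_tree: dendropy.Tree, replicate_trees) -> dendropy.Tree:
    """Label each internal node of ``point_tree`` with the percent of
    replicate trees containing its split."""
    replicate_trees = list(replicate_trees)
    n = len(replicate_trees)
    counts: dict[frozenset, int] = {}
    for t in replicate_trees:
        for split in bipartitions(t):
            counts[split] = counts.get(split, 0) + 1
    labels = leaf_labels(point_tree)
    ref = min(labels)
    for node in point_tree.preorder_node_iter():
        if node is point_tree.seed_node or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = labels - below if ref in below else below
        if len(side) < 2 or len(side) > len(labels) - 2:
            continue
        pct = 100.0 * counts.get(frozenset(side), 0) / n
        node.label = f"{pct:g}"
    return point_tree


# --------------------------------------------------------------------------
# neighbour joining

def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbour joining with a fixed tie rule.

    At every agglomeration the pair minimising the Q criterion is joined;
    ties break toward the lowest (row, column) index pair in the current
    label order.  Negative branch lengths are clamped to zero and the total
    clamped deficit is stored on the tree as ``nj_clamped_deficit``.
    """
    d = np.asarray(matrix.d, dtype=float)
    if np.isnan(d).any():
        raise TreeInputError(
            "NJ needs a pairwise-complete matrix (undefined entries present)")
    n = len(matrix.labels)
    if n < 3:
        raise TreeInputError("NJ needs at least 3 taxa")

    # node bookkeeping: newick fragments per active cluster
    frags = [f"{lb}" for lb in matrix.labels]
    active = list(range(n))
    D = d.copy()
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        tot = sub.sum(axis=1)
        q = (r - 2) * sub - tot[:, None] - tot[None, :]
        iu = np.triu_indices(r, k=1)
        flat = q[iu]
        k = int(flat.argmin())  # argmin of row-major upper triangle is the
        ai, aj = int(iu[0][k]), int(iu[1][k])  # lowest-index minimising pair
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        vi = clamp(0.5 * dij + (tot[ai] - tot[aj]) / (2 * (r - 2)))
        vj = clamp(dij - (0.5 * dij + (tot[ai] - tot[aj]) / (2 * (r - 2))))
        new_frag = f"({frags[i]}:{float(vi):.12g},{frags[j]}:{float(vj):.12g})"
        # distances to the new node
        newd = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newd[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newd[:-1]
        D[:-1, -1] = newd[:-1]
        frags.append(new_frag)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    if len(active) == 3:
        i, j, k = active
        # three-point formulas for the final star
        vi = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
        vj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
        vk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
        newick = (f"({frags[i]}:{float(vi):.12g},{frags[j]}:{float(vj):.12g},"
                  f"{frags[k]}:{float(vk):.12g});")
    tree = parse_newick(newick)
    tree.is_rooted = False
    tree.nj_clamped_deficit = deficit
    return tree


# --------------------------------------------------------------------------
# parsimony

def _leaf_state_matrix(aln, weights=None):
    if isinstance(aln, Supermatrix):
        aln = aln.as_alignment()
    states = {r.id: np.array([CHAR_BITS[c] for c in r.seq], dtype=np.uint8)
              for r in aln.records}
    return states, aln.length


def fitch_score(tree: dendropy.Tree, aln, weights=None) -> int:
    """Fitch parsimony length of ``tree`` on ``aln`` (missing data are
    union-neutral); ``weights`` optionally weights columns (bootstrap)."""
    states, length = _leaf_state_matrix(aln)
    w = np.ones(length, dtype=np.int64) if weights is None else np.asarray(weights)
    score = np.zeros(length, dtype=np.int64)

    def post(node):
        if node.is_leaf():
            try:
                return states[node.taxon.label]
            except KeyError:
                raise TreeInputError(
                    f"leaf {node.taxon.label!r} has no sequence") from None
        acc = None
        for ch in node.child_nodes():
            s = post(ch)
            if acc is None:
                acc = s
                continue
            inter = acc & s
            union = acc | s
            miss = inter == 0
            score[miss] += 1
            acc = np.where(miss, union, inter).astype(np.uint8)
        return acc

    post(tree.seed_node)
    return int((score * w).sum())


def _star_tree(labels) -> dendropy.Tree:
    newick = "(" + ",".join(labels) + ");"
    t = parse_newick(newick)
    t.is_rooted = False
    return t


def _attachment_edges(tree):
    return [e for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node]


def _attach_leaf(tree, edge, label):
    """Bisect ``edge`` and hang a new leaf ``label`` off the midpoint."""
    parent, child = edge.tail_node, edge.head_node
    mid = dendropy.Node()
    parent.remove_child(child)
    parent.add_child(mid)
    mid.add_child(child)
    leaf = dendropy.Node()
    tax = tree.taxon_namespace.get_taxon(label)
    leaf.taxon = tax or tree.taxon_namespace.new_taxon(label)
    mid.add_child(leaf)
    return mid, leaf, child


def _detach_leaf(tree, mid, leaf, child):
    parent = mid.parent_node
    mid.remove_child(leaf)
    mid.remove_child(child)
    parent.remove_child(mid)
    parent.add_child(child)


def _stepwise_addition(aln, order) -> dendropy.Tree:
    labels = list(order)
    tree = _star_tree(labels[:3])
    for label in labels[3:]:
        best = None
        for idx, edge in enumerate(list(_attachment_edges(tree))):
            handles = _attach_leaf(tree, edge, label)
            s = fitch_score(tree, aln)
            _detach_leaf(tree, *handles)
            if best is None or s < best[0]:
                best = (s, idx)
        edge = list(_attachment_edges(tree))[best[1]]
        _attach_leaf(tree, edge, label)
    return tree


def _internal_edges(tree):
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        if node.parent_node is not None:
            out.append((node.parent_node, node))
    return out


def _nni_neighbors(tree, parent, child):
    """The two NNI rearrangements around the internal edge (parent, child).

    Yields ``(apply, revert)`` callables mutating the tree in place.
    """
    kids = child.child_nodes()
    others = [c for c in parent.child_nodes() if c is not child]
    if len(kids) < 2 or not others:
        return
    d = others[0]
    for a in kids[:2]:
        def apply(a=a, d=d):
            child.remove_child(a)
            parent.remove_child(d)
            child.add_child(d)
            parent.add_child(a)

        def revert(a=a, d=d):
            child.remove_child(d)
            parent.remove_child(a)
            child.add_child(a)
            parent.add_child(d)

        yield apply, revert


def mp_search(aln, n_starts: int = 3, seed: int = 0):
    """Maximum-parsimony search: NNI hill climbing from an NJ start plus
    ``n_starts − 1`` random-order stepwise-addition starts.

    Returns ``(best_trees, best_score)`` with all distinct co-optimal
    topologies found (as Newick-comparable trees).
    """
    if isinstance(aln, Supermatrix):
        aln = aln.as_alignment()
    if len(aln) < 4:
        raise TreeInputError("parsimony search needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    starts = [_unroot(nj_tree(distance_matrix(aln)))]
    ids = aln.ids()
    for _ in range(max(0, n_starts - 1)):
        order = [ids[i] for i in rng.permutation(len(ids))]
        starts.append(_stepwise_addition(aln, order))

    best_score = None
    best: dict[frozenset, dendropy.Tree] = {}
    for tree in starts:
        score = fitch_score(tree, aln)
        improved = True
        while improved:
            improved = False
            for parent, child in _internal_edges(tree):
                for apply, revert in _nni_neighbors(tree, parent, child):
                    apply()
                    s = fitch_score(tree, aln)
                    if s < score:
                        score = s
                        improved = True
                        break  # topology changed: re-enumerate edges
                    revert()
                if improved:
                    break
        key = frozenset(bipartitions(tree))
        if best_score is None or score < best_score:
            best_score, best = score, {key: tree}
        elif score == best_score and key not in best:
            best[key] = tree
    return list(best.values()), best_score


# --------------------------------------------------------------------------
# likelihood

@dataclass
class SubstitutionModel:
    """Reversible nucleotide model with optional +G (discrete gamma, mean-of-
    quantile categories) and +I (proportion of invariant sites).

    ``rates`` are the GTR exchangeabilities in order AC, AG, AT, CG, CT, GT
    (JC69/K2P/HKY85 fill them from ``kappa``); the rate matrix is scaled to
    mean rate 1 so branch lengths are expected substitutions per site.
    """

    name: str = "JC69"
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 2.0
    rates: tuple | None = None
    gamma_alpha: float | None = None
    ncat: int = 4
    pinv: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if abs(f.sum() - 1.0) > 1e-9 or (f <= 0).any():
            raise ValueError("base frequencies must be positive and sum to 1")
        if not 0 <= self.pinv < 1:
            raise ValueError("pinv must lie in [0, 1)")
        if self.name == "JC69":
            self.freqs = (0.25,) * 4
            self.rates = (1.0,) * 6
        elif self.name == "K2P":
            self.freqs = (0.25,) * 4
            k = self.kappa
            self.rates = (1.0, k, 1.0, 1.0, k, 1.0)
        elif self.name == "HKY85":
            k = self.kappa
            self.rates = (1.0, k, 1.0, 1.0, k, 1.0)
        elif self.name == "GTR":
            if self.rates is None:
                self.rates = (1.0,) * 6
        else:
            raise ValueError(f"unknown model {self.name!r}")

    def q_matrix(self) -> np.ndarray:
        pi = np.asarray(self.freqs)
        s = np.zeros((4, 4))
        ac, ag, at, cg, ct, gt = self.rates
        s[0, 1] = s[1, 0] = ac
        s[0, 2] = s[2, 0] = ag
        s[0, 3] = s[3, 0] = at
        s[1, 2] = s[2, 1] = cg
        s[1, 3] = s[3, 1] = ct
        s[2, 3] = s[3, 2] = gt
        q = s * pi[None, :]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def category_rates(self):
        """(rates, weights) over the discrete mixture including the
        invariant class (rate 0, weight pinv) when pinv > 0."""
        if self.gamma_alpha is None:
            rates, weights = [1.0], [1.0]
        else:
            a = self.gamma_alpha
            # mean of equal-probability quantile slices of Gamma(a, 1/a)
            edges = gamma_dist.ppf(np.linspace(0, 1, self.ncat + 1), a, scale=1 / a)
            rates = []
            for k in range(self.ncat):
                lo, hi = edges[k], edges[k + 1]
                mass = (gamma_dist.cdf(hi, a + 1, scale=1 / a)
                        - gamma_dist.cdf(lo, a + 1, scale=1 / a))
                rates.append(mass * self.ncat)
            weights = [1.0 / self.ncat] * self.ncat
        if self.pinv > 0:
            rates = [0.0] + list(rates)
            weights = [self.pinv] + [w * (1 - self.pinv) for w in weights]
        return np.asarray(rates), np.asarray(weights)

    def transition_matrices(self, t: float):
        """P(r_k · t) per rate category, via eigendecomposition."""
        q = self.q_matrix()
        pi = np.asarray(self.freqs)
        # symmetrise: B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2)
        rates, _ = self.category_rates()
        mats = []
        for r in rates:
            p = (v * np.exp(w * r * t)) @ v.T
            mats.append((p / sq[:, None]) * sq[None, :])
        return mats


_LEAF_PARTIALS = {}
for _c, _bases in IUPAC.items():
    vec = np.zeros(4)
    for _b in _bases:
        vec["ACGT".index(_b)] = 1.0
    _LEAF_PARTIALS[_c] = vec
_LEAF_PARTIALS["-"] = np.ones(4)
_LEAF_PARTIALS["?"] = np.ones(4)


def _patterns(aln):
    """Unique site patterns and their counts (pattern compression)."""
    if isinstance(aln, Supermatrix):
        aln = aln.as_alignment()
    cols = ["".join(r.seq[c] for r in aln.records) for c in range(aln.length)]
    uniq: dict[str, int] = {}
    for col in cols:
        uniq[col] = uniq.get(col, 0) + 1
    ids = aln.ids()
    return ids, list(uniq.keys()), np.array(list(uniq.values()), dtype=float)


class _PruningEngine:
    """Felsenstein pruning with pattern compression and up/down partial
    caching, so single-branch optimisation costs O(patterns × 16) per
    likelihood evaluation instead of a full-tree traversal."""

    def __init__(self, aln, model: SubstitutionModel):
        self.model = model
        ids, patterns, counts = _patterns(aln)
        row_of = {rid: i for i, rid in enumerate(ids)}
        self.counts = counts
        self.npat = len(patterns)
        self.leaf_part = {
            rid: np.stack([_LEAF_PARTIALS[p[row_of[rid]]] for p in patterns])
            for rid in ids}
        self.rates, self.weights = model.category_rates()
        self.ncat = len(self.rates)
        self.pi = np.asarray(model.freqs)

    def _leaf(self, node):
        try:
            lp = self.leaf_part[node.taxon.label]
        except KeyError:
            raise TreeInputError(
                f"leaf {node.taxon.label!r} has no sequence") from None
        return np.broadcast_to(lp, (self.ncat, self.npat, 4))

    def _down(self, tree):
        """Postorder conditional likelihoods below each node, and the
        per-edge contribution (child partial propagated through its edge)."""
        down: dict = {}
        through: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                down[node] = self._leaf(node)
            else:
                part = np.ones((self.ncat, self.npat, 4))
                for ch in node.child_nodes():
                    part = part * through[ch]
                down[node] = part
            if node.parent_node is not None:
                mats = self.model.transition_matrices(node.edge.length or 0.0)
                through[node] = np.stack(
                    [down[node][k] @ mats[k].T for k in range(self.ncat)])
        return down, through

    def _site_mix(self, root_part):
        site_l = np.einsum("kpa,a->kp", root_part, self.pi)
        return np.einsum("k,kp->p", self.weights, site_l)

    def loglik(self, tree) -> float:
        down, _ = self._down(tree)
        mix = self._site_mix(down[tree.seed_node])
        if not np.all(mix > 0):
            raise ArithmeticError(
                "non-finite site likelihood (pattern indices "
                f"{np.where(mix <= 0)[0].tolist()})")
        return float((np.log(mix) * self.counts).sum())

    def optimize_branches(self, tree, sweeps: int = 2, tol: float = 1e-6):
        """Brent optimisation of every branch; partials are refreshed once
        per sweep (the staleness within a sweep washes out over sweeps)."""
        ll = self.loglik(tree)
        for _ in range(sweeps):
            down, through = self._down(tree)
            # preorder "up" vectors: likelihood of everything outside the
            # child's subtree, conditional on the state at the parent
            up = {tree.seed_node: np.broadcast_to(
                np.ones(4), (self.ncat, self.npat, 4))}
            improved = False
            for node in tree.preorder_node_iter():
                kids = node.child_nodes()
                for ch in kids:
                    b = up[node].copy()
                    for sib in kids:
                        if sib is not ch:
                            b = b * through[sib]
                    # optimize this edge with cheap evaluations
                    def f(t, b=b, ch=ch):
                        mats = self.model.transition_matrices(t)
                        mix = np.zeros(self.npat)
                        for k in range(self.ncat):
                            prop = down[ch][k] @ mats[k].T
                            site = np.einsum("pa,pa,a->p", b[k], prop, self.pi)
                            mix += self.weights[k] * site
                        with np.errstate(divide="ignore"):
                            return -float((np.log(mix) * self.counts).sum())

                    current = ch.edge.length or 0.0
                    res = minimize_scalar(f, bounds=(1e-8, 10.0),
                                          method="bounded",
                                          options={"xatol": 1e-7})
                    if -res.fun > -f(current) + tol:
                        ch.edge.length = float(res.x)
                        improved = True
                    else:
                        ch.edge.length = current
                    mats = self.model.transition_matrices(ch.edge.length)
                    through[ch] = np.stack(
                        [down[ch][k] @ mats[k].T for k in range(self.ncat)])
                    # up vector for the child itself (propagated through edge)
                    up[ch] = np.stack(
                        [(b[k] * self.pi[None, :]) @ mats[k]
                         for k in range(self.ncat)]) / self.pi[None, None, :]
            ll = self.loglik(tree)
            if not improved:
                break
        return ll


def log_likelihood(tree: dendropy.Tree, aln, model: SubstitutionModel) -> float:
    """Felsenstein pruning log-likelihood; missing leaf data integrate to 1."""
    return _PruningEngine(aln, model).loglik(tree)


def _optimize_branches(tree, aln, model, rounds=2, tol=1e-6):
    return _PruningEngine(aln, model).optimize_branches(
        tree, sweeps=rounds, tol=tol)


def ml_search(aln, model: SubstitutionModel | None = None, seed: int = 0,
              tol: float = 1e-6, max_rounds: int = 10):
    """Maximum-likelihood search: NJ start, then alternate Brent single-
    branch optimisation with NNI moves until no improvement > ``tol``.

    Returns ``(tree, loglik)``; the tree carries optimised branch lengths.
    """
    if isinstance(aln, Supermatrix):
        aln = aln.as_alignment()
    if len(aln) < 4:
        raise TreeInputError("ML search needs at least 4 taxa")
    model = model or SubstitutionModel("JC69")
    tree = _unroot(nj_tree(distance_matrix(aln)))
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None and (e.length is None or e.length <= 0):
            e.length = 1e-6
    ll = _optimize_branches(tree, aln, model, tol=tol)
    for _ in range(max_rounds):
        improved = False
        for parent, child in _internal_edges(tree):
            for apply, revert in _nni_neighbors(tree, parent, child):
                apply()
                trial = log_likelihood(tree, aln, model)
                if trial > ll + tol:
                    ll = _optimize_branches(tree, aln, model, rounds=1, tol=tol)
                    improved = True
                    break  # topology changed: re-enumerate edges
                revert()
            if improved:
                break
        if not improved:
            break
    return tree, ll


# --------------------------------------------------------------------------
# bootstrap

@dataclass
class _Inference:
    method: str
    model: SubstitutionModel | None = None
    mp_starts: int = 1

    def __call__(self, aln, seed=0):
        if self.method == "nj":
            return _unroot(nj_tree(distance_matrix(aln)))
        if self.method == "mp":
            trees, _ = mp_search(aln, n_starts=self.mp_starts, seed=seed)
            return trees[0]
        if self.method == "ml":
            tree, _ = ml_search(aln, model=self.model, seed=seed)
            return tree
        raise ValueError(f"unknown inference method {self.method!r}")


def resample_columns(aln: Alignment, rng) -> Alignment:
    cols = rng.integers(0, aln.length, size=aln.length)
    from dataclasses import replace
    records = [replace(r, seq="".join(r.seq[c] for c in cols))
               for r in aln.records]
    return Alignment(locus=aln.locus, records=records)


def bootstrap_support(aln, method: str = "nj", reps: int = 1000,
                      seed: int = 0, model: SubstitutionModel | None = None,
                      point_tree: dendropy.Tree | None = None) -> dendropy.Tree:
    """Point-estimate tree with percent bootstrap supports on internal nodes.

    Columns are resampled with replacement over the whole (super)matrix,
    ignoring partition boundaries; each replicate is re-inferred with the
    chosen method and split frequencies are mapped onto the point tree.
    """
    if isinstance(aln, Supermatrix):
        aln = aln.as_alignment()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    infer = _Inference(method, model=model)
    if point_tree is None:
        point_tree = infer(aln, seed=seed)
    rng = np.random.default_rng(seed)
    reps_trees = []
    for r in range(reps):
        boot = resample_columns(aln, rng)
        reps_trees.append(infer(boot, seed=seed + r + 1))
    return map_supports(point_tree, reps_trees)
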