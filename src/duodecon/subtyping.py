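"""Combinatorial cell-state patient subtyping from deconvolution output.

The framework stratifies a patient cohort from the two deconvolution
products:

* proportion-based subtypes: PCA on predicted cell-type proportions, Leiden
  clustering in PCA space (resolution tuned to a requested cluster count),
  and KNN label transfer onto an external cohort embedded in the same space;
* cell-state subtypes: per cell type, patients are clustered on that type's
  predicted expression profile into exactly two groups ("cell states");
  conjunctions of k chosen states over k cell types (k = 1..c) each define a
  two-group patient partition; partitions are screened for survival
  differences with a BH-adjusted log-rank test, near-duplicate definitions
  (IoU of their smaller groups > threshold) are merged into connected
  components, and a consensus assignment per component is computed by
  Hamming-distance group matching followed by majority voting; finally,
  components sharing a survival direction are merged into one favorable and
  one unfavorable patient group.

The consensus stage follows two explicit algorithms: group correspondence is
resolved by pairing each definition's indicator with whichever orientation
of the other definition has the smaller Hamming distance to the reference
definition (the one with the smallest survival p-value), and the consensus
assigns a patient to a group only when more than (n+1)/2 of the n+1 aligned
definitions agree, with ties going to an explicit "unresolved" label 2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components as _sp_components
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "SubtypeSpace", "CellStateTable", "GroupDefinition", "DefinitionGraph",
    "proportion_subtypes", "knn_transfer", "binarize_cell_states",
    "enumerate_definitions", "screen_survival", "build_definition_graph",
    "match_groups", "consensus_patients", "merge_patterns",
    "external_validation",
]


# --------------------------------------------------------------------- Leiden

def _leiden(X: np.ndarray, resolution: float, seed: int, n_neighbors: int = 15) -> np.ndarray:
    """Leiden community detection on a KNN graph of the rows of X."""
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    k = min(n_neighbors, X.shape[0] - 1)
    adj = kneighbors_graph(X, n_neighbors=k, include_self=False)
    adj = adj.maximum(adj.T)  # undirected
    sources, targets = adj.nonzero()
    keep = sources < targets
    graph = igraph.Graph(n=X.shape[0],
                         edges=list(zip(sources[keep], targets[keep])))
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    return np.asarray(part.membership)


def _leiden_k_clusters(X: np.ndarray, k: int, seed: int,
                       max_iter: int = 40) -> np.ndarray | None:
    """Search the Leiden resolution for exactly k clusters; None if unreachable."""
    lo, hi = 1e-4, 1.0
    # grow hi until at least k clusters (or give up)
    for _ in range(20):
        labels = _leiden(X, hi, seed)
        if labels.max() + 1 >= k:
            break
        hi *= 2
    else:
        return None
    if labels.max() + 1 == k:
        return labels
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        labels = _leiden(X, mid, seed)
        n = labels.max() + 1
        if n == k:
            return labels
        if n < k:
            lo = mid
        else:
            hi = mid
    return None


# ------------------------------------------------- proportion-based subtypes

@dataclass
class SubtypeSpace:
    """Fitted PCA space + training embedding and labels, for label transfer."""

    pca: PCA
    embedding: np.ndarray
    labels: np.ndarray


def proportion_subtypes(P: np.ndarray, n_clusters_expected: int | None = None,
                        seed: int = 0) -> SubtypeSpace:
    """Cluster patients on predicted proportions: PCA then Leiden.

    When ``n_clusters_expected`` is given the Leiden resolution is tuned until
    exactly that many clusters emerge; an unreachable count raises.
    """
    P = np.asarray(P, dtype=float)
    if n_clusters_expected is not None and P.shape[0] < n_clusters_expected:
        raise ValueError("fewer patients than requested clusters")
    if np.allclose(P.var(axis=0), 0):
        raise ValueError("proportion matrix is degenerate (no variance)")
    pca = PCA(n_components=min(P.shape[1], P.shape[0]), random_state=seed)
    emb = pca.fit_transform(P)
    if n_clusters_expected is None:
        labels = _leiden(emb, 1.0, seed)
    else:
        labels = _leiden_k_clusters(emb, n_clusters_expected, seed)
        if labels is None:
            raise ValueError(
                f"could not reach {n_clusters_expected} Leiden clusters on this data")
    return SubtypeSpace(pca=pca, embedding=emb, labels=labels)


def knn_transfer(space: SubtypeSpace, new_P: np.ndarray, k: int = 5) -> np.ndarray:
    """Majority label of the k nearest training points in the fitted PCA space.

    Deterministic tie-breaks: neighbors are ordered by (distance, label) and
    vote ties go to the smallest label.
    """
    new_P = np.asarray(new_P, dtype=float)
    emb = space.pca.transform(new_P)
    diff = emb[:, None, :] - space.embedding[None, :, :]
    dists = np.sqrt((diff ** 2).sum(axis=2))
    out = np.empty(new_P.shape[0], dtype=space.labels.dtype)
    n_labels = int(space.labels.max()) + 1
    for i in range(new_P.shape[0]):
        order = np.lexsort((space.labels, dists[i]))[:k]
        votes = np.bincount(space.labels[order], minlength=n_labels)
        out[i] = int(np.argmax(votes))  # argmax returns the smallest label on ties
    return out


# --------------------------------------------------------------- cell states

@dataclass
class CellStateTable:
    """Binary cell state per patient per cell type (0 = larger patient group)."""

    states: pd.DataFrame  # patients x cell types, values in {0, 1}
    fallback_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [c for c in self.states.columns
               if not set(np.unique(self.states[c])) <= {0, 1}]
        if bad:
            raise ValueError(f"non-binary states for {bad}")


def _orient_binary(labels: np.ndarray) -> np.ndarray:
    """Relabel a 2-cluster assignment so 0 is the larger group (ties: the
    group containing the first patient)."""
    n0, n1 = (labels == 0).sum(), (labels == 1).sum()
    if n1 > n0 or (n1 == n0 and labels[0] == 1):
        return 1 - labels
    return labels


def binarize_cell_states(G_stack: np.ndarray, cell_types: list[str],
                         patients, seed: int = 0) -> CellStateTable:
    """Per cell type, split patients into two groups on the predicted GEPs.

    ``G_stack`` has shape (patients, genes, cell types).  Leiden resolution is
    searched for exactly two clusters; if unreachable (e.g. degenerate
    profiles) a 2-way Ward cut is used instead and the type is logged.
    """
    n = G_stack.shape[0]
    if n < 4:
        raise ValueError("need at least 4 patients to derive cell states")
    cols = {}
    fallback = []
    for ti, t in enumerate(cell_types):
        X = G_stack[:, :, ti]
        labels = None
        if np.ptp(X, axis=0).max() > 0:
            labels = _leiden_k_clusters(X, 2, seed)
        if labels is None:
            fallback.append(t)
            log.warning("cell type %s: Leiden could not produce 2 clusters; "
                        "falling back to hierarchical 2-way cut", t)
            if np.ptp(X, axis=0).max() == 0:
                labels = np.zeros(n, dtype=int)
                labels[n // 2:] = 1  # fully degenerate: arbitrary halves
            else:
                labels = fcluster(linkage(X, method="ward"), 2, criterion="maxclust") - 1
        cols[t] = _orient_binary(np.asarray(labels, dtype=int))
    states = pd.DataFrame(cols, index=patients)
    return CellStateTable(states, fallback_types=fallback)


# ----------------------------------------------------- definition enumeration

@dataclass
class GroupDefinition:
    """A conjunction of required cell states inducing a two-group partition.

    ``group1`` is the indicator vector of patients satisfying every
    constraint; the complement forms group 2.
    """

    constraints: dict[str, int]
    group1: np.ndarray  # boolean indicator v1; v2 = ~v1
    patients: pd.Index

    @property
    def v1(self) -> np.ndarray:
        return self.group1.astype(int)

    @property
    def v2(self) -> np.ndarray:
        return 1 - self.v1

    @property
    def degenerate(self) -> bool:
        s = int(self.group1.sum())
        return s == 0 or s == self.group1.size

    def small_group_indicator(self) -> tuple[np.ndarray, bool]:
        """Indicator of the smaller group (ties keep the group1 encoding)."""
        n1 = int(self.group1.sum())
        n2 = self.group1.size - n1
        if n1 > n2:
            return ~self.group1, True
        if n1 == n2:
            log.info("definition %s: equal group sizes; keeping group1 encoding",
                     self.constraints)
        return self.group1.copy(), False


def enumerate_definitions(states: CellStateTable) -> list[GroupDefinition]:
    """All conjunction definitions over k = 1..c cell types, one per induced
    two-group partition.

    Each raw definition picks k cell types and one required state per type;
    the matching patients form one group and the rest the other.  Raw
    definitions inducing the same partition (in particular the two
    complementary k=1 definitions of one type) are counted once.  With all
    2^c state combinations populated this yields 3^c - 1 - c partitions.
    """
    df = states.states
    types = list(df.columns)
    values = {t: df[t].to_numpy() for t in types}
    seen: dict[tuple, GroupDefinition] = {}
    out: list[GroupDefinition] = []
    for k in range(1, len(types) + 1):
        for chosen in itertools.combinations(types, k):
            for assignment in itertools.product((0, 1), repeat=k):
                mask = np.ones(len(df), dtype=bool)
                for t, s in zip(chosen, assignment):
                    mask &= values[t] == s
                key_a = tuple(mask.tolist())
                key_b = tuple((~mask).tolist())
                key = min(key_a, key_b)
                if key in seen:
                    continue
                d = GroupDefinition(dict(zip(chosen, assignment)), mask.copy(), df.index)
                seen[key] = d
                out.append(d)
    return out


# --------------------------------------------------------- survival screening

@dataclass
class ScreenedDefinition:
    definition: GroupDefinition
    p_value: float
    p_adjusted: float


def screen_survival(defs: list[GroupDefinition], survival: pd.DataFrame,
                    alpha: float = 0.05, min_group_size: int = 5) -> list[ScreenedDefinition]:
    """Two-group log-rank test per definition with BH adjustment.

    ``survival`` has columns patient_id, time, event and must cover the
    definitions' patients.  Definitions with a group smaller than
    ``min_group_size`` or with no events in one group are skipped; BH spans
    all tested definitions and survivors have adjusted p < alpha.
    """
    surv = survival.set_index("patient_id")
    tested: list[tuple[GroupDefinition, float]] = []
    for d in defs:
        if d.degenerate:
            continue
        g1 = d.group1
        if g1.sum() < min_group_size or (~g1).sum() < min_group_size:
            continue
        rows = surv.loc[d.patients.astype(str)]
        t, e = rows["time"].to_numpy(), rows["event"].to_numpy()
        if e[g1].sum() == 0 or e[~g1].sum() == 0:
            log.info("definition %s skipped: a group has no events", d.constraints)
            continue
        res = logrank_test(t[g1], t[~g1], event_observed_A=e[g1], event_observed_B=e[~g1])
        tested.append((d, float(res.p_value)))
    if not tested:
        return []
    pvals = np.array([p for _, p in tested])
    padj = multipletests(pvals, method="fdr_bh")[1]
    out = [ScreenedDefinition(d, p, q)
           for (d, p), q in zip(tested, padj) if q < alpha]
    out.sort(key=lambda s: (s.p_adjusted, s.p_value))
    return out


# ------------------------------------------------------------ IoU def. graph

@dataclass
class DefinitionGraph:
    similarity: np.ndarray          # symmetric, unit diagonal
    adjacency: np.ndarray           # similarity thresholded
    components: list[list[int]]     # indices into the screened definition list


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return np.logical_and(a, b).sum() / union


def build_definition_graph(screened: list[ScreenedDefinition],
                           threshold: float = 0.8) -> DefinitionGraph:
    """Pairwise similarity = max IoU of the smaller groups (either
    orientation), thresholded into an adjacency whose connected components
    group near-identical definitions."""
    if not screened:
        raise ValueError("no screened definitions")
    smalls = [s.definition.small_group_indicator()[0] for s in screened]
    n = len(screened)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a = smalls[i]
            S[i, j] = S[j, i] = max(_iou(a, smalls[j]), _iou(a, ~smalls[j]))
    adj = (S >= threshold).astype(int)
    n_comp, labels = _sp_components(adj, directed=False)
    comps = [sorted(np.flatnonzero(labels == c).tolist()) for c in range(n_comp)]
    comps.sort(key=lambda c: c[0])
    return DefinitionGraph(similarity=S, adjacency=adj, components=comps)


# ------------------------------------------------------ consensus (Alg. 1+2)

def match_groups(component: list[ScreenedDefinition]) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Align group orientations within a component to its smallest-p definition.

    For the reference definition C (smallest survival p-value) and every other
    definition D, v1(C) is paired with whichever of v1(D)/v2(D) lies at the
    smaller Hamming distance, and v2(C) with the other orientation; exact
    distance ties keep v1(D) and are logged.  Returns the two aligned
    families, each starting with C's own assignment.
    """
    if not component:
        raise ValueError("empty component")
    ref_idx = int(np.argmin([s.p_value for s in component]))
    C = component[ref_idx].definition
    fam1, fam2 = [C.v1], [C.v2]
    for i, s in enumerate(component):
        if i == ref_idx:
            continue
        D = s.definition
        d11 = int(np.sum((C.v1 + D.v1) % 2))  # Hamming distance
        d12 = int(np.sum((C.v1 + D.v2) % 2))
        if d11 == d12:
            log.info("definition %s: orientation tie against reference; keeping v1",
                     D.constraints)
        if d11 <= d12:
            fam1.append(D.v1)
            fam2.append(D.v2)
        else:
            fam1.append(D.v2)
            fam2.append(D.v1)
    return fam1, fam2


def _consensus_one(family: list[np.ndarray]) -> np.ndarray:
    arr = np.stack(family)           # (n+1, patients)
    n = arr.shape[0] - 1
    thr = (n + 1) / 2.0
    zeros = (arr == 0).sum(axis=0)
    ones = (arr == 1).sum(axis=0)
    out = np.full(arr.shape[1], 2, dtype=int)
    out[zeros > thr] = 0
    out[ones > thr] = 1
    return out


def consensus_patients(fam1: list[np.ndarray], fam2: list[np.ndarray] | None = None) -> np.ndarray:
    """Majority-vote consensus over aligned assignments.

    A patient joins group 0 (or 1) when more than (n+1)/2 of the n+1 aligned
    definitions put them there, and is otherwise unresolved (group 2).  When
    both orientations are supplied the one leaving fewer patients unresolved
    wins (ties keep the first).
    """
    c1 = _consensus_one(fam1)
    if fam2 is None:
        return c1
    c2 = _consensus_one(fam2)
    if (c2 == 2).sum() < (c1 == 2).sum():
        return c2
    return c1


# ----------------------------------------------------------- pattern merging

@dataclass
class FinalGrouping:
    labels: pd.Series  # per patient: "favorable" / "unfavorable" / "rest"
    directions: list[str]  # per input consensus
    n_definitions: int


def _rmst(time, event, horizon) -> float:
    km = KaplanMeierFitter().fit(time, event)
    from lifelines.utils import restricted_mean_survival_time
    return float(restricted_mean_survival_time(km, t=horizon))


def _direction(member: np.ndarray, survival: pd.DataFrame, patients,
               method: str = "rmst") -> str:
    surv = survival.set_index("patient_id").loc[np.asarray(patients, dtype=str)]
    t, e = surv["time"].to_numpy(), surv["event"].to_numpy()
    if method == "median":
        a = KaplanMeierFitter().fit(t[member], e[member]).median_survival_time_
        b = KaplanMeierFitter().fit(t[~member], e[~member]).median_survival_time_
        return "favorable" if a > b else "unfavorable"
    horizon = t.max()
    a = _rmst(t[member], e[member], horizon)
    b = _rmst(t[~member], e[~member], horizon)
    return "favorable" if a > b else "unfavorable"


def merge_patterns(consensuses: list[np.ndarray], survival: pd.DataFrame,
                   patients, method: str = "rmst") -> FinalGrouping:
    """Merge per-component consensuses into favorable/unfavorable/rest groups.

    Each consensus's distinguished group (its group 0, ignoring unresolved
    patients) is labeled favorable or unfavorable by comparing restricted
    mean survival (or median survival) against the remaining patients;
    same-direction consensuses are merged by another round of majority
    voting.  A patient claimed by both final groups falls back to "rest".
    """
    patients = pd.Index(patients)
    if not consensuses:
        log.warning("no consensus definitions: returning all-rest grouping")
        return FinalGrouping(pd.Series("rest", index=patients), [], 0)
    directions = []
    indicator_by_dir: dict[str, list[np.ndarray]] = {"favorable": [], "unfavorable": []}
    for cons in consensuses:
        member = cons == 0
        d = _direction(member, survival, patients, method=method)
        directions.append(d)
        # Algorithm-2 encoding: the distinguished group is "group 0"
        indicator_by_dir[d].append(np.where(member, 0, 1))
    final_members: dict[str, np.ndarray] = {}
    for d, fams in indicator_by_dir.items():
        if not fams:
            continue
        votes = consensus_patients(fams)
        final_members[d] = votes == 0
    labels = pd.Series("rest", index=patients)
    fav = final_members.get("favorable", np.zeros(len(patients), bool))
    unf = final_members.get("unfavorable", np.zeros(len(patients), bool))
    both = fav & unf
    if both.any():
        log.warning("%d patients claimed by both final groups; moved to rest",
                    int(both.sum()))
    labels[fav & ~both] = "favorable"
    labels[unf & ~both] = "unfavorable"
    return FinalGrouping(labels=labels, directions=directions,
                         n_definitions=len(consensuses))


# ------------------------------------------------------ external validation

def _rank_sum_degs(expr: pd.DataFrame, member: np.ndarray, alpha: float = 0.05) -> list[str]:
    from scipy import stats
    a = expr.loc[:, member].to_numpy()
    b = expr.loc[:, ~member].to_numpy()
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    padj = multipletests(np.nan_to_num(res.pvalue, nan=1.0), method="fdr_bh")[1]
    return list(expr.index[padj < alpha])


def external_validation(train_bulk: pd.DataFrame, grouping: FinalGrouping,
                        test_bulk: pd.DataFrame, deg_alpha: float = 0.05,
                        seed: int = 0) -> pd.Series:
    """Transfer the favorable/unfavorable grouping to an external cohort.

    Per direction: select group-vs-rest rank-sum DEGs on the training cohort's
    bulk expression (genes x patients), fit a 1-component PCA per cohort on
    those genes (sign-aligned via the gene loadings), train a logistic
    regression on the training cohort's component scores, and classify the
    test cohort.  Patients claimed by both directions fall back to "rest".
    """
    shared = train_bulk.index.intersection(test_bulk.index)
    if shared.empty:
        raise ValueError("no shared genes between cohorts")
    tr = train_bulk.loc[shared]
    te = test_bulk.loc[shared]
    claims: dict[str, np.ndarray] = {}
    for direction in ("favorable", "unfavorable"):
        member = (grouping.labels.loc[tr.columns] == direction).to_numpy()
        if member.sum() == 0:
            continue
        degs = _rank_sum_degs(tr, member, alpha=deg_alpha)
        if not degs:
            raise ValueError(f"no DEGs for the {direction} group")
        pca_tr = PCA(n_components=1, random_state=seed)
        z_tr = pca_tr.fit_transform(tr.loc[degs].T.to_numpy())
        pca_te = PCA(n_components=1, random_state=seed)
        z_te = pca_te.fit_transform(te.loc[degs].T.to_numpy())
        # per-cohort PCA sign is arbitrary; align by loading correlation
        if np.corrcoef(pca_tr.components_[0], pca_te.components_[0])[0, 1] < 0:
            z_te = -z_te
        clf = LogisticRegression(random_state=seed)
        clf.fit(z_tr, member.astype(int))
        claims[direction] = clf.predict(z_te).astype(bool)
    labels = pd.Series("rest", index=te.columns)
    fav = claims.get("favorable", np.zeros(te.shape[1], bool))
    unf = claims.get("unfavorable", np.zeros(te.shape[1], bool))
    both = fav & unf
    if both.any():
        log.warning("%d external patients claimed by both groups; moved to rest",
                    int(both.sum()))
    labels[fav & ~both] = "favorable"
    labels[unf & ~both] = "unfavorable"
    return labels
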