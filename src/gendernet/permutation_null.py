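"""Gender-permutation reference model for network indicators.

Subsampling would alter network structure, so imbalance in the two gender
groups is handled by a label-permutation null instead: gender labels are
randomly permuted over the nodes with the topology held fixed (conserving the
observed gender counts), each indicator is recomputed on every realization,
and the observed value is summarized against the null ensemble by

    z = (x - mean(x_null)) / sd(x_null)

and by one-sided permutation p-values (strict counting, so p = 0 is
representable).  The ensemble size defaults to 2E, where E is the number of
edges in the network analyzed.

Indicators: mean per-node same-gender neighbor fraction (per gender), raw
dyad counts (FF/MM/FM), and closed-triangle triad counts (FFF/MMM/mixed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse

from .network_metrics import enumerate_triangles

INDICATORS = (
    "same_gender_fraction_mean_female",
    "same_gender_fraction_mean_male",
    "dyads_FF",
    "dyads_MM",
    "dyads_FM",
    "triads_FFF",
    "triads_MMM",
    "triads_mixed",
)

#: Above this triangle count the engine switches from enumerated-triangle
#: gathering to a dense trace(A_g^3)/6 matrix path per permutation.
_DENSE_TRIANGLE_LIMIT = 500_000


def permute_genders(labels, seed=None):
    """Uniformly random permutation of the gender-label multiset.

    Accepts a sequence (returns a list) or a mapping node->label (returns a
    dict over the same nodes).  Female and male counts are conserved exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(labels, dict):
        keys = list(labels)
        vals = np.array([labels[k] for k in keys], dtype=object)
        return dict(zip(keys, rng.permutation(vals)))
    arr = np.asarray(list(labels), dtype=object)
    return list(rng.permutation(arr))


def z_score(observed: float, null_values) -> float:
    """(x - mean(null)) / sd(null), sd with n-1 denominator.

    A degenerate null (sd = 0) yields a signed-infinity marker (0.0 when the
    observed value equals the constant null) rather than an exception.
    """
    null_values = np.asarray(null_values, dtype=float)
    if len(null_values) < 2:
        raise ValueError("need at least 2 null values")
    mu = null_values.mean()
    sd = null_values.std(ddof=1)
    diff = observed - mu
    if sd == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / sd)


def permutation_pvalue(
    observed: float, null_values, tail: str = "greater", corrected: bool = False
) -> float:
    """Fraction of null values strictly beyond the observed value.

    ``tail='greater'`` counts null values > observed; ``'less'`` counts
    null values < observed.  With ``corrected=True`` the add-one estimator
    (k+1)/(n+1) is used instead of the plain k/n.
    """
    null_values = np.asarray(null_values, dtype=float)
    if len(null_values) == 0:
        raise ValueError("empty null sample")
    if tail == "greater":
        k = int((null_values > observed).sum())
    elif tail == "less":
        k = int((null_values < observed).sum())
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    n = len(null_values)
    return (k + 1) / (n + 1) if corrected else k / n


@dataclass
class PermutationEnsemble:
    indicator: str
    observed: float
    null_values: np.ndarray
    n_edges: int

    @property
    def z(self) -> float:
        return z_score(self.observed, self.null_values)

    def p_value(self, tail: str = "greater", corrected: bool = False) -> float:
        return permutation_pvalue(self.observed, self.null_values, tail, corrected)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values, ddof=1)),
            "z": self.z,
            "p_greater": self.p_value("greater"),
            "p_less": self.p_value("less"),
            "n_perm": len(self.null_values),
            "n_edges": self.n_edges,
        }


class _LabeledGraphArrays:
    """Flat array view of a labeled graph for fast per-permutation indicator
    evaluation.  Nodes without a gender label (outside-cohort alters) are
    dropped before analysis."""

    def __init__(self, graph: nx.Graph):
        labeled = [n for n, d in graph.nodes(data=True) if d.get("gender") in ("F", "M")]
        sub = graph.subgraph(labeled)
        self.nodes = list(labeled)
        index = {n: i for i, n in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.female = np.array(
            [graph.nodes[n]["gender"] == "F" for n in self.nodes], dtype=bool
        )
        edges = np.array(
            [(index[u], index[v]) for u, v in sub.edges], dtype=np.int64
        ).reshape(-1, 2)
        self.src, self.dst = edges[:, 0], edges[:, 1]
        self.n_edges = len(self.src)
        data = np.ones(2 * self.n_edges)
        rows = np.concatenate([self.src, self.dst])
        cols = np.concatenate([self.dst, self.src])
        self.adj = sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n, self.n)
        )
        self.deg = np.asarray(self.adj.sum(axis=1)).ravel()
        self.adj_dense = None
        self.triangles = None
        n_tri = self._triangle_count()
        if n_tri <= _DENSE_TRIANGLE_LIMIT:
            tri = enumerate_triangles(sub)
            t = np.array([(index[a], index[b], index[c]) for a, b, c in tri],
                         dtype=np.int64).reshape(-1, 3)
            self.triangles = t
            self.n_triangles = len(t)
        else:
            self.adj_dense = self.adj.toarray().astype(np.float32)
            self.n_triangles = n_tri

    def _triangle_count(self) -> int:
        a = self.adj.astype(np.float32).toarray()
        return int(round(float(np.sum(a @ a * a)) / 6.0))

    def _dense_same_triangles(self, mask: np.ndarray) -> int:
        sub = self.adj_dense[np.ix_(mask, mask)]
        return int(round(float(np.sum(sub @ sub * sub)) / 6.0))

    def indicators(self, female: np.ndarray) -> dict[str, float]:
        f = female.astype(float)
        fem_neighbors = self.adj @ f
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_female_nb = np.where(self.deg > 0, fem_neighbors / self.deg, np.nan)
        active = self.deg > 0
        fem_active = female & active
        male_active = ~female & active
        out = {
            "same_gender_fraction_mean_female": float(
                np.mean(frac_female_nb[fem_active]) if fem_active.any() else np.nan
            ),
            "same_gender_fraction_mean_male": float(
                np.mean(1.0 - frac_female_nb[male_active]) if male_active.any() else np.nan
            ),
        }
        fs, ft = female[self.src], female[self.dst]
        ff = int(np.sum(fs & ft))
        mm = int(np.sum(~fs & ~ft))
        out["dyads_FF"] = float(ff)
        out["dyads_MM"] = float(mm)
        out["dyads_FM"] = float(self.n_edges - ff - mm)
        if self.triangles is not None:
            if len(self.triangles):
                nf = female[self.triangles].sum(axis=1)
                fff = int(np.sum(nf == 3))
                mmm = int(np.sum(nf == 0))
            else:
                fff = mmm = 0
        else:
            fff = self._dense_same_triangles(female)
            mmm = self._dense_same_triangles(~female)
        out["triads_FFF"] = float(fff)
        out["triads_MMM"] = float(mmm)
        out["triads_mixed"] = float(self.n_triangles - fff - mmm)
        return out


def homophily_test(
    graph: nx.Graph,
    n_perm: int | None = None,
    seed=None,
    corrected: bool = False,
) -> dict[str, PermutationEnsemble]:
    """Permutation-null test of gender homophily on one labeled graph.

    Topology is held fixed; gender labels are permuted ``n_perm`` times
    (default 2E); every indicator is recomputed per realization.  Returns one
    :class:`PermutationEnsemble` per indicator, from which z-scores and
    one-sided p-values are read off.
    """
    arrays = _LabeledGraphArrays(graph)
    if arrays.n_edges < 1:
        raise ValueError("graph must have at least one edge between labeled nodes")
    if arrays.female.all() or not arrays.female.any():
        warnings.warn("single-gender cohort: homophily indicators are degenerate")
    if n_perm is None:
        n_perm = 2 * arrays.n_edges
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = arrays.indicators(arrays.female)
    null = {name: np.empty(n_perm) for name in INDICATORS}
    female = arrays.female.copy()
    for i in range(n_perm):
        perm = rng.permutation(arrays.n)
        vals = arrays.indicators(female[perm])
        for name in INDICATORS:
            null[name][i] = vals[name]
    return {
        name: PermutationEnsemble(
            indicator=name,
            observed=observed[name],
            null_values=null[name],
            n_edges=arrays.n_edges,
        )
        for name in INDICATORS
    }
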