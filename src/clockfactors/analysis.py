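"""Statistical interpretation of the learned latent space.

Four analyses mirror the downstream read-out of the clock-factor model:

* latent traversals — decode a sweep of one latent coordinate (−3..+3 by
  default, the others held at the prior mean) to visualize what each
  dimension encodes;
* propensity-score matching on age and education to de-confound the
  dementia/control comparison;
* per-dimension Welch t-tests with Benjamini–Hochberg correction at
  FDR q = 0.01, plus counts of "atypical occurrences" (dementia values
  more than two control SDs from the control mean);
* a Pearson correlation network over the latents and the binary label,
  thresholded at ±0.2, whose positive-edge connected components define
  subnetworks of co-occurring construction errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TraversalGrid", "GroupComparison", "CorrelationNetwork", "MatchResult",
    "traverse_latent", "propensity_match", "compare_groups", "count_atypical",
    "correlation_network", "traversal_montage",
]


@dataclass
class TraversalGrid:
    """Decoded frames for one latent dimension swept over a value grid."""

    dim_index: int
    values: np.ndarray
    images: np.ndarray            # (len(values), 64, 64), white=1
    base_code: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.diff(self.values) > 0):
            raise ValueError("traversal values must be strictly increasing")
        if self.images.shape[0] != self.values.size:
            raise ValueError("frame count must equal value count")


def traverse_latent(model, dim: int, lo: float = -3.0, hi: float = 3.0,
                    steps: int = 7, base_code: np.ndarray | None = None
                    ) -> TraversalGrid:
    """Decode a sweep of latent dimension ``dim`` (1-based), others fixed.

    The default base code is the zero vector (the prior mean), so the
    central frame is the model's prototype clock.
    """
    d = model.latent_dim
    if not (1 <= dim <= d):
        raise ValueError(f"dim must be in 1..{d}, got {dim}")
    if base_code is None:
        base_code = np.zeros(d)
    values = np.linspace(lo, hi, steps)
    codes = np.tile(base_code, (steps, 1))
    codes[:, dim - 1] = values
    images = np.atleast_3d(model.decode(codes))
    if images.ndim == 2:
        images = images[None]
    return TraversalGrid(dim_index=dim, values=values, images=images,
                         base_code=np.asarray(base_code, dtype=np.float64))


def traversal_montage(model, steps: int = 7, lo: float = -3.0,
                      hi: float = 3.0) -> np.ndarray:
    """All-dimension traversal montage: one column per latent dimension."""
    cols = []
    for dim in range(1, model.latent_dim + 1):
        grid = traverse_latent(model, dim, lo=lo, hi=hi, steps=steps)
        cols.append(np.concatenate(list(grid.images), axis=0))
    return np.concatenate(cols, axis=1)


# --- propensity matching -------------------------------------------------

@dataclass
class MatchResult:
    matched: pd.DataFrame
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    shortfall: int = 0            # cases with fewer than `ratio` controls


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (pooled-SD denominator)."""
    sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    return float((a.mean() - b.mean()) / sp) if sp > 0 else 0.0


def propensity_match(subjects: pd.DataFrame,
                     covariates: list[str] = ("age", "education"),
                     ratio: int = 2, case_label: str = "dementia",
                     label_col: str = "label", caliper: float | None = None
                     ) -> MatchResult:
    """1:ratio nearest-neighbor propensity matching without replacement.

    A logistic model of case membership on the covariates yields the
    propensity score; cases are processed in descending score order and
    greedily matched to the nearest-score unused controls.  Returns the
    matched cohort plus standardized mean differences before/after.
    """
    covariates = list(covariates)
    cases = subjects[subjects[label_col] == case_label]
    ctls = subjects[subjects[label_col] != case_label]
    if cases.empty or ctls.empty:
        raise ValueError("both groups must be non-empty")
    if subjects[covariates].isna().any().any():
        raise ValueError("covariates contain missing values")

    X = subjects[covariates].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0                 # constant covariate carries no signal
    X = (X - X.mean(axis=0)) / sd
    y = (subjects[label_col] == case_label).to_numpy(dtype=int)
    lr = LogisticRegression(max_iter=1000)
    lr.fit(X, y)
    score = lr.predict_proba(X)[:, 1]
    score = pd.Series(score, index=subjects.index)

    case_idx = score[cases.index].sort_values(ascending=False).index
    avail = dict(score[ctls.index])
    pairs: list = []
    shortfall = 0
    for ci in case_idx:
        got = 0
        for _ in range(ratio):
            if not avail:
                break
            best = min(avail, key=lambda k: abs(avail[k] - score[ci]))
            if caliper is not None and abs(avail[best] - score[ci]) > caliper:
                break
            pairs.append(best)
            del avail[best]
            got += 1
        if got < ratio:
            shortfall += 1
    if shortfall:
        warnings.warn(f"{shortfall} case(s) matched to fewer than {ratio} "
                      "controls", stacklevel=2)
    matched = pd.concat([cases, subjects.loc[pairs]])

    def smds(df: pd.DataFrame) -> dict[str, float]:
        a = df[df[label_col] == case_label]
        b = df[df[label_col] != case_label]
        return {c: _smd(a[c].to_numpy(float), b[c].to_numpy(float))
                for c in covariates}

    return MatchResult(matched=matched, smd_before=smds(subjects),
                       smd_after=smds(matched), shortfall=shortfall)


# --- group statistics ----------------------------------------------------

@dataclass
class GroupComparison:
    """Per-dimension Welch t-test table with BH-adjusted p-values."""

    table: pd.DataFrame
    q: float

    @property
    def significant(self) -> pd.Series:
        return self.table["significant"]


def benjamini_hochberg(pvals, q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up: (reject flags, adjusted p-values) controlling FDR at q."""
    reject, p_adj, _, _ = multipletests(np.asarray(pvals, dtype=float),
                                        alpha=q, method="fdr_bh")
    return reject, p_adj


def compare_groups(latents: np.ndarray, labels: np.ndarray, q: float = 0.01,
                   names: list[str] | None = None) -> GroupComparison:
    """Welch two-tailed t-test per latent dimension, BH step-up across dims.

    ``labels`` is boolean/0-1 with 1 = dementia.  Dimensions with zero
    variance in both groups get t = 0, p = 1 and a ``degenerate`` flag.
    """
    Z = np.asarray(latents, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    a, b = Z[y], Z[~y]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs >= 2 samples")
    D = Z.shape[1]
    names = names or [f"z{d}" for d in range(D)]
    rows = []
    for d in range(D):
        x1, x2 = a[:, d], b[:, d]
        degenerate = x1.var(ddof=1) == 0 and x2.var(ddof=1) == 0
        if degenerate:
            t, p, df = 0.0, 1.0, np.nan
        else:
            res = stats.ttest_ind(x1, x2, equal_var=False)
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        rows.append({"dimension": names[d],
                     "mean_dementia": x1.mean(), "sd_dementia": x1.std(ddof=1),
                     "mean_control": x2.mean(), "sd_control": x2.std(ddof=1),
                     "t": t, "df": df, "p_raw": p, "degenerate": degenerate})
    table = pd.DataFrame(rows)
    reject, p_adj = benjamini_hochberg(table["p_raw"], q)
    table["p_adj"] = p_adj
    table["significant"] = reject
    return GroupComparison(table=table, q=q)


def count_atypical(latents_dementia: np.ndarray, control_mean: np.ndarray,
                   control_sd: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Per-dimension count of dementia samples beyond k control SDs.

    Strictly greater than: a value exactly k SDs out does not count.
    """
    Z = np.atleast_2d(np.asarray(latents_dementia, dtype=np.float64))
    mu = np.asarray(control_mean, dtype=np.float64)
    sd = np.asarray(control_sd, dtype=np.float64)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise ValueError(f"control SD must be positive; zero at dimension(s) "
                         f"{bad.tolist()}")
    return (np.abs(Z - mu) / sd > k).sum(axis=0)


# --- correlation network -------------------------------------------------

@dataclass
class CorrelationNetwork:
    """Thresholded signed Pearson network over latents + label."""

    corr: pd.DataFrame
    edges: pd.DataFrame           # node_a, node_b, r, sign
    subnetworks: list[set] = field(default_factory=list)
    threshold: float = 0.2
    dropped: list[str] = field(default_factory=list)

    @property
    def pos_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["sign"] > 0]

    @property
    def neg_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["sign"] < 0]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.corr.columns)
        for _, e in self.edges.iterrows():
            g.add_edge(e["node_a"], e["node_b"], r=float(e["r"]),
                       sign=int(e["sign"]))
        return g


def correlation_network(latents: np.ndarray, labels: np.ndarray | None = None,
                        threshold: float = 0.2,
                        names: list[str] | None = None,
                        label_name: str = "dementia_label"
                        ) -> CorrelationNetwork:
    """Pearson correlation network of the latents (plus the 0/1 label).

    Edges keep correlations with |r| > threshold and their sign; the
    label enters as a plain 0/1 column (point-biserial correlation).
    Subnetworks are the connected components of the positive-edge graph
    excluding the label node, counting only components with >= 2 nodes.
    Constant columns are dropped with a warning.
    """
    Z = np.asarray(latents, dtype=np.float64)
    if Z.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    D = Z.shape[1]
    names = list(names or [f"z{d}" for d in range(D)])
    cols = [Z[:, d] for d in range(D)]
    if labels is not None:
        cols.append(np.asarray(labels, dtype=np.float64))
        names.append(label_name)

    keep, dropped = [], []
    for name, col in zip(names, cols):
        if col.std(ddof=0) == 0:
            dropped.append(name)
        else:
            keep.append((name, col))
    if dropped:
        warnings.warn(f"dropping constant column(s): {dropped}", stacklevel=2)
    names = [n for n, _ in keep]
    M = np.column_stack([c for _, c in keep])
    corr = pd.DataFrame(np.corrcoef(M, rowvar=False), index=names,
                        columns=names)

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = corr.iat[i, j]
            if abs(r) > threshold:
                rows.append({"node_a": names[i], "node_b": names[j],
                             "r": r, "sign": 1 if r > 0 else -1})
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "r", "sign"])

    g = nx.Graph()
    for _, e in edges.iterrows():
        if e["sign"] > 0 and label_name not in (e["node_a"], e["node_b"]):
            g.add_edge(e["node_a"], e["node_b"])
    subnetworks = [set(c) for c in nx.connected_components(g) if len(c) >= 2]
    return CorrelationNetwork(corr=corr, edges=edges, subnetworks=subnetworks,
                              threshold=threshold, dropped=dropped)
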