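"""Correlation-structure analyses of the windowed features.

Two views of the same window samples: a lagged Pearson matrix over
(feature x within-window hour) variables plus statics and the onset
outcome, turned into a time-ordered DAG (edges only run from earlier lags
to later lags or to the outcome, so the graph is acyclic by construction);
and an unlagged feature-level matrix used to cluster features into tiers
seeded by descending model importance.  A median-split odds ratio
quantifies the association between the importance ranking and the
outcome-correlation ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .featurize import WindowDataset, parse_column

OUTCOME = "onset"


@dataclass
class LaggedCorrelationMatrix:
    """Pearson matrix over lagged variables, statics and the outcome.

    ``lags`` orders variables in time: statics get -1 (known at admission),
    in-window hours 0..W-1, the outcome W+gap (strictly after every
    feature hour).  Constant variables are flagged and their correlations
    set to 0.
    """

    corr: pd.DataFrame
    lags: dict[str, float]
    constant: set[str]


def _corr(data: np.ndarray, names: list[str]) -> tuple[pd.DataFrame, set[str]]:
    sd = data.std(axis=0)
    constant = {names[j] for j in np.flatnonzero(~(sd > 0))}
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=names, columns=names), constant


def pearson_matrix(
    ds: WindowDataset, lagged: bool = True, include_statics: bool = True
) -> LaggedCorrelationMatrix:
    """Textbook Pearson correlations over window samples.

    Lagged: one variable per (dynamic feature, within-window hour) from the
    value channel.  Unlagged: the six in-window hours of each feature are
    averaged first.  The binary outcome enters via the same Pearson formula
    (point-biserial).
    """
    if len(ds) < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    frame = ds.to_frame()
    cols: list[str] = []
    names: list[str] = []
    lags: dict[str, float] = {}
    feats: dict[str, list[str]] = {}
    for c in ds.columns:
        fid, chan, h = parse_column(c)
        if chan == "value":
            feats.setdefault(fid, []).append(c)
        elif chan == "static" and include_statics:
            names.append(fid)
            cols.append(c)
            lags[fid] = -1.0
    W = ds.window.feature_window
    if lagged:
        data_parts = [frame[cols].to_numpy(float)] if cols else []
        for fid, cc in feats.items():
            for c in cc:
                _, _, h = parse_column(c)
                names.append(f"{fid}@h{h}")
                lags[f"{fid}@h{h}"] = float(h)
            data_parts.append(frame[cc].to_numpy(float))
        data = np.concatenate(
            [p for p in data_parts if p.size] or [np.empty((len(ds), 0))], axis=1
        )
    else:
        parts = [frame[cols].to_numpy(float)] if cols else []
        for fid, cc in feats.items():
            names.append(fid)
            lags[fid] = 0.0
            parts.append(frame[cc].to_numpy(float).mean(axis=1, keepdims=True))
        data = np.concatenate(parts, axis=1)
    names.append(OUTCOME)
    lags[OUTCOME] = float(W + ds.window.gap)
    data = np.column_stack([data, ds.y.astype(float)])
    corr, constant = _corr(data, names)
    return LaggedCorrelationMatrix(corr, lags, constant)


def build_dag(
    lcm: LaggedCorrelationMatrix, threshold: float = 0.5
) -> nx.DiGraph:
    """Directed edges u -> v for |r(u, v)| >= threshold and lag(u) < lag(v);
    acyclic by the time-ordering rule."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    g = nx.DiGraph()
    g.add_nodes_from(lcm.corr.index)
    names = list(lcm.corr.index)
    r = lcm.corr.to_numpy()
    for i, u in enumerate(names):
        for j, v in enumerate(names):
            if lcm.lags[u] < lcm.lags[v] and abs(r[i, j]) >= threshold:
                g.add_edge(u, v, weight=float(abs(r[i, j])))
    return g


def dag_to_dot(g: nx.DiGraph) -> str:
    lines = ["digraph features {"]
    for u, v, d in g.edges(data=True):
        lines.append(f'  "{u}" -> "{v}" [label="{d["weight"]:.2f}"];')
    lines.append("}")
    return "\n".join(lines)


def assign_tiers(
    importance: pd.Series,
    corr: pd.DataFrame,
    importance_floor: float = 0.01,
    corr_cutoff: float = 0.5,
) -> dict[str, int]:
    """Cluster features into importance-seeded correlation tiers.

    Iterate features by descending importance while importance >= floor;
    each still-unassigned feature seeds a new tier and pulls in every
    unassigned feature with |r| >= cutoff to the seed.  Leftovers form one
    residual tier.
    """
    if not len(importance):
        raise ValueError("empty importance ranking")
    assignment: dict[str, int] = {}
    tier = 0
    for fid in importance.index:
        if importance[fid] < importance_floor:
            break
        if fid in assignment:
            continue
        tier += 1
        assignment[fid] = tier
        if fid in corr.index:
            for other in corr.index:
                if other not in assignment and other in importance.index:
                    if abs(corr.loc[fid, other]) >= corr_cutoff:
                        assignment[other] = tier
    leftovers = [f for f in importance.index if f not in assignment]
    if leftovers:
        tier += 1
        for f in leftovers:
            assignment[f] = tier
    return assignment


def outcome_correlation_ranking(lcm: LaggedCorrelationMatrix) -> pd.Series:
    """|Pearson r| of each (unlagged) variable with the outcome, descending."""
    r = lcm.corr[OUTCOME].drop(OUTCOME).abs()
    return r.sort_values(ascending=False)


def importance_correlation_odds_ratio(
    importance_ranking, correlation_ranking
) -> float:
    """Median-split 2x2 odds ratio between two rankings of one feature set.

    Both rankings are split into the top ceil(n/2) and bottom floor(n/2)
    features; the odds ratio of joint membership uses the
    Haldane-Anscombe 0.5 correction when any cell is empty.
    """
    a_list = list(importance_ranking)
    b_list = list(correlation_ranking)
    if set(a_list) != set(b_list):
        raise ValueError("rankings must cover the identical feature set")
    n = len(a_list)
    if n < 4:
        raise ValueError("need at least 4 features")
    top = math.ceil(n / 2)
    A, B = set(a_list[:top]), set(b_list[:top])
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = n - len(A | B)
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)
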