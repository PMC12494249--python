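"""Empirical first->second repeat-test transition matrices.

For each patient the two chronologically earliest results form a (first,
second) pair. Pairs are binned on both axes; dividing each cell count by its
row total gives the empirical probability of the second result's bin given
the first result's bin. Exceedance probabilities for the minimal clinically
important difference (MCID, default 5.5 mmol/mol) are counted per first-bin
from the raw, unbinned values — binning is for display only.

An analytic companion computes the same matrix in closed form under the
normal measurement model (two conditionally independent draws
N(mu, cv * mu) mixed over a discrete law of true means), which the empirical
builder must converge to on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import BinningError, DataError

__all__ = [
    "TransitionMatrix",
    "first_second_pairs",
    "default_bin_edges",
    "build_matrix",
    "expected_matrix_normal",
]

DEFAULT_MCID = 5.5
#: The 5-wide display grid is anchored at the diabetes diagnostic cut-point
#: 48 mmol/mol so that the "48 to 53" cell exists verbatim.
_ANCHOR = 48.0
_BIN_WIDTH = 5.0


@dataclass
class TransitionMatrix:
    bin_edges: np.ndarray
    counts: np.ndarray  # first-bin x second-bin
    row_probs: np.ndarray
    n_pairs_per_row: np.ndarray
    mcid: float
    p_drop: np.ndarray  # P(second <= first - mcid | first bin), raw values
    p_rise: np.ndarray
    p_beyond: np.ndarray
    row_mass: np.ndarray | None = None  # P(first in bin); counts/total when empirical

    @property
    def labels(self) -> list:
        e = self.bin_edges
        return [f"[{e[i]:g}, {e[i + 1]:g})" for i in range(len(e) - 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.row_probs, index=self.labels, columns=self.labels)

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "counts": self.counts.tolist(),
            "row_probs": self.row_probs.tolist(),
            "n_pairs_per_row": self.n_pairs_per_row.tolist(),
            "mcid": self.mcid,
            "p_drop": self.p_drop.tolist(),
            "p_rise": self.p_rise.tolist(),
            "p_beyond": self.p_beyond.tolist(),
            "row_mass": None if self.row_mass is None else self.row_mass.tolist(),
        }


def first_second_pairs(results: pd.DataFrame) -> pd.DataFrame:
    """One (first_value, second_value) pair per patient with >= 2 records,
    taken from the two chronologically earliest records."""
    r = results.sort_values(["patient_id", "date"], kind="stable")
    g = r.groupby("patient_id", sort=False)
    head = g.head(2)
    sizes = head.groupby("patient_id", sort=False)["value"].size()
    keep = sizes[sizes == 2].index
    head = head[head["patient_id"].isin(keep)]
    pos = head.groupby("patient_id", sort=False).cumcount()
    wide = head.assign(_pos=pos.map({0: "first", 1: "second"})).pivot(
        index="patient_id", columns="_pos", values="value"
    )
    return wide.reset_index()[["patient_id", "first", "second"]]


def default_bin_edges(low: float = 20.1, high: float = 195.1) -> np.ndarray:
    """5 mmol/mol-wide edges anchored at 48, covering [low, high]."""
    start = _ANCHOR - _BIN_WIDTH * np.ceil((_ANCHOR - low) / _BIN_WIDTH)
    stop = _ANCHOR + _BIN_WIDTH * np.ceil((high - _ANCHOR) / _BIN_WIDTH)
    return np.arange(start, stop + _BIN_WIDTH / 2, _BIN_WIDTH)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    outside = (values < edges[0]) | (values >= edges[-1])
    if outside.any():
        raise BinningError(f"value {values[outside][0]} outside bin range [{edges[0]}, {edges[-1]})")
    return np.digitize(values, edges) - 1


def build_matrix(pairs: pd.DataFrame, bin_edges: np.ndarray | None = None,
                 mcid: float = DEFAULT_MCID) -> TransitionMatrix:
    """Bin the pairs and row-normalize; MCID exceedance uses raw values."""
    edges = np.asarray(bin_edges if bin_edges is not None else default_bin_edges(), dtype=float)
    first = pairs["first"].to_numpy(dtype=float)
    second = pairs["second"].to_numpy(dtype=float)
    fi = _bin_index(first, edges)
    si = _bin_index(second, edges)
    nb = len(edges) - 1
    counts = np.zeros((nb, nb), dtype=np.int64)
    np.add.at(counts, (fi, si), 1)
    n_row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_probs = np.where(n_row[:, None] > 0, counts / np.maximum(n_row, 1)[:, None], 0.0)
    drop = np.zeros(nb)
    rise = np.zeros(nb)
    beyond = np.zeros(nb)
    for b in range(nb):
        mask = fi == b
        if not mask.any():
            continue
        d = second[mask] - first[mask]
        drop[b] = float((d <= -mcid).mean())
        rise[b] = float((d >= mcid).mean())
        beyond[b] = float((np.abs(d) >= mcid).mean())
    return TransitionMatrix(
        bin_edges=edges,
        counts=counts,
        row_probs=row_probs,
        n_pairs_per_row=n_row,
        mcid=mcid,
        p_drop=drop,
        p_rise=rise,
        p_beyond=beyond,
        row_mass=n_row / max(int(n_row.sum()), 1),
    )


def expected_matrix_normal(bin_edges: np.ndarray, means: np.ndarray, weights: np.ndarray,
                           cv: float, mcid: float = DEFAULT_MCID,
                           n_quad: int = 64) -> TransitionMatrix:
    """Closed-form transition matrix under the normal measurement model.

    ``means``/``weights`` define a discrete mixing law over true means; both
    results of a pair are conditionally independent N(mu, cv * mu) given mu.
    MCID exceedance probabilities integrate Phi over each first-result bin by
    Gauss-Legendre quadrature.
    """
    if cv < 0:
        raise DataError("cv must be >= 0")
    edges = np.asarray(bin_edges, dtype=float)
    means = np.asarray(means, dtype=float)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    nb = len(edges) - 1

    if cv == 0.0:
        # degenerate: both draws equal mu exactly
        fi = _bin_index(means, edges)
        joint = np.zeros((nb, nb))
        np.add.at(joint, (fi, fi), weights)
        row_mass = joint.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row_probs = np.where(row_mass[:, None] > 0, joint / np.maximum(row_mass, 1e-300)[:, None], 0.0)
        p = np.zeros(nb) if mcid > 0 else np.where(row_mass > 0, 1.0, 0.0)
        return TransitionMatrix(edges, np.zeros((nb, nb), dtype=np.int64), row_probs,
                                np.zeros(nb, dtype=np.int64), mcid, p, p,
                                np.minimum(2 * p, 1.0) if mcid == 0 else p,
                                row_mass=row_mass)

    sigma = cv * means  # per mixture component
    z = (edges[None, :] - means[:, None]) / sigma[:, None]
    cdf = stats.norm.cdf(z)  # (m, nb+1)
    bin_p = np.diff(cdf, axis=1)  # (m, nb): P(result in bin | mu)
    joint = np.einsum("m,ma,mb->ab", weights, bin_p, bin_p)
    row_mass = joint.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_probs = np.where(row_mass[:, None] > 0, joint / np.maximum(row_mass, 1e-300)[:, None], 0.0)

    # MCID exceedance: integrate over the first result x within each bin
    nodes, wq = np.polynomial.legendre.leggauss(n_quad)
    drop = np.zeros(nb)
    rise = np.zeros(nb)
    for b in range(nb):
        a, c = edges[b], edges[b + 1]
        x = 0.5 * (c - a) * nodes + 0.5 * (c + a)  # (q,)
        scale = 0.5 * (c - a)
        pdf = stats.norm.pdf((x[None, :] - means[:, None]) / sigma[:, None]) / sigma[:, None]
        p2_drop = stats.norm.cdf((x[None, :] - mcid - means[:, None]) / sigma[:, None])
        p2_rise = stats.norm.sf((x[None, :] + mcid - means[:, None]) / sigma[:, None])
        drop[b] = scale * float(np.einsum("m,mq,q->", weights, pdf * p2_drop, wq))
        rise[b] = scale * float(np.einsum("m,mq,q->", weights, pdf * p2_rise, wq))
    with np.errstate(invalid="ignore", divide="ignore"):
        p_drop = np.where(row_mass > 0, drop / np.maximum(row_mass, 1e-300), 0.0)
        p_rise = np.where(row_mass > 0, rise / np.maximum(row_mass, 1e-300), 0.0)
    return TransitionMatrix(
        bin_edges=edges,
        counts=np.zeros((nb, nb), dtype=np.int64),
        row_probs=row_probs,
        n_pairs_per_row=np.zeros(nb, dtype=np.int64),
        mcid=mcid,
        p_drop=p_drop,
        p_rise=p_rise,
        p_beyond=p_drop + p_rise,
        row_mass=row_mass,
    )
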