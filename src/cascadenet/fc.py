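"""Functional-connectivity statistics on BOLD series.

Centres on the edge-centric view: z-score every region over the whole
series (population SD), multiply pairs of z-scores frame by frame to get
the edge co-activation series E_nm(t).  The time average of each edge
equals the Pearson correlation of the pair exactly, so the static FC is the
time mean of the edge series and each column of E is an instantaneous FC
(iFC).  Two dynamic-FC variants are provided: dFC_e correlates iFC frames,
dFC_w correlates windowed FC matrices; the variance of the upper triangle
of dFC_w is the switching index.  Event analysis thresholds the root sum
square (RSS) of the edge series at a percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .hemodynamics import BoldSeries

__all__ = [
    "EdgeSeries", "DFCMatrix", "CaEventPartition",
    "edge_timeseries", "static_fc", "dfc_edge", "dfc_windowed",
    "switching_index", "rss", "partition_events",
    "event_correlation_distributions", "functional_hubs", "pca_modes",
    "sort_dfc_by_rss",
]


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class EdgeSeries:
    """Edge co-activation series; rows indexed by pairs (n, m), n < m."""

    E: np.ndarray  # edge x frame
    edge_index: list[tuple[int, int]]
    TR: float
    n_regions: int

    @property
    def n_frames(self) -> int:
        return self.E.shape[1]


@dataclass(frozen=True)
class DFCMatrix:
    M: np.ndarray
    variant: str  # "edge" | "windowed"
    window_size: float | None = None  # s
    window_step: float | None = None  # s
    degenerate_entries: bool = False  # some zero-variance frames were zeroed


@dataclass(frozen=True)
class CaEventPartition:
    rss: np.ndarray
    threshold: float
    percentile: float
    event_frames: np.ndarray
    nonevent_frames: np.ndarray


def _zscore_pop(X: np.ndarray, what: str = "region") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateInputError(f"{what} {bad[0]} has zero variance")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def edge_timeseries(B: BoldSeries) -> EdgeSeries:
    """E_nm(t) = z_n(t) * z_m(t) for n < m, z-scored over the whole series."""
    Z = _zscore_pop(B.B)
    n = Z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    E = Z[iu] * Z[ju]
    return EdgeSeries(E=E, edge_index=list(zip(iu.tolist(), ju.tolist())),
                      TR=B.TR, n_regions=n)


def static_fc(B: BoldSeries) -> np.ndarray:
    """Pearson correlation matrix across regions (population normalisation)."""
    Z = _zscore_pop(B.B)
    return (Z @ Z.T) / Z.shape[1]


def _corrcoef_cols(X: np.ndarray) -> tuple[np.ndarray, bool]:
    """Pairwise Pearson between columns; zero-variance columns give 0."""
    sd = X.std(axis=0)
    degenerate = bool(np.any(sd == 0))
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd_safe
    C = (Z.T @ Z) / X.shape[0]
    if degenerate:
        bad = sd == 0
        C[bad, :] = 0.0
        C[:, bad] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0), degenerate


def dfc_edge(E: EdgeSeries) -> DFCMatrix:
    """Frame-by-frame correlation of iFC columns (edge-centric dFC)."""
    if E.n_frames < 2:
        raise ValueError("need at least 2 frames")
    M, degen = _corrcoef_cols(E.E)
    return DFCMatrix(M=M, variant="edge", degenerate_entries=degen)


def dfc_windowed(B: BoldSeries, window: float = 60.0, step: float = 2.0) -> DFCMatrix:
    """Window-by-window correlation of FC upper triangles.

    A window of ``window`` seconds holds floor(window/TR) frames, anchored
    left; windows advance by ``step`` seconds and a trailing partial window
    is dropped.  FC inside each window is computed on the windowed segment
    alone (local z-scoring).
    """
    wlen = int(window // B.TR)
    wstep = max(1, int(round(step / B.TR)))
    if wlen < 2:
        raise ValueError(f"window of {window}s holds <2 frames at TR={B.TR}s")
    if B.n_frames < wlen:
        raise ValueError("series shorter than one window")
    n = B.n_regions
    iu, ju = np.triu_indices(n, k=1)
    starts = range(0, B.n_frames - wlen + 1, wstep)
    vecs = []
    for s in starts:
        seg = B.B[:, s : s + wlen]
        sd = seg.std(axis=1)
        sd_safe = np.where(sd == 0, 1.0, sd)
        Z = (seg - seg.mean(axis=1, keepdims=True)) / sd_safe[:, None]
        fc = (Z @ Z.T) / wlen
        if np.any(sd == 0):
            bad = sd == 0
            fc[bad, :] = 0.0
            fc[:, bad] = 0.0
        vecs.append(fc[iu, ju])
    V = np.array(vecs).T  # edge-triangle x window
    M, degen = _corrcoef_cols(V)
    return DFCMatrix(M=M, variant="windowed", window_size=window,
                     window_step=step, degenerate_entries=degen)


def switching_index(M: DFCMatrix) -> float:
    """Variance of the strictly-upper-triangle entries of a windowed dFC."""
    A = M.M
    if A.shape[0] < 2:
        return 0.0
    iu, ju = np.triu_indices(A.shape[0], k=1)
    return float(np.var(A[iu, ju]))


def rss(E: EdgeSeries) -> np.ndarray:
    """Root sum square of all edge co-activations per frame."""
    return np.sqrt(np.sum(E.E**2, axis=0))


def partition_events(rss_values: np.ndarray, percentile: float = 98.0) -> CaEventPartition:
    """Split frames at a percentile of the RSS; events are strictly above."""
    rss_values = np.asarray(rss_values, dtype=float)
    thr = float(np.percentile(rss_values, percentile))
    ev = np.flatnonzero(rss_values > thr)
    nev = np.flatnonzero(rss_values <= thr)
    return CaEventPartition(rss=rss_values, threshold=thr, percentile=percentile,
                            event_frames=ev, nonevent_frames=nev)


def event_correlation_distributions(E: EdgeSeries, part: CaEventPartition):
    """Pairwise iFC correlations split by event membership.

    Returns a dict with samples and summaries for within-events,
    events-vs-non-events and within-non-events (the off-diagonal entries of
    dFC_e grouped by the partition).
    """
    M = dfc_edge(E).M
    ev, nev = part.event_frames, part.nonevent_frames
    out = {}
    for name, rows, cols, within in (
        ("within_events", ev, ev, True),
        ("events_nonevents", ev, nev, False),
        ("within_nonevents", nev, nev, True),
    ):
        if within:
            sub = M[np.ix_(rows, cols)]
            iu, ju = np.triu_indices(len(rows), k=1)
            sample = sub[iu, ju]
        else:
            sample = M[np.ix_(rows, cols)].ravel()
        out[name] = {
            "sample": sample,
            "mean": float(sample.mean()) if sample.size else np.nan,
            "sd": float(sample.std()) if sample.size else np.nan,
            "n": int(sample.size),
        }
    return out


def _frame_to_matrix(frame: np.ndarray, n_regions: int) -> np.ndarray:
    A = np.eye(n_regions)
    iu, ju = np.triu_indices(n_regions, k=1)
    A[iu, ju] = frame
    A[ju, iu] = frame
    return A


def functional_hubs(iFC_frame: np.ndarray, n_regions: int):
    """Leading eigenvector of one iFC frame (reshaped to a symmetric matrix
    with unit diagonal); returns ``(loadings, eigenvalue, ratio)``.

    Both the raw leading eigenvalue and its normalised share
    ``lambda_1 / sum |lambda|`` are reported, since hub-selection
    thresholds in the literature are quoted under either convention.  The
    sign is fixed so the largest-magnitude loading is positive.  A
    degenerate (flat) spectrum yields ``(None, eigenvalue, ratio)``.
    """
    A = _frame_to_matrix(np.asarray(iFC_frame, float), n_regions)
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    lead = vecs[:, order[0]]
    ratio = float(vals[0] / np.sum(np.abs(vals)))
    if vals.size > 1 and abs(vals[0] - vals[1]) < 1e-12:
        return None, float(vals[0]), ratio
    k = int(np.argmax(np.abs(lead)))
    if lead[k] < 0:
        lead = -lead
    return lead, float(vals[0]), ratio


def pca_modes(X: np.ndarray, mode: str = "global", window_s: float = 2.0,
              rate_hz: float = 1000.0):
    """PCA of a region-by-time matrix over time samples.

    ``global``: one PCA of the whole series; returns (components
    [n_comp x regions], explained-variance ratios).  ``windowed``: PCA in
    consecutive non-overlapping windows of ``window_s`` seconds; returns
    the leading loading vector and leading ratio per window.
    """
    X = np.asarray(X, dtype=float)
    if mode == "global":
        p = PCA()
        p.fit(X.T)
        return p.components_, p.explained_variance_ratio_
    if mode == "windowed":
        wlen = int(round(window_s * rate_hz))
        if wlen < 2:
            raise ValueError("window too short")
        loadings, ratios = [], []
        for s in range(0, X.shape[1] - wlen + 1, wlen):
            p = PCA(n_components=1)
            p.fit(X[:, s : s + wlen].T)
            loadings.append(p.components_[0])
            ratios.append(p.explained_variance_ratio_[0])
        return np.array(loadings), np.array(ratios)
    raise ValueError(f"unknown mode {mode!r}")


def sort_dfc_by_rss(M: DFCMatrix, rss_values: np.ndarray):
    """Reorder a dFC matrix by ascending RSS; returns (matrix, permutation)."""
    order = np.argsort(np.asarray(rss_values), kind="stable")
    A = M.M[np.ix_(order, order)]
    return DFCMatrix(M=A, variant=M.variant, window_size=M.window_size,
                     window_step=M.window_step,
                     degenerate_entries=M.degenerate_entries), order
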