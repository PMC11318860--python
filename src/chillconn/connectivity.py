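"""Partial-correlation connectivity features.

Functional connectivity between ROI pairs is quantified as the partial
Pearson correlation — the correlation between two ROI time courses after
regressing out every other ROI in the set — read off the precision
(inverse covariance) matrix:

    pcorr(i, j) = -P_ij / sqrt(P_ii * P_jj),   P = Sigma^{-1}

With short pre-listening windows (tens of volumes) and hundreds of ROIs
the sample covariance is singular, so it is shrunk toward a scaled
identity before inversion.  By default the shrinkage coefficient is chosen
by the Ledoit-Wolf formula; an explicit coefficient can be given for
sensitivity analyses, and the coefficient actually used is carried in the
resulting :class:`ConnectivityFeatures`.  Correlations are mapped through
Fisher's r-to-z (atanh) before modeling.

Edge ordering is fixed as the row-major upper triangle of the matrix
indexed by *sorted* ROI id, so weight vectors are portable across runs and
cohorts (required for weight-transfer prediction).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf

from .exceptions import (
    EmptyAverageError,
    InsufficientDataError,
    SamplingError,
    UndefinedCorrelationError,
)
from .preprocess import RoiTimeSeries, extract_window

HEMISPHERES = ("L", "R", "mid")


@dataclass(frozen=True)
class ParcellationSpec:
    """Assignment of ROIs to functional networks and hemispheres.

    The default cohort uses 288 ROIs in 13 networks, among them a
    12-ROI auditory network (6 per hemisphere) and an 8-ROI reward
    network (amygdala, accumbens, orbitofrontal; 4 per hemisphere).
    """

    roi_ids: tuple
    network: tuple
    hemisphere: tuple

    def __post_init__(self):
        object.__setattr__(self, "roi_ids", tuple(self.roi_ids))
        object.__setattr__(self, "network", tuple(self.network))
        object.__setattr__(self, "hemisphere", tuple(self.hemisphere))
        n = len(self.roi_ids)
        if len(self.network) != n or len(self.hemisphere) != n:
            raise ValueError("network/hemisphere must match roi_ids length")
        if len(set(self.roi_ids)) != n:
            raise ValueError("duplicate ROI ids")
        for h in self.hemisphere:
            if h not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere {h!r}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def networks(self) -> tuple:
        seen = []
        for n in self.network:
            if n not in seen:
                seen.append(n)
        return tuple(seen)

    def network_of(self, roi_id: str) -> str:
        return self.network[self.roi_ids.index(roi_id)]

    def rois_in(self, network: str, side: str | None = None) -> tuple:
        if network not in self.networks:
            raise KeyError(f"unknown network {network!r}")
        out = []
        for rid, net, hemi in zip(self.roi_ids, self.network, self.hemisphere):
            if net == network and (side is None or hemi == side):
                out.append(rid)
        return tuple(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "network": self.network,
                "hemisphere": self.hemisphere,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParcellationSpec":
        return cls(
            roi_ids=tuple(df["roi_id"].astype(str)),
            network=tuple(df["network"].astype(str)),
            hemisphere=tuple(df["hemisphere"].astype(str)),
        )


@dataclass(frozen=True)
class ConnectivityFeatures:
    """A Fisher-z edge vector with explicit edge identities.

    ``edges`` are (roi_i, roi_j) pairs with roi_i < roi_j (string order);
    ``window`` records (start_s, end_s, epoch) provenance; ``shrinkage``
    is the covariance shrinkage coefficient used; ``n_averaged`` counts
    the trials averaged into the vector.
    """

    values: np.ndarray
    edges: tuple
    window: tuple | None = None
    shrinkage: float | None = None
    n_averaged: int = 1

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        if self.values.ndim != 1 or self.values.size != len(self.edges):
            raise ValueError("values length must match edge count")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    def __len__(self) -> int:
        return self.values.size


def partial_corr_matrix(
    series: RoiTimeSeries | np.ndarray,
    shrinkage: str | float = "auto",
    roi_ids: Sequence[str] | None = None,
    return_shrinkage: bool = False,
):
    """Partial-correlation matrix from the shrunk-precision route.

    Parameters
    ----------
    series:
        ROI time series (volumes x ROIs) or a bare array.
    shrinkage:
        ``"auto"`` selects the Ledoit-Wolf coefficient; a float in [0, 1]
        shrinks the sample covariance toward ``trace(S)/p * I`` by that
        amount.
    return_shrinkage:
        If true, also return the shrinkage coefficient used.
    """
    if isinstance(series, RoiTimeSeries):
        X = series.data
        ids = series.roi_ids
    else:
        X = np.asarray(series, dtype=float)
        ids = tuple(roi_ids) if roi_ids is not None else tuple(
            f"roi{i}" for i in range(X.shape[1])
        )
    n, p = X.shape
    if n < 3:
        raise InsufficientDataError("partial correlation needs >=3 volumes")
    if p < 2:
        raise InsufficientDataError("partial correlation needs >=2 ROIs")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = ids[int(np.argmax(sd == 0))]
        raise UndefinedCorrelationError(
            f"ROI {bad!r} has a constant time course; correlation undefined"
        )
    if shrinkage == "auto":
        cov, alpha = ledoit_wolf(X)
    else:
        alpha = float(shrinkage)
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("shrinkage coefficient must lie in [0, 1]")
        Xc = X - X.mean(axis=0)
        S = (Xc.T @ Xc) / n
        cov = (1.0 - alpha) * S + alpha * (np.trace(S) / p) * np.eye(p)
    prec = np.linalg.inv(cov)
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    pc = np.clip(pc, -1.0, 1.0)
    pc = (pc + pc.T) / 2.0
    np.fill_diagonal(pc, 1.0)
    if return_shrinkage:
        return pc, float(alpha)
    return pc


def fisher_z(r):
    """Fisher's r-to-z (atanh); |r| >= 1 is clipped with a warning."""
    r = np.asarray(r, dtype=float)
    clip = 1.0 - 1e-7
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlations at +/-1 clipped before atanh", stacklevel=2)
        r = np.clip(r, -clip, clip)
    z = np.arctanh(r)
    if z.ndim == 0:
        return float(z)
    return z


def _sorted_index(parcellation: ParcellationSpec):
    order = sorted(range(parcellation.n_rois), key=lambda i: parcellation.roi_ids[i])
    return order


def edge_list(
    parcellation: ParcellationSpec,
    mode: str = "network_pair",
    networks: Sequence[str] | None = None,
    side: str | None = None,
    edges: Iterable[tuple] | None = None,
) -> tuple:
    """The ordered edge identities for a feature-set mode.

    Modes
    -----
    ``network_pair``: cross-network edges between two named networks only
    (e.g. 12 auditory x 8 reward = 96 edges).
    ``hemispheric``: the full upper triangle (within + between) of the
    selected networks' ROIs restricted to one hemisphere (e.g. 6 auditory
    + 4 reward ROIs on the right = C(10,2) = 45 edges).
    ``whole_brain``: the full upper triangle of all ROIs.
    ``explicit``: a caller-provided edge list (validated, reordered).
    """
    ids = parcellation.roi_ids
    net = dict(zip(ids, parcellation.network))
    if mode == "explicit":
        if edges is None:
            raise ValueError("explicit mode requires an edge list")
        out = []
        for a, b in edges:
            if a not in ids or b not in ids:
                raise KeyError(f"unknown ROI in edge ({a}, {b})")
            out.append((a, b) if a < b else (b, a))
        return tuple(out)
    order = _sorted_index(parcellation)
    sorted_ids = [ids[i] for i in order]
    if mode == "whole_brain":
        sel = sorted_ids
        keep = lambda a, b: True  # noqa: E731
    elif mode == "network_pair":
        if networks is None or len(networks) != 2:
            raise ValueError("network_pair mode needs two network names")
        na, nb = networks
        for nn in (na, nb):
            if nn not in parcellation.networks:
                raise KeyError(f"unknown network {nn!r}")
        sel = [r for r in sorted_ids if net[r] in (na, nb)]
        keep = lambda a, b: net[a] != net[b]  # noqa: E731
    elif mode == "hemispheric":
        if networks is None:
            raise ValueError("hemispheric mode needs network names")
        if side not in ("L", "R"):
            raise ValueError("hemispheric mode needs side 'L' or 'R'")
        for nn in networks:
            if nn not in parcellation.networks:
                raise KeyError(f"unknown network {nn!r}")
        hemi = dict(zip(ids, parcellation.hemisphere))
        sel = [r for r in sorted_ids if net[r] in networks and hemi[r] == side]
        keep = lambda a, b: True  # noqa: E731
    else:
        raise ValueError(f"unknown edge mode {mode!r}")
    out = []
    for i in range(len(sel)):
        for j in range(i + 1, len(sel)):
            if keep(sel[i], sel[j]):
                out.append((sel[i], sel[j]))
    return tuple(out)


def select_edges(
    matrix: np.ndarray,
    parcellation: ParcellationSpec,
    mode: str = "network_pair",
    networks: Sequence[str] | None = None,
    side: str | None = None,
    edges: Iterable[tuple] | None = None,
    window: tuple | None = None,
    shrinkage: float | None = None,
) -> ConnectivityFeatures:
    """Extract an ordered edge vector from a square connectivity matrix.

    The matrix rows/columns follow ``parcellation.roi_ids`` order; values
    are taken as-is (apply :func:`fisher_z` first for z-features).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (parcellation.n_rois, parcellation.n_rois):
        raise ValueError("matrix shape does not match parcellation")
    wanted = edge_list(parcellation, mode=mode, networks=networks, side=side,
                       edges=edges)
    pos = {rid: i for i, rid in enumerate(parcellation.roi_ids)}
    vals = np.array([matrix[pos[a], pos[b]] for a, b in wanted])
    return ConnectivityFeatures(
        values=vals, edges=wanted, window=window, shrinkage=shrinkage
    )


def connectivity_features(
    series: RoiTimeSeries,
    parcellation: ParcellationSpec,
    mode: str = "network_pair",
    networks: Sequence[str] | None = ("auditory", "reward"),
    side: str | None = None,
    shrinkage: str | float = "auto",
    window: tuple[float, float] | None = None,
) -> ConnectivityFeatures:
    """Partial correlation -> Fisher z -> edge selection, in one call.

    The precision matrix is computed over *all* ROIs in ``series`` (the
    conditioning set is the full ROI set), then edges are selected.
    """
    if window is not None:
        series = extract_window(series, window[0], window[1])
        win = (float(window[0]), float(window[1]), series.epoch)
    else:
        win = (0.0, series.duration, series.epoch)
    if tuple(series.roi_ids) != tuple(parcellation.roi_ids):
        raise ValueError("series ROI order does not match parcellation")
    pc, alpha = partial_corr_matrix(series, shrinkage=shrinkage,
                                    return_shrinkage=True)
    pc = pc.copy()
    np.fill_diagonal(pc, 0.0)
    z = fisher_z(pc)
    return select_edges(z, parcellation, mode=mode, networks=networks,
                        side=side, window=win, shrinkage=alpha)


def list_network_pairs(parcellation: ParcellationSpec) -> tuple:
    """All unordered network pairs, in deterministic (sorted) order.

    13 networks yield C(13,2) = 78 pairs, 12 of which contain the
    auditory network.
    """
    nets = sorted(parcellation.networks)
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    return tuple(itertools.combinations(nets, 2))


def pairs_containing(pairs: Iterable[tuple], network: str) -> tuple:
    """Subset of network pairs that include ``network``."""
    return tuple(p for p in pairs if network in p)


def average_features(
    features: Sequence[ConnectivityFeatures | None],
    missing_policy: str = "drop",
) -> ConnectivityFeatures:
    """Elementwise mean over trials; ``None`` entries are missing trials.

    With ``missing_policy="drop"`` missing trials are skipped and the
    number actually averaged is recorded; any other policy raises on
    missing input.  All present trials must share the same edge set.
    """
    present = [f for f in features if f is not None]
    if not present:
        raise EmptyAverageError("all trials missing; nothing to average")
    if missing_policy != "drop" and len(present) != len(features):
        raise EmptyAverageError("missing trials not allowed under policy "
                                f"{missing_policy!r}")
    edges0 = present[0].edges
    for f in present[1:]:
        if f.edges != edges0:
            raise ValueError("edge sets differ across trials")
    vals = np.mean([f.values for f in present], axis=0)
    return ConnectivityFeatures(
        values=vals,
        edges=edges0,
        window=present[0].window,
        shrinkage=present[0].shrinkage,
        n_averaged=len(present),
    )


def sample_intrinsic_windows(
    series: RoiTimeSeries,
    k: int,
    window: float,
    reps: int,
    seed: int,
    parcellation: ParcellationSpec,
    mode: str = "network_pair",
    networks: Sequence[str] | None = ("auditory", "reward"),
    side: str | None = None,
    shrinkage: str | float = "auto",
) -> ConnectivityFeatures:
    """Connectivity from randomly sampled short windows of a long rest.

    Emulates the comparison of pre-task and intrinsic connectivity on an
    equal footing: each repetition draws ``k`` non-overlapping windows of
    ``window`` seconds uniformly at random from the epoch, averages their
    feature vectors, and the mean over repetitions is returned.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    total = series.duration
    slack = total - k * window
    if slack < 0:
        raise SamplingError(
            f"cannot pack {k} non-overlapping {window}-s windows into "
            f"{total}-s epoch"
        )
    rng = np.random.default_rng(seed)
    acc = None
    shrink_acc = 0.0
    edges = None
    for _ in range(reps):
        offsets = np.sort(rng.uniform(0.0, slack, size=k))
        starts = offsets + np.arange(k) * window
        per_win = []
        for s in starts:
            f = connectivity_features(
                series, parcellation, mode=mode, networks=networks, side=side,
                shrinkage=shrinkage, window=(s, s + window),
            )
            per_win.append(f)
        rep_mean = average_features(per_win)
        if acc is None:
            acc = rep_mean.values.copy()
            edges = rep_mean.edges
        else:
            acc += rep_mean.values
        shrink_acc += rep_mean.shrinkage if rep_mean.shrinkage is not None else 0.0
    vals = acc / reps
    return ConnectivityFeatures(
        values=vals,
        edges=edges,
        window=(0.0, total, series.epoch),
        shrinkage=shrink_acc / reps,
        n_averaged=k * reps,
    )
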