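"""Scalar reaction coordinates, free-energy surfaces and diagnostics.

The 2D free-energy surface is G(x, y) = -RT ln P(x, y) over a weighted
histogram of two reaction coordinates, shifted so the lowest unmasked
bin is zero, with empty bins masked.  R = 1.987e-3 kcal/(mol K) so
surfaces come out in kcal/mol.  Basin detection uses topographic
persistence: a local minimum is a basin when the lowest saddle
connecting it to any deeper minimum lies at least ``depth_threshold``
above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import jensenshannon

from .model import Conformation, Ensemble

R_KCAL = 1.987e-3  # kcal/(mol K)


# ---------------------------------------------------------------------------
# reaction coordinates
# ---------------------------------------------------------------------------

def radius_of_gyration(frame: Conformation, masses: np.ndarray,
                       selection: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration (nm) over a selection."""
    idx = np.arange(len(masses)) if selection is None else np.asarray(selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    xyz = frame.coords[idx]
    m = np.asarray(masses, dtype=float)[idx]
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    d2 = ((xyz - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def rg_series(ensemble: Ensemble, selection: np.ndarray | None = None) -> np.ndarray:
    masses = ensemble.topology.masses()
    return np.array([radius_of_gyration(f, masses, selection)
                     for f in ensemble.frames])


# ---------------------------------------------------------------------------
# 2D free-energy surface
# ---------------------------------------------------------------------------

@dataclass
class FESGrid:
    """Binned -RT ln P surface over two named reaction coordinates."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    G: np.ma.MaskedArray     # kcal/mol, masked where P = 0
    temperature_K: float
    x_name: str = "x"
    y_name: str = "y"
    probability: np.ndarray = field(default=None)  # the input P, for round-trips

    def __post_init__(self):
        if self.G.count() and abs(float(self.G.min())) > 1e-9:
            raise ValueError("surface must be shifted so its minimum is 0")

    @property
    def x_centers(self):
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self):
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def reprobability(self) -> np.ndarray:
        """Re-exponentiate the surface back to normalised probabilities."""
        RT = R_KCAL * self.temperature_K
        P = np.where(self.G.mask, 0.0, np.exp(-self.G.filled(0.0) / RT))
        return P / P.sum()


def fes2d(samples: np.ndarray, bins, temperature_K: float = 310.0,
          weights: np.ndarray | None = None, x_name: str = "x",
          y_name: str = "y", range_=None) -> FESGrid:
    """Free-energy surface from (x, y) samples.

    ``samples`` is (n, 2); ``bins`` anything np.histogram2d accepts.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] < 1:
        raise ValueError("samples must be a nonempty (n, 2) array")
    H, xe, ye = np.histogram2d(samples[:, 0], samples[:, 1], bins=bins,
                               range=range_, weights=weights)
    if len(xe) < 2 or len(ye) < 2 or xe[0] == xe[-1] or ye[0] == ye[-1]:
        raise ValueError("degenerate (zero-width) bin range")
    P = H / H.sum()
    mask = P == 0
    RT = R_KCAL * temperature_K
    with np.errstate(divide="ignore"):
        G = -RT * np.log(np.where(mask, 1.0, P))
    G = np.ma.MaskedArray(G, mask=mask)
    G = G - G.min()
    grid = FESGrid(xe, ye, G, temperature_K, x_name, y_name, P)
    # invariant: re-exponentiation recovers the input histogram
    assert np.allclose(grid.reprobability(), P, atol=1e-9)
    return grid


def find_basins(grid: FESGrid, depth_threshold: float = 0.5
                ) -> list[tuple[float, float, float]]:
    """Persistent local minima of the surface, deepest first.

    A bin is a candidate minimum when no unmasked 8-neighbour is lower;
    candidates are kept when their persistence (lowest connecting saddle
    minus the minimum's G, via watershed flooding in order of increasing
    G) reaches ``depth_threshold``.  Empty (masked) bins are treated as
    passable barriers at the height of the worst sampled bin, so sampling
    islands separated only by empty bins do not count as independent
    basins unless they are at least ``depth_threshold`` below that
    height.  Returns (x_center, y_center, G).
    """
    G = grid.G
    if G.count() == 0:
        raise ValueError("all-masked surface")
    nx, ny = G.shape
    sea = float(G.max())
    filled = G.filled(sea)
    is_masked = np.ma.getmaskarray(G)

    order = np.argsort(filled, axis=None)
    parent = {}
    basin_min: dict[int, float] = {}
    persistence: dict[int, float] = {}
    label = -np.ones((nx, ny), dtype=int)
    minima: list[tuple[int, int]] = []

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    next_label = 0
    for flat in order:
        i, j = divmod(int(flat), ny)
        g = filled[i, j]
        neigh_labels = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and label[a, b] >= 0:
                    neigh_labels.add(find(label[a, b]))
        if not neigh_labels:
            label[i, j] = next_label
            parent[next_label] = next_label
            basin_min[next_label] = g
            minima.append((i, j))
            next_label += 1
        else:
            deepest = min(neigh_labels, key=lambda L: basin_min[L])
            label[i, j] = deepest
            for L in neigh_labels:
                if L != deepest:
                    # saddle at height g merges basin L into the deeper one
                    persistence.setdefault(L, g - basin_min[L])
                    parent[L] = deepest

    out = []
    for k, (i, j) in enumerate(minima):
        if is_masked[i, j]:
            continue  # a sea-level (empty-bin) component is not a basin
        pers = persistence.get(k, np.inf)  # unmerged basin: infinite persistence
        if pers >= depth_threshold:
            out.append((float(grid.x_centers[i]), float(grid.y_centers[j]),
                        float(filled[i, j])))
    out.sort(key=lambda t: t[2])
    return out


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def split_half_convergence(ensemble: Ensemble, metrics: dict, bins=30) -> dict:
    """Jensen-Shannon distance between first- and second-half metric PDFs.

    ``metrics`` maps a name to a callable ``f(ensemble) -> 1D sample
    array``.  Each metric's samples are histogrammed per half on a
    common binning and compared with the base-2 Jensen-Shannon distance
    (0 = identical, 1 = disjoint).  Metrics that raise are skipped with
    a warning entry of NaN.
    """
    if ensemble.n_frames < 4:
        raise ValueError("need at least 4 frames to split")
    half = ensemble.n_frames // 2
    e1 = ensemble.subset(range(half))
    e2 = ensemble.subset(range(half, ensemble.n_frames))
    out = {}
    for name, fn in metrics.items():
        try:
            v1, v2 = np.asarray(fn(e1), float), np.asarray(fn(e2), float)
        except Exception:
            out[name] = float("nan")
            continue
        lo = min(v1.min(), v2.min())
        hi = max(v1.max(), v2.max())
        if hi == lo:
            out[name] = 0.0
            continue
        p1, _ = np.histogram(v1, bins=bins, range=(lo, hi))
        p2, _ = np.histogram(v2, bins=bins, range=(lo, hi))
        out[name] = float(jensenshannon(p1, p2, base=2))
    return out


def replica_traversal(series: np.ndarray, n_replicas: int) -> np.ndarray:
    """Completed bottom-to-top-to-bottom round trips per replica.

    ``series`` is (n_replicas, n_steps) of temperature-ladder indices in
    ``[0, n_replicas)``.
    """
    series = np.atleast_2d(np.asarray(series, dtype=int))
    if series.min() < 0 or series.max() >= n_replicas:
        raise ValueError("temperature index out of range")
    top = n_replicas - 1
    out = np.zeros(series.shape[0], dtype=int)
    for r, s in enumerate(series):
        state = "seek_bottom"   # need to start from the bottom rung
        trips = 0
        for v in s:
            if state == "seek_bottom" and v == 0:
                state = "seek_top"
            elif state == "seek_top" and v == top:
                state = "seek_home"
            elif state == "seek_home" and v == 0:
                trips += 1
                state = "seek_top"
        out[r] = trips
    return out


# ---------------------------------------------------------------------------
# replica-exchange temperature ladder
# ---------------------------------------------------------------------------

@dataclass
class LadderSpec:
    T_min: float
    T_max: float
    n_replicas: int

    def __post_init__(self):
        if not self.T_min < self.T_max:
            raise ValueError("T_min must be < T_max")
        if self.n_replicas < 2:
            raise ValueError("need at least 2 replicas")


def temperature_ladder(spec: LadderSpec) -> np.ndarray:
    """Geometrically spaced temperatures with exact endpoints.

    T_i = T_min (T_max/T_min)^(i/(n-1)): constant ratio between
    neighbouring rungs, the standard choice for roughly uniform exchange
    acceptance when heat capacity is flat.
    """
    n = spec.n_replicas
    i = np.arange(n)
    T = spec.T_min * (spec.T_max / spec.T_min) ** (i / (n - 1))
    T[0], T[-1] = spec.T_min, spec.T_max
    return T
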