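"""Landmark preprocessing and shape statistics.

Implements the geometric-morphometric toolkit used throughout the pipeline:
equidistant semilandmark extraction from digitized curves, polygon areas
(yolk sac), standard length, generalized Procrustes analysis (GPA),
morphological disparity with permutation tests, linear models on Procrustes
coordinates evaluated by the randomized residual permutation procedure
(RRPP), and phenotypic trajectory analysis across developmental stages.

Shapes are 2-D landmark configurations.  After GPA, coordinates are treated
as dimensionless; raw units are only meaningful for centroid sizes, lengths
and areas computed before superimposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfig",
    "ProcrustesResult",
    "resample_curve",
    "polygon_area",
    "centroid_size",
    "standard_length",
    "gpa",
    "procrustes_variance",
    "disparity_test",
    "rrpp_regression",
    "trajectory_analysis",
]


@dataclass
class LandmarkConfig:
    """A single specimen's digitized configuration.

    coords holds the k named landmarks used for shape analysis; curves are
    ordered polylines (e.g. head and yolk-sac outlines) from which
    semilandmarks, lengths and areas are extracted; aux_points are named
    single points (e.g. the notochord tip) that are not part of the shape
    configuration proper.
    """

    specimen_id: str
    stage: float | int | str | None
    coords: np.ndarray
    curves: dict[str, np.ndarray] = field(default_factory=dict)
    aux_points: dict[str, np.ndarray] = field(default_factory=dict)
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if self.coords.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in {self.specimen_id!r}")
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"duplicated landmark coordinates in {self.specimen_id!r}"
            )
        self.curves = {k: np.asarray(v, float) for k, v in self.curves.items()}
        self.aux_points = {
            k: np.asarray(v, float) for k, v in self.aux_points.items()
        }

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class ProcrustesResult:
    """Output of generalized Procrustes analysis."""

    aligned: np.ndarray  # (n, k, 2), centred, unit centroid size
    centroid_sizes: np.ndarray  # (n,), in input units
    consensus: np.ndarray  # (k, 2)
    n_iterations: int
    specimen_ids: list[str] | None = None
    stages: list | None = None

    @property
    def flat(self) -> np.ndarray:
        """Aligned coordinates as an (n, 2k) matrix of shape variables."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


# ---------------------------------------------------------------------------
# curves, areas, lengths
# ---------------------------------------------------------------------------

def resample_curve(points: np.ndarray, n: int) -> np.ndarray:
    """Extract ``n`` semilandmarks equally spaced by arc length.

    The curve is treated as piecewise linear; endpoints are preserved
    exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be a (m>=2, 2) array")
    if n < 2:
        raise ValueError("need at least 2 semilandmarks")
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) curve")
    targets = np.linspace(0.0, total, n)
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    out = np.column_stack([x, y])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def polygon_area(points: np.ndarray) -> float:
    """Absolute shoelace area of an ordered polygon (squared input units)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 ordered points")
    x, y = pts[:, 0], pts[:, 1]
    s = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    return float(abs(s) / 2.0)


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks to the centroid."""
    c = np.asarray(coords, dtype=float)
    centred = c - c.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def standard_length(
    config: LandmarkConfig,
    notochord: str = "notochord",
    head_curve: str = "head",
    n_semilandmarks: int = 50,
) -> float:
    """Standard length: Euclidean distance between the notochord tip and the
    farthest of ``n_semilandmarks`` points resampled from the head curve."""
    if notochord not in config.aux_points:
        raise KeyError(
            f"configuration {config.specimen_id!r} has no "
            f"{notochord!r} point"
        )
    if head_curve not in config.curves:
        raise KeyError(
            f"configuration {config.specimen_id!r} has no {head_curve!r} curve"
        )
    tip = config.aux_points[notochord]
    semis = resample_curve(config.curves[head_curve], n_semilandmarks)
    d = np.hypot(semis[:, 0] - tip[0], semis[:, 1] - tip[1])
    return float(d.max())


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper (reflection-free) rotation R minimising ||source @ R - target||."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, d]) @ vt
    return r


def _as_coord_array(configs) -> tuple[np.ndarray, list[str] | None, list | None]:
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError("coordinate array must be (n, k, 2)")
        return arr, None, None
    ks = {c.n_landmarks for c in configs}
    if len(ks) > 1:
        raise ValueError(f"mismatched landmark counts across configurations: {sorted(ks)}")
    arr = np.stack([c.coords for c in configs])
    ids = [c.specimen_id for c in configs]
    stages = [c.stage for c in configs]
    return arr, ids, stages


def gpa(
    configs: Sequence[LandmarkConfig] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes analysis (full Procrustes superimposition).

    Each configuration is centred, scaled to unit centroid size and rotated
    (rotation only, no reflection) onto the current consensus; the consensus
    is recomputed until it changes by less than ``tol``.
    """
    arr, ids, stages = _as_coord_array(configs)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    centred = arr - arr.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centred**2).sum(axis=(1, 2)))
    if np.any(sizes <= 0):
        raise ValueError("configuration with zero centroid size")
    scaled = centred / sizes[:, None, None]

    consensus = scaled[0].copy()
    consensus /= np.sqrt((consensus**2).sum())
    aligned = scaled.copy()
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = scaled[i] @ _optimal_rotation(scaled[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        norm = np.sqrt((new_consensus**2).sum())
        if norm <= 0:
            raise RuntimeError("degenerate consensus during GPA")
        new_consensus /= norm
        change = np.sqrt(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus change {change:.3e}, tol {tol:.1e})"
        )
    return ProcrustesResult(
        aligned=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        n_iterations=it,
        specimen_ids=ids,
        stages=stages,
    )


# ---------------------------------------------------------------------------
# disparity
# ---------------------------------------------------------------------------

def _flatten_shapes(aligned: np.ndarray) -> np.ndarray:
    y = np.asarray(aligned, float)
    if y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    return y


def procrustes_variance(
    aligned: np.ndarray, groups: Sequence
) -> dict:
    """Per-group disparity: mean squared Procrustes distance to the group
    mean shape."""
    y = _flatten_shapes(aligned)
    groups = np.asarray(groups)
    if y.shape[0] != groups.shape[0]:
        raise ValueError("groups length must match number of specimens")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for g in labels:
        yg = y[groups == g]
        if yg.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 specimens")
        out[g] = float(((yg - yg.mean(axis=0)) ** 2).sum(axis=1).mean())
    return out


def disparity_test(
    aligned: np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pairwise absolute differences in Procrustes variance with permutation
    p-values (group labels shuffled; observed included in the null)."""
    y = _flatten_shapes(aligned)
    groups = np.asarray(groups)
    obs = procrustes_variance(y, groups)
    labels = list(obs)
    rng = np.random.default_rng(seed)
    n = y.shape[0]
    masks = {g: groups == g for g in labels}

    # permuting labels over specimens == permuting specimen rows under fixed
    # label positions; vectorize over permutations
    idx = np.empty((n_perm + 1, n), dtype=int)
    idx[0] = np.arange(n)
    for b in range(1, n_perm + 1):
        idx[b] = rng.permutation(n)
    disp = {}
    for g in labels:
        yg = y[idx[:, masks[g]]]  # (B, n_g, p)
        mu = yg.mean(axis=1, keepdims=True)
        disp[g] = ((yg - mu) ** 2).sum(axis=2).mean(axis=1)  # (B,)

    rows = []
    for i, g in enumerate(labels):
        for h in labels[i + 1:]:
            d = np.abs(disp[g] - disp[h])
            p = float((d >= d[0] - 1e-15).mean())
            rows.append(
                {
                    "group1": g,
                    "group2": h,
                    "disparity1": obs[g],
                    "disparity2": obs[h],
                    "abs_diff": float(d[0]),
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RRPP linear models on shape
# ---------------------------------------------------------------------------

def _orth(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of x (SVD-based, rank-revealing)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return u[:, s > tol]


def rrpp_regression(
    aligned: np.ndarray,
    terms: Sequence[tuple[str, np.ndarray]],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sequential (type-I) sums of squares over shape coordinates, with term
    significance from the randomized residual permutation procedure.

    For each term the null distribution is built by permuting the residuals
    of the reduced model (all preceding terms); the effect size is
    Z = (SS_obs - mean SS_perm) / sd SS_perm and p is the rank of the
    observed SS among the permuted values (observed included, so
    p >= 1/(n_perm + 1)).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    y = _flatten_shapes(aligned)
    n = y.shape[0]
    rng = np.random.default_rng(seed)

    y_c = y - y.mean(axis=0)
    ss_total = float((y_c**2).sum())

    idx = np.empty((n_perm + 1, n), dtype=int)
    idx[0] = np.arange(n)
    for b in range(1, n_perm + 1):
        idx[b] = rng.permutation(n)

    rows = []
    ss_sum = 0.0
    x_cum = np.ones((n, 1))
    u_red = _orth(x_cum)
    chunk = max(1, int(2e7 // max(1, n * y.shape[1])))
    for name, x_term in terms:
        x_term = np.asarray(x_term, float)
        if x_term.ndim == 1:
            x_term = x_term[:, None]
        if x_term.shape[0] != n:
            raise ValueError(f"term {name!r} has wrong number of rows")
        x_full = np.hstack([x_cum, x_term])
        u_full = _orth(x_full)
        df = u_full.shape[1] - u_red.shape[1]
        if df == 0:
            raise ValueError(
                f"term {name!r} is aliased with preceding terms "
                "(design rank does not increase)"
            )
        # orthonormal basis of the subspace the term adds over the reduced model
        u_d = _orth(u_full - u_red @ (u_red.T @ u_full))
        resid_red = y - u_red @ (u_red.T @ y)
        ss = np.empty(n_perm + 1)
        for c0 in range(0, n_perm + 1, chunk):
            sl = idx[c0:c0 + chunk]
            t = np.einsum("nd,bnp->bdp", u_d, resid_red[sl])
            ss[c0:c0 + len(sl)] = (t**2).sum(axis=(1, 2))
        ss_obs = float(ss[0])
        sd = float(ss.std(ddof=1))
        z = (ss_obs - float(ss.mean())) / sd if sd > 0 else 0.0
        p = float((ss >= ss_obs - 1e-15).mean())
        rows.append(
            {
                "term": name,
                "df": df,
                "SS": ss_obs,
                "R2": ss_obs / ss_total,
                "Z": z,
                "p": p,
            }
        )
        ss_sum += ss_obs
        x_cum, u_red = x_full, u_full
    rank_red = u_red.shape[1]

    ss_resid = ss_total - ss_sum
    rows.append(
        {
            "term": "Residuals",
            "df": n - rank_red,
            "SS": ss_resid,
            "R2": ss_resid / ss_total,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": ss_total,
            "R2": 1.0,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows)


def dummy_code(labels: Sequence, drop_first: bool = True) -> np.ndarray:
    """Treatment-coded indicator columns for a categorical factor."""
    d = pd.get_dummies(pd.Series(np.asarray(labels)), drop_first=drop_first)
    return d.to_numpy(dtype=float)


def nested_code(outer: Sequence, inner: Sequence) -> np.ndarray:
    """Indicator columns for ``inner`` nested within ``outer`` (one column
    per inner level beyond the first within each outer level)."""
    outer = np.asarray(outer)
    inner = np.asarray(inner)
    cols = []
    for g in pd.unique(outer):
        mask = outer == g
        fams = pd.unique(inner[mask])
        for f in fams[1:]:
            cols.append(((outer == g) & (inner == f)).astype(float))
    if not cols:
        return np.empty((len(outer), 0))
    return np.column_stack(cols)


def head_shape_terms(meta: pd.DataFrame) -> list[tuple[str, np.ndarray]]:
    """Sequential model terms for the head-shape regression:

    coordinates ~ log10(size) + cross + age + cross/family
                + cross:log10(size) + cross:age
                + cross:family:log10(size) + cross:family:age

    ``meta`` needs columns ``size`` (centroid size), ``cross``, ``family``
    and ``age``.
    """
    logsize = np.log10(meta["size"].to_numpy(float))[:, None]
    age = meta["age"].to_numpy(float)[:, None]
    cross = dummy_code(meta["cross"])
    fam = nested_code(meta["cross"], meta["family"])
    return [
        ("log(size)", logsize),
        ("Cross type", cross),
        ("Age", age),
        ("Cross type x Family", fam),
        ("Cross type x log(size)", cross * logsize),
        ("Cross type x Age", cross * age),
        ("Cross type x log(size) x Family", fam * logsize),
        ("Cross type x Age x Family", fam * age),
    ]


# ---------------------------------------------------------------------------
# trajectory analysis
# ---------------------------------------------------------------------------

def _trajectory_stats(y, groups, stages, glabels, slabels):
    """Stage-mean trajectories and their summary statistics per group."""
    traj = {}
    for g in glabels:
        m = np.empty((len(slabels), y.shape[1]))
        for j, s in enumerate(slabels):
            mask = (groups == g) & (stages == s)
            if not mask.any():
                raise ValueError(f"missing group x stage cell: {g!r} x {s!r}")
            m[j] = y[mask].mean(axis=0)
        traj[g] = m
    lengths = {
        g: float(np.sqrt((np.diff(m, axis=0) ** 2).sum(axis=1)).sum())
        for g, m in traj.items()
    }
    axes = {}
    for g, m in traj.items():
        mc = m - m.mean(axis=0)
        _, _, vt = np.linalg.svd(mc, full_matrices=False)
        axes[g] = vt[0]
    return traj, lengths, axes


def _traj_shape_distance(m1: np.ndarray, m2: np.ndarray) -> float:
    """Procrustes distance between two trajectories treated as point
    configurations in shape space (centred, unit-scaled, optimally rotated)."""
    z1 = m1 - m1.mean(axis=0)
    z2 = m2 - m2.mean(axis=0)
    n1 = np.sqrt((z1**2).sum())
    n2 = np.sqrt((z2**2).sum())
    if n1 <= 0 or n2 <= 0:
        return 0.0
    z1, z2 = z1 / n1, z2 / n2
    u, s, vt = np.linalg.svd(z2.T @ z1)
    rot = u @ vt
    return float(np.sqrt(((z1 - z2 @ rot) ** 2).sum()))


def trajectory_analysis(
    aligned: np.ndarray,
    groups: Sequence,
    stages: Sequence,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    subjects: Sequence | None = None,
) -> pd.DataFrame:
    """Pairwise differences between group ontogenetic trajectories.

    A trajectory is the sequence of stage mean shapes.  Compared statistics:
    absolute difference in path length, angle (degrees) between first
    principal axes, and shape distance between size-standardized
    trajectories.  Nulls come from permuting group labels — at the subject
    level when ``subjects`` is given (keeping each subject's stages
    together), otherwise stratified within stage.
    """
    y = _flatten_shapes(aligned)
    groups = np.asarray(groups)
    stages = np.asarray(stages)
    glabels = list(pd.unique(groups))
    slabels = list(pd.unique(stages))
    if len(glabels) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)

    def stats_for(glab):
        traj, lengths, axes = _trajectory_stats(y, glab, stages, glabels, slabels)
        out = {}
        for i, g in enumerate(glabels):
            for h in glabels[i + 1:]:
                dl = abs(lengths[g] - lengths[h])
                c = abs(float(np.dot(axes[g], axes[h])))
                ang = float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
                ds = _traj_shape_distance(traj[g], traj[h])
                out[(g, h)] = (dl, ang, ds)
        return out

    obs = stats_for(groups)

    if subjects is not None:
        subjects = np.asarray(subjects)
        uniq_subj = pd.unique(subjects)
        subj_group = {}
        for s in uniq_subj:
            gs = pd.unique(groups[subjects == s])
            if len(gs) != 1:
                raise ValueError(f"subject {s!r} appears in multiple groups")
            subj_group[s] = gs[0]
        subj_labels = np.array([subj_group[s] for s in uniq_subj])
        pos = {s: np.flatnonzero(subjects == s) for s in uniq_subj}

    null = {pair: np.empty((n_perm + 1, 3)) for pair in obs}
    for pair, v in obs.items():
        null[pair][0] = v
    for b in range(1, n_perm + 1):
        if subjects is None:
            glab = groups.copy()
            for s in slabels:
                m = stages == s
                glab[m] = rng.permutation(glab[m])
        else:
            perm = rng.permutation(subj_labels)
            glab = np.empty_like(groups)
            for s, lab in zip(uniq_subj, perm):
                glab[pos[s]] = lab
        st = stats_for(glab)
        for pair, v in st.items():
            null[pair][b] = v

    rows = []
    for (g, h), v in obs.items():
        d = null[(g, h)]
        ps = [(d[:, j] >= d[0, j] - 1e-15).mean() for j in range(3)]
        rows.append(
            {
                "group1": g,
                "group2": h,
                "path_length_diff": v[0],
                "p_length": float(ps[0]),
                "direction_angle_deg": v[1],
                "p_direction": float(ps[1]),
                "shape_distance": v[2],
                "p_shape": float(ps[2]),
            }
        )
    return pd.DataFrame(rows)
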