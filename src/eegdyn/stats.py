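"""Cohort-level inference.

Paired t-tests with 2xIQR outlier exclusion on the paired differences,
Cohen's d = t/sqrt(n), electrode-cluster permutation testing with
half-cohort label reversal, and brain-behavior correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .montage import AdjacencyGraph

logger = logging.getLogger(__name__)

IQR_FACTOR = 2.0  # note: 2 x IQR, not the common 1.5
DEFAULT_P_THRESH = 0.01
DEFAULT_MIN_CLUSTER = 4
DEFAULT_N_PERM = 2000


def exclude_outliers(values, factor: float = IQR_FACTOR):
    """Keep x with Q1 - factor*IQR <= x <= Q3 + factor*IQR.

    Quartiles use linear interpolation between order statistics.
    Returns (kept boolean mask, excluded index array).
    """
    values = np.asarray(values, dtype=np.float64)
    if len(values) < 4:
        raise ValueError("outlier exclusion needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    keep = (values >= q1 - factor * iqr) & (values <= q3 + factor * iqr)
    return keep, np.flatnonzero(~keep)


@dataclass
class PairedSample:
    """Per-participant feature values under two matched conditions."""

    a: np.ndarray
    b: np.ndarray
    ids: tuple = ()

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be matching 1-D arrays")
        if not self.ids:
            self.ids = tuple(str(i) for i in range(len(self.a)))
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("participant ids must be unique")

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass
class EffectStats:
    t: float
    df: int
    p: float
    n: int
    d: float
    excluded: tuple = ()


def _t_from_diffs(d: np.ndarray) -> tuple[float, int, float]:
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2 * sstats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return float(t), df, float(p)


def paired_t(sample: PairedSample, exclude: bool = True) -> EffectStats:
    """Paired two-tailed t-test on A-B differences; d = t/sqrt(n) exactly.

    Outlier exclusion (2xIQR rule) is applied to the paired differences
    before the test.
    """
    d = sample.differences
    excluded: tuple = ()
    if exclude and len(d) >= 4:
        keep, exc = exclude_outliers(d)
        excluded = tuple(sample.ids[i] for i in exc)
        d = d[keep]
    if len(d) < 3:
        raise ValueError("need at least 3 pairs after exclusion")
    t, df, p = _t_from_diffs(d)
    n = len(d)
    return EffectStats(t=t, df=df, p=p, n=n, d=t / np.sqrt(n), excluded=excluded)


@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    electrodes: tuple
    clusters: list  # list of dicts: labels, sign, t_sum, p
    null_max_tsum: np.ndarray
    n_permutations: int


def _vector_paired_t(diffs: np.ndarray) -> np.ndarray:
    """Per-electrode paired t for a (participants x electrodes) matrix."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.where(mean == 0, 0.0, np.inf))
    return t


def _find_clusters(
    t: np.ndarray, p: np.ndarray, neighbor_idx: list, p_thresh: float, min_cluster: int
) -> list:
    """Connected components of same-sign suprathreshold electrodes."""
    supra = p < p_thresh
    seen = np.zeros(len(t), dtype=bool)
    clusters = []
    for start in np.flatnonzero(supra):
        if seen[start]:
            continue
        sign = np.sign(t[start])
        comp = [start]
        seen[start] = True
        stack = [start]
        while stack:
            u = stack.pop()
            for v in neighbor_idx[u]:
                if supra[v] and not seen[v] and np.sign(t[v]) == sign:
                    seen[v] = True
                    comp.append(v)
                    stack.append(v)
        if len(comp) >= min_cluster:
            clusters.append((comp, sign, float(t[comp].sum())))
    return clusters


def cluster_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    electrodes,
    adjacency: AdjacencyGraph,
    p_thresh: float = DEFAULT_P_THRESH,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> ClusterTestResult:
    """Electrode-cluster permutation test on paired condition data.

    *a*, *b*: (participants x electrodes) feature matrices.  Clusters are
    connected sets (in *adjacency*) of >= min_cluster same-sign electrodes
    with uncorrected p < p_thresh.  Each permutation reverses the A/B
    labels in a random floor(n/2) participant subset and records the
    maximum |t'_sum| over its clusters (0 if none); cluster p-values are
    (1 + #{max|t'_sum| >= |t_sum|}) / (n_perm + 1).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    electrodes = tuple(electrodes)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("a and b must be matching participants x electrodes matrices")
    n, n_el = a.shape
    if n_el < 2:
        raise ValueError("need at least 2 electrodes")
    if n < 4:
        raise ValueError("need at least 4 participants")
    if len(electrodes) != n_el:
        raise ValueError("electrode label count mismatch")
    missing = set(electrodes) - set(adjacency.nodes)
    if missing:
        raise ValueError(f"adjacency graph missing electrodes: {sorted(missing)}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; permutation p-values will be coarse")

    nm = adjacency.neighbor_map()
    e_index = {e: i for i, e in enumerate(electrodes)}
    neighbor_idx = [
        [e_index[v] for v in nm[e] if v in e_index] for e in electrodes
    ]

    diffs = a - b
    df = n - 1
    t_obs = _vector_paired_t(diffs)
    p_obs = 2 * sstats.t.sf(np.abs(t_obs), df)
    observed = _find_clusters(t_obs, p_obs, neighbor_idx, p_thresh, min_cluster)

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    k_flip = n // 2
    for i in range(n_perm):
        flip = rng.choice(n, size=k_flip, replace=False)
        signs = np.ones(n)
        signs[flip] = -1.0
        t_perm = _vector_paired_t(diffs * signs[:, None])
        p_perm = 2 * sstats.t.sf(np.abs(t_perm), df)
        cl = _find_clusters(t_perm, p_perm, neighbor_idx, p_thresh, min_cluster)
        if cl:
            null[i] = max(abs(ts) for _, _, ts in cl)

    clusters = []
    for comp, sign, t_sum in observed:
        p_val = (1 + int(np.sum(null >= abs(t_sum)))) / (n_perm + 1)
        clusters.append(
            {
                "labels": tuple(electrodes[i] for i in comp),
                "sign": int(sign),
                "t_sum": t_sum,
                "p": p_val,
            }
        )
    return ClusterTestResult(
        t_map=t_obs,
        electrodes=electrodes,
        clusters=clusters,
        null_max_tsum=null,
        n_permutations=n_perm,
    )


def behavior_correlation(x, y, exclude: bool = True) -> dict:
    """Pearson r (two-tailed) and OLS fit of y on x.

    Outlier exclusion (2xIQR, applied to each variable separately; a
    participant flagged on either is dropped) precedes the test.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    if exclude and len(x) >= 4:
        kx, _ = exclude_outliers(x)
        ky, _ = exclude_outliers(y)
        keep = kx & ky
        x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValueError("need at least 4 pairs after exclusion")
    r, p = sstats.pearsonr(x, y)
    fit = sstats.linregress(x, y)
    return {
        "r": float(r),
        "p": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": len(x),
    }
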