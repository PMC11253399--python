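"""Clonal decomposition from multi-sample read counts.

Mutations of one tumour are clustered on per-sample cancer-cell fractions
(CCF) with a finite binomial mixture fitted by expectation-maximisation:
each clone is a vector of per-sample CCF centroids, mapped to an expected
variant-allele fraction through purity, copy number and multiplicity, and
read counts enter through the binomial likelihood. Model size is chosen by
BIC over K = 1..max_clusters with the best of many seeded restarts kept.
Clones below 1% of a tumour's mutations are pruned, per-timepoint
prevalences are averaged for fishplot-style summaries, and a clone tree is
built by a greedy containment heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import MutationKey, MutationRecord

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class CountMatrix:
    """Alt/depth read counts for every (mutation, sample) cell of a tumour."""

    keys: list[MutationKey]
    samples: list[str]
    alt: np.ndarray  # (n, S) int
    depth: np.ndarray  # (n, S) int
    purity: np.ndarray  # (S,) in (0, 1]
    cn_total: np.ndarray  # (n, S) int
    cn_major: np.ndarray  # (n, S) int
    missing: np.ndarray | None = None  # (n, S) bool, cells absent from pileup

    def __post_init__(self) -> None:
        n, S = len(self.keys), len(self.samples)
        self.alt = np.asarray(self.alt, dtype=int)
        self.depth = np.asarray(self.depth, dtype=int)
        self.purity = np.asarray(self.purity, dtype=float)
        self.cn_total = np.asarray(self.cn_total, dtype=int)
        self.cn_major = np.asarray(self.cn_major, dtype=int)
        for name, arr, shape in (
            ("alt", self.alt, (n, S)),
            ("depth", self.depth, (n, S)),
            ("purity", self.purity, (S,)),
            ("cn_total", self.cn_total, (n, S)),
            ("cn_major", self.cn_major, (n, S)),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.alt > self.depth):
            raise ValueError("alt exceeds depth in the count matrix")
        if np.any((self.purity <= 0) | (self.purity > 1)):
            raise ValueError("purity must lie in (0, 1]")
        if self.missing is None:
            self.missing = np.zeros((n, S), dtype=bool)

    @property
    def n_mutations(self) -> int:
        return len(self.keys)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class CloneModel:
    """Fitted clone set for one tumour.

    Clones are indexed 0..K-1 in order of decreasing mean prevalence
    (clone 0 is the founder candidate); reported names are C1..CK.
    """

    K: int
    samples: list[str]
    prevalence: np.ndarray  # (K, S) CCF centroids in [0, 1]
    assignment: dict[MutationKey, int]
    clone_fraction: np.ndarray  # (K,) fractions of the tumour's mutations
    tree: dict[int, int | None] | None = None
    unassigned: set[MutationKey] = field(default_factory=set)
    original_fraction: np.ndarray | None = None
    log_likelihood: float = float("nan")
    bic: float = float("nan")
    flagged_forest: bool = False

    def clone_name(self, clone_id: int) -> str:
        return f"C{clone_id + 1}"


# ---------------------------------------------------------------------------
# Count-matrix assembly


def build_count_matrix(
    records: Iterable[MutationRecord],
    pileup_table: pd.DataFrame | None = None,
    purity: Mapping[str, float] | None = None,
    default_depth: int = 0,
) -> CountMatrix:
    """Collate per-sample read counts over the union of a tumour's calls.

    Cells covered by a call take the record's counts; uncalled cells are
    filled from ``pileup_table`` (columns chrom, pos, ref_allele,
    alt_allele, sample_id, alt_count, depth); cells absent from the pileup
    default to alt 0 / depth ``default_depth`` and are flagged missing.
    Copy-number annotations default to diploid (2 total / 1 major) when a
    record does not carry them.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    tumours = {r.tumour_id for r in records}
    if len(tumours) > 1:
        raise ValueError(f"records span multiple tumours: {sorted(tumours)}")

    by_pos: dict[tuple[str, int], MutationKey] = {}
    for r in records:
        prev = by_pos.get((r.chrom, r.pos))
        if prev is not None and prev != r.key:
            raise ValueError(
                f"inconsistent ref/alt at {r.chrom}:{r.pos}: {prev} vs {r.key}"
            )
        by_pos[(r.chrom, r.pos)] = r.key

    keys = sorted({r.key for r in records})
    samples = sorted({r.sample_id for r in records})
    key_idx = {k: i for i, k in enumerate(keys)}
    samp_idx = {s: j for j, s in enumerate(samples)}
    n, S = len(keys), len(samples)

    alt = np.zeros((n, S), dtype=int)
    depth = np.full((n, S), default_depth, dtype=int)
    cn_total = np.full((n, S), 2, dtype=int)
    cn_major = np.ones((n, S), dtype=int)
    filled = np.zeros((n, S), dtype=bool)

    if pileup_table is not None:
        for row in pileup_table.itertuples(index=False):
            key = MutationKey(
                str(row.chrom), int(row.pos), str(row.ref_allele), str(row.alt_allele)
            )
            if key in key_idx and str(row.sample_id) in samp_idx:
                i, j = key_idx[key], samp_idx[str(row.sample_id)]
                alt[i, j] = int(row.alt_count)
                depth[i, j] = int(row.depth)
                filled[i, j] = True

    for r in records:  # called cells override the pileup
        i, j = key_idx[r.key], samp_idx[r.sample_id]
        alt[i, j] = r.alt_count
        depth[i, j] = r.depth
        filled[i, j] = True
        if r.cn_total is not None:
            cn_total[i, :] = r.cn_total
        if r.cn_major is not None:
            cn_major[i, :] = r.cn_major

    missing = ~filled
    if missing.any():
        logger.info(
            "build_count_matrix: %d of %d cells missing from calls and pileup",
            int(missing.sum()),
            n * S,
        )
    if purity is None:
        purity_arr = np.ones(S)
    else:
        purity_arr = np.array([purity[s] for s in samples], dtype=float)
    return CountMatrix(
        keys=keys,
        samples=samples,
        alt=alt,
        depth=depth,
        purity=purity_arr,
        cn_total=cn_total,
        cn_major=cn_major,
        missing=missing,
    )


# ---------------------------------------------------------------------------
# CCF estimation


def ccf(
    alt: int | np.ndarray,
    depth: int | np.ndarray,
    purity: float | np.ndarray,
    cn_total: int | np.ndarray = 2,
    cn_major: int | np.ndarray = 1,
) -> np.ndarray:
    """Multiplicity-based cancer-cell-fraction point estimate.

    ``vaf * (purity*cn_total + (1-purity)*2) / purity`` gives the expected
    mutation copies per cancer cell; the integer multiplicity is its
    nearest integer clamped to [1, cn_major], and the CCF is the ratio of
    the two, clamped to [0, 1]. Cells with zero depth return NaN.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    denom = purity * np.asarray(cn_total, float) + (1.0 - purity) * 2.0
    copies = vaf * denom / purity
    m = np.clip(np.round(copies), 1, np.maximum(np.asarray(cn_major, float), 1))
    out = np.clip(copies / m, 0.0, 1.0)
    return np.where(depth > 0, out, np.nan)


def _vaf_factor(matrix: CountMatrix) -> np.ndarray:
    """Per-cell map q from CCF to expected VAF: vaf = q * ccf."""
    pur = matrix.purity[None, :]
    denom = pur * matrix.cn_total + (1.0 - pur) * 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(matrix.depth > 0, matrix.alt / np.maximum(matrix.depth, 1), 0.0)
    copies = vaf * denom / pur
    m = np.clip(np.round(copies), 1, np.maximum(matrix.cn_major, 1))
    return pur * m / denom


def observed_ccf(matrix: CountMatrix) -> np.ndarray:
    """(n, S) matrix of per-cell CCF point estimates (NaN at zero depth)."""
    return ccf(
        matrix.alt,
        matrix.depth,
        matrix.purity[None, :],
        matrix.cn_total,
        matrix.cn_major,
    )


# ---------------------------------------------------------------------------
# Binomial-mixture EM


def _log_binom_coeff(alt: np.ndarray, depth: np.ndarray) -> np.ndarray:
    return gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)


def _component_loglik(
    alt: np.ndarray, depth: np.ndarray, q: np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    """(n, K) binomial log-likelihood of each mutation under each clone.

    The success probability factorises as p = q_i * c_k, so the alt-read
    term splits into a per-mutation constant plus ``alt @ log(c).T``; only
    the reference-read term needs the full (n, K, S) tensor.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        aq = np.where(alt > 0, alt * np.log(np.clip(q, _EPS, None)), 0.0).sum(axis=1)
    term_alt = alt @ np.log(np.clip(centroids, 1e-12, None)).T  # (n, K)
    log_ref = np.log1p(-np.clip(q[:, None, :] * centroids[None, :, :], None, 1 - _EPS))
    term_ref = np.einsum("is,iks->ik", depth - alt, log_ref)
    return term_alt + term_ref + aq[:, None]


def _mstep_centroids(
    resp: np.ndarray,
    alt: np.ndarray,
    depth: np.ndarray,
    q: np.ndarray,
    c: np.ndarray,
    newton_iters: int = 8,
) -> np.ndarray:
    """Weighted binomial MLE of every clone/sample CCF centroid.

    The weighted log-likelihood is concave in each centroid, so clamped
    Newton from the ratio estimator converges to the global maximum; all
    (clone, sample) cells are updated simultaneously. ``newton_iters=0``
    returns the ratio estimator itself (the exact MLE in the small-VAF
    limit), used for cheap exploratory bursts.
    """
    wa = resp.T @ alt  # (K, S)
    wdq = resp.T @ (depth * q)
    da_q = (depth - alt) * q  # (n, S)
    da_q2 = da_q * q
    c = np.clip(np.where(wdq > 0, wa / np.maximum(wdq, _EPS), 0.0), 1e-6, 1.0)
    active = wa > 0
    for _ in range(newton_iters):
        inv = 1.0 / np.clip(1.0 - q[:, None, :] * c[None, :, :], _EPS, None)  # (n,K,S)
        grad = wa / c - np.einsum("ik,is,iks->ks", resp, da_q, inv)
        hess = -wa / c**2 - np.einsum("ik,is,iks->ks", resp, da_q2, inv * inv)
        step = np.where(active, grad / np.minimum(hess, -_EPS), 0.0)
        c_new = np.clip(c - step, 1e-6, 1.0)
        if np.max(np.abs(c_new - c)) < 1e-7:
            c = c_new
            break
        c = c_new
    return np.where(active, c, 1e-6)


def _run_em(
    alt: np.ndarray,
    depth: np.ndarray,
    q: np.ndarray,
    centroids: np.ndarray,
    weights: np.ndarray,
    max_iter: int,
    tol: float = 1e-6,
    trace: list[float] | None = None,
    mstep_newton: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """EM iterations; returns (centroids, weights, responsibilities, loglik)."""
    K = centroids.shape[0]
    const = _log_binom_coeff(alt, depth).sum()
    prev_ll = -np.inf
    resp = np.full((alt.shape[0], K), 1.0 / K)
    ll = prev_ll
    for _ in range(max_iter):
        comp = _component_loglik(alt, depth, q, centroids)  # (n, K)
        joint = comp + np.log(np.clip(weights, _EPS, None))[None, :]
        mx = joint.max(axis=1)
        ez = np.exp(joint - mx[:, None])
        ssum = ez.sum(axis=1)
        norm = mx + np.log(ssum)
        ll = float(norm.sum() + const)
        if trace is not None:
            trace.append(ll)
        resp = ez / ssum[:, None]
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
        weights = resp.mean(axis=0)
        centroids = _mstep_centroids(resp, alt, depth, q, centroids, mstep_newton)
    return centroids, weights, resp, ll


def _fit_k(
    matrix: CountMatrix,
    q: np.ndarray,
    ccf_obs: np.ndarray,
    K: int,
    restarts: int,
    seed: int,
    short_iter: int = 10,
    subsample: int = 800,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Best of ``restarts`` seeded initialisations for a fixed K.

    Restart r uses seed ``seed + r`` for reproducibility. To keep large
    tumours tractable the short exploratory bursts run on a seeded
    subsample of mutations; the top candidates are then polished on the
    full data and the best polished fit is run to convergence.
    """
    n = matrix.n_mutations
    alt, depth = matrix.alt, matrix.depth
    sub_rng = np.random.default_rng(seed)
    if n > subsample:
        sub = np.sort(sub_rng.choice(n, size=subsample, replace=False))
    else:
        sub = np.arange(n)
    alt_s, depth_s, q_s = alt[sub], depth[sub], q[sub]

    candidates = []
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        idx = rng.choice(n, size=K, replace=K > n)
        init = np.nan_to_num(ccf_obs[idx], nan=0.5)
        init = np.clip(init + rng.normal(0, 0.03, init.shape), 1e-3, 1.0)
        weights = np.full(K, 1.0 / K)
        cent, w, _, ll = _run_em(
            alt_s, depth_s, q_s, init.copy(), weights, short_iter, mstep_newton=0
        )
        candidates.append((ll, cent, w))
    candidates.sort(key=lambda t: -t[0])
    best = None
    for ll_s, cent, w in candidates[:2]:
        res = _run_em(alt, depth, q, cent.copy(), w.copy(), 300, tol=1e-4)
        if best is None or res[3] > best[3]:
            best = res
    return best


def cluster_mutations(
    matrix: CountMatrix,
    max_clusters: int = 40,
    restarts: int = 100,
    seed: int = 0,
    bic_patience: int = 3,
) -> CloneModel:
    """Cluster a tumour's mutations into clones by binomial-mixture EM.

    Fits K = 1..``max_clusters`` (stopping early once BIC has worsened for
    ``bic_patience`` consecutive sizes), keeping the best of ``restarts``
    seeded initialisations per K. Deterministic given ``seed``. Clones are
    relabelled in order of decreasing mean prevalence.
    """
    if matrix.n_mutations == 0:
        raise ValueError("empty count matrix")
    q = _vaf_factor(matrix)
    ccf_obs = observed_ccf(matrix)
    n = matrix.n_mutations
    n_obs = int((matrix.depth > 0).sum())

    best_model = None
    best_bic = np.inf
    worse_streak = 0
    for K in range(1, min(max_clusters, n) + 1):
        cent, w, resp, ll = _fit_k(matrix, q, ccf_obs, K, restarts, seed + 1000 * K)
        n_params = K * matrix.n_samples + (K - 1)
        bic = -2.0 * ll + n_params * np.log(max(n_obs, 1))
        if bic < best_bic - 1e-9:
            best_bic = bic
            best_model = (K, cent, w, resp, ll, bic)
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= bic_patience:
                break

    K, cent, w, resp, ll, bic = best_model
    hard = resp.argmax(axis=1)
    # drop clones that attract no mutations at all, then order by prevalence
    occupied = np.array([np.any(hard == k) for k in range(K)])
    cent, w = cent[occupied], w[occupied]
    remap = np.cumsum(occupied) - 1
    hard = remap[hard]
    K = int(occupied.sum())
    order = np.argsort(-cent.mean(axis=1), kind="stable")
    rank = np.empty(K, dtype=int)
    rank[order] = np.arange(K)
    cent = cent[order]
    hard = rank[hard]
    counts = np.bincount(hard, minlength=K)
    assignment = {key: int(hard[i]) for i, key in enumerate(matrix.keys)}
    return CloneModel(
        K=K,
        samples=list(matrix.samples),
        prevalence=np.clip(cent, 0.0, 1.0),
        assignment=assignment,
        clone_fraction=counts / counts.sum(),
        log_likelihood=ll,
        bic=float(bic),
    )


# ---------------------------------------------------------------------------
# Post-processing


def prune_clones(model: CloneModel, min_fraction: float = 0.01) -> CloneModel:
    """Remove clones holding fewer than ``min_fraction`` of the mutations.

    Pruned clones' mutations are flagged unassigned. Reported fractions
    are renormalised over the survivors; the pre-prune fractions are kept
    in ``original_fraction``.
    """
    keep = model.clone_fraction >= min_fraction
    if keep.all():
        return replace(model, original_fraction=model.clone_fraction.copy())
    keep_ids = np.flatnonzero(keep)
    remap = {int(old): new for new, old in enumerate(keep_ids)}
    assignment = {}
    unassigned = set(model.unassigned)
    for key, cid in model.assignment.items():
        if cid in remap:
            assignment[key] = remap[cid]
        else:
            unassigned.add(key)
    surviving = model.clone_fraction[keep]
    return CloneModel(
        K=int(keep.sum()),
        samples=model.samples,
        prevalence=model.prevalence[keep],
        assignment=assignment,
        clone_fraction=surviving / surviving.sum(),
        tree=None,
        unassigned=unassigned,
        original_fraction=model.clone_fraction.copy(),
        log_likelihood=model.log_likelihood,
        bic=model.bic,
    )


def clone_mutations(model: CloneModel) -> dict[int, set[MutationKey]]:
    """Partition of assigned mutation keys by clone id.

    These per-clone mutation sets are disjoint by construction, so
    per-clone signature fits never share mutations between clones.
    """
    out: dict[int, set[MutationKey]] = {k: set() for k in range(model.K)}
    for key, cid in model.assignment.items():
        out[cid].add(key)
    return out


def timepoint_prevalence(
    model: CloneModel, sample_timepoints: Mapping[str, str]
) -> pd.DataFrame:
    """Average clone prevalences within each timepoint.

    Returns a fishplot-ready table with one row per clone and one column
    per timepoint present among the samples.
    """
    tps = sorted({sample_timepoints[s] for s in model.samples})
    data = {}
    for tp in tps:
        cols = [j for j, s in enumerate(model.samples) if sample_timepoints[s] == tp]
        data[tp] = model.prevalence[:, cols].mean(axis=1)
    return pd.DataFrame(
        data, index=[model.clone_name(k) for k in range(model.K)]
    ).rename_axis("clone")


def infer_tree(model: CloneModel, tol: float = 0.05) -> dict[int, int | None]:
    """Greedy clone-tree construction under containment and sum rules.

    Clones are visited in decreasing mean prevalence; each is attached to
    the already-placed candidate parent with the smallest mean prevalence
    such that (a) the child's prevalence does not exceed the parent's in
    any sample by more than ``tol`` and (b) the parent's children sum to
    at most the parent plus ``tol`` in every sample. Unattachable clones
    fall back to the founder. When no clone spans all samples at maximal
    prevalence the result is flagged as a forest on the model.
    """
    K, prev = model.K, model.prevalence
    order = sorted(range(K), key=lambda k: (-prev[k].mean(), k))
    parent: dict[int, int | None] = {}
    children: dict[int, list[int]] = {k: [] for k in range(K)}
    root = order[0]
    parent[root] = None
    max_prev = prev.max(axis=0)
    model.flagged_forest = bool(np.any(prev[root] < max_prev - tol))
    for k in order[1:]:
        candidates = []
        for p in parent:  # already placed
            if np.any(prev[k] > prev[p] + tol):
                continue
            child_sum = prev[children[p]].sum(axis=0) if children[p] else 0.0
            if np.any(child_sum + prev[k] > prev[p] + tol):
                continue
            candidates.append(p)
        if candidates:
            chosen = min(candidates, key=lambda p: (prev[p].mean(), p))
        else:
            chosen = root
        parent[k] = chosen
        children[chosen].append(k)
    model.tree = parent
    return parent


def clone_table(model: CloneModel) -> pd.DataFrame:
    """Long-format clone summary: one row per clone per sample."""
    rows = []
    tree = model.tree or {}
    for k in range(model.K):
        for j, s in enumerate(model.samples):
            rows.append(
                {
                    "clone": model.clone_name(k),
                    "sample_id": s,
                    "prevalence": float(model.prevalence[k, j]),
                    "fraction": float(model.clone_fraction[k]),
                    "parent": (
                        model.clone_name(tree[k]) if tree.get(k) is not None else ""
                    ),
                }
            )
    return pd.DataFrame(rows)
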