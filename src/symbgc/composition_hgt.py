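"""Compositional evidence for horizontal acquisition.

Canonical (strand-collapsed) 5-mer frequency vectors, a centroid-distance
outlier score with an empirical p value, per-gene GC%, and one-way ANOVA
followed by Tukey HSD over gene categories. The 2-D embedding is retained
for plotting only; the quantitative statistic is the centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .sequence_io import Contig, GeneRecord, InputError

DEFAULT_K = 5
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_CANON_CACHE: dict[int, tuple[np.ndarray, int]] = {}


def _canonical_maps(k: int) -> tuple[np.ndarray, int]:
    """Map each k-mer integer code to the rank of its canonical form.

    Canonical = lexicographic min of the k-mer and its reverse complement;
    ranks follow lexicographic order of the canonical k-mers.
    """
    if k in _CANON_CACHE:
        return _CANON_CACHE[k]
    n = 4**k
    codes = np.arange(n)
    rc = np.zeros(n, dtype=np.int64)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    canon = np.minimum(codes, rc)
    uniq = np.unique(canon)
    rank = np.full(n, -1, dtype=np.int64)
    rank[uniq] = np.arange(uniq.size)
    mapping = rank[canon]
    _CANON_CACHE[k] = (mapping, uniq.size)
    return mapping, uniq.size


def n_canonical_kmers(k: int = DEFAULT_K) -> int:
    return _canonical_maps(k)[1]


@dataclass
class KmerProfile:
    """Normalized canonical k-mer frequencies for one sequence."""

    id: str
    k: int
    freq: np.ndarray  # length n_canonical_kmers(k); sums to 1 if any window counted
    n_windows: int


def kmer_profile(seq: str | Contig, k: int = DEFAULT_K, id: str | None = None) -> KmerProfile:
    """Count canonical k-mers with a step-1 sliding window.

    Windows containing N (or any non-ACGT character) are excluded. Raises
    for sequences shorter than k.
    """
    if isinstance(seq, Contig):
        id = id or seq.id
        seq = seq.seq
    if len(seq) < k:
        raise InputError(f"sequence shorter than k={k}")
    mapping, dim = _canonical_maps(k)
    codes = _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    n_win = len(seq) - k + 1
    window_codes = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        col = codes[j : j + n_win]
        valid &= col >= 0
        window_codes = window_codes * 4 + np.where(col >= 0, col, 0)
    ranks = mapping[window_codes[valid]]
    counts = np.bincount(ranks, minlength=dim).astype(float)
    total = counts.sum()
    freq = counts / total if total > 0 else counts
    return KmerProfile(id=id or "", k=k, freq=freq, n_windows=int(total))


@dataclass
class OutlierResult:
    """Centroid-distance outlier scores with an empirical p per profile."""

    table: pd.DataFrame  # columns: id, is_focus, distance, score, empirical_p
    embedding: pd.DataFrame  # columns: id, x, y

    def score(self, profile_id: str) -> float:
        return float(self.table.set_index("id").loc[profile_id, "score"])

    def empirical_p(self, profile_id: str) -> float:
        return float(self.table.set_index("id").loc[profile_id, "empirical_p"])


def composition_outlier_scores(
    profiles: Sequence[KmerProfile],
    focus_ids: Iterable[str],
    seed: int = 0,
    min_background: int = 10,
) -> OutlierResult:
    """Score each profile by distance from the background centroid.

    Background = all non-focus profiles. The score is the Euclidean
    distance standardized by the background distance distribution (0 when
    all background distances are identical); the empirical p is the
    fraction of background profiles at least as distant.
    """
    focus = set(focus_ids)
    ids = [p.id for p in profiles]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate profile ids")
    mat = np.vstack([p.freq for p in profiles])
    is_focus = np.array([i in focus for i in ids])
    n_bg = int((~is_focus).sum())
    if n_bg < min_background:
        raise InputError(
            f"need >= {min_background} background profiles, got {n_bg} "
            "(centroid unstable)"
        )
    centroid = mat[~is_focus].mean(axis=0)
    dist = np.linalg.norm(mat - centroid, axis=1)
    bg_dist = dist[~is_focus]
    mu, sigma = bg_dist.mean(), bg_dist.std(ddof=0)
    score = (dist - mu) / sigma if sigma > 0 else np.zeros_like(dist)
    emp_p = np.array([(bg_dist >= d).mean() for d in dist])
    table = pd.DataFrame(
        {
            "id": ids,
            "is_focus": is_focus,
            "distance": dist,
            "score": score,
            "empirical_p": emp_p,
        }
    )
    embedding = _embed_2d(mat, ids, seed)
    return OutlierResult(table=table, embedding=embedding)


def _embed_2d(mat: np.ndarray, ids: list[str], seed: int) -> pd.DataFrame:
    """Seeded 2-D embedding for plotting (t-SNE; PCA fallback for tiny n)."""
    n = mat.shape[0]
    if np.allclose(mat, mat[0]):  # degenerate: identical profiles crash BH-tSNE
        return pd.DataFrame({"id": ids, "x": np.zeros(n), "y": np.zeros(n)})
    if n >= 8:
        from sklearn.manifold import TSNE

        perplexity = max(2.0, min(30.0, (n - 1) / 3))
        xy = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
        ).fit_transform(mat)
    else:
        from sklearn.decomposition import PCA

        xy = PCA(n_components=min(2, n), random_state=seed).fit_transform(mat)
        if xy.shape[1] < 2:
            xy = np.column_stack([xy, np.zeros(n)])
    return pd.DataFrame({"id": ids, "x": xy[:, 0], "y": xy[:, 1]})


# ---------------------------------------------------------------------------
# per-gene GC and category contrasts
# ---------------------------------------------------------------------------


@dataclass
class GcObservation:
    gene_id: str
    category: str
    gc_percent: float


def gc_percent(seq: str) -> float:
    """GC% over A/C/G/T only; all-N (or empty) sequences are an error."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise InputError("sequence has no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def gene_gc(genes: Iterable[GeneRecord]) -> list[GcObservation]:
    return [GcObservation(g.gene_id, g.category, gc_percent(g.cds_seq)) for g in genes]


@dataclass
class CategoryContrast:
    """One-way ANOVA plus Tukey HSD over category pairs."""

    response: str
    anova_F: float
    anova_p: float
    tukey: pd.DataFrame  # columns: category_a, category_b, mean_diff, p_adj, different

    def pair_p(self, a: str, b: str) -> float:
        key = tuple(sorted((a, b)))
        sub = self.tukey.set_index(["category_a", "category_b"])
        return float(sub.loc[key, "p_adj"])

    def is_different(self, a: str, b: str) -> bool:
        key = tuple(sorted((a, b)))
        sub = self.tukey.set_index(["category_a", "category_b"])
        return bool(sub.loc[key, "different"])


def category_anova_tukey(
    observations: Sequence[GcObservation] | Sequence,
    response: str = "gc",
    alpha: float = 0.05,
) -> CategoryContrast:
    """One-way fixed-effects ANOVA and Tukey HSD over gene categories.

    Uses the Tukey-Kramer denominator (pooled within-group variance with
    unbalanced group sizes). Requires >= 2 categories with >= 2
    observations each.
    """
    if response == "gc":
        values = np.array([o.gc_percent for o in observations], dtype=float)
    elif response == "cai":
        values = np.array([o.cai for o in observations], dtype=float)
    else:
        raise InputError(f"unknown response {response!r}")
    cats = np.array([o.category for o in observations])
    unique = sorted(set(cats))
    if len(unique) < 2:
        raise InputError("need >= 2 categories")
    for cat in unique:
        if (cats == cat).sum() < 2:
            raise InputError(f"category {cat!r} has < 2 observations")
    groups = [values[cats == cat] for cat in unique]
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        # all observations identical: F = 0, nothing distinguishable
        rows = [
            {"category_a": a, "category_b": b, "mean_diff": 0.0, "p_adj": 1.0,
             "different": False}
            for i, a in enumerate(unique)
            for b in unique[i + 1 :]
        ]
        return CategoryContrast(response, 0.0, 1.0, pd.DataFrame(rows))
    anova = stats.f_oneway(*groups)
    hsd = pairwise_tukeyhsd(values, cats, alpha=alpha)
    rows = []
    group_pairs = [
        (str(a), str(b))
        for i, a in enumerate(hsd.groupsunique)
        for b in hsd.groupsunique[i + 1 :]
    ]
    for (a, b), mean_diff, p_adj in zip(group_pairs, hsd.meandiffs, hsd.pvalues):
        a, b = sorted((a, b))
        p_adj = float(p_adj)
        rows.append(
            {
                "category_a": a,
                "category_b": b,
                "mean_diff": float(mean_diff),
                "p_adj": p_adj,
                "different": p_adj < alpha,
            }
        )
    tukey = pd.DataFrame(rows).sort_values(["category_a", "category_b"]).reset_index(
        drop=True
    )
    return CategoryContrast(
        response=response,
        anova_F=float(anova.statistic),
        anova_p=float(anova.pvalue),
        tukey=tukey,
    )
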