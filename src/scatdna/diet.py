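"""Diet quantification and niche-overlap statistics.

Per-scat prey taxa are mapped to diet categories; the weighted percent of
occurrence (wPOO) gives each scat equal weight and each item within a scat
weight 1/(items in scat), so the resulting profile is a probability vector
over categories. Overlap between units is measured with Pianka's index and
Bray-Curtis dissimilarity; differences between individuals are tested with
pairwise PERMANOVA (pseudo-F on a Bray-Curtis distance matrix over per-scat
binary category profiles, significance by label permutation) with
Benjamini-Hochberg correction across all pairs.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .taxonomy import ScatClassification


@dataclass(frozen=True)
class DietProfile:
    """wPOO probability vector over prey categories for one aggregation unit."""

    unit_id: str
    n_scats: int
    wpoo: Mapping[str, float]

    def vector(self, categories: Sequence[str]) -> np.ndarray:
        return np.array([self.wpoo.get(c, 0.0) for c in categories])


@dataclass(frozen=True)
class OverlapResult:
    """Pairwise overlap / dissimilarity statistics for two units."""

    unit_i: str
    unit_j: str
    pianka: float
    bray_curtis: float
    pseudo_f: float
    p_raw: float
    p_adjusted: float


def scat_items(
    classification: ScatClassification,
    category_map: Mapping[str, str],
    config: RunConfig | None = None,
) -> frozenset[str]:
    """Map one diet scat's prey taxa to its set of diet items.

    With ``items_mode='categories'`` (default) a category occurring via two
    prey species counts once per scat; with ``'species'`` each species is an
    item (used only for sensitivity analyses; the category-set semantics is
    the primary definition).
    """
    config = config or RunConfig()
    if classification.status != "wolf_diet":
        raise ValueError(
            f"scat {classification.sample_id}: status {classification.status!r}, "
            "only wolf_diet scats enter the diet analysis"
        )
    unmapped = [t.taxon_name for t in classification.prey_taxa
                if t.taxon_name not in category_map]
    if unmapped:
        raise KeyError(
            f"scat {classification.sample_id}: taxa missing from category map: "
            f"{sorted(unmapped)}"
        )
    if config.items_mode == "species":
        return frozenset(t.taxon_name for t in classification.prey_taxa)
    return frozenset(category_map[t.taxon_name] for t in classification.prey_taxa)


def wpoo(item_sets: Sequence[frozenset[str]], unit_id: str = "all") -> DietProfile:
    """Weighted percent of occurrence over a set of scats.

    wPOO_i = (1/S) * sum_s 1{i in s} / |s|; each scat contributes equally and
    splits its weight over its items, so the vector sums to one.
    """
    if not item_sets:
        raise ValueError(f"unit {unit_id!r}: no scats")
    if any(not s for s in item_sets):
        raise ValueError(f"unit {unit_id!r}: a scat has an empty item set")
    acc: dict[str, float] = {}
    for s in item_sets:
        share = 1.0 / len(s)
        for item in s:
            acc[item] = acc.get(item, 0.0) + share
    n = len(item_sets)
    return DietProfile(unit_id, n, {k: v / n for k, v in sorted(acc.items())})


def individual_profiles(
    scat_item_sets: Mapping[str, frozenset[str]],
    assignments: Mapping[str, str],
    config: RunConfig | None = None,
) -> tuple[list[DietProfile], pd.DataFrame]:
    """Per-individual wPOO profiles, restricted to adequately sampled wolves.

    Individuals with fewer than ``config.min_scats`` diet scats are not
    profiled; they are returned in an exclusion table (individual, n_scats).
    """
    config = config or RunConfig()
    by_individual: dict[str, list[frozenset[str]]] = {}
    for scat_id, items in scat_item_sets.items():
        ind = assignments.get(scat_id)
        if ind is None:
            continue
        by_individual.setdefault(ind, []).append(items)
    profiles, excluded = [], []
    for ind in sorted(by_individual):
        sets = by_individual[ind]
        if len(sets) >= config.min_scats:
            profiles.append(wpoo(sets, unit_id=ind))
        else:
            excluded.append({"individual_id": ind, "n_scats": len(sets)})
    return profiles, pd.DataFrame(excluded, columns=["individual_id", "n_scats"])


def pianka(p: DietProfile | Sequence[float], q: DietProfile | Sequence[float]) -> float:
    """Pianka's niche overlap O = sum(p*q) / sqrt(sum(p^2) * sum(q^2)).

    0 means disjoint resource use, 1 identical; symmetric and invariant to
    common rescaling of either profile.
    """
    pv, qv = _pair_vectors(p, q)
    np2, nq2 = float(pv @ pv), float(qv @ qv)
    if np2 == 0.0 or nq2 == 0.0:
        raise ValueError("Pianka overlap undefined for a zero profile")
    return float(pv @ qv) / math.sqrt(np2 * nq2)


def bray_curtis(p: DietProfile | Sequence[float], q: DietProfile | Sequence[float]) -> float:
    """Bray-Curtis dissimilarity BC = sum|p-q| / sum(p+q) in [0, 1]."""
    pv, qv = _pair_vectors(p, q)
    if pv.sum() == 0.0 and qv.sum() == 0.0:
        raise ValueError("Bray-Curtis undefined for two zero profiles")
    return float(_scipy_braycurtis(pv, qv))


def _pair_vectors(p, q) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, DietProfile) and isinstance(q, DietProfile):
        cats = sorted(set(p.wpoo) | set(q.wpoo))
        return p.vector(cats), q.vector(cats)
    pv, qv = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError("profiles live on different category spaces")
    if (pv < 0).any() or (qv < 0).any():
        raise ValueError("profiles must be non-negative")
    return pv, qv


# -- PERMANOVA ---------------------------------------------------------------

def _pseudo_f_two_groups(d2: np.ndarray, mask_a: np.ndarray) -> float:
    """Pseudo-F for a 2-group split of a squared-distance matrix.

    SS_total = sum_{i<j} d2_ij / n; SS_within = sum over groups of the
    analogous within-group term; F = (SS_between/(g-1)) / (SS_within/(n-g)).
    """
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for mask in (mask_a, ~mask_a):
        sub = d2[np.ix_(mask, mask)]
        m = int(mask.sum())
        ss_within += sub[np.triu_indices(m, 1)].sum() / m
    ss_between = ss_total - ss_within
    g = 2
    denom = ss_within / (n - g)
    if denom == 0.0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / (g - 1)) / denom


def permanova_two_groups(
    distances: np.ndarray,
    labels: Sequence[str],
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """One 2-group PERMANOVA: observed pseudo-F and its permutation p-value.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"expected 2 groups, got {groups.size}")
    d2 = np.asarray(distances, dtype=float) ** 2
    mask = labels == groups[0]
    f_obs = _pseudo_f_two_groups(d2, mask)
    n = len(labels)
    n_a = int(mask.sum())
    count = 0
    for _ in range(n_permutations):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_a, replace=False)] = True
        if _pseudo_f_two_groups(d2, perm) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return f_obs, p


def scat_distance_matrix(
    item_sets: Sequence[frozenset[str]], categories: Sequence[str] | None = None
) -> np.ndarray:
    """Bray-Curtis distances between per-scat binary category profiles."""
    if categories is None:
        categories = sorted(set().union(*item_sets))
    profiles = np.array(
        [[1.0 if c in s else 0.0 for c in categories] for s in item_sets]
    )
    return squareform(pdist(profiles, metric="braycurtis"))


def pairwise_permanova(
    item_sets: Mapping[str, frozenset[str]],
    assignments: Mapping[str, str],
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pairwise PERMANOVA between individuals on per-scat category profiles.

    For every pair of individuals with at least two diet scats each, tests
    whether their scat-level diet composition differs; p-values are BH
    (false-discovery-rate) adjusted across all pairs in one family. Pairs
    with an undersized group are skipped (reported with NaN statistics).
    """
    config = config or RunConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    scat_ids = [s for s in item_sets if s in assignments]
    sets = [item_sets[s] for s in scat_ids]
    labels = np.array([assignments[s] for s in scat_ids])
    categories = sorted(set().union(*sets)) if sets else []
    dm = scat_distance_matrix(sets, categories) if sets else np.zeros((0, 0))
    counts = pd.Series(labels).value_counts()
    individuals = sorted(counts.index)
    rows = []
    for a, b in itertools.combinations(individuals, 2):
        if counts[a] < 2 or counts[b] < 2:
            rows.append({"unit_i": a, "unit_j": b, "pseudo_f": np.nan,
                         "p_raw": np.nan, "skipped": True})
            continue
        sel = np.flatnonzero((labels == a) | (labels == b))
        f_obs, p = permanova_two_groups(
            dm[np.ix_(sel, sel)], labels[sel], config.n_permutations, rng
        )
        rows.append({"unit_i": a, "unit_j": b, "pseudo_f": f_obs,
                     "p_raw": p, "skipped": False})
    df = pd.DataFrame(rows, columns=["unit_i", "unit_j", "pseudo_f", "p_raw", "skipped"])
    df["p_adjusted"] = np.nan
    tested = ~df["skipped"]
    if tested.any():
        df.loc[tested, "p_adjusted"] = multipletests(
            df.loc[tested, "p_raw"].to_numpy(), method="fdr_bh"
        )[1]
    return df


def overlap_summary(profiles: Sequence[DietProfile]) -> tuple[float, float | None]:
    """Mean and SD of pairwise Pianka overlap within one group.

    With exactly two profiles there is a single pair and the SD is reported
    as None (not available).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles for pairwise overlap")
    values = [pianka(p, q) for p, q in itertools.combinations(profiles, 2)]
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return mean, sd


def overlap_matrix(profiles: Sequence[DietProfile]) -> pd.DataFrame:
    """Symmetric Pianka overlap matrix over a set of unit profiles."""
    ids = [p.unit_id for p in profiles]
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for p, q in itertools.combinations(profiles, 2):
        o = pianka(p, q)
        mat.loc[p.unit_id, q.unit_id] = o
        mat.loc[q.unit_id, p.unit_id] = o
    return mat


def profiles_to_frame(profiles: Sequence[DietProfile]) -> pd.DataFrame:
    """Long-format wPOO table (unit_id, category, wpoo, n_scats)."""
    rows = [
        {"unit_id": p.unit_id, "category": c, "wpoo": v, "n_scats": p.n_scats}
        for p in profiles
        for c, v in p.wpoo.items()
    ]
    return pd.DataFrame(rows, columns=["unit_id", "category", "wpoo", "n_scats"])


def nmds_coordinates(
    profiles: Sequence[DietProfile], seed: int = 0
) -> pd.DataFrame:  # pragma: no cover - plotting convenience, not validated
    """2-D NMDS embedding of Bray-Curtis dissimilarities (plotting aid only)."""
    from sklearn.manifold import MDS

    cats = sorted(set().union(*(p.wpoo for p in profiles)))
    x = np.array([p.vector(cats) for p in profiles])
    d = squareform(pdist(x, metric="braycurtis"))
    mds = MDS(n_components=2, metric=False, dissimilarity="precomputed",
              random_state=seed, normalized_stress="auto")
    coords = mds.fit_transform(d)
    return pd.DataFrame(coords, index=[p.unit_id for p in profiles],
                        columns=["nmds1", "nmds2"])
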