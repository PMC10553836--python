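"""Bruvo genetic distances, principal coordinate analysis, distance AMOVA.

The Bruvo distance between two alleles is ``1 - 2**(-|da - db| / motif)``:
zero for identical fragment lengths and saturating towards 1 with the number
of repeat units separating them. Allele *sets* of equal size are compared by
the minimum, over all bijections, of the mean per-pair distance; this is an
assignment problem and is solved exactly. Dosage is unknown in polyploid
allelic phenotypes, so sets of unequal size are first brought to the larger
set's size, either by averaging over all multiset completions of the smaller
set from its own alleles (``mean_completion``) or by padding it with a
virtual allele at distance 1 to everything (``virtual_allele``).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotype_io import LocusPanel, SampleRecord

log = logging.getLogger(__name__)

STRATEGIES = ("mean_completion", "virtual_allele")


class StructureError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise StructureError("distance matrix shape does not match id list")
        if not np.allclose(d, d.T, atol=1e-12):
            raise StructureError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise StructureError("nonzero diagonal")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise StructureError("distances outside [0, 1]")
        self.values = d


@dataclass
class PCoAResult:
    ids: tuple[str, ...]
    coordinates: np.ndarray          # (n, n_axes)
    eigenvalues: np.ndarray          # positive eigenvalues, descending
    percent_variance: np.ndarray     # of the positive-eigenvalue total


@dataclass
class AMOVAResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    sigma2_among: float
    sigma2_within: float
    percent_among: float
    percent_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int | None


def bruvo_allele_distance(set_a: Sequence[int], set_b: Sequence[int],
                          motif_len: int) -> float:
    """Minimum over bijections of the mean per-allele-pair Bruvo distance.

    Both sets must have the same cardinality; complete unequal phenotypes
    first (see :func:`bruvo_sample_distance`).
    """
    a, b = tuple(set_a), tuple(set_b)
    if len(a) != len(b):
        raise StructureError(
            f"allele sets of unequal cardinality ({len(a)} vs {len(b)})")
    if not a:
        raise StructureError("empty allele set")
    if motif_len < 1:
        raise StructureError("motif length must be >= 1")
    cost = _pair_costs(a, b, motif_len)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() / len(a))


def _pair_costs(a: tuple[int, ...], b: tuple[int, ...], motif: int) -> np.ndarray:
    da = np.abs(np.subtract.outer(np.asarray(a, float), np.asarray(b, float))) / motif
    return 1.0 - 2.0 ** (-da)


def _completions(alleles: tuple[int, ...], size: int):
    """All multiset completions of a phenotype to `size` using its own alleles."""
    deficit = size - len(alleles)
    if deficit <= 0:
        yield alleles
        return
    for extra in itertools.combinations_with_replacement(alleles, deficit):
        yield alleles + extra


@lru_cache(maxsize=200_000)
def _locus_distance(a: tuple[int, ...], b: tuple[int, ...],
                    motif: int, strategy: str) -> float:
    size = max(len(a), len(b))
    if strategy == "virtual_allele":
        cost = np.ones((size, size))
        cost[: len(a), : len(b)] = _pair_costs(a, b, motif)
        rows, cols = linear_sum_assignment(cost)
        return float(cost[rows, cols].sum() / size)
    # mean_completion: the smaller phenotype is completed to the larger one's
    # size, averaging the exact-matching distance over all multiset
    # completions from its own alleles; equal-size phenotypes compare as-is,
    # so identical phenotypes are at distance zero.
    total, n_pairs = 0.0, 0
    for ca in _completions(a, size):
        for cb in _completions(b, size):
            total += bruvo_allele_distance(ca, cb, motif)
            n_pairs += 1
    return total / n_pairs


def bruvo_sample_distance(record_a: SampleRecord, record_b: SampleRecord,
                          panel: LocusPanel,
                          ploidy_pair: tuple[int, int] | None = None,
                          strategy: str = "mean_completion") -> float:
    """Mean per-locus Bruvo distance over loci non-missing in both samples.

    Per locus, the smaller phenotype is brought up to the larger one's size
    (so equal-size phenotypes, whatever the samples' ploidies, compare
    directly and identical phenotypes are at distance zero); ``ploidy_pair``
    is accepted for interface symmetry with the ploidy-aware callers but does
    not alter the per-locus comparison.
    """
    if strategy not in STRATEGIES:
        raise StructureError(f"unknown strategy {strategy!r}")
    total, shared = 0.0, 0
    for locus in panel.locus_ids:
        a = record_a.phenotype.get(locus)
        b = record_b.phenotype.get(locus)
        if a is None or b is None:
            continue
        motif = panel.motif(locus)
        if a <= b:   # canonical order for the symmetric cache
            total += _locus_distance(a, b, motif, strategy)
        else:
            total += _locus_distance(b, a, motif, strategy)
        shared += 1
    if shared == 0:
        raise StructureError(
            f"samples {record_a.sample_id} and {record_b.sample_id} share no "
            "non-missing locus")
    return total / shared


def one_mlg_per_species(records: Sequence[SampleRecord],
                        panel: LocusPanel) -> list[SampleRecord]:
    """Keep the first sample of each (species, phenotype) pair — the sampling
    unit used for ordination and AMOVA so clonal copies do not weight them."""
    seen: set[tuple] = set()
    kept = []
    for r in records:
        key = (r.species, r.mlg_key(panel.locus_ids))
        if key not in seen:
            seen.add(key)
            kept.append(r)
    return kept


def bruvo_distance_matrix(records: Sequence[SampleRecord], panel: LocusPanel,
                          strategy: str = "mean_completion",
                          ploidies: dict[str, int] | None = None) -> DistanceMatrix:
    if ploidies is None:
        from .clonality import estimate_ploidies
        ploidies = estimate_ploidies(records, panel)
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bruvo_sample_distance(
                records[i], records[j], panel,
                (ploidies[records[i].sample_id], ploidies[records[j].sample_id]),
                strategy)
    return DistanceMatrix(ids=tuple(r.sample_id for r in records), values=d)


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Classical scaling (principal coordinate analysis).

    Double-centers -D**2/2, eigendecomposes, and keeps the positive-eigenvalue
    axes. Percent variance is relative to the positive-eigenvalue sum. Axis
    signs are fixed so the largest-magnitude loading on each axis is positive.
    """
    n = len(dm.ids)
    if n < 2:
        raise StructureError("PCoA needs at least 2 samples")
    d2 = dm.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    keep = eigval > tol
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(eigval)
    for k in range(coords.shape[1]):
        i_max = int(np.argmax(np.abs(coords[:, k])))
        if coords[i_max, k] < 0:
            coords[:, k] = -coords[:, k]
    pct = 100.0 * eigval / eigval.sum() if eigval.size else eigval
    return PCoAResult(ids=dm.ids, coordinates=coords,
                      eigenvalues=eigval, percent_variance=pct)


def _amova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def _phi_from_ss(d2, labels) -> float:
    """Unclamped phi statistic used for permutation comparisons (negative
    among-group components are kept so the null distribution is continuous)."""
    n = d2.shape[0]
    groups, counts = np.unique(labels, return_counts=True)
    g = len(groups)
    ss_total, ss_within = _amova_ss(d2, labels)
    ss_among = ss_total - ss_within
    df_among, df_within = g - 1, n - g
    if df_within == 0:
        return float("nan")
    ms_among, ms_within = ss_among / df_among, ss_within / df_within
    n0 = (n - (counts ** 2).sum() / n) / df_among
    sigma_among = (ms_among - ms_within) / n0
    total = sigma_among + ms_within
    return sigma_among / total if total > 0 else 0.0


def amova(dm: DistanceMatrix, group_labels: Sequence[str], n_perm: int = 999,
          seed: int | None = None, squared: bool = True) -> AMOVAResult:
    """One-level distance-based AMOVA with a permutation test on phi_st.

    Sums of squares follow the standard squared-pairwise-distance identity
    (SS_total = sum_{i<j} d_ij^2 / n, within-group analogue per group);
    variance components use the average-group-size coefficient n0. The
    permutation p-value is (1 + #{perm phi >= observed}) / (n_perm + 1).
    ``squared=False`` feeds the raw distances in as already-squared.
    """
    labels = np.asarray(group_labels)
    if len(labels) != len(dm.ids):
        raise StructureError("label vector length mismatch")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise StructureError("AMOVA needs at least 2 groups")
    if n_perm < 1:
        raise StructureError("n_perm must be >= 1")
    n, g = len(labels), len(groups)
    d2 = dm.values ** 2 if squared else dm.values.copy()

    ss_total, ss_within = _amova_ss(d2, labels)
    ss_among = ss_total - ss_within
    df_among, df_within = g - 1, n - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within else float("nan")
    n0 = (n - (counts ** 2).sum() / n) / df_among
    sigma_among_raw = (ms_among - ms_within) / n0
    sigma_among = sigma_among_raw
    if sigma_among < 0:
        log.info("negative among-group variance component %.4g clamped to 0",
                 sigma_among)
        sigma_among = 0.0
    sigma_within = ms_within
    total = sigma_among + sigma_within
    phi = sigma_among / total if total > 0 else 0.0
    # permutations compare the unclamped statistic so the null is continuous
    raw_total = sigma_among_raw + ms_within
    phi_raw = sigma_among_raw / raw_total if raw_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _phi_from_ss(d2, perm) >= phi_raw - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return AMOVAResult(
        df_among=df_among, df_within=df_within,
        ss_among=ss_among, ss_within=ss_within,
        ms_among=ms_among, ms_within=ms_within,
        sigma2_among=sigma_among, sigma2_within=sigma_within,
        percent_among=100 * sigma_among / total if total > 0 else 0.0,
        percent_within=100 * sigma_within / total if total > 0 else 100.0,
        phi_st=phi, p_value=p, n_permutations=n_perm, seed=seed)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    import pandas as pd
    pd.DataFrame(dm.values, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    import pandas as pd
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(ids=tuple(str(c) for c in df.columns),
                          values=df.to_numpy(dtype=float))
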