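"""Disentangling admixed tetraploid progeny when a parent is unknown.

Markers that are monomorphic (nulliplex or quadruplex) in the shared
mother are uninformative for her and expose the paternal contribution:
pairwise genetic distances restricted to such markers, projected by
principal coordinates analysis (classical metric scaling), separate
progeny by father.  On top of the split this module rejects an incompatible
candidate father, reconstructs the unknown parent's marker dosages by
maximum likelihood, and tests the selfing hypothesis (segregation-type
consistency plus reduced offspring heterozygosity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .dosageio import DosageMatrix
from .segqc import (
    count_offspring_dosages,
    enumerate_segregation_patterns,
    expected_offspring_distribution,
    fit_segregation,
)

__all__ = [
    "DistanceMatrix",
    "PcoResult",
    "PopulationSplit",
    "SelfingEvidence",
    "select_monomorphic_markers",
    "genetic_distance",
    "pco",
    "split_population",
    "reject_parent",
    "reconstruct_parent",
    "selfing_test",
    "heterozygosity",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise genetic distances in [0, 1] with pair support."""

    ids: list[str]
    values: np.ndarray
    n_markers_used: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise ValueError("distance matrix must be square and symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("self-distances must be zero")


@dataclass
class PcoResult:
    """Principal-coordinate embedding with explained variance fractions."""

    ids: list[str]
    coordinates: np.ndarray  # individuals × axes
    explained_fraction: np.ndarray


@dataclass
class PopulationSplit:
    assignment: pd.Series  # individual -> subpopulation label
    silhouette: float
    axes_used: int
    k: int


@dataclass
class SelfingEvidence:
    sxn_to_sxs_consistency: float
    offspring_mean_heterozygosity: float
    parent_heterozygosity: float
    het_p_value: float
    verdict: str
    n_reference_sxn: int = 0


def select_monomorphic_markers(dm: DosageMatrix, parent_dosage: pd.Series) -> list[str]:
    """Markers where the named parent is monomorphic (dosage 0 or 4)."""
    sel = [
        m
        for m in dm.marker_ids
        if m in parent_dosage.index and parent_dosage[m] in (0, 4)
    ]
    if not sel:
        warnings.warn("no markers monomorphic in the given parent", stacklevel=2)
    return sel


def genetic_distance(dm: DosageMatrix, markers=None) -> DistanceMatrix:
    """Mean absolute dosage difference scaled to [0, 1] over shared markers.

    d(i, j) = mean over jointly non-missing markers of |dᵢ − dⱼ| / 4;
    pairs with no shared marker are imputed with the overall mean distance.
    """
    sub = dm if markers is None else dm.subset_markers(list(markers))
    if sub.n_markers < 1:
        raise ValueError("at least one marker is required")
    x = sub.calls.to_numpy(dtype=float).T  # individuals × markers
    valid = ~np.isnan(x)
    n_shared = (valid.astype(float) @ valid.T.astype(float)).astype(int)
    # sum |xi - xj| over shared markers, via expansion per dosage level
    n = x.shape[0]
    abs_sum = np.zeros((n, n))
    for level in range(5):
        ind = np.where(valid, (x == level).astype(float), 0.0)
        absdiff = np.abs(np.where(valid, x - level, 0.0))
        abs_sum += ind @ absdiff.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = abs_sum / n_shared / 4.0
    have = n_shared > 0
    if not have.all():
        off = have & ~np.eye(n, dtype=bool)
        fill = d[off].mean() if off.any() else 0.0
        d[~have] = fill
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(sub.sample_ids), d, n_shared)


def pco(distance: DistanceMatrix, n_axes: int = 2) -> PcoResult:
    """Classical metric scaling of a distance matrix.

    Double-centre −½·J·D²·J, eigendecompose, and scale eigenvectors by the
    square root of the positive eigenvalues; explained fractions are
    eigenvalues over the positive-eigenvalue total (0 for a degenerate
    all-zero matrix).
    """
    d = distance.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-10 if evals.max() > 0 else evals > np.inf
    total = evals[pos].sum()
    n_axes = min(n_axes, n)
    coords = np.zeros((n, n_axes))
    frac = np.zeros(n_axes)
    for k in range(n_axes):
        if k < pos.sum():
            coords[:, k] = evecs[:, k] * np.sqrt(evals[k])
            frac[k] = evals[k] / total
    return PcoResult(list(distance.ids), coords, frac)


def split_population(
    pco_result: PcoResult,
    max_k: int = 3,
    min_silhouette: float = 0.5,
    seed: int = 0,
    n_restarts: int = 50,
) -> PopulationSplit:
    """Silhouette-gated k-means on the first two principal coordinates.

    k ∈ {2, …, max_k} is chosen by the best silhouette; if that best score
    falls below ``min_silhouette`` a single population (k = 1) is reported.
    The default gate of 0.5 (the usual "reasonable structure" rule of
    thumb) is needed because k-means on a featureless cloud still scores
    ≈ 0.35; genuine father-structure scores well above 0.9 here.
    """
    x = pco_result.coordinates[:, : min(2, pco_result.coordinates.shape[1])]
    n = x.shape[0]
    if n < 4:
        raise ValueError("at least 4 individuals are required for a split")
    best_k, best_sil, best_labels = 1, -1.0, np.zeros(n, dtype=int)
    for k in range(2, max_k + 1):
        if k >= n:
            break
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(x)
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(x, labels))
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    if best_sil < min_silhouette:
        best_k, best_labels = 1, np.zeros(n, dtype=int)
    # deterministic label order: relabel clusters by first occurrence
    remap, next_id = {}, 0
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(best_labels):
        if lab not in remap:
            remap[lab] = next_id
            next_id += 1
        out[i] = remap[lab]
    assignment = pd.Series(
        [f"pop{c + 1}" for c in out], index=pco_result.ids, name="subpopulation"
    )
    return PopulationSplit(assignment, best_sil, x.shape[1], best_k)


# ---------------------------------------------------------------------------
# parentage
# ---------------------------------------------------------------------------


def _union_support(d_mother: int, d_father: int) -> np.ndarray:
    """Offspring dosage classes possible under any inheritance mode."""
    support = expected_offspring_distribution(d_mother, d_father, "polysomic") > 0
    from .segqc import _disomic_arrangements

    for ma in _disomic_arrangements(d_mother):
        for fa in _disomic_arrangements(d_father):
            support |= (
                expected_offspring_distribution(d_mother, d_father, "disomic", ma, fa)
                > 0
            )
    return support


def reject_parent(
    dm: DosageMatrix,
    mother_dosage: pd.Series,
    candidate_dosage: pd.Series,
    min_impossible_obs: int = 2,
    fit_alpha: float = 1e-3,
    reject_fraction: float = 0.05,
):
    """Test whether a candidate father can explain the progeny segregation.

    A marker is incompatible if any offspring dosage class with at least
    ``min_impossible_obs`` non-missing observations has zero probability
    under every inheritance mode for the scored parental dosages, or if the
    best goodness-of-fit p-value for those dosages falls below
    ``fit_alpha``.  The candidate is rejected when the incompatible-marker
    fraction exceeds ``reject_fraction``.

    Returns ``(rejected: bool, fraction: float, per_marker: DataFrame)``.
    """
    from .segqc import SegregationModel, _chi2_against, _disomic_arrangements

    records = []
    markers = [
        m
        for m in dm.marker_ids
        if m in mother_dosage.index and m in candidate_dosage.index
    ]
    for m in markers:
        counts = count_offspring_dosages(dm.calls.loc[m])
        if counts.sum() == 0:
            continue
        dmo = int(mother_dosage[m])
        dfa = int(candidate_dosage[m])
        support = _union_support(dmo, dfa)
        impossible = bool(np.any((counts >= min_impossible_obs) & ~support))
        best_p = 0.0
        models = [SegregationModel(dmo, dfa, "polysomic")] + [
            SegregationModel(dmo, dfa, "disomic", ma, fa)
            for ma in _disomic_arrangements(dmo)
            for fa in _disomic_arrangements(dfa)
        ]
        for model in models:
            # counts below the impossible-class tolerance are presumed
            # genotyping errors: drop them so the χ² route applies the
            # same ≥ min_impossible_obs rule as the class test
            probs = model.distribution
            tolerated = counts.copy()
            tolerated[(probs <= 0) & (counts < min_impossible_obs)] = 0
            _, p = _chi2_against(tolerated, probs)
            best_p = max(best_p, p)
        records.append(
            {
                "marker": m,
                "impossible_class": impossible,
                "best_p": best_p,
                "incompatible": impossible or best_p < fit_alpha,
            }
        )
    per_marker = pd.DataFrame(records).set_index("marker")
    fraction = float(per_marker["incompatible"].mean()) if len(per_marker) else 0.0
    return fraction > reject_fraction, fraction, per_marker


def reconstruct_parent(dm: DosageMatrix, mother_dosage: pd.Series) -> pd.DataFrame:
    """ML reconstruction of the unknown father's dosage per marker.

    For each marker the father dosage maximising the multinomial likelihood
    of the observed offspring counts under the polysomic model is reported,
    with ``confidence`` = log10 likelihood ratio of best to second-best
    (0 for ties, flagged ``ambiguous``; all-missing markers are
    ``undetermined``).
    """
    rows = []
    for m in dm.marker_ids:
        if m not in mother_dosage.index:
            continue
        counts = count_offspring_dosages(dm.calls.loc[m])
        n = counts.sum()
        dmo = int(mother_dosage[m])
        if n == 0:
            rows.append(
                {"marker": m, "father_dosage": -1, "confidence": np.nan,
                 "status": "undetermined"}
            )
            continue
        ll = np.full(5, -np.inf)
        for df_ in range(5):
            probs = expected_offspring_distribution(dmo, df_, "polysomic")
            if counts[probs <= 0].sum() > 0:
                continue
            with np.errstate(divide="ignore"):
                ll[df_] = float(np.sum(counts[probs > 0] * np.log(probs[probs > 0])))
        order = np.argsort(ll)[::-1]
        best, second = order[0], order[1]
        if not np.isfinite(ll[best]):
            rows.append(
                {"marker": m, "father_dosage": -1, "confidence": np.nan,
                 "status": "undetermined"}
            )
            continue
        gap = (ll[best] - ll[second]) / np.log(10.0) if np.isfinite(ll[second]) else np.inf
        status = "ambiguous" if gap == 0 else "ok"
        rows.append(
            {"marker": m, "father_dosage": int(best), "confidence": gap,
             "status": status}
        )
    return pd.DataFrame(rows).set_index("marker")


# ---------------------------------------------------------------------------
# selfing
# ---------------------------------------------------------------------------


def heterozygosity(dosages) -> float:
    """Fraction of non-missing dosage calls in the heterozygous classes
    {1, 2, 3}."""
    arr = np.asarray(dosages, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return np.nan
    return float(np.isin(arr, (1, 2, 3)).mean())


def selfing_test(
    dm: DosageMatrix,
    parent_dosage: pd.Series,
    reference_sxn_markers=None,
    consistency_threshold: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
) -> SelfingEvidence:
    """Test whether a population is consistent with selfing of the parent.

    (i) Of the markers segregating S×N from the parent in a reference
    (outcross) population, the fraction whose best-fitting pattern here is
    S×S; (ii) mean offspring heterozygosity versus the parent's, with a
    two-sided bootstrap over markers.  Verdict ``selfing-consistent``
    requires consistency ≥ threshold (when a reference is available) and
    significantly lower offspring heterozygosity.
    """
    patterns = enumerate_segregation_patterns()
    candidates = [models[0] for _, models in patterns]
    consistency, n_ref = np.nan, 0
    if reference_sxn_markers is not None:
        ref = [m for m in reference_sxn_markers if m in dm.marker_ids]
        n_ref = len(ref)
        if n_ref:
            # S×S is identified by the fitted distribution (1:2:1), not the
            # shorthand of one generating config: several parental configs
            # share a distribution and the fit cannot tell them apart
            sxs = np.round(expected_offspring_distribution(1, 1, "polysomic"), 12)
            hits = 0
            for m in ref:
                fit = fit_segregation(dm.calls.loc[m], candidates, m)
                if fit.best_model is not None and np.array_equal(
                    np.round(fit.best_model.distribution, 12), sxs
                ):
                    hits += 1
            consistency = hits / n_ref
    shared = [m for m in dm.marker_ids if m in parent_dosage.index]
    calls = dm.calls.loc[shared].to_numpy(dtype=float)
    # per-marker mean offspring heterozygosity and parent indicator
    het = np.isin(calls, (1, 2, 3)) & ~np.isnan(calls)
    valid = ~np.isnan(calls)
    with np.errstate(invalid="ignore"):
        marker_het = het.sum(axis=1) / valid.sum(axis=1)
    parent_het = np.isin(parent_dosage[shared].to_numpy(), (1, 2, 3)).astype(float)
    keep = ~np.isnan(marker_het)
    marker_het, parent_het = marker_het[keep], parent_het[keep]
    off_het = float(marker_het.mean())
    par_het = float(parent_het.mean())
    rng = np.random.default_rng(seed)
    nm = marker_het.size
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, nm, size=nm)
        diffs[b] = marker_het[idx].mean() - parent_het[idx].mean()
    p = 2.0 * min((diffs >= 0).mean(), (diffs <= 0).mean())
    p = float(min(p, 1.0))
    het_ok = off_het < par_het and p < 0.05
    cons_ok = np.isnan(consistency) or consistency >= consistency_threshold
    verdict = "selfing-consistent" if (het_ok and cons_ok) else "not-selfing"
    return SelfingEvidence(consistency, off_het, par_het, p, verdict, n_ref)
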