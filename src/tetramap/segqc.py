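"""Marker quality control against expected tetraploid segregation patterns.

An F1 marker in a tetraploid cross is characterised by the parental dosage
pair (d_mother, d_father) and the inheritance mode.  Under polysomic
(tetrasomic) inheritance each parent transmits a hypergeometric gamete
dosage — 2 of 4 homologs drawn at random — and the offspring dosage
distribution is the convolution of the two gamete laws.  Under disomic
inheritance (strict preferential pairing) the allele copies sit on two
fixed subgenome pairs and each pair segregates like a diploid locus.

This module enumerates those expected distributions, χ²-tests observed
offspring dosage counts against them, merges the two array probes per SNP,
and applies the marker filters: (a) missing data, (b) probe disagreement,
(c) segregation fit, (d) parental-dosage match.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .dosageio import DosageMatrix
from .simcross import ProbePair, gamete_dosage_distribution

__all__ = [
    "SegregationModel",
    "SegregationFit",
    "expected_offspring_distribution",
    "enumerate_segregation_patterns",
    "fit_segregation",
    "merge_probes",
    "filter_markers",
    "segregation_type",
    "count_offspring_dosages",
]


# ---------------------------------------------------------------------------
# expected distributions
# ---------------------------------------------------------------------------


def _disomic_arrangements(d: int):
    """Unordered splits of dosage d over the two subgenome pairs (each ≤ 2)."""
    seen = set()
    for a in range(max(0, d - 2), min(2, d) + 1):
        arr = tuple(sorted((a, d - a)))
        seen.add(arr)
    return sorted(seen)


def _disomic_gamete(arrangement) -> np.ndarray:
    """Gamete dosage law for one parent under disomic pairing.

    Each subgenome pair contributes one chromosome: Mendelian transmission
    per pair (0 → 0; 1 → 0/1 equally; 2 → 1), convolved over the two pairs.
    """
    dist = np.array([1.0])
    for da in arrangement:
        g = {0: [1.0], 1: [0.5, 0.5], 2: [0.0, 1.0]}[da]
        dist = np.convolve(dist, g)
    out = np.zeros(3)
    out[: dist.size] = dist
    return out


def expected_offspring_distribution(
    d_mother: int,
    d_father: int,
    mode: str = "polysomic",
    mother_arrangement=None,
    father_arrangement=None,
) -> np.ndarray:
    """Probability vector over offspring dosages 0..4.

    ``mode='polysomic'``: convolution of the two parents' hypergeometric
    gamete distributions.  ``mode='disomic'``: convolution of per-subgenome
    Mendelian gamete distributions for the given allele arrangements
    (defaults to the most heterogenic split if not supplied).
    """
    for d in (d_mother, d_father):
        if d not in range(5):
            raise ValueError("parental dosage must be in 0..4")
    if mode == "polysomic":
        gm = gamete_dosage_distribution(d_mother)
        gf = gamete_dosage_distribution(d_father)
    elif mode == "disomic":
        ma = mother_arrangement or _disomic_arrangements(d_mother)[-1]
        fa = father_arrangement or _disomic_arrangements(d_father)[-1]
        gm = _disomic_gamete(ma)
        gf = _disomic_gamete(fa)
    else:
        raise ValueError(f"unknown inheritance mode {mode!r}")
    out = np.zeros(5)
    conv = np.convolve(gm, gf)
    out[: conv.size] = conv
    return out


@dataclass(frozen=True)
class SegregationModel:
    """One expected offspring dosage distribution and a generating config."""

    mother_dosage: int
    father_dosage: int
    mode: str
    mother_arrangement: tuple | None = None
    father_arrangement: tuple | None = None

    @property
    def distribution(self) -> np.ndarray:
        return expected_offspring_distribution(
            self.mother_dosage,
            self.father_dosage,
            self.mode,
            self.mother_arrangement,
            self.father_arrangement,
        )

    def type_shorthand(self) -> str:
        return segregation_type(self.mother_dosage, self.father_dosage)


_TYPE_NAMES = {0: "N", 1: "S", 2: "D", 3: "T", 4: "Q"}


def segregation_type(d_mother: int, d_father: int) -> str:
    """Shorthand such as SxN, DxN, SxS; dosages 3/4 mirror 1/0 by allele swap."""
    dm, df = d_mother, d_father
    if dm + df > 4:  # canonical representative under allele swap
        dm, df = 4 - dm, 4 - df
    return f"{_TYPE_NAMES[dm]}x{_TYPE_NAMES[df]}"


def enumerate_segregation_patterns(modes=("polysomic", "disomic")):
    """All distinct expected offspring distributions over parental dosage
    pairs and inheritance modes, deduplicated by distribution.

    Returns a list of ``(distribution, [SegregationModel, ...])`` sorted by
    the distribution tuple; each entry carries every generating config.
    """
    found: dict[tuple, list[SegregationModel]] = {}
    for dm, df in product(range(5), repeat=2):
        configs = []
        if "polysomic" in modes:
            configs.append(SegregationModel(dm, df, "polysomic"))
        if "disomic" in modes:
            for ma in _disomic_arrangements(dm):
                for fa in _disomic_arrangements(df):
                    configs.append(SegregationModel(dm, df, "disomic", ma, fa))
        for model in configs:
            key = tuple(np.round(model.distribution, 12))
            found.setdefault(key, []).append(model)
    return [(np.array(k), v) for k, v in sorted(found.items())]


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


@dataclass
class SegregationFit:
    """Best-fitting segregation pattern for one marker."""

    marker_id: str
    best_model: SegregationModel | None
    chi2: float
    p_value: float
    n_offspring_used: int
    flagged: bool = False
    reason: str = ""


def _chi2_against(counts: np.ndarray, probs: np.ndarray):
    """χ² GOF with zero-expectation classes dropped and small-expectation
    classes pooled into their neighbour.  Observed counts in an impossible
    class reject the candidate outright (chi2 = inf, p = 0)."""
    n = counts.sum()
    if counts[probs <= 0].sum() > 0:
        return np.inf, 0.0
    keep = probs > 0
    obs = counts[keep].astype(float)
    exp = n * probs[keep]
    # pool adjacent classes until every expected count is ≥ 1
    while obs.size > 1 and exp.min() < 1.0:
        i = int(np.argmin(exp))
        j = i - 1 if i > 0 else i + 1
        lo, hi = min(i, j), max(i, j)
        obs[lo] += obs[hi]
        exp[lo] += exp[hi]
        obs = np.delete(obs, hi)
        exp = np.delete(exp, hi)
    if obs.size < 2:
        return 0.0, 1.0
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=obs.size - 1))
    return chi2, p


def count_offspring_dosages(calls) -> np.ndarray:
    """Counts of offspring dosages 0..4, ignoring missing calls."""
    arr = np.asarray(calls, dtype=float)
    arr = arr[~np.isnan(arr)]
    return np.bincount(arr.astype(int), minlength=5)[:5]


def fit_segregation(
    calls, candidates=None, marker_id: str = "", alpha: float = 0.05
) -> SegregationFit:
    """Test offspring dosage calls against candidate segregation models.

    The best model is the one with the highest χ² p-value; a marker for
    which no candidate reaches ``alpha`` (or with all calls missing) is
    flagged rather than raising.
    """
    counts = count_offspring_dosages(calls)
    n = int(counts.sum())
    if n == 0:
        return SegregationFit(marker_id, None, np.nan, np.nan, 0, True, "all calls missing")
    if candidates is None:
        candidates = [m for _, models in enumerate_segregation_patterns() for m in models[:1]]
    best, best_chi2, best_p = None, np.inf, -1.0
    for model in candidates:
        chi2, p = _chi2_against(counts, model.distribution)
        if p > best_p or (p == best_p and chi2 < best_chi2):
            best, best_chi2, best_p = model, chi2, p
    flagged = best is None or best_p < alpha
    return SegregationFit(
        marker_id, best, best_chi2, best_p, n, flagged,
        "no candidate fits" if flagged else "",
    )


# ---------------------------------------------------------------------------
# probe merging and marker filters
# ---------------------------------------------------------------------------


@dataclass
class MergeResult:
    kept: bool
    calls: pd.Series | None
    confidence: pd.Series | None
    reason: str = ""
    disagreement: float = np.nan


def merge_probes(
    a_calls: pd.Series,
    a_conf: pd.Series,
    b_calls: pd.Series,
    b_conf: pd.Series,
    candidates=None,
    max_disagreement: float = 0.04,
    alpha: float = 0.05,
) -> MergeResult:
    """Merge the two probe layers of one SNP, or reject the marker.

    Kept only if (a) the dosage disagreement rate among jointly non-missing
    calls is below ``max_disagreement`` and (b) both probes' best-fitting
    segregation patterns are identical.  The merged call per sample is the
    one with the higher confidence; missing only if both probes are missing.
    """
    both = a_calls.notna() & b_calls.notna()
    n_both = int(both.sum())
    disagreement = (
        float((a_calls[both] != b_calls[both]).mean()) if n_both else np.nan
    )
    if n_both and disagreement >= max_disagreement:
        return MergeResult(False, None, None, "probe disagreement", disagreement)
    fit_a = fit_segregation(a_calls, candidates, alpha=alpha)
    fit_b = fit_segregation(b_calls, candidates, alpha=alpha)
    if fit_a.best_model is None or fit_b.best_model is None:
        return MergeResult(False, None, None, "no segregation fit", disagreement)
    da = tuple(np.round(fit_a.best_model.distribution, 12))
    db = tuple(np.round(fit_b.best_model.distribution, 12))
    if da != db:
        return MergeResult(False, None, None, "probe pattern mismatch", disagreement)
    use_a = a_conf.fillna(-1) >= b_conf.fillna(-1)
    use_a |= b_calls.isna()
    use_a &= a_calls.notna()
    merged = a_calls.where(use_a, b_calls)
    conf = a_conf.where(use_a, b_conf)
    return MergeResult(True, merged, conf, "", disagreement)


@dataclass
class QcThresholds:
    max_missing: float = 0.10
    max_probe_disagreement: float = 0.04
    segregation_alpha: float = 0.05


def filter_markers(
    probes: ProbePair,
    mother_dosage: pd.Series,
    father_dosage: pd.Series | None = None,
    thresholds: QcThresholds | None = None,
) -> tuple[DosageMatrix, pd.DataFrame]:
    """Apply the marker filters in order and merge retained probe pairs.

    (a) missing-data fraction above threshold on either probe layer;
    (b) probe disagreement / probe pattern mismatch (``merge_probes``);
    (c) no expected segregation pattern fits at the significance level;
    (d) the fitted pattern's parental dosages contradict the scored
    parental dosages (father unconstrained when unknown).

    Returns the merged retained matrix and a per-marker report with the
    rejection reason, best pattern, χ² and p.
    """
    thr = thresholds or QcThresholds()
    a, b = probes.probe_a, probes.probe_b
    patterns = enumerate_segregation_patterns()
    # one representative per distinct distribution is enough for fitting;
    # the full config lists are consulted again for the parental match
    candidates = [models[0] for _, models in patterns]
    records, merged_calls, merged_conf = [], {}, {}
    for marker in a.marker_ids:
        row = {
            "marker": marker, "status": "retained", "reason": "",
            "best_type": "", "mother_dosage_fit": np.nan,
            "father_dosage_fit": np.nan, "chi2": np.nan, "p": np.nan,
        }
        ac, bc = a.calls.loc[marker], b.calls.loc[marker]
        miss = max(ac.isna().mean(), bc.isna().mean())
        if miss > thr.max_missing:
            row.update(status="rejected", reason="missing")
            records.append(row)
            continue
        res = merge_probes(
            ac, a.confidence.loc[marker], bc, b.confidence.loc[marker],
            candidates, thr.max_probe_disagreement, thr.segregation_alpha,
        )
        if not res.kept:
            reason = "segregation" if res.reason == "no segregation fit" else res.reason
            row.update(status="rejected", reason=reason)
            records.append(row)
            continue
        fit = fit_segregation(res.calls, candidates, marker, thr.segregation_alpha)
        if fit.best_model is None or fit.flagged:
            row.update(status="rejected", reason="segregation",
                       chi2=fit.chi2, p=fit.p_value)
            records.append(row)
            continue
        # (d) parental match: some generating config of the best-fit
        # distribution must agree with the scored parental dosages
        key = tuple(np.round(fit.best_model.distribution, 12))
        configs = next(models for dist, models in patterns
                       if tuple(np.round(dist, 12)) == key)
        dm_obs = mother_dosage.get(marker, np.nan)
        df_obs = father_dosage.get(marker, np.nan) if father_dosage is not None else np.nan
        def _match(cfg):
            ok_m = np.isnan(dm_obs) or cfg.mother_dosage == dm_obs
            ok_f = np.isnan(df_obs) or cfg.father_dosage == df_obs
            return ok_m and ok_f
        matching = [c for c in configs if _match(c)]
        if not matching:
            row.update(status="rejected", reason="parental mismatch",
                       best_type=fit.best_model.type_shorthand(),
                       chi2=fit.chi2, p=fit.p_value)
            records.append(row)
            continue
        best = matching[0]
        row.update(
            best_type=best.type_shorthand(),
            mother_dosage_fit=best.mother_dosage,
            father_dosage_fit=best.father_dosage,
            chi2=fit.chi2, p=fit.p_value,
        )
        records.append(row)
        merged_calls[marker] = res.calls
        merged_conf[marker] = res.confidence
    report = pd.DataFrame(records).set_index("marker")
    if merged_calls:
        calls = pd.DataFrame(merged_calls).T
        conf = pd.DataFrame(merged_conf).T
        calls.index.name = conf.index.name = "marker"
        retained = DosageMatrix(calls, conf)
    else:
        empty = pd.DataFrame(columns=a.sample_ids)
        retained = DosageMatrix(empty, None)
    return retained, report
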