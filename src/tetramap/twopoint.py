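"""Two-point recombination-fraction and LOD estimation between tetraploid
dosage markers under random bivalent pairing, with phase inference.

Model
-----
For one parent, the allele copies of marker 1 sit on a homolog subset A1
and those of marker 2 on A2; only the overlap |A1 ∩ A2| matters under
random pairing (|overlap| = min dosage ⇒ coupling, 0 ⇒ repulsion).  The
four homologs pair into two bivalents (3 equiprobable pairings).  A
transmitted chromatid takes either member of its bivalent at marker 1 with
probability 1/2 and stays/switches at marker 2 with probability 1−r / r.
One chromatid per bivalent composes the gamete; the two parents' joint
gamete dosage distributions convolve into the 5×5 offspring joint dosage
law.  Maximising the multinomial likelihood of the observed joint dosage
table over r ∈ [0, 0.5] per admissible phase yields r̂, the best phase,
and LOD = log10 L(r̂) − log10 L(0.5).

For linkage-map building the scan can instead force a coupling
interpretation (trying both marker orientations), the treatment under
which same-position markers on different homologs appear ~1/3 recombinant
— the premise of the ~40 cM homolog-gap rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "PhaseConfiguration",
    "MarkerPairEstimate",
    "parent_gamete_joint",
    "joint_dosage_probabilities",
    "admissible_overlaps",
    "estimate_rf",
    "pairwise_scan",
    "joint_counts",
    "write_pwd",
]

_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))
_PROB_FLOOR = 1e-9  # robustness floor for observed cells outside the model


def admissible_overlaps(d1: int, d2: int) -> list[int]:
    """Possible |A1 ∩ A2| for marker dosages d1, d2 on 4 homologs."""
    return list(range(max(0, d1 + d2 - 4), min(d1, d2) + 1))


def parent_gamete_joint(d1: int, d2: int, overlap: int, r):
    """Joint gamete dosage distribution (3×3) for one parent.

    ``r`` may be a scalar or an array; the result has shape
    ``np.shape(r) + (3, 3)`` with axes (dosage at marker 1, at marker 2).
    """
    if overlap not in admissible_overlaps(d1, d2):
        raise ValueError(f"overlap {overlap} not admissible for dosages ({d1},{d2})")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    a1 = frozenset(range(d1))
    a2 = frozenset(range(overlap)) | frozenset(range(d1, d1 + d2 - overlap))
    out = np.zeros(r.shape + (3, 3))
    same = 0.5 * (1.0 - r)
    diff = 0.5 * r
    for pairing in _PAIRINGS:
        biv = []
        for h, g in pairing:
            dist = np.zeros(r.shape + (2, 2))
            for o1 in (h, g):
                for o2 in (h, g):
                    p = same if o1 == o2 else diff
                    dist[..., int(o1 in a1), int(o2 in a2)] += p
            biv.append(dist)
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    for l in range(2):
                        out[..., i + k, j + l] += biv[0][..., i, j] * biv[1][..., k, l] / 3.0
    return out


def joint_dosage_probabilities(mother, father, r):
    """Offspring 5×5 joint dosage probabilities.

    ``mother``/``father`` are ``(d_marker1, d_marker2, overlap)`` triples;
    ``r`` a scalar or array.  Rows and columns marginalise to the
    single-marker segregation distributions.
    """
    gm = parent_gamete_joint(*mother, r)
    gf = parent_gamete_joint(*father, r)
    r = np.asarray(r, dtype=float)
    out = np.zeros(r.shape + (5, 5))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    out[..., i + k, j + l] += gm[..., i, j] * gf[..., k, l]
    return out


def _phase_name(d1, d2, overlap):
    if min(d1, d2) == 0 or max(d1, d2) == 4:
        return "n/a"
    if overlap == 0:
        return "repulsion"
    if overlap == min(d1, d2):
        return "coupling"
    return f"mixed-{overlap}"


@dataclass(frozen=True)
class PhaseConfiguration:
    """Per-parent homolog overlap of the two markers' allele copies."""

    mother_overlap: int
    father_overlap: int
    mirrored: bool = False  # marker 2 recoded x -> 4 - x

    def label(self, dosages) -> str:
        d1m, d2m, d1f, d2f = dosages
        if self.mirrored:
            d2m, d2f = 4 - d2m, 4 - d2f
        m = _phase_name(d1m, d2m, self.mother_overlap)
        f = _phase_name(d1f, d2f, self.father_overlap)
        return f"m:{m}|f:{f}" + ("|mirrored" if self.mirrored else "")


@dataclass
class MarkerPairEstimate:
    """ML two-point estimate for one marker pair."""

    marker1: str
    marker2: str
    r_hat: float
    lod: float
    loglik: float
    phase: PhaseConfiguration
    dosages: tuple  # (d1m, d2m, d1f, d2f) as analysed
    n: int
    low_information: bool = False


def _phase_set(dosages, phases: str):
    """Candidate (PhaseConfiguration, analysed-dosages) pairs.

    ``phases='all'``: every admissible overlap combination on the original
    coding.  ``phases='coupling'``: the maximal-overlap (coupling)
    configuration on the original coding and on the mirrored marker-2
    coding — the JoinMap-style treatment used for map construction.
    """
    d1m, d2m, d1f, d2f = dosages
    out = []
    if phases == "all":
        for ovm in admissible_overlaps(d1m, d2m):
            for ovf in admissible_overlaps(d1f, d2f):
                out.append((PhaseConfiguration(ovm, ovf), dosages))
    elif phases == "coupling":
        out.append(
            (
                PhaseConfiguration(
                    admissible_overlaps(d1m, d2m)[-1],
                    admissible_overlaps(d1f, d2f)[-1],
                ),
                dosages,
            )
        )
        dm2, df2 = 4 - d2m, 4 - d2f
        out.append(
            (
                PhaseConfiguration(
                    admissible_overlaps(d1m, dm2)[-1],
                    admissible_overlaps(d1f, df2)[-1],
                    mirrored=True,
                ),
                (d1m, dm2, d1f, df2),
            )
        )
    else:
        raise ValueError("phases must be 'all' or 'coupling'")
    return out


def _loglik_grid(counts_flat, dosages, phase, r_grid):
    probs = joint_dosage_probabilities(
        (dosages[0], dosages[1], phase.mother_overlap),
        (dosages[2], dosages[3], phase.father_overlap),
        r_grid,
    ).reshape(r_grid.size, 25)
    return np.log(np.clip(probs, _PROB_FLOOR, None)) @ counts_flat


def estimate_rf(
    counts,
    dosages,
    marker1: str = "m1",
    marker2: str = "m2",
    phases: str = "all",
    refine: bool = True,
) -> MarkerPairEstimate:
    """ML estimate of r, phase and LOD from a 5×5 joint dosage count table.

    ``dosages`` is ``(d1_mother, d2_mother, d1_father, d2_father)``.  Each
    admissible phase is profiled over r ∈ [0, 0.5] (201-point grid plus a
    bounded scalar refinement to 1e-6); the best phase is the one with the
    highest maximised likelihood.  LOD compares against independence
    (r = 0.5).  Degenerate tables are flagged ``low_information``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (5, 5):
        raise ValueError("counts must be a 5×5 table")
    n = int(counts.sum())
    if n < 1:
        raise ValueError("at least one observed offspring is required")
    r_grid = np.linspace(0.0, 0.5, 201)
    flat = counts.reshape(25)
    best = None
    for phase, dos in _phase_set(tuple(dosages), phases):
        cf = counts[:, ::-1].reshape(25) if phase.mirrored else flat
        ll = _loglik_grid(cf, dos, phase, r_grid)
        k = int(np.argmax(ll))
        r0, ll0 = r_grid[k], ll[k]
        if refine:
            lo = r_grid[max(k - 1, 0)]
            hi = r_grid[min(k + 1, r_grid.size - 1)]
            if hi > lo:
                mo = (dos[0], dos[1], phase.mother_overlap)
                fa = (dos[2], dos[3], phase.father_overlap)

                def negll(r):
                    p = joint_dosage_probabilities(mo, fa, np.asarray(r)).reshape(25)
                    return -float(np.log(np.clip(p, _PROB_FLOOR, None)) @ cf)

                res = minimize_scalar(
                    negll, bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-6},
                )
                if -res.fun >= ll0:
                    r0, ll0 = float(res.x), -float(res.fun)
        lod = (ll0 - ll[-1]) / np.log(10.0)
        # profile-likelihood curvature on the grid; flat profiles are flagged
        curv = float(np.max(np.abs(np.diff(ll, 2)))) if ll.size > 2 else 0.0
        cand = (ll0, r0, lod, phase, dos, curv)
        if best is None or cand[0] > best[0]:
            best = cand
    ll0, r0, lod, phase, dos, curv = best
    low_info = curv < 1e-6 or np.count_nonzero(counts) <= 1
    return MarkerPairEstimate(
        marker1, marker2, r0, max(lod, 0.0), ll0, phase, dos, n, low_info
    )


# ---------------------------------------------------------------------------
# vectorised pairwise scan
# ---------------------------------------------------------------------------


def joint_counts(x_i: np.ndarray, x_j: np.ndarray) -> np.ndarray:
    """Complete-case 5×5 joint dosage counts for all marker pairs.

    ``x_i`` (Mi, N) and ``x_j`` (Mj, N) are dosage call matrices with NaN
    for missing; returns an (Mi, Mj, 25) array, cell (a, b) at index 5a+b.
    """
    out = np.empty((x_i.shape[0], x_j.shape[0], 25), dtype=np.int32)
    ind_i = [(x_i == a).astype(np.float64) for a in range(5)]
    ind_j = [(x_j == b).astype(np.float64) for b in range(5)]
    for a in range(5):
        for b in range(5):
            out[:, :, 5 * a + b] = np.rint(ind_i[a] @ ind_j[b].T).astype(np.int32)
    return out


def _recode_for_focal(dm: int, df: int):
    """Map a marker to its focal-parent class, mirroring alleles if needed.

    Returns (class, mirrored, (dm', df')) with class in {SxN, DxN, SxS} by
    (focal, other) dosage convention, or (None, ...) if the marker is not
    one of the supported mapping/bridge types.
    """
    for mirrored, (a, b) in ((False, (dm, df)), (True, (4 - dm, 4 - df))):
        if (a, b) in {(1, 0), (0, 1), (2, 0), (0, 2), (1, 1)}:
            cls = {(1, 0): "SxN", (0, 1): "NxS", (2, 0): "DxN",
                   (0, 2): "NxD", (1, 1): "SxS"}[(a, b)]
            return cls, mirrored, (a, b)
    return None, False, (dm, df)


def _grid_batch_estimates(counts25, dosages, phases, r_grid, chunk: int = 5000):
    """Vectorised grid ML for a batch of pairs sharing one dosage quadruple.

    Returns r̂, LOD, phase index arrays; r̂ is refined by parabolic
    interpolation around the best grid point.  Processed in chunks to keep
    the (pairs × grid) likelihood array small.
    """
    n_pairs = counts25.shape[0]
    if n_pairs > chunk:
        parts = [
            _grid_batch_estimates(counts25[k : k + chunk], dosages, phases, r_grid)
            for k in range(0, n_pairs, chunk)
        ]
        models = parts[0][3]
        return (
            np.concatenate([p[0] for p in parts]),
            np.concatenate([p[1] for p in parts]),
            np.concatenate([p[2] for p in parts]),
            models,
        )
    models = _phase_set(tuple(dosages), phases)
    ll_all = []
    for phase, dos in models:
        probs = joint_dosage_probabilities(
            (dos[0], dos[1], phase.mother_overlap),
            (dos[2], dos[3], phase.father_overlap),
            r_grid,
        ).reshape(r_grid.size, 25)
        logp = np.log(np.clip(probs, _PROB_FLOOR, None))
        c = counts25.reshape(-1, 5, 5)
        cf = (c[:, :, ::-1] if phase.mirrored else c).reshape(-1, 25)
        ll_all.append(cf @ logp.T)  # (B, G)
    ll = np.stack(ll_all)  # (P, B, G)
    ll_flat = ll.reshape(len(models), -1, r_grid.size)
    best_per_phase = ll_flat.max(axis=2)  # (P, B)
    phase_idx = best_per_phase.argmax(axis=0)  # (B,)
    B = counts25.shape[0]
    ll_best = ll_flat[phase_idx, np.arange(B), :]  # (B, G)
    k = ll_best.argmax(axis=1)
    # parabolic refinement on the grid
    k_c = np.clip(k, 1, r_grid.size - 2)
    y0, y1, y2 = (ll_best[np.arange(B), k_c + d] for d in (-1, 0, 1))
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = r_grid[1] - r_grid[0]
    r_hat = np.clip(r_grid[k_c] + shift * step, 0.0, 0.5)
    r_hat = np.where((k == 0) & (shift >= 0) & (y1 >= y2), 0.0, r_hat)
    ll_max = ll_best.max(axis=1)
    lod = np.maximum((ll_max - ll_best[:, -1]) / np.log(10.0), 0.0)
    return r_hat, lod, phase_idx, models


def pairwise_scan(
    calls: pd.DataFrame,
    marker_info: pd.DataFrame,
    parent: str = "mother",
    phases: str = "coupling",
    r_grid_points: int = 201,
) -> pd.DataFrame:
    """Two-point estimates for every informative marker pair of one parent.

    ``calls`` is a markers × individuals dosage matrix (NaN missing);
    ``marker_info`` must carry ``mother_dosage``/``father_dosage`` per
    marker.  Pairs analysed: focal S×N with S×N, plus bridge combinations
    S×N–D×N, S×N–S×S, D×N–D×N and S×S–S×S.  ``phases='coupling'`` gives the
    JoinMap-style mapping estimates; ``phases='all'`` full phase ML.

    Returns a canonically ordered, deterministic DataFrame.
    """
    if parent not in ("mother", "father"):
        raise ValueError("parent must be 'mother' or 'father'")
    classes: dict[str, list[str]] = {"SxN": [], "DxN": [], "SxS": []}
    recoded = {}
    quad = {}
    for m in calls.index:
        dm = int(marker_info.loc[m, "mother_dosage"])
        df_ = int(marker_info.loc[m, "father_dosage"])
        dfoc, doth = (dm, df_) if parent == "mother" else (df_, dm)
        cls, mirrored, (a, b) = _recode_for_focal(dfoc, doth)
        if cls in ("NxS", "NxD") or cls is None:
            continue  # not informative for the focal parent
        classes[cls].append(m)
        x = calls.loc[m].to_numpy(dtype=float)
        recoded[m] = (4.0 - x) if mirrored else x
        # analysed dosages in (mother, father) order for the model
        dfoc_r, doth_r = a, b
        quad[m] = (dfoc_r, doth_r) if parent == "mother" else (doth_r, dfoc_r)
    pair_blocks = [
        ("SxN", "SxN"), ("SxN", "DxN"), ("SxN", "SxS"),
        ("DxN", "DxN"), ("SxS", "SxS"),
    ]
    r_grid = np.linspace(0.0, 0.5, r_grid_points)
    records = []
    for c1, c2 in pair_blocks:
        mk1, mk2 = classes[c1], classes[c2]
        if not mk1 or not mk2:
            continue
        x1 = np.vstack([recoded[m] for m in mk1])
        x2 = np.vstack([recoded[m] for m in mk2])
        counts = joint_counts(x1, x2)
        if c1 == c2:
            ii, jj = np.triu_indices(len(mk1), k=1)
        else:
            ii, jj = np.meshgrid(range(len(mk1)), range(len(mk2)), indexing="ij")
            ii, jj = ii.ravel(), jj.ravel()
        if ii.size == 0:
            continue
        batch = counts[ii, jj, :]
        # all pairs in a block share the same dosage quadruple
        d1m, d1f = quad[mk1[0]]
        d2m, d2f = quad[mk2[0]]
        dosages = (d1m, d2m, d1f, d2f)
        r_hat, lod, phase_idx, models = _grid_batch_estimates(
            batch, dosages, phases, r_grid
        )
        nn = batch.sum(axis=1)
        for t in range(ii.size):
            phase, dos = models[phase_idx[t]]
            records.append(
                {
                    "marker1": mk1[ii[t]],
                    "marker2": mk2[jj[t]],
                    "type1": c1,
                    "type2": c2,
                    "phase": phase.label(dos),
                    "mother_overlap": phase.mother_overlap,
                    "father_overlap": phase.father_overlap,
                    "mirrored": phase.mirrored,
                    "r_hat": float(r_hat[t]),
                    "lod": float(lod[t]),
                    "n": int(nn[t]),
                }
            )
    df = pd.DataFrame(records)
    if not df.empty:
        swap = df["marker1"] > df["marker2"]
        df.loc[swap, ["marker1", "marker2"]] = df.loc[
            swap, ["marker2", "marker1"]
        ].to_numpy()
        df.loc[swap, ["type1", "type2"]] = df.loc[swap, ["type2", "type1"]].to_numpy()
        df = df.sort_values(["marker1", "marker2"], kind="mergesort").reset_index(
            drop=True
        )
    return df


def write_pwd(pairs: pd.DataFrame, path, population: str = "population") -> None:
    """Write a JoinMap-style pairwise data file (.pwd dialect)."""
    with open(path, "w") as fh:
        fh.write("; generated by tetramap\n")
        fh.write(f"name = {population}\n")
        fh.write("popt = CP\n")
        for _, row in pairs.iterrows():
            fh.write(
                f"{row['marker1']} {row['marker2']} "
                f"{row['r_hat']:.4f} {row['lod']:.4f}\n"
            )


def write_pairs_tsv(pairs: pd.DataFrame, path) -> None:
    """TSV twin of the pwd content, with full phase annotation."""
    out = pairs.copy()
    for col in ("r_hat", "lod"):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)
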