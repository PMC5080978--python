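"""Synthetic tetraploid-cross simulator.

Simulates autotetraploid meiosis (random bivalent pairing, optional
quadrivalent formation with position-dependent double reduction), crosses
(outcross, selfing, admixed multi-father batches) and array-style dosage
observation with per-call confidence and two probe layers per SNP, so the
whole downstream analysis is testable without any external data.

Model summary
-------------
* Per chromosome, the four homologs are paired uniformly at random into two
  bivalents.  A transmitted chromatid starts on either member of its
  bivalent with probability 1/2 and switches partner between adjacent loci
  with probability equal to the inverse-Kosambi transform of the cM
  interval (a Markov walk along intervals).  At any single locus the gamete
  dosage of a parent with dosage d is therefore hypergeometric:
  P(k) = C(d,k)·C(4−d,2−k)/C(4,2).
* With probability ``quadrivalent_prob`` all four homologs instead form one
  quadrivalent.  The gamete draws two chromatid mosaics; at each locus the
  second chromatid is replaced by a sister copy of the first with
  probability linear in relative locus position, from 0 at the proximal end
  up to ``double_reduction_max`` at the distal end (double reduction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dosageio import DosageMatrix
from .mapfunc import inverse_kosambi

__all__ = [
    "Chromosome",
    "ParentalHaplotypes",
    "MeiosisConfig",
    "CrossDesign",
    "ObservationConfig",
    "Population",
    "ProbePair",
    "SELF",
    "simulate_gamete",
    "simulate_gametes",
    "simulate_population",
    "observe_dosages",
    "simulate_marker_panel",
    "gamete_dosage_distribution",
]

SELF = "SELF"


@dataclass
class Chromosome:
    """One chromosome of a tetraploid parent: 4 homolog allele rows."""

    name: str
    positions_cm: np.ndarray  # strictly increasing? non-decreasing allowed (co-located contig SNPs)
    alleles: np.ndarray  # (4, n_loci) binary
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (4, self.positions_cm.size):
            raise ValueError("alleles must be 4 × n_loci")
        if np.any(np.diff(self.positions_cm) < 0):
            raise ValueError("positions must be non-decreasing")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("allele matrix entries must be 0/1")
        if not self.markers:
            self.markers = [f"{self.name}_m{i}" for i in range(self.positions_cm.size)]

    @property
    def n_loci(self) -> int:
        return self.positions_cm.size

    @property
    def dosage(self) -> np.ndarray:
        return self.alleles.sum(axis=0)


@dataclass
class ParentalHaplotypes:
    """Phased tetraploid parent: four homologs per chromosome."""

    parent_id: str
    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("parent must carry at least one chromosome")

    @property
    def n_loci(self) -> int:
        return sum(c.n_loci for c in self.chromosomes)

    def dosage_vector(self) -> pd.Series:
        """Per-marker allele dosage (column sums of the homolog matrix)."""
        vals = np.concatenate([c.dosage for c in self.chromosomes])
        names = [m for c in self.chromosomes for m in c.markers]
        return pd.Series(vals, index=names, name=self.parent_id)


@dataclass
class MeiosisConfig:
    """Meiosis model parameters.

    ``crossover_model`` is fixed to the per-interval Markov walk with
    inverse-Kosambi switch probabilities; ``quadrivalent_prob`` (q) is the
    chance a chromosome forms a quadrivalent, and ``double_reduction_max``
    the sister-co-segregation probability at the distal chromosome end
    given a quadrivalent.
    """

    quadrivalent_prob: float = 0.0
    double_reduction_max: float = 0.0
    crossover_model: str = "kosambi-markov"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.quadrivalent_prob, self.double_reduction_max):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class CrossDesign:
    """A mother crossed to one or more fathers (``SELF`` = selfing)."""

    mother: ParentalHaplotypes
    fathers: list[tuple]  # (ParentalHaplotypes | SELF, n_offspring)

    def __post_init__(self) -> None:
        if sum(n for _, n in self.fathers) < 1:
            raise ValueError("design must produce at least one offspring")


@dataclass
class ObservationConfig:
    """fitTetra-style observation noise for dosage calls."""

    missing_rate: float = 0.0
    error_rate: float = 0.0
    probe_disagreement_rate: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.missing_rate, self.error_rate, self.probe_disagreement_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class Population:
    """Simulated offspring genotypes with simulation truth attached."""

    genotypes: np.ndarray  # (n_offspring, 4, n_loci) binary
    sample_ids: list[str]
    father_labels: list[str]
    markers: pd.DataFrame  # marker, chrom, pos_cM, contig, parental dosages, homologs
    mother: ParentalHaplotypes
    fathers: dict

    @property
    def n_offspring(self) -> int:
        return self.genotypes.shape[0]

    def true_dosages(self) -> pd.DataFrame:
        """Markers × individuals matrix of true allele dosages."""
        d = self.genotypes.sum(axis=1)  # (n, L)
        return pd.DataFrame(
            d.T, index=self.markers["marker"].tolist(), columns=self.sample_ids
        )


@dataclass
class ProbePair:
    """The two probe layers observed for every SNP."""

    probe_a: DosageMatrix
    probe_b: DosageMatrix


def _rng(cfg_seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(cfg_seed)


def gamete_dosage_distribution(d: int) -> np.ndarray:
    """Hypergeometric gamete dosage law for a parent of dosage ``d`` (q=0):
    P(k) = C(d,k)·C(4−d,2−k)/C(4,2), k = 0..2."""
    from math import comb

    if d not in range(5):
        raise ValueError("parental dosage must be 0..4")
    return np.array([comb(d, k) * comb(4 - d, 2 - k) / comb(4, 2) for k in range(3)])


def _chain4(n: int, n_loci: int, r_int: np.ndarray, rng) -> np.ndarray:
    """Markov mosaic over the 4 homologs of a quadrivalent."""
    o = np.empty((n, n_loci), dtype=np.int8)
    o[:, 0] = rng.integers(0, 4, size=n)
    for k in range(1, n_loci):
        sw = rng.random(n) < r_int[k - 1]
        jump = rng.integers(1, 4, size=n).astype(np.int8)
        o[:, k] = np.where(sw, (o[:, k - 1] + jump) % 4, o[:, k - 1])
    return o


def _gamete_origins_chrom(
    positions: np.ndarray, cfg: MeiosisConfig, n: int, rng
) -> np.ndarray:
    """Homolog-of-origin indices for n gametes: (n, 2 chromatids, n_loci)."""
    n_loci = positions.size
    r_int = inverse_kosambi(np.diff(positions)) if n_loci > 1 else np.empty(0)
    origins = np.empty((n, 2, n_loci), dtype=np.int8)

    # --- bivalent pathway: random pairing of the four homologs ---
    perm = np.argsort(rng.random((n, 4)), axis=1).astype(np.int8)
    for b in range(2):
        pair = perm[:, 2 * b : 2 * b + 2]  # (n, 2)
        start = rng.integers(0, 2, size=n)
        if n_loci > 1:
            switch = rng.random((n, n_loci - 1)) < r_int
            within = (start[:, None] + np.cumsum(switch, axis=1, dtype=int)) % 2
            within = np.concatenate([start[:, None], within], axis=1)
        else:
            within = start[:, None]
        origins[:, b, :] = np.take_along_axis(pair, within.astype(np.int8), axis=1)

    # --- quadrivalent pathway with distally increasing double reduction ---
    if cfg.quadrivalent_prob > 0:
        quad = rng.random(n) < cfg.quadrivalent_prob
        nq = int(quad.sum())
        if nq:
            c1 = _chain4(nq, n_loci, r_int, rng)
            b2 = _chain4(nq, n_loci, r_int, rng)
            span = positions[-1] if positions[-1] > 0 else 1.0
            alpha = cfg.double_reduction_max * (positions / span)
            dr = rng.random((nq, n_loci)) < alpha[None, :]
            c2 = np.where(dr, c1, b2)
            origins[quad, 0, :] = c1
            origins[quad, 1, :] = c2
    return origins


def simulate_gametes(
    parent: ParentalHaplotypes,
    cfg: MeiosisConfig,
    n: int,
    rng=None,
    return_origins: bool = False,
):
    """Simulate ``n`` gametes; returns a list over chromosomes of
    (n, 2, n_loci) chromatid allele arrays (optionally with origins)."""
    rng = _rng(cfg.rng_seed, rng)
    out, orig_out = [], []
    for chrom in parent.chromosomes:
        origins = _gamete_origins_chrom(chrom.positions_cm, cfg, n, rng)
        alleles = chrom.alleles[origins, np.arange(chrom.n_loci)[None, None, :]]
        out.append(alleles)
        orig_out.append(origins)
    if return_origins:
        return out, orig_out
    return out


def simulate_gamete(parent: ParentalHaplotypes, cfg: MeiosisConfig, rng=None):
    """Single gamete: list over chromosomes of (2, n_loci) allele arrays."""
    return [a[0] for a in simulate_gametes(parent, cfg, 1, rng=rng)]


def simulate_population(
    design: CrossDesign, cfg: MeiosisConfig, rng=None, markers: pd.DataFrame | None = None
) -> Population:
    """Cross the mother to each father; offspring = maternal + paternal gamete.

    True father labels are retained for downstream accuracy scoring.
    """
    rng = _rng(cfg.rng_seed, rng)
    mother = design.mother
    blocks, labels = [], []
    fathers: dict = {}
    for father, n_off in design.fathers:
        if father == SELF or father is mother:
            father_obj, label = mother, SELF
        else:
            father_obj, label = father, father.parent_id
        fathers[label] = father_obj
        gm = simulate_gametes(mother, cfg, n_off, rng=rng)
        gf = simulate_gametes(father_obj, cfg, n_off, rng=rng)
        per_chrom = [np.concatenate([m, f], axis=1) for m, f in zip(gm, gf)]
        blocks.append(np.concatenate(per_chrom, axis=2))  # (n_off, 4, L)
        labels.extend([label] * n_off)
    genotypes = np.concatenate(blocks, axis=0)
    sample_ids = [f"S{i + 1:03d}" for i in range(genotypes.shape[0])]
    if markers is None:
        markers = _marker_table_from_parent(mother)
    return Population(genotypes, sample_ids, labels, markers, mother, fathers)


def _marker_table_from_parent(parent: ParentalHaplotypes) -> pd.DataFrame:
    rows = []
    for chrom in parent.chromosomes:
        for i, m in enumerate(chrom.markers):
            rows.append(
                {
                    "marker": m,
                    "chrom": chrom.name,
                    "pos_cM": chrom.positions_cm[i],
                    "contig": m.rsplit("_", 1)[0],
                }
            )
    return pd.DataFrame(rows)


def observe_dosages(
    true_dosages: pd.DataFrame, obs: ObservationConfig, rng=None
) -> ProbePair:
    """Perturb true dosages into two probe layers with confidences.

    A shared error layer emulates mis-clustered dosage calls (±1, clipped
    to 0..4); probe B duplicates probe A except at disagreeing calls and
    carries its own missingness and confidence draws.
    """
    rng = _rng(obs.rng_seed, rng)
    base = true_dosages.to_numpy(dtype=float)
    shape = base.shape

    def perturb(mat, mask):
        delta = rng.choice([-1.0, 1.0], size=shape)
        return np.clip(np.where(mask, mat + delta, mat), 0, 4)

    err = rng.random(shape) < obs.error_rate
    called = perturb(base, err)

    a_vals = called.copy()
    b_vals = perturb(called, rng.random(shape) < obs.probe_disagreement_rate)

    layers = []
    for vals in (a_vals, b_vals):
        missing = rng.random(shape) < obs.missing_rate
        conf = np.where(
            missing,
            0.5 + 0.45 * rng.random(shape),
            0.95 + 0.05 * rng.random(shape),
        )
        out = vals.copy()
        out[missing] = np.nan
        calls = pd.DataFrame(out, index=true_dosages.index, columns=true_dosages.columns)
        confidence = pd.DataFrame(
            conf, index=true_dosages.index, columns=true_dosages.columns
        )
        layers.append(DosageMatrix(calls, confidence))
    return ProbePair(*layers)


# ---------------------------------------------------------------------------
# marker panel / parent generation
# ---------------------------------------------------------------------------

#: per-chromosome marker counts by (mother dosage, father dosage)
DEFAULT_CLASS_COUNTS = {
    (1, 0): 24,
    (0, 1): 24,
    (1, 1): 48,
    (2, 0): 8,
    (0, 2): 8,
    (0, 0): 20,
    (4, 4): 8,
    (0, 4): 6,
    (4, 0): 6,
}


def simulate_marker_panel(
    n_chromosomes: int = 7,
    chrom_length_cm: float = 100.0,
    class_counts: dict | None = None,
    class_weights: dict | None = None,
    n_markers_per_chromosome: int | None = None,
    seed: int = 0,
    parent_ids: Sequence[str] = ("MOTHER", "FATHER"),
):
    """Generate a phased mother/father pair and a marker truth table.

    Markers are placed on contigs of 1–3 co-located SNPs (array probes from
    one source sequence), named ``K<contig>_<index>`` so the contig id is
    recoverable from the name.  Either exact per-chromosome ``class_counts``
    or sampling ``class_weights`` over (mother, father) dosage classes can
    be given.

    Returns ``(mother, father, marker_table)``.
    """
    rng = np.random.default_rng(seed)
    if class_counts is None and class_weights is None:
        class_counts = DEFAULT_CLASS_COUNTS
    m_chroms, f_chroms, rows = [], [], []
    contig_counter = 0
    for ci in range(n_chromosomes):
        cname = f"chr{ci + 1}"
        if class_counts is not None:
            classes = [cfg for cfg, k in sorted(class_counts.items()) for _ in range(k)]
            rng.shuffle(classes)
        else:
            keys = sorted(class_weights)
            w = np.array([class_weights[k] for k in keys], dtype=float)
            w = w / w.sum()
            total = n_markers_per_chromosome or 100
            idx = rng.choice(len(keys), size=total, p=w)
            classes = [keys[i] for i in idx]
        n_mark = len(classes)
        # contigs of 1-3 SNPs at a shared position
        sizes = []
        while sum(sizes) < n_mark:
            sizes.append(int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1])))
        over = sum(sizes) - n_mark
        if over:
            sizes[-1] -= over
            if sizes[-1] == 0:
                sizes.pop()
        contig_pos = np.sort(rng.uniform(0, chrom_length_cm, size=len(sizes)))
        positions, names, contigs = [], [], []
        for s, cpos in zip(sizes, contig_pos):
            contig_counter += 1
            cid = f"K{contig_counter:04d}"
            for j in range(s):
                positions.append(cpos)
                names.append(f"{cid}_{j + 1}")
                contigs.append(cid)
        positions = np.asarray(positions)
        m_all = np.zeros((4, n_mark), dtype=np.int8)
        f_all = np.zeros((4, n_mark), dtype=np.int8)
        for i, (dm, df) in enumerate(classes):
            mh = rng.choice(4, size=dm, replace=False) if dm else np.empty(0, int)
            fh = rng.choice(4, size=df, replace=False) if df else np.empty(0, int)
            m_all[mh, i] = 1
            f_all[fh, i] = 1
            rows.append(
                {
                    "marker": names[i],
                    "chrom": cname,
                    "pos_cM": positions[i],
                    "contig": contigs[i],
                    "mother_dosage": dm,
                    "father_dosage": df,
                    "mother_homologs": ",".join(map(str, sorted(mh))),
                    "father_homologs": ",".join(map(str, sorted(fh))),
                }
            )
        m_chroms.append(Chromosome(cname, positions, m_all, names))
        f_chroms.append(Chromosome(cname, positions.copy(), f_all, list(names)))
    mother = ParentalHaplotypes(parent_ids[0], m_chroms)
    father = ParentalHaplotypes(parent_ids[1], f_chroms)
    table = pd.DataFrame(rows)
    return mother, father, table
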