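"""End-to-end pipeline: simulate → qc → split → linkage → map → report.

Every stage reads and writes plain delimited text under one output
directory, so stages can be run separately from the CLI or in one shot
with :func:`run_pipeline`.  All randomness flows from the single config
seed through named substreams; rerunning with the same config produces
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import disentangle, mapbuild, segqc, twopoint
from .dosageio import DosageMatrix, read_dosage_csv, write_dosage_csv
from .simcross import (
    DEFAULT_CLASS_COUNTS,
    SELF,
    CrossDesign,
    MeiosisConfig,
    ObservationConfig,
    ProbePair,
    observe_dosages,
    simulate_marker_panel,
    simulate_population,
)

logger = logging.getLogger("tetramap")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config", "save_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults mirror the analysis thresholds
    (segregation P<0.05, probe disagreement <4%, LOD>4, ~35 cM homolog gap)
    and the study-like cross design (103 selfed + 74 outcrossed progeny)."""

    # simulation design
    n_chromosomes: int = 7
    chrom_length_cm: float = 100.0
    n_self: int = 103
    n_outcross: int = 74
    quadrivalent_prob: float = 0.0
    double_reduction_max: float = 0.0
    missing_rate: float = 0.02
    error_rate: float = 0.005
    probe_disagreement_rate: float = 0.01
    # analysis thresholds
    max_missing: float = 0.10
    max_probe_disagreement: float = 0.04
    segregation_alpha: float = 0.05
    lod_threshold: float = 4.0
    gap_threshold_cm: float = 35.0
    parent_rejection_fraction: float = 0.05
    selfing_consistency: float = 0.95
    # labels and seed
    mother_id: str = "MOTHER"
    father_id: str = "UP"
    candidate_id: str = "CANDIDATE"
    seed: int = 1

    def substream(self, name: str) -> np.random.Generator:
        """Named child RNG derived deterministically from the config seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _stable_int(name, self.seed)])
        )

    def substream_int(self, name: str) -> int:
        return _stable_int(name, self.seed)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def _stable_int(name: str, seed: int) -> int:
    # hash() is salted per process; use a deterministic digest instead
    import hashlib

    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    """Simulate the admixed batch and write dosage + truth files."""
    outdir.mkdir(parents=True, exist_ok=True)
    mother, father, table = simulate_marker_panel(
        n_chromosomes=cfg.n_chromosomes,
        chrom_length_cm=cfg.chrom_length_cm,
        class_counts=DEFAULT_CLASS_COUNTS,
        seed=cfg.substream_int("panel"),
        parent_ids=(cfg.mother_id, cfg.father_id),
    )
    meiosis = MeiosisConfig(cfg.quadrivalent_prob, cfg.double_reduction_max)
    design = CrossDesign(mother, [(SELF, cfg.n_self), (father, cfg.n_outcross)])
    pop = simulate_population(design, meiosis, rng=cfg.substream("meiosis"), markers=table)
    obs = ObservationConfig(cfg.missing_rate, cfg.error_rate, cfg.probe_disagreement_rate)
    probes = observe_dosages(pop.true_dosages(), obs, rng=cfg.substream("observe"))
    # an unrelated candidate father (dosages drawn from the panel marginals)
    rng = cfg.substream("candidate")
    cand = pd.Series(
        rng.permutation(table["father_dosage"].to_numpy()),
        index=table["marker"], name=cfg.candidate_id,
    )
    parents = pd.DataFrame(
        {
            cfg.mother_id: mother.dosage_vector(),
            cfg.candidate_id: cand,
        }
    )
    write_dosage_csv(probes.probe_a, outdir / "dosage_probeA.csv",
                     outdir / "dosage_probeA.conf.csv")
    write_dosage_csv(probes.probe_b, outdir / "dosage_probeB.csv",
                     outdir / "dosage_probeB.conf.csv")
    parents.round(0).astype(int).to_csv(outdir / "parents.tsv", sep="\t")
    pd.DataFrame({"sample": pop.sample_ids, "father": pop.father_labels}).to_csv(
        outdir / "truth_fathers.tsv", sep="\t", index=False
    )
    truth = table.copy()
    truth["pos_cM"] = truth["pos_cM"].map(lambda v: f"{v:.4f}")
    truth.to_csv(outdir / "truth_markers.tsv", sep="\t", index=False)
    logger.info("simulate: %d markers, %d offspring", len(table), pop.n_offspring)
    return {"probes": probes, "parents": parents, "population": pop, "markers": table}


def _load_inputs(outdir: Path):
    probes = ProbePair(
        read_dosage_csv(outdir / "dosage_probeA.csv", outdir / "dosage_probeA.conf.csv"),
        read_dosage_csv(outdir / "dosage_probeB.csv", outdir / "dosage_probeB.conf.csv"),
    )
    parents = pd.read_csv(outdir / "parents.tsv", sep="\t", index_col=0)
    return probes, parents


def naive_merge(probes: ProbePair) -> DosageMatrix:
    """Pre-QC merge for the split stage: higher-confidence call per cell,
    falling back to whichever probe is non-missing."""
    a, b = probes.probe_a, probes.probe_b
    use_a = (a.confidence.fillna(-1) >= b.confidence.fillna(-1)) | b.calls.isna()
    use_a &= a.calls.notna()
    calls = a.calls.where(use_a, b.calls)
    conf = a.confidence.where(use_a, b.confidence)
    return DosageMatrix(calls, conf)


def stage_split(cfg: PipelineConfig, outdir: Path) -> dict:
    """PCO on mother-monomorphic markers and silhouette-gated k-means."""
    probes, parents = _load_inputs(outdir)
    merged = naive_merge(probes)
    mother_dosage = parents[cfg.mother_id]
    mono = disentangle.select_monomorphic_markers(merged, mother_dosage)
    if not mono:
        raise PipelineError("split: no mother-monomorphic markers available")
    dist = disentangle.genetic_distance(merged, mono)
    pco_res = disentangle.pco(dist, n_axes=2)
    split = disentangle.split_population(
        pco_res, seed=cfg.substream_int("kmeans")
    )
    split.assignment.rename("subpopulation").to_frame().to_csv(
        outdir / "split_assignment.tsv", sep="\t"
    )
    coords = pd.DataFrame(
        pco_res.coordinates, index=pco_res.ids,
        columns=[f"PCo{k + 1}" for k in range(pco_res.coordinates.shape[1])],
    ).round(6)
    coords.to_csv(outdir / "pco_coordinates.tsv", sep="\t")
    logger.info(
        "split: %d markers used, k=%d, silhouette=%.3f",
        len(mono), split.k, split.silhouette,
    )
    return {"split": split, "pco": pco_res, "n_markers": len(mono)}


def stage_populations(cfg: PipelineConfig, outdir: Path) -> dict:
    """Per-subpopulation QC, candidate-father rejection, selfing test and
    unknown-parent reconstruction."""
    probes, parents = _load_inputs(outdir)
    assignment = pd.read_csv(outdir / "split_assignment.tsv", sep="\t", index_col=0)[
        "subpopulation"
    ]
    mother_dosage = parents[cfg.mother_id]
    cand_dosage = parents[cfg.candidate_id] if cfg.candidate_id in parents else None
    thr = segqc.QcThresholds(cfg.max_missing, cfg.max_probe_disagreement,
                             cfg.segregation_alpha)
    pops: dict[str, dict] = {}
    for label in sorted(assignment.unique()):
        samples = assignment.index[assignment == label].tolist()
        sub = ProbePair(
            probes.probe_a.subset_samples(samples),
            probes.probe_b.subset_samples(samples),
        )
        retained, report = segqc.filter_markers(sub, mother_dosage, None, thr)
        report.to_csv(outdir / f"qc_{label}.tsv", sep="\t")
        logger.info(
            "qc[%s]: %d markers in, %d retained (%s)",
            label, len(report), (report["status"] == "retained").sum(),
            ", ".join(f"{k}={v}" for k, v in
                      report.loc[report.status == "rejected", "reason"]
                      .value_counts().items()),
        )
        pops[label] = {"samples": samples, "retained": retained, "report": report}
    # reference S×N lists for the cross-population selfing test
    sxn = {
        label: [
            m for m, row in d["report"].iterrows()
            if row["status"] == "retained" and row["best_type"] == "SxN"
            and row["mother_dosage_fit"] in (1, 3)
        ]
        for label, d in pops.items()
    }
    selfing_lines = []
    for label, d in pops.items():
        others = [l for l in pops if l != label]
        ref = sxn[others[0]] if others else None
        evidence = disentangle.selfing_test(
            d["retained"], mother_dosage, ref,
            consistency_threshold=cfg.selfing_consistency,
            seed=cfg.substream_int(f"boot-{label}"),
        )
        d["selfing"] = evidence
        if cand_dosage is not None:
            rejected, fraction, _ = disentangle.reject_parent(
                d["retained"], mother_dosage, cand_dosage,
                reject_fraction=cfg.parent_rejection_fraction,
            )
            d["candidate_rejected"] = rejected
            d["candidate_fraction"] = fraction
        recon = disentangle.reconstruct_parent(d["retained"], mother_dosage)
        recon.to_csv(outdir / f"reconstructed_parent_{label}.tsv", sep="\t")
        d["reconstruction"] = recon
        selfing_lines += [
            f"population: {label}",
            f"n_offspring: {len(d['samples'])}",
            f"sxn_to_sxs_consistency: {evidence.sxn_to_sxs_consistency:.4f}",
            f"offspring_mean_heterozygosity: {evidence.offspring_mean_heterozygosity:.4f}",
            f"parent_heterozygosity: {evidence.parent_heterozygosity:.4f}",
            f"het_p_value: {evidence.het_p_value:.4f}",
            f"verdict: {evidence.verdict}",
        ]
        if cand_dosage is not None:
            selfing_lines += [
                f"candidate_father_incompatible_fraction: {d['candidate_fraction']:.4f}",
                f"candidate_father_rejected: {d['candidate_rejected']}",
            ]
        selfing_lines.append("")
        logger.info("selfing[%s]: %s (consistency=%.3f, het %.3f vs %.3f)",
                    label, evidence.verdict, evidence.sxn_to_sxs_consistency,
                    evidence.offspring_mean_heterozygosity,
                    evidence.parent_heterozygosity)
    (outdir / "selfing_report.txt").write_text("\n".join(selfing_lines))
    return pops


def build_parent_maps(
    retained: DosageMatrix,
    report: pd.DataFrame,
    parent: str,
    cfg: PipelineConfig,
    prefix: str,
):
    """Linkage groups, homolog separation, bridging and per-homolog maps
    for one focal parent in one population."""
    kept = report[report["status"] == "retained"]
    info = pd.DataFrame(
        {
            "mother_dosage": kept["mother_dosage_fit"].astype(int),
            "father_dosage": kept["father_dosage_fit"].astype(int),
        }
    )
    calls = retained.calls.loc[info.index]
    pairs = twopoint.pairwise_scan(calls, info, parent=parent, phases="coupling")
    if pairs.empty:
        raise PipelineError(f"linkage[{prefix}]: no informative marker pairs")
    sxn_pairs = pairs[(pairs["type1"] == "SxN") & (pairs["type2"] == "SxN")]
    map_type = "SxN" if not sxn_pairs.empty else "SxS"
    map_pairs = pairs[(pairs["type1"] == map_type) & (pairs["type2"] == map_type)]
    if map_pairs.empty:
        raise PipelineError(f"linkage[{prefix}]: no {map_type} mapping pairs")
    groups, singletons = mapbuild.group_markers(
        map_pairs, cfg.lod_threshold, parent=parent
    )
    # homolog separation: assigned phase first, then the ~40 cM gap rule
    fragments: list[list[str]] = []
    for grp in groups:
        for comp in mapbuild.phase_components(grp.markers, map_pairs, cfg.lod_threshold):
            if len(comp) < 2:
                singletons.extend(comp)
                continue
            gmap = mapbuild.order_and_fit(comp, map_pairs, grp.group_id, parent)
            fragments.extend(
                f for f in mapbuild.split_homologs(gmap, cfg.gap_threshold_cm)
                if len(f) >= 2
            )
    homolog_maps = [
        mapbuild.order_and_fit(frag, map_pairs, f"{prefix}_h{i + 1:02d}", parent)
        for i, frag in enumerate(fragments)
    ]
    bridge_pairs = pairs[(pairs["type1"] != map_type) | (pairs["type2"] != map_type)]
    bridge_pairs = bridge_pairs[~bridge_pairs["mirrored"]]
    overlap_col = "mother_overlap" if parent == "mother" else "father_overlap"
    clusters, flags = mapbuild.connect_homologs(
        [m.markers for m in homolog_maps], bridge_pairs,
        cfg.lod_threshold, overlap_col=overlap_col,
    )
    named = []
    for ci, cluster in enumerate(clusters):
        for hj, gi in enumerate(cluster):
            g = homolog_maps[gi]
            named.append(
                mapbuild.GeneticMap(
                    f"{prefix}_c{ci + 1:02d}_h{hj + 1}", g.markers, g.positions,
                    g.fit_stress, parent,
                )
            )
    return {
        "pairs": pairs,
        "map_pairs": map_pairs,
        "maps": named,
        "singletons": singletons,
        "clusters": clusters,
        "overflow_flags": flags,
        "map_type": map_type,
    }


def stage_linkage(cfg: PipelineConfig, outdir: Path, pops: dict) -> dict:
    """Maps for each population: the shared mother everywhere, plus the
    reconstructed unknown father in the outcross population."""
    results = {}
    for label, d in sorted(pops.items()):
        if d["retained"].n_markers == 0:
            raise PipelineError(f"linkage: no markers retained for {label}")
        focal_parents = ["mother"]
        kept = d["report"][d["report"]["status"] == "retained"]
        # father-informative S×N markers carry the canonical type NxS
        if (kept["best_type"] == "NxS").any():
            focal_parents.append("father")
        for parent in focal_parents:
            prefix = f"{label}_{parent}"
            try:
                res = build_parent_maps(d["retained"], d["report"], parent, cfg, prefix)
            except PipelineError as err:
                logger.info("linkage[%s]: skipped (%s)", prefix, err)
                continue
            twopoint.write_pwd(res["map_pairs"], outdir / f"pairs_{prefix}.pwd",
                               population=prefix)
            twopoint.write_pairs_tsv(res["pairs"], outdir / f"pairs_{prefix}.tsv")
            mapbuild.write_map_tsv(res["maps"], outdir / f"map_{prefix}.tsv")
            mapbuild.write_mapchart(res["maps"], outdir / f"mapchart_{prefix}.txt")
            results[prefix] = res
            logger.info(
                "linkage[%s]: %d homolog maps in %d chromosome clusters",
                prefix, len(res["maps"]), len(res["clusters"]),
            )
    if not results:
        raise PipelineError("linkage: no maps could be built")
    return results


def stage_report(cfg: PipelineConfig, outdir: Path, linkage: dict) -> pd.DataFrame:
    all_maps = [m for res in linkage.values() for m in res["maps"]]
    summary = mapbuild.summarize_maps(all_maps)
    out = summary.per_group.copy()
    out["length_cM"] = out["length_cM"].map(lambda v: f"{v:.3f}")
    out.to_csv(outdir / "map_summary.tsv", sep="\t", index=False)
    totals = (
        f"total_length_cM: {summary.total_length_cm:.3f}\n"
        f"total_markers: {summary.total_markers}\n"
        f"mean_interval_cM: {summary.mean_interval_cm:.4f}\n"
        f"max_interval_cM: {summary.max_interval_cm:.4f}\n"
    )
    (outdir / "map_totals.txt").write_text(totals)
    return summary


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run all stages in order; identical config+seed ⇒ identical outputs."""
    outdir = Path(outdir)
    stage = "simulate"
    try:
        sim = stage_simulate(cfg, outdir)
        stage = "split"
        split = stage_split(cfg, outdir)
        stage = "populations"
        pops = stage_populations(cfg, outdir)
        stage = "linkage"
        linkage = stage_linkage(cfg, outdir, pops)
        stage = "report"
        summary = stage_report(cfg, outdir, linkage)
    except PipelineError:
        raise
    except Exception as err:  # pragma: no cover - defensive
        raise PipelineError(f"stage {stage!r} failed: {err}") from err
    save_config(cfg, outdir / "config.yaml")
    return {
        "simulation": sim,
        "split": split,
        "populations": pops,
        "linkage": linkage,
        "summary": summary,
    }


# ---------------------------------------------------------------------------
# truth-based evaluation helpers (simulation studies)
# ---------------------------------------------------------------------------


def evaluate_split(outdir: Path) -> float:
    """Fraction of individuals whose subpopulation matches the true father
    (best label permutation)."""
    truth = pd.read_csv(outdir / "truth_fathers.tsv", sep="\t", index_col=0)["father"]
    assign = pd.read_csv(outdir / "split_assignment.tsv", sep="\t", index_col=0)[
        "subpopulation"
    ]
    assign = assign.loc[truth.index]
    best = 0.0
    from itertools import permutations

    t_labels = sorted(truth.unique())
    a_labels = sorted(assign.unique())
    for perm in permutations(a_labels, min(len(a_labels), len(t_labels))):
        mapping = dict(zip(perm, t_labels))
        acc = float((assign.map(mapping) == truth).mean())
        best = max(best, acc)
    return best


def evaluate_maps(outdir: Path, maps, parent_col: str = "mother_homologs"):
    """Homolog membership accuracy, per-homolog order correlation and
    length recovery of fitted maps against the simulation truth."""
    from scipy.stats import spearmanr

    truth = pd.read_csv(outdir / "truth_markers.tsv", sep="\t").set_index("marker")
    rows, n_correct, n_scored = [], 0, 0
    tot_fit, tot_true = 0.0, 0.0
    for g in maps:
        sub = truth.loc[[m for m in g.markers if m in truth.index]]
        homolog = sub["chrom"].astype(str) + ":" + sub[parent_col].astype(str)
        single = sub[parent_col].astype(str).str.fullmatch(r"\d")
        if single.sum() == 0:
            continue
        maj = homolog[single].mode().iloc[0]
        n_correct += int((homolog[single] == maj).sum())
        n_scored += int(single.sum())
        true_pos = sub["pos_cM"].astype(float)
        rho = np.nan
        if len(sub) >= 4 and true_pos.nunique() > 2:
            fitted = pd.Series(g.positions, index=g.markers).loc[sub.index]
            rho = abs(spearmanr(fitted, true_pos).statistic)
        span = float(true_pos.max() - true_pos.min())
        tot_fit += g.length_cm
        tot_true += span
        rows.append(
            {"map": g.name, "n_markers": g.n_markers, "majority_homolog": maj,
             "order_rho": rho, "length_cM": g.length_cm, "true_span_cM": span}
        )
    per_map = pd.DataFrame(rows)
    return {
        "per_map": per_map,
        "membership_accuracy": n_correct / n_scored if n_scored else np.nan,
        "length_ratio": tot_fit / tot_true if tot_true else np.nan,
    }
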