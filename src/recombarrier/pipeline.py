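"""End-to-end orchestration: simulate (or load) -> analyze -> report.

A single global seed fans out to per-stage seeds at fixed offsets, so any
stage can be re-run in isolation and two runs with the same configuration
produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import genecontent, homoplasy, painting, phylo, regionscan, simdata, variants

log = logging.getLogger("recombarrier")

STAGE_SEEDS = {"painting": 11, "genecontent": 13, "regionscan": 17, "phylo": 19}

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Either a simulate block or explicit input paths (exactly one).

    Input paths: ``alignment`` (FASTA), ``gene_content`` (TSV),
    ``labels`` (TSV: genome, clade, population, ct) and optionally
    ``families`` (TSV annotations) and ``tree`` (Newick).
    """

    out_dir: str
    seed: int = 0
    simulate: simdata.SimulationConfig | None = None
    inputs: dict[str, str] | None = None
    window_snps: int = 10
    bootstrap: int = 100
    k_range: tuple[int, int] = (2, 10)
    scan_window: int = 10_000
    scan_step: int = 1_000
    scan_k_sd: float = 3.0
    divergence_ratio: float | None = None  # derived from divergences if None
    pan_permutations: int = 50
    region_bootstrap: int = 100
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of simulate block or input paths required")

    @classmethod
    def from_json(cls, path, out_dir=None, seed=None) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if raw.get("simulate") is not None:
            raw["simulate"] = simdata.SimulationConfig.from_dict(raw["simulate"])
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        if out_dir is not None:
            raw["out_dir"] = out_dir
        if seed is not None:
            raw["seed"] = seed
            if raw.get("simulate") is not None:
                raw["simulate"].seed = seed
        return cls(**raw)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def _derive_subclades(tree, clade_members: list[str]) -> dict[str, str]:
    """Label the two sides of the clade MRCA's first split as subclades.

    The tree is midpoint-rooted first so the clade MRCA is well defined on
    an unrooted inference tree."""
    tree = tree.clone(depth=1)
    tree.reroot_at_midpoint()
    tree.is_rooted = True
    taxa = [t for t in tree.taxon_namespace if t.label in clade_members]
    mrca = tree.mrca(taxa=taxa)
    children = mrca.child_nodes()
    out: dict[str, str] = {}
    member_set = set(clade_members)
    for side, child in enumerate(children):
        for leaf in child.leaf_iter():
            if leaf.taxon.label in member_set:
                out[leaf.taxon.label] = f"sub{side}"
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run variants -> phylo -> painting -> homoplasy -> genecontent ->
    regionscan, writing per-module files and one JSON report."""
    level = {"quiet": logging.WARNING, "info": logging.INFO,
             "debug": logging.DEBUG}[config.verbosity]
    logging.basicConfig(level=level, format="%(message)s")
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"seed": config.seed}
    stage = "setup"
    try:
        # ---------------- data ----------------
        stage = "data"
        t0 = time.time()
        if config.simulate is not None:
            aln, matrix, truth = simdata.simulate_dataset(config.simulate)
            labels = truth.labels
            simdata.emit_dataset(aln, matrix, truth, config.out_dir,
                                 config.simulate)
        else:
            paths = config.inputs
            aln = variants.read_alignment(paths["alignment"])
            matrix = genecontent.GeneContentMatrix.read_tsv(
                paths["gene_content"], paths.get("families")
            )
            labels = {}
            with open(paths["labels"]) as fh:
                header = fh.readline()
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    labels[parts[0]] = (parts[1], parts[2],
                                        parts[3] if len(parts) > 3 and parts[3]
                                        else None)
            if "labels" not in paths:
                raise KeyError("labels")
        missing = [g for g in aln.names if g not in labels]
        if missing:
            raise ValueError(f"labels file missing genomes: {missing}")
        log.info("data: %d genomes, %d sites, %d families (%.1fs)",
                 aln.n_genomes, aln.length, len(matrix.families),
                 time.time() - t0)

        # ---------------- variants ----------------
        stage = "variants"
        t0 = time.time()
        snps = variants.call_snps(aln)
        per_site, counts = variants.pairwise_divergence(aln)
        clade_of = {g: labels[g][0] for g in aln.names}
        between = [
            per_site.values[i, j]
            for i in range(aln.n_genomes)
            for j in range(i + 1, aln.n_genomes)
            if clade_of[aln.names[i]] != clade_of[aln.names[j]]
        ]
        report["variants"] = {
            "n_snps": snps.n_sites,
            "alignment_length": aln.length,
            "mean_between_clade_divergence_pct":
                100.0 * float(np.mean(between)) if between else None,
        }
        per_site.write_tsv(os.path.join(config.out_dir, "divergence.tsv"))
        variants.write_variants_tsv(snps, os.path.join(config.out_dir,
                                                       "snps.tsv"))
        log.info("variants: %d SNPs (%.1fs)", snps.n_sites, time.time() - t0)

        # ---------------- phylo ----------------
        stage = "phylo"
        t0 = time.time()
        nj = phylo.neighbor_joining(per_site)
        phylo.write_newick(nj, os.path.join(config.out_dir, "nj_tree.nwk"))
        report["phylo"] = {"method": "neighbor_joining",
                           "n_leaves": aln.n_genomes}
        log.info("phylo: NJ tree on %d leaves (%.1fs)", aln.n_genomes,
                 time.time() - t0)

        # ---------------- painting ----------------
        stage = "painting"
        t0 = time.time()
        pconf = painting.PaintingConfig(
            window_snps=config.window_snps,
            bootstrap=config.bootstrap,
            seed=config.seed + STAGE_SEEDS["painting"],
            k_range=config.k_range,
        )
        coancestry = painting.paint_genomes(snps, pconf)
        assignment = painting.cluster_coancestry(coancestry, pconf)
        confidence = painting.membership_confidence(snps, pconf, assignment)
        summary = painting.coancestry_summary(
            coancestry, {g: (labels[g][0], labels[g][1]) for g in aln.names}
        )
        coancestry.write_tsv(os.path.join(config.out_dir, "coancestry.tsv"))
        assignment.to_frame().to_csv(
            os.path.join(config.out_dir, "populations.tsv"), sep="\t",
            index=False)
        summary.to_csv(os.path.join(config.out_dir, "coancestry_summary.tsv"),
                       sep="\t", index=False)
        report["painting"] = {
            "K": assignment.K,
            "min_confidence": float(confidence.min()),
            "summary": _jsonify(summary.to_dict(orient="records")),
        }
        log.info("painting: K=%d, min confidence %.3f (%.1fs)", assignment.K,
                 confidence.min(), time.time() - t0)

        # ---------------- homoplasy ----------------
        stage = "homoplasy"
        t0 = time.time()
        clade_labels = sorted(set(clade_of.values()))
        subclades: dict[str, str] = {}
        focal_clade = None
        if len(clade_labels) >= 2:
            # deep-subclade structure is tested in the most diverse clade
            within_div = {}
            for c in clade_labels:
                members = [g for g in aln.names if clade_of[g] == c]
                if len(members) < 4:
                    continue
                idx = [aln.names.index(g) for g in members]
                within_div[c] = float(
                    np.mean(per_site.values[np.ix_(idx, idx)])
                )
            if within_div:
                focal_clade = max(within_div, key=within_div.get)
                members = [g for g in aln.names if clade_of[g] == focal_clade]
                subclades = _derive_subclades(nj, members)
        partition = homoplasy.CladePartition(clades=clade_of,
                                             subclades=subclades)
        sites = homoplasy.detect_homoplasies(snps, nj)
        hcounts = homoplasy.classify_homoplasies(sites, partition)
        homo_report = {
            "n_homoplasies": len(sites),
            "n_between": hcounts.n_between,
            "n_within_cross_subclade": hcounts.n_within,
            "n_other": hcounts.n_other,
            "tree_used": "neighbor_joining",
            "note": ("binomial barrier test is this package's formalisation "
                     "of the divergence-proportionality argument"),
        }
        if hcounts.n_between + hcounts.n_within > 0 and focal_clade:
            R = config.divergence_ratio
            if R is None:
                sub_members = [g for g in subclades]
                pairs = [
                    (i, j)
                    for i in range(aln.n_genomes)
                    for j in range(i + 1, aln.n_genomes)
                    if subclades.get(aln.names[i])
                    and subclades.get(aln.names[j])
                    and subclades[aln.names[i]] != subclades[aln.names[j]]
                ]
                cross_sub = float(np.mean([per_site.values[i, j]
                                           for i, j in pairs]))
                R = float(np.mean(between)) / cross_sub if cross_sub > 0 else None
            if R is not None and R > 0:
                test = homoplasy.barrier_test(hcounts.n_between,
                                              hcounts.n_within, R)
                homo_report["barrier_test"] = {
                    "R": test.divergence_ratio,
                    "null_proportion": test.null_proportion,
                    "p_value": test.p_value,
                    "direction": test.direction,
                }
        report["homoplasy"] = homo_report
        homoplasy.homoplasy_table(sites, partition).to_csv(
            os.path.join(config.out_dir, "homoplasies.tsv"), sep="\t",
            index=False)
        log.info("homoplasy: %d sites, %d between / %d cross-subclade (%.1fs)",
                 len(sites), hcounts.n_between, hcounts.n_within,
                 time.time() - t0)

        # ---------------- genecontent ----------------
        stage = "genecontent"
        t0 = time.time()
        pairs = genecontent.select_independent_pairs(nj)
        content_diffs = [genecontent.gene_content_distance(matrix, a, b)
                         for a, b in pairs]
        aa_diffs = [genecontent.amino_acid_distance(aln, a, b)
                    for a, b in pairs]
        gc_report: dict = {"n_independent_pairs": len(pairs)}
        try:
            fit = genecontent.fit_turnover(pairs, content_diffs, aa_diffs)
            gc_report["turnover"] = {
                "intercept": fit.intercept,
                "slope": fit.slope,
                "rate_ratio": fit.rate_ratio,
                "n_excluded": fit.n_excluded,
                "trend_rho": fit.trend_rho,
                "trend_p": fit.trend_p,
            }
        except ValueError as exc:
            gc_report["turnover"] = {"error": str(exc)}
        fluidity = genecontent.genomic_fluidity(matrix)
        curve = genecontent.pan_genome_curve(
            matrix, P=config.pan_permutations,
            seed=config.seed + STAGE_SEEDS["genecontent"])
        specific = genecontent.clade_specific_genes(matrix, clade_of)
        gc_report["fluidity_phi"] = fluidity.phi
        gc_report["pan_genome_tail_slope"] = curve.tail_slope
        gc_report["pan_genome_final"] = float(curve.means[-1])
        gc_report["clade_specific_counts"] = {
            f"{a}_not_{b}": len(fams) for (a, b), fams in specific.items()
        }
        report["genecontent"] = gc_report
        curve.to_frame().to_csv(os.path.join(config.out_dir,
                                             "pan_genome.tsv"),
                                sep="\t", index=False)
        log.info("genecontent: phi=%.3f, %d pairs (%.1fs)", fluidity.phi,
                 len(pairs), time.time() - t0)

        # ---------------- regionscan ----------------
        stage = "regionscan"
        t0 = time.time()
        scan = regionscan.snp_density_scan(snps, L=aln.length,
                                           window=config.scan_window,
                                           step=config.scan_step)
        regions = regionscan.detect_regions(scan, k_sd=config.scan_k_sd)
        scan.to_frame().to_csv(os.path.join(config.out_dir, "scan.tsv"),
                               sep="\t", index=False)
        rs_report: dict = {
            "n_regions": len(regions),
            "regions": [
                {"start_1based": r.report_coords()[0],
                 "end_1based": r.report_coords()[1],
                 "mean_density": r.mean_density}
                for r in regions
            ],
        }
        ct_labels = {g: labels[g][2] for g in aln.names}
        if regions and all(ct_labels.values()) and matrix.intervals:
            top = max(regions, key=lambda r: r.mean_density)
            try:
                conc = regionscan.ct_concordance(
                    matrix, top, ct_labels, nj,
                    bootstrap=config.region_bootstrap,
                    seed=config.seed + STAGE_SEEDS["regionscan"])
                rs_report["ct_concordance"] = {
                    "ari": conc.ari,
                    "n_region_families": len(conc.region_families),
                    "ct_monophyletic": _jsonify(conc.ct_monophyly),
                    "incongruent": conc.incongruent,
                }
                if conc.region_tree is not None:
                    phylo.write_newick(
                        conc.region_tree,
                        os.path.join(config.out_dir, "region_tree.nwk"))
                enr = regionscan.category_enrichment(matrix, top)
                rs_report["phage_enrichment"] = {
                    "in_region": enr.in_region_category,
                    "outside": enr.outside_category,
                    "odds_ratio": enr.odds_ratio,
                    "p_value": enr.p_value,
                }
            except ValueError as exc:
                rs_report["ct_concordance"] = {"error": str(exc)}
        report["regionscan"] = rs_report
        log.info("regionscan: %d region(s) (%.1fs)", len(regions),
                 time.time() - t0)

    except Exception as exc:
        with open(os.path.join(config.out_dir, "FAILED"), "w") as fh:
            fh.write(f"stage: {stage}\ncause: {exc}\n")
        raise PipelineError(stage, exc) from exc

    report_json = json.dumps(_jsonify(report), indent=2, sort_keys=True)
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        fh.write(report_json)
    return report
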