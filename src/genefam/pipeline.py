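"""End-to-end orchestration of the gene-family analysis.

One configuration drives the whole chain — simulate (or load) inputs,
identify the family, build the phylogeny with bootstrap, chain synteny
blocks and classify duplicates, estimate Ka/Ks and dates for duplicate
pairs, scan for miRNA target sites, and post-process expression — with
fixed-name TSV outputs and a machine-readable run manifest.  A
"table1 mode" reproduces the derived columns (ratio, selection, date)
of a printed Ka/Ks duplication table without any sequence data.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

import genefam
from genefam import expression as expr
from genefam import family, io, kaks, mirtarget, phylo, simulate, synteny

logger = logging.getLogger("genefam")


def bundled_mirna() -> str:
    """The bundled mature maize miR156 sequence (5'->3', RNA)."""
    path = importlib.resources.files("genefam.data").joinpath("mir156.fa")
    lines = path.read_text().splitlines()
    return "".join(l.strip() for l in lines if not l.startswith(">"))


def bundled_table1() -> pd.DataFrame:
    """Bundled printed (pair, Ka, Ks) values of the duplication table."""
    path = importlib.resources.files("genefam.data").joinpath("table1_kaks.tsv")
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def table1_mode(table: pd.DataFrame | None = None,
                lam: float = kaks.GRASS_LAMBDA) -> pd.DataFrame:
    """Derive ratio / selection / date columns from printed Ka and Ks."""
    if table is None:
        table = bundled_table1()
    return kaks.derive_table_columns(table, lam=lam)


@dataclass
class PipelineConfig:
    """Parameters of one full run; everything downstream is a pure
    function of this object."""

    out_dir: str = "genefam_run"
    seed: int = 0
    # synthetic fixture layout
    n_chromosomes: int = 3
    genes_per_chromosome: int = 30
    planted_blocks: list = field(default_factory=lambda: [
        (("chr1", "chr2"), 6, "+"), (("chr2", "chr3"), 5, "-")])
    planted_tandem_arrays: list = field(default_factory=lambda: [("chr1", 3, 1)])
    # stage parameters
    family_prefix: str = "FAM"
    bootstrap_reps: int = 200
    support_threshold: int = 50
    distance_model: str = "p"  # deeply diverged families saturate Poisson
    score_cutoff: float = 0.5
    min_anchors: int = 5
    max_gap: int = 25
    tandem_max_rank_gap: int = 10
    window_size: int = 150
    step_size: int = 9
    lam: float = kaks.GRASS_LAMBDA
    max_expectation: float = 3.0
    mirna: str | None = None
    n_tissues: int = 18
    utr_length: int = 120


def _stage(manifest: dict, name: str, **params) -> None:
    logger.info("stage=%s %s", name,
                " ".join(f"{k}={v}" for k, v in params.items()))
    manifest["stages"].append({"name": name, "params": params})


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic fixture; returns the manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "package": "genefam", "version": genefam.__version__,
        "seed": config.seed, "stages": [],
    }
    out = lambda name: os.path.join(config.out_dir, name)

    try:
        # ------------------------------------------------ simulate
        fixture = simulate.simulate_genomes(simulate.GenomeFixtureParams(
            n_chromosomes=config.n_chromosomes,
            genes_per_chromosome=config.genes_per_chromosome,
            planted_blocks=config.planted_blocks,
            planted_tandem_arrays=config.planted_tandem_arrays,
            seed=config.seed,
        ))
        mir_seq = config.mirna or bundled_mirna()
        rng = np.random.default_rng(config.seed + 1)
        fam_truth = list(dict.fromkeys(fixture.family_ids))
        by_id = {g.id: g for g in fixture.genes}
        for gid in fam_truth:
            by_id[gid].utr3 = simulate.random_cds(rng, config.utr_length // 3)
        n_cds = max(1, round(len(fam_truth) * 11 / 13))
        site_specs = []
        for i, gid in enumerate(fam_truth):
            region = "CDS" if i < n_cds else "3UTR"
            site_specs.append(simulate.PlantedSite(gid, region, n_mismatches=i % 3))
        keep = lambda g: bool(family.scan_sbp_domain(g.protein, family.ScanConfig()))
        _, mir_truth = simulate.plant_mir_sites(
            fixture.genes, mir_seq, site_specs, seed=config.seed + 2, preserve=keep)
        fixture.write(out("fixture"))
        io.write_tsv(mir_truth, out("fixture/truth_mir_sites.tsv"))
        _stage(manifest, "simulate", seed=config.seed,
               n_genes=len(fixture.genes), n_family_truth=len(fam_truth))

        # ------------------------------------------------ identify
        fam_genes = family.identify_family(
            fixture.genes, prefix=config.family_prefix)
        stats = family.family_stats_table(fam_genes)
        io.write_tsv(stats, out("family_stats.tsv"))
        _stage(manifest, "identify", family_size=len(fam_genes))

        # ------------------------------------------------ phylogeny
        msa = phylo.msa_proteins({g.id: g.protein for g in fam_genes})
        tree = phylo.bootstrap_support(
            msa, n_reps=config.bootstrap_reps, seed=config.seed,
            model=config.distance_model)
        with open(out("tree.nwk"), "w") as fh:
            fh.write(tree.to_newick() + "\n")
        groups = phylo.assign_subfamilies(tree, config.support_threshold)
        io.write_tsv(pd.DataFrame(
            sorted(groups.items()), columns=["gene_id", "subfamily"]),
            out("subfamilies.tsv"))
        n_groups = len({v for v in groups.values() if v != "ungrouped"})
        _stage(manifest, "phylogeny", bootstrap_reps=config.bootstrap_reps,
               n_subfamilies=n_groups)

        # ------------------------------------------------ synteny + duplicates
        anchors = synteny.find_homolog_pairs(fixture.genes, config.score_cutoff)
        blocks = synteny.chain_anchors(
            anchors, min_anchors=config.min_anchors, max_gap=config.max_gap)
        fam_source = {g.source_id or g.id for g in fam_genes}
        fam_pairs = [a for a in anchors
                     if a.gene_a.id in fam_source and a.gene_b.id in fam_source]
        calls = synteny.classify_duplicates(
            fam_pairs, blocks, config.tandem_max_rank_gap)
        summary = synteny.summarize_duplication(calls, sorted(fam_source))
        io.write_tsv(synteny.blocks_table(blocks), out("blocks.tsv"))
        io.write_tsv(synteny.calls_table(calls), out("duplication_calls.tsv"))
        io.write_tsv(pd.DataFrame([asdict(summary)]), out("duplication_summary.tsv"))
        _stage(manifest, "synteny", n_blocks=len(blocks),
               pct_segmental=summary.pct_segmental)

        # ------------------------------------------------ Ka/Ks + dating
        rows, window_rows = [], []
        for call in calls:
            ga, gb = by_id[call.gene_a], by_id[call.gene_b]
            aln = kaks.protein_guided_codon_align(ga.cds, gb.cds, ga.id, gb.id)
            est = kaks.estimate_kaks(aln, lam=config.lam)
            rows.append({
                "pair": f"{call.gene_a}-{call.gene_b}",
                "ka": round(est.ka, 3), "ks": round(est.ks, 3),
                "ratio": round(est.ratio, 3) if est.ratio is not None else "NA",
                "purifying": "Yes" if est.selection_class == "purifying" else "No",
                "date_mya": round(est.date_mya, 2),
                "duplicate_type": call.type,
            })
            if len(aln) >= config.window_size:
                for w in kaks.sliding_window_kaks(
                        aln, config.window_size, config.step_size):
                    window_rows.append({
                        "pair": f"{call.gene_a}-{call.gene_b}",
                        "start_bp": w.start_bp, "end_bp": w.end_bp,
                        "ka": w.ka, "ks": w.ks,
                        "ratio": w.ratio if w.ratio is not None else "NA",
                    })
        io.write_tsv(pd.DataFrame(rows, columns=[
            "pair", "ka", "ks", "ratio", "purifying", "date_mya",
            "duplicate_type"]), out("kaks_pairs.tsv"))
        io.write_tsv(pd.DataFrame(window_rows, columns=[
            "pair", "start_bp", "end_bp", "ka", "ks", "ratio"]),
            out("kaks_windows.tsv"))
        _stage(manifest, "kaks", n_pairs=len(rows), lam=config.lam)

        # ------------------------------------------------ miRNA targets
        query = mirtarget.MirQuery(mir_seq)
        fam_transcripts = [by_id[g] for g in fam_truth]
        sites = mirtarget.scan_targets(
            query, fam_transcripts, config.max_expectation)
        io.write_tsv(mirtarget.sites_table(sites), out("mir_sites.tsv"))
        with open(out("mir_alignments.txt"), "w") as fh:
            for s in sites:
                fh.write(f"{s.gene_id} ({s.region}, E={s.expectation})\n")
                fh.write(s.alignment + "\n\n")
        _stage(manifest, "mir_target",
               n_target_genes=len({s.gene_id for s in sites}))

        # ------------------------------------------------ expression
        fpkm, expr_truth = simulate.simulate_expression(
            simulate.ExpressionFixtureParams(
                n_genes=len(fam_genes), n_tissues=config.n_tissues,
                seed=config.seed + 3),
            gene_ids=[g.id for g in fam_genes])
        io.write_tsv(fpkm.reset_index(), out("fpkm.tsv"))
        io.write_tsv(expr.log_transform(fpkm).round(4).reset_index(),
                     out("expression_log2.tsv"))
        classes = expr.classify_breadth(fpkm)
        io.write_tsv(classes.rename_axis("gene_id").reset_index(),
                     out("expression_classes.tsv"))
        ct = simulate.simulate_ct_table(simulate.CtSimParams(
            genes=[g.id for g in fam_genes[:4]],
            samples=["control", "drought"], calibrator="control",
            fold_changes={(fam_genes[0].id, "drought"): 4.0},
            seed=config.seed + 4))
        io.write_tsv(ct, out("qpcr_ct.tsv"))
        rel = expr.delta_delta_ct(ct, ref_gene="RefActin", calibrator="control")
        io.write_tsv(rel, out("qpcr_relative.tsv"))
        _stage(manifest, "expression", n_genes=len(fam_genes),
               n_tissues=config.n_tissues)
    except Exception as exc:
        stage = manifest["stages"][-1]["name"] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    manifest["n_stages_completed"] = len(manifest["stages"])
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
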