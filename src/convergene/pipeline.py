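"""End-to-end orchestration: bundle in, result tables and manifest out.

Runs marker dependency filtering, marker set enrichment, key driver
analysis, rare/common variant convergence and the pathway report over a
study bundle directory, writing each stage's tables under the output
directory plus a ``manifest.json`` echoing every analysis parameter in
force.  All randomness flows from one pipeline seed, so identical inputs
and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

from . import convergence as cvg
from . import io, kda, mdf, msea, report, synthdata


def load_bundle(bundle_dir) -> dict:
    """Read every input file of a study bundle into memory."""
    b = Path(bundle_dir)
    maps = {t: io.read_map(p, t)
            for t, p in io.find_tissue_files(b, "map", ".tsv").items()}
    modules = {t: {mid: sorted(genes) for mid, genes in io.read_gmt(p).items()}
               for t, p in io.find_tissue_files(b, "modules", ".gmt").items()}
    networks = {g: io.read_network(p, group=g)
                for g, p in io.find_tissue_files(b, "network",
                                                 ".edges.tsv").items()}
    bundle = {
        "gwas": io.read_gwas(b / "gwas.tsv"),
        "ld": io.read_ld(b / "ld.tsv"),
        "genes": io.read_genes(b / "genes.tsv"),
        "maps": maps,
        "modules": modules,
        "networks": networks,
        "rare_catalog": io.read_rare_catalog(b / "rare_catalog.tsv"),
    }
    if (b / "pathways.gmt").exists():
        bundle["pathways"] = io.read_gmt(b / "pathways.gmt")
    if (b / "systems.tsv").exists():
        bundle["systems"] = io.read_systems(b / "systems.tsv")
    return bundle


def run_pipeline(bundle_dir, out_dir, seed: int = 0,
                 mdf_config: mdf.MdfConfig | None = None,
                 msea_config: msea.EnrichmentConfig | None = None,
                 kda_config: kda.KdaConfig | None = None,
                 conv_config: cvg.ConvergenceConfig | None = None,
                 n_export_subnetworks: int = 2) -> dict:
    """Run every stage over a bundle; returns the in-memory results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_bundle(bundle_dir)

    mdf_config = mdf_config or mdf.MdfConfig()
    msea_config = msea_config or msea.EnrichmentConfig(seed=seed)
    kda_config = kda_config or kda.KdaConfig(seed=seed)
    conv_config = conv_config or cvg.ConvergenceConfig()

    mdf_res = mdf.run_mdf(bundle["gwas"], bundle["maps"], bundle["ld"],
                          bundle["genes"], mdf_config)
    mdf.write_mdf(mdf_res, out / "mdf")

    msea_res = msea.run_msea(mdf_res.gene_markers, mdf_res.retained,
                             bundle["modules"], msea_config)
    msea.write_msea(msea_res, out / "msea")

    disease = msea.significant_genes(msea_res.results, bundle["modules"],
                                     msea_config.fdr_threshold)
    kda_res = conv_res = None
    network_nodes = set().union(*(set(n.nodes())
                                  for n in bundle["networks"].values()))
    if disease & network_nodes:
        kda_res = kda.run_kda(bundle["networks"],
                              {g: disease for g in bundle["networks"]},
                              kda_config)
        kda.write_kda(kda_res, out / "kda")

        common = cvg.common_variant_genes(mdf_res.gene_markers,
                                          mdf_res.retained,
                                          conv_config.common_p_threshold)
        nodes_by_group = {g: set(net.nodes())
                          for g, net in bundle["networks"].items()}
        conv_res = cvg.run_convergence(kda_res.subnetworks, nodes_by_group,
                                       bundle["rare_catalog"], common,
                                       conv_config)
        cvg.write_convergence(conv_res, out / "convergence")

    report_res = None
    if "pathways" in bundle and "systems" in bundle:
        background = set(bundle["genes"]["GENE"])
        report_res = report.run_report(
            msea_res.results, bundle["modules"], bundle["pathways"],
            bundle["systems"], background,
            fdr_threshold=msea_config.fdr_threshold)
        report.write_report(report_res, out / "report")
        if kda_res is not None:
            _export_top_subnetworks(bundle, kda_res, mdf_res, conv_config,
                                    out / "report", n_export_subnetworks)

    manifest = {
        "seed": seed,
        "mdf": asdict(mdf_config),
        "msea": {**asdict(msea_config), "quantile_start": 0.5},
        "kda": asdict(kda_config),
        "convergence": asdict(conv_config),
        "bundle_dir": str(bundle_dir),
        "n_tissues": len(bundle["maps"]),
        "n_network_groups": len(bundle["networks"]),
    }
    io.write_json(manifest, out / "manifest.json")
    return {"mdf": mdf_res, "msea": msea_res, "kda": kda_res,
            "convergence": conv_res, "report": report_res,
            "manifest": manifest}


def _export_top_subnetworks(bundle, kda_res, mdf_res, conv_config, out_dir,
                            n_export: int) -> None:
    rare = dict(zip(bundle["rare_catalog"]["GENE"],
                    bundle["rare_catalog"]["LEVEL"]))
    strength = cvg.gene_association_strength(mdf_res.gene_markers,
                                             mdf_res.retained)
    top = kda_res.results.head(n_export)
    for kd_gene, group in zip(top["KD"], top["GROUP"]):
        subnet = kda_res.subnetworks[(group, kd_gene)]
        nodes, edges = report.export_subnetwork(
            bundle["networks"][group], kd_gene, subnet, rare, strength)
        nodes.to_csv(Path(out_dir) / f"subnet.{kd_gene}.nodes.tsv", sep="\t",
                     index=False)
        edges.to_csv(Path(out_dir) / f"subnet.{kd_gene}.edges.tsv", sep="\t",
                     index=False)


def simulate_and_run(config: synthdata.SyntheticConfig, work_dir,
                     seed: int | None = None, **kwargs) -> dict:
    """Generate a synthetic bundle, then run the full pipeline over it."""
    work = Path(work_dir)
    if seed is not None:
        config = synthdata.with_overrides(config, seed=seed)
    truth = synthdata.generate_study(config, work / "bundle")
    results = run_pipeline(work / "bundle", work / "results",
                           seed=config.seed, **kwargs)
    results["truth"] = truth
    return results
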