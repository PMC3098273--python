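"""Pipeline orchestration: screen -> encode -> distance -> ordinate/cluster
-> assign types -> PPTase motifs -> trait statistics -> GC report.

The stages are thin compositions of the library modules; every stage writes
a TSV (or newick/PHYLIP) artifact into the run directory together with an
echo of the effective configuration, so a rerun with the same configuration
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import composition, model, pptase, similarity, simulate, traits

log = logging.getLogger("seclipid")


@dataclass
class RunConfig:
    """Defaults mirror the analysis settings: e-value cut 1e-30, 25 NMDS
    starts with minimum stress 0.01, 10,000 CAP permutations, |rho| >= 0.4
    biplot threshold and the n >= 5 formal-test gate."""

    out_dir: str = "seclipid_run"
    seed: int = 0
    evalue_max: float = 1e-30
    distance_mode: str = "raw"
    nmds_k: int = 2
    nmds_starts: int = 25
    nmds_min_stress: float = 0.01
    nmds_max_iter: int = 300
    assign_threshold: float = 0.2
    permanova_permutations: int = 999
    cap_permutations: int = 10000
    cap_m: int | str = "auto"
    biplot_min_rho: float = 0.4
    min_group_n: int = 5
    clusters_tsv: str | None = None
    hits_tsv: str | None = None
    pptase_fasta: str | None = None
    trait_values_tsv: str | None = None
    trait_groups_tsv: str | None = None
    region_fasta: str | None = None
    background_fasta: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _echo_config(config: RunConfig, out: Path) -> None:
    payload = dataclasses.asdict(config)
    payload["config_hash"] = config.config_hash()
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for which the configuration names an input, plus
    the catalog summary; returns a manifest of written artifacts."""
    out = Path(config.out_dir)
    started = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    try:
        _echo_config(config, out)
        catalog = model.load_catalog()

        summary = model.catalog_summary(catalog)
        srows = [{"type_letter": t, "n_members": n}
                 for t, n in sorted(summary["per_type_counts"].items())]
        sdf = pd.DataFrame(srows)
        sdf.to_csv(out / "catalog_summary.tsv", sep="\t", index=False)
        with open(out / "catalog_counts.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            for key in ("n_types", "n_genomes", "n_genera"):
                fh.write(f"{key}\t{summary[key]}\n")
        manifest["catalog_summary"] = str(out / "catalog_summary.tsv")
        log.info("catalog: %d Types, %d genomes, %d genera",
                 summary["n_types"], summary["n_genomes"], summary["n_genera"])

        if config.hits_tsv:
            hits = model.read_hit_table(config.hits_tsv)
            kept = model.filter_hits(hits, config.evalue_max)
            model.write_hit_table(kept, out / "screened_hits.tsv")
            manifest["screen"] = str(out / "screened_hits.tsv")
            log.info("screen: %d/%d hits pass e-value <= %g",
                     len(kept), len(hits), config.evalue_max)

        clusters = None
        if config.clusters_tsv:
            clusters = model.read_clusters_tsv(config.clusters_tsv)
        if clusters:
            enc = pd.DataFrame(
                [{"cluster_id": c.cluster_id,
                  "architecture": model.encode_architecture(c),
                  "n_domains": c.n_domains}
                 for c in clusters])
            enc.to_csv(out / "architectures.tsv", sep="\t", index=False)
            manifest["encode"] = str(out / "architectures.tsv")

            if len(clusters) >= 2:
                dist = similarity.pairwise_distances(clusters,
                                                     mode=config.distance_mode)
                dist.write_phylip(out / "distances.phylip")
                manifest["distance"] = str(out / "distances.phylip")

                ord_res = similarity.nmds(dist, k=config.nmds_k,
                                          n_starts=config.nmds_starts,
                                          min_stress=config.nmds_min_stress,
                                          max_iter=config.nmds_max_iter,
                                          seed=config.seed)
                ord_res.write_tsv(out / "nmds_coordinates.tsv")
                manifest["ordinate"] = str(out / "nmds_coordinates.tsv")
                log.info("NMDS stress = %.4f", ord_res.stress)

                dend = similarity.average_linkage(dist)
                with open(out / "dendrogram.nwk", "w") as fh:
                    fh.write(dend.to_newick() + "\n")
                manifest["cluster"] = str(out / "dendrogram.nwk")

            arows = []
            for c in clusters:
                a = similarity.assign_type(c, catalog,
                                           threshold=config.assign_threshold)
                arows.append({"cluster_id": a.cluster_id,
                              "best_type": a.best_type,
                              "distance_to_best": f"{a.distance_to_best:.6f}",
                              "runner_up": a.runner_up or "NA",
                              "margin": f"{a.margin:.6f}"})
            pd.DataFrame(arows).to_csv(out / "type_assignments.tsv",
                                       sep="\t", index=False)
            manifest["classify"] = str(out / "type_assignments.tsv")

        if config.pptase_fasta:
            calls = pptase.classify_fasta(config.pptase_fasta)
            calls.to_csv(out / "pptase_calls.tsv", sep="\t", index=False)
            manifest["pptase"] = str(out / "pptase_calls.tsv")

        if config.trait_values_tsv and config.trait_groups_tsv:
            tm = traits.TraitMatrix.read_tsv(config.trait_values_tsv,
                                             config.trait_groups_tsv)
            tm = tm.filter_by_group_size(config.min_group_n)
            dist = traits.bray_curtis_matrix(tm)
            res = traits.permanova(dist, tm.groups,
                                   n_permutations=config.permanova_permutations,
                                   seed=config.seed)
            with open(out / "permanova.tsv", "w") as fh:
                fh.write("statistic\tvalue\n")
                fh.write(f"pseudo_F\t{res.pseudo_F:.6f}\n")
                fh.write(f"p_value\t{res.p_value:.6f}\n")
                fh.write(f"n_permutations\t{res.n_permutations}\n")
            pw = traits.pairwise_permanova(
                dist, tm.groups, n_permutations=config.permanova_permutations,
                seed=config.seed)
            pw.to_csv(out / "pairwise_permanova.tsv", sep="\t", index=False)
            cap_res = traits.cap(dist, tm.groups, m=config.cap_m,
                                 n_permutations=config.cap_permutations,
                                 seed=config.seed)
            crow = {"m": cap_res.m,
                    "allocation_success_overall": cap_res.allocation_success_overall,
                    "chance_threshold": cap_res.chance_threshold,
                    "permutation_p": cap_res.permutation_p}
            crow.update({f"success_{g}": v for g, v
                         in sorted(cap_res.allocation_success_per_group.items())})
            pd.DataFrame([crow]).to_csv(out / "cap_summary.tsv", sep="\t",
                                        index=False)
            biplot = traits.trait_biplot(cap_res, tm,
                                         min_abs_rho=config.biplot_min_rho)
            biplot.to_csv(out / "cap_biplot.tsv", sep="\t", index=False)
            manifest["traits"] = str(out / "cap_summary.tsv")

        if config.region_fasta and config.background_fasta:
            rep = composition.compare_gc_fasta(config.region_fasta,
                                               config.background_fasta)
            rep.to_csv(out / "gc_report.tsv", sep="\t", index=False)
            manifest["gc"] = str(out / "gc_report.tsv")
    except Exception:
        if started:
            shutil.rmtree(out, ignore_errors=True)
        raise
    return manifest


def simulate_bundle(out_dir: str | Path, seed: int = 0, n_per_type: int = 10,
                    perturb_p: float = 0.05, theta: float = 0.8) -> dict:
    """Emit a complete synthetic input bundle with ground-truth sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = model.load_catalog()
    letters = ["A", "B", "F", "I", "L", "R"]

    clusters, truth = [], []
    for letter in letters:
        for c in simulate.gen_clusters_from_type(catalog.types[letter],
                                                 n_per_type, perturb_p, seed):
            truth.append({"cluster_id": c.cluster_id, "source_type": letter})
            clusters.append(c)
    model.write_clusters_tsv(clusters, out / "clusters.tsv")
    simulate.write_ground_truth(truth, out / "clusters.truth.tsv")

    records, ptruth = {}, []
    for i, label in enumerate(["PUFA_like"] * 5 + ["PKS_NRPS_like"] * 5):
        seq, planted = simulate.gen_pptase(label, seed=seed + i)
        name = f"pptase_{label}_{i:02d}"
        records[name] = seq
        ptruth.append({"sequence_id": name, "class_label": label,
                       **{f"{m}_start": p for m, p in planted.items()}})
    simulate.write_pptase_fasta(records, out / "pptases.fasta")
    simulate.write_ground_truth(ptruth, out / "pptases.truth.tsv")

    tm = simulate.gen_trait_matrix({letter: 8 for letter in letters},
                                   theta=theta, seed=seed)
    tm.write_tsv(out / "traits.tsv", out / "trait_groups.tsv")

    genome, (start, end) = simulate.gen_genome_with_cluster(
        100_000, 0.39, 20_000, 0.46, seed=seed)
    with open(out / "genome.fasta", "w") as fh:
        fh.write(">synthetic_genome\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i:i + 70] + "\n")
    with open(out / "region.fasta", "w") as fh:
        fh.write(f">planted_cluster {start}..{end}\n")
        region = genome[start - 1:end]
        for i in range(0, len(region), 70):
            fh.write(region[i:i + 70] + "\n")
    simulate.write_ground_truth(
        [{"region_id": "planted_cluster", "start": start, "end": end,
          "target_region_gc": 0.46, "target_genome_gc": 0.39}],
        out / "gc.truth.tsv")
    return {"out_dir": str(out), "n_clusters": len(clusters)}
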