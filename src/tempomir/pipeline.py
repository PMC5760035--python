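"""End-to-end orchestration of the synthetic study analysis.

One call runs, per brain region: outlier removal -> detection filtering
-> quantile normalization -> moderated-t differential expression with
the role/time threshold scheme -> confidence-filtered temporal pairing
(six datasets) -> temporal-profile clustering with validation-measure
model selection -> knowledgebase network construction, growth, merging,
hub and critical-gene calls, and cell-type enrichment.  Every threshold
applied is recorded in the resolved-config file next to the outputs,
and a manifest JSON carries per-stage counts.  Identical config + seed
gives byte-identical manifests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, diffexpr, io, network, pairing, preprocess
from .datasets import ExpressionDataset, GroundTruth
from .simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_interactions,
    simulate_knowledgebase,
)


@dataclass
class PipelineConfig:
    """Resolved thresholds and the synthetic-study configuration."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    detection_p: float = preprocess.DETECTION_P_THRESHOLD
    detection_fraction: float = preprocess.DETECTION_FRACTION
    mirna_alpha: float = 0.05
    mrna_alpha: float = 0.05
    context_score: float = pairing.CONTEXT_SCORE_CUTOFF
    network_size: int = network.NETWORK_SIZE
    n_networks: int = network.N_NETWORKS
    grow_n: int = network.GROW_N
    hub_top_k: int = network.HUB_TOP_K
    k_range: tuple[int, ...] = clustering.DEFAULT_K_RANGE

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["k_range"] = list(self.k_range)
        return d


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline; write outputs under ``out_dir``; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ds_mirna, ds_mrna, truth = simulate_expression(config.sim)
    records = simulate_interactions(config.sim, truth)
    kb, cell_lists = simulate_knowledgebase(config.sim, truth)

    io.write_interactions(records, out / "interactions.tsv")
    io.write_kb(kb, out / "knowledgebase.tsv")
    io.write_gmt(cell_lists, out / "cell_types.gmt")
    io.write_ground_truth(truth, out / "ground_truth.json")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    passing = pairing.confidence_filter(records, context_cutoff=config.context_score)
    kb_net = network.inject_interaction_edges(kb, [(r.mirna_id, r.gene_id) for r in passing])
    family_map = {m: kb_net.nodes[m].get("family_id", "") for m in kb_net.nodes}
    universe_genes = {m for m in kb.nodes if kb.nodes[m].get("type") == "gene"}

    manifest: dict = {"regions": {}, "seed": config.sim.seed}
    for region in config.sim.regions:
        rdir = out / region
        rdir.mkdir(exist_ok=True)
        rman: dict = {}

        # ---- preprocess ------------------------------------------------
        mirna_clean, mirna_report = preprocess.preprocess_region(
            ds_mirna, region, p_thresh=config.detection_p, frac=config.detection_fraction
        )
        mrna_clean, mrna_report = preprocess.preprocess_region(
            ds_mrna, region, p_thresh=config.detection_p, frac=config.detection_fraction
        )
        io.write_json(
            {"mirna": mirna_report.to_dict(), "mrna": mrna_report.to_dict()},
            rdir / "preprocess_report.json",
        )
        rman["mirna_probes_detected"] = mirna_clean.n_probes
        rman["mrna_probes_detected"] = mrna_clean.n_probes
        rman["outliers_removed"] = sorted(
            s for s, _ in mirna_report.outliers_removed + mrna_report.outliers_removed
        )

        # ---- differential expression ------------------------------------
        times = tuple(config.sim.times_h)
        mirna_calls = diffexpr.run_contrasts(
            mirna_clean, region, role=diffexpr.MIRNA, times_h=times, alpha=config.mirna_alpha
        )
        mrna_calls = diffexpr.run_contrasts(
            mrna_clean, region, role=diffexpr.MRNA, times_h=times, alpha=config.mrna_alpha
        )
        cols = ["probe_id", "annotation", "region", "time_h", "beta", "fc_signed", "t_mod", "p", "fdr", "is_de"]
        mirna_calls[cols].to_csv(rdir / "de_mirna.tsv", sep="\t", index=False, float_format="%.6g")
        mrna_calls[cols].to_csv(rdir / "de_mrna.tsv", sep="\t", index=False, float_format="%.6g")
        de_mirnas = diffexpr.de_sets_by_time(mirna_calls)
        de_targets = diffexpr.de_sets_by_time(mrna_calls)
        rman["de_mirnas_by_time"] = {str(t): len(s) for t, s in sorted(de_mirnas.items())}
        rman["de_mrnas_by_time"] = {str(t): len(s) for t, s in sorted(de_targets.items())}

        # ---- temporal pairing -------------------------------------------
        paired = pairing.temporal_pairing(
            de_mirnas, de_targets, passing, region=region, prefiltered=True
        )
        rman["paired_datasets"] = {}
        for psd in paired:
            fname = psd.name.replace("/", "_") + ".tsv"
            psd.to_frame().to_csv(rdir / fname, sep="\t", index=False)
            rman["paired_datasets"][psd.name] = {
                "n_pairs": len(psd.pairs),
                "n_mirnas": len(psd.mirnas),
                "n_targets": len(psd.targets),
            }
        tgt_by_mirna_time = {
            psd.target_time_h: psd.targets for psd in paired if psd.mirna_time_h == 0
        }
        ov = pairing.overlap_proportion(
            tgt_by_mirna_time.get(0, set()), tgt_by_mirna_time.get(8, set())
        )
        rman["overlap_0h_targets_0h_vs_8h_pct"] = None if ov is None else round(ov, 2)

        # ---- clustering ---------------------------------------------------
        de_any = sorted(set().union(*de_mirnas.values()) if de_mirnas else set())
        profiles = (
            mirna_calls.pivot_table(index="annotation", columns="time_h", values="beta")
            .loc[de_any]
            .sort_index()
        )
        if len(profiles) >= 4:
            scaled = clustering.scale_profiles(profiles)
            k_max = min(max(config.k_range), len(scaled) - 1)
            k_range = [k for k in config.k_range if k <= k_max]
            sol = clustering.select_solution(scaled, k_range=k_range)
            memb = pd.DataFrame(
                {"mirna": sol.assignment.index, "cluster": sol.assignment.to_numpy()}
            )
            memb.to_csv(rdir / "clusters.tsv", sep="\t", index=False)
            clustering.cluster_mean_profiles(scaled, sol.assignment).to_csv(
                rdir / "cluster_mean_profiles.tsv", sep="\t", float_format="%.6g"
            )
            rman["clustering"] = {
                "algorithm": sol.algorithm,
                "k": sol.k,
                "connectivity": round(sol.connectivity, 6),
                "dunn": round(sol.dunn, 6),
                "silhouette": round(sol.silhouette, 6),
            }
        else:
            warnings.warn(f"region {region}: too few DE miRNAs to cluster")
            rman["clustering"] = None

        # ---- networks -----------------------------------------------------
        nets_by_dataset: dict[str, list[network.Network]] = {}
        for psd in paired:
            if psd.target_time_h != 120 or not psd.pairs:
                continue
            nets = network.build_networks(
                psd.molecules,
                kb_net,
                size=config.network_size,
                n_networks=config.n_networks,
                dataset_name=psd.name,
            )
            if nets:
                grown = network.grow(nets[0], sorted(de_targets.get(0, set())), kb_net, n=config.grow_n)
                grown = network.grow(grown, sorted(de_targets.get(8, set())), kb_net, n=config.grow_n)
                nets_by_dataset[psd.name] = nets
                rman.setdefault("networks", {})[psd.name] = [
                    {
                        "rank": n.rank,
                        "score": round(n.score, 4),
                        "n_molecules": len(n.molecules),
                        "n_focus": len(n.focus),
                    }
                    for n in nets
                ] + [{"grown_top_network_size": len(grown.molecules)}]

        io.write_json(
            {
                name: [
                    {"rank": n.rank, "score": n.score, "molecules": n.molecules, "focus": sorted(n.focus)}
                    for n in nets
                ]
                for name, nets in nets_by_dataset.items()
            },
            rdir / "networks.json",
        )

        name0 = "0hDEmiR/120hDEtargets"
        name8 = "8hDEmiR/120hDEtargets"
        if name0 in nets_by_dataset and name8 in nets_by_dataset:
            ds_mols = set().union(
                *(psd.molecules for psd in paired if psd.name in (name0, name8))
            )
            critical = network.merge_and_critical_genes(
                nets_by_dataset[name0],
                nets_by_dataset[name8],
                de_targets.get(120, set()),
                ds_mols,
                family_map,
            )
            crit_rows = mrna_calls[
                (mrna_calls["time_h"] == 120) & (mrna_calls["annotation"].isin(critical))
            ][["annotation", "fc_signed", "p"]].rename(columns={"annotation": "gene"})
            crit_rows.sort_values("gene").to_csv(
                rdir / "critical_genes.tsv", sep="\t", index=False, float_format="%.4g"
            )
            rman["critical_genes"] = sorted(critical)
        else:
            rman["critical_genes"] = []

        hubs = network.find_hubs(nets_by_dataset, kb_net, top_k_degree=config.hub_top_k)
        pd.DataFrame(
            [
                {
                    "molecule": h.molecule,
                    "n_datasets": h.n_datasets,
                    "supporting": ";".join(f"{d}|rank{r}|deg{g}" for d, r, g in h.supporting_networks),
                }
                for h in hubs
            ]
        ).to_csv(rdir / "hubs.tsv", sep="\t", index=False)
        rman["hubs"] = sorted(h.molecule for h in hubs)

        # ---- cell-type enrichment -----------------------------------------
        dataset_genes = set().union(*(psd.targets for psd in paired)) if paired else set()
        enr = {}
        for name, genes in cell_lists.items():
            odds, p = network.gene_set_enrichment(dataset_genes, set(genes), universe_genes)
            import math as _math

            enr[name] = {
                "odds_ratio": round(odds, 4) if _math.isfinite(odds) else None,
                "p": round(p, 6),
            }
        io.write_json(enr, rdir / "cell_type_enrichment.json")
        rman["cell_type_enrichment_p"] = {k: v["p"] for k, v in sorted(enr.items())}

        manifest["regions"][region] = rman

    io.write_json(manifest, out / "manifest.json")
    return manifest
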