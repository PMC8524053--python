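"""End-to-end orchestration of the four-compartment network analysis.

``run_all`` drives, per compartment: prevalence filtering (8 of 12
replicates), the optional 0.01%-of-total abundance cut, relative-abundance
conversion, RMT threshold selection, and construction/summary of the three
network kinds (bacterial, fungal, and the merged bacterial-fungal
association network), followed by module detection, Zi-Pi roles and the
keystone report; optionally gene-panel enrichment and Mantel tests.  Every
output is a plain tab-separated table plus GraphML, and a JSON manifest
records parameters, seeds and per-file checksums so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import abundance as ab
from .mantel import bray_curtis, euclidean_env, mantel as mantel_test
from . import modules as md
from . import network as nw
from . import panels as pn
from . import rmt
from . import synth

COMPARTMENTS = ab.COMPARTMENTS


@dataclass
class RunConfig:
    """Parameters of a full run; the printed defaults are the study constants."""

    output_dir: str = "rhizonet_out"
    compartments: tuple[str, ...] = COMPARTMENTS
    # stage parameters
    prevalence_min_detected: int = 8
    prevalence_of_replicates: int = 12
    abundance_cut_enabled: bool = True
    abundance_cut_fraction: float = 1e-4
    st_min: float = 0.30
    st_max: float = 0.99
    st_step: float = 0.01
    module_min_size: int = 15
    bh_alpha: float = 0.05
    mantel_permutations: int = 999
    seed: int = 0
    # inputs; when None, synthetic data are generated from the seed
    bacterial_table: str | None = None
    fungal_table: str | None = None
    sample_metadata: str | None = None
    gene_counts: str | None = None
    env_table: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.compartments) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown compartment labels: {sorted(unknown)}")
        if self.prevalence_min_detected < 0 or self.module_min_size < 0:
            raise ValueError("thresholds must be nonnegative")


def _stage_seed(seed: int, label: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed and a stage label."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_or_generate(config: RunConfig) -> dict:
    """One merged (bacteria+fungi) counts table per compartment."""
    tables = {}
    if config.bacterial_table and config.fungal_table and config.sample_metadata:
        bact = ab.read_abundance(config.bacterial_table, config.sample_metadata, "bacteria")
        fungi = ab.read_abundance(config.fungal_table, config.sample_metadata, "fungi")
        merged = ab.merge_domains(bact, fungi)
        for comp in config.compartments:
            tables[comp] = merged.select_compartment(comp)
    else:
        # Endosphere-like mixing in Endo; progressively more domain-sorted
        # modules toward the bulk soil.
        mixes = {"Non": 0.15, "Rhi": 0.25, "Epi": 0.35, "Endo": 0.5}
        for comp in config.compartments:
            scenario = synth.SyntheticScenario(
                modules=tuple((20, mixes[comp]) for _ in range(6)),
                compartment=comp,
                seed=_stage_seed(config.seed, f"community:{comp}"),
            )
            tables[comp], _ = synth.generate_community(scenario)
    return tables


def analyze_compartment(table: ab.AbundanceTable, config: RunConfig, compartment: str) -> dict:
    """Filter, threshold, build and summarize the three networks of one compartment."""
    results = {}
    filtered = ab.prevalence_filter(
        table, config.prevalence_min_detected, config.prevalence_of_replicates
    )
    if config.abundance_cut_enabled:
        filtered = ab.abundance_cut(filtered, config.abundance_cut_fraction)
    for kind in nw.NETWORK_KINDS:
        if kind == "bacterial":
            sub = filtered.select_domain("bacteria")
        elif kind == "fungal":
            sub = filtered.select_domain("fungi")
        else:
            sub = filtered
        rel = ab.to_relative_abundance(sub)
        corr = rmt.correlation_matrix(rel)
        scan = rmt.select_threshold(corr, config.st_min, config.st_max, config.st_step)
        net = nw.build_network(corr, scan.selected_st, rel.domain, kind, compartment)
        summary = nw.summarize(net)
        entry = {"scan": scan, "network": net, "summary": summary}
        if net.n_edges > 0:
            partition = md.detect_modules(net)
            summary.modularity = partition.modularity
            roles = md.classify_roles(md.zi_pi(net, partition))
            entry.update(
                partition=partition,
                roles=roles,
                keystones=md.keystone_report(roles, domains=rel.domain),
                composition=md.module_composition(partition, rel.domain, config.module_min_size),
                modular=md.is_modular(partition.modularity),
            )
        results[kind] = entry
    return results


def run_all(config: RunConfig) -> dict:
    """Run the whole analysis; write outputs and return the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages": {},
        "checksums": {},
    }
    t0 = time.time()
    tables = _load_or_generate(config)

    for comp in config.compartments:
        results = analyze_compartment(tables[comp], config, comp)
        for kind, entry in results.items():
            stem = f"{comp}_{kind}"
            entry["scan"].records.to_csv(out / f"{stem}_stscan.tsv", sep="\t", index=False)
            nw.write_edge_list(entry["network"], out / f"{stem}_edges.tsv")
            nw.write_graphml(entry["network"], out / f"{stem}.graphml")
            if "roles" in entry:
                entry["roles"].to_csv(out / f"{stem}_roles.tsv", sep="\t")
                entry["keystones"].to_csv(out / f"{stem}_keystones.tsv", sep="\t")
                entry["composition"].to_csv(out / f"{stem}_modules.tsv", sep="\t")
            summary = entry["summary"].as_dict()
            summary.update(
                st=entry["network"].st,
                modular=bool(entry.get("modular", False)),
                intra_inter_edges=nw.edge_domain_counts(entry["network"]) if kind == "BFA" else None,
            )
            manifest["stages"][stem] = summary

    # gene panels
    gene_seed = _stage_seed(config.seed, "genes")
    if config.gene_counts:
        gene_table = pd.read_csv(config.gene_counts, sep="\t", index_col=0, comment="#")
    else:
        panels = pn.load_panels()
        genes = tuple(
            (gene, 900 + 50 * i, 1.0)
            for i, gene in enumerate(g for p in panels.values() for g in p.genes)
        )
        gene_table = synth.generate_gene_counts(
            synth.GeneScenario(
                genes=genes,
                enriched={"lasI": ("Endo", 4.0), "rhlI": ("Endo", 6.0), "cobG": ("Endo", 4.0), "cbiT": ("Non", 3.0)},
                seed=gene_seed,
            )
        )
    lengths = gene_table["length_bp"]
    counts = gene_table.drop(columns="length_bp")
    tpm = pn.tpm_normalize(counts, lengths)
    tpm.to_csv(out / "gene_tpm.tsv", sep="\t")
    totals = counts.sum(axis=0)
    enrichment = []
    for name, panel in pn.load_panels().items():
        res = pn.pairwise_enrichment(counts, totals, panel, config.bh_alpha)
        res.insert(0, "panel", name)
        enrichment.append(res)
    enrichment = pd.concat(enrichment, ignore_index=True)
    enrichment.to_csv(out / "panel_enrichment.tsv", sep="\t", index=False)
    manifest["stages"]["panels"] = {
        "n_tests": int(len(enrichment)),
        "n_significant": int(enrichment["significant"].sum()),
    }

    # Mantel: community vs environment, per compartment
    mantel_rows = []
    for comp in config.compartments:
        rel = ab.to_relative_abundance(tables[comp])
        if config.env_table:
            env = pd.read_csv(config.env_table, sep="\t", index_col=0).loc[rel.sample_ids]
        else:
            env = synth.generate_env_matrix(
                rel.n_samples, 0.5, _stage_seed(config.seed, f"community:{comp}")
            )
            env.index = rel.sample_ids
        r, p = mantel_test(
            bray_curtis(rel),
            euclidean_env(env),
            config.mantel_permutations,
            _stage_seed(config.seed, f"mantel:{comp}"),
        )
        mantel_rows.append((comp, r, p))
    mantel_df = pd.DataFrame(mantel_rows, columns=["compartment", "mantel_r", "p"])
    mantel_df.to_csv(out / "mantel.tsv", sep="\t", index=False)
    manifest["stages"]["mantel"] = mantel_df.to_dict(orient="records")

    for path in sorted(out.glob("*.tsv")):
        manifest["checksums"][path.name] = _checksum(path)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
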