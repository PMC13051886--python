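"""End-to-end pipeline runs: configuration, manifests, and the two arms.

The integrative arm runs miRNA differential expression, the regulated
transcriptome's DE, binding-site enrichment with activity inference, the
DE-miRNA intersection, network assembly, and the qPCR validation arithmetic.
The single-cell arm runs gating, QC, normalization, HVG selection, batch
alignment, SNN-Louvain clustering, pseudobulk NB-QL DE, preranked GSEA on the
signed -log10 p ranking, AUC program scoring, and frequency comparison.
Every run writes its tables plus a manifest (config, seeds, input hashes,
per-stage counts) so outputs are traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mircell import diffexpr, enrich, io, programs, qpcr, scpipe, siteact, synthio

__all__ = ["PipelineConfig", "PipelineError", "validate_config",
           "run_integrative_arm", "run_singlecell_arm"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Effective configuration of a pipeline run (defaults = study constants)."""

    seed: int = 1
    out_dir: str = "mircell_run"
    # miRNA DE stage
    top_k_mirnas: int = 400
    mirna_q_max: float = 0.05
    mirna_min_abs_fc: float = 1.0
    n_sv: int | str = "auto"
    # gene DE stage
    gene_q_max: float = 0.1
    gene_min_abs_fc: float = 1.5
    intensity_threshold: float = 6.0
    # enrichment
    min_set_size: int = 8
    enrich_adj_p: float = 0.1
    gsea_n_perm: int = 1000
    # binding sites
    site_adj_p: float = 0.05
    # single cell
    qc_nmads: float = 3.0
    n_hvgs: int = 5000
    knn_k: int = 5
    louvain_resolution: float = 1.0
    n_pcs: int = 50
    min_cells_per_donor: int = 10
    # programs
    treg_threshold: float = 0.17
    tc17_threshold: float = 0.22
    top_markers: int = 250
    aucell_top_fraction: float = 0.05
    # synthetic inputs
    sim: dict = field(default_factory=dict)

    def sim_config(self, **overrides) -> synthio.SimConfig:
        kwargs = {"seed": self.seed, **self.sim, **overrides}
        return synthio.SimConfig(**kwargs)


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Parse a YAML config, filling defaults and rejecting unknown keys."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    if cfg.seed is None:
        raise ValueError("seed is mandatory for stochastic stages")
    return cfg


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv().encode()
    ).hexdigest()[:16]


def _write_manifest(out: Path, cfg: PipelineConfig, hashes: dict, counts: dict) -> None:
    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "input_hashes": hashes,
        "stage_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_integrative_arm(cfg: PipelineConfig) -> Path:
    """Bulk integrative arm on synthetic inputs; returns the artifact directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashes: dict = {}
    counts: dict = {}

    stage = "simulate"
    try:
        sim = cfg.sim_config()
        mirna_m, mirna_truth = synthio.simulate_mirna_matrix(sim)
        gene_m, sites, inter, gene_truth = synthio.simulate_regulated_transcriptome(
            sim, mirna_truth, allow_empty_regulon=True
        )
        hashes["mirna_matrix"] = _hash_frame(mirna_m.values)
        hashes["gene_matrix"] = _hash_frame(gene_m.values)
        hashes["sites"] = _hash_frame(sites)
        hashes["interactions"] = _hash_frame(inter)

        stage = "diffexpr_mirna"
        top = diffexpr.filter_top_expressed(
            mirna_m, min(cfg.top_k_mirnas, mirna_m.n_features)
        )
        sv = diffexpr.estimate_surrogate_variables(top, n_sv=cfg.n_sv, seed=cfg.seed)
        de_mirna = diffexpr.moderated_t_test(top, covariates=sv if sv.shape[1] else None)
        io.write_de_result(de_mirna, out / "de_mirna.tsv")
        mirna_calls = diffexpr.call_de(
            de_mirna, q_max=cfg.mirna_q_max, min_abs_fc=cfg.mirna_min_abs_fc
        )
        counts["de_mirnas"] = {"up": len(mirna_calls.up), "down": len(mirna_calls.down)}

        stage = "diffexpr_genes"
        gene_f = diffexpr.filter_low_intensity(gene_m, cfg.intensity_threshold)
        de_gene = diffexpr.moderated_t_test(gene_f)
        io.write_de_result(de_gene, out / "de_genes.tsv")
        gene_calls = diffexpr.call_de(
            de_gene, q_max=cfg.gene_q_max, min_abs_fc=cfg.gene_min_abs_fc
        )
        counts["de_genes"] = {"up": len(gene_calls.up), "down": len(gene_calls.down)}

        stage = "siteact"
        rows = siteact.site_enrichment(
            sites, gene_calls.up, gene_calls.down,
            list(gene_f.values.index), alpha=cfg.site_adj_p,
        )
        de_dirs = {m: "Upregulated" for m in mirna_calls.up}
        de_dirs |= {m: "Downregulated" for m in mirna_calls.down}
        influential = siteact.intersect_influential(rows, de_dirs)
        io.write_site_rows(influential, out / "influential_sites.tsv")
        counts["influential_motifs"] = int(len(influential))
        inter_f = siteact.filter_interactions_by_confidence(inter)
        net = siteact.build_network(influential, inter_f, de_gene,
                                    q_max=cfg.gene_q_max,
                                    min_abs_fc=cfg.gene_min_abs_fc)
        io.write_network(net, out / "network_edges.tsv")
        counts["network"] = {"nodes": net.number_of_nodes(),
                             "edges": net.number_of_edges()}

        stage = "recovery"
        planted = {m for m, e in mirna_truth.de_features if e < 0}
        recovered = set()
        for _, row in influential.iterrows():
            if row["estimated_activity"] == "Downregulated":
                recovered |= set(row["mirnas"]) & planted
        recovery = {
            "planted_down_mirnas": sorted(planted),
            "recovered": sorted(recovered),
            "sensitivity": len(recovered) / len(planted) if planted else None,
        }
        (out / "recovery.json").write_text(json.dumps(recovery, indent=2))

        stage = "qpcr"
        folds = {"hsa-miR-A": 4.0, "hsa-miR-B": 0.5}
        ct = synthio.simulate_qpcr(sim, folds)
        hashes["ct_table"] = _hash_frame(ct)
        qrows = []
        for assay in folds:
            rel = qpcr.ddct(ct, target=assay, reference="hsa-miR-HK")
            test = qpcr.group_test(rel["dct"], rel["group"])
            eff = qpcr.fit_efficiency(ct, assay=assay)
            qrows.append({"assay": assay,
                          "mean_case_fold": float(rel.loc[rel["group"] == "case", "fold"].mean()),
                          "welch_p": test["p"],
                          "efficiency_pct": eff.efficiency_percent})
        pd.DataFrame(qrows).to_csv(out / "qpcr_validation.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    _write_manifest(out, cfg, hashes, counts)
    return out


def run_singlecell_arm(cfg: PipelineConfig) -> Path:
    """Single-cell arm on synthetic inputs; returns the artifact directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashes: dict = {}
    counts: dict = {}
    stage = "simulate"
    try:
        sim = cfg.sim_config()
        adata, truth = synthio.simulate_single_cell(sim)
        hashes["counts"] = hashlib.sha256(
            np.ascontiguousarray(adata.X).tobytes()
        ).hexdigest()[:16]
        counts["cells_in"] = adata.n_obs

        stage = "gate"
        adata = scpipe.gate_cd8(adata)
        counts["cells_gated"] = adata.n_obs
        stage = "qc"
        adata = scpipe.qc_filter(adata, nmads=cfg.qc_nmads)
        counts["cells_qc"] = adata.n_obs
        stage = "normalize"
        adata = scpipe.normalize_log(adata)
        stage = "hvg"
        hvgs = scpipe.select_hvgs(adata, n=min(cfg.n_hvgs, adata.n_vars))
        stage = "correct"
        emb = scpipe.correct_batch(
            adata, batch_key="donor", hvgs=hvgs, n_pcs=cfg.n_pcs, seed=cfg.seed
        )
        stage = "cluster"
        labels = scpipe.snn_louvain(
            emb, k=cfg.knn_k, seed=cfg.seed, resolution=cfg.louvain_resolution
        )
        adata.obs["cluster"] = pd.Categorical(labels.astype(str))
        counts["n_clusters"] = int(len(set(labels)))
        adata.obs[["donor", "group", "cluster"]].to_csv(out / "clusters.tsv", sep="\t")

        stage = "pseudobulk_de"
        pb = scpipe.pseudobulk(adata, min_cells=cfg.min_cells_per_donor)
        pb.factors = scpipe.tmm_factors(pb)
        de = scpipe.nb_ql_test(pb)
        de.to_csv(out / "pseudobulk_de.tsv", sep="\t")
        counts["pseudobulk_degs_q10"] = int((de["q"] < 0.1).sum())

        stage = "gsea"
        score = pd.Series(
            -np.log10(np.clip(de["p"], 1e-300, 1.0)) * np.sign(de["log2FC"]),
            index=de.index,
        )
        sets = enrich.FeatureSetCollection(
            {f"{name}_signature": list(genes)
             for name, genes in sim.sc_signatures.items()}
        )
        gsea = enrich.gsea_preranked(
            score, sets, n_perm=cfg.gsea_n_perm, seed=cfg.seed
        )
        io.write_enrichment(gsea.table, out / "gsea.tsv")

        stage = "score"
        freq_rows = {}
        for name, threshold in (
            ("Tc17", cfg.tc17_threshold),
            ("Treg", cfg.treg_threshold),
        ):
            sig = sim.sc_signatures.get(name)
            if not sig:
                continue
            auc = programs.aucell_score(
                adata, sig, top_fraction=cfg.aucell_top_fraction, seed=cfg.seed
            )
            positive = programs.classify_cells(auc, threshold)
            fractions, test = programs.compare_frequencies(
                positive, adata.obs, min_cells=cfg.min_cells_per_donor
            )
            fractions.to_csv(out / f"fractions_{name}.tsv", sep="\t")
            freq_rows[name] = {
                "case_mean": float(
                    fractions.loc[fractions["group"] == "case", "fraction"].mean()
                ),
                "control_mean": float(
                    fractions.loc[fractions["group"] == "control", "fraction"].mean()
                ),
                "welch_p": test["p"],
            }
        (out / "frequencies.json").write_text(json.dumps(freq_rows, indent=2))
        counts["frequencies"] = freq_rows
    except Exception as exc:  # noqa: BLE001
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    _write_manifest(out, cfg, hashes, counts)
    return out
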