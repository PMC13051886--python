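"""Seeded synthetic-data generators with planted ground truth.

Every generator draws all randomness from one `numpy` Generator derived from
the mandatory config seed (plus a fixed per-generator stream id), so identical
configs give byte-identical outputs.  The bulk layers use Gaussian noise on the
log2 scale (microarray-like intensities); the single-cell layer draws
negative-binomial counts with log-normal gene means and contains rare
signature-bearing subpopulations at controlled per-group frequencies; the qPCR
layer emits dilution-series standards with a controlled slope and group Ct
offsets equal to -log2(fold) at 100% amplification efficiency.

The returned :class:`SyntheticTruth` records exactly what was planted (DE
features with signed log2 effects, miRNA-target regulon, per-cell program
labels, per-donor program frequencies, per-batch feature shifts) so that
downstream recovery can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from mircell.diffexpr import ExpressionMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_mirna_matrix",
    "simulate_regulated_transcriptome",
    "simulate_single_cell",
    "simulate_qpcr",
]

# default program signatures: curated CD8-Treg and Tc17 gene lists
CD8_TREG_SIGNATURE = [
    "FOXP3", "IKZF2", "PRDM1", "CTLA4", "PDCD1", "LAG3", "IL10",
    "TGFB1", "IL2RA", "ENTPD1", "NT5E", "IKZF4", "GZMB", "ENPP1",
]
TC17_SIGNATURE = ["RORC", "BATF", "STAT3", "IL17A", "IL17F", "IL22", "IL23R", "KLRB1"]

_GATING_GENES = ["CD3G", "CD8A", "CD8B"]
_N_MITO_GENES = 10

# internal stream ids so the four generators decorrelate under a shared seed
_STREAM_MIRNA, _STREAM_GENES, _STREAM_SC, _STREAM_QPCR = 11, 13, 17, 19


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators.

    de_features: (feature id, true log2 effect in cases) pairs.
    regulon: (mirna, target gene, suppression strength >= 0) triples.
    cell_labels: per-cell true program in {none, Tc17, Treg}.
    donor_frequencies: per-donor realized fraction per program.
    batch_effects: per-batch per-feature additive shift.
    """

    de_features: list[tuple[str, float]] = field(default_factory=list)
    regulon: list[tuple[str, str, float]] = field(default_factory=list)
    cell_labels: pd.Series | None = None
    donor_frequencies: pd.DataFrame | None = None
    batch_effects: pd.DataFrame | None = None

    def validate_against(self, feature_ids: Sequence[str]) -> None:
        ids = set(feature_ids)
        for f, _ in self.de_features:
            if f not in ids:
                raise ValueError(f"truth feature {f} missing from matrix")
        for _, _, s in self.regulon:
            if not np.isfinite(s) or s < 0:
                raise ValueError("suppression strengths must be finite and >= 0")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study's default conditions.

    Bulk miRNA layer: ``n_features`` x 2*``n_samples_per_group`` log2-normal
    matrix with ``n_de`` planted features shifted by ``effect_size`` (signed,
    log2 units) in cases, additive per-batch shifts of sd ``batch_sd`` on a
    ``batch_affected_fraction`` of features, and iid noise ``noise_sd``.

    Regulated transcriptome: ``n_genes`` universe; each planted down-regulated
    miRNA suppresses ``targets_per_mirna`` genes with strength ``suppression``
    (targets shift up by suppression*|miRNA effect| in cases).

    Single cell: ``n_donors`` per group, ``cells_per_donor`` cells, NB counts
    with dispersion ``nb_dispersion`` and log-normal gene means centred on
    ``nb_mean``; program frequencies per group in ``program_frequencies``;
    signature genes multiplied by ``signature_fold`` in labeled cells.

    qPCR: per-assay standards with ``qpcr_slope`` per decade of dilution and
    Ct noise ``qpcr_noise_sd``; ``qpcr_n_per_group`` samples per group.
    """

    seed: int
    # bulk miRNA layer
    n_features: int = 400
    n_samples_per_group: int = 10
    n_de: int = 20
    effect_size: float = 1.0
    batch_count: int = 1
    batch_sd: float = 0.0
    batch_affected_fraction: float = 0.5
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    # regulated transcriptome layer
    n_genes: int = 4000
    targets_per_mirna: int = 60
    suppression: float = 1.0
    background_motif_density: float = 0.02
    n_decoy_motifs: int = 20
    n_decoy_edges: int = 200
    # single-cell layer
    n_donors: int = 12
    cells_per_donor: int = 400
    n_sc_genes: int = 1000
    nb_mean: float = 0.5
    nb_dispersion: float = 0.3
    program_frequencies: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "control": {"Tc17": 0.02, "Treg": 0.02},
            "case": {"Tc17": 0.04, "Treg": 0.04},
        }
    )
    signature_fold: float = 4.0
    sc_signatures: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "Tc17": list(TC17_SIGNATURE),
            "Treg": list(CD8_TREG_SIGNATURE),
        }
    )
    sc_gene_names: Sequence[str] | None = None
    # qPCR layer
    qpcr_n_per_group: int = 10
    qpcr_replicates: int = 3
    qpcr_noise_sd: float = 0.2
    qpcr_slope: float = -3.3219
    qpcr_standards_noise_sd: float = 0.0
    qpcr_dilutions: Sequence[float] = (1.0, 1e-1, 1e-2, 1e-3, 1e-4)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory; no implicit randomness")
        for name in (
            "n_features", "n_samples_per_group", "batch_count", "n_genes",
            "targets_per_mirna", "n_donors", "cells_per_donor", "n_sc_genes",
            "qpcr_n_per_group", "qpcr_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_de < 0 or self.n_de > self.n_features:
            raise ValueError("n_de must lie in [0, n_features]")
        for sd in (self.noise_sd, self.batch_sd, self.qpcr_noise_sd):
            if sd < 0:
                raise ValueError("noise sds must be >= 0")
        if self.suppression < 0:
            raise ValueError("suppression must be >= 0")
        for grp, freqs in self.program_frequencies.items():
            tot = sum(freqs.values())
            if any(f < 0 for f in freqs.values()) or tot > 1:
                raise ValueError(
                    f"program frequencies for group {grp} must be >= 0, sum <= 1"
                )


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def _sample_frame(cfg: SimConfig) -> pd.DataFrame:
    names, groups, batches = [], [], []
    # batches cycle within each group so group and batch stay identifiable
    for g in ("case", "control"):
        for i in range(cfg.n_samples_per_group):
            names.append(f"{g}_{i+1:02d}")
            groups.append(g)
            batches.append(f"batch{i % cfg.batch_count + 1}")
    return pd.DataFrame(
        {"group": groups, "batch": batches,
         "donor": [f"donor_{n}" for n in names]},
        index=pd.Index(names, name="sample"),
    )


def simulate_mirna_matrix(cfg: SimConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-group log2 miRNA matrix with planted DE features and batch shifts."""
    rng = _rng(cfg, _STREAM_MIRNA)
    features = [f"miR-{i+1:04d}" for i in range(cfg.n_features)]
    samples = _sample_frame(cfg)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_features)
    Y = baseline[:, None] + rng.normal(
        0.0, cfg.noise_sd, (cfg.n_features, len(samples))
    )
    de_idx = rng.choice(cfg.n_features, size=cfg.n_de, replace=False)
    case_mask = (samples["group"] == "case").to_numpy()
    for i in de_idx:
        Y[i, case_mask] += cfg.effect_size
    batch_effects = None
    if cfg.batch_count > 1 and cfg.batch_sd > 0:
        n_aff = int(round(cfg.batch_affected_fraction * cfg.n_features))
        affected = rng.choice(cfg.n_features, size=n_aff, replace=False)
        shifts = np.zeros((cfg.batch_count, cfg.n_features))
        shifts[:, affected] = rng.normal(0, cfg.batch_sd, (cfg.batch_count, n_aff))
        batch_names = [f"batch{b+1}" for b in range(cfg.batch_count)]
        for b, bname in enumerate(batch_names):
            cols = (samples["batch"] == bname).to_numpy()
            Y[:, cols] += shifts[b][:, None]
        batch_effects = pd.DataFrame(shifts, index=batch_names, columns=features)
    truth = SyntheticTruth(
        de_features=[(features[i], float(cfg.effect_size)) for i in sorted(de_idx)],
        batch_effects=batch_effects,
    )
    m = ExpressionMatrix(
        pd.DataFrame(Y, index=pd.Index(features, name="feature"),
                     columns=samples.index),
        samples,
    )
    truth.validate_against(m.values.index)
    return m, truth


_MOTIF_ALPHABET = np.array(list("ACGU"))


def _random_motif(rng: np.random.Generator) -> str:
    return "".join(rng.choice(_MOTIF_ALPHABET, size=7))


def simulate_regulated_transcriptome(
    cfg: SimConfig,
    mirna_truth: SyntheticTruth,
    allow_empty_regulon: bool = False,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Gene matrix where targets of planted down-regulated miRNAs shift up.

    Each down-regulated miRNA (negative planted effect) gets a disjoint set of
    ``targets_per_mirna`` target genes whose case samples gain
    ``suppression * |miRNA effect|`` log2 units.  The binding-site table
    contains the regulator's 7-mer motif in every target gene plus background
    motif decoration in non-targets; the interaction table lists all planted
    edges as ``validated`` plus random decoy edges as ``predicted``.
    """
    rng = _rng(cfg, _STREAM_GENES)
    down_mirnas = [(f, e) for f, e in mirna_truth.de_features if e < 0]
    if not down_mirnas and not allow_empty_regulon:
        raise ValueError(
            "no down-regulated miRNAs in truth; pass allow_empty_regulon=True "
            "to simulate a null transcriptome"
        )
    genes = [f"G{i+1:05d}" for i in range(cfg.n_genes)]
    samples = _sample_frame(cfg)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    Y = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, len(samples)))
    case_mask = (samples["group"] == "case").to_numpy()

    needed = len(down_mirnas) * cfg.targets_per_mirna
    if needed > cfg.n_genes:
        raise ValueError("not enough genes for the requested regulon")
    target_pool = rng.choice(cfg.n_genes, size=needed, replace=False)
    regulon: list[tuple[str, str, float]] = []
    site_rows: list[tuple[str, str, str, int]] = []
    motif_of: dict[str, str] = {}
    for k, (mirna, effect) in enumerate(down_mirnas):
        motif = _random_motif(rng)
        while motif in motif_of.values():
            motif = _random_motif(rng)
        motif_of[mirna] = motif
        t_idx = target_pool[k * cfg.targets_per_mirna : (k + 1) * cfg.targets_per_mirna]
        shift = cfg.suppression * abs(effect)
        for gi in t_idx:
            Y[gi, case_mask] += shift
            regulon.append((mirna, genes[gi], float(cfg.suppression)))
            site_rows.append((motif, mirna, genes[gi], int(rng.integers(1, 4))))
    target_set = {g for _, g, _ in regulon}

    # background decoration: each regulator motif appears in non-target genes
    # at the configured density
    for mirna, motif in motif_of.items():
        hits = rng.random(cfg.n_genes) < cfg.background_motif_density
        for gi in np.nonzero(hits)[0]:
            if genes[gi] not in target_set:
                site_rows.append((motif, mirna, genes[gi], int(rng.integers(1, 3))))
    # decoy motifs belonging to non-DE miRNAs
    de_ids = {f for f, _ in mirna_truth.de_features}
    for k in range(cfg.n_decoy_motifs):
        mirna = f"miR-decoy-{k+1:03d}"
        if mirna in de_ids:  # pragma: no cover - decoy namespace is disjoint
            continue
        motif = _random_motif(rng)
        hits = rng.random(cfg.n_genes) < cfg.background_motif_density
        for gi in np.nonzero(hits)[0]:
            site_rows.append((motif, mirna, genes[gi], int(rng.integers(1, 3))))

    sites = pd.DataFrame(site_rows, columns=["motif", "mirna", "gene", "n_sites"])
    sites = sites.drop_duplicates(subset=["motif", "mirna", "gene"])

    inter_rows = [
        (mirna, gene, "validated", "synthetic-validated", "very high")
        for mirna, gene, _ in regulon
    ]
    conf_classes = np.array(["very high", "high", "medium", "low"])
    for _ in range(cfg.n_decoy_edges):
        mirna = f"miR-decoy-{int(rng.integers(1, cfg.n_decoy_motifs + 1)):03d}"
        gene = genes[int(rng.integers(cfg.n_genes))]
        inter_rows.append(
            (mirna, gene, "predicted", "synthetic-predicted",
             str(rng.choice(conf_classes)))
        )
    interactions = pd.DataFrame(
        inter_rows, columns=["mirna", "gene", "evidence", "source", "confidence"]
    ).drop_duplicates(subset=["mirna", "gene", "source"])

    truth = SyntheticTruth(
        de_features=[
            (genes[gi], cfg.suppression * abs(down_mirnas[k][1]))
            for k, (_, _) in enumerate(down_mirnas)
            for gi in target_pool[k * cfg.targets_per_mirna : (k + 1) * cfg.targets_per_mirna]
        ],
        regulon=regulon,
    )
    m = ExpressionMatrix(
        pd.DataFrame(Y, index=pd.Index(genes, name="feature"), columns=samples.index),
        samples,
    )
    truth.validate_against(m.values.index)
    return m, sites, interactions, truth


def _sc_gene_universe(cfg: SimConfig) -> list[str]:
    sig_genes: list[str] = []
    for gl in cfg.sc_signatures.values():
        sig_genes.extend(gl)
    if cfg.sc_gene_names is not None:
        universe = list(cfg.sc_gene_names)
        missing = [g for g in sig_genes if g not in universe]
        if missing:
            raise ValueError(f"signature genes absent from gene universe: {missing}")
        return universe
    mito = [f"MT-G{i+1}" for i in range(_N_MITO_GENES)]
    fixed = list(dict.fromkeys(sig_genes)) + _GATING_GENES + mito
    n_filler = cfg.n_sc_genes - len(fixed)
    if n_filler < 0:
        raise ValueError("n_sc_genes too small for signatures + markers")
    return fixed + [f"GENE{i+1:05d}" for i in range(n_filler)]


def simulate_single_cell(cfg: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Multi-donor NB count matrix with rare planted Tc17/Treg subpopulations.

    Returns an AnnData (cells x genes, raw counts in ``X``) with ``donor``,
    ``group`` and ``true_program`` in ``.obs`` and a mitochondrial flag in
    ``.var``.  Gene means are log-normal around ``nb_mean``; the CD3G/CD8A/CD8B
    gating markers are highly expressed in every cell (the cells are CD8 T
    cells); labeled cells have their program's signature genes multiplied by
    ``signature_fold``.
    """
    rng = _rng(cfg, _STREAM_SC)
    genes = _sc_gene_universe(cfg)
    n_genes = len(genes)
    gene_means = np.exp(rng.normal(np.log(cfg.nb_mean), 1.0, n_genes))
    means_by_name = dict(zip(genes, gene_means))
    for g in _GATING_GENES:
        means_by_name[g] = 8.0
    for g in genes:
        if g.startswith("MT-"):
            means_by_name[g] = 3.0
    # moderate signature baseline: program-positive cells (signature_fold x)
    # then place most signature genes in the top-ranked slice, the premise
    # under which fixed AUC thresholds separate the score distribution
    for gl in cfg.sc_signatures.values():
        for g in gl:
            means_by_name[g] = 1.5
    base_means = np.array([means_by_name[g] for g in genes])

    programs = list(cfg.sc_signatures.keys())
    sig_idx = {p: [genes.index(g) for g in cfg.sc_signatures[p]] for p in programs}

    obs_rows, counts_blocks, labels = [], [], []
    freq_records = []
    for group in ("case", "control"):
        freqs = cfg.program_frequencies.get(group, {})
        probs = [freqs.get(p, 0.0) for p in programs]
        probs.append(1.0 - sum(probs))
        for d in range(cfg.n_donors):
            donor = f"{group}_donor{d+1:02d}"
            draws = rng.choice(len(probs), size=cfg.cells_per_donor, p=probs)
            cell_programs = [
                programs[k] if k < len(programs) else "none" for k in draws
            ]
            mu = np.tile(base_means, (cfg.cells_per_donor, 1))
            for ci, prog in enumerate(cell_programs):
                if prog != "none":
                    mu[ci, sig_idx[prog]] *= cfg.signature_fold
            size_factor = np.exp(rng.normal(0.0, 0.3, cfg.cells_per_donor))
            mu *= size_factor[:, None]
            r = 1.0 / cfg.nb_dispersion
            p_nb = r / (r + mu)
            counts = rng.negative_binomial(r, p_nb)
            counts_blocks.append(counts)
            labels.extend(cell_programs)
            for ci in range(cfg.cells_per_donor):
                obs_rows.append((f"{donor}_c{ci+1:04d}", donor, group))
            realized = pd.Series(cell_programs).value_counts(normalize=True)
            freq_records.append(
                {"donor": donor, "group": group,
                 **{p: float(realized.get(p, 0.0)) for p in programs}}
            )
    X = np.vstack(counts_blocks)
    obs = pd.DataFrame(
        obs_rows, columns=["cell", "donor", "group"]
    ).set_index("cell")
    obs["true_program"] = labels
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mito"] = [g.startswith("MT-") for g in genes]
    adata = ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)
    truth = SyntheticTruth(
        cell_labels=obs["true_program"].copy(),
        donor_frequencies=pd.DataFrame(freq_records).set_index("donor"),
    )
    return adata, truth


def simulate_qpcr(
    cfg: SimConfig,
    fold_changes: Mapping[str, float],
    reference_assay: str = "hsa-miR-HK",
) -> pd.DataFrame:
    """Ct table with planted case/control folds plus dilution-series standards.

    At 100% amplification efficiency a planted fold f appears as a case-group
    Ct offset of -log2(f).  The housekeeping/reference assay is generated with
    zero group effect.  Standards follow
    Ct = intercept + slope * log10(dilution) + noise.
    """
    if any(f <= 0 for f in fold_changes.values()):
        raise ValueError("fold changes must be > 0")
    rng = _rng(cfg, _STREAM_QPCR)
    assays = dict(fold_changes)
    assays.setdefault(reference_assay, 1.0)
    rows = []
    base_ct = {a: float(rng.uniform(20.0, 28.0)) for a in assays}
    for group in ("case", "control"):
        for i in range(cfg.qpcr_n_per_group):
            sample = f"{group}_{i+1:02d}"
            # shared per-sample loading offset, cancelled by the reference
            loading = float(rng.normal(0.0, 0.3))
            for assay, fold in assays.items():
                shift = -np.log2(fold) if (group == "case" and assay != reference_assay) else 0.0
                for rep in range(cfg.qpcr_replicates):
                    ct = (base_ct[assay] + loading + shift
                          + float(rng.normal(0.0, cfg.qpcr_noise_sd)))
                    rows.append((sample, group, assay, rep + 1, ct, np.nan))
    for assay in assays:
        for dil in cfg.qpcr_dilutions:
            for rep in range(cfg.qpcr_replicates):
                ct = (base_ct[assay] + cfg.qpcr_slope * np.log10(dil)
                      + float(rng.normal(0.0, cfg.qpcr_standards_noise_sd)))
                rows.append((f"std_{assay}_{dil:g}", "standard", assay,
                             rep + 1, ct, dil))
    return pd.DataFrame(
        rows, columns=["sample", "group", "assay", "replicate", "ct", "dilution"]
    )
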