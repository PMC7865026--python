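"""Synthetic multi-omic cohort generator.

Emits negative-binomial count matrices for a four-group design (CTRL, AS,
HIV, HIV_AS), a duplicate-well cytokine panel, TF target gene sets, a miRNA
target prediction table and a ground-truth record of every planted effect,
so each downstream stage of the pipeline can be exercised and scored without
any external data.

Generative model
----------------
* counts ~ NB(mean = base * libsize * effects, variance = mu + alpha*mu^2)
* library sizes log-uniform over a 4-fold range
* one TF whose target-gene means are scaled by a per-subject latent factor;
  one cytokine tracks that factor with Pearson r ~ tf_axis_strength
* one miRNA whose (log) expression linearly represses its target genes
* cytokines log-normal with 10% CV multiplicative duplicate noise
* one "hub" cytokine coupled to genes and miRNAs only in the HIV_AS group
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import GROUPS
from .mirna_integration import PREDICTION_ALGORITHMS
from .omics_io import CytokinePanel, ExpressionMatrix

__all__ = ["CohortConfig", "FixtureBundle", "simulate_cohort", "plant_mirna_de", "write_fixture_bundle"]

MIRNA_GROUPS = ("HIV", "HIV_AS")


class ConfigurationError(ValueError):
    pass


@dataclass
class CohortConfig:
    n_per_group: int = 6
    n_genes: int = 300
    n_mirnas: int = 60
    n_cytokines: int = 10
    n_tfs: int = 4
    nb_dispersion: float = 0.2
    planted_lfc: float = 2.0
    n_de_mirnas_up: int = 3
    n_de_mirnas_down: int = 9
    tf_axis_strength: float = 0.8
    mirna_repression_slope: float = -1.0
    seed: int = 0
    targets_per_tf: int = 20
    n_planted_mrna_de: int = 10
    mirna_targets: int = 8
    hub_strength: float = 0.9
    hub_spokes: int = 8

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_genes", "n_mirnas", "n_cytokines", "n_tfs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.mirna_repression_slope >= 0:
            raise ConfigurationError("mirna_repression_slope must be < 0")
        if not 0.0 <= self.tf_axis_strength <= 1.0:
            raise ConfigurationError("tf_axis_strength must be in [0, 1]")
        if self.n_de_mirnas_up + self.n_de_mirnas_down > self.n_mirnas:
            raise ConfigurationError("more planted DE miRNAs than miRNAs")


@dataclass
class FixtureBundle:
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    cytokines: CytokinePanel
    tf_targets: dict[str, set[str]]
    mir_predictions: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with mean mu and variance mu + alpha*mu^2 via gamma-Poisson."""
    mean = np.clip(mean, 1e-8, None)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_cohort(config: CohortConfig) -> FixtureBundle:
    """Generate a deterministic multi-omic fixture bundle for *config*."""
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    samples = [f"{g}_{i + 1:02d}" for g in GROUPS for i in range(n)]
    groups = pd.Series(
        {s: g for g in GROUPS for s in samples if s.startswith(g + "_")}
    ).reindex(samples)
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    mirnas = [f"miR-{i + 1}" for i in range(config.n_mirnas)]
    cytos = [f"CYT{i + 1:02d}" for i in range(config.n_cytokines)]

    lib = np.exp(rng.uniform(np.log(1.0), np.log(4.0), size=len(samples)))
    base_gene = np.exp(rng.normal(np.log(100.0), 1.0, size=config.n_genes))

    # --- TF programs -------------------------------------------------------
    tf_names = [f"TF{i + 1}" for i in range(config.n_tfs)]
    perm = rng.permutation(config.n_genes)
    tf_targets: dict[str, set[str]] = {}
    k = min(config.targets_per_tf, config.n_genes // config.n_tfs)
    k = max(k, 2)
    for i, tf in enumerate(tf_names):
        idx = perm[(i * k) % config.n_genes : (i * k) % config.n_genes + k]
        tf_targets[tf] = {genes[j] for j in idx}
    planted_tf = tf_names[0]
    planted_tf_idx = sorted(perm[:k])

    # Latent structure on the planted TF's targets, two orthogonal factors:
    # a uniform-loading "program level" nuisance that dominates PC1 (the
    # component the score excludes) and a signed activity axis with zero-mean
    # gene gains that lands on PC2.  The activity score is a magnitude, so
    # the planted cytokine tracks the amplitude |z| of the activity axis.
    z_tf = rng.normal(size=len(samples))
    z_tf = (z_tf - z_tf.mean()) / (z_tf.std() + 1e-12)
    u_nuis = rng.normal(size=len(samples))
    u_nuis = u_nuis - u_nuis.mean()
    u_nuis -= z_tf * (u_nuis @ z_tf) / (z_tf @ z_tf)  # realized orthogonality
    u_nuis = u_nuis / (u_nuis.std() + 1e-12)
    amp = np.abs(z_tf)
    amp_std = (amp - amp.mean()) / (amp.std() + 1e-12)
    a = config.tf_axis_strength
    cyto_latent = a * amp_std + np.sqrt(max(1.0 - a * a, 0.0)) * rng.normal(size=len(samples))
    planted_cyto = cytos[0]

    log2_gene = np.tile(np.log2(base_gene)[:, None], (1, len(samples)))
    # alternating zero-mean gains keep the axis off the nuisance direction
    tf_gain = 0.575 * np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(planted_tf_idx))])
    tf_gain -= tf_gain.mean()
    for gi, g_idx in enumerate(planted_tf_idx):
        log2_gene[g_idx] += 0.75 * u_nuis + tf_gain[gi] * z_tf

    # --- planted mRNA group effects ---------------------------------------
    n_de = min(config.n_planted_mrna_de, config.n_genes)
    de_gene_idx = sorted(rng.choice(config.n_genes, size=n_de, replace=False))
    hiv_as_cols = np.array([groups[s] == "HIV_AS" for s in samples])
    for g_idx in de_gene_idx:
        log2_gene[g_idx, hiv_as_cols] += config.planted_lfc

    # --- miRNA block (HIV groups only) ------------------------------------
    mir_samples = [s for s in samples if groups[s] in MIRNA_GROUPS]
    mir_cols = [samples.index(s) for s in mir_samples]
    base_mir = np.exp(rng.normal(np.log(200.0), 1.0, size=config.n_mirnas))
    log2_mir = np.tile(np.log2(base_mir)[:, None], (1, len(mir_samples)))

    planted_mir = mirnas[0]
    mir_dev = rng.normal(0.0, 1.0, size=len(mir_samples))  # log2 deviation
    log2_mir[0] += mir_dev

    # repression: planted miRNA's targets move with slope * deviation
    n_tgt = min(config.mirna_targets, config.n_genes)
    taken = set(de_gene_idx) | set(planted_tf_idx)
    candidates = [i for i in range(config.n_genes) if i not in taken]
    tgt_idx = sorted(rng.choice(candidates, size=n_tgt, replace=False))
    for g_idx in tgt_idx:
        log2_gene[g_idx, mir_cols] += config.mirna_repression_slope * mir_dev

    # hub: spoke genes track a shared latent factor only in HIV_AS samples,
    # making a star around the hub cytokine (set below) in that group only
    hub_cyto = cytos[1] if config.n_cytokines > 1 else None
    hub_feats_g: list[str] = []
    h_lat = rng.normal(size=len(samples))
    # standardized within HIV_AS, the only block where the factor acts
    h_as = h_lat[hiv_as_cols]
    h_lat = (h_lat - h_as.mean()) / (h_as.std() + 1e-12)
    if hub_cyto is not None:
        free = [i for i in candidates if i not in set(tgt_idx)]
        n_spokes = min(config.hub_spokes, len(free))
        spoke_idx = sorted(rng.choice(free, size=n_spokes, replace=False))
        hub_feats_g = [genes[i] for i in spoke_idx]
        for g_idx in spoke_idx:
            log2_gene[g_idx, hiv_as_cols] += 1.5 * h_lat[hiv_as_cols]

    # planted miRNA DE between the two HIV groups
    up_idx = list(range(1, 1 + config.n_de_mirnas_up))
    down_idx = list(
        range(1 + config.n_de_mirnas_up, 1 + config.n_de_mirnas_up + config.n_de_mirnas_down)
    )
    as_cols = np.array([groups[s] == "HIV_AS" for s in mir_samples])
    for i in up_idx:
        log2_mir[i, as_cols] += config.planted_lfc
    for i in down_idx:
        log2_mir[i, as_cols] -= config.planted_lfc

    # --- draw counts -------------------------------------------------------
    gene_mean = 2.0**log2_gene * lib[None, :]
    mrna_counts = _nb_draw(rng, gene_mean, config.nb_dispersion)
    mir_lib = lib[mir_cols]
    mir_mean = 2.0**log2_mir * mir_lib[None, :]
    mirna_counts = _nb_draw(rng, mir_mean, config.nb_dispersion)

    mrna = ExpressionMatrix(
        pd.DataFrame(mrna_counts, index=genes, columns=samples), groups, "counts"
    )
    mirna = ExpressionMatrix(
        pd.DataFrame(mirna_counts, index=mirnas, columns=mir_samples),
        groups.loc[mir_samples],
        "counts",
    )

    # --- cytokines: log-normal, duplicate wells with 10% CV ----------------
    log_cyto = rng.normal(np.log(50.0), 0.5, size=(len(samples), config.n_cytokines))
    log_cyto[:, 0] = np.log(50.0) + 0.5 * cyto_latent
    # hub cytokine tracks the hub latent factor in HIV_AS samples only, so
    # both the spokes and the hub itself are pure noise in every other group
    if hub_cyto is not None:
        h = config.hub_strength
        hub_track = np.where(hiv_as_cols, h * h_lat, 0.0)
        log_cyto[:, 1] = np.log(50.0) + 0.5 * (
            hub_track + np.sqrt(max(1.0 - h * h, 0.0)) * rng.normal(size=len(samples))
        )
    true_cyto = np.exp(log_cyto)
    wells = []
    rows = []
    for si, s in enumerate(samples):
        for rep in ("1", "2"):
            noise = np.exp(rng.normal(0.0, 0.0998, size=config.n_cytokines))  # ~10% CV
            wells.append(f"{s}/{rep}")
            rows.append(true_cyto[si] * noise)
    panel = CytokinePanel(
        pd.DataFrame(rows, index=wells, columns=cytos),
        replicate_of=pd.Series([w.rsplit("/", 1)[0] for w in wells], index=wells),
    )

    # --- prediction table --------------------------------------------------
    algos = sorted(PREDICTION_ALGORITHMS)
    pred_rows = []
    for g_idx in tgt_idx:  # planted pairs: 3 supporting algorithms
        for al in algos[:3]:
            pred_rows.append((planted_mir, genes[g_idx], al))
    n_decoy = min(3 * n_tgt, config.n_genes)
    decoys = rng.choice(config.n_genes, size=n_decoy, replace=False)
    for d_i, g_idx in enumerate(decoys):
        m = mirnas[1 + d_i % (config.n_mirnas - 1)] if config.n_mirnas > 1 else planted_mir
        n_sup = 1 + (d_i % 3)  # 1..3 algorithms
        for al in algos[2 : 2 + n_sup]:
            pred_rows.append((m, genes[g_idx], al))
    mir_predictions = pd.DataFrame(pred_rows, columns=["mirna", "gene", "algorithm"])

    truth = {
        "planted_de_genes": [genes[i] for i in de_gene_idx],
        "planted_de_mirnas_up": [mirnas[i] for i in up_idx],
        "planted_de_mirnas_down": [mirnas[i] for i in down_idx],
        "planted_tf": planted_tf,
        "planted_cytokine": planted_cyto,
        "tf_axis_strength": config.tf_axis_strength,
        "planted_mirna": planted_mir,
        "planted_mir_targets": [genes[i] for i in tgt_idx],
        "hub_cytokine": hub_cyto,
        "hub_coupled_genes": hub_feats_g if hub_cyto is not None else [],
        "hub_group": "HIV_AS",
        "mrna_lfc": config.planted_lfc,
        "mirna_lfc": config.planted_lfc,
    }
    return FixtureBundle(mrna, mirna, panel, tf_targets, mir_predictions, truth)


def plant_mirna_de(
    bundle: FixtureBundle, n_up: int, n_down: int, lfc: float
) -> FixtureBundle:
    """Shift designated miRNAs by ±lfc (log2) in the HIV_AS group.

    Counts of the first ``n_up`` unplanted miRNAs are scaled up by 2**lfc in
    HIV_AS samples and the next ``n_down`` scaled down, with rounding to keep
    integer counts; the truth record's planted lists are replaced.  ``lfc=0``
    leaves the counts untouched.  Intended for bundles generated with
    ``n_de_mirnas_up = n_de_mirnas_down = 0`` so planting is not compounded.
    """
    mir_ids = bundle.mirna.feature_ids
    if n_up + n_down > len(mir_ids):
        raise ConfigurationError("more planted DE miRNAs than miRNAs in the bundle")
    new = copy.deepcopy(bundle)
    counts = new.mirna.values
    as_samples = [s for s in new.mirna.sample_ids if new.mirna.sample_group[s] == "HIV_AS"]
    reserved = {new.truth.get("planted_mirna")}
    free = [m for m in mir_ids if m not in reserved]
    up = free[:n_up]
    down = free[n_up : n_up + n_down]
    if lfc != 0.0:
        counts.loc[up, as_samples] = np.rint(counts.loc[up, as_samples] * 2.0**lfc).astype(int)
        counts.loc[down, as_samples] = np.rint(counts.loc[down, as_samples] * 2.0**-lfc).astype(
            int
        )
    new.truth["planted_de_mirnas_up"] = up
    new.truth["planted_de_mirnas_down"] = down
    new.truth["mirna_lfc"] = lfc
    return new


def write_fixture_bundle(bundle: FixtureBundle, out_dir: str | Path) -> dict:
    """Write the bundle as TSV/GMT/JSON files and return a manifest.

    The manifest lists every emitted file with its row and column counts and
    is itself written as ``manifest.json``.
    """
    from .omics_io import write_cytokine_panel, write_expression_table, write_gene_sets

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    write_expression_table(bundle.mrna, out / "mrna_counts.tsv")
    manifest["mrna_counts.tsv"] = {
        "rows": bundle.mrna.n_features,
        "columns": bundle.mrna.n_samples,
    }
    write_expression_table(bundle.mirna, out / "mirna_counts.tsv")
    manifest["mirna_counts.tsv"] = {
        "rows": bundle.mirna.n_features,
        "columns": bundle.mirna.n_samples,
    }
    write_cytokine_panel(bundle.cytokines, out / "cytokines.tsv")
    manifest["cytokines.tsv"] = {
        "rows": len(bundle.cytokines.values),
        "columns": len(bundle.cytokines.analyte_ids),
    }
    write_gene_sets(bundle.tf_targets, out / "tf_targets.gmt")
    manifest["tf_targets.gmt"] = {"rows": len(bundle.tf_targets), "columns": 0}
    bundle.mir_predictions.to_csv(out / "mir_predictions.tsv", sep="\t", index=False)
    manifest["mir_predictions.tsv"] = {
        "rows": len(bundle.mir_predictions),
        "columns": bundle.mir_predictions.shape[1],
    }
    groups_df = pd.DataFrame(
        {"sample": bundle.mrna.sample_ids, "group": bundle.mrna.sample_group.values}
    )
    groups_df.to_csv(out / "sample_groups.tsv", sep="\t", index=False)
    manifest["sample_groups.tsv"] = {"rows": len(groups_df), "columns": 2}
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    manifest["truth.json"] = {"rows": len(bundle.truth), "columns": 0}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
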