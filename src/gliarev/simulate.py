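"""Synthetic glial cohort generator with recorded ground truth.

Emulates a 2 age x 2 treatment x 3 replicate targeted scRNA-seq design over
three glial cell types: negative-binomial counts with per-cell library sizes
and mitochondrial fractions, pathway-block-structured age effects, a tunable
treatment reversal fraction rho* (treatment log fold change = -rho* x age
log fold change on affected genes, applied to aged IL2 samples), a rare
DAM-like program in aged microglia, and a branching latent maturation axis
with a per-group branch-occupancy shift.

Every structural parameter is recorded in a :class:`GroundTruth` object so
downstream estimators can be tested for recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from .cohort import AGES, GROUPS, TREATMENTS, CellCohort, CohortDesign, ParameterError

LOG2 = float(np.log(2.0))

#: Canonical murine DAM marker panel used as the default planted program.
DAM_MARKERS = ["Trem2", "Cst7", "Lpl", "Itgax", "Apoe", "Clec7a", "Tyrobp", "Axl", "Cd9", "Spp1"]

#: First 13 symbols follow murine mitochondrial gene naming.
_MITO_SYMBOLS = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]

#: Latent maturation-axis segments: trunk, mature arm, immature arm.
SEGMENTS = ("trunk", "armA", "armB")


@dataclass
class DamSimParams:
    """Planted DAM-like program: marker boost in a rare aged-microglia state."""

    dam_fraction_aged: float = 0.02
    dam_fraction_young: float = 0.0
    marker_log2_boost: float = 1.5
    # DAM markers are robustly detected microglial genes (Apoe, Tyrobp, ...);
    # their baseline sits above the genome-wide average.
    marker_baseline_log2: float = 1.5
    markers: list[str] = field(default_factory=lambda: list(DAM_MARKERS))


@dataclass
class TrajectorySimParams:
    """Latent maturation axis: a trunk splitting into two arms at t = 0.5.

    ``delta_aged`` moves aged-GFP branch occupancy toward the mature arm as a
    total-variation shift: p_aged = (1 - delta) * p_young + delta * e_armA.
    Aged-IL2 occupancy uses delta * (1 - rho*) unless overridden, so a fully
    reverting treatment restores the young occupancy.
    """

    geometry: str = "branch"  # "branch" (Y-shape) or "path" (no arm divergence)
    delta_aged: float = 0.3
    delta_aged_il2: float | None = None  # default: delta_aged * (1 - rho*)
    young_occupancy: tuple[float, float, float] = (0.5, 0.25, 0.25)
    young_occupancy_path: tuple[float, float] = (0.65, 0.35)  # early/late halves
    n_gradient_genes: int = 60  # shared maturation gradient (includes S100b-like marker)
    gradient_log2_span: float = 2.0
    n_arm_genes: int = 30  # per arm, switched on past the branch point
    arm_log2_boost: float = 2.0
    maturation_marker: str = "S100b"


@dataclass
class SimParams:
    """Full parameterization of a synthetic cohort."""

    n_samples_per_group: int = 3
    n_cells_per_sample: int = 300
    n_genes: int = 2000
    celltype_mixture: dict[str, float] = field(
        default_factory=lambda: {"microglia": 0.4, "astrocyte": 0.3, "oligodendrocyte": 0.3}
    )
    nb_dispersion: float = 0.05  # inverse-size parameterization: var = mu + phi mu^2
    libsize_lognormal: tuple[float, float] = (np.log(2500.0), 0.35)
    mito_gene_fraction: float = 0.05
    mito_frac_mean: float = 0.04
    mito_frac_sd: float = 0.02
    mito_tail_fraction: float = 0.03  # cells redrawn above the 10% QC rule
    mito_tail_range: tuple[float, float] = (0.12, 0.30)
    # Age effect: block-structured sparse log2 vector.
    n_affected_genes: int = 500
    n_pathways: int = 5
    age_effect_log2_sd: float = 0.5
    reversal_fraction_true: float = 0.5  # rho*: fraction of age effect countered in aged IL2
    treat_young_log2_sd: float = 0.0  # optional treatment effect in young IL2 (default none)
    # Celltype identity programs.
    n_celltype_marker_genes: int = 40
    celltype_marker_log2: float = 1.5
    # Optional subcluster programs within microglia.
    n_subclusters: int = 1
    n_subcluster_genes: int = 30
    subcluster_log2: float = 2.0
    subcluster_props_young: list[float] | None = None
    subcluster_props_aged: list[float] | None = None
    dam: DamSimParams = field(default_factory=DamSimParams)
    trajectory: TrajectorySimParams = field(default_factory=TrajectorySimParams)
    seed: int = 0

    def validate(self) -> None:
        mix = np.array(list(self.celltype_mixture.values()), dtype=float)
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-8:
            raise ParameterError(
                f"celltype_mixture must be nonnegative and sum to 1 (got sum {mix.sum():.6g})"
            )
        for name in ("n_samples_per_group", "n_cells_per_sample", "n_genes"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0.0 <= self.reversal_fraction_true <= 1.0:
            raise ParameterError("reversal_fraction_true must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ParameterError("nb_dispersion must be nonnegative")
        for f in (self.dam.dam_fraction_aged, self.dam.dam_fraction_young):
            if not 0.0 <= f <= 1.0:
                raise ParameterError("DAM fractions must lie in [0, 1]")
        if self.trajectory.geometry not in ("branch", "path"):
            raise ParameterError(f"unknown trajectory geometry {self.trajectory.geometry!r}")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    cells: pd.DataFrame  # barcode, sample, latent_t, segment, is_dam
    genes: pd.DataFrame  # gene_id, symbol, true_age_lfc, true_treatment_lfc, pathway, role
    occupancy: pd.DataFrame  # group x segment expected occupancy probabilities
    rho_star: float
    params: SimParams


def _allocate_genes(params: SimParams) -> pd.DataFrame:
    """Assign every gene index a symbol and a structural role, deterministically."""
    p = params
    n_mito = max(1, int(round(p.mito_gene_fraction * p.n_genes)))
    roles = np.array(["null"] * p.n_genes, dtype=object)
    symbols = np.array([f"Gene{i + 1:05d}" for i in range(p.n_genes)], dtype=object)
    pathway = np.array([""] * p.n_genes, dtype=object)

    cursor = 0

    def take(n: int, role: str) -> np.ndarray:
        nonlocal cursor
        idx = np.arange(cursor, cursor + n)
        if cursor + n > p.n_genes:
            raise ParameterError(
                f"n_genes={p.n_genes} too small for the structured gene sets "
                f"(need at least {cursor + n})"
            )
        roles[idx] = role
        cursor += n
        return idx

    mito = take(n_mito, "mito")
    for j, gi in enumerate(mito):
        symbols[gi] = _MITO_SYMBOLS[j] if j < len(_MITO_SYMBOLS) else f"mt-Gene{j + 1}"
    dam = take(len(p.dam.markers), "dam_marker")
    symbols[dam] = p.dam.markers
    grad = take(p.trajectory.n_gradient_genes, "gradient")
    symbols[grad[0]] = p.trajectory.maturation_marker
    take(p.trajectory.n_arm_genes, "armA")
    take(p.trajectory.n_arm_genes, "armB")
    affected = take(p.n_affected_genes, "age_affected")
    block = np.array_split(affected, p.n_pathways)
    for b, idx in enumerate(block):
        pathway[idx] = f"AgePath{b + 1}"
    for ct in p.celltype_mixture:
        take(p.n_celltype_marker_genes, f"marker:{ct}")
    if p.n_subclusters > 1:
        for k in range(p.n_subclusters):
            take(p.n_subcluster_genes, f"subcluster:{k}")

    return pd.DataFrame(
        {
            "gene_id": [f"ENSMUSG{i + 1:08d}" for i in range(p.n_genes)],
            "symbol": symbols,
            "is_mitochondrial": [r == "mito" for r in roles],
            "role": roles,
            "pathway": pathway,
        }
    )


def _segment_probs(params: SimParams, group: str) -> np.ndarray:
    tp = params.trajectory
    if tp.geometry == "path":
        base = np.array([*tp.young_occupancy_path, 0.0], dtype=float)
    else:
        base = np.asarray(tp.young_occupancy, dtype=float)
    base = base / base.sum()
    if group == "agedGFP":
        delta = tp.delta_aged
    elif group == "agedIL2":
        delta = (
            tp.delta_aged_il2
            if tp.delta_aged_il2 is not None
            else tp.delta_aged * (1.0 - params.reversal_fraction_true)
        )
    else:
        delta = 0.0
    e_mature = np.array([0.0, 1.0, 0.0])
    return (1.0 - delta) * base + delta * e_mature


def simulate_cohort(params: SimParams) -> tuple[CellCohort, GroundTruth]:
    """Draw a cohort from the generative model.

    Per cell, expected expression is libsize x softmax(log-scale effects) with
    the mitochondrial mass re-weighted to the cell's drawn mito fraction;
    counts are negative binomial with shared per-run dispersion.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    genes = _allocate_genes(p)
    roles = genes["role"].to_numpy()
    n_genes = p.n_genes

    # Per-gene structural vectors (log2 scale).
    baseline = rng.normal(0.0, 1.25, n_genes)
    baseline[roles == "dam_marker"] += p.dam.marker_baseline_log2
    age_lfc = np.zeros(n_genes)
    aff = np.flatnonzero(roles == "age_affected")
    # Pathway-coordinated effects: one sign per block, |N(0, sd)| magnitudes.
    for b, name in enumerate(sorted(set(genes.loc[aff, "pathway"]))):
        idx = np.flatnonzero((genes["pathway"] == name).to_numpy())
        sign = 1.0 if b % 2 == 0 else -1.0
        age_lfc[idx] = sign * np.abs(rng.normal(0.0, p.age_effect_log2_sd, idx.size))
    treat_lfc = -p.reversal_fraction_true * age_lfc
    young_treat_lfc = np.zeros(n_genes)
    if p.treat_young_log2_sd > 0:
        young_treat_lfc[aff] = rng.normal(0.0, p.treat_young_log2_sd, aff.size)

    dam_boost = np.where(roles == "dam_marker", p.dam.marker_log2_boost, 0.0)
    grad_slope = np.zeros(n_genes)
    gi = np.flatnonzero(roles == "gradient")
    grad_slope[gi] = rng.choice([-1.0, 1.0], gi.size) * rng.uniform(1.0, 3.0, gi.size)
    grad_slope[gi[0]] = 3.0  # maturation marker rises monotonically along the axis
    grad_slope *= p.trajectory.gradient_log2_span / 2.0
    armA = np.where(roles == "armA", p.trajectory.arm_log2_boost, 0.0)
    armB = np.where(roles == "armB", p.trajectory.arm_log2_boost, 0.0)

    ct_marker = {
        ct: np.where(roles == f"marker:{ct}", p.celltype_marker_log2, 0.0)
        for ct in p.celltype_mixture
    }
    sub_boost = [
        np.where(roles == f"subcluster:{k}", p.subcluster_log2, 0.0)
        for k in range(p.n_subclusters)
    ] if p.n_subclusters > 1 else []

    mito_mask = genes["is_mitochondrial"].to_numpy()
    celltypes = list(p.celltype_mixture)
    mix = np.array([p.celltype_mixture[ct] for ct in celltypes])

    counts_blocks: list[sp.csc_matrix] = []
    cell_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    occ_rows = []

    for group in GROUPS:
        age = "young" if group.startswith("young") else "aged"
        treatment = group[len(age):]
        seg_p = _segment_probs(p, group)
        occ_rows.append({"group": group, **dict(zip(SEGMENTS, seg_p))})
        for rep in range(1, p.n_samples_per_group + 1):
            sample = f"{group}_{rep}"
            nc = p.n_cells_per_sample
            ct_idx = rng.choice(len(celltypes), nc, p=mix)
            seg = rng.choice(3, nc, p=seg_p)
            t = np.where(seg == 0, rng.uniform(0.0, 0.5, nc), rng.uniform(0.5, 1.0, nc))
            dam_frac = p.dam.dam_fraction_aged if age == "aged" else p.dam.dam_fraction_young
            is_dam = (rng.random(nc) < dam_frac) & (np.array(celltypes)[ct_idx] == "microglia")
            sub = rng.choice(
                max(p.n_subclusters, 1),
                nc,
                p=(p.subcluster_props_young if age == "young" else p.subcluster_props_aged)
                if (p.subcluster_props_young is not None and age == "young")
                or (p.subcluster_props_aged is not None and age == "aged")
                else None,
            )
            libsize = rng.lognormal(*p.libsize_lognormal, nc)
            # Truncated-normal mito fraction with a heavy tail crossing the QC rule.
            m = rng.normal(p.mito_frac_mean, p.mito_frac_sd, nc).clip(1e-4, 1.0)
            tail = rng.random(nc) < p.mito_tail_fraction
            m[tail] = rng.uniform(*p.mito_tail_range, tail.sum())

            eta = np.tile(baseline, (nc, 1))  # cells x genes, log2
            if age == "aged":
                eta += age_lfc
                if treatment == "IL2":
                    eta += treat_lfc
            elif treatment == "IL2":
                eta += young_treat_lfc
            eta[is_dam] += dam_boost
            eta += np.outer(t - 0.5, grad_slope)
            if p.trajectory.geometry == "branch":  # arm programs only past the branch point
                on_arm = np.maximum(t - 0.5, 0.0) * 2.0
                eta += np.outer(np.where(seg == 1, on_arm, 0.0), armA)
                eta += np.outer(np.where(seg == 2, on_arm, 0.0), armB)
            for j, ct in enumerate(celltypes):
                eta[ct_idx == j] += ct_marker[ct]
            for k, boost in enumerate(sub_boost):
                eta[(sub == k) & (ct_idx == 0)] += boost  # programs live in the first cell type

            # Softmax over genes, then impose the cell's mitochondrial share.
            w = np.exp(LOG2 * (eta - eta.max(axis=1, keepdims=True)))
            w_m = w[:, mito_mask].sum(axis=1, keepdims=True)
            w_o = w[:, ~mito_mask].sum(axis=1, keepdims=True)
            prob = np.empty_like(w)
            prob[:, mito_mask] = w[:, mito_mask] / w_m * m[:, None]
            prob[:, ~mito_mask] = w[:, ~mito_mask] / w_o * (1.0 - m[:, None])
            mu = prob * libsize[:, None]
            if p.nb_dispersion > 0:
                size = 1.0 / p.nb_dispersion
                draw = rng.negative_binomial(size, size / (size + mu))
            else:
                draw = rng.poisson(mu)

            barcodes = [f"{sample}-{i + 1:04d}" for i in range(nc)]
            counts_blocks.append(sp.csc_matrix(draw.T))
            cell_rows.append(
                pd.DataFrame(
                    {
                        "barcode": barcodes,
                        "sample": sample,
                        "age": age,
                        "treatment": treatment,
                        "replicate": rep,
                        "celltype": np.array(celltypes)[ct_idx],
                    }
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "barcode": barcodes,
                        "sample": sample,
                        "latent_t": t,
                        "segment": np.array(SEGMENTS)[seg],
                        "subcluster": sub,
                        "is_dam": is_dam,
                    }
                )
            )

    counts = sp.hstack(counts_blocks, format="csr")
    cohort = CellCohort(
        counts=counts,
        gene_table=genes[["gene_id", "symbol", "is_mitochondrial"]].copy(),
        cell_table=pd.concat(cell_rows, ignore_index=True),
    )
    truth_genes = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "symbol": genes["symbol"],
            "true_age_lfc": age_lfc,
            "true_treatment_lfc": treat_lfc,
            "pathway": genes["pathway"],
            "role": genes["role"],
        }
    )
    truth = GroundTruth(
        cells=pd.concat(truth_rows, ignore_index=True),
        genes=truth_genes,
        occupancy=pd.DataFrame(occ_rows).set_index("group"),
        rho_star=p.reversal_fraction_true,
        params=p,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Persistence


def write_cohort(cohort: CellCohort, outdir: str | Path) -> Path:
    """Write a cohort in 10x triplet convention: matrix.mtx + features.tsv +
    barcodes.tsv + metadata.tsv.  Round-trips losslessly via io.read_cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(cohort.counts), field="integer")
    feats = cohort.gene_table[["gene_id", "symbol"]].copy()
    feats["feature_type"] = "Gene Expression"
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    cohort.cell_table[["barcode"]].to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    cohort.cell_table.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    return outdir


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> Path:
    """Sidecar tables + JSON params for a simulated cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(outdir / "ground_truth_cells.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "ground_truth_genes.tsv", sep="\t", index=False)
    truth.occupancy.to_csv(outdir / "ground_truth_occupancy.tsv", sep="\t")
    blob = dataclasses.asdict(truth.params)
    (outdir / "sim_params.json").write_text(json.dumps(blob, indent=2, default=list))
    return outdir


def write_truth_gmt(
    truth: GroundTruth, path: str | Path, n_null_sets: int = 10, null_size: int = 50,
    seed: int = 0,
) -> Path:
    """GMT file with the planted age-affected pathway blocks plus random null
    sets drawn from unaffected genes, for gene-set stage tests."""
    rng = np.random.default_rng(seed)
    g = truth.genes
    lines = []
    for name in sorted(set(g["pathway"]) - {""}):
        members = g.loc[g["pathway"] == name, "symbol"]
        lines.append("\t".join([name, "planted age-affected block", *members]))
    null_pool = g.loc[(g["role"] == "null"), "symbol"].to_numpy()
    for k in range(n_null_sets):
        members = rng.choice(null_pool, size=min(null_size, null_pool.size), replace=False)
        lines.append("\t".join([f"NullSet{k + 1}", "random unaffected genes", *members]))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def design_from_params(params: SimParams) -> CohortDesign:
    rows = []
    for group in GROUPS:
        age = "young" if group.startswith("young") else "aged"
        for rep in range(1, params.n_samples_per_group + 1):
            rows.append(
                {"sample": f"{group}_{rep}", "age": age,
                 "treatment": group[len(age):], "replicate": rep}
            )
    return CohortDesign(pd.DataFrame(rows).set_index("sample"))
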