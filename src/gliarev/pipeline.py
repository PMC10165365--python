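"""Staged pipeline driver: qc -> cluster -> dam -> trajectory -> de ->
reversal -> genesets, configured from YAML/JSON.

Each stage persists its tables under the output directory and a JSON log of
the parameters and package version, so any stage can be re-run later from
the persisted upstream outputs.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cluster as cl
from . import dam as dam_mod
from . import de as de_mod
from . import genesets as gs
from . import io as io_mod
from . import qc as qc_mod
from . import simulate as sim
from . import trajectory as traj
from .cohort import CellCohort, CohortDesign, DependencyError, ParameterError

log = logging.getLogger(__name__)

STAGES = ("qc", "cluster", "dam", "trajectory", "de", "reversal", "genesets")

#: Primary persisted table per stage.
STAGE_TABLES = {
    "qc": "qc_report.csv",
    "cluster": "composition_tests.csv",
    "dam": "dam_prevalence.csv",
    "trajectory": "deviance.csv",
    "de": "de_microglia_AGE.csv",
    "reversal": "reversal.csv",
    "genesets": "directionality.csv",
}


def simparams_from_dict(d: dict) -> sim.SimParams:
    d = dict(d or {})
    dam_d = d.pop("dam", {})
    traj_d = d.pop("trajectory", {})
    params = sim.SimParams(**d)
    if dam_d:
        params.dam = dataclasses.replace(params.dam, **dam_d)
    if traj_d:
        tq = dict(traj_d)
        for key in ("young_occupancy",):
            if key in tq:
                tq[key] = tuple(tq[key])
        params.trajectory = dataclasses.replace(params.trajectory, **tq)
    return params


def _write_log(outdir: Path, stage: str, params: dict) -> None:
    logs = outdir / "logs"
    logs.mkdir(parents=True, exist_ok=True)
    blob = {"stage": stage, "version": __version__, "params": params}
    (logs / f"{stage}.json").write_text(json.dumps(blob, indent=2, sort_keys=True, default=str))


def _load_filtered(outdir: Path, cfg: dict) -> tuple[CellCohort, CohortDesign]:
    cdir = outdir / "cohort_filtered"
    if not cdir.is_dir():
        raise DependencyError("qc stage outputs missing; run the qc stage first")
    cohort = io_mod.read_cohort(cdir)
    design = CohortDesign.from_cell_table(cohort.cell_table)
    qc_mod.compute_qc_metrics(cohort)
    qc_mod.normalize(cohort, dispersion=float(cfg.get("qc", {}).get("pearson_dispersion", 0.05)))
    return cohort, design


def _load_de_tables(outdir: Path, celltype: str, contrasts: list[str]) -> dict[str, pd.DataFrame]:
    tables = {}
    for c in contrasts:
        p = outdir / f"de_{celltype}_{c}.csv"
        if not p.is_file():
            raise DependencyError(f"missing DE output {p.name}; run the de stage first")
        tables[c] = pd.read_csv(p)
    return tables


def run_pipeline(
    config: str | Path | dict,
    stages: list[str] | None = None,
    seed: int | None = None,
) -> int:
    """Run the configured stages in order; returns 0 on success.

    ``stages``/``seed`` override the config.  Stages not listed are skipped;
    a stage finding its upstream outputs missing raises DependencyError.
    """
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        cfg = yaml.safe_load(text)
    else:
        cfg = dict(config)
    outdir = Path(cfg.get("outdir", "gliarev_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    todo = list(stages if stages is not None else cfg.get("stages", STAGES))
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ParameterError(f"unknown stage(s) {sorted(unknown)}; valid: {STAGES}")
    todo = [s for s in STAGES if s in todo]  # enforce canonical order

    cohort: CellCohort | None = None
    design: CohortDesign | None = None

    if "qc" in todo:
        inp = cfg.get("input", {})
        if "simulate" in inp:
            params = simparams_from_dict({**inp["simulate"], "seed": seed})
            cohort, truth = sim.simulate_cohort(params)
            cdir = outdir / "cohort"
            sim.write_cohort(cohort, cdir)
            sim.write_ground_truth(truth, cdir)
            sim.write_truth_gmt(truth, cdir / "pathways.gmt", seed=seed)
        elif "dir" in inp:
            cohort = io_mod.read_cohort(
                inp["dir"],
                metadata=inp.get("metadata"),
                mito_prefix=inp.get("mito_prefix", "mt-"),
            )
        else:
            raise ParameterError("config input must name either 'simulate' or 'dir'")
        design = CohortDesign.from_cell_table(cohort.cell_table)
        cohort.check_samples(design)

        qcfg = cfg.get("qc", {})
        qparams = qc_mod.QCParams(
            mito_threshold=float(qcfg.get("mito_threshold", 0.10)),
            min_counts_per_cell=int(qcfg.get("min_counts_per_cell", 200)),
            min_cells_per_gene=int(qcfg.get("min_cells_per_gene", 3)),
        )
        qc_mod.compute_qc_metrics(cohort)
        cohort, report = qc_mod.filter_cells(cohort, qparams)
        qc_mod.normalize(cohort, dispersion=float(qcfg.get("pearson_dispersion", 0.05)))
        sim.write_cohort(cohort, outdir / "cohort_filtered")
        io_mod.write_results({"qc_report": report}, outdir)
        _write_log(outdir, "qc", dataclasses.asdict(qparams))
        design = CohortDesign.from_cell_table(cohort.cell_table)

    def ensure_cohort() -> tuple[CellCohort, CohortDesign]:
        nonlocal cohort, design
        if cohort is None or "lognorm" not in cohort.layers:
            cohort, design = _load_filtered(outdir, cfg)
        return cohort, design

    if "cluster" in todo:
        cohort, design = ensure_cohort()
        ccfg = cfg.get("cluster", {})
        celltypes = ccfg.get("celltypes", sorted(cohort.cell_table["celltype"].unique()))
        comp_rows, pca_rows, test_rows, clus_rows = [], [], [], []
        for ct in celltypes:
            cl.subcluster(
                cohort, ct,
                resolution=float(ccfg.get("resolution", 0.5)),
                n_neighbors=int(ccfg.get("n_neighbors", 15)),
                method=ccfg.get("method", "leiden"),
                k=ccfg.get("k"),
                seed=seed,
            )
            table = cl.composition_table(cohort, ct, design=design)
            tests = cl.composition_tests(table, design)
            tests.insert(0, "celltype", ct)
            test_rows.append(tests)
            long = table.drop(columns=["age", "treatment", "replicate"]).reset_index().melt(
                id_vars="sample", var_name="cluster", value_name="proportion"
            )
            long.insert(0, "celltype", ct)
            comp_rows.append(long)
            try:
                scores, _evr = cl.composition_pca(table)
                scores = scores.reset_index()
                scores.insert(0, "celltype", ct)
                pca_rows.append(scores)
            except ParameterError:
                pass
            idx = cohort.cells_of_type(ct)
            clus_rows.append(
                pd.DataFrame(
                    {"barcode": cohort.cell_table["barcode"].iloc[idx],
                     "celltype": ct,
                     "cluster": cohort.cell_table["cluster"].iloc[idx]}
                )
            )
        io_mod.write_results(
            {
                "composition": pd.concat(comp_rows, ignore_index=True),
                "composition_pca": pd.concat(pca_rows, ignore_index=True)
                if pca_rows else pd.DataFrame(),
                "composition_tests": pd.concat(test_rows, ignore_index=True),
                "clusters": pd.concat(clus_rows, ignore_index=True),
            },
            outdir,
        )
        _write_log(outdir, "cluster", {"celltypes": list(celltypes), **ccfg, "seed": seed})

    if "dam" in todo:
        cohort, design = ensure_cohort()
        dcfg = cfg.get("dam", {})
        dparams = dam_mod.DAMParams(
            markers=dcfg.get("markers", dam_mod.default_markers()),
            n_control_bins=int(dcfg.get("n_control_bins", 25)),
            n_control_genes_per_marker=int(dcfg.get("n_control_genes_per_marker", 50)),
            threshold=float(dcfg.get("threshold", 0.07)),
            seed=seed,
        )
        dam_mod.dam_score(cohort, dparams)
        prev, tests = dam_mod.dam_prevalence(cohort, design, dparams)
        idx = cohort.cells_of_type("microglia")
        scores_df = pd.DataFrame(
            {"barcode": cohort.cell_table["barcode"].iloc[idx],
             "score": cohort.cell_table["dam_score"].iloc[idx],
             "is_dam": cohort.cell_table["is_dam"].iloc[idx]}
        )
        io_mod.write_results(
            {"dam_scores": scores_df,
             "dam_prevalence": prev.reset_index(names="sample"),
             "dam_tests": tests},
            outdir,
        )
        _write_log(outdir, "dam", {**dataclasses.asdict(dparams), "seed": seed})

    if "trajectory" in todo:
        cohort, design = ensure_cohort()
        tcfg = cfg.get("trajectory", {})
        celltypes = tcfg.get("celltypes", ["oligodendrocyte"])
        traj_rows, dev_rows = [], []
        for ct in celltypes:
            tree = traj.fit_tree(
                cohort, ct,
                n_nodes=int(tcfg.get("n_nodes", 20)),
                n_components=int(tcfg.get("n_components", 3)),
                seed=seed,
            )
            traj.root_tree(tree, cohort, design)
            (outdir / f"tree_{ct}.json").write_text(json.dumps(tree.to_dict(), indent=2))
            traj_rows.append(
                pd.DataFrame(
                    {"barcode": cohort.cell_table["barcode"].iloc[tree.cell_index],
                     "celltype": ct,
                     "branch": tree.cell_branch,
                     "pseudotime": tree.cell_pseudotime}
                )
            )
            dev = traj.sum_of_deviance(tree, cohort, design)
            dev.insert(0, "celltype", ct)
            dev_rows.append(dev)
        io_mod.write_results(
            {"trajectory": pd.concat(traj_rows, ignore_index=True),
             "deviance": pd.concat(dev_rows, ignore_index=True)},
            outdir,
        )
        _write_log(outdir, "trajectory", {"celltypes": list(celltypes), **tcfg, "seed": seed})

    decfg = cfg.get("de", {})
    de_celltypes = decfg.get("celltypes", ["microglia"])
    de_contrasts = decfg.get("contrasts", list(de_mod.CONTRASTS))

    if "de" in todo:
        cohort, design = ensure_cohort()
        for ct in de_celltypes:
            for contrast in de_contrasts:
                table = de_mod.nb_de(
                    cohort, ct, contrast, design,
                    min_detect_frac=float(decfg.get("min_detect_frac", 0.01)),
                    mode=decfg.get("mode", "percell"),
                )
                io_mod.write_results({f"de_{ct}_{contrast}": table}, outdir)
        _write_log(outdir, "de", {"celltypes": list(de_celltypes), "contrasts": list(de_contrasts)})

    if "reversal" in todo:
        rcfg = cfg.get("reversal", {})
        rows = []
        for ct in de_celltypes:
            tabs = _load_de_tables(outdir, ct, ["AGE", "TREAT_AGED"])
            paired = de_mod.two_dim_de(
                tabs["AGE"], tabs["TREAT_AGED"],
                padj_threshold=float(rcfg.get("padj_threshold", 0.05)),
            )
            io_mod.write_results({f"twodim_{ct}": paired}, outdir)
            rows.append(de_mod.reversal_fraction(paired, celltype=ct).as_row())
        io_mod.write_results({"reversal": pd.DataFrame(rows)}, outdir)
        _write_log(outdir, "reversal", rcfg)

    if "genesets" in todo:
        gcfg = cfg.get("genesets", {})
        gmt_path = gcfg.get("gmt") or (outdir / "cohort" / "pathways.gmt")
        if not Path(gmt_path).is_file():
            raise DependencyError(f"gene-set GMT not found at {gmt_path}")
        sets = io_mod.read_gmt(gmt_path)
        enr_rows, dir_rows = [], []
        for ct in gcfg.get("celltypes", de_celltypes):
            tabs = _load_de_tables(outdir, ct, de_contrasts)
            for contrast, tab in tabs.items():
                enr = gs.gage_test(
                    tab, sets,
                    n_perm=int(gcfg.get("n_perm", 1000)),
                    min_size=int(gcfg.get("min_size", 10)),
                    seed=seed,
                )
                enr.insert(0, "celltype", ct)
                enr_rows.append(enr)
            dmap = gs.directionality_map(tabs, sets, min_size=int(gcfg.get("min_size", 10)))
            dmap.insert(0, "celltype", ct)
            dir_rows.append(dmap)
        enrichment = pd.concat(enr_rows, ignore_index=True)
        io_mod.write_results(
            {"genesets": enrichment,
             "directionality": pd.concat(dir_rows, ignore_index=True)},
            outdir,
        )
        curated = gs.curate_pathways(
            enrichment,
            include=gcfg.get("include"),
            exclude=gcfg.get("exclude"),
            q_threshold=float(gcfg.get("q_threshold", 0.1)),
        )
        (outdir / "curated_pathways.txt").write_text("\n".join(curated) + "\n")
        _write_log(outdir, "genesets", {k: v for k, v in gcfg.items()})

    return 0
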