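"""End-to-end pipeline: simulate -> atlas -> DE -> modules -> networks -> labels -> summary.

Every run writes its outputs plus a ``manifest.json`` recording the stage
statuses, the full parameter set and SHA-256 checksums of the input files.
Identical config and seed produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import coexpression as coex
from . import de as de_mod
from . import io as io_mod
from . import networks as net_mod
from .config import CATEGORIES, RunConfig
from .labels import compare_label_sets
from .simulate import simulate_atlas, simulate_ppi, write_fixture

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline", "summarize"]

STAGES = ("simulate", "atlas", "de", "modules", "networks", "labels", "summarize")


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Execute all stages; returns the run directory."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg.to_dict(), "stages": [], "inputs": {}}
    status = {name: "pending" for name in STAGES}

    def fail(stage, exc):
        status[stage] = f"failed: {exc}"
        _finish()
        raise PipelineError(f"[{stage}] {exc}") from exc

    def _finish():
        manifest["stages"] = [{"name": s, "status": status[s]} for s in STAGES]
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    # ---- stage: simulate (or load inputs) ------------------------------
    truth = None
    label_files = dict(cfg.labels)
    try:
        if cfg.simulate:
            atlas, counts, truth = simulate_atlas(cfg.sim)
            ppi_frame = simulate_ppi(truth, cfg.sim)
            fixture_dir = out / "fixture"
            paths = write_fixture(fixture_dir, atlas, counts, truth, ppi_frame)
            cfg = dataclasses.replace(
                cfg,
                expression=paths["expression"], counts=paths["counts"],
                design=paths["design"], ppi=paths["ppi"],
            )
            # a synthetic positively-selected-like label set drawn from the
            # broadly expressed genes, for the label-association stage
            rng = np.random.default_rng([cfg.sim.seed, 2])
            pool = truth.genes.index[
                truth.genes["category"].isin(["Mixed", "ExpressedInAll"])
            ].to_numpy()
            picked = sorted(rng.choice(pool, size=min(100, len(pool)), replace=False))
            gups_path = fixture_dir / "gups.txt"
            gups_path.write_text("\n".join(picked) + "\n", encoding="utf-8")
            label_files.setdefault("GUPS", str(gups_path))
            status["simulate"] = "completed"
        else:
            for field in ("expression", "counts", "design"):
                p = getattr(cfg, field)
                if not p or not Path(p).exists():
                    raise FileNotFoundError(f"required input {field!r} not found: {p}")
            atlas = io_mod.read_atlas(cfg.expression, cfg.design)
            counts = io_mod.read_matrix(cfg.counts)
            status["simulate"] = "skipped (inputs supplied)"
        for field in ("expression", "counts", "design", "ppi", "ncrna"):
            p = getattr(cfg, field)
            if p and Path(p).exists():
                manifest["inputs"][field] = _sha256(p)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("simulate", exc)

    # ---- stage: atlas ---------------------------------------------------
    try:
        profile = atlas_mod.average_replicates(atlas)
        ncrna = io_mod.read_gene_list(cfg.ncrna) if cfg.ncrna else ()
        retained = atlas_mod.filter_genes(profile, ncrna_ids=ncrna, min_mean=cfg.min_mean)
        tau = atlas_mod.compute_tau(retained)
        classified = atlas_mod.classify_genes(
            retained, tau,
            detect_tpm=cfg.detect_tpm, tau_specific=cfg.tau_specific,
            fold_specific=cfg.fold_specific, tau_group=cfg.tau_group,
            group_max=cfg.group_max,
        )
        _write_tsv(classified.rename_axis("gene_id"), out / "tau_classification.tsv")
        ts_genes = classified.index[classified["category"] == "TissueSpecific"]
        if len(ts_genes) >= 3:
            corr = atlas_mod.tissue_correlation(retained, ts_genes)
            _write_tsv(corr.rename_axis("tissue"), out / "tissue_correlation.tsv")
        try:
            rho, rho_p = atlas_mod.foldchange_tau_correlation(classified)
        except ValueError:
            rho, rho_p = float("nan"), float("nan")
        manifest["foldchange_tau_spearman"] = {"rho": rho, "p": rho_p}
        status["atlas"] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail("atlas", exc)

    # ---- stage: de ------------------------------------------------------
    try:
        de_results = de_mod.de_all_tissues(counts, atlas.design)
        de_results = de_mod.call_degs(
            de_results, log2fc_cutoff=cfg.log2fc_cutoff,
            p_cutoff=cfg.p_cutoff, absolute=cfg.absolute_log2fc,
        )
        _write_tsv(de_results, out / "de_results.tsv", index=False)
        status["de"] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail("de", exc)

    # ---- stage: modules -------------------------------------------------
    # differential co-expression modules live among the tissue-specific
    # genes; the variance filter only caps the problem size
    try:
        ts_idx = classified.index[classified["category"] == "TissueSpecific"]
        universe = ts_idx if len(ts_idx) >= 3 * cfg.min_module_size else retained.index
        n_top = min(cfg.n_top, len(universe))
        expr_retained = atlas.expression.loc[universe]
        top_genes = coex.select_genes(expr_retained, n_top)
        logx = pd.DataFrame(
            np.log2(expr_retained.loc[top_genes].values.astype(float) + 1.0).T,
            index=expr_retained.columns, columns=top_genes,
        )
        corr_genes = np.nan_to_num(np.corrcoef(logx.values.T), nan=0.0)
        beta = coex.select_soft_power(corr_genes, n_samples=logx.shape[0])
        modules, adjacency = coex.detect_modules(
            logx, beta, min_module_size=cfg.min_module_size,
            cut_height=cfg.cut_height,
        )
        for i, mod in enumerate(modules):
            mod.activity = coex.module_activity(
                mod.genes, atlas, n_perm=cfg.n_perm, seed=[cfg.seed, 10, i],
            )
            mod.hubs = coex.find_hubs(mod.genes, adjacency, k=5)
        with open(out / "modules.gmt", "w", encoding="utf-8") as fh:
            for mod in modules:
                fh.write("\t".join([mod.id, f"n={len(mod)};beta={beta}"] + list(mod.genes)) + "\n")
        act_rows = [
            {"module": m.id, "tissue": t, "nes": nes, "p": p}
            for m in modules for t, (nes, p) in sorted(m.activity.items())
        ]
        _write_tsv(pd.DataFrame(act_rows, columns=["module", "tissue", "nes", "p"]),
                   out / "module_activity.tsv", index=False)
        hub_rows = [
            {"module": m.id, "rank": r + 1, "gene_id": g, "connectivity": c}
            for m in modules for r, (g, c) in enumerate(m.hubs)
        ]
        _write_tsv(pd.DataFrame(hub_rows, columns=["module", "rank", "gene_id", "connectivity"]),
                   out / "hubs.tsv", index=False)
        manifest["soft_power"] = int(beta)
        status["modules"] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail("modules", exc)

    # ---- stage: networks ------------------------------------------------
    try:
        if not cfg.ppi or not Path(cfg.ppi).exists():
            raise FileNotFoundError(f"PPI edge list not found: {cfg.ppi}")
        ppi = net_mod.load_ppi(cfg.ppi, min_score=cfg.min_score)
        tsn_rows = []
        for tissue in atlas.tissues:
            net = net_mod.extract_tissue_network(
                ppi, classified, modules, tissue,
                activity_p=cfg.activity_p, min_component=cfg.min_component,
            )
            edge_df = pd.DataFrame(
                sorted((min(a, b), max(a, b), s) for a, b, s in net.edges),
                columns=["protein1", "protein2", "combined_score"],
            )
            _write_tsv(edge_df, out / f"tissue_{tissue}_network.tsv", index=False)
            if not net.is_empty():
                nx.write_graphml(net.graph, out / f"tissue_{tissue}_network.graphml")
            tsn_rows.append(
                {
                    "tissue": tissue,
                    "n_nodes": net.graph.number_of_nodes(),
                    "n_edges": net.graph.number_of_edges(),
                    "n_components": len(net.components),
                    "hubs": ";".join(h[0] for h in net.hubs),
                }
            )
        _write_tsv(pd.DataFrame(tsn_rows), out / "network_hubs.tsv", index=False)
        status["networks"] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail("networks", exc)

    # ---- stage: labels --------------------------------------------------
    try:
        if label_files:
            sets = [io_mod.read_label_file(p, name) for name, p in sorted(label_files.items())]
            report = compare_label_sets(classified, atlas, sets)
            _write_tsv(report["summary"], out / "label_report.tsv", index=False)
            _write_tsv(report["crosstab"].rename_axis("label"), out / "label_crosstab.tsv")
            _write_tsv(report["tests"], out / "label_tests.tsv", index=False)
            _write_tsv(report["tissue_means"].rename_axis("label"), out / "label_tissue_means.tsv")
            status["labels"] = "completed"
        else:
            status["labels"] = "skipped (no label sets)"
    except Exception as exc:  # noqa: BLE001
        fail("labels", exc)

    # ---- stage: summarize ----------------------------------------------
    try:
        _finish()  # manifest must exist for summarize
        summarize(out)
        status["summarize"] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail("summarize", exc)

    _finish()
    return out


def summarize(run_dir) -> dict:
    """Build the run's summary tables from a completed run directory.

    Writes and returns: per-category counts/fractions, per-tissue
    tissue-specific counts, the module table (size, upregulated tissues,
    hubs) and the tissue-network table.
    """
    run_dir = Path(run_dir)
    cls_path = run_dir / "tau_classification.tsv"
    if not cls_path.exists():
        raise PipelineError("[summarize] incomplete run: tau_classification.tsv missing")
    classified = pd.read_csv(cls_path, sep="\t", index_col=0)

    counts = classified["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    categories = pd.DataFrame(
        {
            "category": counts.index,
            "n_genes": counts.values,
            "fraction_pct": (100.0 * counts.values / counts.sum()).round(2),
        }
    )
    _write_tsv(categories, run_dir / "summary_categories.tsv", index=False)

    ts = classified[classified["category"] == "TissueSpecific"]
    per_tissue = ts["max_tissue"].value_counts().sort_index()
    _write_tsv(
        per_tissue.rename_axis("tissue").rename("n_tissue_specific").reset_index(),
        run_dir / "summary_tissue_specific.tsv", index=False,
    )

    module_rows = []
    gmt = run_dir / "modules.gmt"
    if gmt.exists():
        activity = pd.read_csv(run_dir / "module_activity.tsv", sep="\t")
        hubs = pd.read_csv(run_dir / "hubs.tsv", sep="\t")
        for line in gmt.read_text(encoding="utf-8").splitlines():
            parts = line.split("\t")
            mid, genes = parts[0], parts[2:]
            act = activity[activity["module"] == mid]
            up = act[(act["nes"] > 0) & (act["p"] < 0.05)].sort_values("nes", ascending=False)
            hub_genes = hubs.loc[hubs["module"] == mid].sort_values("rank")["gene_id"]
            module_rows.append(
                {
                    "module": mid,
                    "n_genes": len(genes),
                    "upregulated_tissues": ";".join(up["tissue"]),
                    "hubs": ";".join(hub_genes),
                }
            )
    _write_tsv(pd.DataFrame(module_rows, columns=["module", "n_genes", "upregulated_tissues", "hubs"]),
               run_dir / "summary_modules.tsv", index=False)

    tsn_path = run_dir / "network_hubs.tsv"
    tsn = pd.read_csv(tsn_path, sep="\t") if tsn_path.exists() else pd.DataFrame()
    if not tsn.empty:
        _write_tsv(tsn[tsn["n_nodes"] > 0], run_dir / "summary_tsn.tsv", index=False)

    return {
        "categories": categories,
        "tissue_specific": per_tissue,
        "modules": pd.DataFrame(module_rows),
        "tsn": tsn,
    }
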